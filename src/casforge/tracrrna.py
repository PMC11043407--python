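"""tracrRNA inference and sgRNA scaffold construction.

Starting from a CRISPR array's direct repeat, anti-repeats are sought by
local alignment in 3000-bp windows flanking the array, a Rho-independent
terminator (hairpin + U-tract) is located downstream, and the putative
tracrRNA (anti-repeat through terminator, or through the first poly-T) is
fused to the repeat via a GAAA tetraloop into a single-guide scaffold.
Scaffolds are screened for the three functional modules of type II guides:
the repeat:anti-repeat duplex, the nexus stem-loop, and a 3'-terminal
hairpin, using a base-pair-maximisation folding engine (or, optionally, a
thermodynamic engine via the RNAsubopt executable).
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .core_io import ScoringParams, SequenceRecord, TracrParams, revcomp, transcribe

_RNA_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_DNA_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def can_pair(a: str, b: str, alphabet: str = "rna") -> bool:
    pairs = _RNA_PAIRS if alphabet == "rna" else _DNA_PAIRS
    return (a, b) in pairs


@dataclass
class AntiRepeatHit:
    """A local-alignment hit of the direct repeat in the flanking sequence."""

    contig_id: str
    start: int  # 1-based inclusive, flank/contig frame
    end: int
    strand: str
    score: float
    evalue: float
    aligned_fraction: float


@dataclass
class Terminator:
    """A hairpin + U-tract intrinsic terminator call (window-local, 1-based)."""

    start: int
    end: int
    stem_len: int
    loop_len: int
    u_tract_len: int

    @property
    def score(self) -> int:
        return 2 * self.stem_len + self.u_tract_len


@dataclass
class TracrRNACandidate:
    """A putative tracrRNA: anti-repeat through terminator (RNA alphabet)."""

    sequence: str
    anti_len: int  # anti-repeat occupies sequence[:anti_len]
    terminator: Terminator | None  # None => poly-T fallback
    contig_start: int = 0  # 1-based span on the source contig/flank
    contig_end: int = 0
    strand: str = "+"


@dataclass
class ScaffoldAnnotations:
    repeat_span: tuple[int, int]  # 0-based inclusive scaffold coords
    tetraloop_span: tuple[int, int]
    anti_span: tuple[int, int]
    duplex_pairs: list[tuple[int, int]]
    nexus_span: tuple[int, int] | None = None
    hairpin_spans: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SgRNAScaffold:
    form: str  # natural | FS | FS-opt | TS | TS-opt
    sequence: str  # RNA
    tetraloop: str
    annotations: ScaffoldAnnotations


@dataclass
class StructurePrediction:
    structures: list[frozenset[tuple[int, int]]]
    scores: list[float]  # pair counts (maxpair) or energies (external)
    engine: str
    band: float
    length: int

    def dot_brackets(self) -> list[str]:
        return [dot_bracket(s, self.length) for s in self.structures]


def dot_bracket(pairs: frozenset[tuple[int, int]], n: int) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


# ---------------------------------------------------------------------------
# anti-repeat search


def _karlin_altschul(flank: str, repeat: str) -> tuple[float, float]:
    """Ungapped lambda and K for the +1/-1 two-valued score.

    With match probability p = sum_b f_b * r_b, the moment equation
    p e^l + (1-p) e^-l = 1 solves to l = ln((1-p)/p), and excursion
    statistics of the +-1 random walk give K = (1 - 2p)^2.
    """
    def comp(s: str) -> dict[str, float]:
        tot = max(1, sum(s.count(b) for b in "ACGT"))
        return {b: s.count(b) / tot for b in "ACGT"}

    f, r = comp(flank), comp(repeat)
    p = sum(f[b] * r[b] for b in "ACGT")
    p = min(max(p, 1e-6), 0.49)
    lam = math.log((1 - p) / p)
    k = (1 - 2 * p) ** 2
    return lam, k


def _local_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = -params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _has_seed(aln, word_size: int) -> bool:
    """Word-seeded search: the hit must contain word_size consecutive identities."""
    t, q = str(aln[0]), str(aln[1])
    run = 0
    for a, b in zip(t, q):
        if a == b and a != "-":
            run += 1
            if run >= word_size:
                return True
        else:
            run = 0
    return False


def find_anti_repeats(
    flank: SequenceRecord | str,
    repeat: str,
    params: ScoringParams | None = None,
    array_span: tuple[int, int] | None = None,
    contig_id: str = "",
) -> list[AntiRepeatHit]:
    """Local-alignment search of the repeat against both strands of a flank.

    Hits must contain an exact ``word_size`` seed, score at least
    ``word_size``, pass the ungapped Karlin-Altschul e-value filter, and lie
    outside ``array_span`` (1-based, flank frame) when given.  Returned
    sorted by score descending.
    """
    params = params or ScoringParams()
    seq = flank.sequence if isinstance(flank, SequenceRecord) else flank
    seq = seq.upper()
    if len(repeat) < params.word_size:
        raise ValueError(f"repeat ({len(repeat)} nt) shorter than word_size {params.word_size}")
    lam, kka = _karlin_altschul(seq, repeat)
    search_space = len(repeat) * 2 * len(seq)
    aligner = _local_aligner(params)
    hits: list[AntiRepeatHit] = []

    for strand in ("+", "-"):
        target = list(seq if strand == "+" else revcomp(seq))
        for _ in range(20):  # iterative best-hit extraction with masking
            t = "".join(target)
            alns = aligner.align(t, repeat)
            if alns.score < params.word_size:
                break
            aln = alns[0]
            (tstart, tend) = (aln.aligned[0][0][0], aln.aligned[0][-1][1])
            if strand == "+":
                span = (tstart + 1, tend)
            else:
                span = (len(seq) - tend + 1, len(seq) - tstart)
            ok = alns.score >= params.word_size and _has_seed(aln, params.word_size)
            if ok and array_span is not None:
                if not (span[1] < array_span[0] or span[0] > array_span[1]):
                    ok = False
            if ok:
                evalue = kka * search_space * math.exp(-lam * alns.score)
                if evalue <= params.evalue_max:
                    qaligned = sum(e - s for s, e in aln.aligned[1])
                    hits.append(
                        AntiRepeatHit(
                            contig_id, span[0], span[1], strand,
                            float(alns.score), evalue, qaligned / len(repeat),
                        )
                    )
            for i in range(tstart, tend):  # mask and continue
                target[i] = "N"

    hits.sort(key=lambda h: (-h.score, h.start))
    return hits


# ---------------------------------------------------------------------------
# terminator prediction


def predict_terminators(
    window: SequenceRecord | str,
    min_stem: int = 5,
    loop_range: tuple[int, int] = (3, 10),
    min_u: int = 4,
    tract_gap: int = 3,
    tract_window: int = 6,
) -> list[Terminator]:
    """Rho-independent terminator scan: hairpin followed by a T-rich tract.

    Every maximal hairpin (stem >= 5 bp, G.T wobble allowed, loop 3-10 nt)
    followed within <= 3 nt by a 6-nt window containing >= 4 T is reported
    with score 2*stem + T-count, sorted by score descending.  Coordinates
    are 1-based within the window.
    """
    seq = (window.sequence if isinstance(window, SequenceRecord) else window).upper()
    n = len(seq)
    raw: list[Terminator] = []
    for l in range(1, n):  # l = loop start; stem grows outward from the loop
        for loop in range(loop_range[0], loop_range[1] + 1):
            t = 0
            while (
                l - 1 - t >= 0
                and l + loop + t < n
                and can_pair(seq[l - 1 - t], seq[l + loop + t], "dna")
            ):
                t += 1
            stem = t
            if stem < min_stem:
                continue
            a = l - stem  # hairpin start, 0-based
            hp_end = l + loop + stem  # 0-based exclusive
            for d in range(tract_gap + 1):
                w = seq[hp_end + d : hp_end + d + tract_window]
                if len(w) < min_u:
                    continue
                u = w.count("T")
                if u >= min_u:
                    last_t = hp_end + d + max(i for i, c in enumerate(w) if c == "T")
                    raw.append(Terminator(a + 1, last_t + 1, stem, loop, u))
                    break

    # keep best-scoring call among overlapping hairpins
    raw.sort(key=lambda t: (-t.score, t.start, t.loop_len))
    kept: list[Terminator] = []
    for t in raw:
        if all(t.end < o.start or t.start > o.end for o in kept):
            kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# tracrRNA candidate extraction


def extract_tracr_candidates(
    flank: str,
    hits: list[AntiRepeatHit],
    term_search_nt: int = 200,
    min_polyt: int = 4,
) -> list[TracrRNACandidate]:
    """Build tracrRNA candidates downstream of each anti-repeat hit.

    A strand '-' hit means the flank's forward strand carries the
    anti-repeat (the repeat matched its reverse complement), so the tracr
    runs rightward; a '+' hit is processed on the reverse complement.
    The candidate runs from the anti-repeat start to the end of the best
    terminator, or to the first poly-T (>= 4 T) when no terminator is found.
    The returned list is parallel to ``hits``; entries with no terminator
    and no poly-T are None.
    """
    out: list[TracrRNACandidate | None] = []
    n = len(flank)
    for hit in hits:
        if hit.strand == "-":
            oriented = flank
            a0, a1 = hit.start - 1, hit.end  # 0-based half-open
            tr_strand = "+"
        else:
            oriented = revcomp(flank)
            a0, a1 = n - hit.end, n - hit.start + 1
            tr_strand = "-"
        window = oriented[a1 : a1 + term_search_nt]
        terms = predict_terminators(window)
        terminator = None
        end = None
        if terms:
            terminator = terms[0]
            end = a1 + terminator.end
        else:
            run, best = 0, None
            for i, c in enumerate(window):
                run = run + 1 if c == "T" else 0
                if run >= min_polyt:
                    best = i
                    break
            if best is not None:
                end = a1 + best + 1
        if end is None:
            out.append(None)
            continue
        if tr_strand == "+":
            span = (a0 + 1, end)
        else:
            span = (n - end + 1, n - a0)
        out.append(
            TracrRNACandidate(
                sequence=transcribe(oriented[a0:end]),
                anti_len=a1 - a0,
                terminator=terminator,
                contig_start=span[0],
                contig_end=span[1],
                strand=tr_strand,
            )
        )
    return out


# ---------------------------------------------------------------------------
# sgRNA scaffold assembly


def _best_duplex(repeat_rna: str, anti_rna: str) -> tuple[int, list[tuple[int, int]]]:
    """Best antiparallel gapless register between repeat and anti-repeat.

    Pairs repeat index i with anti index c - i; returns (c, pair list).
    """
    lr, la = len(repeat_rna), len(anti_rna)
    best_c, best_pairs = -1, []
    for c in range(lr + la - 1):
        pairs = [
            (i, c - i)
            for i in range(max(0, c - la + 1), min(lr, c + 1))
            if can_pair(repeat_rna[i], anti_rna[c - i])
        ]
        if len(pairs) > len(best_pairs) or (len(pairs) == len(best_pairs) and c > best_c):
            best_c, best_pairs = c, pairs
    return best_c, best_pairs


def assemble_sgrna(
    repeat: str,
    candidate: TracrRNACandidate,
    form: str = "FS",
    tetraloop: str = "GAAA",
    trim_len: int = 12,
    substitutions: list[tuple[int, str]] | None = None,
) -> SgRNAScaffold:
    """Fuse the direct repeat to the tracrRNA candidate into an sgRNA.

    FS/natural: repeat (3'-truncated at the duplex end) + tetraloop +
    candidate.  TS: the repeat:anti-repeat duplex is trimmed to ``trim_len``
    pairs symmetric about the tetraloop.  The -opt forms additionally apply
    the configured (position, base) substitutions.
    """
    if form not in {"natural", "FS", "FS-opt", "TS", "TS-opt"}:
        raise ValueError(f"unknown scaffold form {form!r}")
    substitutions = list(substitutions or [])
    if form.endswith("-opt") and not substitutions:
        raise ValueError("opt form requires substitutions")

    repeat_rna = transcribe(repeat.upper())
    anti = candidate.sequence[: candidate.anti_len]
    body = candidate.sequence[candidate.anti_len :]
    c, pairs = _best_duplex(repeat_rna, anti)
    if len(pairs) < 8:
        raise ValueError(f"no duplex: only {len(pairs)} pairable positions (need >= 8)")

    rep_idx = [i for i, _ in pairs]
    anti_idx = [j for _, j in pairs]
    r_last = max(rep_idx)
    base_form = "TS" if form.startswith("TS") else "FS"

    if base_form == "FS":
        rep_seg = repeat_rna[: r_last + 1]
        anti_seg = anti
        kept = pairs
        rep_off = 0
    else:
        kept = sorted(pairs, key=lambda p: -p[0])[:trim_len]
        kept.sort()
        r_first = min(i for i, _ in kept)
        j_last = max(j for _, j in kept)
        rep_seg = repeat_rna[r_first : r_last + 1]
        anti_seg = anti[: j_last + 1]
        rep_off = r_first

    tl = transcribe(tetraloop.upper())
    seq = rep_seg + tl + anti_seg + body
    rep_span = (0, len(rep_seg) - 1)
    tl_span = (len(rep_seg), len(rep_seg) + len(tl) - 1)
    anti_start = tl_span[1] + 1
    anti_span = (anti_start, anti_start + len(anti_seg) + len(body) - 1)
    duplex = sorted(
        (i - rep_off, anti_start + j)
        for i, j in kept
        if i - rep_off >= 0 and j < len(anti_seg)
    )

    for pos, base in substitutions:
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"substitution position {pos} outside scaffold")
        seq = seq[: pos - 1] + transcribe(base.upper()) + seq[pos:]

    ann = ScaffoldAnnotations(rep_span, tl_span, (anti_start, anti_start + len(anti_seg) - 1), duplex)
    return SgRNAScaffold(form, seq, tl, ann)


# ---------------------------------------------------------------------------
# folding (base-pair maximisation, no lonely pairs)

_MIN_LOOP = 3


def _pair_ok(seq: str, i: int, j: int) -> bool:
    return can_pair(seq[i], seq[j])


def fold(
    seq: str,
    engine: str = "maxpair",
    band: float = 5.0,
    noLP: bool = True,
    band_pairs: int = 1,
    max_structures: int = 100,
) -> StructurePrediction:
    """Predict secondary structures of an RNA.

    The default ``maxpair`` engine maximises canonical base pairs (G.U
    allowed, hairpin loops >= 3 nt, no lonely pairs when ``noLP``) and
    returns all structures within ``band_pairs`` of the optimum, capped at
    ``max_structures``.  The ``external`` engine shells out to RNAsubopt
    with ``--noLP -e band`` and returns energy-banded structures.
    """
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"non-RNA characters {sorted(bad)}")
    if len(seq) > 400:
        raise ValueError("sequence longer than 400 nt")
    if engine == "external":
        return _fold_external(seq, band)
    if engine != "maxpair":
        raise ValueError(f"unknown engine {engine!r}")

    n = len(seq)
    NEG = -(10**9)
    # two DPs sharing one loop: pair count alone (W/V, defines the optimum,
    # the band and the enumeration), and a combined score K*pairs + stacks
    # (Wc/Vc) whose traceback picks the stack-coherent structure among the
    # maximal-pair ties — a deterministic stand-in for thermodynamic
    # stability that never changes the optimal pair count
    K = 1024  # exceeds any possible stack count, so the order is lexicographic
    W = np.zeros((n, n), dtype=np.int64)
    V = np.full((n, n), NEG, dtype=np.int64)
    Wc = np.zeros((n, n), dtype=np.int64)
    Vc = np.full((n, n), NEG, dtype=np.int64)
    min_motif = 2 * 2 + _MIN_LOOP if noLP else 2 + _MIN_LOOP

    def w_at(i: int, j: int, M=None) -> int:
        if i > j:
            return 0
        return int((W if M is None else M)[i, j])

    for j in range(n):
        for i in range(j - min_motif + 1, -1, -1):
            # V[i][j]: (i, j) closes a helix
            best_v = best_vc = NEG
            if noLP:
                h = 0
                while _pair_ok(seq, i + h, j - h) and (j - h) - (i + h) - 1 >= _MIN_LOOP:
                    h += 1
                    if h >= 2:
                        interior_len = j - i + 1 - 2 * h
                        if interior_len >= _MIN_LOOP:
                            best_v = max(best_v, h + w_at(i + h, j - h))
                            best_vc = max(best_vc, h * K + (h - 1) + w_at(i + h, j - h, Wc))
                    if i + h >= j - h:
                        break
            else:
                if _pair_ok(seq, i, j) and j - i - 1 >= _MIN_LOOP:
                    best_v = 1 + w_at(i + 1, j - 1)
                    best_vc = K + w_at(i + 1, j - 1, Wc)
            V[i, j] = best_v
            Vc[i, j] = best_vc
            for Wm, Vm in ((W, V), (Wc, Vc)):
                best = w_at(i, j - 1, Wm)
                ks = np.arange(i, j - min_motif + 2)
                if len(ks) > 0:
                    vcol = Vm[ks, j]
                    left = np.empty(len(ks), dtype=np.int64)
                    left[0] = 0
                    if len(ks) > 1:
                        left[1:] = Wm[i, ks[1:] - 1]
                    m = int((vcol + left).max())
                    if m > best:
                        best = m
                Wm[i, j] = best

    opt = int(W[0, n - 1]) if n else 0
    need = max(0, opt - band_pairs)

    def opt_w(i: int, j: int) -> set[tuple[int, int]]:
        """The stack-coherent optimal structure (combined-score traceback)."""
        if i > j or j - i + 1 < min_motif:
            return set()
        target = int(Wc[i, j])
        if target == w_at(i, j - 1, Wc):
            return opt_w(i, j - 1)
        for k in range(i, j - min_motif + 2):
            if int(Vc[k, j]) >= 1 and w_at(i, k - 1, Wc) + int(Vc[k, j]) == target:
                return opt_w(i, k - 1) | opt_v_tb(k, j)
        return set()

    def opt_v_tb(i: int, j: int) -> set[tuple[int, int]]:
        target = int(Vc[i, j])
        if noLP:
            h = 0
            helix: set[tuple[int, int]] = set()
            while _pair_ok(seq, i + h, j - h) and (j - h) - (i + h) - 1 >= _MIN_LOOP:
                helix.add((i + h, j - h))
                h += 1
                if h >= 2 and j - i + 1 - 2 * h >= _MIN_LOOP:
                    if h * K + (h - 1) + w_at(i + h, j - h, Wc) == target:
                        return helix | opt_w(i + h, j - h)
                if i + h >= j - h:
                    break
            return helix
        return {(i, j)} | opt_w(i + 1, j - 1)

    structures: list[frozenset[tuple[int, int]]] = []
    seen: set[frozenset[tuple[int, int]]] = set()
    if n and opt > 0:
        best = frozenset(opt_w(0, n - 1))
        seen.add(best)
        structures.append(best)

    work = [500_000]  # bounded enumeration effort; keeps worst cases fast

    def enum_w(i: int, j: int, req: int, budget: list[int]) -> list[frozenset]:
        work[0] -= 1
        if budget[0] <= 0 or work[0] <= 0:
            return []
        if i > j or j - i + 1 < min_motif:
            return [frozenset()] if req <= 0 else []
        if w_at(i, j) < req:
            return []
        res: list[frozenset] = []
        for s in enum_w(i, j - 1, req, budget):
            res.append(s)
            if len(res) >= budget[0]:
                return res
        for k in range(i, j - min_motif + 2):
            vkj = int(V[k, j])
            if vkj < 1:
                continue
            wl = w_at(i, k - 1)
            if wl + vkj < req:
                continue
            rights = enum_v(k, j, max(1, req - wl), budget)
            for r in rights:
                lefts = enum_w(i, k - 1, req - len(r), budget)
                for l in lefts:
                    res.append(r | l)
                    if len(res) >= budget[0]:
                        return res
        return res

    def enum_v(i: int, j: int, req: int, budget: list[int]) -> list[frozenset]:
        work[0] -= 1
        if int(V[i, j]) < req or work[0] <= 0:
            return []
        res: list[frozenset] = []
        if noLP:
            h = 0
            helix: list[tuple[int, int]] = []
            while _pair_ok(seq, i + h, j - h) and (j - h) - (i + h) - 1 >= _MIN_LOOP:
                helix.append((i + h, j - h))
                h += 1
                if h >= 2:
                    interior_len = j - i + 1 - 2 * h
                    if interior_len >= _MIN_LOOP:
                        for inner in enum_w(i + h, j - h, req - h, budget):
                            if (i + h, j - h) in inner:
                                continue  # same set reachable with h+1
                            res.append(frozenset(helix) | inner)
                            if len(res) >= budget[0]:
                                return res
                if i + h >= j - h:
                    break
        else:
            if _pair_ok(seq, i, j) and j - i - 1 >= _MIN_LOOP:
                for inner in enum_w(i + 1, j - 1, req - 1, budget):
                    res.append(frozenset({(i, j)}) | inner)
                    if len(res) >= budget[0]:
                        return res
        return res

    budget = [max_structures * 4]
    for s in enum_w(0, n - 1, need, budget) if n else [frozenset()]:
        if s not in seen:
            seen.add(s)
            structures.append(s)
        if len(structures) >= max_structures:
            break
    if not structures:
        structures = [frozenset()]
    structures.sort(key=lambda s: (-len(s), sorted(s)))
    return StructurePrediction(structures, [float(len(s)) for s in structures], "maxpair", band_pairs, n)


def _db_to_pairs(db: str) -> frozenset[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.append((stack.pop(), i))
    return frozenset(pairs)


def _fold_external(seq: str, band: float) -> StructurePrediction:
    exe = shutil.which("RNAsubopt")
    if exe is None:
        raise RuntimeError("RNAsubopt executable not found; use engine='maxpair'")
    proc = subprocess.run(
        [exe, "--noLP", "-e", str(band)], input=seq + "\n",
        capture_output=True, text=True, check=True,
    )
    structures, scores = [], []
    for line in proc.stdout.splitlines()[1:]:
        parts = line.split()
        if len(parts) >= 2 and set(parts[0]) <= set("()."):
            structures.append(_db_to_pairs(parts[0]))
            scores.append(float(parts[1]))
    order = np.argsort(scores)
    return StructurePrediction(
        [structures[i] for i in order], [scores[i] for i in order], "external", band, len(seq)
    )


# ---------------------------------------------------------------------------
# module check


def _helices(pairs: frozenset[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    pset = set(pairs)
    helices = []
    for a, b in sorted(pairs):
        if (a - 1, b + 1) in pset:
            continue
        helix = []
        t = 0
        while (a + t, b - t) in pset:
            helix.append((a + t, b - t))
            t += 1
        helices.append(helix)
    return helices


def _is_hairpin(helix: list[tuple[int, int]], pairs: frozenset[tuple[int, int]]) -> bool:
    ai, bi = helix[-1]
    return not any(ai < x < y < bi for x, y in pairs)


def check_modules(
    scaffold: SgRNAScaffold,
    prediction: StructurePrediction,
    duplex_min_pairs: int = 8,
    nexus_max_offset: int = 6,
    nexus_min_stem: int = 2,
    hairpin_tail_nt: int = 60,
) -> tuple[bool, list[str]]:
    """Verify the duplex, nexus and 3' hairpin modules of an sgRNA scaffold.

    Passes when some predicted structure simultaneously shows (i) at least
    ``duplex_min_pairs`` pairs between the repeat- and anti-repeat-derived
    segments, (ii) a stem-loop of >= ``nexus_min_stem`` bp starting within
    ``nexus_max_offset`` nt downstream of the duplex, and (iii) a hairpin
    wholly within the 3'-terminal ``hairpin_tail_nt`` nt.  On failure the
    missing modules of the best structure are listed.
    """
    ann = scaffold.annotations
    if ann is None:
        raise ValueError("scaffold lacks module annotations")
    n = prediction.length
    rs, re_ = ann.repeat_span
    as_, ae = ann.anti_span
    best_missing: list[str] | None = None

    annotated = set(ann.duplex_pairs)
    for pairs in prediction.structures:
        missing = []
        # realized duplex = annotated repeat:anti-repeat register pairs present
        # in the structure; incidental cross-segment pairs do not count
        duplex = [p for p in pairs if p in annotated and rs <= p[0] <= re_ and as_ <= p[1] <= ae]
        if len(duplex) < duplex_min_pairs:
            missing.append("duplex")
            dend = ae
        else:
            dend = max(b for _, b in duplex)
        helices = _helices(pairs)
        nexus = None
        for h in helices:
            a, b = h[0]
            if a > dend and a - dend <= nexus_max_offset and len(h) >= nexus_min_stem and _is_hairpin(h, pairs):
                nexus = h
                break
        if nexus is None:
            missing.append("nexus")
        # the 3' hairpin is a distinct module downstream of the nexus
        after = nexus[0][1] if nexus is not None else dend
        tail_ok = any(
            h[0][0] >= max(n - hairpin_tail_nt, after + 1) and _is_hairpin(h, pairs) and h is not nexus
            for h in helices
        )
        if not tail_ok:
            missing.append("3' hairpin")
        if not missing:
            ann.nexus_span = (nexus[0][0], nexus[0][1])
            ann.hairpin_spans = [
                (h[0][0], h[0][1])
                for h in helices
                if h[0][0] >= n - hairpin_tail_nt and _is_hairpin(h, pairs)
            ]
            return True, []
        if best_missing is None or len(missing) < len(best_missing):
            best_missing = missing
    return False, best_missing if best_missing is not None else ["duplex", "nexus", "3' hairpin"]


# ---------------------------------------------------------------------------
# pipeline orchestration


@dataclass
class TracrResult:
    hit: AntiRepeatHit
    candidate: TracrRNACandidate
    scaffold: SgRNAScaffold | None
    prediction: StructurePrediction | None
    passed: bool
    reasons: list[str]


def infer_tracrrnas(
    contig: SequenceRecord,
    array,
    params: TracrParams | None = None,
    engine: str = "maxpair",
    max_hits_folded: int = 6,
) -> list[TracrResult]:
    """Full tracrRNA inference for one array: flanks -> hits -> scaffolds.

    Flanks of ``flank_window`` bp are taken on each side of the array; each
    anti-repeat hit is extended to a terminator (or poly-T), fused to the
    repeat consensus and screened for the three structural modules.
    """
    params = params or TracrParams()
    seq = contig.sequence
    win = params.scoring.flank_window
    a0, a1 = array.start - 1, array.end  # 0-based half-open array span
    left = (max(0, a0 - win), a0)
    right = (a1, min(len(seq), a1 + win))
    # the search space is the concatenation of both windows; a 10-N spacer
    # prevents alignments from straddling the junction
    spacer = "N" * 10
    flank = seq[left[0] : left[1]] + spacer + seq[right[0] : right[1]]
    l1 = left[1] - left[0]

    def lift(pos: int) -> int:
        """1-based concatenated-flank coordinate -> 1-based contig coordinate."""
        if pos <= l1:
            return left[0] + pos
        return right[0] + (pos - l1 - len(spacer))

    results: list[TracrResult] = []
    if len(flank) >= params.scoring.word_size:
        hits = find_anti_repeats(flank, array.repeat_consensus, params.scoring, contig_id=contig.id)
        cands = extract_tracr_candidates(flank, hits)
        for hit, cand in list(zip(hits, cands))[:max_hits_folded]:
            if cand is None:
                continue
            # lift spans to contig coordinates
            hit.start, hit.end = lift(hit.start), lift(hit.end)
            cand.contig_start = lift(cand.contig_start)
            cand.contig_end = lift(cand.contig_end)
            try:
                scaffold = assemble_sgrna(
                    array.repeat_consensus, cand, "FS",
                    tetraloop=params.tetraloop, trim_len=params.trim_len,
                )
            except ValueError as exc:
                results.append(TracrResult(hit, cand, None, None, False, [str(exc)]))
                continue
            pred = fold(scaffold.sequence, engine=engine, band_pairs=params.band_pairs)
            ok, reasons = check_modules(
                scaffold, pred,
                params.duplex_min_pairs, params.nexus_max_offset,
                params.nexus_min_stem, params.hairpin_tail_nt,
            )
            results.append(TracrResult(hit, cand, scaffold, pred, ok, reasons))
    results.sort(key=lambda r: (-int(r.passed), -r.hit.score))
    return results
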