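"""PAM determination from randomized-library cleavage reads.

Reads from a cleaved and an uncleaved control library of a plasmid pool
carrying an 8-nt randomized PAM are reduced to 8-mer counts, per-position
nucleotide profiles (logo matrices), a 256-entry enrichment table over the
four most informative positions, and a minimal set of degenerate IUPAC
consensus patterns covering the enriched combinations.  Adapter-ligation
end positions from cleaved fragments yield the cut-site offset and end
geometry (blunt vs staggered).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd

from .core_io import SequenceRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC.items()}
_BASES = "ACGT"


def iupac_match(pattern: str, seq: str) -> bool:
    """True when seq matches the IUPAC pattern (N in seq matches only N)."""
    if len(pattern) != len(seq):
        return False
    for p, s in zip(pattern, seq):
        if s == "N":
            if p != "N":
                return False
        elif s not in IUPAC[p]:
            return False
    return True


def expand_iupac(pattern: str) -> list[str]:
    return ["".join(t) for t in itertools.product(*(IUPAC[c] for c in pattern))]


@dataclass
class PamLibraryDesign:
    """Geometry of the randomized-PAM amplicon."""

    protospacer: str
    pam_len: int = 8
    anchor: str = ""  # sequence immediately 5' of the PAM; defaults to the protospacer 3' end
    backbone_context: str = "GAATTCGCTAGCTAGGTCTC"

    def __post_init__(self) -> None:
        self.protospacer = self.protospacer.upper()
        if not self.anchor:
            self.anchor = self.protospacer[-14:]
        self.anchor = self.anchor.upper()
        if len(self.anchor) < 10:
            raise ValueError("anchor must be at least 10 nt")


@dataclass
class PamCounts:
    counts: dict[str, int]
    total: int = 0
    qc: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.total:
            self.total = sum(self.counts.values())


@dataclass
class PositionProfile:
    freq: pd.DataFrame  # rows A,C,G,T x columns 1..pam_len
    info: np.ndarray  # bits per position


@dataclass
class EnrichmentTable:
    positions: tuple[int, ...]  # 1-based PAM positions
    table: pd.DataFrame  # index: 4-mer; columns: cleaved_freq, control_freq, ratio
    pseudocount: float

    @property
    def ratio(self) -> dict[str, float]:
        return self.table["ratio"].to_dict()


@dataclass
class PamConsensusSet:
    patterns: list[str]  # full-pam_len IUPAC strings (N-prefixed)
    threshold: float
    enriched: list[str] = field(default_factory=list)  # the covered combinations


@dataclass
class CutSiteCall:
    offset_bp: int | None
    geometry: str  # blunt | five_prime_overhang(n) | three_prime_overhang(n) | undetermined
    support: int


# ---------------------------------------------------------------------------


def extract_pams(
    reads: list[SequenceRecord],
    design: PamLibraryDesign,
    max_anchor_mismatch: int = 1,
) -> PamCounts:
    """Count the pam_len bases immediately 3' of the anchor in each read.

    Reads whose anchor is absent (beyond ``max_anchor_mismatch``), too close
    to the read end, or whose PAM slot contains non-ACGT characters are
    skipped and tallied in the QC report.
    """
    anchor = design.anchor
    al, pl = len(anchor), design.pam_len
    qc = Counter()
    counts: Counter = Counter()

    seqs = [r.sequence for r in reads]
    maxlen = max((len(s) for s in seqs), default=0)
    if maxlen < al:
        raise ValueError("no PAMs extracted: reads shorter than anchor")
    mat = np.full((len(seqs), maxlen), ord(" "), dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)
    lens = np.array([len(s) for s in seqs])
    avec = np.frombuffer(anchor.encode(), dtype=np.uint8)

    best_off = np.full(len(seqs), -1, dtype=np.int64)
    for off in range(0, maxlen - al + 1):
        undecided = best_off == -1
        if not undecided.any():
            break
        mism = (mat[:, off : off + al] != avec).sum(axis=1)
        ok = undecided & (mism <= max_anchor_mismatch) & (lens >= off + al)
        best_off[ok] = off

    for i, s in enumerate(seqs):
        off = int(best_off[i])
        if off < 0:
            qc["no_anchor"] += 1
            continue
        start = off + al
        if start + pl > len(s):
            qc["anchor_too_close_to_end"] += 1
            continue
        pam = s[start : start + pl]
        if set(pam) - set(_BASES):
            qc["ambiguous_pam"] += 1
            continue
        counts[pam] += 1
    qc["extracted"] = sum(counts.values())
    if not counts:
        raise ValueError("no PAMs extracted")
    return PamCounts(dict(counts), qc=dict(qc))


def position_profile(counts: PamCounts) -> PositionProfile:
    """Per-position base frequencies and information content (bits)."""
    if counts.total <= 0:
        raise ValueError("empty PAM counts")
    pam_len = len(next(iter(counts.counts)))
    freq = np.zeros((4, pam_len))
    for pam, c in counts.counts.items():
        for i, b in enumerate(pam):
            freq[_BASES.index(b), i] += c
    freq /= counts.total
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(freq > 0, np.log2(np.where(freq > 0, freq, 1.0)), 0.0)
    entropy = -(freq * logf).sum(axis=0)
    info = 2.0 - entropy
    df = pd.DataFrame(freq, index=list(_BASES), columns=range(1, pam_len + 1))
    return PositionProfile(df, info)


def select_informative_positions(profile: PositionProfile, k: int = 4) -> tuple[int, ...]:
    """The k highest-information PAM positions (ties leftmost), in order."""
    pam_len = len(profile.info)
    if k > pam_len:
        raise ValueError(f"k={k} exceeds PAM length {pam_len}")
    order = sorted(range(pam_len), key=lambda i: (-profile.info[i], i))[:k]
    return tuple(sorted(i + 1 for i in order))


def enrichment(
    cleaved: PamCounts,
    control: PamCounts,
    positions: tuple[int, ...],
    pseudocount: float = 1.0,
) -> EnrichmentTable:
    """Cleaved/control frequency ratio of every combination at ``positions``.

    Marginal counts sum over the non-selected positions; each frequency gets
    a pseudocount before division.
    """
    if cleaved.total <= 0 or control.total <= 0:
        raise ValueError("both libraries must be non-empty")
    k = len(positions)
    ncomb = 4**k
    idx = [p - 1 for p in positions]

    def marginal(pc: PamCounts) -> Counter:
        m: Counter = Counter()
        for pam, c in pc.counts.items():
            m["".join(pam[i] for i in idx)] += c
        return m

    mc, mu = marginal(cleaved), marginal(control)
    combos = ["".join(t) for t in itertools.product(_BASES, repeat=k)]
    rows = []
    for c in combos:
        fc = (mc.get(c, 0) + pseudocount) / (cleaved.total + ncomb * pseudocount)
        fu = (mu.get(c, 0) + pseudocount) / (control.total + ncomb * pseudocount)
        rows.append((c, mc.get(c, 0) / cleaved.total, mu.get(c, 0) / control.total, fc / fu))
    df = pd.DataFrame(rows, columns=["combination", "cleaved_freq", "control_freq", "ratio"])
    df = df.set_index("combination")
    return EnrichmentTable(tuple(positions), df, pseudocount)


# ---------------------------------------------------------------------------
# consensus calling: minimal exact cover of the enriched set by IUPAC products


def _valid_products(E: set[str]) -> list[tuple[str, frozenset[str]]]:
    """All IUPAC products (over observed per-position alphabets) contained in E."""
    k = len(next(iter(E)))
    per_pos = [sorted({c[i] for c in E}) for i in range(k)]
    products = []
    for combo in itertools.product(
        *(
            [frozenset(s) for r in range(1, len(vals) + 1) for s in itertools.combinations(vals, r)]
            for vals in per_pos
        )
    ):
        exp = ["".join(t) for t in itertools.product(*(sorted(s) for s in combo))]
        if all(e in E for e in exp):
            pattern = "".join(_SET_TO_IUPAC[frozenset(s)] for s in combo)
            products.append((pattern, frozenset(exp)))
    return products


def _greedy_cover(E: set[str]) -> list[str]:
    """Disjoint greedy: repeatedly take the largest product inside the remainder."""
    remaining = set(E)
    chosen: list[str] = []
    while remaining:
        products = _valid_products(remaining)
        best = max(products, key=lambda pe: (len(pe[1]), pe[0]))
        chosen.append(best[0])
        remaining -= best[1]
    return chosen


def _exact_cover(E: set[str], cap: int) -> list[str] | None:
    """Minimum-cardinality partition of E into IUPAC products (small E only)."""
    elements = sorted(E)
    products = _valid_products(E)
    by_elem: dict[str, list[tuple[str, frozenset[str]]]] = {e: [] for e in elements}
    for p, exp in products:
        for e in exp:
            by_elem[e].append((p, exp))
    best: list[list[str]] = []

    def dfs(remaining: frozenset[str], chosen: list[str]) -> None:
        if best and len(chosen) >= len(best[0]):
            return
        if not remaining:
            best[:] = [list(chosen)]
            return
        e = min(remaining)
        for p, exp in sorted(by_elem[e], key=lambda pe: (-len(pe[1]), pe[0])):
            if exp <= remaining:
                chosen.append(p)
                dfs(remaining - exp, chosen)
                chosen.pop()

    dfs(frozenset(E), [])
    return best[0] if best else None


def _hierarchical_cover(E: set[str]) -> list[str]:
    """Canonical prefix partition: split on the leftmost position, merging
    letters with identical residual suffix sets into one IUPAC symbol.

    Mirrors how degenerate consensus strings are read off a heatmap: branches
    keyed on the earliest discriminating position (e.g. GW.../GC.../AT...).
    """

    def factor(S: frozenset[str]) -> list[str]:
        k = len(next(iter(S)))
        if k == 0:
            return [""]
        # single product?
        per_pos = [frozenset(c[i] for c in S) for i in range(k)]
        if np.prod([len(s) for s in per_pos]) == len(S):
            return ["".join(_SET_TO_IUPAC[s] for s in per_pos)]
        groups: dict[frozenset[str], set[str]] = {}
        for letter in sorted({c[0] for c in S}):
            suffix = frozenset(c[1:] for c in S if c[0] == letter)
            groups.setdefault(suffix, set()).add(letter)
        out = []
        for suffix, letters in sorted(groups.items(), key=lambda kv: sorted(kv[1])):
            sym = _SET_TO_IUPAC[frozenset(letters)]
            out.extend(sym + tail for tail in factor(suffix))
        return out

    return factor(frozenset(E))


def call_consensus(table: EnrichmentTable, tau: float = 0.2, pam_len: int = 8) -> PamConsensusSet:
    """Degenerate consensus patterns covering the enriched combinations.

    The enriched set E holds every combination with ratio >= tau * max
    ratio.  Patterns are a minimal-cardinality exact cover (disjoint
    partition) of E by per-position IUPAC products, found greedily with an
    exhaustive branch-and-bound for |E| <= 32; among minimal covers the
    canonical prefix partition (branches keyed on the leftmost
    discriminating position) is preferred when it attains the minimum.
    Patterns are N-prefixed to the full PAM length.
    """
    ratios = table.ratio
    mx = max(ratios.values())
    E = {c for c, r in ratios.items() if r >= tau * mx}
    if not E:
        raise ValueError("no enriched PAMs")
    k = len(next(iter(E)))
    if len(E) == 4**k:
        patterns = ["N" * k]
    else:
        patterns = _greedy_cover(E)
        if len(E) <= 32:
            exact = _exact_cover(E, cap=len(patterns))
            if exact is not None and len(exact) < len(patterns):
                patterns = exact
        hier = _hierarchical_cover(E)
        if len(hier) <= len(patterns):
            patterns = hier
    pam_len = max(pam_len, max(table.positions))
    full = []
    for p in sorted(patterns):
        chars = ["N"] * pam_len
        for sym, pos in zip(p, table.positions):
            chars[pos - 1] = sym
        full.append("".join(chars))
    return PamConsensusSet(full, tau, sorted(E))


# ---------------------------------------------------------------------------
# cut-site geometry


def infer_cut_site(
    adapter_end_positions: list[tuple[str, int]],
    min_support: int = 10,
) -> CutSiteCall:
    """Modal cut position per strand and blunt/staggered geometry call.

    Positions count upstream from the PAM's 5' edge into the protospacer
    (positive = within the protospacer).  The call is blunt when the two
    strand modes coincide; otherwise the overhang length is their
    difference (top mode > bottom mode => 5' overhang).  Either strand with
    fewer than ``min_support`` observations yields "undetermined".
    """
    by_strand: dict[str, Counter] = {"+": Counter(), "-": Counter()}
    for strand, pos in adapter_end_positions:
        by_strand[strand][pos] += 1
    n_top, n_bot = sum(by_strand["+"].values()), sum(by_strand["-"].values())
    if n_top < min_support or n_bot < min_support:
        return CutSiteCall(None, "undetermined", min(n_top, n_bot))
    mode_top = min(sorted(by_strand["+"]), key=lambda p: (-by_strand["+"][p], p))
    mode_bot = min(sorted(by_strand["-"]), key=lambda p: (-by_strand["-"][p], p))
    if mode_top == mode_bot:
        return CutSiteCall(mode_top, "blunt", n_top + n_bot)
    diff = mode_top - mode_bot
    kind = "five_prime_overhang" if diff > 0 else "three_prime_overhang"
    return CutSiteCall(min(mode_top, mode_bot), f"{kind}({abs(diff)})", n_top + n_bot)
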