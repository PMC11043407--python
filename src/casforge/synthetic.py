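"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and a seed, emulating
the study's data-generating processes: MAG-like contigs with planted
CRISPR-Cas loci (array + cas1/cas2/cas9 within 10 kbp, a planted
anti-repeat and intrinsic terminator between the genes and the array),
randomized 8-nt PAM amplicon reads with a planted cleavage preference and
uniform substitution sequencing error, adapter-ligated cut-fragment end
positions, a reference genome of controlled base composition with planted
G>A / C>T SNVs of known per-editor targetability, and per-guide editing
matrices.  Every planted feature is recorded in a JSON-serializable truth
dict sufficient to score recall and precision of every stage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dataclasses import dataclass

from .core_io import FeatureRecord, SequenceRecord, revcomp, rng
from .pam_discovery import IUPAC, PamLibraryDesign, iupac_match
from .targeting import EditingWindow, PamScheme, SnvRecord, snv_targetable

GENERATOR_VERSION = "1"

_BASES = "ACGT"

# one codon per amino acid for deterministic reverse translation
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_AA = "".join(sorted(_CODON))


@dataclass
class CleavageModel:
    """PAM-dependent retention probabilities of the cleaved library."""

    p_match: float = 0.9
    p_background: float = 0.02
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if not (0 <= self.p_background < self.p_match <= 1):
            raise ValueError("require 0 <= p_background < p_match <= 1")


def _random_dna(generator: np.random.Generator, n: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = generator.choice(4, size=n, p=probs)
    return "".join(_BASES[c] for c in codes)


def _random_protein(generator: np.random.Generator, n_aa: int) -> str:
    body = "".join(_AA[i] for i in generator.integers(0, len(_AA), n_aa - 1))
    return "M" + body


def _reverse_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + "TAA"


def save_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# CRISPR genomes


DEFAULT_LOCUS_SPEC = {
    "repeat_len": 36,
    "n_spacers": 24,
    "spacer_len": 32,
    "cas9_aa": 1004,
    "cas1_aa": 300,
    "cas2_aa": 94,
    "anti_mismatches": 2,
}


def make_crispr_genome(
    n_loci: int = 3,
    background_len: int = 20_000,
    seed: int = 0,
    locus_spec: dict | None = None,
    n_decoys: int = 2,
    decoy_len: int = 8_000,
    array_only_decoy: bool = True,
) -> tuple[list[SequenceRecord], list[FeatureRecord], dict]:
    """Contigs with planted CRISPR-Cas9 loci plus negative decoy contigs.

    Each locus sits on its own contig of ``background_len`` bp, laid out as
    cas9 - cas1 - cas2 - tracrRNA - array on the forward strand.  The
    tracrRNA is an imperfect reverse complement of the direct repeat
    followed by a nexus-like hairpin and a terminator hairpin + T-tract.
    Decoys are plain random contigs plus, optionally, one carrying an array
    with no cas genes (a precision control).
    """
    spec = dict(DEFAULT_LOCUS_SPEC)
    spec.update(locus_spec or {})
    contigs: list[SequenceRecord] = []
    features: list[FeatureRecord] = []
    truth: dict = {"seed": seed, "version": GENERATOR_VERSION, "loci": [], "decoys": []}

    for li in range(n_loci):
        g = rng(seed, f"genome.locus{li}")
        name = f"contig{li}"
        repeat = _random_dna(g, spec["repeat_len"])
        spacers = [_random_dna(g, spec["spacer_len"]) for _ in range(spec["n_spacers"])]
        array_seq = repeat + "".join(s + repeat for s in spacers)

        proteins = {k: _random_protein(g, spec[f"{k}_aa"]) for k in ("cas9", "cas1", "cas2")}
        genes = {k: _reverse_translate(p) for k, p in proteins.items()}

        anti = list(revcomp(repeat))
        mm_pos = g.choice(
            np.arange(8, len(anti) - 8), size=spec["anti_mismatches"], replace=False
        )
        for p in sorted(int(x) for x in mm_pos):
            anti[p] = _BASES[(_BASES.index(anti[p]) + int(g.integers(1, 4))) % 4]
        anti = "".join(anti)
        # fixed stems with strictly alternating {A,G}/{C,T} arms and C-only
        # linkers: no arm offers two consecutive partners to the T-tract or
        # to another segment (G.T wobble included), so the planted duplex,
        # nexus and terminator remain the pair-maximal fold
        nexus = "ATGCAT" + "CAAC" + revcomp("ATGCAT")
        terminator_stem = "GCATACGC"
        terminator = terminator_stem + "TTCG" + revcomp(terminator_stem) + "TTTTTT"
        tracr = anti + "CCCC" + nexus + "CC" + terminator

        gaps = [int(g.integers(100, 400)) for _ in range(3)] + [int(g.integers(60, 200))]
        parts = [genes["cas9"], genes["cas1"], genes["cas2"], tracr, array_seq]
        locus_len = sum(len(p) for p in parts) + sum(gaps)
        if background_len < locus_len + 400:
            raise ValueError(
                f"background_len {background_len} too short for locus of {locus_len} bp"
            )
        left = int(g.integers(200, background_len - locus_len - 200))
        pieces = []
        cursor = 0
        spans: dict[str, tuple[int, int]] = {}
        bg_left = _random_dna(g, left)
        pieces.append(bg_left)
        cursor = left
        order = ["cas9", "cas1", "cas2", "tracr", "array"]
        for idx, key in enumerate(order):
            part = parts[idx]
            spans[key] = (cursor + 1, cursor + len(part))  # 1-based inclusive
            pieces.append(part)
            cursor += len(part)
            if idx < len(gaps):
                gap_seq = _random_dna(g, gaps[idx])
                pieces.append(gap_seq)
                cursor += len(gap_seq)
        pieces.append(_random_dna(g, background_len - cursor))
        contig_seq = "".join(pieces)
        contigs.append(SequenceRecord(name, contig_seq, "dna", f"synthetic locus {li}"))

        coverage = float(np.round(g.uniform(8, 50), 1))
        species = f"species_{li}"
        for k in ("cas9", "cas1", "cas2"):
            features.append(
                FeatureRecord(
                    name, spans[k][0], spans[k][1], "+", k,
                    {
                        "ID": f"{name}_{k}",
                        "gene": k,
                        "protein_length_aa": len(proteins[k]),
                        "protein_sequence": proteins[k],
                        "coverage": coverage,
                        "species": species,
                    },
                )
            )

        anti_start = spans["tracr"][0]
        rep_len = spec["repeat_len"]
        repeat_spans = []
        pos = spans["array"][0]
        for _ in range(spec["n_spacers"] + 1):
            repeat_spans.append([pos, pos + rep_len - 1])
            pos += rep_len + spec["spacer_len"]
        truth["loci"].append(
            {
                "contig": name,
                "species": species,
                "coverage": coverage,
                "array": {
                    "start": spans["array"][0],
                    "end": spans["array"][1],
                    "repeat": repeat,
                    "spacers": spacers,
                    "n_repeats": spec["n_spacers"] + 1,
                    "n_spacers": spec["n_spacers"],
                    "repeat_spans": repeat_spans,
                },
                "cas9": {"span": spans["cas9"], "aa": len(proteins["cas9"])},
                "cas1": {"span": spans["cas1"], "aa": len(proteins["cas1"])},
                "cas2": {"span": spans["cas2"], "aa": len(proteins["cas2"])},
                "tracr": {
                    "start": anti_start,
                    "end": spans["tracr"][1],
                    "strand": "+",
                    "anti_span": [anti_start, anti_start + len(anti) - 1],
                    "anti_mismatches": spec["anti_mismatches"],
                    "terminator_span": [
                        spans["tracr"][1] - len(terminator) + 1,
                        spans["tracr"][1],
                    ],
                },
                "expected_filter_pass": (
                    950 <= spec["cas9_aa"] < 1100 and spec["n_spacers"] >= 6
                ),
            }
        )

    gdec = rng(seed, "genome.decoys")
    for di in range(n_decoys):
        name = f"decoy{di}"
        contigs.append(SequenceRecord(name, _random_dna(gdec, decoy_len), "dna", "decoy"))
        truth["decoys"].append({"contig": name, "kind": "random"})
    if array_only_decoy:
        name = "decoy_array_only"
        repeat = _random_dna(gdec, spec["repeat_len"])
        spacers = [_random_dna(gdec, spec["spacer_len"]) for _ in range(8)]
        arr = repeat + "".join(s + repeat for s in spacers)
        left = _random_dna(gdec, 2000)
        seq = left + arr + _random_dna(gdec, 2000)
        contigs.append(SequenceRecord(name, seq, "dna", "decoy with array, no cas genes"))
        truth["decoys"].append(
            {"contig": name, "kind": "array_only", "array_span": [2001, 2000 + len(arr)]}
        )
    return contigs, features, truth


# ---------------------------------------------------------------------------
# randomized PAM library


def _pattern_tables(patterns: list[str], pam_len: int) -> np.ndarray:
    """(n_patterns, pam_len, 4) bool lookup for vectorized matching."""
    t = np.zeros((len(patterns), pam_len, 4), dtype=bool)
    for pi, p in enumerate(patterns):
        for j, sym in enumerate(p):
            for b in IUPAC[sym]:
                t[pi, j, _BASES.index(b)] = True
    return t


def _match_any(codes: np.ndarray, tables: np.ndarray) -> np.ndarray:
    """codes (n, pam_len) in 0..3 -> bool match against any pattern."""
    n = codes.shape[0]
    hit = np.zeros(n, dtype=bool)
    for pi in range(tables.shape[0]):
        ok = np.ones(n, dtype=bool)
        for j in range(codes.shape[1]):
            ok &= tables[pi, j][codes[:, j]]
        hit |= ok
    return hit


def make_pam_library(
    design: PamLibraryDesign,
    patterns: list[str],
    model: CleavageModel | None = None,
    n_reads: int = 100_000,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[SequenceRecord], dict]:
    """Cleaved and control read sets from a randomized 8-nt PAM library.

    Control PAMs are uniform over 4^pam_len; cleaved reads are retained by
    acceptance sampling with probability ``p_match`` when the PAM matches
    any planted pattern, else ``p_background``; per-base substitution
    errors are applied at ``error_rate`` across the whole read.
    """
    if n_reads < 1000:
        raise ValueError("n_reads must be >= 1000")
    model = model or CleavageModel()
    g = rng(seed, "pamlib")
    pl = design.pam_len
    tables = _pattern_tables([p[-pl:].rjust(pl, "N") for p in patterns], pl)

    control = g.integers(0, 4, size=(n_reads, pl), dtype=np.int8)

    kept: list[np.ndarray] = []
    total = 0
    while total < n_reads:
        batch = g.integers(0, 4, size=(max(n_reads, 20_000), pl), dtype=np.int8)
        match = _match_any(batch, tables)
        p = np.where(match, model.p_match, model.p_background)
        accept = g.random(batch.shape[0]) < p
        sel = batch[accept]
        kept.append(sel)
        total += sel.shape[0]
    cleaved = np.vstack(kept)[:n_reads]

    def finish(codes: np.ndarray, label: str) -> list[SequenceRecord]:
        pre = np.frombuffer(design.anchor.encode(), dtype=np.uint8)
        suf = np.frombuffer(design.backbone_context.encode(), dtype=np.uint8)
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        inv = np.full(256, -1, dtype=np.int8)
        for i, b in enumerate(b"ACGT"):
            inv[b] = i
        full = np.hstack(
            [
                np.tile(inv[pre], (codes.shape[0], 1)),
                codes,
                np.tile(inv[suf], (codes.shape[0], 1)),
            ]
        ).astype(np.int8)
        if model.error_rate > 0:
            mask = g.random(full.shape) < model.error_rate
            shift = g.integers(1, 4, size=int(mask.sum()), dtype=np.int8)
            full[mask] = (full[mask] + shift) % 4
        chars = lut[full]
        w = chars.shape[1]
        raw = chars.tobytes()
        qual = "I" * w
        return [
            SequenceRecord(f"{label}_{i}", raw[i * w : (i + 1) * w].decode(), "dna", "", {"quality": qual})
            for i in range(chars.shape[0])
        ]

    cleaved_reads = finish(cleaved, "cleaved")
    control_reads = finish(control, "control")

    match_frac = float(_match_any(cleaved, tables).mean())
    truth = {
        "seed": seed,
        "version": GENERATOR_VERSION,
        "patterns": list(patterns),
        "p_match": model.p_match,
        "p_background": model.p_background,
        "error_rate": model.error_rate,
        "n_reads": n_reads,
        "cleaved_match_fraction_pre_error": match_frac,
    }
    return cleaved_reads, control_reads, truth


# ---------------------------------------------------------------------------
# cut fragments


def make_cut_fragments(
    offset: int = 3,
    geometry: str = "blunt",
    n: int = 200,
    noise: float = 0.1,
    seed: int = 0,
) -> tuple[list[tuple[str, int]], dict]:
    """Per-strand adapter-ligation end positions around a planted cut.

    Positions count upstream from the PAM's 5' edge into the protospacer.
    90% of reads (1 - ``noise``) sit at the modal position, the rest +-1.
    ``geometry`` is "blunt", "five_prime_overhang(k)" or
    "three_prime_overhang(k)".
    """
    g = rng(seed, "cutsites")
    top_mode, bot_mode = offset, offset
    if geometry.startswith("five_prime_overhang"):
        k = int(geometry.rstrip(")").split("(")[1])
        top_mode = offset + k
    elif geometry.startswith("three_prime_overhang"):
        k = int(geometry.rstrip(")").split("(")[1])
        bot_mode = offset + k
    elif geometry != "blunt":
        raise ValueError(f"unknown geometry {geometry!r}")
    out: list[tuple[str, int]] = []
    for strand, mode in (("+", top_mode), ("-", bot_mode)):
        deltas = np.zeros(n, dtype=int)
        noisy = g.random(n) < noise
        signs = np.where(g.random(n) < 0.5, -1, 1)
        deltas[noisy] = signs[noisy]
        out.extend((strand, int(mode + d)) for d in deltas)
    truth = {
        "seed": seed,
        "version": GENERATOR_VERSION,
        "offset": offset,
        "geometry": geometry,
        "n_per_strand": n,
        "noise": noise,
    }
    return out, truth


# ---------------------------------------------------------------------------
# reference genome + SNVs


def _concrete_pam(pattern: str, g: np.random.Generator) -> str:
    return "".join(IUPAC[sym][int(g.integers(0, len(IUPAC[sym])))] for sym in pattern)


def _pam_slot(pos0: int, klass: str, w: int, pam_len: int) -> tuple[int, int]:
    """0-based [start, end) genome span of the PAM slot for window position w."""
    if klass == "G>A":
        return pos0 + w, pos0 + w + pam_len
    return pos0 - w - pam_len + 1, pos0 - w + 1


def _slot_pam(genome: list[str], slot: tuple[int, int], klass: str) -> str:
    s = "".join(genome[slot[0] : slot[1]])
    return s if klass == "G>A" else revcomp(s)


def _write_slot(genome: list[str], slot: tuple[int, int], pam: str, klass: str) -> None:
    s = pam if klass == "G>A" else revcomp(pam)
    genome[slot[0] : slot[1]] = list(s)


def _verdict(genome: list[str], snv: SnvRecord, scheme: PamScheme, window: EditingWindow, pad: int) -> bool:
    pos0 = snv.pos - 1
    ctx = "".join(genome[pos0 - pad : pos0 + pad + 1])
    ok, _ = snv_targetable(snv, ctx, scheme, window, center=pad)
    return ok


def make_reference_and_snvs(
    length: int = 120_000,
    gc_content: float = 0.41,
    n_snv: int = 60,
    class_mix: float = 0.5,
    schemes: dict[str, PamScheme] | None = None,
    windows: dict[str, EditingWindow] | None = None,
    seed: int = 0,
    positive_fraction: float = 0.5,
    exclusive: bool = False,
) -> tuple[SequenceRecord, pd.DataFrame, dict]:
    """A synthetic reference genome with SNVs of planted targetability.

    The genome is drawn i.i.d. at ``gc_content``; G>A and C>T SNVs are
    placed at well-separated positions, and for each (SNV, editor) pair a
    PAM is planted (positives) or every qualifying PAM placement scrubbed
    (negatives) so the intended verdicts are exact.  ``exclusive`` assigns
    each positive SNV to exactly one editor, round-robin.
    """
    if length < 10_000:
        raise ValueError("length must be >= 10 kb")
    from .targeting import COCAS9  # default editor scheme

    schemes = schemes or {"CoABE8e": COCAS9}
    windows = windows or {name: EditingWindow(frozenset(range(3, 15))) for name in schemes}
    editors = sorted(schemes)
    g = rng(seed, "reference")

    pad = max(s.spacer_len + s.pam_len for s in schemes.values()) + max(
        max(windows[e].positions) for e in editors
    )
    margin = pad + 10
    spacing = (length - 2 * margin) // max(1, n_snv)
    if spacing < 2 * pad + 10:
        raise ValueError(f"n_snv={n_snv} exceeds placeable positions for length {length}")

    genome = list(_random_dna(g, length, gc_content))

    snvs: list[SnvRecord] = []
    intents: dict[str, dict[str, bool]] = {}
    for i in range(n_snv):
        pos = margin + i * spacing + int(g.integers(0, spacing // 4))
        klass = "G>A" if g.random() < class_mix else "C>T"
        ref, alt = ("G", "A") if klass == "G>A" else ("C", "T")
        genome[pos] = ref
        snv = SnvRecord(f"snv{i}", "chrS", pos + 1, ref, alt)
        snvs.append(snv)
        if exclusive:
            chosen = editors[i % len(editors)]
            intents[snv.id] = {e: e == chosen for e in editors}
        else:
            intents[snv.id] = {e: bool(g.random() < positive_fraction) for e in editors}

    for snv in snvs:
        pos0 = snv.pos - 1
        klass = snv.snv_class
        for _round in range(10):
            stable = True
            for e in editors:
                scheme, window = schemes[e], windows[e]
                want = intents[snv.id][e]
                wlist = sorted(p for p in window.positions if 1 <= p <= scheme.spacer_len)
                have = _verdict(genome, snv, scheme, window, pad)
                if have == want:
                    continue
                stable = False
                if want:
                    w = wlist[int(g.integers(0, len(wlist)))]
                    pattern = scheme.patterns[int(g.integers(0, len(scheme.patterns)))]
                    slot = _pam_slot(pos0, klass, w, scheme.pam_len)
                    _write_slot(genome, slot, _concrete_pam(pattern, g), klass)
                else:
                    for w in wlist:
                        slot = _pam_slot(pos0, klass, w, scheme.pam_len)
                        pam = _slot_pam(genome, slot, klass)
                        if not any(iupac_match(p, pam) for p in scheme.patterns):
                            continue
                        fixed = False
                        for j in range(scheme.pam_len):
                            for b in _BASES:
                                if b == pam[j]:
                                    continue
                                trial = pam[:j] + b + pam[j + 1 :]
                                if not any(iupac_match(p, trial) for p in scheme.patterns):
                                    _write_slot(genome, slot, trial, klass)
                                    fixed = True
                                    break
                            if fixed:
                                break
                        if not fixed:
                            raise RuntimeError(f"cannot scrub PAM for {snv.id}/{e}")
            if stable:
                break
        else:
            raise RuntimeError(f"targetability enforcement did not converge for {snv.id}")

    for snv in snvs:  # final verification against intent
        for e in editors:
            assert _verdict(genome, snv, schemes[e], windows[e], pad) == intents[snv.id][e]

    seq = "".join(genome)
    record = SequenceRecord("chrS", seq, "dna", "synthetic reference")
    table = pd.DataFrame(
        [
            {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt, "id": s.id, "class": s.snv_class}
            for s in snvs
        ]
    )
    truth = {
        "seed": seed,
        "version": GENERATOR_VERSION,
        "length": length,
        "gc_content": gc_content,
        "editors": editors,
        "windows": {e: sorted(windows[e].positions) for e in editors},
        "verdicts": intents,
    }
    return record, table, truth


# ---------------------------------------------------------------------------
# editing matrices


def make_editing_matrix(
    window: set[int] | frozenset[int] = frozenset({4, 5, 6}),
    peak: float = 0.4,
    off_window: float = 0.02,
    n_guides: int = 10,
    noise_sd: float = 0.03,
    spacer_len: int = 23,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-guide A>G conversion fractions with a planted editing window.

    In-window positions have mean ``peak``, the rest ``off_window``; guide
    level Gaussian noise (sd ``noise_sd``) is added and values truncated to
    [0, 1].  Columns are spacer positions numbered from the PAM-proximal
    end.
    """
    if not (0 <= off_window < 0.10 <= peak <= 1):
        raise ValueError("require 0 <= off_window < 0.10 <= peak <= 1")
    g = rng(seed, "editing")
    base = np.full(spacer_len, off_window)
    for p in window:
        base[p - 1] = peak
    data = base + g.normal(0, noise_sd, size=(n_guides, spacer_len)) if noise_sd > 0 else np.tile(base, (n_guides, 1))
    data = np.clip(data, 0.0, 1.0)
    df = pd.DataFrame(
        data,
        index=[f"guide_{i}" for i in range(n_guides)],
        columns=range(1, spacer_len + 1),
    )
    truth = {
        "seed": seed,
        "version": GENERATOR_VERSION,
        "window": sorted(window),
        "peak": peak,
        "off_window": off_window,
    }
    return df, truth
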