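"""Targeting-range and base-editor targetability estimation.

Counts genomic positions that can serve as the PAM-proximal protospacer
base for a nuclease's PAM pattern set (union over strands), estimates
adenine-base-editor editing windows from per-guide A>G conversion matrices
(positions with >= 10% mean editing), and classifies G>A / C>T SNVs as
targetable when a PAM on the appropriate strand places the mutated adenine
inside the window.  Window positions are spacer coordinates counted from
the PAM-proximal end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import SequenceRecord, revcomp
from .pam_discovery import IUPAC

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class PamScheme:
    """A nuclease's PAM patterns plus guide geometry."""

    name: str
    pam_len: int
    patterns: list[str]
    spacer_len: int = 23
    cut_offset: int = 3

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"scheme {self.name}: no PAM patterns")
        for p in self.patterns:
            if len(p) != self.pam_len:
                raise ValueError(f"scheme {self.name}: pattern {p} length != pam_len")


# comparator schemes: canonical PAMs of the cited orthologs
COCAS9 = PamScheme("CoCas9", 8, ["NNNNGWNT", "NNNNGCDT", "NNNNATDT"], 23, 3)
SPCAS9 = PamScheme("SpCas9", 3, ["NGG"], 20, 3)
SACAS9 = PamScheme("SaCas9", 6, ["NNGRRT"], 21, 3)
NME2CAS9 = PamScheme("Nme2Cas9", 6, ["NNNNCC"], 23, 3)
CJCAS9 = PamScheme("CjCas9", 8, ["NNNNRYAC"], 22, 3)
SCHEMES = {s.name: s for s in (COCAS9, SPCAS9, SACAS9, NME2CAS9, CJCAS9)}


@dataclass
class GenomeScanResult:
    n_positions_scanned: int
    n_targetable_positions: int
    plus_pam_count: int
    minus_pam_count: int

    @property
    def fraction_targetable(self) -> float:
        if self.n_positions_scanned == 0:
            return 0.0
        return self.n_targetable_positions / self.n_positions_scanned


@dataclass
class EditingWindow:
    positions: frozenset[int]
    threshold: float = 0.10


@dataclass
class SnvRecord:
    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    @property
    def snv_class(self) -> str:
        if (self.ref, self.alt) == ("G", "A"):
            return "G>A"
        if (self.ref, self.alt) == ("C", "T"):
            return "C>T"
        raise ValueError(f"SNV {self.id}: ref/alt {self.ref}>{self.alt} is neither G>A nor C>T")


@dataclass
class TargetabilityReport:
    targetable: dict[str, set[str]]
    solely: dict[str, set[str]]
    universe: int
    fractions: dict[str, float] = field(default_factory=dict)
    solely_fractions: dict[str, float] = field(default_factory=dict)
    union_fraction: float = 0.0


# ---------------------------------------------------------------------------
# genome scanning


def _pattern_table(pattern: str) -> np.ndarray:
    """bool table[j, code]: may genome symbol `code` sit at pattern position j.

    Genome N matches only pattern symbol N.
    """
    table = np.zeros((len(pattern), 5), dtype=bool)
    for j, sym in enumerate(pattern):
        for b in IUPAC[sym]:
            table[j, _BASE_CODE[b]] = True
        if sym == "N":
            table[j, 4] = True
    return table


def _revcomp_pattern(pattern: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
            "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}
    return "".join(comp[c] for c in reversed(pattern))


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(arr.shape, 4, dtype=np.uint8)
    for b, v in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        code[arr == ord(b)] = v
    return code


def _match_starts(code: np.ndarray, pattern: str) -> np.ndarray:
    """Boolean vector over start positions of full pattern matches."""
    pl = len(pattern)
    n = len(code)
    if n < pl:
        return np.zeros(0, dtype=bool)
    table = _pattern_table(pattern)
    acc = table[0][code[: n - pl + 1]]
    for j in range(1, pl):
        acc &= table[j][code[j : n - pl + 1 + j]]
    return acc


def scan_genome(
    genome: list[SequenceRecord] | SequenceRecord | str,
    scheme: PamScheme,
) -> GenomeScanResult:
    """Count positions usable as the PAM-proximal protospacer base.

    A position is targetable when a PAM pattern matches immediately 3' of it
    on the + strand, or immediately 3' on the - strand (i.e. the reverse
    complement of the preceding pam_len bases matches).  The denominator
    excludes positions within max(pam_len, spacer_len - 1) of contig ends so
    both strands are fully evaluable everywhere counted.
    """
    if isinstance(genome, (SequenceRecord, str)):
        genome = [genome if isinstance(genome, SequenceRecord) else SequenceRecord("g", genome)]
    pl = scheme.pam_len
    margin = max(pl, scheme.spacer_len - 1)
    scanned = targetable = plus_total = minus_total = 0
    for contig in genome:
        code = _encode(contig.sequence)
        n = len(code)
        lo, hi = margin, n - 1 - margin
        if hi < lo:
            continue
        plus = np.zeros(max(0, n - pl + 1), dtype=bool)
        minus = np.zeros(max(0, n - pl + 1), dtype=bool)
        for pattern in scheme.patterns:
            plus |= _match_starts(code, pattern)
            minus |= _match_starts(code, _revcomp_pattern(pattern))
        scanned += hi - lo + 1
        idx = np.arange(lo, hi + 1)
        t_plus = plus[idx + 1]  # PAM starts right after the position
        t_minus = minus[idx - pl]  # rc-pattern match ending right before it
        targetable += int((t_plus | t_minus).sum())
        plus_total += int(plus.sum())
        minus_total += int(minus.sum())
    return GenomeScanResult(scanned, targetable, plus_total, minus_total)


# ---------------------------------------------------------------------------
# editing windows and SNV targetability


def estimate_window(matrix: pd.DataFrame, threshold: float = 0.10) -> EditingWindow:
    """Window = spacer positions with across-guide mean editing >= threshold."""
    if matrix.empty:
        raise ValueError("empty editing matrix")
    means = matrix.mean(axis=0)
    positions = frozenset(int(p) for p, m in means.items() if m >= threshold)
    return EditingWindow(positions, threshold)


def _matches_any(seq: str, patterns: list[str]) -> str | None:
    from .pam_discovery import iupac_match

    for p in patterns:
        if iupac_match(p, seq):
            return p
    return None


def snv_targetable(
    snv: SnvRecord,
    context: str,
    scheme: PamScheme,
    window: EditingWindow,
    center: int | None = None,
) -> tuple[bool, list[tuple[str, int, int]]]:
    """Is the SNV's mutated adenine placeable inside the editing window?

    ``context`` is genomic sequence centered on the variant (ref base at the
    center).  For G>A the editable adenine is the variant base on the +
    strand; for C>T it is its complement on the - strand, evaluated on the
    reverse complement.  Supporting sites are (strand, genomic PAM start,
    window position) triples.
    """
    if not window.positions:
        raise ValueError("empty editing window")
    c = len(context) // 2 if center is None else center
    context = context.upper()
    if context[c] != snv.ref:
        raise ValueError(f"SNV {snv.id}: context center {context[c]} != ref {snv.ref}")
    klass = snv.snv_class
    edited = context[:c] + snv.alt + context[c + 1 :]
    supports: list[tuple[str, int, int]] = []
    if klass == "G>A":
        seq, strand = edited, "+"
    else:
        seq, strand = revcomp(edited), "-"
        c = len(edited) - 1 - c
    usable = False
    for w in sorted(window.positions):
        if not (1 <= w <= scheme.spacer_len):
            continue
        pam_start = c + w  # adenine at spacer position w from the PAM-proximal end
        if pam_start - scheme.spacer_len < 0 or pam_start + scheme.pam_len > len(seq):
            continue
        usable = True
        if _matches_any(seq[pam_start : pam_start + scheme.pam_len], scheme.patterns):
            if strand == "+":
                genomic = snv.pos + w
            else:
                genomic = snv.pos - w
            supports.append((strand, genomic, w))
    if not usable:
        raise ValueError(f"SNV {snv.id}: context too short to evaluate any placement")
    return bool(supports), supports


def exclusive_targetability(
    reports: dict[str, set[str]], universe: int
) -> TargetabilityReport:
    """Per-editor targetable fractions, solely-targetable sets, and the union."""
    if universe <= 0:
        raise ValueError("universe size must be positive")
    editors = sorted(reports)
    solely = {}
    for e in editors:
        others: set[str] = set()
        for o in editors:
            if o != e:
                others |= reports[o]
        solely[e] = reports[e] - others
    union = set().union(*(reports[e] for e in editors)) if editors else set()
    return TargetabilityReport(
        targetable={e: set(reports[e]) for e in editors},
        solely=solely,
        universe=universe,
        fractions={e: len(reports[e]) / universe for e in editors},
        solely_fractions={e: len(solely[e]) / universe for e in editors},
        union_fraction=len(union) / universe,
    )


# ---------------------------------------------------------------------------
# guide design


@dataclass
class TargetSite:
    protospacer: str
    pam: str
    strand: str
    start: int  # 1-based protospacer span on the + strand
    end: int
    cut_offset: int  # bp from the PAM-proximal protospacer end
    cut_between: tuple[int, int]  # 1-based + strand coords flanking the cut


def design_guides(region: str | SequenceRecord, scheme: PamScheme) -> list[TargetSite]:
    """Enumerate all guide target sites in a region for a PAM scheme.

    Every PAM match on either strand yields one site whose protospacer is
    the ``spacer_len`` bases 5' of the PAM (in PAM-strand orientation) and
    whose cut lies ``cut_offset`` bp from the PAM-proximal protospacer end.
    Sites are ordered + strand first, then by coordinate.
    """
    seq = (region.sequence if isinstance(region, SequenceRecord) else region).upper()
    n = len(seq)
    pl, sl, co = scheme.pam_len, scheme.spacer_len, scheme.cut_offset
    if n < sl + pl:
        return []
    code = _encode(seq)
    sites: list[TargetSite] = []
    plus = np.zeros(n - pl + 1, dtype=bool)
    minus = np.zeros(n - pl + 1, dtype=bool)
    for pattern in scheme.patterns:
        plus |= _match_starts(code, pattern)
        minus |= _match_starts(code, _revcomp_pattern(pattern))
    for p in np.flatnonzero(plus):
        p = int(p)
        if p - sl < 0:
            continue
        sites.append(
            TargetSite(
                protospacer=seq[p - sl : p],
                pam=seq[p : p + pl],
                strand="+",
                start=p - sl + 1,
                end=p,
                cut_offset=co,
                cut_between=(p - co, p - co + 1),
            )
        )
    for s in np.flatnonzero(minus):
        s = int(s)
        p = s + pl  # PAM-proximal protospacer base position (0-based) on - strand
        if p + sl > n:
            continue
        sites.append(
            TargetSite(
                protospacer=revcomp(seq[p : p + sl]),
                pam=revcomp(seq[s : s + pl]),
                strand="-",
                start=p + 1,
                end=p + sl,
                cut_offset=co,
                cut_between=(p + co, p + co + 1),
            )
        )
    sites.sort(key=lambda t: (t.strand != "+", t.start))
    return sites
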