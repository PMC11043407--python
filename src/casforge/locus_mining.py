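"""CRISPR-Cas9 locus mining from assembled contigs.

Detects CRISPR arrays with a CRT-style seed-and-extend scan, assembles
candidate loci from arrays plus annotated cas1/cas2/cas9 genes under a
co-localization rule (all components within 10 kbp of each other), and
applies the discovery filters: Cas9 length within [950, 1100) aa, more
than 5 spacers, no deletions in nuclease domains, and highest sequencing
coverage per species.  Greedy centroid clustering and a within-cluster
length-outlier filter support ortholog collection curation.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from Bio import Align

from .core_io import ArrayParams, FeatureRecord, SequenceRecord


@dataclass
class CrisprArray:
    """A detected repeat-spacer array (1-based inclusive span)."""

    contig_id: str
    start: int
    end: int
    repeat_consensus: str
    # ordered (repeat_start, repeat_end, spacer_sequence_or_None)
    units: list[tuple[int, int, str | None]] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.units)

    @property
    def n_spacers(self) -> int:
        return sum(1 for u in self.units if u[2] is not None)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class CrisprLocus:
    """An array plus cas1/cas2/cas9 genes passing co-localization."""

    array: CrisprArray
    cas1: FeatureRecord
    cas2: FeatureRecord
    cas9: FeatureRecord
    species_id: str = ""
    coverage: float = 0.0
    complete: bool = True

    @property
    def contig_id(self) -> str:
        return self.array.contig_id

    def cas9_length_aa(self) -> int:
        attrs = self.cas9.attributes
        if "protein_length_aa" in attrs:
            return int(attrs["protein_length_aa"])
        if "protein_sequence" in attrs:
            return len(attrs["protein_sequence"])
        raise ValueError(
            f"locus on {self.contig_id} at {self.array.span}: cas9 lacks protein_length_aa"
        )


@dataclass
class SequenceCluster:
    centroid_id: str
    member_ids: list[str]
    identity_threshold: float
    coverage_threshold: float


# ---------------------------------------------------------------------------
# array detection


def _span_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Edge-to-edge gap between two 1-based inclusive spans (0 if touching)."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]) - 1)


def _consensus(columns: list[str]) -> str:
    out = []
    for col in columns:
        out.append(max(set(col), key=lambda b: (col.count(b), b)))
    return "".join(out)


def detect_crispr_arrays(contig: SequenceRecord, params: ArrayParams | None = None) -> list[CrisprArray]:
    """Find repeat-spacer arrays by exact k-mer seeding and extension.

    Seeds are exact ``seed_k``-mers recurring with a period compatible with
    the repeat/spacer length bounds; seeded repeat sets are extended outward
    while every copy stays within ``max_repeat_mismatches`` of the column
    consensus, then trimmed back to unanimous boundary columns.  Candidate
    arrays are validated against the length bounds and made non-overlapping
    (most repeats wins, then longer span, then leftmost).
    """
    params = params or ArrayParams()
    seq = contig.sequence
    n = len(seq)
    if n < 2 * params.repeat_min + params.spacer_min:
        return []

    k = params.seed_k
    period_min = params.repeat_min + params.spacer_min
    period_max = params.repeat_max + params.spacer_max

    kmer_pos: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer_pos.setdefault(seq[i : i + k], []).append(i)

    candidates: list[CrisprArray] = []
    seen_spans: set[tuple[int, int]] = set()

    for positions in kmer_pos.values():
        if len(positions) < params.min_repeats:
            continue
        # chain positions whose consecutive gaps fit one repeat+spacer period
        chain = [positions[0]]
        chains = []
        for p in positions[1:]:
            if period_min <= p - chain[-1] <= period_max:
                chain.append(p)
            else:
                if len(chain) >= params.min_repeats:
                    chains.append(chain)
                chain = [p]
        if len(chain) >= params.min_repeats:
            chains.append(chain)

        for chain in chains:
            arr = _extend_chain(seq, chain, k, params)
            if arr is None:
                continue
            arr.contig_id = contig.id
            key = (arr.start, arr.end)
            if key not in seen_spans:
                seen_spans.add(key)
                candidates.append(arr)

    # resolve overlaps: most repeats, then longest, then leftmost
    candidates.sort(key=lambda a: (-a.n_repeats, -(a.end - a.start), a.start))
    chosen: list[CrisprArray] = []
    for cand in candidates:
        if all(_span_gap(cand.span, c.span) > 0 for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda a: a.start)
    return chosen


def _extend_chain(seq: str, starts: list[int], k: int, params: ArrayParams) -> CrisprArray | None:
    m = len(starts)
    budget = params.max_repeat_mismatches
    mism = [0] * m
    left, right = 0, k  # repeat occupies [s+left, s+right) for each seed s

    def column(offset: int) -> str | None:
        cols = []
        for s in starts:
            p = s + offset
            if p < 0 or p >= len(seq):
                return None
            cols.append(seq[p])
        return "".join(cols)

    def try_extend(offset: int) -> bool:
        col = column(offset)
        if col is None:
            return False
        cons = max(set(col), key=lambda b: (col.count(b), b))
        add = [0 if c == cons else 1 for c in col]
        if any(mism[i] + add[i] > budget for i in range(m)):
            return False
        # require a clear repeat signal: at most one outlier copy per column
        if col.count(cons) < max(m - 1, 2):
            return False
        for i in range(m):
            mism[i] += add[i]
        return True

    while right - left < params.repeat_max and try_extend(right):
        right += 1
    while right - left < params.repeat_max and try_extend(left - 1):
        left -= 1

    # trim boundary columns that are not unanimous
    def unanimous(offset: int) -> bool:
        col = column(offset)
        return col is not None and len(set(col)) == 1

    while right - left > k and not unanimous(right - 1):
        right -= 1
    while right - left > k and not unanimous(left):
        left += 1

    rep_len = right - left
    if not (params.repeat_min <= rep_len <= params.repeat_max):
        return None

    spans = [(s + left, s + right) for s in starts]  # 0-based half-open
    # adjacent repeats must not overlap and spacers must satisfy bounds
    units: list[tuple[int, int, str | None]] = []
    for idx, (rs, re) in enumerate(spans):
        if idx < len(spans) - 1:
            spacer = seq[re : spans[idx + 1][0]]
            if not (params.spacer_min <= len(spacer) <= params.spacer_max):
                return None
        else:
            spacer = None
        units.append((rs + 1, re, spacer))  # to 1-based inclusive

    repeats = [seq[rs : rs + rep_len] for rs, _ in spans]
    consensus = _consensus(["".join(r[i] for r in repeats) for i in range(rep_len)])
    return CrisprArray(
        contig_id="",
        start=spans[0][0] + 1,
        end=spans[-1][1],
        repeat_consensus=consensus,
        units=units,
    )


# ---------------------------------------------------------------------------
# locus assembly and filtering


def assemble_loci(
    arrays: list[CrisprArray],
    features: list[FeatureRecord],
    max_locus_gap: int = 10_000,
) -> list[CrisprLocus]:
    """Pair each array with cas1/cas2/cas9 genes on the same contig.

    A locus is emitted only when the array and all three genes are mutually
    within ``max_locus_gap`` bp (edge-to-edge); incomplete combinations are
    dropped.  When several cas1/cas2 qualify, the nearest to the array wins.
    """
    by_contig: dict[str, dict[str, list[FeatureRecord]]] = {}
    for f in features:
        by_contig.setdefault(f.contig_id, {}).setdefault(f.kind, []).append(f)

    loci: list[CrisprLocus] = []
    for arr in arrays:
        kinds = by_contig.get(arr.contig_id, {})
        for cas9 in kinds.get("cas9", []):
            if _span_gap(arr.span, cas9.span) > max_locus_gap:
                continue
            best: CrisprLocus | None = None
            for cas1 in sorted(kinds.get("cas1", []), key=lambda f: _span_gap(arr.span, f.span)):
                for cas2 in sorted(kinds.get("cas2", []), key=lambda f: _span_gap(arr.span, f.span)):
                    spans = [arr.span, cas1.span, cas2.span, cas9.span]
                    if all(
                        _span_gap(spans[i], spans[j]) <= max_locus_gap
                        for i in range(4)
                        for j in range(i + 1, 4)
                    ):
                        cov = float(cas9.attributes.get("coverage", 0.0))
                        sp = cas9.attributes.get("species", arr.contig_id)
                        best = CrisprLocus(arr, cas1, cas2, cas9, sp, cov, True)
                        break
                if best:
                    break
            if best:
                loci.append(best)
    return loci


def filter_loci(
    loci: list[CrisprLocus],
    min_cas9_aa: int = 950,
    max_cas9_aa: int = 1100,
    min_spacers: int = 6,
) -> list[CrisprLocus]:
    """Keep loci with min_cas9_aa <= Cas9 length < max_cas9_aa and > 5 spacers."""
    out = []
    for locus in loci:
        aa = locus.cas9_length_aa()
        if min_cas9_aa <= aa < max_cas9_aa and locus.array.n_spacers >= min_spacers:
            out.append(locus)
    return out


# ---------------------------------------------------------------------------
# alignment helpers (shared scoring: match +1, mismatch -1, gap -2 linear)


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _alignment_stats(a: str, b: str) -> tuple[int, int, int, list[tuple[int, int, int]]]:
    """Globally align two sequences.

    Returns (matches, core_columns, shorter_core_residues, gap_runs) where
    the core excludes terminal gaps and gap_runs lists (seq_index, ref_start,
    length) for gaps in sequence *a* relative to *b* coordinates.
    """
    aln = _global_aligner().align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    ncol = len(sa)
    first = 0
    while first < ncol and (sa[first] == "-" or sb[first] == "-"):
        first += 1
    last = ncol - 1
    while last >= 0 and (sa[last] == "-" or sb[last] == "-"):
        last -= 1
    matches = 0
    core_cols = max(0, last - first + 1)
    short_core = 0
    shorter_is_a = len(a) <= len(b)
    pos_b = 0
    gap_runs: list[tuple[int, int, int]] = []
    run_start = None
    run_len = 0
    for i in range(ncol):
        ca, cb = sa[i], sb[i]
        in_core = first <= i <= last
        if ca == "-" and cb != "-":
            if run_start is None:
                run_start = pos_b
                run_len = 0
            run_len += 1
        else:
            if run_start is not None:
                gap_runs.append((0, run_start, run_len))
                run_start = None
        if in_core:
            if ca == cb and ca != "-":
                matches += 1
            if (shorter_is_a and ca != "-") or (not shorter_is_a and cb != "-"):
                short_core += 1
        if cb != "-":
            pos_b += 1
    if run_start is not None:
        gap_runs.append((0, run_start, run_len))
    return matches, core_cols, short_core, gap_runs


def dedupe_by_coverage(
    loci: list[CrisprLocus],
    nuclease_domain_spans: dict[str, list[tuple[int, int]]] | list[tuple[int, int]] | None = None,
    deletion_min_aa: int = 5,
) -> list[CrisprLocus]:
    """Per species: drop domain-deleted proteins, keep the highest-coverage locus.

    Members of each species group are globally aligned to the group reference
    (its longest protein); a gap run of >= ``deletion_min_aa`` residues whose
    reference coordinates intersect a configured nuclease-domain span
    disqualifies the member.  Of the survivors the maximal-coverage locus is
    returned (ties: longer protein, then lexicographic cas9 feature id).
    """
    groups: dict[str, list[CrisprLocus]] = {}
    for locus in loci:
        groups.setdefault(locus.species_id, []).append(locus)

    selected: list[CrisprLocus] = []
    for species in sorted(groups):
        members = groups[species]
        if len(members) == 1:
            selected.append(members[0])
            continue
        if isinstance(nuclease_domain_spans, dict):
            domains = nuclease_domain_spans.get(species, [])
        else:
            domains = nuclease_domain_spans or []
        proteins = {id(m): m.cas9.attributes.get("protein_sequence", "") for m in members}
        reference = max(members, key=lambda m: (len(proteins[id(m)]), _locus_id(m)))
        ref_seq = proteins[id(reference)]
        survivors = []
        for m in members:
            seq = proteins[id(m)]
            if not seq or not ref_seq or m is reference:
                survivors.append(m)
                continue
            _, _, _, gap_runs = _alignment_stats(seq, ref_seq)
            deleted = False
            for _, ref_start, length in gap_runs:
                if length < deletion_min_aa:
                    continue
                gap_span = (ref_start + 1, ref_start + length)  # 1-based on reference
                if any(not (gap_span[1] < d[0] or gap_span[0] > d[1]) for d in domains):
                    deleted = True
                    break
            if not deleted:
                survivors.append(m)
        if not survivors:
            continue  # all members domain-deleted; logged group is empty
        survivors.sort(key=lambda m: (-m.coverage, -len(proteins[id(m)]), _locus_id(m)))
        selected.append(survivors[0])
    return selected


def _locus_id(locus: CrisprLocus) -> str:
    return str(locus.cas9.attributes.get("ID", f"{locus.contig_id}:{locus.cas9.start}"))


def cluster_sequences(
    records: list[SequenceRecord], identity: float, coverage: float
) -> list[SequenceCluster]:
    """Greedy incremental centroid clustering (CD-HIT style).

    Records are sorted by length descending; each joins the first centroid
    with pairwise identity >= ``identity`` over an alignment core (terminal
    gaps excluded) covering >= ``coverage`` of the shorter sequence, else it
    founds a new cluster.
    """
    clusters: list[SequenceCluster] = []
    centroids: dict[str, SequenceRecord] = {}
    for rec in sorted(records, key=lambda r: (-len(r.sequence), r.id)):
        placed = False
        for cl in clusters:
            cen = centroids[cl.centroid_id]
            matches, core_cols, short_core, _ = _alignment_stats(rec.sequence, cen.sequence)
            if core_cols == 0:
                continue
            ident = matches / core_cols
            cov = short_core / min(len(rec.sequence), len(cen.sequence))
            if ident >= identity and cov >= coverage:
                cl.member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(rec.id, [rec.id], identity, coverage))
            centroids[rec.id] = rec
    return clusters


def filter_length_outliers(
    cluster: SequenceCluster, member_lengths: dict[str, int]
) -> SequenceCluster:
    """Drop members shorter than median - 2 * population sd of cluster lengths."""
    lengths = [member_lengths[m] for m in cluster.member_ids]
    if len(lengths) < 2:
        return cluster
    med = statistics.median(lengths)
    sd = statistics.pstdev(lengths)
    cutoff = med - 2 * sd
    kept = [m for m in cluster.member_ids if member_lengths[m] >= cutoff]
    if cluster.centroid_id not in kept:
        kept.insert(0, cluster.centroid_id)
    return SequenceCluster(cluster.centroid_id, kept, cluster.identity_threshold, cluster.coverage_threshold)
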