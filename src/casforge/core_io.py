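"""Shared I/O, configuration and randomness services.

Every stage of the pipeline reads and writes through this module: FASTA
contigs and proteins, GFF3 gene annotations, FASTQ read sets, tab-separated
report tables, and JSON ground-truth records.  All readers validate rather
than coerce: malformed input raises :class:`ParseError` naming the offending
line.  Coordinates are 1-based inclusive everywhere (GFF3 convention).

Randomness is centralised in :func:`rng`: every stochastic operation in the
repository draws from a named stream derived from the global seed, so a full
pipeline run with a fixed config and seed is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

DNA_ALPHABET = set("ACGTN")
RNA_ALPHABET = set("ACGUN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def transcribe(seq: str) -> str:
    """DNA -> RNA (T becomes U)."""
    return seq.replace("T", "U").replace("t", "u")


@dataclass
class SequenceRecord:
    """A named sequence with a declared molecule type.

    ``moltype`` is one of ``dna``, ``rna``, ``protein``; the sequence is
    uppercased and restricted to the declared alphabet.
    """

    id: str
    sequence: str
    moltype: str = "dna"
    description: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        alphabet = {"dna": DNA_ALPHABET, "rna": RNA_ALPHABET, "protein": PROTEIN_ALPHABET}.get(self.moltype)
        if alphabet is None:
            raise ValueError(f"record {self.id!r}: unknown moltype {self.moltype!r}")
        bad = set(self.sequence) - alphabet
        if bad:
            raise ValueError(f"record {self.id!r}: characters {sorted(bad)} outside {self.moltype} alphabet")

    def __len__(self) -> int:
        return len(self.sequence)


KINDS = {"cas1", "cas2", "cas9", "crispr_array", "other"}


@dataclass
class FeatureRecord:
    """A located genome feature (1-based inclusive coordinates)."""

    contig_id: str
    start: int
    end: int
    strand: str
    kind: str = "other"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"feature on {self.contig_id}: invalid span {self.start}..{self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature on {self.contig_id}: strand must be + or -")
        if self.kind not in KINDS:
            raise ValueError(f"feature on {self.contig_id}: unknown kind {self.kind!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def infer_moltype(seq: str) -> str:
    """Classify a sequence by alphabet; ambiguous strings default to dna.

    U and T are never interconverted: a sequence containing U is rna, one
    containing T is dna.
    """
    chars = set(seq.upper())
    if chars <= DNA_ALPHABET:
        return "dna"
    if chars <= RNA_ALPHABET:
        return "rna"
    if chars <= PROTEIN_ALPHABET:
        return "protein"
    raise ValueError(f"sequence characters {sorted(chars - PROTEIN_ALPHABET)} fit no supported alphabet")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into records.

    Raises :class:`ParseError` on malformed headers, empty sequences or
    duplicate ids, naming the line number.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal header
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {header!r} has an empty sequence")
        name, _, desc = header.partition(" ")
        if name in seen:
            raise ParseError(f"{path}:{header_line}: duplicate sequence id {name!r}")
        seen.add(name)
        records.append(SequenceRecord(name, seq, infer_moltype(seq), desc))
        header = None
        chunks.clear()

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].strip()
                header_line = lineno
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: sequence data before any header")
                chunks.append(line)
        flush(-1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_GFF_KIND_KEYS = ("gene", "Name", "ID", "product")


def _gff_kind(ftype: str, attrs: dict) -> str:
    ftype_l = ftype.lower()
    if ftype_l in KINDS:
        return ftype_l
    if ftype_l in {"repeat_region", "crispr"} and "crispr" in str(attrs).lower():
        return "crispr_array"
    for key in _GFF_KIND_KEYS:
        val = str(attrs.get(key, "")).lower()
        if val in KINDS:
            return val
    return "other"


def read_gff(path: str | Path) -> list[FeatureRecord]:
    """Read GFF3 features; unknown types map to kind ``other``."""
    feats: list[FeatureRecord] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ParseError(f"{path}:{lineno}: end ({end}) < start ({start})")
            attrs: dict = {}
            for item in attr_s.split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition("=")
                attrs[key] = val
            if strand == ".":
                strand = "+"
            feats.append(FeatureRecord(contig, start, end, strand, _gff_kind(ftype, attrs), attrs))
    return feats


def write_gff(features: Iterable[FeatureRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            ftype = "repeat_region" if f.kind == "crispr_array" else "CDS"
            attrs = dict(f.attributes)
            if f.kind in {"cas1", "cas2", "cas9"}:
                attrs.setdefault("gene", f.kind)
            if f.kind == "crispr_array":
                attrs.setdefault("rpt_family", "CRISPR")
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(f"{f.contig_id}\t.\t{ftype}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attr_s}\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read 4-line-per-record FASTQ; quality retained in attributes."""
    records: list[SequenceRecord] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise ParseError(f"{path}: truncated FASTQ (line count {len(lines)} not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise ParseError(f"{path}:{lineno}: record must start with '@'")
        if not plus.startswith("+"):
            raise ParseError(f"{path}:{lineno + 2}: expected '+' separator line")
        if len(seq) != len(qual):
            raise ParseError(f"{path}:{lineno + 3}: quality length != sequence length")
        name, _, desc = head[1:].partition(" ")
        records.append(SequenceRecord(name, seq, "dna", desc, {"quality": qual}))
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            qual = rec.attributes.get("quality", "I" * len(rec.sequence))
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def rng(seed: int, stream_name: str) -> np.random.Generator:
    """A deterministic generator for one named random stream.

    Identical (seed, stream_name) pairs yield identical draw sequences;
    distinct stream names yield statistically independent streams.
    """
    key = zlib.crc32(stream_name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ArrayParams:
    """CRISPR array detection parameters (CRT/MinCED default bounds)."""

    min_repeats: int = 3
    repeat_min: int = 23
    repeat_max: int = 47
    spacer_min: int = 26
    spacer_max: int = 50
    seed_k: int = 8
    max_repeat_mismatches: int = 1


@dataclass
class MiningParams:
    max_locus_gap: int = 10_000
    min_cas9_aa: int = 950
    max_cas9_aa: int = 1100
    min_spacers: int = 6
    deletion_min_aa: int = 5
    cluster_identity: float = 0.95
    cluster_coverage: float = 0.50


@dataclass
class ScoringParams:
    """Short-word local alignment scoring for the anti-repeat search."""

    match: int = 1
    mismatch: int = 1
    gap_open: int = 2
    gap_extend: int = 1
    word_size: int = 8
    evalue_max: float = 1.0
    flank_window: int = 3000

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        for name in ("mismatch", "gap_open", "gap_extend"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} is a penalty and must be positive")


@dataclass
class TracrParams:
    scoring: ScoringParams = field(default_factory=ScoringParams)
    duplex_min_pairs: int = 8
    nexus_max_offset: int = 6
    nexus_min_stem: int = 2
    hairpin_tail_nt: int = 60
    band_pairs: int = 1
    tetraloop: str = "GAAA"
    trim_len: int = 12


@dataclass
class PamParams:
    pam_len: int = 8
    max_anchor_mismatch: int = 1
    n_informative: int = 4
    pseudocount: float = 1.0
    consensus_tau: float = 0.2
    min_support: int = 10


@dataclass
class TargetParams:
    spacer_len: int = 23
    cut_offset: int = 3
    window_threshold: float = 0.10


@dataclass
class RunConfig:
    """All tunable parameters of every stage plus the global seed."""

    seed: int = 0
    arrays: ArrayParams = field(default_factory=ArrayParams)
    mining: MiningParams = field(default_factory=MiningParams)
    tracr: TracrParams = field(default_factory=TracrParams)
    pam: PamParams = field(default_factory=PamParams)
    targeting: TargetParams = field(default_factory=TargetParams)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = yaml.safe_load(io.StringIO(text)) or {}
        kwargs: dict = {"seed": int(data.get("seed", 0))}
        sections = {
            "arrays": ArrayParams,
            "mining": MiningParams,
            "tracr": TracrParams,
            "pam": PamParams,
            "targeting": TargetParams,
        }
        for name, klass in sections.items():
            sub = dict(data.get(name, {}))
            if name == "tracr" and "scoring" in sub:
                sub["scoring"] = ScoringParams(**sub["scoring"])
            kwargs[name] = klass(**sub)
        return cls(**kwargs)
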