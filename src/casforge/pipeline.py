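"""End-to-end demonstration pipeline on synthetic fixtures.

Runs mining -> tracrRNA inference -> PAM discovery -> genome scanning ->
SNV targetability on generated data and writes every report as text.  With
a fixed seed the output directory is byte-identical across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import core_io, locus_mining, pam_discovery, synthetic, targeting, tracrrna
from .core_io import RunConfig


def _write_tsv(rows: list[dict], path: Path) -> None:
    if not rows:
        path.write_text("")
        return
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n")


def mine_contigs(
    contigs: list[core_io.SequenceRecord],
    features: list[core_io.FeatureRecord],
    config: RunConfig | None = None,
) -> tuple[list[locus_mining.CrisprArray], list[locus_mining.CrisprLocus]]:
    """Detect arrays, assemble loci, apply the discovery filters."""
    config = config or RunConfig()
    arrays: list[locus_mining.CrisprArray] = []
    for contig in contigs:
        arrays.extend(locus_mining.detect_crispr_arrays(contig, config.arrays))
    loci = locus_mining.assemble_loci(arrays, features, config.mining.max_locus_gap)
    kept = locus_mining.filter_loci(
        loci, config.mining.min_cas9_aa, config.mining.max_cas9_aa, config.mining.min_spacers
    )
    kept = locus_mining.dedupe_by_coverage(kept)
    return arrays, kept


def run_demo(out_dir: str | Path, seed: int = 0, config: RunConfig | None = None) -> dict:
    """Full synthetic pipeline; returns a summary dict, writes text reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig(seed=seed)
    summary: dict = {"seed": seed}

    # --- mine ---------------------------------------------------------------
    contigs, features, truth = synthetic.make_crispr_genome(
        n_loci=2, background_len=12_000, seed=seed
    )
    core_io.write_fasta(contigs, out / "contigs.fasta")
    core_io.write_gff(features, out / "annotations.gff3")
    synthetic.save_truth(truth, out / "genome.truth.json")
    arrays, loci = mine_contigs(contigs, features, config)
    _write_tsv(
        [
            {
                "contig": a.contig_id,
                "start": a.start,
                "end": a.end,
                "repeat": a.repeat_consensus,
                "n_repeats": a.n_repeats,
                "n_spacers": a.n_spacers,
            }
            for a in arrays
        ],
        out / "arrays.tsv",
    )
    _write_tsv(
        [
            {
                "contig": l.contig_id,
                "array_start": l.array.start,
                "array_end": l.array.end,
                "repeat": l.array.repeat_consensus,
                "n_spacers": l.array.n_spacers,
                "cas1": f"{l.cas1.start}-{l.cas1.end}",
                "cas2": f"{l.cas2.start}-{l.cas2.end}",
                "cas9": f"{l.cas9.start}-{l.cas9.end}",
                "cas9_aa": l.cas9_length_aa(),
                "coverage": l.coverage,
                "species": l.species_id,
            }
            for l in loci
        ],
        out / "loci.tsv",
    )
    summary["n_arrays"] = len(arrays)
    summary["n_loci"] = len(loci)

    # --- tracrRNA -----------------------------------------------------------
    by_id = {c.id: c for c in contigs}
    tracr_rows = []
    for locus in loci:
        results = tracrrna.infer_tracrrnas(by_id[locus.contig_id], locus.array, config.tracr)
        for r in results:
            if r.scaffold is None:
                continue
            tracr_rows.append(
                {
                    "contig": locus.contig_id,
                    "anti_start": r.hit.start,
                    "anti_end": r.hit.end,
                    "strand": r.hit.strand,
                    "score": r.hit.score,
                    "evalue": f"{r.hit.evalue:.3g}",
                    "terminator": "yes" if r.candidate.terminator else "polyT",
                    "scaffold": r.scaffold.sequence,
                    "modules_pass": r.passed,
                    "reasons": ",".join(r.reasons),
                    "structure": r.prediction.dot_brackets()[0],
                }
            )
    _write_tsv(tracr_rows, out / "tracrrna.tsv")
    summary["n_tracr_pass"] = sum(1 for r in tracr_rows if r["modules_pass"])

    # --- PAM discovery -------------------------------------------------------
    design = pam_discovery.PamLibraryDesign(protospacer="GTCACCTCCAATGACTAGGGTGG")
    patterns = ["NNNNGWNT", "NNNNGCDT", "NNNNATDT"]
    cleaved, control, pam_truth = synthetic.make_pam_library(
        design, patterns, synthetic.CleavageModel(), n_reads=20_000, seed=seed
    )
    synthetic.save_truth(pam_truth, out / "pamlib.truth.json")
    cc = pam_discovery.extract_pams(cleaved, design, config.pam.max_anchor_mismatch)
    uc = pam_discovery.extract_pams(control, design, config.pam.max_anchor_mismatch)
    profile = pam_discovery.position_profile(cc)
    positions = pam_discovery.select_informative_positions(profile, config.pam.n_informative)
    table = pam_discovery.enrichment(cc, uc, positions, config.pam.pseudocount)
    consensus = pam_discovery.call_consensus(table, config.pam.consensus_tau, config.pam.pam_len)
    profile.freq.to_csv(out / "pam.profile.tsv", sep="\t")
    table.table.to_csv(out / "pam.enrichment.tsv", sep="\t")
    (out / "pam.consensus.txt").write_text("\n".join(consensus.patterns) + "\n")
    _write_tsv([dict(cc.qc)], out / "pam.qc.tsv")
    summary["consensus"] = consensus.patterns
    summary["informative_positions"] = list(positions)

    # --- cut site ------------------------------------------------------------
    ends, cut_truth = synthetic.make_cut_fragments(seed=seed)
    call = pam_discovery.infer_cut_site(ends, config.pam.min_support)
    (out / "cutsite.json").write_text(
        json.dumps(
            {"offset_bp": call.offset_bp, "geometry": call.geometry, "support": call.support,
             "planted": cut_truth}, indent=1, sort_keys=True,
        )
        + "\n"
    )
    summary["cut_offset"] = call.offset_bp
    summary["cut_geometry"] = call.geometry

    # --- targeting range ------------------------------------------------------
    scheme = targeting.PamScheme(
        "called", config.pam.pam_len, consensus.patterns,
        config.targeting.spacer_len, config.targeting.cut_offset,
    )
    matrix, mat_truth = synthetic.make_editing_matrix(seed=seed)
    window = targeting.estimate_window(matrix, config.targeting.window_threshold)
    matrix.to_csv(out / "editing_matrix.tsv", sep="\t")
    genome, snvs, snv_truth = synthetic.make_reference_and_snvs(
        length=60_000, n_snv=24, schemes={"CoABE8e": scheme},
        windows={"CoABE8e": window}, seed=seed,
    )
    core_io.write_fasta([genome], out / "reference.fasta")
    snvs.to_csv(out / "snvs.tsv", sep="\t", index=False)
    synthetic.save_truth(snv_truth, out / "snvs.truth.json")
    scan = targeting.scan_genome([genome], scheme)
    _write_tsv(
        [
            {
                "scheme": scheme.name,
                "n_scanned": scan.n_positions_scanned,
                "n_targetable": scan.n_targetable_positions,
                "fraction": f"{scan.fraction_targetable:.6f}",
                "plus_pams": scan.plus_pam_count,
                "minus_pams": scan.minus_pam_count,
            }
        ],
        out / "scan.tsv",
    )
    rows = []
    pad = len(genome.sequence)
    for _, row in snvs.iterrows():
        snv = targeting.SnvRecord(row["id"], row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        ctx_pad = 120
        ctx = genome.sequence[snv.pos - 1 - ctx_pad : snv.pos + ctx_pad]
        ok, supports = targeting.snv_targetable(snv, ctx, scheme, window, center=ctx_pad)
        rows.append({"id": snv.id, "class": snv.snv_class, "targetable": ok, "n_supports": len(supports)})
    _write_tsv(rows, out / "snv_targetability.tsv")
    summary["scan_fraction"] = scan.fraction_targetable
    summary["editing_window"] = sorted(window.positions)

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary
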