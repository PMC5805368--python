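"""End-to-end pipeline: simulate -> map -> clean -> signatures -> metrics ->
master loci -> methylation (-> assembly QC), with a run manifest.

Every stage writes plain-text outputs (FASTA/BED/SAM/TSV) that reload as
the next stage's inputs, and the manifest records the package version,
seed, parameters and per-stage row counts, so a run is reproducible from
its output directory alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

import srnasurv
from srnasurv import io
from srnasurv.alignments import (
    assign_to_features,
    cap_multimappers,
    discover_expressed_loci,
    map_reads_exact,
)
from srnasurv.assembly_qc import assembly_stats, filter_contaminated, read_blast_hits
from srnasurv.locus_metrics import class_bias_summary, locus_metrics_table, size_distribution
from srnasurv.master_loci import call_master_loci, te_read_accountability
from srnasurv.methylation import context_rates, filter_coverage, load_calls
from srnasurv.signatures import averaged_overhang, plot_signature_matrix, signature_matrix
from srnasurv.simulate import SimConfig, collapse_reads, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    seed: int = 0
    outdir: str = "srnasurv_out"
    simulate: dict[str, Any] = field(default_factory=dict)
    genome: str | None = None  # FASTA; defaults to the simulated genome
    reads: str | None = None  # FASTA/FASTQ collapsed reads
    annotation: str | None = None  # BED6
    methyl_calls: str | None = None  # TSV
    contig_hits: str | None = None  # BLAST outfmt-6-like TSV (assembly QC)
    max_hits: int = 100
    min_reads: int = 1000
    min_len: int = 200
    merge_gap: int = 50
    bias_cutoff: float = 0.3
    min_match: int = 25
    methyl_min_reads: int = 4
    contamination_threshold: float = 0.10
    render_heatmaps: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run manifest.

    Simulation runs when no external reads are supplied; mapping, capping,
    segmentation, signatures, locus metrics and master-locus discovery run
    whenever reads and a genome are available; methylation and assembly QC
    run when their input tables are present (the simulator provides a
    methylation table).  Partial outputs are kept on failure, with the
    manifest marking the failed stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "srnasurv",
        "version": srnasurv.__version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
    }
    stage = "setup"
    try:
        # --- inputs / simulation -------------------------------------------
        dataset = None
        methyl_df = None
        te_catalog: dict[str, str] = {}
        if config.reads is None:
            stage = "simulate"
            sim_params = dict(config.simulate)
            sim_params.setdefault("seed", config.seed)
            dataset = simulate_dataset(SimConfig(**sim_params))
            genome = dataset.genome
            annotation = list(dataset.annotation)
            reads = collapse_reads(dataset.reads)
            te_catalog = dataset.te_catalog
            methyl_df = dataset.methyl_calls
            io.write_genome_fasta(genome, outdir / "genome.fa")
            io.write_bed(annotation, outdir / "annotation.bed")
            io.write_reads_fasta(reads, outdir / "reads.fa")
            dataset.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)
            methyl_df.to_csv(outdir / "methyl_calls.tsv", sep="\t", index=False)
            manifest["stages"]["simulate"] = {
                "n_reads": len(dataset.reads),
                "n_collapsed": len(reads),
                "n_loci": len(annotation),
                "genome_bp": sum(len(s) for s in genome.values()),
            }
        else:
            stage = "load"
            if config.genome is None:
                raise ValueError("reads supplied without a genome FASTA")
            genome = io.read_genome_fasta(config.genome)
            reads = io.read_reads(config.reads)
            annotation = io.read_bed(config.annotation) if config.annotation else []
            manifest["stages"]["load"] = {"n_reads": len(reads), "n_loci": len(annotation)}

        # --- map + cap ------------------------------------------------------
        stage = "map"
        alignments, unmapped = map_reads_exact(reads, genome)
        kept, discarded_fraction = cap_multimappers(alignments, config.max_hits)
        assign_to_features(kept, annotation)
        io.write_alignments_sam(kept, genome, outdir / "alignments.sam")
        manifest["stages"]["map"] = {
            "n_alignments": len(alignments),
            "n_after_cap": len(kept),
            "n_unmapped_reads": len(unmapped),
            "multimap_discarded_fraction": discarded_fraction,
        }

        # --- expressed loci -------------------------------------------------
        stage = "discover_loci"
        expressed = discover_expressed_loci(
            kept, annotation, config.min_reads, config.min_len, config.merge_gap
        )
        io.write_bed(expressed, outdir / "expressed_loci.bed")
        manifest["stages"]["discover_loci"] = {"n_expressed": len(expressed)}

        # --- signatures -----------------------------------------------------
        stage = "signatures"
        matrix = signature_matrix(kept)
        matrix.to_csv(outdir / "signature_matrix.tsv", sep="\t")
        if config.render_heatmaps:
            plot_signature_matrix(matrix, str(outdir / "signature_matrix.png"))
        try:
            hs, curve, h_best = averaged_overhang(kept)
            pd.DataFrame({"overhang": hs, "mean_z": curve}).to_csv(
                outdir / "averaged_overhang.tsv", sep="\t", index=False
            )
            manifest["stages"]["signatures"] = {"argmax_overhang": h_best}
        except ValueError:
            manifest["stages"]["signatures"] = {"argmax_overhang": None}

        # --- locus metrics --------------------------------------------------
        stage = "metrics"
        hist, mode = size_distribution(kept)
        hist.rename("fraction").to_csv(outdir / "size_distribution.tsv", sep="\t")
        locus_metrics_table(annotation, kept).to_csv(
            outdir / "locus_metrics.tsv", sep="\t", index=False
        )
        class_bias_summary(annotation, kept).to_csv(outdir / "class_bias.tsv", sep="\t")
        manifest["stages"]["metrics"] = {
            "modal_size": mode,
            "n_loci": len(annotation),
        }

        # --- master loci ----------------------------------------------------
        stage = "master_loci"
        candidates = expressed + [l for l in annotation if l.feature_class == "master"]
        masters = call_master_loci(
            candidates, kept, te_catalog, genome, config.bias_cutoff, config.min_match
        )
        io.write_bed([m.locus for m in masters], outdir / "master_loci.bed")
        accountability = None
        if masters:
            te_read_ids = {
                a.read_id for a in kept if a.feature_class in ("TE", "master")
            }
            te_reads = [r for r in reads if r.id in te_read_ids]
            seqs = [genome[m.locus.chrom][m.locus.start : m.locus.end] for m in masters]
            if te_reads:
                accountability = te_read_accountability(te_reads, seqs)
        manifest["stages"]["master_loci"] = {
            "n_called": len(masters),
            "te_read_accountability": accountability,
        }

        # --- methylation ----------------------------------------------------
        if config.methyl_calls is not None:
            methyl_df = load_calls(config.methyl_calls)
        if methyl_df is not None:
            stage = "methylation"
            covered = filter_coverage(methyl_df, config.methyl_min_reads)
            rates = context_rates(covered, annotation)
            rates.to_csv(outdir / "methylation_rates.tsv", sep="\t")
            manifest["stages"]["methylation"] = {
                "n_sites": len(methyl_df),
                "n_covered": len(covered),
                "global_rate_percent": None
                if rates.loc["genome", "all_contexts"] != rates.loc["genome", "all_contexts"]
                else float(rates.loc["genome", "all_contexts"]),
            }

        # --- assembly QC ----------------------------------------------------
        if config.contig_hits is not None:
            stage = "assembly_qc"
            lengths = {name: len(seq) for name, seq in genome.items()}
            hitsets = read_blast_hits(config.contig_hits, lengths)
            kept_ids, discarded_ids = filter_contaminated(
                hitsets, config.contamination_threshold
            )
            n, total, n50 = assembly_stats([lengths[c] for c in kept_ids])
            pd.DataFrame(
                {"contig": kept_ids + discarded_ids,
                 "status": ["kept"] * len(kept_ids) + ["discarded"] * len(discarded_ids)}
            ).to_csv(outdir / "contig_filter.tsv", sep="\t", index=False)
            manifest["stages"]["assembly_qc"] = {
                "n_kept": len(kept_ids),
                "n_discarded": len(discarded_ids),
                "total_bp": total,
                "N50": n50,
            }
        manifest["status"] = "ok"
    except Exception as exc:  # pragma: no cover - exercised via CLI error paths
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
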