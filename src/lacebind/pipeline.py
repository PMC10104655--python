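"""End-to-end orchestration: pileup -> peaks -> filter -> annotate ->
metagene -> motifs -> integration, with a machine-readable run report.

Every intermediate is written to the output directory in plain-text
formats so any later stage can be re-run in isolation. Optional
integrations (TE, poly(A), proteomics) are skipped with a notice when
their input tables are absent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .annotate import (
    annotate_peaks,
    annotated_peaks_to_frame,
    category_distribution,
    metaprofile,
)
from .integrate import (
    bound_vs_unbound_shift,
    compute_te,
    count_differential,
    derive_target_set,
    quartile_association,
)
from .motifs import (
    consensus_from_top_hexamers,
    gc_rich_motifs,
    hexamer_zscores,
    motif_peak_fraction,
    motif_positional_profile,
    peak_sequences,
    top_motifs,
)
from .signal import (
    call_candidate_peaks,
    filter_peaks_by_controls,
    gene_binding_density,
    merge_coverages,
    peaks_to_dataframe,
    pileup_read_ends,
    read_bed6,
    replicate_correlation,
)
from .transcriptome import load_annotation

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    gtf: str
    ip_beds: List[str]
    control_beds: Dict[str, str]  # library id -> BED path
    outdir: str
    repeats_bed: Optional[str] = None
    transcript_fasta: Optional[str] = None
    rpf_counts: Optional[str] = None
    rna_counts: Optional[str] = None
    polya: Optional[str] = None
    proteomics: Optional[str] = None

    fold: float = 5.0
    window: int = 50
    merge_distance: int = 10
    min_reads: int = 5
    peak_p: float = 0.01
    min_replicate_r: float = 0.5
    n_shuffles: int = 100
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.fold <= 0:
            raise ConfigurationError("fold must be > 0")
        if not self.ip_beds:
            raise ConfigurationError("at least one IP library is required")
        required = [self.gtf, *self.ip_beds, *self.control_beds.values()]
        for p in (self.repeats_bed, self.transcript_fasta):
            if p is not None:
                required.append(p)
        missing = [p for p in required if not os.path.exists(p)]
        if missing:
            raise ConfigurationError(f"missing input files: {missing}")


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages and return (and write) the run report."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report: Dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    annotation = load_annotation(
        config.gtf,
        repeats_path=config.repeats_bed,
        fasta_path=config.transcript_fasta,
        fasta_mode="transcript" if config.transcript_fasta else "auto",
    )
    report["stages"]["annotation"] = {
        "n_genes": len(annotation.gene_to_canonical),
        "n_transcripts": len(annotation.transcripts),
        "n_repeats": len(annotation.repeats),
    }

    # --- stage 1: pileup, replicate gate, peaks, control filter ---------
    ip_covs = [
        pileup_read_ends(read_bed6(path), f"ip_rep{i + 1}")
        for i, path in enumerate(config.ip_beds)
    ]
    controls = [
        pileup_read_ends(read_bed6(path), lib)
        for lib, path in sorted(config.control_beds.items())
    ]
    rep_r = None
    if len(ip_covs) >= 2:
        rep_r = replicate_correlation(ip_covs[0], ip_covs[1], annotation)
        if rep_r < config.min_replicate_r:
            logger.warning(
                "replicate correlation %.3f below gate %.3f; replicates pooled anyway",
                rep_r,
                config.min_replicate_r,
            )
    ip = merge_coverages(ip_covs, "ip_pooled") if len(ip_covs) > 1 else ip_covs[0]

    candidates = call_candidate_peaks(
        ip,
        annotation,
        window=config.window,
        merge_distance=config.merge_distance,
        min_reads=config.min_reads,
        p_threshold=config.peak_p,
    )
    peaks = filter_peaks_by_controls(candidates, ip, controls, fold=config.fold)
    peaks_df = peaks_to_dataframe(peaks)
    peaks_df.to_csv(os.path.join(config.outdir, "peaks.tsv"), sep="\t", index=False)
    mean_len = float(peaks_df["end"].sub(peaks_df["start"]).mean()) if len(peaks_df) else 0.0
    report["stages"]["peaks"] = {
        "n_candidates": len(candidates),
        "n_filtered": len(peaks),
        "replicate_r": rep_r,
        "mean_peak_length_nt": mean_len,
        "total_ip_reads": ip.total_reads,
    }

    densities = gene_binding_density(peaks, ip, annotation)
    density_map = {d.gene_id: d.density for d in densities}
    pd.DataFrame([dataclasses.asdict(d) for d in densities]).to_csv(
        os.path.join(config.outdir, "gene_binding_density.tsv"), sep="\t", index=False
    )

    # --- stage 2: categories and metagene profiles ----------------------
    annotated = annotate_peaks(peaks, annotation)
    annotated_peaks_to_frame(annotated).to_csv(
        os.path.join(config.outdir, "annotated_peaks.tsv"), sep="\t", index=False
    )
    dist = category_distribution(annotated) if annotated else None
    if dist is not None:
        pd.DataFrame(
            {
                "category": list(dist.counts),
                "count": list(dist.counts.values()),
                "fraction": [dist.fractions[c] for c in dist.counts],
            }
        ).to_csv(os.path.join(config.outdir, "category_distribution.tsv"), sep="\t", index=False)
        report["stages"]["categories"] = {
            "fractions": dist.fractions,
            "utr_fraction": dist.utr_fraction,
            "n_peaks": dist.n_peaks,
        }

    profiles = {}
    gene_body = metaprofile(ip, annotation, mode="gene_body")
    gene_body.to_frame().to_csv(
        os.path.join(config.outdir, "metaprofile_gene_body.tsv"), sep="\t", index=False
    )
    profiles["gene_body"] = gene_body.n_transcripts
    for anchor in ("start_codon", "stop_codon", "polyA_site"):
        try:
            prof = metaprofile(ip, annotation, mode="anchored", anchor=anchor)
        except ValueError as exc:
            logger.warning("anchored profile %s skipped: %s", anchor, exc)
            continue
        prof.to_frame().to_csv(
            os.path.join(config.outdir, f"metaprofile_{anchor}.tsv"), sep="\t", index=False
        )
        profiles[anchor] = prof.n_transcripts
    report["stages"]["metaprofiles"] = profiles

    # --- stage 3: motifs -------------------------------------------------
    motif_report = {}
    if annotation.sequences and peaks:
        seqs = peak_sequences(peaks, annotation)
        table = hexamer_zscores(seqs, n_shuffles=config.n_shuffles, seed=config.seed)
        table.table.head(100).to_csv(
            os.path.join(config.outdir, "hexamers.tsv"), sep="\t", index=False
        )
        consensus = consensus_from_top_hexamers(table, k=min(20, int((table.table["observed"] > 0).sum())))
        with open(os.path.join(config.outdir, "consensus.json"), "w") as fh:
            json.dump(
                {
                    "columns": [int(c) for c in consensus.matrix.columns],
                    "rows": list(consensus.matrix.index),
                    "matrix": consensus.matrix.to_numpy().tolist(),
                    "source_hexamers": consensus.source_hexamers,
                    "consensus": consensus.consensus,
                },
                fh,
                indent=1,
            )
        gc_set = gc_rich_motifs(table)
        top_set = top_motifs(table)
        motif_report = {
            "top20": table.top(20)[["hexamer", "observed", "z"]].to_dict("records"),
            "gc_rich_fraction": motif_peak_fraction(seqs, gc_set) if len(gc_set) else None,
            "top20_fraction": motif_peak_fraction(seqs, top_set),
        }
        try:
            pos_prof = motif_positional_profile(top_set, annotation)
            pos_prof.to_frame().to_csv(
                os.path.join(config.outdir, "motif_positional_profile.tsv"),
                sep="\t",
                index=False,
            )
        except ValueError as exc:
            logger.warning("motif positional profile skipped: %s", exc)
    report["stages"]["motifs"] = motif_report

    # --- stage 4: integration -------------------------------------------
    targets = derive_target_set(peaks)
    report["stages"]["targets"] = {"n_targets": len(targets)}
    with open(os.path.join(config.outdir, "targets.txt"), "w") as fh:
        fh.write("\n".join(sorted(targets.genes)) + "\n")

    integration: Dict = {}
    if config.rpf_counts and config.rna_counts:
        rpf = pd.read_csv(config.rpf_counts, sep="\t", index_col=0).iloc[:, 0]
        rna = pd.read_csv(config.rna_counts, sep="\t", index_col=0).iloc[:, 0]
        te = compute_te(rpf.to_dict(), rna.to_dict(), annotation)
        te.to_csv(os.path.join(config.outdir, "te.tsv"), sep="\t", index=False)
        te_map = dict(zip(te["gene_id"], te["te"]))
        try:
            qa = quartile_association(density_map, te_map)
            integration["te_quartiles"] = {
                "medians": qa.medians,
                "p": qa.pairwise_p,
                "sizes": [s.n for s in qa.summaries],
            }
        except ValueError as exc:
            logger.warning("TE quartile association skipped: %s", exc)
    else:
        logger.info("TE tables absent; TE integration skipped")

    if config.polya:
        polya = pd.read_csv(config.polya, sep="\t")
        tail_map = dict(zip(polya["gene_id"], polya["tail_length_nt"]))
        try:
            qa = quartile_association(tail_map, density_map)
            integration["polya_quartiles"] = {
                "medians": qa.medians,
                "p": qa.pairwise_p,
                "sizes": [s.n for s in qa.summaries],
            }
        except ValueError as exc:
            logger.warning("poly(A) quartile association skipped: %s", exc)

    if config.proteomics:
        prot = pd.read_csv(config.proteomics, sep="\t")
        wt_cols = [c for c in prot.columns if c.startswith("wt_")]
        ko_cols = [c for c in prot.columns if c.startswith("cko_")]
        if "log2fc" not in prot.columns:
            prot["log2fc"] = prot[ko_cols].mean(axis=1) - prot[wt_cols].mean(axis=1)
        try:
            shift = bound_vs_unbound_shift(prot, targets)
            diff = count_differential(prot, wt_cols, ko_cols, alpha=config.alpha)
            integration["proteomics"] = {
                "bound_median_log2fc": shift.bound.median,
                "unbound_median_log2fc": shift.unbound.median,
                "p": shift.p,
                "n_down": diff.n_down,
                "n_up": diff.n_up,
                "n_tested": diff.n_tested,
            }
        except ValueError as exc:
            logger.warning("proteomics integration skipped: %s", exc)

    report["stages"]["integration"] = integration

    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
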