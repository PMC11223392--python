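"""End-to-end orchestration of the synthetic cross-platform analysis.

simulate -> (differential expression x2) -> panel join -> concordance ->
qPCR -> validation -> QC, with every stage's table written to an output
directory and a manifest capturing config, seed, and package version.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .concord import ConcordanceSummary, classify_overlap
from .containers import DOSE_CONDITIONS, ExpressionMatrix, SampleDesign, XplatError
from .diffexpr import (
    ARRAY_CRITERIA,
    SEQ_CRITERIA,
    ArrayDEModel,
    CountsDEModel,
    DEResults,
    cpm_normalize,
)
from .gtfio import write_gtf
from .panels import map_probe_pairs, write_alignments_tsv, write_panel_tsv
from .qc import dose_heatmap, flag_outliers, pca_scores
from .qpcr import QpcrModel, QpcrResults
from .synthdata import SimConfig, simulate_all, simulate_ct
from .validate import (
    ValidationSummary,
    assign_genesets,
    classify_validation,
    summarize_validation,
)


@dataclass
class ReportBundle:
    """All stage outputs of one pipeline run."""

    config: SimConfig
    truth: pd.DataFrame
    design: SampleDesign
    counts: ExpressionMatrix
    intensities: ExpressionMatrix
    join: object
    shared_genes: list
    de_seq: dict  # condition -> DEResults (shared universe)
    de_array: dict
    concord_records: pd.DataFrame
    concord_summary: ConcordanceSummary
    qpcr: QpcrResults
    geneset_assignment: pd.Series
    validation_records: pd.DataFrame
    validation_summary: ValidationSummary
    pca_seq: object
    pca_array: object
    outliers_seq: pd.Series
    outliers_array: pd.Series
    heatmap_matrix: pd.DataFrame
    heatmap_order: list
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    config: SimConfig,
    outdir: str | Path | None = None,
    seed: int | None = None,
    validated_condition: str = "HD",
) -> ReportBundle:
    """Run the full synthetic study; optionally write all tables."""
    if seed is not None:
        config = SimConfig.from_dict({**config.to_dict(), "seed": int(seed)})
    config.validate()

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, XplatError):
                    raise XplatError(f"stage {name!r} failed: {exc}") from exc
                if isinstance(exc, XplatError):
                    raise XplatError(f"stage {name!r}: {exc}") from exc
                return False

        return _Ctx()

    with stage("simulate"):
        sim = simulate_all(config)
        truth, counts, intensities = sim["truth"], sim["counts"], sim["intensities"]
        design = sim["design"]
        panel_a, panel_b = sim["panel_a"], sim["panel_b"]

    with stage("map"):
        join = map_probe_pairs(panel_a, panel_b)
        shared_genes = sorted({ga for ga, gb in join.gene_pairs(panel_a, panel_b) if ga == gb})

    with stage("de"):
        genes_a = sorted({p.gene_id for p in panel_a if p.gene_id})
        genes_b = sorted({p.gene_id for p in panel_b if p.gene_id})
        seq_model = CountsDEModel(counts.subset_features(genes_b), design)
        arr_model = ArrayDEModel(intensities.subset_features(genes_a), design)
        contrasts = [c for c in design.conditions if c != design.reference_condition]
        de_seq = {c: seq_model.fit(c, criteria=SEQ_CRITERIA).subset(shared_genes) for c in contrasts}
        de_array = {c: arr_model.fit(c, criteria=ARRAY_CRITERIA).subset(shared_genes) for c in contrasts}

    with stage("concord"):
        concord_records, concord_summary = classify_overlap(
            de_array[validated_condition], de_seq[validated_condition], shared_genes
        )

    with stage("qpcr"):
        deg_union = sorted(
            set(de_array[validated_condition].deg_ids)
            | set(de_seq[validated_condition].deg_ids)
        )
        refs = [g for g in truth.index[truth["ref_candidate"]]]
        panel_genes = sorted(set(deg_union) | set(refs))
        ct = simulate_ct(truth, config, panel_genes)
        qpcr_res = QpcrModel(ct, design, references="auto").fit()

    with stage("validate"):
        assignment = assign_genesets(
            de_array[validated_condition], de_seq[validated_condition], refs
        )
        validation_records = classify_validation(
            assignment, de_array[validated_condition], de_seq[validated_condition],
            qpcr_res, condition=validated_condition,
        )
        validation_summary = summarize_validation(validation_records)

    with stage("qc"):
        log_cpm = cpm_normalize(counts, log=True)
        pca_seq = pca_scores(log_cpm, k=2)
        pca_array = pca_scores(intensities, k=2)
        outliers_seq = flag_outliers(pca_seq, design)
        outliers_array = flag_outliers(pca_array, design)
        doses = [d for d in DOSE_CONDITIONS if d in design.conditions]
        heat_genes = deg_union if deg_union else shared_genes[:1]
        tables = {}
        for d in doses:
            tables[("array", d)] = de_array[d].table.loc[heat_genes, "log2fc"]
            tables[("seq", d)] = de_seq[d].table.loc[heat_genes, "log2fc"]
        heat_matrix, heat_order, _ = dose_heatmap(tables)

    manifest = {
        "package": "xplatcord",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "validated_condition": validated_condition,
        "python": platform.python_version(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    bundle = ReportBundle(
        config=config,
        truth=truth,
        design=design,
        counts=counts,
        intensities=intensities,
        join=join,
        shared_genes=shared_genes,
        de_seq=de_seq,
        de_array=de_array,
        concord_records=concord_records,
        concord_summary=concord_summary,
        qpcr=qpcr_res,
        geneset_assignment=assignment,
        validation_records=validation_records,
        validation_summary=validation_summary,
        pca_seq=pca_seq,
        pca_array=pca_array,
        outliers_seq=outliers_seq,
        outliers_array=outliers_array,
        heatmap_matrix=heat_matrix,
        heatmap_order=heat_order,
        manifest=manifest,
    )
    if outdir is not None:
        write_bundle(bundle, Path(outdir), sim)
    return bundle


def write_bundle(bundle: ReportBundle, outdir: Path, sim: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t")
    bundle.counts.to_tsv(outdir / "counts.tsv")
    bundle.intensities.to_tsv(outdir / "intensities.tsv")
    bundle.design.to_tsv(outdir / "design.tsv")
    if sim is not None:
        write_panel_tsv(sim["panel_a"], outdir / "panel_a.tsv")
        write_panel_tsv(sim["panel_b"], outdir / "panel_b.tsv")
        write_gtf(sim["transcript_models"], outdir / "transcripts.gtf")
        write_alignments_tsv(sim["alignments"], outdir / "alignments.tsv")
    bundle.join.per_label_summary.to_csv(outdir / "coverage_summary.tsv", sep="\t")
    for cond, res in bundle.de_seq.items():
        res.to_tsv(outdir / f"de_seq_{cond}.tsv")
    for cond, res in bundle.de_array.items():
        res.to_tsv(outdir / f"de_array_{cond}.tsv")
    bundle.concord_records.to_csv(outdir / "concord_records.tsv", sep="\t")
    pd.Series(vars(bundle.concord_summary)).to_csv(
        outdir / "concord_summary.tsv", sep="\t", header=False
    )
    bundle.qpcr.to_tsv(outdir / "qpcr_results.tsv")
    bundle.geneset_assignment.to_csv(outdir / "genesets.tsv", sep="\t")
    bundle.validation_records.to_csv(outdir / "validation_records.tsv", sep="\t", na_rep="NA")
    bundle.validation_summary.to_tsv(outdir / "validation_summary.tsv")
    bundle.pca_seq.scores.to_csv(outdir / "pca_seq.tsv", sep="\t")
    bundle.pca_array.scores.to_csv(outdir / "pca_array.tsv", sep="\t")
    pd.DataFrame(
        {"outlier_seq": bundle.outliers_seq, "outlier_array": bundle.outliers_array}
    ).to_csv(outdir / "outliers.tsv", sep="\t")
    bundle.heatmap_matrix[bundle.heatmap_order].to_csv(outdir / "dose_heatmap.tsv", sep="\t")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)
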