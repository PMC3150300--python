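"""End-to-end pipeline: annotate -> cluster -> quantify -> correlate ->
classify -> star -> tss, with TSV/figure outputs and a machine-readable
summary."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns
import yaml

from . import annotation as ann
from . import correlation as corr
from . import expression as expr
from . import star_analysis as star
from . import tss_analysis as tss

log = logging.getLogger("mircluster")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    annotation_path: str
    fasta_path: str | None = None
    counts_path: str | None = None
    library_paths: dict[str, str] = field(default_factory=dict)  # id -> FASTA/FASTQ
    tss_path: str | None = None
    output_dir: str = "mircluster_out"
    # thresholds
    max_gap: int = 1000
    hi: float = 0.6
    lo: float = 0.3
    split_threshold: float = 0.6
    min_total_count: int = 50
    window: int = 5000
    prefix_len: int = 18
    ecdf_cap: int = 100_000
    relfreq_scale: float = 1e6
    # modes
    both_strands: bool = False
    same_strand_clustering: bool = True
    use_profile: str = "relfreq"  # relfreq | log
    refine_by_correlation: bool = True
    skip_tss: bool = False
    render_figures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError(f"hi ({self.hi}) must exceed lo ({self.lo})")
        for name in ("max_gap", "window", "prefix_len", "ecdf_cap", "min_total_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages, writing tables, figures, and summary.json.

    Stage failures raise :class:`StageError` naming the stage; outputs of
    completed stages are retained in the run directory.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": []}

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - report stage and re-raise
                log.error("stage %s failed: %s", name, exc)
                raise StageError(name, exc) from exc
            summary["stages"].append(name)
            return result
        return deco

    @stage("annotate")
    def genes():
        g = ann.load_annotation(config.annotation_path, config.fasta_path)
        log.info("annotate: %d genes", len(g))
        return g

    gene_map = {g.gene_id: g for g in genes}

    @stage("cluster")
    def clustering():
        res = ann.build_clusters(
            genes, max_gap=config.max_gap, same_strand=config.same_strand_clustering
        )
        res.clusters = [
            ann.collapse_paralogs_within_cluster(c, gene_map) for c in res.clusters
        ]
        log.info(
            "cluster: %d clusters (%d excluded), %d non-clustered",
            len(res.clusters), sum(c.excluded for c in res.clusters),
            len(res.nonclustered),
        )
        ann.write_cluster_table(res, outdir / "clusters.tsv")
        return res

    @stage("quantify")
    def matrix():
        pool = expr.paralog_pool_map(genes)
        if config.counts_path:
            m = expr.load_count_table(config.counts_path)
            m = expr.pool_rows(m, pool)
        elif config.library_paths:
            arms = [a for g in genes for a in g.arms]
            assignments = {}
            for lib, path in config.library_paths.items():
                res = expr.assign_reads(
                    expr.read_library_fasta(path), arms,
                    prefix_len=config.prefix_len, pool=pool,
                )
                log.info(
                    "quantify %s: %d assigned, %d ambiguous, %d skipped of %d",
                    lib, res.assigned, res.ambiguous, res.skipped, res.total,
                )
                assignments[lib] = res
            m = expr.counts_from_assignments(assignments)
        else:
            raise ValueError("neither counts_path nor library_paths provided")
        expr.counts_to_relfreq(m, scale=config.relfreq_scale)
        expr.zscore_rows(m)
        expr.write_matrix_sheets(m, outdir / "expression")
        return m

    @stage("correlate")
    def report():
        rep = corr.pairwise_pearson(matrix, use=config.use_profile)
        return rep

    @stage("refine")
    def refined_clusters():
        if not config.refine_by_correlation:
            return clustering.clusters
        out = []
        for c in clustering.clusters:
            if c.excluded:
                out.append(c)
            else:
                out.extend(
                    ann.refine_clusters_by_correlation(
                        c, report, gene_map, split_threshold=config.split_threshold
                    )
                )
        return out

    @stage("categorize")
    def _categorize():
        corr.categorize_pairs(report, refined_clusters, clustering.nonclustered, genes)
        try:
            corr.compare_groups(report, corr.CATEGORY_SAME, corr.CATEGORY_DIFF)
        except corr.CorrelationError as exc:
            log.warning("group comparison skipped: %s", exc)
        corr.r_histograms(report)
        corr.write_pair_table(report, outdir / "pairs.tsv")
        corr.write_histogram_table(report.histograms, outdir / "r_histograms.tsv")
        return report

    @stage("classify")
    def classifications():
        totals = {
            g.gene_id: int(matrix.counts.loc[g.mir_arm.arm_id].sum())
            for g in genes
            if g.mir_arm.arm_id in matrix.counts.index
        }
        out = [
            corr.classify_cluster(
                c, report, gene_map, hi=config.hi, lo=config.lo,
                min_total_count=config.min_total_count, totals=totals,
            )
            for c in refined_clusters
        ]
        corr.write_classification_table(out, outdir / "classification.tsv")
        return out

    @stage("star")
    def star_report():
        rep = star.star_correlations(
            matrix, refined_clusters, gene_map, min_total_count=config.min_total_count
        )
        star.flag_regulation(
            rep, classifications, hi=config.hi, lo=config.lo
        )
        star.write_star_tables(rep, matrix, refined_clusters, gene_map,
                               outdir / "star")
        return rep

    tss_summary = None
    if config.tss_path and not config.skip_tss:
        @stage("tss")
        def assessment():
            tss_list = tss.load_tss_bed(config.tss_path)
            a = tss.assess_clusters(
                [c for c in refined_clusters if not c.excluded], genes, tss_list,
                window=config.window, cap=config.ecdf_cap,
                both_strands=config.both_strands,
            )
            tss.write_tss_tables(a, outdir)
            return a
        tss_summary = {
            "mean_P": assessment.mean_P,
            "median_P": assessment.median_P,
            "clusters_without_upstream_tss": sorted(
                cid for cid, hits in assessment.upstream.items() if not hits
            ),
            "clusters_with_intra_tss": sorted(
                cid for cid, per in assessment.intra.items()
                if any(per.values())
            ),
        }

    if config.render_figures:
        @stage("figures")
        def _figures():
            render_heatmaps(matrix, refined_clusters, gene_map, outdir / "heatmaps")

    summary.update(
        {
            "n_genes": len(genes),
            "n_clusters": len(refined_clusters),
            "n_excluded_clusters": sum(c.excluded for c in refined_clusters),
            "n_nonclustered": len(clustering.nonclustered),
            "classification": {
                c.cluster_id: {
                    "status": c.status,
                    "uncorrelated_members": c.uncorrelated_members,
                }
                for c in classifications
            },
            "regulation_flags": {
                rec.gene_id: rec.flag
                for rec in star_report.records.values()
                if rec.flag != star.FLAG_NONE
            },
            "group_test": (
                {"t": report.group_test[0], "p": report.group_test[1]}
                if report.group_test else None
            ),
            "tss": tss_summary,
            "config": asdict(config),
        }
    )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_report_text(summary, outdir / "report.txt")
    return outdir


def _write_report_text(summary: dict, path: Path) -> None:
    lines = [
        "mircluster run report",
        "=====================",
        f"genes: {summary['n_genes']}  clusters: {summary['n_clusters']} "
        f"({summary['n_excluded_clusters']} excluded)  "
        f"non-clustered: {summary['n_nonclustered']}",
        "",
        "cluster classification:",
    ]
    for cid, info in sorted(summary["classification"].items()):
        extra = (
            f"  uncorrelated: {', '.join(info['uncorrelated_members'])}"
            if info["uncorrelated_members"] else ""
        )
        lines.append(f"  {cid}: {info['status']}{extra}")
    if summary.get("group_test"):
        gt = summary["group_test"]
        lines.append(
            f"\nsame-cluster vs different-cluster r (Welch t-test): "
            f"t = {gt['t']:.2f}, p = {gt['p']:.3g}"
        )
    if summary.get("regulation_flags"):
        lines.append("\npost-transcriptional regulation flags:")
        for gid, flag in sorted(summary["regulation_flags"].items()):
            lines.append(f"  {gid}: {flag}")
    if summary.get("tss"):
        t = summary["tss"]
        lines.append(
            f"\nTSS gap probabilities: mean P = {t['mean_P']:.3f}, "
            f"median P = {t['median_P']:.3f}"
        )
        if t["clusters_with_intra_tss"]:
            lines.append(
                "  clusters with intra-cluster TSS: "
                + ", ".join(t["clusters_with_intra_tss"])
            )
    path.write_text("\n".join(lines) + "\n")


def render_heatmaps(
    matrix: "expr.ExpressionMatrix",
    clusters: Sequence["ann.Cluster"],
    genes,
    outdir: str | Path,
) -> list[Path]:
    """Per-cluster heatmaps of row-z-scored profiles: miRs on top, stars below."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if matrix.zscores is None:
        expr.zscore_rows(matrix)
    z = matrix.zscores
    written = []
    for c in clusters:
        if c.excluded:
            continue
        mir_rows = [
            genes[g].mir_arm.arm_id for g in c.members
            if genes[g].mir_arm.arm_id in z.index
        ]
        star_rows = [
            genes[g].star_arm.arm_id for g in c.members
            if genes[g].star_arm and genes[g].star_arm.arm_id in z.index
        ]
        rows = mir_rows + star_rows
        if not rows:
            continue
        fig, ax = plt.subplots(
            figsize=(1.2 + 0.5 * z.shape[1], 1.0 + 0.4 * len(rows))
        )
        sns.heatmap(
            z.loc[rows], cmap="RdBu_r", center=0, ax=ax,
            cbar_kws={"label": "row z-score"},
        )
        ax.set_title(c.cluster_id)
        path = outdir / f"{c.cluster_id.replace('/', '_')}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
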