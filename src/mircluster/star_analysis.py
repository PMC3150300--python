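"""miR / miR* profile comparison and post-transcriptional regulation flags.

Both arms of a hairpin come from the same primary transcript, so under purely
transcriptional control their tissue profiles should agree.  Three discordance
patterns are flagged per gene:

``mir_level_regulation``
    The miR decouples from its cluster AND from its own star, while the star
    still tracks the other members — the mature miR's stability (or arm
    selection) is modulated after transcription.
``star_level_regulation``
    The miR stays coordinated but its star correlates with neither its own
    miR nor the other members — the star product is independently regulated.
``hairpin_level_regulation``
    miR and star track each other tightly but both drift from the rest of the
    cluster — the whole hairpin's processing or stability is modulated
    (the let-7/Lin28-style pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Cluster, MiRNAGene
from .correlation import ClusterClassification, UNCOORDINATED
from .expression import ExpressionMatrix, counts_to_relfreq

FLAG_MIR = "mir_level_regulation"
FLAG_STAR = "star_level_regulation"
FLAG_HAIRPIN = "hairpin_level_regulation"
FLAG_NONE = "none"
FLAGS = (FLAG_MIR, FLAG_STAR, FLAG_HAIRPIN, FLAG_NONE)


@dataclass
class GeneStarRecord:
    gene_id: str
    cluster_id: str
    r_mir_star: float | None
    r_star_vs_others: dict[str, float] = field(default_factory=dict)
    r_mir_vs_others: dict[str, float] = field(default_factory=dict)
    flag: str = FLAG_NONE
    reason: str = ""


@dataclass
class StarReport:
    records: dict[str, GeneStarRecord] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)  # gene -> why

    def frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records.values():
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "cluster_id": rec.cluster_id,
                    "r_mir_star": rec.r_mir_star,
                    "r_star_vs_others": ";".join(
                        f"{k}={v:.3f}" for k, v in rec.r_star_vs_others.items()
                    ),
                    "flag": rec.flag,
                    "reason": rec.reason,
                }
            )
        return pd.DataFrame(rows)


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if np.std(x, ddof=1) == 0 or np.std(y, ddof=1) == 0:
        return None
    return float(stats.pearsonr(x, y)[0])


def star_correlations(
    matrix: ExpressionMatrix,
    clusters: Sequence[Cluster],
    genes: Mapping[str, MiRNAGene],
    min_total_count: int = 50,
) -> StarReport:
    """Correlate each clustered gene's miR and miR* relfreq profiles.

    Genes lacking an annotated/detected star arm, or whose star's summed raw
    counts fall under ``min_total_count``, are excluded with a reason.
    Zero-variance profiles yield undefined (None) r values, flagged in the
    record's reason.
    """
    if matrix.relfreq is None:
        counts_to_relfreq(matrix)
    rf = matrix.relfreq
    totals = matrix.counts.sum(axis=1)
    report = StarReport()
    for cluster in clusters:
        if cluster.excluded:
            continue
        for gid in cluster.members:
            g = genes[gid]
            if g.star_arm is None:
                report.excluded[gid] = "no annotated star arm"
                continue
            star_id = g.star_arm.arm_id
            if star_id not in rf.index or g.mir_arm.arm_id not in rf.index:
                report.excluded[gid] = "arm absent from expression matrix"
                continue
            if totals.get(star_id, 0) < min_total_count:
                report.excluded[gid] = (
                    f"star counts {int(totals.get(star_id, 0))} < {min_total_count}"
                )
                continue
            star = rf.loc[star_id].to_numpy()
            mir = rf.loc[g.mir_arm.arm_id].to_numpy()
            rec = GeneStarRecord(
                gene_id=gid,
                cluster_id=cluster.cluster_id,
                r_mir_star=_pearson(mir, star),
            )
            if rec.r_mir_star is None:
                rec.reason = "zero-variance profile"
            for other in cluster.members:
                if other == gid:
                    continue
                other_mir = rf.loc[genes[other].mir_arm.arm_id].to_numpy()
                r_s = _pearson(star, other_mir)
                r_m = _pearson(mir, other_mir)
                if r_s is not None:
                    rec.r_star_vs_others[other] = r_s
                if r_m is not None:
                    rec.r_mir_vs_others[other] = r_m
            report.records[gid] = rec
    return report


def flag_regulation(
    star_report: StarReport,
    classifications: Mapping[str, ClusterClassification] | Sequence[ClusterClassification],
    hi: float = 0.6,
    lo: float = 0.3,
    hairpin_band: float = 0.6,
) -> StarReport:
    """Assign exactly one regulation flag per gene from its r pattern.

    The three flag conditions are mutually exclusive by construction
    (mir/star level require r_mir_star < ``lo``, hairpin requires > ``hi``;
    mir vs star level differ on the gene's uncorrelated-member status).
    The hairpin "both arms vs other members" band uses ``hairpin_band``
    (default 0.6) rather than ``lo``: the canonical let-7 pattern sits in the
    0.27-0.53 range, a softer drift than a full decorrelation.
    """
    if not isinstance(classifications, Mapping):
        classifications = {c.cluster_id: c for c in classifications}
    for rec in star_report.records.values():
        cls = classifications.get(rec.cluster_id)
        rec.flag, rec.reason = _flag_one(rec, cls, hi, lo, hairpin_band)
    return star_report


def _flag_one(
    rec: GeneStarRecord,
    cls: ClusterClassification | None,
    hi: float,
    lo: float,
    hairpin_band: float,
) -> tuple[str, str]:
    if rec.r_mir_star is None:
        return FLAG_NONE, "undefined miR/miR* correlation"
    if not rec.r_star_vs_others:
        return FLAG_NONE, "no defined star-vs-member correlations"
    if cls is None:
        return FLAG_NONE, "no classification for cluster"
    uncorr = (
        cls.status == UNCOORDINATED and rec.gene_id in cls.uncorrelated_members
    )
    svo = list(rec.r_star_vs_others.values())
    mvo = list(rec.r_mir_vs_others.values())
    if uncorr and rec.r_mir_star < lo and max(svo) > hi:
        return FLAG_MIR, (
            "miR decoupled from cluster and own star; star tracks other members"
        )
    if not uncorr and rec.r_mir_star < lo and max(svo) < lo:
        return FLAG_STAR, (
            "miR coordinated; star correlates with neither own miR nor members"
        )
    if (
        rec.r_mir_star > hi
        and mvo
        and max(mvo) < hairpin_band
        and max(svo) < hairpin_band
    ):
        return FLAG_HAIRPIN, (
            "miR and star track each other but both drift from other members"
        )
    return FLAG_NONE, ""


def write_star_tables(
    star_report: StarReport,
    matrix: ExpressionMatrix,
    clusters: Sequence[Cluster],
    genes: Mapping[str, MiRNAGene],
    outdir: str | Path,
) -> list[Path]:
    """Per-cluster miR/miR* correlation tables (miRs on top, stars below)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if matrix.relfreq is None:
        counts_to_relfreq(matrix)
    rf = matrix.relfreq
    written = []
    for cluster in clusters:
        if cluster.excluded:
            continue
        mir_rows = [genes[g].mir_arm.arm_id for g in cluster.members]
        star_rows = [
            genes[g].star_arm.arm_id
            for g in cluster.members
            if genes[g].star_arm and genes[g].star_arm.arm_id in rf.index
        ]
        rows = [a for a in mir_rows if a in rf.index] + star_rows
        if len(rows) < 2:
            continue
        sub = rf.loc[rows]
        corr = sub.T.corr(method="pearson")
        path = outdir / f"{cluster.cluster_id.replace('/', '_')}.star_corr.tsv"
        corr.to_csv(path, sep="\t", index_label="arm_id", float_format="%.3f")
        written.append(path)
    summary = outdir / "star_flags.tsv"
    star_report.frame().to_csv(summary, sep="\t", index=False)
    written.append(summary)
    return written
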