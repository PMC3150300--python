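"""Pairwise expression correlation and cluster coordination classification.

Profiles are per-library relative frequencies.  Pairwise Pearson r across
libraries drives three analyses: the four-way pair-category comparison
(same-cluster vs different-cluster vs non-clustered pairs), a Welch t-test
between category r distributions, and the per-cluster classification into
coordinated (all pairwise r above the high threshold), uncoordinated (one
member decorrelated from an otherwise coherent rest), or indeterminate.

Thresholds default to the field's working values: r > 0.6 for coherence,
r < 0.3 for decorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Cluster, MiRNAGene
from .expression import ExpressionMatrix, counts_to_relfreq

CATEGORY_SAME = "cl.vs.cl.same"
CATEGORY_DIFF = "cl.vs.cl.diff"
CATEGORY_CL_NCL = "cl.vs.n-cl"
CATEGORY_NCL_NCL = "n-cl.vs.n-cl"
CATEGORIES = (CATEGORY_SAME, CATEGORY_DIFF, CATEGORY_CL_NCL, CATEGORY_NCL_NCL)

COORDINATED = "coordinated"
UNCOORDINATED = "uncoordinated"
EXCLUDED = "excluded"
INDETERMINATE = "indeterminate"


class CorrelationError(ValueError):
    pass


@dataclass
class Histogram:
    edges: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray  # counts / max(counts); max bin == 1 when nonempty


@dataclass
class CorrelationReport:
    """All pairwise Pearson r values with categories and derived summaries."""

    arm_ids: list[str]
    n_libraries: int
    flagged_rows: list[str] = field(default_factory=list)  # zero-variance arms
    group_test: tuple | None = None
    histograms: dict[str, Histogram] | None = None
    _r: dict[frozenset, float] = field(default_factory=dict, repr=False)
    _category: dict[frozenset, str | None] = field(default_factory=dict, repr=False)

    def r(self, a: str, b: str) -> float | None:
        """Pearson r for an unordered pair, or None if undefined/absent."""
        return self._r.get(frozenset((a, b)))

    def category(self, a: str, b: str) -> str | None:
        return self._category.get(frozenset((a, b)))

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for a, b in combinations(self.arm_ids, 2):
            if frozenset((a, b)) not in self._r:
                out.append((a, b))
        return out

    def pairs_frame(self) -> pd.DataFrame:
        rows = []
        for a, b in combinations(self.arm_ids, 2):
            key = frozenset((a, b))
            rows.append(
                {
                    "arm_a": a,
                    "arm_b": b,
                    "r": self._r.get(key, np.nan),
                    "n": self.n_libraries,
                    "category": self._category.get(key),
                }
            )
        return pd.DataFrame(rows)

    def category_values(self, category: str) -> list[float]:
        return [
            r
            for key, r in self._r.items()
            if self._category.get(key) == category
        ]


@dataclass
class ClusterClassification:
    cluster_id: str
    status: str
    uncorrelated_members: list[str] = field(default_factory=list)
    min_pairwise_r: float | None = None
    details: list[tuple[str, str, float]] = field(default_factory=list)
    low_expression_members: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.status == UNCOORDINATED) != bool(self.uncorrelated_members):
            raise CorrelationError(
                f"cluster {self.cluster_id}: uncorrelated_members must be "
                f"nonempty iff status is {UNCOORDINATED}"
            )


def pairwise_pearson(
    matrix: ExpressionMatrix, use: str = "relfreq"
) -> CorrelationReport:
    """Pearson product-moment r for every arm pair across libraries.

    ``use`` selects the profile: "relfreq" (default; computed on demand),
    "counts", or "log" (log10 of relfreq plus a 1-count-equivalent
    pseudocount).  Requires >=3 libraries.  Zero-variance rows are excluded
    with a flag; their pairs are left undefined.
    """
    if matrix.counts.shape[1] < 3:
        raise CorrelationError(
            f"need >=3 libraries for correlation, got {matrix.counts.shape[1]}"
        )
    if use == "counts":
        data = matrix.counts.astype(float)
    else:
        if matrix.relfreq is None:
            counts_to_relfreq(matrix)
        data = matrix.relfreq
        if use == "log":
            pseudo = matrix.scale / matrix.counts.sum(axis=0).mean()
            data = np.log10(data + pseudo)
        elif use != "relfreq":
            raise CorrelationError(f"unknown profile selector {use!r}")

    arm_ids = list(data.index)
    values = data.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    ok = sd > 0
    report = CorrelationReport(
        arm_ids=arm_ids,
        n_libraries=values.shape[1],
        flagged_rows=[a for a, good in zip(arm_ids, ok) if not good],
    )
    idx = np.flatnonzero(ok)
    if len(idx) >= 2:
        cm = np.corrcoef(values[idx])
        for i, j in combinations(range(len(idx)), 2):
            a, b = arm_ids[idx[i]], arm_ids[idx[j]]
            report._r[frozenset((a, b))] = float(cm[i, j])
    return report


def categorize_pairs(
    report: CorrelationReport,
    clusters: Sequence[Cluster],
    nonclustered_ids: Sequence[str],
    genes: Sequence[MiRNAGene] | None = None,
) -> CorrelationReport:
    """Label every miR-miR pair with one of the four pair categories.

    Star arms are excluded from this categorization (it concerns mature miRs
    only).  Members of clusters marked ``excluded`` are skipped.  A miR arm
    resolving to a gene in neither a cluster nor the non-clustered set is an
    error.
    """
    mir_of_gene: dict[str, str] = {}
    if genes is not None:
        mir_of_gene = {g.gene_id: g.mir_arm.arm_id for g in genes}

    cluster_of: dict[str, str | None] = {}
    for c in clusters:
        for gid in c.members:
            arm = mir_of_gene.get(gid, gid)
            cluster_of[arm] = None if c.excluded else c.cluster_id
    for gid in nonclustered_ids:
        arm = mir_of_gene.get(gid, gid)
        cluster_of[arm] = "n-cl"

    mir_arms = {g.mir_arm.arm_id for g in genes} if genes is not None else None

    def is_mir(arm: str) -> bool:
        if mir_arms is not None:
            return arm in mir_arms
        return not arm.endswith("*")

    for key in report._r:
        a, b = tuple(key)
        if not (is_mir(a) and is_mir(b)):
            report._category[key] = None
            continue
        try:
            ca, cb = cluster_of[a], cluster_of[b]
        except KeyError as exc:
            raise CorrelationError(f"unknown gene for arm {exc.args[0]!r}") from None
        if ca is None or cb is None:  # excluded cluster
            report._category[key] = None
        elif ca == "n-cl" and cb == "n-cl":
            report._category[key] = CATEGORY_NCL_NCL
        elif ca == "n-cl" or cb == "n-cl":
            report._category[key] = CATEGORY_CL_NCL
        elif ca == cb:
            report._category[key] = CATEGORY_SAME
        else:
            report._category[key] = CATEGORY_DIFF
    return report


def compare_groups(
    report: CorrelationReport, group_a: str, group_b: str
) -> tuple[float, float]:
    """Welch two-sample two-sided t-test between two categories' r values."""
    a = report.category_values(group_a)
    b = report.category_values(group_b)
    if len(a) < 2 or len(b) < 2:
        raise CorrelationError(
            f"need >=2 r values per group ({group_a}: {len(a)}, {group_b}: {len(b)})"
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    report.group_test = (float(t), float(p), (group_a, group_b))
    return float(t), float(p)


def r_histograms(
    report: CorrelationReport, bin_width: float = 0.1
) -> dict[str, Histogram]:
    """Per-category r histograms over [-1, 1], each normalized to its max bin."""
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 10)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    out: dict[str, Histogram] = {}
    for cat in CATEGORIES:
        values = report.category_values(cat)
        if not values:
            warnings.warn(f"no pairs in category {cat}; empty histogram")
            out[cat] = Histogram(edges=edges, counts=np.zeros(len(edges) - 1, dtype=int),
                                 normalized=np.zeros(len(edges) - 1))
            continue
        counts, _ = np.histogram(values, bins=edges)
        out[cat] = Histogram(
            edges=edges, counts=counts, normalized=counts / counts.max()
        )
    report.histograms = out
    return out


def classify_cluster(
    cluster: Cluster,
    report: CorrelationReport,
    genes: Mapping[str, MiRNAGene] | None = None,
    hi: float = 0.6,
    lo: float = 0.3,
    min_total_count: int = 50,
    totals: Mapping[str, float] | None = None,
) -> ClusterClassification:
    """Classify one cluster as coordinated, uncoordinated, or indeterminate.

    coordinated: every member-pair r > ``hi``.  A member g is *uncorrelated*
    when r(g, m) < ``lo`` against every other member m and the remaining
    members are pairwise r > ``hi`` among themselves; any such member makes
    the cluster uncoordinated.  A two-member cluster with r < ``lo`` is
    uncoordinated with both members listed as mutually uncorrelated.
    Intermediate patterns are reported as indeterminate with the full r table.

    ``totals`` (summed raw counts per gene's miR arm, keyed by gene id)
    activates the low-expression guard: members under ``min_total_count`` are
    set aside before classification, encoding the requirement that
    decorrelation calls rest on sufficiently expressed profiles.
    """
    if cluster.excluded:
        return ClusterClassification(cluster.cluster_id, EXCLUDED,
                                     notes=["paralog-degenerate cluster"])

    arm_of = {gid: genes[gid].mir_arm.arm_id for gid in cluster.members} \
        if genes else {gid: gid for gid in cluster.members}

    low = []
    members = []
    for gid in cluster.members:
        if totals is not None and totals.get(gid, 0) < min_total_count:
            low.append(gid)
        else:
            members.append(gid)

    notes = []
    if len(members) < 2:
        return ClusterClassification(
            cluster.cluster_id, INDETERMINATE, low_expression_members=low,
            notes=["fewer than 2 members above the expression threshold"],
        )

    r: dict[tuple[str, str], float] = {}
    for a, b in combinations(members, 2):
        val = report.r(arm_of[a], arm_of[b])
        if val is None:
            return ClusterClassification(
                cluster.cluster_id, INDETERMINATE, low_expression_members=low,
                notes=[f"undefined correlation for pair ({a}, {b})"],
            )
        r[(a, b)] = r[(b, a)] = val

    details = [(a, b, r[(a, b)]) for a, b in combinations(members, 2)]
    min_r = min(v for _, _, v in details)

    if genes is not None:
        for gid in members:
            g = genes[gid]
            group_mates = [
                h.gene_id for h in genes.values()
                if h.paralog_group == g.paralog_group and h.gene_id != gid
            ]
            external = [m for m in group_mates if m not in cluster.members]
            if external:
                notes.append(
                    f"{gid} has identical extra-cluster paralog(s) "
                    f"{','.join(external)}; its profile superposes theirs"
                )

    if all(v > hi for v in r.values()):
        return ClusterClassification(
            cluster.cluster_id, COORDINATED, min_pairwise_r=min_r,
            details=details, low_expression_members=low, notes=notes,
        )

    if len(members) == 2:
        a, b = members
        if r[(a, b)] < lo:
            return ClusterClassification(
                cluster.cluster_id, UNCOORDINATED,
                uncorrelated_members=[a, b], min_pairwise_r=min_r,
                details=details, low_expression_members=low,
                notes=notes + ["two-member cluster: members mutually uncorrelated"],
            )
        return ClusterClassification(
            cluster.cluster_id, INDETERMINATE, min_pairwise_r=min_r,
            details=details, low_expression_members=low, notes=notes,
        )

    uncorrelated = []
    for gid in members:
        rest = [m for m in members if m != gid]
        decoupled = all(r[(gid, m)] < lo for m in rest)
        rest_coherent = all(r[(a, b)] > hi for a, b in combinations(rest, 2))
        if decoupled and rest_coherent:
            uncorrelated.append(gid)

    if uncorrelated:
        return ClusterClassification(
            cluster.cluster_id, UNCOORDINATED,
            uncorrelated_members=uncorrelated, min_pairwise_r=min_r,
            details=details, low_expression_members=low, notes=notes,
        )
    return ClusterClassification(
        cluster.cluster_id, INDETERMINATE, min_pairwise_r=min_r,
        details=details, low_expression_members=low, notes=notes,
    )


# ---------------------------------------------------------------------------
# Writers

def write_pair_table(report: CorrelationReport, path: str | Path) -> None:
    report.pairs_frame().to_csv(path, sep="\t", index=False)


def write_classification_table(
    classifications: Sequence[ClusterClassification], path: str | Path
) -> None:
    rows = [
        {
            "cluster_id": c.cluster_id,
            "status": c.status,
            "uncorrelated_members": ",".join(c.uncorrelated_members),
            "min_pairwise_r": c.min_pairwise_r,
            "low_expression_members": ",".join(c.low_expression_members),
            "notes": "; ".join(c.notes),
        }
        for c in classifications
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_histogram_table(
    histograms: Mapping[str, Histogram], path: str | Path
) -> None:
    rows = []
    for cat, h in histograms.items():
        for lo_edge, hi_edge, count, norm in zip(
            h.edges[:-1], h.edges[1:], h.counts, h.normalized
        ):
            rows.append(
                {"category": cat, "bin_lo": lo_edge, "bin_hi": hi_edge,
                 "count": int(count), "normalized": float(norm)}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
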