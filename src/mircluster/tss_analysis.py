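"""Predicted TSS placement relative to miRNA clusters, and gap probabilities.

If a cluster is one transcription unit, its promoter should sit upstream of
the first hairpin and the inter-hairpin gaps should be promoter-free.  Whether
an *absent* intra-cluster TSS is informative depends on how likely a TSS is in
a span that short: with F the empirical CDF of nearest-upstream-TSS distances
over all miRNA genes, the probability of finding a TSS within a gap of length
x is taken as P = F(x).  Small mean P / zero median P means the missing
internal TSSs are statistically unsurprising.

TSS positions are consumed as a strand-annotated BED track produced by an
external promoter predictor; only sense-strand TSSs count by default.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.distributions.empirical_distribution import ECDF

from .annotation import Cluster, MiRNAGene


class TSSError(ValueError):
    pass


@dataclass(frozen=True)
class TSS:
    chrom: str
    position: int  # 0-based
    strand: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise TSSError(f"negative TSS position {self.position}")
        if self.strand not in ("+", "-", "."):
            raise TSSError(f"bad TSS strand {self.strand!r}")


@dataclass
class EcdfResult:
    """Right-continuous ECDF of nearest-upstream-TSS distances."""

    ecdf: Callable[[float], float]
    distances: np.ndarray
    n_genes: int
    n_without_tss: int  # genes with no upstream TSS within the cap

    def __call__(self, x: float) -> float:
        return float(self.ecdf(x))


@dataclass
class TSSAssessment:
    upstream: dict[str, list[tuple[TSS, int]]] = field(default_factory=dict)
    intra: dict[str, dict[str, list[TSS]]] = field(default_factory=dict)
    gap_table: pd.DataFrame | None = None
    mean_P: float | None = None
    median_P: float | None = None


def load_tss_bed(path: str | Path, require_strand: bool = True) -> list[TSS]:
    """Read TSS positions from BED (position = start), sorted per chromosome."""
    out: list[TSS] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 6 or cols[5] not in ("+", "-"):
                if require_strand:
                    raise TSSError(
                        f"{path}:{lineno}: missing strand column "
                        "(use require_strand=False for unstranded tracks)"
                    )
                strand = "."
            else:
                strand = cols[5]
            try:
                pos = int(cols[1])
            except ValueError:
                raise TSSError(f"{path}:{lineno}: non-integer start") from None
            score = None
            if len(cols) >= 5 and cols[4] not in (".", ""):
                try:
                    score = float(cols[4])
                except ValueError:
                    score = None
            out.append(TSS(chrom=cols[0], position=pos, strand=strand, score=score))
    out.sort(key=lambda t: (t.chrom, t.position, t.strand))
    return out


def write_tss_bed(tss_list: Sequence[TSS], path: str | Path) -> None:
    lines = [
        "\t".join(
            [
                t.chrom, str(t.position), str(t.position + 1), "tss",
                "." if t.score is None else repr(t.score), t.strand,
            ]
        )
        for t in sorted(tss_list, key=lambda t: (t.chrom, t.position, t.strand))
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _index_by_chrom(tss_list: Sequence[TSS]) -> dict[str, tuple[list[int], list[TSS]]]:
    by: dict[str, list[TSS]] = {}
    for t in tss_list:
        by.setdefault(t.chrom, []).append(t)
    out = {}
    for chrom, items in by.items():
        items.sort(key=lambda t: t.position)
        out[chrom] = ([t.position for t in items], items)
    return out


def _strand_ok(t: TSS, strand: str, both_strands: bool) -> bool:
    return both_strands or t.strand == strand or t.strand == "."


def _upstream_hits(
    chrom: str,
    strand: str,
    five_prime: int,
    window: int,
    index: Mapping[str, tuple[list[int], list[TSS]]],
    both_strands: bool,
) -> list[tuple[TSS, int]]:
    """TSSs within ``window`` nt upstream of a 5' anchor; distance >= 1."""
    if chrom not in index:
        return []
    positions, items = index[chrom]
    if strand == "+":
        lo, hi = five_prime - window, five_prime  # positions in [lo, hi)
    else:
        lo, hi = five_prime + 1, five_prime + 1 + window
    i0, i1 = bisect_left(positions, lo), bisect_left(positions, hi)
    hits = []
    for t in items[i0:i1]:
        if _strand_ok(t, strand, both_strands):
            dist = five_prime - t.position if strand == "+" else t.position - five_prime
            hits.append((t, dist))
    hits.sort(key=lambda pair: pair[1])
    return hits


def upstream_tss_for_cluster(
    cluster: Cluster,
    tss_list: Sequence[TSS],
    genes: Mapping[str, MiRNAGene],
    window: int = 5000,
    both_strands: bool = False,
) -> list[tuple[TSS, int]]:
    """Sense-strand TSSs within ``window`` nt upstream of the first precursor.

    "First" is in transcription order; distance is the strand-aware offset to
    the first precursor's 5' start.  An empty result is valid (some clusters
    have no nearby predicted TSS).
    """
    first = genes[cluster.transcription_order()[0]]
    index = _index_by_chrom(tss_list)
    return _upstream_hits(
        cluster.chrom, cluster.strand, first.five_prime, window, index, both_strands
    )


def intra_cluster_tss(
    cluster: Cluster,
    tss_list: Sequence[TSS],
    genes: Mapping[str, MiRNAGene],
    both_strands: bool = False,
) -> dict[str, list[TSS]]:
    """TSSs inside the inter-precursor gap upstream of each internal member.

    The gap between a member and its transcription-order predecessor is the
    only span whose TSS would imply independent transcription of that member;
    TSSs inside precursor bodies are not intra-gap calls.  Keys are internal
    member gene ids (every member except the transcription-first one).
    """
    order = cluster.transcription_order()
    index = _index_by_chrom(tss_list)
    out: dict[str, list[TSS]] = {}
    if cluster.chrom not in index:
        return {gid: [] for gid in order[1:]}
    positions, items = index[cluster.chrom]
    for prev_id, gid in zip(order, order[1:]):
        prev, g = genes[prev_id], genes[gid]
        if cluster.strand == "+":
            lo, hi = prev.precursor_end, g.precursor_start
        else:
            lo, hi = g.precursor_end, prev.precursor_start
        i0, i1 = bisect_left(positions, lo), bisect_left(positions, hi)
        out[gid] = [
            t for t in items[i0:i1] if _strand_ok(t, cluster.strand, both_strands)
        ]
    return out


def tss_distance_ecdf(
    all_genes: Sequence[MiRNAGene],
    tss_list: Sequence[TSS],
    cap: int = 100_000,
    both_strands: bool = False,
    min_n: int = 10,
) -> EcdfResult:
    """ECDF of distances from gene 5' starts to the nearest upstream TSS.

    Genes with no upstream TSS within ``cap`` are excluded and counted.
    The ECDF is right-continuous: F(x) = #(d <= x) / n.
    """
    index = _index_by_chrom(tss_list)
    distances = []
    missing = 0
    for g in all_genes:
        hits = _upstream_hits(
            g.chrom, g.strand, g.five_prime, cap, index, both_strands
        )
        if hits:
            distances.append(hits[0][1])
        else:
            missing += 1
    if len(distances) < min_n:
        raise TSSError(
            f"only {len(distances)} genes have an upstream TSS within {cap} nt "
            f"(need >= {min_n}); {missing} without"
        )
    arr = np.asarray(sorted(distances), dtype=float)
    return EcdfResult(
        ecdf=ECDF(arr, side="right"),
        distances=arr,
        n_genes=len(all_genes),
        n_without_tss=missing,
    )


def gap_probabilities(
    clusters: Sequence[Cluster], ecdf: EcdfResult
) -> TSSAssessment:
    """P = ecdf(x) for every inter-precursor gap length x, plus global summary."""
    rows = []
    for c in clusters:
        for i, x in enumerate(c.gaps):
            rows.append(
                {"cluster_id": c.cluster_id, "gap_index": i, "gap_nt": x,
                 "P": ecdf(x)}
            )
    table = pd.DataFrame(rows, columns=["cluster_id", "gap_index", "gap_nt", "P"])
    assessment = TSSAssessment(gap_table=table)
    if len(table):
        assessment.mean_P = float(table["P"].mean())
        assessment.median_P = float(table["P"].median())
    return assessment


def assess_clusters(
    clusters: Sequence[Cluster],
    all_genes: Sequence[MiRNAGene],
    tss_list: Sequence[TSS],
    window: int = 5000,
    cap: int = 100_000,
    both_strands: bool = False,
) -> TSSAssessment:
    """Full TSS assessment: upstream calls, intra-gap calls, gap probabilities."""
    gene_map = {g.gene_id: g for g in all_genes}
    ecdf = tss_distance_ecdf(all_genes, tss_list, cap=cap, both_strands=both_strands)
    assessment = gap_probabilities(clusters, ecdf)
    for c in clusters:
        assessment.upstream[c.cluster_id] = upstream_tss_for_cluster(
            c, tss_list, gene_map, window=window, both_strands=both_strands
        )
        assessment.intra[c.cluster_id] = intra_cluster_tss(
            c, tss_list, gene_map, both_strands=both_strands
        )
    return assessment


def write_tss_tables(assessment: TSSAssessment, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    up_rows = [
        {"cluster_id": cid, "tss_position": t.position, "tss_strand": t.strand,
         "distance_nt": d}
        for cid, hits in assessment.upstream.items()
        for t, d in hits
    ]
    intra_rows = [
        {"cluster_id": cid, "internal_member": gid, "tss_position": t.position,
         "tss_strand": t.strand}
        for cid, per_member in assessment.intra.items()
        for gid, hits in per_member.items()
        for t in hits
    ]
    paths = []
    for name, rows, cols in [
        ("tss_upstream.tsv", up_rows,
         ["cluster_id", "tss_position", "tss_strand", "distance_nt"]),
        ("tss_intra.tsv", intra_rows,
         ["cluster_id", "internal_member", "tss_position", "tss_strand"]),
    ]:
        p = outdir / name
        pd.DataFrame(rows, columns=cols).to_csv(p, sep="\t", index=False)
        paths.append(p)
    if assessment.gap_table is not None:
        p = outdir / "gap_probabilities.tsv"
        assessment.gap_table.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths
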