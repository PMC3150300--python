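"""miRNA gene annotation: loading, paralog grouping, and genomic cluster building.

A miRNA gene is an annotated hairpin precursor with one or two mature arm
products: the dominant miR and, when annotated and detected, the minor miR*
from the opposite arm.  Genes on the same chromosome and strand whose
precursors lie within ``max_gap`` (default 1 kb) of each other form a genomic
cluster, the presumed unit of polycistronic pri-miRNA transcription.

Coordinates are 0-based, half-open throughout.  GFF3 input (miRBase dialect:
``miRNA_primary_transcript`` parents with ``miRNA`` children) is converted from
its native 1-based inclusive convention on read; BED input is taken as-is.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from itertools import groupby
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .correlation import CorrelationReport

MIR = "miR"
STAR = "miR*"

_VALID_STRANDS = frozenset("+-")


class AnnotationError(ValueError):
    """Invalid annotation content (coordinates, structure, or sequences)."""


class AnnotationParseError(AnnotationError):
    """Malformed annotation file; message names the offending line."""


@dataclass
class ArmRecord:
    """One mature product (miR or miR*) excised from a hairpin arm."""

    arm_id: str
    start: int
    end: int
    sequence: str
    arm_role: str  # MIR or STAR

    def __post_init__(self) -> None:
        if self.arm_role not in (MIR, STAR):
            raise AnnotationError(
                f"arm {self.arm_id}: arm_role must be {MIR!r} or {STAR!r}, "
                f"got {self.arm_role!r}"
            )
        if not 0 <= self.start < self.end:
            raise AnnotationError(
                f"arm {self.arm_id}: invalid interval [{self.start}, {self.end})"
            )
        self.sequence = normalize_seq(self.sequence)
        if len(self.sequence) != self.end - self.start:
            raise AnnotationError(
                f"arm {self.arm_id}: sequence length {len(self.sequence)} != "
                f"interval length {self.end - self.start}"
            )
        if not 18 <= len(self.sequence) <= 26:
            raise AnnotationError(
                f"arm {self.arm_id}: mature length {len(self.sequence)} outside 18-26 nt"
            )


@dataclass
class MiRNAGene:
    """An annotated miRNA hairpin with its mature arm products.

    ``paralog_group`` labels genes whose mature miR sequences are identical
    (and therefore indistinguishable to sequencing); it is assigned by
    :func:`assign_paralog_groups`.
    """

    gene_id: str
    chrom: str
    strand: str
    precursor_start: int
    precursor_end: int
    mir_arm: ArmRecord
    star_arm: ArmRecord | None = None
    paralog_group: str = ""

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not 0 <= self.precursor_start < self.precursor_end:
            raise AnnotationError(
                f"gene {self.gene_id}: invalid precursor interval "
                f"[{self.precursor_start}, {self.precursor_end})"
            )
        for arm in self.arms:
            if arm.start < self.precursor_start or arm.end > self.precursor_end:
                raise AnnotationError(
                    f"gene {self.gene_id}: arm {arm.arm_id} "
                    f"[{arm.start}, {arm.end}) extends outside precursor "
                    f"[{self.precursor_start}, {self.precursor_end})"
                )
        if self.star_arm is not None:
            a, b = sorted(self.arms, key=lambda x: x.start)
            if a.end > b.start:
                raise AnnotationError(
                    f"gene {self.gene_id}: arm intervals overlap"
                )

    @property
    def arms(self) -> list[ArmRecord]:
        return [self.mir_arm] + ([self.star_arm] if self.star_arm else [])

    @property
    def five_prime(self) -> int:
        """Strand-aware 5' start coordinate of the precursor (0-based base)."""
        return self.precursor_start if self.strand == "+" else self.precursor_end - 1

    @property
    def short_name(self) -> str:
        return short_name(self.gene_id)


@dataclass
class Cluster:
    """An ordered run of same-strand miRNA genes with inter-precursor gaps <= max_gap.

    ``members`` is ordered by genomic start.  ``excluded`` marks clusters whose
    paralog collapsing left fewer than two distinguishable members (they are
    excluded from expression analysis).  ``collapsed`` maps each representative
    to the member gene ids it absorbed.
    """

    cluster_id: str
    members: list[str]
    chrom: str
    strand: str
    gaps: list[int]
    excluded: bool = False
    collapsed: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise AnnotationError(f"cluster {self.cluster_id}: bad strand")
        if len(self.members) < 2 and not self.excluded:
            raise AnnotationError(
                f"cluster {self.cluster_id}: needs >=2 members, got {len(self.members)}"
            )
        if len(self.gaps) != max(len(self.members) - 1, 0):
            raise AnnotationError(
                f"cluster {self.cluster_id}: {len(self.gaps)} gaps for "
                f"{len(self.members)} members"
            )
        if any(g < 0 for g in self.gaps):
            raise AnnotationError(f"cluster {self.cluster_id}: negative gap")

    def transcription_order(self) -> list[str]:
        """Members in 5'->3' transcription order (reverse genomic order on -)."""
        return self.members if self.strand == "+" else self.members[::-1]


@dataclass
class ClusteringResult:
    clusters: list[Cluster]
    nonclustered: list[str]  # gene ids not in any cluster


_NAME_PREFIX = re.compile(r"^[a-z]{3,4}-(mir-|miR-)?", re.IGNORECASE)


def short_name(gene_id: str) -> str:
    """Strip the species/"mir" prefix: dme-mir-283 -> 283, dme-let-7 -> let-7."""
    return _NAME_PREFIX.sub("", gene_id) or gene_id


def normalize_seq(seq: str) -> str:
    """Uppercase and DNA-alphabet (U -> T) normalization."""
    return seq.strip().upper().replace("U", "T")


def assign_paralog_groups(genes: Sequence[MiRNAGene]) -> None:
    """Label genes with identical mature miR sequences as one paralog group.

    The group label is the gene_id of the genomically first member, so pooled
    counts and collapsed cluster members agree on the representative.
    """
    by_seq: dict[str, list[MiRNAGene]] = {}
    for g in genes:
        by_seq.setdefault(g.mir_arm.sequence, []).append(g)
    for members in by_seq.values():
        rep = min(members, key=lambda g: (g.chrom, g.precursor_start, g.gene_id))
        for g in members:
            g.paralog_group = rep.gene_id


# ---------------------------------------------------------------------------
# Loading

def load_annotation(path: str | Path, fasta_path: str | Path | None = None) -> list[MiRNAGene]:
    """Load miRNA genes from GFF3 (miRBase dialect) or BED6, with mature sequences.

    Sequences come from ``fasta_path`` (records keyed by arm id) or from a
    ``sequence`` attribute embedded in the GFF3.  Paralog groups are assigned
    by exact mature-miR sequence identity.
    """
    path = Path(path)
    seqs = _read_fasta(fasta_path) if fasta_path else {}
    if path.suffix.lower() == ".bed":
        genes = _load_bed(path, seqs)
    else:
        genes = _load_gff3(path, seqs)
    assign_paralog_groups(genes)
    return genes


def _read_fasta(fasta_path: str | Path) -> dict[str, str]:
    return {
        rec.id: normalize_seq(str(rec.seq))
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def _prescan_gff3(path: Path) -> None:
    # gffutils does not report line numbers; scan first so coordinate errors
    # name the offending line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates {cols[3]!r}/{cols[4]!r}"
                ) from None
            if start < 1 or end < start:
                raise AnnotationParseError(
                    f"{path}:{lineno}: invalid coordinate range {start}-{end}"
                )


def _load_gff3(path: Path, seqs: Mapping[str, str]) -> list[MiRNAGene]:
    _prescan_gff3(path)

    def _derives_from_as_parent(feature):
        # miRBase links arms to precursors via Derives_from; gffutils builds
        # relations from Parent only.
        attrs = feature.attributes
        if "Derives_from" in attrs and "Parent" not in attrs:
            attrs["Parent"] = attrs["Derives_from"]
        return feature

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True,
        transform=_derives_from_as_parent,
    )
    genes: list[MiRNAGene] = []
    for pre in db.features_of_type("miRNA_primary_transcript"):
        gene_id = pre.attributes.get("Name", pre.attributes.get("ID", [pre.id]))[0]
        arms = []
        for child in db.children(pre.id, featuretype="miRNA"):
            arm_id = child.attributes.get("Name", [child.id])[0]
            seq = seqs.get(arm_id) or child.attributes.get("sequence", [None])[0]
            if seq is None:
                raise AnnotationError(
                    f"gene {gene_id}: no sequence for arm {arm_id} "
                    "(missing from FASTA and no sequence attribute)"
                )
            role = child.attributes.get("arm_role", [None])[0]
            if role is None:
                role = STAR if arm_id.endswith("*") else MIR
            arms.append(
                ArmRecord(arm_id, child.start - 1, child.end, seq, role)
            )
        genes.append(
            _assemble_gene(gene_id, pre.seqid, pre.strand, pre.start - 1, pre.end, arms)
        )
    return genes


_BED_NAME = re.compile(r"^(precursor|mir|star):")


def _load_bed(path: Path, seqs: Mapping[str, str]) -> list[MiRNAGene]:
    """BED6 dialect: name column ``precursor:<gene>``, ``mir:<gene>:<arm>``,
    ``star:<gene>:<arm>``; sequences must come from the FASTA."""
    precursors: dict[str, tuple[str, int, int, str]] = {}
    arm_rows: list[tuple[str, str, str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 6:
                raise AnnotationParseError(
                    f"{path}:{lineno}: BED6 requires 6 columns, got {len(cols)}"
                )
            chrom, name, strand = cols[0], cols[3], cols[5]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if not _BED_NAME.match(name):
                raise AnnotationParseError(
                    f"{path}:{lineno}: name {name!r} lacks precursor:/mir:/star: prefix"
                )
            kind, _, rest = name.partition(":")
            if kind == "precursor":
                precursors[rest] = (chrom, start, end, strand)
            else:
                gene_id, _, arm_id = rest.partition(":")
                arm_rows.append((kind, gene_id, arm_id or rest, start, end))
    genes = []
    arm_map: dict[str, list[ArmRecord]] = {g: [] for g in precursors}
    for kind, gene_id, arm_id, start, end in arm_rows:
        if gene_id not in precursors:
            raise AnnotationError(f"arm {arm_id}: no parent precursor {gene_id}")
        seq = seqs.get(arm_id)
        if seq is None:
            raise AnnotationError(f"arm {arm_id}: sequence missing from FASTA")
        role = MIR if kind == "mir" else STAR
        arm_map[gene_id].append(ArmRecord(arm_id, start, end, seq, role))
    for gene_id, (chrom, start, end, strand) in precursors.items():
        genes.append(_assemble_gene(gene_id, chrom, strand, start, end, arm_map[gene_id]))
    return genes


def _assemble_gene(
    gene_id: str, chrom: str, strand: str, start: int, end: int, arms: list[ArmRecord]
) -> MiRNAGene:
    mirs = [a for a in arms if a.arm_role == MIR]
    stars = [a for a in arms if a.arm_role == STAR]
    if len(mirs) != 1:
        raise AnnotationError(
            f"gene {gene_id}: expected exactly one miR arm, got {len(mirs)} "
            f"(cannot determine arm roles)"
        )
    if len(stars) > 1:
        raise AnnotationError(f"gene {gene_id}: more than one miR* arm")
    return MiRNAGene(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        precursor_start=start,
        precursor_end=end,
        mir_arm=mirs[0],
        star_arm=stars[0] if stars else None,
    )


# ---------------------------------------------------------------------------
# Clustering

def build_clusters(
    genes: Sequence[MiRNAGene],
    max_gap: int = 1000,
    same_strand: bool = True,
) -> ClusteringResult:
    """Single-linkage chaining of genes along each (chrom, strand).

    Consecutive genes join a cluster when the inter-precursor gap
    (next start minus previous end) is <= ``max_gap`` (boundary inclusive:
    "not more than 1 kb").  Genes joining no cluster are returned as
    non-clustered singletons.  The result is independent of input order.
    """
    def key(g: MiRNAGene):
        return (g.chrom, g.strand) if same_strand else (g.chrom,)

    ordered = sorted(genes, key=lambda g: (*key(g), g.precursor_start, g.gene_id))
    clusters: list[Cluster] = []
    nonclustered: list[str] = []
    used_ids: dict[str, int] = {}

    for _, group in groupby(ordered, key=key):
        run: list[MiRNAGene] = []
        run_end = -1
        gaps: list[int] = []

        def flush() -> None:
            if len(run) >= 2:
                clusters.append(_make_cluster(run, gaps, used_ids))
            elif run:
                nonclustered.append(run[0].gene_id)

        for g in group:
            if run:
                gap = g.precursor_start - run_end
                if gap <= max_gap:
                    run.append(g)
                    gaps.append(max(gap, 0))
                    run_end = max(run_end, g.precursor_end)
                    continue
                flush()
                run, gaps = [], []
            run = [g]
            gaps = []
            run_end = g.precursor_end
        flush()

    clusters.sort(key=lambda c: (c.chrom, c.strand, c.cluster_id))
    nonclustered.sort()
    return ClusteringResult(clusters=clusters, nonclustered=nonclustered)


def _make_cluster(
    run: Sequence[MiRNAGene], gaps: Sequence[int], used_ids: dict[str, int]
) -> Cluster:
    first, last = run[0], run[-1]
    if first.strand == "-":
        first, last = last, first  # name in transcription order, e.g. 283~12
    base = f"{first.short_name}~{last.short_name}"
    used_ids[base] = used_ids.get(base, 0) + 1
    cid = base if used_ids[base] == 1 else f"{base}.{used_ids[base]}"
    return Cluster(
        cluster_id=cid,
        members=[g.gene_id for g in run],
        chrom=run[0].chrom,
        strand=run[0].strand,
        gaps=list(gaps),
    )


def collapse_paralogs_within_cluster(
    cluster: Cluster, genes: Mapping[str, MiRNAGene]
) -> Cluster:
    """Merge identical-paralog members of one cluster into a single representative.

    Members sharing a paralog group keep the genomically first gene as
    representative; counts are pooled at read-assignment time.  A cluster whose
    members all collapse onto one representative (e.g. the 281-1/281-2 tandem)
    is marked ``excluded`` from expression analysis.
    """
    seen: dict[str, str] = {}
    reps: list[str] = []
    collapsed: dict[str, list[str]] = {}
    for gid in cluster.members:
        group = genes[gid].paralog_group or gid
        if group in seen:
            collapsed.setdefault(seen[group], []).append(gid)
        else:
            seen[group] = gid
            reps.append(gid)
    if len(reps) == len(cluster.members):
        return cluster
    rep_genes = [genes[gid] for gid in reps]
    gaps = [
        max(b.precursor_start - a.precursor_end, 0)
        for a, b in zip(rep_genes, rep_genes[1:])
    ]
    return replace(
        cluster,
        members=reps,
        gaps=gaps,
        excluded=len(reps) < 2,
        collapsed=collapsed,
    )


def refine_clusters_by_correlation(
    cluster: Cluster,
    corr: "CorrelationReport",
    genes: Mapping[str, MiRNAGene],
    split_threshold: float = 0.6,
) -> list[Cluster]:
    """Split a cluster at a genomic boundary where expression decouples.

    Two independently behaving sub-runs can sit within 1 kb of each other and
    be chained by the gap rule alone; the split looks for a positional
    boundary such that every cross-boundary miR pair has r below
    ``split_threshold`` while each side is internally correlated above it.  Both sides must keep >=2 members
    (refinement separates multi-member sub-runs, it does not emit singletons).
    Returns ``[cluster]`` unchanged when no boundary qualifies; missing r for
    any member pair skips refinement with a warning.
    """
    ids = cluster.members
    arm = {gid: genes[gid].mir_arm.arm_id for gid in ids}
    r: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            val = corr.r(arm[a], arm[b])
            if val is None:
                warnings.warn(
                    f"cluster {cluster.cluster_id}: missing correlation for "
                    f"({a}, {b}); refinement skipped"
                )
                return [cluster]
            r[(a, b)] = r[(b, a)] = val

    def internally_high(side: Sequence[str]) -> bool:
        return all(
            r[(a, b)] > split_threshold
            for i, a in enumerate(side)
            for b in side[i + 1:]
        )

    for cut in range(2, len(ids) - 1):
        left, right = ids[:cut], ids[cut:]
        cross_low = all(r[(a, b)] < split_threshold for a in left for b in right)
        if cross_low and internally_high(left) and internally_high(right):
            return [
                _subcluster(cluster, left, genes),
                _subcluster(cluster, right, genes),
            ]
    return [cluster]


def _subcluster(
    cluster: Cluster, members: list[str], genes: Mapping[str, MiRNAGene]
) -> Cluster:
    gs = [genes[m] for m in members]
    first, last = gs[0], gs[-1]
    if cluster.strand == "-":
        first, last = last, first
    return Cluster(
        cluster_id=f"{first.short_name}~{last.short_name}",
        members=members,
        chrom=cluster.chrom,
        strand=cluster.strand,
        gaps=[max(b.precursor_start - a.precursor_end, 0) for a, b in zip(gs, gs[1:])],
        collapsed={
            k: v for k, v in cluster.collapsed.items() if k in members
        },
    )


# ---------------------------------------------------------------------------
# Writers

def write_gff3(genes: Iterable[MiRNAGene], path: str | Path) -> None:
    """Write genes in the miRBase GFF3 dialect (1-based inclusive on disk)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.precursor_start)):
        lines.append(
            "\t".join(
                [
                    g.chrom, "mircluster", "miRNA_primary_transcript",
                    str(g.precursor_start + 1), str(g.precursor_end), ".",
                    g.strand, ".", f"ID={g.gene_id};Name={g.gene_id}",
                ]
            )
        )
        for arm in g.arms:
            lines.append(
                "\t".join(
                    [
                        g.chrom, "mircluster", "miRNA",
                        str(arm.start + 1), str(arm.end), ".",
                        g.strand, ".",
                        f"ID={arm.arm_id};Name={arm.arm_id};"
                        f"Derives_from={g.gene_id};arm_role={arm.arm_role}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_mature_fasta(genes: Iterable[MiRNAGene], path: str | Path) -> None:
    lines = []
    for g in genes:
        for arm in g.arms:
            lines.append(f">{arm.arm_id}")
            lines.append(arm.sequence)
    Path(path).write_text("\n".join(lines) + "\n")


def write_cluster_table(result: ClusteringResult, path: str | Path) -> None:
    """TSV: cluster_id, chrom, strand, members, gaps (comma-joined)."""
    lines = ["cluster_id\tchrom\tstrand\tmembers\tgaps\texcluded"]
    for c in result.clusters:
        lines.append(
            f"{c.cluster_id}\t{c.chrom}\t{c.strand}\t"
            f"{','.join(c.members)}\t{','.join(map(str, c.gaps))}\t{int(c.excluded)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
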