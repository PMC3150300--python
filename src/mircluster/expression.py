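"""Small-RNA read assignment and expression profile construction.

Reads are assigned directly to mature arm sequences by exact match of the
first 18 bases (T/U normalized), bypassing genome alignment: the endpoint of
interest is the per-arm count table.  Counts are converted to per-library
relative frequencies (the unit on which all correlations are computed) and,
for heatmaps, to row Z-scores.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .annotation import ArmRecord, MiRNAGene, normalize_seq


class ExpressionError(ValueError):
    pass


class DegenerateLibraryError(ExpressionError):
    """A library with zero assigned counts cannot be normalized."""


@dataclass
class Library:
    library_id: str
    tissue_label: str = ""
    total_reads: int = 0
    source: str = "count_table"  # fasta | fastq | count_table | synthetic

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ExpressionError(f"library {self.library_id}: negative total_reads")


@dataclass
class ExpressionMatrix:
    """Arms x libraries matrix of raw counts with derived normalized views.

    ``counts`` rows are arm ids (miR and miR* entries, paralog-pooled),
    columns library ids.  ``relfreq`` is per-library scaled counts
    (column sums equal ``scale``); ``zscores`` is the row-standardized
    relfreq view used for heatmaps.  ``constant_rows`` flags rows whose
    relfreq profile had zero variance (their z-rows are all zero).
    """

    counts: pd.DataFrame
    relfreq: pd.DataFrame | None = None
    scale: float | None = None
    zscores: pd.DataFrame | None = None
    constant_rows: list[str] = field(default_factory=list)
    side_table: pd.DataFrame | None = None  # rows with unrecognized arm ids

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ExpressionError("negative counts")

    @property
    def arm_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class AssignmentResult:
    """Per-library read assignment tally.

    Conservation holds by construction:
    ``assigned + ambiguous + skipped == total``.
    """

    counts: dict[str, int]
    assigned: int = 0
    ambiguous: int = 0
    skipped_short: int = 0
    skipped_long: int = 0
    skipped_invalid: int = 0
    unmatched: int = 0
    total: int = 0

    @property
    def skipped(self) -> int:
        return self.skipped_short + self.skipped_long + self.skipped_invalid + self.unmatched


def paralog_pool_map(genes: Sequence[MiRNAGene]) -> dict[str, str]:
    """Map each arm id to its pooled representative arm id.

    miR arms of genes in one paralog group pool onto the representative
    gene's miR arm; star arms pool by exact sequence identity (identical
    full-duplicate genes also have identical stars).
    """
    pool: dict[str, str] = {}
    rep_gene: dict[str, MiRNAGene] = {}
    for g in genes:
        group = g.paralog_group or g.gene_id
        rep_gene.setdefault(group, g)
    for g in genes:
        rep = rep_gene[g.paralog_group or g.gene_id]
        pool[g.mir_arm.arm_id] = rep.mir_arm.arm_id
    star_by_seq: dict[str, str] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.precursor_start, g.gene_id)):
        if g.star_arm is None:
            continue
        rep_arm = star_by_seq.setdefault(g.star_arm.sequence, g.star_arm.arm_id)
        pool[g.star_arm.arm_id] = rep_arm
    return pool


_VALID_CHARS = frozenset("ACGTN")


def assign_reads(
    reads: Iterable,
    arms: Sequence[ArmRecord],
    prefix_len: int = 18,
    pool: Mapping[str, str] | None = None,
    min_len: int = 18,
    max_len: int = 30,
) -> AssignmentResult:
    """Assign reads to arms by perfect match of the first ``prefix_len`` bases.

    A read is assigned iff its first ``prefix_len`` bases exactly match an arm
    sequence's first ``prefix_len`` bases; bases beyond the prefix are ignored.
    Reads matching arms pooled together (same paralog group) increment the
    representative once; reads matching arms in different pools are discarded
    as ambiguous.  Reads outside the ``min_len``-``max_len`` window or with
    non-ACGTUN characters are skipped with a tally.

    ``reads`` yields strings or Biopython SeqRecords.
    """
    if pool is None:
        pool = {}
    index: dict[str, frozenset[str]] = {}
    for arm in arms:
        rep = pool.get(arm.arm_id, arm.arm_id)
        prefix = arm.sequence[:prefix_len]
        index[prefix] = index.get(prefix, frozenset()) | {rep}

    res = AssignmentResult(counts={})
    counts = res.counts
    for read in reads:
        res.total += 1
        seq = normalize_seq(str(read.seq) if hasattr(read, "seq") else str(read))
        n = len(seq)
        if n < max(min_len, prefix_len):
            res.skipped_short += 1
            continue
        if n > max_len:
            res.skipped_long += 1
            continue
        if not set(seq) <= _VALID_CHARS:
            res.skipped_invalid += 1
            continue
        reps = index.get(seq[:prefix_len])
        if reps is None:
            res.unmatched += 1
        elif len(reps) == 1:
            (rep,) = reps
            counts[rep] = counts.get(rep, 0) + 1
            res.assigned += 1
        else:
            res.ambiguous += 1
    return res


def read_library_fasta(path: str | Path) -> Iterator[str]:
    """Yield read sequences from plain or gzipped FASTA/FASTQ."""
    path = Path(path)
    name = path.name.lower().removesuffix(".gz")
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq)


def counts_from_assignments(
    assignments: Mapping[str, AssignmentResult],
    arm_ids: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Stack per-library assignment results into an ExpressionMatrix."""
    cols = {
        lib: pd.Series(res.counts, dtype="int64")
        for lib, res in assignments.items()
    }
    df = pd.DataFrame(cols).fillna(0).astype("int64")
    if arm_ids is not None:
        df = df.reindex(list(arm_ids), fill_value=0)
    return ExpressionMatrix(counts=df)


def counts_to_relfreq(matrix: ExpressionMatrix, scale: float = 1e6) -> ExpressionMatrix:
    """Divide each library column by its total assigned count, times ``scale``.

    The denominator is the total over annotated arms (not total library
    reads), making profiles robust to non-miRNA content differences.
    """
    totals = matrix.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DegenerateLibraryError(
            f"library with no assigned counts: {', '.join(zero.index)}"
        )
    matrix.relfreq = matrix.counts / totals * scale
    matrix.scale = scale
    return matrix


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Row-standardize relfreq: subtract mean, divide by sample (n-1) SD.

    Constant rows become all-zero and are flagged in ``constant_rows``.
    """
    if matrix.relfreq is None:
        counts_to_relfreq(matrix)
    rf = matrix.relfreq
    if rf.shape[1] < 2:
        raise ExpressionError("z-scoring requires >=2 libraries")
    mean = rf.mean(axis=1)
    sd = rf.std(axis=1, ddof=1)
    constant = sd == 0
    safe_sd = sd.mask(constant, 1.0)
    z = rf.sub(mean, axis=0).div(safe_sd, axis=0)
    z[constant] = 0.0
    matrix.zscores = z
    matrix.constant_rows = list(rf.index[constant])
    return matrix


def pool_rows(matrix: ExpressionMatrix, pool: Mapping[str, str]) -> ExpressionMatrix:
    """Sum count rows onto their pooled representatives (paralog pooling)."""
    grouped = matrix.counts.groupby(
        [pool.get(a, a) for a in matrix.counts.index]
    ).sum()
    order = []
    for a in matrix.counts.index:
        rep = pool.get(a, a)
        if rep not in order:
            order.append(rep)
    return ExpressionMatrix(counts=grouped.loc[order])


def load_count_table(
    path: str | Path, known_arms: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Read a TSV count table (arm_id rows, library columns, integer cells).

    With ``known_arms`` given, unrecognized arm ids are warned about and moved
    to ``side_table``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ExpressionError(f"{path}: duplicate arm ids")
    for col in df.columns:
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ExpressionError(
                f"{path}: non-numeric cell at row {bad.index[0]!r}, column {col!r}"
            )
    values = df.astype(float)
    neg = values < 0
    if neg.to_numpy().any():
        row = values.index[neg.any(axis=1)][0]
        col = values.columns[neg.any(axis=0)][0]
        raise ExpressionError(f"{path}: negative cell at row {row!r}, column {col!r}")
    if not np.allclose(values, values.round()):
        raise ExpressionError(f"{path}: non-integer counts")
    counts = values.round().astype("int64")
    side = None
    if known_arms is not None:
        unknown = [a for a in counts.index if a not in set(known_arms)]
        if unknown:
            import warnings

            warnings.warn(f"{path}: {len(unknown)} unknown arm ids kept aside")
            side = counts.loc[unknown]
            counts = counts.drop(index=unknown)
    return ExpressionMatrix(counts=counts, side_table=side)


def write_count_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="arm_id")


def write_matrix_sheets(matrix: ExpressionMatrix, prefix: str | Path) -> list[Path]:
    """Write counts plus available relfreq/zscore views as TSV sheets."""
    prefix = Path(prefix)
    out = []
    for name, df in [
        ("counts", matrix.counts),
        ("relfreq", matrix.relfreq),
        ("zscores", matrix.zscores),
    ]:
        if df is not None:
            p = prefix.with_name(prefix.name + f".{name}.tsv")
            df.to_csv(p, sep="\t", index_label="arm_id")
            out.append(p)
    return out
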