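"""Synthetic miRNA annotations, TSS tracks, and small-RNA count libraries.

The generator emulates the statistical structure the analysis assumes:

* clustered gene geometry on virtual chromosomes, with intra-cluster gaps
  calibrated to the real genome's gap statistics (mean ~213 nt, median ~75 nt)
  and inter-unit spacing far beyond the 1-kb cluster rule;
* polycistronic expression — every member of a cluster shares one per-tissue
  activity vector a_{c,t}, drawn log-normally over a per-cluster subset of
  active tissues;
* per-gene arm asymmetry f_g ~ Beta(8, 2) (the miR share of hairpin output);
* optional tissue-specific post-transcriptional modulation m_{g,t} of the miR,
  the star, or the whole hairpin;
* fixed-depth multinomial sequencing noise (counts are compositional, as in
  real libraries), with a background fraction of non-miRNA reads;
* TSS tracks with upstream-only placements (plus optional implanted
  intra-cluster TSSs and a genome-wide background) for negative controls.

All randomness flows through one ``numpy`` Generator seeded from the config;
identical seed and config give byte-identical emitted files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import MIR, STAR, ArmRecord, MiRNAGene, assign_paralog_groups
from .tss_analysis import TSS

MODE_MIR = "mir_stability"
MODE_STAR = "star_stability"
MODE_HAIRPIN = "hairpin"
MODES = (MODE_MIR, MODE_STAR, MODE_HAIRPIN)

_ALPHABET = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass
class Modulation:
    """Tissue-specific post-transcriptional modulation of one gene.

    ``factors`` multiplies the affected arm's expected abundance per tissue:
    the miR only (``mir_stability``), the star only (``star_stability``), or
    both arms (``hairpin``).
    """

    gene_id: str
    mode: str
    factors: list[float]

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise SimulationError(f"unknown modulation mode {self.mode!r}")
        if any(f <= 0 for f in self.factors):
            raise SimulationError("modulation factors must be positive")


@dataclass
class SimConfig:
    seed: int = 0
    n_tissues: int = 9
    n_clusters: int = 8
    members_per_cluster: tuple[int, int] = (2, 6)
    n_nonclustered: int = 12
    # Intra-cluster gap model: mixture of a log-normal body and a uniform
    # long-gap tail, calibrated to mean ~213 nt / median ~75 nt on (0, 1000].
    gap_lognorm_mu: float = 4.038
    gap_lognorm_sigma: float = 1.0
    gap_long_prob: float = 0.18
    gap_long_range: tuple[int, int] = (500, 1000)
    max_gap: int = 1000
    # Expression model
    activity_sigma: float = 1.5
    active_tissues_range: tuple[int, int] = (3, 7)
    inactive_scale: float = 1e-3
    arm_fraction_beta: tuple[float, float] = (8.0, 2.0)
    modulations: list[Modulation] = field(default_factory=list)
    library_depth: int = 1_000_000
    background_fraction: float = 0.2
    # Geometry
    precursor_len: int = 90
    arm_len: int = 22
    unit_spacing: tuple[int, int] = (8000, 20000)
    paralog_pairs: int = 0  # identical-duplicate tandems implanted in clusters
    # TSS model
    tss_per_unit: tuple[int, int] = (1, 3)
    tss_upstream_range: tuple[int, int] = (50, 3000)
    intra_tss_clusters: int = 0
    background_tss_rate: float = 0.0  # expected TSSs per nt, genome-wide

    def __post_init__(self) -> None:
        if self.n_tissues < 2:
            raise SimulationError("need at least 2 tissues")
        if self.members_per_cluster[0] < 2:
            raise SimulationError("clusters need >=2 members")
        if not 0 <= self.background_fraction < 1:
            raise SimulationError("background_fraction must be in [0, 1)")

    @property
    def tissue_labels(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        mods = [Modulation(**m) for m in d.pop("modulations", [])]
        for key in (
            "members_per_cluster", "gap_long_range", "active_tissues_range",
            "arm_fraction_beta", "unit_spacing", "tss_per_unit",
            "tss_upstream_range",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(modulations=mods, **d)


@dataclass
class SimAnnotation:
    genes: list[MiRNAGene]
    true_clusters: list[list[str]]  # member gene ids, genomic order
    nonclustered: list[str]
    chrom_lengths: dict[str, int]

    @property
    def gene_map(self) -> dict[str, MiRNAGene]:
        return {g.gene_id: g for g in self.genes}


@dataclass
class SimLibraries:
    counts: pd.DataFrame  # arm_id x tissue label
    activities: pd.DataFrame  # unit label x tissue
    arm_fractions: dict[str, float]
    applied_modulations: list[Modulation]


def draw_gaps(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Intra-cluster gap lengths: log-normal body + uniform long-gap tail.

    Rejection-resampled into (0, max_gap]; integers >= 1.
    """
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        k = n - filled
        long = rng.random(k) < config.gap_long_prob
        vals = np.where(
            long,
            rng.integers(config.gap_long_range[0], config.gap_long_range[1] + 1, k),
            np.maximum(
                rng.lognormal(config.gap_lognorm_mu, config.gap_lognorm_sigma, k), 1.0
            ).astype(int),
        )
        keep = vals[(vals >= 1) & (vals <= config.max_gap)]
        out[filled:filled + len(keep)] = keep[: n - filled]
        filled += min(len(keep), n - filled)
    return out


def _random_arm_seq(
    rng: np.random.Generator, length: int, used_prefixes: set[str], prefix_len: int = 18
) -> str:
    for _ in range(1000):
        seq = "".join(rng.choice(_ALPHABET, size=length))
        if seq[:prefix_len] not in used_prefixes:
            used_prefixes.add(seq[:prefix_len])
            return seq
    raise SimulationError("could not draw a unique arm prefix")  # pragma: no cover


def simulate_annotation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimAnnotation:
    """Place clustered and singleton genes on a virtual chromosome.

    Precursors never overlap; intra-cluster gaps follow the configured gap
    distribution, and consecutive units are separated well beyond ``max_gap``
    so the true cluster structure is unambiguous.  Arm sequences are random
    with globally unique 18-nt prefixes, except implanted paralog tandems
    (``paralog_pairs``), which copy both arm sequences of their neighbor to
    exercise paralog collapsing.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes: list[MiRNAGene] = []
    true_clusters: list[list[str]] = []
    nonclustered: list[str] = []
    used_prefixes: set[str] = set()
    chrom = "chrSim1"
    cursor = 10_000
    counter = 0

    def new_gene(strand: str, copy_of: MiRNAGene | None = None) -> MiRNAGene:
        nonlocal cursor, counter
        counter += 1
        start, end = cursor, cursor + config.precursor_len
        if copy_of is None:
            mir_seq = _random_arm_seq(rng, config.arm_len, used_prefixes)
            star_seq = _random_arm_seq(rng, config.arm_len, used_prefixes)
        else:
            mir_seq = copy_of.mir_arm.sequence
            star_seq = copy_of.star_arm.sequence
        gid = f"sim-mir-{counter}"
        L = config.arm_len
        # miR on the 5' arm, star on the 3' arm of the hairpin (strand-aware)
        a = ArmRecord(f"{gid}", start + 4, start + 4 + L, mir_seq, MIR)
        b = ArmRecord(f"{gid}*", end - 4 - L, end - 4, star_seq, STAR)
        if strand == "-":
            a, b = (
                ArmRecord(f"{gid}", end - 4 - L, end - 4, mir_seq, MIR),
                ArmRecord(f"{gid}*", start + 4, start + 4 + L, star_seq, STAR),
            )
        cursor = end
        return MiRNAGene(gid, chrom, strand, start, end, a, b)

    cluster_sizes = rng.integers(
        config.members_per_cluster[0], config.members_per_cluster[1] + 1,
        config.n_clusters,
    )
    paralog_budget = config.paralog_pairs
    for ci, size in enumerate(cluster_sizes):
        strand = "+" if rng.random() < 0.5 else "-"
        gaps = draw_gaps(config, int(size) - 1, rng)
        members: list[MiRNAGene] = []
        copy_slot = None
        if paralog_budget > 0 and size >= 3:
            copy_slot = 1  # second member duplicates the first
            paralog_budget -= 1
        for j in range(int(size)):
            copy = members[0] if (copy_slot is not None and j == copy_slot) else None
            g = new_gene(strand, copy_of=copy)
            members.append(g)
            if j < len(gaps):
                cursor += int(gaps[j])
        genes.extend(members)
        true_clusters.append([g.gene_id for g in members])
        cursor += int(rng.integers(*config.unit_spacing))
    for _ in range(config.n_nonclustered):
        strand = "+" if rng.random() < 0.5 else "-"
        g = new_gene(strand)
        genes.append(g)
        nonclustered.append(g.gene_id)
        cursor += int(rng.integers(*config.unit_spacing))

    assign_paralog_groups(genes)
    return SimAnnotation(
        genes=genes,
        true_clusters=true_clusters,
        nonclustered=nonclustered,
        chrom_lengths={chrom: cursor + 10_000},
    )


def simulate_tss(
    config: SimConfig,
    annotation: SimAnnotation,
    rng: np.random.Generator | None = None,
) -> list[TSS]:
    """Place sense TSSs upstream of each transcription unit.

    1-3 TSSs at 50-3000 nt upstream of each cluster's first member and of
    each non-clustered gene.  ``intra_tss_clusters`` implants one sense TSS
    inside a gap of that many leading clusters (positive controls for the
    intra-gap scan); ``background_tss_rate`` adds a uniform genome-wide track
    on random strands.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    gene_map = annotation.gene_map
    out: list[TSS] = []

    def place_upstream(g: MiRNAGene) -> None:
        k = int(rng.integers(config.tss_per_unit[0], config.tss_per_unit[1] + 1))
        for _ in range(k):
            off = int(rng.integers(*config.tss_upstream_range))
            pos = g.five_prime - off if g.strand == "+" else g.five_prime + off
            if pos >= 0:
                out.append(TSS(g.chrom, pos, g.strand))

    for members in annotation.true_clusters:
        first_id = members[0] if gene_map[members[0]].strand == "+" else members[-1]
        place_upstream(gene_map[first_id])
    for gid in annotation.nonclustered:
        place_upstream(gene_map[gid])

    for members in annotation.true_clusters[: config.intra_tss_clusters]:
        gs = [gene_map[m] for m in members]
        i = int(rng.integers(0, len(gs) - 1))
        lo, hi = gs[i].precursor_end, gs[i + 1].precursor_start
        if hi > lo:
            out.append(
                TSS(gs[0].chrom, int(rng.integers(lo, hi)), gs[0].strand)
            )

    if config.background_tss_rate > 0:
        for chrom, length in annotation.chrom_lengths.items():
            n = rng.poisson(config.background_tss_rate * length)
            positions = np.sort(rng.integers(0, length, n))
            strands = rng.random(n) < 0.5
            out.extend(
                TSS(chrom, int(p), "+" if s else "-")
                for p, s in zip(positions, strands)
            )
    out.sort(key=lambda t: (t.chrom, t.position, t.strand))
    return out


def make_tissue_modulation(
    gene_id: str,
    mode: str,
    rng: np.random.Generator,
    n_tissues: int = 9,
    n_modulated: int = 4,
    factor: float = 0.25,
    active_tissues: Sequence[int] | None = None,
) -> Modulation:
    """Suppress one gene ``factor``-fold in ``n_modulated`` tissues.

    Modulated tissues are drawn from the cluster's active subset when given
    (a stability change in a tissue where the cluster is silent is
    unobservable), padded from the remaining tissues if the subset is small.
    """
    pool = list(active_tissues) if active_tissues is not None else list(range(n_tissues))
    chosen = list(rng.choice(pool, size=min(n_modulated, len(pool)), replace=False))
    if len(chosen) < n_modulated:
        rest = [t for t in range(n_tissues) if t not in chosen]
        chosen += list(
            rng.choice(rest, size=n_modulated - len(chosen), replace=False)
        )
    factors = [factor if t in set(chosen) else 1.0 for t in range(n_tissues)]
    return Modulation(gene_id=gene_id, mode=mode, factors=factors)


@dataclass
class ExpressionModel:
    """The latent polycistronic expression state, before sequencing noise."""

    activities: pd.DataFrame  # unit label x tissue
    active_tissues: dict[str, np.ndarray]  # unit label -> active tissue indices
    arm_fractions: dict[str, float]  # gene -> miR share f_g
    unit_of_gene: dict[str, str]


def draw_expression_model(
    config: SimConfig,
    annotation: SimAnnotation,
    rng: np.random.Generator,
) -> ExpressionModel:
    """Draw per-unit tissue activities and per-gene arm fractions.

    Every cluster (and each singleton gene) is one transcription unit with a
    per-tissue rate a_{c,t} ~ LogNormal(0, activity_sigma), scaled down by
    ``inactive_scale`` outside the unit's randomly chosen active-tissue subset.
    """
    T = config.n_tissues
    units: list[tuple[str, list[str]]] = [
        (f"cluster{ci + 1:02d}", members)
        for ci, members in enumerate(annotation.true_clusters)
    ] + [(gid, [gid]) for gid in annotation.nonclustered]

    activity_rows = {}
    unit_of_gene: dict[str, str] = {}
    active_sets: dict[str, np.ndarray] = {}
    for label, members in units:
        k = int(rng.integers(config.active_tissues_range[0],
                             config.active_tissues_range[1] + 1))
        active = np.sort(rng.choice(T, size=k, replace=False))
        a = rng.lognormal(0.0, config.activity_sigma, T)
        mask = np.full(T, config.inactive_scale)
        mask[active] = 1.0
        activity_rows[label] = a * mask
        active_sets[label] = active
        for gid in members:
            unit_of_gene[gid] = label
    fractions = {
        g.gene_id: float(rng.beta(*config.arm_fraction_beta))
        for g in annotation.genes
    }
    return ExpressionModel(
        activities=pd.DataFrame(activity_rows, index=config.tissue_labels).T,
        active_tissues=active_sets,
        arm_fractions=fractions,
        unit_of_gene=unit_of_gene,
    )


def sample_counts(
    config: SimConfig,
    annotation: SimAnnotation,
    model: ExpressionModel,
    rng: np.random.Generator,
    modulations: Sequence[Modulation] | None = None,
) -> SimLibraries:
    """Sample the arm count table from an expression model.

    Expected miR abundance of gene g in tissue t is a_{c(g),t} * f_g *
    m_miR(g,t); the star gets a_{c(g),t} * (1 - f_g) * m_star(g,t).  Counts
    per tissue are Multinomial(round(depth * (1 - background_fraction)),
    normalized abundances) — fixed-depth compositional sampling.
    """
    if modulations is None:
        modulations = config.modulations
    T = config.n_tissues
    mods = {m.gene_id: m for m in modulations}
    arm_ids: list[str] = []
    expected = []
    for g in annotation.genes:
        a = model.activities.loc[model.unit_of_gene[g.gene_id]].to_numpy()
        f = model.arm_fractions[g.gene_id]
        m_mir = np.ones(T)
        m_star = np.ones(T)
        mod = mods.get(g.gene_id)
        if mod is not None:
            factors = np.asarray(mod.factors, dtype=float)
            if mod.mode in (MODE_MIR, MODE_HAIRPIN):
                m_mir = factors
            if mod.mode in (MODE_STAR, MODE_HAIRPIN):
                m_star = factors
        arm_ids.append(g.mir_arm.arm_id)
        expected.append(a * f * m_mir)
        arm_ids.append(g.star_arm.arm_id)
        expected.append(a * (1.0 - f) * m_star)

    exp = np.asarray(expected)
    depth = int(round(config.library_depth * (1.0 - config.background_fraction)))
    counts = np.empty(exp.shape, dtype=np.int64)
    for t in range(T):
        p = exp[:, t] / exp[:, t].sum()
        counts[:, t] = rng.multinomial(depth, p)
    df = pd.DataFrame(counts, index=arm_ids, columns=config.tissue_labels)
    return SimLibraries(
        counts=df,
        activities=model.activities,
        arm_fractions=model.arm_fractions,
        applied_modulations=list(modulations),
    )


def simulate_libraries(
    config: SimConfig,
    annotation: SimAnnotation,
    rng: np.random.Generator | None = None,
) -> SimLibraries:
    """Convenience wrapper: draw the expression model, then sample counts."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    model = draw_expression_model(config, annotation, rng)
    return sample_counts(config, annotation, model, rng)


def emit_reads(
    counts: pd.DataFrame,
    annotation: SimAnnotation,
    rng: np.random.Generator,
    library: str,
) -> list[str]:
    """Expand one library's counts into read sequences.

    Each counted molecule is its arm sequence with +-1 nt random 3'-end
    variation (trim one base, keep, or append one random base), mimicking the
    heterogeneous 3' ends of real small-RNA reads while preserving the 18-nt
    5' prefix used for assignment.
    """
    seq_of: dict[str, str] = {}
    for g in annotation.genes:
        for arm in g.arms:
            seq_of[arm.arm_id] = arm.sequence
    reads: list[str] = []
    for arm_id, c in counts[library].items():
        seq = seq_of[arm_id]
        deltas = rng.choice([-1, 0, 1], size=int(c), p=[0.25, 0.5, 0.25])
        for d in deltas:
            if d == -1:
                reads.append(seq[:-1])
            elif d == 0:
                reads.append(seq)
            else:
                reads.append(seq + str(rng.choice(_ALPHABET)))
    return reads


def write_truth_tables(
    annotation: SimAnnotation, libraries: SimLibraries, outdir: str | Path
) -> list[Path]:
    """Truth TSVs for test assertions: true clusters and applied modulations."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p1 = outdir / "true_clusters.tsv"
    rows = [
        {"cluster_index": i, "members": ",".join(members)}
        for i, members in enumerate(annotation.true_clusters)
    ]
    pd.DataFrame(rows).to_csv(p1, sep="\t", index=False)
    p2 = outdir / "true_modulations.tsv"
    rows = [
        {"gene_id": m.gene_id, "mode": m.mode,
         "factors": ",".join(f"{f:g}" for f in m.factors)}
        for m in libraries.applied_modulations
    ]
    pd.DataFrame(rows, columns=["gene_id", "mode", "factors"]).to_csv(
        p2, sep="\t", index=False
    )
    return [p1, p2]
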