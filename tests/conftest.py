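"""Shared fixtures and builders for the test suite.

All synthetic inputs are generated programmatically; nothing is read from
checked-in data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from mircluster.annotation import MIR, STAR, ArmRecord, MiRNAGene

ARM_LEN = 22
PRE_LEN = 90


def arm_seq(i: int, length: int = ARM_LEN) -> str:
    """Deterministic arm sequence with a unique 18-nt prefix per index."""
    digits = []
    x = i
    for _ in range(9):
        digits.append("ACGT"[x % 4])
        x //= 4
    core = "".join(digits)
    tail = ("ACGTACGT" * 4)[: length - len(core)]
    return core + tail


def make_gene(
    i: int,
    start: int,
    chrom: str = "chrT",
    strand: str = "+",
    gene_id: str | None = None,
    mir_seq: str | None = None,
    star_seq: str | None = None,
    with_star: bool = True,
) -> MiRNAGene:
    gid = gene_id or f"dme-mir-{i}"
    end = start + PRE_LEN
    mir = ArmRecord(gid, start + 4, start + 4 + ARM_LEN,
                    mir_seq or arm_seq(2 * i), MIR)
    star = (
        ArmRecord(gid + "*", end - 4 - ARM_LEN, end - 4,
                  star_seq or arm_seq(2 * i + 1), STAR)
        if with_star else None
    )
    return MiRNAGene(gid, chrom, strand, start, end, mir, star)


def random_genes(
    rng: np.random.Generator,
    n: int,
    chroms: tuple[str, ...] = ("chrA", "chrB"),
    span: int = 60_000,
) -> list[MiRNAGene]:
    """Random annotation with possibly overlapping precursors for oracles."""
    genes = []
    for i in range(n):
        genes.append(
            make_gene(
                i,
                int(rng.integers(0, span)),
                chrom=str(rng.choice(list(chroms))),
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return genes


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """One small seeded synthetic dataset shared across tests (read-only)."""
    from mircluster import synthetic as syn

    config = syn.SimConfig(seed=11, n_clusters=5, n_nonclustered=6,
                           library_depth=200_000)
    master = np.random.default_rng(config.seed)
    annotation = syn.simulate_annotation(config, master)
    libraries = syn.simulate_libraries(config, annotation, master)
    tss_list = syn.simulate_tss(config, annotation)
    return config, annotation, libraries, tss_list
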