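"""Pairwise Pearson r, pair categories, group test, histograms, classification."""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from mircluster import correlation as corr
from mircluster.annotation import Cluster, assign_paralog_groups, build_clusters
from mircluster.expression import ExpressionMatrix

from conftest import make_gene


def matrix_from(rows: dict, columns=None) -> ExpressionMatrix:
    df = pd.DataFrame(rows).T
    if columns is not None:
        df.columns = columns
    m = ExpressionMatrix(counts=pd.DataFrame(np.ones_like(df, dtype=int),
                                             index=df.index, columns=df.columns))
    m.relfreq = df.astype(float)
    m.scale = 1.0
    return m


def fake_report(r_values: dict, arm_ids=None) -> corr.CorrelationReport:
    ids = arm_ids or sorted({a for pair in r_values for a in pair})
    rep = corr.CorrelationReport(arm_ids=list(ids), n_libraries=9)
    for (a, b), v in r_values.items():
        rep._r[frozenset((a, b))] = v
    return rep


# ---------------------------------------------------------------------------
# pairwise_pearson


def test_identical_and_opposed_profiles():
    m = matrix_from({
        "a": [1, 2, 3, 4],
        "b": [2, 4, 6, 8],       # identical up to scale -> r = 1
        "c": [4, 3, 2, 1],       # exact negation about the mean -> r = -1
    })
    rep = corr.pairwise_pearson(m)
    assert rep.r("a", "b") == pytest.approx(1.0)
    assert rep.r("a", "c") == pytest.approx(-1.0)


def test_pearson_matches_product_moment_formula(rng):
    def direct(x, y):
        xc, yc = x - x.mean(), y - y.mean()
        return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))

    for _ in range(100):
        data = rng.random((5, 9))
        m = matrix_from({f"g{i}": data[i] for i in range(5)})
        rep = corr.pairwise_pearson(m)
        for i, j in combinations(range(5), 2):
            assert rep.r(f"g{i}", f"g{j}") == pytest.approx(
                direct(data[i], data[j]), abs=1e-12)


def test_pearson_is_invariant_to_relfreq_scale(rng):
    counts = pd.DataFrame(rng.integers(1, 1000, (4, 6)),
                          index=list("abcd"), columns=[f"l{i}" for i in range(6)])
    from mircluster.expression import counts_to_relfreq

    r1 = corr.pairwise_pearson(
        counts_to_relfreq(ExpressionMatrix(counts=counts.copy()), scale=1.0))
    r2 = corr.pairwise_pearson(
        counts_to_relfreq(ExpressionMatrix(counts=counts.copy()), scale=1e6))
    for a, b in combinations("abcd", 2):
        assert r1.r(a, b) == pytest.approx(r2.r(a, b), abs=1e-12)


def test_too_few_libraries_and_zero_variance_rows():
    with pytest.raises(corr.CorrelationError, match=">=3"):
        corr.pairwise_pearson(matrix_from({"a": [1, 2], "b": [2, 1]}))
    rep = corr.pairwise_pearson(matrix_from({
        "flat": [5, 5, 5, 5], "a": [1, 2, 3, 4], "b": [1, 3, 2, 4]}))
    assert rep.flagged_rows == ["flat"]
    assert rep.r("flat", "a") is None
    assert ("a", "flat") in rep.undefined_pairs or ("flat", "a") in rep.undefined_pairs


# ---------------------------------------------------------------------------
# categorize_pairs


@pytest.fixture
def categorized():
    genes = [
        make_gene(1, 1000), make_gene(2, 1500),          # cluster A
        make_gene(3, 50_000), make_gene(4, 50_500),      # cluster B
        make_gene(5, 200_000), make_gene(6, 300_000),    # non-clustered
    ]
    assign_paralog_groups(genes)
    res = build_clusters(genes)
    arm = {g.gene_id: g.mir_arm.arm_id for g in genes}
    ids = [g.gene_id for g in genes]
    r = {(arm[a], arm[b]): 0.5 for a, b in combinations(ids, 2)}
    # one star pair to confirm stars are left uncategorized
    r[(genes[0].mir_arm.arm_id, genes[0].star_arm.arm_id)] = 0.9
    rep = fake_report(r)
    corr.categorize_pairs(rep, res.clusters, res.nonclustered, genes)
    return genes, rep, arm


def test_pair_categories(categorized):
    genes, rep, arm = categorized
    get = lambda i, j: rep.category(arm[f"dme-mir-{i}"], arm[f"dme-mir-{j}"])
    assert get(1, 2) == corr.CATEGORY_SAME
    assert get(1, 3) == corr.CATEGORY_DIFF
    assert get(1, 5) == corr.CATEGORY_CL_NCL
    assert get(5, 6) == corr.CATEGORY_NCL_NCL
    assert rep.category(genes[0].mir_arm.arm_id, genes[0].star_arm.arm_id) is None


def test_category_counts_cover_all_mir_pairs(categorized):
    genes, rep, arm = categorized
    n_mirs = len(genes)
    n_categorized = sum(
        len(rep.category_values(cat)) for cat in corr.CATEGORIES
    )
    assert n_categorized == n_mirs * (n_mirs - 1) // 2


def test_unknown_gene_is_error():
    rep = fake_report({("x", "y"): 0.5})
    with pytest.raises(corr.CorrelationError, match="unknown gene"):
        corr.categorize_pairs(rep, [], ["x"])  # y unaccounted for


# ---------------------------------------------------------------------------
# compare_groups


def test_identical_groups_give_t0_p1():
    r = {}
    for i, v in enumerate([0.1, 0.5, 0.9]):
        r[(f"a{i}", f"b{i}")] = v
        r[(f"c{i}", f"d{i}")] = v
    rep = fake_report(r)
    for key in list(rep._r):
        a = sorted(key)[0]
        rep._category[key] = (
            corr.CATEGORY_SAME if a.startswith("a") else corr.CATEGORY_DIFF
        )
    t, p = corr.compare_groups(rep, corr.CATEGORY_SAME, corr.CATEGORY_DIFF)
    assert t == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_separated_groups_give_small_p(rng):
    r = {}
    cats = {}
    for i in range(10):
        r[(f"a{i}", f"b{i}")] = 0.9 + rng.normal(0, 1e-3)
        cats[frozenset((f"a{i}", f"b{i}"))] = corr.CATEGORY_SAME
        r[(f"c{i}", f"d{i}")] = 0.1 + rng.normal(0, 1e-3)
        cats[frozenset((f"c{i}", f"d{i}"))] = corr.CATEGORY_DIFF
    rep = fake_report(r)
    rep._category = cats
    _, p = corr.compare_groups(rep, corr.CATEGORY_SAME, corr.CATEGORY_DIFF)
    assert p < 1e-10


def test_undersized_group_is_error():
    rep = fake_report({("a", "b"): 0.5})
    rep._category[frozenset(("a", "b"))] = corr.CATEGORY_SAME
    with pytest.raises(corr.CorrelationError, match=">=2"):
        corr.compare_groups(rep, corr.CATEGORY_SAME, corr.CATEGORY_DIFF)


# ---------------------------------------------------------------------------
# r_histograms


def test_histogram_normalization_and_counts(rng):
    values = rng.uniform(-1, 1, 40)
    r = {(f"a{i}", f"b{i}"): float(v) for i, v in enumerate(values)}
    rep = fake_report(r)
    for key in rep._r:
        rep._category[key] = corr.CATEGORY_SAME
    with pytest.warns(UserWarning):  # other categories are empty
        hists = corr.r_histograms(rep)
    h = hists[corr.CATEGORY_SAME]
    assert h.normalized.max() == pytest.approx(1.0)
    assert h.counts.sum() == 40  # binning conserves the category size
    # independently recount one bin
    lo, hi = h.edges[3], h.edges[4]
    assert h.counts[3] == np.sum((values >= lo) & (values < hi))


def test_single_value_category_has_one_full_bin():
    rep = fake_report({("a", "b"): 0.55})
    rep._category[frozenset(("a", "b"))] = corr.CATEGORY_DIFF
    with pytest.warns(UserWarning):
        hists = corr.r_histograms(rep)
    h = hists[corr.CATEGORY_DIFF]
    assert h.counts.sum() == 1
    assert sorted(h.normalized)[-1] == 1.0
    assert hists[corr.CATEGORY_SAME].counts.sum() == 0


# ---------------------------------------------------------------------------
# classify_cluster


def _cluster(members, cid="test"):
    return Cluster(cid, list(members), "chrT", "+", [100] * (len(members) - 1))


def test_uncoordinated_cluster_with_single_uncorrelated_member():
    # the 283~12 pattern: two members agree, one decouples from both
    members = ["dme-mir-283", "dme-mir-304", "dme-mir-12"]
    rep = fake_report({
        ("dme-mir-304", "dme-mir-12"): 0.69,
        ("dme-mir-283", "dme-mir-304"): 0.04,
        ("dme-mir-283", "dme-mir-12"): 0.02,
    })
    cls = corr.classify_cluster(_cluster(members, "283~12"), rep)
    assert cls.status == corr.UNCOORDINATED
    assert cls.uncorrelated_members == ["dme-mir-283"]


def test_uniformly_high_r_is_coordinated():
    members = list("abcd")
    rep = fake_report({p: 0.95 for p in combinations(members, 2)})
    cls = corr.classify_cluster(_cluster(members), rep)
    assert cls.status == corr.COORDINATED
    assert cls.min_pairwise_r == pytest.approx(0.95)


def test_two_member_cluster_low_r_lists_both():
    rep = fake_report({("a", "b"): 0.1})
    cls = corr.classify_cluster(_cluster(["a", "b"]), rep)
    assert cls.status == corr.UNCOORDINATED
    assert cls.uncorrelated_members == ["a", "b"]


def test_low_expression_members_are_set_aside():
    members = list("abc")
    rep = fake_report({p: 0.9 for p in combinations(members, 2)})
    cls = corr.classify_cluster(
        _cluster(members), rep, totals={"a": 10, "b": 500, "c": 500},
        min_total_count=50,
    )
    assert cls.status == corr.COORDINATED
    assert cls.low_expression_members == ["a"]


def oracle_classify(members, r_of, hi=0.6, lo=0.3):
    """Independent restatement of the classification rule via set logic."""
    pairs = list(combinations(members, 2))
    if all(r_of[p] > hi for p in pairs):
        return corr.COORDINATED, []
    if len(members) == 2:
        if r_of[pairs[0]] < lo:
            return corr.UNCOORDINATED, list(members)
        return corr.INDETERMINATE, []
    unc = []
    for g in members:
        rest = set(members) - {g}
        gone = all(
            r_of[p] < lo for p in pairs if g in p
        )
        coherent = all(
            r_of[p] > hi for p in pairs if set(p) <= rest
        )
        if gone and coherent:
            unc.append(g)
    if unc:
        return corr.UNCOORDINATED, unc
    return corr.INDETERMINATE, []


@pytest.mark.parametrize("size", [2, 3, 4, 5])
def test_classification_matches_exhaustive_rule_enumeration(size):
    members = [f"m{i}" for i in range(size)]
    cluster = _cluster(members)
    pairs = list(combinations(members, 2))
    rep = corr.CorrelationReport(arm_ids=members, n_libraries=9)
    for values in product((0.1, 0.5, 0.9), repeat=len(pairs)):
        r_of = dict(zip(pairs, values))
        rep._r = {frozenset(p): v for p, v in r_of.items()}
        got = corr.classify_cluster(cluster, rep)
        want_status, want_unc = oracle_classify(members, r_of)
        assert got.status == want_status
        assert sorted(got.uncorrelated_members) == sorted(want_unc)


def test_raising_lo_only_moves_toward_uncoordinated(rng):
    members = list("abcd")
    cluster = _cluster(members)
    pairs = list(combinations(members, 2))
    order = {corr.COORDINATED: 0, corr.INDETERMINATE: 1, corr.UNCOORDINATED: 2}
    for _ in range(200):
        r_of = {p: float(rng.uniform(-1, 1)) for p in pairs}
        rep = fake_report(r_of, arm_ids=members)
        ranks = [
            order[corr.classify_cluster(cluster, rep, lo=lo).status]
            for lo in (0.1, 0.3, 0.5)
        ]
        assert ranks == sorted(ranks)


def test_excluded_cluster_short_circuits():
    c = Cluster("281-1~281-2", ["dme-mir-281-1"], "chrT", "+", [],
                excluded=True)
    cls = corr.classify_cluster(c, fake_report({}))
    assert cls.status == corr.EXCLUDED
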