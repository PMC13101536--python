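"""Diversity, Bray-Curtis, Mantel, Spearman, regression, Venn partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import amfassembly as A
from amfassembly.community_io import OtuTable
from amfassembly.phylo_turnover import BntiResult
from amfassembly.pollution_index import PollutionResult
from conftest import random_count_table


class TestAlphaDiversity:
    def test_uniform_maximum(self):
        t = OtuTable(["s"], list("abcd"), np.full((1, 4), 25.0))
        d = A.alpha_diversity(t)[0]
        assert d.richness == 4
        assert d.shannon == pytest.approx(np.log(4))

    def test_single_otu(self):
        t = OtuTable(["s"], ["a", "b"], np.array([[9.0, 0.0]]))
        d = A.alpha_diversity(t)[0]
        assert (d.richness, d.shannon) == (1, 0.0)

    def test_hand_case(self):
        t = OtuTable(["s"], list("abc"), np.array([[50.0, 25.0, 25.0]]))
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert A.alpha_diversity(t)[0].shannon == pytest.approx(expected)

    def test_shannon_bounded_by_log_richness(self, neutral_table_small):
        for d in A.alpha_diversity(neutral_table_small):
            assert d.shannon <= np.log(max(d.richness, 1)) + 1e-12


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = OtuTable(["x", "y", "z"], list("ab"),
                     np.array([[3.0, 1.0], [6.0, 2.0], [0.0, 5.0]]))
        bc = A.bray_curtis(t)
        assert bc[0, 1] == pytest.approx(0.0)   # identical compositions
        assert bc[0, 2] < 1.0
        t2 = OtuTable(["x", "y"], list("ab"), np.array([[3.0, 0.0], [0.0, 5.0]]))
        assert A.bray_curtis(t2)[0, 1] == pytest.approx(1.0)

    def test_hand_case(self):
        t = OtuTable(["x", "y"], list("abc"),
                     np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5]]))
        assert A.bray_curtis(t)[0, 1] == pytest.approx(0.5)

    def test_range_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(1)
        t = random_count_table(rng, 8, 15)
        bc = A.bray_curtis(t)
        assert np.all((bc >= -1e-12) & (bc <= 1 + 1e-12))
        assert np.allclose(bc, bc.T)
        assert np.allclose(np.diag(bc), 0.0)


def euclid(points):
    p = np.asarray(points, float)
    return np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(-1))


class TestMantel:
    def test_perfect_concordance(self):
        rng = np.random.default_rng(2)
        d = euclid(rng.random((10, 2)))
        res = A.mantel_test(d, d.copy(), n_perm=199, seed=3)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        d1 = euclid(rng.random((9, 2)))
        d2 = euclid(rng.random((9, 2)))
        r = A.mantel_test(d1, d2, n_perm=99, seed=5).r
        perm = rng.permutation(9)
        r2 = A.mantel_test(d1[np.ix_(perm, perm)], d2[np.ix_(perm, perm)],
                           n_perm=99, seed=5).r
        assert r2 == pytest.approx(r)

    def test_constant_matrix_rejected(self):
        d = np.ones((5, 5)) - np.eye(5)
        d2 = euclid(np.random.default_rng(6).random((5, 2)))
        with pytest.raises(ValueError):
            A.mantel_test(d, d2, n_perm=99, seed=1)

    def test_agrees_with_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        d1 = euclid(rng.random((12, 3)))
        d2 = euclid(rng.random((12, 3)))
        ours = A.mantel_test(d1, d2, n_perm=999, seed=8)
        r_ref, p_ref, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1), skbio_distance.DistanceMatrix(d2),
            method="pearson", permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(r_ref, abs=1e-10)
        assert ours.p_value == pytest.approx(p_ref, abs=0.05)

    def test_p_value_never_zero(self):
        rng = np.random.default_rng(9)
        d = euclid(rng.random((8, 2)))
        res = A.mantel_test(d, d * 2.0, n_perm=99, seed=10)
        assert res.p_value >= 1 / 100


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        y = pd.DataFrame({"cube": np.arange(10.0) ** 3, "neg": -np.arange(10.0)})
        rho, _ = A.spearman_matrix(x, y)
        assert rho.loc["x", "cube"] == pytest.approx(1.0)
        assert rho.loc["x", "neg"] == pytest.approx(-1.0)

    def test_matches_pearson_on_midranks_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.integers(0, 5, size=30).astype(float)  # heavy ties
            b = rng.integers(0, 5, size=30).astype(float)
            rho, _ = A.spearman_matrix(pd.DataFrame({"a": a}), pd.DataFrame({"b": b}))
            oracle = np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1]
            assert rho.loc["a", "b"] == pytest.approx(oracle, abs=1e-10)

    def test_constant_column_flagged_not_fatal(self):
        x = pd.DataFrame({"c": np.ones(6), "v": np.arange(6.0)})
        y = pd.DataFrame({"y": np.arange(6.0)})
        rho, p = A.spearman_matrix(x, y)
        assert np.isnan(rho.loc["c", "y"])
        assert rho.loc["v", "y"] == pytest.approx(1.0)


def make_pairs(pn_values, bnti_values):
    ids = [f"s{i}" for i in range(len(pn_values))]
    poll = [PollutionResult(s, {}, pn, pn > 1) for s, pn in zip(ids, pn_values)]
    k = 0
    res = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            res.append(BntiResult(ids[i], ids[j], 1.0, 1.0, 0.1,
                                  bnti_values[k], 99, False))
            k += 1
    return res, poll


class TestBntiVsPollution:
    def test_noiseless_linear_recovery(self):
        pn = [0.5, 1.0, 1.5, 2.0, 3.0]
        n = len(pn)
        xs = [(pn[i] + pn[j]) / 2 for i in range(n) for j in range(i + 1, n)]
        bnti = [2.0 * x - 1.0 for x in xs]
        res, poll = make_pairs(pn, bnti)
        reg = A.bnti_vs_pollution(res, poll, pairing="pair_mean")
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(-1.0)
        assert reg.r_squared == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        res, poll = make_pairs([1.0, 1.0, 1.0, 1.0], np.arange(6.0))
        with pytest.raises(ValueError):
            A.bnti_vs_pollution(res, poll)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            pn = rng.random(6) * 3
            bnti = rng.normal(0, 2, size=15)
            res, poll = make_pairs(pn, bnti)
            reg = A.bnti_vs_pollution(res, poll)
            x = np.array([(pn[i] + pn[j]) / 2 for i in range(6) for j in range(i + 1, 6)])
            X = np.column_stack([x, np.ones_like(x)])
            slope, intercept = np.linalg.solve(X.T @ X, X.T @ bnti)
            assert reg.slope == pytest.approx(slope, abs=1e-10)
            assert reg.intercept == pytest.approx(intercept, abs=1e-10)

    def test_abs_difference_pairing(self):
        pn = [0.0, 1.0, 3.0]
        res, poll = make_pairs(pn, [1.0, 3.0, 2.0])
        reg = A.bnti_vs_pollution(res, poll, pairing="pair_abs_difference")
        assert reg.n == 3


class TestVennPartition:
    def _records(self, cats):
        return [A.SampleMetadata(f"s{i}", c, float(i)) for i, c in enumerate(cats)]

    def test_everywhere_otu_in_full_intersection(self):
        counts = np.ones((4, 1))
        t = OtuTable([f"s{i}" for i in range(4)], ["cosmo"], counts)
        out = A.shared_otu_partition(t, self._records(A.CATEGORIES))
        assert out["regions"]["&".join(A.CATEGORIES)] == 1
        assert out["shared_by_all_fraction"] == 1.0

    def test_disjoint_otus_in_singletons(self):
        counts = np.eye(4)
        t = OtuTable([f"s{i}" for i in range(4)], [f"o{i}" for i in range(4)], counts)
        out = A.shared_otu_partition(t, self._records(A.CATEGORIES))
        assert all(v == 1 for v in out["regions"].values())
        assert all("&" not in k for k in out["regions"])

    def test_regions_partition_observed_otus(self):
        rng = np.random.default_rng(13)
        t = random_count_table(rng, 12, 40)
        cats = [A.CATEGORIES[i % 4] for i in range(12)]
        out = A.shared_otu_partition(t, self._records(cats))
        assert sum(out["regions"].values()) == out["n_otus_observed"] == 40

    def test_empty_category_warned_and_skipped(self, caplog):
        counts = np.ones((3, 2))
        t = OtuTable([f"s{i}" for i in range(3)], ["a", "b"], counts)
        with caplog.at_level("WARNING", logger="amfassembly"):
            out = A.shared_otu_partition(t, self._records(["urban", "urban", "rural"]))
        assert out["categories"] == ["urban", "rural"]
        assert any("empty categor" in r.message for r in caplog.records)


class TestOrdinationContract:
    def test_one_row_per_sample(self):
        coords = pd.DataFrame(np.random.default_rng(14).random((3, 2)),
                              index=["s2", "s1", "s3"], columns=["nmds1", "nmds2"])
        out = A.check_ordination(coords, ["s1", "s2", "s3"])
        assert list(out.index) == ["s1", "s2", "s3"]
        with pytest.raises(ValueError):
            A.check_ordination(coords, ["s1", "s4"])


@pytest.mark.parametrize("p,expected", [(0.0005, "***"), (0.005, "**"),
                                        (0.03, "*"), (0.2, "")])
def test_significance_stars(p, expected):
    assert A.significance_stars(p) == expected
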