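import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from oracles import exhaustive_anosim

from hgtenrich import stats as hs
from hgtenrich.errors import DegenerateDataError, DomainError, InputError, InsufficientDataError
from hgtenrich.models import DistanceMatrix


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(values))]
    return DistanceMatrix(ids=ids, values=values)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        prof = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["x", "y"])
        assert hs.bray_curtis(prof).values[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        prof = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["x", "y"])
        assert hs.bray_curtis(prof).values[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        prof = pd.DataFrame([[2.0, 2.0], [1.0, 1.0]], index=["x", "y"])
        assert hs.bray_curtis(prof).values[0, 1] == pytest.approx(1 / 3)

    def test_matches_scipy_on_nonnegative_profiles(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.uniform(0, 10, (12, 6)))
        ours = hs.bray_curtis(prof).values
        ref = squareform(pdist(prof.to_numpy(), metric="braycurtis"))
        assert np.allclose(ours, ref, atol=1e-12)

    def test_negative_entries_shifted(self):
        prof = pd.DataFrame([[-1.0, 1.0], [0.0, 2.0]], index=["x", "y"])
        out = hs.bray_curtis(prof)  # shifted to [[0,2],[1,3]]
        assert out.values[0, 1] == pytest.approx((1 + 1) / (2 + 4))

    def test_negative_entries_rejected_under_strict_policy(self):
        prof = pd.DataFrame([[-1.0, 1.0], [0.0, 2.0]])
        with pytest.raises(DomainError):
            hs.bray_curtis(prof, offset_policy="error_on_negative")

    def test_all_zero_rows_warn_distance_zero(self):
        prof = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning):
            out = hs.bray_curtis(prof)
        assert out.values[0, 1] == 0.0


def _separated_groups():
    # two tight clusters of 3, far apart: perfect separation
    within, between = 1.0, 10.0
    n = 6
    vals = np.full((n, n), between)
    for i, j in itertools.product(range(3), range(3)):
        vals[i, j] = within
        vals[i + 3, j + 3] = within
    np.fill_diagonal(vals, 0)
    labels = ["u"] * 3 + ["v"] * 3
    return _dm(vals), np.array(labels)


class TestAnosimOneway:
    def test_fully_separated_groups_r_one(self):
        dist, labels = _separated_groups()
        res = hs.anosim_oneway(dist, labels, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_random_labels_mean_r_near_zero(self):
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(30):
            v = rng.uniform(1, 5, (10, 10))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            labels = rng.permutation(["u"] * 5 + ["v"] * 5)
            rs.append(hs.anosim_oneway(_dm(v), labels, n_perm=9, seed=0).statistic)
        assert abs(np.mean(rs)) < 0.1

    def test_r_stays_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            v = rng.uniform(0, 1, (8, 8))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            labels = rng.permutation(["u"] * 4 + ["v"] * 4)
            r = hs.anosim_oneway(_dm(v), labels, n_perm=9, seed=0).statistic
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12

    def test_matches_exhaustive_enumeration_n8(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(1, 9, (8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        labels = np.array(["u"] * 4 + ["v"] * 4)
        dist = _dm(v)
        r_oracle, p_oracle = exhaustive_anosim(dist.values, labels)
        res = hs.anosim_oneway(dist, labels, n_perm=999, seed=11)
        assert res.statistic == pytest.approx(r_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=0.02)

    def test_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        v = rng.uniform(1, 9, (12, 12))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        labels = ["u"] * 6 + ["v"] * 6
        ours = hs.anosim_oneway(_dm(v), labels, n_perm=999, seed=0)
        ref = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(v), grouping=list(labels), permutations=999
        )
        assert ours.statistic == pytest.approx(float(ref["test statistic"]), abs=1e-12)
        assert abs(ours.p_value - float(ref["p-value"])) < 0.05

    def test_small_group_error_names_group(self):
        dist, labels = _separated_groups()
        labels = np.array(["u"] * 5 + ["w"])
        with pytest.raises(InsufficientDataError, match="w"):
            hs.anosim_oneway(dist, labels)

    def test_seed_reproducible_and_p_never_zero(self):
        dist, labels = _separated_groups()
        a = hs.anosim_oneway(dist, labels, n_perm=99, seed=5)
        b = hs.anosim_oneway(dist, labels, n_perm=99, seed=5)
        assert a == b
        assert a.p_value >= 1 / 100


class TestAnosimTwoway:
    def test_constant_second_factor_equals_oneway(self):
        dist, labels = _separated_groups()
        const = np.array(["k"] * 6)
        two, _ = hs.anosim_twoway(dist, labels, const, n_perm=99, seed=7)
        one = hs.anosim_oneway(dist, labels, n_perm=99, seed=7)
        assert two.statistic == pytest.approx(one.statistic)
        assert two.p_value == pytest.approx(one.p_value)

    def test_swapping_factors_swaps_results(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(1, 9, (16, 16))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        f1 = np.array((["u"] * 4 + ["v"] * 4) * 2)
        f2 = np.array(["x"] * 8 + ["y"] * 8)
        a1, a2 = hs.anosim_twoway(_dm(v), f1, f2, n_perm=49, seed=9)
        b2, b1 = hs.anosim_twoway(_dm(v), f2, f1, n_perm=49, seed=9)
        assert a1.statistic == pytest.approx(b1.statistic)
        assert a2.statistic == pytest.approx(b2.statistic)

    def test_no_valid_stratum_rejected(self):
        dist, labels = _separated_groups()
        strata = np.array(["s1", "s2", "s3"] * 2)  # every stratum has 2 singletons
        with pytest.raises(InsufficientDataError):
            hs.anosim_twoway(dist, labels, strata)


class TestMantel:
    @staticmethod
    def _random_dm(rng, n=10):
        v = rng.uniform(1, 9, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        return _dm(v)

    def test_identity_gives_r_one(self):
        d = self._random_dm(np.random.default_rng(0))
        res = hs.mantel(d, d, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_affine_invariance(self):
        d = self._random_dm(np.random.default_rng(1))
        v2 = 3.0 + 2.0 * d.values
        np.fill_diagonal(v2, 0)
        res = hs.mantel(d, _dm(v2, ids=d.ids), n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(2)
        d1 = self._random_dm(rng, 12)
        d2 = self._random_dm(rng, 12)
        ours = hs.mantel(d1, d2, n_perm=999, seed=0)
        r_ref, p_ref, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(d1.values), skbio_stats.DistanceMatrix(d2.values),
            permutations=999, alternative="greater",
        )
        assert ours.statistic == pytest.approx(float(r_ref), abs=1e-10)
        assert abs(ours.p_value - float(p_ref)) < 0.1

    def test_null_p_values_spread_uniformly(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(30):
            d1 = self._random_dm(rng, 12)
            d2 = self._random_dm(rng, 12)
            ps.append(hs.mantel(d1, d2, n_perm=99, seed=0).p_value)
        # mean of Uniform(0,1] over 30 draws: 0.5 +/- 3*sqrt(1/12/30)
        assert abs(np.mean(ps) - 0.5) < 3 * np.sqrt(1 / 12 / 30)

    def test_size_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(InputError):
            hs.mantel(self._random_dm(rng, 5), self._random_dm(rng, 6))


class TestRootDistanceMatrix:
    def test_absolute_differences(self):
        out = hs.root_distance_matrix(pd.Series([1.0, 3.0, 6.0], index=list("abc")))
        assert out.values[0, 1] == 2.0
        assert out.values[0, 2] == 5.0
        assert out.values[1, 2] == 3.0

    def test_constant_vector_all_zero(self):
        out = hs.root_distance_matrix(pd.Series([2.0, 2.0], index=list("ab")))
        assert (out.values == 0).all()

    def test_missing_value_names_bacterium(self):
        with pytest.raises(InputError, match="bad_b"):
            hs.root_distance_matrix(pd.Series([1.0, np.nan], index=["ok", "bad_b"]))

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 100), min_size=3, max_size=8))
    def test_triangle_inequality(self, vec):
        s = pd.Series(vec, index=[f"b{i}" for i in range(len(vec))])
        D = hs.root_distance_matrix(s).values
        n = len(vec)
        for i, j, k in itertools.permutations(range(n), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-9
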