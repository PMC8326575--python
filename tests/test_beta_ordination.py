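import itertools

import numpy as np
import pytest
import skbio

from amfpipe import (
    ConfigError,
    DistanceMatrix,
    bray_curtis,
    pcoa,
    permanova,
)
from amfpipe.beta_ordination import _permanova_stats
from test_community_tables import make_table


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        table = make_table({"t1": [5, 5], "t2": [3, 3]})
        dm = bray_curtis(table)
        assert dm.d[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        table = make_table({"t1": [5, 0], "t2": [0, 7]})
        dm = bray_curtis(table)
        assert dm.d[0, 1] == pytest.approx(1.0)

    def test_hand_computed(self):
        table = make_table({"t1": [6, 2], "t2": [2, 2]})
        dm = bray_curtis(table)
        assert dm.d[0, 1] == pytest.approx((4 + 0) / (8 + 4))

    def test_all_zero_column_rejected(self):
        table = make_table({"t1": [5, 0], "t2": [1, 0]})
        with pytest.raises(ConfigError):
            bray_curtis(table)


class TestPcoa:
    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords, eigvals, proportion = pcoa(DistanceMatrix(["a", "b", "c"], d))
        positive = eigvals[eigvals > 1e-10]
        assert len(positive) == 2
        assert positive[0] == pytest.approx(positive[1])

    def test_round_trip_for_euclidean_input(self):
        rng = np.random.default_rng(40)
        points = rng.normal(size=(6, 2))
        d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        labels = [f"s{i}" for i in range(6)]
        coords, _, _ = pcoa(DistanceMatrix(labels, d))
        X = coords.to_numpy()
        recovered = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        assert np.allclose(recovered, d, atol=1e-9)

    def test_duplicate_samples_coincide(self):
        d = np.array(
            [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
        )
        coords, _, _ = pcoa(DistanceMatrix(["a", "a2", "b"], d))
        assert np.allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)

    def test_matches_skbio(self):
        rng = np.random.default_rng(41)
        X = rng.poisson(20, size=(5, 8)).astype(float)
        table = make_table({f"t{i}": list(X[i]) for i in range(5)})
        dm = bray_curtis(table)
        coords, eigvals, _ = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.d, ids=dm.labels), method="eigh"
        )
        ref_pos = np.sort(ref.eigvals.values[ref.eigvals.values > 1e-10])[::-1]
        ours = np.sort(eigvals[eigvals > 1e-10])[::-1]
        assert np.allclose(ours, ref_pos, atol=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(ConfigError):
            pcoa(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestPermanova:
    def _structureless(self, rng, n=12):
        X = rng.normal(size=(n, 4))
        d = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        return DistanceMatrix([f"s{i}" for i in range(n)], d)

    def test_separated_clouds_minimum_p(self):
        rng = np.random.default_rng(50)
        a = rng.normal(0, 0.1, size=(10, 2))
        b = rng.normal(50, 0.1, size=(10, 2))
        X = np.vstack([a, b])
        d = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        dm = DistanceMatrix([f"s{i}" for i in range(20)], d)
        result = permanova(dm, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=1)
        assert result.p == pytest.approx(1 / 1000)

    def test_f_and_r2_match_exhaustive_permutations(self):
        # 2 groups of 2: enumerate all 4! label orders by brute force
        rng = np.random.default_rng(51)
        X = rng.normal(size=(4, 3))
        d = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        d2 = d**2
        labels = np.array(["a", "a", "b", "b"])
        F_obs, R2 = _permanova_stats(
            d2, [np.array([0, 1]), np.array([2, 3])]
        )
        n_ge = 0
        n_total = 0
        for perm in itertools.permutations(range(4)):
            permuted = labels[list(perm)]
            idx = [np.flatnonzero(permuted == g) for g in ("a", "b")]
            F_perm, _ = _permanova_stats(d2, idx)
            n_total += 1
            n_ge += F_perm >= F_obs - 1e-12
        exact_p = n_ge / n_total
        dm = DistanceMatrix(list("wxyz"), d)
        result = permanova(dm, list(labels), n_perm=2000, seed=3)
        assert result.F == pytest.approx(F_obs)
        assert abs(result.p - exact_p) < 0.05
        # R2 plus residual fraction is exactly 1
        ss_frac_resid = 1 - R2
        assert R2 + ss_frac_resid == pytest.approx(1.0, abs=1e-15)

    def test_equal_distances_give_f_one(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("abcd"), d)
        result = permanova(dm, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert result.F == pytest.approx(1.0)

    def test_invariances(self):
        rng = np.random.default_rng(52)
        dm = self._structureless(rng)
        labels = ["a"] * 6 + ["b"] * 6
        r1 = permanova(dm, labels, n_perm=99, seed=7)
        r2 = permanova(dm, ["grp_" + l for l in labels], n_perm=99, seed=7)
        assert r1.p == r2.p and r1.F == pytest.approx(r2.F)

    def test_matches_skbio_f(self):
        rng = np.random.default_rng(53)
        dm = self._structureless(rng, n=10)
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(dm, labels, n_perm=99, seed=1)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.d, ids=dm.labels), grouping=labels, permutations=0
        )
        assert ours.F == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(54)
        dm = self._structureless(rng, n=5)
        with pytest.raises(ConfigError):
            permanova(dm, ["a", "a", "a", "a", "b"])

    def test_null_calibration(self):
        # under a structureless null the rejection rate at alpha = 0.05
        # stays near nominal
        rng = np.random.default_rng(55)
        n_sim, rejections = 300, 0
        labels = ["a"] * 5 + ["b"] * 5
        for s in range(n_sim):
            dm = self._structureless(rng, n=10)
            result = permanova(dm, labels, n_perm=99, seed=1000 + s)
            rejections += result.p <= 0.05
        assert 0.02 <= rejections / n_sim <= 0.08
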