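"""PCA, clustering, correlation thresholds, BH step-up, paired comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sweatlipidomics.multivariate import (
    bh_reject,
    correlation_matrix,
    critical_r,
    hca,
    network_summary,
    paired_compare,
    pca,
)
from sweatlipidomics.normalization import pqn, scale_matrix
from sweatlipidomics.synthetic import GeneratorParams, generate_dataset


def bh_brute_force(p, q):
    """Independent step-up oracle: largest k with p_(k) <= k q / m."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    if k_star:
        reject[order[:k_star]] = True
    return reject


class TestPca:
    def test_collinear_points_single_component(self):
        t = np.linspace(0, 1, 8)
        m = pd.DataFrame(np.outer(t, [1.0, -2.0, 0.5]))
        res = pca(m)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_explained_variance_matches_eigenvalue_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = pd.DataFrame(rng.normal(size=(10, 6)))
            res = pca(m)
            eig = np.sort(np.linalg.eigvalsh(np.cov(m.to_numpy().T)))[::-1]
            oracle = eig / eig.sum()
            np.testing.assert_allclose(
                res.explained_variance_ratio, oracle[:len(res.explained_variance_ratio)],
                atol=1e-8)

    def test_isotropic_gaussian_splits_evenly(self):
        rng = np.random.default_rng(42)
        m = pd.DataFrame(rng.normal(size=(4000, 2)))
        res = pca(m)
        np.testing.assert_allclose(res.explained_variance_ratio, [0.5, 0.5],
                                   atol=0.05)

    def test_full_reconstruction(self):
        m = pd.DataFrame(np.random.default_rng(1).normal(size=(9, 5)))
        res = pca(m)
        np.testing.assert_allclose(res.reconstruct(), m.to_numpy(), atol=1e-8)

    def test_excess_components_truncated_with_warning(self):
        m = pd.DataFrame(np.random.default_rng(2).normal(size=(4, 3)))
        with pytest.warns(UserWarning, match="truncated"):
            res = pca(m, n_components=10)
        assert res.scores.shape[1] == 3


class TestHca:
    def test_separated_blobs_pure(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.1, size=(6, 4))
        b = rng.normal(10, 0.1, size=(6, 4))
        m = pd.DataFrame(np.vstack([a, b]))
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=m.index)
        res = hca(m, k=2, groups=groups)
        assert res.purity == 1.0

    def test_identical_samples_zero_heights(self):
        m = pd.DataFrame(np.ones((5, 3)))
        res = hca(m, k=2)
        np.testing.assert_allclose(res.merge_heights, 0.0, atol=1e-12)

    def test_k_larger_than_n_rejected(self):
        m = pd.DataFrame(np.ones((3, 2)))
        with pytest.raises(ValueError):
            hca(m, k=5)

    def test_individual_recovery_on_synthetic_lnpqn(self, default_dataset):
        table, _ = default_dataset
        analytes = table.select_labels(table.analyte_labels())
        matrix = scale_matrix(
            scale_matrix(pqn(analytes.study_areas).matrix, "ln"), "pareto")
        individuals = analytes.manifest.loc[analytes.study_ids, "individual"]
        res = hca(matrix, k=10, groups=individuals)
        assert res.purity >= 0.9


class TestCriticalR:
    def test_study_size_threshold(self):
        assert critical_r(60, 0.05) <= 0.26

    def test_three_samples_closed_form(self):
        # t(0.975, df=1) = 12.706 -> r* = sqrt(t^2/(t^2+1))
        t = 12.706204736
        assert critical_r(3, 0.05) == pytest.approx(
            np.sqrt(t ** 2 / (t ** 2 + 1)), abs=1e-6)

    def test_alpha_to_one_limit(self):
        assert critical_r(30, 0.999) < 0.01

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            critical_r(2, 0.05)


class TestCorrelationMatrix:
    def _matrix(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=10)
        return pd.DataFrame({
            "FA 16:0": base,
            "FA 18:0": 3 * base + 1,
            "PC 34:1": -base,
            "PC 36:2": rng.normal(size=10),
            "TG 52:2": np.ones(10),
        })

    def test_proportional_and_antiproportional(self):
        r, mask = correlation_matrix(self._matrix())
        assert r.loc["FA 16:0", "FA 16:0"] == pytest.approx(1.0)
        assert r.loc["FA 16:0", "FA 18:0"] == pytest.approx(1.0)
        assert r.loc["FA 16:0", "PC 34:1"] == pytest.approx(-1.0)

    def test_mask_symmetric_with_true_diagonal(self):
        r, mask = correlation_matrix(self._matrix())
        assert (mask.to_numpy() == mask.to_numpy().T).all()
        assert np.diag(mask.to_numpy()).all()

    def test_zero_variance_lipid_missing(self):
        r, _ = correlation_matrix(self._matrix())
        assert r.loc["TG 52:2", "FA 16:0"] != r.loc["TG 52:2", "FA 16:0"]  # NaN

    def test_columns_grouped_by_class(self):
        r, _ = correlation_matrix(self._matrix())
        classes = [c.split()[0] for c in r.columns]
        assert classes == sorted(classes)


class TestBhRejection:
    def test_hand_example(self):
        reject = bh_reject([0.01, 0.02, 0.2, 0.9], q=0.25)
        assert reject.tolist() == [True, True, False, False]

    def test_matches_brute_force_exhaustively(self):
        """Step-up flags agree with the oracle on a 0.05 p-value grid."""
        grid = np.round(np.arange(0.05, 1.0001, 0.05), 10)
        for m in range(1, 5):
            for combo in itertools.combinations_with_replacement(grid, m):
                p = np.array(combo)
                np.testing.assert_array_equal(
                    bh_reject(p, 0.25), bh_brute_force(p, 0.25))

    def test_matches_brute_force_sampled_longer(self):
        grid = np.round(np.arange(0.05, 1.0001, 0.05), 10)
        rng = np.random.default_rng(9)
        for m in (5, 6, 7, 8):
            for _ in range(300):
                p = rng.choice(grid, size=m)
                q = rng.choice([0.05, 0.1, 0.25])
                np.testing.assert_array_equal(
                    bh_reject(p, q), bh_brute_force(p, q))

    def test_flags_monotone_in_p(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=40)
        reject = bh_reject(p, 0.25)
        if reject.any():
            assert p[reject].max() <= p[~reject].min() or not (~reject).any()


class TestPairedCompare:
    def test_identical_sides_nothing_significant(self, default_dataset):
        table, _ = default_dataset
        analytes = table.select_labels(table.analyte_labels())
        # overwrite R with the matching L values
        man = analytes.manifest
        for (ind, day), ids in man[man["type"] == "study"].groupby(
                ["individual", "day"]).groups.items():
            sides = man.loc[ids, "side"]
            l_id = sides.index[sides == "L"][0]
            r_id = sides.index[sides == "R"][0]
            analytes.areas.loc[r_id] = analytes.areas.loc[l_id]
        res = paired_compare(analytes, q=0.25)
        assert res.n_significant == 0
        np.testing.assert_allclose(res.results["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.results["log2_fc"], 0.0, atol=1e-12)

    def test_pairing_uses_individual_day(self, default_dataset):
        table, _ = default_dataset
        res = paired_compare(table.select_labels(table.analyte_labels()))
        assert res.n_pairs == 30

    def test_network_summary_nodes(self, default_dataset):
        table, _ = default_dataset
        res = paired_compare(table.select_labels(table.analyte_labels()))
        net = network_summary(res)
        assert len(net["nodes"]) == len(res.results)
        assert {"lipid_class", "p", "log2_fc"} <= set(net["nodes"][0])
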