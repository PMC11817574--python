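"""Spearman correlation, avg.RAE and method-comparison statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import petadc as pa
from petadc.analysis import correlation_grid


def rank_oracle(x):
    """Average ranks computed from first principles (sort + tie groups)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    rx, ry = rank_oracle(x), rank_oracle(y)
    mx, my = rx.mean(), ry.mean()
    num = float(np.sum((rx - mx) * (ry - my)))
    den = math.sqrt(float(np.sum((rx - mx) ** 2)) * float(np.sum((ry - my) ** 2)))
    return num / den


class TestSpearman:
    def test_perfect_inverse_and_monotone_invariance(self):
        rho, _ = pa.spearman_rho([1, 2, 3], [3, 2, 1])
        assert rho == -1.0
        x = np.array([0.3, 1.1, 2.0, 5.5, 9.0, 9.5, 12.0, 15.0])
        rho, p = pa.spearman_rho(x, np.exp(x))
        assert rho == 1.0
        assert p == 0.0

    def test_matches_first_principles_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.normal(0, 1, n)
            if np.unique(x).size < 2:
                continue
            rho, _ = pa.spearman_rho(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_matches_scipy_rho(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 25)
        y = 0.5 * x + rng.normal(0, 1, 25)
        rho, p = pa.spearman_rho(x, y)
        sp = stats.spearmanr(x, y)
        assert rho == pytest.approx(sp.statistic, abs=1e-12)
        assert p == pytest.approx(sp.pvalue, rel=1e-9)

    def test_exact_small_sample_p_by_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.2, 3.4, 2.2, 4.8]
        rho, p = pa.spearman_rho(x, y)
        rx = rank_oracle(x)
        ry = rank_oracle(y)
        hits = 0
        total = 0
        for perm in itertools.permutations(range(4)):
            total += 1
            if abs(spearman_oracle(rx, ry[list(perm)])) >= abs(rho) - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / total, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pa.spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestAvgRae:
    def test_identity_and_uniform_scaling(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0.5, 10.0, 200)
        assert pa.avg_rae(x, x) == 0.0
        assert pa.avg_rae(1.1 * x, x) == pytest.approx(10.0, rel=1e-9)

    def test_hand_evaluated_formula(self):
        assert pa.avg_rae([2.0, 2.0], [1.0, 2.0]) == pytest.approx(50.0, abs=1e-12)

    def test_floor_exclusion_counted(self):
        value, n_excl = pa.avg_rae(
            [2.0, 5.0, 7.0], [1.0, 0.0, -3.0], with_count=True
        )
        assert n_excl == 2
        assert value == pytest.approx(100.0)
        with pytest.raises(ValueError):
            pa.avg_rae([1.0, 2.0], [0.0, 0.0])


class TestMannWhitney:
    def test_fully_separated_exact_p(self):
        # U = 0; two-sided exact p = 2 / C(6,3) = 0.1
        assert pa.mann_whitney([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_maximal_p(self):
        p = pa.mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_exhaustive_permutation_oracle(self):
        values = np.array([0.3, 1.7, 2.2, 3.1, 4.9, 5.4, 6.6, 8.2])
        n1 = 4
        # null distribution of U over all C(8,4) group assignments
        def u_stat(group):
            xs = values[list(group)]
            ys = values[[i for i in range(8) if i not in group]]
            return sum((x > y) for x in xs for y in ys)

        splits = list(itertools.combinations(range(8), n1))
        u_all = np.array([u_stat(g) for g in splits])
        for group in splits[::7]:
            xs = values[list(group)]
            ys = values[[i for i in range(8) if i not in group]]
            u = u_stat(group)
            p_oracle = min(1.0, 2.0 * min(np.mean(u_all <= u), np.mean(u_all >= u)))
            assert pa.mann_whitney(xs, ys) == pytest.approx(p_oracle, abs=1e-12)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            pa.mann_whitney([1.0, 2.0], [3.0, 4.0, 5.0])


class TestCorrelationGrid:
    @staticmethod
    def _table(n=10, seed=0, constant_col=None):
        rng = np.random.default_rng(seed)
        data = {"subject_id": [f"s{i}" for i in range(n)]}
        for f in pa.FEATURE_NAMES:
            data[f"adc_{f}"] = rng.normal(1.0, 0.2, n)
            data[f"suv_{f}"] = rng.normal(10.0, 2.0, n)
        if constant_col:
            data[constant_col] = np.ones(n)
        return pd.DataFrame(data)

    def test_antimonotone_truth_gives_exact_minus_one(self):
        table = self._table(8, seed=1)
        table["adc_mean"] = np.arange(8.0)
        table["suv_mean"] = -np.arange(8.0) ** 3
        grid = correlation_grid(table, "CT_reference", 0)
        assert grid.rho[0, 0] == -1.0
        assert grid.n == 8

    def test_degenerate_column_marked_missing_not_zero(self):
        grid = correlation_grid(self._table(8, 2, "suv_kurtosis"), "CT_reference", 0)
        assert np.isnan(grid.rho[0, 4])
        assert ("mean", "kurtosis") in grid.missing_cells
        assert not np.isnan(grid.rho[0, 0])

    def test_grid_invariant_under_monotone_feature_transforms(self):
        table = self._table(12, seed=3)
        g1 = correlation_grid(table, "CT_reference", 0)
        warped = table.copy()
        for f in pa.FEATURE_NAMES:
            warped[f"adc_{f}"] = np.exp(warped[f"adc_{f}"])
            warped[f"suv_{f}"] = warped[f"suv_{f}"] ** 3
        g2 = correlation_grid(warped, "CT_reference", 0)
        assert np.allclose(g1.rho, g2.rho, atol=1e-12)


class TestFeatureErrorReport:
    def test_identical_methods_give_zero_error_and_na_tests(self):
        spec = pa.PhantomSpec.compact(pet_noise_sigma=0.0)
        bias = (
            pa.BiasSpec("CT_reference", 0.0),
            pa.BiasSpec("A_like", 0.0),
            pa.BiasSpec("B_like", 0.0),
        )
        cohort = pa.generate_cohort(
            spec, n_subjects=4, n_pz=2, coupling_rho=-0.5, seed=21, bias_specs=bias
        )
        report = pa.feature_error_report(cohort, "CT_reference", ("A_like", "B_like"))
        for label in ("A_like", "B_like"):
            assert np.allclose(report.table[f"{label}_mean"], 0.0)
        assert report.table["t_test_p"].isna().all()

    def test_report_structure_on_default_methods(self, small_cohort):
        report = pa.feature_error_report(small_cohort)
        assert list(report.table.index) == list(pa.FEATURE_NAMES)
        assert (report.table[["MRI_like_mean", "DL_like_mean"]] >= 0).all().all()
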