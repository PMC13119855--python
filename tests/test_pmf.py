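"""PMF solver: uncertainty model, objective oracle, recovery and
diagnostics."""

import numpy as np
import pandas as pd
import pytest

from soilrisk import pmf
from soilrisk.core_io import METALS


def q_oracle(X, U, G, F):
    """Naive triple-loop evaluation of the weighted objective."""
    n, m = X.shape
    p = G.shape[1]
    total = 0.0
    for i in range(n):
        for j in range(m):
            recon = 0.0
            for k in range(p):
                recon += G[i, k] * F[k, j]
            total += ((X[i, j] - recon) / U[i, j]) ** 2
    return total


class TestBuildUncertainty:
    def test_below_mdl_branch(self, reference):
        """A Cd cell at 0.02 ≤ MDL 0.03 gets u = (5/6)·MDL = 0.025."""
        X = pd.DataFrame({"Cd": [0.02]})
        assert pmf.build_uncertainty(X, reference).iloc[0, 0] == pytest.approx(0.025)

    def test_above_mdl_branch(self, reference):
        X = pd.DataFrame({"Cd": [1.0]})
        u = pmf.build_uncertainty(X, reference, rsd=0.2).iloc[0, 0]
        assert u == pytest.approx(np.sqrt(0.2**2 + 0.015**2), rel=1e-12)
        assert u == pytest.approx(0.20056, abs=5e-6)

    def test_mdl_term_negligible_for_large_values(self, reference):
        X = pd.DataFrame({"As": [8.87]})
        u = pmf.build_uncertainty(X, reference).iloc[0, 0]
        assert u == pytest.approx(1.774, abs=1e-3)

    def test_negative_or_nonfinite_rejected(self, reference):
        with pytest.raises(ValueError):
            pmf.build_uncertainty(pd.DataFrame({"Cd": [-1.0]}), reference)


class TestObjective:
    @pytest.mark.parametrize("seed", range(5))
    def test_q_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m, p = 5, 7, 3
        X = rng.uniform(0.1, 10, (n, m))
        U = rng.uniform(0.05, 1, (n, m))
        G = rng.uniform(0, 2, (n, p))
        F = rng.uniform(0, 5, (p, m))
        assert pmf.q_value(X, U, G, F) == pytest.approx(
            q_oracle(X, U, G, F), rel=1e-10
        )

    def test_fixed_3x3_candidate(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 1.0], [0.5, 0.5, 4.0]])
        U = np.full((3, 3), 0.5)
        G = np.array([[1.0], [1.0], [1.0]])
        F = np.array([[1.0, 1.0, 2.0]])
        assert pmf.q_value(X, U, G, F) == pytest.approx(q_oracle(X, U, G, F), rel=1e-12)

    def test_robust_q_downweights_outliers(self):
        X = np.array([[10.0, 1.0], [1.0, 1.0]])
        U = np.full((2, 2), 0.1)
        G = np.ones((2, 1))
        F = np.array([[1.0, 1.0]])  # cell (0,0) has scaled residual 90
        assert pmf.q_value(X, U, G, F, robust=True) < pmf.q_value(X, U, G, F)


class TestFit:
    def test_rank_one_data_fit_perfectly(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(0.5, 2, 12)
        f = rng.uniform(1, 5, 6)
        X = np.outer(g, f)
        U = np.full(X.shape, 0.3)
        model = pmf.fit(X, U, p=1, n_starts=3, seed=1)
        assert model.Q_true < 1e-6 * X.size

    def test_q_trace_monotone_non_increasing(self, pmf_base):
        _, _, model, _ = pmf_base
        trace = np.array(model.q_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1.0))

    def test_model_q_equals_oracle_at_solution(self, pmf_base):
        X, U, model, _ = pmf_base
        assert model.Q_true == pytest.approx(
            q_oracle(X.to_numpy(), U.to_numpy(), model.G, model.F), rel=1e-10
        )

    def test_scale_indeterminacy_leaves_q_and_shares_unchanged(self, pmf_base):
        X, U, model, _ = pmf_base
        d = np.array([2.0, 0.5, 3.0, 1.0])
        G2, F2 = model.G * d, model.F / d[:, None]
        assert pmf.q_value(X, U, G2, F2) == pytest.approx(model.Q_true, rel=1e-10)
        pd.testing.assert_frame_equal(
            pmf.contributions_pct(G2, F2, model.metals),
            model.contributions_pct,
            rtol=1e-9,
        )

    def test_dominance_pattern_recovered(self, pmf_base):
        """The factor owning each metal matches the ground truth for at
        least 6 of the 7 metals."""
        _, _, model, truth = pmf_base
        F_true = truth["F_true"]
        shares = model.contributions_pct
        # map each fitted factor to the truth source of max profile cosine
        Ft = F_true.to_numpy()
        norm = lambda A: A / np.linalg.norm(A, axis=1, keepdims=True)
        mapping = np.argmax(norm(model.F) @ norm(Ft).T, axis=1)
        true_owner = F_true.index[
            np.argmax(Ft / Ft.sum(axis=0, keepdims=True), axis=0)
        ]
        fitted_owner = [
            F_true.index[mapping[k]] for k in np.argmax(shares.to_numpy(), axis=0)
        ]
        assert sum(a == b for a, b in zip(fitted_owner, true_owner)) >= 6

    def test_invalid_inputs_rejected(self):
        X = np.ones((4, 3))
        U = np.ones((4, 3))
        with pytest.raises(ValueError, match="factor count"):
            pmf.fit(X, U, p=3)
        with pytest.raises(ValueError, match="shape"):
            pmf.fit(X, U[:2], p=1)
        with pytest.raises(ValueError, match="finite"):
            pmf.fit(X * np.nan, U, p=1)


@pytest.fixture(scope="module")
def rank4_noiseless():
    rng = np.random.default_rng(5)
    G = rng.lognormal(0, 0.8, (60, 4))
    F = rng.uniform(0.5, 10, (4, 7))
    X = G @ F
    U = 0.2 * X + 0.05
    return X, U


class TestScanFactors:
    def test_true_rank_attains_perfect_r2(self, rank4_noiseless):
        X, U = rank4_noiseless
        diag = pmf.scan_factors(X, U, p_range=[4], n_starts=8, seed=0)
        assert diag.loc[4, "min_r2"] >= 1 - 1e-6

    def test_underfactorization_degrades_fit(self, rank4_noiseless):
        X, U = rank4_noiseless
        diag = pmf.scan_factors(X, U, p_range=[3, 4], n_starts=8, seed=0)
        assert diag.loc[3, "min_r2"] < diag.loc[4, "min_r2"]
        assert diag.loc[3, "q_true"] > diag.loc[4, "q_true"]

    def test_diagnostics_finite_and_ratio_positive(self, rank4_noiseless):
        X, U = rank4_noiseless
        diag = pmf.scan_factors(X, U, p_range=[3, 4, 5], n_starts=4, seed=0)
        assert np.isfinite(diag.to_numpy()).all()
        assert (diag["q_ratio"] > 0).all()


class TestBootstrapAndContributions:
    def test_single_factor_contributions_are_100(self):
        G = np.random.default_rng(0).uniform(0.1, 2, (10, 1))
        F = np.array([[1.0, 2.0, 3.0]])
        pct = pmf.contributions_pct(G, F)
        np.testing.assert_allclose(pct.to_numpy(), 100.0)

    def test_columns_sum_to_100(self, pmf_base):
        _, _, model, _ = pmf_base
        np.testing.assert_allclose(
            model.contributions_pct.sum(axis=0).to_numpy(), 100.0, atol=1e-6
        )

    def test_zero_metal_column_reported_missing(self):
        G = np.ones((4, 2))
        F = np.array([[1.0, 0.0], [2.0, 0.0]])
        pct = pmf.contributions_pct(G, F)
        assert pct.iloc[:, 1].isna().all()

    def test_noiseless_bootstrap_maps_perfectly(self):
        rng = np.random.default_rng(9)
        G = rng.lognormal(0, 0.8, (40, 2))
        F = np.array([[10.0, 1.0, 0.5, 8.0], [0.5, 6.0, 9.0, 1.0]])
        X = G @ F
        U = 0.2 * X + 0.05
        base = pmf.fit(X, U, p=2, n_starts=5, seed=3)
        res = pmf.bootstrap(X, U, base, n_boot=10, seed=4)
        assert (res.mapping_rate == 100.0).all()
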