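"""Drift-corrected GLS: transform, pseudo-correlation, ML fitting, model
search and the empirical inflation-factor correction."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize

from ooadrift import synth
from ooadrift.driftgls import (
    DriftCorrelationMatrix,
    GlsFit,
    ModelSpec,
    arcsine_sqrt,
    build_design,
    correct_pvalues,
    drift_to_correlation,
    enumerate_models,
    fit_model,
    gls_fit,
    inflation_factor,
    scan,
    select_best_aic,
)
from ooadrift.popdata import DriftDistanceMatrix


class TestArcsineSqrt:
    @pytest.mark.parametrize("p,expected", [(0, 0), (1, math.pi / 2), (0.5, math.pi / 4)])
    def test_known_values(self, p, expected):
        assert arcsine_sqrt(p) == pytest.approx(expected)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            arcsine_sqrt(1.0001)
        with pytest.raises(ValueError):
            arcsine_sqrt(-0.0001)


class TestDriftToCorrelation:
    def test_direct_arithmetic(self):
        D = DriftDistanceMatrix(("a", "b", "c"), np.array([[0, 1, 4], [1, 0, 2], [4, 2, 0]], float))
        R = drift_to_correlation(D).R
        assert np.allclose(R, [[1, 0.75, 0], [0.75, 1, 0.5], [0, 0.5, 1]])

    def test_degenerate_all_zero(self):
        D = DriftDistanceMatrix(("a", "b"), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            drift_to_correlation(D)

    def test_structure_properties(self):
        _, _, D2 = synth.simulate_drift_frequencies(synth.DriftSimConfig(n_pops=10, seed=3))
        R = drift_to_correlation(D2).R
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert np.all((R >= 0) & (R <= 1))
        imax, jmax = np.unravel_index(np.argmax(D2.D2), R.shape)
        assert R[imax, jmax] == 0.0

    def test_ridge_restores_near_singular_psd(self):
        # two identical populations make R exactly singular
        D = DriftDistanceMatrix(("a", "b", "c"), np.array([[0, 0, 4], [0, 0, 4], [4, 4, 0]], float))
        R = drift_to_correlation(D)
        assert R.ridge > 0
        np.linalg.cholesky(R.R)  # positive definite after the ridge

    def test_indefinite_matrix_errors_in_fit(self):
        D = DriftDistanceMatrix(("a", "b", "c"), np.array([[0, 1, 4], [1, 0, 1], [4, 1, 0]], float))
        R = drift_to_correlation(D)  # indefinite: ridge cannot repair it
        with pytest.raises(ValueError, match="positive definite"):
            gls_fit(np.column_stack([np.ones(3), [0.1, 0.2, 0.3]]), np.array([1.0, 2.0, 3.5]), R)


class TestBuildDesign:
    def test_univariate_design_shape(self, table1):
        X, y, terms, names = build_design(table1, ModelSpec(("rs2209313",)))
        assert X.shape == (43, 2)
        assert terms == ("intercept", "rs2209313")
        assert np.allclose(X[:, 0], 1.0)
        assert len(names) == 43

    def test_interaction_column_is_rowwise_product(self, table1):
        spec = ModelSpec(("rs2209313", "rs6074896"), (("rs2209313", "rs6074896"),))
        X, _, terms, _ = build_design(table1, spec)
        brute = np.array(
            [
                arcsine_sqrt(r.freqs["rs2209313"]) * arcsine_sqrt(r.freqs["rs6074896"])
                for r in table1.records
            ]
        )
        assert np.allclose(X[:, terms.index("rs2209313*rs6074896")], brute)

    def test_zero_variance_column_names_marker(self, table1):
        from ooadrift.popdata import PopulationRecord, PopulationTable

        recs = tuple(
            PopulationRecord(f"p{i}", float(i), {"flat": 1.0, "ok": 0.1 * i}) for i in range(5)
        )
        t = PopulationTable(recs, ("flat", "ok"))
        with pytest.raises(ValueError, match="flat"):
            build_design(t, ModelSpec(("flat",)))

    def test_interaction_with_constant_marker_collinear_with_main(self):
        from ooadrift.popdata import PopulationRecord, PopulationTable

        # marker b == 1 everywhere: interaction column equals a's column * (pi/2)
        recs = tuple(
            PopulationRecord(f"p{i}", float(i), {"a": 0.1 + 0.1 * i, "b": 1.0}) for i in range(6)
        )
        t = PopulationTable(recs, ("a", "b"))
        X, y, terms, _ = build_design(t, ModelSpec(("a",), (("a", "b"),)))
        ratio = X[:, terms.index("a*b")] / X[:, terms.index("a")]
        assert np.allclose(ratio, math.pi / 2)
        with pytest.raises(ValueError, match="collinear"):
            gls_fit(X, y)


class TestGlsFit:
    def test_identity_R_equals_closed_form_ols(self, table1):
        X, y, terms, _ = build_design(table1, ModelSpec(("rs2209313",)))
        fit = gls_fit(X, y, terms=terms)
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.beta, beta_ols, rtol=1e-8)

    def test_matches_statsmodels_gls(self, table1):
        import statsmodels.api as sm

        X, y, _, _ = build_design(table1, ModelSpec(("rs2209313", "rs6074896")))
        rng = np.random.default_rng(0)
        A = rng.normal(size=(43, 43))
        V = A @ A.T + 43 * np.eye(43)
        d = np.sqrt(np.diag(V))
        R = V / np.outer(d, d)
        fit = gls_fit(X, y, R)
        ref = sm.GLS(y, X, sigma=R).fit()
        assert np.allclose(fit.beta, ref.params, rtol=1e-10)
        assert fit.loglik == pytest.approx(ref.llf, rel=1e-10)

    def test_brute_force_likelihood_oracle(self):
        # 4-population toy with a non-identity correlation: the analytic
        # (beta, sigma2) must maximize the stated Gaussian log-likelihood
        y = np.array([0.0, 3.0, 5.0, 11.0])
        X = np.column_stack([np.ones(4), [0.1, 0.4, 0.5, 0.9]])
        R = np.array(
            [[1.0, 0.5, 0.2, 0.1], [0.5, 1.0, 0.5, 0.2], [0.2, 0.5, 1.0, 0.5], [0.1, 0.2, 0.5, 1.0]]
        )
        fit = gls_fit(X, y, R)
        Rinv = np.linalg.inv(R)
        logdet = np.linalg.slogdet(R)[1]

        def negloglik(theta):
            b = theta[:2]
            s2 = math.exp(theta[2])
            e = y - X @ b
            return 0.5 * (4 * math.log(2 * math.pi * s2) + e @ Rinv @ e / s2 + logdet)

        res = minimize(
            negloglik,
            x0=np.array([fit.beta[0] + 0.5, fit.beta[1] - 0.5, math.log(fit.sigma2) + 0.3]),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
        )
        assert np.allclose(fit.beta, res.x[:2], rtol=1e-6, atol=1e-6)
        assert fit.sigma2 == pytest.approx(math.exp(res.x[2]), rel=1e-5)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_local_maximality(self, table1):
        X, y, terms, _ = build_design(table1, ModelSpec(("rs2209313",)))
        fit = gls_fit(X, y, terms=terms)
        n = len(y)
        rng = np.random.default_rng(42)
        for _ in range(100):
            db = rng.normal(scale=np.abs(fit.beta) * 0.01 + 1.0)
            ds = rng.normal(scale=0.05)
            b = fit.beta + db
            s2 = fit.sigma2 * math.exp(ds)
            e = y - X @ b
            ll = -0.5 * (n * math.log(2 * math.pi * s2) + e @ e / s2)
            assert ll <= fit.loglik + 1e-9

    def test_constant_response_is_degenerate(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="degenerate"):
            gls_fit(X, np.full(5, 7.0))

    def test_aic_identity(self, table1):
        fit = fit_model(table1, ModelSpec(("rs2209313",)))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * (fit.k + 1))

    def test_aic_shift_under_km_to_m_rescaling(self, table1):
        """Rescaling distances by c shifts every AIC by 2 n log c, so the
        AIC ranking of models is invariant."""
        from dataclasses import replace
        from ooadrift.popdata import PopulationRecord, PopulationTable

        c = 1000.0  # km -> m
        scaled = PopulationTable(
            tuple(replace(r, distance_km=r.distance_km * c) for r in table1.records),
            table1.markers,
        )
        specs = [ModelSpec((m,)) for m in table1.markers]
        aic_km = [fit_model(table1, s).aic for s in specs]
        aic_m = [fit_model(scaled, s).aic for s in specs]
        shift = 2 * 43 * math.log(c)
        assert np.allclose(np.array(aic_m) - np.array(aic_km), shift)
        assert np.argsort(aic_km).tolist() == np.argsort(aic_m).tolist()


class TestEnumerateModels:
    def test_single_marker(self):
        assert enumerate_models(["a"]) == [ModelSpec(("a",))]

    def test_two_markers_order2_exhaustive(self):
        models = enumerate_models(["a", "b"], 2)
        expected = {
            ModelSpec(("a",)),
            ModelSpec(("b",)),
            ModelSpec(("a", "b")),
            ModelSpec(("a", "b"), (("a", "b"),)),
        }
        assert len(models) == 4
        assert set(models) == expected

    @pytest.mark.parametrize("n_markers,order", [(3, 2), (4, 2), (3, 3), (4, 3)])
    def test_count_matches_combinatorial_recount(self, n_markers, order):
        markers = [f"m{i}" for i in range(n_markers)]
        expected = 0
        for s in range(1, n_markers + 1):
            n_inter = sum(math.comb(s, o) for o in range(2, order + 1))
            expected += math.comb(n_markers, s) * 2**n_inter
        assert len(enumerate_models(markers, order)) == expected

    def test_deterministic_ordering(self):
        a = enumerate_models(["x", "y", "z"], 2)
        b = enumerate_models(["x", "y", "z"], 2)
        assert a == b

    def test_nonhierarchical_flag_allows_dropped_mains(self):
        models = enumerate_models(["a", "b"], 2, require_main_effects=False)
        assert ModelSpec((), (("a", "b"),)) in models
        assert set(enumerate_models(["a", "b"], 2)) <= set(models)


def _make_fit(aic, k, terms=("intercept", "x")):
    z = np.zeros(len(terms))
    return GlsFit(terms=tuple(terms), beta=z, se=z + 1, pvalues=z + 0.5,
                  sigma2=1.0, loglik=-(aic - 2 * (k + 1)) / 2, aic=aic, n=20, k=k)


class TestSelectBestAic:
    def test_single_fit(self):
        f = _make_fit(10.0, 2)
        assert select_best_aic([f]) is f

    def test_tie_broken_by_fewer_parameters(self):
        f2 = _make_fit(10.0, 2)
        f3 = _make_fit(10.0, 3, terms=("intercept", "x", "y"))
        assert select_best_aic([f3, f2]) is f2

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_best_aic([])


class TestInflationCorrection:
    def test_extremes(self):
        assert inflation_factor([0.5, 0.9, 0.7]) == 0.0
        assert inflation_factor([0.01, 0.02]) == pytest.approx(20.0)

    def test_uniform_null_is_calibrated(self):
        rng = np.random.default_rng(12345)
        p = rng.uniform(size=10_000)
        assert inflation_factor(p) == pytest.approx(1.0, abs=0.1)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            inflation_factor([])

    @pytest.mark.parametrize(
        "p,factor,expected",
        [(0.3, 1.0, 0.3), (0.6, 2.0, 1.0), (0.01, 2.5, 0.025)],
    )
    def test_correct_pvalues(self, p, factor, expected):
        assert correct_pvalues([p], factor)[0] == pytest.approx(expected)

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            correct_pvalues([0.5], -1.0)


class TestScan:
    def test_univariate_slope_signs_match_reported_table(self, table1_oriented):
        """Unadjusted univariate slopes: (+, -, +, +) for
        (rs1535882, rs2209313, rs4814391, rs6074896)."""
        report = scan(table1_oriented, ["rs1535882", "rs2209313", "rs4814391", "rs6074896"],
                      max_interaction_order=2)
        signs = {}
        for fit in report.fits:
            if fit.k == 2:
                signs[fit.terms[1]] = np.sign(fit.beta[1])
        assert signs == {
            "rs1535882": 1.0, "rs2209313": -1.0, "rs4814391": 1.0, "rs6074896": 1.0,
        }

    def test_single_marker_scan_reduces_to_gls_fit(self, table1):
        report = scan(table1, ["rs2209313"])
        direct = fit_model(table1, ModelSpec(("rs2209313",)))
        assert len(report.fits) == 1
        assert np.allclose(report.fits[0].beta, direct.beta)
        assert report.factor is None

    def test_corrected_rejection_controlled_on_null_drift_data(self):
        """Drift-corrected fits plus drift-structured empirical null keep
        the corrected false-positive rate near nominal."""
        rej = 0
        n_reps = 200
        for rep in range(n_reps):
            table, truth, _ = synth.simulate_drift_frequencies(
                synth.DriftSimConfig(beta_true=0.0, seed=300_000 + rep)
            )
            report = scan(
                table, ["sim"], R=truth.cov,
                null_marker_generator=lambda t, n, s: synth.simulate_null_markers(
                    t, n, s, mode="drift", drift_sd=0.03
                ),
                n_null=200, seed=rep,
            )
            rej += report.corrected[0][1] < 0.05
        assert rej / n_reps <= 0.07

    def test_parameter_recovery_with_true_correlation(self):
        """With mild drift, the drift-corrected slope estimate is unbiased
        to well within its standard error."""
        betas, ses = [], []
        for rep in range(200):
            table, truth, _ = synth.simulate_drift_frequencies(
                synth.DriftSimConfig(beta_true=20_000.0, drift_sd=0.01, seed=310_000 + rep)
            )
            f = fit_model(table, ModelSpec(("sim",)), R=truth.cov)
            betas.append(f.coef("sim"))
            ses.append(f.se_of("sim"))
        assert abs(np.mean(betas) - 20_000.0) < 2 * np.mean(ses)
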