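"""Quadratic surface fitting, ANOVA decomposition, reduction and diagnostics.

statsmodels OLS on the actual-scale design matrix serves as the independent
oracle for coefficients; explicit leave-one-out refits are the oracle for
PRESS.
"""

import numpy as np
import pytest
import statsmodels.api as sm

from racewayrsm.datasets import RESPONSE_NAME, raceway_factors
from racewayrsm.design import generate_ccf
from racewayrsm.errors import (
    PureErrorUnavailableError,
    SingularFitError,
    UndefinedDiagnosticsError,
)
from racewayrsm.rsm import (
    INTERCEPT,
    TermSpec,
    anova,
    backward_eliminate,
    diagnostics,
    fit_quadratic,
    full_quadratic_terms,
    load_model,
    model_from_actual_coefficients,
    model_matrix,
    predict,
    pure_error,
    save_model,
)
from racewayrsm.simulate import SyntheticSpec, simulate_design_response

A = TermSpec("linear", (0,))
B = TermSpec("linear", (1,))
AB = TermSpec("interaction", (0, 1))
A2 = TermSpec("quadratic", (0,))
B2 = TermSpec("quadratic", (1,))


def _synthetic(coefs_by_term, noise_sd=0.0, seed=0, n_replicates=1):
    factors = raceway_factors()
    terms = list(coefs_by_term)
    truth = model_from_actual_coefficients(
        RESPONSE_NAME, factors, terms, list(coefs_by_term.values())
    )
    design = generate_ccf(factors, n_center=3)
    table = simulate_design_response(
        SyntheticSpec(truth, noise_sd=noise_sd, n_replicates=n_replicates, seed=seed),
        design,
    )
    return truth, design, table


class TestFitQuadratic:
    def test_noiseless_data_recovered_to_machine_precision(self):
        truth, _, table = _synthetic(
            {INTERCEPT: 4.0, A: 30.0, B: -12.0, AB: -50.0, A2: -70.0, B2: 8.0}
        )
        model = fit_quadratic(table, RESPONSE_NAME, truth.terms)
        assert model.coefficients_actual == pytest.approx(
            truth.coefficients_actual, rel=1e-9, abs=1e-9
        )

    def test_coded_fit_reexpanded_matches_direct_actual_ols(self, table1):
        # oracle: statsmodels OLS on the actual-scale columns (same span)
        terms = full_quadratic_terms(2)
        for season in ("winter", "spring", "summer", "autumn"):
            model = fit_quadratic(table1, season, terms)
            X = model_matrix(table1.actual_matrix(), model.terms)
            oracle = sm.OLS(table1.response(season), X).fit()
            assert model.coefficients_actual == pytest.approx(
                oracle.params, rel=1e-8, abs=1e-8
            )

    def test_coded_and_actual_scales_predict_identically(self, table1):
        model = fit_quadratic(table1, "spring", [INTERCEPT, A, B, A2])
        rng = np.random.default_rng(7)
        pts = rng.uniform([0.15, 0.05], [0.50, 0.20], size=(25, 2))
        from racewayrsm.design import actual_to_coded

        actual_pred = model_matrix(pts, model.terms) @ model.coefficients_actual
        coded_pred = (
            model_matrix(actual_to_coded(pts, model.factors), model.terms)
            @ model.coefficients_coded
        )
        assert actual_pred == pytest.approx(coded_pred, rel=1e-10)

    def test_collinear_terms_are_named(self):
        # a two-level depth column makes depth^2 collinear with the intercept
        from racewayrsm.design import DesignRun, DesignTable

        factors = raceway_factors()
        codes = [(-1, -1), (1, -1), (-1, 1), (1, 1), (0, -1), (0, 1), (0, -1), (0, 1)]
        runs = [
            DesignRun(i + 1, (float(a), float(b)), (0.0, 0.0), False)
            for i, (a, b) in enumerate(codes)
        ]
        table = DesignTable(
            factors=factors, runs=runs, responses={"y": list(range(8))}
        )
        with pytest.raises(SingularFitError, match="depth"):
            fit_quadratic(table, "y", full_quadratic_terms(2))

    def test_too_few_runs_rejected(self, table1):
        small = type(table1)(
            factors=table1.factors,
            runs=table1.runs[:5],
            responses={"winter": list(table1.response("winter")[:5])},
        )
        with pytest.raises(SingularFitError):
            fit_quadratic(small, "winter", full_quadratic_terms(2))


class TestPredict:
    def test_intercept_only_model_is_constant(self):
        model = model_from_actual_coefficients(
            RESPONSE_NAME, raceway_factors(), [INTERCEPT], [3.5]
        )
        assert predict(model, [0.3, 0.1]) == pytest.approx(3.5)

    def test_extrapolation_warns_but_evaluates(self):
        model = model_from_actual_coefficients(
            RESPONSE_NAME, raceway_factors(), [INTERCEPT, A], [1.0, 2.0]
        )
        with pytest.warns(UserWarning, match="extrapolation"):
            value = predict(model, [0.60, 0.10])
        assert value == pytest.approx(1.0 + 2.0 * 0.60)


class TestAnova:
    def test_pure_error_df_from_three_centre_runs(self, table1):
        model = fit_quadratic(table1, "winter", [INTERCEPT, A, B, A2])
        table = anova(model, table1)
        assert table.df_pure_error == 2

    def test_ss_additivity(self, table1):
        for season in ("winter", "spring", "summer", "autumn"):
            model = fit_quadratic(table1, season, full_quadratic_terms(2))
            t = anova(model, table1)
            y = table1.response(season)
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            assert t.ss_model + t.ss_pure_error + t.ss_lack_of_fit == pytest.approx(
                ss_tot, rel=1e-8
            )
            assert t.ss_residual == pytest.approx(
                t.ss_pure_error + t.ss_lack_of_fit, rel=1e-8
            )

    def test_zero_noise_fit_is_exact(self):
        truth, _, table = _synthetic({INTERCEPT: 4.0, A: 30.0, B: -12.0, A2: -70.0})
        model = fit_quadratic(table, RESPONSE_NAME, full_quadratic_terms(2))
        t = anova(model, table)
        assert t.ss_residual == pytest.approx(0.0, abs=1e-16)
        assert t.p_model < 1e-10

    def test_winter_model_adequacy_p_value(self, table1):
        # overall-model p of the reduced winter fit, printed as 0.0018
        model = fit_quadratic(table1, "winter", [INTERCEPT, A, B, A2])
        t = anova(model, table1)
        assert t.p_model == pytest.approx(0.0018, abs=0.0005)

    def test_lack_of_fit_not_significant_for_reduced_models(self, table1):
        for season, terms in [
            ("winter", [INTERCEPT, A, B, A2]),
            ("summer", [INTERCEPT, A, B, AB, A2]),
            ("autumn", [INTERCEPT, A, B, A2]),
        ]:
            model = fit_quadratic(table1, season, terms)
            t = anova(model, table1)
            assert t.p_lack_of_fit > 0.05

    def test_no_replicates_raises(self, table1):
        unreplicated = type(table1)(
            factors=table1.factors,
            runs=table1.runs[2:],  # drops two of the three centre runs
            responses={"winter": list(table1.response("winter")[2:])},
        )
        model = fit_quadratic(unreplicated, "winter", [INTERCEPT, A, B, A2])
        with pytest.raises(PureErrorUnavailableError):
            pure_error(unreplicated, "winter")
        t = anova(model, unreplicated)
        assert t.lack_of_fit_unavailable


class TestBackwardElimination:
    def test_winter_retains_linear_terms_and_dilution_quadratic(self, table1):
        model = backward_eliminate(table1, "winter")
        assert set(model.terms) == {INTERCEPT, A, B, A2}

    def test_summer_retains_interaction(self, table1):
        model = backward_eliminate(table1, "summer")
        assert set(model.terms) == {INTERCEPT, A, B, AB, A2}

    def test_autumn_matches_winter_structure(self, table1):
        model = backward_eliminate(table1, "autumn")
        assert set(model.terms) == {INTERCEPT, A, B, A2}

    def test_spring_keeps_significant_interaction(self, table1):
        # the spring interaction is significant on these data (the published
        # text agrees even though the published equation omits it)
        model = backward_eliminate(table1, "spring")
        assert AB in model.terms

    def test_stepwise_variant_differs_on_summer(self, table1):
        # the summer interaction p-value crosses alpha after the first
        # removal, so the one-at-a-time variant drops it
        model = backward_eliminate(table1, "summer", method="stepwise")
        assert AB not in model.terms

    def test_pure_main_effects_drop_second_order_terms(self):
        # each second-order term should be discarded in >= 90% of replicates
        factors = raceway_factors()
        truth = model_from_actual_coefficients(
            RESPONSE_NAME, factors, [INTERCEPT, A, B], [10.0, 20.0, -10.0]
        )
        design = generate_ccf(factors, n_center=3)
        kept = {AB: 0, A2: 0, B2: 0}
        n = 200
        for seed in range(n):
            table = simulate_design_response(
                SyntheticSpec(truth, noise_sd=0.3, n_replicates=2, seed=seed), design
            )
            model = backward_eliminate(table, RESPONSE_NAME)
            for term in kept:
                kept[term] += term in model.terms
        for term, count in kept.items():
            assert count / n <= 0.10, f"{term} retained too often"

    def test_invariant_to_run_ordering(self, table1):
        perm = np.random.default_rng(3).permutation(table1.n_runs)
        shuffled = type(table1)(
            factors=table1.factors,
            runs=[table1.runs[i] for i in perm],
            responses={
                name: [values[i] for i in perm]
                for name, values in table1.responses.items()
            },
        )
        for season in ("winter", "spring", "summer", "autumn"):
            assert set(backward_eliminate(table1, season).terms) == set(
                backward_eliminate(shuffled, season).terms
            )


class TestDiagnostics:
    def test_perfect_fit_has_unit_r2(self):
        truth, _, table = _synthetic({INTERCEPT: 4.0, A: 30.0, B: -12.0, A2: -70.0})
        model = fit_quadratic(table, RESPONSE_NAME, truth.terms)
        d = diagnostics(model, table)
        assert d.r2 == pytest.approx(1.0, abs=1e-12)

    def test_press_matches_explicit_leave_one_out(self, table1):
        model = fit_quadratic(table1, "spring", [INTERCEPT, A, B, A2])
        d = diagnostics(model, table1)
        X = model_matrix(table1.coded_matrix(), model.terms)
        y = table1.response("spring")
        press = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
            press += (y[i] - X[i] @ beta) ** 2
        assert d.press == pytest.approx(press, rel=1e-10)

    def test_removing_a_term_never_increases_r2(self, table1):
        terms = full_quadratic_terms(2)
        full = diagnostics(fit_quadratic(table1, "summer", terms), table1)
        for drop in terms[1:]:
            reduced = fit_quadratic(
                table1, "summer", [t for t in terms if t != drop]
            )
            assert diagnostics(reduced, table1).r2 <= full.r2 + 1e-12

    def test_adjusted_below_r2(self, table1):
        model = fit_quadratic(table1, "winter", [INTERCEPT, A, B, A2])
        d = diagnostics(model, table1)
        assert d.r2_adjusted <= d.r2
        assert d.press >= 0

    def test_constant_response_rejected(self, table1):
        flat = table1.with_response("flat", np.full(11, 5.0))
        model = fit_quadratic(flat, "flat", [INTERCEPT, A, B, A2])
        with pytest.raises(UndefinedDiagnosticsError):
            diagnostics(model, flat)


class TestCoefficientInference:
    def test_coverage_of_nominal_95_intervals(self):
        # 1000 seeded replicates at replicate-level noise sd 1: pooled
        # coverage of the actual-scale coefficient CIs should be ~95%
        factors = raceway_factors()
        truth = model_from_actual_coefficients(
            RESPONSE_NAME, factors, [INTERCEPT, A, B, A2], [8.68, 32.60, -15.53, -60.56]
        )
        design = generate_ccf(factors, n_center=3)
        hits, total = 0, 0
        for seed in range(1000):
            table = simulate_design_response(
                SyntheticSpec(truth, noise_sd=1.0, n_replicates=1, seed=seed), design
            )
            model = fit_quadratic(table, RESPONSE_NAME, truth.terms)
            ci = model.confint_actual(0.95)
            hits += int(
                np.sum((ci[:, 0] <= truth.coefficients_actual)
                       & (truth.coefficients_actual <= ci[:, 1]))
            )
            total += len(truth.terms)
        assert 0.93 <= hits / total <= 0.97

    def test_parameter_recovery_within_three_standard_errors(self):
        factors = raceway_factors()
        truth = model_from_actual_coefficients(
            RESPONSE_NAME, factors, [INTERCEPT, A, B, A2], [5.90, 113.41, -47.82, -145.43]
        )
        design = generate_ccf(factors, n_center=3)
        n = 500
        within = np.zeros(len(truth.terms))
        for seed in range(n):
            table = simulate_design_response(
                SyntheticSpec(truth, noise_sd=1.0, n_replicates=2, seed=seed), design
            )
            model = fit_quadratic(table, RESPONSE_NAME, truth.terms)
            se = model.stderr_actual()
            within += (
                np.abs(model.coefficients_actual - truth.coefficients_actual)
                <= 3.0 * se
            )
        # per coefficient: a |t| < 3 event has probability ~0.98 at 7 df
        assert np.all(within / n >= 0.95)


class TestModelJSON:
    def test_round_trip_preserves_terms_and_coefficients(self, table1, tmp_path):
        model = backward_eliminate(table1, "summer", season_label="summer")
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.terms == model.terms
        assert back.coefficients_actual == pytest.approx(model.coefficients_actual)
        assert back.coefficients_coded == pytest.approx(model.coefficients_coded)
        assert back.season_label == "summer"
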