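"""POR model design construction, maximum-likelihood fitting, prediction."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

from ovaclock import CohortRecord, FittedPorModel, ModelSpec, build_design, fit_por_model
from ovaclock.errors import ConfigError, DegenerateDesignError, DegenerateFitError
from ovaclock.por_models import predict_por_probabilities, predict_por_probability


def _record(age, amh):
    return CohortRecord("r", age, amh)


class TestBuildDesign:
    @pytest.mark.parametrize(
        "age,amh,spec,expected",
        [
            (30, 2, ModelSpec(name="model2"), [30, 900, 2, 4, 8]),
            (41, 1.5, ModelSpec(name="model1"), [41, 1.5]),
            (33, 0.9, ModelSpec(name="model0", age_bins=(35,), amh_bins=(1.1,)), [0, 0]),
            (37, 1.3, ModelSpec(name="model0", age_bins=(35,), amh_bins=(1.1,)), [1, 1]),
        ],
    )
    def test_examples(self, age, amh, spec, expected):
        np.testing.assert_allclose(build_design(_record(age, amh), spec), expected)

    def test_centering_shifts_before_powers(self):
        spec = ModelSpec(name="model2", center=True, center_age=35, center_amh=2)
        np.testing.assert_allclose(
            build_design(_record(30, 3), spec), [-5, 25, 1, 1, 1]
        )

    def test_model0_out_of_range_goes_to_outermost_bin(self):
        spec = ModelSpec(name="model0", age_bins=(30.0, 40.0), amh_bins=(1.0, 3.0))
        # age 15 below all cuts -> reference bin; amh 50 above all -> top bin
        np.testing.assert_allclose(build_design(_record(15, 50), spec), [0, 0, 0, 1])

    def test_decreasing_cutpoints_rejected(self):
        with pytest.raises(ConfigError):
            ModelSpec(name="model0", age_bins=(40.0, 30.0), amh_bins=(1.0,))


def _toy_nll_factory(cohort):
    X = np.column_stack(
        [np.ones(len(cohort)), [r.age_years for r in cohort], [r.amh_ng_ml for r in cohort]]
    )
    y = np.array([float(r.por) for r in cohort])

    def nll(beta):
        eta = X @ beta
        return -float(np.sum(y * eta - np.log1p(np.exp(eta))))

    return nll


class TestFit:
    def test_toy_mle_matches_independent_search_oracle(self, toy_cohort):
        """The fitted coefficients agree with a multi-start derivative-free
        maximization of a hand-written Bernoulli log-likelihood."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_por_model(toy_cohort, ModelSpec(name="model1"))
        nll = _toy_nll_factory(toy_cohort)
        best = None
        for start in itertools.product([-5, 0, 5], [-0.5, 0, 0.5], [-1, 0, 1]):
            res = minimize(
                nll,
                np.array(start, dtype=float),
                method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000, maxfev=20000),
            )
            if best is None or res.fun < best.fun:
                best = res
        np.testing.assert_allclose(fit.beta, best.x, atol=1e-3)
        assert fit.log_likelihood == pytest.approx(-best.fun, abs=1e-8)

    def test_fitted_loglik_beats_null(self, cc_cohort):
        fit = fit_por_model(cc_cohort, ModelSpec(name="model1"))
        n = fit.n_fit
        ll_null = n * np.log(0.5)  # beta = 0 gives p = 0.5 everywhere
        assert fit.log_likelihood >= ll_null
        assert fit.log_likelihood <= 0
        assert fit.converged

    def test_nesting_never_decreases_loglik(self, cc_cohort):
        ll1 = fit_por_model(cc_cohort, ModelSpec(name="model1")).log_likelihood
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ll2 = fit_por_model(cc_cohort, ModelSpec(name="model2")).log_likelihood
        assert ll2 >= ll1 - 1e-6

    def test_centering_invariance_of_probabilities(self, cc_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = fit_por_model(cc_cohort, ModelSpec(name="model2", center=False))
            cen = fit_por_model(cc_cohort, ModelSpec(name="model2", center=True))
        p_raw = predict_por_probabilities(raw, cc_cohort)
        p_cen = predict_por_probabilities(cen, cc_cohort)
        np.testing.assert_allclose(p_raw, p_cen, atol=1e-6)

    def test_single_class_outcome_rejected(self):
        cohort = [
            CohortRecord(f"s{i}", 25 + (i % 20), 2.0 + 0.1 * i, por=False) for i in range(60)
        ]
        with pytest.raises(DegenerateFitError):
            fit_por_model(cohort, ModelSpec(name="model1"))

    def test_constant_amh_column_rejected(self, rng):
        cohort = [
            CohortRecord(f"s{i}", float(rng.uniform(25, 42)), 2.0, por=bool(rng.random() < 0.3))
            for i in range(100)
        ]
        with pytest.raises(DegenerateDesignError):
            fit_por_model(cohort, ModelSpec(name="model1"))

    def test_separated_cohort_flagged_not_raised(self):
        # AMH perfectly splits the classes: MLE is unbounded
        cohort = [
            CohortRecord(f"s{i}", 30.0 + i % 5, amh, por=amh < 1.0)
            for i, amh in enumerate([0.2, 0.4, 0.6, 0.8, 2.0, 3.0, 4.0, 5.0])
        ]
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_por_model(cohort, ModelSpec(name="model1"))
        assert not fit.converged

    def test_model0_default_quintile_bins_resolved(self, cc_cohort):
        fit = fit_por_model(cc_cohort, ModelSpec(name="model0"))
        assert fit.spec.age_bins is not None and len(fit.spec.age_bins) == 4
        assert fit.spec.amh_bins is not None and len(fit.spec.amh_bins) == 4
        assert all(np.diff(fit.spec.age_bins) > 0)

    def test_json_round_trip(self, toy_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_por_model(toy_cohort, ModelSpec(name="model1"))
        clone = FittedPorModel.from_json(fit.to_json())
        np.testing.assert_allclose(clone.beta, fit.beta)
        assert clone.spec == fit.spec
        rec = _record(35, 1.8)
        assert predict_por_probability(clone, rec) == pytest.approx(
            predict_por_probability(fit, rec)
        )


class TestPredict:
    def _model(self, beta, name="model1"):
        return FittedPorModel(
            spec=ModelSpec(name=name), beta=np.asarray(beta, dtype=float),
            n_fit=100, log_likelihood=-1.0, converged=True,
        )

    def test_zero_beta_gives_half(self):
        model = self._model([0.0, 0.0, 0.0])
        assert predict_por_probability(model, _record(33, 2.5)) == 0.5

    def test_inverse_logit_arithmetic(self):
        # eta = -2 + 0.5 * 4 = 0 -> p = 1 / (1 + e^0) = 0.5
        model = self._model([-2.0, 0.0, 0.5])
        assert predict_por_probability(model, _record(30, 4.0)) == pytest.approx(0.5)

    def test_probabilities_strictly_inside_unit_interval(self):
        model = self._model([0.0, 5.0, -100.0])
        for age, amh in [(60, 0), (15, 1e6 ** (1 / 3)), (40, 50)]:
            p = predict_por_probability(model, _record(age, amh))
            assert 0.0 < p < 1.0

    def test_monotone_in_linear_predictor(self):
        model = self._model([-3.0, 0.0, 1.0])
        probs = [predict_por_probability(model, _record(30, a)) for a in np.linspace(0, 10, 20)]
        assert np.all(np.diff(probs) > 0)
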