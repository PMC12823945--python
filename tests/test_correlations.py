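import itertools

import numpy as np
import pytest

from itdispersion import correlations as co
from itdispersion.physiology import DEFAULT_MOLECULAR_DIFFUSIVITY as D0
from itdispersion.physiology import csf_state


def make_summary(state, d_exp, ccv=None):
    return co.ExperimentSummary(
        frequency=state.frequency,
        stroke_volume=state.stroke_volume,
        urms=state.urms,
        womersley=state.womersley,
        peclet=state.peclet,
        amplitude_ratio=state.amplitude_ratio,
        d_exp=d_exp,
        ccv=ccv,
    )


@pytest.fixture(scope="module")
def states():
    return [
        csf_state(f, sv)
        for f in (40.0, 55.0, 72.0, 90.0, 110.0, 127.0)
        for sv in (0.5, 1.0)
    ]


class TestDimensionalFit:
    def test_exact_recovery_of_reference_coefficients(self, states):
        summaries = [
            make_summary(s, float(co.dimensional_law(s.frequency, s.urms)))
            for s in states
        ]
        fit = co.fit_dimensional(summaries)
        for name, truth in co.DIMENSIONAL_COEFFS.items():
            assert fit.coefficients[name] == pytest.approx(truth, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_fit_has_r2_below_one(self, states):
        rng = np.random.default_rng(11)
        summaries = [
            make_summary(
                s,
                float(co.dimensional_law(s.frequency, s.urms))
                * 10.0 ** (0.05 * rng.standard_normal()),
            )
            for s in states
        ]
        fit = co.fit_dimensional(summaries)
        assert fit.r_squared < 1.0
        # power-law slope still close to truth
        assert fit.coefficients["kappa"] == pytest.approx(
            co.DIMENSIONAL_COEFFS["kappa"], abs=0.3
        )

    def test_too_few_experiments_error(self, states):
        summaries = [make_summary(states[0], 5.0), make_summary(states[1], 6.0)]
        with pytest.raises(ValueError):
            co.fit_dimensional(summaries)

    def test_collinear_design_error(self):
        # single frequency makes f and f^2 collinear with the intercept
        state = csf_state(72.0, 1.0)
        summaries = [make_summary(state, 5.0 + i * 0.1) for i in range(6)]
        with pytest.raises(ValueError, match="collinear"):
            co.fit_dimensional(summaries)


class TestDimensionlessFit:
    def _designed_summaries(self):
        out = []
        for a, pe in itertools.product((0.2, 0.5, 0.8, 1.1), (3.0, 10.0, 30.0, 100.0)):
            d = float(co.dimensionless_law(a, pe, D0))
            out.append(
                co.ExperimentSummary(
                    frequency=60.0, stroke_volume=1.0, urms=1.0,
                    womersley=a, peclet=pe, amplitude_ratio=0.01, d_exp=d,
                )
            )
        return out

    def test_exact_recovery_of_reference_coefficients(self):
        fit = co.fit_dimensionless(self._designed_summaries(), D0)
        for name, truth in co.DIMENSIONLESS_COEFFS.items():
            assert fit.coefficients[name] == pytest.approx(truth, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_baseline_violation_errors(self, states):
        summaries = [make_summary(s, D0) for s in states]
        with pytest.raises(ValueError):
            co.fit_dimensionless(summaries, D0)


class TestScaleFit:
    def test_exact_recovery_and_vertex(self, states):
        summaries = [
            make_summary(s, float(co.scale_law(s.womersley, s.amplitude_ratio, D0)))
            for s in states
        ]
        fit = co.fit_scale(summaries, D0)
        for name, truth in co.SCALE_COEFFS.items():
            assert fit.coefficients[name] == pytest.approx(truth, rel=1e-8)
        assert fit.coefficients["lambda2"] < 0
        assert co.quadratic_vertex(fit) == pytest.approx(9.394, abs=1e-3)

    def test_zero_amplitude_ratio_rejected(self):
        with pytest.raises(ValueError):
            co.ExperimentSummary(
                frequency=72.0, stroke_volume=1.0, urms=1.0, womersley=7.0,
                peclet=100.0, amplitude_ratio=0.0, d_exp=5.0,
            )


class TestCCV:
    def test_reference_frequency_law_at_72bpm(self):
        assert co.ccv_law(72.0, co.CCV_FREQUENCY_COEFFS) == pytest.approx(0.3440, abs=1e-4)

    def test_reference_urms_law(self):
        assert co.ccv_law(10.0, co.CCV_URMS_COEFFS) == pytest.approx(0.3110, abs=1e-4)

    def test_exact_line_recovery(self, states):
        summaries = [
            make_summary(
                s, 5.0, ccv=float(co.ccv_law(s.frequency, co.CCV_FREQUENCY_COEFFS))
            )
            for s in states
        ]
        fit = co.fit_ccv(summaries, "frequency")
        assert fit.coefficients["a"] == pytest.approx(0.0018, abs=1e-10)
        assert fit.coefficients["b"] == pytest.approx(0.2144, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_regressor_errors(self):
        state = csf_state(72.0, 1.0)
        summaries = [make_summary(state, 5.0, ccv=0.3) for _ in range(4)]
        with pytest.raises(ValueError):
            co.fit_ccv(summaries, "frequency")


class TestPredictDispersion:
    def test_dimensional_reproduces_training_point(self, states):
        summaries = [
            make_summary(s, float(co.dimensional_law(s.frequency, s.urms)))
            for s in states
        ]
        fit = co.fit_dimensional(summaries)
        s = states[4]
        assert co.predict_dispersion(
            fit, frequency=s.frequency, urms=s.urms
        ) == pytest.approx(summaries[4].d_exp, rel=1e-9)

    def test_scale_model_definition(self):
        fit = co.CorrelationFit(
            model="scale", coefficients=dict(co.SCALE_COEFFS), r_squared=1.0, n=10
        )
        expected = D0 * 0.003 * (
            co.SCALE_COEFFS["lambda0"]
            + co.SCALE_COEFFS["lambda1"] * 7.0
            + co.SCALE_COEFFS["lambda2"] * 49.0
        )
        assert co.predict_dispersion(
            fit, womersley=7.0, amplitude_ratio=0.003, d0=D0
        ) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_urms_at_fixed_frequency(self):
        fit = co.CorrelationFit(
            model="dimensional",
            coefficients=dict(co.DIMENSIONAL_COEFFS),
            r_squared=1.0,
            n=26,
        )
        d_low = co.predict_dispersion(fit, frequency=72.0, urms=1.0)
        d_high = co.predict_dispersion(fit, frequency=72.0, urms=2.0)
        assert d_high > d_low

    def test_mismatched_arguments_error(self):
        fit = co.CorrelationFit(
            model="dimensional",
            coefficients=dict(co.DIMENSIONAL_COEFFS),
            r_squared=1.0,
            n=26,
        )
        with pytest.raises(ValueError):
            co.predict_dispersion(fit, womersley=7.0)


def test_kappa_invariant_under_urms_unit_rescale(states):
    """Rescaling Urms units shifts only the frequency intercepts, not kappa."""
    summaries = [
        make_summary(s, float(co.dimensional_law(s.frequency, s.urms))) for s in states
    ]
    rescaled = [
        co.ExperimentSummary(
            frequency=s.frequency, stroke_volume=s.stroke_volume, urms=s.urms * 10.0,
            womersley=s.womersley, peclet=s.peclet, amplitude_ratio=s.amplitude_ratio,
            d_exp=m.d_exp,
        )
        for s, m in zip(states, summaries)
    ]
    fit_a = co.fit_dimensional(summaries)
    fit_b = co.fit_dimensional(rescaled)
    assert fit_b.coefficients["kappa"] == pytest.approx(
        fit_a.coefficients["kappa"], abs=1e-9
    )
    assert fit_b.coefficients["a0"] != pytest.approx(fit_a.coefficients["a0"], abs=1e-3)
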