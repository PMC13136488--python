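"""Adaptation metrics and evolutionary ruggedness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circuitgen.dynamics import SignalConfig, SignalResponse, SolverConfig, run_signal_protocol
from circuitgen.energetics import RateSet
from circuitgen.metrics import (
    AdaptationConstants,
    AdaptationThresholds,
    adaptation_score,
    classify_adaptable,
    compute_metrics,
    random_perturbation,
    response_features,
    ruggedness,
    sensitivity_precision,
)
from circuitgen.sampling import EnergyCircuit


def make_response(I1, I2, I_peak, O1, O2, O_peak, t=None, out=None):
    """Minimal response with a synthetic phase-2 output trace."""
    if t is None:
        t = np.linspace(0.0, 100.0, 11)
    if out is None:
        out = np.full_like(t, O2)
        out[0] = O1
    y2 = np.zeros((9, t.size))
    y2[2] = out
    y2[0] = np.linspace(I1, I2, t.size)
    return SignalResponse(
        t1=np.array([0.0, 1.0]),
        y1=np.zeros((9, 2)),
        t2=t,
        y2=y2,
        input_node=0,
        output_node=2,
        I1=I1, I2=I2, I_peak=I_peak, O1=O1, O2=O2, O_peak=O_peak,
    )


class TestSensitivityPrecision:
    def test_direct_arithmetic(self):
        resp = make_response(I1=1, I2=2, I_peak=2, O1=10, O2=11, O_peak=15)
        S, P = sensitivity_precision(resp)
        assert S == pytest.approx(0.5)
        assert P == pytest.approx(10.0)

    def test_flat_peak_gives_zero_sensitivity(self):
        resp = make_response(I1=1, I2=2, I_peak=2, O1=10, O2=11, O_peak=10)
        S, _ = sensitivity_precision(resp)
        assert S == 0.0

    def test_perfect_return_is_nan_precision(self):
        # O2 == O1 exactly: the inverse is a division by zero -> NaN
        resp = make_response(I1=1, I2=2, I_peak=2, O1=10, O2=10, O_peak=15)
        _, P = sensitivity_precision(resp)
        assert np.isnan(P)

    def test_zero_input_change_is_nan(self):
        resp = make_response(I1=1, I2=1, I_peak=1, O1=10, O2=11, O_peak=15)
        S, P = sensitivity_precision(resp)
        assert np.isnan(S) and np.isnan(P)

    def test_sensitivity_invariant_to_output_rescaling(self):
        a = make_response(I1=1, I2=2, I_peak=2, O1=10, O2=11, O_peak=15)
        b = make_response(I1=1, I2=2, I_peak=2, O1=30, O2=33, O_peak=45)
        assert sensitivity_precision(a)[0] == pytest.approx(sensitivity_precision(b)[0])


class TestAdaptationScore:
    def test_concentric_centre_value(self):
        assert adaptation_score(10.0**7, 10.0**7.5) == pytest.approx(1000.0)

    def test_hand_evaluated_point(self):
        # 1000 - (3*(1-7)^2 + (1-7.5)^2) = 1000 - 150.25
        assert adaptation_score(10.0, 10.0) == pytest.approx(849.75)

    def test_worst_operational_corner_positive(self):
        assert adaptation_score(1e-7, 1e-2) == pytest.approx(321.75)

    def test_nonpositive_inputs_are_nan(self):
        assert np.isnan(adaptation_score(0.0, 10.0))
        assert np.isnan(adaptation_score(10.0, -1.0))
        assert np.isnan(adaptation_score(np.nan, 10.0))

    @settings(deadline=None, max_examples=200)
    @given(
        st.floats(min_value=-7, max_value=2),
        st.floats(min_value=-2, max_value=7),
    )
    def test_bounded_by_C_and_positive_on_operational_box(self, ls, lp):
        a = adaptation_score(10.0**ls, 10.0**lp)
        assert a <= 1000.0
        assert a >= 321.75 - 1e-9  # the corner is the box minimum

    def test_equality_only_at_centre(self):
        assert adaptation_score(10.0**6.9, 10.0**7.5) < 1000.0


class TestClassification:
    def test_default_thresholds(self):
        assert classify_adaptable(20.0, 5.0)
        assert not classify_adaptable(5.0, 5.0)

    def test_alternative_convention(self):
        thr = AdaptationThresholds(S_min=1.0, P_min=10.0)
        assert classify_adaptable(5.0, 20.0, thr)
        assert not classify_adaptable(5.0, 20.0)  # default convention differs

    def test_nan_classifies_false(self):
        assert not classify_adaptable(np.nan, 5.0)


class TestResponseFeatures:
    def test_monotone_trace_has_zero_overshoot(self):
        t = np.linspace(0, 100, 50)
        out = 10 + 5 * (1 - np.exp(-t / 10))
        resp = make_response(1, 2, 2, 10, out[-1], out.max(), t=t, out=out)
        feats = response_features(resp)
        assert feats["overshoot"] == pytest.approx(0.0, abs=1e-6)

    def test_constant_trace_settles_immediately(self):
        resp = make_response(1, 2, 2, 10, 10.0, 10.0, out=np.full(11, 10.0))
        feats = response_features(resp)
        assert feats["settling_time"] == 0.0
        assert feats["response_time"] == 0.0

    def test_overshoot_definition(self):
        t = np.linspace(0, 100, 101)
        out = 10 + 8 * np.exp(-t / 20) * np.sin(t / 6)
        resp = make_response(1, 2, 2, 10, 10.0, out.max(), t=t, out=out)
        feats = response_features(resp)
        assert feats["overshoot"] == pytest.approx(abs(out.max() - 10.0))
        assert feats["overshoot_ratio"] == pytest.approx(feats["overshoot"] / 10.0)


@pytest.fixture(scope="module")
def adaptive_circuit():
    return EnergyCircuit("rc", np.array([-21.0, -6.0, -25.0, -4.0, -13.0, -17.0]))


class TestRuggedness:
    def test_brute_force_oracle_equality(self, adaptive_circuit, rates):
        """Pipeline ruggedness equals an independent loop that rebuilds and
        re-simulates every perturbed circuit from scratch."""
        signal, solver = SignalConfig(), SolverConfig()
        constants = AdaptationConstants()
        eps = 1.0
        r, dk = ruggedness(adaptive_circuit, rates, signal, solver, constants, eps)

        # brute force, sharing only the public simulation entry point
        resp0 = run_signal_protocol(adaptive_circuit, rates, signal, solver)
        S0, P0 = sensitivity_precision(resp0)
        a0 = adaptation_score(S0, P0, constants)
        dk_expected = np.empty(6)
        for i in range(6):
            e = adaptive_circuit.energies.copy()
            e[i] += eps
            resp = run_signal_protocol(EnergyCircuit("x", e), rates, signal, solver)
            Si, Pi = sensitivity_precision(resp)
            dk_expected[i] = (adaptation_score(Si, Pi, constants) - a0) / eps
        np.testing.assert_array_equal(dk, dk_expected)
        assert r == pytest.approx(np.sum(dk_expected**2))

    def test_order_invariance_and_nonnegativity(self, adaptive_circuit, rates):
        r, dk = ruggedness(adaptive_circuit, rates)
        assert r >= 0.0
        # the per-interaction gradients fully determine r, independent of order
        assert r == pytest.approx(np.sum(np.sort(dk) ** 2))

    def test_simple_arithmetic_of_definition(self):
        # one interaction changing adaptation by 0.5 at eps=1 -> dk=0.5, r=0.25
        dk = np.array([0.5, 0, 0, 0, 0, 0])
        assert np.sum(dk**2) == pytest.approx(0.25)

    def test_nan_baseline_propagates(self, rates, monkeypatch):
        circuit = EnergyCircuit("c", np.full(6, -10.0))
        r, dk = ruggedness(circuit, rates, baseline_adaptation=np.nan)
        assert np.isnan(r) and np.all(np.isnan(dk))

    def test_zero_epsilon_rejected(self, adaptive_circuit):
        with pytest.raises(ValueError):
            ruggedness(adaptive_circuit, epsilon=0.0)


class TestComputeMetrics:
    def test_full_record_from_simulation(self, adaptive_circuit, rates):
        resp = run_signal_protocol(adaptive_circuit, rates)
        fm = compute_metrics(resp, "rc")
        rec = fm.to_record()
        assert rec["circuit_id"] == "rc"
        assert np.isfinite(rec["S"]) and np.isfinite(rec["P"])
        assert rec["adaptation"] == pytest.approx(
            adaptation_score(rec["S"], rec["P"])
        )

    def test_random_perturbation_scale(self):
        circuit = EnergyCircuit("c", np.full(6, -10.0))
        rng = np.random.default_rng(0)
        perturbed = [random_perturbation(circuit, -30.0, rng) for _ in range(400)]
        deltas = np.array([p.energies - circuit.energies for p in perturbed]).ravel()
        assert deltas.std() == pytest.approx(3.0, rel=0.1)  # 10% of |-30|
        assert abs(deltas.mean()) < 0.2
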