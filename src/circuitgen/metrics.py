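"""Functional metrics: sensitivity, precision, adaptation, ruggedness.

Sensitivity and precision compare the output excursion at node 3 with
the input change at node 1::

    S = | ((O_peak - O1) / O1) / ((I_peak - I1) / I1) |
    P = | ((O2   - O1) / O1) / ((I2    - I1) / I1) | ^ -1

A perfectly adapting circuit responds strongly (high S) and returns to
its pre-stimulus output (high P).  The scalar adaptation objective is a
concentric quadratic in (log10 S, log10 P) that increases towards the
adaptable region; divisions by zero anywhere propagate as NaN.

Evolutionary ruggedness perturbs each of the m = 6 unique interactions
by a fixed energy epsilon, re-simulates, and sums the squared adaptation
changes per unit perturbation:  dk_i = (a_eps - a0)/eps,  r = sum dk_i^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import RateSet, SignalConfig, SignalResponse, SolverConfig, run_signal_protocol
from .sampling import EnergyCircuit


@dataclass(frozen=True)
class AdaptationConstants:
    """Constants of the scalar adaptation objective.

    The objective peaks (value ``C``) at log10 S = ``s_centre`` and
    log10 P = ``p_centre``; ``alpha`` boosts the sensitivity term.  The
    operational box is where simulated circuits live; the objective is
    positive everywhere on it (321.75 at the worst corner).
    """

    s_centre: float = 7.0
    p_centre: float = 7.5
    alpha: float = 3.0
    C: float = 1000.0
    log_s_range: tuple[float, float] = (-7.0, 2.0)
    log_p_range: tuple[float, float] = (-2.0, 7.0)

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.C <= 0:
            raise ValueError("alpha and C must be positive")


@dataclass(frozen=True)
class AdaptationThresholds:
    """Binary adaptability thresholds (defaults: S > 10, P > 1)."""

    S_min: float = 10.0
    P_min: float = 1.0

    def __post_init__(self) -> None:
        if self.S_min <= 0 or self.P_min <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class FunctionalMetrics:
    circuit_id: str
    S: float
    P: float
    adaptation: float
    overshoot: float
    overshoot_ratio: float
    settling_time: float
    response_time: float
    steady_state_initial: float
    steady_state_final: float
    ruggedness: float = np.nan
    dk: np.ndarray | None = None
    converged: bool = True
    settled: bool = True
    flag: str = ""

    def to_record(self) -> dict:
        rec = {
            "circuit_id": self.circuit_id,
            "S": self.S,
            "P": self.P,
            "adaptation": self.adaptation,
            "overshoot": self.overshoot,
            "overshoot_ratio": self.overshoot_ratio,
            "settling_time": self.settling_time,
            "response_time": self.response_time,
            "steady_state_initial": self.steady_state_initial,
            "steady_state_final": self.steady_state_final,
            "ruggedness": self.ruggedness,
            "converged": self.converged,
            "settled": self.settled,
            "flag": self.flag,
        }
        if self.dk is not None:
            rec.update({f"dk{i + 1}": v for i, v in enumerate(self.dk)})
        return rec


def _safe_ratio(num: float, den: float) -> float:
    if den == 0 or not np.isfinite(num) or not np.isfinite(den):
        return np.nan
    return num / den


def sensitivity_precision(resp: SignalResponse) -> tuple[float, float]:
    """(S, P) from a signal response; degenerate divisions give NaN."""
    rel_peak_out = _safe_ratio(resp.O_peak - resp.O1, resp.O1)
    rel_final_out = _safe_ratio(resp.O2 - resp.O1, resp.O1)
    rel_peak_in = _safe_ratio(resp.I_peak - resp.I1, resp.I1)
    rel_final_in = _safe_ratio(resp.I2 - resp.I1, resp.I1)

    S = np.abs(_safe_ratio(rel_peak_out, rel_peak_in))
    inv_P = np.abs(_safe_ratio(rel_final_out, rel_final_in))
    # |x|^-1 with x = 0 is a division by zero -> NaN, per the metric contract
    P = _safe_ratio(1.0, inv_P) if not np.isnan(inv_P) else np.nan
    return float(S), float(P)


def adaptation_score(
    S: float, P: float, constants: AdaptationConstants = AdaptationConstants()
) -> float:
    """Concentric adaptation objective; NaN for nonpositive or NaN S/P."""
    if not (np.isfinite(S) and np.isfinite(P)) or S <= 0 or P <= 0:
        return np.nan
    ls, lp = np.log10(S), np.log10(P)
    return float(
        -(constants.alpha * (ls - constants.s_centre) ** 2 + (lp - constants.p_centre) ** 2)
        + constants.C
    )


def classify_adaptable(
    S: float, P: float, thresholds: AdaptationThresholds = AdaptationThresholds()
) -> bool:
    """Binary adaptability call; NaN metrics classify False."""
    if not (np.isfinite(S) and np.isfinite(P)):
        return False
    return bool(S > thresholds.S_min and P > thresholds.P_min)


def response_features(
    resp: SignalResponse,
    settling_band: float = 0.02,
    response_fraction: float = 0.5,
) -> dict:
    """Overshoot and timing features of the phase-2 output trace.

    Settling time: first time after which the output stays within
    ``settling_band`` x |terminal deviation| of its final value.
    Response time: first time the output covers ``response_fraction`` of
    its peak deviation from the phase-2 initial value.
    """
    t = resp.t2
    out = resp.output_trace
    o_init = out[0]
    o_final = resp.O2
    overshoot = abs(resp.O_peak - o_final)
    ratio = overshoot / resp.O1 if resp.O1 > 0 else np.nan

    band = settling_band * abs(o_final - o_init)
    if band == 0:
        settling_time = 0.0
    else:
        outside = np.abs(out - o_final) > band
        if outside.any():
            last_out = int(np.max(np.nonzero(outside)[0]))
            settling_time = float(t[min(last_out + 1, t.size - 1)])
        else:
            settling_time = 0.0

    peak_dev = abs(resp.O_peak - o_init)
    if peak_dev == 0:
        response_time = 0.0
    else:
        reached = np.abs(out - o_init) >= response_fraction * peak_dev
        response_time = float(t[int(np.argmax(reached))]) if reached.any() else float(t[-1])

    return {
        "overshoot": float(overshoot),
        "overshoot_ratio": float(ratio),
        "settling_time": settling_time,
        "response_time": response_time,
    }


def compute_metrics(
    resp: SignalResponse,
    circuit_id: str = "",
    constants: AdaptationConstants = AdaptationConstants(),
) -> FunctionalMetrics:
    """All per-response functional metrics (ruggedness computed separately)."""
    S, P = sensitivity_precision(resp)
    a = adaptation_score(S, P, constants)
    feats = response_features(resp)
    flag = ""
    if np.isnan(S) or np.isnan(P):
        flag = "nan_metric"
    elif not resp.converged:
        flag = "phase1_unconverged"
    elif not resp.settled:
        flag = "phase2_unsettled"
    return FunctionalMetrics(
        circuit_id=circuit_id or "unnamed",
        S=S,
        P=P,
        adaptation=a,
        steady_state_initial=resp.O1,
        steady_state_final=resp.O2,
        converged=resp.converged,
        settled=resp.settled,
        flag=flag,
        **feats,
    )


def ruggedness(
    circuit: EnergyCircuit,
    rates: RateSet = RateSet(),
    signal: SignalConfig = SignalConfig(),
    solver: SolverConfig = SolverConfig(),
    constants: AdaptationConstants = AdaptationConstants(),
    epsilon: float = 1.0,
    baseline_adaptation: float | None = None,
) -> tuple[float, np.ndarray]:
    """Evolutionary ruggedness of one circuit.

    Each of the m unique interactions is perturbed by ``+epsilon``
    kcal/mol (towards weaker binding; pass a negative epsilon for the
    other direction) and the protocol re-run.  Returns (r, dk).  Any NaN
    adaptation -- baseline or perturbed -- makes r NaN.
    """
    if epsilon == 0:
        raise ValueError("epsilon must be nonzero")
    if baseline_adaptation is None:
        resp0 = run_signal_protocol(circuit, rates, signal, solver)
        S0, P0 = sensitivity_precision(resp0)
        baseline_adaptation = adaptation_score(S0, P0, constants)
    m = circuit.energies.size
    dk = np.full(m, np.nan)
    if np.isnan(baseline_adaptation):
        return np.nan, dk
    for i in range(m):
        resp = run_signal_protocol(circuit.perturbed(i, epsilon), rates, signal, solver)
        S, P = sensitivity_precision(resp)
        a_eps = adaptation_score(S, P, constants)
        dk[i] = (a_eps - baseline_adaptation) / epsilon
    if np.any(np.isnan(dk)):
        return np.nan, dk
    return float(np.sum(dk**2)), dk


def random_perturbation(
    circuit: EnergyCircuit,
    strongest_energy: float,
    rng: np.random.Generator,
    relative_sd: float = 0.10,
) -> EnergyCircuit:
    """Exploratory whole-circuit mutation (not part of ruggedness).

    Adds zero-mean normal noise to every interaction with standard
    deviation ``relative_sd`` x |strongest training binding energy|.
    """
    sd = relative_sd * abs(strongest_energy)
    noise = rng.normal(0.0, sd, size=circuit.energies.size)
    return EnergyCircuit(
        f"{circuit.circuit_id}_mut", circuit.energies + noise, metadata=dict(circuit.metadata)
    )
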