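"""Mass-action dynamics of RNA circuits and the two-phase signal protocol.

For a 3-node circuit the state holds 9 species: the three free RNAs and
the six pairwise complexes (in canonical packing order).  Reactions:

* production of each free RNA at a constant rate,
* first-order degradation of every species (free and bound),
* reversible binding ``RNA_i + RNA_j <=> C_ij`` with per-pair rates;
  self-binding consumes (and releases) two copies of the same RNA.

The signal protocol relaxes the circuit to its pre-signal steady state
(phase 1), perturbs node 1 -- by default a step that doubles its
production rate; optionally an impulse added to its free copies -- and
simulates phase 2 until the system settles, bookkeeping the input and
output levels (I1, I2, I_peak, O1, O2, O_peak) used by the adaptation
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
from scipy.integrate import solve_ivp

from .energetics import RateSet
from .sampling import EnergyCircuit, interaction_pairs


@numba.njit(cache=True)
def _rhs(t, y, pairs, production, kf, kr, d):
    n = production.size
    dy = np.empty(y.size)
    for i in range(n):
        dy[i] = production[i] - d * y[i]
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        c = n + k
        dy[c] = -d * y[c]
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        c = n + k
        v = kf[k] * y[i] * y[j] - kr[k] * y[c]
        if i == j:
            dy[i] -= 2.0 * v
        else:
            dy[i] -= v
            dy[j] -= v
        dy[c] += v
    return dy


@numba.njit(cache=True)
def _jac(t, y, pairs, production, kf, kr, d):
    n = production.size
    m = y.size
    J = np.zeros((m, m))
    for i in range(m):
        J[i, i] = -d
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        c = n + k
        dv_di = kf[k] * y[j]
        dv_dj = kf[k] * y[i]
        if i == j:
            J[i, i] -= 2.0 * (dv_di + dv_dj)
            J[i, c] += 2.0 * kr[k]
            J[c, i] += dv_di + dv_dj
        else:
            J[i, i] -= dv_di
            J[i, j] -= dv_dj
            J[j, i] -= dv_di
            J[j, j] -= dv_dj
            J[i, c] += kr[k]
            J[j, c] += kr[k]
            J[c, i] += dv_di
            J[c, j] += dv_dj
        J[c, c] -= kr[k]
    return J


@dataclass
class ReactionSystem:
    """Compiled reaction network for one circuit."""

    n_nodes: int
    pairs: np.ndarray  # (m, 2) node indices, canonical order
    production: np.ndarray  # (n,) copies/s, free species only
    kf: np.ndarray  # (m,) per-copy association rates
    kr: np.ndarray  # (m,) dissociation rates, s^-1
    degradation: float
    input_node: int = 0
    output_node: int = 2

    @property
    def n_species(self) -> int:
        return self.n_nodes + self.pairs.shape[0]

    @property
    def species_names(self) -> list[str]:
        free = [f"RNA{i + 1}" for i in range(self.n_nodes)]
        bound = [f"C{i + 1}{j + 1}" for i, j in self.pairs]
        return free + bound

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return _rhs(t, y, self.pairs, self.production, self.kf, self.kr, self.degradation)

    def residual(self, y: np.ndarray, rtol: float, atol: float) -> float:
        """max_i |dy_i/dt| / (atol + rtol |y_i|); <= 1 means steady."""
        dy = self.rhs(0.0, y)
        return float(np.max(np.abs(dy) / (atol + rtol * np.abs(y))))

    def default_initial_state(self, x0: float) -> np.ndarray:
        y = np.zeros(self.n_species)
        y[: self.n_nodes] = x0
        return y

    def with_production(self, production: np.ndarray) -> "ReactionSystem":
        return ReactionSystem(
            self.n_nodes, self.pairs, np.asarray(production, float),
            self.kf, self.kr, self.degradation, self.input_node, self.output_node,
        )


def build_system(
    circuit: EnergyCircuit,
    rates: RateSet,
    input_node: int = 0,
    output_node: int = 2,
) -> ReactionSystem:
    """Assemble the mass-action network for one energy circuit."""
    n = circuit.n_nodes
    pairs = np.asarray(interaction_pairs(n), dtype=np.int64)
    if not np.all(np.isfinite(circuit.energies)):
        raise ValueError("circuit has missing/non-finite interaction energies")
    kr = rates.reverse_rates(circuit.energies)
    kf = np.full(pairs.shape[0], rates.k_f_percopy)
    production = np.full(n, rates.production)
    return ReactionSystem(n, pairs, production, kf, kr, rates.degradation,
                          input_node, output_node)


@dataclass(frozen=True)
class SignalConfig:
    """Perturbation applied to the input node at the phase boundary.

    ``step`` multiplies the input-node production rate by ``magnitude``
    (default 2: a doubling step).  ``impulse`` instead adds
    ``magnitude x`` the steady-state free copies of the input node.
    """

    mode: str = "step"
    magnitude: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("step", "impulse"):
            raise ValueError("signal mode must be 'step' or 'impulse'")
        if self.magnitude <= 0:
            raise ValueError("signal magnitude must be positive")


@dataclass(frozen=True)
class SolverConfig:
    rtol: float = 1e-6
    atol: float = 1e-9
    t_max: float = 1e5  # per phase, seconds
    method: str = "LSODA"
    # geometric integration chunks for steady-state detection
    first_chunk: float = 2e3
    chunk_growth: float = 10.0


@dataclass
class SteadyStateResult:
    state: np.ndarray
    residual: float
    converged: bool
    t_elapsed: float


@dataclass
class SignalResponse:
    """Two-phase trajectories with input/output bookmarks (copies)."""

    t1: np.ndarray
    y1: np.ndarray  # (n_species, len(t1)), phase-1 trajectory
    t2: np.ndarray
    y2: np.ndarray  # phase-2 trajectory; t2 restarts at 0
    input_node: int
    output_node: int
    I1: float
    I2: float
    I_peak: float
    O1: float
    O2: float
    O_peak: float
    signal: SignalConfig = field(default_factory=SignalConfig)
    phase1_residual: float = np.nan
    phase2_residual: float = np.nan
    converged: bool = True
    settled: bool = True
    species_names: list[str] = field(default_factory=list)

    @property
    def output_trace(self) -> np.ndarray:
        return self.y2[self.output_node]

    @property
    def input_trace(self) -> np.ndarray:
        return self.y2[self.input_node]


def _integrate_to_steady(
    system: ReactionSystem,
    y0: np.ndarray,
    solver: SolverConfig,
    keep_trajectory: bool = False,
):
    """Integrate in geometric chunks until the normalised derivative test
    passes or ``t_max`` is reached; optionally retain the trajectory."""
    args = (system.pairs, system.production, system.kf, system.kr, system.degradation)
    t_done = 0.0
    y = np.asarray(y0, dtype=float)
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    chunk = solver.first_chunk
    converged = system.residual(y, solver.rtol, solver.atol) <= 1.0
    if converged and keep_trajectory:
        ts.append(np.array([0.0]))
        ys.append(y[:, None])
    while not converged and t_done < solver.t_max:
        t_end = min(t_done + chunk, solver.t_max)
        sol = solve_ivp(
            _rhs, (t_done, t_end), y, method=solver.method, jac=_jac,
            args=args, rtol=solver.rtol, atol=solver.atol,
        )
        if not sol.success:
            break
        if keep_trajectory:
            ts.append(sol.t)
            ys.append(sol.y)
        y = sol.y[:, -1]
        t_done = sol.t[-1]
        chunk *= solver.chunk_growth
        converged = system.residual(y, solver.rtol, solver.atol) <= 1.0
    residual = system.residual(y, solver.rtol, solver.atol)
    if keep_trajectory:
        if ts:
            t_arr = np.concatenate(ts)
            y_arr = np.concatenate(ys, axis=1)
        else:
            t_arr = np.array([0.0])
            y_arr = y[:, None]
        return SteadyStateResult(y, residual, converged, t_done), t_arr, y_arr
    return SteadyStateResult(y, residual, converged, t_done), None, None


def simulate_steady_state(
    system: ReactionSystem,
    y0: np.ndarray | None = None,
    solver: SolverConfig = SolverConfig(),
    x0: float = 100.0,
) -> SteadyStateResult:
    """Relax a system to steady state.

    Returns the first chunk-boundary state whose normalised derivative
    residual is <= 1, or the state at ``t_max`` flagged unconverged.
    Solver failures are reported through the ``converged`` flag rather
    than raised, so batch runs continue.
    """
    if y0 is None:
        y0 = system.default_initial_state(x0)
    if np.any(np.asarray(y0) < 0):
        raise ValueError("initial copies must be nonnegative")
    result, _, _ = _integrate_to_steady(system, y0, solver)
    return result


def _peak(trace: np.ndarray, reference: float) -> float:
    """Trajectory point with the largest |deviation| from ``reference``
    (handles both up- and down-going responses)."""
    idx = int(np.argmax(np.abs(trace - reference)))
    return float(trace[idx])


def run_signal_protocol(
    circuit: EnergyCircuit,
    rates: RateSet = RateSet(),
    signal: SignalConfig = SignalConfig(),
    solver: SolverConfig = SolverConfig(),
) -> SignalResponse:
    """Run the full two-phase protocol for one circuit.

    Phase 1 relaxes from the default initial state (all free RNAs at
    ``rates.x0`` copies) and records I1/O1.  The signal is applied to
    the input node only at the phase boundary; phase 2 keeps the full
    trajectory and records peaks and terminal levels.
    """
    system = build_system(circuit, rates)
    ss1, _, _ = _integrate_to_steady(
        system, system.default_initial_state(rates.x0), solver
    )
    y_boundary = ss1.state.copy()
    I1 = float(y_boundary[system.input_node])
    O1 = float(y_boundary[system.output_node])

    system2 = system
    if signal.mode == "step":
        production = system.production.copy()
        production[system.input_node] *= signal.magnitude
        system2 = system.with_production(production)
    else:  # impulse: add magnitude x steady-state copies to the free input
        y_boundary[system.input_node] += signal.magnitude * I1

    ss2, t2, y2 = _integrate_to_steady(system2, y_boundary, solver, keep_trajectory=True)
    I2 = float(ss2.state[system.input_node])
    O2 = float(ss2.state[system.output_node])
    I_peak = _peak(y2[system.input_node], y_boundary[system.input_node])
    O_peak = _peak(y2[system.output_node], y_boundary[system.output_node])
    t2 = t2 - t2[0]

    return SignalResponse(
        t1=np.array([0.0, ss1.t_elapsed]),
        y1=np.column_stack([system.default_initial_state(rates.x0), ss1.state]),
        t2=t2,
        y2=y2,
        input_node=system.input_node,
        output_node=system.output_node,
        I1=I1, I2=I2, I_peak=I_peak, O1=O1, O2=O2, O_peak=O_peak,
        signal=signal,
        phase1_residual=ss1.residual,
        phase2_residual=ss2.residual,
        converged=ss1.converged,
        settled=ss2.converged,
        species_names=system.species_names,
    )
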