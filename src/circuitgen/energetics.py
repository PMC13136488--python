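"""Binding free energies to mass-action rates, and sequence->energy engines.

The pipeline runs in copies-per-cell units.  A textbook Gibbs conversion
``K = exp(-dG/RT)`` is provided for reference, but the dynamics use an
empirical calibration of the equilibrium constant against sRNA/mRNA
repression measurements::

    K ~= exp(-0.8 (dG + 10)) / x0        [per-copy]

with ``x0`` the initial RNA copy number.  The association rate is fixed
(fast binding); the dissociation rate follows as ``k_r = k_f / K``.  The
two association rates below (per-molar and per-copy) are consistent with
an effective cell volume of roughly 1.1 fL via Avogadro scaling.
"""

from __future__ import annotations

import hashlib
import shutil
import subprocess
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from .sampling import EnergyCircuit, SequenceCircuit, interaction_pairs

#: Gas constant in kcal/(mol K).
R_KCAL = 1.987e-3
#: Default temperature (K) for the reference Gibbs conversion.
T_DEFAULT = 310.0

KF_MOLAR = 1.0e6  # association rate, M^-1 s^-1 (informational)
KF_PER_COPY = 1.50958097e-3  # association rate, copies^-1 s^-1
X0_DEFAULT = 100.0  # starting copies per free RNA
DEGRADATION_DEFAULT = 0.01175  # first-order decay, s^-1


@dataclass(frozen=True)
class RateSet:
    """Kinetic constants shared by every circuit simulation.

    ``production`` defaults to ``d * x0`` copies/s so that an unbound
    species relaxes to exactly ``x0`` copies at steady state.
    """

    k_f_percopy: float = KF_PER_COPY
    k_f_molar: float = KF_MOLAR
    x0: float = X0_DEFAULT
    degradation: float = DEGRADATION_DEFAULT
    production: float | None = None

    def __post_init__(self) -> None:
        if self.k_f_percopy <= 0 or self.x0 <= 0 or self.degradation < 0:
            raise ValueError("rates must be positive (degradation nonnegative)")
        if self.production is None:
            object.__setattr__(self, "production", self.degradation * self.x0)

    def reverse_rates(self, energies: np.ndarray) -> np.ndarray:
        """Dissociation rate (s^-1) for each packed interaction energy."""
        K = empirical_equilibrium(np.asarray(energies, dtype=float), self.x0)
        return self.k_f_percopy / K


def gibbs_equilibrium(dG: float, R: float = R_KCAL, T: float = T_DEFAULT) -> float:
    """Equilibrium constant from ``dG0 = -RT ln K`` (reference only)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(-dG / (R * T)))


def empirical_equilibrium(dG, x0: float = X0_DEFAULT):
    """Per-copy equilibrium constant from the empirical calibration.

    ``K = exp(-0.8 (dG + 10)) / x0``; strictly decreasing in ``dG`` so
    stronger (more negative) binding gives larger ``K``.
    """
    if x0 <= 0:
        raise ValueError("x0 must be positive")
    return np.exp(-0.8 * (np.asarray(dG, dtype=float) + 10.0)) / x0


def rates_from_energy(
    dG, x0: float = X0_DEFAULT, k_f_percopy: float = KF_PER_COPY
) -> tuple[float, np.ndarray]:
    """(k_f, k_r) for a binding energy; k_r is increasing in dG."""
    K = empirical_equilibrium(dG, x0)
    return k_f_percopy, k_f_percopy / K


class EngineError(RuntimeError):
    pass


class EngineNotAvailableError(EngineError):
    """The external prediction tool is not installed on this system."""


class EngineExecutionError(EngineError):
    """The external tool ran but failed; carries its captured output."""


class EnergyEngine(ABC):
    """Contract for RNA-RNA interaction energy predictors.

    Implementations must be deterministic for an ordered (query, target)
    pair; a pair with no predicted interaction scores 0 kcal/mol.
    """

    name: str = "abstract"
    deterministic: bool = True

    @abstractmethod
    def predict(self, query: str, target: str) -> float:
        """Minimum free energy (kcal/mol) of the query-target interaction."""


class ConstantEnergyEngine(EnergyEngine):
    """Stub engine returning a fixed energy for every pair."""

    name = "constant"

    def __init__(self, energy: float = -12.0):
        self.energy = float(energy)

    def predict(self, query: str, target: str) -> float:
        return self.energy


class HashEnergyEngine(EnergyEngine):
    """Stub engine mapping each ordered pair to a deterministic energy.

    The energy is a uniform draw on ``energy_range`` keyed by a SHA-256
    digest of the pair, so it behaves like a fixed random oracle.
    """

    name = "hash"

    def __init__(self, energy_range: tuple[float, float] = (-30.0, 0.0), salt: str = ""):
        self.energy_range = energy_range
        self.salt = salt

    def predict(self, query: str, target: str) -> float:
        digest = hashlib.sha256(f"{self.salt}|{query}|{target}".encode()).digest()
        u = int.from_bytes(digest[:8], "big") / 2**64
        low, high = self.energy_range
        return low + u * (high - low)


class _SubprocessEngine(EnergyEngine):
    executable: str = ""

    def _require(self) -> str:
        path = shutil.which(self.executable)
        if path is None:
            raise EngineNotAvailableError(
                f"external tool '{self.executable}' is not installed; "
                "use a stub engine or the parameter-sampled path"
            )
        return path

    def _run(self, args: list[str], stdin: str | None = None) -> str:
        self._require()
        proc = subprocess.run(
            args, input=stdin, capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise EngineExecutionError(
                f"{self.executable} failed (exit {proc.returncode}): "
                f"stdout={proc.stdout!r} stderr={proc.stderr!r}"
            )
        return proc.stdout


class IntaRNAEngine(_SubprocessEngine):
    """Adapter around the IntaRNA 2.x command line tool (default settings).

    IntaRNA is invoked in CSV output mode and the minimum-free-energy
    column of the top-ranked interaction is parsed.  If IntaRNA reports
    no interaction the pair is inert and scores 0.
    """

    name = "intarna"
    executable = "IntaRNA"

    def predict(self, query: str, target: str) -> float:
        out = self._run(
            [
                self.executable,
                "--query", query,
                "--target", target,
                "--outMode", "C",
                "--outCsvCols", "E",
            ]
        )
        lines = [ln for ln in out.strip().splitlines() if ln.strip()]
        if len(lines) < 2:  # header only: no interaction found
            return 0.0
        return float(lines[1].split(";")[0])


class RNADuplexEngine(_SubprocessEngine):
    """Adapter around ViennaRNA's RNAduplex hybridisation predictor."""

    name = "rnaduplex"
    executable = "RNAduplex"

    def predict(self, query: str, target: str) -> float:
        out = self._run([self.executable, "--noLP"], stdin=f"{query}\n{target}\n")
        # last parenthesised token is the duplex MFE, e.g. "( -5.40)"
        last = out.strip().splitlines()[-1]
        mfe = last[last.rfind("(") + 1 : last.rfind(")")]
        energy = float(mfe)
        return min(energy, 0.0)


def predict_energies(circuit: SequenceCircuit, engine: EnergyEngine) -> EnergyCircuit:
    """Score all unique ordered pairs (self-pairs included) of a circuit.

    A 3-node circuit triggers exactly 6 engine evaluations, one per
    canonical packed interaction.
    """
    energies = [
        engine.predict(circuit.sequences[i], circuit.sequences[j])
        for i, j in interaction_pairs(circuit.n_nodes)
    ]
    return EnergyCircuit(
        circuit.circuit_id,
        np.asarray(energies, dtype=float),
        sequences=list(circuit.sequences),
        metadata={"engine": engine.name},
    )
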