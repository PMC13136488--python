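"""Sampling of RNA circuits, as sequences or as binding-energy vectors.

A circuit of ``n`` RNA species has ``n(n+1)/2`` unique pairwise
interactions (self-pairs included).  For the default 3-node circuit the
canonical packing order is ``[k11, k12, k13, k22, k23, k33]`` -- the
upper triangle of the symmetric interaction matrix, row-major.  Every
module in the package indexes interactions only through this packing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = "ACGU"

#: Nucleotide proportions of the E. coli transcriptome, used as the
#: default sequence-sampling distribution (order A, C, G, U).
ECOLI_NUCLEOTIDE_FREQS = (0.2451, 0.2458, 0.2622, 0.2469)


def interaction_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """Zero-based (i, j) node pairs, i <= j, in canonical packing order."""
    return [(i, j) for i in range(n_nodes) for j in range(i, n_nodes)]


def interaction_labels(n_nodes: int = 3) -> list[str]:
    return [f"k{i + 1}{j + 1}" for i, j in interaction_pairs(n_nodes)]


#: Canonical column labels for the 3-node circuit tables.
INTERACTION_LABELS = interaction_labels(3)


class ConfigurationError(ValueError):
    """Raised when a sampling configuration violates its invariants."""


@dataclass(frozen=True)
class SamplingConfig:
    """Configuration for both the sequence and the energy sampler.

    Parameters
    ----------
    n_circuits
        Number of circuits to draw.
    n_nodes
        RNA species per circuit (3 throughout the study).
    seq_length
        Length of each sampled RNA in nucleotides.
    nucleotide_freqs
        Probabilities for (A, C, G, U); defaults to E. coli proportions.
    energy_range
        (low, high) bounds in kcal/mol for uniform energy sampling; the
        default [-30, 0] spans the plausible range for 20-nt RNAs.
    seed
        Seed of the sampler's private RNG, recorded in outputs.
    """

    n_circuits: int
    n_nodes: int = 3
    seq_length: int = 20
    nucleotide_freqs: tuple[float, float, float, float] = ECOLI_NUCLEOTIDE_FREQS
    energy_range: tuple[float, float] = (-30.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_circuits <= 0:
            raise ConfigurationError("n_circuits must be positive")
        if self.n_nodes <= 0 or self.seq_length <= 0:
            raise ConfigurationError("n_nodes and seq_length must be positive")
        freqs = np.asarray(self.nucleotide_freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs < 0):
            raise ConfigurationError("nucleotide_freqs must be 4 nonnegative values")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("nucleotide_freqs must sum to 1 within 1e-9")
        low, high = self.energy_range
        if not (low < high <= 0):
            raise ConfigurationError("energy_range must satisfy low < high <= 0")


@dataclass
class SequenceCircuit:
    """A circuit given as its constituent RNA sequences."""

    circuit_id: str
    sequences: list[str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("all sequences in a circuit must have equal length")
        for s in self.sequences:
            bad = set(s) - set(RNA_ALPHABET)
            if bad:
                raise ValueError(
                    f"sequence contains non-RNA characters {sorted(bad)}; "
                    "DNA 'T' is rejected, not converted"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.sequences)


@dataclass
class EnergyCircuit:
    """A circuit given as its packed pairwise binding energies (kcal/mol)."""

    circuit_id: str
    energies: np.ndarray
    sequences: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        n = self.n_nodes
        if n * (n + 1) // 2 != self.energies.size:
            raise ValueError(
                f"energy vector length {self.energies.size} is not triangular"
            )

    @property
    def n_nodes(self) -> int:
        # invert m = n(n+1)/2
        m = self.energies.size
        n = int((np.sqrt(8 * m + 1) - 1) / 2)
        if n * (n + 1) // 2 != m:
            raise ValueError(f"energy vector length {m} is not triangular")
        return n

    def matrix(self) -> np.ndarray:
        return unpack_energies(self.energies)

    def perturbed(self, index: int, epsilon: float) -> "EnergyCircuit":
        """Copy with interaction ``index`` shifted by ``epsilon`` kcal/mol."""
        e = self.energies.copy()
        e[index] += epsilon
        return EnergyCircuit(f"{self.circuit_id}_p{index}", e, metadata=dict(self.metadata))


def pack_energies(matrix: np.ndarray, *, atol: float = 1e-12) -> np.ndarray:
    """Pack a symmetric interaction matrix into the canonical 6-vector.

    For ``n`` nodes the packed length is ``n(n+1)/2`` (6 for n=3).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("interaction matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=atol, rtol=0):
        raise ValueError("interaction matrix must be symmetric")
    n = matrix.shape[0]
    return np.array([matrix[i, j] for i, j in interaction_pairs(n)])


def unpack_energies(packed: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pack_energies`."""
    packed = np.asarray(packed, dtype=float)
    m = packed.size
    n = int((np.sqrt(8 * m + 1) - 1) / 2)
    if n * (n + 1) // 2 != m:
        raise ValueError(f"packed length {m} is not triangular")
    out = np.zeros((n, n))
    for value, (i, j) in zip(packed, interaction_pairs(n)):
        out[i, j] = value
        out[j, i] = value
    return out


def sample_sequences(config: SamplingConfig) -> list[SequenceCircuit]:
    """Draw circuits of i.i.d. random RNA sequences.

    Each of the ``n_nodes`` sequences is sampled position-wise from
    ``config.nucleotide_freqs``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(RNA_ALPHABET))
    freqs = np.asarray(config.nucleotide_freqs, dtype=float)
    freqs = freqs / freqs.sum()  # exact normalisation for the RNG
    circuits = []
    for idx in range(config.n_circuits):
        draws = rng.choice(4, size=(config.n_nodes, config.seq_length), p=freqs)
        seqs = ["".join(alphabet[row]) for row in draws]
        circuits.append(SequenceCircuit(f"seq{idx:06d}", seqs))
    return circuits


def sample_energy_circuits(config: SamplingConfig) -> list[EnergyCircuit]:
    """Draw circuits directly in energy space.

    Each unique interaction is sampled independently and uniformly on
    ``config.energy_range`` (a uniform [0, 1] draw scaled onto the
    range).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    low, high = config.energy_range
    m = config.n_nodes * (config.n_nodes + 1) // 2
    raw = rng.uniform(0.0, 1.0, size=(config.n_circuits, m))
    energies = low + raw * (high - low)
    meta = {"seed": config.seed, "energy_range": list(config.energy_range)}
    return [
        EnergyCircuit(f"par{idx:06d}", energies[idx], metadata=dict(meta))
        for idx in range(config.n_circuits)
    ]


def circuits_to_frame(circuits: list[EnergyCircuit]) -> pd.DataFrame:
    """Tabulate energy circuits: circuit_id plus one column per interaction."""
    if not circuits:
        return pd.DataFrame(columns=["circuit_id", *INTERACTION_LABELS])
    labels = interaction_labels(circuits[0].n_nodes)
    rows = [{"circuit_id": c.circuit_id, **dict(zip(labels, c.energies))} for c in circuits]
    return pd.DataFrame(rows)


def frame_to_circuits(frame: pd.DataFrame) -> list[EnergyCircuit]:
    labels = [c for c in frame.columns if c.startswith("k") and c[1:].isdigit()]
    labels = sorted(labels)
    return [
        EnergyCircuit(str(row["circuit_id"]), np.array([row[c] for c in labels]))
        for _, row in frame.iterrows()
    ]


def write_fasta(circuits: list[SequenceCircuit], path: str | Path) -> None:
    """Write circuits as FASTA with record ids ``{circuit_id}_node{i}``."""
    records = [
        SeqRecord(Seq(seq), id=f"{c.circuit_id}_node{i + 1}", description="")
        for c in circuits
        for i, seq in enumerate(c.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[SequenceCircuit]:
    """Read circuits back from FASTA written by :func:`write_fasta`."""
    groups: dict[str, list[tuple[int, str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        cid, _, node = rec.id.rpartition("_node")
        groups.setdefault(cid, []).append((int(node), str(rec.seq)))
    circuits = []
    for cid, members in groups.items():
        members.sort()
        circuits.append(SequenceCircuit(cid, [s for _, s in members]))
    return circuits
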