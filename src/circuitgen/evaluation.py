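"""Model-quality evaluation: R^2, KDE prompt adherence, F1, motif clusters.

Prompt adherence is scored by fitting a Gaussian KDE to the realised
metric distribution of each prompt group, evaluating all KDEs on a
shared 1000-point grid, unit-normalising each curve on the grid, and
integrating the pointwise minimum of each pair.  The overlap is then
exactly on a [0, 1] scale: 1 for identical distributions, ~0 for
disjoint ones.  Lower mean overlap across prompts = better adherence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)


def pooled_r2(true: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination pooled over all matrix entries."""
    t = np.asarray(true, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if t.size == 0:
        raise ValueError("empty arrays")
    ss_res = np.sum((t - p) ** 2)
    ss_tot = np.sum((t - t.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)


def reconstruction_r2(results, x_test: np.ndarray, c_test: np.ndarray) -> float:
    """Held-out pooled R^2 of a fitted CVAE (evaluation noise = 0)."""
    x_test = np.atleast_2d(x_test)
    if x_test.shape[0] == 0:
        raise ValueError("empty test set")
    return pooled_r2(x_test, results.reconstruct(x_test, c_test))


def _kde_curve(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    try:
        return gaussian_kde(values)(grid)
    except np.linalg.LinAlgError:
        # degenerate (zero-variance) group: epsilon-bandwidth fallback
        logger.warning("zero-variance KDE group; using epsilon bandwidth")
        bw = max(1e-9, 1e-6 * (abs(float(values[0])) or 1.0))
        diff = (grid[None, :] - values[:, None]) / bw
        return np.exp(-0.5 * diff**2).sum(axis=0) / (values.size * bw * np.sqrt(2 * np.pi))


def _bandwidth(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if sd == 0:
        return 1e-9
    return sd * values.size ** (-1.0 / 5.0)  # Scott's rule, 1-D


def kde_overlap(
    groups: dict | list, n_points: int = 1000
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Pairwise KDE overlap between metric sample groups.

    Parameters
    ----------
    groups
        Mapping (or list) of per-prompt 1-D metric samples; at least 2
        groups of >= 5 samples each.
    n_points
        Size of the shared evaluation grid spanning the pooled sample
        range, padded by 3 bandwidths.

    Returns
    -------
    overlap : (g, g) symmetric matrix, unit diagonal, entries in [0, 1]
    per_group : mean overlap of each group with the others
    grand_mean : mean of the per-group means (lower = better adherence)
    grid : the evaluation grid
    """
    if isinstance(groups, dict):
        samples = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        samples = [np.asarray(v, dtype=float) for v in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for s in samples:
        if s.size < 5:
            raise ValueError("each group needs at least 5 samples")

    pooled = np.concatenate(samples)
    pad = 3.0 * max(_bandwidth(s) for s in samples)
    grid = np.linspace(pooled.min() - pad, pooled.max() + pad, n_points)
    delta = grid[1] - grid[0]

    curves = []
    for s in samples:
        k = _kde_curve(s, grid)
        area = k.sum() * delta
        curves.append(k / area if area > 0 else k)

    g = len(curves)
    overlap = np.ones((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            ov = float(np.minimum(curves[i], curves[j]).sum() * delta)
            overlap[i, j] = overlap[j, i] = min(ov, 1.0)
    per_group = (overlap.sum(axis=1) - 1.0) / (g - 1)
    return overlap, per_group, float(per_group.mean()), grid


def precision_recall_f1(
    generated: pd.DataFrame,
    prompt_col: str = "prompt",
    realised_col: str = "realised",
    bound: float = 0.1,
) -> pd.DataFrame:
    """Per-prompt precision, recall and F1 against realised metrics.

    A circuit fulfils a prompt iff |realised - prompt| <= bound (both in
    normalised units).  Precision: fulfilled fraction among a prompt's
    own generations.  Recall: of all circuits fulfilling a prompt,
    the fraction generated under it.  F1 = 2PR/(P+R) (0 when P+R=0).
    """
    prompts = np.sort(generated[prompt_col].unique())
    realised = generated[realised_col].to_numpy(dtype=float)
    own = generated[prompt_col].to_numpy(dtype=float)
    rows = []
    for p in prompts:
        fulfils = np.abs(realised - p) <= bound
        generated_under = own == p
        n_gen = int(generated_under.sum())
        precision = float((fulfils & generated_under).sum() / n_gen) if n_gen else 0.0
        n_fulfil = int(fulfils.sum())
        recall = float((fulfils & generated_under).sum() / n_fulfil) if n_fulfil else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append(
            {"prompt": p, "precision": precision, "recall": recall, "f1": f1, "n": n_gen}
        )
    return pd.DataFrame(rows)


@dataclass
class AdherenceReport:
    """Prompt-adherence summary of a generated-circuit collection."""

    prompts: list[float]
    overlap_matrix: np.ndarray
    per_prompt_overlap: np.ndarray
    mean_overlap: float
    prf: pd.DataFrame
    reconstruction_r2: float = np.nan
    kde_grid: np.ndarray | None = None
    convention: str = "area-of-minimum of unit-normalised KDEs"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "prompts": list(map(float, self.prompts)),
            "overlap_matrix": self.overlap_matrix.tolist(),
            "per_prompt_overlap": self.per_prompt_overlap.tolist(),
            "mean_overlap": self.mean_overlap,
            "precision_recall_f1": self.prf.to_dict(orient="records"),
            "reconstruction_r2": self.reconstruction_r2,
            "convention": self.convention,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def adherence_report(
    generated: pd.DataFrame,
    prompt_col: str = "prompt",
    realised_col: str = "realised",
    bound: float = 0.1,
    n_points: int = 1000,
    reconstruction: float = np.nan,
) -> AdherenceReport:
    """Full adherence evaluation of re-simulated generated circuits."""
    prompts = np.sort(generated[prompt_col].unique())
    groups = {
        p: generated.loc[generated[prompt_col] == p, realised_col].dropna().to_numpy()
        for p in prompts
    }
    groups = {p: v for p, v in groups.items() if v.size >= 5}
    overlap, per_prompt, grand, grid = kde_overlap(groups, n_points=n_points)
    prf = precision_recall_f1(generated.dropna(subset=[realised_col]),
                              prompt_col, realised_col, bound)
    return AdherenceReport(
        prompts=[float(p) for p in groups],
        overlap_matrix=overlap,
        per_prompt_overlap=per_prompt,
        mean_overlap=grand,
        prf=prf,
        reconstruction_r2=reconstruction,
        kde_grid=grid,
    )


@dataclass
class MotifReport:
    """Hierarchical-clustering view of adaptable circuit topologies."""

    labels: np.ndarray  # cluster id per circuit, 1..k
    medians: pd.DataFrame  # per-cluster median interaction vector
    metric_summary: pd.DataFrame  # per-cluster metric distribution stats
    linkage_method: str = "ward"
    n_clusters: int = 5

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_clusters": self.n_clusters,
            "linkage_method": self.linkage_method,
            "cluster_sizes": {
                str(k): int(v) for k, v in zip(*np.unique(self.labels, return_counts=True))
            },
            "medians": self.medians.to_dict(orient="index"),
            "metric_summary": self.metric_summary.to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


def cluster_motifs(
    energies: np.ndarray,
    metrics: pd.DataFrame | None = None,
    k: int = 5,
    feature_names: list[str] | None = None,
) -> MotifReport:
    """Agglomerative (Ward) clustering of raw interaction 6-vectors.

    Circuits should be pre-filtered to the adaptable set (see
    :func:`circuitgen.metrics.classify_adaptable`).  The tree is cut at
    ``k`` clusters; identical inputs collapse into fewer groups.
    """
    energies = np.atleast_2d(np.asarray(energies, dtype=float))
    n = energies.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} circuits, got {n}")
    Z = linkage(energies, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")

    names = feature_names or [f"k{i}" for i in range(energies.shape[1])]
    med_rows = {}
    met_rows = {}
    for cl in np.unique(labels):
        mask = labels == cl
        med_rows[int(cl)] = dict(zip(names, np.median(energies[mask], axis=0)))
        if metrics is not None:
            stats = {}
            for col in ("adaptation", "ruggedness", "S", "P"):
                if col in metrics.columns:
                    vals = metrics.loc[mask, col].astype(float)
                    stats[f"{col}_median"] = float(vals.median())
                    stats[f"{col}_iqr"] = float(vals.quantile(0.75) - vals.quantile(0.25))
            stats["n"] = int(mask.sum())
            met_rows[int(cl)] = stats
    return MotifReport(
        labels=labels,
        medians=pd.DataFrame.from_dict(med_rows, orient="index"),
        metric_summary=pd.DataFrame.from_dict(met_rows, orient="index"),
        n_clusters=k,
    )


def export_embeddings(
    results, x: np.ndarray, c: np.ndarray, labels: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Encoder means per circuit with attached metric labels.

    The H-dimensional table is the input for any downstream projection
    (UMAP and friends), which is plotting convenience and out of scope.
    """
    mu = results.encode(x, c)
    out = pd.DataFrame(mu, columns=[f"z{i}" for i in range(mu.shape[1])])
    if labels is not None:
        out = pd.concat([out, labels.reset_index(drop=True)], axis=1)
    return out
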