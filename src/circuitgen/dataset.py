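"""Filtering, normalisation and labelling of simulated circuits.

Features are the six binding energies.  They are negated (so strong
binding maps to the high end of the scale), robust-scaled by the median
and interquartile range, then min-max scaled to [0, 1].  The fitted
:class:`NormalisationState` is invertible and JSON-serialisable, so
generated circuits can be mapped back to kcal/mol exactly.

Labels support the study's objective variants: scalar adaptation,
[log10 S, log10 P], their binary thresholded form, the 3-metric variant
with overshoot/initial, and the joint adaptation + log10-ruggedness
objective.  Label scaling statistics are fitted on the training split
only; records whose labels fall outside the fitted [0, 1] range are
excluded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sampling import INTERACTION_LABELS

logger = logging.getLogger(__name__)

OBJECTIVES = (
    "adaptation",
    "log_s_log_p",
    "binary",
    "three_metric",
    "adaptation_ruggedness",
)

#: metric columns consumed by each objective, in label order
_OBJECTIVE_COLUMNS = {
    "adaptation": ["adaptation"],
    "log_s_log_p": ["S", "P"],
    "binary": ["S", "P"],
    "three_metric": ["S", "P", "overshoot_ratio"],
    "adaptation_ruggedness": ["adaptation", "ruggedness"],
}


class EmptyDatasetError(RuntimeError):
    """All records were removed by filtering; carries per-rule counts."""

    def __init__(self, counts: dict):
        super().__init__(f"filtering removed every record: {counts}")
        self.counts = counts


def filter_records(
    records: pd.DataFrame,
    horizon: float = 1e5,
    slow_fraction: float = 0.8,
    duplicate_decimals: int = 9,
) -> tuple[pd.DataFrame, dict]:
    """Apply the record filters; returns (kept, per-rule removal counts).

    Rules: drop NaN sensitivity/precision, exact-duplicate energy
    vectors (first kept; energies rounded to 1e-9 kcal/mol), and slow
    responders (unsettled, or settling time > ``slow_fraction`` x the
    phase-2 horizon).
    """
    counts = {"nan_metric": 0, "duplicate": 0, "slow": 0}
    df = records.copy()

    nan_mask = df["S"].isna() | df["P"].isna()
    counts["nan_metric"] = int(nan_mask.sum())
    df = df[~nan_mask]

    energy_cols = [c for c in INTERACTION_LABELS if c in df.columns]
    if energy_cols:
        rounded = df[energy_cols].round(duplicate_decimals)
        dup_mask = rounded.duplicated(keep="first")
        counts["duplicate"] = int(dup_mask.sum())
        df = df[~dup_mask]

    slow_mask = pd.Series(False, index=df.index)
    if "settled" in df.columns:
        slow_mask |= ~df["settled"].astype(bool)
    if "settling_time" in df.columns:
        slow_mask |= df["settling_time"] > slow_fraction * horizon
    counts["slow"] = int(slow_mask.sum())
    df = df[~slow_mask]

    if df.empty:
        raise EmptyDatasetError(counts)
    return df.reset_index(drop=True), counts


@dataclass
class NormalisationState:
    """Invertible normalisation state for features and labels."""

    feature_names: list[str]
    medians: np.ndarray
    iqrs: np.ndarray  # 0 where robust scaling was skipped (degenerate IQR)
    mins: np.ndarray  # min/max of the robust-scaled features
    maxs: np.ndarray
    negate: bool = True
    label_names: list[str] = field(default_factory=list)
    label_transforms: list[str] = field(default_factory=list)  # identity|log10|binarise
    label_mins: np.ndarray = field(default_factory=lambda: np.zeros(0))
    label_maxs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    label_thresholds: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "medians": self.medians.tolist(),
            "iqrs": self.iqrs.tolist(),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "negate": self.negate,
            "label_names": self.label_names,
            "label_transforms": self.label_transforms,
            "label_mins": self.label_mins.tolist(),
            "label_maxs": self.label_maxs.tolist(),
            "label_thresholds": self.label_thresholds.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalisationState":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            medians=np.array(d["medians"]),
            iqrs=np.array(d["iqrs"]),
            mins=np.array(d["mins"]),
            maxs=np.array(d["maxs"]),
            negate=d["negate"],
            label_names=d["label_names"],
            label_transforms=d["label_transforms"],
            label_mins=np.array(d["label_mins"]),
            label_maxs=np.array(d["label_maxs"]),
            label_thresholds=np.array(d["label_thresholds"]),
        )


def fit_feature_normalisation(
    energies: np.ndarray, feature_names: list[str] | None = None
) -> NormalisationState:
    """Fit the negate -> robust scale -> min-max pipeline."""
    energies = np.asarray(energies, dtype=float)
    v = -energies
    medians = np.median(v, axis=0)
    q75, q25 = np.percentile(v, [75, 25], axis=0)
    iqrs = q75 - q25
    degenerate = iqrs <= 0
    if degenerate.any():
        logger.warning(
            "zero IQR for features %s: falling back to min-max only",
            [i for i, d in enumerate(degenerate) if d],
        )
    iqrs = np.where(degenerate, 0.0, iqrs)
    scaled = _robust(v, medians, iqrs)
    mins = scaled.min(axis=0)
    maxs = scaled.max(axis=0)
    if np.any(maxs <= mins):
        # constant feature: map to 0.5 by widening the span symmetrically
        flat = maxs <= mins
        mins = np.where(flat, mins - 0.5, mins)
        maxs = np.where(flat, maxs + 0.5, maxs)
    names = feature_names or list(INTERACTION_LABELS[: energies.shape[1]])
    return NormalisationState(names, medians, iqrs, mins, maxs)


def _robust(v: np.ndarray, medians: np.ndarray, iqrs: np.ndarray) -> np.ndarray:
    denom = np.where(iqrs > 0, iqrs, 1.0)
    return (v - medians) / denom


def normalise_features(energies: np.ndarray, state: NormalisationState) -> np.ndarray:
    """Map raw energies (kcal/mol) to the [0, 1] model scale.

    The most negative training energy maps to 1.0 (strong binding high).
    """
    v = -np.asarray(energies, dtype=float) if state.negate else np.asarray(energies, float)
    scaled = _robust(v, state.medians, state.iqrs)
    return (scaled - state.mins) / (state.maxs - state.mins)


def denormalise_features(x: np.ndarray, state: NormalisationState) -> np.ndarray:
    """Inverse of :func:`normalise_features` (exact roundtrip)."""
    scaled = np.asarray(x, dtype=float) * (state.maxs - state.mins) + state.mins
    denom = np.where(state.iqrs > 0, state.iqrs, 1.0)
    v = scaled * denom + state.medians
    return -v if state.negate else v


def _raw_label_columns(df: pd.DataFrame, objective: str) -> np.ndarray:
    cols = _OBJECTIVE_COLUMNS[objective]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"objective '{objective}' needs metric columns {missing}")
    return df[cols].to_numpy(dtype=float)


def _label_spec(objective: str) -> tuple[list[str], list[str]]:
    if objective == "adaptation":
        return ["adaptation"], ["identity"]
    if objective == "log_s_log_p":
        return ["log10_S", "log10_P"], ["log10", "log10"]
    if objective == "binary":
        return ["log10_S_gt_0", "log10_P_gt_1"], ["binarise", "binarise"]
    if objective == "three_metric":
        return ["log10_S", "log10_P", "overshoot_ratio"], ["log10", "log10", "identity"]
    if objective == "adaptation_ruggedness":
        return ["adaptation", "log10_ruggedness"], ["identity", "log10"]
    raise ValueError(f"unknown objective '{objective}'; choose from {OBJECTIVES}")


def build_labels(
    metrics: pd.DataFrame,
    objective: str,
    state: NormalisationState | None = None,
    fit_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, NormalisationState, np.ndarray]:
    """Label matrix ``c`` in [0, 1] for an objective.

    Returns ``(c, state, keep_mask)``.  When ``state`` is None the
    min-max statistics are fitted on the rows selected by ``fit_mask``
    (the training split; all rows if None).  ``keep_mask`` flags rows
    whose transformed labels are finite and inside [0, 1]; rows outside
    the fitted range (possible for non-training rows) are excluded.
    """
    raw = _raw_label_columns(metrics, objective)
    names, transforms = _label_spec(objective)
    # binary thresholds on the log10 scale
    thresholds = np.array([0.0, 1.0]) if objective == "binary" else np.zeros(0)

    transformed = np.empty_like(raw)
    for j, tr in enumerate(transforms):
        col = raw[:, j]
        if tr == "log10":
            with np.errstate(divide="ignore", invalid="ignore"):
                transformed[:, j] = np.log10(col)
        elif tr == "binarise":
            with np.errstate(divide="ignore", invalid="ignore"):
                transformed[:, j] = (np.log10(col) > thresholds[j]).astype(float)
        else:
            transformed[:, j] = col

    finite = np.all(np.isfinite(transformed), axis=1)
    if state is None:
        fit_rows = finite if fit_mask is None else (finite & np.asarray(fit_mask, bool))
        if not fit_rows.any():
            raise ValueError("no finite label rows to fit normalisation on")
        fit_vals = transformed[fit_rows]
        mins = fit_vals.min(axis=0)
        maxs = fit_vals.max(axis=0)
        flat = maxs <= mins
        mins = np.where(flat, mins - 0.5, mins)
        maxs = np.where(flat, maxs + 0.5, maxs)
        state = NormalisationState(
            feature_names=[], medians=np.zeros(0), iqrs=np.zeros(0),
            mins=np.zeros(0), maxs=np.zeros(0),
            label_names=names, label_transforms=transforms,
            label_mins=mins, label_maxs=maxs, label_thresholds=thresholds,
        )
    c = (transformed - state.label_mins) / (state.label_maxs - state.label_mins)
    keep = finite & np.all((c >= 0) & (c <= 1), axis=1)
    return c, state, keep


@dataclass
class ConditionedDataset:
    """Training-ready (x, c) matrices with split and provenance."""

    x: np.ndarray  # (n, m) normalised interactions in [0, 1]
    c: np.ndarray  # (n, c_n) normalised labels in [0, 1]
    energies: np.ndarray  # raw kcal/mol, aligned with x
    circuit_ids: list[str]
    is_train: np.ndarray  # boolean split assignment
    state: NormalisationState
    provenance: dict = field(default_factory=dict)

    @property
    def c_n(self) -> int:
        return self.c.shape[1]

    @property
    def m(self) -> int:
        return self.x.shape[1]

    def split(self, train: bool = True) -> tuple[np.ndarray, np.ndarray]:
        mask = self.is_train if train else ~self.is_train
        return self.x[mask], self.c[mask]

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        feat = pd.DataFrame(self.x, columns=[f"x_{n}" for n in self.state.feature_names])
        for j, name in enumerate(self.state.feature_names):
            feat[name] = self.energies[:, j]
        feat.insert(0, "circuit_id", self.circuit_ids)
        feat["is_train"] = self.is_train
        # %.17g keeps the float64 roundtrip exact through the text format
        feat.to_csv(d / "features.csv", index=False, float_format="%.17g")
        pd.DataFrame(self.c, columns=self.state.label_names).to_csv(
            d / "labels.csv", index=False, float_format="%.17g"
        )
        self.state.to_json(d / "normalisation.json")
        (d / "provenance.json").write_text(json.dumps(self.provenance, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ConditionedDataset":
        d = Path(directory)
        state = NormalisationState.from_json(d / "normalisation.json")
        feat = pd.read_csv(d / "features.csv", float_precision="round_trip")
        c = pd.read_csv(d / "labels.csv", float_precision="round_trip").to_numpy(dtype=float)
        x = feat[[f"x_{n}" for n in state.feature_names]].to_numpy(dtype=float)
        energies = feat[state.feature_names].to_numpy(dtype=float)
        provenance = json.loads((d / "provenance.json").read_text())
        return cls(
            x=x, c=c, energies=energies,
            circuit_ids=feat["circuit_id"].astype(str).tolist(),
            is_train=feat["is_train"].to_numpy(dtype=bool),
            state=state, provenance=provenance,
        )


def train_test_split_mask(n: int, test_fraction: float, seed: int) -> np.ndarray:
    """Boolean train mask: disjoint, seed-reproducible 80/20 by default."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    mask = np.ones(n, dtype=bool)
    mask[order[:n_test]] = False
    return mask


def build_dataset(
    metrics: pd.DataFrame,
    objective: str = "adaptation",
    seed: int = 0,
    test_fraction: float = 0.2,
    horizon: float = 1e5,
    provenance: dict | None = None,
) -> ConditionedDataset:
    """Filter, normalise and label a metrics table into a dataset bundle.

    Feature scaling is fitted jointly on all filtered circuits; label
    scaling on the training split only.
    """
    filtered, counts = filter_records(metrics, horizon=horizon)
    energy_cols = [c for c in INTERACTION_LABELS if c in filtered.columns]
    energies = filtered[energy_cols].to_numpy(dtype=float)

    is_train = train_test_split_mask(len(filtered), test_fraction, seed)
    feat_state = fit_feature_normalisation(energies, energy_cols)
    c, label_state, keep = build_labels(filtered, objective, fit_mask=is_train)

    state = NormalisationState(
        feature_names=feat_state.feature_names,
        medians=feat_state.medians, iqrs=feat_state.iqrs,
        mins=feat_state.mins, maxs=feat_state.maxs, negate=feat_state.negate,
        label_names=label_state.label_names,
        label_transforms=label_state.label_transforms,
        label_mins=label_state.label_mins, label_maxs=label_state.label_maxs,
        label_thresholds=label_state.label_thresholds,
    )
    x = normalise_features(energies, state)

    prov = dict(provenance or {})
    prov.update(
        {
            "objective": objective,
            "seed": seed,
            "test_fraction": test_fraction,
            "removal_counts": counts,
            "label_range_excluded": int((~keep).sum()),
            "n_final": int(keep.sum()),
        }
    )
    ids = filtered["circuit_id"].astype(str).tolist()
    return ConditionedDataset(
        x=x[keep],
        c=c[keep],
        energies=energies[keep],
        circuit_ids=[cid for cid, k in zip(ids, keep) if k],
        is_train=is_train[keep],
        state=state,
        provenance=prov,
    )
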