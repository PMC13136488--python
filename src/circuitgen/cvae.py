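"""Conditional variational autoencoder over circuit interaction vectors.

The encoder consumes the normalised interaction vector ``x``
concatenated with the condition ``c`` and produces the Gaussian
posterior parameters ``mu`` and ``logvar``; the latent is drawn by the
reparameterisation ``z = mu + exp(logvar/2) * eps``.  The decoder
consumes ``[z, c]`` and reconstructs ``x``.  Both stacks are 3 linear
layers of width 32 with leaky-ReLU activations and He-normal
initialisation; the mu/logvar heads and the decoder output layer are
extra linear layers.

The loss is mean-squared reconstruction error plus a weighted Gaussian
KL term ``(-logvar - 1 + e^logvar + mu^2) / 2`` summed over latent
dimensions and averaged over samples (the standard VAE aggregation),
with an optional contrastive term (off by default) that compares
dot-product label similarity against a threshold.

The network is small enough that forward, backward and the Adam
optimiser are implemented directly in NumPy; gradients are exact (and
verified against finite differences in the test suite), and training is
bitwise reproducible for a fixed seed.

API follows the model/results convention: ``CVAE(x, c, ...)`` holds
data and architecture, ``fit()`` returns a :class:`CVAEResults` with
the learned weights, training history, ``summary()``, and ``sample()``
for prompted generation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ConditionedDataset, NormalisationState, denormalise_features


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the CVAE.

    ``n_features`` is the circuit interaction count m (6 for 3 nodes),
    ``c_n`` the condition dimension.  Encoder input is m + c_n wide,
    decoder input latent + c_n, decoder output m.
    """

    n_features: int = 6
    c_n: int = 1
    hidden: int = 32
    n_hidden_layers: int = 3
    latent: int = 32
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if min(self.n_features, self.c_n, self.hidden, self.latent) <= 0:
            raise ValueError("all dimensions must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule and stopping rules."""

    kl_weight: float = 1e-4
    lr_peak: float = 1e-3
    warmup_epochs: int = 20
    max_epochs: int = 2000
    patience: int = 500
    val_accuracy_target: float = 0.98
    error_bound: float = 0.1
    accuracy_mode: str = "all"  # 'all': every coordinate within bound; 'mae'
    batch_size: int = 256
    seed: int = 0
    contrastive: bool = False
    contrastive_temperature: float = 1.0
    contrastive_threshold: float = 0.9

    def __post_init__(self) -> None:
        if min(self.kl_weight, self.lr_peak, self.error_bound) <= 0:
            raise ValueError("kl_weight, lr_peak and error_bound must be positive")
        if not 1e-6 <= self.kl_weight <= 1e-2:
            warnings.warn(
                f"kl_weight={self.kl_weight:g} is outside the usual working "
                "band [1e-6, 1e-2]; reconstruction or adherence may degrade",
                stacklevel=2,
            )
        if self.accuracy_mode not in ("all", "mae"):
            raise ValueError("accuracy_mode must be 'all' or 'mae'")


# ---------------------------------------------------------------------------
# parameter containers and primitive ops


def init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-normal weights, zero biases, in a flat name -> array dict."""

    def he(n_in: int, n_out: int) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))

    p: dict[str, np.ndarray] = {}
    sizes_enc = [config.n_features + config.c_n] + [config.hidden] * config.n_hidden_layers
    for i in range(config.n_hidden_layers):
        p[f"enc{i}_W"] = he(sizes_enc[i], sizes_enc[i + 1])
        p[f"enc{i}_b"] = np.zeros(sizes_enc[i + 1])
    p["mu_W"] = he(config.hidden, config.latent)
    p["mu_b"] = np.zeros(config.latent)
    p["logvar_W"] = he(config.hidden, config.latent)
    p["logvar_b"] = np.zeros(config.latent)
    sizes_dec = [config.latent + config.c_n] + [config.hidden] * config.n_hidden_layers
    for i in range(config.n_hidden_layers):
        p[f"dec{i}_W"] = he(sizes_dec[i], sizes_dec[i + 1])
        p[f"dec{i}_b"] = np.zeros(sizes_dec[i + 1])
    p["out_W"] = he(config.hidden, config.n_features)
    p["out_b"] = np.zeros(config.n_features)
    return p


def _lrelu(a: np.ndarray, slope: float) -> np.ndarray:
    return np.where(a > 0, a, slope * a)


def _lrelu_grad(a: np.ndarray, slope: float) -> np.ndarray:
    return np.where(a > 0, 1.0, slope)


def reparameterise(mu: np.ndarray, logvar: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """z = mu + exp(logvar / 2) * noise."""
    return mu + np.exp(logvar / 2.0) * noise


def kl_elements(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Per-(sample, dimension) Gaussian KL term; nonnegative everywhere."""
    return (-logvar - 1.0 + np.exp(logvar) + mu**2) / 2.0


def forward(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    x: np.ndarray,
    c: np.ndarray,
    noise: np.ndarray | None = None,
    return_cache: bool = False,
):
    """Full forward pass; ``noise=None`` means the deterministic z = mu."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    c = np.atleast_2d(np.asarray(c, dtype=float))
    s = config.leaky_slope
    cache: dict[str, np.ndarray] = {}

    a = np.concatenate([x, c], axis=1)
    cache["enc_in"] = a
    for i in range(config.n_hidden_layers):
        pre = a @ params[f"enc{i}_W"] + params[f"enc{i}_b"]
        cache[f"enc{i}_pre"] = pre
        a = _lrelu(pre, s)
        cache[f"enc{i}_act"] = a
    h = a
    mu = h @ params["mu_W"] + params["mu_b"]
    logvar = h @ params["logvar_W"] + params["logvar_b"]
    if noise is None:
        noise = np.zeros_like(mu)
    z = reparameterise(mu, logvar, noise)
    cache.update(h=h, mu=mu, logvar=logvar, noise=noise, z=z)

    a = np.concatenate([z, c], axis=1)
    cache["dec_in"] = a
    for i in range(config.n_hidden_layers):
        pre = a @ params[f"dec{i}_W"] + params[f"dec{i}_b"]
        cache[f"dec{i}_pre"] = pre
        a = _lrelu(pre, s)
        cache[f"dec{i}_act"] = a
    y = a @ params["out_W"] + params["out_b"]
    cache["y"] = y
    if return_cache:
        return y, mu, logvar, cache
    return y, mu, logvar


def decode(
    params: dict[str, np.ndarray], config: ModelConfig, z: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Decoder alone: used at generation, where noise stands in for z."""
    s = config.leaky_slope
    a = np.concatenate([np.atleast_2d(z), np.atleast_2d(c)], axis=1)
    for i in range(config.n_hidden_layers):
        a = _lrelu(a @ params[f"dec{i}_W"] + params[f"dec{i}_b"], s)
    return a @ params["out_W"] + params["out_b"]


def loss_and_grads(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    x: np.ndarray,
    c: np.ndarray,
    noise: np.ndarray,
    train: TrainConfig,
) -> tuple[float, dict[str, float], dict[str, np.ndarray]]:
    """Total loss, its components and exact parameter gradients."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    c = np.atleast_2d(np.asarray(c, dtype=float))
    y, mu, logvar, cache = forward(params, config, x, c, noise, return_cache=True)
    B, m = x.shape
    H = config.latent
    s = config.leaky_slope

    mse = float(np.mean((y - x) ** 2))
    # sum over latent dims, mean over the batch
    kl = float(np.mean(kl_elements(mu, logvar).sum(axis=1)))
    components = {"mse": mse, "kl": kl, "contrastive": 0.0}
    total = mse + train.kl_weight * kl

    grads = {k: np.zeros_like(v) for k, v in params.items()}

    # decoder backward
    dy = 2.0 * (y - x) / (B * m)
    grads["out_W"] = cache[f"dec{config.n_hidden_layers - 1}_act"].T @ dy
    grads["out_b"] = dy.sum(axis=0)
    da = dy @ params["out_W"].T
    for i in reversed(range(config.n_hidden_layers)):
        dpre = da * _lrelu_grad(cache[f"dec{i}_pre"], s)
        prev = cache["dec_in"] if i == 0 else cache[f"dec{i - 1}_act"]
        grads[f"dec{i}_W"] = prev.T @ dpre
        grads[f"dec{i}_b"] = dpre.sum(axis=0)
        da = dpre @ params[f"dec{i}_W"].T
    dz = da[:, :H]  # gradient w.r.t. the latent part of [z, c]

    # reparameterisation and KL
    dmu = dz + train.kl_weight * mu / B
    dlogvar = (
        dz * cache["noise"] * np.exp(logvar / 2.0) / 2.0
        + train.kl_weight * (np.exp(logvar) - 1.0) / (2.0 * B)
    )

    dh = dmu @ params["mu_W"].T + dlogvar @ params["logvar_W"].T

    if train.contrastive and B > 1:
        h = cache["h"]
        sim_c = c @ c.T - train.contrastive_threshold
        np.fill_diagonal(sim_c, 0.0)
        gram = h @ h.T
        n_off = B * (B - 1)
        cl = float(-np.sum(gram * sim_c) / (train.contrastive_temperature * n_off))
        components["contrastive"] = cl
        total += cl
        dh += -2.0 * (sim_c @ h) / (train.contrastive_temperature * n_off)

    grads["mu_W"] = cache["h"].T @ dmu
    grads["mu_b"] = dmu.sum(axis=0)
    grads["logvar_W"] = cache["h"].T @ dlogvar
    grads["logvar_b"] = dlogvar.sum(axis=0)

    da = dh
    for i in reversed(range(config.n_hidden_layers)):
        dpre = da * _lrelu_grad(cache[f"enc{i}_pre"], s)
        prev = cache["enc_in"] if i == 0 else cache[f"enc{i - 1}_act"]
        grads[f"enc{i}_W"] = prev.T @ dpre
        grads[f"enc{i}_b"] = dpre.sum(axis=0)
        da = dpre @ params[f"enc{i}_W"].T

    return total, components, grads


def learning_rate(epoch: int, train: TrainConfig) -> float:
    """Linear warmup to ``lr_peak`` then cosine decay to ``max_epochs``."""
    if epoch < train.warmup_epochs:
        return train.lr_peak * epoch / train.warmup_epochs
    span = max(train.max_epochs - train.warmup_epochs, 1)
    progress = (epoch - train.warmup_epochs) / span
    return train.lr_peak * 0.5 * (1.0 + np.cos(np.pi * min(progress, 1.0)))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] = params[k] - lr * m_hat / (np.sqrt(v_hat) + self.eps)


def validation_accuracy(
    params, config: ModelConfig, x, c, error_bound: float, mode: str = "all"
) -> float:
    """Fraction of samples reconstructed within the error bound.

    'all' counts a sample only if every coordinate deviates <= bound;
    'mae' uses the per-sample mean absolute error instead.
    """
    y, _, _ = forward(params, config, x, c, noise=None)
    err = np.abs(y - np.atleast_2d(x))
    if mode == "all":
        ok = np.all(err <= error_bound, axis=1)
    else:
        ok = err.mean(axis=1) <= error_bound
    return float(ok.mean())


# ---------------------------------------------------------------------------
# model / results


class CVAE:
    """Conditional VAE model over (x, c) pairs.

    Parameters
    ----------
    x, c
        Training feature and condition matrices, both scaled to [0, 1].
    val_x, val_c
        Held-out data used for the validation-accuracy stopping rule.
    config
        Architecture; inferred dimensions from the data if omitted.
    state
        Optional normalisation state, carried into the results so that
        generated circuits can be reported in kcal/mol.
    """

    def __init__(
        self,
        x: np.ndarray,
        c: np.ndarray,
        val_x: np.ndarray | None = None,
        val_c: np.ndarray | None = None,
        config: ModelConfig | None = None,
        state: NormalisationState | None = None,
    ):
        self.x = np.atleast_2d(np.asarray(x, dtype=float))
        self.c = np.atleast_2d(np.asarray(c, dtype=float))
        if self.x.shape[0] != self.c.shape[0]:
            raise ValueError("x and c must have the same number of rows")
        self.val_x = None if val_x is None else np.atleast_2d(np.asarray(val_x, float))
        self.val_c = None if val_c is None else np.atleast_2d(np.asarray(val_c, float))
        self.config = config or ModelConfig(
            n_features=self.x.shape[1], c_n=self.c.shape[1]
        )
        if self.config.n_features != self.x.shape[1] or self.config.c_n != self.c.shape[1]:
            raise ValueError("config dimensions do not match the data")
        self.state = state

    @classmethod
    def from_dataset(
        cls, dataset: ConditionedDataset, config: ModelConfig | None = None
    ) -> "CVAE":
        """Build the model from a dataset bundle (train split trains,
        test split drives validation accuracy)."""
        x_tr, c_tr = dataset.split(train=True)
        x_te, c_te = dataset.split(train=False)
        return cls(x_tr, c_tr, x_te, c_te, config=config, state=dataset.state)

    def fit(self, train: TrainConfig = TrainConfig()) -> "CVAEResults":
        """Train with Adam under the warmup/cosine schedule.

        Stops early once validation accuracy exceeds the target or after
        ``patience`` epochs without improvement; a NaN loss aborts and
        returns the last finite-loss parameters.
        """
        rng = np.random.default_rng(train.seed)
        params = init_params(self.config, rng)
        opt = _Adam(params)
        n = self.x.shape[0]
        val_x = self.val_x if self.val_x is not None else self.x
        val_c = self.val_c if self.val_c is not None else self.c

        history: list[dict] = []
        best_acc = -np.inf
        best_params = {k: v.copy() for k, v in params.items()}
        best_epoch = 0
        stop_reason = "max_epochs"

        for epoch in range(train.max_epochs):
            lr = learning_rate(epoch, train)
            order = rng.permutation(n)
            epoch_comps = {"mse": 0.0, "kl": 0.0, "contrastive": 0.0}
            epoch_total = 0.0
            n_batches = 0
            diverged = False
            for start in range(0, n, train.batch_size):
                idx = order[start : start + train.batch_size]
                noise = rng.standard_normal((idx.size, self.config.latent))
                total, comps, grads = loss_and_grads(
                    params, self.config, self.x[idx], self.c[idx], noise, train
                )
                if not np.isfinite(total):
                    diverged = True
                    break
                opt.step(params, grads, lr)
                epoch_total += total
                for k in epoch_comps:
                    epoch_comps[k] += comps[k]
                n_batches += 1
            if diverged:
                stop_reason = "diverged"
                params = best_params
                break

            acc = validation_accuracy(
                params, self.config, val_x, val_c, train.error_bound, train.accuracy_mode
            )
            history.append(
                {
                    "epoch": epoch,
                    "lr": lr,
                    "total": epoch_total / max(n_batches, 1),
                    **{k: v / max(n_batches, 1) for k, v in epoch_comps.items()},
                    "val_accuracy": acc,
                }
            )
            if acc > best_acc:
                best_acc = acc
                best_params = {k: v.copy() for k, v in params.items()}
                best_epoch = epoch
            if acc > train.val_accuracy_target:
                stop_reason = "val_accuracy"
                break
            if epoch - best_epoch >= train.patience:
                stop_reason = "patience"
                params = best_params
                break

        return CVAEResults(
            model=self,
            params=best_params,
            config=self.config,
            train_config=train,
            history=pd.DataFrame(history),
            state=self.state,
            best_val_accuracy=float(best_acc),
            stop_reason=stop_reason,
        )


@dataclass
class CVAEResults:
    """Fitted CVAE: weights, history, diagnostics and prompted sampling."""

    model: CVAE | None
    params: dict[str, np.ndarray]
    config: ModelConfig
    train_config: TrainConfig
    history: pd.DataFrame
    state: NormalisationState | None = None
    best_val_accuracy: float = np.nan
    stop_reason: str = ""

    def reconstruct(self, x: np.ndarray, c: np.ndarray, noise=None) -> np.ndarray:
        y, _, _ = forward(self.params, self.config, x, c, noise)
        return y

    def encode(self, x: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Posterior means mu (the embedding used for export/projection)."""
        _, mu, _ = forward(self.params, self.config, x, c, noise=None)
        return mu

    def r2(self, x: np.ndarray, c: np.ndarray) -> float:
        """Pooled coefficient of determination over all entries."""
        from .evaluation import pooled_r2

        return pooled_r2(np.atleast_2d(x), self.reconstruct(x, c))

    def sample(
        self,
        prompts: np.ndarray,
        n_per_prompt: int = 100,
        seed: int = 0,
        denormalise: bool = True,
    ) -> pd.DataFrame:
        """Generate circuits for each prompt row.

        For every prompt, ``n_per_prompt`` standard-normal latent draws
        are decoded with the prompt as condition.  Columns: one per
        interaction (kcal/mol when a normalisation state is attached,
        otherwise the [0, 1] model scale) plus the prompt value(s).
        """
        prompts = np.atleast_2d(np.asarray(prompts, dtype=float))
        if prompts.shape[1] != self.config.c_n:
            raise ValueError(f"prompts must have {self.config.c_n} columns")
        rng = np.random.default_rng(seed)
        frames = []
        for row in prompts:
            z = rng.standard_normal((n_per_prompt, self.config.latent))
            cmat = np.tile(row, (n_per_prompt, 1))
            y = decode(self.params, self.config, z, cmat)
            if denormalise and self.state is not None:
                values = denormalise_features(y, self.state)
                cols = self.state.feature_names
            else:
                values = y
                cols = [f"x{i}" for i in range(y.shape[1])]
            frame = pd.DataFrame(values, columns=cols)
            if self.config.c_n == 1:
                frame["prompt"] = row[0]
            else:
                for j, v in enumerate(row):
                    frame[f"prompt_{j}"] = v
            frames.append(frame)
        out = pd.concat(frames, ignore_index=True)
        out.insert(0, "circuit_id", [f"gen{i:06d}" for i in range(len(out))])
        return out

    def summary(self) -> str:
        lines = [
            "Conditional VAE results",
            "=" * 47,
            f"{'features (m)':<30}{self.config.n_features:>17}",
            f"{'condition dim (c_n)':<30}{self.config.c_n:>17}",
            f"{'latent dim':<30}{self.config.latent:>17}",
            f"{'hidden layers':<30}{self.config.n_hidden_layers:>17}",
            f"{'hidden width':<30}{self.config.hidden:>17}",
            f"{'KL weight':<30}{self.train_config.kl_weight:>17.2e}",
            f"{'epochs run':<30}{len(self.history):>17}",
            f"{'stop reason':<30}{self.stop_reason:>17}",
            f"{'best val accuracy':<30}{self.best_val_accuracy:>17.4f}",
        ]
        if len(self.history):
            last = self.history.iloc[-1]
            lines.append(f"{'final mse':<30}{last['mse']:>17.3e}")
            lines.append(f"{'final kl':<30}{last['kl']:>17.3e}")
        lines.append("=" * 47)
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Checkpoint: weights (.npz) plus a JSON sidecar with configs,
        history and the normalisation state."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        sidecar = {
            "model_config": asdict(self.config),
            "train_config": asdict(self.train_config),
            "history": self.history.to_dict(orient="list"),
            "best_val_accuracy": self.best_val_accuracy,
            "stop_reason": self.stop_reason,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        if self.state is not None:
            self.state.to_json(path.parent / (path.stem + "_normalisation.json"))

    @classmethod
    def load(cls, path: str | Path) -> "CVAEResults":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as npz:
            params = {k: npz[k] for k in npz.files}
        sidecar = json.loads(path.with_suffix(".json").read_text())
        state_file = path.parent / (path.stem + "_normalisation.json")
        state = NormalisationState.from_json(state_file) if state_file.exists() else None
        return cls(
            model=None,
            params=params,
            config=ModelConfig(**sidecar["model_config"]),
            train_config=TrainConfig(**sidecar["train_config"]),
            history=pd.DataFrame(sidecar["history"]),
            state=state,
            best_val_accuracy=sidecar["best_val_accuracy"],
            stop_reason=sidecar["stop_reason"],
        )


def train_multi_seed(
    dataset: ConditionedDataset,
    seeds: list[int],
    config: ModelConfig | None = None,
    train: TrainConfig = TrainConfig(),
    score: "callable | None" = None,
) -> tuple[CVAEResults, list[CVAEResults]]:
    """Train one model per seed and select the best.

    Prompt adherence varies with the initialisation seed, so training a
    handful of seeds and selecting is the standard mitigation.  The
    default score is held-out pooled R^2; pass ``score(results)`` for a
    different criterion (e.g. KDE adherence).
    """
    model = CVAE.from_dataset(dataset, config=config)
    results = []
    for seed in seeds:
        cfg = TrainConfig(**{**asdict(train), "seed": int(seed)})
        results.append(model.fit(cfg))
    if score is None:
        x_te, c_te = dataset.split(train=False)
        score = lambda r: r.r2(x_te, c_te)  # noqa: E731
    best = max(results, key=score)
    return best, results
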