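"""Neural-network surrogate of the steady-shear constitutive map.

A fully connected feed-forward network maps the six inputs (five molecular
parameters Θ and the shear rate γ̇) to the two steady stresses (σxy, N1).
All hidden layers use tanh; the output layer is affine.  Trained on
steady-state solutions of the Rolie-Poly model sampled over the parameter
box, the network becomes a fast, smooth, differentiable stand-in for the
constitutive map — the property the gradient-descent inverse solver relies
on.

Feature scaling: ηp, τD, τR and γ̇ span three to eight decades and enter as
log10, then min-max scaled to [−1, 1] from their declared bounds; χmax and
β are min-max scaled linearly.  The outputs σxy and N1 are log10-transformed
and standardized on the training split.  The relative-error metric is always
evaluated in raw stress space.

Training is minibatch Adam with backpropagation, implemented directly on
the float32 weight arrays; early stopping, learning-rate decay and model
selection all use the validation-split relative error in raw stress space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .forward_model import SteadyStateError, steady_stress_grid
from .params import (
    CCR_STRETCH_EXPONENT,
    FREE_PARAMETERS,
    WATER_VISCOSITY,
    ParamBounds,
    RoliePolyParams,
)

__all__ = [
    "NetConfig",
    "TrainingConfig",
    "StressDataset",
    "SurrogateNet",
    "sample_parameters",
    "sample_parameter_array",
    "generate_dataset",
    "net_forward",
    "loss",
    "train",
    "evaluate_relative_error",
    "architecture_scan",
    "SurrogateBackend",
]

CHECKPOINT_FORMAT_VERSION = 1

#: log10 bounds of the canonical shear-rate sweep, used for input scaling.
RATE_LOG10_RANGE = (-4.0, 4.0)


@dataclass(frozen=True)
class NetConfig:
    """Architecture of the fully connected surrogate.

    ``n_hidden_layers`` hidden layers of ``neurons_per_layer`` units each,
    tanh activations, affine (no-activation) output layer.
    """

    n_hidden_layers: int = 5
    neurons_per_layer: int = 192
    activation: str = "tanh"
    input_dim: int = 6
    output_dim: int = 2

    def __post_init__(self) -> None:
        if self.n_hidden_layers < 1 or self.neurons_per_layer < 1:
            raise ValueError("network needs at least one hidden layer and one neuron")
        if self.activation != "tanh":
            raise ValueError("only tanh hidden activations are supported")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings for surrogate training.

    ``split`` counts parameter sets (not rows): every rate row of one
    sampled fluid lands in the same split, so validation measures
    generalization to unseen fluids rather than to unseen rates of a fluid
    already in the training set.  ``n_repeats`` independent runs are
    trained and the best by validation relative error is kept.
    """

    learning_rate: float = 1.0e-3
    l2_rate: float = 1.0e-6
    n_epochs: int = 400
    batch_size: int = 1024
    split: tuple[int, int, int] = (10_000, 3_000, 2_000)
    seed: int | None = None
    n_repeats: int = 3
    patience: int = 50
    #: halve the learning rate when the validation error has not improved
    #: for ``lr_patience`` epochs (the plateau is usually set by step-size
    #: jitter, so decaying the rate lowers the attainable error floor)
    lr_decay: float = 0.5
    lr_patience: int = 15

    def __post_init__(self) -> None:
        if min(self.split) <= 0 or self.learning_rate <= 0 or self.l2_rate < 0:
            raise ValueError("invalid training configuration")


# ---------------------------------------------------------------------------
# Sampling and dataset generation
# ---------------------------------------------------------------------------

def sample_parameter_array(bounds: ParamBounds, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 5) parameter draws, uniform on each parameter's declared scale."""
    out = np.empty((n, len(FREE_PARAMETERS)))
    for i, (_, lo, hi, scale) in enumerate(bounds.items()):
        if scale == "log":
            out[:, i] = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), n)
        else:
            out[:, i] = rng.uniform(lo, hi, n)
    return out


def sample_parameters(
    bounds: ParamBounds,
    n: int,
    seed: int | np.random.Generator | None = None,
    eta_s: float = WATER_VISCOSITY,
    delta: float = CCR_STRETCH_EXPONENT,
) -> list[RoliePolyParams]:
    """Draw ``n`` molecular parameter sets, reproducibly under ``seed``."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = sample_parameter_array(bounds, n, rng)
    return [RoliePolyParams.from_free_vector(row, eta_s=eta_s, delta=delta) for row in arr]


@dataclass
class StressDataset:
    """Sampled (Θ, γ̇) → (σxy, N1) rows with train/validation/test labels."""

    frame: pd.DataFrame
    bounds: ParamBounds
    rates: np.ndarray
    seed: int | None = None

    COLUMNS = (*FREE_PARAMETERS, "shear_rate", "sigma_xy", "N1", "split", "set_id")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"dataset frame is missing columns {sorted(missing)}")

    def rows(self, split: str) -> pd.DataFrame:
        return self.frame[self.frame["split"] == split]

    def xy(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        df = self.rows(split)
        X = df[[*FREE_PARAMETERS, "shear_rate"]].to_numpy()
        Y = df[["sigma_xy", "N1"]].to_numpy()
        return X, Y

    def __len__(self) -> int:
        return len(self.frame)


def generate_dataset(
    bounds: ParamBounds,
    n_param_sets: int,
    rates: Sequence[float],
    seed: int | None = None,
    split: tuple[int, int, int] | None = None,
    eta_s: float = WATER_VISCOSITY,
    delta: float = CCR_STRETCH_EXPONENT,
) -> StressDataset:
    """Sample parameter sets and label them with forward-model stresses.

    Splits are assigned per parameter set, proportionally to ``split``
    (default 10000/3000/2000).  The rare parameter set on which the steady
    solver fails is resampled and the event recorded in the dataset's
    ``resampled`` metadata count.
    """
    rates = np.asarray(rates, dtype=float)
    rng = np.random.default_rng(seed)
    if split is None:
        split = (10_000, 3_000, 2_000)
    frac = np.array(split, dtype=float) / sum(split)
    n_val = int(round(frac[1] * n_param_sets))
    n_test = int(round(frac[2] * n_param_sets))
    n_train = n_param_sets - n_val - n_test

    theta = sample_parameter_array(bounds, n_param_sets, rng)
    n_resampled = 0
    try:
        sigma, N1 = steady_stress_grid(theta, rates, eta_s, delta)
    except SteadyStateError:
        # isolate the failing set(s), resample each and retry
        sigma = np.empty((n_param_sets, rates.size))
        N1 = np.empty_like(sigma)
        for i in range(n_param_sets):
            for _attempt in range(20):
                try:
                    s_i, n_i = steady_stress_grid(theta[i : i + 1], rates, eta_s, delta)
                    sigma[i], N1[i] = s_i[0], n_i[0]
                    break
                except SteadyStateError:
                    theta[i] = sample_parameter_array(bounds, 1, rng)[0]
                    n_resampled += 1
            else:
                raise SteadyStateError(
                    f"could not find a solvable replacement for parameter set {i}"
                )

    labels = np.array(["train"] * n_train + ["val"] * n_val + ["test"] * n_test)
    rng.shuffle(labels)
    m = rates.size
    frame = pd.DataFrame(
        {
            **{name: np.repeat(theta[:, i], m) for i, name in enumerate(FREE_PARAMETERS)},
            "shear_rate": np.tile(rates, n_param_sets),
            "sigma_xy": sigma.ravel(),
            "N1": N1.ravel(),
            "split": np.repeat(labels, m),
            "set_id": np.repeat(np.arange(n_param_sets), m),
        }
    )
    ds = StressDataset(frame=frame, bounds=bounds, rates=rates, seed=seed)
    ds.frame.attrs["resampled"] = n_resampled
    return ds


# ---------------------------------------------------------------------------
# Scalers and the network container
# ---------------------------------------------------------------------------

@dataclass
class FeatureScaler:
    """Per-feature affine map in (optionally) log10 space: x ↦ (f(x) − off) * scl."""

    log_mask: np.ndarray
    offset: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        F = np.where(self.log_mask, np.log10(np.where(X > 0, X, np.nan)), X)
        return (F - self.offset) * self.scale

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        F = Z / self.scale + self.offset
        return np.where(self.log_mask, 10.0**F, F)

    def deriv(self, X: np.ndarray) -> np.ndarray:
        """d(scaled)/d(raw) at X, elementwise."""
        X = np.asarray(X, dtype=float)
        inner = np.where(self.log_mask, 1.0 / (X * np.log(10.0)), 1.0)
        return inner * self.scale

    def inverse_deriv(self, Z: np.ndarray) -> np.ndarray:
        """d(raw)/d(scaled) at scaled value Z, elementwise."""
        raw = self.inverse(Z)
        return np.where(self.log_mask, raw * np.log(10.0), 1.0) / self.scale


def input_scaler(bounds: ParamBounds, rate_log10_range=RATE_LOG10_RANGE) -> FeatureScaler:
    """Min-max scaler to [−1, 1] built from the declared bounds (no data needed)."""
    log_mask = np.append(bounds.log_mask, True)
    lo = np.append(bounds.lower, 10.0 ** rate_log10_range[0])
    hi = np.append(bounds.upper, 10.0 ** rate_log10_range[1])
    flo = np.where(log_mask, np.log10(lo), lo)
    fhi = np.where(log_mask, np.log10(hi), hi)
    return FeatureScaler(
        log_mask=log_mask,
        offset=(flo + fhi) / 2.0,
        scale=2.0 / (fhi - flo),
    )


def output_scaler(Y_train: np.ndarray) -> FeatureScaler:
    """log10-then-standardize scaler fitted on training-split stresses."""
    logY = np.log10(Y_train)
    mean = logY.mean(axis=0)
    std = logY.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return FeatureScaler(
        log_mask=np.array([True, True]),
        offset=mean,
        scale=1.0 / std,
    )


@dataclass
class SurrogateNet:
    """Trained surrogate: layer weights/biases plus input/output scalers.

    ``weights[k]`` has shape (fan_in, fan_out); the forward pass is
    x ↦ tanh(x W + b) on hidden layers and affine on the last layer.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_scaler: FeatureScaler
    y_scaler: FeatureScaler
    config: NetConfig = field(default_factory=NetConfig)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k in range(len(self.weights) - 1):
            if self.weights[k].shape[1] != self.weights[k + 1].shape[0]:
                raise ValueError("layer shapes do not chain consistently")

    # -- scaled-space pass ---------------------------------------------------

    def forward_scaled(self, Z: np.ndarray) -> np.ndarray:
        H = Z
        last = len(self.weights) - 1
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            H = H @ W + b
            if k < last:
                H = np.tanh(H)
        return H

    def forward_scaled_with_hidden(self, Z: np.ndarray):
        H = Z
        hidden = []
        last = len(self.weights) - 1
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            H = H @ W + b
            if k < last:
                H = np.tanh(H)
                hidden.append(H)
        return H, hidden

    def vjp_scaled(self, Z: np.ndarray, seed: np.ndarray) -> np.ndarray:
        """Reverse-mode product seedᵀ · d(forward_scaled)/dZ, rowwise."""
        _, hidden = self.forward_scaled_with_hidden(Z)
        g = seed
        for k in range(len(self.weights) - 1, -1, -1):
            g = g @ self.weights[k].T
            if k > 0:
                g = g * (1.0 - hidden[k - 1] ** 2)
        return g

    # -- raw-space predictions ----------------------------------------------

    def predict_rows(self, X: np.ndarray) -> np.ndarray:
        """Raw-space stresses for raw-space input rows (…, 6)."""
        Z = self.x_scaler.transform(X)
        return self.y_scaler.inverse(self.forward_scaled(Z))

    def predict(self, theta: np.ndarray, rates: np.ndarray) -> np.ndarray:
        """(M, 2) stresses for one parameter vector over a rate sweep."""
        rates = np.asarray(rates, dtype=float)
        X = np.column_stack([np.broadcast_to(theta, (rates.size, 5)), rates])
        return self.predict_rows(X)

    def predict_vjp(self, theta: np.ndarray, rates: np.ndarray, seed: np.ndarray) -> np.ndarray:
        """Σ_j seed_j · d(pred_j)/dθ — the reverse-mode parameter gradient (5,)."""
        rates = np.asarray(rates, dtype=float)
        X = np.column_stack([np.broadcast_to(theta, (rates.size, 5)), rates])
        Z = self.x_scaler.transform(X)
        out_scaled = self.forward_scaled(Z)
        seed_scaled = seed * self.y_scaler.inverse_deriv(out_scaled)
        gZ = self.vjp_scaled(Z, seed_scaled)
        gX = gZ * self.x_scaler.deriv(X)
        return gX[:, :5].sum(axis=0)

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": asdict(self.config),
            "provenance": self.provenance,
            "n_layers": len(self.weights),
        }
        arrays = {
            "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            "x_log_mask": self.x_scaler.log_mask,
            "x_offset": self.x_scaler.offset,
            "x_scale": self.x_scaler.scale,
            "y_log_mask": self.y_scaler.log_mask,
            "y_offset": self.y_scaler.offset,
            "y_scale": self.y_scaler.scale,
        }
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{k}"] = W
            arrays[f"b{k}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SurrogateNet":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
            n = meta["n_layers"]
            weights = [z[f"W{k}"] for k in range(n)]
            biases = [z[f"b{k}"] for k in range(n)]
            xs = FeatureScaler(z["x_log_mask"], z["x_offset"], z["x_scale"])
            ys = FeatureScaler(z["y_log_mask"], z["y_offset"], z["y_scale"])
        return cls(weights, biases, xs, ys, NetConfig(**meta["config"]), meta.get("provenance", {}))


def net_forward(net: SurrogateNet, x: np.ndarray) -> np.ndarray:
    """Scaled-space forward pass: affine maps with tanh on hidden layers only."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != net.weights[0].shape[0]:
        raise ValueError(
            f"input dimension {x.shape[-1]} does not match the network ({net.weights[0].shape[0]})"
        )
    return net.forward_scaled(x)


def loss(net: SurrogateNet, batch: tuple[np.ndarray, np.ndarray], l2_rate: float) -> float:
    """Mean squared error over a scaled-space batch plus ξ Σ w² (weights only)."""
    X, Y = batch
    if len(X) == 0:
        raise ValueError("batch must be non-empty")
    pred = net.forward_scaled(np.asarray(X, dtype=float))
    mse = float(np.mean(np.sum((pred - np.asarray(Y, dtype=float)) ** 2, axis=-1)))
    reg = l2_rate * float(sum(np.sum(W**2) for W in net.weights))
    return mse + reg


def evaluate_relative_error(net: SurrogateNet, split_frame: pd.DataFrame) -> float:
    """Mean relative stress error over a split, in percent.

    Averages |predicted − true| / |true| over rows and over both stress
    components.  Rows with a zero true stress (only possible at γ̇ = 0,
    which is never sampled) are excluded.
    """
    if len(split_frame) == 0:
        raise ValueError("split is empty")
    X = split_frame[[*FREE_PARAMETERS, "shear_rate"]].to_numpy()
    Y = split_frame[["sigma_xy", "N1"]].to_numpy()
    keep = np.all(Y != 0.0, axis=1)
    X, Y = X[keep], Y[keep]
    pred = net.predict_rows(X)
    return float(np.mean(np.abs(pred - Y) / np.abs(Y))) * 100.0


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _glorot_init(net_config: NetConfig, rng: np.random.Generator):
    dims = [net_config.input_dim] + [net_config.neurons_per_layer] * net_config.n_hidden_layers + [net_config.output_dim]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-bound, bound, (fan_in, fan_out)).astype(np.float32))
        biases.append(np.zeros(fan_out, dtype=np.float32))
    return weights, biases


def _adam_epoch(W, b, mW, mb, vW, vb, Xtr, Ytr, order, tc, lr, t0, xi):
    """One epoch of minibatch Adam on the tanh network (float32).

    Backpropagation of the batch objective mean_i ||pred_i − y_i||² + ξ Σ w².
    Returns the updated Adam step counter.
    """
    beta1, beta2, eps = 0.9, 0.999, 1.0e-8
    L = len(W)
    t = t0
    for start in range(0, len(order), tc.batch_size):
        idx = order[start : start + tc.batch_size]
        X, Y = Xtr[idx], Ytr[idx]
        B = len(idx)
        # forward, keeping hidden activations
        acts = []
        H = X
        for k in range(L - 1):
            H = np.tanh(H @ W[k] + b[k])
            acts.append(H)
        pred = H @ W[-1] + b[-1]
        delta = (2.0 / B) * (pred - Y)
        t += 1
        corr1 = 1.0 - beta1**t
        corr2 = 1.0 - beta2**t
        for k in range(L - 1, -1, -1):
            Hin = acts[k - 1] if k > 0 else X
            gW = Hin.T @ delta + 2.0 * xi * W[k]
            gb = delta.sum(axis=0)
            if k > 0:
                delta = (delta @ W[k].T) * (1.0 - acts[k - 1] ** 2)
            mW[k] = beta1 * mW[k] + (1 - beta1) * gW
            vW[k] = beta2 * vW[k] + (1 - beta2) * gW * gW
            mb[k] = beta1 * mb[k] + (1 - beta1) * gb
            vb[k] = beta2 * vb[k] + (1 - beta2) * gb * gb
            W[k] -= lr * (mW[k] / corr1) / (np.sqrt(vW[k] / corr2) + eps)
            b[k] -= lr * (mb[k] / corr1) / (np.sqrt(vb[k] / corr2) + eps)
    return t


def _train_once(net_config, Xtr, Ytr, Xval, val_frame, x_sc, y_sc, tc: TrainingConfig, seed: int):
    """One Adam training run (minibatch backprop in float32); returns (net, history)."""
    rng = np.random.default_rng(seed)
    W, b = _glorot_init(net_config, rng)
    mW = [np.zeros_like(w) for w in W]
    vW = [np.zeros_like(w) for w in W]
    mb = [np.zeros_like(x) for x in b]
    vb = [np.zeros_like(x) for x in b]
    Xtr = np.ascontiguousarray(Xtr, dtype=np.float32)
    Ytr = np.ascontiguousarray(Ytr, dtype=np.float32)
    n = len(Xtr)
    # fixed monitoring subsamples keep the per-epoch bookkeeping cheap
    # relative to the actual optimization work
    mon = rng.choice(n, size=min(n, 4096), replace=False)
    if len(val_frame) > 5000:
        val_frame = val_frame.sample(5000, random_state=int(rng.integers(2**31 - 1)))
    best_val = np.inf
    best_snapshot = None
    history = {"train_loss": [], "val_rel_err": []}
    stale = 0
    lr_stale = 0
    lr = tc.learning_rate
    t_adam = 0
    for epoch in range(tc.n_epochs):
        order = rng.permutation(n)
        t_adam = _adam_epoch(W, b, mW, mb, vW, vb, Xtr, Ytr, order, tc, lr, t_adam, tc.l2_rate)
        if not all(np.all(np.isfinite(w)) for w in W):
            raise FloatingPointError(f"training diverged (seed {seed}, epoch {epoch})")
        net = SurrogateNet(
            [w.astype(np.float64) for w in W],
            [x.astype(np.float64) for x in b],
            x_sc,
            y_sc,
            net_config,
        )
        history["train_loss"].append(loss(net, (Xtr[mon], Ytr[mon]), tc.l2_rate))
        val_err = evaluate_relative_error(net, val_frame)
        history["val_rel_err"].append(val_err)
        if val_err < best_val:
            best_val = val_err
            best_snapshot = ([w.copy() for w in W], [x.copy() for x in b])
            stale = 0
            lr_stale = 0
        else:
            stale += 1
            lr_stale += 1
            if stale >= tc.patience:
                break
            if lr_stale >= tc.lr_patience and lr > 1.0e-6:
                lr *= tc.lr_decay
                lr_stale = 0
    Wb, bb = best_snapshot
    net = SurrogateNet(
        [w.astype(np.float64) for w in Wb],
        [x.astype(np.float64) for x in bb],
        x_sc,
        y_sc,
        net_config,
    )
    return net, history, best_val


def train(
    net_config: NetConfig,
    dataset: StressDataset,
    training_config: TrainingConfig | None = None,
) -> tuple[SurrogateNet, dict[str, Any]]:
    """Train the surrogate, keeping the best of ``n_repeats`` runs.

    Model selection and early stopping both use the validation-split
    relative error in raw stress space.  Returns the best network and a
    history dict (per-repeat loss/validation trajectories).
    """
    tc = training_config or TrainingConfig()
    for s in ("train", "val", "test"):
        if len(dataset.rows(s)) == 0:
            raise ValueError(f"dataset has an empty {s!r} split")
    x_sc = input_scaler(dataset.bounds)
    Xtr_raw, Ytr_raw = dataset.xy("train")
    Xval_raw, _ = dataset.xy("val")
    Xtr = x_sc.transform(Xtr_raw)
    y_sc = output_scaler(Ytr_raw)
    Ytr = y_sc.transform(Ytr_raw)
    val_frame = dataset.rows("val")

    root = np.random.default_rng(tc.seed)
    best = None
    histories = []
    for rep in range(tc.n_repeats):
        seed = int(root.integers(2**31 - 1))
        try:
            net, history, val_err = _train_once(
                net_config, Xtr, Ytr, x_sc.transform(Xval_raw), val_frame, x_sc, y_sc, tc, seed
            )
        except FloatingPointError:
            histories.append({"diverged_seed": seed})
            continue
        history["seed"] = seed
        histories.append(history)
        if best is None or val_err < best[1]:
            best = (net, val_err)
    if best is None:
        raise RuntimeError("all training repeats diverged")
    net = best[0]
    net.provenance = {
        "net_config": asdict(net_config),
        "training_config": {**asdict(tc), "split": list(tc.split)},
        "dataset_seed": dataset.seed,
        "n_param_sets": int(dataset.frame["set_id"].nunique()),
        "validation_rel_err_pct": best[1],
    }
    return net, {"repeats": histories, "best_val_rel_err_pct": best[1]}


def architecture_scan(
    dataset: StressDataset,
    hidden_layer_grid: Sequence[int],
    neuron_grid: Sequence[int],
    training_config: TrainingConfig | None = None,
) -> pd.DataFrame:
    """Train one net per (layers, neurons) grid cell; tabulate test errors.

    Returns a tidy frame with columns ``n_hidden_layers, neurons_per_layer,
    test_rel_err_pct, val_rel_err_pct``.
    """
    records = []
    for L in hidden_layer_grid:
        for N in neuron_grid:
            net, hist = train(NetConfig(n_hidden_layers=L, neurons_per_layer=N), dataset, training_config)
            records.append(
                {
                    "n_hidden_layers": L,
                    "neurons_per_layer": N,
                    "val_rel_err_pct": hist["best_val_rel_err_pct"],
                    "test_rel_err_pct": evaluate_relative_error(net, dataset.rows("test")),
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Inverse-solver backend
# ---------------------------------------------------------------------------

class SurrogateBackend:
    """Adapter exposing a trained net to the inverse solver."""

    name = "surrogate"

    def __init__(self, net: SurrogateNet, rates: np.ndarray):
        self.net = net
        self.rates = np.asarray(rates, dtype=float)

    def predict(self, theta: np.ndarray) -> np.ndarray:
        return self.net.predict(theta, self.rates)

    def predict_and_grad(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        net = self.net
        M = self.rates.size
        X = np.column_stack([np.broadcast_to(theta, (M, 5)), self.rates])
        Z = net.x_scaler.transform(X)
        out_scaled, hidden = net.forward_scaled_with_hidden(Z)
        pred = net.y_scaler.inverse(out_scaled)
        dy = net.y_scaler.inverse_deriv(out_scaled)
        dx = net.x_scaler.deriv(X)[:, :5]
        grad = np.empty((M, 2, 5))
        for c in range(2):
            # one reverse pass per output component, all rates at once
            g = np.zeros((M, 2))
            g[:, c] = dy[:, c]
            for k in range(len(net.weights) - 1, -1, -1):
                g = g @ net.weights[k].T
                if k > 0:
                    g = g * (1.0 - hidden[k - 1] ** 2)
            grad[:, c, :] = g[:, :5] * dx
        return pred, grad
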