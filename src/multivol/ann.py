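"""Single-hidden-layer perceptrons for multi-volume prediction.

The network maps (DBH, H, TX, d) — or the 3-input variant without TX — to a
stem volume.  Hidden *and* output units use the logistic activation, so all
inputs and the target are affinely rescaled into the unit interval before
training and the prediction is mapped back.  Training is plain full-batch
gradient-descent backpropagation on the squared error with a momentum term;
the architecture search trains many randomly initialized candidates with
1..max_hidden hidden neurons, scores each on a held-out slice of the
fitting records, and retains the best few.  Variable importance uses
Garson's partition of absolute connection weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_INPUTS = ("DBH", "H", "TX", "d")
DEFAULT_LEARNING_RATE = 10.0
DEFAULT_MOMENTUM = 0.9
DEFAULT_EPOCHS = 2000
DEFAULT_TOL = 1e-8


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class RangeScaler:
    """Per-variable affine map onto [margin, 1 - margin]."""

    mins: np.ndarray
    maxs: np.ndarray
    margin: float = 0.0

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        return self.margin + (1.0 - 2.0 * self.margin) * (X - self.mins) / span

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        return self.mins + (Z - self.margin) / (1.0 - 2.0 * self.margin) * span

    @classmethod
    def fit(cls, X: np.ndarray, margin: float = 0.0) -> "RangeScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mins, maxs = X.min(axis=0), X.max(axis=0)
        if np.any(maxs - mins <= 0):
            bad = np.flatnonzero(maxs - mins <= 0)
            raise ValueError(f"constant variable(s) at column(s) {bad.tolist()}: cannot scale")
        return cls(mins=mins, maxs=maxs, margin=margin)


def scale_records(records: pd.DataFrame,
                  inputs: Sequence[str] = DEFAULT_INPUTS,
                  margin: float = 0.0,
                  ) -> tuple[np.ndarray, np.ndarray, RangeScaler, RangeScaler]:
    """Build the scaled design matrix and target from a record table."""
    X = records[list(inputs)].to_numpy(dtype=float)
    y = records["V"].to_numpy(dtype=float).reshape(-1, 1)
    xs = RangeScaler.fit(X, margin=margin)
    ys = RangeScaler.fit(y, margin=margin)
    return xs.transform(X), ys.transform(y), xs, ys


@dataclass
class MLPModel:
    """One trained i-h-1 perceptron with its scalers and training metadata."""

    input_names: tuple[str, ...]
    W1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_hidden,)
    b2: float
    input_scaling: RangeScaler
    target_scaling: RangeScaler
    meta: dict = field(default_factory=dict)
    error_trace: Optional[np.ndarray] = None

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def architecture(self) -> str:
        return f"{self.W1.shape[1]}-{self.n_hidden}-1"

    def _forward_scaled(self, Xs: np.ndarray) -> np.ndarray:
        hidden = _logistic(Xs @ self.W1.T + self.b1)
        return _logistic(hidden @ self.W2 + self.b2)

    def to_dict(self) -> dict:
        return {
            "input_names": list(self.input_names),
            "architecture": self.architecture,
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2,
            "input_scaling": {"mins": self.input_scaling.mins.tolist(),
                              "maxs": self.input_scaling.maxs.tolist(),
                              "margin": self.input_scaling.margin},
            "target_scaling": {"mins": self.target_scaling.mins.tolist(),
                               "maxs": self.target_scaling.maxs.tolist(),
                               "margin": self.target_scaling.margin},
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        return cls(
            input_names=tuple(d["input_names"]),
            W1=np.array(d["W1"]), b1=np.array(d["b1"]),
            W2=np.array(d["W2"]), b2=float(d["b2"]),
            input_scaling=RangeScaler(np.array(d["input_scaling"]["mins"]),
                                      np.array(d["input_scaling"]["maxs"]),
                                      d["input_scaling"]["margin"]),
            target_scaling=RangeScaler(np.array(d["target_scaling"]["mins"]),
                                       np.array(d["target_scaling"]["maxs"]),
                                       d["target_scaling"]["margin"]),
            meta=d.get("meta", {}),
        )


def train_mlp(records: pd.DataFrame, n_hidden: int = 5,
              learning_rate: float = DEFAULT_LEARNING_RATE,
              momentum: float = DEFAULT_MOMENTUM,
              epochs: int = DEFAULT_EPOCHS,
              seed: Optional[int] = None,
              inputs: Sequence[str] = DEFAULT_INPUTS,
              margin: float = 0.0,
              tol: float = DEFAULT_TOL) -> MLPModel:
    """Backpropagation with momentum on the mean squared (scaled) error.

    Weights start uniform in (-0.5, 0.5) from ``seed``; training stops early
    when the epoch-to-epoch error change falls below ``tol``, and raises if
    the error ever becomes non-finite.
    """
    if not 1 <= n_hidden <= 10:
        raise ValueError("n_hidden must be in 1..10")
    Xs, ys, xscale, yscale = scale_records(records, inputs=inputs, margin=margin)
    W1, b1, W2, b2, trace = _fit_weights(Xs, ys[:, 0], n_hidden, learning_rate,
                                         momentum, epochs, seed, tol)
    return MLPModel(
        input_names=tuple(inputs), W1=W1, b1=b1, W2=W2, b2=b2,
        input_scaling=xscale, target_scaling=yscale,
        meta={"seed": seed, "epochs_run": len(trace), "epochs": epochs,
              "learning_rate": learning_rate, "momentum": momentum},
        error_trace=np.array(trace),
    )


def _fit_weights(Xs: np.ndarray, ys: np.ndarray, n_hidden: int,
                 learning_rate: float, momentum: float, epochs: int,
                 seed: Optional[int], tol: float):
    rng = np.random.default_rng(seed)
    n, p = Xs.shape
    W1 = rng.uniform(-0.5, 0.5, size=(n_hidden, p))
    b1 = rng.uniform(-0.5, 0.5, size=n_hidden)
    W2 = rng.uniform(-0.5, 0.5, size=n_hidden)
    b2 = float(rng.uniform(-0.5, 0.5))

    vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2); vb2 = 0.0
    trace = []
    prev = np.inf
    for epoch in range(epochs):
        hidden = _logistic(Xs @ W1.T + b1)        # (n, h)
        out = _logistic(hidden @ W2 + b2)          # (n,)
        err = out - ys
        mse = float(np.mean(err ** 2))
        trace.append(mse)
        if not np.isfinite(mse):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        if abs(prev - mse) < tol:
            break
        prev = mse

        delta_out = err * out * (1.0 - out)                    # (n,)
        gW2 = (delta_out @ hidden) / n
        gb2 = float(delta_out.mean())
        delta_hid = np.outer(delta_out, W2) * hidden * (1.0 - hidden)  # (n, h)
        gW1 = delta_hid.T @ Xs / n
        gb1 = delta_hid.mean(axis=0)

        vW1 = momentum * vW1 - learning_rate * gW1
        vb1 = momentum * vb1 - learning_rate * gb1
        vW2 = momentum * vW2 - learning_rate * gW2
        vb2 = momentum * vb2 - learning_rate * gb2
        W1 += vW1; b1 += vb1; W2 += vW2; b2 += vb2
    return W1, b1, W2, b2, trace


def mlp_predict(model: MLPModel, DBH, H, TX=None, d=None) -> np.ndarray | float:
    """Predict volume (m^3); warns when inputs leave the training ranges."""
    supplied = {"DBH": DBH, "H": H, "TX": TX, "d": d}
    cols = []
    for name in model.input_names:
        if supplied.get(name) is None:
            raise ValueError(f"model expects input {name!r}")
        cols.append(np.asarray(supplied[name], dtype=float))
    extras = [k for k, v in supplied.items()
              if v is not None and k not in model.input_names]
    if extras:
        raise ValueError(f"model does not take input(s) {extras}")
    X = np.column_stack([np.atleast_1d(c) for c in cols])
    scalar = all(np.ndim(c) == 0 for c in cols)

    span = model.input_scaling.maxs - model.input_scaling.mins
    low = model.input_scaling.mins - 0.05 * span
    high = model.input_scaling.maxs + 0.05 * span
    if np.any(X < low) or np.any(X > high):
        warnings.warn("inputs outside the training range: extrapolating", stacklevel=2)

    out = model._forward_scaled(model.input_scaling.transform(X))
    vol = model.target_scaling.inverse(out.reshape(-1, 1))[:, 0]
    return float(vol[0]) if scalar else vol


def predict_records(model: MLPModel, records: pd.DataFrame) -> np.ndarray:
    kwargs = {name: records[name].to_numpy(dtype=float) for name in model.input_names}
    return mlp_predict(model, **kwargs)


@dataclass
class SearchResult:
    """Outcome of the random architecture search."""

    retained: list[tuple[MLPModel, float]]  # (model, held-out RMSE), ascending
    log: pd.DataFrame  # trial, n_hidden, seed, error

    @property
    def best(self) -> MLPModel:
        return self.retained[0][0]


def architecture_search(records: pd.DataFrame, n_trials: int = 1000,
                        max_hidden: int = 10, retain: int = 5,
                        validation_fraction: float = 0.25,
                        seed: Optional[int] = None,
                        inputs: Sequence[str] = DEFAULT_INPUTS,
                        **train_kwargs) -> SearchResult:
    """Train ``n_trials`` randomly configured networks and keep the best.

    Each trial draws a hidden-layer size uniformly in 1..max_hidden and a
    fresh initialization seed, trains on a random (1 - validation_fraction)
    share of the records, and is scored by RMSE (m^3) on the held-out share.
    Retained models are sorted by that error; ties break toward fewer hidden
    neurons, then the earlier trial.
    """
    if n_trials < retain:
        raise ValueError("n_trials must be >= retain")
    if not 0.0 < validation_fraction <= 0.5:
        raise ValueError("validation_fraction must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    n = len(records)
    n_val = max(1, int(round(validation_fraction * n)))
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    train_rec = records.iloc[train_idx].reset_index(drop=True)
    val_rec = records.iloc[val_idx].reset_index(drop=True)
    y_val = val_rec["V"].to_numpy(dtype=float)

    entries = []
    log_rows = []
    for trial in range(n_trials):
        h = int(rng.integers(1, max_hidden + 1))
        init_seed = int(rng.integers(0, 2 ** 31 - 1))
        try:
            model = train_mlp(train_rec, n_hidden=h, seed=init_seed,
                              inputs=inputs, **train_kwargs)
            err = float(np.sqrt(np.mean((predict_records(model, val_rec) - y_val) ** 2)))
        except FloatingPointError:
            # a diverged candidate scores infinitely bad but does not kill the search
            model, err = None, np.inf
        if model is not None:
            entries.append((err, h, trial, model))
        log_rows.append({"trial": trial, "n_hidden": h, "seed": init_seed, "error": err})

    if not entries:
        raise RuntimeError("every candidate network diverged")
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    retained = [(m, err) for err, _, _, m in entries[:retain]]
    return SearchResult(retained=retained, log=pd.DataFrame(log_rows))


def variable_importance(model: MLPModel) -> list[tuple[str, float]]:
    """Garson importance shares: non-negative, summing to one, sorted descending.

    Each hidden neuron's absolute output weight is split among the inputs in
    proportion to their absolute incoming weights; shares are then summed
    over neurons and normalized.
    """
    absW1 = np.abs(model.W1)           # (h, p)
    absW2 = np.abs(model.W2)           # (h,)
    row_sum = absW1.sum(axis=1)
    contrib = np.zeros(absW1.shape[1])
    for j in range(absW1.shape[0]):
        if row_sum[j] == 0:
            continue
        contrib += absW2[j] * absW1[j] / row_sum[j]
    total = contrib.sum()
    shares = contrib / total if total > 0 else contrib
    ranked = sorted(zip(model.input_names, shares), key=lambda t: -t[1])
    return [(name, float(s)) for name, s in ranked]


def save_models(models: Sequence[MLPModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps([m.to_dict() for m in models], indent=2))


def load_models(path: str | Path) -> list[MLPModel]:
    return [MLPModel.from_dict(d) for d in json.loads(Path(path).read_text())]
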