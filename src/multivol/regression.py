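"""Allometric volume regressions.

Two strategies are implemented:

* the Schumacher-Hall model, fitted separately for each volume of interest,

      V = b0 * DBH^b1 * H^b2 + e

* the Leite multi-volume model, a single equation covering total and
  merchantable volumes with and without bark,

      V = b0 * DBH^b1 * H^b2 * exp(b3 * TX / DBH)
            * [1 - (d / DBH)^(1 + b4 * d)] + e

  where TX is 1 for without-bark volumes (so exp(b3*TX/DBH) is a bark
  reduction when b3 < 0) and d is the merchantable top diameter in cm
  (d = 0 recovers the total volume: the bracket is 1).

Both are estimated by ordinary nonlinear least squares.  Starting values
come from the log-linearized regression ln V ~ ln DBH + ln H; fits that do
not converge are restarted from jittered starts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .evaluation import FitStatistics, fit_statistics

_FTOL = 1e-10
_N_RESTARTS = 3


@dataclass
class SHFit:
    """A fitted Schumacher-Hall equation for one volume label."""

    volume_label: str
    beta: tuple[float, float, float]
    fit_stats: FitStatistics
    stderr: tuple[float, float, float]
    converged: bool
    n_iterations: int
    message: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fit_stats"] = asdict(self.fit_stats)
        return d


@dataclass
class MVFit:
    """The fitted multi-volume equation (five coefficients)."""

    beta: tuple[float, float, float, float, float]
    fit_stats: FitStatistics
    stderr: tuple[float, ...]
    converged: bool
    n_iterations: int
    message: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fit_stats"] = asdict(self.fit_stats)
        return d


def sh_predict(fit: SHFit | Sequence[float], DBH, H) -> np.ndarray | float:
    """Schumacher-Hall prediction b0 * DBH^b1 * H^b2 (m^3)."""
    b0, b1, b2 = fit.beta if isinstance(fit, SHFit) else fit
    DBH = np.asarray(DBH, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(DBH <= 0) or np.any(H <= 0):
        raise ValueError("DBH and H must be positive")
    out = b0 * DBH ** b1 * H ** b2
    return float(out) if out.ndim == 0 else out


def mv_predict(fit: MVFit | Sequence[float], DBH, H, TX, d) -> np.ndarray | float:
    """Multi-volume prediction; d = 0 gives the total volume, TX = 1 without bark."""
    beta = fit.beta if isinstance(fit, MVFit) else tuple(fit)
    DBH = np.asarray(DBH, dtype=float)
    H = np.asarray(H, dtype=float)
    TX = np.asarray(TX, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(DBH <= 0) or np.any(H <= 0):
        raise ValueError("DBH and H must be positive")
    if np.any(d < 0):
        raise ValueError("negative top diameter")
    if np.any(d > DBH):
        raise ValueError("top diameter d exceeds DBH: merchantable volume undefined")
    out = _mv_eval(np.array(beta), DBH, H, TX, d)
    return float(out) if out.ndim == 0 else out


def _mv_eval(beta: np.ndarray, DBH, H, TX, d) -> np.ndarray:
    b0, b1, b2, b3, b4 = beta
    ratio = np.divide(d, DBH)
    expo = 1.0 + b4 * d
    with np.errstate(invalid="ignore"):
        bracket = np.where(ratio > 0, 1.0 - np.sign(ratio) * np.abs(ratio) ** expo, 1.0)
    return b0 * DBH ** b1 * H ** b2 * np.exp(b3 * TX / DBH) * bracket


def _loglinear_start(V, DBH, H) -> np.ndarray:
    X = np.column_stack([np.ones_like(V), np.log(DBH), np.log(H)])
    coef, *_ = np.linalg.lstsq(X, np.log(V), rcond=None)
    return np.array([np.exp(coef[0]), coef[1], coef[2]])


def _run_nls(residual_fn, x0: np.ndarray, jitter_rng: np.random.Generator):
    """least_squares with jittered restarts on failure; returns best result."""
    best = None
    start = x0.copy()
    for attempt in range(_N_RESTARTS + 1):
        try:
            res = least_squares(residual_fn, start, method="trf",
                                ftol=_FTOL, xtol=1e-12, gtol=1e-12,
                                x_scale="jac", max_nfev=20000)
        except Exception:
            res = None
        if res is not None and (best is None or res.cost < best.cost):
            best = res
        if res is not None and res.status > 0:
            break
        scale = np.where(np.abs(x0) > 0, np.abs(x0), 1.0)
        start = x0 + jitter_rng.normal(0, 0.2, size=x0.size) * scale
    if best is None:
        raise RuntimeError("nonlinear least squares failed on all restarts")
    return best


def _stderr(res) -> np.ndarray:
    """Asymptotic coefficient standard errors from the final Jacobian."""
    m, p = res.jac.shape
    if m <= p:
        return np.full(p, np.nan)
    s2 = 2.0 * res.cost / (m - p)
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def fit_schumacher_hall(data: pd.DataFrame, volume_label: str = "",
                        seed: int = 0) -> SHFit:
    """Fit V = b0 DBH^b1 H^b2 by ordinary nonlinear least squares.

    ``data`` needs columns V, DBH, H (one volume label's subset).  Start
    values come from the log-linear regression; non-convergence triggers up
    to three jittered restarts before raising.
    """
    V = data["V"].to_numpy(dtype=float)
    DBH = data["DBH"].to_numpy(dtype=float)
    H = data["H"].to_numpy(dtype=float)
    if len(V) < 10:
        raise ValueError("need at least 10 observations")
    if np.any(V <= 0) or np.any(DBH <= 0) or np.any(H <= 0):
        raise ValueError("V, DBH and H must all be positive")

    x0 = _loglinear_start(V, DBH, H)
    res = _run_nls(lambda b: b[0] * DBH ** b[1] * H ** b[2] - V,
                   x0, np.random.default_rng(seed))
    if res.status <= 0:
        raise RuntimeError(f"Schumacher-Hall fit did not converge: {res.message}")
    beta = tuple(float(b) for b in res.x)
    yhat = sh_predict(beta, DBH, H)
    return SHFit(volume_label=volume_label, beta=beta,
                 fit_stats=fit_statistics(V, yhat),
                 stderr=tuple(float(s) for s in _stderr(res)),
                 converged=True, n_iterations=int(res.nfev), message=res.message)


def fit_multivolume(records: pd.DataFrame, seed: int = 0) -> MVFit:
    """Fit the multi-volume equation jointly over all records.

    ``records`` needs columns V, DBH, H, TX, d and must contain both bark
    states and at least two distinct top diameters; otherwise the design is
    degenerate and b3 or b4 is unidentifiable.  Starting values: b0..b2 from
    the log-linear Schumacher-Hall fit on the total with-bark records
    (fallback: all records), b3 = -1, b4 = 0.1.
    """
    V = records["V"].to_numpy(dtype=float)
    DBH = records["DBH"].to_numpy(dtype=float)
    H = records["H"].to_numpy(dtype=float)
    TX = records["TX"].to_numpy(dtype=float)
    d = records["d"].to_numpy(dtype=float)
    if len(np.unique(TX)) < 2:
        raise ValueError("records must include both TX values")
    if len(np.unique(d)) < 2:
        raise ValueError("records must include at least two distinct top diameters")
    if np.any(d > DBH):
        raise ValueError("records with d > DBH must be rejected before fitting")

    total_b = (TX == 0) & (d == 0)
    if total_b.sum() >= 10:
        b012 = _loglinear_start(V[total_b], DBH[total_b], H[total_b])
    else:
        b012 = _loglinear_start(V, DBH, H)
    x0 = np.concatenate([b012, [-1.0, 0.1]])

    res = _run_nls(lambda b: _mv_eval(b, DBH, H, TX, d) - V,
                   x0, np.random.default_rng(seed))
    if res.status <= 0:
        raise RuntimeError(f"multi-volume fit did not converge: {res.message}")
    beta = tuple(float(b) for b in res.x)
    if beta[3] > 0:
        warnings.warn("beta3 > 0: bark factor exceeds 1, check the TX coding", stacklevel=2)
    yhat = _mv_eval(np.array(beta), DBH, H, TX, d)
    return MVFit(beta=beta, fit_stats=fit_statistics(V, yhat),
                 stderr=tuple(float(s) for s in _stderr(res)),
                 converged=True, n_iterations=int(res.nfev), message=res.message)


def save_fits(fits: dict, path: str | Path) -> None:
    """Serialize SHFit/MVFit objects (or dicts of them) to JSON."""
    def encode(obj):
        if isinstance(obj, (SHFit, MVFit)):
            return obj.to_dict()
        raise TypeError(type(obj))
    Path(path).write_text(json.dumps(fits, default=encode, indent=2))
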