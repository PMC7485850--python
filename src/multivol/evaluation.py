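"""Fit-quality statistics, residual summaries and validation t-tests.

All percent statistics are expressed relative to the observed mean:

    R2       = 1 - SSres / SStot
    RMSE(%)  = 100/ybar * sqrt( sum (y - yhat)^2 / n )
    MAE(%)   = 100/ybar * sum |y - yhat| / n
    MBE(%)   = 100/ybar * sum (y - yhat) / n

so a positive MBE means the model underestimates on average (observed above
predicted).  Per-observation residuals are 100 * (y - yhat) / y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FitStatistics:
    r2: float
    rmse_pct: float
    mae_pct: float
    mbe_pct: float
    n: int


def _as_arrays(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted vectors differ in length")
    return y, yhat


def r_squared(y, yhat) -> float:
    y, yhat = _as_arrays(y, yhat)
    if len(y) < 2:
        raise ValueError("need at least two observations")
    sstot = np.sum((y - y.mean()) ** 2)
    if sstot == 0:
        raise ValueError("observed values are constant")
    return float(1.0 - np.sum((y - yhat) ** 2) / sstot)


def _mean_or_raise(y: np.ndarray) -> float:
    ybar = float(y.mean())
    if ybar <= 0:
        raise ValueError("observed mean must be positive for percent statistics")
    return ybar


def rmse_pct(y, yhat) -> float:
    y, yhat = _as_arrays(y, yhat)
    return 100.0 / _mean_or_raise(y) * float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae_pct(y, yhat) -> float:
    y, yhat = _as_arrays(y, yhat)
    return 100.0 / _mean_or_raise(y) * float(np.mean(np.abs(y - yhat)))


def mbe_pct(y, yhat) -> float:
    y, yhat = _as_arrays(y, yhat)
    return 100.0 / _mean_or_raise(y) * float(np.mean(y - yhat))


def residual_pct(y, yhat) -> np.ndarray:
    """Per-observation residual as a percent of the observed value."""
    y, yhat = _as_arrays(y, yhat)
    if np.any(y == 0):
        raise ValueError("zero observed value in percent residual")
    return 100.0 * (y - yhat) / y


def fit_statistics(y, yhat) -> FitStatistics:
    y, yhat = _as_arrays(y, yhat)
    return FitStatistics(
        r2=r_squared(y, yhat),
        rmse_pct=rmse_pct(y, yhat),
        mae_pct=mae_pct(y, yhat),
        mbe_pct=mbe_pct(y, yhat),
        n=len(y),
    )


@dataclass
class TTestResult:
    statistic: float
    p_value: float
    decision: str  # "no difference" or "difference"
    mode: str

    @property
    def significant(self) -> bool:
        return self.decision == "difference"


def volume_t_test(observed, estimated, alpha: float = 0.05,
                  mode: str = "paired") -> TTestResult:
    """t-test between scaled (observed) and estimated volumes.

    Paired by default, since the same stems are both scaled and predicted;
    ``mode="welch"`` gives the unequal-variance two-sample alternative.
    All-zero paired differences are a defined no-difference result.
    """
    y, yhat = _as_arrays(observed, estimated)
    if len(y) < 2:
        raise ValueError("need at least two pairs")
    if mode == "paired":
        diff = y - yhat
        if np.std(diff) == 0:
            if np.all(diff == 0):
                return TTestResult(0.0, 1.0, "no difference", mode)
            raise ValueError("constant non-zero paired differences: t undefined")
        t, p = stats.ttest_rel(y, yhat)
    elif mode == "welch":
        t, p = stats.ttest_ind(y, yhat, equal_var=False)
    else:
        raise ValueError(f"unknown t-test mode {mode!r}")
    decision = "no difference" if p > alpha else "difference"
    return TTestResult(float(t), float(p), decision, mode)


def per_volume_summary(records: pd.DataFrame, predictions,
                       label_column: str = "volume_label") -> pd.DataFrame:
    """Five-number summary (+mean) of percent residuals per volume label,
    with a pooled row over all labels."""
    yhat = np.asarray(predictions, dtype=float)
    y = records["V"].to_numpy(dtype=float)
    res = residual_pct(y, yhat)
    frame = pd.DataFrame({"label": records[label_column].to_numpy(), "residual": res})
    rows = []

    def describe(label: str, r: np.ndarray) -> dict:
        return {
            "volume_label": label, "n": len(r),
            "min": float(r.min()), "q1": float(np.percentile(r, 25)),
            "median": float(np.median(r)), "q3": float(np.percentile(r, 75)),
            "max": float(r.max()), "mean": float(r.mean()),
        }

    for label, grp in frame.groupby("label", sort=False):
        rows.append(describe(str(label), grp["residual"].to_numpy()))
    rows.append(describe("joint", res))
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Per-strategy, per-volume statistics plus joint rows and t-tests."""

    table: pd.DataFrame  # strategy, volume_label, n, r2, rmse/mae/mbe pct, t, p, decision
    residual_summaries: dict[str, pd.DataFrame]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "table": self.table.to_dict(orient="records"),
            "residual_summaries": {k: v.to_dict(orient="records")
                                   for k, v in self.residual_summaries.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def joint(self, strategy: str) -> FitStatistics:
        row = self.table[(self.table["strategy"] == strategy)
                         & (self.table["volume_label"] == "joint")].iloc[0]
        return FitStatistics(row["r2"], row["rmse_pct"], row["mae_pct"],
                             row["mbe_pct"], int(row["n"]))


def evaluate_predictions(records: pd.DataFrame,
                         predictions: Mapping[str, Sequence[float]],
                         alpha: float = 0.05,
                         t_test_mode: str = "paired") -> ValidationReport:
    """Build a ValidationReport from aligned prediction vectors.

    ``predictions`` maps strategy name -> predicted volumes aligned with the
    rows of ``records``.  Per volume label and jointly, the fit statistics
    and the observed-vs-estimated t-test are computed for each strategy.
    Labels with fewer than two records are skipped with a notice.
    """
    y_all = records["V"].to_numpy(dtype=float)
    rows = []
    residuals = {}
    lengths = {k: len(np.asarray(v)) for k, v in predictions.items()}
    if any(n != len(records) for n in lengths.values()):
        raise ValueError(f"prediction vectors misaligned with records: {lengths}")

    for strategy, yhat in predictions.items():
        yhat = np.asarray(yhat, dtype=float)
        for label, idx in _label_groups(records):
            yl, yhl = y_all[idx], yhat[idx]
            if len(yl) < 2:
                continue
            st = fit_statistics(yl, yhl)
            tt = volume_t_test(yl, yhl, alpha=alpha, mode=t_test_mode)
            rows.append({"strategy": strategy, "volume_label": label, "n": st.n,
                         "r2": st.r2, "rmse_pct": st.rmse_pct, "mae_pct": st.mae_pct,
                         "mbe_pct": st.mbe_pct, "t": tt.statistic, "p": tt.p_value,
                         "decision": tt.decision})
        st = fit_statistics(y_all, yhat)
        tt = volume_t_test(y_all, yhat, alpha=alpha, mode=t_test_mode)
        rows.append({"strategy": strategy, "volume_label": "joint", "n": st.n,
                     "r2": st.r2, "rmse_pct": st.rmse_pct, "mae_pct": st.mae_pct,
                     "mbe_pct": st.mbe_pct, "t": tt.statistic, "p": tt.p_value,
                     "decision": tt.decision})
        residuals[strategy] = per_volume_summary(records, yhat)
    return ValidationReport(pd.DataFrame(rows), residuals)


def _label_groups(records: pd.DataFrame):
    labels = records["volume_label"].to_numpy()
    for label in pd.unique(labels):
        yield str(label), np.flatnonzero(labels == label)
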