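"""Precision metrics and decile calibration of utility predictions.

Model comparison uses two complementary views:

* precision — RMSE, MAE and the range of the predictions;
* calibration — observations are grouped by deciles of the predicted
  values, the mean observed and mean predicted utility are computed per
  group, and a straight line is fitted through the ten points by
  ordinary least squares.  A well-calibrated model has intercept
  beta0 = 0 and slope beta1 = 1.  Aberrant deciles are detected on the
  10-point regression by externally studentized residuals (|r| > 2.5)
  or Cook's distance (> 0.5); at most two deciles are excluded and the
  line refitted once.

Metrics are computed on fixed-effect-only predictions (zero random
effects), i.e. on the scale at which a new patient would be predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError

__all__ = [
    "FitMetrics",
    "CalibrationResult",
    "precision_metrics",
    "calibration_by_deciles",
    "split_patients",
]

STUDENTIZED_THRESHOLD = 2.5
COOKS_THRESHOLD = 0.5
MAX_EXCLUDED = 2


@dataclass(frozen=True)
class FitMetrics:
    """Root-mean-squared error, mean absolute error, prediction range."""

    rmse: float
    mae: float
    prediction_range: tuple[float, float]


@dataclass
class CalibrationResult:
    """Decile means, calibration line, and excluded-decile bookkeeping."""

    decile_table: pd.DataFrame  # columns: decile, mean_predicted, mean_observed, n
    intercept: float
    slope: float
    excluded_deciles: list[int] = field(default_factory=list)
    exclusion_reasons: dict[int, str] = field(default_factory=dict)


def split_patients(df: pd.DataFrame, test_fraction: float = 0.25, seed: int = 0):
    """Patient-level train/test split for held-out evaluation.

    Evaluation is within-sample by default (fit and evaluate on the same
    cohort); this helper supports the held-out alternative.  All rows of
    a patient land on the same side.
    """
    if not 0.0 < test_fraction < 1.0:
        raise DataError("test_fraction must be in (0, 1)")
    ids = df["patient_id"].unique()
    rng = np.random.default_rng(seed)
    test_ids = set(rng.choice(ids, size=max(1, int(round(test_fraction * len(ids)))),
                              replace=False))
    mask = df["patient_id"].isin(test_ids)
    return df[~mask].copy(), df[mask].copy()


def precision_metrics(observed, predicted) -> FitMetrics:
    """RMSE, MAE and (min, max) of the predictions."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise DataError(f"length mismatch: {o.shape} observed vs {p.shape} predicted")
    if o.size == 0:
        raise DataError("empty inputs")
    err = o - p
    return FitMetrics(
        rmse=float(np.sqrt(np.mean(err**2))),
        mae=float(np.mean(np.abs(err))),
        prediction_range=(float(p.min()), float(p.max())),
    )


def _decile_groups(predicted: np.ndarray) -> np.ndarray:
    """Group labels 0..9 by deciles of predictions, stable-rank ties."""
    n = len(predicted)
    order = np.argsort(predicted, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * 10) // n


def _fit_line(x: np.ndarray, y: np.ndarray):
    X = sm.add_constant(x)
    return sm.OLS(y, X).fit()


def calibration_by_deciles(observed, predicted) -> CalibrationResult:
    """Decile calibration line of observed on predicted group means.

    Partitions into 10 groups by predicted deciles (sizes differ by at
    most one), regresses the 10 observed means on the 10 predicted means
    (unweighted OLS), applies the outlier rule once, and refits.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise DataError("length mismatch between observed and predicted")
    if len(o) < 10:
        raise DataError("calibration needs at least 10 observations")
    groups = _decile_groups(p)
    table = pd.DataFrame(
        {
            "decile": np.arange(10),
            "mean_predicted": [p[groups == g].mean() for g in range(10)],
            "mean_observed": [o[groups == g].mean() for g in range(10)],
            "n": [int((groups == g).sum()) for g in range(10)],
        }
    )
    fit = _fit_line(table["mean_predicted"].to_numpy(), table["mean_observed"].to_numpy())
    if np.sqrt(max(fit.mse_resid, 0.0)) < 1e-8:
        # numerically perfect line: studentized residuals are 0/0 noise
        return CalibrationResult(
            decile_table=table,
            intercept=float(fit.params[0]),
            slope=float(fit.params[1]),
        )
    influence = fit.get_influence()
    student = influence.resid_studentized_external
    cooks = influence.cooks_distance[0]
    flagged = {}
    for g in range(10):
        reasons = []
        if abs(student[g]) > STUDENTIZED_THRESHOLD:
            reasons.append(f"|studentized residual| = {abs(student[g]):.2f} > {STUDENTIZED_THRESHOLD}")
        if cooks[g] > COOKS_THRESHOLD:
            reasons.append(f"Cook's distance = {cooks[g]:.2f} > {COOKS_THRESHOLD}")
        if reasons:
            flagged[g] = "; ".join(reasons)
    excluded = sorted(flagged, key=lambda g: -cooks[g])[:MAX_EXCLUDED]
    if excluded:
        keep = np.setdiff1d(np.arange(10), excluded)
        if len(keep) < 3:
            raise DataError("fewer than 3 deciles left after exclusion")
        fit = _fit_line(
            table.loc[keep, "mean_predicted"].to_numpy(),
            table.loc[keep, "mean_observed"].to_numpy(),
        )
    beta0, beta1 = fit.params
    return CalibrationResult(
        decile_table=table,
        intercept=float(beta0),
        slope=float(beta1),
        excluded_deciles=sorted(excluded),
        exclusion_reasons={g: flagged[g] for g in excluded},
    )


def plot_calibration(result: CalibrationResult, path=None, ax=None):
    """Observed-vs-predicted decile means with the identity line.

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    t = result.decile_table
    ax.scatter(t["mean_predicted"], t["mean_observed"], color="black", zorder=3)
    if result.excluded_deciles:
        excl = t.iloc[result.excluded_deciles]
        ax.scatter(excl["mean_predicted"], excl["mean_observed"],
                   facecolors="none", edgecolors="red", s=120, label="excluded")
    lims = [
        min(t["mean_predicted"].min(), t["mean_observed"].min()) - 0.05,
        max(t["mean_predicted"].max(), t["mean_observed"].max()) + 0.05,
    ]
    ax.plot(lims, lims, color="green", lw=1, label="perfect calibration")
    xs = np.linspace(*lims, 10)
    ax.plot(xs, result.intercept + result.slope * xs, color="black", ls="--",
            label=f"b0={result.intercept:.3f}, b1={result.slope:.3f}")
    ax.set_xlabel("mean predicted HSUV (decile)")
    ax.set_ylabel("mean observed HSUV (decile)")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
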