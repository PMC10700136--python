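"""LOWESS-calibrated age gaps.

A clock's raw prediction drifts systematically with chronological age
(regression dilution, cohort effects), so the *age gap* is defined against
a locally weighted regression of predicted on chronological age (tricube
weights, neighborhood fraction 2/3): gap_i = predicted_i - lowess(age_i).
Gaps are computed separately per cohort and then z-scored per (model,
cohort) so organ models with different variability are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

logger = logging.getLogger(__name__)


@dataclass
class GapConfig:
    lowess_fraction: float = 2 / 3
    robustifying_iterations: int = 3
    #: lowess linear-interpolation window as a fraction of the x range;
    #: 0 = exact fit at every observed x
    delta_frac: float = 0.0
    min_cohort_size: int = 50
    zscore_reference: str = "all"  # or "healthy"
    #: sample (n-1) or population (n) SD convention for the z-score
    zscore_ddof: int = 1
    pool_cohorts_for_zscore: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.lowess_fraction <= 1:
            raise ValueError("lowess_fraction must be in (0, 1]")


@dataclass
class LowessCalibration:
    """An evaluable smoother: fitted values at observed x, interpolated
    in between and clamped to the boundary fit outside the observed range."""

    x_: np.ndarray
    y_: np.ndarray
    kind: str = "lowess"

    def __call__(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.x_, self.y_)


def fit_lowess_calibration(
    chronological: np.ndarray,
    predicted: np.ndarray,
    config: GapConfig | None = None,
) -> LowessCalibration:
    """Fit the predicted-vs-chronological calibration curve.

    Cohorts smaller than ``min_cohort_size`` fall back to an ordinary
    least-squares line with a warning (local regression is unstable there).
    """
    config = config or GapConfig()
    x = np.asarray(chronological, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.std() == 0:
        raise ValueError("constant chronological age: no calibration possible")
    if len(x) < config.min_cohort_size:
        logger.warning(
            "n=%d below min_cohort_size=%d: linear calibration fallback",
            len(x), config.min_cohort_size,
        )
        slope, intercept = np.polyfit(x, y, 1)
        xs = np.unique(x)
        return LowessCalibration(xs, intercept + slope * xs, kind="linear")
    delta = config.delta_frac * (x.max() - x.min())
    fitted = sm_lowess(
        y, x,
        frac=config.lowess_fraction,
        it=config.robustifying_iterations,
        delta=delta,
        return_sorted=True,
    )
    xs, ys = fitted[:, 0], fitted[:, 1]
    # collapse duplicate x for interpolation (lowess already returns
    # identical fits at identical x)
    ux, first = np.unique(xs, return_index=True)
    return LowessCalibration(ux, ys[first])


def compute_age_gaps(
    predicted: np.ndarray,
    chronological: np.ndarray,
    cohort_labels: np.ndarray,
    model_name: str,
    config: GapConfig | None = None,
    subject_ids=None,
) -> pd.DataFrame:
    """Raw age gaps, calibrated independently within each cohort label.

    Returns a DataFrame with subject, cohort, model, predicted_age and
    raw_gap columns.
    """
    config = config or GapConfig()
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    cohort_labels = np.asarray(cohort_labels)
    if subject_ids is None:
        subject_ids = np.arange(len(predicted))
    raw = np.empty(len(predicted))
    for label in pd.unique(cohort_labels):
        m = cohort_labels == label
        if m.sum() < 3:
            raise ValueError(f"cohort {label!r} has fewer than 3 subjects")
        cal = fit_lowess_calibration(chronological[m], predicted[m], config)
        raw[m] = predicted[m] - cal(chronological[m])
    return pd.DataFrame(
        {
            "subject": np.asarray(subject_ids),
            "cohort": cohort_labels,
            "model": model_name,
            "predicted_age": predicted,
            "raw_gap": raw,
        }
    )


def zscore_gaps(
    gaps: pd.DataFrame,
    config: GapConfig | None = None,
    healthy: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fill the z_gap column, standardizing per (model, cohort).

    The reference set defaults to all subjects of the (model, cohort) cell;
    with ``zscore_reference='healthy'`` the mean/SD come from healthy
    subjects only (``healthy`` aligned with ``gaps`` rows). With
    ``pool_cohorts_for_zscore`` standardization is per model across
    cohorts.
    """
    config = config or GapConfig()
    out = gaps.copy()
    if config.zscore_reference == "healthy":
        if healthy is None:
            raise ValueError("healthy mask required for healthy-only reference")
        ref_mask = np.asarray(healthy, dtype=bool)
    else:
        ref_mask = np.ones(len(out), dtype=bool)
    keys = ["model"] if config.pool_cohorts_for_zscore else ["model", "cohort"]
    z = np.empty(len(out))
    grouped = out.groupby(keys, sort=False).indices
    for key, idx in grouped.items():
        ref = idx[ref_mask[idx]]
        vals = out["raw_gap"].to_numpy()[ref]
        sd = vals.std(ddof=config.zscore_ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero SD of raw gaps for {key!r}: cannot z-score")
        z[idx] = (out["raw_gap"].to_numpy()[idx] - vals.mean()) / sd
    out["z_gap"] = z
    return out


def gaps_to_wide(gaps: pd.DataFrame, value: str = "z_gap") -> pd.DataFrame:
    """Pivot a long gap table to subjects x models."""
    return gaps.pivot_table(index="subject", columns="model", values=value, sort=False)
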