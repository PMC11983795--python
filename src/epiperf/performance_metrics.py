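"""Pearson correlation and median absolute error, overall and per stratum."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc_conversions import AnalysisSet

__all__ = [
    "MetricUndefinedError",
    "StratifiedMetric",
    "pearson_r",
    "median_abs_error",
    "stratified_metrics",
    "GRIMAGE_R_THRESHOLD",
]

#: Correlation cutoff historically used to screen plasma-protein surrogate
#: predictors; computed for every predictor but meaningful for the protein
#: family only.
GRIMAGE_R_THRESHOLD = 0.35

STRATA_VARIABLES = ("race_ethnicity", "sex", "overall")


class MetricUndefinedError(ValueError):
    """Raised when a metric is undefined (e.g. zero variance) instead of
    silently returning NaN."""


@dataclass(frozen=True)
class StratifiedMetric:
    predictor: str
    stratum: str
    n: int
    pearson_r: float
    mae: float
    passes_grimage_threshold: bool
    analysable: bool = True


def _paired_arrays(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return x, y


def pearson_r(x, y) -> float:
    """Product-moment correlation; symmetric in its arguments.

    Raises :class:`MetricUndefinedError` if either vector has zero variance.
    """
    x, y = _paired_arrays(x, y, min_n=3)
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if den == 0:
        raise MetricUndefinedError("zero variance: correlation undefined")
    return float(np.clip((xc * yc).sum() / den, -1.0, 1.0))


def median_abs_error(x, y) -> float:
    """Median of |y_i - x_i| in the units of ``x``.

    The median of an even count is the midpoint of the two central order
    statistics.
    """
    x, y = _paired_arrays(x, y, min_n=1)
    return float(np.median(np.abs(y - x)))


def stratified_metrics(analysis_set, strata_var: str = "race_ethnicity") -> pd.DataFrame:
    """One row per stratum plus the overall population.

    Strata with fewer than 3 pairs are flagged unanalysable (NaN metrics)
    rather than reported.  Accepts an :class:`AnalysisSet` or any frame with
    ``phenotype`` / ``prediction`` columns.
    """
    if strata_var not in STRATA_VARIABLES:
        raise ValueError(f"unknown strata variable {strata_var!r}")
    if isinstance(analysis_set, AnalysisSet):
        frame = analysis_set.frame
        predictor = analysis_set.spec.name
    else:
        frame = analysis_set
        predictor = str(frame["predictor"].iloc[0]) if "predictor" in frame.columns else ""

    def one(stratum: str, sub: pd.DataFrame) -> StratifiedMetric:
        x = sub["phenotype"].to_numpy(float)
        y = sub["prediction"].to_numpy(float)
        if len(sub) < 3:
            return StratifiedMetric(predictor, stratum, len(sub), np.nan, np.nan, False, False)
        try:
            r = pearson_r(x, y)
        except MetricUndefinedError:
            return StratifiedMetric(predictor, stratum, len(sub), np.nan, np.nan, False, False)
        return StratifiedMetric(
            predictor, stratum, len(sub), r, median_abs_error(x, y), bool(r > GRIMAGE_R_THRESHOLD)
        )

    rows = [one("overall", frame)]
    if strata_var != "overall":
        if strata_var not in frame.columns:
            raise ValueError(f"strata column {strata_var!r} not present")
        for label, sub in frame.groupby(strata_var, sort=False, observed=True):
            rows.append(one(str(label), sub))
    return pd.DataFrame([r.__dict__ for r in rows])
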