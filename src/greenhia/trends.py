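"""Linear greenness trends per analysis unit, 2000-2020 style.

Ordinary least squares of annual exposure on (centred) survey year, with a
two-sided t-test on the slope (n - 2 degrees of freedom).  A unit is
classified "Increase"/"Decrease" when the slope is positive/negative with
p < 0.05, else "NoChange".  With the default five quinquennial time points
the t-test has only 3 degrees of freedom, so nothing here assumes
asymptotics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("greenhia")

ALPHA = 0.05

#: On-disk rendering of the classification labels.
DISPLAY = {"Increase": "Increase", "Decrease": "Decrease", "NoChange": "No change"}


@dataclass(frozen=True)
class TrendResult:
    unit_id: str
    slope: float       # NDVI per year
    intercept: float   # NDVI at the mean survey year
    p_value: float
    classification: str
    n_points: int


def fit_trend(years, values, unit_id: str = "") -> TrendResult:
    """OLS trend of exposure on centred year with a slope t-test.

    Requires >= 3 points with distinct years.  Degenerate conventions: a
    zero-variance (constant) exposure series has slope 0 and p = 1; an
    exact nonzero-slope fit has p = 0.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size != values.size:
        raise ValueError("years and values must have equal length")
    if years.size < 3:
        raise ValueError("trend fit needs at least 3 points")
    if np.unique(years).size < 2:
        raise ValueError("trend fit needs at least two distinct years")
    x = years - years.mean()
    # numerically constant series (spread at rounding-error level) follow the
    # constant-series convention: slope 0, p = 1
    if np.ptp(values) <= 1e-12 * max(1.0, float(np.max(np.abs(values)))):
        return TrendResult(unit_id, 0.0, float(np.mean(values)), 1.0, "NoChange",
                           years.size)
    res = stats.linregress(x, values)
    slope = float(res.slope)
    # an exactly-zero residual breaks the t statistic; apply the exact-fit
    # convention only then, so epsilon-level jitter still goes through the test
    resid = values - (res.intercept + slope * x)
    if float(resid @ resid) == 0.0:
        p = 0.0 if slope != 0.0 else 1.0
    else:
        p = float(res.pvalue)
    return TrendResult(
        unit_id, slope, float(res.intercept), p,
        classify_trend(slope, p), int(years.size),
    )


def classify_trend(slope: float, p_value: float, alpha: float = ALPHA) -> str:
    """Significance-gated direction; ties at p == alpha count as NoChange."""
    if p_value < alpha:
        if slope > 0:
            return "Increase"
        if slope < 0:
            return "Decrease"
    return "NoChange"


def compute_trends(
    exposures: pd.DataFrame,
    *,
    column: str = "weighted_ndvi",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Fit one trend per city from an exposure table.

    ``column`` selects the exposure (population-weighted by default, the
    unweighted mean as the sensitivity option).
    """
    rows = []
    for unit_id, grp in exposures.groupby("city_id", sort=True):
        grp = grp.dropna(subset=[column])
        if len(grp) < 3:
            logger.warning("unit %s: <3 exposure points, trend skipped", unit_id)
            continue
        res = fit_trend(grp["year"].to_numpy(), grp[column].to_numpy(), str(unit_id))
        klass = classify_trend(res.slope, res.p_value, alpha)
        rows.append(
            {
                "unit_id": res.unit_id,
                "slope": res.slope,
                "intercept": res.intercept,
                "p_value": res.p_value,
                "classification": klass,
                "n_points": res.n_points,
            }
        )
    return pd.DataFrame(
        rows, columns=["unit_id", "slope", "intercept", "p_value",
                       "classification", "n_points"]
    )


def write_trends(trends: pd.DataFrame, path: str | Path) -> None:
    """CSV output with the published label rendering ("No change")."""
    out = trends.copy()
    out["classification"] = out["classification"].map(DISPLAY)
    out.to_csv(path, index=False)
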