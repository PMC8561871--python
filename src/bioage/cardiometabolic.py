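"""Composite cardiometabolic risk (CMR) scoring.

The score sums within-sample z-scores of four adverse components
measured at the second visit: reciprocal HDL cholesterol, LDL
cholesterol, fasting glucose and mean arterial pressure (MAP).  HDL is
protective, so its reciprocal is taken *before* standardisation; every
component then points in the "higher = worse" direction.  Because the
z-scores are computed within the analysis sample, the score is
sample-specific and carries no clinical cut-point; a median split
provides the low/high dichotomy used in the risk models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateSampleError",
    "mean_bp",
    "mean_arterial_pressure",
    "cmr_score",
    "median_split",
    "CMR_COMPONENTS",
]

logger = logging.getLogger(__name__)

CMR_COMPONENTS = ("inv_hdl", "ldl", "glucose", "map")


class DegenerateSampleError(ValueError):
    """A CMR component has zero variance in the supplied sample."""


def mean_bp(reading1, reading2):
    """Mean of two successive blood-pressure readings (mmHg)."""
    r1 = np.asarray(reading1, dtype=float)
    r2 = np.asarray(reading2, dtype=float)
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("blood-pressure readings must be positive")
    m = 0.5 * (r1 + r2)
    return float(m) if np.ndim(m) == 0 else m


def mean_arterial_pressure(sbp, dbp):
    """MAP = (SBP + 2*DBP) / 3, in mmHg.

    Diastolic above systolic is physiologically implausible; it is
    logged as a warning rather than rejected (transcription noise in
    cohort data is common and the formula remains well defined).
    """
    s = np.asarray(sbp, dtype=float)
    d = np.asarray(dbp, dtype=float)
    if np.any(s <= 0) or np.any(d <= 0):
        raise ValueError("blood pressures must be positive")
    if np.any(d > s):
        logger.warning("DBP exceeds SBP for %d input(s)", int(np.sum(np.atleast_1d(d > s))))
    m = (s + 2.0 * d) / 3.0
    return float(m) if np.ndim(m) == 0 else m


def _zscore(values: np.ndarray, name: str) -> np.ndarray:
    sd = values.std(ddof=1)
    if not sd > 0:
        raise DegenerateSampleError(f"component {name!r} has zero variance in this sample")
    return (values - values.mean()) / sd


def cmr_score(
    panel: pd.DataFrame,
    group: pd.Series | None = None,
) -> pd.DataFrame:
    """Composite CMR scores for an analysis sample.

    ``panel`` needs columns ``glucose``, ``hdl``, ``ldl`` (mmol/L) and
    either ``map`` or the four raw readings ``sbp1, sbp2, dbp1, dbp2``
    (mmHg).  Z-scores are taken within the supplied sample (sample SD,
    n-1 denominator); pass ``group`` (e.g. sex) to standardise within
    strata instead of pooled.  Returns a frame indexed like ``panel``
    with the MAP, the four z components, ``cmr`` (their sum) and
    ``risk_class`` from a median split of ``cmr`` within the sample.
    """
    if len(panel) < 2:
        raise ValueError("CMR standardisation needs at least 2 children")
    for col in ("glucose", "hdl", "ldl"):
        if col not in panel.columns:
            raise ValueError(f"panel lacks column {col!r}")
        if np.any(panel[col].to_numpy(dtype=float) <= 0):
            raise ValueError(f"column {col!r} must be strictly positive")
    if "map" in panel.columns:
        map_values = panel["map"].to_numpy(dtype=float)
    else:
        for col in ("sbp1", "sbp2", "dbp1", "dbp2"):
            if col not in panel.columns:
                raise ValueError("panel needs 'map' or sbp1/sbp2/dbp1/dbp2 columns")
        map_values = mean_arterial_pressure(
            mean_bp(panel["sbp1"], panel["sbp2"]),
            mean_bp(panel["dbp1"], panel["dbp2"]),
        )

    components = {
        "inv_hdl": 1.0 / panel["hdl"].to_numpy(dtype=float),
        "ldl": panel["ldl"].to_numpy(dtype=float),
        "glucose": panel["glucose"].to_numpy(dtype=float),
        "map": np.asarray(map_values, dtype=float),
    }

    out = pd.DataFrame(index=panel.index)
    out["map"] = components["map"]
    if group is None:
        for name, values in components.items():
            out[f"z_{name}"] = _zscore(values, name)
    else:
        group = pd.Series(group, index=panel.index)
        for name, values in components.items():
            z = np.empty(len(panel))
            series = pd.Series(values, index=panel.index)
            for level, idx in series.groupby(group).groups.items():
                sub = series.loc[idx].to_numpy()
                if len(sub) < 2:
                    raise ValueError(f"stratum {level!r} too small for standardisation")
                z[panel.index.get_indexer(idx)] = _zscore(sub, f"{name}[{level}]")
            out[f"z_{name}"] = z
    out["cmr"] = sum(out[f"z_{name}"] for name in CMR_COMPONENTS)
    out["risk_class"] = median_split(out["cmr"].to_numpy())
    return out


def median_split(values) -> np.ndarray:
    """Dichotomise at the sample median: strictly above -> "high", else "low".

    Ties at the median are assigned to "low" (deterministic).  A
    constant sample yields all "low" with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("median split needs at least 2 values")
    med = np.median(values)
    labels = np.where(values > med, "high", "low")
    if np.all(labels == "low"):
        logger.warning("median split degenerate: no value above the median")
    return labels
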