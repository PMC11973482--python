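"""Growth-phenotype metrics from OD600 plate-reader time series.

Two metrics summarize each well: the maximum 5-point sliding-window growth
slope between 2 and 10 h (a proxy for maximum growth rate) and the mean
optical density over the 5 readings nearest 12 h (a carrying-capacity
proxy). Relative fitness normalizes each line's metric to the mean of the
ancestor replicates measured in the same batch/day, cancelling day effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "max_growth_slope",
    "carrying_capacity",
    "relative_fitness",
    "growth_metrics",
    "read_curves",
    "curves_to_frame",
    "frame_to_curves",
]

CURVE_COLUMNS = ("well_id", "sample_id", "batch", "time_h", "od600")


@dataclass
class GrowthCurve:
    """One well's OD600 time series with its sample and batch labels."""

    well_id: str
    sample_id: str
    batch: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od.shape:
            raise ValueError("times and od must be matching 1-d arrays")
        if self.times.size < 2:
            raise ValueError("a growth curve needs at least 2 readings")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"times for well {self.well_id} are not strictly increasing")
        if np.any(self.od < 0):
            raise ValueError(f"negative OD600 readings in well {self.well_id}")


def max_growth_slope(curve: GrowthCurve, window_points: int = 5,
                     t_min: float = 2.0, t_max: float = 10.0,
                     method: str = "ols") -> float:
    """Maximum windowed growth slope (OD/h) within [t_min, t_max].

    Every run of ``window_points`` consecutive readings falling entirely in
    the window contributes either its least-squares slope (``method="ols"``,
    the default) or the mean of its adjacent finite differences
    (``method="diff"``); the maximum over runs is returned.
    """
    if method not in ("ols", "diff"):
        raise ValueError(f"unknown slope method {method!r}")
    mask = (curve.times >= t_min) & (curve.times <= t_max)
    t = curve.times[mask]
    y = curve.od[mask]
    if t.size < window_points:
        raise ValueError(
            f"only {t.size} readings in [{t_min}, {t_max}] h for well "
            f"{curve.well_id}; need {window_points}"
        )
    best = -np.inf
    for i in range(t.size - window_points + 1):
        tw = t[i:i + window_points]
        yw = y[i:i + window_points]
        if method == "ols":
            slope = np.polyfit(tw, yw, 1)[0]
        else:
            slope = float(np.mean(np.diff(yw) / np.diff(tw)))
        best = max(best, float(slope))
    return best


def carrying_capacity(curve: GrowthCurve, t_center: float = 12.0,
                      n_points: int = 5) -> float:
    """Mean OD over the ``n_points`` readings nearest ``t_center`` hours.

    Distance ties are broken toward the earlier reading.
    """
    if curve.times.size < n_points:
        raise ValueError(
            f"well {curve.well_id} has {curve.times.size} readings; need {n_points}"
        )
    # stable sort on (|t - center|, t): equal distances favor the earlier time
    order = np.lexsort((curve.times, np.abs(curve.times - t_center)))
    return float(curve.od[order[:n_points]].mean())


def relative_fitness(metrics: pd.DataFrame, ancestor_id: str,
                     value_col: str = "value") -> pd.DataFrame:
    """Normalize per-sample metrics to the same-batch ancestor mean.

    ``metrics`` needs columns sample_id, batch and ``value_col``. Returns the
    frame with a ``relative`` column; a batch with no ancestor replicate is
    an error because nothing can anchor it.
    """
    required = {"sample_id", "batch", value_col}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics frame missing columns: {sorted(missing)}")
    out = metrics.copy()
    out["relative"] = np.nan
    for batch, group in metrics.groupby("batch"):
        anc = group.loc[group["sample_id"] == ancestor_id, value_col]
        if anc.empty:
            raise ValueError(f"batch {batch!r} has no ancestor ({ancestor_id!r}) replicate")
        anc_mean = anc.mean()
        if anc_mean == 0:
            raise ZeroDivisionError(f"ancestor mean metric is zero in batch {batch!r}")
        out.loc[group.index, "relative"] = group[value_col] / anc_mean
    return out


def growth_metrics(curves: Iterable[GrowthCurve], window_points: int = 5,
                   t_min: float = 2.0, t_max: float = 10.0,
                   t_center: float = 12.0, n_capacity_points: int = 5,
                   ) -> pd.DataFrame:
    """Per-well max slope and 12-h capacity, one row per curve."""
    rows = []
    for c in curves:
        rows.append({
            "well_id": c.well_id,
            "sample_id": c.sample_id,
            "batch": c.batch,
            "max_slope": max_growth_slope(c, window_points, t_min, t_max),
            "capacity": carrying_capacity(c, t_center, n_capacity_points),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# long-format TSV I/O
# ---------------------------------------------------------------------------

def curves_to_frame(curves: Iterable[GrowthCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od):
            rows.append((c.well_id, c.sample_id, c.batch, t, od))
    return pd.DataFrame(rows, columns=list(CURVE_COLUMNS))


def frame_to_curves(frame: pd.DataFrame) -> list[GrowthCurve]:
    missing = set(CURVE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"curve table missing columns: {sorted(missing)}")
    curves = []
    for well_id, group in frame.groupby("well_id", sort=True):
        group = group.sort_values("time_h")
        curves.append(GrowthCurve(
            well_id=str(well_id),
            sample_id=str(group["sample_id"].iloc[0]),
            batch=str(group["batch"].iloc[0]),
            times=group["time_h"].to_numpy(dtype=float),
            od=group["od600"].to_numpy(dtype=float),
        ))
    return curves


def read_curves(path: str | Path) -> list[GrowthCurve]:
    """Read a long-format plate-reader export (well_id, sample_id, batch, time_h, od600)."""
    return frame_to_curves(pd.read_csv(path, sep="\t"))
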