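"""Vehicle-control normalization of raw well signals.

Every treatment effect is expressed relative to the mean of the solvent-only
(vehicle) wells of the same plate, readout and timepoint, so a normalized
value of 1 means "indistinguishable from untreated" and 0.4 means 40% of the
vehicle signal.  Kinetic imaging readouts are additionally referenced to
their own time-zero baseline, giving fold-growth of treated wells relative
to fold-growth of vehicle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DesignError
from .screen_model import ScreenDataset

__all__ = ["NormalizedValue", "normalize_to_vehicle", "normalize_kinetic",
           "normalize_dataset"]


@dataclass(frozen=True)
class NormalizedValue:
    """A unitless relative response (vehicle = 1)."""

    value: float
    basis: str  # "vehicle" or "vehicle_and_t0"
    n_vehicle: int


def _vehicle_mean(vehicle_values: Sequence[float], what: str) -> float:
    vals = np.asarray(list(vehicle_values), dtype=float)
    if vals.size == 0:
        raise DesignError(f"no vehicle wells available for {what}")
    mean = float(vals.mean())
    if mean <= 0:
        raise DesignError(f"nonpositive vehicle mean ({mean}) for {what}: assay failure")
    return mean


def normalize_to_vehicle(raw: float, vehicle_values: Sequence[float]) -> NormalizedValue:
    """raw signal / mean(vehicle signals) from the same plate, readout, timepoint."""
    mean = _vehicle_mean(vehicle_values, "normalization")
    return NormalizedValue(value=float(raw) / mean, basis="vehicle",
                           n_vehicle=len(list(vehicle_values)))


def normalize_kinetic(raw_t: float, raw_0: float,
                      vehicle_t: Sequence[float],
                      vehicle_0: Sequence[float]) -> NormalizedValue:
    """Fold-growth of a treated well relative to fold-growth of vehicle.

    value = (raw_t / raw_0) / (mean(vehicle_t) / mean(vehicle_0)).
    """
    if raw_0 <= 0:
        raise DesignError("zero or negative time-zero baseline for treated well")
    v0 = _vehicle_mean(vehicle_0, "kinetic baseline")
    vt = _vehicle_mean(vehicle_t, "kinetic endpoint")
    growth_vehicle = vt / v0
    if growth_vehicle <= 0:
        raise DesignError("nonpositive vehicle growth ratio")
    value = (float(raw_t) / float(raw_0)) / growth_vehicle
    n = min(len(list(vehicle_t)), len(list(vehicle_0)))
    return NormalizedValue(value=value, basis="vehicle_and_t0", n_vehicle=n)


def normalize_dataset(dataset: ScreenDataset) -> pd.DataFrame:
    """Normalize every well of a screen to its plate's vehicle mean.

    Vehicle wells are matched per (plate, readout, timepoint).  Returns a copy
    of the records frame with two extra columns, ``norm_value`` and
    ``n_vehicle``.  Positive-control wells are normalized like any other well
    and are meant for QC reporting only.
    """
    df = dataset.records.copy()
    group_cols = ["plate_id", "readout", "timepoint"]
    veh = df[df["role"] == "vehicle"]
    stats = veh.groupby(group_cols)["value"].agg(["mean", "count"])
    empty = [k for k in df.groupby(group_cols).groups if k not in stats.index]
    if empty:
        raise DesignError(f"no vehicle wells on plate group(s): {empty[:5]}")
    bad = stats[stats["mean"] <= 0]
    if len(bad):
        raise DesignError(
            f"nonpositive vehicle mean on plate group(s): {list(bad.index[:5])}")
    merged = df.merge(stats, left_on=group_cols, right_index=True, how="left")
    df["norm_value"] = (merged["value"] / merged["mean"]).to_numpy()
    df["n_vehicle"] = merged["count"].astype(int).to_numpy()
    return df
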