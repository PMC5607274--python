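"""Plate-based triage: replicate summaries and the two screening stages.

The first screen passes a compound when its mean inhibition over
replicate wells is (a) above an absolute floor (25% by default) and
(b) above its plate's mean plus three plate standard deviations, where
plate statistics are computed over the per-compound means of that plate
with control wells excluded.  The plate-wise rule makes hit calling
robust to additive plate effects that a global threshold would not be.
The second screen re-assays first-screen passes and keeps compounds
whose mean exceeds a fixed threshold (~50%).  All inequalities are
strict ("greater than").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ScreeningError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlateStatistics:
    """Per-plate screening statistics over per-compound means."""

    plate_id: str
    n_compounds: int
    plate_mean: float
    plate_sd: float
    abs_threshold: float
    k_sd: float

    @property
    def cutoff(self) -> float:
        return self.plate_mean + self.k_sd * self.plate_sd


def summarize_replicates(plate_data: pd.DataFrame) -> pd.DataFrame:
    """Per-compound replicate summaries: mean and sample (n-1) SD.

    ``plate_data`` is well-level (columns ``plate_id``, ``well_id``,
    ``role``, ``compound_id``, ``inhibition_pct``); control wells are
    ignored.  A compound split across plates within one stage violates
    the layout and raises.  A single-replicate compound gets SD 0 with a
    logged warning.
    """
    for col in ("plate_id", "role", "compound_id", "inhibition_pct"):
        if col not in plate_data.columns:
            raise InputError(f"plate table lacks column {col!r}")
    wells = plate_data[plate_data["role"] == "compound"]
    if (wells["compound_id"].astype(str) == "").any():
        raise InputError("compound well without a compound id")
    plates_per_compound = wells.groupby("compound_id")["plate_id"].nunique()
    split = plates_per_compound[plates_per_compound > 1]
    if not split.empty:
        raise InputError(
            f"compound(s) split across plates: {sorted(split.index.tolist())}"
        )
    rows = []
    for (cid, pid), grp in wells.groupby(["compound_id", "plate_id"], sort=True):
        vals = grp["inhibition_pct"].to_numpy(dtype=float)
        if len(vals) == 1:
            logger.warning("compound %s has a single replicate; SD set to 0", cid)
            sd = 0.0
        else:
            sd = float(np.std(vals, ddof=1))
        rows.append((cid, pid, len(vals), float(np.mean(vals)), sd))
    return pd.DataFrame(rows, columns=["compound_id", "plate_id", "n_replicates",
                                       "mean", "sd"])


def first_screen(summaries: pd.DataFrame, abs_threshold: float = 25.0,
                 k_sd: float = 3.0):
    """First-stage triage: absolute floor plus plate mean + k_sd * SD rule.

    Returns ``(verdicts, plate_stats)``; ``verdicts`` adds plate
    statistics and a boolean ``passed`` per compound.  Plates with fewer
    than two compounds have undefined plate SD and raise.
    """
    stats_by_plate = {}
    for pid, grp in summaries.groupby("plate_id", sort=True):
        if len(grp) < 2:
            raise ScreeningError(
                f"plate {pid} has {len(grp)} compound(s); plate SD undefined"
            )
        means = grp["mean"].to_numpy(dtype=float)
        stats_by_plate[pid] = PlateStatistics(
            plate_id=pid, n_compounds=len(grp),
            plate_mean=float(np.mean(means)),
            plate_sd=float(np.std(means, ddof=1)),
            abs_threshold=abs_threshold, k_sd=k_sd,
        )
    out = summaries.copy()
    out["plate_mean"] = out["plate_id"].map(lambda p: stats_by_plate[p].plate_mean)
    out["plate_sd"] = out["plate_id"].map(lambda p: stats_by_plate[p].plate_sd)
    out["passed"] = (out["mean"] > abs_threshold) & (
        out["mean"] > out["plate_mean"] + k_sd * out["plate_sd"]
    )
    return out, stats_by_plate


def second_screen(summaries: pd.DataFrame, threshold: float = 50.0) -> pd.DataFrame:
    """Second-stage triage: pass iff re-assayed mean > threshold (strict)."""
    out = summaries.copy()
    out["passed"] = out["mean"] > threshold
    return out
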