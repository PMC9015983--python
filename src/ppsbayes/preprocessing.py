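"""RT filtering, cell-mean aggregation and VT - TO normalization.

Trials without a response are dropped, then each participant's pooled RTs
are filtered with a 2/3-IQR fence (values outside
[Q1 - (2/3) IQR, Q3 + (2/3) IQR] removed, bounds inclusive, quartiles by
linear interpolation).  Surviving trials are averaged into per-participant
cells (trial type x distance x light x tactile), and the normalized dataset
is the per-cell difference of visuo-tactile minus tactile-only means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IQR_MULTIPLIER",
    "FilterReport",
    "iqr_bounds",
    "iqr_filter",
    "remove_nonresponses",
    "filter_trials",
    "aggregate_cell_means",
    "normalize_vt",
]

#: Fence width in units of the interquartile range.
IQR_MULTIPLIER = 2.0 / 3.0

CELL_KEY = ["participant", "trial_type", "distance", "light_location", "tactile_location"]
NORM_KEY = ["participant", "distance", "light_location", "tactile_location"]


@dataclass
class FilterReport:
    """Per-participant account of the outlier/non-response filtering."""

    rows: list[dict] = field(default_factory=list)

    def add(self, participant, lower, upper, n_removed_outlier, n_removed_nonresponse, n_kept):
        self.rows.append(
            {
                "participant": participant,
                "lower_ms": lower,
                "upper_ms": upper,
                "n_removed_outlier": int(n_removed_outlier),
                "n_removed_nonresponse": int(n_removed_nonresponse),
                "n_kept": int(n_kept),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        cols = ["participant", "lower_ms", "upper_ms", "n_removed_outlier", "n_removed_nonresponse", "n_kept"]
        return pd.DataFrame(self.rows, columns=cols)


def iqr_bounds(rts: Sequence[float], multiplier: float = IQR_MULTIPLIER) -> tuple[float, float]:
    """Inclusive keep-range [Q1 - m*IQR, Q3 + m*IQR] of a pooled RT sample."""
    arr = np.asarray(rts, dtype=float)
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    return q1 - multiplier * iqr, q3 + multiplier * iqr


def iqr_filter(
    rts: Sequence[float], multiplier: float = IQR_MULTIPLIER
) -> tuple[np.ndarray, dict]:
    """Keep RTs inside the participant's IQR fence.

    Returns the kept values (input order preserved) and a report row with
    the bounds and removal counts.  An empty input yields an empty output
    and a zero-count report, not an error.
    """
    arr = np.asarray(rts, dtype=float)
    if arr.size == 0:
        return arr, {"lower_ms": np.nan, "upper_ms": np.nan, "n_removed_outlier": 0, "n_kept": 0}
    lo, hi = iqr_bounds(arr, multiplier)
    keep = (arr >= lo) & (arr <= hi)
    return arr[keep], {
        "lower_ms": float(lo),
        "upper_ms": float(hi),
        "n_removed_outlier": int((~keep).sum()),
        "n_kept": int(keep.sum()),
    }


def remove_nonresponses(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop missed trials and catch trials.

    Catch trials are excluded from RT analyses whether or not the
    participant (falsely) responded to them.
    """
    mask = trials["responded"].astype(bool) & (trials["trial_type"] != "catch")
    return trials.loc[mask].reset_index(drop=True)


def filter_trials(
    trials: pd.DataFrame,
    multiplier: float = IQR_MULTIPLIER,
    per_condition: bool = False,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply non-response removal and the per-participant IQR fence.

    By default the fence is computed on each participant's RTs pooled over
    all conditions and trial types; ``per_condition=True`` instead computes
    it within each participant x trial-type stratum.
    """
    report = FilterReport()
    responded = remove_nonresponses(trials)
    n_nonresp = (
        trials.loc[trials["trial_type"] != "catch"]
        .groupby("participant", sort=True)["responded"]
        .apply(lambda r: int((~r.astype(bool)).sum()))
    )
    kept_parts: list[pd.DataFrame] = []
    for pid, grp in responded.groupby("participant", sort=True):
        strata: Iterable[pd.DataFrame] = (
            (g for _, g in grp.groupby("trial_type", sort=True)) if per_condition else (grp,)
        )
        kept_n = removed = 0
        lo = hi = np.nan
        for g in strata:
            _, rep = iqr_filter(g["rt_ms"].to_numpy(), multiplier)
            mask = (g["rt_ms"] >= rep["lower_ms"]) & (g["rt_ms"] <= rep["upper_ms"])
            kept_parts.append(g.loc[mask])
            kept_n += int(mask.sum())
            removed += int((~mask).sum())
            lo, hi = rep["lower_ms"], rep["upper_ms"]
        report.add(pid, lo, hi, removed, int(n_nonresp.get(pid, 0)), kept_n)
    kept = (
        pd.concat(kept_parts, ignore_index=True)
        if kept_parts
        else responded.iloc[0:0].reset_index(drop=True)
    )
    return kept, report


def aggregate_cell_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean RT per (participant, trial_type, distance, light, tactile) cell.

    Cells left empty by filtering are simply absent from the output; callers
    that need the gap list can compare against their design grid (see
    :func:`normalize_vt`, which reports keys lacking a counterpart).
    """
    if trials.empty:
        return pd.DataFrame(columns=CELL_KEY + ["mean_rt", "n_trials"])
    out = (
        trials.groupby(CELL_KEY, sort=True, dropna=False)["rt_ms"]
        .agg(mean_rt="mean", n_trials="count")
        .reset_index()
    )
    return out[out["n_trials"] >= 1].reset_index(drop=True)


def normalize_vt(cells: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell VT mean minus TO mean for every key where both exist.

    Returns the normalized table (columns ``norm_rt``, ``n_vt``, ``n_to``)
    and a report of keys skipped because one counterpart was missing; no
    imputation is performed.
    """
    vt = cells[cells["trial_type"] == "VT"].set_index(NORM_KEY)
    to = cells[cells["trial_type"] == "TO"].set_index(NORM_KEY)
    joined = vt[["mean_rt", "n_trials"]].join(
        to[["mean_rt", "n_trials"]], how="outer", lsuffix="_vt", rsuffix="_to"
    )
    both = joined.dropna(subset=["mean_rt_vt", "mean_rt_to"])
    norm = both.reset_index()
    norm["norm_rt"] = norm["mean_rt_vt"] - norm["mean_rt_to"]
    norm = norm.rename(columns={"n_trials_vt": "n_vt", "n_trials_to": "n_to"})[
        NORM_KEY + ["norm_rt", "n_vt", "n_to"]
    ]
    norm[["n_vt", "n_to"]] = norm[["n_vt", "n_to"]].astype(int)
    missing = joined[joined[["mean_rt_vt", "mean_rt_to"]].isna().any(axis=1)].reset_index()
    missing["missing"] = np.where(missing["mean_rt_vt"].isna(), "VT", "TO")
    return norm, missing[NORM_KEY + ["missing"]]
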