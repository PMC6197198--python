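"""Dose-change and dose-continuation interval detection.

An interval is a pair of consecutive same-ingredient prescriptions for one
patient, with identical route and unit, at most 20 days apart. The second
dose relative to the first labels the interval:

* reduction — quantity drops without a frequency rise, or frequency drops
  without a quantity rise;
* increase — the mirror image;
* continuation — quantity and frequency both unchanged.

Opposite moves of quantity and frequency are resolved on the daily dose
(quantity x frequency); an exact daily-dose tie is a continuation.

After labelling, outlier intervals are trimmed (all shorter than 6 h, then
the longest until 10% of the pool is removed) and continuations are
restricted to patients who never had a dose change for that ingredient.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .config import AnalysisConfig

log = logging.getLogger(__name__)

LABELS = ("reduction", "increase", "continuation")

INTERVAL_COLUMNS = [
    "interval_id",
    "patient_id",
    "ingredient",
    "t1",
    "t2",
    "dose_quantity1",
    "frequency1",
    "dose_quantity2",
    "frequency2",
    "route",
    "unit",
    "duration_hours",
    "label",
]


def classify_interval(dose1: tuple[float, float],
                      dose2: tuple[float, float]) -> str:
    """Label one candidate interval from its two (quantity, frequency) pairs."""
    q1, f1 = dose1
    q2, f2 = dose2
    if q2 == q1 and f2 == f1:
        return "continuation"
    if (q2 < q1 and f2 <= f1) or (f2 < f1 and q2 <= q1):
        return "reduction"
    if (q2 > q1 and f2 >= f1) or (f2 > f1 and q2 >= q1):
        return "increase"
    # opposite moves: compare daily dose, exact tie -> continuation
    daily1, daily2 = q1 * f1, q2 * f2
    if daily2 < daily1:
        return "reduction"
    if daily2 > daily1:
        return "increase"
    return "continuation"


def _classify_vector(df: pd.DataFrame) -> pd.Series:
    q1, f1 = df["dose_quantity1"].to_numpy(), df["frequency1"].to_numpy()
    q2, f2 = df["dose_quantity2"].to_numpy(), df["frequency2"].to_numpy()
    cont = (q1 == q2) & (f1 == f2)
    red = ((q2 < q1) & (f2 <= f1)) | ((f2 < f1) & (q2 <= q1))
    inc = ((q2 > q1) & (f2 >= f1)) | ((f2 > f1) & (q2 >= q1))
    mixed = ~(cont | red | inc)
    daily1, daily2 = q1 * f1, q2 * f2
    red |= mixed & (daily2 < daily1)
    inc |= mixed & (daily2 > daily1)
    labels = np.where(red, "reduction", np.where(inc, "increase", "continuation"))
    return pd.Series(labels, index=df.index)


def pair_prescriptions(prescriptions: pd.DataFrame,
                       max_days: float = 20.0) -> pd.DataFrame:
    """Form candidate intervals from consecutive same-ingredient
    prescriptions of each patient.

    Pairs with a different route, a different unit, a non-positive gap or a
    gap longer than ``max_days`` are discarded. Consecutiveness guarantees
    no third same-ingredient prescription falls strictly between t1 and t2.
    """
    df = prescriptions.sort_values(
        ["patient_id", "ingredient", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)
    grp = df.groupby(["patient_id", "ingredient"], sort=False)
    nxt = grp.shift(-1)
    cand = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "ingredient": df["ingredient"],
            "t1": df["timestamp"],
            "t2": nxt["timestamp"],
            "dose_quantity1": df["dose_quantity"],
            "frequency1": df["frequency"],
            "dose_quantity2": nxt["dose_quantity"],
            "frequency2": nxt["frequency"],
            "route": df["route"],
            "unit": df["unit"],
            "route2": nxt["route"],
            "unit2": nxt["unit"],
        }
    ).dropna(subset=["t2"])
    gap = cand["t2"] - cand["t1"]
    keep = (
        (cand["route2"] == cand["route"])
        & (cand["unit2"] == cand["unit"])
        & (gap > pd.Timedelta(0))
        & (gap <= pd.Timedelta(days=max_days))
    )
    out = cand[keep].drop(columns=["route2", "unit2"]).reset_index(drop=True)
    out["duration_hours"] = (
        (out["t2"] - out["t1"]).dt.total_seconds() / 3600.0
    )
    return out


def label_intervals(candidates: pd.DataFrame) -> pd.DataFrame:
    out = candidates.copy()
    out["label"] = _classify_vector(out) if len(out) else pd.Series(dtype=object)
    return out


def trim_outliers(
    intervals: pd.DataFrame,
    min_hours: float = 6.0,
    target_fraction: float = 0.10,
    scope: str = "ingredient",
) -> pd.DataFrame:
    """Remove outlier intervals: every interval shorter than ``min_hours``,
    then the longest remaining intervals until ``target_fraction`` of the
    input pool is removed in total.

    With fewer than 10 intervals in a pool, only the short arm is applied
    (a warning is logged). Long-arm ties break deterministically by
    (duration desc, patient_id asc, t1 asc). ``scope="ingredient"`` trims
    within each ingredient's pool; ``"global"`` over the whole table.
    Removal counts per arm are recorded in ``attrs["trim_counts"]``.
    """

    def _trim(pool: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
        n = len(pool)
        short = pool["duration_hours"] < min_hours
        n_short = int(short.sum())
        kept = pool[~short]
        target = math.floor(n * target_fraction)
        n_long = max(0, target - n_short)
        if n < 10:
            if n_long:
                log.warning(
                    "pool of %d intervals: skipping long-side trimming", n
                )
            n_long = 0
        if n_long:
            order = kept.sort_values(
                ["duration_hours", "patient_id", "t1"],
                ascending=[False, True, True],
                kind="mergesort",
            )
            kept = kept.drop(order.index[:n_long])
        return kept, n_short, n_long

    counts = {"short": 0, "long": 0}
    if scope == "global" or intervals.empty:
        kept, n_short, n_long = _trim(intervals)
        counts["short"], counts["long"] = n_short, n_long
    else:
        parts = []
        for _, pool in intervals.groupby("ingredient", sort=False):
            part, n_short, n_long = _trim(pool)
            parts.append(part)
            counts["short"] += n_short
            counts["long"] += n_long
        kept = pd.concat(parts) if parts else intervals
    log.info("outlier trimming removed %d short and %d long interval(s)",
             counts["short"], counts["long"])
    out = kept.sort_index().reset_index(drop=True)
    out.attrs["trim_counts"] = counts
    return out


def select_study_intervals(intervals: pd.DataFrame,
                           scope: str = "ingredient") -> pd.DataFrame:
    """Keep all dose changes, but keep a continuation only when its patient
    never had a dose change — for that ingredient (``scope="ingredient"``)
    or for any drug (``scope="patient"``)."""
    changed = intervals[intervals["label"] != "continuation"]
    if scope == "ingredient":
        changed_keys = set(
            map(tuple, changed[["patient_id", "ingredient"]].itertuples(index=False))
        )
        keys = list(
            map(tuple, intervals[["patient_id", "ingredient"]].itertuples(index=False))
        )
        is_changed_key = pd.Series(
            [k in changed_keys for k in keys], index=intervals.index
        )
    else:
        changed_patients = set(changed["patient_id"])
        is_changed_key = intervals["patient_id"].isin(changed_patients)
    keep = (intervals["label"] != "continuation") | ~is_changed_key
    return intervals[keep].reset_index(drop=True)


def _assign_ids(intervals: pd.DataFrame) -> pd.DataFrame:
    out = intervals.copy()
    out["interval_id"] = [
        f"{p}|{i}|{t.isoformat()}"
        for p, i, t in zip(out["patient_id"], out["ingredient"], out["t1"])
    ]
    return out


def extract_intervals(prescriptions: pd.DataFrame,
                      config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Full extraction: pair, label, trim outliers, restrict continuations.

    Returns one row per study interval with a stable ``interval_id``
    (patient, ingredient and t1 — unique because consecutive pairs share no
    first prescription).
    """
    config = config or AnalysisConfig()
    cand = pair_prescriptions(prescriptions, max_days=config.max_interval_days)
    labelled = label_intervals(cand)
    trimmed = trim_outliers(
        labelled,
        min_hours=config.min_interval_hours,
        target_fraction=config.outlier_fraction,
        scope=config.trim_scope,
    )
    selected = select_study_intervals(trimmed, scope=config.continuation_scope)
    out = _assign_ids(selected)
    return out[INTERVAL_COLUMNS]


def write_intervals(intervals: pd.DataFrame, path) -> None:
    out = intervals.copy()
    for col in ("t1", "t2"):
        out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_intervals(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "ingredient": str})
    for col in ("t1", "t2"):
        df[col] = pd.to_datetime(df[col], format="ISO8601").dt.floor("s")
    return df
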