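"""Per-interval phenotype feature construction.

Each interval is associated with the set of (feature_type, feature_id)
pairs observed in the patient's record strictly before the interval's first
prescription (t1). Diagnosis and condition features are then expanded with
all their is-a ancestors; lab-order features carry no hierarchy and are
never expanded. Features are binary presence — repeat mentions collapse.

Feature sets are held in long form: a DataFrame with columns
``interval_id, feature_type, feature_id`` and one row per present feature.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .config import AnalysisConfig
from .ehr_io import HIERARCHICAL_TYPES, OntologyGraph

log = logging.getLogger(__name__)

FEATURE_SET_COLUMNS = ["interval_id", "feature_type", "feature_id"]


def history_features(
    intervals: pd.DataFrame,
    clinical_events: pd.DataFrame,
    max_lookback_days: float | None = None,
) -> pd.DataFrame:
    """Raw (unexpanded) feature sets: every event of the interval's patient
    with timestamp strictly before t1 (and, when a lookback window is set,
    not older than ``t1 - max_lookback_days``)."""
    if intervals.empty or clinical_events.empty:
        return pd.DataFrame(columns=FEATURE_SET_COLUMNS)
    merged = intervals[["interval_id", "patient_id", "t1"]].merge(
        clinical_events[["patient_id", "feature_id", "feature_type", "timestamp"]],
        on="patient_id",
        how="inner",
    )
    keep = merged["timestamp"] < merged["t1"]
    if max_lookback_days is not None:
        keep &= merged["timestamp"] >= (
            merged["t1"] - pd.Timedelta(days=max_lookback_days)
        )
    out = (
        merged.loc[keep, FEATURE_SET_COLUMNS]
        .drop_duplicates()
        .sort_values(FEATURE_SET_COLUMNS, kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def expand_features(
    feature_sets: pd.DataFrame,
    ontologies: Mapping[str, OntologyGraph],
) -> pd.DataFrame:
    """Union each interval's feature set with all ancestors of its
    hierarchical (diagnosis, condition) features. Lab features never gain
    ancestors. Output is deduplicated and deterministically sorted."""
    if feature_sets.empty:
        return feature_sets.copy()
    parts = [feature_sets[FEATURE_SET_COLUMNS]]
    for ftype in HIERARCHICAL_TYPES:
        graph = ontologies.get(ftype)
        if graph is None or len(graph) == 0:
            continue
        sub = feature_sets[feature_sets["feature_type"] == ftype]
        if sub.empty:
            continue
        closure = graph.ancestor_frame(sub["feature_id"].unique())
        if closure.empty:
            continue
        added = sub.merge(closure, on="feature_id", how="inner")
        added = added[["interval_id", "feature_type", "ancestor_id"]].rename(
            columns={"ancestor_id": "feature_id"}
        )
        parts.append(added)
    out = (
        pd.concat(parts, ignore_index=True)
        .drop_duplicates()
        .sort_values(FEATURE_SET_COLUMNS, kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def build_dataset(
    intervals: pd.DataFrame,
    clinical_events: pd.DataFrame,
    ontologies: Mapping[str, OntologyGraph],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """One expanded feature set per interval (long form).

    A patient with no prior events yields an empty feature set (valid);
    intervals with a missing patient reference are a fatal error.
    """
    config = config or AnalysisConfig()
    if not intervals.empty and intervals["patient_id"].isna().any():
        raise ValueError("interval with missing patient reference")
    raw = history_features(
        intervals, clinical_events, max_lookback_days=config.max_lookback_days
    )
    expanded = expand_features(raw, ontologies)
    counts = feature_count_summary(raw, expanded)
    log.info("feature counts (raw -> expanded):\n%s", counts)
    expanded.attrs["count_summary"] = counts
    return expanded


def feature_count_summary(
    raw: pd.DataFrame, expanded: pd.DataFrame
) -> pd.DataFrame:
    """Per-type totals of interval-feature associations before and after
    ontology expansion (the shape of the corpus-size report)."""
    rows = {}
    for name, df in (("before_expansion", raw), ("after_expansion", expanded)):
        if df.empty:
            rows[name] = pd.Series(dtype=int)
        else:
            rows[name] = df.groupby("feature_type").size()
    out = pd.DataFrame(rows).fillna(0).astype(int)
    out.index.name = "feature_type"
    return out


def write_feature_sets(feature_sets: pd.DataFrame, path) -> None:
    feature_sets[FEATURE_SET_COLUMNS].to_csv(path, index=False)


def read_feature_sets(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str)
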