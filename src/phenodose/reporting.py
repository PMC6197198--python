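"""Result tables, profile exports and the ADR disproportionality check."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import EvaluationResult
from .profiles import PhenotypeProfile

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdrDisproportion:
    """Disproportionality of adverse-drug-reaction mentions during dose
    reduction vs continuation intervals (a risk ratio on mention rates)."""

    subject: str
    adr_mentions_reduction: int
    n_reduction: int
    adr_mentions_continuation: int
    n_continuation: int
    rr: float


def adr_disproportionality(
    intervals: pd.DataFrame,
    condition_events: pd.DataFrame,
    adr_codes: Sequence[str],
    subject: str = "",
) -> AdrDisproportion:
    """Count mentions of ADR-classified conditions inside intervals
    (timestamps in the closed window [t1, t2]) and compare the per-interval
    mention rate of the reduction arm with the continuation arm.

    Counting is mention-level: every qualifying event occurrence counts,
    not distinct conditions. A zero mention count in either arm gets the
    Haldane +0.5 correction so the ratio stays finite.
    """
    n_red = int((intervals["label"] == "reduction").sum())
    n_cont = int((intervals["label"] == "continuation").sum())
    if n_cont == 0:
        raise ValueError("zero continuation intervals")
    if n_red == 0:
        raise ValueError("zero reduction intervals")
    adr = condition_events[
        (condition_events["feature_type"] == "condition")
        & condition_events["feature_id"].isin(set(adr_codes))
    ]
    merged = intervals[["patient_id", "t1", "t2", "label"]].merge(
        adr[["patient_id", "timestamp"]], on="patient_id", how="inner"
    )
    inside = (merged["timestamp"] >= merged["t1"]) & (
        merged["timestamp"] <= merged["t2"]
    )
    hits = merged[inside]
    m_red = int((hits["label"] == "reduction").sum())
    m_cont = int((hits["label"] == "continuation").sum())
    mr, mc = float(m_red), float(m_cont)
    if m_red == 0 or m_cont == 0:
        mr, mc = mr + 0.5, mc + 0.5
    rr = (mr / n_red) / (mc / n_cont)
    return AdrDisproportion(
        subject=subject,
        adr_mentions_reduction=m_red,
        n_reduction=n_red,
        adr_mentions_continuation=m_cont,
        n_continuation=n_cont,
        rr=float(rr),
    )


def results_table(results: Iterable[EvaluationResult]) -> pd.DataFrame:
    """One row per subject x outcome with cross-validation and holdout
    metrics side by side, sorted by holdout F-measure descending. Skipped
    runs render as a dash with the reason."""
    rows: dict[tuple[str, str], dict] = {}
    for res in results:
        key = (res.subject, res.outcome)
        row = rows.setdefault(key, {"subject": res.subject, "outcome": res.outcome})
        tag = "cv10" if res.setting == "cv10" else "holdout"
        if res.skipped_reason is not None:
            row[f"{tag}_n"] = res.n_instances
            for metric in ("auc_roc", "f_measure", "precision", "recall"):
                row[f"{tag}_{metric}"] = None
            row[f"{tag}_reason"] = res.skipped_reason
        else:
            row[f"{tag}_n"] = res.n_instances
            row[f"{tag}_auc_roc"] = res.auc_roc
            row[f"{tag}_f_measure"] = res.f_measure
            row[f"{tag}_precision"] = res.precision
            row[f"{tag}_recall"] = res.recall
            row[f"{tag}_reason"] = ""
    df = pd.DataFrame(rows.values())
    if df.empty:
        return df
    df["_sort"] = df.get("holdout_f_measure", pd.Series(dtype=float))
    df = df.sort_values(
        ["_sort", "subject"], ascending=[False, True], na_position="last",
        kind="mergesort",
    ).drop(columns="_sort")
    return df.reset_index(drop=True)


def render_markdown(table: pd.DataFrame, dash: str = "—") -> str:
    """Markdown rendering of a results table; missing metrics show a dash."""
    show = table.copy()
    for col in show.columns:
        if show[col].dtype.kind == "f":
            show[col] = show[col].map(
                lambda v: dash if pd.isna(v) else f"{v:.2f}"
            )
        else:
            show[col] = show[col].map(lambda v: dash if v is None else v)
    return show.to_markdown(index=False)


def ablation_table(results_by_variant: dict[str, Iterable[EvaluationResult]]) -> pd.DataFrame:
    """F-measure per subject for each feature-set variant (e.g. top-100
    diagnostics only, conditions only, labs only, top-300 combined)."""
    frames = {}
    for variant, results in results_by_variant.items():
        frames[variant] = {
            res.subject: res.f_measure for res in results
        }
    out = pd.DataFrame(frames)
    out.index.name = "subject"
    return out.reset_index()


def export_profile_json(profile: PhenotypeProfile, out_path: str | Path) -> None:
    """Write a profile as JSON (the schema behind the profile browser):
    per-feature label, counts, p, Bonferroni threshold, RR, IC and
    direction, in display order (|log RR| descending)."""
    disp = profile.display_frame()
    features = [
        {
            "type": row["feature_type"],
            "id": row["feature_id"],
            "label": row["display_label"],
            "a": int(row["a"]),
            "b": int(row["b"]),
            "c": int(row["c"]),
            "d": int(row["d"]),
            "p": float(row["p_value"]),
            "p_bonferroni_threshold": profile.alpha / profile.bonferroni_m,
            "rr": float(row["rr"]),
            "ic": float(row["ic"]),
            "direction": row["direction"],
        }
        for _, row in disp.iterrows()
    ]
    payload = {
        "subject": profile.subject,
        "outcome": profile.outcome,
        "bonferroni_m": profile.bonferroni_m,
        "alpha": profile.alpha,
        "features": features,
    }
    with open(out_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_profile_json(path: str | Path) -> PhenotypeProfile:
    """Inverse of :func:`export_profile_json` (step counts are not
    serialized; the stats frame returns in p-ascending order)."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    rows = [
        {
            "feature_type": f["type"],
            "feature_id": f["id"],
            "a": f["a"],
            "b": f["b"],
            "c": f["c"],
            "d": f["d"],
            "p_value": f["p"],
            "rr": f["rr"],
            "ic": f["ic"],
            "direction": f["direction"],
            "display_label": f["label"],
        }
        for f in payload["features"]
    ]
    stats = pd.DataFrame(
        rows,
        columns=[
            "feature_type", "feature_id", "a", "b", "c", "d",
            "p_value", "rr", "ic", "direction", "display_label",
        ],
    )
    stats = stats.sort_values(
        ["p_value", "feature_type", "feature_id"], kind="mergesort"
    ).reset_index(drop=True)
    return PhenotypeProfile(
        subject=payload["subject"],
        outcome=payload["outcome"],
        stats=stats,
        bonferroni_m=int(payload["bonferroni_m"]),
        alpha=float(payload["alpha"]),
    )
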