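"""Phenotype-profile construction by enrichment analysis.

A phenotype profile for one subject (drug or drug set) and outcome
(reduction or increase) is the set of features significantly over- or
under-represented in case intervals relative to continuation intervals.
The unit of analysis is the interval, not the patient.

For each feature a 2x2 table is formed::

                    with feature   without
    case intervals       a            b
    control intervals    c            d

and three statistics are computed:

* ``p`` — one-sided hypergeometric tail probability in the direction of
  the observed association (upper tail P(X >= a) when RR >= 1, lower tail
  P(X <= a) otherwise), with population N = a+b+c+d, successes K = a+c and
  draws n = a+b;
* ``RR`` — risk ratio (a/(a+b)) / (c/(c+d)), with the Haldane–Anscombe
  +0.5 correction applied to every cell when a or c is zero;
* ``IC`` — information content −log2(f), f the feature's frequency over
  the corpus of study intervals; screens features too common or too rare.

The filter cascade keeps a feature when it (1) passes the uncorrected
p < 0.05 screen, (2) has RR outside (0.5, 2), (3) has IC inside the
retained band (inter-quartile band of the IC distribution of all tested
features of its type, or a fixed per-type override), (4) stays significant
under Bonferroni correction, and (5) survives elim pruning — a more
general (ancestor) feature is dropped when some more specific feature is
associated at least as significantly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .config import AnalysisConfig
from .ehr_io import HIERARCHICAL_TYPES, OntologyGraph

log = logging.getLogger(__name__)

STATS_COLUMNS = [
    "feature_type", "feature_id", "a", "b", "c", "d",
    "p_value", "rr", "ic", "direction", "display_label",
]

CASCADE_STEPS = [
    "tested", "p_screen", "rr_filter", "ic_filter", "bonferroni", "elim",
]


def contingency_counts(
    feature_sets: pd.DataFrame,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
) -> pd.DataFrame:
    """Exact presence counts per feature over two disjoint interval groups.

    Returns one row per feature observed in either group with columns
    a, b, c, d. Raises when either group is empty.
    """
    case_ids = pd.Index(pd.unique(pd.Series(list(case_ids), dtype=object)))
    control_ids = pd.Index(pd.unique(pd.Series(list(control_ids), dtype=object)))
    if len(case_ids) == 0 or len(control_ids) == 0:
        raise ValueError("empty case or control interval group")
    overlap = case_ids.intersection(control_ids)
    if len(overlap):
        raise ValueError(f"case/control groups overlap: {list(overlap[:3])}")
    n_case, n_control = len(case_ids), len(control_ids)
    sub = feature_sets[feature_sets["interval_id"].isin(case_ids.union(control_ids))]
    if sub.empty:
        return pd.DataFrame(columns=["feature_type", "feature_id", "a", "b", "c", "d"])
    tmp = sub.assign(_in_case=sub["interval_id"].isin(case_ids).astype(int))
    grp = tmp.groupby(["feature_type", "feature_id"], sort=True)["_in_case"]
    a = grp.sum()
    total = grp.size()
    out = pd.DataFrame({"a": a, "c": total - a}).reset_index()
    out["b"] = n_case - out["a"]
    out["d"] = n_control - out["c"]
    return out[["feature_type", "feature_id", "a", "b", "c", "d"]]


def risk_ratio(a, b, c, d):
    """Risk ratio of feature prevalence in cases vs controls.

    Vectorized; applies the Haldane–Anscombe correction (add 0.5 to every
    cell) whenever a or c is zero, keeping the ratio finite and non-zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    corrected = (a == 0) | (c == 0)
    h = np.where(corrected, 0.5, 0.0)
    ah, bh, ch, dh = a + h, b + h, c + h, d + h
    rr = (ah / (ah + bh)) / (ch / (ch + dh))
    return rr if rr.ndim else float(rr)


def hypergeom_pvalue(a, b, c, d, direction=None):
    """Direction-consistent one-sided hypergeometric tail probability.

    ``direction`` is ``"positive"`` (upper tail, P(X >= a)), ``"negative"``
    (lower tail, P(X <= a)), or None to pick the tail from the observed
    proportions (upper when a/(a+b) >= c/(c+d)). Vectorized.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    N = a + b + c + d
    K = a + c
    n = a + b
    if direction is None:
        upper = a * (c + d) >= c * (a + b)
    elif isinstance(direction, str):
        upper = np.full(a.shape, direction == "positive")
    else:
        upper = np.asarray([dd == "positive" for dd in direction])
    p_upper = hypergeom.sf(a - 1, N, K, n)
    p_lower = hypergeom.cdf(a, N, K, n)
    p = np.where(upper, p_upper, p_lower)
    p = np.clip(p, 0.0, 1.0)
    return p if p.ndim else float(p)


def information_content(
    feature_sets: pd.DataFrame,
    corpus_ids: Sequence[str],
) -> pd.DataFrame:
    """IC = −log2(corpus frequency) per feature, over the given corpus of
    intervals (intervals with empty feature sets count in the denominator)."""
    corpus_ids = pd.Index(pd.unique(pd.Series(list(corpus_ids), dtype=object)))
    n_corpus = len(corpus_ids)
    if n_corpus == 0:
        raise ValueError("empty corpus")
    sub = feature_sets[feature_sets["interval_id"].isin(corpus_ids)]
    counts = sub.groupby(["feature_type", "feature_id"], sort=True).size()
    out = counts.rename("n_with").reset_index()
    out["frequency"] = out["n_with"] / n_corpus
    out["ic"] = -np.log2(out["frequency"])
    return out


def ic_bands(
    ic_table: pd.DataFrame,
    fixed_bands: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    """Retained IC band per feature type: the inter-quartile band (Q1, Q3)
    of the IC distribution of all tested features of that type, unless a
    fixed override is configured."""
    fixed_bands = fixed_bands or {}
    bands: dict[str, tuple[float, float]] = {}
    for ftype, grp in ic_table.groupby("feature_type"):
        if ftype in fixed_bands:
            lo, hi = fixed_bands[ftype]
        else:
            lo = float(np.quantile(grp["ic"], 0.25))
            hi = float(np.quantile(grp["ic"], 0.75))
        bands[str(ftype)] = (lo, hi)
    return bands


def elim_filter(stats: pd.DataFrame, ontology: OntologyGraph) -> pd.DataFrame:
    """Ontology-aware pruning of one feature type's statistics.

    A feature g is removed iff some feature f in the input list has g among
    its strict ancestors and p(g) >= p(f) — i.e. a more specific feature is
    at least as significant. Decisions are taken in a single pass against
    the original list (no iterative re-testing). An empty ontology (labs)
    is a no-op.
    """
    if stats.empty or len(ontology) == 0:
        return stats.reset_index(drop=True)
    pvals = dict(zip(stats["feature_id"], stats["p_value"]))
    present = set(pvals)
    removed: set[str] = set()
    for fid, p_f in pvals.items():
        for anc in ontology.ancestors(fid):
            if anc in present and anc != fid and pvals[anc] >= p_f:
                removed.add(anc)
    keep = ~stats["feature_id"].isin(removed)
    return stats[keep].reset_index(drop=True)


@dataclass
class PhenotypeProfile:
    """Filtered, ordered feature statistics for one subject x outcome."""

    subject: str
    outcome: str
    stats: pd.DataFrame
    bonferroni_m: int
    alpha: float = 0.05
    step_counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def is_empty(self) -> bool:
        return len(self.stats) == 0

    @property
    def features(self) -> list[tuple[str, str]]:
        return list(zip(self.stats["feature_type"], self.stats["feature_id"]))

    def display_frame(self) -> pd.DataFrame:
        """Features ordered for presentation by |log RR| descending
        (ties: p ascending, then feature id)."""
        df = self.stats.copy()
        df["_mag"] = np.abs(np.log(df["rr"].astype(float)))
        df = df.sort_values(
            ["_mag", "p_value", "feature_type", "feature_id"],
            ascending=[False, True, True, True],
            kind="mergesort",
        ).drop(columns="_mag")
        return df.reset_index(drop=True)


def _finalize_stats(stats: pd.DataFrame, rr_low: float) -> pd.DataFrame:
    out = stats.copy()
    out["direction"] = np.where(out["rr"] <= rr_low, "negative", "positive")
    out["display_label"] = np.where(
        out["direction"] == "negative",
        "NO " + out["feature_id"].astype(str),
        out["feature_id"].astype(str),
    )
    return out


def compute_feature_stats(
    feature_sets: pd.DataFrame,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    corpus_ids: Sequence[str] | None = None,
    rr_low: float = 0.5,
) -> pd.DataFrame:
    """Counts, p, RR and IC for every feature observed in the two groups."""
    counts = contingency_counts(feature_sets, case_ids, control_ids)
    if counts.empty:
        return pd.DataFrame(columns=STATS_COLUMNS)
    counts["rr"] = risk_ratio(counts["a"], counts["b"], counts["c"], counts["d"])
    counts["p_value"] = hypergeom_pvalue(
        counts["a"], counts["b"], counts["c"], counts["d"]
    )
    if corpus_ids is None:
        corpus_ids = list(case_ids) + list(control_ids)
    ic = information_content(feature_sets, corpus_ids)
    merged = counts.merge(
        ic[["feature_type", "feature_id", "ic"]],
        on=["feature_type", "feature_id"],
        how="left",
    )
    return _finalize_stats(merged, rr_low)[STATS_COLUMNS]


def build_profile(
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    feature_sets: pd.DataFrame,
    ontologies: Mapping[str, OntologyGraph],
    config: AnalysisConfig | None = None,
    subject: str = "",
    outcome: str = "reduction",
    corpus_ids: Sequence[str] | None = None,
) -> PhenotypeProfile:
    """Run the full filter cascade and return the phenotype profile.

    ``corpus_ids`` is the interval corpus over which IC is computed; it
    defaults to case + control intervals of this subject. Per-step survivor
    counts per feature type are kept in ``profile.step_counts``.
    """
    config = config or AnalysisConfig()
    stats = compute_feature_stats(
        feature_sets, case_ids, control_ids,
        corpus_ids=corpus_ids, rr_low=config.rr_low,
    )
    counts_log: dict[str, pd.Series] = {}

    def _record(step: str, df: pd.DataFrame) -> None:
        counts_log[step] = (
            df.groupby("feature_type").size() if len(df) else pd.Series(dtype=int)
        )

    _record("tested", stats)
    m_tested = len(stats)

    step1 = stats[stats["p_value"] < config.p_screen]
    _record("p_screen", step1)

    weak = (step1["rr"] > config.rr_low) & (step1["rr"] < config.rr_high)
    step2 = step1[~weak]
    _record("rr_filter", step2)

    bands = ic_bands(
        stats[["feature_type", "ic"]].rename(columns={"ic": "ic"}),
        fixed_bands=config.ic_fixed_bands,
    ) if len(stats) else {}
    if len(step2):
        lo = step2["feature_type"].map(lambda t: bands.get(t, (-np.inf, np.inf))[0])
        hi = step2["feature_type"].map(lambda t: bands.get(t, (-np.inf, np.inf))[1])
        step3 = step2[(step2["ic"] > lo) & (step2["ic"] < hi)]
    else:
        step3 = step2
    _record("ic_filter", step3)

    m = m_tested if config.bonferroni_scope == "tested" else len(step3)
    m = max(m, 1)
    step4 = step3[step3["p_value"] < config.alpha / m]
    _record("bonferroni", step4)

    parts = []
    for ftype, grp in step4.groupby("feature_type", sort=True):
        graph = ontologies.get(str(ftype))
        if str(ftype) in HIERARCHICAL_TYPES and graph is not None:
            parts.append(elim_filter(grp.reset_index(drop=True), graph))
        else:
            parts.append(grp.reset_index(drop=True))
    step5 = (
        pd.concat(parts, ignore_index=True) if parts
        else step4.reset_index(drop=True)
    )
    _record("elim", step5)

    step_counts = (
        pd.DataFrame(counts_log).T.fillna(0).astype(int).reindex(CASCADE_STEPS)
        .fillna(0).astype(int)
    )
    step_counts.index.name = "step"

    ordered = step5.sort_values(
        ["p_value", "feature_type", "feature_id"], kind="mergesort"
    ).reset_index(drop=True)
    if ordered.empty:
        log.info("%s/%s: empty phenotype profile", subject, outcome)
    return PhenotypeProfile(
        subject=subject,
        outcome=outcome,
        stats=ordered,
        bonferroni_m=int(m),
        alpha=config.alpha,
        step_counts=step_counts,
    )


def top_k_per_type(profile: PhenotypeProfile, k: int = 100) -> PhenotypeProfile:
    """Keep the k smallest-p features of each type (ties: |log RR|
    descending, then feature id ascending)."""
    df = profile.stats.copy()
    if df.empty:
        return replace(profile)
    df["_mag"] = np.abs(np.log(df["rr"].astype(float)))
    df = df.sort_values(
        ["feature_type", "p_value", "_mag", "feature_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    kept = df.groupby("feature_type", sort=True).head(k).drop(columns="_mag")
    kept = kept.sort_values(
        ["p_value", "feature_type", "feature_id"], kind="mergesort"
    ).reset_index(drop=True)
    return replace(profile, stats=kept)
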