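"""Balanced random-forest prediction of dose changes with per-training-set
feature selection.

Two evaluation protocols are provided:

* stratified 10-fold cross-validation in which the whole profile cascade
  (and the per-type top-k selection) is recomputed on the nine training
  folds of each split — test intervals never contribute to the contingency
  counts that select their fold's features;
* hold-last-year-out: profiles and the forest are built on intervals whose
  t1 falls before a cutoff calendar year, and scored on the cutoff year.

Training sets are balanced by undersampling the majority class. The forest
uses 100 trees, unlimited depth and int(log2(m) + 1) candidate features per
split for m profile features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .config import AnalysisConfig
from .ehr_io import OntologyGraph
from .profiles import PhenotypeProfile, build_profile, top_k_per_type

log = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    """Aggregated metrics of one evaluation run.

    ``f_measure`` is the harmonic mean of the aggregated precision and
    recall; ``n_instances`` counts training instances only (averaged over
    folds for cross-validation). Per-fold values, the per-fold profile
    feature lists and the per-fold training interval ids are retained for
    leakage auditing.
    """

    subject: str
    outcome: str
    setting: str
    n_instances: float = 0.0
    auc_roc: float | None = None
    precision: float | None = None
    recall: float | None = None
    f_measure: float | None = None
    per_fold: dict = field(default_factory=dict)
    fold_features: list = field(default_factory=list)
    fold_train_ids: list = field(default_factory=list)
    skipped_reason: str | None = None


def check_eligibility(
    n_case: int,
    n_control: int,
    profile: PhenotypeProfile | None,
    n_prescriptions: int,
    config: AnalysisConfig | None = None,
) -> tuple[bool, str]:
    """Subject inclusion rules: enough case and control intervals, a
    non-empty phenotype profile, and a drug not prescribed so often that it
    would dominate the corpus."""
    config = config or AnalysisConfig()
    if n_case < config.min_case_intervals:
        return False, "min case count"
    if n_control < config.min_control_intervals:
        return False, "min control count"
    if profile is None or profile.is_empty:
        return False, "empty profile"
    if n_prescriptions > config.max_prescription_count:
        return False, "prescription volume cap"
    return True, "eligible"


def encode_matrix(
    interval_ids: Sequence[str],
    features: Sequence[tuple[str, str]],
    feature_sets: pd.DataFrame,
    universe: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Binary interval x feature matrix over exactly the given profile
    features (column order preserved; rows follow ``interval_ids``).

    When a feature universe is supplied, a profile feature outside it is a
    fatal error (guards against features leaking in from outside the
    training data's vocabulary).
    """
    if universe is not None:
        missing = [f for f in features if f not in universe]
        if missing:
            raise ValueError(f"profile features outside universe: {missing[:5]}")
    cols = [f"{t}:{i}" for t, i in features]
    ids = pd.Index(interval_ids)
    if len(features) == 0:
        return pd.DataFrame(index=ids, columns=cols, dtype=np.int8)
    want = pd.MultiIndex.from_tuples(features)
    sub = feature_sets[feature_sets["interval_id"].isin(ids)]
    sub = sub.set_index(["feature_type", "feature_id"])
    sub = sub[sub.index.isin(want)].reset_index()
    if sub.empty:
        mat = pd.DataFrame(0, index=ids, columns=cols, dtype=np.int8)
        return mat
    sub["_col"] = sub["feature_type"] + ":" + sub["feature_id"]
    pres = pd.crosstab(sub["interval_id"], sub["_col"]).clip(upper=1)
    mat = pres.reindex(index=ids, columns=cols, fill_value=0).astype(np.int8)
    return mat


def balance(
    interval_ids: Sequence[str],
    labels: Sequence[int],
    seed: int | np.random.Generator,
) -> list[str]:
    """Undersample the majority class without replacement to the minority
    size; returns the retained interval ids (seeded, deterministic)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ids = np.asarray(interval_ids, dtype=object)
    y = np.asarray(labels)
    pos, neg = ids[y == 1], ids[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("cannot balance: a class is empty")
    k = min(len(pos), len(neg))
    pos_kept = pos if len(pos) == k else rng.choice(pos, size=k, replace=False)
    neg_kept = neg if len(neg) == k else rng.choice(neg, size=k, replace=False)
    return list(pos_kept) + list(neg_kept)


def split_features_per_tree(m: int) -> int:
    """Candidate features per split: int(log2(m) + 1)."""
    if m <= 0:
        raise ValueError("cannot train on zero features")
    return int(math.log2(m) + 1)


def train_rf(
    X: pd.DataFrame,
    y: Sequence[int],
    seed: int,
    n_estimators: int = 100,
) -> RandomForestClassifier:
    """Random forest with the study's hyper-parameters: ``n_estimators``
    trees, unlimited depth, int(log2(m)+1) features per split."""
    m = X.shape[1]
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=None,
        max_features=min(split_features_per_tree(m), m),
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    model.fit(X.to_numpy(), np.asarray(y))
    return model


def _fold_metrics(y_true, scores) -> dict:
    auc = roc_auc_score(y_true, scores)
    pred = (np.asarray(scores) >= 0.5).astype(int)
    prec, rec, _, _ = precision_recall_fscore_support(
        y_true, pred, average="macro", zero_division=0.0
    )
    return {"auc_roc": float(auc), "precision": float(prec),
            "recall": float(rec)}


def _chance_metrics() -> dict:
    # an empty training-fold profile carries no information: score 0.5
    return {"auc_roc": 0.5, "precision": 0.5, "recall": 0.5}


def _select_profile(
    case_train: list[str],
    control_train: list[str],
    feature_sets: pd.DataFrame,
    ontologies: Mapping[str, OntologyGraph],
    config: AnalysisConfig,
    subject: str,
    outcome: str,
) -> PhenotypeProfile:
    profile = build_profile(
        case_train, control_train, feature_sets, ontologies, config,
        subject=subject, outcome=outcome,
        corpus_ids=case_train + control_train,
    )
    if config.profile_variant == "top_k":
        profile = top_k_per_type(profile, config.top_k_per_type)
    return profile


def _aggregate(
    result: EvaluationResult, folds: list[dict], train_sizes: list[int]
) -> EvaluationResult:
    result.per_fold = {
        key: [f[key] for f in folds] for key in ("auc_roc", "precision", "recall")
    }
    result.auc_roc = float(np.mean(result.per_fold["auc_roc"]))
    result.precision = float(np.mean(result.per_fold["precision"]))
    result.recall = float(np.mean(result.per_fold["recall"]))
    p, r = result.precision, result.recall
    result.f_measure = 0.0 if p + r == 0 else float(2 * p * r / (p + r))
    result.n_instances = float(np.mean(train_sizes))
    return result


def cross_validate_10fold(
    intervals: pd.DataFrame,
    feature_sets: pd.DataFrame,
    ontologies: Mapping[str, OntologyGraph],
    config: AnalysisConfig | None = None,
    seed: int = 0,
    subject: str = "",
    outcome: str = "reduction",
) -> EvaluationResult:
    """Stratified k-fold evaluation with per-fold profile construction.

    ``intervals`` must carry ``interval_id`` and ``label`` columns; case
    intervals are those labelled ``outcome``, controls are continuations.
    The balanced set is drawn first (seeded), folds are stratified on the
    class label, and within each fold the profile cascade and top-k
    selection see the training intervals only.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    case_ids = intervals.loc[intervals["label"] == outcome, "interval_id"]
    control_ids = intervals.loc[
        intervals["label"] == "continuation", "interval_id"
    ]
    ids = list(case_ids) + list(control_ids)
    y = [1] * len(case_ids) + [0] * len(control_ids)
    if config.balance_mode == "before":
        kept = set(balance(ids, y, rng))
        ids, y = zip(*[(i, lab) for i, lab in zip(ids, y) if i in kept])
        ids, y = list(ids), list(y)
    ids_arr = np.asarray(ids, dtype=object)
    y_arr = np.asarray(y)
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True,
        random_state=int(rng.integers(2**31)),
    )
    result = EvaluationResult(subject=subject, outcome=outcome, setting="cv10")
    folds, train_sizes = [], []
    universe = set(zip(feature_sets["feature_type"], feature_sets["feature_id"]))
    for train_idx, test_idx in skf.split(ids_arr, y_arr):
        train_ids, test_ids = ids_arr[train_idx], ids_arr[test_idx]
        y_train, y_test = y_arr[train_idx], y_arr[test_idx]
        if config.balance_mode == "per-fold":
            kept = set(balance(train_ids, y_train, rng))
            mask = np.array([i in kept for i in train_ids])
            train_ids, y_train = train_ids[mask], y_train[mask]
        case_train = list(train_ids[y_train == 1])
        control_train = list(train_ids[y_train == 0])
        profile = _select_profile(
            case_train, control_train, feature_sets, ontologies, config,
            subject, outcome,
        )
        result.fold_features.append(profile.features)
        result.fold_train_ids.append(set(train_ids))
        train_sizes.append(len(train_ids))
        if profile.is_empty:
            folds.append(_chance_metrics())
            continue
        X_train = encode_matrix(train_ids, profile.features, feature_sets,
                                universe=universe)
        X_test = encode_matrix(test_ids, profile.features, feature_sets,
                               universe=universe)
        model = train_rf(X_train, y_train, seed=int(rng.integers(2**31)),
                         n_estimators=config.n_estimators)
        scores = model.predict_proba(X_test.to_numpy())[:, 1]
        folds.append(_fold_metrics(y_test, scores))
    return _aggregate(result, folds, train_sizes)


def holdout_last_year(
    intervals: pd.DataFrame,
    feature_sets: pd.DataFrame,
    ontologies: Mapping[str, OntologyGraph],
    config: AnalysisConfig | None = None,
    seed: int = 0,
    subject: str = "",
    outcome: str = "reduction",
    cutoff_year: int | None = None,
) -> EvaluationResult:
    """Temporal validation: train on intervals with t1 before the cutoff
    year, test on intervals with t1 in the cutoff year. Both sides are
    balanced independently; the profile is built on the training side only.
    An empty training-side profile skips the subject with a reason.
    """
    config = config or AnalysisConfig()
    cutoff_year = cutoff_year if cutoff_year is not None else config.holdout_year
    rng = np.random.default_rng(seed)
    years = pd.DatetimeIndex(intervals["t1"]).year
    is_case = intervals["label"] == outcome
    is_ctrl = intervals["label"] == "continuation"
    pre = years < cutoff_year
    post = years == cutoff_year
    result = EvaluationResult(subject=subject, outcome=outcome, setting="holdout")

    def _side(mask) -> tuple[list[str], np.ndarray]:
        side_ids = list(intervals.loc[mask & is_case, "interval_id"]) + list(
            intervals.loc[mask & is_ctrl, "interval_id"]
        )
        side_y = [1] * int((mask & is_case).sum()) + [0] * int((mask & is_ctrl).sum())
        if not side_ids or min(sum(side_y), len(side_y) - sum(side_y)) == 0:
            raise ValueError("empty training or test side at cutoff year")
        kept = set(balance(side_ids, side_y, rng))
        pairs = [(i, lab) for i, lab in zip(side_ids, side_y) if i in kept]
        ids, yy = zip(*pairs)
        return list(ids), np.asarray(yy)

    train_ids, y_train = _side(pre)
    test_ids, y_test = _side(post)
    case_train = [i for i, lab in zip(train_ids, y_train) if lab == 1]
    control_train = [i for i, lab in zip(train_ids, y_train) if lab == 0]
    profile = _select_profile(
        case_train, control_train, feature_sets, ontologies, config,
        subject, outcome,
    )
    result.fold_features.append(profile.features)
    result.fold_train_ids.append(set(train_ids))
    if profile.is_empty:
        result.skipped_reason = "empty profile on training side"
        result.n_instances = float(len(train_ids))
        return result
    universe = set(zip(feature_sets["feature_type"], feature_sets["feature_id"]))
    X_train = encode_matrix(train_ids, profile.features, feature_sets,
                            universe=universe)
    X_test = encode_matrix(test_ids, profile.features, feature_sets,
                           universe=universe)
    model = train_rf(X_train, y_train, seed=int(rng.integers(2**31)),
                     n_estimators=config.n_estimators)
    scores = model.predict_proba(X_test.to_numpy())[:, 1]
    return _aggregate(result, [_fold_metrics(y_test, scores)], [len(train_ids)])
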