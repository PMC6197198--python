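"""Analysis configuration.

All thresholds of the pipeline live here with their study defaults, so a
single YAML file fully determines an analysis run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Tunable parameters of the dose-change analysis pipeline.

    Interval extraction
    -------------------
    max_interval_days
        Maximum gap between the two prescriptions delimiting an interval.
    min_interval_hours
        Intervals shorter than this are outliers (short arm).
    outlier_fraction
        Combined fraction of intervals removed by outlier trimming:
        sub-``min_interval_hours`` intervals first, then the longest
        intervals until the fraction is reached.
    trim_scope
        ``"ingredient"``: trimming operates within each ingredient's
        interval pool; ``"global"``: over the whole pool.
    continuation_scope
        ``"ingredient"``: a continuation is kept when the patient never had
        a dose change *for that ingredient*; ``"patient"``: never for any
        ingredient.

    Feature construction
    --------------------
    max_lookback_days
        History window before t1; ``None`` uses the full record.

    Profile construction
    --------------------
    p_screen
        Uncorrected p-value screen applied first.
    rr_low, rr_high
        Features with ``rr_low < RR < rr_high`` are discarded (association
        too weak in either direction).
    ic_band_mode
        ``"quartile"``: keep features whose information content lies within
        the inter-quartile band of the IC distribution of all features
        tested for that type.
    ic_fixed_bands
        Optional per-type ``(low, high)`` IC band overrides, e.g.
        ``{"condition": (4.25, 12.75)}``.
    alpha
        Family-wise error target of the Bonferroni step.
    bonferroni_scope
        ``"tested"``: m = number of features tested for this subject and
        outcome (family-wise control holds under the null);
        ``"surviving"``: m = features entering the correction step.
    top_k_per_type
        Size of the per-type top list for the compact profile variant.

    Classifier & evaluation
    -----------------------
    n_estimators
        Trees in the random forest (depth unlimited; candidate features per
        split are ``int(log2(m) + 1)``).
    n_folds
        Cross-validation folds.
    balance_mode
        ``"before"``: undersample once before fold splitting; ``"per-fold"``:
        balance each training fold independently.
    min_case_intervals / min_control_intervals
        Eligibility floors per subject (together the 300-instance rule).
    max_prescription_count
        Subjects whose drug was prescribed more often than this are
        excluded (dominant-drug bias guard).
    holdout_year
        Calendar year held out for temporal validation; training uses all
        earlier years.
    """

    # interval extraction
    max_interval_days: float = 20.0
    min_interval_hours: float = 6.0
    outlier_fraction: float = 0.10
    trim_scope: str = "ingredient"
    continuation_scope: str = "ingredient"
    # feature construction
    max_lookback_days: float | None = None
    # profile construction
    p_screen: float = 0.05
    rr_low: float = 0.5
    rr_high: float = 2.0
    ic_band_mode: str = "quartile"
    ic_fixed_bands: dict = field(default_factory=dict)
    alpha: float = 0.05
    bonferroni_scope: str = "tested"
    top_k_per_type: int = 100
    profile_variant: str = "top_k"
    # classifier
    n_estimators: int = 100
    n_folds: int = 10
    balance_mode: str = "before"
    min_case_intervals: int = 150
    min_control_intervals: int = 150
    max_prescription_count: int = 55_000
    holdout_year: int = 2014

    def __post_init__(self) -> None:
        if self.trim_scope not in ("ingredient", "global"):
            raise ValueError(f"trim_scope: {self.trim_scope!r}")
        if self.continuation_scope not in ("ingredient", "patient"):
            raise ValueError(f"continuation_scope: {self.continuation_scope!r}")
        if self.bonferroni_scope not in ("tested", "surviving"):
            raise ValueError(f"bonferroni_scope: {self.bonferroni_scope!r}")
        if self.balance_mode not in ("before", "per-fold"):
            raise ValueError(f"balance_mode: {self.balance_mode!r}")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        self.ic_fixed_bands = {
            k: tuple(v) for k, v in dict(self.ic_fixed_bands).items()
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["ic_fixed_bands"] = {
            k: list(v) for k, v in data["ic_fixed_bands"].items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
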