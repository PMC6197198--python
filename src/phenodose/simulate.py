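"""Seeded synthetic EHR corpora with known ground truth.

The generator emulates the data regime the pipeline targets: patients with
prescription chains per ingredient whose consecutive pairs are labelled
reduction / increase / continuation; three clinical-event streams
(diagnosis codes, note-derived condition mentions, lab orders) with
timestamps preceding the first prescription of each pair; DAG-structured
vocabularies for the two hierarchical streams; and planted case/control
feature-frequency differences with configurable risk ratios.

Signal is planted at interval level: for each prescription pair, the
planted features are drawn with the case prevalence when the pair carries
the target label and with the control prevalence otherwise, and their
events are placed strictly inside the history segment preceding that
pair's first prescription. With the default chain length of 2 (one pair
per patient x ingredient) the per-interval planted contrast is exact; with
longer chains the cumulative patient history dilutes it.

Inter-prescription gaps are lognormal, fitted by moment matching to a mean
of 3.64 days and a standard deviation of 4.41 days. Doses move on a
discrete grid (quantity halves or doubles) so interval labels are
unambiguous. "Trap" features are planted at or after t1 with strong label
dependence: any pipeline that leaks post-t1 events into history features
will surface them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .ehr_io import (
    FEATURE_TYPES,
    HIERARCHICAL_TYPES,
    OntologyGraph,
    write_clinical_events,
    write_prescriptions,
)

_SECOND = np.timedelta64(1, "s")
_TYPE_PREFIX = {"diagnosis": "DX", "condition": "CN", "lab": "LAB"}


@dataclass(frozen=True)
class PlantedFeature:
    """A feature with a label-dependent history prevalence.

    ``prev_case`` applies to intervals carrying ``target_label``;
    ``prev_control`` to every other interval and to patients without pairs.
    """

    feature_type: str
    prev_case: float
    prev_control: float
    feature_id: str | None = None
    target_label: str = "reduction"

    @property
    def true_rr(self) -> float:
        return self.prev_case / self.prev_control


def _default_planted() -> tuple[PlantedFeature, ...]:
    # five detectable features, true RR 4, corpus IC ~3.4 (mid-band
    # relative to the default noise IC range of ~[1, 7.6])
    return (
        PlantedFeature("diagnosis", 0.16, 0.04),
        PlantedFeature("diagnosis", 0.16, 0.04),
        PlantedFeature("condition", 0.16, 0.04),
        PlantedFeature("condition", 0.16, 0.04),
        PlantedFeature("lab", 0.16, 0.04),
    )


@dataclass
class SimulationConfig:
    n_patients: int = 1000
    ingredients: tuple[str, ...] = ("DRUG_A",)
    chain_length: int = 2
    p_reduction: float = 0.2
    p_increase: float = 0.2
    gap_mean_days: float = 3.64
    gap_sd_days: float = 4.41
    history_days: float = 365.0
    years_span: tuple[int, int] = (2008, 2014)
    planted_features: tuple[PlantedFeature, ...] = field(
        default_factory=_default_planted
    )
    n_noise_features: Mapping[str, int] = field(
        default_factory=lambda: {"diagnosis": 200, "condition": 200, "lab": 200}
    )
    noise_prevalence_range: tuple[float, float] = (0.005, 0.5)
    ontology_depth: int = 3
    ontology_branching: int = 6
    cross_link_p: float = 0.0
    trap_post_t1: bool = True
    trap_prevalences: tuple[float, float] = (0.5, 0.05)
    adr_rate_reduction: float = 0.10
    adr_rate_continuation: float = 0.05
    adr_codes: tuple[str, ...] = ("ADR_EVENT_1", "ADR_EVENT_2")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_reduction + self.p_increase <= 1:
            raise ValueError("p_reduction + p_increase must be in [0, 1]")
        if self.chain_length < 2:
            raise ValueError("chain_length must be at least 2")
        for pf in self.planted_features:
            if not (0 < pf.prev_case < 1 and 0 < pf.prev_control < 1):
                raise ValueError("planted prevalences must be in (0, 1)")
            if pf.feature_type not in FEATURE_TYPES:
                raise ValueError(f"unknown feature type {pf.feature_type!r}")
        lo, hi = self.noise_prevalence_range
        if not 0 < lo <= hi < 1:
            raise ValueError("noise_prevalence_range must satisfy 0<lo<=hi<1")

    @property
    def target_ingredient(self) -> str:
        return self.ingredients[0]

    @property
    def p_continuation(self) -> float:
        return 1.0 - self.p_reduction - self.p_increase


@dataclass
class GroundTruth:
    """What was planted: per-feature truth, per-pair labels, ADR rates."""

    planted: pd.DataFrame
    pair_labels: pd.DataFrame
    adr: dict
    noise_prevalences: pd.DataFrame
    trap_ids: dict = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    prescriptions: pd.DataFrame
    clinical_events: pd.DataFrame
    ontologies: dict[str, OntologyGraph]
    truth: GroundTruth
    config: SimulationConfig


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given mean and sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def make_ontology(
    depth: int,
    branching: int,
    prefix: str = "N",
    cross_link_p: float = 0.0,
    seed: int = 0,
) -> tuple[OntologyGraph, list[str]]:
    """A rooted is-a tree of the given depth and branching factor, node ids
    ``{prefix}{index}`` in breadth-first order, optionally with extra
    cross-links from a node to a strictly shallower node (keeps the graph
    acyclic). Returns the graph and its leaf list (the deepest level)."""
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    levels: list[list[str]] = [[f"{prefix}0"]]
    counter = 1
    edges: list[tuple[str, str]] = []
    for _ in range(depth):
        nxt: list[str] = []
        for parent in levels[-1]:
            for _ in range(branching):
                node = f"{prefix}{counter}"
                counter += 1
                edges.append((node, parent))
                nxt.append(node)
        levels.append(nxt)
    if cross_link_p > 0:
        shallow: list[str] = list(levels[0])
        for lvl in range(2, depth + 1):
            shallow.extend(levels[lvl - 1])
            for node in levels[lvl]:
                if rng.random() < cross_link_p:
                    target = shallow[int(rng.integers(len(shallow)))]
                    edges.append((node, target))
    return OntologyGraph(edges), levels[-1]


def _assign_feature_ids(config: SimulationConfig) -> dict:
    """Deterministic feature-id layout: planted, trap, then noise ids per
    type; hierarchical types live on ontology leaves, labs are flat codes."""
    ontologies: dict[str, OntologyGraph] = {}
    leaves: dict[str, list[str]] = {}
    for ftype in HIERARCHICAL_TYPES:
        graph, leaf = make_ontology(
            config.ontology_depth,
            config.ontology_branching,
            prefix=_TYPE_PREFIX[ftype],
            cross_link_p=config.cross_link_p,
            seed=config.seed,
        )
        ontologies[ftype] = graph
        leaves[ftype] = leaf
    ontologies["lab"] = OntologyGraph()

    cursor = {ftype: 0 for ftype in FEATURE_TYPES}

    def _next_id(ftype: str) -> str:
        i = cursor[ftype]
        cursor[ftype] += 1
        if ftype in HIERARCHICAL_TYPES:
            pool = leaves[ftype]
            if i >= len(pool):
                raise ValueError(
                    f"ontology for {ftype} has only {len(pool)} leaves; "
                    "increase depth/branching"
                )
            return pool[i]
        return f"{_TYPE_PREFIX[ftype]}_{i:04d}"

    planted_ids = [
        pf.feature_id if pf.feature_id is not None else _next_id(pf.feature_type)
        for pf in config.planted_features
    ]
    trap_ids = {
        ftype: _next_id(ftype) + "_TRAP" if ftype == "lab" else _next_id(ftype)
        for ftype in FEATURE_TYPES
    } if config.trap_post_t1 else {}
    noise_ids = {
        ftype: [_next_id(ftype) for _ in range(int(config.n_noise_features.get(ftype, 0)))]
        for ftype in FEATURE_TYPES
    }
    return {
        "ontologies": ontologies,
        "planted_ids": planted_ids,
        "trap_ids": trap_ids,
        "noise_ids": noise_ids,
    }


def _uniform_times(rng, start: np.ndarray, stop: np.ndarray) -> np.ndarray:
    """Seeded uniform datetimes in [start, stop), second resolution."""
    span = np.maximum(
        ((stop - start) / _SECOND).astype(np.int64), 1
    )
    offs = (rng.random(len(start)) * span).astype(np.int64)
    return start + offs * _SECOND


def simulate_cohort(
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> SimulatedCohort:
    """Generate a cohort: prescription chains with planted pair labels,
    pre-t1 clinical events with planted case/control prevalence contrasts,
    label-independent noise features, post-t1 trap features and in-interval
    ADR mentions. Deterministic for a fixed seed."""
    config = config or SimulationConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    layout = _assign_feature_ids(config)
    n = config.n_patients
    patients = np.array([f"P{i:06d}" for i in range(n)], dtype=object)

    mu, sigma = lognormal_params(
        config.gap_mean_days * 24.0, config.gap_sd_days * 24.0
    )
    year_lo, year_hi = config.years_span
    base = np.datetime64(f"{year_lo}-01-01T00:00:00", "s")
    end = np.datetime64(f"{year_hi}-12-01T00:00:00", "s")
    span_s = int((end - base) / _SECOND)

    presc_frames = []
    pair_rows = []
    chain_times: dict[str, np.ndarray] = {}
    chain_labels: dict[str, np.ndarray] = {}
    n_pairs = config.chain_length - 1
    for ingredient in config.ingredients:
        t0 = base + (rng.integers(0, span_s, size=n)).astype(np.int64) * _SECOND
        gaps_h = rng.lognormal(mu, sigma, size=(n, n_pairs))
        gap_s = np.maximum((gaps_h * 3600.0).astype(np.int64), 1)
        times = np.empty((n, config.chain_length), dtype="datetime64[s]")
        times[:, 0] = t0
        for j in range(n_pairs):
            times[:, j + 1] = times[:, j] + gap_s[:, j] * _SECOND
        labels = rng.choice(
            np.array(["reduction", "increase", "continuation"], dtype=object),
            size=(n, n_pairs),
            p=[config.p_reduction, config.p_increase, config.p_continuation],
        )
        q = np.empty((n, config.chain_length))
        f = np.empty((n, config.chain_length))
        q[:, 0] = rng.choice([10.0, 20.0], size=n)
        f[:, 0] = rng.choice([1.0, 2.0], size=n)
        for j in range(n_pairs):
            move = labels[:, j]
            q[:, j + 1] = np.where(
                move == "reduction", q[:, j] / 2.0,
                np.where(move == "increase", q[:, j] * 2.0, q[:, j]),
            )
            f[:, j + 1] = f[:, j]
        presc_frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(patients, config.chain_length),
                    "ingredient": ingredient,
                    "dose_quantity": q.ravel(),
                    "frequency": f.ravel(),
                    "route": "oral",
                    "unit": "mg",
                    "timestamp": times.ravel(),
                }
            )
        )
        for j in range(n_pairs):
            pair_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": patients,
                        "ingredient": ingredient,
                        "pair_index": j,
                        "t1": times[:, j],
                        "t2": times[:, j + 1],
                        "label": labels[:, j],
                    }
                )
            )
        chain_times[ingredient] = times
        chain_labels[ingredient] = labels

    prescriptions = (
        pd.concat(presc_frames, ignore_index=True)
        .sort_values(["patient_id", "ingredient", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )
    prescriptions["timestamp"] = prescriptions["timestamp"].astype("datetime64[s]")
    pair_labels = pd.concat(pair_rows, ignore_index=True)

    target = config.target_ingredient
    times = chain_times[target]
    labels = chain_labels[target]
    hist_s = int(config.history_days * 86400)

    event_frames = []

    def _events(patient_idx, ftype, fid, start, stop, at_start_mask=None):
        ts = _uniform_times(rng, start, stop)
        if at_start_mask is not None:
            ts = np.where(at_start_mask, start, ts)
        event_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patients[patient_idx],
                    "feature_id": fid,
                    "feature_type": ftype,
                    "timestamp": ts,
                }
            )
        )

    # planted features: per pair, prevalence conditional on the pair label
    for pf, fid in zip(config.planted_features, layout["planted_ids"]):
        for j in range(n_pairs):
            seg_start = (
                times[:, j] - hist_s * _SECOND if j == 0 else times[:, j - 1]
            )
            prev = np.where(
                labels[:, j] == pf.target_label, pf.prev_case, pf.prev_control
            )
            present = rng.random(n) < prev
            idx = np.nonzero(present)[0]
            if len(idx):
                _events(idx, pf.feature_type, fid,
                        seg_start[idx], times[idx, j])

    # trap features: label-dependent but placed AT or AFTER t1 — they must
    # never reach a history feature set
    if config.trap_post_t1:
        prev_case, prev_control = config.trap_prevalences
        for ftype, fid in layout["trap_ids"].items():
            for j in range(n_pairs):
                prev = np.where(
                    labels[:, j] == "reduction", prev_case, prev_control
                )
                present = rng.random(n) < prev
                idx = np.nonzero(present)[0]
                if len(idx):
                    at_t1 = rng.random(len(idx)) < 0.5
                    _events(idx, ftype, fid,
                            times[idx, j], times[idx, j + 1],
                            at_start_mask=at_t1)

    # noise features: label-independent, drawn once per patient in the
    # pre-chain history window
    lo, hi = config.noise_prevalence_range
    noise_rows = []
    hist_start = times[:, 0] - hist_s * _SECOND
    for ftype in FEATURE_TYPES:
        ids = layout["noise_ids"][ftype]
        if not ids:
            continue
        prevs = np.exp(
            rng.uniform(math.log(lo), math.log(hi), size=len(ids))
        )
        noise_rows.extend(
            {"feature_type": ftype, "feature_id": fid, "prevalence": float(p)}
            for fid, p in zip(ids, prevs)
        )
        present = rng.random((len(ids), n)) < prevs[:, None]
        f_idx, p_idx = np.nonzero(present)
        if len(p_idx):
            _events(p_idx, ftype, np.array(ids, dtype=object)[f_idx],
                    hist_start[p_idx], times[p_idx, 0])

    # ADR mentions during target-ingredient intervals
    for j in range(n_pairs):
        rate = np.where(
            labels[:, j] == "reduction",
            config.adr_rate_reduction,
            config.adr_rate_continuation,
        )
        counts = rng.poisson(rate)
        idx = np.repeat(np.arange(n), counts)
        if len(idx):
            codes = np.array(config.adr_codes, dtype=object)[
                rng.integers(0, len(config.adr_codes), size=len(idx))
            ]
            _events(idx, "condition", codes, times[idx, j], times[idx, j + 1])

    clinical_events = (
        pd.concat(event_frames, ignore_index=True)
        if event_frames
        else pd.DataFrame(
            columns=["patient_id", "feature_id", "feature_type", "timestamp"]
        )
    )
    if len(clinical_events):
        clinical_events["timestamp"] = clinical_events["timestamp"].astype(
            "datetime64[s]"
        )
        clinical_events = clinical_events.sort_values(
            ["patient_id", "timestamp", "feature_type", "feature_id"],
            kind="mergesort",
        ).reset_index(drop=True)

    planted = pd.DataFrame(
        {
            "feature_type": [pf.feature_type for pf in config.planted_features],
            "feature_id": layout["planted_ids"],
            "prev_case": [pf.prev_case for pf in config.planted_features],
            "prev_control": [pf.prev_control for pf in config.planted_features],
            "target_label": [pf.target_label for pf in config.planted_features],
            "true_rr": [pf.true_rr for pf in config.planted_features],
        }
    )
    adr_truth = {
        "rate_reduction": config.adr_rate_reduction,
        "rate_continuation": config.adr_rate_continuation,
        "true_ratio": config.adr_rate_reduction / config.adr_rate_continuation,
        "codes": list(config.adr_codes),
    }
    truth = GroundTruth(
        planted=planted,
        pair_labels=pair_labels,
        adr=adr_truth,
        noise_prevalences=pd.DataFrame(noise_rows),
        trap_ids=dict(layout["trap_ids"]),
    )
    return SimulatedCohort(
        prescriptions=prescriptions,
        clinical_events=clinical_events,
        ontologies=layout["ontologies"],
        truth=truth,
        config=config,
    )


def expected_noise_ic_band(config: SimulationConfig) -> tuple[float, float]:
    """Inter-quartile band of the noise-feature IC distribution implied by
    the log-uniform prevalence range (IC is uniform on [-log2 hi, -log2 lo])."""
    lo, hi = config.noise_prevalence_range
    ic_lo, ic_hi = -math.log2(hi), -math.log2(lo)
    width = ic_hi - ic_lo
    return ic_lo + 0.25 * width, ic_lo + 0.75 * width


def truth_report(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Expected detectability of each planted feature, derived from the
    configuration alone: true RR, expected corpus IC (for the case-vs-
    continuation study) and whether the feature should survive the RR and
    IC filters."""
    config = config or SimulationConfig()
    layout = _assign_feature_ids(config)
    w_case = config.p_reduction / (config.p_reduction + config.p_continuation)
    band_lo, band_hi = expected_noise_ic_band(config)
    rows = []
    for pf, fid in zip(config.planted_features, layout["planted_ids"]):
        freq = w_case * pf.prev_case + (1 - w_case) * pf.prev_control
        ic = -math.log2(freq)
        rr_ok = pf.true_rr >= 2.0 or pf.true_rr <= 0.5
        ic_ok = band_lo < ic < band_hi
        rows.append(
            {
                "feature_type": pf.feature_type,
                "feature_id": fid,
                "true_rr": pf.true_rr,
                "expected_corpus_freq": freq,
                "expected_ic": ic,
                "rr_detectable": rr_ok,
                "ic_in_band": ic_ok,
                "detectable": rr_ok and ic_ok,
            }
        )
    return pd.DataFrame(rows)


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write the cohort in the pipeline's input formats plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_prescriptions(cohort.prescriptions, outdir / "prescriptions.csv")
    for ftype in FEATURE_TYPES:
        sub = cohort.clinical_events[
            cohort.clinical_events["feature_type"] == ftype
        ]
        write_clinical_events(sub, outdir / f"events_{ftype}.csv")
    for ftype in HIERARCHICAL_TYPES:
        cohort.ontologies[ftype].to_edge_list(outdir / f"ontology_{ftype}.csv")
    pair_labels = cohort.truth.pair_labels.copy()
    for col in ("t1", "t2"):
        pair_labels[col] = pair_labels[col].astype("datetime64[s]").astype(str)
    payload = {
        "planted": cohort.truth.planted.to_dict(orient="records"),
        "adr": cohort.truth.adr,
        "pair_labels": pair_labels.to_dict(orient="records"),
        "noise_prevalences": cohort.truth.noise_prevalences.to_dict(
            orient="records"
        ),
        "config": _config_payload(cohort.config),
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def _config_payload(config: SimulationConfig) -> dict:
    data = asdict(config)
    data["planted_features"] = [asdict(pf) for pf in config.planted_features]
    data["n_noise_features"] = dict(config.n_noise_features)
    return data
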