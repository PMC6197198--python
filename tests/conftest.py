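"""Shared fixtures: hand-built prescription fixtures, toy ontologies and
small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phenodose import AnalysisConfig, OntologyGraph
from phenodose.simulate import SimulationConfig, simulate_cohort
from phenodose.studies import prepare_study


def _ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(s).floor("s")


def make_prescriptions(rows: list[tuple]) -> pd.DataFrame:
    """rows: (patient, ingredient, quantity, frequency, route, unit, time)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "ingredient", "dose_quantity", "frequency",
            "route", "unit", "timestamp",
        ],
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.floor("s")
    return df


@pytest.fixture(scope="session")
def hand_prescriptions() -> pd.DataFrame:
    """14 prescriptions covering route mismatch, unit mismatch, a >20-day
    gap, a <6 h interval, a mixed quantity/frequency move, and the
    never-changed-patient continuation rule.

    Hand-derived expected study intervals: one reduction (P1), two
    continuations (P2 and the P5 daily-dose tie); P1's own continuation is
    dropped by the never-changed rule, the 3 h increase by the short-arm
    trim, and three pairs never become candidates (route, gap, unit).
    """
    return make_prescriptions([
        # P1: reduction then continuation (continuation dropped later)
        ("P1", "X", 10, 2, "oral", "mg", "2010-01-01 08:00"),
        ("P1", "X", 5, 2, "oral", "mg", "2010-01-03 08:00"),
        ("P1", "X", 5, 2, "oral", "mg", "2010-01-05 08:00"),
        # P2: route mismatch breaks the first pair; iv continuation kept
        ("P2", "X", 10, 1, "oral", "mg", "2010-02-01 08:00"),
        ("P2", "X", 10, 1, "iv", "mg", "2010-02-04 08:00"),
        ("P2", "X", 10, 1, "iv", "mg", "2010-02-10 08:00"),
        # P3: 27-day gap, no candidate
        ("P3", "X", 10, 1, "oral", "mg", "2010-03-01 08:00"),
        ("P3", "X", 5, 1, "oral", "mg", "2010-03-28 08:00"),
        # P4: 3-hour increase, trimmed as too short
        ("P4", "X", 10, 1, "oral", "mg", "2010-04-01 08:00"),
        ("P4", "X", 20, 1, "oral", "mg", "2010-04-01 11:00"),
        # P5: mixed move with equal daily dose -> continuation
        ("P5", "X", 10, 2, "oral", "mg", "2010-05-01 08:00"),
        ("P5", "X", 20, 1, "oral", "mg", "2010-05-05 08:00"),
        # P6: unit mismatch, no candidate
        ("P6", "X", 10, 1, "oral", "mg", "2010-06-01 08:00"),
        ("P6", "X", 5, 1, "oral", "mL", "2010-06-03 08:00"),
    ])


HAND_EXPECTED_LABELS = {"reduction": 1, "continuation": 2}


@pytest.fixture(scope="session")
def chain_ontology() -> OntologyGraph:
    """Stomatitis -> Inflammatory disorder of digestive tract -> Disorder
    of digestive tract."""
    return OntologyGraph([
        ("Stomatitis", "Inflammatory disorder of digestive tract"),
        ("Inflammatory disorder of digestive tract",
         "Disorder of digestive tract"),
    ])


@pytest.fixture(scope="session")
def diamond_ontology() -> OntologyGraph:
    return OntologyGraph([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 600-patient cohort with the default planted
    RR-4 features; shared by invariants tests."""
    cfg = SimulationConfig(
        n_patients=600, p_reduction=0.4, p_increase=0.2, seed=11
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_study(small_cohort):
    acfg = AnalysisConfig()
    intervals, feature_sets = prepare_study(small_cohort, acfg)
    return small_cohort, intervals, feature_sets, acfg


def random_dag(rng: np.random.Generator, n_nodes: int) -> list[tuple[str, str]]:
    """Random DAG edges child->parent; node i may only point at j > i, so
    acyclicity holds by construction."""
    edges = []
    for i in range(n_nodes - 1):
        for j in range(i + 1, n_nodes):
            if rng.random() < min(2.0 / n_nodes, 0.5):
                edges.append((f"n{i}", f"n{j}"))
    return edges


def brute_force_ancestors(edges: list[tuple[str, str]], node: str) -> set[str]:
    """Independent reachability oracle: iterative DFS over the raw edge
    list, no graph library."""
    out_edges: dict[str, list[str]] = {}
    for c, p in edges:
        out_edges.setdefault(c, []).append(p)
    seen: set[str] = set()
    stack = list(out_edges.get(node, []))
    while stack:
        cur = stack.pop()
        if cur in seen:
            continue
        seen.add(cur)
        stack.extend(out_edges.get(cur, []))
    return seen
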