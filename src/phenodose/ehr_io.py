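"""Reading, validating and writing EHR event tables, ontologies and drug sets.

Event tables are plain CSV with a header row:

* prescriptions: ``patient_id,ingredient,dose_quantity,frequency,route,unit,timestamp``
* clinical events: ``patient_id,feature_id,feature_type,timestamp``

Timestamps are ISO-8601 and held internally at second resolution.
Ontologies are directed is-a edge lists (child,parent CSV, or OBO); the lab
vocabulary has no ontology, represented as an empty graph.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

FEATURE_TYPES = ("diagnosis", "condition", "lab")
#: feature types whose vocabulary carries an is-a hierarchy
HIERARCHICAL_TYPES = ("diagnosis", "condition")

PRESCRIPTION_COLUMNS = [
    "patient_id",
    "ingredient",
    "dose_quantity",
    "frequency",
    "route",
    "unit",
    "timestamp",
]
EVENT_COLUMNS = ["patient_id", "feature_id", "feature_type", "timestamp"]


class SchemaError(ValueError):
    """A mandatory column is missing or the file cannot be interpreted."""


class OntologyCycleError(ValueError):
    """The is-a graph contains a cycle (names one member)."""


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    """ISO-8601 -> datetime64[s]; unparseable entries become NaT."""
    ts = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    return ts.dt.floor("s")


def _positive_number(raw: pd.Series) -> pd.Series:
    vals = pd.to_numeric(raw, errors="coerce")
    return vals.where(vals > 0)


def load_prescriptions(path: str | Path) -> pd.DataFrame:
    """Load and validate a prescription event table.

    Rows with unparseable timestamps or non-positive dose_quantity /
    frequency are dropped; their count is logged and recorded in
    ``df.attrs["n_rejected"]`` (1-based data line numbers in
    ``df.attrs["rejected_lines"]``). The result is sorted by
    ``(patient_id, timestamp)``.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in PRESCRIPTION_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = raw[PRESCRIPTION_COLUMNS].copy()
    df["timestamp"] = _parse_timestamps(df["timestamp"])
    df["dose_quantity"] = _positive_number(df["dose_quantity"])
    df["frequency"] = _positive_number(df["frequency"])
    bad = df[["timestamp", "dose_quantity", "frequency"]].isna().any(axis=1)
    bad |= df[["patient_id", "ingredient", "route", "unit"]].isna().any(axis=1)
    rejected = df.index[bad]
    if len(rejected):
        for line in rejected[:10]:
            log.warning("%s: rejected row at data line %d", path, line + 1)
        log.warning("%s: %d malformed row(s) rejected", path, len(rejected))
    out = (
        df[~bad]
        .sort_values(["patient_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )
    out.attrs["n_rejected"] = int(len(rejected))
    out.attrs["rejected_lines"] = [int(i) + 1 for i in rejected]
    return out


def load_clinical_events(
    path: str | Path,
    feature_type: str | None = None,
    semantic_types: Mapping[str, str] | None = None,
    allowed_semantic_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Load a clinical event stream (diagnosis codes, condition mentions or
    lab orders).

    If ``feature_type`` is given, every row must carry it (or the column may
    be absent, in which case it is filled in). When a concept ->
    semantic-type map and an allow-list are both provided, condition events
    whose concept is absent from the allow-list are dropped — mirroring the
    semantic-type screen normally applied by the upstream note annotator.
    """
    raw = pd.read_csv(path, dtype=str)
    cols = EVENT_COLUMNS if "feature_type" in raw.columns else [
        c for c in EVENT_COLUMNS if c != "feature_type"
    ]
    missing = [c for c in cols if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = raw[cols].copy()
    if "feature_type" not in df.columns:
        if feature_type is None:
            raise SchemaError(f"{path}: no feature_type column and none given")
        df["feature_type"] = feature_type
    if feature_type is not None:
        off = df["feature_type"].notna() & (df["feature_type"] != feature_type)
        if off.any():
            raise SchemaError(
                f"{path}: stream declared {feature_type!r} but contains "
                f"{sorted(df.loc[off, 'feature_type'].unique())}"
            )
    unknown_types = set(df["feature_type"].dropna()) - set(FEATURE_TYPES)
    if unknown_types:
        raise SchemaError(f"{path}: unknown feature types {sorted(unknown_types)}")
    df["timestamp"] = _parse_timestamps(df["timestamp"])
    bad = df.isna().any(axis=1)
    rejected = df.index[bad]
    if len(rejected):
        log.warning("%s: %d malformed row(s) rejected", path, len(rejected))
    df = df[~bad]
    n_filtered = 0
    if semantic_types is not None and allowed_semantic_types is not None:
        allowed = set(allowed_semantic_types)
        is_cond = df["feature_type"] == "condition"
        keep = ~is_cond | df["feature_id"].map(
            lambda f: semantic_types.get(f) in allowed
        )
        n_filtered = int((~keep).sum())
        df = df[keep]
    out = (
        df[EVENT_COLUMNS]
        .sort_values(["patient_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )
    out.attrs["n_rejected"] = int(len(rejected))
    out.attrs["n_semantic_filtered"] = n_filtered
    return out


def write_prescriptions(df: pd.DataFrame, path: str | Path) -> None:
    out = df[PRESCRIPTION_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_clinical_events(df: pd.DataFrame, path: str | Path) -> None:
    out = df[EVENT_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


class OntologyGraph:
    """An is-a DAG over a feature vocabulary (edges child -> parent).

    Supports ancestor closure for ontology expansion and elim pruning.
    Feature ids absent from the graph are valid leaves with no ancestors
    (logged once per id). The lab vocabulary is the empty graph.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = ()) -> None:
        g = nx.DiGraph()
        g.add_edges_from((str(c), str(p)) for c, p in edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyCycleError(
                f"is-a graph has a cycle through node {cycle[0][0]!r}"
            )
        self._graph = g
        self._closure: dict[str, frozenset[str]] = {}
        self._warned: set[str] = set()

    @classmethod
    def from_edge_list(cls, path: str | Path) -> "OntologyGraph":
        """Two-column child,parent CSV (header optional: 'child,parent')."""
        path = Path(path)
        if path.stat().st_size == 0:
            return cls()
        df = pd.read_csv(path, dtype=str, header=None)
        if df.shape[1] < 2:
            raise SchemaError(f"{path}: expected two columns child,parent")
        first = (str(df.iloc[0, 0]).lower(), str(df.iloc[0, 1]).lower())
        if first == ("child", "parent"):
            df = df.iloc[1:]
        df = df.dropna()
        return cls(zip(df.iloc[:, 0], df.iloc[:, 1]))

    @classmethod
    def from_obo(cls, path: str | Path) -> "OntologyGraph":
        """OBO file; only is_a edges are used."""
        import obonet

        g = obonet.read_obo(path)
        edges = [
            (c, p) for c, p, key in g.edges(keys=True) if key == "is_a"
        ]
        return cls(edges)

    @classmethod
    def load(cls, path: str | Path) -> "OntologyGraph":
        path = Path(path)
        if path.suffix.lower() == ".obo":
            return cls.from_obo(path)
        return cls.from_edge_list(path)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def parents(self, feature_id: str) -> frozenset[str]:
        if feature_id not in self._graph:
            return frozenset()
        return frozenset(self._graph.successors(feature_id))

    def ancestors(self, feature_id: str) -> frozenset[str]:
        """All strict ancestors of ``feature_id`` (transitive closure,
        excluding the node itself). Unknown ids yield the empty set."""
        cached = self._closure.get(feature_id)
        if cached is not None:
            return cached
        if feature_id not in self._graph:
            if feature_id not in self._warned:
                self._warned.add(feature_id)
                log.info("feature %r not in ontology; treated as isolated leaf",
                         feature_id)
            return frozenset()
        # nx.descendants follows edge direction, i.e. child->parent here
        result = frozenset(nx.descendants(self._graph, feature_id))
        self._closure[feature_id] = result
        return result

    def ancestor_frame(self, feature_ids: Iterable[str]) -> pd.DataFrame:
        """Long table (feature_id, ancestor_id) over the closure of each id."""
        rows: list[tuple[str, str]] = []
        for fid in feature_ids:
            rows.extend((fid, anc) for anc in self.ancestors(fid))
        return pd.DataFrame(rows, columns=["feature_id", "ancestor_id"])

    def to_edge_list(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("child,parent\n")
            for c, p in sorted(self._graph.edges):
                fh.write(f"{c},{p}\n")


def empty_ontologies() -> dict[str, OntologyGraph]:
    """One (empty) ontology per feature type; labs always stay empty."""
    return {ftype: OntologyGraph() for ftype in FEATURE_TYPES}


@dataclass(frozen=True)
class DrugSet:
    """A named group of drug ingredients (e.g. an ATC class or a P450
    enzyme's substrate list)."""

    name: str
    members: tuple[str, ...]
    grouping_criterion: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"drug set {self.name!r} has no members")


def load_drug_sets(path: str | Path) -> list[DrugSet]:
    """Load drug sets from JSON: a mapping set-name -> ingredient array, or
    name -> {"members": [...], "grouping_criterion": "..."}."""
    def _reject_duplicates(pairs):
        seen: set[str] = set()
        for key, _ in pairs:
            if key in seen:
                raise SchemaError(f"{path}: duplicate drug set name {key!r}")
            seen.add(key)
        return dict(pairs)

    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh, object_pairs_hook=_reject_duplicates)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a JSON object of named sets")
    sets: list[DrugSet] = []
    for name, val in raw.items():
        if isinstance(val, dict):
            members = tuple(str(m) for m in val.get("members", []))
            criterion = str(val.get("grouping_criterion", ""))
        else:
            members = tuple(str(m) for m in val)
            criterion = ""
        sets.append(DrugSet(name=name, members=members,
                            grouping_criterion=criterion))
    log.info("%s: %d drug sets over %d ingredients", path, len(sets),
             len({m for s in sets for m in s.members}))
    return sets


def singleton_drug_sets(ingredients: Iterable[str]) -> list[DrugSet]:
    """One DrugSet per individual drug analyzed."""
    return [
        DrugSet(name=ing, members=(ing,), grouping_criterion="single drug")
        for ing in sorted(set(ingredients))
    ]


def write_drug_sets(sets: Sequence[DrugSet], path: str | Path) -> None:
    payload = {
        s.name: {"members": list(s.members),
                 "grouping_criterion": s.grouping_criterion}
        for s in sets
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
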