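"""Enrichment statistics, the filter cascade and elim pruning."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from phenodose import (
    AnalysisConfig,
    OntologyGraph,
    build_profile,
    contingency_counts,
    elim_filter,
    hypergeom_pvalue,
    information_content,
    risk_ratio,
    top_k_per_type,
)
from phenodose.profiles import compute_feature_stats, ic_bands

from conftest import random_dag


def exact_tail(a, b, c, d, upper=True):
    """Integer-arithmetic hypergeometric tail oracle: exact rational sum
    of C(K,k) C(N-K,n-k) / C(N,n), converted to float at the end."""
    N, K, n = a + b + c + d, a + c, a + b
    lo = max(0, n - (N - K))
    hi = min(n, K)
    ks = range(a, hi + 1) if upper else range(lo, a + 1)
    num = sum(comb(K, k) * comb(N - K, n - k) for k in ks)
    return num / comb(N, n)


def _fs(rows):
    return pd.DataFrame(
        rows, columns=["interval_id", "feature_type", "feature_id"]
    )


class TestContingency:
    def test_counts_match_presence(self):
        rows = [(f"c{i}", "lab", "F") for i in range(10)]
        rows += [(f"t{i}", "lab", "F") for i in range(5)]
        fs = _fs(rows)
        cases = [f"c{i}" for i in range(20)]
        controls = [f"t{i}" for i in range(20)]
        out = contingency_counts(fs, cases, controls)
        assert out.iloc[0][["a", "b", "c", "d"]].tolist() == [10, 10, 5, 15]

    def test_empty_group_is_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            contingency_counts(_fs([]), [], ["t1"])

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            contingency_counts(_fs([]), ["x"], ["x"])


class TestHypergeom:
    def test_upper_tail_from_zero_is_one(self):
        assert hypergeom_pvalue(0, 10, 0, 10, "positive") == pytest.approx(1.0)

    def test_extreme_table_equals_reciprocal_binomial(self):
        # all 10 case intervals carry the feature, no control does
        expected = 1 / comb(20, 10)
        assert hypergeom_pvalue(10, 0, 0, 10, "positive") == pytest.approx(
            expected, abs=1e-12
        )

    def test_balanced_table_matches_enumeration(self):
        expected = exact_tail(5, 5, 5, 5, upper=True)
        assert expected == pytest.approx(0.6719, abs=5e-5)
        assert hypergeom_pvalue(5, 5, 5, 5, "positive") == pytest.approx(
            expected, abs=1e-12
        )

    def test_auto_direction_picks_consistent_tail(self):
        # enriched in cases -> upper tail; depleted -> lower tail
        assert hypergeom_pvalue(9, 1, 2, 8) == pytest.approx(
            exact_tail(9, 1, 2, 8, upper=True), abs=1e-12
        )
        assert hypergeom_pvalue(1, 9, 8, 2) == pytest.approx(
            exact_tail(1, 9, 8, 2, upper=False), abs=1e-12
        )

    def test_vectorized_agrees_with_scalar_on_small_sweep(self):
        tables = [
            (a, b, c, d)
            for a in range(4) for b in range(4)
            for c in range(4) for d in range(4)
            if (a + b) and (c + d)
        ]
        arr = np.array(tables)
        vec = hypergeom_pvalue(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])
        for row, p in zip(tables, vec):
            assert p == pytest.approx(hypergeom_pvalue(*row), abs=1e-15)


class TestRiskRatio:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((10, 10, 5, 15), 2.0),
            ((5, 5, 5, 5), 1.0),
            # Haldane: (0.5/11) / (5.5/11)
            ((0, 10, 5, 5), (0.5 / 11) / (5.5 / 11)),
        ],
    )
    def test_values(self, table, expected):
        assert risk_ratio(*table) == pytest.approx(expected, rel=1e-12)

    def test_zero_control_cell_stays_finite(self):
        rr = risk_ratio(5, 5, 0, 10)
        assert np.isfinite(rr) and rr > 1


class TestInformationContent:
    def test_ubiquitous_feature_has_zero_ic(self):
        fs = _fs([(f"i{k}", "lab", "F") for k in range(8)])
        out = information_content(fs, [f"i{k}" for k in range(8)])
        assert out["ic"].iloc[0] == pytest.approx(0.0)

    def test_one_in_1024_gives_ten_bits(self):
        fs = _fs([("i0", "lab", "F")])
        out = information_content(fs, [f"i{k}" for k in range(1024)])
        assert out["ic"].iloc[0] == pytest.approx(10.0)

    def test_band_override_for_conditions(self):
        ic_table = pd.DataFrame({
            "feature_type": ["condition"] * 4 + ["lab"] * 4,
            "ic": [1.0, 2.0, 3.0, 4.0] * 2,
        })
        bands = ic_bands(ic_table, fixed_bands={"condition": (4.25, 12.75)})
        assert bands["condition"] == (4.25, 12.75)
        assert bands["lab"] == (np.quantile([1, 2, 3, 4], 0.25),
                                np.quantile([1, 2, 3, 4], 0.75))


def _stats(rows):
    return pd.DataFrame(rows, columns=["feature_type", "feature_id", "p_value"])


class TestElim:
    def test_parent_with_equal_p_removed(self):
        ont = OntologyGraph([("leaf", "parent")])
        out = elim_filter(
            _stats([("diagnosis", "leaf", 1e-6), ("diagnosis", "parent", 1e-6)]),
            ont,
        )
        assert list(out["feature_id"]) == ["leaf"]

    def test_more_significant_parent_retained(self):
        ont = OntologyGraph([("leaf", "parent")])
        out = elim_filter(
            _stats([("diagnosis", "leaf", 1e-6), ("diagnosis", "parent", 1e-9)]),
            ont,
        )
        assert set(out["feature_id"]) == {"leaf", "parent"}

    def test_empty_ontology_is_noop(self):
        stats = _stats([("lab", "L1", 0.01), ("lab", "L2", 0.5)])
        out = elim_filter(stats, OntologyGraph())
        pd.testing.assert_frame_equal(out, stats)

    def test_matches_brute_force_on_random_dags(self):
        """Single-pass elim equals the all-pairs definition: g goes iff
        some listed descendant f reaches g with p(f) <= p(g)."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(3, 51))
            edges = random_dag(rng, n)
            graph = OntologyGraph(edges)
            nodes = [f"n{i}" for i in range(n)]
            pvals = dict(zip(nodes, rng.random(n)))
            stats = _stats([("diagnosis", f, p) for f, p in pvals.items()])
            got = set(elim_filter(stats, graph)["feature_id"])
            from conftest import brute_force_ancestors

            removed = {
                g for g in nodes
                for f in nodes
                if g in brute_force_ancestors(edges, f) and pvals[g] >= pvals[f]
            }
            assert got == set(nodes) - removed


class TestCascade:
    def test_screen_and_rr_filters(self):
        """A feature failing the p screen and one failing the RR band are
        both excluded; a strong planted feature survives."""
        rng = np.random.default_rng(0)
        rows = []
        cases = [f"c{i}" for i in range(300)]
        controls = [f"t{i}" for i in range(300)]
        # strong: 40% vs 8%; weak-RR: 50% vs 40%; null: 20% both
        for ids, prev_case, prev_ctrl, fid in [
            (None, 0.40, 0.08, "STRONG"),
            (None, 0.50, 0.40, "WEAK_RR"),
            (None, 0.20, 0.20, "NULL"),
        ]:
            for i in range(300):
                if rng.random() < prev_case:
                    rows.append((f"c{i}", "lab", fid))
                if rng.random() < prev_ctrl:
                    rows.append((f"t{i}", "lab", fid))
        # spread of noise features so the IC quartile band is wide
        for k in range(40):
            prev = 0.01 * (k + 1)
            for i in range(300):
                if rng.random() < prev:
                    rows.append((f"c{i}", "lab", f"N{k:02d}"))
                if rng.random() < prev:
                    rows.append((f"t{i}", "lab", f"N{k:02d}"))
        profile = build_profile(cases, controls, _fs(rows), {},
                                subject="drug", outcome="reduction")
        ids = set(profile.stats["feature_id"])
        assert "STRONG" in ids
        assert "WEAK_RR" not in ids and "NULL" not in ids
        sc = profile.step_counts["lab"]
        assert (sc.sort_index(ascending=False).diff().dropna() >= 0).all() or (
            sc.loc["tested"] >= sc.loc["p_screen"] >= sc.loc["rr_filter"]
            >= sc.loc["ic_filter"] >= sc.loc["bonferroni"] >= sc.loc["elim"]
        )

    def test_profile_directionality_invariant(self, small_study):
        cohort, intervals, feature_sets, acfg = small_study
        case = list(intervals.loc[intervals.label == "reduction", "interval_id"])
        ctrl = list(
            intervals.loc[intervals.label == "continuation", "interval_id"]
        )
        profile = build_profile(case, ctrl, feature_sets, cohort.ontologies,
                                acfg, subject="DRUG_A", outcome="reduction")
        rr = profile.stats["rr"]
        assert ((rr >= acfg.rr_high) | (rr <= acfg.rr_low)).all()
        assert (
            profile.stats["p_value"] < acfg.alpha / profile.bonferroni_m
        ).all()
        neg = profile.stats["direction"] == "negative"
        assert (
            profile.stats.loc[neg, "display_label"].str.startswith("NO ")
        ).all()
        assert (
            ~profile.stats.loc[~neg, "display_label"].str.startswith("NO ")
        ).all()

    def test_cascade_counts_are_monotone(self, small_study):
        cohort, intervals, feature_sets, acfg = small_study
        case = list(intervals.loc[intervals.label == "reduction", "interval_id"])
        ctrl = list(
            intervals.loc[intervals.label == "continuation", "interval_id"]
        )
        profile = build_profile(case, ctrl, feature_sets, cohort.ontologies,
                                acfg)
        diffs = profile.step_counts.diff().dropna()
        assert (diffs <= 0).all().all()


class TestTopK:
    def _profile_with(self, n_lab, n_cond=0):
        rng = np.random.default_rng(1)
        rows = [
            ("lab", f"L{i:03d}", i, 10, 1, 10, rng.uniform(1e-9, 1e-3),
             3.0 + i * 0.01, 5.0, "positive", f"L{i:03d}")
            for i in range(n_lab)
        ] + [
            ("condition", f"C{i:03d}", i, 10, 1, 10, rng.uniform(1e-9, 1e-3),
             4.0, 5.0, "positive", f"C{i:03d}")
            for i in range(n_cond)
        ]
        stats = pd.DataFrame(rows, columns=[
            "feature_type", "feature_id", "a", "b", "c", "d",
            "p_value", "rr", "ic", "direction", "display_label",
        ])
        from phenodose.profiles import PhenotypeProfile

        return PhenotypeProfile("s", "reduction", stats, bonferroni_m=100)

    def test_truncates_to_k_per_type(self):
        prof = top_k_per_type(self._profile_with(150, 40), k=100)
        counts = prof.stats["feature_type"].value_counts()
        assert counts["lab"] == 100 and counts["condition"] == 40

    def test_equal_p_tie_broken_by_log_rr_then_id(self):
        from phenodose.profiles import PhenotypeProfile

        stats = pd.DataFrame({
            "feature_type": ["lab"] * 3,
            "feature_id": ["L1", "L2", "L3"],
            "a": [1, 1, 1], "b": [1, 1, 1], "c": [1, 1, 1], "d": [1, 1, 1],
            "p_value": [1e-4, 1e-4, 1e-4],
            "rr": [2.0, 8.0, 8.0],
            "ic": [5.0] * 3,
            "direction": ["positive"] * 3,
            "display_label": ["L1", "L2", "L3"],
        })
        prof = PhenotypeProfile("s", "reduction", stats, bonferroni_m=10)
        kept = top_k_per_type(prof, k=2)
        assert sorted(kept.stats["feature_id"]) == ["L2", "L3"]

    def test_display_order_is_by_abs_log_rr(self):
        from phenodose.profiles import PhenotypeProfile

        stats = pd.DataFrame({
            "feature_type": ["lab"] * 3,
            "feature_id": ["L1", "L2", "L3"],
            "a": [1, 1, 1], "b": [1, 1, 1], "c": [1, 1, 1], "d": [1, 1, 1],
            "p_value": [1e-6, 1e-4, 1e-5],
            "rr": [2.5, 0.1, 6.0],
            "ic": [5.0] * 3,
            "direction": ["positive", "negative", "positive"],
            "display_label": ["L1", "NO L2", "L3"],
        })
        prof = PhenotypeProfile("s", "reduction", stats, bonferroni_m=10)
        disp = prof.display_frame()
        assert list(disp["feature_id"]) == ["L2", "L3", "L1"]


class TestPlantedRecovery:
    def test_planted_features_recovered_without_spurious_leaves(
        self, small_study
    ):
        """At 600 patients most planted RR-4 features already pass the
        cascade, and every surviving feature is either planted or an
        ancestor of a planted leaf (ancestors legitimately inherit
        enrichment through pooling)."""
        cohort, intervals, feature_sets, acfg = small_study
        case = list(intervals.loc[intervals.label == "reduction", "interval_id"])
        ctrl = list(
            intervals.loc[intervals.label == "continuation", "interval_id"]
        )
        profile = build_profile(case, ctrl, feature_sets, cohort.ontologies,
                                acfg)
        planted = set(zip(cohort.truth.planted["feature_type"],
                          cohort.truth.planted["feature_id"]))
        found = set(profile.features)
        assert len(planted & found) >= 3
        allowed = set(planted)
        for ftype, fid in planted:
            graph = cohort.ontologies.get(ftype)
            if graph is not None:
                allowed |= {(ftype, anc) for anc in graph.ancestors(fid)}
        assert found <= allowed
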