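from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from komnet import (
    KOProfile,
    SelectionConfig,
    TopologyTable,
    compare_seasonal_betweenness,
    pathway_enrichment,
    select_key_functionalities,
)
from komnet.keystone import read_pathway_map
from oracles import bh_adjust, hypergeom_upper_tail, wilcoxon_exact_two_sided


def mk_topo(load_scores, betweenness=None, choke=None):
    ids = sorted(load_scores)
    betweenness = betweenness or {n: 0.0 for n in ids}
    df = pd.DataFrame(
        {
            "members": ids,
            "degree": [2] * len(ids),
            "betweenness": [betweenness[n] for n in ids],
            "load_score": [load_scores[n] for n in ids],
            "weighted_load_score": [float("nan")] * len(ids),
            "choke_point": [bool(choke and n in choke) for n in ids],
            "unique_metabolites": [""] * len(ids),
            "isolated": [False] * len(ids),
        },
        index=pd.Index(ids, name="node_id"),
    )
    return TopologyTable(
        nodes=df, total_edges_parallel=10, total_edges_simple=10, avg_shortest_path=2.0
    )


def mk_profiles(rel_expr):
    return {
        k: KOProfile(ko_id=k, koga=1.0, kota=v if v is not None else 1.0, rel_expr=v)
        for k, v in rel_expr.items()
    }


class TestSelection:
    def test_distinct_scores_top_decile_counts_ceiling(self):
        loads = {f"K{i:03d}": float(i) for i in range(20)}
        expr = {f"K{i:03d}": float(i) for i in range(20)}
        rep = select_key_functionalities(
            mk_topo(loads), mk_profiles(expr), SelectionConfig()
        )
        # ceil(0.1*20) = 2 on each axis; same ranking on both -> 2 selected
        assert rep.selected_ids == {"K018", "K019"}
        assert rep.load_threshold == 18.0

    def test_degenerate_ties_include_all(self):
        loads = {f"K{i}": float(i) for i in range(10)}
        expr = {f"K{i}": 1.0 for i in range(10)}
        rep = select_key_functionalities(
            mk_topo(loads), mk_profiles(expr),
            SelectionConfig(tie_policy="include_ties"),
        )
        # every node ties the expression threshold -> expression passes all
        assert rep.selected_ids == {"K9"}  # limited by the load axis only

    def test_strict_tie_policy_caps_count(self):
        loads = {f"K{i}": 1.0 for i in range(10)}
        expr = {f"K{i}": 1.0 for i in range(10)}
        rep = select_key_functionalities(
            mk_topo(loads), mk_profiles(expr), SelectionConfig(tie_policy="strict")
        )
        assert len(rep.selected_ids) == 1

    def test_matches_brute_force_double_filter(self):
        rng = np.random.default_rng(100)
        ids = [f"K{i:04d}" for i in range(200)]
        loads = {k: float(rng.random()) for k in ids}
        expr = {k: float(rng.random()) for k in ids}
        rep = select_key_functionalities(
            mk_topo(loads), mk_profiles(expr), SelectionConfig()
        )
        k = math.ceil(0.1 * 200)
        load_thr = sorted(loads.values(), reverse=True)[k - 1]
        expr_thr = sorted(expr.values(), reverse=True)[k - 1]
        expected = {
            i for i in ids if loads[i] >= load_thr and expr[i] >= expr_thr
        }
        assert rep.selected_ids == expected

    def test_monotone_in_load_quantile(self):
        rng = np.random.default_rng(7)
        ids = [f"K{i:03d}" for i in range(60)]
        loads = {k: float(rng.random()) for k in ids}
        expr = {k: float(rng.random()) for k in ids}
        prev: set[str] = set()
        for q in (0.05, 0.10, 0.25, 0.50, 1.0):
            rep = select_key_functionalities(
                mk_topo(loads), mk_profiles(expr),
                SelectionConfig(load_quantile=q),
            )
            assert prev <= rep.selected_ids
            prev = rep.selected_ids

    def test_full_quantiles_select_every_expressed_node(self):
        loads = {f"K{i}": float(i) for i in range(10)}
        expr = {f"K{i}": float(i + 1) for i in range(10)}
        rep = select_key_functionalities(
            mk_topo(loads), mk_profiles(expr),
            SelectionConfig(load_quantile=1.0, expr_quantile=1.0),
        )
        assert rep.selected_ids == set(loads)

    def test_mt_only_nodes_excluded_from_ranking(self):
        loads = {"K1": 3.0, "K2": 2.0, "K3": 1.0}
        profiles = mk_profiles({"K1": None, "K2": 5.0, "K3": 1.0})
        profiles["K1"] = KOProfile(ko_id="K1", koga=0.0, kota=1.0, rel_expr=None,
                                   flags=("MT-only",))
        rep = select_key_functionalities(
            mk_topo(loads), profiles, SelectionConfig(load_quantile=0.5, expr_quantile=0.5)
        )
        assert "K1" not in rep.selected_ids

    def test_every_selected_satisfies_both_thresholds(self):
        rng = np.random.default_rng(3)
        ids = [f"K{i:03d}" for i in range(97)]
        loads = {k: float(rng.random()) for k in ids}
        expr = {k: float(rng.random()) for k in ids}
        rep = select_key_functionalities(mk_topo(loads), mk_profiles(expr))
        for n in rep.selected_ids:
            assert loads[n] >= rep.load_threshold
            assert expr[n] >= rep.expr_threshold

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            select_key_functionalities(
                mk_topo({"K1": 1.0}), {}, SelectionConfig()
            )


class TestEnrichment:
    def test_maximal_enrichment_is_smallest_p(self):
        selected = {f"K{i}" for i in range(10)}
        background = selected | {f"B{i}" for i in range(10)}
        res = pathway_enrichment(selected, background, {"pw": frozenset(selected)})
        expected = hypergeom_upper_tail(10, 10, 10, 20)
        assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_pathway_p_one(self):
        selected = {"K1", "K2"}
        background = selected | {"B1", "B2", "B3"}
        res = pathway_enrichment(selected, background, {"pw": frozenset({"B1", "B2"})})
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_p_matches_hypergeometric_tail_sum(self):
        # 2x2: 8 selected-in-pathway, 2 selected-out, 10 bg-in (non-sel), 80 bg-out
        selected = {f"S{i}" for i in range(10)}
        pw = {f"S{i}" for i in range(8)} | {f"N{i}" for i in range(10)}
        background = selected | {f"N{i}" for i in range(90)}
        res = pathway_enrichment(selected, background, {"pw": frozenset(pw)})
        expected = hypergeom_upper_tail(8, 10, 18, 100)
        assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(6)
        background = {f"K{i:04d}" for i in range(120)}
        for _ in range(25):
            selected = set(
                rng.choice(sorted(background), size=rng.integers(1, 30), replace=False)
            )
            pw = frozenset(
                rng.choice(sorted(background), size=rng.integers(1, 60), replace=False)
            )
            res = pathway_enrichment(selected, background, {"pw": pw})
            a = len(pw & selected)
            expected = hypergeom_upper_tail(a, len(selected), len(pw), len(background))
            assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_bh_adjustment_matches_manual_step_up(self):
        rng = np.random.default_rng(2)
        background = {f"K{i:04d}" for i in range(200)}
        selected = set(list(sorted(background))[:25])
        pmap = {}
        for j in range(12):
            pmap[f"pw{j}"] = frozenset(
                rng.choice(sorted(background), size=rng.integers(5, 50), replace=False)
            )
        res = pathway_enrichment(selected, background, pmap).sort_values("pathway")
        manual = bh_adjust(list(res["p"]))
        assert list(res["fdr_adjusted_p"]) == pytest.approx(manual, rel=1e-12)
        assert ((res["p"] >= 0) & (res["p"] <= 1)).all()

    def test_selected_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            pathway_enrichment({"K1"}, {"K2"}, {})

    def test_pathway_map_reader(self, tmp_path):
        path = tmp_path / "pw.tsv"
        path.write_text("pathway_id\tko_id\npw1\tK1\npw1\tK2\npw2\tK3\n")
        assert read_pathway_map(path) == {
            "pw1": frozenset({"K1", "K2"}),
            "pw2": frozenset({"K3"}),
        }


class TestSeasonalComparison:
    def mk(self, values):
        return mk_topo(
            {k: 0.0 for k in values}, betweenness={k: v for k, v in values.items()}
        )

    def test_identical_topologies(self):
        vals = {f"K{i}": float(i + 1) for i in range(6)}
        res = compare_seasonal_betweenness(
            self.mk(vals), self.mk(vals), {"pw": frozenset(vals)}
        )
        assert res.loc[0, "median_fold_change"] == pytest.approx(1.0)
        assert res.loc[0, "wilcoxon_p"] == pytest.approx(1.0)

    def test_constant_fourfold_change(self):
        a = {f"K{i}": float(i + 1) for i in range(8)}
        b = {k: 4 * v for k, v in a.items()}
        res = compare_seasonal_betweenness(self.mk(a), self.mk(b), {"pw": frozenset(a)})
        assert res.loc[0, "median_fold_change"] == pytest.approx(4.0)
        assert res.loc[0, "wilcoxon_p"] < 0.05

    def test_wilcoxon_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        a = {f"K{i}": float(v) for i, v in enumerate(rng.uniform(1, 10, size=10))}
        b = {k: v + float(d) for (k, v), d in zip(a.items(), rng.uniform(-3, 3, 10))}
        res = compare_seasonal_betweenness(self.mk(a), self.mk(b), {"pw": frozenset(a)})
        diffs = [b[k] - a[k] for k in a]
        assert res.loc[0, "wilcoxon_p"] == pytest.approx(
            wilcoxon_exact_two_sided(diffs), rel=1e-9
        )

    def test_zero_pairs_excluded_from_median(self):
        a = {"K1": 0.0, "K2": 2.0, "K3": 3.0}
        b = {"K1": 5.0, "K2": 4.0, "K3": 6.0}
        res = compare_seasonal_betweenness(self.mk(a), self.mk(b), {"pw": frozenset(a)})
        assert res.loc[0, "n_zero_excluded"] == 1
        assert res.loc[0, "median_fold_change"] == pytest.approx(2.0)

    def test_small_pathways_skipped(self):
        a = {"K1": 1.0, "K2": 2.0}
        res = compare_seasonal_betweenness(
            self.mk(a), self.mk(a), {"tiny": frozenset({"K1"}), "ok": frozenset(a)}
        )
        assert list(res["pathway"]) == ["ok"]
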