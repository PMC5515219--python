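"""Selection of genes encoding key functionalities, with comparative stats.

A KO (or node group) encodes a key functionality when it sits in the
top load-score percentile of the season-specific metabolic network
*and* in the top relative-expression percentile — topologically
important and disproportionately transcribed. The default cut is the
top 10% on both axes.

Also provided: one-sided Fisher-exact pathway enrichment with
Benjamini–Hochberg FDR control, and a paired seasonal comparison of
node betweenness per pathway (median fold change + Wilcoxon
signed-rank test).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import KOProfile
from .topology import TopologyTable

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "KeystoneReport",
    "select_key_functionalities",
    "pathway_enrichment",
    "compare_seasonal_betweenness",
    "read_pathway_map",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Dual-percentile selection settings.

    load_quantile / expr_quantile: top fraction retained on each axis
    (0.10 = top 10 per cent). tie_policy ``include_ties`` admits every
    entity tied with the threshold value; ``strict`` retains exactly
    ceil(q*N) entities, breaking threshold ties by node id.
    group_expr_agg: how a collapsed group's relative expression is
    aggregated over member KOs (max, sum or mean).
    """

    load_quantile: float = 0.10
    expr_quantile: float = 0.10
    tie_policy: str = "include_ties"
    group_expr_agg: str = "max"
    include_mt_only: bool = False

    def __post_init__(self) -> None:
        for name in ("load_quantile", "expr_quantile"):
            q = getattr(self, name)
            if not (0 < q <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {q}")
        if self.tie_policy not in ("include_ties", "strict"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")
        if self.group_expr_agg not in ("max", "sum", "mean"):
            raise ValueError(f"unknown group_expr_agg {self.group_expr_agg!r}")


@dataclass
class KeystoneReport:
    """Selected nodes with the thresholds and config that produced them."""

    selected: pd.DataFrame  # index node_id; members, load_score, rel_expr, choke_point
    load_threshold: float
    expr_threshold: float
    config: SelectionConfig
    season: str = ""
    n_candidates: int = 0

    @property
    def selected_ids(self) -> set[str]:
        return set(self.selected.index)

    @property
    def selected_kos(self) -> set[str]:
        return {
            ko
            for members in self.selected["members"]
            for ko in str(members).split(";")
        }

    def to_tsv(self, path) -> None:
        df = self.selected.copy()
        df.insert(0, "node_id", df.index)
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    def sidecar(self, **extra) -> dict:
        rec = {
            "load_threshold": self.load_threshold,
            "expr_threshold": self.expr_threshold,
            "config": asdict(self.config),
            "season": self.season,
            "n_candidates": self.n_candidates,
            "n_selected": int(len(self.selected)),
        }
        rec.update(extra)
        return rec

    def to_json(self, path, **extra) -> None:
        with open(path, "w") as fh:
            json.dump(self.sidecar(**extra), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _top_quantile_ids(
    scores: Mapping[str, float], q: float, tie_policy: str
) -> tuple[set[str], float]:
    """Ids in the top-q fraction of scores, plus the threshold used.

    The threshold is the ceil(q*N)-th largest value; with distinct
    scores exactly ceil(q*N) entities pass.
    """
    if not scores:
        return set(), float("nan")
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    k = math.ceil(q * len(items))
    threshold = items[k - 1][1]
    if tie_policy == "include_ties":
        ids = {i for i, v in items if v >= threshold}
    else:
        ids = {i for i, _ in items[:k]}
    return ids, threshold


def node_rel_expr(
    topo: TopologyTable,
    profiles: Mapping[str, KOProfile],
    agg: str = "max",
    include_mt_only: bool = False,
) -> dict[str, float]:
    """Relative expression per node, aggregated over member KOs.

    KOs without a profile or with undefined (MT-only-flagged) relative
    expression are skipped; nodes with no usable member value are
    absent from the result and thus excluded from percentile ranking.
    """
    out: dict[str, float] = {}
    for node_id, row in topo.nodes.iterrows():
        vals = []
        for ko in str(row["members"]).split(";"):
            p = profiles.get(ko)
            if p is None:
                continue
            if p.rel_expr is None and not include_mt_only:
                continue
            if p.rel_expr is not None:
                vals.append(p.rel_expr)
        if vals:
            fn = {"max": max, "sum": sum, "mean": lambda v: sum(v) / len(v)}[agg]
            out[str(node_id)] = float(fn(vals))
    return out


def select_key_functionalities(
    topo: TopologyTable,
    profiles: Mapping[str, KOProfile],
    cfg: SelectionConfig = SelectionConfig(),
    season: str = "",
) -> KeystoneReport:
    """Intersect the top load-score and top relative-expression percentiles.

    Thresholds are empirical (1-q) quantiles over the ranked entities:
    all network nodes for load score, nodes with defined relative
    expression for the expression axis.
    """
    if topo.nodes.empty:
        raise ValueError("topology table is empty; nothing to select from")
    if not profiles:
        raise ValueError("no KO profiles supplied; nothing to select from")

    load = {str(n): float(v) for n, v in topo.nodes["load_score"].items()}
    expr = node_rel_expr(
        topo, profiles, agg=cfg.group_expr_agg, include_mt_only=cfg.include_mt_only
    )
    if not expr:
        raise ValueError("no node has a defined relative expression value")

    top_load, load_thr = _top_quantile_ids(load, cfg.load_quantile, cfg.tie_policy)
    top_expr, expr_thr = _top_quantile_ids(expr, cfg.expr_quantile, cfg.tie_policy)
    chosen = sorted(top_load & top_expr)

    df = topo.nodes.loc[chosen, ["members", "load_score", "choke_point"]].copy()
    df["rel_expr"] = [expr[n] for n in chosen]
    df = df[["members", "load_score", "rel_expr", "choke_point"]]
    return KeystoneReport(
        selected=df,
        load_threshold=float(load_thr),
        expr_threshold=float(expr_thr),
        config=cfg,
        season=season,
        n_candidates=len(load),
    )


def read_pathway_map(path) -> dict[str, frozenset[str]]:
    """Read a long-format TSV pathway map: pathway_id, ko_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"pathway_id", "ko_id"}.issubset(df.columns):
        raise ValueError(f"pathway map {path} must have columns pathway_id, ko_id")
    out: dict[str, set[str]] = {}
    for pw, ko in zip(df["pathway_id"], df["ko_id"]):
        out.setdefault(pw, set()).add(ko)
    return {pw: frozenset(kos) for pw, kos in out.items()}


def pathway_enrichment(
    selected: Iterable[str],
    background: Iterable[str],
    pathway_map: Mapping[str, frozenset[str]],
) -> pd.DataFrame:
    """One-sided Fisher-exact over-representation test per pathway.

    For each pathway the 2x2 table is (selected vs not) x (in pathway
    vs not) over the background universe; p-values are BH-adjusted
    across the tested pathways. Pathways with no selected member report
    p = 1 (the one-sided tail at a = 0).
    """
    sel = set(selected)
    bg = set(background)
    if not sel <= bg:
        raise ValueError(
            f"selected set is not a subset of the background "
            f"(e.g. {sorted(sel - bg)[:5]})"
        )
    rows = []
    for pw in sorted(pathway_map):
        in_pw = pathway_map[pw] & bg
        a = len(in_pw & sel)
        b = len(sel) - a
        c = len(in_pw) - a
        d = len(bg) - len(sel) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "pathway": pw,
                "n_selected_in": a,
                "n_background_in": len(in_pw),
                "odds_ratio": float(odds),
                "p": float(p),
            }
        )
    df = pd.DataFrame(
        rows, columns=["pathway", "n_selected_in", "n_background_in", "odds_ratio", "p"]
    )
    if len(df):
        df["fdr_adjusted_p"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["fdr_adjusted_p"] = pd.Series(dtype=float)
    return df


def compare_seasonal_betweenness(
    topo_a: TopologyTable,
    topo_b: TopologyTable,
    pathway_map: Mapping[str, frozenset[str]],
) -> pd.DataFrame:
    """Paired per-pathway comparison of node betweenness between seasons.

    For KOs present in both networks, per pathway: the median of
    per-KO betweenness fold changes (season b / season a; pairs with a
    zero in either season are excluded from the median and counted)
    and the two-sided Wilcoxon signed-rank p-value on the paired
    differences. Pathways with fewer than 2 shared KOs are skipped.
    """
    bet_a = topo_a.betweenness_by_ko()
    bet_b = topo_b.betweenness_by_ko()
    shared = set(bet_a) & set(bet_b)

    rows = []
    for pw in sorted(pathway_map):
        kos = sorted(pathway_map[pw] & shared)
        if len(kos) < 2:
            logger.warning(
                "pathway %s has %d shared KO(s); skipped (need >= 2)", pw, len(kos)
            )
            continue
        a = np.array([bet_a[k] for k in kos])
        b = np.array([bet_b[k] for k in kos])
        both_pos = (a > 0) & (b > 0)
        folds = b[both_pos] / a[both_pos]
        median_fc = float(np.median(folds)) if folds.size else float("nan")
        diffs = b - a
        if np.all(diffs == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(b, a, alternative="two-sided").pvalue)
        rows.append(
            {
                "pathway": pw,
                "n_shared": len(kos),
                "n_zero_excluded": int(len(kos) - both_pos.sum()),
                "median_fold_change": median_fc,
                "wilcoxon_p": p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway",
            "n_shared",
            "n_zero_excluded",
            "median_fold_change",
            "wilcoxon_p",
        ],
    )
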