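"""Synthetic multi-omic data with planted keystone KOs.

The generator emulates the KO-annotated count structure of coupled
metagenomic/metatranscriptomic libraries, not raw reads. Its metabolic
map is built from ring-shaped pathway modules connected by *bridge*
KOs:

* each module is a ring of KOs chained by shared metabolites (KO i
  converts M_i -> M_{i+1}), so within-module betweenness is flat;
* each bridge KO exchanges two pendant metabolites, one anchored in
  each of two different modules. A bridge is therefore a degree-2 cut
  vertex carrying all shortest paths between its two modules — a
  topological load point by construction.

Bridges additionally receive a transcriptional boost
(``expression_effect``-fold) in the metatranscriptome, making them the
planted ground-truth keystones that the dual top-percentile selection
should recover.

Read counts are negative-binomial with gene-length-proportional means
(the standard overdispersed model for sequencing counts); the
metatranscriptome scales metagenomic expectations by the per-KO
expression multiplier.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .netrecon import ReactionPairMap
from .quantify import GeneCatalogue, Layer, OmicCounts

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_pair_map",
    "generate_catalogue",
    "generate_counts",
    "generate_pathway_map",
    "end_to_end_fixture",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic community configuration.

    n_kos includes the n_bridge_kos planted bridges; the remainder is
    split evenly into n_modules ring modules (each needs >= 3 KOs).
    n_metabolites, if given, must match the count the module layout
    implies (ring metabolites + 2 pendants per bridge); left ``None``
    it is derived. genes_per_ko and gene_length_range are inclusive
    uniform integer ranges; effective length is
    max(1, gene_length - read_length + 1). dispersion is the
    negative-binomial overdispersion (variance = mu + dispersion*mu^2);
    0 gives Poisson counts.
    """

    n_kos: int = 60
    n_modules: int = 3
    n_bridge_kos: int = 3
    n_metabolites: Optional[int] = None
    genes_per_ko: tuple[int, int] = (1, 3)
    mg_depth: int = 200_000
    mt_depth: int = 200_000
    expression_effect: float = 10.0
    dispersion: float = 0.1
    read_length: int = 100
    gene_length_range: tuple[int, int] = (300, 1500)
    abundance_sigma: float = 0.5
    seed: int = 0

    def module_sizes(self) -> list[int]:
        n_module_kos = self.n_kos - self.n_bridge_kos
        base, extra = divmod(n_module_kos, self.n_modules)
        return [base + (1 if j < extra else 0) for j in range(self.n_modules)]

    def validate(self) -> None:
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if not (0 <= self.n_bridge_kos < self.n_kos):
            raise ValueError("need 0 <= n_bridge_kos < n_kos")
        max_bridges = self.n_modules * (self.n_modules - 1) // 2
        if self.n_bridge_kos > max_bridges:
            raise ValueError(
                f"{self.n_bridge_kos} bridge KO(s) requested but only "
                f"{max_bridges} module pair(s) exist for {self.n_modules} module(s)"
            )
        if min(self.module_sizes()) < 3:
            raise ValueError(
                "each ring module needs >= 3 KOs; increase n_kos or reduce "
                "n_modules/n_bridge_kos"
            )
        required = self._required_metabolites()
        if self.n_metabolites is not None and self.n_metabolites != required:
            raise ValueError(
                f"n_metabolites={self.n_metabolites} inconsistent with module "
                f"layout (requires exactly {required})"
            )

    def _required_metabolites(self) -> int:
        return (self.n_kos - self.n_bridge_kos) + 2 * self.n_bridge_kos


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: keystone KOs, module labels, expression effects."""

    planted_keystones: frozenset[str]
    module_assignment: Mapping[str, str]
    expression_multipliers: Mapping[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_keystones": sorted(self.planted_keystones),
                    "module_assignment": dict(sorted(self.module_assignment.items())),
                    "expression_multipliers": dict(
                        sorted(self.expression_multipliers.items())
                    ),
                },
                fh,
                indent=2,
            )
            fh.write("\n")

    @classmethod
    def read_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            planted_keystones=frozenset(raw["planted_keystones"]),
            module_assignment=raw["module_assignment"],
            expression_multipliers={
                k: float(v) for k, v in raw["expression_multipliers"].items()
            },
        )


def _bridge_pairs(n_modules: int, n_bridges: int) -> list[tuple[int, int]]:
    """Module pairs to bridge: a spanning chain first, then the rest."""
    chain = [(j, j + 1) for j in range(n_modules - 1)]
    rest = [p for p in itertools.combinations(range(n_modules), 2) if p not in chain]
    return (chain + rest)[:n_bridges]


def generate_pair_map(cfg: SynthConfig) -> tuple[ReactionPairMap, GroundTruth]:
    """Deterministically build the reaction-pair map and its ground truth.

    The layout is a pure function of the configuration (no randomness),
    so identical configs give byte-identical pair maps.
    """
    cfg.validate()
    sizes = cfg.module_sizes()

    pairs: dict[str, set[tuple[str, str]]] = {}
    module_of: dict[str, str] = {}
    ko_counter = itertools.count(1)
    module_kos: list[list[str]] = []

    for j, size in enumerate(sizes):
        kos = [f"K{next(ko_counter):05d}" for _ in range(size)]
        module_kos.append(kos)
        for i, ko in enumerate(kos):
            sub = f"M{j}_{i}"
            prod = f"M{j}_{(i + 1) % size}"
            pairs[ko] = {(sub, prod)}
            module_of[ko] = f"module_{j}"

    multipliers = {ko: 1.0 for ko in pairs}
    planted: set[str] = set()
    anchor_slot = [0] * cfg.n_modules
    for t, (ja, jb) in enumerate(_bridge_pairs(cfg.n_modules, cfg.n_bridge_kos)):
        bridge = f"K{next(ko_counter):05d}"
        pend_a, pend_b = f"P{t}_a", f"P{t}_b"
        for j, pend in ((ja, pend_a), (jb, pend_b)):
            # spread anchors around the ring so bridges attach at distinct KOs
            idx = (anchor_slot[j] * 2) % sizes[j]
            anchor_slot[j] += 1
            anchor = module_kos[j][idx]
            pairs[anchor].add((f"M{j}_{idx}", pend))
        pairs[bridge] = {(pend_a, pend_b), (pend_b, pend_a)}
        module_of[bridge] = f"bridge_{ja}-{jb}"
        multipliers[bridge] = cfg.expression_effect
        planted.add(bridge)

    pair_map = ReactionPairMap(pairs={k: frozenset(v) for k, v in pairs.items()})
    truth = GroundTruth(
        planted_keystones=frozenset(planted),
        module_assignment=module_of,
        expression_multipliers=multipliers,
    )
    return pair_map, truth


def generate_catalogue(cfg: SynthConfig, truth: GroundTruth, seed: int) -> GeneCatalogue:
    """Draw a gene catalogue: 1+ genes per KO with uniform gene lengths."""
    rng = np.random.default_rng(seed)
    lengths: dict[str, int] = {}
    kos: dict[str, frozenset[str]] = {}
    gene_counter = itertools.count(1)
    for ko in sorted(truth.module_assignment):
        n_genes = int(rng.integers(cfg.genes_per_ko[0], cfg.genes_per_ko[1] + 1))
        for _ in range(n_genes):
            gene = f"g{next(gene_counter):06d}"
            glen = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
            lengths[gene] = max(1, glen - cfg.read_length + 1)
            kos[gene] = frozenset({ko})
    return GeneCatalogue(effective_length=lengths, ko_ids=kos)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_counts(
    catalogue: GeneCatalogue,
    truth: GroundTruth,
    cfg: SynthConfig,
    seed: int,
    sample_id: str = "synthetic",
) -> tuple[OmicCounts, OmicCounts]:
    """Draw per-gene MG and MT read counts.

    Gene-level MG means are proportional to (lognormal per-KO community
    abundance) x (effective length) and sum to mg_depth; MT means scale
    the same baseline by each KO's expression multiplier and sum to
    mt_depth. Counts are negative binomial at the configured
    overdispersion.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(catalogue.gene_ids)
    ko_of = {g: next(iter(catalogue.ko_ids[g])) for g in genes}
    ko_list = sorted({ko_of[g] for g in genes})
    base = dict(
        zip(ko_list, np.exp(rng.normal(0.0, cfg.abundance_sigma, size=len(ko_list))))
    )

    eff = np.array([catalogue.effective_length[g] for g in genes], dtype=float)
    w_mg = np.array([base[ko_of[g]] for g in genes]) * eff
    mult = np.array(
        [truth.expression_multipliers.get(ko_of[g], 1.0) for g in genes]
    )
    w_mt = w_mg * mult

    mu_mg = cfg.mg_depth * w_mg / w_mg.sum()
    mu_mt = cfg.mt_depth * w_mt / w_mt.sum()
    mg = _nb_draw(rng, mu_mg, cfg.dispersion)
    mt = _nb_draw(rng, mu_mt, cfg.dispersion)

    mg_counts = OmicCounts(
        layer=Layer.MG, sample_id=sample_id, counts={g: float(c) for g, c in zip(genes, mg)}
    )
    mt_counts = OmicCounts(
        layer=Layer.MT, sample_id=sample_id, counts={g: float(c) for g, c in zip(genes, mt)}
    )
    return mg_counts, mt_counts


def generate_pathway_map(truth: GroundTruth) -> dict[str, frozenset[str]]:
    """Pathway map mirroring the planted modules (bridges form their own set)."""
    out: dict[str, set[str]] = {}
    for ko, label in truth.module_assignment.items():
        key = "bridges" if label.startswith("bridge") else label
        out.setdefault(key, set()).add(ko)
    return {k: frozenset(v) for k, v in sorted(out.items())}


def end_to_end_fixture(cfg: SynthConfig, outdir, seed: Optional[int] = None) -> dict[str, Path]:
    """Write a complete input bundle (catalogue, counts, maps, truth).

    Returns the path of every file written. Identical config and seed
    reproduce a byte-identical bundle.
    """
    seed = cfg.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pair_map, truth = generate_pair_map(cfg)
    catalogue = generate_catalogue(cfg, truth, seed)
    mg, mt = generate_counts(catalogue, truth, cfg, seed + 1)
    pathway_map = generate_pathway_map(truth)

    paths = {
        "catalogue": outdir / "catalogue.tsv",
        "mg_counts": outdir / "mg_counts.tsv",
        "mt_counts": outdir / "mt_counts.tsv",
        "pair_map": outdir / "pair_map.tsv",
        "pathway_map": outdir / "pathway_map.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "manifest": outdir / "manifest.json",
    }
    catalogue.to_tsv(paths["catalogue"])
    mg.to_tsv(paths["mg_counts"])
    mt.to_tsv(paths["mt_counts"])
    pair_map.to_tsv(paths["pair_map"])
    pd.DataFrame(
        [
            {"pathway_id": pw, "ko_id": ko}
            for pw in sorted(pathway_map)
            for ko in sorted(pathway_map[pw])
        ],
        columns=["pathway_id", "ko_id"],
    ).to_csv(paths["pathway_map"], sep="\t", index=False, lineterminator="\n")
    truth.to_json(paths["ground_truth"])

    manifest = {
        "config": asdict(cfg),
        "seed": seed,
        "files": {k: v.name for k, v in paths.items() if k != "manifest"},
        "n_genes": len(catalogue.gene_ids),
        "n_kos": len(truth.module_assignment),
        "planted_keystones": sorted(truth.planted_keystones),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def evaluate_recovery(cfg: SynthConfig, seed: int, selection=None) -> dict:
    """Run the full pipeline in memory and score keystone recovery.

    Generates a synthetic community, quantifies KO abundances,
    reconstructs and collapses the expressed-KO network, applies the
    dual top-percentile selection, and compares the selected KOs with
    the planted ground truth. Returns sensitivity (planted keystones
    recovered) and the false-positive rate among non-planted KOs,
    along with the intermediate objects' summary numbers.
    """
    from .keystone import SelectionConfig, select_key_functionalities
    from .netrecon import build_network, collapse_redundant, season_subset
    from .quantify import aggregate_ko, normalize_by_length, relative_expression
    from .topology import compute_topology

    pair_map, truth = generate_pair_map(cfg)
    catalogue = generate_catalogue(cfg, truth, seed)
    mg, mt = generate_counts(catalogue, truth, cfg, seed + 1)
    koga = aggregate_ko(normalize_by_length(mg, catalogue), catalogue)
    kota = aggregate_ko(normalize_by_length(mt, catalogue), catalogue)
    profiles = relative_expression(koga, kota)

    net = collapse_redundant(build_network(pair_map, season_subset(pair_map, kota)))
    topo = compute_topology(net)
    report = select_key_functionalities(
        topo, profiles, selection or SelectionConfig()
    )

    planted = truth.planted_keystones
    non_planted = frozenset(truth.module_assignment) - planted
    selected = report.selected_kos
    return {
        "sensitivity": len(selected & planted) / len(planted) if planted else 1.0,
        "false_positive_rate": (
            len(selected & non_planted) / len(non_planted) if non_planted else 0.0
        ),
        "n_selected": len(selected),
        "n_nodes": int(net.graph.number_of_nodes()),
        "n_edges": int(net.n_edges_parallel),
        "avg_shortest_path": float(topo.avg_shortest_path),
        "selected": sorted(selected),
        "planted": sorted(planted),
        "load_threshold": report.load_threshold,
        "expr_threshold": report.expr_threshold,
    }
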