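"""End-to-end pipeline: quantify -> build-net -> topology -> keystone.

Each stage writes plain-text tables that the next stage (or the
corresponding CLI subcommand) can consume standalone. A provenance
record captures the configuration, seeds, package version and SHA-256
checksums of every output; reruns on unchanged inputs are
byte-identical (no timestamps are recorded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .keystone import (
    SelectionConfig,
    compare_seasonal_betweenness,
    pathway_enrichment,
    read_pathway_map,
    select_key_functionalities,
)
from .netrecon import (
    ReactionPairMap,
    build_network,
    collapse_redundant,
    export_network,
    season_subset,
)
from .quantify import (
    GeneCatalogue,
    Layer,
    MTOnlyPolicy,
    OmicCounts,
    aggregate_ko,
    normalize_by_length,
    read_ko_profiles,
    relative_expression,
    subsample_counts,
    write_ko_profiles,
)
from .topology import compute_topology, network_summary

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    catalogue: str
    mg_counts: str
    mt_counts: str
    pair_map: str
    outdir: str
    pathway_map: Optional[str] = None
    sample_id: str = "sample"
    subsample_depth: Optional[int] = None
    seed: int = 0
    network_mode: str = "shared_metabolite"
    edge_count_convention: str = "parallel"
    load_quantile: float = 0.10
    expr_quantile: float = 0.10
    tie_policy: str = "include_ties"
    mt_only_policy: str = "flag"
    season: str = ""

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        paths = {
            "catalogue": self.catalogue,
            "mg_counts": self.mg_counts,
            "mt_counts": self.mt_counts,
            "pair_map": self.pair_map,
        }
        if self.pathway_map:
            paths["pathway_map"] = self.pathway_map
        return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute all stages; return the paths of every artefact written."""
    for name, p in cfg.input_paths().items():
        if not Path(p).exists():
            raise PipelineError("config", f"input {name} not found: {p}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    # --- quantify -----------------------------------------------------
    try:
        catalogue = GeneCatalogue.read_tsv(cfg.catalogue)
        mg = OmicCounts.read_tsv(cfg.mg_counts, Layer.MG, cfg.sample_id)
        mt = OmicCounts.read_tsv(cfg.mt_counts, Layer.MT, cfg.sample_id)
        if cfg.subsample_depth is not None:
            mg = subsample_counts(mg, cfg.subsample_depth, cfg.seed)
            mt = subsample_counts(mt, cfg.subsample_depth, cfg.seed + 1)
        koga = aggregate_ko(normalize_by_length(mg, catalogue), catalogue)
        kota = aggregate_ko(normalize_by_length(mt, catalogue), catalogue)
        profiles = relative_expression(koga, kota, MTOnlyPolicy(cfg.mt_only_policy))
        out["ko_profiles"] = outdir / "ko_profiles.tsv"
        write_ko_profiles(profiles, out["ko_profiles"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("quantify", str(exc)) from exc

    # --- build-net ----------------------------------------------------
    try:
        pair_map = ReactionPairMap.read_tsv(cfg.pair_map)
        subset = season_subset(pair_map, kota)
        if not subset:
            raise ValueError("no KO has both transcript signal and pair annotation")
        net = collapse_redundant(
            build_network(pair_map, subset, mode=cfg.network_mode)
        )
        out["network"] = outdir / "network.graphml"
        export_network(net, out["network"], format="graphml")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("build-net", str(exc)) from exc

    # --- topology -----------------------------------------------------
    try:
        topo = compute_topology(
            net, edge_count_convention=cfg.edge_count_convention, with_weighted=True
        )
        out["topology"] = outdir / "topology.tsv"
        topo.to_tsv(out["topology"])
        out["summary"] = outdir / "network_summary.json"
        with open(out["summary"], "w") as fh:
            json.dump(network_summary(net), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise PipelineError("topology", str(exc)) from exc

    # --- keystone -----------------------------------------------------
    try:
        sel_cfg = SelectionConfig(
            load_quantile=cfg.load_quantile,
            expr_quantile=cfg.expr_quantile,
            tie_policy=cfg.tie_policy,
        )
        report = select_key_functionalities(topo, profiles, sel_cfg, season=cfg.season)
        out["keystones"] = outdir / "keystones.tsv"
        report.to_tsv(out["keystones"])
        out["keystones_json"] = outdir / "keystones.json"
        report.to_json(out["keystones_json"], seed=cfg.seed, version=__version__)
        if cfg.pathway_map:
            pathway_map = read_pathway_map(cfg.pathway_map)
            enrich = pathway_enrichment(
                report.selected_kos, {ko for ko in kota}, pathway_map
            )
            out["enrichment"] = outdir / "pathway_enrichment.tsv"
            enrich.to_csv(out["enrichment"], sep="\t", index=False, lineterminator="\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("keystone", str(exc)) from exc

    # --- provenance ---------------------------------------------------
    prov = {
        "config": asdict(cfg),
        "version": __version__,
        "outputs": {k: {"path": v.name, "sha256": _sha256(v)} for k, v in sorted(out.items())},
    }
    prov_path = outdir / "provenance.json"
    with open(prov_path, "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
        fh.write("\n")
    out["provenance"] = prov_path
    return out
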