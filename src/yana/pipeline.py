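"""End-to-end orchestration: simulate or ingest, score, map, network, overlap.

A :class:`PipelineConfig` (flat YAML on disk) drives the whole workflow and
records every threshold in one place: the hit-calling alpha (0.05), the
interaction-confidence cutoff (0.900), the modifier-degree filter (k=2) and
the ortholog consensus policy.  ``run()`` executes the stages in order,
writes every intermediate as a plain-text table in the run directory, and
finishes with a manifest of SHA-256 checksums — identical config plus seed
gives an identical manifest.

Stages
------
1. inputs       colony grids + strain maps (simulated or loaded), edge
                lists, ortholog tables
2. call-hits    per-screen scoring and SL/SS hit tables (wt and mut)
3. merge        unique modifier set across the four lists
4. orthologs    mapped count / percent, humanized symbol set
5. networks     pombe primary, degree-filtered, extended (+ rescued
                orphans); human primary and degree-filtered
6. overlap      cross-species target nominations with provenance
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import hit_calling, network_analysis, ortholog_map, screen_io, synthetic_data

logger = logging.getLogger("yana.pipeline")

__all__ = ["PipelineConfig", "run"]


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run."""

    out_dir: str = "yana_run"
    seed: int = 0
    alpha: float = 0.05
    min_conf: float = 0.900
    degree_k: int = 2
    ortholog_policy: str = "union"
    replicate_exclusion: bool = True
    day: int = 1

    # simulation block (used when no explicit input paths are given)
    n_genes: int = 500
    n_planted_sl: int = 15
    n_planted_ss: int = 15
    noise_sigma: float = 0.1
    plate_effect_sigma: float = 0.15
    gradient_amplitude: float = 0.1
    global_induction_cost: float = 0.8
    ppi_frac_above_threshold: float = 0.02
    ortholog_frac_mapped: float = 0.838

    # explicit inputs: paths keyed colony_wt, colony_mut, strain_map_wt,
    # strain_map_mut, pombe_edges, human_edges, orthologs
    inputs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 <= self.min_conf <= 1:
            raise ValueError("min_conf must lie in [0, 1]")
        if self.degree_k < 0:
            raise ValueError("degree_k must be >= 0")
        if self.ortholog_policy not in ortholog_map.POLICIES:
            raise ValueError(f"ortholog_policy must be one of {ortholog_map.POLICIES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_inputs(config: PipelineConfig, out: Path) -> dict[str, Path]:
    """Generate every pipeline input from the config's simulation block."""
    paths: dict[str, Path] = {}
    planted: dict[str, tuple[list[str], list[str]]] = {}
    gene_ids = synthetic_data.ScreenSimConfig(n_genes=config.n_genes).gene_ids()

    rng_seed = config.seed
    for offset, screen in enumerate(("wt", "mut")):
        # different query strains modify different gene sets; shift the
        # planted window so the wt and mut hit lists overlap only partially
        shift = offset * (config.n_planted_sl // 2 + config.n_planted_ss // 2)
        sl = gene_ids[shift: shift + config.n_planted_sl]
        ss = gene_ids[shift + config.n_planted_sl:
                      shift + config.n_planted_sl + config.n_planted_ss]
        planted[screen] = (sl, ss)
        sim = synthetic_data.ScreenSimConfig(
            n_genes=config.n_genes,
            planted_sl=frozenset(sl),
            planted_ss=frozenset(ss),
            noise_sigma=config.noise_sigma,
            plate_effect_sigma=config.plate_effect_sigma,
            gradient_amplitude=config.gradient_amplitude,
            global_induction_cost=config.global_induction_cost,
            screen=screen,
            day=config.day,
            seed=rng_seed + offset,
        )
        grids, strain_map, _ = synthetic_data.simulate_screen(sim)
        colony = out / f"colony_{screen}.csv"
        smap = out / f"strain_map_{screen}.tsv"
        screen_io.write_colony_table(grids, colony)
        screen_io.write_strain_map(strain_map, smap)
        paths[f"colony_{screen}"] = colony
        paths[f"strain_map_{screen}"] = smap

    # ortholog tables over the full gene universe
    tables = synthetic_data.simulate_orthologs(
        gene_ids, frac_mapped=config.ortholog_frac_mapped, seed=rng_seed + 10
    )
    orth = out / "orthologs.tsv"
    ortholog_map.write_ortholog_tables(tables, orth)
    paths["orthologs"] = orth

    # pombe network: modules among planted genes, plus a rescue star whose
    # center is a non-planted gene bridging two otherwise-orphan hits
    wt_sl = planted["wt"][0]
    wt_ss = planted["wt"][1]
    modules = []
    if len(wt_sl) >= 8:
        modules = [wt_sl[:4], wt_sl[4:8], wt_ss[:4]]
    stars = [[gene_ids[-1], *wt_ss[-3:]]]
    if len(wt_sl) >= 11:
        stars.append([gene_ids[-2], *wt_sl[8:11]])
    df = synthetic_data.simulate_ppi(
        n_nodes=config.n_genes,
        frac_above_threshold=config.ppi_frac_above_threshold,
        planted_modules=modules,
        planted_stars=stars,
        seed=rng_seed + 20,
        node_names=gene_ids,
    )
    pombe_edges = out / "pombe_edges.tsv"
    df.to_csv(pombe_edges, sep="\t", index=False, header=["geneA", "geneB", "score"])
    paths["pombe_edges"] = pombe_edges

    # human network: mirror the pombe modules through the ortholog tables
    human_universe = sorted(
        ortholog_map.humanize(gene_ids, tables, config.ortholog_policy)
    )
    human_modules = []
    for module in modules + stars:
        mirrored = sorted(ortholog_map.humanize(module, tables, config.ortholog_policy))
        if len(mirrored) >= 2:
            human_modules.append(mirrored)
    # drop any overlap between mirrored modules (one-to-many maps can collide)
    seen: set[str] = set()
    disjoint = []
    for m in human_modules:
        m = [s for s in m if s not in seen]
        if len(m) >= 2:
            disjoint.append(m)
            seen.update(m)
    df_h = synthetic_data.simulate_ppi(
        n_nodes=len(human_universe),
        frac_above_threshold=config.ppi_frac_above_threshold,
        planted_modules=disjoint,
        seed=rng_seed + 30,
        node_names=human_universe,
    )
    human_edges = out / "human_edges.tsv"
    df_h.to_csv(human_edges, sep="\t", index=False, header=["geneA", "geneB", "score"])
    paths["human_edges"] = human_edges
    return paths


def run(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    Outputs: per-screen score and hit tables, the merged modifier list,
    ortholog coverage, pombe primary/filtered/extended networks with
    cluster reports and rescued orphans, the human primary/filtered
    networks, the cross-species overlap table, and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    if config.inputs:
        required = ["colony_wt", "colony_mut", "strain_map_wt", "strain_map_mut",
                    "pombe_edges", "human_edges", "orthologs"]
        missing = [k for k in required if k not in config.inputs]
        if missing:
            raise ValueError(f"inputs block missing keys: {missing}")
        paths = {k: Path(v) for k, v in config.inputs.items()}
        for k, p in paths.items():
            if not p.exists():
                raise FileNotFoundError(f"input {k}: {p} does not exist")
    else:
        paths = _simulate_inputs(config, out)

    # --- stage: call hits per screen -------------------------------------
    tables = {}
    for screen in ("wt", "mut"):
        grids = screen_io.read_colony_table(paths[f"colony_{screen}"])
        smap = screen_io.read_strain_map(paths[f"strain_map_{screen}"])
        model = hit_calling.ScreenModel(
            grids, smap, screen=screen, day=config.day,
            replicate_exclusion=config.replicate_exclusion,
        )
        results = model.fit(alpha=config.alpha)
        tables[screen] = results.hit_table
        results.scores_frame().to_csv(out / f"scores_{screen}.tsv", sep="\t",
                                      index=False)
        screen_io.write_hit_table(results.hit_table, out / f"hits_{screen}.tsv")
        logger.info("%s screen: %d genes scored, %d SL, %d SS", screen,
                    len(results.table),
                    len(results.hit_table.genes(screen, "SL")),
                    len(results.hit_table.genes(screen, "SS")))

    # --- stage: merge ------------------------------------------------------
    modifiers = hit_calling.merge_hit_tables(tables["wt"], tables["mut"])
    (out / "modifiers.txt").write_text("".join(f"{g}\n" for g in sorted(modifiers)))
    logger.info("merged modifiers: %d unique genes", len(modifiers))

    # --- stage: orthologs --------------------------------------------------
    orth_tables = ortholog_map.read_ortholog_tables(paths["orthologs"])
    empty_run = not modifiers
    if empty_run:
        count, percent = 0, 0.0
        human_hits: set[str] = set()
    else:
        count, percent = ortholog_map.ortholog_fraction(
            modifiers, orth_tables, config.ortholog_policy
        )
        human_hits = ortholog_map.humanize(modifiers, orth_tables,
                                           config.ortholog_policy)
    (out / "ortholog_coverage.json").write_text(json.dumps(
        {"modifiers": len(modifiers), "mapped": count, "percent": percent,
         "human_symbols": len(human_hits)}, indent=2, sort_keys=True) + "\n")
    logger.info("orthologs: %d/%d modifiers mapped (%.1f%%)",
                count, len(modifiers), percent)

    # --- stage: networks ---------------------------------------------------
    pombe_full = network_analysis.load_edges(paths["pombe_edges"], config.min_conf,
                                             species="pombe")
    human_full = network_analysis.load_edges(paths["human_edges"], config.min_conf,
                                             species="human")

    pombe_primary = network_analysis.primary_network(modifiers, pombe_full)
    pombe_extended = network_analysis.extend_with_neighbors(modifiers, pombe_full)
    rescued = network_analysis.rescue_orphans(modifiers, pombe_primary,
                                              pombe_extended)
    human_primary = network_analysis.primary_network(human_hits, human_full)
    human_filtered = network_analysis.degree_filter(human_hits, human_full,
                                                    config.degree_k)

    categories = _gene_categories(tables)
    for name, net in (("pombe_primary", pombe_primary),
                      ("pombe_extended", pombe_extended),
                      ("human_primary", human_primary),
                      ("human_filtered", human_filtered)):
        network_analysis.export_graph(net, out / f"{name}.graphml", "graphml")
        network_analysis.export_graph(net, out / f"{name}.sif", "sif")
        _write_cluster_report(net, out / f"{name}_clusters.tsv", categories)
        logger.info("%s: %d nodes, %d edges, %d clusters", name,
                    net.graph.number_of_nodes(), net.graph.number_of_edges(),
                    len(network_analysis.clusters(net)))

    with open(out / "rescued_orphans.tsv", "w") as fh:
        fh.write("rescued_node\torphans\n")
        for node in sorted(rescued):
            fh.write(f"{node}\t{','.join(sorted(rescued[node]))}\n")
    logger.info("rescued orphans: %d connector nodes", len(rescued))

    # --- stage: cross-species overlap -------------------------------------
    overlap = network_analysis.cross_species_overlap(
        pombe_extended, human_primary, orth_tables, config.ortholog_policy
    ) if not empty_run else network_analysis.OverlapReport(set(), {})
    with open(out / "overlap.tsv", "w") as fh:
        fh.write("human_symbol\tyeast_gene\tyeast_role\n")
        for sym in sorted(overlap.shared):
            for gene, role in overlap.provenance[sym]:
                fh.write(f"{sym}\t{gene}\t{role}\n")
    logger.info("cross-species overlap: %d shared symbols", len(overlap.shared))

    # --- manifest ----------------------------------------------------------
    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "checksums": {p.name: _sha256(p) for p in files},
        "counts": {
            "modifiers": len(modifiers),
            "mapped": count,
            "percent_mapped": percent,
            "rescued": len(rescued),
            "overlap": len(overlap.shared),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True)
                                       + "\n")
    return out


def _gene_categories(tables: Mapping[str, screen_io.HitTable]) -> dict[str, str]:
    """gene -> comma-joined screen:category labels, for cluster reports."""
    out: dict[str, list[str]] = {}
    for screen, table in tables.items():
        for (scr, cat), records in table.lists.items():
            for r in records:
                out.setdefault(r.gene_id, []).append(f"{scr}:{cat}")
    return {g: ",".join(sorted(v)) for g, v in out.items()}


def _write_cluster_report(
    net: network_analysis.PPINetwork, path: Path, categories: Mapping[str, str]
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember\trole\tcategory\n")
        for i, cluster in enumerate(network_analysis.clusters(net), 1):
            for member in sorted(cluster.members):
                fh.write(f"{i}\t{member}\t{cluster.roles[member]}"
                         f"\t{categories.get(member, '')}\n")
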