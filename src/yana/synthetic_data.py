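"""Seeded generators for every pipeline input, with ground truth.

The generators emulate the statistical structure the analysis assumes and
nothing more:

* ``simulate_screen`` — quadruplicate 1536-format colony grids in both
  induction conditions with multiplicative plate effects, a linear spatial
  gradient, log-normal colony noise, a genome-wide induction cost (the
  wild-type query slows every strain), and planted SL/SS genes whose
  effect multiplies only the inducing condition.
* ``simulate_ppi`` — a preferential-attachment background graph whose
  confidence scores straddle the 0.900 threshold, plus planted modules
  whose within-module edges always qualify.
* ``simulate_orthologs`` — multi-source ortholog tables with a target
  mapped fraction, one-to-many expansions and per-source dropout.
* ``simulate_embryos`` — severity-profile draws with per-experiment
  structure, inverse to :func:`yana.phenotype_stats.classify_embryo`.

Every generator is a pure function of its config plus seed: identical
inputs give bit-identical outputs (and files, via the package writers).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ortholog_map import OrthologTable
from .phenotype_stats import DEFAULT_BINS, EmbryoScore, SeverityBins
from .screen_io import ColonyGrid, StrainMap

__all__ = [
    "BASE_COLONY_SIZE",
    "ScreenSimConfig",
    "SimTruth",
    "simulate_screen",
    "simulate_ppi",
    "simulate_orthologs",
    "simulate_embryos",
]

#: Baseline colony size in scanner area units before any modifier.
BASE_COLONY_SIZE = 200.0

_GRID_ROWS, _GRID_COLS = 32, 48  # 1536 format
_BLOCKS_PER_PLATE = (_GRID_ROWS // 2) * (_GRID_COLS // 2)  # 384 quadruplicate blocks


@dataclass
class ScreenSimConfig:
    """Study conditions of one simulated modifier screen.

    Defaults encode the scenario the analysis is built for: colony noise is
    log-normal with sigma 0.1 on the natural-log scale, plate effects are
    log-normal with sigma 0.15, the spatial gradient tilts sizes by +/-10%
    across the plate, planted SL genes grow at 50% and SS genes at 150%
    under induction, and induction itself costs every strain 20% growth.
    """

    n_genes: int
    n_plates: int | None = None
    planted_sl: frozenset[str] = frozenset()
    planted_ss: frozenset[str] = frozenset()
    effect_multiplier_sl: float = 0.5
    effect_multiplier_ss: float = 1.5
    noise_sigma: float = 0.1
    plate_effect_sigma: float = 0.15
    gradient_amplitude: float = 0.1
    global_induction_cost: float = 0.8
    screen: str = "wt"
    day: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_sl = frozenset(self.planted_sl)
        self.planted_ss = frozenset(self.planted_ss)
        if self.planted_sl & self.planted_ss:
            raise ValueError("planted SL and SS sets must be disjoint")
        for name in ("noise_sigma", "plate_effect_sigma", "gradient_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.effect_multiplier_sl < 1:
            raise ValueError("effect_multiplier_sl must lie in (0, 1)")
        if self.effect_multiplier_ss <= 1:
            raise ValueError("effect_multiplier_ss must exceed 1")
        if not 0 < self.global_induction_cost <= 1:
            raise ValueError("global_induction_cost must lie in (0, 1]")
        needed = -(-self.n_genes // _BLOCKS_PER_PLATE)
        if self.n_plates is None:
            self.n_plates = needed
        elif self.n_plates < needed:
            raise ValueError(
                f"{self.n_genes} genes need {needed} plates "
                f"({_BLOCKS_PER_PLATE} quadruplicate blocks each); "
                f"got n_plates={self.n_plates}"
            )

    def gene_ids(self) -> list[str]:
        return [f"SPSIM{i + 1:05d}" for i in range(self.n_genes)]


@dataclass
class SimTruth:
    """Ground truth behind one simulated screen."""

    categories: dict[str, str]  # gene -> SL | SS | null
    plate_effects: dict[tuple[str, str], float]  # (plate_id, condition) -> factor
    gradient: np.ndarray  # per-position multiplicative factor, 32 x 48


def _gradient(amplitude: float) -> np.ndarray:
    r = np.arange(_GRID_ROWS)[:, None] / (_GRID_ROWS - 1) - 0.5
    c = np.arange(_GRID_COLS)[None, :] / (_GRID_COLS - 1) - 0.5
    return 1.0 + amplitude * (r + c)


def simulate_screen(
    config: ScreenSimConfig,
) -> tuple[list[ColonyGrid], StrainMap, SimTruth]:
    """Generate quadruplicate colony grids for one screen plus ground truth.

    Each gene occupies one 2x2 block; blocks fill plates row-major.  A
    position's size is

        200 * plate_effect * gradient(row, col) * condition_factor
            * gene_effect * exp(N(0, noise_sigma^2))

    where ``condition_factor`` is the global induction cost on inducing
    plates only and ``gene_effect`` is the planted multiplier (inducing
    plates, planted genes only).
    """
    genes = config.gene_ids()
    unknown = (config.planted_sl | config.planted_ss) - set(genes)
    if unknown:
        raise ValueError(f"planted genes outside the simulated set: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    gradient = _gradient(config.gradient_amplitude)
    plate_ids = [f"plate{p + 1:02d}" for p in range(config.n_plates)]

    plate_effects = {
        (pid, cond): float(np.exp(rng.normal(0.0, config.plate_effect_sigma)))
        for pid in plate_ids
        for cond in ("inducing", "non_inducing")
    }

    entries: dict[tuple[str, int, int], str] = {}
    gene_at: dict[tuple[str, int, int], str] = {}
    for i, gene in enumerate(genes):
        pid = plate_ids[i // _BLOCKS_PER_PLATE]
        block = i % _BLOCKS_PER_PLATE
        br, bc = divmod(block, _GRID_COLS // 2)
        for dr, dc in itertools.product((0, 1), repeat=2):
            pos = (pid, 2 * br + dr + 1, 2 * bc + dc + 1)
            entries[pos] = gene
            gene_at[pos] = gene

    effect = {g: 1.0 for g in genes}
    effect.update({g: config.effect_multiplier_sl for g in config.planted_sl})
    effect.update({g: config.effect_multiplier_ss for g in config.planted_ss})

    grids: list[ColonyGrid] = []
    for pid in plate_ids:
        for cond in ("inducing", "non_inducing"):
            sizes = np.zeros((_GRID_ROWS, _GRID_COLS))
            noise = rng.normal(0.0, config.noise_sigma, size=sizes.shape)
            for r in range(_GRID_ROWS):
                for c in range(_GRID_COLS):
                    gene = gene_at.get((pid, r + 1, c + 1))
                    if gene is None:
                        continue
                    size = (
                        BASE_COLONY_SIZE
                        * plate_effects[(pid, cond)]
                        * gradient[r, c]
                        * np.exp(noise[r, c])
                    )
                    if cond == "inducing":
                        size *= config.global_induction_cost * effect[gene]
                    sizes[r, c] = size
            grids.append(ColonyGrid(pid, cond, config.day, sizes))

    categories = {
        g: "SL" if g in config.planted_sl else "SS" if g in config.planted_ss else "null"
        for g in genes
    }
    strain_map = StrainMap(entries, query=f"{config.screen}UBA1")
    return grids, strain_map, SimTruth(categories, plate_effects, gradient)


def simulate_ppi(
    n_nodes: int,
    attachment: int = 2,
    frac_above_threshold: float = 0.05,
    planted_modules: Sequence[Iterable] = (),
    seed: int = 0,
    node_names: Sequence[str] | None = None,
    path: str | Path | None = None,
    planted_stars: Sequence[Iterable] = (),
) -> pd.DataFrame:
    """Preferential-attachment PPI edge list with planted high-confidence modules.

    Background edges come from a Barabasi-Albert graph; each gets a score
    >= 900 with probability ``frac_above_threshold`` (uniform 900-1000) and
    a sub-threshold score (uniform 150-899) otherwise.  Planted modules are
    node sets whose every within-module pair is added at a score >= 900, so
    cluster extraction at 0.900 is guaranteed to see them.  Planted stars
    (first element the center, the rest leaves) add only center-leaf
    edges >= 900 — the motif behind orphan rescue, where leaves stay
    unconnected to each other.  Modules and stars may be given as 1-based
    node indices or as names from ``node_names``.

    Returns a DataFrame (gene_a, gene_b, score on the 0-1000 integer
    scale); also written as TSV when ``path`` is given.
    """
    if node_names is None:
        node_names = [f"G{i + 1:04d}" for i in range(n_nodes)]
    elif len(node_names) != n_nodes:
        raise ValueError("node_names length must equal n_nodes")

    def resolve(module: Iterable) -> set[str]:
        out = set()
        for m in module:
            if isinstance(m, (int, np.integer)):
                if not 1 <= m <= n_nodes:
                    raise ValueError(f"module node index {m} outside 1..{n_nodes}")
                out.add(node_names[m - 1])
            elif m in node_names:
                out.add(m)
            else:
                raise ValueError(f"module node {m!r} not among the simulated nodes")
        return out

    modules = [resolve(m) for m in planted_modules]
    for a, b in itertools.combinations(modules, 2):
        if a & b:
            raise ValueError("planted modules must be disjoint")

    import networkx as nx

    rng = np.random.default_rng(seed)
    background = nx.barabasi_albert_graph(n_nodes, attachment,
                                          seed=int(rng.integers(2**31)))
    scores: dict[tuple[str, str], int] = {}
    for u, v in sorted(background.edges):
        key = tuple(sorted((node_names[u], node_names[v])))
        if rng.random() < frac_above_threshold:
            scores[key] = int(rng.integers(900, 1001))
        else:
            scores[key] = int(rng.integers(150, 900))
    for module in modules:
        for a, b in itertools.combinations(sorted(module), 2):
            scores[(a, b)] = int(rng.integers(900, 1001))
    for star in planted_stars:
        star = list(star)
        center = sorted(resolve([star[0]]))[0]
        for leaf in sorted(resolve(star[1:])):
            if leaf != center:
                scores[tuple(sorted((center, leaf)))] = int(rng.integers(900, 1001))

    df = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(scores.items())],
        columns=["gene_a", "gene_b", "score"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False, header=["geneA", "geneB", "score"])
    return df


def simulate_orthologs(
    genes: Sequence[str],
    frac_mapped: float = 0.838,
    one_to_many_rate: float = 0.1,
    n_sources: int = 4,
    source_dropout: float = 0.2,
    seed: int = 0,
) -> list[OrthologTable]:
    """Multi-source ortholog tables over a yeast gene list.

    Each gene is mapped (gets >= 1 synthetic human symbol) independently
    with probability ``frac_mapped`` — 0.838 by default, the orthology
    coverage characteristic of the conserved fission-yeast core genome.  A
    mapped gene gains a second co-ortholog with probability
    ``one_to_many_rate``.  Each (gene, symbol) pair appears in each of the
    ``n_sources`` tables independently with probability 1 - dropout, but
    always in at least one.
    """
    for name, v in (("frac_mapped", frac_mapped),
                    ("one_to_many_rate", one_to_many_rate),
                    ("source_dropout", source_dropout)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tables = [OrthologTable(f"source_{k + 1}") for k in range(n_sources)]
    for i, gene in enumerate(genes):
        if rng.random() >= frac_mapped:
            continue
        symbols = [f"HSA{i + 1:05d}"]
        if rng.random() < one_to_many_rate:
            symbols.append(f"HSA{i + 1:05d}B")
        for sym in symbols:
            present = rng.random(n_sources) >= source_dropout
            if not present.any():
                present[rng.integers(n_sources)] = True
            for k in np.flatnonzero(present):
                tables[k].pairs.setdefault(gene, set()).add(sym)
    return tables


def simulate_embryos(
    group_profiles: Mapping[str, Mapping[str, float]],
    n_experiments: int = 4,
    n_per_experiment: int = 25,
    seed: int = 0,
    bins: SeverityBins = DEFAULT_BINS,
) -> list[EmbryoScore]:
    """Draw embryo severity scores from per-group category profiles.

    Per embryo, a category is drawn from its group's profile, then the
    abnormal-axon count is drawn uniformly from that category's bin — the
    exact inverse of :func:`yana.phenotype_stats.classify_embryo`, so
    classification recovers the drawn category for every embryo.
    """
    rng = np.random.default_rng(seed)
    scores: list[EmbryoScore] = []
    for group in group_profiles:
        profile = dict(group_profiles[group])
        if abs(sum(profile.values()) - 1.0) > 1e-9:
            raise ValueError(f"profile for {group!r} does not sum to 1")
        unknown = set(profile) - set(bins.edges)
        if unknown:
            raise ValueError(f"profile categories without bins: {sorted(unknown)}")
        cats = sorted(profile)
        probs = np.array([profile[c] for c in cats])
        for exp in range(1, n_experiments + 1):
            draws = rng.choice(len(cats), size=n_per_experiment, p=probs)
            for j, d in enumerate(draws, 1):
                lo, hi = bins.edges[cats[d]]
                n_axons = int(rng.integers(lo, hi + 1))
                scores.append(
                    EmbryoScore(f"{group}-e{exp}-{j:03d}", group, exp, n_axons)
                )
    return scores
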