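"""Colony-fitness scoring: from normalized grids to SL/SS hit lists.

The screen compares each deletion strain's growth with the disease-gene
query induced against its growth with the query repressed.  The statistic
is a log growth ratio

    lgr = ln(mean non-inducing size / mean inducing size)

computed from plate-median-normalized colony sizes, standardized robustly
(median / normal-consistent MAD) against the population of all scored
genes on the screen.  Positive lgr means the
strain grows worse when the query is expressed; large positive z-scores are
synthetic-lethal (SL) candidates, large negative ones synthetic-suppressor
(SS) candidates.  Centering on the population absorbs the genome-wide
growth cost the wild-type query imposes on every strain.

The entry point is :class:`ScreenModel`, a model object built from colony
grids plus a strain map; ``fit()`` returns a :class:`ScreenResults` carrying
per-gene scores, the hit table at the chosen alpha, and a ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen_io import ColonyGrid, HitRecord, HitTable, StrainMap

__all__ = [
    "normalize_grid",
    "exclude_replicates",
    "log_growth_ratio",
    "GeneMeasurement",
    "ScreenScores",
    "score_screen",
    "call_hits",
    "merge_hit_tables",
    "ScreenModel",
    "ScreenResults",
]

#: Default CV threshold for single-replicate exclusion.
DEFAULT_CV_THRESHOLD = 0.35

#: Minimum number of scoreable genes for population standardization.
MIN_POPULATION = 20


def normalize_grid(grid: ColonyGrid) -> ColonyGrid:
    """Divide every nonzero colony size by the plate's median nonzero size.

    After normalization the median of nonzero sizes is exactly 1 and zeros
    (missing/dead colonies) stay zero, so downstream statistics are
    comparable across plates regardless of pinning density or scanner gain.
    Raises ``ValueError`` on an all-zero plate.
    """
    nonzero = grid.sizes[grid.sizes > 0]
    if nonzero.size == 0:
        raise ValueError(
            f"plate {grid.plate_id} ({grid.condition}, day {grid.day}) is all-zero"
        )
    return ColonyGrid(
        grid.plate_id, grid.condition, grid.day, grid.sizes / np.median(nonzero)
    )


def _cv(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        return math.inf
    return values.std(ddof=1) / mean


def exclude_replicates(
    quad: Sequence[float], cv_threshold: float = DEFAULT_CV_THRESHOLD
) -> list[float]:
    """Drop at most one outlying replicate from a quadruplicate.

    If the coefficient of variation (sample SD / mean) exceeds
    ``cv_threshold`` and removing the single value farthest from the median
    brings it below the threshold, that value is excluded.  Fewer than 3
    values, or a removal that would not fix the CV, leaves the quad
    unchanged — pinning quadruplicates are too small for anything more
    aggressive than a single-outlier rule.
    """
    values = list(quad)
    if len(values) < 3:
        return values
    arr = np.asarray(values, dtype=float)
    if _cv(arr) <= cv_threshold:
        return values
    median = np.median(arr)
    dist = np.abs(arr - median)
    # ties on distance: try each farthest value, keep the removal with lowest CV
    candidates = np.flatnonzero(dist == dist.max())
    best_idx, best_cv = None, math.inf
    for i in candidates:
        cv_after = _cv(np.delete(arr, i))
        if cv_after < best_cv:
            best_idx, best_cv = i, cv_after
    if best_cv <= cv_threshold:
        return [v for j, v in enumerate(values) if j != best_idx]
    return values


def log_growth_ratio(mean_non_inducing: float, mean_inducing: float) -> float:
    """ln(mean non-inducing / mean inducing); positive = slower induced growth."""
    if mean_non_inducing <= 0 or mean_inducing <= 0:
        raise ValueError("log_growth_ratio needs positive means; zeros are handled upstream")
    return math.log(mean_non_inducing / mean_inducing)


@dataclass
class GeneMeasurement:
    """Normalized replicate sizes of one gene in both conditions."""

    gene_id: str
    screen: str
    sizes_inducing: list[float]
    sizes_non_inducing: list[float]
    excluded_replicates: set[int] = field(default_factory=set)


@dataclass
class ScreenScores:
    """Per-gene lgr/z/p table plus the population statistics behind z.

    ``population_center`` is the median lgr and ``population_scale`` the
    normal-consistent MAD — robust location/scale so that genuine hits do
    not inflate the null scale they are judged against.
    """

    screen: str
    table: pd.DataFrame  # index gene_id; columns lgr, z, p, flagged
    population_center: float
    population_scale: float
    dropped: list[str] = field(default_factory=list)  # dead in both conditions


def score_screen(
    measurements: Iterable[GeneMeasurement],
    *,
    min_retained: int = 2,
) -> ScreenScores:
    """Standardize log growth ratios across the screen's gene population.

    Zero handling: a gene dead in the non-inducing condition is dropped
    (dead independent of induction); a gene alive uninduced but dead
    induced is the strongest possible SL signal and gets the largest finite
    lgr plus one population scale unit, flagged.  Genes with fewer than
    ``min_retained`` replicates in either condition are dropped.

    z = (lgr - population median) / (normal-consistent population MAD),
    two-tailed p from the standard normal.  Robust location and scale keep
    the standardization honest when a few percent of genes carry real
    effects: genuine modifiers would inflate a mean/SD estimate and mask
    each other.  Raises ``ValueError`` if fewer than 20 genes are
    scoreable or the population scale is 0.
    """
    measurements = list(measurements)
    screens = {m.screen for m in measurements}
    if len(screens) > 1:
        raise ValueError(f"measurements mix screens {screens}; score one at a time")
    screen = screens.pop() if screens else "wt"

    finite: dict[str, float] = {}
    capped: list[str] = []
    dropped: list[str] = []
    for m in measurements:
        ind = [s for s in m.sizes_inducing if s > 0]
        non = [s for s in m.sizes_non_inducing if s > 0]
        if len(non) < min_retained:
            dropped.append(m.gene_id)
            continue
        if len(m.sizes_inducing) < min_retained:
            dropped.append(m.gene_id)
            continue
        mean_non = float(np.mean(non))
        mean_ind = float(np.mean(ind)) if ind else 0.0
        if mean_ind == 0.0:
            capped.append(m.gene_id)
        else:
            finite[m.gene_id] = log_growth_ratio(mean_non, mean_ind)

    if len(finite) + len(capped) < MIN_POPULATION:
        raise ValueError(
            f"only {len(finite) + len(capped)} scoreable genes; "
            f"population standardization needs >= {MIN_POPULATION}"
        )
    finite_values = np.array(list(finite.values()))
    finite_scale = stats.median_abs_deviation(finite_values, scale="normal")
    if finite_values.size < 2 or finite_scale == 0:
        raise ValueError("degenerate screen: population scale of lgr is 0")
    cap = finite_values.max() + finite_scale

    lgr = dict(finite)
    lgr.update({g: cap for g in capped})
    genes = sorted(lgr)
    values = np.array([lgr[g] for g in genes])
    center = np.median(values)
    scale = stats.median_abs_deviation(values, scale="normal")
    if scale == 0:
        raise ValueError("degenerate screen: population scale of lgr is 0")
    z = (values - center) / scale
    p = 2 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {"lgr": values, "z": z, "p": p, "flagged": [g in set(capped) for g in genes]},
        index=pd.Index(genes, name="gene_id"),
    )
    return ScreenScores(screen, table, float(center), float(scale), dropped)


def call_hits(
    scores: ScreenScores,
    alpha: float = 0.05,
    *,
    fdr: bool = False,
) -> HitTable:
    """Threshold scores at ``alpha`` and split into SL/SS lists.

    Genes with p <= alpha enter the table: z > 0 is SL (slower induced
    growth), z < 0 is SS.  Within a list, rank is by ascending p, ties
    broken by |z| descending then gene ID.  ``fdr=True`` applies a
    Benjamini-Hochberg correction to the p-values before thresholding
    (off by default: the screen convention is raw P <= 0.05).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    df = scores.table.copy()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        df["p"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    sig = df[df["p"] <= alpha]
    lists: dict[tuple[str, str], list[HitRecord]] = {}
    for category, sub in (("SL", sig[sig["z"] > 0]), ("SS", sig[sig["z"] < 0])):
        ordered = sorted(
            sub.itertuples(),
            key=lambda r: (r.p, -abs(r.z), r.Index),
        )
        lists[(scores.screen, category)] = [
            HitRecord(
                gene_id=r.Index,
                screen=scores.screen,
                category=category,
                rank=i,
                statistic=float(r.z),
                p_value=float(r.p),
            )
            for i, r in enumerate(ordered, 1)
        ]
    return HitTable(lists)


def merge_hit_tables(*tables: HitTable) -> set[str]:
    """Unique modifiers across every SL/SS list of every given table."""
    out: set[str] = set()
    for t in tables:
        out |= t.all_genes()
    return out


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

class ScreenModel:
    """Modifier-screen scoring model over colony grids and a strain map.

    Parameters
    ----------
    grids
        Colony grids covering both conditions of one screen (one query
        strain), typically several plates.
    strain_map
        Position -> gene assignment; every gene a quadruplicate.
    screen
        ``"wt"`` or ``"mut"`` — which query variant the grids belong to.
    day
        Scan day to analyze; plates are documented on several consecutive
        days and the model scores exactly one of them.
    replicate_exclusion
        Apply the single-outlier CV rule per quadruplicate per condition.
    cv_threshold
        CV threshold of the exclusion rule.
    """

    def __init__(
        self,
        grids: Iterable[ColonyGrid],
        strain_map: StrainMap,
        *,
        screen: str = "wt",
        day: int | None = None,
        replicate_exclusion: bool = True,
        cv_threshold: float = DEFAULT_CV_THRESHOLD,
    ) -> None:
        grids = list(grids)
        days = sorted({g.day for g in grids})
        if day is None:
            if len(days) != 1:
                raise ValueError(f"grids span days {days}; pass day= to select one")
            day = days[0]
        self.day = day
        self.screen = screen
        self.replicate_exclusion = replicate_exclusion
        self.cv_threshold = cv_threshold
        self.strain_map = strain_map
        self._grids = {
            (g.plate_id, g.condition): normalize_grid(g)
            for g in grids
            if g.day == day
        }
        if not self._grids:
            raise ValueError(f"no grids for day {day}")

    def measurements(self) -> list[GeneMeasurement]:
        """Per-gene normalized replicate sizes in both conditions."""
        out = []
        for gene, positions in self.strain_map.by_gene().items():
            sizes = {"inducing": [], "non_inducing": []}
            for condition in sizes:
                for plate, r, c in positions:
                    grid = self._grids.get((plate, condition))
                    if grid is None:
                        raise ValueError(
                            f"no {condition} grid for plate {plate} on day {self.day}"
                        )
                    sizes[condition].append(float(grid.sizes[r - 1, c - 1]))
                if self.replicate_exclusion:
                    sizes[condition] = exclude_replicates(
                        sizes[condition], self.cv_threshold
                    )
            out.append(
                GeneMeasurement(
                    gene_id=gene,
                    screen=self.screen,
                    sizes_inducing=sizes["inducing"],
                    sizes_non_inducing=sizes["non_inducing"],
                )
            )
        return out

    def fit(self, alpha: float = 0.05, *, fdr: bool = False) -> "ScreenResults":
        scores = score_screen(self.measurements())
        hits = call_hits(scores, alpha, fdr=fdr)
        return ScreenResults(self, scores, hits, alpha)


class ScreenResults:
    """Fitted screen: per-gene scores, hit table and a text summary."""

    def __init__(
        self, model: ScreenModel, scores: ScreenScores, hits: HitTable, alpha: float
    ) -> None:
        self.model = model
        self.scores = scores
        self.hit_table = hits
        self.alpha = alpha

    @property
    def table(self) -> pd.DataFrame:
        return self.scores.table

    def scores_frame(self) -> pd.DataFrame:
        """Audit table (gene_id, screen, lgr, z, p) ready for TSV export."""
        df = self.scores.table.reset_index()
        df.insert(1, "screen", self.scores.screen)
        return df[["gene_id", "screen", "lgr", "z", "p"]]

    def summary(self) -> str:
        s = self.scores
        n_sl = len(self.hit_table.genes(s.screen, "SL"))
        n_ss = len(self.hit_table.genes(s.screen, "SS"))
        lines = [
            f"Modifier screen results ({s.screen} query, day {self.model.day})",
            "=" * 54,
            f"genes scored          {len(s.table):>8d}",
            f"genes dropped (dead)  {len(s.dropped):>8d}",
            f"population median lgr {s.population_center:>8.4f}",
            f"population MAD scale  {s.population_scale:>8.4f}",
            f"alpha                 {self.alpha:>8.3g}",
            f"SL hits (z > 0)       {n_sl:>8d}",
            f"SS hits (z < 0)       {n_ss:>8d}",
            f"replicate exclusion   {str(self.model.replicate_exclusion):>8s}",
        ]
        return "\n".join(lines)
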