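"""Motor-axon severity scoring for zebrafish knockdown experiments.

Each embryo contributes a count of abnormal motor axons out of the 20
scored (myotomes 6-15, both sides of the trunk).  Counts are binned into
severity categories — none / mild / moderate / severe — per a configurable
partition of 0..20, percentages are computed per experiment, and groups
are summarized as mean percent +/- SEM *across experiments* (the unit of
replication is the experiment, not the embryo).

Group comparison pools category counts and runs a chi-square test of
homogeneity, falling back to a seeded permutation test when any expected
count is below 5; the result always names the method used.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MAX_AXONS",
    "DEFAULT_BINS",
    "SeverityBins",
    "EmbryoScore",
    "GroupSummary",
    "classify_embryo",
    "group_summary",
    "compare_groups",
    "read_embryo_table",
    "write_embryo_table",
    "summary_frame",
]

#: Axons scored per embryo: myotomes 6-15, both sides.
MAX_AXONS = 20

CATEGORY_ORDER = ("severe", "moderate", "mild", "none")


@dataclass(frozen=True)
class SeverityBins:
    """Partition of 0..20 abnormal-axon counts into severity categories.

    ``edges`` maps category -> (lo, hi) inclusive.  The bins must cover
    0..20 exactly once; the published figure legends name the categories
    but not the cut points, so the cut points are configuration.
    """

    edges: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        covered: dict[int, str] = {}
        for cat, (lo, hi) in self.edges.items():
            if lo > hi:
                raise ValueError(f"bin {cat}: lo {lo} > hi {hi}")
            for n in range(lo, hi + 1):
                if n in covered:
                    raise ValueError(f"bins overlap at {n} ({covered[n]} / {cat})")
                covered[n] = cat
        missing = set(range(MAX_AXONS + 1)) - set(covered)
        if missing:
            raise ValueError(f"bins leave counts uncovered: {sorted(missing)}")

    @property
    def categories(self) -> list[str]:
        """Categories in canonical severe -> none order, then any extras."""
        known = [c for c in CATEGORY_ORDER if c in self.edges]
        extra = sorted(set(self.edges) - set(CATEGORY_ORDER))
        return known + extra

    def category_of(self, n: int) -> str:
        for cat, (lo, hi) in self.edges.items():
            if lo <= n <= hi:
                return cat
        raise ValueError(f"count {n} outside 0..{MAX_AXONS}")


DEFAULT_BINS = SeverityBins(
    {"none": (0, 0), "mild": (1, 3), "moderate": (4, 7), "severe": (8, MAX_AXONS)}
)


@dataclass(frozen=True)
class EmbryoScore:
    """One embryo's abnormal-axon count within one experiment of one group."""

    embryo_id: str
    group: str
    experiment_id: int
    n_abnormal_axons: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_abnormal_axons <= MAX_AXONS:
            raise ValueError(
                f"n_abnormal_axons must lie in 0..{MAX_AXONS}, "
                f"got {self.n_abnormal_axons}"
            )


@dataclass
class GroupSummary:
    """Mean percent +/- SEM per severity category for one group."""

    group: str
    mean_percent: dict[str, float]
    sem_percent: dict[str, float | None]  # None when only one experiment
    n_per_experiment: list[int]

    @property
    def n_experiments(self) -> int:
        return len(self.n_per_experiment)


def classify_embryo(n_abnormal_axons: int, bins: SeverityBins = DEFAULT_BINS) -> str:
    """Severity category of one abnormal-axon count under the given bins."""
    if not 0 <= n_abnormal_axons <= MAX_AXONS:
        raise ValueError(f"count must lie in 0..{MAX_AXONS}")
    return bins.category_of(n_abnormal_axons)


def _per_experiment_percent(
    scores: Sequence[EmbryoScore], bins: SeverityBins
) -> pd.DataFrame:
    """Rows = experiments, columns = categories, values = percent (sums to 100)."""
    rows = {}
    for exp in sorted({s.experiment_id for s in scores}):
        embryos = [s for s in scores if s.experiment_id == exp]
        counts = {c: 0 for c in bins.categories}
        for s in embryos:
            counts[classify_embryo(s.n_abnormal_axons, bins)] += 1
        total = len(embryos)
        rows[exp] = {c: 100.0 * counts[c] / total for c in bins.categories}
    return pd.DataFrame.from_dict(rows, orient="index")[list(bins.categories)]


def group_summary(
    scores: Iterable[EmbryoScore], bins: SeverityBins = DEFAULT_BINS
) -> GroupSummary:
    """Mean and SEM of category percentages across experiments for one group.

    Percentages are computed within each experiment first; mean and SEM
    (sample SD / sqrt(n_experiments)) are then taken across experiments.
    With a single experiment the mean is reported and SEM is ``None``.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("no embryos given")
    groups = {s.group for s in scores}
    if len(groups) > 1:
        raise ValueError(f"scores mix groups {groups}; summarize one at a time")
    pct = _per_experiment_percent(scores, bins)
    n_exp = len(pct)
    mean = pct.mean(axis=0).to_dict()
    if n_exp >= 2:
        sem = (pct.std(axis=0, ddof=1) / np.sqrt(n_exp)).to_dict()
    else:
        sem = {c: None for c in pct.columns}
    n_per_exp = [
        sum(1 for s in scores if s.experiment_id == exp) for exp in pct.index
    ]
    return GroupSummary(groups.pop(), mean, sem, n_per_exp)


def compare_groups(
    g1: Iterable[EmbryoScore],
    g2: Iterable[EmbryoScore],
    bins: SeverityBins = DEFAULT_BINS,
    *,
    n_permutations: int = 10000,
    seed: int = 0,
) -> dict:
    """Test whether two groups share one severity distribution.

    Pools embryos across experiments into a categories x 2 contingency
    table and applies a chi-square test of homogeneity.  When any expected
    count is < 5 the chi-square approximation is unreliable, so a seeded
    permutation test on the same statistic is used instead.  Returns a dict
    with ``method`` ("chi2" or "permutation"), ``statistic``, ``p_value``
    and the pooled table.
    """
    g1, g2 = list(g1), list(g2)
    if not g1 or not g2:
        raise ValueError("both groups need at least one embryo")
    cats = list(bins.categories)
    counts = np.zeros((len(cats), 2))
    labels = []
    values = []
    for j, grp in enumerate((g1, g2)):
        for s in grp:
            i = cats.index(classify_embryo(s.n_abnormal_axons, bins))
            counts[i, j] += 1
            labels.append(j)
            values.append(i)
    # rows empty in both groups carry no information
    keep = counts.sum(axis=1) > 0
    table = counts[keep]
    if table.shape[0] < 2:
        return {"method": "chi2", "statistic": 0.0, "p_value": 1.0, "table": counts}
    expected = stats.contingency.expected_freq(table)
    if (expected >= 5).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return {"method": "chi2", "statistic": float(chi2), "p_value": float(p),
                "table": counts}

    def statistic(tab: np.ndarray) -> float:
        exp = stats.contingency.expected_freq(tab)
        mask = exp > 0
        return float((((tab - exp) ** 2)[mask] / exp[mask]).sum())

    observed = statistic(table)
    rng = np.random.default_rng(seed)
    labels_arr = np.array(labels)
    values_arr = np.array(values)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels_arr)
        tab = np.zeros((len(cats), 2))
        np.add.at(tab, (values_arr, perm), 1)
        tab = tab[tab.sum(axis=1) > 0]
        if statistic(tab) >= observed - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return {"method": "permutation", "statistic": observed, "p_value": float(p),
            "table": counts}


# ---------------------------------------------------------------------------
# I/O and report layout
# ---------------------------------------------------------------------------

def read_embryo_table(path: str | Path) -> list[EmbryoScore]:
    """Read embryo TSV (embryo_id, group, experiment_id, n_abnormal_axons)."""
    df = pd.read_csv(path, sep="\t", dtype={"embryo_id": str, "group": str})
    expected = ["embryo_id", "group", "experiment_id", "n_abnormal_axons"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}")
    return [
        EmbryoScore(r.embryo_id, r.group, int(r.experiment_id),
                    int(r.n_abnormal_axons))
        for r in df.itertuples()
    ]


def write_embryo_table(scores: Iterable[EmbryoScore], path: str | Path) -> None:
    rows = sorted(scores, key=lambda s: (s.group, s.experiment_id, s.embryo_id))
    with open(path, "w") as fh:
        fh.write("embryo_id\tgroup\texperiment_id\tn_abnormal_axons\n")
        for s in rows:
            fh.write(f"{s.embryo_id}\t{s.group}\t{s.experiment_id}"
                     f"\t{s.n_abnormal_axons}\n")


def summary_frame(
    scores: Iterable[EmbryoScore],
    bins: SeverityBins = DEFAULT_BINS,
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Categories x groups report: 'mean (± SEM)' cells plus an 'n (per exp)' row."""
    scores = list(scores)
    groups = group_order or sorted({s.group for s in scores})
    columns = {}
    for grp in groups:
        gs = group_summary([s for s in scores if s.group == grp], bins)
        col = {}
        for cat in bins.categories:
            mean = gs.mean_percent[cat]
            sem = gs.sem_percent[cat]
            col[cat] = (
                f"{mean:.1f} (± {sem:.1f})" if sem is not None else f"{mean:.1f} (n/a)"
            )
        col["n (per exp)"] = "/".join(str(n) for n in gs.n_per_experiment)
        columns[grp] = col
    index = list(bins.categories) + ["n (per exp)"]
    return pd.DataFrame(columns)[list(groups)].reindex(index)
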