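# yana — yeast-augmented network analysis

`yana` is a pipeline for turning a fission-yeast (*Schizosaccharomyces
pombe*) genetic-modifier screen of a human disease gene into a ranked set
of candidate therapeutic targets.  It is aimed at groups who run synthetic
genetic array (SGA) screens — crossing a query strain that expresses a
human gene against a genome-wide deletion collection and reading out
colony sizes — and who want the downstream analysis (hit calling, ortholog
mapping, interaction-network construction and cross-species comparison) as
reproducible, tested code rather than a chain of spreadsheets.

## What it computes

**Hit calling.**  Each deletion strain is pinned in quadruplicate on
inducing and non-inducing plates (a thiamine-repressible *nmt1* promoter
drives the query gene).  After per-plate median normalization, each gene
gets a log growth ratio

```
lgr_g = ln( mean non-inducing size / mean inducing size )
```

standardized robustly across the screen, `z_g = (lgr_g − median) / MAD*`
(MAD* = normal-consistent median absolute deviation), with a two-tailed
normal p-value.  Genes at `p ≤ 0.05` are *synthetic lethal* (SL, `z > 0`:
deletion worsens growth under induction) or *synthetic suppressors* (SS,
`z < 0`).  Centering on the population absorbs the genome-wide growth cost
the wild-type query imposes on every strain; an optional single-outlier
CV rule handles bad pinnings within a quadruplicate.

**Network augmentation.**  The merged modifier set induces a *primary*
subnetwork on a STRING-style interaction map thresholded at the
highest-confidence experiments channel (score ≥ 0.900).  Modifiers with no
edge to any other modifier are *orphans*.  The yeast network is *extended*
with all first-degree neighbors; a neighbor adjacent to at least two
orphans *rescues* them into a cluster the primary map could not show.  A
one-pass degree filter (≥ k interactions with other modifiers, default
k = 2) trims the human network to its densest clusters.

**Cross-species overlap.**  Yeast genes are mapped to human symbols by
consensus over several curated ortholog tables (union or majority policy);
symbols present in both the humanized extended yeast network and the human
primary network are the cross-validated target nominations, reported with
their yeast provenance (hit / rescued / neighbor).

**Phenotype statistics.**  For downstream validation in a zebrafish
knockdown model, per-embryo abnormal motor-axon counts (out of 20 scored)
are binned into severity categories and summarized as mean percent ± SEM
across experiments, with a chi-square (or seeded permutation) test between
groups.

A seeded synthetic-data module generates every input — colony grids with
plate effects, spatial gradients and log-normal noise, PPI edge lists with
planted modules, ortholog tables, embryo scores — so the whole pipeline is
testable offline, with ground truth.

The package also ships the published four-list hit table of the
*UBA1*/mut*UBA1* screens as a checksummed fixture
(`yana.read_table1_fixture()`); the union of its lists is the screen's
173 unique modifiers.

## Worked example

```python
from yana import ScreenSimConfig, simulate_screen, ScreenModel

genes = ScreenSimConfig(n_genes=400).gene_ids()
config = ScreenSimConfig(
    n_genes=400,
    planted_sl=frozenset(genes[:10]),    # grow at 50% under induction
    planted_ss=frozenset(genes[10:20]),  # grow at 150% under induction
    seed=7,
)
grids, strain_map, truth = simulate_screen(config)
results = ScreenModel(grids, strain_map, screen="wt").fit(alpha=0.05)
print(results.summary())
```

```
Modifier screen results (wt query, day 1)
======================================================
genes scored               400
genes dropped (dead)         0
population median lgr   0.0108
population MAD scale    0.0727
alpha                     0.05
SL hits (z > 0)             16
SS hits (z < 0)             21
replicate exclusion       True
```

All 10 planted SL genes are recovered on the SL side (the strongest at
`z ≈ 11`, `p ≈ 2e-29`) and all 10 planted SS genes on the SS side; the
remaining calls are the ~5% of 400 null genes expected at a raw
`p ≤ 0.05` cutoff.  The positive population median lgr (0.011) is the
genome-wide induction cost that the centering removes.

The same thing end-to-end, through networks and overlap:

```python
from yana import PipelineConfig, run

out = run(PipelineConfig(out_dir="demo_run", seed=3, n_genes=400))
```

writes hit tables, score audits, GraphML/SIF networks, cluster reports,
rescued-orphan and overlap tables into `demo_run/`, plus a
`manifest.json` whose counts for this config read

```json
{
  "modifiers": 69,
  "mapped": 55,
  "percent_mapped": 79.7,
  "rescued": 1,
  "overlap": 61
}
```

i.e. 69 unique modifiers across the wt and mut screens, 55 of them with a
human ortholog, one neighbor rescuing two orphan hits, and 61 human
symbols shared between the humanized extended yeast network and the human
primary network.  Re-running with the same config reproduces the manifest
checksums byte for byte.

The same stages are available from a shell:

```sh
yana run-all --config config.yaml
yana call-hits --colony colony_wt.csv --strain-map strain_map_wt.tsv \
    --screen wt --out hits_wt.tsv
yana map-orthologs --hits hits_wt.tsv --hits hits_mut.tsv \
    --orthologs orthologs.tsv
```

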