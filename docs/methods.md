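# Methods

This note records the statistical model, the defaults and the design
choices behind `yana`, in the order the pipeline runs them.

## Screen model and hit statistic

An SGA modifier screen crosses a query strain (here: one expressing a
human disease gene from the thiamine-repressible *nmt1* promoter) into a
genome-wide deletion collection, pins each cross in quadruplicate into a
1536-format array (32 × 48; each gene a 2 × 2 block), and photographs the
plates under inducing (−thiamine) and non-inducing (+thiamine) conditions.
The data model is a per-plate matrix of colony sizes in arbitrary area
units, with 0 meaning "no colony" — a pinning failure and a dead strain
are not distinguishable from a single image, so zeros are excluded from
statistics rather than imputed.

Scoring proceeds per screen (one query variant at a time):

1. **Plate normalization.**  Every nonzero size is divided by the median
   nonzero size of its plate.  This removes plate-to-plate effects
   (media batch, pinning pressure, scanner gain) and makes the statistic
   scale-invariant: multiplying a plate by any c > 0 changes nothing
   downstream.  A spatial row/column gradient that is common to the two
   conditions cancels exactly in the ratio below and is deliberately not
   modeled further (no lowess correction).
2. **Replicate exclusion (optional, on by default).**  Within a
   quadruplicate and condition, if the coefficient of variation
   (sample SD / mean) exceeds 0.35 and removing the single value farthest
   from the median brings it under the threshold, that value is dropped.
   At most one value is ever dropped, and nothing is attempted with fewer
   than three values.  Both modes (with/without exclusion) are first-class
   because pinning artifacts are common but an aggressive rule would eat
   real variance.
3. **Log growth ratio.**  Per gene,
   `lgr = ln(mean non-inducing / mean inducing)` over the retained nonzero
   replicates.  Positive lgr = slower growth when the query is induced.
   A gene dead in the non-inducing condition is dropped (dead regardless
   of the query); a gene alive uninduced but dead induced is the strongest
   possible SL signal and is assigned the largest finite lgr on the screen
   plus one population scale unit, flagged as capped — this keeps it at
   the top of the ranking without introducing infinities.
4. **Robust standardization.**  `z = (lgr − median) / MAD*` with MAD* the
   normal-consistent median absolute deviation (MAD × 1.4826) over all
   scored genes, and a two-tailed p from the standard normal.  Centering
   absorbs the genome-wide induction cost (the wild-type query slows
   every strain, so the *contrast* per gene must be judged against the
   screen-wide typical contrast, not against zero).  Location and scale
   are robust rather than mean/SD because the screen's own hits are part
   of the population: with a few percent of genes carrying real effects,
   a mean/SD estimate inflates (in the simulated acceptance conditions,
   from ≈0.07 to ≈0.12), attenuating every z-score and masking the weaker
   class of hits.  Under a pure null the two choices coincide in
   expectation, so type-I calibration is unaffected.
5. **Hit calling.**  Genes at `p ≤ α` (default α = 0.05, raw — the screen
   convention is an uncorrected rank list; a Benjamini–Hochberg option
   exists behind `fdr=True`, off by default) split by sign into SL
   (z > 0) and SS (z < 0), ranked by ascending p, ties broken by |z|
   descending then gene ID.  At least 20 scoreable genes and 2 retained
   replicates per condition are required; a zero population scale
   (a noise-free degenerate simulation) is an error, not a silent pass.

The p-value is a population z-test by construction.  Whether the original
screen software used a z-test, t-test, or an internal empirical model is
not documented anywhere we could verify, so the statistic above is a
reimplementation of the standard colony-screen scheme, documented as such,
and not a bit-compatible clone of any particular tool.

## Ortholog consensus

Curated orthology resources are loaded as static tables (source,
yeast ID, human symbol); nothing is fetched at run time.  Two policies
combine them: **union** (default — any source suffices; conflicts are rare
in the conserved core genome and union maximizes downstream network
recall) and **majority** (a symbol needs more than half of the sources
that mention the gene).  The majority denominator is per-gene, so a gene
absent from half the resources is not penalized for their silence.
Coverage is reported as the mapped count and the percentage rounded to
one decimal.

## Network construction and augmentation

Interaction data follow the STRING convention: integer scores 0–1000 on
disk, divided by 1000, experiments channel only, thresholded inclusively
at 0.900 (the "highest confidence" preset).  Symmetric duplicates keep
the maximum score.

* **Primary network** — subgraph induced on the modifier set; modifiers
  the map never connects stay as degree-0 *orphans* (an orphan is defined
  as a hit with zero edges to other hits at threshold).
* **Clusters** — connected components of size ≥ 2, ordered by size then
  smallest member.
* **Degree filter** — one pass: degrees are measured against the
  unfiltered hit-induced subgraph and nodes with ≥ k (default 2) survive.
  This is deliberately not an iterative k-core: the criterion is
  "interacts with ≥ k screen modifiers", which does not change when a
  weakly connected partner is trimmed.
* **Extension** — hits plus all first-degree neighbors, keeping *all*
  qualifying edges among the extended node set, including
  neighbor–neighbor edges (the alternative — hit–neighbor edges only —
  would hide neighbor-mediated structure; anyone wanting it can induce on
  roles afterwards).
* **Orphan rescue** — a non-hit node of the extended network adjacent to
  ≥ 2 orphans.  Rescue exists because a connector may be essential (absent
  from a deletion collection) or simply missed by the screen; requiring
  two orphans keeps single-neighbor noise out.
* **Cross-species overlap** — every yeast node of the extended network is
  humanized through the ortholog tables and intersected with the human
  primary network's node set; each shared symbol is reported with the
  yeast gene(s) and role(s) (hit / rescued / neighbor) that produced it.

Species ID spaces never mix inside one graph; the only crossing point is
the ortholog mapping.  Exports are SIF and GraphML with deterministic
(lexicographic) ordering, so identical networks give byte-identical files.

## Phenotype statistics

Validation experiments score 20 motor axons per embryo (myotomes 6–15,
both sides) and classify each embryo by its abnormal-axon count.  The
severity cut points are configuration, not constants — the source figure
legends name the categories (severe / moderate / mild / none) but not the
bin edges — with defaults none = 0, mild = 1–3, moderate = 4–7,
severe = ≥ 8, validated to partition 0..20.  Percentages are computed
within each experiment and then averaged, with SEM = SD/√(n experiments)
*across experiments*: the experiment, not the embryo, is the unit of
replication.  Group comparison pools counts into a categories × 2 table
and uses a chi-square test of homogeneity, replaced by a seeded
permutation test on the same statistic whenever an expected count falls
below 5 (there is no closed-form exact test for r × 2 tables in our
stack); the output always names the method used.  No attempt is made to
reproduce any particular published p-value, whose underlying test is
unidentified.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of config + seed (bit-reproducible files).

* **Screen** — `size = 200 × plate_effect × gradient × condition ×
  gene_effect × exp(N(0, σ²))`.  Defaults: log-normal colony noise
  σ = 0.1; log-normal plate effects σ = 0.15, drawn independently per
  physical plate (inducing and non-inducing plates are different pieces of
  agar); a ±10% linear row+column gradient; a global induction cost of
  0.8 (the query slows every strain by 20%); planted SL genes at ×0.5 and
  SS at ×1.5 under induction.  Multiplicative log-normal noise makes lgr
  exactly normal under the null, so calibration tests have clean
  expectations — real colony noise is only approximately so, with
  edge-of-plate and pinning artifacts the generator does not model.
* **PPI** — Barabási–Albert background (attachment 2) with scores
  straddling the 0.900 cutoff; planted modules are cliques wholly above
  threshold, planted stars (used for rescue scenarios) add only
  center–leaf edges.  Real interaction maps have far richer structure;
  what the planted-module tests show is that *extraction is exact when
  the signal is*, not that real modules are recovered.
* **Orthologs** — per-gene Bernoulli mapping at 0.838 (the coverage level
  typical of the conserved fission-yeast core genome), 10% one-to-many
  expansions, four sources with 20% per-pair dropout but guaranteed
  presence in at least one.
* **Embryos** — category drawn from a per-group profile, count drawn
  uniformly within the category's bin (the exact inverse of the
  classifier).

Passing tests on these generators demonstrates the statistical machinery
(calibration, recovery, graph rules) under the stated assumptions; they do
not certify performance on any particular real screen.

## Problem sizes and determinism

The simulation-based checks run at 2000 genes (≈ 6 × 1536-format plates
per condition), 30 planted SL + 30 SS, 4 replicates, 5 seeds — large
enough for stable population statistics and tight binomial bounds, small
enough to run in seconds.  The rescue rule is verified against brute-force
enumeration on 200 random graphs (≤ 12 nodes) and exhaustively over all
2¹⁰ edge subsets of a 5-node template.  All randomness flows through
`numpy.random.default_rng` seeds; the pipeline manifest records a config
hash and per-file SHA-256 so identical runs are verifiably identical.

## Known limitations

* The published cluster counts (22 unfiltered / 10 degree-filtered human
  clusters) and the specific nominated targets depend on a particular
  historical STRING snapshot that is not shipped; the package reproduces
  the *logic* on synthetic and toy data, not those numbers.
* Hit calling assumes the two conditions are imaged at comparable pinning
  generations; the `day` selector picks one scan day rather than modeling
  growth over days.
* One-to-many ortholog expansions can let a single yeast gene contribute
  several human symbols to the overlap; provenance in the report makes
  this visible rather than collapsing it.
* The permutation fallback in group comparison is Monte-Carlo (seeded,
  10 000 draws by default), so its p-values carry ~1/√N resolution.
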