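# Methods

## Pan-marker screen

The screen asks, per gene and target cluster, two questions: is the gene
*ubiquitous* in the cluster, and is it *specific* to it.

* **Ubiquity** is the in-cluster positivity fraction, computed on raw UMI
  counts (`count > 0`). No normalization enters this statistic, because
  positivity at the UMI level is the detection event itself.
* **Specificity** is the minimum pairwise log2 fold-change of cluster means
  against every other cluster. Means are taken on depth-normalized
  expression: counts are scaled to `scale_total` (default 10 000) per cell,
  log1p-transformed for storage, and de-logged back to the linear
  counts-per-10k scale before averaging; a pseudocount of 1 is added to
  both cluster means. Base 2 with pseudocount on de-logged cluster means is
  the dominant single-cell ecosystem convention for reported fold changes,
  and both the base and the pseudocount are arguments.

Thresholds (`pct_in > 0.90`, `min_logfc > 1`) are strict inequalities, and
passing genes are ranked by `min_logfc` descending, ties broken by `pct_in`
descending then gene id ascending, so output order is deterministic.

Simple library-size normalization (CP10K log1p) is used rather than a
variance-stabilizing regression model: positivity is defined on raw counts
regardless, and the fold-change statistic compares cluster means, which is
robust to the choice of depth normalization. The normalization is its own
operation and can be swapped without touching the screen logic.

Note that the measured `min_logfc` of a marker planted at fold change *f*
sits slightly below log2(*f*): the pseudocount shrinks large ratios, and a
strongly expressed marker inflates its own cells' library sizes. Both
effects shrink as expression depth grows; recovery tests account for them
by testing at adequate depth.

## Positivity overlap analysis

`overlap_analysis` builds the complete sign-pattern contingency table over
a marker panel and derives: per-marker counts and percentages (denominator:
all cells), conditional positivity A|B (denominator: B-positive cells;
undefined — serialized `"NA"`, never 0 — when no cell is B-positive), and,
given a reference marker, the distribution of how many *other* markers each
reference-positive cell carries (denominators: reference-positive cells for
the all-negative fraction; reference-positive cells with ≥ 1 other marker
for the exclusivity fraction). Internal coherence (pattern sums, marginal
consistency, inclusion–exclusion) is asserted on every construction.
Percentages for printed-precision comparison are rounded half away from
zero; raw fractions are always available.

## The RC overlap fixture

The packaged fixture reconstructs the joint positivity structure of the
resting-chondrocyte cluster of the growth-plate scRNA-seq dataset:
1 359 cells over (Apoe, Pthlh, Axin2, Foxa2). The published analysis fixes
the marginals (1 324 / 237 / 32 / 57), the Apoe-intersections
(233 / 32 / 51), the Apoe+ union (301), the exactly-one count (286), the
Apoe+ triple-negative count (1 023) and the absence of
Pthlh+Axin2+Foxa2+ triples. By inclusion–exclusion with zero triples the
Apoe+ double-positives number (233+32+51) − 301 = 15, but their split
across marker pairs is not published, nor is the overlap structure of the
35 Apoe− cells. The default table therefore assigns all 15 doubles to the
Pthlh∩Foxa2 pair and keeps the 4 Apoe−Pthlh+ and 6 Apoe−Foxa2+ cells
disjoint. Any assignment consistent with the published sums yields
identical values for every quantity the package reports, so this choice is
consequence-free; it is documented rather than hidden. Positive entries are
stored as count 1 — the positivity rule is `count > 0`, so magnitude is
irrelevant downstream.

Whole-dataset screen statistics (the 41-gene passing set, the top fold
change of 3.87, the >97% positivity on the real cluster) require the
deposited expression matrix and are not reproducible from printed numbers;
they are covered by simulation-based recovery tests instead.

## Synthetic count generator

`generate_counts` emulates five growth-plate chondrocyte clusters with
negative-binomial (mean + size parameterization) UMI counts.

* Background genes: NB(`baseline_mean` = 0.5, `dispersion` = 1.0) shared
  across clusters — typical magnitudes for non-marker genes in shallow
  10x-style data (positivity ≈ 0.33/gene, library sizes of a few hundred
  to a thousand UMIs at 500–2000 genes).
* Planted markers: in non-target clusters, NB(`background_mean`); in the
  target cluster, a Bernoulli(`in_cluster_positivity`) zero-inflation over
  a *zero-truncated* NB. Truncation makes expected positivity exactly the
  requested value, independently of the expression magnitude; the
  expressed-cell mean is solved (Brent root finding on the truncated-mean
  identity) so the target-cluster mean equals
  `fold_change x background_mean` exactly. When `background_mean` is 0 the
  ratio constraint is vacuous and a unit reference mean is used. A
  requested combination whose expressed-cell mean would fall below 1 (every
  positive count is at least 1) is rejected as infeasible.
* All randomness flows from one integer seed through a counter-based
  Philox generator; outputs are bit-identical across platforms.

The generator makes no attempt to emulate ambient RNA, doublets, batch
effects, variance-stabilized residuals, or realistic gene–gene correlation;
passing recovery tests show the statistics behave as designed under clean
NB sampling, not that they are robust to those artifacts.

## Flow events and gating

A gating tree is an ordered list of named nodes, each a conjunction of
strict threshold comparisons ('+' means strictly above; events exactly at
threshold are negative). The packaged default encodes the skeletal
stem/progenitor scheme: viability− → CD45−Tie2−Ter119− (lineage
exclusion) → mCherry+ → {BCSP: CD51+Thy−6C3−CD105+;
SSC: CD51+Thy−6C3−CD105−CD200+; pre-BCSP: CD51+Thy−6C3−CD105−CD200−}.
The BCSP (CD105+) branch is declared first, since BCSP is defined
irrespective of CD200; declared order is the tie-break, though the three
signatures are mutually exclusive by construction. Thresholds are explicit
per-channel numbers in the tree file (gating thresholds are operator-set in
practice); the synthetic default is 0 on a log-intensity scale with
population modes at ±2 (spread 0.5).

`generate_flow_events` fills the denominator compartment: every event
satisfies the denominator chain; events of a requested population
additionally satisfy exactly that population's signature (guaranteed-side
draws: threshold ± |N(2, 0.5)|), and remainder events are constructed to
fail every population's signature (CD51-negative under the default tree).
Recovered percentages therefore differ from requested fractions only by
multinomial sampling noise, which is what the recovery tests bound.

## EdU pulse-chase model

Each cell is a renewal process: i.i.d. log-normal cycle lengths with mean
`mean_cycle_time` (hours) and coefficient of variation `cycle_time_cv`
(cv = 0 gives deterministic cycles); cells start at uniform random phase
(or synchronized at cycle start for oracle comparisons). S phase occupies
`s_phase_fraction` (default 0.3, a standard rough figure for cycling
mammalian cells) of the cycle, centered in it.

Labeling requires S-phase **entry** during the pulse window (days
[0, `pulse_days`) with 24 h resolution; sub-day pharmacokinetics are not
modeled). Entry, rather than mere S-phase overlap, is the operative rule:
EdU incorporates during active DNA synthesis of cycling cells, and under
the entry rule a quiescent cell parked mid-cycle never labels — the
mean-cycle-time → ∞ limit correctly gives a labeled fraction of 0.
Relabeling during the pulse resets the division counter. The label halves
at each division, and a cell scores EdU+ at sampling iff its divisions
since last labeling is ≤ `detection_divisions` (default k = 4 — the
conventional ~16-fold dilution-to-background assumption; configurable).
Sampling for chase offset c happens at (pulse_days − 1 + c) days, i.e. c
days after the last injection; divisions in (last label, sample] count.

With the default configuration (slow population 200 h cycles ≈ 8.3 d vs
fast 30 h, 8-day pulse, chase at 1/4/14 d), fast cells label early and
dilute below detection by day 14, while slow cells complete ≤ 2 divisions
in the chase and retain label — the qualitative slow-vs-fast ordering the
label-retention assay is designed to read out. The model has no spatial
component: labeled cells do not migrate between zones, so it does not
reproduce effects attributable to labeled resting cells transiting into
the proliferative zone between samplings.

## Zone proportions

Given per-cell axial positions and zone calls (RZ/PZ/HZ, e.g. from FISH
markers such as Apoe/C1qtnf3/Col10a1), the RZ|PZ and PZ|HZ boundaries are
fitted by exhaustive scan over midpoints between adjacent distinct
positions, minimizing total misclassification of the three-segment
labeling; ties resolve toward the smaller RZ (lexicographically smallest
boundary pair). Zone extents are percentages of the span between the first
and last cell and sum to 100 by construction. This is a deliberate
concrete choice for a step that is usually done by eye on histology; any
two-changepoint fit with the same loss would be interchangeable.

## Problem sizes and determinism

Recovery tests run 20 independent seeds at moderate sizes (5 clusters x
300 cells x 2000 genes for the screen; 5 000 events for gating; 200 cells
per population for EdU), chosen so that binomial/multinomial sampling
error is small against the tested margins while the whole suite stays
fast. Every stochastic component takes an explicit integer seed
(Philox streams; child seeds via `SeedSequence.spawn`), so all results in
the README and the acceptance output are exactly reproducible.
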