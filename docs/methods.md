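# Methods

## Model and procedure

`isletshift` works on a proteins × samples table of strictly positive,
normalized abundance values (the typical output of isobaric-label
quantification) over five condition groups: two 2D-culture differentiation
stages (S5, S7), their alginate-encapsulated counterparts (S5_bead,
S7_bead) and native human islets (ISLET), the reference. The default
replicate design is (2, 2, 2, 2, 3).

All inference is performed in log2 space. Group means are arithmetic means
of log2 values — equivalently geometric means of ratios — which makes every
fold change antisymmetric under swapping the two groups and invariant to
global rescaling of the matrix. The package deliberately log-transforms
exactly once, at the contrast step; files always hold linear-scale values.

### Differential expression

The protein universe is restricted to proteins quantified in at least one
sample of every condition; proteins never seen in a condition cannot be
anchored to the reference. For a contrast of groups A and B, the per-protein
statistic is the unpaired two-tailed pooled-variance (Student) t-test on the
log2 values, using only the available observations (missing values reduce
the per-group n, never impute). A protein is a DEP versus the reference when

    |log2 FC| ≥ log2(fc_threshold)   and   p ≤ p_threshold

with defaults fc_threshold = 1.5, p_threshold = 0.05. Both comparisons are
inclusive; a `strict_p` switch gives the strict variant. No multiple-testing
correction is applied by default, matching the anchored-filter convention
for this kind of screen; Benjamini–Hochberg adjustment is available behind
the `fdr` flag.

**Degenerate variances.** With n = 2 replicates, groups can be exactly
constant. We take the limit of the t statistic: both groups constant and
equal → p = 1.0; constant but different → p = 0.0 (infinite t). The NaN
"undefined" marker is reserved for groups with fewer than two observations,
and undefined p always excludes a protein from DEP calling. The p = 0 limit
is what makes noise-free simulated data behave continuously: as noise → 0
the t statistic of a truly shifted protein diverges, and the calls converge
to the fold-change criterion alone. On real data exact ties at machine
precision are vanishingly rare, so the convention is inert there.

### Effect classification

Four effects are assessed, each a (baseline, effect-condition) pair:

| effect | baseline | effect condition |
|---|---|---|
| differentiation_cocktail | S5 | S7 |
| early_encapsulation | S5 | S5_bead |
| confounding | S5 | S7_bead |
| late_encapsulation | S7 | S7_bead |

For every baseline DEP, with b = log2FC(baseline/ISLET) and
e = log2FC(effect/ISLET), the movement Δ = e − b is classified with the same
single fold threshold used for DEP calling:

* |Δ| ≥ log2 1.5 and sign(Δ) = −sign(b): **islet-promoting**;
* |Δ| ≥ log2 1.5 and sign(Δ) = sign(b): **islet-antagonizing**;
* otherwise **unchanged**.

The movement criterion is fold-change-only by design — the classification
rests on one stated threshold; an optional effect-vs-baseline t-test can be
layered on via `movement_contrast`. Each call records the baseline
direction (`from_up`/`from_down`), islet-level **attainment**
(|e| < log2 1.5, the strict complement of the DEP fold criterion; optionally
also requiring a non-significant effect-vs-islet test, off by default
because n = 2 makes non-significance weak evidence), and an **overshoot**
flag for promoting proteins that land ≥ 1.5-fold on the far side of the
islet level (they remain promoting — they did move toward and past the
reference — but are flagged). DEPs unquantified in the effect condition are
dropped from that effect with a logged count, never imputed. Summaries
report attainment against both denominators (all DEPs and the promoting
subset), since either convention is defensible.

### Set analysis

The promoting sets of 2–4 effects are decomposed into exclusive Venn
regions; each region's size is additionally reported as a share of every
contributing effect's own total. Over-representation uses the
hypergeometric upper tail P(X ≥ overlap) against caller-supplied GMT
annotation sets intersected with the universe (no pathway database is
bundled; commercial knowledge bases cannot be redistributed). Direction
concordance between two contrast tables (e.g. protein vs transcript) is the
fraction of shared identifiers with the same fold-change sign, optionally
restricted to |log2 FC| above a floor in both tables; identifier mapping is
the caller's responsibility.

### Clustering

Sample distances are squared Euclidean over complete-case proteins
(quantified in all samples; no imputation), on log2 values by default with
optional per-protein median centering. Agglomeration is Ward's method via
the Lance–Williams recurrence on squared-Euclidean input; ties pick the
lowest-index pair, making the merge order platform-deterministic. The merge
height is the Lance–Williams Ward distance, which on squared-Euclidean
input equals **twice** the increase in within-cluster sum of squares — so
two singletons merge exactly at their squared-Euclidean distance, and
heights are the squares of those reported by Euclidean-metric Ward
implementations (verified against scipy in the tests). Condition proximity
to the reference is the squared distance between condition centroids and
the islet centroid, computed from the pairwise sample distances alone via
the standard centroid identity, so it needs no access to coordinates.

## The synthetic generator

The generator exists so every downstream claim is testable against planted
truth. It emulates:

* log-normal observation noise (Gaussian in log2 space, default sd 0.15 —
  a typical replicate scatter for normalized isobaric ratios at this depth);
* per-protein islet log2 means drawn from N(0, 2);
* baseline classes (null / dep_up / dep_down, default 30/35/35 %) with
  offsets drawn from log2 1.5 + [0.5, 1.5] — the margin, not the classifier,
  carries identifiability;
* per-effect response classes with planted shifts beyond the same margin;
  encapsulation-containing effects default to a higher promoting share
  (45 % vs 25 %) so the generated studies show the qualitative structure the
  analysis is designed to detect;
* optional uniform missingness that always keeps ≥ 1 observation per
  protein and condition — universe-filter violations are produced only by
  the separate `inject_missingness(condition_knockout)` tool, keeping the
  two concerns independently testable;
* a separate gradient generator planting toward-islet shift fractions
  (S7_bead 0.8 > S5_bead 0.55 > S7 0.15 > S5 0) for the clustering
  geometry; the uneven spacing keeps the dendrogram question well-posed —
  encapsulated conditions must chain onto the islet-proximal branch rather
  than pair with an equidistant 2D stage.

Two constraints make the planted labels mutually consistent:

1. S7_bead is shared by the confounding effect (baseline S5) and the
   late-encapsulation effect (baseline S7). The two response classes are
   therefore drawn **jointly**: each class defines an admissible interval
   set for the S7_bead position in islet-centred log2 coordinates, and the
   pair is sampled from the feasible combinations with renormalised
   weights, then the position uniformly from the intersection.
2. The S7-vs-islet DEP universe is *derived* from the planted cocktail
   response, so cocktail positions keep a ±0.3 log2 exclusion gap around
   the fold band. Membership in the late-encapsulation universe is then
   itself robust to replicate noise (≈ 2 sd of a two-vs-three-replicate
   fold-change estimate at noise 0.15), as are unchanged responses (stay
   margin 0.3).

What the generator does **not** emulate: peptide-level roll-up, channel
interference/ratio compression, batch effects, heavy-tailed noise, or
abundance-dependent missingness. Passing recovery tests therefore
demonstrates the correctness of the decision logic and its robustness to
exchangeable Gaussian replicate noise at the design's replicate counts — not
robustness to the full error structure of real quantification.

## Numerical choices

* Thresholds are inclusive (≥ fold band, ≤ p) except attainment, which is
  strict (< band) so that attainment is exactly the complement of the DEP
  fold criterion at equal thresholds.
* Fold-change band comparisons use the exact `log2(1.5)` double; generated
  positions are continuous, so boundary coincidences have probability zero.
* File round-trips serialize floats with 17 significant digits and parse
  with exact conversion, so read(write(x)) is bit-faithful.
* Ties in agglomeration and in proximity ordering are broken by index/name
  for cross-platform determinism.
* All randomness flows from `numpy.random.default_rng(seed)` with a fixed
  draw order; identical configs are bit-reproducible.

## Problem sizes

Recovery tests run at 5 000 proteins (zero-noise and noisy), calibration at
20 × 2 000 null proteins, structural-invariant sweeps at 100 × 60 proteins,
and clustering at the 11-sample design — sizes chosen so the planted-truth
comparisons are statistically sharp while the whole suite stays fast enough
to run routinely.

## Known limitations

* The pooled-variance test at n = 2 vs 3 has little power for small shifts;
  the pipeline reports what passes the stated thresholds, not effect-size
  confidence.
* With both fold and p filters at these replicate counts the realized null
  DEP rate is far below the nominal p threshold; the thresholds are a
  screen, not a calibrated error rate.
* Venn partitions compare promoting sets drawn from different baseline
  universes (S5- vs S7-anchored); proteins present in only one universe
  simply cannot appear in cross-universe intersections.
* The attainment flag at n = 2 is a point estimate against a band; the
  optional non-significance requirement does not fix its power problem.
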