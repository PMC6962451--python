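# isletshift

Reference-anchored differential-proteome classification for stem-cell-to-islet
differentiation studies.

## The problem

Protocols that differentiate human induced pluripotent stem cells (hiPSCs)
toward pancreatic islet cells are usually judged by a handful of markers. A
more stringent question is proteome-wide: under some experimental effect
(a differentiation-cocktail stage, encapsulation of the cells in alginate
microbeads, or both), does each protein's abundance move **toward** or **away
from** the level measured in native human islets? `isletshift` implements
that analysis for quantitative (e.g. TMT-ratio) protein abundance tables over
the five-group design

| condition | meaning | replicates |
|---|---|---|
| `S5` | pancreatic endocrine progenitor, 2D culture | 2 |
| `S7` | maturing β-like cell, 2D culture | 2 |
| `S5_bead` | encapsulated during early differentiation | 2 |
| `S7_bead` | encapsulated during late differentiation | 2 |
| `ISLET` | native human islets (the reference) | 3 |

## The method

All statistics are computed on log2 abundances. With the islet reference
anchoring every comparison:

1. **Universe filter** — keep proteins quantified in ≥ 1 sample of every
   condition.
2. **Baseline DEPs** — a protein is differentially expressed vs the reference
   when |log2 FC| ≥ log2 1.5 and an unpaired two-tailed pooled-variance
   (Student) t-test gives p ≤ 0.05. Two baseline lists are built: S5 vs ISLET
   and S7 vs ISLET.
3. **Effect classification** — for each of four effects
   (`differentiation_cocktail` S5→S7, `early_encapsulation` S5→S5_bead,
   `confounding` S5→S7_bead, `late_encapsulation` S7→S7_bead), every baseline
   DEP's movement Δ = log2FC(effect/ISLET) − log2FC(baseline/ISLET) is scored:
   |Δ| ≥ log2 1.5 toward the islet level → *islet-promoting*; away →
   *islet-antagonizing*; otherwise *unchanged*. A DEP whose effect-condition
   level lands strictly inside the 1.5-fold band around the islet level
   *reaches the islet level*.
4. **Set analysis** — exclusive Venn partition of the promoting sets across
   effects (with each region's share of every contributing set), optional
   hypergeometric over-representation against GMT annotation sets, and sign
   concordance with an external (e.g. transcript-level) contrast.
5. **Clustering** — Ward linkage on squared-Euclidean sample distances, plus
   per-condition centroid distance to the islet centroid.

A synthetic-study generator plants known DEP classes, per-effect responses,
attainment flags and a toward-islet gradient, so the entire chain is
verifiable without any deposited dataset (see `docs/methods.md`).

## Worked example

```sh
isletshift simulate --n-proteins 1000 --seed 11 --out-dir demo
isletshift all --matrix demo/abundance.tsv --annotation demo/annotation.tsv \
               --out-dir demo/results --seed 11
```

prints (abridged):

```
Protein universe (expressed in every condition): 1000

| effect | DEPs | promoting (from up / from down) | antagonizing | unchanged | reaching islet level |
|---|---|---|---|---|---|
| differentiation_cocktail | 675 | 162 (51.9% / 48.1%) | 318 (47.1% of DEPs) | 195 (28.9% of DEPs) | 31 (4.6% of DEPs, 19.1% of promoting) |
| early_encapsulation | 675 | 304 (51.6% / 48.4%) | 153 (22.7% of DEPs) | 218 (32.3% of DEPs) | 107 (15.9% of DEPs, 35.2% of promoting) |
| confounding | 675 | 368 (49.5% / 50.5%) | 96 (14.2% of DEPs) | 211 (31.3% of DEPs) | 141 (20.9% of DEPs, 38.0% of promoting) |
| late_encapsulation | 642 | 465 (48.4% / 51.6%) | 37 (5.8% of DEPs) | 140 (21.8% of DEPs) | 136 (21.2% of DEPs, 29.2% of promoting) |
```

Reading it: of the 675 proteins that differ ≥ 1.5-fold from islets at S5,
only 162 move toward islet levels under the differentiation cocktail alone,
versus 304–368 under the encapsulation-containing effects — and the fraction
reaching islet-indistinguishable abundance rises from 4.6 % to 16–21 %. That
is the planted structure of this synthetic study (encapsulation effects were
generated with more islet-promoting responses), recovered by the pipeline.
The run directory also contains every intermediate table (contrasts, DEP
lists, per-protein regulation calls), the promoting-set Venn partition, the
Ward dendrogram (Newick + JSON), the condition-to-islet proximity table and
a `manifest.json` that fully determines the run.

Each stage is also available standalone (`isletshift filter | contrast |
classify | venn | cluster | enrich | concordance`) and as library functions
(`isletshift.compute_contrast`, `isletshift.classify_effect`, ...).

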