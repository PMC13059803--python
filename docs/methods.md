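# Methods

## The analysis problem

Bacterial effectors of the IcsB family are lysine fatty-acid acyltransferases
(k-FATs): they transfer long-chain fatty acids onto lysines of host proteins.
A chemical-proteomics screen for their substrates expresses each enzyme
("bait") in yeast alongside an empty-vector (EV) control, labels acylated
proteins metabolically with an alkyne fatty acid, enriches them by click
chemistry and pulldown, and quantifies them by label-free mass spectrometry
(LFQ). A protein is a candidate substrate ("prey") of a bait when its LFQ
intensity is enriched in that bait relative to the EV control. `acylscan`
implements the downstream statistics of such a screen, starting from the
protein x sample LFQ matrix; raw spectra, peptide-spectrum matching and
protein inference are upstream of its scope.

## Pipeline stages

### 1. Replicate quality control (Grubbs screen)

Each condition's biological replicates are reduced to one scalar each — the
median log2 intensity over that replicate's detected proteins — and screened
with a single-pass, two-sided Grubbs test at alpha = 0.05 (critical value
from the Student-t quantile at alpha/(2n) with n-2 df). At most one
replicate per condition is removed, and a removal that would leave fewer
than two replicates is an error. The per-replicate statistic is a design
choice: a robust global-scale summary catches the failure mode that
motivates replicate exclusion (a systematically depressed or inflated run)
while being invariant to protein ordering and insensitive to a few aberrant
proteins. It is isolated behind `replicate_summary` so another summary can
be swapped in. No iterative (generalized ESD) multi-outlier procedure is
offered: the screen's convention is a single discard.

### 2. Left-censored imputation

LFQ zeros are treated as non-detections that arise preferentially at low
abundance (missing-not-at-random left-censoring). For each condition, a
protein detected in at least one replicate but not in others has its zero
cells replaced by values picked uniformly at random from the pool of
observed intensities at or below the 10% quantile of all nonzero intensities
(linear-interpolation quantile, inclusive threshold). "Uniform" means
uniform over the multiset of pooled observed values — resampling — not over
a continuous interval. Proteins undetected in *every* replicate of a
condition are left at zero there. The pool is built from the whole matrix by
default (`pool_scope="whole_dataset"`); a per-condition pool is available
because either reading of "the corresponding data set" is defensible.
Imputation runs after replicate QC and is a pure function of
(matrix, fraction, scope, seed); the pool bounds and imputed-cell count are
recorded in the run manifest.

### 3. Differential testing and prey calling

For every (protein, bait) pair where the protein was detected in the bait
(>= 1 nonzero replicate pre-imputation):

* **Fold change** FC = mean(bait) / mean(EV) on the imputed intensities.
  When the protein is absent from every EV replicate the denominator is
  floored at the imputation pool's lower bound and the row is flagged
  `control_all_missing`, keeping FC finite and auditable.
* **Welch test**: one-tailed (greater) unpaired t-test with unequal
  variances; t = (m1-m2)/sqrt(s1²/n1 + s2²/n2), df by Welch–Satterthwaite,
  p from the upper Student-t tail. Degenerate zero-variance pairs with equal
  means return p = 0.5 by convention.
* **BH adjustment** runs within each bait over its tested proteins (the
  per-pair tables are adjusted before merging). In the merged table a
  protein absent from a bait's tested set carries adj_p = 1 there.

Prey calling is inclusive at both thresholds: a protein is a member of bait
b when FC >= 2 there, and enters the prey universe when it additionally has
adj_p <= 0.1 in at least one bait. Tests run on the raw (not log)
intensity scale by default, matching the convention of applying the t-test
directly to the imputed LFQ values; `--log2` switches both the tests and
the PCA to log2 intensities.

### 4. Conservation across baits

Membership sets feed three read-outs: exclusive UpSet-style intersection
counts (each protein counted once under its exact bait set; per-bait totals
reported separately as marginals), the conserved ("shared") prey selected at
>= k_min of the baits (default 6 of 8), and a dot-plot table of (protein,
bait, log2FC, adj_p) for the conserved set with rows above the adjusted-P
gate flagged. PCA runs on the imputed matrix with samples as observations
and proteins as variables, centered and unit-scaled, zero-variance proteins
dropped with a logged count; component signs are fixed so the
largest-magnitude loading of each component is positive, making scores
reproducible. All quantified proteins enter the PCA, not only tested or
prey proteins; the variable count is logged.

### 5. Ortholog-overlap enrichment

Whether the conserved prey set is enriched for orthologs of a reference
substrate list from another organism is tested with the exact
hypergeometric upper tail P(X >= x) (a one-tailed Fisher test):
population = organism-B proteins with organism-A orthologs, successes = the
reference subset of that population, draws = conserved organism-A prey with
B orthologs, x = those whose ortholog lies in the reference. Many-to-many
orthology is collapsed to "has >= 1 ortholog in the set": proteins are
counted, not pairs. The universe defaults to all B-side proteins in the
pair table. Unmapped-id counts on both sides are reported so coverage gaps
are visible. Note the convention: successes are the reference-orthologed
class, which is the standard orientation for an upper-tail enrichment test;
the p-value is P(X >= x), not the point mass.

## Synthetic data generator

`simulate_experiment` emulates the screen's design: ~1,500 proteins with
log2 abundances ~ Normal(23, 2) (typical LFQ log-intensity range), 8 baits
plus EV, 4 replicates per condition with 3 for one designated bait, ~5%
prey. Prey effects are multiplicative: a per-protein log2 effect
~ Normal(2, 0.5) applied in each bait where the protein is prey. A
configurable fraction of prey (default 0.3) is shared by all baits; the
rest hit each bait independently with probability 0.5. Replicate noise is
multiplicative log-normal (sd 0.3 on the log2 scale, a moderate ~23% CV).
Detection is logistic in log2 intensity (midpoint 19.5, steepness 1.0),
giving ~10% missingness concentrated at low abundance — the MNAR mechanism
that motivates bottom-decile imputation. Dispersion and censoring defaults
are designed values chosen to look like a desk-scale LFQ experiment, not
values fitted to any deposited data set.

What the generator does **not** emulate: peptide-level quantification and
roll-up, shared/degenerate peptides, batch effects, correlated protein
complexes, contaminants, or intensity-dependent variance beyond the
log-normal model. Passing recovery tests therefore demonstrates that the
statistical machinery is correct and well-calibrated under the stated
model, not that the thresholds are optimal for any particular real
experiment.

## Numerical and design choices

* Quantile convention for the imputation pool: linear interpolation,
  inclusive threshold — pinned for reproducibility and recorded in the
  manifest.
* FC aggregates replicates by the arithmetic mean on the intensity scale.
* BH family = proteins tested within one bait; merging happens after
  adjustment.
* Single global seed per run; stage-level generators derive from it by
  fixed offsets, so a full run is a pure function of (inputs, config, seed).
* Welch p-values are computed from `scipy.stats.t.sf`; the implementation
  is cross-checked in the tests against `scipy.stats.ttest_ind` and the BH
  step against `statsmodels.multipletests` and a brute-force step-up.
* Degenerate inputs error early and loudly: < 3 replicates for Grubbs, zero
  spread, pools smaller than 10 values, empty pair tables, references
  outside the universe.

## Calibration and recovery (what the benchmarks measure)

`acylscan.calibration` re-derives the package's quantitative claims at run
time; `scripts/acceptance.py` reports them and the test suite asserts them:

* Grubbs null flag rate over 1,000 homogeneous 4-replicate conditions
  (expected ~ alpha).
* Moments and support of 10,000 imputed draws against the
  uniform-over-pool law.
* Exact agreement of Welch/BH with independent implementations on 1,000
  random inputs each.
* Null type-I error of the differential stage on a no-prey default
  simulation (~12,000 tests). Measured size sits slightly below nominal
  (~0.045-0.049): a one-tailed t-test on raw-scale log-normal intensities
  is mildly conservative, partially offset by detection/imputation
  artifacts at the censoring boundary.
* Recovery on the default spiked design, averaged over three simulations
  to damp Monte-Carlo noise: (protein, bait)-level sensitivity and FDR of
  prey calling, and the Jaccard index between recovered and true all-bait
  shared prey.
* Worst-case relative error of the hypergeometric tail against exhaustive
  enumeration for populations <= 15.

Problem sizes (1,500 proteins, 1,000-trial calibrations, 3 simulation
replicates) are desk-scale choices that keep a full benchmark run under a
minute while leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* The per-replicate Grubbs statistic and the one-vs-two-sided choice are
  artifact decisions; the screen convention they mirror names only the test
  and the alpha.
* Raw-scale t-tests on skewed intensities are conservative; `--log2` is
  available where calibration matters more than convention fidelity.
* FDR control is nominal per bait; the global prey-universe gate (adj_p in
  >= 1 bait) does not control a family-wise error across baits.
* The enrichment test treats ortholog pairs as ground truth and ignores
  paralog structure beyond set membership.
* No moderated variance estimators, model-based imputation, or permutation
  tests; these are deliberate non-goals.
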