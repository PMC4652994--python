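# Methods

This note documents the models behind each screenkit module, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## Pooled in vivo screen model

### Infection and library

Lentiviral integration counts per cell are Poisson(MOI). At the standard
MOI of 1, 63.2% of cells are infected and 58.2% of infected cells carry a
single integration; uninfected cells are removed by antibiotic selection.
Cells with multiple integrations are assigned a single hairpin uniformly at
random — fitness attribution stays well defined, at the cost of ignoring
genuine multi-integrant epistasis (which the screen design itself tries to
avoid by titrating MOI).

The default library mirrors the screen design this package targets: 24
genes, 5–7 hairpins per gene (~200 hairpins), each tagged with a unique
21-nt barcode. Knockdown efficacy per hairpin is Beta(5, 2) (mean 0.71,
occasional weak hairpins); driver (tumor-suppressor) genes carry a
per-doubling selection coefficient, default 0.15 for a "typical" driver,
0 for neutral genes.

### Population dynamics

`simulate_screen` runs four stages per tumor:

1. **Post-selection pool** — a multinomial draw of `post_selection_cells`
   (default 10^6) with equal expected representation. The control sample is
   sequenced from this pool directly (it is collected at injection time and
   never grows in vivo).
2. **Injection bottleneck** — a multinomial draw of `bottleneck_cells`
   (default 100,000, i.e. ~500 cells per hairpin, the representation the
   screen design specifies to avoid stochastic dropout).
3. **Growth** — discrete-generation Wright–Fisher resampling: at doubling
   *t* the population size is `N_t = min(N_0·2^t, carrying_capacity)`
   (capacity default 10^7 cells, a realistic ceiling for an intracranial
   xenograft) and hairpin counts are multinomially resampled with
   probabilities proportional to `count × w`, `w = 1 + efficacy × gene_effect`.
   This is the simplest model that exhibits both drift and selection; a
   branching-process alternative would decouple population size from the
   doubling schedule but adds nothing the downstream statistics exercise.
4. **Sequencing** — a multinomial draw of `reads_per_sample` (default
   2×10^6) from the final proportions, or Dirichlet-multinomial when a
   finite `overdispersion` concentration is set (PCR/sampling
   overdispersion; ∞ = pure multinomial).

An `expectation=True` mode replaces every draw with its expectation, so
tumor proportions follow `p_i w_i^D / Σ_j p_j w_j^D` exactly; it exists to
verify the stochastic engine against the closed form (agreement is at
machine precision) and for quick deterministic what-ifs.

With the default driver parameters used throughout the tests (selection
0.2/doubling, efficacy 0.9, 15 doublings) a driver hairpin grows by
1.18^15 ≈ 12× before normalization, landing at ~7–9 fold after
renormalization against the neutral background — comfortably above the
3-fold hit threshold and consistent with the >5-fold enrichment expected
of a strong tumor suppressor.

### What the simulator does not model

PCR chemistry and amplification bias (beyond the Dirichlet overdispersion
knob), spatial tumor structure, immune editing, cell-cell interactions,
multi-integrant fitness, and paired-end read artifacts. Passing tests
therefore demonstrate correctness of the *statistical pipeline* under a
drift+selection null, not robustness to every artifact of real deep
sequencing.

### FASTQ emission and barcode counting

Reads place the barcode at a configurable offset between fixed flanks
(default: barcode only, Phred 'I' qualities) with independent per-base
substitution errors. Counting assigns a read to the unique barcode within
Hamming distance ≤ 1 (default) of its window; ties and non-matches are
counted as unassigned rather than guessed. The mismatch tolerance must stay
below the library's minimum pairwise Hamming distance (exposed by
`BarcodeMap.min_hamming`) for assignment to be unambiguous.

## Hit calling

A gene is a hit when ≥ `min_shrnas` (2) distinct hairpins exceed the fold
threshold (3, strict) in some tumor, enriched hairpins appear in ≥
`min_tumors` (2) tumors and ≥ `min_lines` (2) lines. "Detected" is
operationalized as ≥ `detection_min_count` (10) raw reads in the enriched
tumor, which suppresses pseudocount-driven fold artifacts at near-zero
counts. Criteria 2/3 are evaluated at gene level (any enriched hairpin of
the gene counts toward tumor/line reproducibility); the stricter
same-hairpin reading is available as `per_shrna=True`. No multiple-testing
correction is applied — the rule set is deterministic; `screen_power`
quantifies its false-positive behavior by replicate simulation instead
(empirically ≈ 0 hits per neutral 12–24 gene screen at defaults).

## Limiting-dilution analysis

Under the single-hit Poisson model a well seeded with *d* cells stays
negative with probability `exp(-f·d)`. The estimator regresses
`ln(negative fraction)` on dose through the origin with inverse-variance
weights `wells·p/(1-p)`, iteratively re-evaluated at the fitted
probabilities (Fisher-scoring-style), and applies the second-order bias
correction `E[ln p̂] ≈ ln p − (1−p)/(2np)` to the log response. These two
numerical choices matter: observed-fraction weights alone undercover the
Wald CI (~92% instead of ~94–95%) and the uncorrected log response biases
the reciprocal ~0.5–1% low at small frequencies. The estimator agrees with
the binomial MLE to < 0.5% relative at 500 wells/dose and its 95% CI covers
the truth in ~94% of simulated replicates.

Doses where *every* well grew are excluded (log of zero) and listed in
`excluded_doses`; doses where *no* well grew are retained with a half-well
weight adjustment. All-negative experiments raise a no-growth error,
all-positive ones a saturation error suggesting lower doses.

The historical "inverse of the x-intercept" recipe — an unweighted linear
regression of raw negative-well counts on dose — is provided as
`fit_lda_raw` for comparison only: raw counts decay exponentially, not
linearly, in dose, so that recipe is inconsistent with the single-hit model
that gives frequencies their "1 in N cells" meaning, and it does not
reproduce frequencies like 1/95 from realistic designs.

A note on precision: at 500 wells/dose the Fisher information of the
standard dose grid bounds the SD of the recovered reciprocal at roughly
±0.15 (truth 4), ±1.0 (truth 27) and ±3.2 (truth 95). Single-experiment
estimates therefore round reliably to the truth only for frequent
clonogenic fractions; rare fractions need the median over many replicates
(or more wells) to pin the integer reciprocal.

## Candidate selection

Deletion frequency is the fraction of tumors with copy number strictly
below 1.6 (vs diploid 2.0), missing values excluded from numerator and
denominator; candidates additionally require Benjamini–Hochberg q < 0.05
from a per-gene Welch t-test with the tumor mean below the normal mean.
Strict inequalities at both thresholds follow the filter's stated wording.
The t-test/BH combination is the conventional two-group array analysis; it
is configurable in code but not re-derived. A user-supplied
mutation-frequency column passes through unmodified and is never fetched
from any external service.

## Synthetic expression cohort

Per sample: a subtype is drawn from (Proneural 0.27, Neural 0.17,
Classical 0.29, Mesenchymal 0.27); latent WNT activity `W ~ N(0,1)`;
mesenchymal activity `M = ρW + √(1−ρ²)ε + δ·1[Mesenchymal]` with δ = 1.0;
each signature gene expresses its activity plus N(0, 0.3²) noise; each
subtype carries a 30-gene marker block shifted by +1.5 so nearest-centroid
classification is learnable (>90% accuracy at default noise); the NLK-like
marker gene is `marker_means[subtype] + N(0,1)`; the remaining genes are
pure noise. Copy numbers are N(2, 0.1²) with configurable focal deletions.
Survival is exponential with the marker-low quartile's hazard multiplied by
the configured ratio (default 2) and administrative censoring at 5 years.

The defaults were calibrated by brute-force simulation (400 seeds): with
marker means (Mesenchymal −1.45, Proneural −0.45, Neural +0.70, Classical
+0.49) and ρ = 0.97, the 24 lowest-marker samples of a 165-sample cohort
are ~75% Mesenchymal, the 24 highest ~50% Classical, and the WNT and
mesenchymal metagene scores correlate at r ≈ 0.87 on the union of the
extreme groups. ρ is set above the target r because the δ shift adds
marker-linked but WNT-independent variance that attenuates the observed
correlation. The generator emulates subtype structure, activity coupling
and marker stratification — not batch effects, platform noise models, or
the gene-gene correlation structure of real arrays, so cohort tests
validate the scoring/stratification machinery rather than biology.

## Signatures and stratification

Activity score = mean z-score (population-SD convention, n denominator)
over the set genes present in the matrix; the simplest score consistent
with "metagene" usage — ssGSEA and eigengene scores are deliberately out of
scope. Zero-variance genes z-score to 0 with a warning. Subtype centroids
are per-subtype means of z-scored expression over labeled training samples;
assignment correlates each sample's raw profile with each centroid (Pearson
over genes is invariant to per-sample affine maps, so no further
normalization is applied) and breaks ties in the fixed order Proneural,
Neural, Classical, Mesenchymal. Stratification ties break by sample ID
(stable sort), making group membership deterministic under ties.

## Survival and qPCR

Kaplan–Meier estimation and the two-group log-rank test delegate to
lifelines; the median is the smallest time with S(t) ≤ 0.5 and is undefined
(NaN) when never reached — an all-censored group yields S ≡ 1. ΔΔCt
averages replicate Ct values per sample × gene, normalizes to the reference
gene within sample, then to the calibrator sample, and reports `2^(−ΔΔCt)`
assuming exactly 2-fold amplification per cycle; multi-reference
normalization and efficiency correction are out of scope.

## Pipelines and reproducibility

Both pipelines derive each stage's seed as
`sha256(global_seed:stage_name) mod 2^31`, so adding a stage never perturbs
the random streams of earlier ones. Every run writes a manifest with the
parameter snapshot, per-stage wall times and sha256 hashes of all outputs;
identical configurations reproduce identical hashes. File-ingest and
in-memory modes are equivalent for every stage (verified in tests to
floating-point round-trip precision).

## Problem sizes used in the test suite

Simulation-backed checks use deliberately moderate sizes chosen to make
Monte-Carlo assertions stable: 200 seeded replicates for LDA recovery, CI
coverage and cohort calibration; 20–25 replicate screens for power checks;
10^5–10^6 wells or reads where a closed form is being verified against
sampling error. These sizes are the package's own testing choices and are
documented here so they can be scaled up for sharper estimates.
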