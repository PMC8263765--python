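# Methods

## Quantitation model

Methylation-specific qPCR reports a cycle threshold Ct for each methylated
target and for the ACTB reference amplified from the same bisulfite-treated
DNA. The quantity carried forward is ΔCt = Ct(gene) − Ct(ACTB), which
normalises for input DNA amount. Calibration mixtures with a known
methylated fraction f follow, to good approximation for an efficient PCR,

    ΔCt(f) = a·log₂ f + b ,

with slope a ≈ −1 cycles per two-fold change (halving the methylated
template costs one cycle) and intercept b the ΔCt of fully methylated DNA.
The two-fold dilution design (100, 50, 25, 12.5, 6.25, 3.125%) makes log2
the natural scale; the curve model is an implementation choice, since the
functional form of historical standard curves is a laboratory convention.
Curves are fitted per gene by ordinary least squares of ΔCt on log₂ f and
inverted as percent = 100·2^((ΔCt−b)/a).

Numerical conventions:

- Inversion is clamped to [0, 100]%. Extrapolation below the lowest
  calibration point (3.125%) is allowed down to the clamp; values above
  100% clamp to 100.
- An undetected target (no amplification) quantifies as 0% — absence of
  methylated template, not missing data.
- Each gene's ΔCt uses the ACTB of its own cartridge/marker set; a sample
  has two ACTB references, one per five-gene set.
- DNA adequacy: a sample is evaluable iff both ACTB references are
  detected at or before a configurable cutoff (default 40 cycles,
  boundary inclusive). Inadequate samples are excluded and counted, never
  silently dropped.
- When per-gene plates are absent (synthetic work), a shared
  ideal-efficiency curve (a = −1, b = 5) stands in.

The cumulative methylation score CM is the sum of the ten per-gene
percents (0–1000 "CM units"). Outputs render percents and CM to one
decimal; internal arithmetic is full precision.

## Classification

A node is called malignant when CM exceeds the laboratory threshold of
8.5 CM units; the threshold itself ("threshold for benign") is read as
benign, and the boundary rule is configurable. Data-driven threshold
selection enumerates midpoints between adjacent unique scores (±∞
sentinels) and returns the cutpoint maximising sensitivity subject to a
specificity floor (default 90%), breaking ties by higher specificity and
then lower threshold — the rule used to set the companion laboratory
assay's cutoff. Combining with cytology uses OR-positivity (either assay
positive ⇒ positive); an indeterminate cytology read contributes nothing.
OR is the only combination rule consistent with a sensitivity gain at
some specificity cost, which is how the combined assay behaves.

## Evaluation

Sensitivity, specificity, PPV and NPV are the usual ratios of confusion
counts; their CIs are Clopper–Pearson exact intervals (the exact method
reproduces the study's printed cytology CI for 98/106 to within 0.1
percentage points, which is why it was chosen over Wilson or normal
intervals). The ROC area is the empirical P(malignant score > benign
score) with ties counting ½; its CI uses the DeLong midrank variance with
a normal interval clipped to [0, 1], with a seeded stratified bootstrap
available behind a flag. Indeterminate cytology samples are excluded from
cytology-vs-truth evaluations and reported as an exclusion count.
Cross-platform concordance (e.g. against a reference laboratory assay's
cumulative methylation index) is Spearman rank correlation with average
ranks for ties; the external score is treated as an opaque vector — the
reference assay's internal index formula is out of scope.

## Subgroup statistics

Two-group CM comparisons use the two-sided Mann–Whitney test — exact
enumeration when both groups have fewer than 8 tie-free observations,
otherwise the asymptotic form with tie correction — and Kruskal–Wallis
for more than two groups. Call-rate-by-subtype tables use Fisher's exact
test for 2×2; for 2×k the p-value is a seeded Monte-Carlo Fisher test
(≥10⁵ label permutations, which sample tables from the
margin-conditional multivariate hypergeometric null; p is the fraction of
tables at most as probable as the observed one, with the +1 correction).
Age trends are OLS of CM on age with the two-sided slope p-value, the
Pearson correlation reported alongside (the two are kept side by side and
not reconciled into a single "r"). The misclassification scan fits, per
CM threshold, a logistic regression of the misclassification indicator on
age — separately for false positives among benign samples and false
negatives among malignant ones; fits that fail to converge or separate
completely are flagged as non-converged rather than raised.

## Study design

Two calculations. (1) CI-width control: per replicate, n Bernoulli(p)
outcomes are drawn and the proportion is bootstrapped with a percentile
interval; the summary is the distribution of half-widths across
replicates. Resampling a size-n binary vector with replacement is
distributionally identical to drawing Binomial(n, p̂)/n, and the bootstrap
is vectorised through that identity (defaults: 2000 replicates, 1000
bootstrap resamples, seeded). With no pilot data available to resample,
Bernoulli draws at the stated rate stand in for it. At p = 0.9, n = 100
the mean 90% half-width is ≈0.048, below the 0.1 design bound and close
to the normal-approximation value 1.645·√(p(1−p)/n) = 0.0494.
(2) Enrollment: the probability of at least m subjects per arm when
enrolling N at prevalence π is the exact binomial sum
P(m ≤ K ≤ N−m), K ~ Bin(N, π) — 0.959 for (230, 0.5, 100). Monte-Carlo
appears only as a test oracle.

## Synthetic cohort generator

The generator emulates the statistical structure of the two study designs
so that every pipeline stage is testable without the non-public patient
data. What it models:

- **Cohort composition** — defaults of 110 malignant / 120 benign
  enrolled (230 total, ≈50% prevalence, the prospective design), with an
  exact-count inadequate-DNA exclusion of round(12/230 · n) samples whose
  ACTB fails to amplify.
- **Malignant methylation** — two-part per gene: a Bernoulli gate (is
  this gene methylated in this tumor? heterogeneous probabilities of
  0.5–0.8 across the panel) times a scaled-Beta(1.2, 2.5) percent level.
  On top sits a per-sample "detectable" gate at 0.907: an FNA of a
  malignant node can miss tumor cells, and such samples draw benign-like
  background. This fraction matches the study's observed sensitivity at
  the 8.5 threshold and makes the generator's implied sensitivity ≈0.91.
- **Benign background** — small exponential per-gene percents (mean 0.19%
  per gene) giving a benign CM median ≈1.9 units, within the study's
  regional benign medians (1.4 and 2.4), plus a rare (1%) low-level
  elevated gene (uniform 5–30%) reproducing the occasional benign score
  above threshold; implied specificity ≈0.99. Benign scale drifts mildly
  with age (+0.4%/year relative), the modest nonsignificant trend the
  study reports.
- **Ct synthesis** — percents are inverted through the calibration line
  to ΔCt, Gaussian Ct noise (sd 0.25 cycles) is added, and gene Ct =
  ACTB Ct + ΔCt with ACTB ~ N(25, 0.8); any Ct past the 40-cycle
  detection limit is emitted as undetected.
- **Cytology** — correct with probability 0.925 (malignant) / 0.953
  (benign), then overridden to indeterminate at rate 6/218 independently
  of truth (the observed 2+4 of 218 is too sparse to model dependence).
- **Metadata** — age, region (85% China), IHC subtype, AJCC stage,
  positive-node counts and Miller–Payne NAC-response grades drawn from
  categorical distributions approximating the study's patient tables.

Generator truth for parameter-recovery tests is computed from the
configuration alone by percent-level Monte Carlo
(`implied_operating_characteristics`), independent of the Ct-level
pipeline being checked.

What the generator does **not** model: inter-cartridge batch effects,
PCR efficiency drift, dependence of cytology error or indeterminacy on
tumor burden, per-subtype methylation profiles, sample-storage effects,
or raw fluorescence traces. Passing recovery tests therefore shows that
the pipeline correctly inverts the generative model it is given at
realistic noise levels and cohort sizes — not that the assay achieves
these operating characteristics on real specimens.

## Problem sizes and determinism

The test suite runs study-scale cohorts (230 samples) for structural
checks and 500 per arm for parameter recovery; generator-truth Monte
Carlo uses 10⁵ draws per arm. The acceptance script uses 2000 simulation
replicates × 1000 bootstrap resamples for the half-width summary and one
full 230-sample pipeline run. Every stochastic component takes an
explicit seed (numpy `default_rng`); cohorts are byte-identical across
runs with the same configuration, and sub-seeds are derived by
`SeedSequence.spawn`.

## Known limitations

- The ten-gene panel membership is configuration-driven: five markers
  (AKR1B1, APC, COL6A2, HOXB4, RASSF1) are named, the remainder are
  placeholders, and no per-gene biology is modelled beyond positivity
  heterogeneity.
- The curve model is a single straight line per gene; no multi-plate
  harmonisation or efficiency correction beyond the fitted slope.
- DeLong vs bootstrap AUC intervals can differ near AUC = 1 where the
  normal interval is clipped.
- The 2×k Monte-Carlo Fisher p has simulation error ~10⁻³ at the default
  draw count; seed it for reproducibility.
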