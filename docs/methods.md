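# Methods

This note documents the models, algorithms, parameter choices, and
known limitations of the toolkit. Values quoted here are defaults; all
are configurable through function arguments or `SimConfig`.

## Signal model and preprocessing

**Generative assumption.** A probe's measured fluorescence in a channel
is signal plus background, `x = s + b`, with `s ~ Exponential(α)` and
`b ~ Normal(μ_b, σ_b²)` truncated at zero. Infinium-I probes read both
alleles in one design channel; their opposite-channel readout carries no
target signal and serves as a background sample ("out-of-band", OOB).
Channel-switch (species-variant) probes are excluded from OOB
collection because their opposite-channel fluorescence is template
driven, not background.

**Detection p-values.** For an in-band total `x` in channel *c*,
`p = (#{o ∈ OOB_c : o ≥ x} + 1)/(|OOB_c| + 1)` — the add-one empirical
survival function, which cannot reach zero and is uniformly distributed
when `x` is itself a draw from the background distribution. Infinium-II
probes read their methylated allele in Green and unmethylated in Red;
their p-value is the minimum of the two per-channel p-values, which
makes a probe "detected" if either allele rises above background.
Because in-band totals sum two allele readouts while OOB entries are
single readouts, probe-level p-values on fully background-driven probes
are conservative only in distributional terms; the calibration property
holds for measurements distributed like the OOB entries. Detection is
computed on raw signals — comparing to background after background
subtraction would be circular.

**Background subtraction.** Method-of-moments: `μ_b`, `σ_b` from the
OOB mean and s.d. (floored at 0.01 with a warning if degenerate), `α`
from the in-band mean excess over `μ_b`, floored at 10 intensity units.
Each intensity is replaced by the posterior mean
`E[s|x] = μ_s + σ_b·φ(z)/Φ(z)` with `μ_s = x − μ_b − σ_b²/α`,
`z = μ_s/σ_b`, evaluated through the scaled complementary error
function so the inverse Mills ratio stays stable at `z ≪ 0`. A fixed
offset of 15 units is added, so corrected intensities are strictly
positive. The closed form is verified against numerical quadrature of
the posterior integral to 10⁻⁶.

**Dye-bias correction.** The Red and Green intensity scales differ by a
smooth monotone distortion. We build per-channel empirical quantile
anchors from the *allele-level* in-band intensities of Type-I probes
(32 equal-count bin means), set the shared target to the quantile-wise
geometric mean, smooth the per-channel log correction across quantile
ranks with LOESS (span 0.75), and map every intensity through the
resulting piecewise-linear function, anchored at (0, 0) and extended
proportionally above the largest anchor. Anchoring on allele-level
values rather than probe totals matters: the map is applied to allele
intensities, which reach below the totals' minimum, where a
totals-anchored map would be undefined. The rank-smoothing exists
because matched raw quantiles from a few hundred probes carry 5–10%
sampling noise while true dye distortion is smooth; it makes the map
nearly noise-free without limiting its ability to capture nonlinear
bias. The correction is monotone and idempotent up to interpolation
error; a single-factor median-matching variant is available
(`linear=True`). With only ~100 Type-I probes per channel the
quantile map is still noticeably noisy — per-sample channel-scale
uncertainty scales as n^(−1/2) — which is why end-to-end accuracy
checks use mini-arrays with ~1,000 Type-I probes per channel,
proportionally closer to the real array (which yields tens of
thousands of OOB readouts).

**β values.** Infinium-I: `β = M/(M+U)` in the design channel;
Infinium-II: `β = MG/(MG+UR)`. Probes with detection p above 0.2 (or
zero total) are masked with reason `detection`; probes flagged for
default masking (unknown/multi-mapping, `uk` prefix) with reason
`default_mask`, removable by option. Pipeline order is fixed:
detection p → background subtraction → dye-bias correction → β.

## Xenograft fraction estimation

Two estimators of the human fraction *f* of a human/mouse DNA mixture:

1. **Variant probes.** Channel-switch Infinium-I probes fluoresce in
   one channel on human template and the other on mouse. Per probe,
   `r = H/(H+M)` over channel totals; the sample summary is the median
   across probes. Background is subtracted first so residual
   fluorescence does not inflate the off-species channel.
2. **Paired-array intensities.** The same DNA on a mouse and a human
   array; `r = medianH/(medianH + medianM)` of per-probe total
   intensities over each array's non-syntenic probes.

Both raw ratios are calibrated on titration series at the 11 mixing
fractions (0, 0.05, 0.1, 0.15, 0.25, 0.5, 0.75, 0.85, 0.9, 0.95, 1):
each calibration series gets a degree-1 tricube LOESS fit (span 0.75 —
unspecified upstream, a conventional default) on a 0.005-step grid; the
standard curve is the pointwise mean across calibration sources. LOESS
is not guaranteed monotone, so inversion goes through an isotonic
projection followed by linear interpolation, giving a unique inverse
without changing fitted values where the curve is already monotone.
Ratios outside the fitted range are clamped to [0, 1] with a warning
(extrapolating a saturating standard curve is not meaningful). A
calibration-free mode returns the raw ratio.

## Strain genotyping

SNP probes yield a variant allele fraction `v = alt/(alt+ref)` with the
same channel arithmetic as β. Given a reference genotype matrix
(0/1/missing per strain × SNP; heterozygous expectation exactly 0.5),
the classifier maximizes a **boundary-censored Gaussian** likelihood:
interior observations contribute `log N(v; g, τ²)`; observations exactly
at 0 or 1 contribute the censored tail mass. The censoring matters —
allele fractions are ratios clipped to [0, 1], and a plain Gaussian
lets the boundary pile-up of a pure strain masquerade as a ~95/5
mixture. τ defaults to 0.1 (calibrated on synthetic panels; 0.05 is
appropriate for clean arrays). Ties are broken lexicographically with
a warning.

**Mixture detection** searches ordered strain pairs and mixing
proportions π on a 0.01 grid restricted to [0.05, 0.95] (a component
below 5% is indistinguishable from boundary noise). The mixture is
reported only if its log-likelihood beats the best single strain by
2.0 per comparison — implemented as 2.0 plus log(#pairs × #grid
points), penalizing the maximum taken over all candidate mixtures.
Specificity on pure strains is 1.0 over 100 simulations at τ ≤ 0.1
while F1 and 75/25 mixtures are detected with π within ±0.05.

**Backcross tracing** reports per-SNP genotype calls over the
donor-oriented fraction (donor-homozygous above 0.75, heterozygous
0.25–0.75, recipient-homozygous below 0.25; symmetric, configurable)
and the mean donor fraction across non-missing SNPs, which halves each
generation (0.5^(n+1) at backcross n).

## Differential methylation

**Regression.** Per probe, OLS of β on an additive design (intercept +
categorical dummies + numeric covariates). Each term is tested with an
F-test of the full model against the model omitting the term; p-values
are BH-adjusted across probes within each term. Effect sizes are
delta-β: for categorical terms, the range of model-adjusted level means
(dummy coefficients plus baseline 0 — robust to confounding; raw group
means differ only when covariates are imbalanced); for continuous
terms, |slope| × observed predictor range. Significance presets:
tissue mode p < 0.05 and effect > 0.1; tumor/age mode adjusted q < 0.01
with |coefficient| > 0.1, split by sign into hyper/hypo. The tumor/age
pre-filter drops sex-chromosome probes, probes missing in > 25% of
samples, and constitutive probes (max β < 0.2 or min β > 0.8). Probes
with missing values are fitted on complete cases; rank-deficient
designs yield missing results with a warning.

**Signatures.** One-vs-rest per tissue: candidates are probes that
separate the target tissue from the rest perfectly (Mann-Whitney AUC
exactly 1 for hyper, 0 for hypo — equivalently strict min/max
separation), ranked by |mean difference| with ties broken by probe ID,
top 200 per direction (fewer if fewer qualify).

**Species/tissue decomposition.** Cell means per tissue × species;
tissue effect = range of tissue marginal means (cells averaged over
species, equally weighted; missing cells are skipped with a warning),
species effect symmetrically. Labels: species-specific iff species
effect > 0.4 and species/tissue ratio > 3; tissue-specific
symmetrically.

**Region enrichment.** Each CpG contributes a fixed 200 bp window
centered on it ([pos−100, pos+100) in 0-based coordinates). Per region
set a 2×2 table (query vs background-minus-query × overlap) is tested
with the two-sided Fisher exact test; the odds ratio uses a 0.5
continuity correction only when a zero cell occurs (flagged), and is
reported as 1 when no CpG overlaps anywhere (an uninformative table);
BH across sets.

**Target genes.** Candidates are, per CpG, up to 10 nearest TSSs within
1 Mb on each side; a gene is retained iff every required factor has at
least one experiment with regulatory-potential score above 2 (absent
genes fail).

**Mono-allelic groups.** Group I: intermediate β (0.3–0.7, exclusive)
in > 50% of somatic samples. Group II: intermediate in > 90% of somatic
samples and polarized (> 0.7 or < 0.3) in every testis sample (testis
is dominated by germ cells, where imprints are reset). Group III: II
and located in an ICR or secondary DMR; Group IV: II and in an ICR.
The highest group is reported and the groups nest by construction.
Without testis samples, groups II–IV are unavailable (warning). The
stricter design-phase screen (0.35–0.65 in > 65% of ≥ 7 samples) is
available as `monoallelic_design_screen`.

## Epigenetic clock

Elastic net (mixing 0.5 between L1 and L2) of age in months on β over a
30-point log-spaced penalty path from the data-derived maximum down
three decades, 10-fold cross-validation minimizing mean absolute error.
The default penalty choice is the **one-standard-error rule** — the
largest penalty whose mean CV MAE is within one SE of the minimum —
matching the default extraction of the reference elastic-net tooling
and yielding a sparser support whose members are overwhelmingly true
age-associated CpGs on synthetic panels (the plain MAE minimizer is
available as `rule="min"`, and a fixed penalty can be supplied, e.g. a
previously published value). Features are not standardized: β values
share the [0, 1] scale. Missing β are imputed by per-probe training
means at both fit and predict time (complete-case filtering would
discard most masked arrays); predictions with more than half of the
weighted probes missing are flagged low-confidence. Models serialize as
a weights TSV plus a JSON header (intercept, mixing, penalty,
imputation means).

## Synthetic data: what it emulates and what it does not

The generators produce a miniature array (default 100/100/800
Infinium-I-Red/-Green/-II CpG probes, 20 CpH, 19 channel-switch probes
— the count of species-variant probes on the real array — plus
controls and `uk` probes) with:

- intensities `background + gain · allele_fraction · Exponential(3000)`
  per allele, truncated-normal background (mean 500, s.d. 100) per
  channel, a multiplicative Red dye factor, and background-only draws
  in OOB slots — exactly the model the background correction assumes,
  so oracle tests are exact;
- methylomes with a low/intermediate/high baseline mixture, 40 planted
  tissue markers per tissue and direction (delta 0.5), 50 age probes
  (±0.02 β/month over ages 1–24 months), 30 imprint probes (0.5 in
  soma, polarized in testis), and Gaussian β noise (s.d. 0.02);
- SNP probes whose allele fractions follow the sample strain's
  genotypes, drawn from a balanced binary phylogeny in which every
  branch (clades and leaves) contributes branch-specific SNPs shared by
  all descendant strains;
- titrations mixed at the molecule level (β_mix = w·β_meth +
  (1−w)·β_unmeth) at the 11 calibration fractions;
- species mixtures splitting channel-switch signal between the species'
  channels and scaling non-syntenic probes by the species fraction,
  with a paired human-array view;
- backcrosses with per-SNP independent inheritance (each heterozygous
  SNP stays heterozygous with probability 1/2 per generation);
- low-input dropout as a single binomial draw per probe,
  `β' = Binomial(n, β)/n`.

Not emulated: realistic probe sequences, linkage/recombination
structure (backcross SNPs are independent, so fraction variance across
SNPs is underestimated relative to chromosome-scale inheritance),
amplification-cycle effects in the low-input model (one binomial draw,
no PCR branching), batch/chip positional effects, FFPE degradation,
and cross-hybridization. Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not
robustness to artifacts absent from it.

All generators are deterministic given a seed; every simulated
observable has a truth-table entry.

## Problem sizes and numerical choices

- End-to-end β-grid recovery and titration checks run on a mini-array
  with 1,000 Type-I probes per channel: the per-sample dye-bias
  quantile map needs adequate anchors, and the real array provides
  tens of thousands of OOB readouts, which the 100-probe default does
  not represent. Other checks use the small default, which runs in
  seconds.
- Ages are modelled in months throughout.
- Coordinates: manifest positions are 1-based; all BED I/O is 0-based
  half-open, converted only at the boundary.
- Thresholds written as "greater than" are strict; "fewer than six"
  CpGs means at most five.
- Curve inversion tolerances: standard-curve grid step 0.005; the
  quantile map extends proportionally beyond its largest anchor.
- Degenerate inputs: constant β probes give F = 0, p = 1; zero-signal
  probes are masked as undetected; constant standard curves are flagged
  non-invertible at fit time and raise at inversion.

## Known limitations

- The dye-bias map, like any per-sample quantile normalization, assumes
  the two channels interrogate exchangeable intensity distributions;
  arrays with strongly channel-biased biology would violate this.
- The strain classifier's shared τ ignores probe-specific efficiency
  differences; heterozygous expectation is exactly 0.5.
- The clock does not model biological-age acceleration; it recovers
  chronological age under the training distribution.
- Mixture deconvolution of tissue signatures (cell-type proportions) is
  out of scope: signatures are produced, deconvolution is not.
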