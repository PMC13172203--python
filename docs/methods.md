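# Methods

This note documents the models, numerical choices and limitations of
`ggnfusion`, in the spirit of a statistical methods appendix.

## Problem setting

A solitary pulmonary ground-glass nodule is observed on thin-section CT at
baseline (T0) and once more at follow-up (T1), Δt ≥ 1 day apart. The
endpoint is binary invasiveness: MIA/IAC versus non-invasive precursors
(AAH/AIS), where the non-invasive class may also be established by
surveillance — a solitary pure GGN with baseline maximum diameter ≤ 6 mm,
≥ 3 years of follow-up and an annualised absolute relative volume-change
rate ≤ 6.0 %/year. Data come from several centres; centre is both the
cross-validation group and the default batch variable.

## Synthetic cohort generator

`cohortsim` draws per-lesion tables with the following structure:

* class prevalence 0.62 invasive; centre weights (0.50, 0.386, 0.114) over
  three centres, the third held out as the external cohort;
* baseline volume log-normal with class medians 400 mm³ (invasive) and
  73 mm³ (non-invasive) and log-scale spreads 0.90/1.10; mean attenuation
  normal with means −632/−706 HU (SD 66/51); semantic-flag prevalences per
  class (e.g. vascular convergence 0.84 vs 0.30, initial solid component
  0.32 vs 0.022); follow-up interval log-normal with medians 413/1450 days;
* growth is exponential in volume under a signed, log-normally distributed
  volume doubling time (median 770 days invasive; median 4000 days with 40 %
  negative signs non-invasive), with multiplicative log-normal measurement
  noise on volumes (CV 5 % by default);
* 65 % of non-invasive lesions are generated as the surveillance-stable
  subgroup: volumes constrained so the baseline long diameter is ≤ 6 mm,
  follow-up ≥ 3 years, and the annualised rate drawn as a half-normal
  (SD 2.2 %/yr) capped strictly below 6 %/yr so that table rounding cannot
  break the stability invariant. These rows carry `label_source =
  surveillance_stable` and round-trip exactly through the stability filter;
* diameters derive from an assumed ellipsoid (long:short ratio ~N(1.3, 0.12),
  truncated at 1) with the lesion's volume, so size variables are mutually
  consistent rather than independently simulated.

The distributional forms (log-normal/normal, exponential growth, Bernoulli
flags) are modelling choices; the generator emulates the moments of a
multi-centre GGN cohort, not any real data-generating process. Batch
effects are affine per centre, `f → scale·f + shift`, with generator shifts
expressed in per-feature SD units (scale 1.0/1.08/0.94, shift 0/+0.3/−0.2 SD
by default) so that small-magnitude rate features and large volumetric
features are distorted comparably; the literal affine injection operator is
exposed separately and accepts scalar or per-feature parameters.

Two feature-table modes exist. **Table mode** (default) derives measured
quantities (volume, ESD, attenuation, diameters, growth and delta features)
deterministically from the cohort table and adds a small block of synthetic
texture features sharing a class- and size-correlated latent, with noise
chosen so the streams' relative informativeness is ordered (clinical
strongest, baseline radiomics weakest). **Image mode** renders an
ellipsoidal voxel phantom pair per lesion (interior HU normal around the
tabled mean, denser core > −300 HU for solid components, noisy lung
background near −1000 HU; grid refined below 1 mm for sub-40 mm³ lesions)
and runs the full radiomic engine on it. Image mode costs roughly 50 ms per
lesion and is used at small n; phantoms are isotropic by construction, so
extraction skips the resampling step that real anisotropic CT would need.

What the generator does **not** emulate: reconstruction-kernel texture,
partial-volume and motion artifacts, segmentation error beyond isotropic
volume noise, correlated semantic flags, multi-nodule patients, or
non-exponential growth. Passing tests therefore demonstrate the pipeline's
statistical machinery, not clinical performance on real CT.

## Radiomic engine

Intensities are discretised with a fixed 25-HU bin width anchored at
−1024 HU (`bin(x) = floor((x + 1024)/25) + 1`), so bins have absolute
physical meaning and no per-image normalisation is applied; −1000 HU falls
in bin 1 and −999 HU opens bin 2. Texture matrices (GLCM, GLRLM) are
accumulated over the 13 unique unit-offset directions of the 3-D
26-neighbourhood and merged into a single matrix ("merged" aggregation);
the GLCM is symmetric. Run percentage is runs per ROI voxel per direction.
First-order statistics use population variance, Fisher skewness/kurtosis
(flagged undefined on constant input), and entropy in bits over occupied
bins. The Laplacian-of-Gaussian filter demeans its input first: the ideal
operator annihilates constants but scipy's truncated kernel does not quite,
and demeaning removes that offset exactly while preserving linearity.
Resampling to 1 mm isotropic voxels uses trilinear interpolation for the
grid and nearest-neighbour for the mask. GLSZM/GLDM and wavelet features
are deliberately out of scope; the feature registry is a flat name→value
map and extensible.

## Harmonisation

ComBat follows the classical parametric empirical-Bayes location/scale
model: per-feature standardisation against a design of batch indicators
plus protected covariates, per-batch location/scale estimates on the
standardised residuals, and normal / inverse-gamma shrinkage solved by
fixed-point iteration (tolerance 1e−6). The outcome label is a protected
covariate by default so harmonisation does not remove class signal; at
apply time, when labels are unknown, the fit-time label mean substitutes.
Zero-variance features are dropped from adjustment and passed through; a
single batch yields identity parameters with a warning. **Fold safety**:
parameters are estimated strictly inside each training partition, and rows
from batches unseen at fit time are passed through bit-identical and
flagged `unharmonised` — no extrapolative adjustment is ever applied. Note
that under leave-one-centre-out validation the held-out centre is by
definition an unseen batch, so internal out-of-fold predictions are made on
unharmonised validation rows; this is the honest consequence of combining
centre-grouped validation with a no-extrapolation policy.

## Modelling pipeline

Outer folds are leave-one-group-out when there are ≤ 5 centres, otherwise a
balanced grouped 5-fold; inner folds repeat the policy inside each
outer-training set, with seeded random pseudo-groups when only one centre
remains (the default three-centre design hits this path, and the fallback
is recorded on the fold plan). Screening is a two-sided Mann–Whitney U per
feature with Benjamini–Hochberg FDR at 0.05; constant features get p = 1 by
convention. Selection prunes |Spearman| > 0.90 pairs (keeping the lower
screening p), then runs an L1 logistic path over C ∈ 10^[−2,2] (13 points)
scored by inner-fold AUC. The penalty is chosen by the 1-SE rule with a
**null guard**: the best mean inner AUC must exceed 0.5 by 2.5 null
standard errors (null AUC variance (n₁+n₀+1)/(12·n₁·n₀) per fold),
otherwise the sparsest path point is taken. The guard corrects the
winner's curse of maximising over the penalty grid, which otherwise
"finds" AUC ≈ 0.58 in pure noise at n = 200.

Base learners are L2 logistic regressions on training-standardised
features; ridge penalisation keeps coefficients finite under separation.
Platt calibration fits a sigmoid on the logit of raw probabilities by
maximum likelihood (no target smoothing), strictly on inner out-of-fold
predictions. The fusion layer is a logistic regression with a small L2
penalty (λ = 1e−3) on the logit-transformed calibrated stream
probabilities in fixed order (t0, t1, delta, clinical), fitted on pooled
outer-fold predictions; logit-scale stacking keeps the fusion linear on
the natural scale of logistic models. Shapley attributions of the fused
logit are exact — enumeration of all 2⁴ coalitions with the interventional
background-mean value function — which for the linear fusion collapses to
wᵢ·(xᵢ′ − μᵢ′) and satisfies the efficiency axiom to 1e−10.

The final locked model refits each stream on all internal rows with
calibration via the internal grouped folds; thresholds are derived on the
pooled internal OOF fusion probabilities (grid step 0.005, classification
convention p ≥ τ positive; p = t₁ falls in the intermediate band, p = t₂
in the high band) and locked with a provenance record (OOF hash, achieved
sensitivity and PPV). The t₁ + 0.05 gap can push t₂ past the grid top on
nearly separable sets, so t₂ is capped at 1.0. Locked thresholds are
immutable and band assignment refuses unlocked thresholds.

## Evaluation layer

AUC is the Mann–Whitney statistic with half credit for ties; DeLong
comparisons use structural components with a two-sided z test and derive
single-model CIs from the same variance. Calibration reports Brier, ECE and
MCE over decile (quantile) bins, with equal-width bins behind a flag and a
single-bin fallback for constant predictions. Proportion CIs are exact
Clopper–Pearson (Beta quantile form), which reproduces the boundary case
k = n (lower bound α/2^(1/n)); percentages are rounded to one decimal for
report parity. McNemar is exact binomial below 25 discordant pairs (with
the central term counted once when b = c), χ² with continuity correction
otherwise. Decision curves use NB(τ) = TP/n − (FP/n)·τ/(1−τ) on a
0.10–0.80 grid (step 0.01), with treat-all/treat-none references and fixed
binary rules for guideline strategies. NRI sums event and non-event
reclassification components over the three ordered tiers, with a binary
high-vs-not variant and bootstrap percentile CIs. ICC(2,1) is two-way
random, absolute agreement, single measure, by ANOVA decomposition
(cross-checked against pingouin in the test suite).

## Comparators

Lung-RADS v2022 and Fleischner 2017 category logic lives in versioned,
human-readable YAML rule tables (first match wins within a nodule-type
block), because the published criteria are applied rather than reprinted;
both tables are reconstructions and editable. Growth defaults to a
> 1.5 mm diameter increase within 12 months, annualised for longer
intervals. The Brock-lite model is a six-covariate logistic
(age, sex, diameter via the (d/10)^−0.5 transform, spiculation, upper
lobe, nodule type) with a reconstructed coefficient set shipped as
configuration with its citation string; it is always Platt-recalibrated
out-of-fold before comparison.

## Problem sizes and determinism

The default end-to-end run simulates 404 lesions (three centres, centre 3
external) in table mode and completes in seconds on one CPU; ablation
bootstraps default to 400 replicates and NRI CIs to 500 inside the runner
(2000 when the metric functions are called directly). Image-mode runs are
sized in the tens of lesions. All randomness funnels through one seed;
reports are rounded to 10 decimals and serialised with sorted keys, so a
fixed seed reproduces the report byte for byte.

## Known limitations

* The locked thresholds derived on synthetic cohorts differ from any
  particular clinical cohort's pair — thresholds are data properties, and
  the simulator makes no attempt to force a specific pair.
* Delta features are computed from the harmonised per-time-point streams'
  raw tabled values before harmonisation of the delta stream itself; the
  ordering of delta computation versus harmonisation is a genuine design
  freedom and is fixed here as delta-then-harmonise.
* Surveillance labels cannot exclude very slow-growing invasive disease;
  the pathology-only toggle and the stability-threshold sensitivity suite
  (label flips and AUC over a threshold grid, bootstrap CI on the derived
  percentile threshold) quantify, but do not remove, that bias.
* The guideline rule tables and Brock-lite coefficients are reconstructions
  for benchmarking scaffolding, not validated clinical implementations.
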