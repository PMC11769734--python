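# Methods

## Setting

A paired split-plot MRMC observer study: readers and cases are partitioned
into blocks; each reader interprets every case of its own block under both
modalities (bpMRI then mpMRI). Every interpretation yields lesion-level
PI-RADS categories (3–5; the patient-level category is their maximum, with
2 encoding a negative exam, collapsing PI-RADS 1–2, since readers only
score suspicious lesions) and a 0–100 patient-level suspicion score. The
reference standard is binary csPCa status (Gleason grade group ≥ 2).

## Accuracy endpoints

* **AUROC** — the empirical area under the ROC curve of the suspicion
  score, computed as the normalized Mann–Whitney statistic with half
  credit for ties. Integer scores tie often; half credit is the standard
  empirical-ROC convention and makes the statistic identical to the
  trapezoidal area. Scores are used as-is (no jitter, no tie-breaking by
  category).
* **Sensitivity / specificity** — of the patient-level category binarized
  under one of three positivity rules: PI-RADS ≥ 3; PI-RADS ≥ 4 or
  PI-RADS 3 with PSA density ≥ 0.15 ng/ml² (threshold inclusive); and
  PI-RADS ≥ 4. A missing PSA density on a category-3 exam is treated as
  below threshold and triggers a warning — the conservative choice for a
  rule whose purpose is to escalate equivocal exams.

Assessments missing one modality are dropped as a pair, so the paired
jackknife stays well defined. Single-class inputs (a reader whose block
lost all positives, or a jackknife deletion that would create one) raise a
degenerate-input error naming the offender rather than returning a value.

## Obuchowski–Rockette analysis on a split-plot design

Within each block, leave-one-case-out jackknife vectors per
(modality, reader) give every pairwise covariance
Ĉov[(i,j),(i′,j′)] = ((n−1)/n) Σₖ (θ̂⁽ᵏ⁾ᵢⱼ − θ̄ᵢⱼ)(θ̂⁽ᵏ⁾ᵢ′ⱼ′ − θ̄ᵢ′ⱼ′);
averaging over qualifying pairs yields the error variance and Cov₁–Cov₃.
Negative component means are truncated at zero before use (raw values are
kept in the diagnostics), and components are capped at the error variance.
Cross-block covariances are structurally zero because blocks share neither
readers nor cases.

Readers and cases are treated as random (generalization to both
populations); a fixed-reader variant is available via
`reader_effects="fixed"`. The variance of the modality difference per
block is (2/J_b)[MS(T·R)_b + J_b·max(Cov₂−Cov₃, 0)]; blocks are pooled
with weights J_b/J (means) and squared weights (variances), so the pooled
difference equals the unweighted mean of per-reader paired differences.
Blocks with fewer than two readers cannot contribute an interaction mean
square and are excluded with a warning.

Intervals are Wald (normal quantile) by default, matching the reporting
style of such studies; `interval="t"` substitutes a t reference with
Hillis denominator degrees of freedom per block, combined across blocks by
Satterthwaite. Single-modality means use the one-treatment OR variance
(1/J)[MS(R)ᵢ + (J−1)·Cov₂ᵢ] with modality-specific quantities.

The noninferiority test is one-sided at α = 0.05 (configurable), oriented
so that larger accuracy is better: p = P(Z ≥ (d̂ + δ)/se) for margin
δ = 0.05. If se = 0 (degenerate data) the test reports p = 0.5 at the
boundary, 0 or 1 otherwise, with a warning.

## Multiplicity

Holm–Bonferroni is implemented by definition (step-down, running maxima,
capped at 1). The default family is the three coprimary endpoints — AUROC,
sensitivity and specificity at PI-RADS ≥ 3 — tested jointly; a deeper
prespecified hierarchy can be configured as a tree of hypotheses in which
a family of siblings is Holm-tested only once its parent is rejected, and
gated-off hypotheses are reported "not tested", never "accepted". No
graphical alpha-propagation weights beyond parent gating are provided.

## Decision curve analysis

Net benefit NB = TP/N − (FP/N)·odds(p_t) on a threshold grid of 5–30% in
0.5% steps (the clinically cited range; the step is our choice). Each
reader contributes one confusion table per strategy over its block's
cases, and curves average NB over readers — consistent with how every
other endpoint is reader-averaged here; pooling reads instead would weight
blocks by read count. Treat-all and treat-none anchor the curves; the net
reduction in interventions per 100 patients is
100·(NB_strategy − NB_all)/odds(p_t), and the reciprocal of a net-benefit
difference is the number of examinations per additional true positive.
Reported NB is rounded to 4 decimals at the export boundary only.

## Simulator

A Roe–Metz-style latent-variable model: for modality i, reader j, case k
with disease label d_k,

X_ijk = μ_e·d_k + Δ·d_k·1[i = mp] + C_k + R_j + RC_jk + MC_ik + MR_ij + ε_ijk.

C, R and RC are drawn once and shared between modalities (pairing);
MC, MR and ε are modality-specific. This exchangeable structure is exactly
what the OR analysis assumes, and the defaults produce
Cov₁ > Cov₂ > Cov₃ > 0. The suspicion score (probit squash, rounded to
0–100) and the PI-RADS category (interval cutpoints) are deterministic
transforms of the same latent draw, so score and category never disagree
in ordering within a reader-modality series.

Default parameters (latent units) and how they were set, all fixed by
closed-form calibration to the emulated study's marginals:

| parameter | default | rationale |
|---|---|---|
| n_cases / prevalence | 400 / 0.3325 | 133 csPCa of 400 cases |
| n_readers / expert fraction | 62 / 46⁄62 | 46 experts, 16 nonexperts |
| n_blocks | 4 | split-plot design, 100 cases per reader |
| σ²_C, σ²_RC | 0.85, 0.10 | shared case difficulty dominates |
| σ²_MC, σ²_MR, σ²_ε | 0.003, 0.0005, 0.004 | small modality-specific noise → ~91% category concordance |
| σ²_R | 0.05 | reader leniency spread (affects categories, not AUROC) |
| μ_sep | 1.513 | AUC = Φ(μ/√(2σ²_w)), σ²_w = 0.957 → expert AUROC 0.863 |
| expertise deficit | 0.225 | nonexpert AUROC 0.824; reader mean 0.853 |
| Δ (modality effect) | 0 | extra mp separation on diseased cases; `delta_for_auc_difference` inverts the closed form for a target AUROC difference |
| cutpoints | calibrated | quantiles of the pooled latent mixture at the target category mix (0.485, 0.07, 0.175, 0.27) |
| score scale | 2.0 | keeps rounded scores off the 0/100 rails |

Cutpoints are exact quantiles of the analytic latent normal mixture
(mixture CDF inverted by root finding) rather than of a simulated sample:
deterministic, and identical in the large-sample limit. PSA density is
log-normal with a class-dependent location (medians 0.115 benign / 0.20
csPCa) so the pooled median/IQR approximates 0.13 (0.09–0.21) ng/ml²;
PSA is reconstructed as density × volume.

Seeding: one master seed; case-level and per-reader substreams are derived
through independent spawn keys, so adding readers never perturbs existing
cases' draws and a fixed seed reproduces the CSV output byte for byte.

**What the simulator does not emulate:** lesion multiplicity and zonal
location (positive reads carry a single index lesion), center effects on
difficulty, the sequential-unblinding reading order, the 5-week washout
and revision round, and verification bias in the reference standard.
Passing calibration tests therefore shows the analysis machinery is
correct under the assumed exchangeable covariance structure, not that the
real study's data-generating process is captured.

## Operating characteristics and a known limitation

With 20 readers and 100 cases (25 per block, ~8 diseased), 500 replicates:

* the 95% Wald interval for the null AUROC difference covers zero at
  ~96%, and the difference estimate is unbiased to < 0.005;
* at the −5% margin boundary the one-sided test rejects at ~8–9%, above
  the nominal 5%. This is a small-per-block-sample effect, not an
  estimator defect: the same code is correctly sized (≈ 0.05) once
  readers see ≥ 50 cases each, and even an oracle test using the true
  replicate standard deviation rejects ~5.4%. At 25 cases per reader the
  per-reader empirical AUROC (mp ≈ 0.90 at the boundary) is compressed
  against 1, which induces a strong negative correlation (≈ −0.74)
  between the estimated difference and its jackknife standard error and
  hence a heavy right tail of the test statistic. The t/Hillis variant
  does not remove it. Interpret margin-boundary rejections cautiously in
  designs with few cases per reader.

Problem sizes used by the test suite and the acceptance script (500
replicates at 20 readers × 100 cases; 20 seeds of the full 62 × 400
design for calibration) were chosen to estimate these rates to within
Monte-Carlo error of about ±1 percentage point.

## Numerical choices

* Jackknife AUROC uses an O(n log n) exact leave-one-out update of the
  rank statistic; sensitivity/specificity use closed-form count updates.
  Both are verified against brute-force recomputation in the tests.
* Holm uses stable sorting, so tied p-values keep input order; rejection
  stops at the first failure by definition.
* All validation is fail-fast with typed errors (schema, integrity,
  cross-reference, pairing, degenerate input, calibration), and warnings
  (not errors) for recoverable issues: unknown exclusion pairs, uneven
  block splits, single-reader blocks.
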