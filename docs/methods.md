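# Methods

This note records the modelling assumptions, default parameters and design
choices behind the package, and what the synthetic-data tests do and do
not demonstrate about real LC–MS data.

## Study design and synthetic data

The generator emulates a spiked-matrix screening design: three
concentration groups (20, 50, 100 ng/mL; nine replicates each), twelve
pooled-QC injections, and two deuterated internal standards per sample.
Marker intensities follow

    I_ij = base_j · C(group i) · recovery_i · (1 + ε),  ε ~ N(0, cv), ε ≥ −0.9

so fold changes between group means equal concentration ratios exactly
when cv = 0 and recoveries are 100%. Noise is multiplicative on the
relative scale — the standard constant-CV behaviour of LC–MS peak
intensities — and truncated at −0.9 to keep intensities positive.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| group levels | 20/50/100 ng/mL | the spiking arithmetic of the design (20 µL of 1 µg/mL into 1 mL, etc.) |
| replicates / QC | 9 / 12 | nonuplicate groups, QC injected in triplets around each group |
| recovery ranges | 72.9–96.4% (IS1), 73.6–96.4% (IS2) | the reported per-standard recovery extremes; drawn uniformly and independently per sample |
| intensity cv | 0.10 | a typical replicate CV for small-molecule LC–MS peaks, comfortably inside the 30% RSD gate |
| QC cv | min(cv, 0.05) | QC pools must cluster tightly for the data to pass PCA diagnostics |
| n_markers | 124 | the size of the bundled P&VD library (69 + 55) |
| n_background | 150 | free parameter: the matrix-background count of real data is unknowable pre-filter; 150 keeps markers a realistic minority while the suite stays fast |
| n_erratic | 34 | mirrors the count of eligible-but-unassignable variables the workflow must report as unknowns |
| m/z, RT jitter | ±5 ppm, ±0.25 min | the identification tolerances themselves |

Erratic features alternate between a noisy concentration-proportional
profile (these become eligible yet match no library compound — the
"unknowns" path) and a non-monotone profile peaking in the middle group
(these fail the fold-change gate). Background features have
group-independent means but are scaled by each sample's recovery, like any
co-extracted matrix component.

What the generator does **not** emulate: chromatographic peak shapes,
correlated background (co-eluting adducts/isotopologues of the same matrix
compound), retention-time drift across a batch, censoring of low
intensities, or missing values. Passing tests therefore show the
statistical machinery is correct under the stated noise model, not that
the workflow is robust to every artefact of real acquisitions.

## Preprocessing

Combined recovery is the harmonic mean of the two internal-standard
recoveries — appropriate because a compound lost in either of two
sequential steps stays lost. Calibration is per group (κ = 100 / group
mean of combined recovery); a per-sample variant is available
(`calibrate(per_sample=True)`) but the group form is the default since the
procedure averages recoveries within each group. QC columns, which have no
recovery records of their own, get the mean of the group coefficients.
RSD uses the sample standard deviation (n−1) and the keep rule is a strict
`< threshold` in QC and in every group. Internal standards survive the
filter unconditionally but are excluded from every ranking — they are not
candidate markers.

## Multivariate models

Unit-variance scaling is the default for PCA and OPLS-DA (Pareto and
centre-only are available); constant columns are centred with a unit
scale factor. The PCA 95% ellipse uses Hotelling's T² with an
F-quantile.

OPLS-DA encodes the two classes as −1/+1, centres the response, removes
`n_orthogonal` (default 1) y-orthogonal components by orthogonal signal
correction, and extracts a single predictive component. R²Y is the
training-data fraction of label variance explained. Q² uses deterministic
interleaved ("venetian-blind") 7-fold cross-validation; each training fold
re-centres X before fitting — without this, centring statistics leak into
the held-out predictions and noise-free leave-one-out Q² saturates near
0.95 instead of 1. VIP is computed over the predictive component(s) with
the mean-square-one normalisation; with a single component it reduces to
`√p·|w_j|/‖w‖`. The S-plot reports cov(t, x_j) against corr(t, x_j).

The permutation test records (|corr(y_perm, y)|, R²Y, Q²Y) per iteration,
fits least-squares lines through the permuted points plus the unpermuted
point at correlation 1, and reports both intercepts plus the empirical
p-value `(1 + #{Q²_perm ≥ Q²}) / (n_iter + 1)`. The composite validity
flag applies all three rules (R²Y-intercept ≤ 0.4 — with 0.3 as a stricter
warning bound — Q²Y-intercept ≤ 0.05, p < 0.05). The pipeline, however,
aborts only on the Q² rules: when variables far outnumber samples a single
PLS component fits even permuted labels to R²Y ≈ 0.4–0.6, so the
R²Y-intercept "experience bound" flags the dimensionality of the design
rather than over-fitting; it is logged as a warning. Note the empirical
p-value has a floor of 1/(n_iter+1): fewer than 20 permutations can never
reach p < 0.05.

## Class balancing

SMOTE interpolates each synthetic minority row between a random minority
sample and one of its k = 5 nearest minority neighbours (Euclidean),
`x_new = x + u (x_nb − x)`, u ~ U(0,1). k = 5 is SMOTE's canonical default
and feasible with nine minority samples. Interpolation happens in the
calibrated intensity space and scaling is refit afterwards, so synthetic
rows never leak scaling statistics. The same balanced design feeds both
OPLS-DA and the SVM stage by default (`smote_for_svm=False` reverts the
SVM to original samples only). Balancing synthetic rows before
cross-validation does couple the folds slightly; the permutation test is
run on the same balanced design for consistency with the modelling choice.

## SVM ranking

The RBF kernel has no primal weight vector, so SVM-RFE uses the
kernel-space margin criterion: with dual coefficients held fixed,
`DJ(i) = ½αᵀKα − ½αᵀK₍₋ᵢ₎α`, where removing variable i rescales the
kernel elementwise (`K₍₋ᵢ₎ = K ∘ exp(g·d²_i)`), which makes the per-step
scores cheap to vectorise. One variable is eliminated per step; its DJ at
elimination becomes its w² (negative scores clamp to zero, ties resolved
by elimination order), and the sign of the univariate class-mean
difference supplies a signed w for export. Features are expected
standardized; the pipeline scales them. Chunked elimination is not needed
at the default problem sizes.

Hyper-parameters come from a 3-fold stratified grid search over
c, g ∈ {2⁻¹⁰ … 2¹⁰}, ties broken toward the smallest c then g — consistent
with best cells like c = g ≈ 2⁻⁸ ≈ 0.0039. On well-separated synthetic
data many cells tie at 100% 3-fold accuracy and the minimum-c tie can
generalise worse in the final repeated 10-fold CV (≈ 78% rather than
100%); the tie-break is kept because it is deterministic and favours the
least complex model. The final accuracy is the mean over 10 repeats of
stratified 10-fold CV with a deterministic per-repeat seed schedule.

## Selection and confirmation

Per contrast, the candidate set is the smallest w²-descending prefix of
the weight table containing every VIP > 1 variable — the kernel ranking is
trusted not to discard sub-VIP variables it ranks highly. This prefix rule
is an inference from the printed prefix sizes; a fixed-length alternative
can be had by slicing the weight table directly. Candidates present in
both contrasts' prefixes proceed to univariate confirmation: two-sided
Welch t-tests for the three group pairs (unequal variances are the safe
default for peak intensities) and group-mean fold changes. Eligibility
demands all three p < 0.05 and both fold changes > 2. No multiplicity
correction is applied by default, matching the workflow's screening
character (`pairwise_ttests(..., fdr_adjust=True)` applies
Benjamini–Hochberg should a user want it); t-tests use only original
samples —
synthetic SMOTE rows would fabricate degrees of freedom.

## Identification and detection limits

A variable is assigned to the library compound with the smallest
|ppm error| among those within |error| < 5 ppm and |ΔRT| ≤ 0.25 min (ties:
smallest |ΔRT|). The RT window covers the ≈ 0.18 min discrepancies seen
between observed and reference retention times for confirmed markers.
Screening rates count distinct compounds (duplicate library entries
collapse by name + mass). LODs follow the EPA MDL form: replicate
intensities at a 20 ng/mL spike are converted to concentrations via
`c_i = I_i · 20 / mean(I)`, and LOD = t₀.₉₉,ₙ₋₁ · sd(c) (3.143 for seven
replicates), converted to µg/kg by the 2.0 g → 1 mL preparation factor
(×0.5).

## Reproducibility and problem sizes

All randomness flows from one master seed through per-stage derived seeds
(SMOTE, grid folds, CV repeats, permutations, generator); reruns are
byte-identical. The default pipeline run — 310 variables × 39 samples, two
contrasts with 200-iteration permutation tests, a 441-cell grid search,
full SVM-RFE, and a blank counter-check — completes in well under a minute
on one core; the test suite runs the full design once and otherwise uses
reduced designs (8–30 markers) chosen to exercise the same code paths
quickly.

## Known limitations

- Two-class OPLS-DA only (one predictive component); no multi-class or
  O2PLS variants.
- The SVM stage is RBF-only, mirroring the workflow it implements.
- The permutation p-value is empirical and therefore granular at small
  iteration counts.
- Identification is accurate-mass/RT only; no MS/MS fragment confirmation.
- Synthetic-data conclusions carry the caveats listed under "Study design
  and synthetic data".
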