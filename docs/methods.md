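# Methods

This note documents the models, conventions and design choices behind
`predmet`, in the spirit of the methods documentation of statsmodels or
scanpy: what is computed, under which assumptions, with which defaults, and
where the genuinely open choices were made.

## Synthetic data

Real GC-TOFMS biomarker studies of the kind this package targets rarely
deposit raw patient data, so the generator in `predmet.simulate` is a
first-class component, not a test fixture. It emulates the structural
features the downstream algorithms must cope with; its defaults define the
study conditions under which the test suite and `scripts/acceptance.py`
operate.

**Raw cubes** (`generate_cube`). The chromatogram is a sequence of time
windows (60 scans of 0.5 s each); each window holds a cluster of Gaussian
elution peaks (SD 2 s) whose centers are `(1 − overlap) · 4σ` apart, so
`overlap = 0` gives baseline separation and `overlap → 1` complete
co-elution. Every component has a fixed sparse non-negative fragment
spectrum (10 of 120 integer m/z bins, unit sum) shared across samples.
Component areas are log-normal (median 100, log-SD 0.3); an optional class
effect shifts informative log-areas by `d` pooled SDs. Internal standards
are extra components with constant spiked areas; an optional per-sample
log-normal recovery factor multiplies the whole signal, which is exactly
the nuisance internal-standard normalization removes. Retention-index
markers form a linear ladder (RI 1000 + 100 per window).

*Noise convention.* `snr` is the signal-to-noise amplitude ratio in the
energy sense: the additive Gaussian noise SD is chosen so that the
Frobenius norm of the noise-free cube is `snr` times the expected Frobenius
norm of the noise. This makes statements like "a two-component window at
SNR 100 is numerically rank 2 to ~10⁻⁴ relative energy" exact and
geometry-independent; a peak-apex-to-noise-SD convention would tie the
effective noise floor to the sparsity of the signal. Intensities are
clipped at zero after noise and baseline addition, as a detector would.

**Feature tables** (`generate_feature_table`). Log-normal positive values
(relative-concentration semantics); the first `n_informative` features get
a class-mean separation of `effect_size` pooled SDs on the log scale with
randomly signed directions; an equicorrelated Gaussian block (parameter
`correlation`) couples the informative set. The standard recovery scenario
used throughout the tests is 40 + 40 samples, 200 features, 10 informative
at d = 2 — a moderately hard problem where selection is non-trivial but
recoverable.

**Failure injection** (`inject_failures`) multiplies outlier samples'
profiles by a gross factor (default 8×, far outside the score-space cloud)
and collapses 80% of a failed sample's features to near zero, emulating
analytical errors and failed derivatization respectively.

*What the generator does not emulate*: peak tailing and spectral skew,
detector saturation, retention-time warping between runs (cubes are
generated aligned; alignment is reduced to the shared time axis plus
RI-marker interpolation), heteroscedastic shot noise, and realistic
metabolite-metabolite correlation structure outside the informative block.
Passing tests therefore demonstrate algorithmic correctness under the
stated model, not robustness to every artifact of real instruments.

## Curve resolution

Baseline: per sample and m/z channel, morphological opening (rolling
minimum then rolling maximum over `window_length` scans, default 21)
followed by a moving-average smooth; the opening tracks sloped baselines
without the half-window offset a bare rolling minimum suffers. Output is
clipped at zero and total ion current can only decrease.

Window segmentation places the `n − 1` interior boundaries at the lowest
local minima of the mean TIC, greedily, subject to a minimum window width;
the TIC is smoothed at the minimum-width scale first so each inter-peak
valley contributes a single candidate. Windows are half-open `[start, end)`
in 0-based scan indices and tile the axis.

Each window's sample-stacked matrix `D` ((samples·scans) × m/z) is
factorized as `D = C Sᵀ` by alternating least squares with non-negativity
on both factors, unit-sum spectra, and unimodality enforced on each
sample's elution segment (monotone clipping away from the apex). The rank
is the smallest number of singular values explaining ≥ 99% of the energy,
capped at `max_components` (default 5); `C` is initialized from
SIMPLISMA-style purest m/z channels, which makes the fit deterministic
without a seed. Convergence is a relative change in lack-of-fit below `tol`
(default 1e-8) with a `max_iter` cap; non-convergence flags the features
rather than raising. Per-sample areas are the least-squares scale of the
sample's elution segment onto the across-sample mean profile, times the
trapezoidal integral of that profile.

Split peaks across adjacent window boundaries are merged automatically
when spectral cosine exceeds 0.98 and apex times agree within 2 scans —
the automated stand-in for the manual curation step of interactive
workflows.

Library matching is the normalized spectral dot product, gated on
|ΔRI| ≤ `ri_tol` (default 30 RI units), accepted above `min_score`
(default 0.8); unidentified features stay in the analysis. Internal-standard
normalization divides each sample's areas by the geometric mean of its IS
areas (robust to a single aberrant standard on the log scale) and flags
samples with non-positive IS areas for exclusion instead of normalizing
them.

## OPLS-DA

The class response is coded {0, 1} and centered. For each of `A_orth`
orthogonal components: `w ∝ Xᵀy`, `t = Xw`, `p = Xᵀt/tᵀt`, the orthogonal
weight is `p` minus its projection on `w` (normalized), and `X` is deflated
by the corresponding orthogonal score/loading product. The predictive
component is then the single-component PLS fit of the filtered matrix, so
with `A_orth = 0` the model is exactly one-component NIPALS PLS (a test
pins this to 1e-8). `w*` has unit norm and is oriented so class 1 has
positive mean predictive score; `R2X` is one minus the residual energy of
the full decomposition, `R2Y` the explained fraction of the centered
response. The exact variance decomposition (predictive + orthogonal +
residual = total) holds to machine precision and is asserted in the tests.

Scaling defaults to unit variance with centering (pareto and plain
centering available); the convention is not derivable from study reports
that omit it, so it is a package default, applied identically to training
and held-out data via stored centering/scaling vectors. Zero-variance
columns cannot be UV-scaled and are dropped with a warning.

Cross-validation is seven-fold by default: samples sorted by class then
original order are dealt round-robin into folds, which is deterministic and
stratified; a seed switches to randomized stratified folds. Scaling and the
full model are refit inside every training split; held-out samples are
projected through the training orthogonal filter to give the
cross-validated predictive score `tcv`. `Q2 = 1 − PRESS/SS` on the
response. Classes smaller than the fold count simply appear in fewer test
folds; training folds always retain both classes.

**CV-ANOVA.** The F statistic is
`F = ((SS − PRESS)/d1) / (PRESS/d2)` with `d1` the number of model
components (1 + `A_orth`) and `d2 = n − 1 − d1`; the p-value is the upper
tail of `F(d1, d2)`, reported as 1 when `F ≤ 0` and floored at the smallest
positive double instead of 0. The degrees-of-freedom convention for
cross-validated ANOVA is not standardized across software; this choice is
pinned empirically by the null simulation (measured type-I rate 1–5% at
nominal 5% over 200-replicate blocks — mildly conservative, never
anti-conservative).

The orthogonal-component count is chosen by the smallest `A_orth` such that
one more component fails to improve Q2 by more than 0.01.

## Feature selection and annotation

Selection keeps features with `w*` outside `mean ± 2 SD` computed on the
*signed* weights — the two-sided reading of the ± band; with ~200 features
the normal tails admit a handful of chance selections, which the refit and
annotation stages tolerate by design. Selection runs once (no iterated
reselect), never uses p-values, and is equivariant to positive rescaling of
raw feature columns under UV scaling. An empty selection raises rather than
silently keeping everything.

Mann–Whitney U counts `a > b` pairs plus half the ties. With the smaller
group ≤ 8 and no ties the two-sided p comes from full enumeration of the
null distribution (ballot-counting recurrence), defined as
`2·P(U ≤ min(u, n₁n₂ − u))` capped at 1; otherwise the normal approximation
with tie correction and continuity correction is used. P-values are
reported uncorrected (annotation, not inference over the feature set); a
Benjamini–Hochberg option exists but is off by default. Direction arrows
compare class medians on the unscaled table; exact ties are flagged
ambiguous.

**Known limitation — selection optimism.** The w*-band is computed on the
full data before the final model is cross-validated, mirroring common
chemometric practice. On null data this leaks information: the
cross-validated Q2/p of the *reduced* model is optimistic, which is why
type-I calibration is asserted on the pre-selection model and why the
pre-selection CV-ANOVA p is the number to trust for "is there any signal at
all". The per-comparison reports include both models' statistics.

## ROC of cross-validated patterns

AUROCC uses the all-pairs definition (concordant + half-tied over
`n₁·n₀`), computed via ranks and identical to `U/(n₁n₀)`; orientation
follows the model's sign convention and is not forced above 0.5. The 95% CI
is a stratified percentile bootstrap (resampling within each class,
default 1000 replicates, seeded); when every replicate separates perfectly
the interval degenerates to (1.000–1.000), and summaries are formatted
`AUC (lower–upper)` with three decimals. ROC is always computed on
cross-validated scores, never on in-sample scores — on null data this pulls
the median AUC back to ~0.5 where in-sample scores overfit upward (asserted
by simulation).

## Curation and survival grouping

Curation drops (1) near-constant artifact features, (2) samples flagged by
internal-standard failure or with a majority of features collapsed to near
zero (failed derivatization), and (3) gross score-space outliers — samples
more than 5 interquartile ranges from the median on either of the first two
PCA score axes of the log-scaled table. The robust fence deliberately
targets only gross analytical deviations: the Hotelling-T² 95% ellipse
(available from `pca_overview`) flags ~5% of perfectly clean samples by
construction and therefore serves as a screening diagnostic, not an
exclusion rule. Curation aborts if more than 25% of samples would be
dropped, which almost always indicates mis-scaled input. Every action is
logged with a reason code; comparisons only ever see curated tables.

Survival is dichotomized by preset: glioblastoma-style (short ≤ 4 months,
long ≥ 36 months) and oligodendroglioma-style (short ≤ 24 months, long
> 36 months, strict), with samples in the middle band excluded from the
comparison. Thresholds and inclusivity are configurable.

## Problem sizes

The simulations behind the tests and the acceptance script use 8-sample
cubes with 1–8 windows for resolution recovery, the 40/40 × 200 table for
power and null calibration (25 and 200 replicates respectively), and a
77-sample, 197-feature demo study for the end-to-end run. These sizes were
chosen so the full statistical battery — including 200 null replicates of a
seven-fold cross-validated model — completes in well under a minute while
keeping every estimate's Monte-Carlo error small relative to the asserted
margins.
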