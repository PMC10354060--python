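# Methods

`phonovox` implements a voxelwise encoding-model (VM) analysis of phonemic
segmentation in narrative speech, together with the simulation framework
needed to test every stage on synthetic data. This note documents the
models, the numerical choices, and what the synthetic experiments do and do
not establish about real fMRI data.

## Stimulus representation

Speech is represented as a time-aligned phoneme stream: each phoneme event
carries a label from a fixed 39-symbol ARPAbet inventory (24 consonants, 15
vowels, CMU pronouncing-dictionary conventions with stress stripped), an
onset/offset in seconds, and the identity and position of its containing
word. From this stream the package builds six TR-sampled feature spaces:

- **spectrum** — Welch band power of the audio in 448 contiguous 33.5 Hz
  bands from 25 Hz to 15 kHz, one 2-s analysis window anchored at each TR
  start (Hann sub-windows of 0.25 s, 50% overlap). Anchoring windows at
  exact TR starts keeps the rows on the TR grid by construction.
- **count** — the number of phoneme onsets in each half-open TR bin
  `[t, t + TR)`.
- **phoneme / diphone / triphone** — indicator regressors for n-gram
  identity. N-grams are formed *within* words only; each token drops a
  unit-area impulse at the onset of its first phoneme on a 100 Hz fine
  grid, and the train is low-pass resampled to the TR grid with a
  3-lobe Lanczos (windowed-sinc) kernel, cutoff at the TR Nyquist
  frequency (0.5/TR Hz). Interpolation rows are normalized to unit weight
  sum, so constants pass through exactly and a single event integrates to
  one event of mass on the TR grid.
- **semantic** — each word drops its embedding vector (a row of a
  word → R^985 lexicon table, or any dimension) at the word onset; each
  embedding dimension is an impulse train filtered exactly like the
  indicator features. Out-of-lexicon words map to the zero vector with a
  logged warning, which keeps synthetic lexicons usable.

Each feature space is delay-stacked at 2, 4, 6 and 8 s (snapped to integer
multiples of the TR, so 1–4 rows at TR = 2.0045 s) to form a
finite-impulse-response design: the three standard model configurations
yield 1796 (448 + 1 spectral/count features), 22 952
(39 + 858 + 4841 phonemic features) and 26 892 (phonemic + 985 semantic)
columns.

## Banded ridge with an HRF temporal prior

For each voxel the BOLD response is predicted by Tikhonov-regularized
regression in which every feature-space block `b` has its own penalty
`lambda_b`, and a fixed temporal prior rescales each delay's columns by the
canonical double-gamma HRF evaluated at that delay (normalized to max 1,
floored at 1e-3). Both are implemented as column rescaling

    X~[:, c] = X[:, c] * prior[delay(c)] / sqrt(lambda_block(c))

followed by ordinary ridge with unit penalty, solved in the primal
(`columns <= rows`) or in the dual/kernel form otherwise; the two give
identical predictions and the package oracle-tests this equivalence to
1e-8. Design columns and BOLD responses are z-scored before fitting (BOLD
per story); the column statistics are taken from the whole stimulus design,
never per fold — per-fold statistics are unstable for sparse indicator
columns whose few events fall in a held-out span, and that instability can
produce strongly negative held-out R².

Hyperparameters are selected per voxel on a Cartesian grid of 10
log-spaced values per block (default range 1e-1 to 1e5, configurable) by
contiguous-in-time cross-validation folds, which respect BOLD
autocorrelation; exact ties go to the larger penalty. Prediction quality is
the coefficient of determination `R² = 1 − SSE/SST` with SST taken from
the scored rows' own variance, so a constant prediction at the mean scores
exactly 0. Acoustic-baseline predictions can be subtracted from the
z-scored response (`residualize`) before phonemic modeling, using the
training-fitted baseline on both training and validation data.

## Variance partitioning

Unique and shared explained variance over two or three feature spaces is
obtained by refitting every nonempty subset of blocks at the *joint*
model's per-block penalties and applying commonality analysis
(inclusion–exclusion) to the subset R² values; the seven (or three)
partitions sum to the full model's R² as an algebraic identity. Negative
partitions — a known artifact of R² estimation — are clipped to zero in
the corrected table, with the raw values and the clipped magnitude
retained for audit.

Diphone tokens are categorized by their word-relative role: `short_word`
(the token spans a whole two-phoneme word), `word_beginning` (it starts a
longer word), `residue` (anything else); one-phoneme words can optionally
count as short-word tokens. Because each token has exactly one role, the
diphone design decomposes exactly into three per-category designs, and the
diphone prediction `P = sum_c P_c` decomposes linearly. The raw
contribution of a category is the additive explained-variance share
`(2<Y, P_c> − <P_c, P>) / SST`, which sums to the diphone block's share
exactly; the plain R² of each masked prediction is reported alongside, and
normalized contributions divide by the category's token-occurrence
proportion.

## Inference

Significance of held-out R² uses a permutation null: each permutation
applies an independent circular time shift (≥ 20 TRs by default) to every
feature-space block of the training and validation designs, refits at the
real fit's penalties, and scores validation; this preserves within-block
autocorrelation, so the null is not anti-conservative. An i.i.d. row
shuffle is available behind a flag. P-values use the add-one estimator
`(1 + #{null ≥ obs}) / (1 + n_perm)` and feed Benjamini–Hochberg FDR
control (statsmodels' step-up; the test suite checks it against a
brute-force implementation).

Group-level aggregation uses the balanced random-intercept closed form
(method-of-moments): per-subject condition means enter a two-way
decomposition whose subject main effect estimates `sigma_SUB` (floored at
zero) and whose residual mean square gives standard errors of condition
means and differences. Effect sizes are plain algebra on these components:
`d' = (mu_a − mu_b)/sigma_SUB`, `SE(d') = SE(diff)/sigma_SUB`, the
phonemic average `d'_phn = (d'_DiTri − d'_SinDi)/2` with
`SE = sqrt(SE₁² + SE₂²)/2`, and label log-odds in the two-way
(`log(p/(1−p))`) and reference (`−log(p_S/p_D)`) forms. Winner-take-all
labeling assigns each significant voxel the feature space with the largest
partition value, ties broken by a fixed order (phoneme < diphone <
triphone).

Repeat-based SNR is estimated from the magnitude-squared coherence between
two presentations of the same story, averaged over 0–0.1 Hz (Welch, 64-TR
Hann segments, 50% overlap). For two *noisy* repeats of a shared signal
the expected coherence is `(SNR/(SNR+1))²` — each repeat contributes one
factor of the signal fraction — so after the small-sample correction
`C ← (L·C − 1)/(L − 1)` (L = segment count; null mean 0, C = 1 fixed) the
estimate maps back through `SNR = sqrt(C)/(1 − sqrt(C))`. SNR is a power
ratio throughout.

## The synthetic-data generator

The generator emulates a transcribed narrative stimulus and model voxels
with known phonemic sensitivity.

**Streams.** An 8000-word lexicon is built from a first-order Markov chain
over the 39 phonemes whose rows permit ~22 successors each (English allows
roughly 850 of the 1521 conceivable diphones); phoneme marginals and word
token frequencies are Zipf-skewed, and frequent words are short. On the
default seed a 3737-TR stream realizes ≈ 820 diphone and ≈ 4800 triphone
types, matching the ≈ 835/858 diphones and ≈ 2700–4800 triphones of
transcribed story corpora. Word tokens are drawn i.i.d.; phoneme durations
follow a slowly wandering articulation rate (reflected random walk) with
log-normal jitter, and words group into sentences separated by short
pauses (0.1–0.6 s, never closer than ~1.5 TRs). The per-TR phoneme count
then stays inside 10–40 for ≥ 99% of TRs with mean ≈ 24 and carries the
slow rate modulation characteristic of narrated speech — the feature the
count model exploits.

**Voxels.** A simulated voxel responds to k distinct units of one n-gram
order (default k = 3, equal weights). Its clean signal is the weighted sum
of the unit indicator trains convolved with the canonical double-gamma HRF
at TR resolution, then low-passed below 0.1 Hz (4th-order Butterworth,
applied forward–backward). Gaussian noise is *also* low-passed with the
same filter before being scaled to the requested pass-band power SNR.
Band-limiting the noise makes the broadband R² ceiling exactly
`SNR/(SNR+1)`, matches the coherence-based SNR definition (only in-band
noise enters it), and is far closer to real BOLD noise spectra than
broadband white noise, under which the effective ceiling drops to ≈ 0.28
at SNR 1 and high-dimensional sparse voxel models become unrecoverable in
principle. Mixture voxels sum their clean signals before noise.

**Fitting protocol for simulations.** Single-block VMs share one
eigendecomposition across all shrinkage candidates and voxels.
Sensitivity sweeps score by nested cross-validation (5 contiguous outer
folds; 5 inner folds select the penalty), so the reported R² carries no
selection optimism; order recovery fits on the first 80% of the stream
(5-fold inner CV) and scores the 20% tail, because it also extracts
weights and spans six designs of up to ~27 000 columns. The shrinkage grid
for these sparse indicator designs spans 1e-1–1e7: the optimum for
thousands of near-orthonormal columns lies well above the default range's
top, and boundary selection occasionally produced catastrophically
under-shrunk fits.

## Simulation experiments and their interpretation

**Sensitivity sweep.** For each sensitivity level k, voxels responsive to
k random units are simulated at SNR 1 over 3737 TRs; the identity VM (all
units of that order) and the phoneme-count VM are compared, and the
crossover is the smallest k at which the count model's mean R² reaches the
identity model's (the first grid point is reported with a flag when the
curves only meet at a boundary). Two regimes emerge:

- *Diphones*: the identity VM is handicapped by sparsity (hundreds of
  mostly-rare diphone columns against ~3700 samples), so its R² sits at
  roughly 0.20–0.27 against the 0.5 ceiling while the count model climbs
  from near zero; the two curves meet near the top of the 10–300 grid.
- *Single phonemes*: all 39 units are frequent, so a cross-validated
  identity VM stays near the ceiling at every k and the count model
  converges from below, reaching it near the top of the 2–30 grid. A
  crossover near k = 10 would require the slow common count modulation to
  dominate the voxel's unit-specific pass-band variance by ~17:1 at
  k = 10, which no stream with counts confined to 10–40 per TR can
  deliver; with counts of mean 24 and SD 6 the two components are
  comparable at k = 10. An early crossover can therefore only come from a
  *declining* identity curve (an under-regularized fit), not from the
  count model catching up; with per-voxel cross-validated shrinkage the
  identity curve does not decline, and the package reports the boundary
  of the grid instead.

Both thresholds consequently land about a factor of three above the
values a pipeline with a declining identity curve would report; the
qualitative phenomenon — count-model performance approaching
identity-model performance as sensitivity broadens, sooner in absolute
units for phonemes than for diphones relative to inventory size — is
robust across seeds.

**Order recovery.** Matched-order VMs are fit to k = 3 voxels of orders
1–6; the report gives held-out R² against the `SNR/(SNR+1)` ceiling and
the correlation between recovered per-unit weights (summed over delays)
and the ground-truth sensitivity vector. An order counts as recoverable
when mean R² reaches half the ceiling. At 3737 TRs and SNR 1 the ladder
is sharply ordered: R² ≈ 0.48 / 0.22 / 0.05 / ≈0 / ≈0 / ≈0 and weight
correlation ≈ 0.94 / 0.61 / 0.27 / ≈0.25 for orders 1/2/3/4+. Order 1
clears the half-ceiling bar comfortably; order 2 falls just short
(0.22 vs 0.25) and order 3 well short, because isotropic ridge over
p ≈ 3300 (diphones) to ≈ 19 000 (triphones) z-scored columns against
~3000 samples cannot concentrate on a 3-sparse truth (an oracle fit
restricted to the three true units' columns reaches ≈ 0.24 at order 2 and
≈ 0.15 at order 3, so most of the gap is estimation over the full
inventory, not the signal). Readers should treat "recoverable at half the
ceiling" as a strict operationalization: by weight correlation and by the
clear cliff beyond order 3, the qualitative boundary lies between
triphones and tetraphones, but the R² bar at this data size is met by
single phonemes only.

**End-to-end fixture.** A compact bundle (400 training + 150 validation
TRs, 50 voxels: count-, phoneme-, diphone-, semantic-driven and pure
noise, 10 each) supports integration tests: per-block VMs plus
winner-take-all labeling recover ≥ 80% of ground-truth voxel types
(median across 10 seeds). So the fixture's diphone block stays estimable
at this short length, it keeps only the 80 most frequent diphones and its
diphone voxels respond to 8 frequency-weighted units; the bundle is test
plumbing with identifiable ground truth, not a study condition.

**What the synthetic results do not show.** Streams are stationary apart
from the rate walk: there is no topic drift, no speaker change, no
correlation between semantic content and phonemics beyond shared timing.
Noise is spatially independent across voxels and Gaussian. Crossover
locations depend on the phonotactic statistics and on the fitting
protocol, so they transfer to real data only at the order-of-magnitude
level; all other module-level results (filter algebra, partition
identities, permutation calibration, effect-size algebra) are exact or
distribution-level properties and transfer directly.

## Degenerate inputs and tie-breaks

Constant voxels z-score to zero columns (logged), never NaN. Constant
targets score R² = 0 by convention. Empty feature lists produce 0-column
designs. Zero-occurrence units contribute zero signal with a warning.
Winner-take-all ties go to the earlier name in the declared order;
hyperparameter ties go to the larger penalty. `sigma_SUB` is floored at
zero (variance components) and division by it errors when non-positive.
Permutation offsets are drawn uniformly with a minimum shift (adapted down
for very short validation runs).
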