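# Methods

This note documents the models, algorithmic choices, defaults and known
limitations of `meaphen`. It is the authoritative account of decisions the
code alone cannot convey.

## Data model and quality control

A recording is a set of spike-sorted units (spike times in seconds, a mean
multi-electrode template in µV, electrode positions in µm) plus culture
metadata (group/genotype, treatment, batch, age in days in vitro). All
internal times are float seconds; ages are integer days with
week = floor(age_days / 7).

QC removes units failing any of three criteria:

* firing rate ≤ 0.01 Hz (strict; `fr_min` configurable);
* refractory-period violations: fraction of inter-spike intervals shorter
  than `refractory_ms` must stay below 2%. The refractory duration is not a
  property of the sorter output, so the default of 2.0 ms follows common
  convention and is configurable;
* waveform irregularity: there is no community-standard definition, so the
  implemented rule is a declared stand-in — the peak-electrode trough must
  reach 10 µV and must precede a positive deflection (biphasic shape). The
  check can be disabled wholesale (`check_waveform=False`).

Units with fewer than two spikes are removed with a distinct reason code
because the refractory criterion is undefined for them. Removing every unit
is reported as a flag, not an error, so batch pipelines keep running.

## Synthetic cultures

The simulator is the package's ground-truth instrument; it emulates the
statistical structure of developing cultures, not their biophysics.

* **Firing.** Each unit is a gamma-renewal process with shape
  k = 1/(1 − regularity); regularity 0 gives Poisson ISIs (CV ≈ 1),
  regularity → 1 approaches clock-like firing (CV ≈ sqrt(1 − regularity)).
  Rate modulation by the burst envelope uses time rescaling: spikes are
  generated homogeneously in operational time Λ(t) = ∫ e(s) ds and mapped
  back through the inverse warp, so renewal statistics survive the
  modulation.
* **Network bursts.** Burst onsets follow a gamma inter-burst-interval
  process (shape 4, mean 60/`burst_rate_per_min` seconds, a floor keeping
  consecutive truth windows disjoint). Each burst multiplies every unit's
  rate by 1 + (gain − 1)·f(t) with f a rise/decay double exponential
  normalized to unit peak (defaults: rise 0.1 s, decay 0.5 s, gain 8). The
  analytic envelope area per burst, (gain − 1)(decay − rise)/f_max, is
  verified numerically in tests.
* **Heterogeneity.** Per-unit lognormal rate factors (σ = 0.25),
  per-culture factors (σ = 0.15, shared across weeks so repeated recordings
  of a culture are correlated), and per-batch multiplicative factors
  (σ = 0.1) emulating batch effects.
* **Study structure.** Defaults describe a two-genotype, two-batch study
  with weekly 15-minute recordings over weeks 1–5 at 20 kHz. The mutant
  group's offsets (less regular firing, fewer and longer bursts, slightly
  lower rate) and the developmental trends (rate, burst rate and regularity
  increasing with age) mirror the qualitative phenotypes such studies
  report. Tests use shorter recordings and fewer units purely as a matter
  of problem size; the generator laws are identical.
* **Waveforms.** Templates are a difference of two temporal Gaussians
  (trough lobe σ 0.08 ms, peak lobe σ 0.15 ms) scaled so the realized
  trough equals the drawn amplitude exactly, attenuated across a 2×4
  electrode patch (17.5 µm pitch) with an exponential spatial constant.
  Units draw their parameters from a small set of archetypes (default: a
  large broad-spiking and a smaller narrow-spiking type). Archetype counts
  per culture follow the configured proportions exactly
  (largest-remainder rounding, then shuffled): the composition is part of
  the designed ground truth, so it is not left to multinomial sampling
  noise.
* **Perturbation.** An acute drug application is modeled as binomial
  thinning of responder units' spike trains (each spike kept with
  probability `responder_fr_ratio`); responder flags are drawn per
  archetype. This captures the observable (a firing-rate ratio), not the
  pharmacology.
* **Determinism.** All randomness descends from one `SeedSequence`; the
  same config and seed reproduce bit-identical spike trains and templates.

What the simulator does *not* model: electrode drift, sorting errors
(merged/split units), non-stationary rates within a recording beyond
bursts, synaptic connectivity (units are conditionally independent given
the envelope), and realistic waveform diversity beyond the archetype
parameterization. Tests passing on synthetic data therefore validate the
*computations*, not the biological claims.

## Single-cell features

Waveform metrics are computed on the electrode with the largest negative
template amplitude: trough and post-trough peak amplitudes,
trough-to-peak latency, width at half trough depth (with linear
interpolation at the crossings), pre/post peak asymmetry using
positive-clipped lobe amplitudes — clipping keeps the statistic in [−1, 1]
and avoids a near-zero denominator when a lobe is absent — repolarization
slope (least-squares, trough to post-peak), recovery slope (0.7 ms window
after the post-peak), and peak/trough ratio.

Spike-time metrics: mean ISI, CVI (sample sd over mean), firing rate, and
the lag-1 partial autocorrelation of the ISI sequence (≥ 5 spikes).
Anything that cannot be computed is NaN — the not-available marker
everywhere in the package — and never silently 0. Culture-level values are
unit means ignoring NaNs, with the contributing unit count recorded.

## Time-series metrics

Twenty-two metrics are computed on 100-ms binned counts (left-closed bins
anchored at t = 0, final partial bin dropped; ≥ 50 bins required). The
series is z-scored internally (sample sd); spectra are single-segment
rectangular-window periodograms with frequencies in cycles/bin; the ACF is
the biased sample estimator; lags are integer bins. Where a published
canonical-feature definition exists the implementation follows it; the
remaining definitions are fixed here:

* RF/RM: argmax of the periodogram and the power there. RM is "the
  magnitude of RF", implemented as spectral power at RF.
* CFS: power-weighted spectral centroid; LPF: proportion of power in the
  lowest fifth of frequencies.
* EAF: first integer lag with ACF < 1/e; FMA: first local ACF minimum;
  CCD: ratio of first zero-crossing lags of the ACF after/before first
  differencing.
* AMI / FMI: histogram automutual information (5×5 even-width bins, nats)
  at lag 1, and the first local minimum of that function over lags 1–40.
* SFR / SFD: two-regime fluctuation analysis of the cumulative sum over 50
  log-spaced scales in [5, n/2] — per-scale linear detrending with either
  residual range (SFR) or RMS residual (SFD); a two-segment log-log fit
  picks the split minimizing squared error and the value is the fraction
  of scales in the first regime.
* MEF: sd of residuals of a rolling 3-sample mean forecast.
* PAM: longest run strictly above the series mean (computed on raw counts;
  identical after any positive affine transform).
* EFD: embed at delay EAF, take successive 2-D distances, compare their
  10-bin density to an exponential fit (rate 1/mean) by mean absolute
  difference.
* TCT: tercile-symbolize the series subsampled at the correlation-length
  stride (boundary values fall in the lower tercile), form the joint 3×3
  transition matrix, report the trace of its column covariance.
* SES: Shannon entropy (nats) of a 10-bin histogram; MD5/MD10: histogram
  modes of the z-scored distribution.
* TRS: mean cubed successive difference (time reversibility).
* TEA: mean gap between successive extreme events (z > 1); NaN with fewer
  than two events.
* RFT: slope of log(peak frequency + 1e-3) across five equal windows.
* PDE: fraction of successive differences exceeding 0.04·sd.

Constant series return NaN for every z-score-dependent metric (PAM and PDE
remain defined, returning 0). Every metric is validated against an
independently written literal-definition oracle on 50 seeded series
(≤ 1e-6 relative error; lag metrics exact). Network-level metrics use the
identical code on the summed population series, with names prefixed `n`
versus `s` for single-cell.

## Network features

**Bursts.** The population count series (100-ms bins, all passing units)
is smoothed with a Gaussian kernel (σ = 0.1 s). The threshold is
median + k·σ̂ with σ̂ = 1.4826·MAD — the MAD scaled to a robust standard
deviation — and k = 5. The scaling matters: an unscaled MAD understates
the spread of low-count series enough to produce false bursts on
stationary recordings, violating the intended null behavior. Supra-
threshold excursions extend outward to where the rate falls below the
median (rise and decay phases), merge across gaps < 0.1 s, and must last
≥ 0.05 s. Zero detected bursts yields NaN burst features, never zeros.
Validated on simulated ground truth: pooled recall ≥ 0.95 and false
discovery ≤ 0.05 at burst gain ≥ 5, inter-burst interval recovered within
10%, and zero bursts on ≥ 18/20 stationary null cultures.

**Connectivity.** STTC follows the tiling formula exactly (checked against
a brute-force implementation to 1e-10); edges at STTC > 0.1 by default;
degenerate denominators yield NaN weights. The CCG route computes, per
ordered pair, spike-count lags in 1-ms bins over a 0–10 ms short-latency
range; significance uses surrogate trains jittered uniformly within
±10 ms. The test statistic is the *maximum* bin count over the
short-latency range, compared with the distribution of surrogate maxima
(p = (1 + #{surrogate ≥ observed})/(n + 1), edge at p ≤ 0.01). Using the
max-statistic rather than per-bin pointwise bands controls the per-pair
family-wise error, keeping the null edge rate at the nominal level; jitter
at the 10-ms scale preserves slow rate comodulation (bursts), so shared
bursting alone does not create edges. Pairs with < 10 spikes on either
side are skipped.

**Graph summaries.** DEC is realized/possible edges respecting
directedness; GEC is the mean inverse shortest-path length over ordered
pairs of the binarized graph, with directed CCG graphs symmetrized first
(edge if either direction is significant) for comparability with STTC
graphs; unreachable pairs contribute 0. Computed with
`scipy.sparse.csgraph`, cross-checked against networkx on random graphs
and closed forms.

CCG is the default graph source for DEC/GEC (matching the feature naming
convention); STTC is selectable and is the economical choice for large
studies since it needs no surrogates.

## Phenotyping (ML layer)

The design matrix is cultures × (weeks × features), week-major column
order. Missing culture-week cells are imputed with the per-column median
of same-group cultures (global median as fallback) and flagged; a
rectangular matrix is required by the classifier.

Normalization is batch-wise z-scoring with parameters estimated from
training rows only; test rows reuse those parameters. Batches with < 2
training rows fall back to global training parameters with a warning;
zero-variance columns map to 0.

Classification uses random forests (500 trees by default, stratified
class-balanced bootstrap) with leave-one-culture-out cross-validation;
each fold re-derives normalization from its own training rows, so no test
information leaks. Permutation importance shuffles all of a feature's
columns jointly (or per week with `by_time`) and reports the mean score
drop over seeded repeats. Hyperparameter search is a seeded randomized
search (tree count, depth, leaf size, features per split) scored by inner
stratified 5-fold CV — a deliberate, deterministic stand-in for Bayesian
optimization at identical budget. Age regression holds out all recordings
of a culture together (preventing culture-identity leakage, which the
rectangular week-major matrix would otherwise permit) and reports MAE
overall, per true week, and against the predict-the-training-mean
baseline.

Model transfer to treated cultures aligns columns by name (missing columns
are a schema error). New batches are normalized with their own statistics
computed on control/untreated rows when at least two exist — treated-only
batches fall back to all rows of the batch, which removes any whole-batch
shift and is flagged in the output; interpret such predictions with care.

Embedding is UMAP (15 neighbors, min-dist 0.1, fixed seed) followed by
k-means (k = 2) on the 2-D coordinates; purity is the fraction of samples
whose cluster majority class matches their own, which is ≥ the largest
class frequency by construction.

## Developmental statistics

Per feature: `value ~ 1 + group*time + (1 | culture)` by REML
(statsmodels MixedLM), group effects-coded (+1 first sorted level, −1
second — estimates are symmetric and relabeling flips signs), time in
weeks centered at the first observed week (stabilizes the intercept; the
covariate coding is otherwise arbitrary). Satterthwaite denominator
degrees of freedom are computed in-package from the closed-form restricted
log-likelihood of the random-intercept model: df = 2g²/(∇g'A∇g) with
g = Var(β̂ᵢ), gradients by central differences over the two variance
components and A the inverse observed information (numeric Hessian). The
implementation reproduces R lmerTest estimates, standard errors, df and
p values on reference data (asserted in tests) and achieves nominal type-I
error (0.03–0.07 at α = 0.05) and CI coverage (0.92–0.98) in simulation.
Boundary fits (zero subject variance) are retained and flagged
`singular`; optimizers fall through lbfgs → bfgs → powell if the
information matrix degenerates at the boundary. Bonferroni adjustment is
min(1, p·n_features); stars at 0.05/0.01/0.001. Random slopes and joint
(ANOVA-style) tests are out of scope.

## Cell typing

Units pooled across cultures are clustered on column-wise z-scored
features — waveform only, or waveform + spike-time + single-cell
time-series ("combined"). Columns whose spread is below 1e-3 of their
magnitude are dropped from the z-scoring: such columns carry only
numerical residue (e.g., a bounded statistic saturating at its limit for
every unit), and standardizing them would inflate that residue into a
full-variance noise axis that corrupts neighbor graphs. Louvain community
detection (python-igraph, seeded, resolution 1.0) runs on the symmetrized
15-nearest-neighbor graph; cluster IDs are relabeled by descending size.
Louvain's resolution limit applies: communities well above ~sqrt(edge
count) in size can split at resolution 1.0, so the archetype-recovery
guarantees are stated for study sizes where ground-truth clusters are
near-cliques of the kNN graph (roughly k ± a few units per cluster);
resolution and k are configurable for other regimes.

The cluster classifier is a random forest with stratified 5-fold CV
(confusion matrix) and per-feature permutation importance; clusters below
5 units are merged into the nearest cluster by centroid distance, with a
warning. Composition prediction reports per-culture cluster fractions
(summing to 1) and counts. Perturbation mapping matches units by ID
between baseline and post recordings, computes the firing-rate ratio, and
calls responders at a > 10% rate decrease by default — the decrease
criterion is a declared convention, not derived from any reference — with
per-cluster responder fractions.

## Problem sizes and determinism

Simulated validation studies use 15-minute recordings where a law is being
checked against its long-run value (rate convergence) and 2–5-minute
recordings with 5–20 units elsewhere; these sizes are the package's own
choice of the smallest designs in which each property is well-posed (e.g.,
burst-interval recovery needs ~30 bursts; Louvain recovery needs clusters
near the kNN clique regime). The acceptance script
(`scripts/acceptance.py --seed N --out file.json`) re-runs every check
from scratch at those sizes and writes the measured quantities as JSON;
all randomness derives from the single `--seed`. The entire ML layer and
the simulator are deterministic given a master seed; re-running feature
extraction byte-identically reproduces its CSV output.

## Known limitations

* The waveform-irregularity QC rule and the responder criterion are
  declared conventions standing in for undefined community standards.
* The CCG edge test is a surrogate-based substitute for analytic
  correction methods; its detection power at very low rates is limited by
  the discrete count statistic.
* Mixed models support exactly two groups (effects-coded contrast) and
  random intercepts only.
* Per-spike (non-template) waveform features, transfer-entropy/GLM
  connectivity, avalanche analysis and spike sorting itself are out of
  scope.
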