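# Methods

This note documents the models implemented in `halodyn`, their assumptions,
the defaults that matter, and what the synthetic generators do and do not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Elastic-scan model and reduction

An elastic neutron scan records counts per momentum transfer Q (Å⁻¹) and
temperature T (K) integrated over the spectrometer's elastic energy window.
The generative model is a mixture of harmonic scatterer populations: each
population *p* contributes weight `w_p · exp(−Q²·u²_p(T)/6)` to the elastic
form factor, with a temperature-linear mean square displacement

    u²_p(T) = u2_ref_p + (2·k_B / k'_p)·(T − t_ref),   t_ref = 278 K.

Two conventions are fixed deliberately and used consistently on both the
generation and analysis sides:

* **The /6 divisor.** The Gaussian approximation is written
  `I ∝ exp(−Q²⟨u²⟩/6)` with ⟨u²⟩ the *full* 3-D mean square displacement
  (the convention of the protein-resilience literature). Analyses using
  the `⟨u²⟩/3` (one-dimensional) convention would report MSDs half as
  large and force constants twice as large; the divisor is therefore
  stated prominently here and in the `dynamics` docstrings.
* **The force constant.** `⟨k'⟩ = 2·k_B/(d⟨u²⟩/dT)`. With ⟨u²⟩ in Å² and
  T in K the conversion is `k' (N/m) = 0.0027613 / slope (Å²/K)`
  (`TWO_KB_A2_PER_K` in `constants.py`). A k' of 0.2 N/m corresponds to an
  MSD slope of 0.0138 Å²/K.

Simulated measurement triplets follow the standard backscattering elastic
protocol: a sample run attenuated by the sample transmission, an empty-cell
run recording the additive background alone, and a vanadium run (a purely
incoherent elastic scatterer) that is Q-flat before detector efficiency and
calibrates it. Reduction divides every run by its beam monitor first (runs
of different durations become commensurable), subtracts
`transmission × empty cell`, and divides by the vanadium scan, combining
relative counting errors in quadrature. Channels with non-positive vanadium
counts are masked, never filled; negative post-subtraction intensities are
retained but counted in the provenance, because clipping at zero would bias
the downstream weighted fits. No multiple-scattering or self-absorption
corrections are applied — the simulated geometry assumes the thin flat cell
(transmission ≈ 0.90, the default) for which those corrections are
negligible.

Instrument defaults: Q grid 0.2–4.9 Å⁻¹ in 0.1 steps, eight temperatures
evenly spaced over 278–315 K (above the freezing point of water, where an
in-vivo scan avoids ice Bragg contamination), monitor 10⁶ with amplitudes
calibrated so the peak channel holds ≈10⁴ counts — i.e. ≈1% counting error,
a realistic figure for hours-long acquisitions per point. The empty-cell
background defaults to a Q-independent 5% of the sample amplitude; real
cell backgrounds have mild Q structure, but no published shape constrains
it and a constant is the neutral choice. Energy resolution (8 µeV FWHM)
is carried as metadata only: the package models elastic intensities, not
the energy axis.

## MSD extraction and ⟨k'⟩

At each temperature, `ln I` is regressed on `Q²` by weighted least squares
with weights `(I/σ_I)²` — the inverse variance of `ln I` under error
propagation — and `⟨u²⟩ = −6·slope`, with the slope variance from the
known-weights expression `1/Σw(x−x̄)²`. The default fit window is
Q ∈ [0.3, 1.5] Å⁻¹: the low-Q end of the accessible range, where the
Gaussian approximation holds for the MSD magnitudes of interest and the
length scale 2π/Q (≈ 4–21 Å here, up to ≈31 Å at the instrument's lower
limit) matches internal macromolecular motions and the larger amplitudes of
unfolding. The window is configurable; its validity is enforced per
temperature by the criterion `q_max²·⟨u²⟩/6 ≤ 2`, trimming always the
single highest-Q point and refitting while more than four points remain
(a deterministic tie-break order). Non-positive intensities inside the
window are dropped and counted. When fewer than four usable points remain
at some temperature, that temperature is flagged and excluded; the fit
fails only when every temperature fails.

⟨k'⟩ comes from a weighted linear regression of ⟨u²⟩ on T (weights
1/σ²_{u²}). A non-positive slope — rigidity indistinguishable from or
exceeding the harmonic limit — sets the `non_positive_slope` flag and
leaves k' undefined (NaN) rather than raising: downstream consumers can
then report the condition instead of crashing on a physically meaningful
degenerate case. Uncertainty is propagated analytically
(σ_k = k·σ_slope/slope) by default, or by a temperature-resampling
bootstrap (resampling the (T, u²) pairs with replacement, 1000 replicates,
seed mandatory).

Two analysis options exist because the corresponding choices in published
reductions are usually unstated: Q values may be declared in nm⁻¹
(`q_unit="invnm"`, converted at ingestion; k' is invariant), and
intensities may be normalized to the lowest-temperature scan
(`normalize_to_reference`, default off). Reference normalization shifts
every ⟨u²⟩ by a constant, so the temperature slope — and hence ⟨k'⟩ — is
invariant; the test suite asserts this.

**Comparing two measured force constants.** The recovery question — "has
the recovered condition regained the control's resilience?" — compares two
*noisy* estimates. `ForceConstant.consistent_with(other)` therefore tests
`|k'_a − k'_b| ≤ z·√(σ_a² + σ_b²)`, the standard two-measurement
equivalence check. Testing instead whether one run's confidence interval
covers the other run's point estimate would be miscalibrated by
construction (for equal variances a perfect estimator passes only ≈84% of
the time at z = 1.96), so the difference-based check is the package's
definition of "recovered the control value".

## Kill curves

Survival under lethal stress is modelled as two subpopulations dying
exponentially: a sensitive fraction *f* at `k_fast` and a tolerant
remainder at `k_slow` (day⁻¹), producing the familiar biphasic log-linear
decline with a plateau when `k_slow ≈ 0`. Fitting is least squares on log
densities (noise on plate/OD counts is multiplicative), with five
deterministic data-driven starts to escape local minima and box constraints
`0 ≤ f ≤ 1`, rates ≥ 0; if the optimizer exits with the rate labels
swapped they are reordered (`f → 1−f`). The single-exponential alternative
is fitted in closed form, and the biphasic model is *selected* only when
`AIC_biphasic < AIC_monophasic − 2` — a small-margin guard against paying
two extra parameters for noise. Below a numerical RSS floor (residuals
≈ 1e-10 per point) the AIC comparison reduces to the parameter-count
penalty, so exactly-representable monophasic data select the parsimonious
model.

## Regrowth lag

The lag model is flat-then-exponential on the log-density scale,
`log n(t) = a + r·max(t − lag, 0)` — the minimal structure matching a lag
phase followed by exponential regrowth, with no shoulder/adjustment term
(a Baranyi-type smooth transition adds a parameter the sampled curves
cannot constrain). The breakpoint is found by grid search over the
observed times (each candidate is a closed-form 2-parameter regression),
refined between the neighbouring grid points by bounded scalar
minimization. Confidence intervals come from a residual bootstrap
(default 500 replicates, seeded); bootstrap refits use the observed-time
candidate grid densified around the point estimate so the bootstrap lag
distribution is not quantized to the sampling grid. A fitted growth rate
below `min_rate` (default 0.01 h⁻¹) flags the curve "no-growth" and leaves
the lag undefined. Calibration under the packaged conditions (growth
0.05 h⁻¹, 5% multiplicative noise, 4 h sampling) is checked by the test
suite: planted lags of 0–7 days are recovered with |bias| < 0.1 d and
≥90% CI coverage.

## Growth-rate ratios

Exponential-phase rates are log-linear regression slopes on the maximal
window with R² ≥ 0.98 (at least 5 points, longest window first, ties
toward the earlier window — deterministic), and the control/stress ratio
carries a first-order log-propagated CI. The R² threshold encodes "clean
exponential phase"; flat or saturating segments fail it.

## Cytometry gating

Manual gating is replaced by a deterministic surrogate: thresholds are set
from an unstressed control sample — PI⁺ above the control's 99.5th PI
percentile, Syto⁻ below the control's 0.5th SYTO9 percentile — or fixed
explicitly via the policy object. Quantile gating requires ≥200 control
events. Reported quantities are the PI⁺ fraction, the Syto⁻ fraction and
the PI⁺/PI⁻ ratio p/(1−p). The synthetic mixture draws each channel as
10^N(µ, σ) per component (independent channels, log-normal marginals — the
standard first-order model of fluorescence intensity distributions); the
generating component index rides along as a hidden truth column so recovery
tests need no re-inference. Real cytometry adds spectral spillover,
doublets and debris that the generator deliberately omits; passing tests
show threshold logic and fraction bookkeeping are correct, not that the
surrogate reproduces any particular instrument's manual gates.

## Respiration

Oxygen microsensor traces are modelled as linear depletion
`O₂(t) = max(o2_0 − rate·t, 0)` with Gaussian sensor noise. The uptake
slope is fitted on the longest window with R² ≥ 0.99 (≥5 points, earliest
on ties) after truncating at the first zero reading — a depleted chamber
reads zero regardless of respiration, so the flat tail is not signal. The
rate is scaled by chamber volume and cell count to nmol·min⁻¹ per 10⁸
cells; with a basal (unstressed) reference the result is also expressed as
percent of basal, 100% for the reference itself. An increasing O₂ trend is
flagged rather than silently negated.

## Synthetic study conditions

The packaged scenario plants a control/recovered proteome of k' = 0.35 N/m
(u2_ref 0.4 Å²) and a stressed condition mixing in an equal-weight softened
subpopulation (k' = 0.1 N/m, u2_ref 1.2 Å²); these magnitudes are typical
of in-vivo resilience measurements on mesophile-to-halophile proteomes,
where published figures span roughly 0.1–0.5 N/m. Kill-curve conditions
are f = 0.99, k_fast = 2 d⁻¹, k_slow = 0.05 d⁻¹ with 5% noise at 15 time
points over 14 days; lag scenarios plant 3-day and 7-day lags (short
severe shock vs week-long incubation); cytometry plants a 30% PI-high
component among 10,000 events; respiration uses 200 µmol/L initial oxygen
over 60 minutes in a 5 mL chamber with 2×10⁸ cells. Monte-Carlo summaries
(recovery error, selection rates, CI coverage) use 100 replicate seeds —
large enough for stable medians and coverage counts while keeping the full
suite interactive.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; pipeline substreams are derived from the run seed by SHA-256
  hashing of the consumer's name (`derive_seed`, always < 2³¹) and logged
  in the report provenance.
* Weighted fits use closed-form WLS with known-variance errors, not
  residual-scaled covariance: the counting errors are real and should not
  be re-estimated from 8–13 points.
* Multiplicative noise is mean-preserving log-normal
  (`exp(N(−σ²/2, σ²))`, σ² = ln(1+cv²)).
* Counting errors default to √counts with a floor of 1 count so
  zero-count channels keep finite weight.
* JSON records map non-finite floats to `null`; report serialization is
  sorted-key with shortest-round-trip floats, so identical (config, seed)
  runs produce byte-identical files.

## Known limitations

* Only the elastic intensity is modelled — no energy-transfer axis,
  resolution convolution, quasielastic broadening or multiple scattering;
  the pipeline starts from Q-binned counts, not instrument-native files.
* The MSD model is strictly harmonic (linear in T); dynamical transitions
  or anharmonic onsets would curve ⟨u²⟩(T) and are out of scope.
* Mixture softening is identified only as an *apparent* (population-
  averaged) k'; no per-population decomposition is attempted, matching
  what a proteome-averaged elastic measurement can support.
* The gating surrogate and the flat-then-exponential lag model are
  deliberate simplifications of manual gating and of richer growth models;
  they are calibrated on the synthetic conditions above and make no claim
  beyond them.
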