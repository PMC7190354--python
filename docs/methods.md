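# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `pcdcn`. Units throughout: current pA, voltage mV,
conductance nS, kinetics ms, time s (t = 0 at sweep start).

## Synthetic recordings

The generator emulates whole-cell voltage-clamp recordings from large DCN
projection neurons at 20 kHz sampling with a 4 kHz low-pass acquisition
filter. With a high-chloride internal (E_Cl = 0 mV) and holding potentials
of −30 to −40 mV, IPSCs are inward; events are negative deflections by
default, with the sign configurable.

**PSC kernel.** Unit-peak biexponential k(t) ∝ e^(−t/τ_d) − e^(−t/τ_r),
defaults τ_r = 0.2 ms and τ_d = 3.4 ms (the measured single-fiber IPSC decay
at this synapse is ≈ 3.4 ms). The kernel spans 8 τ_d, leaving a truncated
tail below 0.05% of peak. Equal time constants (the alpha-function limit)
are rejected rather than special-cased.

**Minis.** Homogeneous Poisson event times; lognormal amplitudes
parameterized by arithmetic mean and CV (defaults 50 pA, 0.5 — stand-ins:
no amplitude distribution for this synapse is published, and they are
flagged as uncalibrated in the config). Noise is white Gaussian passed
through a causal 4-pole Butterworth at the acquisition cutoff, added to the
clean signal; the event waveforms themselves are not re-filtered (at τ_d =
3.4 ms their spectrum lies well below 4 kHz, so the omission changes peak
amplitudes by well under 1% and keeps ground-truth amplitudes exact).
`noise_sd_for_snr` converts a target SNR — peak amplitude over
*filtered*-noise SD — into the white-noise SD, using the filter's variance
gain computed from its impulse response.

**Short-term plasticity.** A deterministic depletion × facilitation
recursion: between stimuli, resources x recover toward 1 with τ_dep and the
release fraction u relaxes toward u₀ with τ_fac; each stimulus yields
amplitude a₁·u·x/u₀ (so the first response is exactly a₁), then depletes
x ← x(1−u) and facilitates u ← u + f_inc(1−u). Pure depletion (f_inc = 0)
has the closed forms used as test oracles: normalized amplitudes (1−u₀)^(i−1)
without recovery, and steady state x* = (1−e^(−Δ/τ))/(1−(1−u₀)e^(−Δ/τ)) at
interval Δ.

Two reference parameter sets:

| set | u₀ | τ_dep (s) | f_inc | τ_fac (s) | behaviour |
|---|---|---|---|---|---|
| `JUVENILE_STP` | 0.30 | 2.0 | 0 | — | depression deepens with frequency |
| `ADULT_STP` | 0.03 | 0.3 | 0.08 | 0.01 | steady state ≈ frequency-invariant (CV 6.6% over 10–100 Hz), facilitation index 2.1 on a 10→100 Hz step |

The adult set was tuned once (differential evolution on steady-state
flatness with a facilitation-index constraint) and then frozen. A structural
limitation of this minimal single-pool model: at high rates the steady state
is recovery-limited (release per interval ≈ Δ/τ_dep), so a steady state that
is both strongly depressed (≪ 1) and flat across 10–100 Hz is not
expressible; the tuned set holds the steady state near 0.8–0.93 of the first
response. The frequency-invariance *phenomenology* (flat steady state,
unmasked facilitation on frequency steps) is reproduced; the absolute
steady-state level of the real adult synapse is not. Its small u₀ matches
the low initial release probability believed to support sustained
transmission at this synapse.

**Minimal stimulation.** Each sweep is independently a failure or a success
(Bernoulli p), successes lognormal around 1050 pA (≈ 30 nS at −35 mV, the
single-fiber scale) with a 0.8 ms latency. **Peri-stimulus backgrounds**
are inhomogeneous Poisson via thinning, rate b·(1 − d·e^(−(t−t_s)/τ_dip))
after each successful stimulus; defaults b = 75 Hz (within the 50–100 Hz
spontaneous range at DCN cells), d = 0.8, τ_dip = 20 ms — the dip shape is
definitional, as no published values quantify it.

**Seeding.** One top-level seed; per-sweep substreams via
`SeedSequence(seed, spawn_key=(…, k))`, so sweep k is bit-for-bit
reproducible in isolation and independent of batch size.

## Event detection

Detection runs on the second derivative of the smoothed trace. Design
choices that matter, with defaults:

- **Smoothing 1.0 ms** (moving average) and a **1.5 ms central-difference
  stencil**, applied twice. A one-sample stencil at 20 kHz is dominated by
  the 4 kHz noise band (detection-statistic SNR ≈ 2.6 at trace SNR 8); the
  wide stencil measures curvature on the event's own time scale (statistic
  SNR ≈ 9). Central differences are exact for quadratics at any step, which
  the tests exploit.
- **Threshold 4.25 robust SDs** of the statistic (MAD-scaled, immune to the
  events themselves), with a floor that keeps noiseless traces from
  triggering on kernel-truncation curvature many orders below real events.
  Chosen on the detector's ROC at the design condition (2 Hz, SNR 8):
  recall ≈ 98% at ≤ 0.03 Hz false positives.
- **Amplitude confirmation, 4 SDs** of the smoothed trace: a curvature
  candidate is kept only if the trace actually deflects — rejects
  curvature-only noise triggers.
- **Onset timing** is refined on the smoothed trace as the last sample below
  a crossing level (10% of peak deflection, floored at 1.5 smoothed-noise
  SDs so small events don't jitter on noise) before the curvature peak; the
  crossing of the wide-stencil statistic itself precedes the physical onset
  by up to the stencil span and is not used as the event time. When the
  deflection never re-enters baseline (overlapping events), the inter-event
  valley serves as the onset.
- **Amplitude** is read as a 0.1 ms local average of the raw trace at the
  onset-to-peak lag estimated once from the sweep's average event waveform.
  Reading the argmax of a noisy trace would overestimate by about one noise
  SD; the fixed-lag averaged reading is unbiased and exact to <1% on
  noiseless events. The local baseline is the median of a 1 ms pre-onset
  window (kept short because spontaneous backgrounds run at 50–100 Hz); when
  its slope is significant against the noise — the tail of a preceding event
  — the baseline is extrapolated to the peak time with a quadratic fit,
  keeping events 4 ms apart accurate to ~4%.
- **Integration threshold 1 SD**: integration (for the event's area) stops
  where the deflection re-enters baseline + 1 noise SD after the peak, at
  the next event onset, or at a 50 ms cap. The exact integration rule is not
  published for this analysis; this reading is one defensible choice and is
  exposed in the config.
- Events whose context windows fall off the trace edge get NaN amplitudes —
  flagged, never silently dropped.

Detection is invariant to DC offsets and equivariant under polarity flip
with the polarity flag flipped (property-tested).

## Evoked measurements

**Classification** of minimal-stimulation sweeps: success iff the peak
deflection in a 10 ms post-stimulus window exceeds 5 pre-stimulus-noise SDs
(5 rather than 4 because the max over ~200 correlated samples exceeds 4 SDs
in a few percent of pure-noise sweeps; real successes sit at ≥ 8 SDs).

**Decay fits** I(t) = A·e^(−t/τ) + C start at the peak; fitting a
biexponential waveform with a single exponential from the peak biases τ̂ by
under 5% (rise contamination), which is the documented accuracy of this
standard reading. Non-convergence is flagged, never defaulted.

**Train amplitudes** are measured from averaged traces. The default
baseline is the 2 ms pre-stimulus mean. If that window deviates from the
pre-train rest level by more than a tolerance — max(3 SEM of the window,
0.1% of the first response) — the previous IPSC has not decayed, and the
baseline becomes a single-exponential fit of its decay (from 1 ms after its
peak to the current stimulus onset) extrapolated to the current peak time.
The sum of same-τ exponential tails is itself a single exponential, so this
extrapolation is near-exact inside a train. With fewer than two decay
samples the code falls back to the 2 ms window with a "fallback" flag. The
per-stimulus peak is read at the stimulus-to-peak lag of the first
(largest) response with a 0.1 ms average, for the same unbiasedness reason
as in detection. At 100 Hz (τ_d = 3.4 ms) the corrected path engages on
every stimulus after the first and recovers noiseless ground truth to
< 0.4%, where the naive baseline errs by ~5–6% (the closed-form kernel
residual).

**Steady state**: mean normalized amplitude over stimuli 50–80 when the
train has ≥ 80 stimuli. The published rule presupposes 80 stimuli although
the trains described have 50; for 50-stimulus trains the window is the final
20% (stimuli 40–50), and the window is configurable.

**λ** is fitted as A(n) = ss + (1−ss)·e^(−(n−1)/λ) with stimulus number n
as the independent variable, reported both in stimulus units and in seconds
(λ/f) since the published unit is ambiguous. Constant trains leave λ
unidentifiable and are flagged.

**Normalized PPR** is A₂/A₁ per cell, averaged across cells afterwards;
alternative normalizations (e.g. to the 1 Hz PPR) would rescale the curve
but not the group comparison.

**STP parameter recovery** refits the generator recursion to measured
normalized amplitudes of 10/20/50/100 Hz trains jointly by least squares.
With f_inc fixed at 0 (the depressing case) u₀ and τ_dep are well
identified: errors are 4–14% per replicate at SNR 10, where SNR is the first
response over the averaged-trace noise SD.

## Peri-stimulus analysis

Histograms pool events across trials of a class (success/failure) in 10 ms
bins over −100 to +200 ms (defaults; both configurable — neither is
published). Rate = count/(n_trials·bin width). The suppression dip fraction
is 1 − min(post)/baseline, where baseline is the pre-stimulus mean; the dip
duration runs until the per-bin count first re-enters the central 95%
Poisson interval of the baseline expectation (the recovery criterion is
ours; none is published). Both the min-based depth and the interval-based
duration are biased at low trial counts (the minimum of noisy bins
undershoots); accurate recovery of a generated 0.8 dip needs ~500 trials at
5 ms bins, which is what the tests use. Metrics are invariant to uniform
time translation (property-tested).

## Statistics

Shapiro–Wilk at α = 0.05 on each group gates the comparison: both pass →
two-tailed unpaired t-test; otherwise a two-tailed rank test. The source
convention names "Wilcoxon signed-rank" for unpaired group comparisons;
signed-rank is a paired test, so this module uses the Mann–Whitney rank-sum
form for unpaired data and offers a signed-rank mode for genuinely paired
designs. The gated procedure's type-I error is ≈ 0.04 under a normal null
(slightly conservative, as a fraction of null samples route to the rank
test). No multiple-testing correction is applied, matching the reproduced
convention; cells are treated as independent units (the pseudo-replication
of cells within animals is acknowledged, not modelled).

## What passing tests do and do not show

The generator reproduces the statistical structure the analysis relies on —
event shapes and rates, overlap at high frequencies, failure/success
mixtures, rate dips — but not acquisition artifacts (stimulus artifacts,
series-resistance errors, capacitance transients, drift), amplitude
correlations, or non-Poisson event clustering. Ground-truth validation
therefore demonstrates the correctness of the measurement chain, not the
detector's performance on arbitrary real recordings; the QC overlay exists
precisely because real data demand visual verification.

## Problem sizes

Validation runs use 100 × 100 s mini sweeps (detector fidelity), 50-stimulus
trains at 4 frequencies × 5 noise replicates (STP recovery), 100 decay-fit
seeds, 2000 null replicates and 400 routing seeds (statistics calibration).
The full suite runs in a few minutes on one CPU; `scripts/acceptance.py` in
about one minute.
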