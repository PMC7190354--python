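"""Synthetic voltage-clamp recordings with known ground truth.

Generates the recording types used to study inhibitory transmission at the
Purkinje-cell (PC) to deep-cerebellar-nuclei (DCN) synapse:

* miniature IPSCs — a homogeneous Poisson train of biexponential events with
  lognormal amplitudes on band-limited Gaussian noise,
* evoked 50-stimulus trains (5–100 Hz) whose per-stimulus amplitudes follow a
  depletion x facilitation short-term-plasticity recursion,
* minimal-stimulation sweeps that interleave failures and single-fiber
  successes,
* spontaneous backgrounds (50–100 Hz) with a transient post-stimulus rate dip.

All generators accept a single integer seed; per-sweep substreams are derived
with ``numpy.random.SeedSequence`` spawn keys so any sweep can be regenerated
in isolation. With ECl = 0 mV and negative holding potentials, IPSCs are
inward currents, so events are negative deflections by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "MiniParams",
    "STPParams",
    "StimProtocol",
    "Trace",
    "GroundTruth",
    "ADULT_STP",
    "JUVENILE_STP",
    "make_kernel",
    "kernel_peak_time_ms",
    "filtered_noise_sd",
    "noise_sd_for_snr",
    "generate_mini_trace",
    "stp_amplitudes",
    "generate_train_trace",
    "generate_minimal_stim_sweeps",
    "generate_perievent_trace",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """One sweep of membrane current versus time.

    ``samples`` are in pA; time of sample ``i`` is ``t0_s + i / sample_rate_hz``.
    ``v_hold_mV`` and ``e_rev_mV`` carry the driving-force information needed
    to convert currents to conductances (high-chloride internal: ECl = 0 mV).
    """

    samples: np.ndarray
    sample_rate_hz: float
    t0_s: float = 0.0
    v_hold_mV: float = -35.0
    e_rev_mV: float = 0.0
    stim_times_s: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        if self.stim_times_s is not None:
            self.stim_times_s = np.asarray(self.stim_times_s, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sample_rate_hz


@dataclass
class GroundTruth:
    """Generator-side truth for a synthetic recording."""

    event_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_amps_pA: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_stimulus_amps_pA: Optional[np.ndarray] = None
    success_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        self.event_amps_pA = np.asarray(self.event_amps_pA, dtype=float)
        if self.event_times_s.shape != self.event_amps_pA.shape:
            raise ValueError("event times and amplitudes must have equal length")


@dataclass
class MiniParams:
    """Parameters of the miniature-IPSC generator.

    Amplitudes are lognormal with arithmetic mean ``amp_mean_pA`` and
    coefficient of variation ``amp_cv``; ``noise_sd_pA`` is the SD of the
    white Gaussian noise *before* the acquisition low-pass filter.
    """

    rate_hz: float = 2.0
    amp_mean_pA: float = 50.0
    amp_cv: float = 0.5
    tau_rise_ms: float = 0.2
    tau_decay_ms: float = 3.4
    noise_sd_pA: float = 10.0
    polarity: int = -1
    duration_s: float = 100.0
    sample_rate_hz: float = 20000.0
    filter_cutoff_hz: float = 4000.0

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate_hz must be non-negative")
        if self.tau_rise_ms >= self.tau_decay_ms:
            raise ValueError("tau_rise_ms must be smaller than tau_decay_ms")
        if self.amp_mean_pA <= 0:
            raise ValueError("amp_mean_pA must be positive")
        if self.amp_cv < 0:
            raise ValueError("amp_cv must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate_hz <= 2 * self.filter_cutoff_hz:
            raise ValueError("sample_rate_hz must exceed twice filter_cutoff_hz")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be -1 or +1")


@dataclass
class STPParams:
    """Depletion x facilitation model of short-term plasticity.

    A released fraction ``u`` acts on a resource ``x`` (both dimensionless).
    Between stimuli, ``x`` recovers toward 1 with time constant ``tau_dep_s``
    and ``u`` relaxes toward its resting value ``u0`` with ``tau_fac_s``;
    each stimulus releases ``u*x`` (amplitude proportional to it) and then
    increments ``u`` by ``f_inc * (1 - u)``. ``f_inc = 0`` gives a pure
    depression synapse; small ``u0`` with strong facilitation reproduces
    frequency-invariant steady states.
    """

    u0: float = 0.3
    tau_dep_s: float = 2.0
    f_inc: float = 0.0
    tau_fac_s: float = 0.1
    a1_pA: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.u0 <= 1:
            raise ValueError("u0 must be in (0, 1]")
        if self.tau_dep_s <= 0:
            raise ValueError("tau_dep_s must be positive")
        if not 0 <= self.f_inc < 1:
            raise ValueError("f_inc must be in [0, 1)")
        if self.tau_fac_s <= 0:
            raise ValueError("tau_fac_s must be positive")


@dataclass
class StimProtocol:
    """Stimulus timing for an evoked-response experiment."""

    stim_times_s: np.ndarray
    frequency_hz: float
    n_stim: int
    step_index: Optional[int] = None
    step_frequency_hz: Optional[float] = None

    def __post_init__(self) -> None:
        self.stim_times_s = np.asarray(self.stim_times_s, dtype=float)
        if self.n_stim != self.stim_times_s.size:
            raise ValueError("n_stim must equal the number of stimulus times")
        if self.stim_times_s.size > 1 and not np.all(np.diff(self.stim_times_s) > 0):
            raise ValueError("stimulus times must be strictly increasing")

    @classmethod
    def regular(cls, frequency_hz: float, n_stim: int, start_s: float = 0.05) -> "StimProtocol":
        """Constant-frequency train of ``n_stim`` stimuli."""
        times = start_s + np.arange(n_stim) / frequency_hz
        return cls(times, frequency_hz, n_stim)

    @classmethod
    def frequency_step(
        cls,
        freq_a_hz: float,
        freq_b_hz: float,
        n_a: int,
        n_b: int,
        start_s: float = 0.05,
    ) -> "StimProtocol":
        """Train that switches from ``freq_a_hz`` to ``freq_b_hz`` after ``n_a`` stimuli."""
        times_a = start_s + np.arange(n_a) / freq_a_hz
        times_b = times_a[-1] + (1 + np.arange(n_b)) / freq_b_hz
        times = np.concatenate([times_a, times_b])
        return cls(times, freq_a_hz, n_a + n_b, step_index=n_a, step_frequency_hz=freq_b_hz)


# Reference parameter sets. The juvenile synapse is dominated by vesicle
# depletion (depression grows with frequency); the adult synapse balances
# depletion against facilitation so the steady state is nearly frequency
# independent over 10-100 Hz.
JUVENILE_STP = STPParams(u0=0.30, tau_dep_s=2.0, f_inc=0.0, tau_fac_s=0.1, a1_pA=1000.0)
ADULT_STP = STPParams(u0=0.03, tau_dep_s=0.3, f_inc=0.08, tau_fac_s=0.01, a1_pA=1000.0)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    """Counter-based substream: sweep k of run `seed` is reproducible alone."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def _lowpass_sos(cutoff_hz: float, sample_rate_hz: float):
    # 4-pole Butterworth, applied causally, emulating the acquisition filter.
    return signal.butter(4, cutoff_hz, fs=sample_rate_hz, output="sos")


def _lognormal_amps(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def make_kernel(tau_rise_ms: float, tau_decay_ms: float, sample_rate_hz: float) -> np.ndarray:
    """Unit-peak biexponential PSC kernel k(t) ∝ exp(-t/τd) − exp(-t/τr).

    The kernel spans at least 8 decay time constants so the truncated tail is
    below 0.04% of the peak. Equal (or nearly equal) time constants are
    rejected; the degenerate alpha-function limit is out of contract.
    """
    if tau_rise_ms >= tau_decay_ms * (1 - 1e-9):
        raise ValueError("tau_rise_ms must be strictly smaller than tau_decay_ms")
    tr = tau_rise_ms / 1000.0
    td = tau_decay_ms / 1000.0
    n = int(math.ceil(8 * td * sample_rate_hz)) + 1
    t = np.arange(n) / sample_rate_hz
    k = np.exp(-t / td) - np.exp(-t / tr)
    return k / k.max()


def kernel_peak_time_ms(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Closed-form time-to-peak of the biexponential kernel, in ms."""
    tr, td = tau_rise_ms, tau_decay_ms
    return tr * td / (td - tr) * math.log(td / tr)


def filtered_noise_sd(noise_sd_pA: float, sample_rate_hz: float, cutoff_hz: float) -> float:
    """SD of white noise of SD ``noise_sd_pA`` after the acquisition low-pass.

    Deterministic: the variance gain is the summed squared impulse response of
    the 4-pole Butterworth filter.
    """
    sos = _lowpass_sos(cutoff_hz, sample_rate_hz)
    impulse = np.zeros(8192)
    impulse[0] = 1.0
    h = signal.sosfilt(sos, impulse)
    return noise_sd_pA * math.sqrt(float(np.sum(h * h)))


def noise_sd_for_snr(
    peak_amp_pA: float,
    snr: float,
    sample_rate_hz: float = 20000.0,
    cutoff_hz: float = 4000.0,
) -> float:
    """Pre-filter white-noise SD giving ``snr = peak / filtered-noise SD``."""
    unit = filtered_noise_sd(1.0, sample_rate_hz, cutoff_hz)
    return peak_amp_pA / (snr * unit)


def _render_events(
    n_samples: int,
    sample_rate_hz: float,
    event_times_s: np.ndarray,
    event_amps_pA: np.ndarray,
    kernel: np.ndarray,
    polarity: int,
) -> np.ndarray:
    """Sum amp-scaled kernels at the sample nearest each event time."""
    out = np.zeros(n_samples)
    idx = np.clip(np.round(event_times_s * sample_rate_hz).astype(int), 0, n_samples - 1)
    for i, a in zip(idx, event_amps_pA):
        stop = min(i + kernel.size, n_samples)
        out[i:stop] += polarity * a * kernel[: stop - i]
    return out


def _add_noise(
    clean: np.ndarray,
    noise_sd_pA: float,
    sample_rate_hz: float,
    cutoff_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if noise_sd_pA <= 0:
        return clean
    white = rng.normal(0.0, noise_sd_pA, clean.size)
    sos = _lowpass_sos(cutoff_hz, sample_rate_hz)
    return clean + signal.sosfilt(sos, white)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_mini_trace(params: MiniParams, seed: int) -> tuple[Trace, GroundTruth]:
    """Miniature-IPSC sweep: Poisson events on band-limited noise.

    Event times are homogeneous Poisson at ``params.rate_hz``; amplitudes are
    lognormal (mean ``amp_mean_pA``, CV ``amp_cv``). Each event adds a scaled
    unit-peak biexponential kernel; Gaussian noise is low-pass filtered at
    ``filter_cutoff_hz`` and added. Ground-truth times/amplitudes returned.
    """
    rng = _rng(seed, 0)
    n_events = rng.poisson(params.rate_hz * params.duration_s)
    times = np.sort(rng.uniform(0.0, params.duration_s, n_events))
    amps = _lognormal_amps(rng, params.amp_mean_pA, params.amp_cv, n_events)

    n = int(round(params.duration_s * params.sample_rate_hz))
    kernel = make_kernel(params.tau_rise_ms, params.tau_decay_ms, params.sample_rate_hz)
    clean = _render_events(n, params.sample_rate_hz, times, amps, kernel, params.polarity)
    samples = _add_noise(clean, params.noise_sd_pA, params.sample_rate_hz, params.filter_cutoff_hz, rng)

    trace = Trace(
        samples,
        params.sample_rate_hz,
        meta={"kind": "minis", "seed": seed, "rate_hz": params.rate_hz},
    )
    return trace, GroundTruth(event_times_s=times, event_amps_pA=amps)


def stp_amplitudes(params: STPParams, protocol: StimProtocol) -> np.ndarray:
    """Per-stimulus IPSC amplitudes from the depletion x facilitation recursion.

    Deterministic. Before stimulus i, resources relax toward 1 with
    ``tau_dep_s`` and the release fraction relaxes toward ``u0`` with
    ``tau_fac_s`` over the preceding inter-stimulus interval; the amplitude is
    ``a1_pA * u_i * x_i / u0`` so the first response equals ``a1_pA`` exactly.
    """
    times = protocol.stim_times_s
    amps = np.empty(times.size)
    x, u = 1.0, params.u0
    for i, t in enumerate(times):
        if i > 0:
            dt = t - times[i - 1]
            rec = math.exp(-dt / params.tau_dep_s)
            x = 1.0 - (1.0 - x) * rec
            u = params.u0 + (u - params.u0) * math.exp(-dt / params.tau_fac_s)
        amps[i] = params.a1_pA * u * x / params.u0
        x = x - u * x
        u = u + params.f_inc * (1.0 - u)
    return amps


def generate_train_trace(
    stp: STPParams,
    protocol: StimProtocol,
    tau_rise_ms: float = 0.2,
    tau_decay_ms: float = 3.4,
    noise_sd_pA: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 20000.0,
    filter_cutoff_hz: float = 4000.0,
    polarity: int = -1,
    post_s: float = 0.2,
    v_hold_mV: float = -35.0,
) -> tuple[Trace, GroundTruth]:
    """Evoked-train sweep: one IPSC per stimulus, amplitudes from the STP model.

    At 100 Hz with τ_decay ≈ 3.4 ms, consecutive IPSCs overlap, as in the
    recordings this emulates; downstream amplitude measurement must then
    correct its baselines. Ground truth holds the per-stimulus amplitudes.
    """
    times = protocol.stim_times_s
    if times.size == 0:
        raise ValueError("protocol has no stimuli")
    amps = stp_amplitudes(stp, protocol)
    duration = float(times[-1] + post_s)
    n = int(round(duration * sample_rate_hz))
    if np.any(times < 0) or np.any(times >= duration):
        raise ValueError("stimulus times must lie within the trace")
    kernel = make_kernel(tau_rise_ms, tau_decay_ms, sample_rate_hz)
    clean = _render_events(n, sample_rate_hz, times, amps, kernel, polarity)
    rng = _rng(seed, 0)
    samples = _add_noise(clean, noise_sd_pA, sample_rate_hz, filter_cutoff_hz, rng)
    trace = Trace(
        samples,
        sample_rate_hz,
        v_hold_mV=v_hold_mV,
        stim_times_s=times,
        meta={"kind": "train", "seed": seed, "frequency_hz": protocol.frequency_hz},
    )
    return trace, GroundTruth(per_stimulus_amps_pA=amps)


def generate_minimal_stim_sweeps(
    p_success: float,
    success_amp_pA: float = 1050.0,
    amp_cv: float = 0.3,
    n_sweeps: int = 50,
    tau_rise_ms: float = 0.2,
    tau_decay_ms: float = 3.4,
    noise_sd_pA: float = 0.0,
    seed: int = 0,
    sweep_duration_s: float = 0.2,
    stim_time_s: float = 0.05,
    latency_ms: float = 0.8,
    sample_rate_hz: float = 20000.0,
    filter_cutoff_hz: float = 4000.0,
    polarity: int = -1,
    v_hold_mV: float = -35.0,
) -> tuple[list[Trace], GroundTruth]:
    """Minimal-stimulation sweeps: Bernoulli mixture of failures and successes.

    Emulates lowering the stimulus intensity until a single PC axon is
    recruited probabilistically. Each sweep is independently a failure (no
    evoked current) or a success whose amplitude is lognormal around
    ``success_amp_pA``. Returns the sweeps and ground-truth labels/amplitudes.
    """
    if not 0 <= p_success <= 1:
        raise ValueError("p_success must be in [0, 1]")
    kernel = make_kernel(tau_rise_ms, tau_decay_ms, sample_rate_hz)
    n = int(round(sweep_duration_s * sample_rate_hz))
    label_rng = _rng(seed, 0)
    labels = label_rng.random(n_sweeps) < p_success
    amps = np.where(
        labels, _lognormal_amps(label_rng, success_amp_pA, amp_cv, n_sweeps), 0.0
    )
    onset = stim_time_s + latency_ms / 1000.0
    sweeps = []
    for k in range(n_sweeps):
        rng = _rng(seed, 1, k)
        clean = np.zeros(n)
        if labels[k]:
            clean = _render_events(
                n, sample_rate_hz, np.array([onset]), np.array([amps[k]]), kernel, polarity
            )
        samples = _add_noise(clean, noise_sd_pA, sample_rate_hz, filter_cutoff_hz, rng)
        sweeps.append(
            Trace(
                samples,
                sample_rate_hz,
                v_hold_mV=v_hold_mV,
                stim_times_s=np.array([stim_time_s]),
                meta={"kind": "minimal_stim", "sweep": k, "seed": seed},
            )
        )
    truth = GroundTruth(
        event_times_s=np.full(n_sweeps, onset),
        event_amps_pA=amps,
        success_labels=labels,
    )
    return sweeps, truth


def _inhomogeneous_poisson_times(
    rng: np.random.Generator,
    duration_s: float,
    base_rate_hz: float,
    stim_times_s: np.ndarray,
    stim_success: np.ndarray,
    dip_depth: float,
    dip_tau_s: float,
) -> np.ndarray:
    """Thinning sampler: rate dips to base*(1-dip_depth) right after each
    successful stimulus and recovers exponentially with ``dip_tau_s``."""
    n_cand = rng.poisson(base_rate_hz * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, n_cand))
    if dip_depth == 0 or stim_times_s.size == 0:
        return cand
    good_stims = stim_times_s[stim_success.astype(bool)]
    rate = np.full(cand.size, 1.0)
    for ts in good_stims:
        after = cand >= ts
        rate[after] = np.minimum(
            rate[after], 1.0 - dip_depth * np.exp(-(cand[after] - ts) / dip_tau_s)
        )
    keep = rng.random(cand.size) < rate
    return cand[keep]


def generate_perievent_trace(
    base_rate_hz: float = 75.0,
    dip_depth: float = 0.8,
    dip_tau_s: float = 0.02,
    stim_times_s: Optional[Sequence[float]] = None,
    success_labels: Optional[Sequence[bool]] = None,
    duration_s: float = 20.0,
    amp_mean_pA: float = 50.0,
    amp_cv: float = 0.5,
    tau_rise_ms: float = 0.2,
    tau_decay_ms: float = 3.4,
    noise_sd_pA: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 20000.0,
    filter_cutoff_hz: float = 4000.0,
    polarity: int = -1,
) -> tuple[Trace, GroundTruth]:
    """Spontaneous background with a transient post-stimulus rate suppression.

    Event intensity is ``base_rate * (1 - dip_depth * exp(-(t - t_stim)/dip_tau))``
    after each stimulus on success trials and constant on failure trials,
    emulating the transient sIPSC-frequency dip seen after evoked responses.
    """
    if not 0 <= dip_depth <= 1:
        raise ValueError("dip_depth must be in [0, 1]")
    stims = np.asarray([] if stim_times_s is None else stim_times_s, dtype=float)
    if success_labels is None:
        success = np.ones(stims.size, dtype=bool)
    else:
        success = np.asarray(success_labels, dtype=bool)
        if success.size != stims.size:
            raise ValueError("success_labels must match stim_times_s in length")
    rng = _rng(seed, 0)
    times = _inhomogeneous_poisson_times(
        rng, duration_s, base_rate_hz, stims, success, dip_depth, dip_tau_s
    )
    amps = _lognormal_amps(rng, amp_mean_pA, amp_cv, times.size)
    n = int(round(duration_s * sample_rate_hz))
    kernel = make_kernel(tau_rise_ms, tau_decay_ms, sample_rate_hz)
    clean = _render_events(n, sample_rate_hz, times, amps, kernel, polarity)
    samples = _add_noise(clean, noise_sd_pA, sample_rate_hz, filter_cutoff_hz, rng)
    trace = Trace(
        samples,
        sample_rate_hz,
        stim_times_s=stims if stims.size else None,
        meta={"kind": "perievent", "seed": seed, "base_rate_hz": base_rate_hz},
    )
    truth = GroundTruth(event_times_s=times, event_amps_pA=amps, success_labels=success)
    return trace, truth
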