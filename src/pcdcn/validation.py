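"""End-to-end validation measurements against generator ground truth.

Each function runs one study-sized check of the pipeline — detector
fidelity on Poisson minis, overlap-corrected train amplitudes, kinetics
recovery, short-term-plasticity phenomenology and parameter recovery, and
the calibration of the gated statistics — and returns the measured
quantities. The functions are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfilt

from . import detect as _detect
from . import evoked as _evoked
from . import stats as _stats
from . import synthgen as _synth

__all__ = [
    "detector_fidelity",
    "overlap_correction",
    "kinetics_recovery",
    "stp_phenomenology",
    "stp_parameter_recovery",
    "stats_gate_calibration",
]

MATCH_TOL_S = 2e-3  # one event rise+decay scale at tau_decay 3.4 ms


def _match(detected: np.ndarray, truth: np.ndarray, tol_s: float = MATCH_TOL_S):
    used = np.zeros(detected.size, dtype=bool)
    matched = 0
    for t in truth:
        if not detected.size:
            break
        d = np.where(used, np.inf, np.abs(detected - t))
        j = int(np.argmin(d))
        if d[j] < tol_s:
            matched += 1
            used[j] = True
    return matched, detected.size - matched


def detector_fidelity(
    seed: int = 0,
    n_seeds: int = 100,
    rate_hz: float = 2.0,
    duration_s: float = 100.0,
    snr: float = 8.0,
) -> dict:
    """Recall, false-positive rate, and frequency accuracy on synthetic minis."""
    noise_sd = _synth.noise_sd_for_snr(50.0, snr)
    params = _synth.MiniParams(rate_hz=rate_hz, duration_s=duration_s, noise_sd_pA=noise_sd)
    cfg = _detect.DetectConfig()
    n_true = n_matched = n_fp = 0
    freq_est = []
    for k in range(n_seeds):
        trace, truth = _synth.generate_mini_trace(params, seed=seed + k)
        events = _detect.detect_events(trace, cfg)
        m, fp = _match(events.times_s, truth.event_times_s)
        n_true += truth.event_times_s.size
        n_matched += m
        n_fp += fp
        freq_est.append(_detect.event_frequency(events, duration_s))
    return {
        "recall_pct": 100.0 * n_matched / n_true,
        "false_positive_hz": n_fp / (n_seeds * duration_s),
        "frequency_error_pct": 100.0 * abs(np.mean(freq_est) - rate_hz) / rate_hz,
        "n_events": n_true,
        "n_seeds": n_seeds,
    }


def overlap_correction(frequency_hz: float = 100.0, n_stim: int = 50) -> dict:
    """Noiseless train: corrected vs naive baseline error, plus the
    closed-form kernel residual the naive path must exceed."""
    protocol = _synth.StimProtocol.regular(frequency_hz, n_stim)
    trace, truth = _synth.generate_train_trace(_synth.JUVENILE_STP, protocol)
    amps, modes = _evoked.train_amplitudes(trace, protocol)
    naive, _ = _evoked.train_amplitudes(trace, protocol, rest_tol_frac=np.inf)
    rel = np.abs(amps - truth.per_stimulus_amps_pA) / truth.per_stimulus_amps_pA
    rel_naive = np.abs(naive - truth.per_stimulus_amps_pA) / truth.per_stimulus_amps_pA

    # closed-form single-kernel residual bound for stimulus 2 (per cent of A2)
    fs = trace.sample_rate_hz
    kernel = _synth.make_kernel(0.2, 3.4, fs)
    t_peak = np.argmax(kernel) / fs
    isi = 1.0 / frequency_hz
    resid_peak = kernel[int(round((isi + t_peak) * fs))]
    bl = kernel[int((isi - 0.002) * fs) : int(isi * fs)].mean()
    a1, a2 = truth.per_stimulus_amps_pA[:2]
    residual_bound_pct = 100.0 * abs(resid_peak - bl) * a1 / a2

    return {
        "corrected_max_error_pct": 100.0 * float(rel.max()),
        "naive_max_error_pct": 100.0 * float(rel_naive.max()),
        "closed_form_residual_pct": float(residual_bound_pct),
        "n_extrapolated": int(sum(m == "exp_extrap" for m in modes)),
        "n_stim": n_stim,
    }


def kinetics_recovery(seed: int = 0, n_seeds: int = 100, snr: float = 10.0) -> dict:
    """Decay-tau recovery at SNR 10 over seeds; conductance noiselessly."""
    fs = 20000.0
    kernel = _synth.make_kernel(0.2, 3.4, fs)
    sos = butter(4, 4000.0, fs=fs, output="sos")
    amp = 500.0
    noise_sd = _synth.noise_sd_for_snr(amp, snr)
    n = int(0.1 * fs)
    clean = np.zeros(n)
    clean[100 : 100 + kernel.size] = -amp * kernel[: n - 100]
    taus = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        x = clean + sosfilt(sos, rng.normal(0, noise_sd, n))
        fit = _evoked.fit_decay_tau(_synth.Trace(x, fs), fit_span_s=0.03)
        if fit.converged:
            taus.append(fit.tau_ms)

    g_true = 30.0
    xg = np.zeros(n)
    xg[100 : 100 + kernel.size] = g_true * (-35.0) * kernel[: n - 100]
    g_rec = _evoked.peak_conductance(_synth.Trace(xg, fs, v_hold_mV=-35.0))

    tau_mean = float(np.mean(taus))
    return {
        "tau_recovered_ms": tau_mean,
        "tau_error_pct": 100.0 * abs(tau_mean - 3.4) / 3.4,
        "conductance_recovered_nS": float(g_rec),
        "conductance_error_pct": 100.0 * abs(g_rec - g_true) / g_true,
        "n_fits": len(taus),
    }


def stp_phenomenology(n_stim: int = 200) -> dict:
    """Deterministic steady-state behaviour of the two reference synapses."""

    def ss(params, f):
        a = _synth.stp_amplitudes(params, _synth.StimProtocol.regular(f, n_stim))
        return float(np.mean(a[-20:]) / a[0])

    juv = [ss(_synth.JUVENILE_STP, f) for f in (5, 10, 20, 50, 100)]
    adult = np.array([ss(_synth.ADULT_STP, f) for f in (10, 20, 50, 100)])
    prot = _synth.StimProtocol.frequency_step(10.0, 100.0, 50, 50)
    amps = _synth.stp_amplitudes(_synth.ADULT_STP, prot)
    step = _evoked.frequency_step_analysis(amps, prot)
    return {
        "juvenile_ss_by_freq": juv,
        "juvenile_monotone_decreasing": bool(np.all(np.diff(juv) < 0)),
        "adult_ss_cv_pct": 100.0 * float(adult.std() / adult.mean()),
        "facilitation_index": float(step["facilitation_index"]),
    }


def stp_parameter_recovery(seed: int = 0, n_rep: int = 5, snr: float = 10.0) -> dict:
    """Recover u0 and tau_dep from noisy measured trains (mean of replicates)."""
    truth = _synth.JUVENILE_STP
    noise_sd = _synth.noise_sd_for_snr(truth.a1_pA, snr)
    u0s, taus = [], []
    for r in range(n_rep):
        trains = {}
        for f in (10.0, 20.0, 50.0, 100.0):
            protocol = _synth.StimProtocol.regular(f, 50)
            trace, _ = _synth.generate_train_trace(
                truth, protocol, noise_sd_pA=noise_sd, seed=seed + 100 * r + int(f)
            )
            amps, _ = _evoked.train_amplitudes(trace, protocol)
            trains[f] = amps
        rec = _evoked.fit_stp_params(trains)
        u0s.append(rec.u0)
        taus.append(rec.tau_dep_s)
    u0_m, tau_m = float(np.mean(u0s)), float(np.mean(taus))
    return {
        "u0_recovered": u0_m,
        "u0_error_pct": 100.0 * abs(u0_m - truth.u0) / truth.u0,
        "tau_dep_recovered_s": tau_m,
        "tau_dep_error_pct": 100.0 * abs(tau_m - truth.tau_dep_s) / truth.tau_dep_s,
        "n_replicates": n_rep,
    }


def stats_gate_calibration(seed: int = 0, n_reps: int = 2000, n_routing: int = 400) -> dict:
    """Type-I error of the gated comparison and routing of skewed samples."""
    rejections = 0
    for k in range(n_reps):
        rng = np.random.default_rng(seed + k)
        res = _stats.compare_groups(rng.normal(size=15), rng.normal(size=15))
        rejections += res.p_value < 0.05
    routed = 0
    for k in range(n_routing):
        rng = np.random.default_rng(seed + 10_000 + k)
        test, _, _ = _stats.normality_gate(
            rng.lognormal(sigma=1.0, size=30), rng.lognormal(sigma=1.0, size=30)
        )
        routed += test == "wilcoxon"
    return {
        "type1_error_rate": rejections / n_reps,
        "skew_rank_routing_pct": 100.0 * routed / n_routing,
        "n_reps": n_reps,
        "n_routing": n_routing,
    }
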