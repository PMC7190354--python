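"""Shared fixtures and helpers for the test suite.

All fixtures are generated programmatically — no stored recordings.
"""

from __future__ import annotations

import numpy as np
import pytest

from pcdcn.synthgen import MiniParams, Trace, make_kernel, noise_sd_for_snr

FS = 20000.0
TAU_RISE_MS = 0.2
TAU_DECAY_MS = 3.4
AMP_PA = 50.0


@pytest.fixture(scope="session")
def kernel():
    return make_kernel(TAU_RISE_MS, TAU_DECAY_MS, FS)


@pytest.fixture(scope="session")
def snr8_noise_sd():
    return noise_sd_for_snr(AMP_PA, 8.0)


def render_events(event_times_s, amps_pA, duration_s, kernel, polarity=-1, fs=FS):
    """Place amp-scaled kernels on a zero trace (no noise)."""
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    for t, a in zip(np.atleast_1d(event_times_s), np.atleast_1d(amps_pA)):
        i = int(round(t * fs))
        stop = min(i + kernel.size, n)
        x[i:stop] += polarity * a * kernel[: stop - i]
    return Trace(x, fs)


def match_events(detected_times, true_times, tol_s=2e-3):
    """Greedy one-to-one matching; returns (n_matched, n_false_positive)."""
    detected_times = np.asarray(detected_times)
    used = np.zeros(detected_times.size, dtype=bool)
    matched = 0
    for t in np.atleast_1d(true_times):
        if not detected_times.size:
            break
        d = np.where(used, np.inf, np.abs(detected_times - t))
        j = int(np.argmin(d))
        if d[j] < tol_s:
            matched += 1
            used[j] = True
    return matched, int(detected_times.size - matched)


@pytest.fixture
def mini_params(snr8_noise_sd):
    return MiniParams(rate_hz=2.0, duration_s=100.0, noise_sd_pA=snr8_noise_sd)
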