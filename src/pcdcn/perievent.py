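"""Peri-stimulus spontaneous-event rate analysis.

DCN cells receive a 50–100 Hz barrage of spontaneous IPSCs. Around an evoked
response, that background transiently drops; these tools quantify the dip:
a peri-stimulus time histogram of event rate per trial class (success vs
failure), and dip magnitude/duration metrics against a Poisson baseline band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PeriEventHistogram",
    "perievent_rate",
    "suppression_metrics",
]


@dataclass
class PeriEventHistogram:
    """Event rate around a stimulus, pooled over trials of one class."""

    bin_edges_s: np.ndarray  # relative to the stimulus, len = n_bins + 1
    rate_hz: np.ndarray
    n_trials: int
    trial_class: str

    def __post_init__(self) -> None:
        self.bin_edges_s = np.asarray(self.bin_edges_s, dtype=float)
        self.rate_hz = np.asarray(self.rate_hz, dtype=float)
        if self.rate_hz.size != self.bin_edges_s.size - 1:
            raise ValueError("rate_hz must have one entry per bin")
        if np.any(np.diff(self.bin_edges_s) <= 0):
            raise ValueError("bin edges must be increasing")
        if np.any(self.rate_hz < 0):
            raise ValueError("rates must be non-negative")

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])

    @property
    def bin_width_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])

    @property
    def total_count(self) -> int:
        return int(round(float(np.sum(self.rate_hz)) * self.bin_width_s * self.n_trials))


def perievent_rate(
    event_times_s: Sequence[float],
    stim_times_s: Sequence[float],
    window_s: tuple[float, float] = (-0.1, 0.2),
    bin_ms: float = 10.0,
    trial_labels: Optional[Sequence[bool]] = None,
) -> dict[str, PeriEventHistogram]:
    """Peri-stimulus time histograms per trial class.

    Events are pooled across trials of each class, binned relative to the
    stimulus, and converted to Hz (count / (n_trials * bin width)). With no
    ``trial_labels`` all trials form a single "all" class; otherwise classes
    "success" and "failure" are returned (a class absent from the labels is
    omitted).
    """
    events = np.asarray(event_times_s, dtype=float)
    stims = np.asarray(stim_times_s, dtype=float)
    if stims.size == 0:
        raise ValueError("need at least one stimulus time")
    lo, hi = window_s
    if hi <= lo:
        raise ValueError("window must have positive extent")
    bw = bin_ms / 1000.0
    n_bins = int(round((hi - lo) / bw))
    if n_bins < 1 or not math.isclose(lo + n_bins * bw, hi, rel_tol=1e-9, abs_tol=1e-12):
        raise ValueError("bin width must tile the window exactly")
    edges = lo + bw * np.arange(n_bins + 1)

    if trial_labels is None:
        classes = {"all": np.ones(stims.size, dtype=bool)}
    else:
        labels = np.asarray(trial_labels, dtype=bool)
        if labels.size != stims.size:
            raise ValueError("trial_labels must match stim_times_s in length")
        classes = {}
        if labels.any():
            classes["success"] = labels
        if (~labels).any():
            classes["failure"] = ~labels

    out = {}
    for name, mask in classes.items():
        counts = np.zeros(n_bins)
        sel = stims[mask]
        for ts in sel:
            rel = events - ts
            inside = rel[(rel >= lo) & (rel < hi)]
            counts += np.histogram(inside, bins=edges)[0]
        out[name] = PeriEventHistogram(
            bin_edges_s=edges,
            rate_hz=counts / (sel.size * bw),
            n_trials=int(sel.size),
            trial_class=name,
        )
    return out


def suppression_metrics(
    hist: PeriEventHistogram,
    baseline_window_s: Optional[tuple[float, float]] = None,
) -> dict:
    """Dip magnitude and duration of a peri-stimulus histogram.

    The baseline rate is the mean over the pre-stimulus window.
    ``dip_fraction`` is 1 − (minimum post-stimulus rate)/baseline, and
    ``dip_duration_s`` runs from the stimulus until the rate first re-enters
    the central 95% interval of the Poisson count expected per bin at the
    baseline rate. A flat histogram yields a dip fraction near 0 and zero
    duration.
    """
    edges = hist.bin_edges_s
    if baseline_window_s is None:
        b_lo, b_hi = float(edges[0]), 0.0
    else:
        b_lo, b_hi = baseline_window_s
    if b_hi > 0:
        raise ValueError("baseline window must be pre-stimulus")
    centers = hist.bin_centers_s
    base_mask = (centers >= b_lo) & (centers < b_hi)
    if not base_mask.any():
        raise ValueError("baseline window contains no bins")
    baseline = float(hist.rate_hz[base_mask].mean())
    post_mask = centers >= 0
    post = hist.rate_hz[post_mask]
    if post.size == 0 or baseline == 0:
        return {"baseline_hz": baseline, "dip_fraction": 0.0, "dip_duration_s": 0.0}

    dip_fraction = 1.0 - float(post.min()) / baseline

    mu = baseline * hist.bin_width_s * hist.n_trials  # expected count per bin
    lo_ct, hi_ct = sps.poisson.interval(0.95, mu)
    post_counts = post * hist.bin_width_s * hist.n_trials
    inside = (post_counts >= lo_ct) & (post_counts <= hi_ct)
    if inside[0]:
        duration = 0.0
    else:
        back = np.flatnonzero(inside)
        end_edge = edges[post_mask.argmax() + (back[0] if back.size else post.size)]
        duration = float(end_edge)
    return {
        "baseline_hz": baseline,
        "dip_fraction": dip_fraction,
        "dip_duration_s": duration,
    }
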