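"""Evoked field-potential quantification for hippocampal slices.

A Schaffer-collateral stimulus produces, in order: a one-sample
stimulus artifact, a brief biphasic afferent volley (AV, the
presynaptic fiber response), and the field EPSP.  Responses are
quantified relative to the pre-stimulus baseline by the EPSP peak
amplitude and the EPSP area (which also captures smaller, slower
responses); the AV is quantified peak-to-trough.  All measurements
exclude the artifact window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .stats import one_way_anova_bonferroni, TestResult

__all__ = [
    "EvokedTrace",
    "EPSPMetrics",
    "DEFAULT_WINDOWS",
    "synth_evoked",
    "measure_epsp",
    "group_compare",
]

#: Measurement windows in seconds relative to stimulus onset.
DEFAULT_WINDOWS: Dict[str, Tuple[float, float]] = {
    "artifact": (0.0, 0.0005),
    "av": (0.0005, 0.003),
    "epsp": (0.003, 0.050),
}


@dataclass(frozen=True)
class EvokedTrace:
    """One evoked sweep: uniform time base, voltage, and windows."""

    time: np.ndarray  # s
    voltage: np.ndarray  # mV
    stimulus_onset: float  # s
    windows: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.voltage, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ParameterError("time and voltage must be matching 1-D arrays")
        dt = np.diff(t)
        if t.size < 2 or not np.allclose(dt, dt[0]):
            raise ParameterError("time base must be uniform")
        if 1.0 / dt[0] < 10_000:
            raise ParameterError("sampling rate must be >= 10 kHz")
        w = self.windows
        if not (w["artifact"][1] <= w["av"][0] and w["av"][1] <= w["epsp"][0]):
            raise ParameterError("windows must be ordered artifact < AV < EPSP")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "voltage", v)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class EPSPMetrics:
    peak_amplitude: float  # mV, magnitude relative to baseline
    area: float  # mV*ms over the EPSP window, rectified to polarity
    av_amplitude: float  # mV, peak-to-trough in the AV window


def alpha_waveform(t: np.ndarray, amplitude: float, tau: float) -> np.ndarray:
    """Alpha function ``a * (t/tau) * exp(1 - t/tau)``; peak ``a`` at ``t = tau``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    u = t[pos] / tau
    out[pos] = amplitude * u * np.exp(1.0 - u)
    return out


def synth_evoked(
    amplitude_mv: float,
    alpha_tau_s: float = 0.010,
    av_amplitude_mv: float = 0.5,
    artifact_mv: float = 5.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    sampling_rate: float = 20_000.0,
    pre_s: float = 0.010,
    post_s: float = 0.080,
    polarity: int = 1,
) -> EvokedTrace:
    """Synthesize one evoked sweep.

    Flat zero baseline; a single-sample square artifact at stimulus
    onset; a biphasic AV wavelet 1-2 ms post-onset with the requested
    peak-to-trough amplitude; an alpha-function EPSP starting 3 ms
    post-onset whose peak equals ``amplitude_mv`` exactly (up to the
    sampling grid); optional additive Gaussian noise.
    """
    if min(amplitude_mv, alpha_tau_s, av_amplitude_mv, artifact_mv, noise_sigma) < 0:
        raise ParameterError("all generator parameters must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round((pre_s + post_s) * sampling_rate))
    t = np.arange(n) / sampling_rate
    onset = pre_s
    v = np.zeros(n)

    # Stimulus artifact: one-sample square deflection at onset.
    v[int(round(onset * sampling_rate))] += artifact_mv

    # Afferent volley: biphasic Gaussian-derivative wavelet at ~1.5 ms.
    if av_amplitude_mv > 0:
        tc = onset + 0.0015
        width = 0.0003
        u = (t - tc) / width
        wavelet = -u * np.exp(-0.5 * u**2)
        ptp = float(np.ptp(wavelet))
        v += wavelet * (av_amplitude_mv / ptp)

    # EPSP: alpha function from 3 ms post-onset.
    v += polarity * alpha_waveform(t - onset - 0.003, amplitude_mv, alpha_tau_s)

    if noise_sigma > 0:
        v += rng.normal(0.0, noise_sigma, size=n)
    return EvokedTrace(time=t, voltage=v, stimulus_onset=onset)


def measure_epsp(trace: EvokedTrace) -> EPSPMetrics:
    """Quantify one sweep: EPSP peak, EPSP area, AV amplitude.

    Baseline is the mean of the pre-stimulus segment (>= 5 ms
    required).  Peak is ``max |V - baseline|`` in the EPSP window; area
    is the trapezoidal integral of ``V - baseline`` rectified to the
    response polarity, reported in mV*ms; AV amplitude is peak-to-trough
    in the AV window.  The artifact window contributes to nothing.
    """
    t, v = trace.time, trace.voltage
    onset = trace.stimulus_onset
    if onset - t[0] < 0.005:
        raise ParameterError("need >= 5 ms of pre-stimulus baseline")
    for name, (lo, hi) in trace.windows.items():
        if onset + hi > t[-1] + 1e-12:
            raise ParameterError(f"{name} window extends beyond the trace")

    baseline = float(v[t < onset].mean())
    dv = v - baseline

    av_lo, av_hi = trace.windows["av"]
    av_mask = (t >= onset + av_lo) & (t <= onset + av_hi)
    av_amp = float(np.ptp(dv[av_mask])) if av_mask.any() else 0.0

    ep_lo, ep_hi = trace.windows["epsp"]
    ep_mask = (t >= onset + ep_lo) & (t <= onset + ep_hi)
    seg = dv[ep_mask]
    if seg.size == 0:
        raise ParameterError("EPSP window contains no samples")
    peak = float(np.max(np.abs(seg)))
    # Rectify to the response polarity (sign of the extremum).
    pol = 1.0 if seg[np.argmax(np.abs(seg))] >= 0 else -1.0
    rectified = np.clip(pol * seg, 0.0, None)
    area_mv_ms = float(np.trapezoid(rectified, t[ep_mask]) * 1000.0)
    return EPSPMetrics(peak_amplitude=peak, area=area_mv_ms, av_amplitude=av_amp)


def group_compare(
    metrics_by_condition: Mapping[str, pd.DataFrame]
) -> Dict[str, Tuple[TestResult, pd.DataFrame]]:
    """One-way ANOVA + Bonferroni on peak and area across conditions.

    ``metrics_by_condition`` maps a condition label to a frame with
    ``peak_amplitude`` and ``area`` columns (one row per sweep).
    """
    if len(metrics_by_condition) < 2:
        raise ParameterError("need at least two conditions to compare")
    labels = list(metrics_by_condition)
    out = {}
    for column in ("peak_amplitude", "area"):
        groups = [np.asarray(metrics_by_condition[c][column], dtype=float) for c in labels]
        out[column] = one_way_anova_bonferroni(groups, labels=labels)
    return out
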