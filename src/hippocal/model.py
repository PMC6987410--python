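"""Biophysical forward model of a genetically encoded calcium indicator.

The model maps a train of action potentials (APs) to a noiseless
fluorescence trace through a latent calcium variable:

* latent calcium ``c`` is expressed in single-AP equivalents; between
  spikes it decays exponentially, ``c(t + dt) = c(t) * exp(-dt / tau)``,
  and each AP increments it by 1;
* fluorescence follows a Hill-type nonlinearity with a soft saturation,

  .. math::

     \\Delta F/F(c) = \\begin{cases}
        A\\, c^{n} & c < 1 \\\\
        \\dfrac{A\\, c^{n}}{1 + \\gamma (c^{n} - 1)} & c \\ge 1
     \\end{cases}

  which is continuous at ``c = 1`` and anchored so a single isolated AP
  produces exactly ``A`` (15% for jRGECO1a);
* an optional slowly varying multiplicative baseline ``b(t)`` models
  signal drift, so the emitted trace is ``b(t) * (1 + dF/F(c(t)))``.

Default parameters are the published jRGECO1a characterization:
single-AP amplitude 0.15, decay time constant 175 ms, Hill coefficient
1.9, saturation 0.001, drift bound 0.03 per recording.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ParameterError

__all__ = [
    "IndicatorParams",
    "SpikeTrain",
    "DffTrace",
    "JRGECO1A",
    "dff_of_calcium",
    "forward_model",
]


@dataclass(frozen=True)
class IndicatorParams:
    """Forward-model parameter set for one indicator.

    Attributes
    ----------
    ap_amplitude:
        Fractional dF/F response to one isolated AP (``A``).
    decay_tau:
        Exponential time constant of latent calcium decay, seconds.
    hill_n:
        Hill coefficient of the calcium-fluorescence nonlinearity.
    saturation:
        Saturation strength ``gamma``; 0 disables saturation.
    drift_bound:
        Maximal fractional baseline drift over one recording (``eta``).
    noise_sigma:
        Gaussian noise SD in dF/F units; ``None`` means "estimate from
        the data" (see :func:`hippocal.inference.estimate_noise`).
    noise_multiplier:
        Factor applied to the estimated noise level.  CA1 recordings use
        1.5 to suppress false positives; DG recordings use 1.0.
    """

    ap_amplitude: float = 0.15
    decay_tau: float = 0.175
    hill_n: float = 1.9
    saturation: float = 0.001
    drift_bound: float = 0.03
    noise_sigma: Optional[float] = None
    noise_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.ap_amplitude <= 0:
            raise ParameterError("ap_amplitude must be > 0")
        if self.decay_tau <= 0:
            raise ParameterError("decay_tau must be > 0")
        if self.hill_n < 1:
            raise ParameterError("hill_n must be >= 1")
        if self.saturation < 0:
            raise ParameterError("saturation must be >= 0")
        if self.drift_bound < 0:
            raise ParameterError("drift_bound must be >= 0")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.noise_multiplier < 1:
            raise ParameterError("noise_multiplier must be >= 1")

    def with_sigma(self, sigma: float) -> "IndicatorParams":
        return replace(self, noise_sigma=float(sigma))


#: Published jRGECO1a parameters.
JRGECO1A = IndicatorParams()


@dataclass(frozen=True)
class SpikeTrain:
    """Per-frame nonnegative integer AP counts for one cell.

    ``counts[k]`` is the number of APs emitted during frame ``k``; the
    frame spans ``[k, k + 1) / frame_rate`` seconds.
    """

    counts: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ParameterError("counts must be one-dimensional")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)):
                raise ParameterError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ParameterError("counts must be nonnegative")
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be > 0")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_frames(self) -> int:
        return int(self.counts.size)

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_frames / self.frame_rate

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def spike_times(self) -> np.ndarray:
        """Spike times in seconds (frame start), with multiplicity."""
        return np.repeat(np.arange(self.n_frames), self.counts) / self.frame_rate


@dataclass(frozen=True)
class DffTrace:
    """A dF/F trace together with the baseline it was computed against."""

    values: np.ndarray
    frame_rate: float
    baseline_f0: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ParameterError("values must be one-dimensional")
        if not np.all(np.isfinite(values)):
            raise ParameterError("dF/F values must be finite")
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be > 0")
        if self.baseline_f0 <= 0:
            raise ParameterError("baseline_f0 must be > 0")
        object.__setattr__(self, "values", values)

    @property
    def n_frames(self) -> int:
        return int(self.values.size)


def dff_of_calcium(c: np.ndarray, params: IndicatorParams) -> np.ndarray:
    """Map latent calcium (AP equivalents) to dF/F.

    Continuous, strictly increasing in ``c``, and exactly ``A`` at
    ``c = 1``.
    """
    c = np.asarray(c, dtype=float)
    cn = np.power(np.maximum(c, 0.0), params.hill_n)
    a = params.ap_amplitude
    g = params.saturation
    sat = a * cn / (1.0 + g * (cn - 1.0))
    return np.where(c < 1.0, a * cn, sat)


def calcium_path(spikes: SpikeTrain, decay_tau: float) -> np.ndarray:
    """Latent calcium per frame: exponential decay plus AP increments.

    ``c[k] = d * c[k-1] + counts[k]`` with ``d = exp(-dt / tau)``; this
    is a first-order IIR filter applied to the count sequence.
    """
    from scipy.signal import lfilter

    d = float(np.exp(-1.0 / (spikes.frame_rate * decay_tau)))
    return lfilter([1.0], [1.0, -d], spikes.counts.astype(float))


def forward_model(
    spikes: SpikeTrain,
    params: IndicatorParams = JRGECO1A,
    drift_path: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Noiseless fluorescence trace, in units of ``1 + dF/F``.

    Parameters
    ----------
    spikes:
        AP counts per frame.
    params:
        Indicator parameters.
    drift_path:
        Optional multiplicative baseline ``b(t)`` (one value per frame).
        Omitted means a constant baseline of 1.

    Returns
    -------
    numpy.ndarray
        ``b(t) * (1 + dF/F(c(t)))`` per frame.
    """
    c = calcium_path(spikes, params.decay_tau)
    out = 1.0 + dff_of_calcium(c, params)
    if drift_path is not None:
        drift_path = np.asarray(drift_path, dtype=float)
        if drift_path.shape != out.shape:
            raise ParameterError("drift_path must have one value per frame")
        out = out * drift_path
    return out
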