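"""Model-based AP extraction from fluorescence traces.

dF/F is computed against a median baseline (F0 = median of F over the
recording).  Spike trains are then inferred as the maximum a posteriori
(MAP) train under the indicator forward model (:mod:`hippocal.model`):
the latent calcium level and a slowly drifting multiplicative baseline
are discretized onto a finite lattice, every frame pays a Gaussian
residual cost ``(y - b (1 + dF/F(c)))^2 / (2 sigma^2)``, every spike
pays a prior cost ``log(1 / (nu dt))`` for an expected firing rate
``nu``, and the jointly optimal path is decoded by dynamic programming
(Viterbi) over frames.

The noise level sigma is estimated from the high-frequency content of
the trace (median absolute deviation of first differences) and may be
inflated by a per-region multiplier: CA1 recordings use 1.5x to lower
the false-positive rate, DG recordings 1.0x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numba
import numpy as np

from .errors import BaselineError, ParameterError
from .model import DffTrace, IndicatorParams, JRGECO1A, SpikeTrain, dff_of_calcium
from .roi import FluorescenceTrace

__all__ = [
    "DecoderSettings",
    "InferenceResult",
    "compute_dff",
    "estimate_noise",
    "infer_spikes",
    "classify_active",
]

#: Lower bound on the working noise SD (dF/F units); keeps the decoder
#: well conditioned on noise-free synthetic traces.
SIGMA_FLOOR = 2e-3


def compute_dff(
    trace: Union[FluorescenceTrace, np.ndarray],
    frame_rate: Optional[float] = None,
) -> DffTrace:
    """dF/F with a median baseline: ``F0 = median(F)``, ``(F - F0)/F0``."""
    if isinstance(trace, FluorescenceTrace):
        values = trace.values
        frame_rate = trace.frame_rate
    else:
        values = np.asarray(trace, dtype=float)
        if frame_rate is None:
            raise ParameterError("frame_rate is required for bare arrays")
    if values.size == 0:
        raise ParameterError("trace is empty")
    f0 = float(np.median(values))
    if f0 <= 0:
        raise BaselineError(f"median baseline {f0} is non-positive")
    return DffTrace(values=(values - f0) / f0, frame_rate=frame_rate, baseline_f0=f0)


def estimate_noise(dff: Union[DffTrace, np.ndarray], multiplier: float = 1.0) -> float:
    """Robust high-frequency noise estimate in dF/F units.

    ``sigma = MAD(diff(dff)) / (0.6745 * sqrt(2)) * multiplier``.  The
    first-difference operator removes slow signal components; the MAD is
    insensitive to the sparse calcium transients.
    """
    values = dff.values if isinstance(dff, DffTrace) else np.asarray(dff, dtype=float)
    if values.size < 10:
        raise ParameterError("need at least 10 frames to estimate noise")
    if multiplier < 1:
        raise ParameterError("multiplier must be >= 1")
    mad = float(np.median(np.abs(np.diff(values) - np.median(np.diff(values)))))
    return mad / (0.6745 * np.sqrt(2.0)) * multiplier


@dataclass(frozen=True)
class DecoderSettings:
    """Discretization of the latent (calcium, baseline) lattice.

    Attributes
    ----------
    c_max, n_c:
        Calcium grid ``[0, c_max]`` with ``n_c`` points.
    n_b:
        Baseline grid points spanning ``1 +/- drift_bound``.
    max_spikes_per_frame:
        Largest simultaneous AP count considered in one frame.
    spike_rate_prior:
        Expected firing rate ``nu`` (Hz) in the per-spike prior cost
        ``log(1 / (nu dt))``.
    drift_block_s:
        The baseline is piecewise constant on blocks of this length;
        block-to-block steps are bounded by the drift bound.
    """

    c_max: float = 10.0
    n_c: int = 201
    n_b: int = 11
    max_spikes_per_frame: int = 6
    spike_rate_prior: float = 0.3
    drift_block_s: float = 10.0


DEFAULT_SETTINGS = DecoderSettings()


@dataclass
class InferenceResult:
    """Output of :func:`infer_spikes`."""

    spikes: SpikeTrain
    baseline_path: np.ndarray  # fitted multiplicative baseline b(t)
    spike_times: np.ndarray  # seconds, with multiplicity
    sigma: float  # noise SD used by the decoder
    clamped: bool  # latent calcium hit the top of the grid
    residual_rms: float  # RMS of y - b(t) (1 + dF/F(c_hat))


@numba.njit(cache=True)
def _viterbi(y, dff_grid, b_grid, fidx, spike_cost, inv2s2, block_frames, max_bstep):
    T = y.shape[0]
    nc = dff_grid.shape[0]
    nb = b_grid.shape[0]
    smax = fidx.shape[0] - 1
    INF = 1e300

    cost = np.full((nc, nb), INF)
    for b in range(nb):
        cost[0, b] = 0.0
    new = np.empty((nc, nb))
    tmp = np.empty((nc, nb))
    bchoice = np.empty((nc, nb), np.int8)

    bp_c = np.zeros((T, nc, nb), np.int16)
    bp_s = np.zeros((T, nc, nb), np.int8)
    bp_b = np.zeros((T, nc, nb), np.int8)

    for t in range(T):
        # Baseline step (only at drift-block boundaries).
        if t > 0 and t % block_frames == 0:
            for i in range(nc):
                for b in range(nb):
                    best = INF
                    bb = b
                    lo = b - max_bstep if b - max_bstep > 0 else 0
                    hi = b + max_bstep + 1 if b + max_bstep + 1 < nb else nb
                    for b2 in range(lo, hi):
                        if cost[i, b2] < best:
                            best = cost[i, b2]
                            bb = b2
                    tmp[i, b] = best
                    bchoice[i, b] = bb
        else:
            for i in range(nc):
                for b in range(nb):
                    tmp[i, b] = cost[i, b]
                    bchoice[i, b] = b

        # Calcium decay + spike transitions (scatter-min).
        for j in range(nc):
            for b in range(nb):
                new[j, b] = INF
        for s in range(smax + 1):
            sc = spike_cost * s
            for i in range(nc):
                j = fidx[s, i]
                for b in range(nb):
                    cand = tmp[i, b] + sc
                    if cand < new[j, b]:
                        new[j, b] = cand
                        bp_c[t, j, b] = i
                        bp_s[t, j, b] = s
                        bp_b[t, j, b] = bchoice[i, b]

        # Emission.
        yt = y[t]
        for j in range(nc):
            base = 1.0 + dff_grid[j]
            for b in range(nb):
                e = yt - b_grid[b] * base
                new[j, b] += e * e * inv2s2

        for j in range(nc):
            for b in range(nb):
                cost[j, b] = new[j, b]

    # Terminal state and traceback.
    best = INF
    jb = 0
    bb = 0
    for j in range(nc):
        for b in range(nb):
            if cost[j, b] < best:
                best = cost[j, b]
                jb = j
                bb = b
    counts = np.zeros(T, np.int64)
    c_idx = np.zeros(T, np.int64)
    b_idx = np.zeros(T, np.int64)
    j = jb
    b = bb
    for t in range(T - 1, -1, -1):
        c_idx[t] = j
        b_idx[t] = b
        counts[t] = bp_s[t, j, b]
        jp = bp_c[t, j, b]
        bp = bp_b[t, j, b]
        j = jp
        b = bp
    return counts, c_idx, b_idx


def _transition_index_map(
    c_grid: np.ndarray, decay: float, smax: int
) -> np.ndarray:
    """``fidx[s, i]``: grid index reached from ``c_grid[i]`` after decay
    plus ``s`` spikes, clamped at the top of the grid."""
    step = c_grid[1] - c_grid[0]
    fidx = np.empty((smax + 1, c_grid.size), dtype=np.int64)
    for s in range(smax + 1):
        target = c_grid * decay + s
        fidx[s] = np.clip(np.floor(target / step + 0.5).astype(np.int64), 0, c_grid.size - 1)
    return fidx


def infer_spikes(
    dff: DffTrace,
    params: IndicatorParams = JRGECO1A,
    settings: DecoderSettings = DEFAULT_SETTINGS,
) -> InferenceResult:
    """MAP spike train under the indicator forward model.

    If ``params.noise_sigma`` is unset, it is estimated from the trace
    (:func:`estimate_noise`, honoring ``params.noise_multiplier``).
    """
    y = 1.0 + dff.values
    fr = dff.frame_rate
    dt = 1.0 / fr

    sigma = params.noise_sigma
    if sigma is None:
        sigma = estimate_noise(dff, multiplier=params.noise_multiplier)
    sigma_eff = max(float(sigma), SIGMA_FLOOR)

    c_grid = np.linspace(0.0, settings.c_max, settings.n_c)
    dff_grid = dff_of_calcium(c_grid, params)
    eta = params.drift_bound
    if eta > 0 and settings.n_b > 1:
        b_grid = 1.0 + np.linspace(-eta, eta, settings.n_b)
    else:
        b_grid = np.array([1.0])
    decay = float(np.exp(-dt / params.decay_tau))
    fidx = _transition_index_map(c_grid, decay, settings.max_spikes_per_frame)
    spike_cost = float(np.log(1.0 / (settings.spike_rate_prior * dt)))
    block_frames = max(int(round(settings.drift_block_s * fr)), 1)
    # Block-to-block baseline step bounded by eta (i.e. the full grid
    # half width): eta relative steps correspond to n_b // 2 grid steps.
    max_bstep = max(b_grid.size // 2, 1)

    counts, c_idx, b_idx = _viterbi(
        np.ascontiguousarray(y, dtype=np.float64),
        dff_grid,
        b_grid,
        fidx,
        spike_cost,
        1.0 / (2.0 * sigma_eff**2),
        block_frames,
        max_bstep,
    )
    spikes = SpikeTrain(counts=counts, frame_rate=fr)
    baseline = b_grid[b_idx]
    fitted = baseline * (1.0 + dff_grid[c_idx])
    residual_rms = float(np.sqrt(np.mean((y - fitted) ** 2)))
    clamped = bool(np.any(c_idx == settings.n_c - 1))
    if clamped:
        import warnings

        warnings.warn("latent calcium clamped at grid maximum", RuntimeWarning)
    return InferenceResult(
        spikes=spikes,
        baseline_path=baseline,
        spike_times=spikes.spike_times(),
        sigma=float(sigma),
        clamped=clamped,
        residual_rms=residual_rms,
    )


def classify_active(train: SpikeTrain) -> bool:
    """A cell is active iff at least one AP was identified."""
    return train.total >= 1
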