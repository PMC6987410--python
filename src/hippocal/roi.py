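"""Ring-shaped somatic ROIs, trace extraction, and contrast QC.

Pyramidal and granule cell somata expressing a cytosolic indicator
appear as bright rings around a dark nucleus.  An ROI is therefore an
annulus of cytosolic pixels; the 5x5 pixel block at the ROI center
samples the nucleus.  The cytosol/nucleus contrast,

    contrast = (mean_ring - mean_nucleus) / mean_nucleus,

is a chronic-window image-quality metric: sessions whose cells fall
below a contrast threshold are excluded from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedContrastError
from .preprocessing import Movie

__all__ = [
    "RingROI",
    "FluorescenceTrace",
    "build_ring_roi",
    "extract_trace",
    "contrast",
    "qc_filter",
]

logger = logging.getLogger(__name__)

NUCLEAR_PATCH = 5  # side of the square nuclear sample, pixels


@dataclass(frozen=True)
class RingROI:
    """Annular cytosolic mask plus the central nuclear patch.

    ``ring_mask`` and ``nuclear_mask`` are boolean images of the full
    frame; the two are disjoint by construction.
    """

    center: Tuple[int, int]
    inner_radius: float
    outer_radius: float
    ring_mask: np.ndarray
    nuclear_mask: np.ndarray

    @property
    def n_ring_pixels(self) -> int:
        return int(self.ring_mask.sum())


@dataclass(frozen=True)
class FluorescenceTrace:
    """Mean-over-ROI fluorescence per frame for one cell."""

    values: np.ndarray
    frame_rate: float
    cell_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ParameterError("trace must be a nonempty 1-D sequence")
        if not np.all(np.isfinite(values)):
            raise ParameterError("trace values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def n_frames(self) -> int:
        return int(self.values.size)


def build_ring_roi(
    center: Tuple[float, float],
    inner_radius: float,
    outer_radius: float,
    frame_shape: Tuple[int, int],
    max_clipped_fraction: float = 0.25,
) -> RingROI:
    """Construct a ring ROI at ``center`` (row, col).

    The ring mask contains pixels whose distance from the center lies in
    ``[inner_radius, outer_radius]``, minus the 5x5 nuclear patch.  ROIs
    losing more than ``max_clipped_fraction`` of their nominal area to
    the frame boundary are rejected.
    """
    if not (0 < inner_radius < outer_radius):
        raise ParameterError("need 0 < inner_radius < outer_radius")
    h, w = frame_shape
    cy, cx = float(center[0]), float(center[1])
    if not (0 <= cy < h and 0 <= cx < w):
        raise ParameterError(f"center {center} outside frame {frame_shape}")

    # Unclipped annulus pixel count, evaluated on an unbounded lattice.
    r = int(np.ceil(outer_radius)) + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    dist0 = np.hypot(yy, xx)
    full_count = int(np.count_nonzero((dist0 >= inner_radius) & (dist0 <= outer_radius)))

    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - cy, xx - cx)
    ring = (dist >= inner_radius) & (dist <= outer_radius)

    icy, icx = int(round(cy)), int(round(cx))
    half = NUCLEAR_PATCH // 2
    nuclear = np.zeros((h, w), dtype=bool)
    nuclear[max(icy - half, 0) : icy + half + 1, max(icx - half, 0) : icx + half + 1] = True
    ring &= ~nuclear

    kept = int(ring.sum()) + int(
        np.count_nonzero(((dist >= inner_radius) & (dist <= outer_radius)) & nuclear)
    )
    if full_count > 0 and kept < (1.0 - max_clipped_fraction) * full_count:
        raise ParameterError(
            f"ROI at {center} clipped by frame boundary "
            f"({kept}/{full_count} annulus pixels inside)"
        )
    if not ring.any():
        raise ParameterError("ring mask is empty")
    return RingROI(
        center=(icy, icx),
        inner_radius=float(inner_radius),
        outer_radius=float(outer_radius),
        ring_mask=ring,
        nuclear_mask=nuclear,
    )


def extract_trace(
    movie: Movie,
    roi: RingROI,
    cell_id: str = "",
    session_id: str = "",
) -> FluorescenceTrace:
    """Per-frame unweighted mean over the ring-mask pixels."""
    if roi.ring_mask.shape != movie.frame_shape:
        raise ParameterError("ROI mask shape does not match movie frames")
    if not roi.ring_mask.any():
        raise ParameterError("ROI ring mask is empty")
    values = movie.frames[:, roi.ring_mask].mean(axis=1)
    return FluorescenceTrace(
        values=values,
        frame_rate=movie.frame_rate,
        cell_id=cell_id,
        session_id=session_id,
    )


def contrast(image_or_movie: Union[np.ndarray, Movie], roi: RingROI) -> float:
    """Cytosol/nucleus contrast on the temporal-mean image.

    ``(mean_ring - mean_nucleus) / mean_nucleus``; invariant under
    multiplicative gain, not under additive offsets.
    """
    if isinstance(image_or_movie, Movie):
        image = image_or_movie.mean_image()
    else:
        image = np.asarray(image_or_movie, dtype=float)
        if image.ndim == 3:
            image = image.mean(axis=0)
    if image.shape != roi.ring_mask.shape:
        raise ParameterError("image shape does not match ROI masks")
    ring_mean = float(image[roi.ring_mask].mean())
    nuc_mean = float(image[roi.nuclear_mask].mean())
    if nuc_mean <= 0:
        raise UndefinedContrastError("nuclear mean is non-positive")
    return (ring_mean - nuc_mean) / nuc_mean


def qc_filter(
    records: pd.DataFrame,
    threshold: float = 0.2,
    contrast_column: str = "contrast",
) -> Tuple[pd.DataFrame, pd.DataFrame, List[str]]:
    """Partition cells by the contrast QC threshold.

    Parameters
    ----------
    records:
        One row per cell with at least a ``contrast`` column; a
        ``session_id`` column, when present, is used to flag sessions in
        which every cell failed QC.
    threshold:
        Cells with ``contrast < threshold`` are excluded.

    Returns
    -------
    (included, excluded, flagged_sessions)
    """
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    keep = records[contrast_column] >= threshold
    included = records[keep].copy()
    excluded = records[~keep].copy()
    for _, row in excluded.iterrows():
        logger.info(
            "QC excluded cell %s (session %s): contrast %.3f < %.3f",
            row.get("cell_id", "?"),
            row.get("session_id", "?"),
            row[contrast_column],
            threshold,
        )
    flagged: List[str] = []
    if "session_id" in records.columns and len(records):
        for session, grp in records.groupby("session_id"):
            if not (grp[contrast_column] >= threshold).any():
                flagged.append(str(session))
                logger.warning("session %s: no usable cells after contrast QC", session)
    return included, excluded, flagged
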