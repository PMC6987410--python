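"""Session-level activity metrics computed from spike trains.

* average rate: total APs divided by the recording duration (200 s by
  default in this workflow);
* maximal instantaneous rate: peak AP count over non-overlapping 1-s
  bins aligned to the recording start;
* burst: at least five APs within a 660-ms window; overlapping
  qualifying windows merge into one burst event;
* session summaries aggregate over *all* segmented cells, including
  silent ones, so the median rate can legitimately reach zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .model import SpikeTrain

__all__ = [
    "CellMetrics",
    "SessionSummary",
    "average_rate",
    "max_instantaneous_rate",
    "detect_bursts",
    "cell_metrics",
    "summarize_session",
    "event_f1",
]

BURST_MIN_SPIKES = 5
BURST_WINDOW_S = 0.66


@dataclass(frozen=True)
class CellMetrics:
    cell_id: str
    is_active: bool
    average_rate: float  # Hz
    max_instantaneous_rate: float  # Hz
    burst_count: int
    fired_burst: bool


@dataclass(frozen=True)
class SessionSummary:
    mouse_id: str
    day: int
    region: str
    n_cells: int
    fraction_active: float
    fraction_bursting: float
    median_rate: float  # Hz
    rate_q25: float
    rate_q75: float


def average_rate(train: SpikeTrain) -> float:
    """Total AP count divided by recording duration (Hz)."""
    if train.duration <= 0:
        raise ParameterError("duration must be positive")
    return train.total / train.duration


def max_instantaneous_rate(train: SpikeTrain, bin_s: float = 1.0) -> float:
    """Peak rate over non-overlapping bins aligned to the start (Hz)."""
    if bin_s <= 0:
        raise ParameterError("bin width must be positive")
    if train.total == 0:
        return 0.0
    times = train.spike_times()
    bins = np.floor(times / bin_s).astype(np.int64)
    counts = np.bincount(bins)
    return float(counts.max()) / bin_s


def detect_bursts(
    train: SpikeTrain,
    k: int = BURST_MIN_SPIKES,
    window: float = BURST_WINDOW_S,
) -> Tuple[int, bool]:
    """Count burst events: >= ``k`` APs within a ``window``-s span.

    A window anchored at each spike time is tested for containing at
    least ``k`` spikes (with multiplicity, endpoints inclusive).
    Overlapping qualifying windows collapse into single burst events:
    the count is the largest set of pairwise-disjoint qualifying
    windows (greedy interval scheduling), which guarantees the count
    never decreases when spikes are added.

    Returns
    -------
    (burst_count, fired_burst)
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if window <= 0:
        raise ParameterError("window must be positive")
    times = train.spike_times()
    n = times.size
    if n < k:
        return 0, False
    # A window [t_i, t_i + window] qualifies iff the k-th spike after i
    # is still inside it.
    qualifies = times[k - 1 :] - times[: n - k + 1] <= window
    anchors = times[: n - k + 1][qualifies]
    if anchors.size == 0:
        return 0, False
    # Greedy disjoint-window selection (earliest end first).
    count = 1
    current_end = anchors[0] + window
    for t in anchors[1:]:
        if t > current_end:
            count += 1
            current_end = t + window
    return count, True


def cell_metrics(train: SpikeTrain, cell_id: str = "") -> CellMetrics:
    burst_count, fired = detect_bursts(train)
    return CellMetrics(
        cell_id=cell_id,
        is_active=train.total >= 1,
        average_rate=average_rate(train),
        max_instantaneous_rate=max_instantaneous_rate(train),
        burst_count=burst_count,
        fired_burst=fired,
    )


def summarize_session(
    cells: Sequence[CellMetrics],
    mouse_id: str = "",
    day: int = 0,
    region: str = "",
) -> SessionSummary:
    """Aggregate per-cell metrics over one mouse x day x region."""
    if len(cells) == 0:
        raise ParameterError("session has no cells")
    rates = np.array([c.average_rate for c in cells], dtype=float)
    active = np.array([c.is_active for c in cells], dtype=bool)
    bursting = np.array([c.fired_burst for c in cells], dtype=bool)
    q25, med, q75 = np.percentile(rates, [25.0, 50.0, 75.0])
    return SessionSummary(
        mouse_id=mouse_id,
        day=day,
        region=region,
        n_cells=len(cells),
        fraction_active=float(active.mean()),
        fraction_bursting=float(bursting.mean()),
        median_rate=float(med),
        rate_q25=float(q25),
        rate_q75=float(q75),
    )


def event_f1(
    truth: SpikeTrain,
    inferred: SpikeTrain,
    window: float = 0.5,
) -> float:
    """Event-level F1 score between two spike trains.

    Spikes are matched greedily in time order; an inferred spike matches
    an unmatched true spike within ``+/- window`` seconds.  Returns 1.0
    when both trains are empty.
    """
    t_true = truth.spike_times()
    t_inf = inferred.spike_times()
    if t_true.size == 0 and t_inf.size == 0:
        return 1.0
    if t_true.size == 0 or t_inf.size == 0:
        return 0.0
    i = j = matched = 0
    while i < t_true.size and j < t_inf.size:
        dt = t_inf[j] - t_true[i]
        if abs(dt) <= window:
            matched += 1
            i += 1
            j += 1
        elif dt < -window:
            j += 1
        else:
            i += 1
    precision = matched / t_inf.size
    recall = matched / t_true.size
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def metrics_frame(trains: Iterable[Tuple[str, SpikeTrain]]) -> pd.DataFrame:
    """Tabulate :func:`cell_metrics` for many cells."""
    rows = []
    for cell_id, train in trains:
        m = cell_metrics(train, cell_id=cell_id)
        rows.append(
            {
                "cell_id": m.cell_id,
                "is_active": m.is_active,
                "average_rate": m.average_rate,
                "max_instantaneous_rate": m.max_instantaneous_rate,
                "burst_count": m.burst_count,
                "fired_burst": m.fired_burst,
            }
        )
    return pd.DataFrame(rows)
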