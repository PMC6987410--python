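"""Synthetic ground-truth generator for chronic hippocampal imaging.

Everything downstream of the microscope is testable against this
module: it generates spike trains with the bursty-CA1 / sparse-DG
phenotypes, renders ring-shaped somata (bright cytosol, dark nucleus)
into fluorescence movies through the indicator forward model, and
assembles multi-session cohorts that follow a programmable
demyelination/remyelination firing-rate timeline.

Spike-generating process
------------------------
A superposition of two independent processes per cell:

* a Poisson process of *burst events* (rate ``burst_event_rate``); each
  event emits a geometric number of spikes (mean
  ``spikes_per_burst_mean``) at ``intra_burst_interval`` spacing; a
  burst running past the end of the recording is truncated;
* a Poisson process of isolated spikes (rate ``isolated_spike_rate``).

The CA1 preset is calibrated so the median per-cell average rate over
200 s falls near 0.21 Hz; the DG preset mixes in a silent fraction
(default 0.65) so roughly a third of cells fire at all.

Timeline presets
----------------
The cuprizone timeline scales both rates per session: a sharp drop
after diet onset (day 9), a decline to 16.5% of baseline on day 53,
a fast rebound after diet cessation (day 58) and partial recovery by
day 100.  Optional mid-diet/mid-recovery "rebound bumps" are off by
default.  The control timeline is identically 1.0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ParameterError
from .model import IndicatorParams, JRGECO1A, SpikeTrain, forward_model
from .preprocessing import Movie, shift_frame, write_movie
from .roi import RingROI, build_ring_roi

__all__ = [
    "CellClassParams",
    "TimelineSpec",
    "SceneSpec",
    "CA1_PRESET",
    "DG_PRESET",
    "cuprizone_timeline",
    "control_timeline",
    "simulate_spike_train",
    "modulate_cohort",
    "render_movie",
    "simulate_cohort",
]

#: Trace-mode baseline fluorescence (arbitrary intensity units).
TRACE_F0 = 1000.0


@dataclass(frozen=True)
class CellClassParams:
    """Firing and contrast statistics for one cell class."""

    class_label: str  # "CA1" | "DG"
    burst_event_rate: float  # burst events / s
    isolated_spike_rate: float  # spikes / s
    spikes_per_burst_mean: float  # geometric mean count
    intra_burst_interval: float  # s
    contrast_range: Tuple[float, float]
    silent_fraction: float = 0.0  # structurally present but silent cells
    rate_spread: float = 0.0  # lognormal sigma of per-cell rate scale

    def __post_init__(self) -> None:
        if self.burst_event_rate < 0 or self.isolated_spike_rate < 0:
            raise ParameterError("rates must be >= 0")
        if self.spikes_per_burst_mean < 1:
            raise ParameterError("spikes_per_burst_mean must be >= 1")
        if self.intra_burst_interval <= 0:
            raise ParameterError("intra_burst_interval must be > 0")
        lo, hi = self.contrast_range
        if not (0 < lo < hi):
            raise ParameterError("contrast_range must satisfy 0 < low < high")
        if not (0 <= self.silent_fraction < 1):
            raise ParameterError("silent_fraction must be in [0, 1)")
        if self.rate_spread < 0:
            raise ParameterError("rate_spread must be >= 0")

    def scaled(self, factor: float) -> "CellClassParams":
        """Scale both rate parameters; class identity/contrast unchanged."""
        if factor < 0:
            raise ParameterError("rate multiplier must be >= 0")
        return replace(
            self,
            burst_event_rate=self.burst_event_rate * factor,
            isolated_spike_rate=self.isolated_spike_rate * factor,
        )


#: CA1 pyramidal cells.  Calibrated by Monte Carlo so the median per-cell
#: average rate over a 200 s recording sits near 0.21 Hz, with a
#: lognormal spread of per-cell rates (firing rates in hippocampal
#: populations are approximately lognormal) so that population medians
#: scale with programmed rate multipliers.
CA1_PRESET = CellClassParams(
    class_label="CA1",
    burst_event_rate=0.006,
    isolated_spike_rate=0.180,
    spikes_per_burst_mean=5.0,
    intra_burst_interval=0.010,
    contrast_range=(2.0, 4.0),
    rate_spread=0.8,
)

#: DG granule cells: mostly silent, sparse firing when active.
DG_PRESET = CellClassParams(
    class_label="DG",
    burst_event_rate=0.004,
    isolated_spike_rate=0.020,
    spikes_per_burst_mean=5.0,
    intra_burst_interval=0.010,
    contrast_range=(0.6, 1.2),
    silent_fraction=0.65,
    rate_spread=0.8,
)


@dataclass(frozen=True)
class TimelineSpec:
    """Session days and per-day firing-rate multipliers for one group."""

    session_days: Tuple[int, ...]
    rate_multiplier_per_day: Mapping[int, float]
    group_label: str

    def __post_init__(self) -> None:
        days = tuple(self.session_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ParameterError("session_days must be strictly increasing")
        for d in days:
            if d not in self.rate_multiplier_per_day:
                raise ParameterError(f"no rate multiplier for day {d}")
            if self.rate_multiplier_per_day[d] < 0:
                raise ParameterError("rate multipliers must be >= 0")
        object.__setattr__(self, "session_days", days)


def cuprizone_timeline(rebound_bumps: bool = False) -> TimelineSpec:
    """Demyelination/remyelination timeline preset.

    Eight recording dates cover the diet period (days 0-53), with the
    day-53 multiplier at 0.165 of baseline; day 58 captures the rapid
    post-diet rebound and day 100 the partial recovery.  With
    ``rebound_bumps`` the transient mid-diet (days 23-30) and
    mid-recovery bumps are added.
    """
    mult = {
        0: 1.0,
        9: 0.43,
        16: 0.38,
        23: 0.33,
        30: 0.29,
        37: 0.25,
        44: 0.21,
        53: 0.165,
        58: 0.70,
        100: 0.435,
    }
    if rebound_bumps:
        mult[23] = 0.45
        mult[30] = 0.40
    return TimelineSpec(
        session_days=tuple(sorted(mult)),
        rate_multiplier_per_day=mult,
        group_label="cuprizone",
    )


def control_timeline(session_days: Optional[Sequence[int]] = None) -> TimelineSpec:
    """Control group: all multipliers 1.0 on the same schedule."""
    if session_days is None:
        session_days = cuprizone_timeline().session_days
    return TimelineSpec(
        session_days=tuple(session_days),
        rate_multiplier_per_day={d: 1.0 for d in session_days},
        group_label="control",
    )


def simulate_spike_train(
    params: CellClassParams,
    duration: float,
    frame_rate: float,
    seed: Union[int, np.random.Generator],
) -> SpikeTrain:
    """Simulate one cell's spike train.

    Burst events arrive as a Poisson process; each emits a geometric
    number of spikes at fixed intra-burst spacing (truncated at the end
    of the recording).  Isolated spikes arrive as an independent Poisson
    process.  Deterministic given the seed.
    """
    if duration <= 0 or frame_rate <= 0:
        raise ParameterError("duration and frame_rate must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = int(round(duration * frame_rate))
    counts = np.zeros(n_frames, dtype=np.int64)

    # Isolated spikes: Poisson count per frame.
    if params.isolated_spike_rate > 0:
        counts += rng.poisson(params.isolated_spike_rate / frame_rate, n_frames)

    # Burst events.
    if params.burst_event_rate > 0:
        n_events = rng.poisson(params.burst_event_rate * duration)
        if n_events:
            starts = rng.uniform(0.0, duration, size=n_events)
            p = 1.0 / params.spikes_per_burst_mean
            sizes = rng.geometric(p, size=n_events)
            for t0, size in zip(starts, sizes):
                times = t0 + np.arange(size) * params.intra_burst_interval
                times = times[times < duration]  # truncate trailing burst
                frames = np.floor(times * frame_rate).astype(np.int64)
                np.add.at(counts, frames, 1)
    return SpikeTrain(counts=counts, frame_rate=frame_rate)


def draw_cell_params(
    params: CellClassParams, rng: np.random.Generator
) -> CellClassParams:
    """Per-cell parameters: silent mixture plus lognormal rate scale.

    A fraction ``silent_fraction`` of cells get zero rates; the rest get
    both rates scaled by ``exp(N(0, rate_spread))`` (median scale 1).
    """
    if params.silent_fraction > 0 and rng.random() < params.silent_fraction:
        return params.scaled(0.0)
    if params.rate_spread > 0:
        return params.scaled(float(np.exp(rng.normal(0.0, params.rate_spread))))
    return params


def modulate_cohort(
    base: CellClassParams, timeline: TimelineSpec
) -> Dict[int, CellClassParams]:
    """Per-session cell-class parameters: rates scaled by the timeline."""
    return {
        day: base.scaled(timeline.rate_multiplier_per_day[day])
        for day in timeline.session_days
    }


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and noise of a rendered field of view."""

    frame_shape: Tuple[int, int] = (128, 128)
    frame_rate: float = 30.0
    duration: float = 20.0
    cell_centers: Tuple[Tuple[int, int], ...] = ()
    soma_inner_radius: float = 3.0
    soma_outer_radius: float = 6.0
    background_level: float = 100.0
    cell_gain: float = 1000.0
    noise_sigma: float = 0.0  # Gaussian SD, intensity units
    poisson_noise: bool = False  # shot-noise mode instead of Gaussian
    motion_shifts: Optional[np.ndarray] = None  # (n_frames, 2) int

    def __post_init__(self) -> None:
        if self.soma_inner_radius >= self.soma_outer_radius:
            raise ParameterError("soma_inner_radius must be < soma_outer_radius")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ParameterError("duration and frame_rate must be > 0")
        h, w = self.frame_shape
        r = self.soma_outer_radius
        for cy, cx in self.cell_centers:
            if not (r <= cy < h - r and r <= cx < w - r):
                raise ParameterError(
                    f"cell center {(cy, cx)} within {r} px of the frame edge"
                )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


def render_movie(
    scene: SceneSpec,
    trains: Sequence[SpikeTrain],
    indicator: IndicatorParams = JRGECO1A,
    contrasts: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> Tuple[Movie, List[RingROI], dict]:
    """Render spike trains into a fluorescence movie.

    Each cell is an annulus whose temporal signal is
    ``cell_gain * (1 + dF/F)`` from the forward model; the nuclear disc
    sits at the cytosolic resting level divided by ``1 + contrast``;
    everything else is at ``background_level``.  Per-frame rigid shifts
    are applied before noise.  The returned ROIs are the noise-free,
    motion-free ground truth.
    """
    if contrasts is None:
        contrasts = [3.0] * len(trains)
    if len(trains) != len(scene.cell_centers) or len(contrasts) != len(trains):
        raise ParameterError("need one train and one contrast per cell center")
    rng = np.random.default_rng(seed)
    n_frames = scene.n_frames
    h, w = scene.frame_shape

    rois: List[RingROI] = []
    signals: List[np.ndarray] = []
    occupied = np.zeros((h, w), dtype=bool)
    overlaps = 0
    for train, center in zip(trains, scene.cell_centers):
        if train.n_frames != n_frames:
            raise ParameterError("train length does not match scene frame count")
        roi = build_ring_roi(
            center, scene.soma_inner_radius, scene.soma_outer_radius, (h, w)
        )
        footprint = roi.ring_mask | roi.nuclear_mask
        if (occupied & footprint).any():
            overlaps += 1
        occupied |= footprint
        rois.append(roi)
        signals.append(forward_model(train, indicator))
    if overlaps:
        warnings.warn(f"{overlaps} overlapping somata in scene", UserWarning)

    frames = np.full((n_frames, h, w), scene.background_level, dtype=np.float64)
    for roi, signal, c in zip(rois, signals, contrasts):
        frames[:, roi.ring_mask] = scene.cell_gain * signal[:, None]
        frames[:, roi.nuclear_mask] = scene.cell_gain / (1.0 + c)

    if scene.motion_shifts is not None:
        shifts = np.asarray(scene.motion_shifts, dtype=np.int64)
        if shifts.shape != (n_frames, 2):
            raise ParameterError("motion_shifts must have shape (n_frames, 2)")
        for k in range(n_frames):
            dy, dx = int(shifts[k, 0]), int(shifts[k, 1])
            if dy or dx:
                frames[k] = shift_frame(frames[k], dy, dx)

    if scene.poisson_noise:
        frames = rng.poisson(np.maximum(frames, 0.0)).astype(np.float64)
    elif scene.noise_sigma > 0:
        frames += rng.normal(0.0, scene.noise_sigma, size=frames.shape)

    movie = Movie(frames=frames, frame_rate=scene.frame_rate)
    meta = {"overlapping_somata": overlaps, "seed": seed}
    return movie, rois, meta


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

PRESETS: Dict[str, CellClassParams] = {"CA1": CA1_PRESET, "DG": DG_PRESET}
TIMELINES = {"cuprizone": cuprizone_timeline, "control": control_timeline}


@dataclass
class CohortConfig:
    """Configuration of a simulated multi-session cohort.

    ``groups`` maps a group name to its timeline preset name; every
    mouse in a group follows that timeline.  ``mode`` selects whether
    fluorescence traces (fast) or rendered movies are written.
    """

    groups: Dict[str, str] = field(
        default_factory=lambda: {"cuprizone": "cuprizone", "control": "control"}
    )
    mice_per_group: int = 3
    region: str = "CA1"
    cells_per_fov: int = 100
    n_fov: int = 1
    duration: float = 200.0
    frame_rate: float = 15.0
    noise_sigma_dff: float = 0.02
    mode: str = "traces"  # "traces" | "movies"
    session_days: Optional[Tuple[int, ...]] = None  # subset of the preset days
    rebound_bumps: bool = False

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown cohort config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in d.items()})
        if cfg.session_days is not None:
            cfg.session_days = tuple(int(x) for x in cfg.session_days)
        return cfg

    def timeline_for(self, group: str) -> TimelineSpec:
        name = self.groups[group]
        if name == "cuprizone":
            tl = cuprizone_timeline(self.rebound_bumps)
        elif name == "control":
            tl = control_timeline()
        else:
            raise ParameterError(f"unknown timeline preset {name!r}")
        if self.session_days is not None:
            days = tuple(d for d in self.session_days)
            missing = set(days) - set(tl.session_days)
            if missing:
                raise ParameterError(f"days {sorted(missing)} not in preset timeline")
            tl = TimelineSpec(
                session_days=days,
                rate_multiplier_per_day={
                    d: tl.rate_multiplier_per_day[d] for d in days
                },
                group_label=tl.group_label,
            )
        return tl


def _session_seed(master: int, group_i: int, mouse_i: int, day: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(group_i, mouse_i, day))
    return np.random.default_rng(ss)


def simulate_session_traces(
    params: CellClassParams,
    n_cells: int,
    duration: float,
    frame_rate: float,
    noise_sigma_dff: float,
    rng: np.random.Generator,
    indicator: IndicatorParams = JRGECO1A,
) -> Tuple[np.ndarray, List[SpikeTrain], np.ndarray, np.ndarray]:
    """Simulate raw fluorescence traces for one session.

    Returns ``(traces (cells x frames), trains, contrasts, silent)``.
    Each trace is ``F0 * b(t) * (1 + dF/F) + noise`` with a random
    linear drift bounded by the indicator drift bound.
    """
    n_frames = int(round(duration * frame_rate))
    traces = np.empty((n_cells, n_frames))
    trains: List[SpikeTrain] = []
    contrasts = rng.uniform(*params.contrast_range, size=n_cells)
    silent = np.zeros(n_cells, dtype=bool)
    for i in range(n_cells):
        cell_params = draw_cell_params(params, rng)
        silent[i] = cell_params.isolated_spike_rate == 0 and cell_params.burst_event_rate == 0
        train = simulate_spike_train(cell_params, duration, frame_rate, rng)
        trains.append(train)
        slope = rng.uniform(-1.0, 1.0) * indicator.drift_bound
        drift = 1.0 + slope * np.linspace(0.0, 1.0, n_frames)
        f = TRACE_F0 * forward_model(train, indicator, drift_path=drift)
        if noise_sigma_dff > 0:
            f = f + rng.normal(0.0, noise_sigma_dff * TRACE_F0, size=n_frames)
        traces[i] = f
    return traces, trains, contrasts, silent


def simulate_cohort(
    config: Union[CohortConfig, Mapping],
    seed: int,
    outdir: Union[str, Path],
) -> pd.DataFrame:
    """Write a cohort dataset to disk and return its session index.

    Layout: ``<outdir>/<group>/mouse_<k>/day_<d>/`` containing
    ``traces.csv`` (frames x cells, header = cell ids) or ``fov_0.tif``,
    ``ground_truth_spikes.csv`` (cell_id, frame, count; nonzero rows),
    and ``cells.csv`` (cell_id, contrast, silent).  A top-level
    ``cohort.json`` records the config, seed, and programmed
    multipliers.
    """
    if not isinstance(config, CohortConfig):
        config = CohortConfig.from_dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = PRESETS[config.region]
    index_rows = []
    for gi, group in enumerate(sorted(config.groups)):
        timeline = config.timeline_for(group)
        for mi in range(config.mice_per_group):
            mouse_id = f"{group}_m{mi}"
            per_day = modulate_cohort(base, timeline)
            for day in timeline.session_days:
                rng = _session_seed(seed, gi, mi, day)
                params = per_day[day]
                sess_dir = outdir / group / f"mouse_{mi}" / f"day_{day:03d}"
                sess_dir.mkdir(parents=True, exist_ok=True)
                n_cells = config.cells_per_fov * config.n_fov
                if config.mode == "traces":
                    traces, trains, contrasts, silent = simulate_session_traces(
                        params,
                        n_cells,
                        config.duration,
                        config.frame_rate,
                        config.noise_sigma_dff,
                        rng,
                    )
                    cols = [f"cell_{i:04d}" for i in range(n_cells)]
                    pd.DataFrame(traces.T, columns=cols).to_csv(
                        sess_dir / "traces.csv", index=False, float_format="%.6f"
                    )
                elif config.mode == "movies":
                    trains, contrasts, silent, cols = _render_session_movies(
                        params, config, rng, sess_dir
                    )
                else:
                    raise ParameterError(f"unknown mode {config.mode!r}")
                _write_ground_truth(sess_dir, cols, trains, contrasts, silent)
                index_rows.append(
                    {
                        "group": group,
                        "mouse_id": mouse_id,
                        "day": day,
                        "region": config.region,
                        "multiplier": timeline.rate_multiplier_per_day[day],
                        "n_cells": n_cells,
                        "path": str(sess_dir),
                    }
                )
    index = pd.DataFrame(index_rows)
    index.to_csv(outdir / "sessions.csv", index=False)
    manifest = {
        "seed": int(seed),
        "region": config.region,
        "mode": config.mode,
        "duration": config.duration,
        "frame_rate": config.frame_rate,
        "noise_sigma_dff": config.noise_sigma_dff,
        "groups": dict(config.groups),
        "mice_per_group": config.mice_per_group,
        "cells_per_fov": config.cells_per_fov,
    }
    (outdir / "cohort.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return index


def _render_session_movies(params, config, rng, sess_dir):
    """Movies mode: render one small FOV per session."""
    h = w = 128
    margin = 10
    n_cells = min(config.cells_per_fov, 16)  # desk-scale FOV
    grid = int(np.ceil(np.sqrt(n_cells)))
    ys = np.linspace(margin, h - margin, grid).astype(int)
    xs = np.linspace(margin, w - margin, grid).astype(int)
    centers = [(int(y), int(x)) for y in ys for x in xs][:n_cells]
    contrasts = rng.uniform(*params.contrast_range, size=n_cells)
    per_cell = [draw_cell_params(params, rng) for _ in range(n_cells)]
    silent = np.array(
        [p.isolated_spike_rate == 0 and p.burst_event_rate == 0 for p in per_cell]
    )
    trains = [
        simulate_spike_train(p, config.duration, config.frame_rate, rng)
        for p in per_cell
    ]
    scene = SceneSpec(
        frame_shape=(h, w),
        frame_rate=config.frame_rate,
        duration=config.duration,
        cell_centers=tuple(centers),
        noise_sigma=config.noise_sigma_dff * 1000.0,
    )
    movie, rois, _ = render_movie(
        scene, trains, contrasts=contrasts, seed=int(rng.integers(2**31))
    )
    write_movie(movie, sess_dir / "fov_0.tif")
    cols = [f"cell_{i:04d}" for i in range(n_cells)]
    roi_rows = pd.DataFrame(
        {
            "cell_id": cols,
            "cy": [r.center[0] for r in rois],
            "cx": [r.center[1] for r in rois],
            "r_in": [r.inner_radius for r in rois],
            "r_out": [r.outer_radius for r in rois],
        }
    )
    roi_rows.to_csv(sess_dir / "rois.csv", index=False)
    return trains, contrasts, silent, cols


def _write_ground_truth(sess_dir, cols, trains, contrasts, silent):
    rows = []
    for cid, train in zip(cols, trains):
        nz = np.nonzero(train.counts)[0]
        for frame in nz:
            rows.append({"cell_id": cid, "frame": int(frame), "count": int(train.counts[frame])})
    pd.DataFrame(rows, columns=["cell_id", "frame", "count"]).to_csv(
        sess_dir / "ground_truth_spikes.csv", index=False
    )
    pd.DataFrame(
        {"cell_id": cols, "contrast": contrasts, "silent": silent.astype(bool)}
    ).to_csv(sess_dir / "cells.csv", index=False)
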