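"""End-to-end orchestration: simulate -> (preprocess/extract) -> infer ->
metrics -> statistics, with a manifest and a recovery report.

Two entry scales exist.  "Traces" mode skips movie rendering and goes
straight from simulated fluorescence traces to inference; "movies" mode
renders small fields of view and exercises the preprocessing and ROI
stages as well.  All randomness derives from a single master seed, split
deterministically per group/mouse/session.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .inference import compute_dff, infer_spikes
from .metrics import cell_metrics, event_f1, summarize_session
from .model import IndicatorParams, SpikeTrain
from .preprocessing import pair_average, read_movie, register_translation
from .roi import build_ring_roi, contrast, extract_trace, qc_filter
from .stats import (
    mann_kendall,
    paired_t,
    repeated_group_time_model,
    wilcoxon_rank_sum,
)
from .synth import CohortConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "recovery_report", "load_config"]

logger = logging.getLogger(__name__)

#: Per-region noise multipliers used at inference time.
REGION_NOISE_MULTIPLIER = {"CA1": 1.5, "DG": 1.0}


@dataclass
class RunConfig:
    """Pipeline run configuration.

    ``cohort`` holds the synthetic cohort parameters (see
    :class:`hippocal.synth.CohortConfig`); ``diet_end_day`` marks the
    last session of the diet period for the trend tests;
    ``compare_days`` lists day pairs for the two-date tests.
    """

    outdir: str = "run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    qc_threshold: float = 0.2
    diet_end_day: int = 53
    compare_days: List[List[int]] = field(default_factory=lambda: [[0, 9], [53, 58]])

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        known = set(cls.__dataclass_fields__) - {"cohort"}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(cohort=CohortConfig.from_dict(cohort), **d)


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_session_trains(sess_dir: Path, frame_rate: float, n_frames: int) -> Dict[str, SpikeTrain]:
    """Ground-truth spike trains of one session keyed by cell id."""
    gt = pd.read_csv(sess_dir / "ground_truth_spikes.csv")
    cells = pd.read_csv(sess_dir / "cells.csv")
    trains: Dict[str, SpikeTrain] = {}
    for cid in cells["cell_id"]:
        counts = np.zeros(n_frames, dtype=np.int64)
        sub = gt[gt["cell_id"] == cid]
        counts[sub["frame"].to_numpy()] = sub["count"].to_numpy()
        trains[cid] = SpikeTrain(counts=counts, frame_rate=frame_rate)
    return trains


def _infer_session_traces(sess_dir: Path, cfg: RunConfig) -> Dict[str, SpikeTrain]:
    """Run dF/F + spike inference on every cell of a traces-mode session."""
    traces = pd.read_csv(sess_dir / "traces.csv")
    fr = cfg.cohort.frame_rate
    mult = REGION_NOISE_MULTIPLIER.get(cfg.cohort.region, 1.0)
    params = IndicatorParams(noise_multiplier=mult)
    out: Dict[str, SpikeTrain] = {}
    for cid in traces.columns:
        dff = compute_dff(traces[cid].to_numpy(), frame_rate=fr)
        res = infer_spikes(dff, params=params)
        out[cid] = res.spikes
    return out


def _infer_session_movie(sess_dir: Path, cfg: RunConfig) -> Dict[str, SpikeTrain]:
    """Movies mode: preprocess, extract ring ROIs, QC, infer."""
    movie = read_movie(sess_dir / "fov_0.tif", frame_rate=cfg.cohort.frame_rate)
    if movie.frame_rate >= 30.0:
        movie = pair_average(movie)
    movie, _ = register_translation(movie, max_shift=5)
    rois_tbl = pd.read_csv(sess_dir / "rois.csv")
    mult = REGION_NOISE_MULTIPLIER.get(cfg.cohort.region, 1.0)
    params = IndicatorParams(noise_multiplier=mult)
    records = []
    traces = {}
    for _, row in rois_tbl.iterrows():
        roi = build_ring_roi(
            (row["cy"], row["cx"]), row["r_in"], row["r_out"], movie.frame_shape
        )
        records.append(
            {"cell_id": row["cell_id"], "session_id": str(sess_dir), "contrast": contrast(movie, roi)}
        )
        traces[row["cell_id"]] = extract_trace(movie, roi, cell_id=row["cell_id"])
    included, _, flagged = qc_filter(pd.DataFrame(records), threshold=cfg.qc_threshold)
    for session in flagged:
        logger.warning("session %s flagged: no usable cells", session)
    out: Dict[str, SpikeTrain] = {}
    for cid in included["cell_id"]:
        dff = compute_dff(traces[cid])
        out[cid] = infer_spikes(dff, params=params).spikes
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run simulate -> infer -> metrics -> statistics end to end.

    Writes under ``cfg.outdir``: the simulated cohort, per-cell metrics
    (``cell_metrics.csv``), session summaries (``session_summary.csv``),
    the statistics table (``stats.csv``), inferred spikes per session,
    and ``manifest.json`` with the config hash and output checksums.
    Returns the manifest.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_dir = outdir / "sim"
    index = simulate_cohort(cfg.cohort, cfg.seed, sim_dir)

    metric_rows = []
    summary_rows = []
    for _, sess in index.iterrows():
        sess_dir = Path(sess["path"])
        if cfg.cohort.mode == "traces":
            inferred = _infer_session_traces(sess_dir, cfg)
        else:
            inferred = _infer_session_movie(sess_dir, cfg)
        spikes_rows = []
        cells = []
        for cid, train in inferred.items():
            m = cell_metrics(train, cell_id=cid)
            cells.append(m)
            metric_rows.append(
                {
                    "group": sess["group"],
                    "mouse_id": sess["mouse_id"],
                    "day": sess["day"],
                    "region": sess["region"],
                    "cell_id": cid,
                    "is_active": m.is_active,
                    "average_rate": m.average_rate,
                    "max_instantaneous_rate": m.max_instantaneous_rate,
                    "burst_count": m.burst_count,
                    "fired_burst": m.fired_burst,
                }
            )
            nz = np.nonzero(train.counts)[0]
            for frame in nz:
                spikes_rows.append(
                    {"cell_id": cid, "frame": int(frame), "count": int(train.counts[frame])}
                )
        pd.DataFrame(spikes_rows, columns=["cell_id", "frame", "count"]).to_csv(
            sess_dir / "inferred_spikes.csv", index=False
        )
        summary = summarize_session(
            cells, mouse_id=sess["mouse_id"], day=int(sess["day"]), region=sess["region"]
        )
        summary_rows.append(
            {
                "group": sess["group"],
                "mouse_id": summary.mouse_id,
                "day": summary.day,
                "region": summary.region,
                "n_cells": summary.n_cells,
                "fraction_active": summary.fraction_active,
                "fraction_bursting": summary.fraction_bursting,
                "median_rate": summary.median_rate,
                "rate_q25": summary.rate_q25,
                "rate_q75": summary.rate_q75,
            }
        )

    cell_table = pd.DataFrame(metric_rows)
    summary_table = pd.DataFrame(summary_rows)
    cell_table.to_csv(outdir / "cell_metrics.csv", index=False)
    summary_table.to_csv(outdir / "session_summary.csv", index=False)

    stats_table = statistics_battery(cell_table, summary_table, cfg)
    stats_table.to_csv(outdir / "stats.csv", index=False)

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "seed": cfg.seed,
                    "qc_threshold": cfg.qc_threshold,
                    "cohort": cfg.cohort.__dict__,
                },
                sort_keys=True,
                default=str,
            ).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "outputs": {
            name: _sha256(outdir / name)
            for name in ("cell_metrics.csv", "session_summary.csv", "stats.csv")
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def statistics_battery(
    cell_table: pd.DataFrame, summary_table: pd.DataFrame, cfg: RunConfig
) -> pd.DataFrame:
    """The longitudinal statistics table.

    Per mouse: Wilcoxon rank-sum between configured day pairs on
    per-cell rates, and a Mann-Kendall trend over the diet-period median
    rates.  Per group: paired t between day pairs on per-mouse medians.
    Across groups: repeated-measures group x time model on median rates
    (only when both groups share all days and have >= 2 mice).
    """
    rows = []
    days_present = set(summary_table["day"].unique())
    for mouse, grp in cell_table.groupby("mouse_id"):
        for d0, d1 in cfg.compare_days:
            if d0 in days_present and d1 in days_present:
                x = grp.loc[grp["day"] == d0, "average_rate"].to_numpy()
                y = grp.loc[grp["day"] == d1, "average_rate"].to_numpy()
                if x.size and y.size:
                    r = wilcoxon_rank_sum(x, y)
                    rows.append(
                        {
                            "test": "wilcoxon_rank_sum",
                            "scope": mouse,
                            "contrast": f"day{d0}_vs_day{d1}",
                            "statistic": r.statistic,
                            "p": r.p_value,
                            "n": str(r.n),
                        }
                    )
    for mouse, grp in summary_table.groupby("mouse_id"):
        diet = grp[grp["day"] <= cfg.diet_end_day].sort_values("day")
        if len(diet) >= 3:
            r = mann_kendall(diet["median_rate"].to_numpy())
            rows.append(
                {
                    "test": "mann_kendall",
                    "scope": mouse,
                    "contrast": f"diet_days_{len(diet)}",
                    "statistic": r.statistic,
                    "p": r.p_value,
                    "n": str(r.n),
                }
            )
    for group, grp in summary_table.groupby("group"):
        for d0, d1 in cfg.compare_days:
            piv = grp.pivot_table(index="mouse_id", columns="day", values="median_rate")
            if d0 in piv.columns and d1 in piv.columns and len(piv) >= 2:
                try:
                    r = paired_t(piv[d0].to_numpy(), piv[d1].to_numpy())
                    rows.append(
                        {
                            "test": "paired_t",
                            "scope": group,
                            "contrast": f"day{d0}_vs_day{d1}",
                            "statistic": r.statistic,
                            "p": r.p_value,
                            "n": str(r.n),
                        }
                    )
                except Exception as exc:  # degenerate medians
                    logger.warning("paired t skipped for %s: %s", group, exc)
    if summary_table["group"].nunique() >= 2:
        try:
            rm = repeated_group_time_model(summary_table, "median_rate")
            for _, eff in rm.iterrows():
                rows.append(
                    {
                        "test": "rm_anova",
                        "scope": "cohort",
                        "contrast": eff["effect"],
                        "statistic": eff["F"],
                        "p": eff["p"],
                        "n": f"df=({int(eff['df1'])},{int(eff['df2'])})",
                    }
                )
        except ParameterError as exc:
            logger.warning("repeated-measures model skipped: %s", exc)
    return pd.DataFrame(rows, columns=["test", "scope", "contrast", "statistic", "p", "n"])


def recovery_report(run_dir: Union[str, Path], cfg: RunConfig) -> pd.DataFrame:
    """Compare inferred spikes with simulated ground truth per session.

    Reports per session: total-count relative error, mean event F1, the
    programmed rate multiplier, and the recovered median-rate ratio to
    day 0 (pooled over mice at each day in a separate column).
    """
    run_dir = Path(run_dir)
    index = pd.read_csv(run_dir / "sim" / "sessions.csv")
    fr = cfg.cohort.frame_rate
    n_frames = int(round(cfg.cohort.duration * fr))
    rows = []
    for _, sess in index.iterrows():
        sess_dir = Path(sess["path"])
        gt = _load_session_trains(sess_dir, fr, n_frames)
        inf_tbl = pd.read_csv(sess_dir / "inferred_spikes.csv")
        f1s = []
        gt_total = 0
        inf_total = 0
        med_gt = []
        med_inf = []
        for cid, train in gt.items():
            counts = np.zeros(n_frames, dtype=np.int64)
            sub = inf_tbl[inf_tbl["cell_id"] == cid]
            if len(sub):
                counts[sub["frame"].to_numpy()] = sub["count"].to_numpy()
            inferred = SpikeTrain(counts=counts, frame_rate=fr)
            gt_total += train.total
            inf_total += inferred.total
            med_gt.append(train.total / train.duration)
            med_inf.append(inferred.total / inferred.duration)
            if train.total or inferred.total:
                f1s.append(event_f1(train, inferred))
        rows.append(
            {
                "group": sess["group"],
                "mouse_id": sess["mouse_id"],
                "day": sess["day"],
                "programmed_multiplier": sess["multiplier"],
                "gt_total_spikes": gt_total,
                "inferred_total_spikes": inf_total,
                "count_rel_error": abs(inf_total - gt_total) / max(gt_total, 1),
                "mean_event_f1": float(np.mean(f1s)) if f1s else 1.0,
                "gt_median_rate": float(np.median(med_gt)),
                "inferred_median_rate": float(np.median(med_inf)),
            }
        )
    return pd.DataFrame(rows)
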