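"""Scoring of Ca2+-imaging recordings from GCaMP-expressing neurons.

A recording is a per-cell fluorescence series (arbitrary units, one value
per frame, default frame period 1.5 s = 0.67 Hz scan rate) plus a stimulus
schedule. The standard protocol applies five stimuli in sequence — 5HT,
ATP, KCl, KCl+GABA, KCl — for 9 s each with >= 80 s of rinse, then repeats
the whole block once (ten stimulations total).

Scoring rules:

* baseline F = mean of the 10 frames immediately preceding stimulus onset;
  baseline noise = s.d. of the same 10 frames, expressed in dF/F units.
* response amplitude (dF/F) = (peak F within 40 s post-onset - F) / F.
* a response is positive iff its amplitude strictly exceeds 5 x the
  baseline noise.
* GABA-mediated inhibition (%) = 100 x (1 - KCl+GABA peak / mean of the two
  flanking KCl-alone peaks); 100 means the KCl response was abolished, -100
  means it doubled.
* a cell passes QC iff every KCl-alone response clears the 5-s.d. rule, each
  pre-stimulus baseline sits within a drift tolerance (default 10%) of the
  first baseline, and fluorescence returns to baseline within 3 min of each
  stimulus.

Only cells whose per-transmitter response calls agree between the two blocks
("consistent" cells) enter the functional clustering, which runs UPGMA on
Euclidean distances over (mean dF/F ATP, mean dF/F 5HT, inhibition / 100).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment, Dendrogram, cut_tree, upgma

__all__ = [
    "CalciumTrace",
    "StimulusEvent",
    "StimulusSchedule",
    "BLOCK_SEQUENCE",
    "baseline_stats",
    "peak_dff",
    "call_response",
    "qc_trace",
    "gaba_inhibition",
    "summarize_cell",
    "summarize_recording",
    "cluster_responses",
    "read_traces",
    "write_traces",
    "read_schedule",
    "write_schedule",
]

BLOCK_SEQUENCE = ("5HT", "ATP", "KCl", "KCl+GABA", "KCl")
STIMULUS_NAMES = {"ATP", "5HT", "GABA", "KCl", "KCl+GABA"}


@dataclass
class CalciumTrace:
    """One cell's fluorescence series."""

    cell_id: str
    fluorescence: np.ndarray
    frame_period_s: float = 1.5

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 1:
            raise ValueError("fluorescence must be a 1-D series")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.fluorescence.size


@dataclass(frozen=True)
class StimulusEvent:
    name: str
    onset_frame: int
    duration_s: float = 9.0

    def __post_init__(self) -> None:
        if self.name not in STIMULUS_NAMES:
            raise ValueError(f"unknown stimulus {self.name!r}")


@dataclass
class StimulusSchedule:
    """Ordered stimulus events; onsets must be strictly increasing."""

    events: list[StimulusEvent]

    def __post_init__(self) -> None:
        onsets = [e.onset_frame for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def blocks(self) -> list[list[StimulusEvent]]:
        """Split into the two five-stimulus blocks, validating the sequence."""
        if len(self.events) != 2 * len(BLOCK_SEQUENCE):
            missing = list(BLOCK_SEQUENCE * 2)[len(self.events):]
            raise ValueError(
                f"schedule has {len(self.events)} events, expected "
                f"{2 * len(BLOCK_SEQUENCE)}; missing {missing}"
            )
        out = []
        for b in range(2):
            block = self.events[b * 5: b * 5 + 5]
            names = tuple(e.name for e in block)
            if names != BLOCK_SEQUENCE:
                raise ValueError(
                    f"block {b + 1} is {names}, expected {BLOCK_SEQUENCE}"
                )
            out.append(block)
        return out


def baseline_stats(trace: CalciumTrace, onset_frame: int) -> tuple[float, float]:
    """Mean and s.d. of the 10 frames just prior to ``onset_frame``."""
    if onset_frame < 10:
        raise ValueError(
            f"onset frame {onset_frame} leaves fewer than 10 pre-stimulus frames"
        )
    window = trace.fluorescence[onset_frame - 10: onset_frame]
    return float(window.mean()), float(window.std(ddof=0))


def peak_dff(trace: CalciumTrace, onset_frame: int, window_s: float = 40.0) -> float:
    """Peak dF/F within ``window_s`` seconds after stimulus onset.

    The window covers frames ``[onset, onset + ceil(window_s / period))``;
    a peak after the window is ignored.
    """
    n_win = math.ceil(window_s / trace.frame_period_s)
    end = onset_frame + n_win
    if end > trace.n_frames:
        raise ValueError(
            f"response window [{onset_frame}, {end}) exceeds trace length "
            f"{trace.n_frames}"
        )
    f0, _ = baseline_stats(trace, onset_frame)
    if f0 <= 0:
        raise ValueError("baseline fluorescence must be positive")
    return float((trace.fluorescence[onset_frame:end].max() - f0) / f0)


def call_response(peak: float, baseline_sd_over_f: float) -> bool:
    """Positive iff the peak dF/F strictly exceeds 5 x the baseline noise."""
    if not np.isfinite(baseline_sd_over_f):
        raise ValueError("baseline noise must be finite")
    return peak > 5.0 * baseline_sd_over_f


def gaba_inhibition(
    peak_kcl_gaba: float, peak_kcl_pre: float, peak_kcl_post: float
) -> float:
    """Percent inhibition of the KCl response by co-applied GABA.

    ``100 * (1 - peak_kcl_gaba / mean(flanks))``: 100% means the KCl-evoked
    response was completely lost, 0% unchanged, -100% doubled. Bounded above
    by 100, unbounded below.
    """
    flank = (peak_kcl_pre + peak_kcl_post) / 2.0
    if flank <= 0:
        raise ValueError("mean of flanking KCl responses must be positive")
    return 100.0 * (1.0 - peak_kcl_gaba / flank)


def qc_trace(
    trace: CalciumTrace,
    schedule: StimulusSchedule,
    drift_tolerance: float = 0.10,
) -> tuple[bool, list[str]]:
    """Health check: KCl responsiveness, flat baselines, 3-min recovery.

    Passes iff (1) every KCl-alone response exceeds 5 s.d. above baseline,
    (2) each pre-stimulus baseline mean lies within ``drift_tolerance`` of
    the first baseline mean, and (3) fluorescence returns to within
    ``drift_tolerance`` of the pre-stimulus baseline within 3 min of each
    stimulus (assessed on the frames available in the trace).
    """
    kcl_events = [e for e in schedule if e.name == "KCl"]
    if not kcl_events:
        raise ValueError("schedule contains no KCl event")
    reasons: list[str] = []

    for e in kcl_events:
        f0, sd = baseline_stats(trace, e.onset_frame)
        peak = peak_dff(trace, e.onset_frame)
        if not call_response(peak, sd / f0):
            reasons.append("kcl_below_5sd")
            break

    first_f0, _ = baseline_stats(trace, schedule.events[0].onset_frame)
    for e in schedule:
        f0, _ = baseline_stats(trace, e.onset_frame)
        if abs(f0 - first_f0) > drift_tolerance * first_f0:
            reasons.append("baseline_drift")
            break

    three_min = math.ceil(180.0 / trace.frame_period_s)
    for e in schedule:
        f0, _ = baseline_stats(trace, e.onset_frame)
        offset = e.onset_frame + math.ceil(e.duration_s / trace.frame_period_s)
        window = trace.fluorescence[offset: min(offset + three_min, trace.n_frames)]
        if window.size and not np.any(np.abs(window - f0) <= drift_tolerance * f0):
            reasons.append("no_recovery")
            break

    return (not reasons), reasons


def summarize_cell(
    trace: CalciumTrace,
    schedule: StimulusSchedule,
    drift_tolerance: float = 0.10,
) -> dict:
    """Replicate-resolved response summary for one cell.

    Requires two complete five-stimulus blocks. Returns per-transmitter
    replicate peaks and their means, response flags (a flag is set only when
    both replicates agree; disagreement marks the cell "inconsistent"),
    per-block inhibition and its mean, and the QC verdict.
    """
    blocks = schedule.blocks()
    row: dict = {"cell_id": trace.cell_id}

    for stim in ("ATP", "5HT"):
        peaks, calls = [], []
        for block in blocks:
            event = next(e for e in block if e.name == stim)
            f0, sd = baseline_stats(trace, event.onset_frame)
            p = peak_dff(trace, event.onset_frame)
            peaks.append(p)
            calls.append(call_response(p, sd / f0))
        key = stim.lower().replace("+", "_")
        row[f"dff_{key}_1"], row[f"dff_{key}_2"] = peaks
        row[f"dff_{key}_mean"] = float(np.mean(peaks))
        row[f"responds_{key}"] = calls[0] if calls[0] == calls[1] else None
        row[f"consistent_{key}"] = calls[0] == calls[1]

    inhibitions = []
    for i, block in enumerate(blocks, start=1):
        kcl_pre, gaba, kcl_post = block[2], block[3], block[4]
        inh = gaba_inhibition(
            peak_dff(trace, gaba.onset_frame),
            peak_dff(trace, kcl_pre.onset_frame),
            peak_dff(trace, kcl_post.onset_frame),
        )
        row[f"inhibition_{i}"] = inh
        inhibitions.append(inh)
    row["inhibition_mean"] = float(np.mean(inhibitions))

    row["consistent"] = bool(row["consistent_atp"] and row["consistent_5ht"])
    ok, why = qc_trace(trace, schedule, drift_tolerance)
    row["qc_pass"] = ok
    row["qc_reasons"] = ";".join(why)
    return row


def summarize_recording(
    traces: Iterable[CalciumTrace],
    schedule: StimulusSchedule,
    drift_tolerance: float = 0.10,
) -> pd.DataFrame:
    """ResponseTable: one summary row per cell."""
    rows = [summarize_cell(t, schedule, drift_tolerance) for t in traces]
    return pd.DataFrame(rows)


def cluster_responses(table: pd.DataFrame, k: int = 4) -> tuple[ClusterAssignment, Dendrogram]:
    """UPGMA functional clustering of QC-passing, consistent cells.

    Features per cell: (mean dF/F ATP, mean dF/F 5HT, mean inhibition / 100),
    the inhibition rescaled so its numeric range matches dF/F. Euclidean
    distances, average linkage, flat cut at ``k``.
    """
    use = table[(table["qc_pass"]) & (table["consistent"])]
    if len(use) < k:
        raise ValueError(f"only {len(use)} usable cells for k={k} clusters")
    feats = use[["dff_atp_mean", "dff_5ht_mean"]].to_numpy(dtype=float)
    feats = np.column_stack([feats, use["inhibition_mean"].to_numpy(dtype=float) / 100.0])
    diff = feats[:, None, :] - feats[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    if np.allclose(dist, 0.0):
        import warnings

        warnings.warn("all response profiles identical; flat cut is arbitrary")
    tree = upgma(dist, list(use["cell_id"]))
    return cut_tree(tree, k=k), tree


# ---------------------------------------------------------------------------
# file formats: traces CSV (frame index + one column per cell, metadata JSON
# with frame_period_s), schedule CSV/JSON (name, onset_frame, duration_s)
# ---------------------------------------------------------------------------

def read_traces(path: str | Path, metadata: str | Path | None = None) -> list[CalciumTrace]:
    path = Path(path)
    period = 1.5
    meta_path = Path(metadata) if metadata else path.with_suffix(".json")
    if meta_path.exists():
        period = float(json.loads(meta_path.read_text()).get("frame_period_s", 1.5))
    frame = pd.read_csv(path, index_col=0)
    return [
        CalciumTrace(str(col), frame[col].to_numpy(dtype=float), period)
        for col in frame.columns
    ]


def write_traces(traces: Sequence[CalciumTrace], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {t.cell_id: t.fluorescence for t in traces},
        index=pd.RangeIndex(traces[0].n_frames, name="frame"),
    )
    frame.to_csv(path, float_format="%.8g")
    path.with_suffix(".json").write_text(
        json.dumps({"frame_period_s": traces[0].frame_period_s}) + "\n"
    )
    return path


def read_schedule(path: str | Path) -> StimulusSchedule:
    path = Path(path)
    if path.suffix.lower() == ".json":
        events = [
            StimulusEvent(e["name"], int(e["onset_frame"]), float(e.get("duration_s", 9.0)))
            for e in json.loads(path.read_text())
        ]
    else:
        frame = pd.read_csv(path)
        events = [
            StimulusEvent(str(r["name"]), int(r["onset_frame"]), float(r["duration_s"]))
            for _, r in frame.iterrows()
        ]
    return StimulusSchedule(events)


def write_schedule(schedule: StimulusSchedule, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps(
                [
                    {"name": e.name, "onset_frame": e.onset_frame, "duration_s": e.duration_s}
                    for e in schedule
                ],
                indent=1,
            )
            + "\n"
        )
    else:
        pd.DataFrame(
            [
                {"name": e.name, "onset_frame": e.onset_frame, "duration_s": e.duration_s}
                for e in schedule
            ]
        ).to_csv(path, index=False)
    return path
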