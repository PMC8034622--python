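"""Binding-event calling and per-molecule observation times.

A binding event is a maximal run of consecutive step-fit segments whose
corrected FRET level exceeds the event threshold (default 0.13), lasting at
least ``min_frames`` frames (default 4, i.e. dwell >= 300 ms at 100 ms
frames with the ``tau = (n_frames - 1) * frame_time`` convention).  Runs of
several above-threshold segments merge into one event — a mid-event level
shift is a probe repositioning, not a new binding — and such events carry a
``merged`` flag.

The observation time of a molecule runs from recording start to donor
photobleach or trace end, whichever comes first; zero-event molecules keep
their observation time and enter the frequency statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from fretpaint.stepfinder import StepFit, estimate_noise_variance
from fretpaint.trace_io import ConstructDataset, IntensityTrace


@dataclass
class BindingEvent:
    """One probe-binding burst called from a step fit."""

    molecule_id: str
    start_frame: int
    n_frames: int
    tau: float  # dwell time, s
    e_mean: float  # duration-weighted mean corrected FRET
    merged: bool = False  # spans more than one step segment
    censored: bool = False  # touches recording start or observation end


@dataclass
class MoleculeRecord:
    """Events plus observation time for one screened molecule."""

    molecule_id: str
    observation_time: float  # s
    events: list[BindingEvent] = field(default_factory=list)
    had_bleach: bool = False

    def __post_init__(self) -> None:
        if not self.observation_time > 0:
            raise ValueError(
                f"molecule {self.molecule_id}: observation_time must be > 0"
            )

    @property
    def n_events(self) -> int:
        return len(self.events)


def detect_bleach(
    trace: IntensityTrace,
    background: float = 0.0,
    n_sd: float = 3.0,
    min_run: int = 10,
) -> int | None:
    """First frame of a terminal dark period (donor photobleach), or None.

    A frame is dark when total intensity I_D + I_A falls below
    ``background + n_sd * sigma`` with sigma estimated robustly from first
    differences of the total.  The bleach frame is the start of the first
    dark run of at least ``min_run`` frames that persists to the end of the
    trace (median of all later totals still dark, tolerating rare noise
    excursions above the threshold).
    """
    total = trace.total
    n = len(total)
    if n < min_run:
        return None
    sigma = float(np.sqrt(max(estimate_noise_variance(total), 0.0)))
    thr = background + n_sd * sigma
    dark = total < thr
    # run-length scan over dark stretches
    idx = 0
    while idx < n:
        if not dark[idx]:
            idx += 1
            continue
        run_end = idx
        while run_end < n and dark[run_end]:
            run_end += 1
        if run_end - idx >= min_run and float(np.median(total[idx:])) < thr:
            return idx
        idx = run_end
    return None


def call_events(
    stepfit: StepFit,
    frame_time: float,
    threshold: float = 0.13,
    min_frames: int = 4,
    molecule_id: str = "",
) -> list[BindingEvent]:
    """Call binding events from a step fit on the corrected-FRET trace.

    Maximal runs of consecutive segments with level > *threshold* become
    candidate events; those spanning at least *min_frames* frames are
    accepted with ``tau = (n_frames - 1) * frame_time`` and ``e_mean`` the
    duration-weighted mean of the run's levels.
    """
    events: list[BindingEvent] = []
    segments = stepfit.segments()
    i = 0
    while i < len(segments):
        if segments[i][2] <= threshold:
            i += 1
            continue
        j = i
        while j < len(segments) and segments[j][2] > threshold:
            j += 1
        start = segments[i][0]
        end = segments[j - 1][1]
        n_frames = end - start
        if n_frames >= min_frames:
            lengths = np.array([seg[1] - seg[0] for seg in segments[i:j]], dtype=float)
            levels = np.array([seg[2] for seg in segments[i:j]])
            events.append(
                BindingEvent(
                    molecule_id=molecule_id,
                    start_frame=start,
                    n_frames=n_frames,
                    tau=(n_frames - 1) * frame_time,
                    e_mean=float(np.sum(levels * lengths) / np.sum(lengths)),
                    merged=(j - i) > 1,
                    censored=(start == 0) or (end == stepfit.n_frames),
                )
            )
        i = j
    return events


def build_molecule_records(
    dataset: ConstructDataset,
    events_per_trace: Sequence[list[BindingEvent]],
    bleach_frames: Sequence[int | None],
) -> list[MoleculeRecord]:
    """One record per screened molecule, zero-event molecules included.

    ``observation_time = (bleach_frame or n_frames - 1) * frame_time`` —
    elapsed time from recording start to bleach or end.  Inputs must be
    aligned with ``dataset.sorted_traces()``.
    """
    traces = dataset.sorted_traces()
    if not (len(traces) == len(events_per_trace) == len(bleach_frames)):
        raise ValueError("per-trace inputs not aligned with dataset")
    records = []
    for trace, events, bleach in zip(traces, events_per_trace, bleach_frames):
        if bleach is not None:
            # a bleach in frame 0 still leaves one screened frame of record
            obs = max(bleach, 1) * dataset.frame_time
            had_bleach = True
        else:
            obs = (trace.n_frames - 1) * dataset.frame_time
            had_bleach = False
        records.append(
            MoleculeRecord(
                molecule_id=trace.molecule_id,
                observation_time=obs,
                events=sorted(events, key=lambda e: e.start_frame),
                had_bleach=had_bleach,
            )
        )
    return records


def events_table(records: Sequence[MoleculeRecord], frame_time: float):
    """Events as a DataFrame (molecule_id, start_s, tau_s, e_mean, flags)."""
    import pandas as pd

    rows = [
        {
            "molecule_id": ev.molecule_id,
            "start_s": ev.start_frame * frame_time,
            "tau_s": ev.tau,
            "e_mean": ev.e_mean,
            "merged": ev.merged,
            "censored": ev.censored,
        }
        for rec in records
        for ev in rec.events
    ]
    return pd.DataFrame(
        rows, columns=["molecule_id", "start_s", "tau_s", "e_mean", "merged", "censored"]
    )


def records_table(records: Sequence[MoleculeRecord]):
    """Records as a DataFrame (molecule_id, observation_s, n_events, had_bleach)."""
    import pandas as pd

    rows = [
        {
            "molecule_id": r.molecule_id,
            "observation_s": r.observation_time,
            "n_events": r.n_events,
            "had_bleach": r.had_bleach,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["molecule_id", "observation_s", "n_events", "had_bleach"])
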