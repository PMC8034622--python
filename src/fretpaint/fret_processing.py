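"""FRET calculation, donor-only (leakage) correction, population histograms.

Apparent FRET is E = I_A / (I_A + I_D) after per-channel background
subtraction.  Molecules with no acceptor bound still show a nonzero
apparent FRET because donor emission leaks into the acceptor channel; these
zero-event molecules define the donor-only (DO) peak.  The DO peak is used
as the reference to shift zero and rescale the range:
``E' = (E - e_do) / (1 - e_do)``, a linear map taking [e_do, 1] onto [0, 1].

Population histograms weight each molecule equally (every molecule's events
share one unit of weight) and are normalized to a total of 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.optimize import curve_fit

from fretpaint.errors import EstimationError
from fretpaint.trace_io import IntensityTrace

if TYPE_CHECKING:
    from fretpaint.event_calling import MoleculeRecord


@dataclass
class FretTrace:
    """Per-frame FRET efficiencies for one molecule.

    ``valid_frames`` is the number of analyzable frames (recording start to
    donor photobleach or trace end); ``valid`` flags frames whose total
    intensity cleared the positivity floor.
    """

    molecule_id: str
    frame_time: float
    e_raw: np.ndarray
    valid: np.ndarray
    e_corrected: np.ndarray | None = None
    valid_frames: int = 0

    def __post_init__(self) -> None:
        self.e_raw = np.asarray(self.e_raw, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid_frames == 0:
            self.valid_frames = len(self.e_raw)

    @property
    def n_frames(self) -> int:
        return len(self.e_raw)


@dataclass
class DonorOnlyModel:
    """Gaussian model of the donor-only peak."""

    e_do: float
    sigma_do: float
    n_molecules_used: int

    def __post_init__(self) -> None:
        if not (0 <= self.e_do < 1):
            raise EstimationError(f"e_do {self.e_do} outside [0, 1)")
        if not self.sigma_do > 0:
            raise EstimationError("sigma_do must be > 0")


@dataclass
class FretHistogram:
    """Molecule-normalized FRET population histogram (totals 100%)."""

    bin_edges: np.ndarray
    percent_per_bin: np.ndarray
    n_molecules: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.percent_per_bin = np.asarray(self.percent_per_bin, dtype=float)
        total = self.percent_per_bin.sum()
        if abs(total - 100.0) > 1e-9:
            raise EstimationError(f"histogram total {total} != 100")
        if np.any(self.percent_per_bin < 0):
            raise EstimationError("negative histogram mass")


def compute_fret(
    trace: IntensityTrace,
    background_d: float = 0.0,
    background_a: float = 0.0,
    floor: float | None = None,
) -> FretTrace:
    """Per-frame apparent FRET E = (I_A - bg_A) / ((I_A - bg_A) + (I_D - bg_D)).

    Frames whose denominator falls at or below a positivity floor (default:
    5% of the 95th-percentile total intensity — i.e. clearly dark frames)
    are flagged invalid; their E is NaN.  E on valid frames is clipped to
    [0, 1], where noise can otherwise push it slightly outside.
    """
    i_d = trace.i_donor - background_d
    i_a = trace.i_acceptor - background_a
    den = i_a + i_d
    if floor is None:
        scale = np.percentile(den, 95)
        floor = 0.05 * max(scale, 0.0)
    valid = den > floor
    e = np.full(trace.n_frames, np.nan)
    e[valid] = np.clip(i_a[valid] / den[valid], 0.0, 1.0)
    return FretTrace(
        molecule_id=trace.molecule_id,
        frame_time=trace.frame_time,
        e_raw=e,
        valid=valid,
    )


def _gaussian(x: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_gaussian_peak(values: np.ndarray, bins: int | str = "auto") -> tuple[float, float]:
    """Fit a single Gaussian to the histogram of *values*; returns (mu, sigma).

    Falls back to the sample mean/SD when the curve fit cannot converge.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise EstimationError("no finite values to fit")
    mu0, sd0 = float(np.mean(values)), float(np.std(values))
    if sd0 == 0.0:
        return mu0, 0.0
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = curve_fit(
            _gaussian,
            centers,
            counts,
            p0=[counts.max(), mu0, sd0],
            bounds=([0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        return float(popt[1]), float(popt[2])
    except (RuntimeError, ValueError):
        return mu0, sd0


def estimate_donor_only(
    dataset_fret: Sequence[FretTrace],
    events_per_trace: Sequence[int],
    min_zero_traces: int = 10,
    fallback_threshold: float = 0.25,
) -> DonorOnlyModel:
    """Estimate the donor-only peak from zero-event molecules.

    Pools raw-FRET frames of molecules that showed no binding event and
    fits a Gaussian to their histogram.  If fewer than ``min_zero_traces``
    such molecules exist, falls back to pooling all frames below
    ``fallback_threshold`` (the raw-scale event threshold) across every
    molecule.
    """
    if len(dataset_fret) != len(events_per_trace):
        raise EstimationError("dataset_fret and events_per_trace length mismatch")
    zero_traces = [
        ft for ft, k in zip(dataset_fret, events_per_trace) if k == 0
    ]
    if len(zero_traces) >= min_zero_traces:
        pool = np.concatenate(
            [ft.e_raw[: ft.valid_frames][ft.valid[: ft.valid_frames]] for ft in zero_traces]
        )
        n_used = len(zero_traces)
    else:
        parts = []
        for ft in dataset_fret:
            e = ft.e_raw[: ft.valid_frames][ft.valid[: ft.valid_frames]]
            parts.append(e[e < fallback_threshold])
        pool = np.concatenate(parts) if parts else np.array([])
        n_used = len(dataset_fret)
    pool = pool[np.isfinite(pool)]
    if len(pool) == 0:
        raise EstimationError("no frames available for donor-only estimation")
    mu, sigma = fit_gaussian_peak(pool)
    if sigma == 0.0:
        # noiseless data: the peak is a point mass at mu
        sigma = 1e-6
    return DonorOnlyModel(e_do=float(np.clip(mu, 0.0, 1.0 - 1e-12)), sigma_do=sigma, n_molecules_used=n_used)


def apply_do_correction(
    e_raw: float | np.ndarray,
    model: DonorOnlyModel,
    clip: tuple[float, float] = (-0.2, 1.0),
) -> float | np.ndarray:
    """Shift the DO peak to zero and rescale: E' = (E - e_do) / (1 - e_do).

    Linear and order-preserving; results are clipped to ``clip`` for
    reporting (default [-0.2, 1] keeps noise-induced negatives visible).
    """
    e = np.asarray(e_raw, dtype=float)
    corrected = (e - model.e_do) / (1.0 - model.e_do)
    corrected = np.clip(corrected, clip[0], clip[1])
    if np.isscalar(e_raw) or np.ndim(e_raw) == 0:
        return float(corrected)
    return corrected


def population_histogram(
    records: "Sequence[MoleculeRecord]",
    bin_width: float = 0.02,
) -> FretHistogram:
    """Molecule-normalized FRET population histogram of binding events.

    Only molecules with at least one event contribute; each event carries
    weight 1/(number of events of its molecule) and the total is scaled to
    100%.  Event FRET values are the events' duration-weighted mean
    corrected levels, clipped into [0, 1].
    """
    with_events = [r for r in records if len(r.events) > 0]
    if not with_events:
        raise EstimationError("population_histogram: no molecules with events")
    n_bins = int(round(1.0 / bin_width))
    if not np.isclose(n_bins * bin_width, 1.0):
        raise EstimationError(f"bin_width {bin_width} does not tile [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mass = np.zeros(n_bins)
    for rec in with_events:
        w = 1.0 / len(rec.events)
        for ev in rec.events:
            e = min(max(ev.e_mean, 0.0), 1.0)
            b = min(int(e / bin_width), n_bins - 1)
            mass[b] += w
    percent = 100.0 * mass / mass.sum()
    return FretHistogram(bin_edges=edges, percent_per_bin=percent, n_molecules=len(with_events))


def low_high_ratio(hist: FretHistogram, split: float = 0.5) -> float:
    """Population ratio (mass below *split*) / (mass above *split*).

    *split* must coincide with a bin edge.  Returns ``inf`` when all mass
    sits below the split.
    """
    edges = hist.bin_edges
    idx = np.flatnonzero(np.isclose(edges, split))
    if len(idx) == 0:
        raise EstimationError(f"split {split} is not a histogram bin edge")
    i = int(idx[0])
    low = float(hist.percent_per_bin[:i].sum())
    high = float(hist.percent_per_bin[i:].sum())
    if high == 0.0:
        return float("inf")
    return low / high
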