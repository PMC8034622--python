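"""Positional (FRET-segment) analysis of binding events.

FRET level reports where along the overhang the probe bound (high FRET =
near the donor).  The FRET scale [0, 1] is divided into five equal
segments of width 0.2; events are classified by their mean corrected FRET
and per-segment dwell and frequency statistics are computed, together with
the significance tests used to compare segments (one-way ANOVA on dwells,
Welch pairwise t on frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from fretpaint.errors import EstimationError
from fretpaint.event_calling import BindingEvent, MoleculeRecord

SEGMENT_EDGES = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
N_SEGMENTS = 5


@dataclass
class SegmentStats:
    """Dwell and frequency statistics for one 0.2-wide FRET segment."""

    segment_index: int
    n_events: int
    mean_dwell: float = float("nan")  # s; NaN when the segment is empty
    sem_dwell: float = float("nan")  # s
    frequency: float = float("nan")  # s^-1
    freq_sigma: float = float("nan")  # s^-1 (bootstrap)


def assign_segment(e_mean: float) -> int:
    """Segment index for a corrected FRET value.

    Half-open bins [0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8) and the
    closed last bin [0.8, 1.0].  Out-of-range input raises.
    """
    if not (0.0 <= e_mean <= 1.0):
        raise EstimationError(f"assign_segment: {e_mean} outside [0, 1]")
    return min(int(e_mean / 0.2), N_SEGMENTS - 1)


def assign_segments(e_means: np.ndarray) -> np.ndarray:
    """Vectorized :func:`assign_segment`."""
    e = np.asarray(e_means, dtype=float)
    if np.any((e < 0) | (e > 1)):
        raise EstimationError("assign_segments: values outside [0, 1]")
    return np.minimum((e / 0.2).astype(int), N_SEGMENTS - 1)


def contour_matrix(
    events: Sequence[BindingEvent],
    dwell_min: float = 1.0,
    dwell_max: float = 7.0,
    fret_bins: int | np.ndarray = 20,
    dwell_bins: int | np.ndarray = 24,
) -> np.ndarray:
    """Joint (FRET, dwell) count matrix for contour plotting.

    Events are filtered to ``dwell_min < tau <= dwell_max`` (default 1-7 s,
    suppressing candidate partial-hybridization events below 1 s); the
    matrix has FRET rows and dwell columns and sums to the filtered count.
    """
    e = np.array([ev.e_mean for ev in events])
    tau = np.array([ev.tau for ev in events])
    keep = (tau > dwell_min) & (tau <= dwell_max) & (e >= 0) & (e <= 1)
    fret_edges = (
        np.linspace(0.0, 1.0, fret_bins + 1) if np.isscalar(fret_bins) else np.asarray(fret_bins)
    )
    dwell_edges = (
        np.linspace(dwell_min, dwell_max, dwell_bins + 1)
        if np.isscalar(dwell_bins)
        else np.asarray(dwell_bins)
    )
    matrix, _, _ = np.histogram2d(e[keep], tau[keep], bins=[fret_edges, dwell_edges])
    return matrix


def segment_dwell_stats(events: Sequence[BindingEvent]) -> list[SegmentStats]:
    """Per-segment mean dwell time and its standard error.

    Empty segments are reported with ``n_events = 0`` and NaN statistics.
    """
    taus_by_seg: list[list[float]] = [[] for _ in range(N_SEGMENTS)]
    for ev in events:
        if 0.0 <= ev.e_mean <= 1.0:
            taus_by_seg[assign_segment(ev.e_mean)].append(ev.tau)
    out = []
    for i, taus in enumerate(taus_by_seg):
        if not taus:
            out.append(SegmentStats(segment_index=i, n_events=0))
            continue
        arr = np.asarray(taus)
        sem = float(np.std(arr, ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
        out.append(
            SegmentStats(
                segment_index=i,
                n_events=len(arr),
                mean_dwell=float(np.mean(arr)),
                sem_dwell=sem,
            )
        )
    return out


def segment_frequencies(
    records: Sequence[MoleculeRecord],
    n_boot: int = 2000,
    seed: int = 0,
) -> list[SegmentStats]:
    """Per-segment binding frequencies with bootstrap uncertainties.

    frequency_j = (events in segment j) / (total observation time); the
    observation time is shared, so segment frequencies sum to the construct
    f_ave exactly.  Uncertainty resamples molecules with replacement, each
    carrying its per-segment event counts and observation time jointly.
    """
    if not records:
        raise EstimationError("segment_frequencies: no molecule records")
    recs = sorted(records, key=lambda r: r.molecule_id)
    n = len(recs)
    times = np.array([r.observation_time for r in recs])
    seg_counts = np.zeros((n, N_SEGMENTS))
    for i, rec in enumerate(recs):
        for ev in rec.events:
            if 0.0 <= ev.e_mean <= 1.0:
                seg_counts[i, assign_segment(ev.e_mean)] += 1
    t_total = float(times.sum())
    if t_total <= 0:
        raise EstimationError("segment_frequencies: zero total observation time")
    freq = seg_counts.sum(axis=0) / t_total

    rng = np.random.default_rng(seed)
    sigmas = np.zeros(N_SEGMENTS)
    if n_boot > 1:
        boot = np.empty((n_boot, N_SEGMENTS))
        done = 0
        while done < n_boot:
            m = min(1000, n_boot - done)
            idx = rng.integers(0, n, size=(m, n))
            boot[done : done + m] = (
                seg_counts[idx].sum(axis=1) / times[idx].sum(axis=1)[:, None]
            )
            done += m
        sigmas = np.std(boot, axis=0, ddof=1)

    return [
        SegmentStats(
            segment_index=i,
            n_events=int(seg_counts[:, i].sum()),
            frequency=float(freq[i]),
            freq_sigma=float(sigmas[i]),
        )
        for i in range(N_SEGMENTS)
    ]


def one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA across groups: (F, p).

    Requires at least two groups of at least two observations each; fully
    degenerate input (every group constant) raises.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise EstimationError("one_way_anova: need >= 2 groups with >= 2 observations")
    if all(np.ptp(a) == 0 for a in arrs):
        raise EstimationError("one_way_anova: all groups constant (zero within-variance)")
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)


@dataclass
class PairwiseTests:
    """Welch pairwise t-tests between segments.

    Symmetric ``t`` matrix with zero diagonal; ``p_raw`` unadjusted and
    ``p_bonferroni`` adjusted for the number of unordered pairs.  Pairs
    involving a group with fewer than two observations are NaN-flagged.
    """

    t: np.ndarray
    p_raw: np.ndarray
    p_bonferroni: np.ndarray


def pairwise_segment_tests(groups: Sequence[np.ndarray]) -> PairwiseTests:
    """Welch two-sample t for every unordered pair of groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise EstimationError("pairwise_segment_tests: need >= 2 groups")
    t = np.zeros((k, k))
    p = np.ones((k, k))
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            if len(arrs[i]) < 2 or len(arrs[j]) < 2:
                t[i, j] = t[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            tij, pij = stats.ttest_ind(arrs[i], arrs[j], equal_var=False)
            t[i, j], t[j, i] = tij, tij
            p[i, j], p[j, i] = pij, pij
    p_adj = np.minimum(p * n_pairs, 1.0)
    np.fill_diagonal(p_adj, 1.0)
    return PairwiseTests(t=t, p_raw=p, p_bonferroni=p_adj)
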