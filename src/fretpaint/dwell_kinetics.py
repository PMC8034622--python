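"""Dwell-time distributions: exponential-decay fits and model comparison.

Dwell times of transient probe binding typically mix a fast component
(partial hybridization, ~0.7 s here) with a slower full-duplex component
(several seconds).  Dwell histograms are therefore fit with

    single:  y = y0 + A1 exp(-(x - x0) / t1)
    double:  y = y0 + A1 exp(-(x - x0) / t1) + A2 exp(-(x - x0) / t2)

by nonlinear least squares on the bin counts, with x0 fixed at the left
edge of the first bin (the minimum accepted dwell).  The nested models are
compared with an F-test on residual sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from fretpaint.errors import EstimationError, FittingError

#: smallest dwell an accepted event can have (4 frames at 100 ms)
MIN_DWELL_S = 0.3


@dataclass
class DwellFit:
    """Result of an exponential-decay fit to a dwell histogram.

    For ``model="single"`` the lone time constant is stored in ``t1`` and
    ``A2``/``t2`` are None.  For double fits components are ordered
    ``t1 < t2`` (fast first).
    """

    model: str  # "single" | "double"
    y0: float
    x0: float
    A1: float
    t1: float
    rss: float
    n_bins: int
    dof: int
    A2: float | None = None
    t2: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("single", "double"):
            raise FittingError(f"unknown model {self.model!r}")
        if not self.t1 > 0:
            raise FittingError("t1 must be > 0")
        if self.model == "double" and not (self.t2 is not None and self.t2 > self.t1):
            raise FittingError("double fit requires t2 > t1")

    def predict(self, x: np.ndarray) -> np.ndarray:
        y = self.y0 + self.A1 * np.exp(-(x - self.x0) / self.t1)
        if self.model == "double":
            y = y + self.A2 * np.exp(-(x - self.x0) / self.t2)
        return y

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "y0": self.y0,
            "x0": self.x0,
            "A1": self.A1,
            "t1": self.t1,
            "A2": self.A2,
            "t2": self.t2,
            "rss": self.rss,
            "n_bins": self.n_bins,
            "dof": self.dof,
        }


def dwell_histogram(
    taus: np.ndarray, bin_width: float = 0.3, t_min: float = MIN_DWELL_S
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-width dwell histogram starting at the minimum accepted dwell.

    Returns ``(bin_centers, counts)`` with raw (not density) counts; the
    total count equals ``len(taus)``.
    """
    taus = np.asarray(taus, dtype=float)
    if len(taus) == 0:
        raise EstimationError("dwell_histogram: empty input")
    if np.any(taus < t_min - 1e-12):
        raise EstimationError(f"dwell_histogram: dwell below t_min={t_min}")
    n_bins = max(int(np.ceil((taus.max() - t_min) / bin_width + 1e-9)), 1)
    edges = t_min + bin_width * np.arange(n_bins + 1)
    # guard the max value landing exactly on the last edge
    edges[-1] += 1e-9 * bin_width
    counts, _ = np.histogram(taus, bins=edges)
    centers = t_min + bin_width * (np.arange(n_bins) + 0.5)
    return centers, counts.astype(float)


def _single(x, y0, a1, t1, x0):
    return y0 + a1 * np.exp(-(x - x0) / t1)


def _double(x, y0, a1, t1, a2, t2, x0):
    return y0 + a1 * np.exp(-(x - x0) / t1) + a2 * np.exp(-(x - x0) / t2)


def _slope_time_constant(x: np.ndarray, y: np.ndarray) -> float | None:
    """Decay constant from a log-linear fit over positive-count bins."""
    pos = y > 0
    if pos.sum() < 2:
        return None
    slope = np.polyfit(x[pos], np.log(y[pos]), 1)[0]
    if slope >= 0:
        return None
    return -1.0 / slope


def _fit_weighted(fun, centers, counts, starts, bounds, weighting):
    """Multistart (optionally iteratively reweighted) least squares.

    Returns ``(chi2, popt)`` with chi2 in the final weighting's metric.
    ``weighting="pearson"`` seeds with data weights sqrt(max(counts, 1))
    and then reweights twice from the fitted model — the proper chi-square
    for Poisson bin counts, which neither over-trusts empty tail bins
    (unweighted) nor systematically downweights upward fluctuations (data
    weights).
    """

    def run(sigma, p0s):
        best, errs = None, []
        for p0 in p0s:
            try:
                popt, _ = curve_fit(
                    fun, centers, counts, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
                )
            except (RuntimeError, ValueError) as exc:
                errs.append(str(exc))
                continue
            w = sigma if sigma is not None else 1.0
            chi2 = float(np.sum(((counts - fun(centers, *popt)) / w) ** 2))
            if best is None or chi2 < best[0]:
                best = (chi2, popt)
        if best is None:
            raise FittingError(f"no start converged ({'; '.join(errs)})")
        return best

    if weighting == "none":
        return run(None, starts)
    sigma = np.sqrt(np.maximum(counts, 1.0))
    best = run(sigma, starts)
    if weighting == "data":
        return best
    if weighting != "pearson":
        raise FittingError(f"unknown weighting {weighting!r}")
    for _ in range(2):
        sigma = np.sqrt(np.maximum(fun(centers, *best[1]), 1.0))
        best = run(sigma, [tuple(best[1]), *starts])
    return best


def fit_decay(
    hist: tuple[np.ndarray, np.ndarray],
    model: str = "double",
    weighting: str = "pearson",
) -> DwellFit:
    """Exponential-decay fit to a dwell histogram by weighted least squares.

    Requires >= 6 nonempty bins for the single model and >= 8 for the
    double model.  ``x0`` is fixed at the left edge of the first bin; all
    parameters are bounded nonnegative; the offset ``y0`` is free (the
    decay formula's baseline term).  Initialization is multistart — the
    fast constant from the histogram head's log-slope, the slow constant
    from its tail, spread-out variants, and (for the double model) the
    single-model solution with a vanishing second amplitude, which also
    guarantees the double fit never scores worse than the single fit.
    Components of double fits are ordered ``t1 < t2``.

    ``weighting`` is "pearson" (default: iteratively reweighted chi-square
    with model-based Poisson variances), "data" (sqrt of observed counts)
    or "none" (plain least squares on raw counts).
    """
    centers, counts = np.asarray(hist[0], float), np.asarray(hist[1], float)
    if len(centers) != len(counts):
        raise EstimationError("histogram centers/counts length mismatch")
    n_nonempty = int(np.sum(counts > 0))
    min_bins = 6 if model == "single" else 8
    if n_nonempty < min_bins:
        raise EstimationError(
            f"fit_decay[{model}]: needs >= {min_bins} nonempty bins, got {n_nonempty}"
        )
    if len(centers) >= 2:
        bin_width = float(centers[1] - centers[0])
    else:  # pragma: no cover - excluded by the bin-count precondition
        bin_width = 2.0 * centers[0]
    x0 = float(centers[0] - bin_width / 2.0)

    total = float(counts.max())
    n_head = max(len(centers) // 4, 3)
    t_head = _slope_time_constant(centers[:n_head], counts[:n_head]) or bin_width
    t_tail = _slope_time_constant(centers[n_head:], counts[n_head:]) or 5 * t_head
    t_head = max(t_head, bin_width / 10)
    t_tail = max(t_tail, 2 * t_head)

    if model == "single":
        fun = lambda x, y0, a1, t1: _single(x, y0, a1, t1, x0)  # noqa: E731
        n_free = 3
        starts = [
            (0.0, total, t_head),
            (0.0, total, t_tail),
            (0.0, total, 0.5 * (t_head + t_tail)),
        ]
        bounds = ([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf])
    elif model == "double":
        fun = lambda x, y0, a1, t1, a2, t2: _double(x, y0, a1, t1, a2, t2, x0)  # noqa: E731
        n_free = 5
        starts = [
            (0.0, 0.7 * total, t_head, 0.3 * total, t_tail),
            (0.0, 0.5 * total, t_head, 0.5 * total, 3 * t_tail),
            (0.0, 0.9 * total, t_head / 2, 0.1 * total, t_tail),
            (0.0, 0.5 * total, t_head, 0.5 * total, max(t_tail, 10 * t_head)),
        ]
        try:
            s = fit_decay(hist, "single", weighting=weighting)
            starts.append((s.y0, s.A1, s.t1, 0.0, max(5 * s.t1, t_tail)))
        except (EstimationError, FittingError):
            pass
        bounds = ([0.0, 0.0, 1e-9, 0.0, 1e-9], [np.inf, np.inf, np.inf, np.inf, np.inf])
    else:
        raise FittingError(f"unknown model {model!r}")

    try:
        rss, popt = _fit_weighted(fun, centers, counts, starts, bounds, weighting)
    except FittingError as exc:
        raise FittingError(f"fit_decay[{model}]: {exc}") from exc
    dof = len(centers) - n_free
    if model == "single":
        y0, a1, t1 = popt
        return DwellFit(
            model="single", y0=float(y0), x0=x0, A1=float(a1), t1=float(t1),
            rss=rss, n_bins=len(centers), dof=dof,
        )
    y0, a1, t1, a2, t2 = popt
    if t1 > t2:  # enforce fast-first ordering
        a1, t1, a2, t2 = a2, t2, a1, t1
    if t1 == t2:  # degenerate double collapses to single; nudge for validity
        t2 = t1 * (1 + 1e-9)
    return DwellFit(
        model="double", y0=float(y0), x0=x0, A1=float(a1), t1=float(t1),
        A2=float(a2), t2=float(t2), rss=rss, n_bins=len(centers), dof=dof,
    )


def f_test(fit_single: DwellFit, fit_double: DwellFit) -> tuple[float, float]:
    """Nested-model F-test: is the double exponential significantly better?

    F = [(RSS_s - RSS_d) / (dof_s - dof_d)] / (RSS_d / dof_d), with p from
    the F distribution on (dof_s - dof_d, dof_d) degrees of freedom.  A
    perfect double fit (RSS 0) reports F = inf, p = 0.
    """
    if fit_single.n_bins != fit_double.n_bins:
        raise EstimationError("f_test: fits must share the same histogram")
    d1 = fit_single.dof - fit_double.dof
    d2 = fit_double.dof
    if d1 <= 0 or d2 <= 0:
        raise EstimationError("f_test: nonpositive degrees of freedom")
    if fit_double.rss == 0.0:
        return float("inf"), 0.0
    num = max(fit_single.rss - fit_double.rss, 0.0) / d1
    den = fit_double.rss / d2
    f = num / den
    p = float(stats.f.sf(f, d1, d2))
    return f, p
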