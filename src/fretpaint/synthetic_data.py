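"""Kinetic Monte-Carlo simulator for FRET-PAINT intensity traces.

The physical picture: a surface-immobilized donor-labeled construct carries
``n_gtracts`` potential binding sites; an acceptor-labeled probe in solution
binds transiently.  While unbound the apparent FRET sits at the donor-only
leakage baseline ``e_do``; a binding event at site *i* raises it to
``e_do + (1 - e_do) * site_fret_levels[i]`` for an exponential-mixture dwell.
Binding is an alternating-renewal process (at most one probe bound at a
time, matching the low-imager-concentration regime of the assay).  Donor
photobleaching is a single exponential hazard that drops both channels to
background.  The camera integrates over frames, so the per-frame apparent
FRET is the time average of the instantaneous signal — sub-frame events are
attenuated exactly as a real camera would attenuate them.

Every simulated trace comes with its :class:`GroundTruth`, so downstream
stages (step detection, event calling, kinetics, frequency statistics) can
be validated by parameter recovery.

RNG discipline: one master seed; molecule *i* uses the ``i``-th child of
``numpy.random.SeedSequence(seed)``.  Per molecule the draw order is fixed:
(1) bleach time, (2) the alternating sequence (unbound gap, site index,
dwell), (3) donor noise, (4) acceptor noise.  Fixed (seed, n_molecules)
therefore reproduces a dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fretpaint.errors import ConfigurationError
from fretpaint.trace_io import ConstructDataset, IntensityTrace


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one simulated construct.

    Defaults emulate the published assay conditions: 100 ms frames, 2000
    frame movies, fast dwell component ~0.7 s and slow component ~5 s in
    roughly equal proportion, ~1 s^-1 total intensity scale with noise giving
    a FRET standard deviation of ~0.05, and a leakage baseline e_do ~ 0.14
    (the value implied by the 0.25 raw / 0.13 corrected threshold pair).
    """

    n_gtracts: int = 4
    k_on: float = 3.2e-3  # per-molecule binding rate while unbound, s^-1
    p_short: float = 0.5
    t_short: float = 0.7  # s
    t_long: float = 5.0  # s
    site_fret_levels: list[float] | None = None
    site_weights: list[float] | None = None
    e_do: float = 0.1379
    total_intensity: float = 1000.0
    noise_sigma: float = 35.0  # per channel, same units as total_intensity
    bleach_rate: float = 1.0 / 150.0  # s^-1; 0 disables bleaching
    frame_time: float = 0.1  # s
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_fret_levels is None:
            # sites spread evenly over the resolvable FRET range; site 0 is
            # nearest the donor (highest FRET)
            self.site_fret_levels = list(
                np.linspace(0.9, 0.2, self.n_gtracts)
            )
        if self.site_weights is None:
            self.site_weights = [1.0 / self.n_gtracts] * self.n_gtracts
        self.validate()

    def validate(self) -> None:
        def bad(msg: str) -> ConfigurationError:
            return ConfigurationError(f"invalid SimulationConfig: {msg}")

        if self.n_gtracts < 1:
            raise bad("n_gtracts must be >= 1")
        if not (0 <= self.e_do < 1):
            raise bad("e_do must lie in [0, 1)")
        if len(self.site_fret_levels) != self.n_gtracts:
            raise bad("len(site_fret_levels) != n_gtracts")
        if len(self.site_weights) != self.n_gtracts:
            raise bad("len(site_weights) != n_gtracts")
        if any(not (0 <= e <= 1) for e in self.site_fret_levels):
            raise bad("site_fret_levels must lie in [0, 1]")
        if any(w < 0 for w in self.site_weights):
            raise bad("site_weights must be nonnegative")
        if not np.isclose(sum(self.site_weights), 1.0):
            raise bad("site_weights must sum to 1")
        if self.k_on < 0:
            raise bad("k_on must be >= 0")
        for name in ("t_short", "t_long", "frame_time", "total_intensity"):
            if not getattr(self, name) > 0:
                raise bad(f"{name} must be > 0")
        if not self.t_short < self.t_long:
            raise bad("t_short must be < t_long")
        if not (0 <= self.p_short <= 1):
            raise bad("p_short must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise bad("noise_sigma must be >= 0")
        if self.bleach_rate < 0:
            raise bad("bleach_rate must be >= 0")
        if self.n_frames < 1:
            raise bad("n_frames must be >= 1")


@dataclass
class GroundTruth:
    """What the simulator actually did to one molecule.

    ``events`` holds ``(start_s, dwell_s, site_index, e_site)`` tuples sorted
    by start time, non-overlapping, all starting before ``bleach_time``.
    """

    molecule_id: str
    events: list[tuple[float, float, int, float]] = field(default_factory=list)
    bleach_time: float | None = None
    effective_on_rate: float = 0.0

    @property
    def observation_time_s(self) -> float:
        """Censored observation time given the trace length is set by caller."""
        return self.bleach_time if self.bleach_time is not None else np.inf

    def observation_time(self, t_end: float) -> float:
        t = t_end if self.bleach_time is None else min(self.bleach_time, t_end)
        return t

    def n_events_with_dwell(self, min_dwell: float) -> int:
        return sum(1 for (_, d, _, _) in self.events if d >= min_dwell)


def _draw_schedule(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[tuple[float, float, int, float]], float | None]:
    """Draw bleach time and the alternating bound/unbound event schedule."""
    t_end = config.n_frames * config.frame_time
    bleach = None
    if config.bleach_rate > 0:
        bleach = float(rng.exponential(1.0 / config.bleach_rate))
        if bleach >= t_end:
            bleach = None
    t_stop = t_end if bleach is None else bleach

    events: list[tuple[float, float, int, float]] = []
    t = 0.0
    if config.k_on > 0:
        weights = np.asarray(config.site_weights, dtype=float)
        levels = np.asarray(config.site_fret_levels, dtype=float)
        while True:
            gap = rng.exponential(1.0 / config.k_on)
            start = t + gap
            if start >= t_stop:
                break
            site = int(rng.choice(config.n_gtracts, p=weights))
            scale = config.t_short if rng.random() < config.p_short else config.t_long
            dwell = float(rng.exponential(scale))
            events.append((float(start), dwell, site, float(levels[site])))
            t = start + dwell
    return events, bleach


def render_trace(
    config: SimulationConfig,
    molecule_id: str,
    events: list[tuple[float, float, int, float]],
    bleach_time: float | None,
    noise_rng: np.random.Generator | None = None,
) -> IntensityTrace:
    """Render a given event schedule to a frame-integrated intensity trace.

    Exposed separately from :func:`simulate_trace` so tests can force exact
    event schedules (e.g. a single noiseless 10-frame event).
    """
    n, dt = config.n_frames, config.frame_time
    t_end = n * dt
    t_stop = t_end if bleach_time is None else min(bleach_time, t_end)

    # per-frame fraction of the frame spent alive (pre-bleach)
    frame_starts = np.arange(n) * dt
    alive = np.clip((t_stop - frame_starts) / dt, 0.0, 1.0)

    # integral of instantaneous FRET over the alive part of each frame,
    # expressed as a fraction of the frame
    e_int = config.e_do * alive.copy()
    for start, dwell, _site, e_site in events:
        lo, hi = start, min(start + dwell, t_stop)
        if hi <= lo:
            continue
        f_lo, f_hi = int(lo // dt), min(int(np.ceil(hi / dt)), n)
        idx = np.arange(f_lo, f_hi)
        overlap = (
            np.minimum(hi, (idx + 1) * dt) - np.maximum(lo, idx * dt)
        ) / dt
        e_int[idx] += (1.0 - config.e_do) * e_site * overlap

    i_a = config.total_intensity * e_int
    i_d = config.total_intensity * (alive - e_int)
    if config.noise_sigma > 0:
        if noise_rng is None:
            noise_rng = np.random.default_rng(config.seed)
        i_d = i_d + noise_rng.normal(0.0, config.noise_sigma, n)
        i_a = i_a + noise_rng.normal(0.0, config.noise_sigma, n)
    return IntensityTrace(
        molecule_id=molecule_id, frame_time=dt, i_donor=i_d, i_acceptor=i_a
    )


def simulate_trace(
    config: SimulationConfig,
    molecule_id: str = "mol0000",
    rng: np.random.Generator | None = None,
) -> tuple[IntensityTrace, GroundTruth]:
    """Simulate one molecule; returns the trace and its ground truth."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    events, bleach = _draw_schedule(config, rng)
    trace = render_trace(config, molecule_id, events, bleach, noise_rng=rng)
    truth = GroundTruth(
        molecule_id=molecule_id,
        events=events,
        bleach_time=bleach,
        effective_on_rate=config.k_on,
    )
    return trace, truth


def simulate_dataset(
    config: SimulationConfig, n_molecules: int
) -> tuple[ConstructDataset, list[GroundTruth]]:
    """Simulate ``n_molecules`` independent traces for one construct.

    Deterministic for fixed (config.seed, n_molecules): molecule *i* always
    consumes the *i*-th child stream of the master seed.
    """
    if n_molecules < 1:
        raise ConfigurationError("n_molecules must be >= 1")
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(n_molecules)
    width = max(4, len(str(n_molecules - 1)))
    traces, truths = [], []
    for i in range(n_molecules):
        mol_id = f"mol{i:0{width}d}"
        rng = np.random.default_rng(children[i])
        trace, truth = simulate_trace(config, mol_id, rng=rng)
        traces.append(trace)
        truths.append(truth)
    dataset = ConstructDataset(
        construct_label=f"{config.n_gtracts}G-Tract",
        n_gtracts=config.n_gtracts,
        frame_time=config.frame_time,
        traces=traces,
    )
    return dataset, truths


def length_accessibility_profile(
    n_gtracts: int, per_tract_rate: float, compaction: float
) -> float:
    """Scenario generator for a length-dependent compaction trend.

    Returns ``k_on = n * r * (1 - c)^max(n - 4, 0)``: with zero compaction
    the total rate grows linearly with the number of sites; with positive
    compaction the per-site rate shrinks with length, emulating reduced
    accessibility of longer overhangs.  A scenario knob, not a mechanism.
    """
    if n_gtracts < 1:
        raise ConfigurationError("n_gtracts must be >= 1")
    if not (0 <= compaction <= 1):
        raise ConfigurationError("compaction must lie in [0, 1]")
    exponent = max(n_gtracts - 4, 0)
    return n_gtracts * per_tract_rate * (1.0 - compaction) ** exponent


def ground_truth_table(truths: list[GroundTruth]) -> "pd.DataFrame":
    """Sidecar table (one row per event) for export next to a dataset."""
    import pandas as pd

    rows = [
        {
            "molecule_id": gt.molecule_id,
            "start_s": s,
            "dwell_s": d,
            "site_index": site,
            "e_site": e,
        }
        for gt in truths
        for (s, d, site, e) in gt.events
    ]
    return pd.DataFrame(rows, columns=["molecule_id", "start_s", "dwell_s", "site_index", "e_site"])
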