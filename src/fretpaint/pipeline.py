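"""End-to-end orchestration: intensity traces in, binding statistics out.

``analyze_dataset`` runs the full chain on one construct dataset:

1. photobleach detection → per-molecule observation times and backgrounds
2. FRET calculation (raw)
3. step-fit idealization of each trace
4. donor-only peak estimation from zero-event molecules (screened with the
   raw-scale threshold) and linear DO correction of the step levels
5. event calling on corrected levels (threshold 0.13, >= 4 frames)
6. dwell-time histograms + single/double exponential fits + F-test
7. binding frequency with molecule-level bootstrap; long-dwell filtered
   frequency (tau > 2 t1)
8. FRET population histogram and positional (segment) statistics

All thresholds live in :class:`PipelineConfig`, whose defaults are the
assay's published operating point (0.13 corrected threshold, 4-frame
minimum, 100 ms frames, 20 000 bootstrap sets, 0.2-wide FRET segments,
1-7 s contour window).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fretpaint import __version__ as _pkg_version
from fretpaint.errors import EstimationError, FretPaintError
from fretpaint.event_calling import (
    BindingEvent,
    MoleculeRecord,
    build_molecule_records,
    call_events,
    detect_bleach,
    events_table,
    records_table,
)
from fretpaint.fret_processing import (
    DonorOnlyModel,
    FretHistogram,
    apply_do_correction,
    compute_fret,
    estimate_donor_only,
    low_high_ratio,
    population_histogram,
)
from fretpaint.frequency_stats import (
    FrequencyEstimate,
    bootstrap_frequency,
    filtered_frequency,
    per_gtract_frequency,
)
from fretpaint.dwell_kinetics import DwellFit, dwell_histogram, f_test, fit_decay
from fretpaint.stepfinder import StepFit, fit_steps
from fretpaint.synthetic_data import SimulationConfig, ground_truth_table, simulate_dataset
from fretpaint.topography import (
    SegmentStats,
    one_way_anova,
    segment_dwell_stats,
    segment_frequencies,
)
from fretpaint.trace_io import ConstructDataset, read_dataset, write_dataset


@dataclass
class PipelineConfig:
    """Analysis operating point; defaults are the published constants."""

    fret_threshold: float = 0.13  # corrected-scale event threshold
    raw_screen_threshold: float = 0.25  # raw-scale threshold for DO screening
    min_event_frames: int = 4  # "4 consecutive points" = tau >= 300 ms
    frame_time: float = 0.1  # s (simulation default; data carries its own)
    dwell_bin_width: float = 0.3  # s
    contour_dwell_min: float = 1.0  # s
    contour_dwell_max: float = 7.0  # s
    n_boot: int = 20000
    segment_n_boot: int = 2000
    seed: int = 0
    histogram_bin_width: float = 0.02
    # step finder: threshold mode is the robust default for event-sparse
    # traces; counter_fit is available for step-rich data
    step_mode: str = "threshold"
    step_min_segment: int = 2
    step_gain_threshold: float | None = None
    step_max_steps: int | None = None
    # bleach detector
    bleach_n_sd: float = 3.0
    bleach_min_run: int = 10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Everything `analyze_dataset` computes for one construct."""

    construct_label: str
    n_gtracts: int
    frame_time: float
    records: list[MoleculeRecord]
    do_model: DonorOnlyModel | None
    frequency: FrequencyEstimate
    frequency_per_gtract: float
    frequency_filtered: FrequencyEstimate | None
    dwell_fit_single: DwellFit | None
    dwell_fit_double: DwellFit | None
    f_statistic: float | None
    f_pvalue: float | None
    histogram: FretHistogram | None
    low_high: float | None
    segment_dwells: list[SegmentStats]
    segment_freqs: list[SegmentStats]
    dwell_anova: tuple[float, float] | None
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def all_events(self) -> list[BindingEvent]:
        return [ev for rec in self.records for ev in rec.events]


def _fill_invalid(e: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Interpolate over invalid frames so step-fit indices stay frame-aligned."""
    if valid.all():
        return e
    out = e.copy()
    idx = np.arange(len(e))
    if not valid.any():
        return np.zeros_like(e)
    out[~valid] = np.interp(idx[~valid], idx[valid], e[valid])
    return out


def _estimate_backgrounds(trace, bleach_frame: int | None) -> tuple[float, float]:
    """Per-channel background: post-bleach mean when a bleach is seen.

    After donor bleaching both channels sit at the dark level, the cleanest
    background sample a trace offers.  Without a bleach the traces are
    assumed background-subtracted upstream (as the movie-processing stage
    does) and zero is used.
    """
    if bleach_frame is not None and trace.n_frames - bleach_frame >= 10:
        return (
            float(np.mean(trace.i_donor[bleach_frame:])),
            float(np.mean(trace.i_acceptor[bleach_frame:])),
        )
    return 0.0, 0.0


def analyze_dataset(dataset: ConstructDataset, config: PipelineConfig | None = None) -> AnalysisReport:
    """Run the full analysis chain on one construct dataset."""
    if config is None:
        config = PipelineConfig()
    if dataset.n_molecules == 0:
        raise EstimationError("analyze_dataset: dataset holds no traces")

    traces = dataset.sorted_traces()
    dt = dataset.frame_time
    excluded: list[tuple[str, str]] = []

    frets, fits, bleaches = [], [], []
    keep_traces = []
    for trace in traces:
        bleach = detect_bleach(
            trace, n_sd=config.bleach_n_sd, min_run=config.bleach_min_run
        )
        bg_d, bg_a = _estimate_backgrounds(trace, bleach)
        fret = compute_fret(trace, bg_d, bg_a)
        vf = bleach if bleach is not None else trace.n_frames
        fret.valid_frames = max(vf, 1)
        valid_slice = fret.valid[: fret.valid_frames]
        if not valid_slice.any():
            excluded.append((trace.molecule_id, "no valid frames before bleach"))
            continue
        signal = _fill_invalid(
            fret.e_raw[: fret.valid_frames], valid_slice
        )
        fit = fit_steps(
            signal,
            min_segment=config.step_min_segment,
            stop_mode=config.step_mode,
            gain_threshold=config.step_gain_threshold,
            max_steps=config.step_max_steps,
        )
        keep_traces.append(trace)
        frets.append(fret)
        fits.append(fit)
        bleaches.append(bleach)
    if not keep_traces:
        raise EstimationError("analyze_dataset: every trace was excluded")

    # donor-only estimation uses a provisional raw-scale event screen
    provisional_counts = [
        len(
            call_events(
                fit, dt,
                threshold=config.raw_screen_threshold,
                min_frames=config.min_event_frames,
                molecule_id=fret.molecule_id,
            )
        )
        for fit, fret in zip(fits, frets)
    ]
    try:
        do_model = estimate_donor_only(
            frets, provisional_counts, fallback_threshold=config.raw_screen_threshold
        )
    except EstimationError:
        do_model = None

    events_per_trace: list[list[BindingEvent]] = []
    for fret, fit in zip(frets, fits):
        if do_model is not None:
            levels = np.asarray(
                apply_do_correction(fit.levels, do_model), dtype=float
            )
            fret.e_corrected = np.asarray(
                apply_do_correction(fret.e_raw, do_model), dtype=float
            )
            corrected_fit = StepFit(
                breakpoints=fit.breakpoints,
                levels=levels,
                chi2=fit.chi2 / (1.0 - do_model.e_do) ** 2,
                n_frames=fit.n_frames,
            )
            threshold = config.fret_threshold
        else:
            corrected_fit = fit
            threshold = config.raw_screen_threshold
        events_per_trace.append(
            call_events(
                corrected_fit, dt,
                threshold=threshold,
                min_frames=config.min_event_frames,
                molecule_id=fret.molecule_id,
            )
        )

    subset = ConstructDataset(
        construct_label=dataset.construct_label,
        n_gtracts=dataset.n_gtracts,
        frame_time=dt,
        traces=keep_traces,
    )
    records = build_molecule_records(subset, events_per_trace, bleaches)
    frequency = bootstrap_frequency(records, n_boot=config.n_boot, seed=config.seed)
    f_per_gtract = per_gtract_frequency(frequency.f_ave, dataset.n_gtracts)

    taus = np.array([ev.tau for rec in records for ev in rec.events])
    t_min = (config.min_event_frames - 1) * dt
    fit_single = fit_double = None
    f_stat = f_p = None
    freq_filtered = None
    if len(taus) > 0:
        hist = dwell_histogram(taus, bin_width=config.dwell_bin_width, t_min=t_min)
        try:
            fit_single = fit_decay(hist, "single")
            fit_double = fit_decay(hist, "double")
            f_stat, f_p = f_test(fit_single, fit_double)
        except (EstimationError, FretPaintError):
            pass
        if fit_double is not None:
            freq_filtered = filtered_frequency(
                records, fit_double.t1, n_boot=config.n_boot, seed=config.seed
            )

    histogram = low_high = None
    try:
        histogram = population_histogram(records, bin_width=config.histogram_bin_width)
        low_high = low_high_ratio(histogram, split=0.5)
    except EstimationError:
        pass

    all_events = [ev for rec in records for ev in rec.events]
    seg_dwells = segment_dwell_stats(all_events)
    seg_freqs = (
        segment_frequencies(records, n_boot=config.segment_n_boot, seed=config.seed)
        if all_events
        else [SegmentStats(segment_index=i, n_events=0) for i in range(5)]
    )
    dwell_groups = []
    for stat in seg_dwells:
        if stat.n_events >= 2:
            dwell_groups.append(
                [ev.tau for ev in all_events if _in_segment(ev, stat.segment_index)]
            )
    anova = None
    if len(dwell_groups) >= 2:
        try:
            anova = one_way_anova(dwell_groups)
        except EstimationError:
            anova = None

    return AnalysisReport(
        construct_label=dataset.construct_label,
        n_gtracts=dataset.n_gtracts,
        frame_time=dt,
        records=records,
        do_model=do_model,
        frequency=frequency,
        frequency_per_gtract=f_per_gtract,
        frequency_filtered=freq_filtered,
        dwell_fit_single=fit_single,
        dwell_fit_double=fit_double,
        f_statistic=f_stat,
        f_pvalue=f_p,
        histogram=histogram,
        low_high=low_high,
        segment_dwells=seg_dwells,
        segment_freqs=seg_freqs,
        dwell_anova=anova,
        excluded=excluded,
    )


def _in_segment(ev: BindingEvent, seg: int) -> bool:
    from fretpaint.topography import assign_segment

    return 0.0 <= ev.e_mean <= 1.0 and assign_segment(ev.e_mean) == seg


def run_analyze(
    data_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Read a dataset, analyze it, and (optionally) write the report bundle."""
    if config is None:
        config = PipelineConfig()
    dataset = read_dataset(data_path)
    report = analyze_dataset(dataset, config)
    if out_dir is not None:
        write_report(report, config, out_dir)
    return report


def write_report(report: AnalysisReport, config: PipelineConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_table(report.records).to_csv(out / "records.csv", index=False)
    events_table(report.records, report.frame_time).to_csv(out / "events.csv", index=False)
    freq = {
        "construct": report.construct_label,
        "n_gtracts": report.n_gtracts,
        "frequency": report.frequency.to_dict(),
        "frequency_per_gtract": report.frequency_per_gtract,
        "frequency_filtered": (
            report.frequency_filtered.to_dict() if report.frequency_filtered else None
        ),
    }
    (out / "frequency.json").write_text(json.dumps(freq, indent=2))
    dwell = {
        "single": report.dwell_fit_single.to_dict() if report.dwell_fit_single else None,
        "double": report.dwell_fit_double.to_dict() if report.dwell_fit_double else None,
        "F": report.f_statistic,
        "p": report.f_pvalue,
    }
    (out / "dwell_fits.json").write_text(json.dumps(dwell, indent=2))
    if report.histogram is not None:
        import pandas as pd

        edges = report.histogram.bin_edges
        pd.DataFrame(
            {
                "bin_low": edges[:-1],
                "bin_high": edges[1:],
                "percent": report.histogram.percent_per_bin,
            }
        ).to_csv(out / "fret_histogram.csv", index=False)
    import pandas as pd

    seg_rows = []
    for d, f in zip(report.segment_dwells, report.segment_freqs):
        seg_rows.append(
            {
                "segment_index": d.segment_index,
                "n_events": d.n_events,
                "mean_dwell_s": d.mean_dwell,
                "sem_dwell_s": d.sem_dwell,
                "frequency_per_s": f.frequency,
                "freq_sigma_per_s": f.freq_sigma,
            }
        )
    pd.DataFrame(seg_rows).to_csv(out / "segments.csv", index=False)
    manifest = {
        "package_version": _pkg_version,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "construct": report.construct_label,
        "n_molecules": len(report.records),
        "n_events": sum(r.n_events for r in report.records),
        "n_excluded": len(report.excluded),
        "excluded": report.excluded,
        "donor_only": (
            {
                "e_do": report.do_model.e_do,
                "sigma_do": report.do_model.sigma_do,
                "n_molecules_used": report.do_model.n_molecules_used,
            }
            if report.do_model
            else None
        ),
        "low_high_ratio": report.low_high,
        "dwell_anova": report.dwell_anova,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))


def run_simulate(
    sim_config: SimulationConfig,
    n_molecules: int,
    out_path: str | Path,
) -> tuple[ConstructDataset, list]:
    """Simulate a dataset and write it plus ground-truth sidecar + manifest."""
    dataset, truths = simulate_dataset(sim_config, n_molecules)
    out = Path(out_path)
    write_dataset(dataset, out)
    ground_truth_table(truths).to_csv(out / "ground_truth.csv", index=False)
    (out / "simulation_config.json").write_text(
        json.dumps(dataclasses.asdict(sim_config), indent=2)
    )
    return dataset, truths
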