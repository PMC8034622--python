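"""Containers and disk I/O for intensity traces and construct datasets.

A *dataset* is one construct (one G-Tract count) worth of per-molecule
donor/acceptor intensity traces recorded at a shared frame time.  On disk a
dataset is a directory::

    <path>/
        metadata.json          # construct_label, n_gtracts, frame_time
        traces.csv             # bundled form: molecule_id, frame, i_donor, i_acceptor
        # -- or --
        traces/<molecule_id>.csv   # per-molecule form: frame, i_donor, i_acceptor

Frames are indexed from 0; the time of frame ``i`` is ``i * frame_time``.
All numbers round-trip at full double precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fretpaint.errors import FormatError

_TRACE_COLUMNS = ["frame", "i_donor", "i_acceptor"]

# one file per molecule is convenient for inspection but slow for thousands
# of molecules; above this count write_dataset switches to the bundled CSV
_BUNDLE_ABOVE = 200


@dataclass
class IntensityTrace:
    """One molecule's donor and acceptor intensity time series.

    Parameters
    ----------
    molecule_id : str
        Unique identifier within its dataset.
    frame_time : float
        Seconds per frame (camera integration time), > 0.
    i_donor, i_acceptor : ndarray
        Background-subtracted intensities in arbitrary units, equal length.
    """

    molecule_id: str
    frame_time: float
    i_donor: np.ndarray
    i_acceptor: np.ndarray

    def __post_init__(self) -> None:
        self.i_donor = np.asarray(self.i_donor, dtype=float)
        self.i_acceptor = np.asarray(self.i_acceptor, dtype=float)
        if self.i_donor.ndim != 1 or self.i_acceptor.ndim != 1:
            raise FormatError(f"trace {self.molecule_id}: channels must be 1-D")
        if len(self.i_donor) != len(self.i_acceptor):
            raise FormatError(
                f"trace {self.molecule_id}: channel length mismatch "
                f"(i_donor={len(self.i_donor)}, i_acceptor={len(self.i_acceptor)})"
            )
        if len(self.i_donor) < 1:
            raise FormatError(f"trace {self.molecule_id}: empty trace")
        if not self.frame_time > 0:
            raise FormatError(f"trace {self.molecule_id}: nonpositive frame_time")

    @property
    def n_frames(self) -> int:
        return len(self.i_donor)

    @property
    def total(self) -> np.ndarray:
        """Total intensity I_D + I_A per frame."""
        return self.i_donor + self.i_acceptor


@dataclass
class ConstructDataset:
    """All traces recorded for one construct (fixed G-Tract count)."""

    construct_label: str
    n_gtracts: int
    frame_time: float
    traces: list[IntensityTrace] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_gtracts < 1:
            raise FormatError(f"dataset {self.construct_label}: n_gtracts < 1")
        if not self.frame_time > 0:
            raise FormatError(f"dataset {self.construct_label}: nonpositive frame_time")
        for tr in self.traces:
            if not np.isclose(tr.frame_time, self.frame_time):
                raise FormatError(
                    f"dataset {self.construct_label}: trace {tr.molecule_id} "
                    f"frame_time {tr.frame_time} != dataset frame_time {self.frame_time}"
                )

    @property
    def n_molecules(self) -> int:
        return len(self.traces)

    def sorted_traces(self) -> list[IntensityTrace]:
        return sorted(self.traces, key=lambda t: t.molecule_id)


def write_dataset(dataset: ConstructDataset, path: str | Path, bundle: bool | None = None) -> None:
    """Write *dataset* to directory *path* (created if missing).

    ``bundle=None`` chooses the layout automatically: per-molecule CSV files
    for small datasets, a single bundled ``traces.csv`` for large ones.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "construct_label": dataset.construct_label,
        "n_gtracts": dataset.n_gtracts,
        "frame_time": dataset.frame_time,
        "n_molecules": dataset.n_molecules,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))
    if bundle is None:
        bundle = dataset.n_molecules > _BUNDLE_ABOVE
    traces = dataset.sorted_traces()
    if bundle:
        frames = []
        for tr in traces:
            frames.append(
                pd.DataFrame(
                    {
                        "molecule_id": tr.molecule_id,
                        "frame": np.arange(tr.n_frames),
                        "i_donor": tr.i_donor,
                        "i_acceptor": tr.i_acceptor,
                    }
                )
            )
        out = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["molecule_id", *_TRACE_COLUMNS])
        )
        out.to_csv(path / "traces.csv", index=False, float_format="%.17g")
    else:
        tdir = path / "traces"
        tdir.mkdir(exist_ok=True)
        for tr in traces:
            df = pd.DataFrame(
                {
                    "frame": np.arange(tr.n_frames),
                    "i_donor": tr.i_donor,
                    "i_acceptor": tr.i_acceptor,
                }
            )
            df.to_csv(tdir / f"{tr.molecule_id}.csv", index=False, float_format="%.17g")


def _require_columns(df: pd.DataFrame, columns: list[str], source: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing column(s) {missing}")


def read_dataset(path: str | Path) -> ConstructDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Molecules are returned sorted by ``molecule_id``.  Malformed input
    raises :class:`~fretpaint.errors.FormatError` naming the file and field.
    """
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise FormatError(f"{meta_path}: metadata file not found")
    meta = json.loads(meta_path.read_text())
    for key in ("construct_label", "n_gtracts", "frame_time"):
        if key not in meta:
            raise FormatError(f"{meta_path}: missing field '{key}'")
    frame_time = float(meta["frame_time"])
    if not frame_time > 0:
        raise FormatError(f"{meta_path}: nonpositive frame_time")

    traces: list[IntensityTrace] = []
    bundle_path = path / "traces.csv"
    trace_dir = path / "traces"
    if bundle_path.exists():
        df = pd.read_csv(bundle_path, dtype={"molecule_id": str}, float_precision="round_trip")
        if len(df):
            _require_columns(df, ["molecule_id", *_TRACE_COLUMNS], str(bundle_path))
            for mol_id, grp in df.groupby("molecule_id", sort=True):
                grp = grp.sort_values("frame")
                traces.append(
                    IntensityTrace(
                        molecule_id=str(mol_id),
                        frame_time=frame_time,
                        i_donor=grp["i_donor"].to_numpy(),
                        i_acceptor=grp["i_acceptor"].to_numpy(),
                    )
                )
    elif trace_dir.exists():
        for csv_path in sorted(trace_dir.glob("*.csv")):
            df = pd.read_csv(csv_path, float_precision="round_trip")
            _require_columns(df, _TRACE_COLUMNS, str(csv_path))
            df = df.sort_values("frame")
            traces.append(
                IntensityTrace(
                    molecule_id=csv_path.stem,
                    frame_time=frame_time,
                    i_donor=df["i_donor"].to_numpy(),
                    i_acceptor=df["i_acceptor"].to_numpy(),
                )
            )
    # neither present: dataset legitimately holds zero traces

    traces.sort(key=lambda t: t.molecule_id)
    return ConstructDataset(
        construct_label=str(meta["construct_label"]),
        n_gtracts=int(meta["n_gtracts"]),
        frame_time=frame_time,
        traces=traces,
    )
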