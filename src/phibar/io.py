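"""Core domain types and file I/O.

The package operates on continuous multichannel recordings (channels x
samples, amplitudes in microvolts), an electrode montage (3-D positions in
cm), and epoched views of a recording.  Recordings are read either from EDF
files (via MNE) or from delimited text matrices whose sampling rate lives in
a JSON sidecar.  Results are written as long-format CSV tables plus a JSON
run summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Unrecognized or malformed input file format."""


class ConfigurationError(ValueError):
    """Missing or inconsistent configuration (e.g. no sampling rate)."""


class IngestionError(ValueError):
    """Data failed validation on ingestion (NaN/Inf, duplicated labels...)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class TimeSeriesMatrix:
    """A channels x samples block of continuous data.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes, conventionally in microvolts.  Never rescaled by the
        package; every downstream quantity is scale-covariant or
        scale-invariant.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel identifiers, one per row.
    state_label : str, optional
        Condition tag (e.g. "baseline", "anesthesia").
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    state_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise IngestionError("data must be 2-D (channels x samples)")
        if not self.fs > 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise IngestionError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise IngestionError("channel labels must be unique")
        bad = ~np.isfinite(self.data).all(axis=1)
        if bad.any():
            names = [l for l, b in zip(self.channel_labels, bad) if b]
            raise IngestionError(f"non-finite samples in channel(s): {names}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.data.shape[1] / self.fs

    def select(self, labels: list[str]) -> "TimeSeriesMatrix":
        """Restrict to ``labels`` (in the order given)."""
        idx = [self.channel_labels.index(l) for l in labels]
        return TimeSeriesMatrix(self.data[idx], self.fs, list(labels), self.state_label)

    def copy_with(self, data: np.ndarray) -> "TimeSeriesMatrix":
        return TimeSeriesMatrix(data, self.fs, list(self.channel_labels), self.state_label)


@dataclass
class Montage:
    """Electrode positions: one 3-D coordinate (cm) per channel label."""

    channel_labels: list[str]
    coordinates: np.ndarray  # (n, 3) in cm

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.shape != (len(self.channel_labels), 3):
            raise IngestionError("coordinates must be (n_channels, 3)")
        d = self.distance_matrix()
        off = d[~np.eye(len(d), dtype=bool)]
        if len(off) and off.min() <= 0:
            raise IngestionError("montage contains coincident electrodes")

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances in cm."""
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((diff ** 2).sum(-1))

    def subset(self, labels: list[str]) -> "Montage":
        idx = [self.channel_labels.index(l) for l in labels]
        return Montage(list(labels), self.coordinates[idx])


@dataclass
class EpochSet:
    """An ordered list of equal-length epochs sharing fs and channel set."""

    epochs: list[TimeSeriesMatrix]
    epoch_length: float
    band: str | None = None

    def __post_init__(self) -> None:
        if not self.epochs:
            raise IngestionError("EpochSet must contain at least one epoch")
        first = self.epochs[0]
        for ep in self.epochs:
            if ep.fs != first.fs or ep.channel_labels != first.channel_labels:
                raise IngestionError("all epochs must share fs and channel set")
            if ep.n_samples != int(round(self.epoch_length * ep.fs)):
                raise IngestionError("epoch_length * fs must equal samples per epoch")

    @property
    def fs(self) -> float:
        return self.epochs[0].fs

    @property
    def channel_labels(self) -> list[str]:
        return self.epochs[0].channel_labels

    @property
    def n_channels(self) -> int:
        return self.epochs[0].n_channels

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def data3d(self) -> np.ndarray:
        """Stack to (n_epochs, n_channels, samples_per_epoch)."""
        return np.stack([ep.data for ep in self.epochs])

    def map(self, fn) -> "EpochSet":
        """Apply ``fn`` to each epoch's data, keeping metadata."""
        return EpochSet([ep.copy_with(fn(ep.data)) for ep in self.epochs],
                        self.epoch_length, self.band)


#: registry of allowed metric names in result tables
METRIC_REGISTRY = frozenset({
    "phi_bar", "phi_bar_mean", "phi_bar_surrogate", "phi_regional",
    "wpli_degree", "avg_degree", "long_range_degree", "n_modules",
    "modularity_q", "rel_power", "bsr",
    "rel_phi", "rel_degree", "sim_phi_topo", "sim_degree_topo", "descriptor_area",
})

RESULT_COLUMNS = ["subject", "state", "band", "metric", "channel", "value"]


@dataclass
class ResultTable:
    """Long-format result rows; ``channel`` is empty for global metrics."""

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RESULT_COLUMNS))

    def __post_init__(self) -> None:
        missing = set(RESULT_COLUMNS) - set(self.rows.columns)
        if missing:
            raise IngestionError(f"result table missing columns: {sorted(missing)}")
        bad = set(self.rows["metric"]) - METRIC_REGISTRY
        if bad:
            raise IngestionError(f"unknown metric name(s): {sorted(bad)}")
        self.rows = self.rows[RESULT_COLUMNS].reset_index(drop=True)

    def add(self, subject, state, band, metric, value, channel="") -> None:
        if metric not in METRIC_REGISTRY:
            raise IngestionError(f"unknown metric name: {metric}")
        row = pd.DataFrame([[subject, state, band, metric, channel, float(value)]],
                           columns=RESULT_COLUMNS)
        self.rows = row if self.rows.empty else pd.concat([self.rows, row],
                                                          ignore_index=True)


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def read_recording(path, format_hint: str | None = None,
                   fs: float | None = None) -> TimeSeriesMatrix:
    """Read a multichannel recording from EDF or a delimited matrix.

    Delimited files are channels-in-rows with the channel label in the first
    column; the sampling rate comes from a JSON sidecar ``<stem>.json``
    (key ``fs``) unless passed explicitly.  Amplitudes are passed through
    unchanged (EDF channels are read in their native physical unit, uV for
    EEG).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return _read_edf(path)
    if fmt in ("csv", "tsv", "txt"):
        return _read_delimited(path, sep="," if fmt == "csv" else "\t", fs=fs)
    raise FormatError(f"unknown recording format: {fmt!r}")


def _read_edf(path: Path) -> TimeSeriesMatrix:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    return TimeSeriesMatrix(data, float(raw.info["sfreq"]), list(raw.ch_names))


def _read_delimited(path: Path, sep: str, fs: float | None) -> TimeSeriesMatrix:
    if fs is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ConfigurationError(
                f"no sampling rate: pass fs= or provide sidecar {sidecar.name}"
            )
        meta = json.loads(sidecar.read_text())
        if "fs" not in meta:
            raise ConfigurationError(f"sidecar {sidecar.name} lacks 'fs'")
        fs = float(meta["fs"])
    df = pd.read_csv(path, sep=sep, header=None, float_precision="round_trip")
    labels = df.iloc[:, 0].astype(str).tolist()
    data = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return TimeSeriesMatrix(data, fs, labels)


def write_recording(ts: TimeSeriesMatrix, path) -> None:
    """Write a delimited recording plus its JSON sidecar (lossless floats)."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    with open(path, "w") as fh:
        for label, row in zip(ts.channel_labels, ts.data):
            fh.write(label + sep + sep.join(repr(float(v)) for v in row) + "\n")
    sidecar = path.with_suffix(".json")
    meta = {"fs": ts.fs}
    if ts.state_label is not None:
        meta["state_label"] = ts.state_label
    sidecar.write_text(json.dumps(meta, sort_keys=True))


def apply_channel_exclusion(recording: TimeSeriesMatrix,
                            exclusion_list: list[str]) -> TimeSeriesMatrix:
    """Drop the listed channels, preserving the order of survivors.

    Mirrors the standard high-density-EEG step of removing face/neck
    channels (e.g. 128 -> 96) before analysis.
    """
    unknown = set(exclusion_list) - set(recording.channel_labels)
    if unknown:
        raise IngestionError(f"exclusion list names unknown channel(s): {sorted(unknown)}")
    keep = [l for l in recording.channel_labels if l not in set(exclusion_list)]
    if not keep:
        raise IngestionError("exclusion would remove every channel")
    return recording.select(keep)


def load_montage(path) -> Montage:
    """Read a montage CSV with columns label,x,y,z (cm)."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    return Montage(df["label"].astype(str).tolist(),
                   df[["x", "y", "z"]].to_numpy(dtype=np.float64))


def write_montage(montage: Montage, path) -> None:
    df = pd.DataFrame(montage.coordinates, columns=["x", "y", "z"])
    df.insert(0, "label", montage.channel_labels)
    df.to_csv(path, index=False, float_format="%.6f")


def bundled_montage_128() -> Montage:
    """The packaged 128-channel hemispheric montage fixture."""
    with resources.as_file(resources.files("phibar.data") / "montage128.csv") as p:
        return load_montage(p)


def bundled_exclusion_32() -> list[str]:
    """Packaged 32-channel face/neck exclusion list (synthetic stand-in).

    The identity of the excluded channels on the real net is not public;
    this list keys to the bundled synthetic montage (its 32 lowest
    electrodes) and is flagged as a stand-in in the docs.
    """
    with resources.as_file(resources.files("phibar.data") / "exclusion32.txt") as p:
        return [l.strip() for l in Path(p).read_text().splitlines() if l.strip()]


def write_results(tables: dict[str, ResultTable] | ResultTable, out_dir,
                  run_info: dict | None = None) -> list[Path]:
    """Write one CSV per metric plus a JSON run summary.

    Output is deterministic: rows sorted on all columns, fixed float format,
    JSON keys sorted — reruns with identical inputs are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(tables, ResultTable):
        tables = {"results": tables}
    written: list[Path] = []
    merged = pd.concat([t.rows for t in tables.values()], ignore_index=True)
    for metric, grp in merged.groupby("metric", sort=True):
        p = out_dir / f"{metric}.csv"
        grp = grp.sort_values(RESULT_COLUMNS[:-1], kind="mergesort")
        grp.to_csv(p, index=False, float_format="%.12g")
        written.append(p)
    summary = dict(run_info or {})
    summary["metrics"] = sorted(merged["metric"].unique())
    summary["n_rows"] = int(len(merged))
    p = out_dir / "run_summary.json"
    p.write_text(json.dumps(summary, sort_keys=True, indent=1))
    written.append(p)
    return written
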