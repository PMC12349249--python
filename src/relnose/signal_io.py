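"""Reading and preprocessing of multichannel gas-sensor recordings.

An electronic-nose acquisition is a dense time series: one column per
metal-oxide sensor, one row per sampling instant.  Two acquisition regimes
are supported:

* ``meta_train`` — long wind-tunnel style recordings (default 40,000 points
  at 10 ms per point, i.e. 400 s of 8 sensors), reduced by per-second
  averaging followed by a fixed 17–257 s window to a ``[240, 8]`` matrix;
* ``meta_test`` — short breath recordings (default 4,000 points over 8 s),
  reduced by equal time-interval extraction to the same ``[240, 8]`` shape.

Both regimes end in per-sample, per-channel min–max normalization so that
samples from different devices share a common scale.  Channel shuffling is
the augmentation used at training time: one random permutation of the sensor
columns applied consistently to every sample of an episode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical preprocessed shape (timesteps, channels)
DEFAULT_TIMESTEPS = 240
DEFAULT_CHANNELS = 8


class DiscardRecording(ValueError):
    """Raised when a recording must be discarded (missing or non-numeric data)."""


@dataclass(frozen=True)
class DialectConfig:
    """How a delimited-text recording file is laid out.

    delimiter: field separator.
    header_rows: number of leading rows to skip.
    time_column: index of a time column to drop, or ``None`` if absent.
    channel_columns: explicit column order for the sensor channels, applied
        after dropping the time column; ``None`` keeps file order.
    float_format: printf format used when writing fixtures.
    """

    delimiter: str = ","
    header_rows: int = 0
    time_column: int | None = None
    channel_columns: tuple[int, ...] | None = None
    float_format: str = "%.17g"


@dataclass
class RawRecording:
    """One sensor-array acquisition before any reduction."""

    channels: np.ndarray          # [n_points, n_sensors]
    sampling_interval: float      # seconds per point
    label: str
    source: str = "meta_train"    # meta_train | meta_test

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 2 or self.channels.shape[0] == 0 or self.channels.shape[1] < 1:
            raise ValueError("channels must be a non-empty [n_points, n_sensors] matrix")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if not np.isfinite(self.channels).all():
            raise DiscardRecording(f"recording '{self.label}' contains missing values")

    @property
    def n_points(self) -> int:
        return self.channels.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.channels.shape[1]


@dataclass
class Sample:
    """A preprocessed [T x C] sample with its class label."""

    matrix: np.ndarray
    label: str
    source: str = "meta_train"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("sample matrix must be 2-D [timesteps, channels]")


@dataclass
class DatasetBundle:
    """An ordered collection of equal-shape samples sharing a class vocabulary."""

    samples: list[Sample]
    classes: list[str] = field(default_factory=list)
    role: str = "meta_train"

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = sorted({s.label for s in self.samples})
        shapes = {s.matrix.shape for s in self.samples}
        if len(shapes) > 1:
            raise ValueError(f"samples disagree on shape: {shapes}")
        unknown = {s.label for s in self.samples} - set(self.classes)
        if unknown:
            raise ValueError(f"labels missing from class vocabulary: {unknown}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def shape(self) -> tuple[int, int]:
        return self.samples[0].matrix.shape if self.samples else (0, 0)

    def by_class(self) -> dict[str, list[Sample]]:
        out: dict[str, list[Sample]] = {c: [] for c in self.classes}
        for s in self.samples:
            out[s.label].append(s)
        return out


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def read_raw_table(path: str | Path, dialect: DialectConfig | None = None,
                   label: str = "", source: str = "meta_train",
                   sampling_interval: float = 0.01) -> RawRecording:
    """Read one delimited-text recording into a :class:`RawRecording`.

    Rows with non-numeric cells or any missing value cause the whole
    recording to be discarded (raising :class:`DiscardRecording`) rather
    than imputed: partial acquisitions are not trusted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or DialectConfig()
    frame = pd.read_csv(path, sep=dialect.delimiter, header=None,
                        skiprows=dialect.header_rows, dtype=str,
                        skip_blank_lines=False)
    if dialect.time_column is not None:
        frame = frame.drop(columns=frame.columns[dialect.time_column])
    if frame.isna().any().any():
        raise DiscardRecording(f"{path.name}: missing cells; recording discarded")
    try:
        # numpy's string parser round-trips full float precision exactly
        values = frame.to_numpy().astype(np.float64)
    except ValueError as err:
        raise DiscardRecording(
            f"{path.name}: non-numeric cells; recording discarded") from err
    if dialect.channel_columns is not None:
        values = values[:, list(dialect.channel_columns)]
    return RawRecording(values, sampling_interval=sampling_interval,
                        label=label, source=source)


def write_raw_table(rec: RawRecording, path: str | Path,
                    dialect: DialectConfig | None = None) -> None:
    """Write a raw recording as delimited text, round-trippable by
    :func:`read_raw_table` at the dialect's float precision."""
    dialect = dialect or DialectConfig()
    np.savetxt(path, rec.channels, fmt=dialect.float_format,
               delimiter=dialect.delimiter)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def per_second_average(rec: RawRecording | np.ndarray,
                       points_per_second: int = 100) -> np.ndarray:
    """Average consecutive blocks of ``points_per_second`` rows.

    A 40,000-point recording at 100 points/s becomes a [400, C] matrix of
    per-second means.  A trailing remainder that does not fill a whole
    second is dropped (and logged).
    """
    if points_per_second <= 0:
        raise ValueError("points_per_second must be positive")
    matrix = rec.channels if isinstance(rec, RawRecording) else np.asarray(rec, float)
    n_points, n_chan = matrix.shape
    n_seconds, remainder = divmod(n_points, points_per_second)
    if remainder:
        logger.warning("dropping %d trailing points (< 1 s of data)", remainder)
        matrix = matrix[: n_seconds * points_per_second]
    return matrix.reshape(n_seconds, points_per_second, n_chan).mean(axis=1)


def window_truncate(matrix: np.ndarray, start_s: int = 17, end_s: int = 257) -> np.ndarray:
    """Keep the per-second rows in the half-open window [start_s, end_s).

    The default 17–257 s window keeps the informative rise/plateau/decay
    portion of a wind-tunnel recording: exactly 240 rows.
    """
    matrix = np.asarray(matrix)
    if not (0 <= start_s < end_s <= matrix.shape[0]):
        raise ValueError(f"window [{start_s}, {end_s}) outside matrix of {matrix.shape[0]} rows")
    return matrix[start_s:end_s]


def equal_interval_extract(matrix: np.ndarray, target: int = DEFAULT_TIMESTEPS) -> np.ndarray:
    """Subsample rows at equal time intervals, endpoints included.

    Row ``i`` of the output is row ``round(i * (n_rows - 1) / (target - 1))``
    of the input (round-half-to-even).
    """
    matrix = np.asarray(matrix)
    n_rows = matrix.shape[0]
    if target < 2 or target > n_rows:
        raise ValueError(f"target {target} incompatible with {n_rows} rows")
    idx = np.round(np.arange(target) * (n_rows - 1) / (target - 1)).astype(int)
    return matrix[idx]


def normalize(sample: Sample) -> Sample:
    """Per-sample, per-channel min–max scaling to [0, 1].

    A constant channel carries no within-sample information and maps to 0.
    Idempotent.
    """
    m = sample.matrix
    if not np.isfinite(m).all():
        raise ValueError("sample matrix must be finite")
    lo = m.min(axis=0, keepdims=True)
    span = m.max(axis=0, keepdims=True) - lo
    out = np.where(span > 0, (m - lo) / np.where(span > 0, span, 1.0), 0.0)
    return Sample(out, label=sample.label, source=sample.source)


def channel_shuffle(batch: Sequence[Sample], permutation: Sequence[int] | None = None,
                    rng: np.random.Generator | None = None) -> list[Sample]:
    """Apply ONE permutation of the sensor channels to every sample in ``batch``.

    Sharing the permutation across the batch (e.g. the support and query of
    one episode) preserves the cross-sample channel correspondence that the
    similarity model compares; it only removes the dependence on a fixed
    channel order.
    """
    if not batch:
        return []
    n_chan = batch[0].matrix.shape[1]
    if permutation is None:
        if rng is None:
            raise ValueError("provide either a permutation or an rng")
        permutation = rng.permutation(n_chan)
    perm = np.asarray(permutation)
    if sorted(perm.tolist()) != list(range(n_chan)):
        raise ValueError(f"not a permutation of 0..{n_chan - 1}: {perm}")
    return [replace(s, matrix=s.matrix[:, perm]) for s in batch]


# ---------------------------------------------------------------------------
# end-to-end preprocessing
# ---------------------------------------------------------------------------

def preprocess_recording(rec: RawRecording, *, points_per_second: int = 100,
                         window: tuple[int, int] = (17, 257),
                         target: int = DEFAULT_TIMESTEPS) -> Sample:
    """Reduce a raw recording to a normalized [target, C] sample.

    ``meta_train`` recordings are averaged per second then windowed;
    ``meta_test`` recordings are subsampled at equal intervals.
    """
    if rec.source == "meta_train":
        matrix = window_truncate(per_second_average(rec, points_per_second), *window)
        if matrix.shape[0] != target:
            raise ValueError(f"window yields {matrix.shape[0]} rows, expected {target}")
    else:
        matrix = equal_interval_extract(rec.channels, target)
    return normalize(Sample(matrix, label=rec.label, source=rec.source))


def preprocess_bundle(recordings: Iterable[RawRecording], role: str,
                      **kwargs) -> DatasetBundle:
    """Preprocess an iterable of recordings into a :class:`DatasetBundle`,
    silently dropping (but logging) recordings flagged for discard."""
    samples = []
    for rec in recordings:
        try:
            samples.append(preprocess_recording(rec, **kwargs))
        except DiscardRecording as err:
            logger.warning("discarded recording: %s", err)
    return DatasetBundle(samples, role=role)


# ---------------------------------------------------------------------------
# bundle persistence (directory of per-sample delimited text + manifest)
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.tsv"


def save_bundle(bundle: DatasetBundle, directory: str | Path,
                dialect: DialectConfig | None = None) -> Path:
    """Write each sample as delimited text plus a manifest; returns the
    manifest path.  Bit-reproducible for identical inputs and dialect."""
    dialect = dialect or DialectConfig()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(bundle.samples):
        fname = f"sample_{i:05d}.csv"
        np.savetxt(directory / fname, s.matrix, fmt=dialect.float_format,
                   delimiter=dialect.delimiter)
        rows.append((fname, s.label, s.source))
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows, columns=["file", "label", "source"]).to_csv(
        manifest, sep="\t", index=False)
    return manifest


def load_bundle(directory: str | Path, role: str | None = None,
                dialect: DialectConfig | None = None) -> DatasetBundle:
    dialect = dialect or DialectConfig()
    directory = Path(directory)
    manifest = pd.read_csv(directory / MANIFEST_NAME, sep="\t")
    samples = []
    for _, row in manifest.iterrows():
        matrix = np.loadtxt(directory / row["file"], delimiter=dialect.delimiter, ndmin=2)
        samples.append(Sample(matrix, label=str(row["label"]), source=str(row["source"])))
    inferred_role = role or (samples[0].source if samples else "meta_train")
    return DatasetBundle(samples, role=inferred_role)
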