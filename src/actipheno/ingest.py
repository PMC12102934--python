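"""Reading, writing and preprocessing of actigraphy recordings.

Two device families are supported: wrist units that ship pre-epoched
activity counts (one count per minute), and raw triaxial accelerometers
(10 Hz by default) whose signal is reduced to per-minute counts with a
PIM-style scheme (band-pass -> magnitude -> per-second maximum -> sum
over the minute).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

EPOCHS_PER_DAY_DEFAULT = 1440  # 1-min epochs, midnight to midnight

__all__ = [
    "RawTriaxialSeries",
    "EpochSeries",
    "FilterSpec",
    "read_epoch_csv",
    "write_epoch_csv",
    "read_raw_csv",
    "pim_from_raw",
    "drop_missing_days",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification in Hz."""

    low_hz: float = 0.25
    high_hz: float = 2.5
    order: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError(f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}")
        if self.order < 1:
            raise ValueError("order must be a positive integer")


@dataclass(frozen=True)
class RawTriaxialSeries:
    """Uniformly sampled triaxial acceleration in g."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y, z must have equal length")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return len(self.x) / self.sampling_rate_hz


@dataclass(frozen=True)
class EpochSeries:
    """One subject's per-epoch activity counts.

    Counts are non-negative reals (PIM sums of filtered magnitudes are
    continuous, not integer). ``day_index`` assigns each epoch to a
    midnight-to-midnight calendar day relative to ``start_time``.
    """

    counts: np.ndarray
    subject_id: str = "anon"
    start_time: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2000-01-03 00:00:00"))
    epoch_len_s: int = 60

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.epoch_len_s <= 0 or 86400 % self.epoch_len_s != 0:
            raise ValueError("epoch_len_s must be a positive divisor of 86400")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "start_time", pd.Timestamp(self.start_time))

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def epochs_per_day(self) -> int:
        return 86400 // self.epoch_len_s

    @property
    def day_index(self) -> np.ndarray:
        """Midnight-to-midnight day number of every epoch."""
        offset = (
            self.start_time - self.start_time.normalize()
        ).total_seconds() // self.epoch_len_s
        return (np.arange(len(self.counts)) + int(offset)) // self.epochs_per_day

    def trim_partial_days(self) -> "EpochSeries":
        """Drop leading/trailing partial days so the record starts at
        midnight and covers whole days only."""
        p = self.epochs_per_day
        offset = int(
            (self.start_time - self.start_time.normalize()).total_seconds()
            // self.epoch_len_s
        )
        lead = 0 if offset == 0 else p - offset
        n_days = (len(self.counts) - lead) // p
        if n_days < 1:
            raise ValueError("record shorter than one whole day after trimming")
        start = self.start_time.normalize() + pd.Timedelta(days=0 if offset == 0 else 1)
        return EpochSeries(
            counts=self.counts[lead : lead + n_days * p],
            subject_id=self.subject_id,
            start_time=start,
            epoch_len_s=self.epoch_len_s,
        )

    def day_view(self) -> np.ndarray:
        """Counts reshaped to (n_days, epochs_per_day); requires an
        already day-aligned record (use :meth:`trim_partial_days`)."""
        p = self.epochs_per_day
        if len(self.counts) == 0 or len(self.counts) % p != 0:
            raise ValueError("series is not aligned to whole days")
        if (self.start_time - self.start_time.normalize()).total_seconds() != 0:
            raise ValueError("series does not start at midnight")
        return self.counts.reshape(-1, p)

    @property
    def n_days(self) -> int:
        return len(self.day_view())


def read_epoch_csv(path, dialect: str = "generic", *, subject_id: str | None = None,
                   start_time=None, epoch_len_s: int = 60) -> EpochSeries:
    """Read a per-epoch count file.

    ``generic`` dialect: header ``subject_id,timestamp,count``.
    ``haukeland`` dialect: a single count column, no header; the start
    time and subject id come from the keyword arguments (sidecar config).
    Counts are returned exactly as stored, no rescaling.
    """
    if dialect not in ("generic", "haukeland"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "haukeland":
        counts = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                text = line.strip()
                if not text:
                    continue
                try:
                    value = float(text)
                except ValueError:
                    raise ValueError(f"{path}: malformed count on line {lineno}: {text!r}")
                if value < 0:
                    raise ValueError(f"{path}: negative count on line {lineno}")
                counts.append(value)
        if not counts:
            raise ValueError(f"{path}: no epochs")
        return EpochSeries(
            counts=np.array(counts),
            subject_id=subject_id or "anon",
            start_time=start_time if start_time is not None else pd.Timestamp("2000-01-03"),
            epoch_len_s=epoch_len_s,
        )

    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no epochs")
    for col in ("subject_id", "timestamp", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: no epochs")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = np.flatnonzero(counts.isna().to_numpy())
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(f"{path}: malformed count on line {bad[0] + 2}")
    if (counts < 0).any():
        line = int(np.flatnonzero((counts < 0).to_numpy())[0]) + 2
        raise ValueError(f"{path}: negative count on line {line}")
    return EpochSeries(
        counts=counts.to_numpy(dtype=float),
        subject_id=str(df["subject_id"].iloc[0]),
        start_time=pd.Timestamp(df["timestamp"].iloc[0]),
        epoch_len_s=epoch_len_s,
    )


def _format_count(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_epoch_csv(series: EpochSeries, path) -> None:
    """Write the generic dialect (``subject_id,timestamp,count``)."""
    times = series.start_time + pd.to_timedelta(
        np.arange(len(series)) * series.epoch_len_s, unit="s"
    )
    with open(path, "w") as fh:
        fh.write("subject_id,timestamp,count\n")
        for t, c in zip(times, series.counts):
            fh.write(f"{series.subject_id},{t.isoformat()},{_format_count(c)}\n")


def read_raw_csv(path, sampling_rate_hz: float = 10.0) -> RawTriaxialSeries:
    """Read raw triaxial acceleration, columns ``t_s,x_g,y_g,z_g``."""
    df = pd.read_csv(path)
    for col in ("t_s", "x_g", "y_g", "z_g"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return RawTriaxialSeries(
        x=df["x_g"].to_numpy(float),
        y=df["y_g"].to_numpy(float),
        z=df["z_g"].to_numpy(float),
        sampling_rate_hz=sampling_rate_hz,
    )


def _bandpass(arr: np.ndarray, band: FilterSpec, fs: float) -> np.ndarray:
    sos = signal.butter(
        band.order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    return signal.sosfiltfilt(sos, arr)


def pim_from_raw(
    raw: RawTriaxialSeries,
    band: FilterSpec | None = FilterSpec(),
    *,
    combine_first: bool = False,
    subject_id: str = "anon",
    start_time=None,
    epoch_len_s: int = 60,
) -> EpochSeries:
    """Reduce raw triaxial acceleration to per-minute PIM-style counts.

    Pipeline: zero-phase Butterworth band-pass of each axis (``band=None``
    bypasses filtering), Euclidean magnitude across axes, maximum of the
    magnitude within each second, sum of the per-second maxima over each
    minute epoch. ``combine_first`` filters the magnitude instead of the
    individual axes.
    """
    fs = raw.sampling_rate_hz
    per_sec = fs
    if abs(per_sec - round(per_sec)) > 1e-9:
        raise ValueError("sampling_rate_hz must be an integer number of samples per second")
    per_sec = int(round(per_sec))
    sec_per_epoch = epoch_len_s
    if len(raw) < per_sec * sec_per_epoch:
        raise ValueError("raw record shorter than one full epoch")
    if band is not None and band.high_hz >= fs / 2:
        raise ValueError(
            f"band high_hz {band.high_hz} not below Nyquist {fs / 2}"
        )

    if band is None:
        mag = np.sqrt(raw.x**2 + raw.y**2 + raw.z**2)
    elif combine_first:
        mag = np.abs(_bandpass(np.sqrt(raw.x**2 + raw.y**2 + raw.z**2), band, fs))
    else:
        fx = _bandpass(raw.x, band, fs)
        fy = _bandpass(raw.y, band, fs)
        fz = _bandpass(raw.z, band, fs)
        mag = np.sqrt(fx**2 + fy**2 + fz**2)

    n_sec = len(mag) // per_sec
    sec_max = mag[: n_sec * per_sec].reshape(n_sec, per_sec).max(axis=1)
    n_epochs = n_sec // sec_per_epoch
    counts = sec_max[: n_epochs * sec_per_epoch].reshape(n_epochs, sec_per_epoch).sum(axis=1)
    return EpochSeries(
        counts=np.maximum(counts, 0.0),
        subject_id=subject_id,
        start_time=start_time if start_time is not None else pd.Timestamp("2000-01-03"),
        epoch_len_s=epoch_len_s,
    )


def drop_missing_days(series: EpochSeries) -> EpochSeries:
    """Remove whole days whose counts are all zero (device shut off or
    off-wrist); partial days are never removed here. Idempotent."""
    days = series.day_view()
    keep = ~(days == 0).all(axis=1)
    if not keep.any():
        raise ValueError("no valid days")
    return replace(series, counts=days[keep].ravel())
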