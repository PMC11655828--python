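"""Uniformly sampled multichannel time series and its CSV/HDF5 round trip.

The model's EEG-like readout and every analysis input share one container:
named real-valued channels on a common uniform time grid. CSV is the
interchange format (first column = time in ms, one column per channel);
HDF5 is available for large per-unit dumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TimeSeries", "read_timeseries", "write_timeseries"]

# Relative jitter above which a time column is rejected as non-uniform.
_UNIFORMITY_TOL = 1e-6


@dataclass
class TimeSeries:
    """Named channels sampled at a common rate.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz. Must be positive.
    channels : dict of str -> ndarray
        Equal-length 1-D float arrays.
    meta : dict
        Free-form provenance (seed, config hash, ...). Never interpreted.
    """

    fs: float
    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {k: v.shape for k, v in self.channels.items()}
        sizes = {v.size for v in self.channels.values()}
        if len(sizes) > 1:
            raise ValueError(f"channels have unequal lengths: {lengths}")
        for k, v in self.channels.items():
            if v.ndim != 1:
                raise ValueError(f"channel {k!r} is not 1-D")

    @property
    def n_samples(self) -> int:
        if not self.channels:
            return 0
        return next(iter(self.channels.values())).size

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    @property
    def time_ms(self) -> np.ndarray:
        """Sample times in milliseconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs * 1000.0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def select(self, names: list[str]) -> "TimeSeries":
        return TimeSeries(self.fs, {n: self.channels[n] for n in names}, dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.time_ms})
        for name, vals in self.channels.items():
            df[name] = vals
        return df


def write_timeseries(ts: TimeSeries, path: str | Path) -> None:
    """Write a TimeSeries as CSV (time_ms first, one column per channel)."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        _write_hdf5(ts, path)
        return
    ts.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read a CSV time series; infer fs from the time column.

    Raises
    ------
    ValueError
        If the file has no data rows, fewer than two columns, or a
        time column with relative jitter above 1e-6.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        return _read_hdf5(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows etc.; keep the line info
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if df.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 samples to infer fs, got {df.shape[0]}")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one channel")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0:
        raise ValueError(f"{path}: time column is not increasing")
    if np.max(np.abs(dt - dt_med)) > _UNIFORMITY_TOL * max(abs(t[-1] - t[0]), dt_med):
        raise ValueError(f"{path}: non-uniform sampling (jitter above tolerance)")
    fs = 1000.0 / dt_med  # time column in ms
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns[1:]}
    return TimeSeries(fs=fs, channels=channels, meta={"source": str(path)})


def _write_hdf5(ts: TimeSeries, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["fs"] = ts.fs
        for k, v in ts.meta.items():
            f.attrs[f"meta_{k}"] = str(v)
        for name, vals in ts.channels.items():
            f.create_dataset(name, data=vals)


def _read_hdf5(path: Path) -> TimeSeries:
    import h5py

    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        channels = {name: np.asarray(f[name]) for name in f}
        meta = {k[5:]: v for k, v in f.attrs.items() if k.startswith("meta_")}
    return TimeSeries(fs=fs, channels=channels, meta=meta)
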