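"""Spike-train data model, sliding-window segmentation and file I/O.

The universal input is an event list of ``(neuron_id, time)`` pairs.  Windowing
turns the recording into a sequence of ``(N, L)`` spike-count matrices: one
window of length ``Tw`` seconds split into ``L`` bins of ``b`` seconds.  Each
bin's count vector is one "character" of the window's "string"; all downstream
similarity computations operate on these matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeData",
    "WindowConfig",
    "WindowMatrix",
    "load_spikes",
    "save_spikes",
    "segment_windows",
    "window_tensor",
]


@dataclass(frozen=True)
class SpikeData:
    """Event list of a population spike recording.

    Parameters
    ----------
    neuron_ids : array of int
        0-based neuron index per spike, all ``< n_neurons``.
    times : array of float
        Spike times in seconds, in ``[0, duration]``.
    n_neurons : int
        Population size ``N``.
    duration : float
        Recording length ``T`` in seconds.
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float

    def __post_init__(self) -> None:
        ids = np.asarray(self.neuron_ids, dtype=np.int64)
        t = np.asarray(self.times, dtype=np.float64)
        if ids.shape != t.shape or ids.ndim != 1:
            raise ValueError("neuron_ids and times must be 1-D arrays of equal length")
        order = np.lexsort((ids, t))
        object.__setattr__(self, "neuron_ids", ids[order])
        object.__setattr__(self, "times", t[order])
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        if ids.size:
            if ids.min() < 0 or ids.max() >= self.n_neurons:
                raise ValueError(
                    f"neuron ids must lie in [0, {self.n_neurons}); "
                    f"found range [{ids.min()}, {ids.max()}]"
                )
            if t.min() < 0 or t.max() > self.duration:
                raise ValueError("spike times must lie in [0, duration]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def spike_counts(self) -> np.ndarray:
        """Per-neuron total spike counts ``#_i`` (length ``n_neurons``)."""
        return np.bincount(self.neuron_ids, minlength=self.n_neurons)

    def rates(self) -> np.ndarray:
        """Per-neuron mean firing rates ``#_i / T`` in Hz."""
        return self.spike_counts() / self.duration


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: ``window_len = L * bin_size``.

    ``stride`` defaults to the window length (non-overlapping windows); a
    smaller stride yields overlapping windows.
    """

    window_len: float
    bin_size: float
    stride: float | None = None

    def __post_init__(self) -> None:
        if self.window_len <= 0 or self.bin_size <= 0:
            raise ValueError("window_len and bin_size must be positive")
        if self.stride is None:
            object.__setattr__(self, "stride", self.window_len)
        if self.stride <= 0:
            raise ValueError("stride must be positive")
        ratio = self.window_len / self.bin_size
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("window_len must be an integer multiple of bin_size")

    @property
    def n_bins(self) -> int:
        """Number of bins ``L`` per window."""
        return int(round(self.window_len / self.bin_size))


@dataclass(frozen=True)
class WindowMatrix:
    """One window's ``(N, L)`` spike-count matrix and its start time."""

    start: float
    counts: np.ndarray  # shape (N, L), non-negative integers

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


def load_spikes(
    path,
    n_neurons: int | None = None,
    duration: float | None = None,
) -> SpikeData:
    """Read a spike CSV with header ``neuron_id,time`` (times in seconds).

    ``n_neurons`` defaults to ``max(neuron_id) + 1`` and ``duration`` to the
    last spike time.  Malformed rows raise with the offending line number.
    """
    try:
        df = pd.read_csv(path, usecols=["neuron_id", "time"])
    except ValueError as exc:
        raise ValueError(f"{path}: expected CSV with header 'neuron_id,time' ({exc})") from exc
    if df.empty:
        raise ValueError(f"{path}: no spike events")
    for col in ("neuron_id", "time"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed value in column '{col}' at line {line}")
    ids = df["neuron_id"].to_numpy(dtype=np.int64)
    times = df["time"].to_numpy(dtype=np.float64)
    if (ids < 0).any():
        raise ValueError(f"{path}: negative neuron id")
    if (times < 0).any():
        raise ValueError(f"{path}: negative spike time")
    if n_neurons is None:
        n_neurons = int(ids.max()) + 1
    if duration is None:
        duration = float(times.max())
    return SpikeData(ids, times, n_neurons=n_neurons, duration=duration)


def save_spikes(data: SpikeData, path) -> None:
    """Write the ``neuron_id,time`` CSV read back by :func:`load_spikes`."""
    pd.DataFrame({"neuron_id": data.neuron_ids, "time": data.times}).to_csv(
        path, index=False
    )


def segment_windows(data: SpikeData, cfg: WindowConfig) -> list[WindowMatrix]:
    """Segment a recording into binned sliding windows.

    Windows start at ``t = 0`` and advance by ``cfg.stride``; only windows
    fully contained in ``[0, T]`` are produced.  A spike at time ``t`` falls in
    bin ``j`` of the window starting at ``t_k`` iff
    ``t_k + j*b <= t < t_k + (j+1)*b`` (half-open bins; a spike exactly on a
    window's right edge belongs to the next window).
    """
    if cfg.window_len > data.duration:
        raise ValueError(
            f"window_len {cfg.window_len} exceeds recording duration {data.duration}"
        )
    tensor, starts = window_tensor(data, cfg)
    return [WindowMatrix(float(t0), tensor[k]) for k, t0 in enumerate(starts)]


def window_tensor(data: SpikeData, cfg: WindowConfig) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized segmentation: returns ``(counts, starts)``.

    ``counts`` has shape ``(M, N, L)`` with integer spike counts; ``starts``
    the ``M`` window start times.  Equivalent to :func:`segment_windows` but
    cheaper for long recordings.
    """
    L = cfg.n_bins
    n_windows = int(np.floor((data.duration - cfg.window_len) / cfg.stride + 1e-9)) + 1
    if n_windows < 1:
        raise ValueError("no window fits in the recording")
    starts = np.arange(n_windows) * cfg.stride
    counts = np.zeros((n_windows, data.n_neurons, L), dtype=np.int64)
    t = data.times
    ids = data.neuron_ids
    if cfg.stride == cfg.window_len:
        # non-overlapping: each spike belongs to at most one window
        k = np.floor(t / cfg.stride + 1e-12).astype(np.int64)
        ok = k < n_windows
        j = np.floor((t[ok] - k[ok] * cfg.stride) / cfg.bin_size + 1e-12).astype(np.int64)
        np.clip(j, 0, L - 1, out=j)
        np.add.at(counts, (k[ok], ids[ok], j), 1)
    else:
        for k in range(n_windows):
            t0 = starts[k]
            sel = (t >= t0 - 1e-12) & (t < t0 + cfg.window_len - 1e-12)
            j = np.floor((t[sel] - t0) / cfg.bin_size + 1e-12).astype(np.int64)
            np.clip(j, 0, L - 1, out=j)
            np.add.at(counts[k], (ids[sel], j), 1)
    return counts, starts
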