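"""Synthetic population spike trains with embedded cell assemblies.

Benchmarks are generated, never stored: homogeneous Poisson background at a
stated per-neuron rate, plus repeated assembly occurrences — synchronous
(all members fire together, up to a timing jitter) or sequential (members
fire evenly spaced across a span, optionally time-compressed) — embedded at
random positions with ground-truth bookkeeping per occurrence and per
window.  Assembly members also emit background spikes: the signal rides on,
rather than replaces, their baseline firing.

Named regimes reproduce the benchmark configurations used throughout the
package's validation (see :func:`benchmark_suite`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import SpikeData, WindowConfig

__all__ = [
    "AssemblySpec",
    "Occurrence",
    "SynthGroundTruth",
    "generate_background",
    "embed_assemblies",
    "benchmark_suite",
    "BENCHMARK_REGIMES",
]


@dataclass(frozen=True)
class AssemblySpec:
    """One embedded assembly.

    ``members`` fire once per occurrence; ``mode`` is ``"synchronous"``,
    ``"sequential"`` (forward) or ``"sequential-reverse"``.  A sequential
    occurrence spreads its members evenly over ``span / time_scale`` seconds;
    a synchronous one places all members at the occurrence start.  Every
    member time is perturbed by uniform jitter on ``±jitter`` seconds.
    """

    members: tuple[int, ...]
    mode: str = "synchronous"
    span: float = 0.0
    jitter: float = 0.0
    occurrences: int = 1
    time_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("synchronous", "sequential", "sequential-reverse"):
            raise ValueError(f"unknown assembly mode {self.mode!r}")
        if self.time_scale < 1.0:
            raise ValueError("time_scale must be >= 1")
        if self.mode != "synchronous" and self.span <= 0:
            raise ValueError("sequential assemblies need a positive span")

    @property
    def effective_span(self) -> float:
        return 0.0 if self.mode == "synchronous" else self.span / self.time_scale


@dataclass(frozen=True)
class Occurrence:
    assembly: int
    start: float


@dataclass(frozen=True)
class SynthGroundTruth:
    """Per-occurrence record plus helpers to label windows."""

    specs: tuple[AssemblySpec, ...]
    occurrences: tuple[Occurrence, ...]
    duration: float

    def window_labels(self, cfg: WindowConfig, n_windows: int, noise: int = -1) -> np.ndarray:
        """True label per non-overlapping window: assembly id or noise.

        A window is a member of true cluster ``a`` iff it overlaps an
        occurrence of assembly ``a``; if several assemblies hit the same
        window the earliest-starting occurrence wins.
        """
        labels = np.full(n_windows, noise, dtype=np.int64)
        claimed = np.full(n_windows, np.inf)
        for occ in self.occurrences:
            spec = self.specs[occ.assembly]
            lo = occ.start - spec.jitter
            hi = occ.start + spec.effective_span + spec.jitter
            k_lo = max(0, int(np.floor(lo / cfg.stride)))
            k_hi = min(n_windows - 1, int(np.floor(max(hi - 1e-12, 0.0) / cfg.stride)))
            for k in range(k_lo, k_hi + 1):
                w0, w1 = k * cfg.stride, k * cfg.stride + cfg.window_len
                if hi > w0 and lo < w1 and occ.start < claimed[k]:
                    labels[k] = occ.assembly
                    claimed[k] = occ.start
        return labels


def generate_background(
    n_neurons: int, rate_hz: float, duration_s: float, seed: int
) -> SpikeData:
    """Independent homogeneous Poisson spike trains for the population."""
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate_hz * duration_s, size=n_neurons)
    ids = np.repeat(np.arange(n_neurons), counts)
    times = rng.uniform(0.0, duration_s, size=counts.sum())
    return SpikeData(ids, times, n_neurons=n_neurons, duration=duration_s)


def _occurrence_times(
    spec: AssemblySpec, start: float, rng: np.random.Generator
) -> np.ndarray:
    m = len(spec.members)
    if spec.mode == "synchronous":
        base = np.full(m, start)
    else:
        span = spec.effective_span
        offsets = np.linspace(0.0, span, m, endpoint=True) if m > 1 else np.zeros(1)
        if spec.mode == "sequential-reverse":
            offsets = offsets[::-1]
        base = start + offsets
    if spec.jitter > 0:
        base = base + rng.uniform(-spec.jitter, spec.jitter, size=m)
    return base


def embed_assemblies(
    background: SpikeData,
    specs: list[AssemblySpec],
    seed: int,
    cfg: WindowConfig | None = None,
) -> tuple[SpikeData, SynthGroundTruth]:
    """Superimpose assembly occurrences on a background recording.

    With a window config given, occurrence starts are drawn so that no
    occurrence (including its jitter margin) crosses a window boundary: a
    window index is drawn without replacement per assembly, then the start is
    placed uniformly within the window's feasible interval.  Without a
    config, starts are uniform on the feasible part of ``[0, T]``.
    """
    rng = np.random.default_rng(seed)
    T = background.duration
    all_ids = [background.neuron_ids]
    all_times = [background.times]
    occurrences: list[Occurrence] = []
    for a, spec in enumerate(specs):
        if spec.members and max(spec.members) >= background.n_neurons:
            raise ValueError(f"assembly {a} has members outside the population")
        extent = spec.effective_span + 2.0 * spec.jitter
        if cfg is not None:
            n_windows = int(np.floor((T - cfg.window_len) / cfg.stride + 1e-9)) + 1
            if extent > cfg.window_len:
                raise ValueError(
                    f"assembly {a} extent {extent:.3f}s does not fit a window"
                )
            if spec.occurrences > n_windows:
                raise ValueError(
                    f"assembly {a}: {spec.occurrences} occurrences but only "
                    f"{n_windows} windows"
                )
            wins = rng.choice(n_windows, size=spec.occurrences, replace=False)
            slack = cfg.window_len - extent
            starts = wins * cfg.stride + spec.jitter + rng.uniform(
                0.0, 1.0, size=spec.occurrences
            ) * slack
        else:
            if extent > T:
                raise ValueError(f"assembly {a} extent exceeds the recording")
            starts = spec.jitter + rng.uniform(
                0.0, T - extent, size=spec.occurrences
            )
        for t0 in np.sort(starts):
            times = _occurrence_times(spec, float(t0), rng)
            np.clip(times, 0.0, T, out=times)
            all_ids.append(np.array(spec.members, dtype=np.int64))
            all_times.append(times)
            occurrences.append(Occurrence(a, float(t0)))
    data = SpikeData(
        np.concatenate(all_ids),
        np.concatenate(all_times),
        n_neurons=background.n_neurons,
        duration=T,
    )
    gt = SynthGroundTruth(tuple(specs), tuple(occurrences), T)
    return data, gt


def _block(first: int, size: int) -> tuple[int, ...]:
    return tuple(range(first, first + size))


#: name -> builder(seed, **overrides) for the printed benchmark regimes.
BENCHMARK_REGIMES = {}


def _regime(name):
    def deco(fn):
        BENCHMARK_REGIMES[name] = fn
        return fn

    return deco


@_regime("three_sequences")
def _three_sequences(seed: int):
    """Three 20-neuron sequential assemblies, 10 occurrences each, 1 Hz noise.

    60 neurons, 60 s, 200 ms windows / 10 ms bins (the original's neuron
    count and duration are unstated; these values are this package's choice).
    """
    cfg = WindowConfig(0.2, 0.01)
    bg = generate_background(60, 1.0, 60.0, seed)
    specs = [
        AssemblySpec(_block(20 * a, 20), "sequential", span=0.1, jitter=0.0,
                     occurrences=10)
        for a in range(3)
    ]
    # n_extra below the 20-member assembly size: members already active by
    # chance shrink the excess coincidence, and the small population bounds
    # the feasible range of the threshold formula
    data, gt = embed_assemblies(bg, specs, seed + 1, cfg)
    return data, gt, {"cfg": cfg, "alpha": 0.1, "n_extra": 6}


def _five_sync_base(seed: int, jitter: float):
    cfg = WindowConfig(0.2, 0.01)
    bg = generate_background(100, 2.0, 300.0, seed)
    specs = [
        AssemblySpec(_block(20 * a, 20), "synchronous", jitter=jitter,
                     occurrences=50)
        for a in range(5)
    ]
    data, gt = embed_assemblies(bg, specs, seed + 1, cfg)
    return data, gt, {"cfg": cfg, "alpha": 1.0, "n_extra": 10}


@_regime("five_sync")
def _five_sync(seed: int):
    """Five 20-neuron synchronous assemblies (±10 ms jitter), 2 Hz, 300 s."""
    return _five_sync_base(seed, 0.01)


@_regime("five_sync_wide_jitter")
def _five_sync_wide_jitter(seed: int):
    """As five_sync but with ±50 ms jitter."""
    return _five_sync_base(seed, 0.05)


@_regime("forward_sync_reverse")
def _forward_sync_reverse(seed: int):
    """Three 20-neuron assemblies in forward/synchronous/reverse order.

    60 neurons at 1 Hz, 60 s, ±10 ms jitter, 20 occurrences each,
    200 ms windows with 10 ms bins.
    """
    cfg = WindowConfig(0.2, 0.01)
    bg = generate_background(60, 1.0, 60.0, seed)
    modes = ["sequential", "synchronous", "sequential-reverse"]
    specs = [
        AssemblySpec(_block(20 * a, 20), m, span=0.1 if m != "synchronous" else 0.0,
                     jitter=0.01, occurrences=20)
        for a, m in enumerate(modes)
    ]
    data, gt = embed_assemblies(bg, specs, seed + 1, cfg)
    return data, gt, {"cfg": cfg, "alpha": 0.1, "n_extra": 10}


@_regime("large_sync_population")
def _large_sync_population(seed: int, n_neurons: int = 1000):
    """One 100-neuron synchronous assembly, no jitter, in a large population.

    20 occurrences in 60 s, 5 Hz per-neuron background, population size
    selectable among 1000/3000/5000.
    """
    cfg = WindowConfig(0.2, 0.01)
    bg = generate_background(n_neurons, 5.0, 60.0, seed)
    specs = [AssemblySpec(_block(0, 100), "synchronous", occurrences=20)]
    data, gt = embed_assemblies(bg, specs, seed + 1, cfg)
    # dense background: mask overlap no longer separates signal from noise,
    # so the MinHash stage is disabled and all pairs are scored
    return data, gt, {"cfg": cfg, "alpha": 1.0, "n_extra": None,
                      "min_pts": 5, "v": 5}


@_regime("multi_timescale")
def _multi_timescale(seed: int, time_scales=(1.0, 3.0, 5.0, 10.0)):
    """30-neuron 200 ms sequences plus time-compressed copies of them.

    The same 30 members recur at each compression factor, 20 occurrences per
    factor, 1 Hz background, 60 s.
    """
    cfg = WindowConfig(0.2, 0.01)
    bg = generate_background(60, 1.0, 60.0, seed)
    members = _block(0, 30)
    specs = [
        AssemblySpec(members, "sequential", span=0.2, jitter=0.0,
                     occurrences=20, time_scale=ts)
        for ts in time_scales
    ]
    data, gt = embed_assemblies(bg, specs, seed + 1, cfg)
    return data, gt, {"cfg": cfg, "alpha": 0.1, "n_extra": 10,
                      "min_pts": 5, "v": 5}


def _embedded_sequence(seed: int, span: float, window_len: float):
    cfg = WindowConfig(window_len, 0.01)
    bg = generate_background(100, 1.0, 60.0, seed)
    specs = [AssemblySpec(_block(0, 10), "sequential", span=span, occurrences=60)]
    data, gt = embed_assemblies(bg, specs, seed + 1, cfg)
    return data, gt, {"cfg": cfg, "alpha": 1.0, "n_extra": 8}


@_regime("sequence_100ms")
def _sequence_100(seed: int):
    """One 10-neuron 100 ms sequence, 60 occurrences, 100 neurons at 1 Hz."""
    return _embedded_sequence(seed, 0.1, 0.2)


@_regime("sequence_500ms")
def _sequence_500(seed: int):
    """As sequence_100ms but the sequence spans 500 ms (500 ms windows)."""
    return _embedded_sequence(seed, 0.5, 0.5)


def benchmark_suite(name: str, n_datasets: int, seed: int, **kwargs):
    """Yield ``(SpikeData, SynthGroundTruth, config)`` for a named regime.

    Per-dataset seeds derive deterministically from the master seed.
    """
    if name not in BENCHMARK_REGIMES:
        raise ValueError(
            f"unknown regime {name!r}; available: {sorted(BENCHMARK_REGIMES)}"
        )
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_datasets)
    for child in children:
        sub = int(child.generate_state(1)[0] % (2**31 - 1))
        yield BENCHMARK_REGIMES[name](sub, **kwargs)
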