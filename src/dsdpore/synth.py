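"""Synthetic nanopore-array ionic-current traces with ground truth.

Emulates a MinION-style flow cell running a voltage-flip script: each channel
shows an open-pore current (Gaussian around ~220 pA), periodically
interrupted by a brief saturated negative flip artifact that ejects any
captured strand.  Between flips, free barcoded output strands are captured as
a Poisson process whose rate is proportional to their solution concentration;
a biotin-streptavidin stopper prevents translocation, so a captured strand
blocks the pore — dropping the current to a barcode-specific fractional
level — until the next flip ejects it.  Background noise blockades (short,
odd-leveled, high-variance) can be injected to exercise the downstream
filters.

All generators are deterministic under their integer seed (bit-identical
traces), and every blockade is annotated in a ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .circuits import CircuitSystem, KineticsTrajectory

__all__ = [
    "BarcodeSignalModel",
    "ChannelConfig",
    "TruthEvent",
    "ChannelTrace",
    "Schedule",
    "SyntheticRun",
    "generate_channel_trace",
    "generate_array_run",
    "inject_noise_events",
    "sample_event_windows",
    "write_run_hdf5",
    "read_run_hdf5",
    "write_trace_csv",
    "read_trace_csv",
]

#: current rendered during the voltage-flip artifact (saturated negative), pA
FLIP_SATURATION_PA = -250.0
#: detection threshold the signal models must stay below (fraction of I_o)
DETECTION_CEILING = 0.7


@dataclass(frozen=True)
class BarcodeSignalModel:
    """Signal model of one barcoded output strand held in a pore.

    The blockade level of an event is ``mean_fractional_current`` plus an
    event-level offset ~ N(0, level_sd) (pore-to-pore and capture-to-capture
    variability); individual samples add N(0, within_event_sd).  Optionally
    the level flickers between two sub-states (telegraph noise with symmetric
    switching rate ``flicker_rate`` and depth ``flicker_depth``), emulating
    the multi-level noise structure real blockades show.
    """

    barcode_id: str
    mean_fractional_current: float
    within_event_sd: float
    level_sd: float = 0.005
    flicker_depth: float = 0.0
    flicker_rate: float = 0.0  # s^-1

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_fractional_current < DETECTION_CEILING:
            raise ValueError(
                f"mean_fractional_current of {self.barcode_id!r} must lie in "
                f"(0, {DETECTION_CEILING}) to be detectable, got "
                f"{self.mean_fractional_current}"
            )
        if self.within_event_sd <= 0:
            raise ValueError("within_event_sd must be > 0")
        if self.level_sd < 0 or self.flicker_depth < 0 or self.flicker_rate < 0:
            raise ValueError("level_sd/flicker parameters must be >= 0")


@dataclass(frozen=True)
class ChannelConfig:
    """Per-channel acquisition and capture-physics parameters."""

    open_pore_current: float = 220.0  # pA
    open_pore_sd: float = 2.0  # pA
    sampling_rate: float = 10_000.0  # Hz
    flip_period: float = 15.0  # s between ejection flips
    flip_dead_time: float = 0.1  # s of saturated artifact after each flip
    capture_rate_per_uM: float = 0.2  # s^-1 uM^-1 (0.5 uM -> mean wait 10 s)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.flip_period > self.flip_dead_time >= 0:
            raise ValueError("need flip_period > flip_dead_time >= 0")
        if self.capture_rate_per_uM < 0:
            raise ValueError("capture_rate_per_uM must be >= 0")


@dataclass(frozen=True)
class TruthEvent:
    start_sample: int
    end_sample: int  # exclusive
    label: str  # barcode_id or "noise"


@dataclass
class ChannelTrace:
    channel_id: int
    samples: np.ndarray  # pA, float32
    config: ChannelConfig
    truth: list[TruthEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        last = 0
        for ev in sorted(self.truth, key=lambda e: e.start_sample):
            if ev.start_sample < last or ev.end_sample > len(self.samples):
                raise ValueError("truth intervals must be non-overlapping and in bounds")
            last = ev.end_sample

    @property
    def duration(self) -> float:
        return len(self.samples) / self.config.sampling_rate


class Schedule:
    """Per-barcode concentration vs time (uM), piecewise-linear."""

    def __init__(self, series: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        self._series = {
            k: (np.asarray(t, dtype=float), np.asarray(c, dtype=float))
            for k, (t, c) in series.items()
        }
        for k, (t, c) in self._series.items():
            if len(t) != len(c) or np.any(c < 0):
                raise ValueError(f"bad schedule for {k!r}")

    @classmethod
    def constant(cls, concs: Mapping[str, float]) -> "Schedule":
        return cls({k: (np.array([0.0]), np.array([float(v)])) for k, v in concs.items()})

    @classmethod
    def from_trajectory(
        cls,
        trajectory: KineticsTrajectory,
        barcode_map: Mapping[str, str],
        system: CircuitSystem | None = None,
    ) -> "Schedule":
        """Map trajectory species to barcodes: ``{species_name: barcode_id}``.

        If ``system`` is given, every species with role ``output`` must be
        mapped (unmapped free outputs would be invisible to the synthesizer).
        """
        if system is not None:
            outputs = {s.name for s in system.species.values() if s.role == "output"}
            missing = outputs - set(barcode_map)
            if missing:
                raise ValueError(f"unmapped output species: {sorted(missing)}")
        series = {}
        for species_name, barcode_id in barcode_map.items():
            if species_name not in trajectory.concentrations.columns:
                raise ValueError(f"species {species_name!r} not in trajectory")
            series[barcode_id] = (trajectory.times, trajectory.species(species_name))
        return cls(series)

    @property
    def barcode_ids(self) -> list[str]:
        return list(self._series)

    def at(self, t: float) -> dict[str, float]:
        return {
            k: float(np.interp(t, ts, cs)) for k, (ts, cs) in self._series.items()
        }


@dataclass
class SyntheticRun:
    traces: list[ChannelTrace]
    schedule: Schedule
    seed: int
    models: dict[str, BarcodeSignalModel] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Event-sample synthesis


def _blockade_fractional(
    rng: np.random.Generator,
    model: BarcodeSignalModel,
    n_samples: int,
    sampling_rate: float,
) -> np.ndarray:
    """Fractional-current samples of one blockade under ``model``."""
    level = model.mean_fractional_current + rng.normal(0.0, model.level_sd)
    frac = np.full(n_samples, level, dtype=np.float64)
    if model.flicker_rate > 0 and model.flicker_depth > 0:
        # symmetric two-state telegraph process, start state random
        state = int(rng.integers(0, 2))
        i = 0
        while i < n_samples:
            hold = rng.exponential(1.0 / model.flicker_rate)
            j = min(n_samples, i + max(1, int(round(hold * sampling_rate))))
            if state == 1:
                frac[i:j] -= model.flicker_depth
            state ^= 1
            i = j
    frac += rng.normal(0.0, model.within_event_sd, n_samples)
    return frac


def sample_event_windows(
    model: BarcodeSignalModel,
    n_events: int,
    n_samples: int = 20_000,
    sampling_rate: float = 10_000.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n_events`` fractional-current event windows directly from a
    barcode model (no full trace synthesis) — the characterization-run
    shortcut used to build classifier training sets.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((n_events, n_samples), dtype=np.float32)
    for i in range(n_events):
        out[i] = _blockade_fractional(rng, model, n_samples, sampling_rate)
    return out


# ---------------------------------------------------------------------------
# Trace generation


def generate_channel_trace(
    config: ChannelConfig,
    models: Sequence[BarcodeSignalModel],
    schedule: Schedule,
    duration: float,
    noise_event_rate: float = 0.0,
    seed: int = 0,
    channel_id: int = 0,
    noise_level_range: tuple[float, float] = (0.05, 0.65),
    noise_duration_range: tuple[float, float] = (0.002, 1.5),
    noise_sd_range: tuple[float, float] = (0.06, 0.15),
) -> ChannelTrace:
    """Synthesize one channel's raw current trace.

    Within each inter-flip window the waiting time to a barcode capture is
    exponential with rate ``capture_rate_per_uM * sum(concentrations)``
    (competing barcodes chosen proportional to concentration, concentrations
    held piecewise-constant per 15 s cycle); a capture blocks the pore until
    the next flip.  Noise blockades occur at ``noise_event_rate`` during
    open-pore time and end on their own.
    """
    if duration < config.flip_period:
        raise ValueError("duration must cover at least one flip period")
    model_by_id = {m.barcode_id: m for m in models}
    missing = set(schedule.barcode_ids) - set(model_by_id)
    if missing:
        raise ValueError(f"schedule references unmodeled barcodes: {sorted(missing)}")

    fs = config.sampling_rate
    n_total = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    samples = rng.standard_normal(n_total, dtype=np.float32)
    samples *= np.float32(config.open_pore_sd)
    samples += np.float32(config.open_pore_current)
    truth: list[TruthEvent] = []

    def s_of(t: float) -> int:
        return min(n_total, int(round(t * fs)))

    t0 = 0.0
    while t0 < duration - 1e-9:
        t_end = min(t0 + config.flip_period, duration)
        # flip artifact (saturated negative excursion), excluded from analysis
        a0, a1 = s_of(t0), s_of(min(t0 + config.flip_dead_time, duration))
        samples[a0:a1] = FLIP_SATURATION_PA + rng.normal(0.0, 1.0, a1 - a0)
        t = t0 + config.flip_dead_time
        concs = schedule.at(t)
        ids = list(concs)
        rates = config.capture_rate_per_uM * np.array([concs[k] for k in ids])
        lam_c = float(rates.sum())
        lam_n = float(noise_event_rate)
        while t < t_end - 1e-9:
            wait_c = rng.exponential(1.0 / lam_c) if lam_c > 0 else np.inf
            wait_n = rng.exponential(1.0 / lam_n) if lam_n > 0 else np.inf
            if not np.isfinite(min(wait_c, wait_n)):
                break
            if wait_c <= wait_n:
                tc = t + wait_c
                if tc >= t_end:
                    break
                bc = ids[rng.choice(len(ids), p=rates / lam_c)]
                e0, e1 = s_of(tc), s_of(t_end)
                if e1 > e0:
                    frac = _blockade_fractional(rng, model_by_id[bc], e1 - e0, fs)
                    samples[e0:e1] = (frac * config.open_pore_current).astype(np.float32)
                    truth.append(TruthEvent(e0, e1, bc))
                break  # captured strand held until the flip
            tn = t + wait_n
            if tn >= t_end:
                break
            dur = rng.uniform(*noise_duration_range)
            ne = min(tn + dur, t_end)
            e0, e1 = s_of(tn), s_of(ne)
            if e1 > e0:
                level = rng.uniform(*noise_level_range)
                sd = rng.uniform(*noise_sd_range)
                noisy = level + rng.normal(0.0, sd, e1 - e0)
                samples[e0:e1] = (noisy * config.open_pore_current).astype(np.float32)
                truth.append(TruthEvent(e0, e1, "noise"))
            t = ne
        t0 += config.flip_period
    return ChannelTrace(channel_id, samples, config, truth)


def generate_array_run(
    n_channels: int,
    schedule: Schedule,
    models: Sequence[BarcodeSignalModel],
    config: ChannelConfig,
    duration: float,
    noise_event_rate: float = 0.0,
    seed: int = 0,
) -> SyntheticRun:
    """Generate a multi-channel run; per-channel seeds are spawned
    deterministically from the run seed."""
    if n_channels < 0:
        raise ValueError("n_channels must be >= 0")
    child_seeds = np.random.SeedSequence(seed).generate_state(max(n_channels, 1))
    traces = [
        generate_channel_trace(
            config,
            models,
            schedule,
            duration,
            noise_event_rate=noise_event_rate,
            seed=int(child_seeds[i]) % (2**31),
            channel_id=i,
        )
        for i in range(n_channels)
    ]
    return SyntheticRun(traces, schedule, seed, {m.barcode_id: m for m in models})


def inject_noise_events(
    trace: ChannelTrace,
    rate: float,
    level_range: tuple[float, float] = (0.05, 0.65),
    duration_range: tuple[float, float] = (0.002, 1.5),
    sd_range: tuple[float, float] = (0.06, 0.15),
    seed: int = 0,
) -> ChannelTrace:
    """Add background noise blockades into the open-pore stretches of an
    existing trace (new trace returned; truth entries labeled "noise").

    Defaults draw durations below the 2 s length filter and sample noise
    well outside barcode feature envelopes, so injected events are
    adversarial for the downstream filters by construction.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return trace
    if not (0 < level_range[0] <= level_range[1] < DETECTION_CEILING):
        raise ValueError("level_range must lie within (0, 0.7)")
    if duration_range[0] <= 0 or duration_range[0] > duration_range[1]:
        raise ValueError("invalid duration_range")

    cfg = trace.config
    fs = cfg.sampling_rate
    n_total = len(trace.samples)
    rng = np.random.default_rng(seed)
    samples = trace.samples.copy()
    truth = list(trace.truth)
    occupied = np.zeros(n_total, dtype=bool)
    for ev in trace.truth:
        occupied[ev.start_sample : ev.end_sample] = True

    t0 = 0.0
    duration = trace.duration
    while t0 < duration - 1e-9:
        t_end = min(t0 + cfg.flip_period, duration)
        t = t0 + cfg.flip_dead_time
        while t < t_end - 1e-9:
            t += rng.exponential(1.0 / rate)
            if t >= t_end:
                break
            dur = rng.uniform(*duration_range)
            e0 = min(n_total, int(round(t * fs)))
            e1 = min(n_total, int(round(min(t + dur, t_end) * fs)))
            if e1 > e0 and not occupied[e0:e1].any():
                level = rng.uniform(*level_range)
                sd = rng.uniform(*sd_range)
                noisy = level + rng.normal(0.0, sd, e1 - e0)
                samples[e0:e1] = (noisy * cfg.open_pore_current).astype(np.float32)
                truth.append(TruthEvent(e0, e1, "noise"))
                occupied[e0:e1] = True
            t += dur
        t0 += cfg.flip_period
    truth.sort(key=lambda e: e.start_sample)
    return ChannelTrace(trace.channel_id, samples, cfg, truth)


# ---------------------------------------------------------------------------
# Trace container I/O (HDF5 bulk-style; CSV fallback for tiny fixtures)


def write_run_hdf5(run: SyntheticRun, path, truth_tsv=None) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["seed"] = run.seed
        for trace in run.traces:
            grp = fh.create_group(f"channels/ch{trace.channel_id}")
            grp.create_dataset("signal", data=trace.samples, compression="gzip")
            for k, v in vars(trace.config).items():
                grp.attrs[k] = v
    if truth_tsv is not None:
        write_truth_tsv(run.traces, truth_tsv)


def write_truth_tsv(traces: Sequence[ChannelTrace], path) -> None:
    import pandas as pd

    rows = [
        (t.channel_id, ev.start_sample, ev.end_sample, ev.label)
        for t in traces
        for ev in t.truth
    ]
    pd.DataFrame(rows, columns=["channel", "start_sample", "end_sample", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_run_hdf5(path, truth_tsv=None) -> list[ChannelTrace]:
    import h5py
    import pandas as pd

    truth_by_ch: dict[int, list[TruthEvent]] = {}
    if truth_tsv is not None:
        tdf = pd.read_csv(truth_tsv, sep="\t")
        for _, row in tdf.iterrows():
            truth_by_ch.setdefault(int(row["channel"]), []).append(
                TruthEvent(int(row["start_sample"]), int(row["end_sample"]), row["label"])
            )
    traces = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh["channels"], key=lambda s: int(s[2:])):
            grp = fh[f"channels/{name}"]
            cfg = ChannelConfig(**{k: grp.attrs[k] for k in vars(ChannelConfig())})
            cid = int(name[2:])
            traces.append(
                ChannelTrace(cid, grp["signal"][:], cfg, truth_by_ch.get(cid, []))
            )
    return traces


def write_trace_csv(trace: ChannelTrace, path) -> None:
    np.savetxt(path, trace.samples, fmt="%.3f", header="current_pA", comments="")


def read_trace_csv(path, config: ChannelConfig, channel_id: int = 0) -> ChannelTrace:
    samples = np.loadtxt(path, skiprows=1).astype(np.float32)
    return ChannelTrace(channel_id, samples, config, [])
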