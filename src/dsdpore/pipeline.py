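"""Orchestration: simulate -> synthesize -> extract -> classify -> quantify.

Each experiment runs from a single integer seed and (optionally) writes a
self-describing run directory: stage artifacts as tidy CSV/TSV/JSON, a log of
every default applied, and a manifest with SHA-256 checksums, so a run is
re-executable and byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify as cls
from . import extract as ex
from . import quantify as qt
from . import synth
from .circuits import CircuitSystem, KineticsTrajectory, simulate

__all__ = [
    "ReferenceBundle",
    "build_reference_bundle",
    "records_from_events",
    "run_titration",
    "run_kinetics_experiment",
    "run_profile_experiment",
    "write_run_dir",
]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def reference_events_from_windows(
    windows: np.ndarray, barcode: str, sampling_rate: float = 10_000.0
) -> list[ex.CaptureEvent]:
    """Wrap characterization windows as events (for envelope calibration)."""
    events = []
    dt = windows.shape[1] / sampling_rate
    for i, w in enumerate(windows):
        events.append(
            ex.CaptureEvent(
                channel_id=-1,
                start_time=i * dt,
                end_time=(i + 1) * dt,
                raw_samples=w,
                fractional_samples=w,
                open_pore_current=1.0,
            )
        )
    return events


@dataclass
class ReferenceBundle:
    """Classifier + filter calibrated on per-barcode characterization data."""

    filter_spec: ex.FilterSpec
    trained: cls.TrainedModel | None  # None when only one barcode is in play
    models: dict[str, synth.BarcodeSignalModel]


def build_reference_bundle(
    models: Sequence[synth.BarcodeSignalModel],
    classifier_spec: cls.ClassifierSpec | None,
    n_events_per_barcode: int = 400,
    seed: int = 0,
    window_samples: int = cls.WINDOW_SAMPLES,
) -> ReferenceBundle:
    """Sample characterization windows per barcode, calibrate the feature
    envelopes, and (if more than one barcode) train the classifier."""
    seeds = _spawn_seeds(seed, len(models) + 1)
    windows, labels, labeled_events = [], [], {}
    for m, s in zip(models, seeds):
        w = synth.sample_event_windows(m, n_events_per_barcode, window_samples, seed=s)
        windows.append(w)
        labels += [m.barcode_id] * len(w)
        labeled_events[m.barcode_id] = reference_events_from_windows(w, m.barcode_id)
    X = np.concatenate(windows, axis=0)
    y = np.array(labels)
    filter_spec = ex.calibrate_filter_envelopes(labeled_events)
    trained = None
    if classifier_spec is not None and len(models) > 1:
        trained = cls.train(classifier_spec, X, y)
    return ReferenceBundle(filter_spec, trained, {m.barcode_id: m for m in models})


def records_from_events(
    events: Sequence[ex.CaptureEvent],
    bundle: ReferenceBundle,
    confidence_threshold: float | None = None,
    window_samples: int = cls.WINDOW_SAMPLES,
) -> tuple[list[qt.CaptureRecord], pd.DataFrame]:
    """Filter + classify detected events into capture records.

    Every detected blockade becomes a record: events failing the feature or
    length filter are labeled "noise"; events passing the filter are
    classified; predictions below the confidence threshold become
    "unclassified".  Noise and unclassified records still count as
    pore-occupied time downstream.

    Single-barcode runs need no classifier, so the 2 s length filter (whose
    only purpose is to guarantee a full classification window) is not
    applied to the label: any event passing the five-feature envelopes is
    the barcode.  Ejection-limited captures that start near a flip would
    otherwise be dropped and bias waiting-time statistics upward.
    """
    labeling_spec = bundle.filter_spec
    if bundle.trained is None:
        # mean/median are the only features whose calibration transfers to
        # arbitrarily short events (extreme-value and sd estimates depend on
        # the event length); envelopes were calibrated on 2 s windows
        labeling_spec = ex.FilterSpec(
            {
                k: v
                for k, v in bundle.filter_spec.feature_ranges.items()
                if k in ("mean", "median")
            },
            min_duration=ex.DEFAULT_MIN_EVENT_DURATION,
            provenance=bundle.filter_spec.provenance,
        )
    reasons = ex.filter_reasons(events, labeling_spec)
    kept_idx = [i for i, r in enumerate(reasons) if r is None]
    labels = ["noise"] * len(events)
    confidences = [np.nan] * len(events)
    if kept_idx:
        if bundle.trained is None:
            only = next(iter(bundle.models))
            for i in kept_idx:
                labels[i] = only
                confidences[i] = 1.0
        else:
            X = cls.windows_matrix([events[i] for i in kept_idx], n_samples=window_samples)
            preds = cls.predict(bundle.trained.model, X, threshold=confidence_threshold)
            for i, p in zip(kept_idx, preds):
                labels[i] = p.predicted_label if p.passed_confidence_filter else "unclassified"
                confidences[i] = p.confidence
    records = [
        qt.CaptureRecord(ev.channel_id, lab, ev.start_time, ev.end_time)
        for ev, lab in zip(events, labels)
    ]
    table = ex.events_table(events, bundle.filter_spec)
    table["label"] = labels
    table["confidence"] = confidences
    return records, table


def _good_channel_count(qc: Mapping[int, dict]) -> int:
    return sum(1 for v in qc.values() if v["good_channel"])


def extract_streamed_run(
    n_channels: int,
    schedule: synth.Schedule,
    models: Sequence[synth.BarcodeSignalModel],
    config: synth.ChannelConfig,
    duration: float,
    noise_event_rate: float = 0.0,
    seed: int = 0,
    max_stored_seconds: float | None = 2.5,
    **extract_kwargs,
) -> tuple[list[ex.CaptureEvent], dict[int, dict]]:
    """Generate and extract one channel at a time (identical seeds and output
    to generate_array_run followed by extract_run, without holding the whole
    multi-gigasample array in memory)."""
    child_seeds = np.random.SeedSequence(seed).generate_state(max(n_channels, 1))
    all_events: list[ex.CaptureEvent] = []
    qc: dict[int, dict] = {}
    for i in range(n_channels):
        trace = synth.generate_channel_trace(
            config,
            models,
            schedule,
            duration,
            noise_event_rate=noise_event_rate,
            seed=int(child_seeds[i]) % (2**31),
            channel_id=i,
        )
        events, chan_qc = ex.extract_channel(
            trace, max_stored_seconds=max_stored_seconds, **extract_kwargs
        )
        all_events.extend(events)
        qc[i] = chan_qc
        del trace
    return all_events, qc


# ---------------------------------------------------------------------------
# Experiments


@dataclass
class TitrationResult:
    curve: qt.StandardCurve
    table: pd.DataFrame  # concentration_uM, duration_s, n_gaps, mean_tbc_s


def run_titration(
    model: synth.BarcodeSignalModel,
    channel_config: synth.ChannelConfig,
    concentrations: Sequence[float],
    durations: Sequence[float],
    n_channels: int | Sequence[int] = 8,
    seed: int = 0,
    noise_event_rate: float = 0.0,
) -> TitrationResult:
    """Constant-concentration runs over a titration grid; standard-curve fit.

    ``n_channels`` may be per-point (low concentrations need more pores for
    the same capture count).  Each point's average TBC is the censoring-aware
    exposure estimate (unoccupied open-pore seconds per capture), with the
    plain mean of completed gaps reported alongside.
    """
    if len(concentrations) < 3:
        raise ValueError("need >= 3 concentrations for a titration")
    if len(durations) != len(concentrations):
        raise ValueError("durations must align with concentrations")
    if np.isscalar(n_channels):
        n_channels = [int(n_channels)] * len(concentrations)
    if len(n_channels) != len(concentrations):
        raise ValueError("n_channels must be scalar or align with concentrations")
    bundle = build_reference_bundle([model], None, seed=seed)
    rows = []
    seeds = _spawn_seeds(seed + 1, len(concentrations))
    for conc, dur, nch, s in zip(concentrations, durations, n_channels, seeds):
        events, qc = extract_streamed_run(
            nch,
            synth.Schedule.constant({model.barcode_id: conc}),
            [model],
            channel_config,
            dur,
            noise_event_rate=noise_event_rate,
            seed=s,
        )
        records, _tab = records_from_events(events, bundle)
        gaps = qt.time_between_captures(records, model.barcode_id)
        n_captures = sum(1 for r in records if r.label == model.barcode_id)
        analyzed = sum(v["analyzed_seconds"] for v in qc.values())
        occupied = sum(r.end_time - r.start_time for r in records)
        rows.append(
            {
                "concentration_uM": conc,
                "duration_s": dur,
                "n_channels": nch,
                "n_captures": n_captures,
                "n_gaps": len(gaps),
                "mean_gap_tbc_s": float(np.mean(gaps)) if gaps else np.nan,
                "mean_tbc_s": qt.exposure_tbc(n_captures, analyzed - occupied)
                if n_captures
                else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    if table["mean_tbc_s"].isna().any():
        raise RuntimeError("titration point collected no captures; run longer")
    curve = qt.fit_standard_curve(
        table["concentration_uM"], table["mean_tbc_s"], table["n_captures"]
    )
    return TitrationResult(curve, table)


@dataclass
class KineticsResult:
    trajectory: KineticsTrajectory
    series: qt.KineticsSeries
    records: list[qt.CaptureRecord]
    events_table: pd.DataFrame
    curve: qt.StandardCurve
    saturated_concentration: float
    qc: dict


def run_kinetics_experiment(
    system: CircuitSystem,
    output_species: str,
    model: synth.BarcodeSignalModel,
    channel_config: synth.ChannelConfig,
    run_duration: float,
    n_channels: int = 30,
    curve: qt.StandardCurve | None = None,
    saturated_concentration: float | None = None,
    metric: str = "concentration",
    bin_seconds: float = qt.DEFAULT_BIN_SECONDS,
    noise_event_rate: float = 0.0,
    seed: int = 0,
) -> KineticsResult:
    """Real-time single-circuit kinetics readout.

    Simulates the circuit, synthesizes a concurrent nanopore run whose
    capture rates track the free output concentration, extracts and filters
    events, and bins the result into a normalized kinetics series.  The
    standard curve defaults to a small internal titration with the same
    channel physics; the saturated reference defaults to a separate
    constant-concentration run at the fully-displaced output level, measured
    through the same pipeline.
    """
    s_traj, s_curve, s_run, s_sat = _spawn_seeds(seed, 4)
    trajectory = simulate(system, run_duration, step=min(10.0, bin_seconds / 10))
    if curve is None:
        grid = [0.1, 0.2, 0.5, 1.0]
        curve = run_titration(
            model,
            channel_config,
            grid,
            [600.0] * len(grid),
            n_channels=max(4, n_channels // 6),
            seed=s_curve,
        ).curve

    bundle = build_reference_bundle([model], None, seed=s_traj)
    schedule = synth.Schedule.from_trajectory(trajectory, {output_species: model.barcode_id})
    events, qc = extract_streamed_run(
        n_channels,
        schedule,
        [model],
        channel_config,
        run_duration,
        noise_event_rate=noise_event_rate,
        seed=s_run,
    )
    records, table = records_from_events(events, bundle)

    if saturated_concentration is None:
        # separate saturated sample: free output at its plateau level; sized
        # so the reference TBC carries only a few percent standard error
        plateau = float(trajectory.species(output_species)[-1])
        sat_events, _ = extract_streamed_run(
            max(8, n_channels // 3),
            synth.Schedule.constant({model.barcode_id: plateau}),
            [model],
            channel_config,
            900.0,
            seed=s_sat,
        )
        sat_records, _ = records_from_events(sat_events, bundle)
        sat_tbc = qt.mean_tbc(sat_records, model.barcode_id)
        saturated_concentration = qt.concentration_from_tbc(
            curve, sat_tbc, warn_extrapolation=False
        )

    series = qt.kinetics_series(
        records,
        model.barcode_id,
        duration=run_duration,
        metric=metric,
        bin_seconds=bin_seconds,
        background=0.0,
        saturated=saturated_concentration,
        curve=curve,
        n_good_channels=max(_good_channel_count(qc), 1),
    )
    return KineticsResult(trajectory, series, records, table, curve, saturated_concentration, qc)


@dataclass
class ProfileResult:
    profile: pd.DataFrame  # barcode, f, f_background, f_saturated, normalized
    records: list[qt.CaptureRecord]
    events_table: pd.DataFrame
    qc: dict
    references: dict[str, tuple[float, float]] = field(default_factory=dict)
    bundle: ReferenceBundle | None = None


def run_profile_experiment(
    present_concentrations: Mapping[str, float],
    models: Sequence[synth.BarcodeSignalModel],
    channel_config: synth.ChannelConfig,
    run_duration: float,
    classifier_spec: cls.ClassifierSpec,
    saturated_concentrations: Mapping[str, float],
    n_channels: int = 16,
    reference_channels: int = 6,
    reference_duration: float = 600.0,
    n_reference_events: int = 400,
    noise_event_rate: float = 0.05,
    confidence_threshold: float | None = None,
    seed: int = 0,
    bundle: ReferenceBundle | None = None,
    references: Mapping[str, tuple[float, float]] | None = None,
) -> ProfileResult:
    """Steady-state multiplex readout (capture-frequency bar profile).

    The sample run contains the barcodes in ``present_concentrations`` at
    their steady-state free-output concentrations.  Every barcode the
    classifier knows is reported: its capture frequency f in the sample run
    is normalized against a background reference (no activation: f measured
    on a run with no output strands) and a saturated reference (the barcode
    alone at its fully-activated concentration), each measured through the
    identical pipeline.
    """
    s_bundle, s_run, s_bg, *s_sats = _spawn_seeds(seed, 3 + len(models))
    if bundle is None:
        bundle = build_reference_bundle(
            models, classifier_spec, n_events_per_barcode=n_reference_events, seed=s_bundle
        )
    unknown = set(present_concentrations) - set(bundle.models)
    if unknown:
        raise ValueError(f"present barcodes without signal models: {sorted(unknown)}")

    def _measure(concs: Mapping[str, float], n_ch: int, dur: float, s: int):
        events, qc = extract_streamed_run(
            n_ch,
            synth.Schedule.constant(dict(concs)),
            models,
            channel_config,
            dur,
            noise_event_rate=noise_event_rate,
            seed=s,
        )
        records, table = records_from_events(
            events, bundle, confidence_threshold=confidence_threshold
        )
        n_good = max(_good_channel_count(qc), 1)
        return records, table, qc, n_good

    records, table, qc, n_good = _measure(
        present_concentrations, n_channels, run_duration, s_run
    )

    if references is None:
        references = {}
        bg_records, _, _, bg_good = _measure({}, reference_channels, reference_duration, s_bg)
        for m, s_sat in zip(models, s_sats):
            bc = m.barcode_id
            f_bg = qt.capture_frequency(bg_records, bc, bg_good, reference_duration / 60.0)
            sat_conc = saturated_concentrations.get(bc)
            if sat_conc is None:
                references[bc] = (f_bg, np.nan)
                continue
            sat_records, _, _, sat_good = _measure(
                {bc: sat_conc}, reference_channels, reference_duration, s_sat
            )
            references[bc] = (
                f_bg,
                qt.capture_frequency(sat_records, bc, sat_good, reference_duration / 60.0),
            )

    rows = []
    for m in models:
        bc = m.barcode_id
        f = qt.capture_frequency(records, bc, n_good, run_duration / 60.0)
        f_bg, f_sat = references[bc]
        rows.append(
            dict(
                barcode=bc,
                f=f,
                f_background=f_bg,
                f_saturated=f_sat,
                normalized=qt.normalize_eq2(f, f_bg, f_sat) if np.isfinite(f_sat) else np.nan,
            )
        )
    profile = pd.DataFrame(rows)
    return ProfileResult(profile, records, table, qc, dict(references), bundle)


# ---------------------------------------------------------------------------
# Run-directory plumbing


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_run_dir(outdir, artifacts: Mapping[str, object], config: Mapping | None = None) -> Path:
    """Write artifacts (DataFrame -> CSV/TSV, dict -> JSON, str -> text) plus
    a checksum manifest; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if config is not None:
        p = outdir / "config.json"
        p.write_text(json.dumps(config, indent=2, sort_keys=True, default=str))
        written.append(p)
    for name, obj in artifacts.items():
        p = outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(p, sep="\t" if name.endswith(".tsv") else ",", index=False)
        elif isinstance(obj, (dict, list)):
            p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        else:
            p.write_text(str(obj))
        written.append(p)
    manifest = {p.name: _sha256(p) for p in written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
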