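"""Capture-event isolation from raw nanopore current.

A capture event is a run of samples at or below 70% of the open-pore current
lasting longer than one millisecond.  The trace is first split into
inter-flip segments (the voltage-flip artifact is a saturated negative
excursion and is excluded); the open-pore level I_o is estimated per segment
with a blockade-robust median; events are expressed as fractional current
I_b / I_o and summarized by five features (mean, median, minimum, maximum,
standard deviation).  Putative output-strand events are then separated from
background noise by a five-feature envelope filter plus a >= 2 s length
filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synth import ChannelTrace

__all__ = [
    "CaptureEvent",
    "FilterSpec",
    "NoOpenPoreError",
    "segment_boundaries",
    "estimate_open_pore",
    "detect_captures",
    "apply_filters",
    "filter_reasons",
    "calibrate_filter_envelopes",
    "extract_channel",
    "extract_run",
    "events_table",
]

FEATURE_NAMES = ("mean", "median", "minimum", "maximum", "sd")

DEFAULT_THRESHOLD_FRACTION = 0.7
DEFAULT_MIN_EVENT_DURATION = 0.001  # s, events must be strictly longer
DEFAULT_MIN_KEPT_DURATION = 2.0  # s, length filter


class NoOpenPoreError(ValueError):
    """Segment contains no identifiable open-pore level."""


@dataclass(eq=False)  # identity equality: events hold large sample arrays
class CaptureEvent:
    channel_id: int
    start_time: float  # s, relative to trace start
    end_time: float
    raw_samples: np.ndarray  # pA
    fractional_samples: np.ndarray  # I_b / I_o
    open_pore_current: float  # the I_o used
    features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("end_time must exceed start_time")
        if not self.features:
            self.features = compute_features(self.fractional_samples)

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def compute_features(fractional: np.ndarray) -> dict[str, float]:
    """The five summary statistics of an event's fractional-current trace.

    Standard deviation is the sample (ddof=1) estimate; a one-sample event
    gets sd 0.
    """
    fractional = np.asarray(fractional, dtype=float)
    sd = float(np.std(fractional, ddof=1)) if len(fractional) > 1 else 0.0
    return {
        "mean": float(np.mean(fractional)),
        "median": float(np.median(fractional)),
        "minimum": float(np.min(fractional)),
        "maximum": float(np.max(fractional)),
        "sd": sd,
    }


@dataclass
class FilterSpec:
    """Envelope + length filter separating output-strand events from noise.

    ``feature_ranges`` maps each of the five feature names to an inclusive
    (lo, hi) interval; an event is kept iff all five features are inside
    their interval and its duration is >= ``min_duration`` (default 2 s).
    ``provenance`` records whether the envelopes are global defaults or
    calibrated on a particular experiment.
    """

    feature_ranges: dict[str, tuple[float, float]]
    min_duration: float = DEFAULT_MIN_KEPT_DURATION
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        unknown = set(self.feature_ranges) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names {sorted(unknown)}")
        for name, (lo, hi) in self.feature_ranges.items():
            if not lo < hi:
                raise ValueError(f"envelope for {name!r} needs lo < hi, got ({lo}, {hi})")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be > 0")


# ---------------------------------------------------------------------------
# Segmentation and open-pore estimation


def segment_boundaries(samples: np.ndarray, min_gap_samples: int = 1) -> list[tuple[int, int]]:
    """Split a trace into analysis segments at voltage-flip artifacts.

    Flip artifacts are rendered (and physically measured) as negative
    current; analysis segments are the maximal non-negative stretches.
    """
    ok = np.asarray(samples) >= 0.0
    if not ok.any():
        return []
    d = np.diff(np.concatenate(([0], ok.astype(np.int8), [0])))
    seg_starts = np.flatnonzero(d == 1)
    seg_ends = np.flatnonzero(d == -1)
    return [
        (int(s), int(e)) for s, e in zip(seg_starts, seg_ends) if e - s >= min_gap_samples
    ]


def estimate_open_pore(
    segment: np.ndarray,
    plausible_range: tuple[float, float] | None = None,
    top_fraction: float = 0.9,
) -> float:
    """Robust open-pore current estimate for one inter-flip segment.

    Median of samples above ``top_fraction`` x the segment maximum — blockade
    samples sit far below the unblocked level, so the estimate is insensitive
    to blockades occupying most of the segment.  If ``plausible_range`` is
    given and the estimate falls outside it (e.g. a segment blocked
    end-to-end), :class:`NoOpenPoreError` is raised so the caller can skip
    the segment.
    """
    segment = np.asarray(segment, dtype=float)
    if len(segment) == 0:
        raise NoOpenPoreError("empty segment")
    top = segment[segment >= top_fraction * segment.max()]
    est = float(np.median(top))
    if plausible_range is not None and not plausible_range[0] <= est <= plausible_range[1]:
        raise NoOpenPoreError(
            f"no open pore: estimate {est:.1f} pA outside {plausible_range}"
        )
    return est


# ---------------------------------------------------------------------------
# Detection


def detect_captures(
    segment: np.ndarray,
    open_pore: float,
    sampling_rate: float,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    min_duration: float = DEFAULT_MIN_EVENT_DURATION,
    segment_start_sample: int = 0,
    channel_id: int = 0,
) -> list[CaptureEvent]:
    """Find blockades in one segment.

    A capture event is a maximal run of samples at or below
    ``threshold_fraction * open_pore`` lasting strictly longer than
    ``min_duration`` (the 1 ms rule).  Events are truncated at the segment
    (flip) boundaries.  Event times are sample_index / sampling_rate relative
    to the whole trace; the span is [first below-threshold sample, one past
    the last], half-open.
    """
    segment = np.asarray(segment)
    below = segment <= threshold_fraction * open_pore
    if not below.any():
        return []
    d = np.diff(np.concatenate(([0], below.astype(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    min_samples = min_duration * sampling_rate
    events = []
    for s, e in zip(starts, ends):
        if (e - s) <= min_samples:
            continue
        raw = np.array(segment[s:e], dtype=np.float32)  # own the memory
        events.append(
            CaptureEvent(
                channel_id=channel_id,
                start_time=(segment_start_sample + s) / sampling_rate,
                end_time=(segment_start_sample + e) / sampling_rate,
                raw_samples=raw,
                fractional_samples=raw / np.float32(open_pore),
                open_pore_current=open_pore,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Filtering


def _reject_reason(event: CaptureEvent, spec: FilterSpec) -> str | None:
    if event.duration < spec.min_duration:
        return "length"
    for name, (lo, hi) in spec.feature_ranges.items():
        if not lo <= event.features[name] <= hi:
            return f"feature:{name}"
    return None


def apply_filters(events: Sequence[CaptureEvent], spec: FilterSpec) -> list[CaptureEvent]:
    """Keep events passing both the five-feature envelope and the length
    filter; input ordering preserved. Idempotent."""
    return [ev for ev in events if _reject_reason(ev, spec) is None]


def filter_reasons(events: Sequence[CaptureEvent], spec: FilterSpec) -> list[str | None]:
    """Per-event reject reason (None = kept), aligned with the input."""
    return [_reject_reason(ev, spec) for ev in events]


def calibrate_filter_envelopes(
    labeled_events: Mapping[str, Sequence[CaptureEvent]],
    coverage: float = 0.995,
    min_events: int = 50,
    pad: float = 0.05,
    min_duration: float = DEFAULT_MIN_KEPT_DURATION,
) -> FilterSpec:
    """Empirical envelope calibration from per-barcode characterization runs.

    For each feature, the envelope is the union over barcodes of the central
    ``coverage`` quantile interval, padded by ``pad`` x its width on each
    side — wide enough to encapsulate every barcode's feature peak while
    excluding gross noise.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    for barcode, events in labeled_events.items():
        if len(events) < min_events:
            raise ValueError(
                f"barcode {barcode!r} has only {len(events)} events; "
                f"need >= {min_events} to calibrate"
            )
    alpha = (1.0 - coverage) / 2.0
    ranges: dict[str, tuple[float, float]] = {}
    for name in FEATURE_NAMES:
        lo = np.inf
        hi = -np.inf
        for events in labeled_events.values():
            vals = np.array([ev.features[name] for ev in events])
            lo = min(lo, float(np.quantile(vals, alpha)))
            hi = max(hi, float(np.quantile(vals, 1.0 - alpha)))
        width = hi - lo
        margin = pad * width if width > 0 else max(pad * abs(hi), 1e-9)
        ranges[name] = (lo - margin, hi + margin)
    return FilterSpec(ranges, min_duration=min_duration, provenance="calibrated")


# ---------------------------------------------------------------------------
# Channel / run orchestration


def extract_channel(
    trace: ChannelTrace,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    min_duration: float = DEFAULT_MIN_EVENT_DURATION,
    open_pore_range: tuple[float, float] | None = (150.0, 400.0),
    min_segment_duration: float = 0.01,
    max_stored_seconds: float | None = None,
) -> tuple[list[CaptureEvent], dict]:
    """Detect all blockades in one channel trace.

    Returns the events plus channel QC info: number of segments analyzed /
    skipped, total analyzed seconds, and whether the channel is "good"
    (>= 1 valid open-pore segment with an in-range estimate).

    ``max_stored_seconds`` truncates the *stored* per-event sample arrays
    (features and boundaries are always computed from the full event) —
    long captures are ejection-limited and can hold many seconds of signal
    that downstream stages never read beyond the classification window.
    """
    fs = trace.config.sampling_rate
    min_seg = int(np.ceil(min_segment_duration * fs))
    events: list[CaptureEvent] = []
    n_ok = n_skipped = 0
    analyzed_samples = 0
    for s0, s1 in segment_boundaries(trace.samples):
        if s1 - s0 < min_seg:
            n_skipped += 1
            continue
        seg = trace.samples[s0:s1]
        try:
            io = estimate_open_pore(seg, plausible_range=open_pore_range)
        except NoOpenPoreError:
            n_skipped += 1
            continue
        n_ok += 1
        analyzed_samples += s1 - s0
        found = detect_captures(
            seg,
            io,
            fs,
            threshold_fraction=threshold_fraction,
            min_duration=min_duration,
            segment_start_sample=s0,
            channel_id=trace.channel_id,
        )
        if max_stored_seconds is not None:
            keep = int(max_stored_seconds * fs)
            for ev in found:
                if len(ev.raw_samples) > keep:
                    ev.raw_samples = ev.raw_samples[:keep].copy()
                    ev.fractional_samples = ev.fractional_samples[:keep].copy()
        events.extend(found)
    qc = {
        "segments_ok": n_ok,
        "segments_skipped": n_skipped,
        "good_channel": n_ok >= 1,
        "analyzed_seconds": analyzed_samples / fs,
    }
    return events, qc


def extract_run(
    traces: Sequence[ChannelTrace], **kwargs
) -> tuple[list[CaptureEvent], dict[int, dict]]:
    """Extract events from every channel; events pooled, QC per channel."""
    all_events: list[CaptureEvent] = []
    qc: dict[int, dict] = {}
    for trace in traces:
        events, chan_qc = extract_channel(trace, **kwargs)
        all_events.extend(events)
        qc[trace.channel_id] = chan_qc
    return all_events, qc


def events_table(
    events: Sequence[CaptureEvent], spec: FilterSpec | None = None
) -> pd.DataFrame:
    """Tidy per-event table (one row per detected blockade)."""
    reasons = filter_reasons(events, spec) if spec is not None else [None] * len(events)
    rows = []
    for ev, reason in zip(events, reasons):
        rows.append(
            {
                "channel": ev.channel_id,
                "start_s": ev.start_time,
                "end_s": ev.end_time,
                "duration_s": ev.duration,
                "io_pA": ev.open_pore_current,
                "mean_frac": ev.features["mean"],
                "median_frac": ev.features["median"],
                "min_frac": ev.features["minimum"],
                "max_frac": ev.features["maximum"],
                "sd_frac": ev.features["sd"],
                "kept_flag": reason is None,
                "reject_reason": reason or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "channel",
            "start_s",
            "end_s",
            "duration_s",
            "io_pA",
            "mean_frac",
            "median_frac",
            "min_frac",
            "max_frac",
            "sd_frac",
            "kept_flag",
            "reject_reason",
        ],
    )
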