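"""From classified capture events to concentrations and kinetics.

Quantification rests on the single-molecule capture statistics: at a pore,
the unoccupied waiting time between consecutive captures of the same barcode
(time between captures, TBC) is inversely related to that strand's free
concentration.  This module implements

* TBC computation with occupied-time subtraction — intervals where the pore
  held noise, another barcode, or an unclassified strand do not count as
  waiting time;
* a titration standard curve ``TBC = a / C + b`` with inversion back to
  concentration;
* the affine normalizations against background (circuit not activated) and
  saturated (fully activated) references, applied to TBC, to capture
  frequency (reads per good channel per minute), or to curve-converted
  concentration;
* five-minute binning of either metric into kinetics series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CaptureRecord",
    "StandardCurve",
    "KineticsSeries",
    "IntegrityError",
    "time_between_captures",
    "mean_tbc",
    "fit_standard_curve",
    "concentration_from_tbc",
    "normalize_eq1",
    "normalize_eq2",
    "capture_frequency",
    "kinetics_series",
]

DEFAULT_BIN_SECONDS = 300.0  # five-minute intervals


class IntegrityError(ValueError):
    """Record stream violates physical constraints (overlap, negative gap)."""


@dataclass(frozen=True)
class CaptureRecord:
    """One classified blockade: barcode label, or "noise"/"unclassified"."""

    channel_id: int
    label: str
    start_time: float
    end_time: float

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("end_time must exceed start_time")


def _by_channel(records: Sequence[CaptureRecord]) -> dict[int, list[CaptureRecord]]:
    chans: dict[int, list[CaptureRecord]] = {}
    for rec in records:
        chans.setdefault(rec.channel_id, []).append(rec)
    for ch, recs in chans.items():
        recs.sort(key=lambda r: r.start_time)
        for a, b in zip(recs, recs[1:]):
            if b.start_time < a.end_time - 1e-9:
                raise IntegrityError(
                    f"overlapping records on channel {ch}: "
                    f"[{a.start_time}, {a.end_time}] and [{b.start_time}, {b.end_time}]"
                )
    return chans


def time_between_captures(
    records: Sequence[CaptureRecord],
    target_barcode: str,
    with_midpoints: bool = False,
):
    """Waiting times between consecutive captures of ``target_barcode``.

    Per channel, each consecutive pair of target captures contributes
    ``start2 - end1`` minus the total duration of any other-label blockades
    (noise, other barcodes, unclassified) inside the gap — those occupy the
    pore and are not waiting time.  Gaps are pooled across channels.  A
    negative corrected gap indicates corrupt records and raises
    :class:`IntegrityError`.

    With ``with_midpoints=True`` returns (gaps, midpoints) where the midpoint
    is the center of the [end1, start2] interval (used for binning).
    """
    gaps: list[float] = []
    mids: list[float] = []
    for recs in _by_channel(records).values():
        prev_end: float | None = None
        occupied = 0.0
        for rec in recs:
            if rec.label == target_barcode:
                if prev_end is not None:
                    gap = rec.start_time - prev_end - occupied
                    if gap < -1e-9:
                        raise IntegrityError(
                            f"negative waiting time {gap:.3g}s on channel "
                            f"{rec.channel_id}"
                        )
                    gaps.append(max(gap, 0.0))
                    mids.append(0.5 * (prev_end + rec.start_time))
                prev_end = rec.end_time
                occupied = 0.0
            elif prev_end is not None:
                occupied += rec.end_time - rec.start_time
    if with_midpoints:
        return gaps, mids
    return gaps


def mean_tbc(records: Sequence[CaptureRecord], target_barcode: str) -> float:
    """Average TBC pooled over all functional pores (nan if < 1 gap)."""
    gaps = time_between_captures(records, target_barcode)
    return float(np.mean(gaps)) if gaps else float("nan")


def exposure_tbc(n_captures: int, open_seconds: float) -> float:
    """Censoring-aware average TBC: unoccupied exposure per capture.

    The plain mean of completed gaps is biased low when the run is only a few
    mean waiting times long (the final, length-biased gap is cut off by the
    run end).  For exponential waiting this estimator — total unoccupied
    open-pore time divided by the number of captures — is the maximum-
    likelihood mean and is what the standard-curve fit consumes.
    """
    if n_captures < 1:
        raise ValueError("need >= 1 capture")
    if open_seconds <= 0:
        raise ValueError("open_seconds must be > 0")
    return open_seconds / n_captures


# ---------------------------------------------------------------------------
# Standard curve


@dataclass
class StandardCurve:
    """First-order capture model ``TBC = a / C + b`` fitted to titrations.

    ``b`` absorbs per-capture dead time; the curve is strictly decreasing in
    concentration over its validity range.
    """

    a: float  # s * uM
    b: float  # s
    concentration_range: tuple[float, float]  # uM
    tbc_range: tuple[float, float]  # s, over the fitted points
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    monotone_warning: str | None = None

    def predict_tbc(self, concentration: float) -> float:
        if concentration <= 0:
            raise ValueError("concentration must be > 0")
        return self.a / concentration + self.b


def fit_standard_curve(
    concentrations: Sequence[float],
    mean_tbcs: Sequence[float],
    n_captures: Sequence[float] | None = None,
) -> StandardCurve:
    """Least-squares fit of TBC = a/C + b over >= 3 titration points.

    With ``n_captures`` given, points are inverse-variance weighted
    (sd of a mean TBC scales as TBC / sqrt(n)).
    """
    conc = np.asarray(concentrations, dtype=float)
    tbc = np.asarray(mean_tbcs, dtype=float)
    if len(conc) != len(tbc):
        raise ValueError("concentrations and mean_tbcs must align")
    if len(conc) < 3:
        raise ValueError("need >= 3 titration points to fit a standard curve")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    order = np.argsort(conc)
    conc, tbc = conc[order], tbc[order]
    weights = None
    if n_captures is not None:
        n = np.asarray(n_captures, dtype=float)[order]
        weights = np.sqrt(n) / tbc
    a, b = np.polyfit(1.0 / conc, tbc, 1, w=weights)
    fitted = a / conc + b
    warning = None
    if np.any(np.diff(tbc) > 1e-9 * np.abs(tbc[:-1]).clip(min=1.0)):
        warning = "mean TBC not strictly decreasing with concentration"
    return StandardCurve(
        a=float(a),
        b=float(b),
        concentration_range=(float(conc.min()), float(conc.max())),
        tbc_range=(float(tbc.min()), float(tbc.max())),
        residuals=tbc - fitted,
        monotone_warning=warning,
    )


def concentration_from_tbc(
    curve: StandardCurve, tbc: float, warn_extrapolation: bool = True
) -> float:
    """Invert the standard curve: ``C = a / (TBC - b)``.

    TBC at or below ``b`` has no finite concentration and raises; TBC outside
    the fitted range is flagged as extrapolation via a warning.
    """
    if tbc <= curve.b:
        raise ValueError(
            f"TBC {tbc:.3g}s is <= curve offset b={curve.b:.3g}s; concentration undefined"
        )
    if warn_extrapolation and not curve.tbc_range[0] <= tbc <= curve.tbc_range[1]:
        warnings.warn(
            f"TBC {tbc:.3g}s outside fitted range {curve.tbc_range}; extrapolating",
            stacklevel=2,
        )
    return curve.a / (tbc - curve.b)


# ---------------------------------------------------------------------------
# Normalization (exact affine maps; no clamping)


def _affine(x: float, background: float, saturated: float) -> float:
    if background == saturated:
        raise ValueError("background and saturated references must differ")
    return (x - background) / (saturated - background)


def normalize_eq1(tbc: float, tbc_background: float, tbc_saturated: float) -> float:
    """(TBC - TBC_background) / (TBC_saturated - TBC_background)."""
    return _affine(tbc, tbc_background, tbc_saturated)


def normalize_eq2(f: float, f_background: float, f_saturated: float) -> float:
    """(f - f_background) / (f_saturated - f_background)."""
    return _affine(f, f_background, f_saturated)


def capture_frequency(
    records: Sequence[CaptureRecord],
    barcode: str,
    n_good_channels: int,
    duration_min: float,
) -> float:
    """Reads of ``barcode`` per good channel per minute."""
    if n_good_channels < 1:
        raise ValueError("n_good_channels must be >= 1")
    if duration_min <= 0:
        raise ValueError("duration_min must be > 0")
    count = sum(1 for r in records if r.label == barcode)
    return count / (n_good_channels * duration_min)


# ---------------------------------------------------------------------------
# Kinetics series


@dataclass
class KineticsSeries:
    barcode: str
    metric: str
    bin_centers: np.ndarray  # s
    raw: np.ndarray  # metric value per bin (nan where undefined)
    normalized: np.ndarray  # affine-normalized value (nan where undefined)
    n_per_bin: np.ndarray  # gaps or events contributing to each bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_s": self.bin_centers,
                "barcode": self.barcode,
                "metric": self.metric,
                "raw": self.raw,
                "normalized": self.normalized,
                "n": self.n_per_bin,
            }
        )


def kinetics_series(
    records: Sequence[CaptureRecord],
    barcode: str,
    duration: float,
    metric: Literal["tbc", "frequency", "concentration"] = "tbc",
    bin_seconds: float = DEFAULT_BIN_SECONDS,
    background: float = 0.0,
    saturated: float = 1.0,
    curve: StandardCurve | None = None,
    n_good_channels: int = 1,
) -> KineticsSeries:
    """Bin the run into ``bin_seconds`` intervals and compute a normalized
    kinetics trace for one barcode.

    * ``tbc`` — per-bin mean TBC (gaps assigned to the bin of their gap
      midpoint), normalized by the affine TBC map; ``background`` /
      ``saturated`` are reference TBCs (background from the first five bins
      of a no-input run, saturated from a fully-displaced-output run).
    * ``frequency`` — per-bin capture frequency (events assigned by their
      midpoint), references are frequencies.
    * ``concentration`` — per-bin mean TBC converted through the standard
      curve, references are concentrations (uM).  This is the metric that is
      affine in the free output concentration itself.

    Bins with no contributing gaps/events have undefined metric and are
    emitted as NaN, never zero-filled.
    """
    if duration < 2 * bin_seconds:
        raise ValueError("run must cover at least two bins")
    edges = np.arange(0.0, duration + 1e-9, bin_seconds)
    if edges[-1] < duration - 1e-9:
        edges = np.append(edges, duration)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = len(centers)
    raw = np.full(n_bins, np.nan)
    norm = np.full(n_bins, np.nan)
    n_per_bin = np.zeros(n_bins, dtype=int)

    if metric in ("tbc", "concentration"):
        gaps, mids = time_between_captures(records, barcode, with_midpoints=True)
        which = np.clip(np.digitize(mids, edges) - 1, 0, n_bins - 1) if gaps else []
        for b in range(n_bins):
            sel = [g for g, w in zip(gaps, which) if w == b]
            n_per_bin[b] = len(sel)
            if not sel:
                continue
            tbc_b = float(np.mean(sel))
            if metric == "tbc":
                raw[b] = tbc_b
                norm[b] = normalize_eq1(tbc_b, background, saturated)
            else:
                if curve is None:
                    raise ValueError("concentration metric requires a standard curve")
                conc_b = concentration_from_tbc(curve, tbc_b, warn_extrapolation=False)
                raw[b] = conc_b
                norm[b] = _affine(conc_b, background, saturated)
    elif metric == "frequency":
        mids = [0.5 * (r.start_time + r.end_time) for r in records if r.label == barcode]
        which = np.clip(np.digitize(mids, edges) - 1, 0, n_bins - 1) if mids else []
        counts = np.bincount(which, minlength=n_bins) if len(which) else np.zeros(n_bins, int)
        for b in range(n_bins):
            n_per_bin[b] = counts[b]
            width_min = (edges[b + 1] - edges[b]) / 60.0
            raw[b] = counts[b] / (n_good_channels * width_min)
            norm[b] = normalize_eq2(raw[b], background, saturated)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return KineticsSeries(barcode, metric, centers, raw, norm, n_per_bin)
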