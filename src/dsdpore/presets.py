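"""Scenario presets: the standard study conditions shipped with the package.

These bundle the circuit operating points (0.5 uM gate / 2 uM fuel / 0.2 uM
input for single- and two-circuit kinetics; 0.2 uM gates / 0.4 uM inputs for
the five-circuit steady-state multiplex; 100 nM probes / 50 nM miRNA inputs
for the let-7 SNV panel; the 0.02-1 uM titration grid) with ready-made
barcode signal-model sets:

* ``separable_barcodes`` — ten widely spaced blockade levels (level gap
  4x the within-event sd), the high-accuracy regime;
* ``hard_barcodes`` — four overlapping-level barcodes whose differences
  live partly in higher moments and temporal (flicker) structure, the
  regime where the classifier ladder separates.
"""

from __future__ import annotations

import numpy as np

from .circuits import CircuitSystem, build_let7_system, build_seesaw
from .synth import BarcodeSignalModel, ChannelConfig

__all__ = [
    "separable_barcodes",
    "hard_barcodes",
    "let7_barcodes",
    "default_channel_config",
    "seesaw_kinetics_system",
    "five_plex_systems",
    "let7_system",
    "TITRATION_GRID_UM",
    "TITRATION_DURATIONS_S",
]

#: titration grid (uM) and per-point run lengths (longer at low concentration
#: so enough captures accumulate)
TITRATION_GRID_UM = (0.02, 0.1, 0.2, 0.5, 1.0)
TITRATION_DURATIONS_S = (1200.0, 900.0, 600.0, 600.0, 600.0)
#: per-point pore counts: low concentrations capture rarely, so more pores
#: are pooled there to collect comparable capture counts per point
TITRATION_CHANNELS = (64, 24, 16, 12, 10)

#: slow displacement rates (uM^-1 s^-1) for live-kinetics demonstrations:
#: the reaction then unfolds over tens of minutes, resolvable in 5-min bins
#: (long-toehold defaults would complete within the first bin)
KINETICS_DEMO_RATES = {"k_displace": 4e-3, "k_fuel": 4e-3}


def default_channel_config(**overrides) -> ChannelConfig:
    return ChannelConfig(**overrides)


def separable_barcodes(n: int = 10) -> list[BarcodeSignalModel]:
    """Well-separated blockade levels: means 0.15..0.60, within-event sd
    0.0125 (level gap = 4x sd), small capture-to-capture jitter."""
    if not 2 <= n <= 10:
        raise ValueError("n must be in [2, 10]")
    means = np.linspace(0.15, 0.60, 10)[:n]
    return [
        BarcodeSignalModel(
            barcode_id=f"S{i}",
            mean_fractional_current=float(m),
            within_event_sd=0.0125,
            level_sd=0.005,
        )
        for i, m in enumerate(means)
    ]


def hard_barcodes() -> list[BarcodeSignalModel]:
    """Overlapping-level set. H0/H1 share a crowded mean region and differ
    mainly in noise amplitude; H2/H3 have identical levels and stationary
    moments but flicker at different timescales, so only temporal structure
    separates them."""
    return [
        BarcodeSignalModel("H0", 0.30, within_event_sd=0.015, level_sd=0.040),
        BarcodeSignalModel(
            "H1", 0.34, within_event_sd=0.015, level_sd=0.040,
            flicker_depth=0.06, flicker_rate=8.0,
        ),
        BarcodeSignalModel(
            "H2", 0.50, within_event_sd=0.015, level_sd=0.020,
            flicker_depth=0.10, flicker_rate=2.0,
        ),
        BarcodeSignalModel(
            "H3", 0.50, within_event_sd=0.015, level_sd=0.020,
            flicker_depth=0.10, flicker_rate=40.0,
        ),
    ]


def let7_barcodes() -> list[BarcodeSignalModel]:
    """Three well-separated barcodes for the let-7a/c/e probe outputs."""
    return [
        BarcodeSignalModel("let7a", 0.20, within_event_sd=0.0125, level_sd=0.005),
        BarcodeSignalModel("let7c", 0.38, within_event_sd=0.0125, level_sd=0.005),
        BarcodeSignalModel("let7e", 0.56, within_event_sd=0.0125, level_sd=0.005),
    ]


def seesaw_kinetics_system(
    gate_conc: float = 0.5,
    input_conc: float = 0.2,
    fuel_conc: float = 2.0,
    rates=None,
    leak_rate: float = 0.0,
) -> CircuitSystem:
    """Single catalytic seesaw at the standard kinetics operating point."""
    return build_seesaw(gate_conc, input_conc, fuel_conc, rates=rates, leak_rate=leak_rate)


def two_plex_systems(
    triggered: str | None,
    barcode_ids: tuple[str, str] = ("S0", "S5"),
    gate_conc: float = 0.5,
    input_conc: float = 0.2,
    fuel_conc: float = 2.0,
    rates=None,
) -> dict[str, CircuitSystem]:
    """Two orthogonal catalytic seesaw circuits mixed in one sample; at most
    one receives its input (the selective-triggering experiment)."""
    if triggered is not None and triggered not in barcode_ids:
        raise ValueError(f"triggered must be one of {barcode_ids} or None")
    return {
        bc: build_seesaw(
            gate_conc,
            input_conc if bc == triggered else 0.0,
            fuel_conc,
            rates=rates,
            label=bc,
        )
        for bc in barcode_ids
    }


def five_plex_systems(
    triggered: set[str] | frozenset[str],
    barcode_ids: list[str] | None = None,
    gate_conc: float = 0.2,
    input_conc: float = 0.4,
    rates=None,
) -> dict[str, CircuitSystem]:
    """Five orthogonal seesaw circuits (no fuel in this steady-state setup);
    only those in ``triggered`` receive input."""
    if barcode_ids is None:
        barcode_ids = [m.barcode_id for m in separable_barcodes()[:5]]
    systems = {}
    for bc in barcode_ids:
        systems[bc] = build_seesaw(
            gate_conc,
            input_conc if bc in triggered else 0.0,
            0.0,
            rates=rates,
            label=bc,
        )
    return systems


def let7_system(
    inputs_present: set[str] | frozenset[str],
    probe_conc: float = 0.1,  # 100 nM
    input_conc: float = 0.05,  # 50 nM
    k_on: float = 0.1,
    crosstalk_e_to_a: float = 0.01,
) -> CircuitSystem:
    """Three-probe let-7 SNV panel with one crosstalk path (let-7e input can
    slowly trigger the let-7a probe)."""
    probes = {"let7a": probe_conc, "let7c": probe_conc, "let7e": probe_conc}
    all_inputs = ["let7a", "let7c", "let7e"]
    input_concs = {k: (input_conc if k in inputs_present else 0.0) for k in all_inputs}
    rate = np.diag([k_on] * 3)
    rate[all_inputs.index("let7e"), all_inputs.index("let7a")] = crosstalk_e_to_a
    return build_let7_system(probes, input_concs, rate, label="let7")
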