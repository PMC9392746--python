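"""Figure helpers: kinetics traces and multiplexed activation bar profiles."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .circuits import KineticsTrajectory
from .quantify import KineticsSeries

__all__ = ["plot_kinetics", "plot_profile"]


def plot_kinetics(
    series: KineticsSeries,
    trajectory: KineticsTrajectory | None = None,
    output_species: str = "output",
    saturated: float | None = None,
    ax=None,
):
    """Normalized kinetics readout vs time, optionally overlaid on the
    driving simulated trajectory (normalized to its saturated level)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ok = np.isfinite(series.normalized)
    ax.plot(
        series.bin_centers[ok] / 60.0,
        series.normalized[ok],
        "o-",
        label=f"nanopore readout ({series.barcode})",
    )
    if trajectory is not None:
        conc = trajectory.species(output_species)
        ref = saturated if saturated is not None else (conc[-1] or 1.0)
        ax.plot(
            trajectory.times / 60.0, conc / ref, "--", color="gray", label="simulated"
        )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("normalized output")
    ax.legend(frameon=False, fontsize=8)
    return ax.figure


def plot_profile(profile: pd.DataFrame, barcodes: Sequence[str] | None = None, ax=None):
    """Bar plot of normalized capture frequency per barcode (one multiplexed
    sample)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    data = profile if barcodes is None else profile[profile.barcode.isin(barcodes)]
    data = data.dropna(subset=["normalized"])
    ax.bar(data.barcode, data.normalized)
    ax.set_ylabel("normalized capture frequency")
    ax.set_xlabel("barcode")
    ax.axhline(0.0, color="black", lw=0.8)
    return ax.figure
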