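import numpy as np
import pytest

from dsdpore import presets, synth


@pytest.fixture(scope="session")
def channel_config() -> synth.ChannelConfig:
    return presets.default_channel_config()


@pytest.fixture(scope="session")
def barcode_model() -> synth.BarcodeSignalModel:
    return synth.BarcodeSignalModel("B0", 0.30, within_event_sd=0.02)


@pytest.fixture(scope="session")
def short_trace(channel_config, barcode_model) -> synth.ChannelTrace:
    """Two minutes of single-barcode signal at 0.5 uM, no noise."""
    return synth.generate_channel_trace(
        channel_config,
        [barcode_model],
        synth.Schedule.constant({"B0": 0.5}),
        duration=120.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def noisy_trace(channel_config, barcode_model) -> synth.ChannelTrace:
    base = synth.generate_channel_trace(
        channel_config,
        [barcode_model],
        synth.Schedule.constant({"B0": 0.5}),
        duration=180.0,
        seed=43,
    )
    return synth.inject_noise_events(base, rate=0.1, seed=44)


def brute_force_scan(segment, open_pore, sampling_rate, threshold=0.7, min_duration=0.001):
    """Independent per-sample reference detector: walk the segment sample by
    sample, tracking runs at or below the threshold; keep runs strictly
    longer than min_duration.  Returns (start, end) sample pairs."""
    limit = threshold * open_pore
    runs = []
    in_run = False
    start = 0
    for i, v in enumerate(np.asarray(segment, dtype=float)):
        if v <= limit:
            if not in_run:
                in_run = True
                start = i
        else:
            if in_run:
                runs.append((start, i))
                in_run = False
    if in_run:
        runs.append((start, len(segment)))
    min_samples = min_duration * sampling_rate
    return [(s, e) for s, e in runs if (e - s) > min_samples]
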