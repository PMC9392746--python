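"""Synthetic trace generator: determinism, capture statistics, annotations."""

import numpy as np
import pytest

from dsdpore import synth


class TestModels:
    def test_undetectable_level_rejected(self):
        with pytest.raises(ValueError, match="0.7"):
            synth.BarcodeSignalModel("bad", 0.75, within_event_sd=0.02)

    @pytest.mark.parametrize("kwargs", [dict(within_event_sd=0.0), dict(level_sd=-1.0)])
    def test_bad_noise_params_rejected(self, kwargs):
        base = dict(
            barcode_id="x", mean_fractional_current=0.3, within_event_sd=0.02
        )
        with pytest.raises(ValueError):
            synth.BarcodeSignalModel(**{**base, **kwargs})

    def test_config_flip_structure_validated(self):
        with pytest.raises(ValueError):
            synth.ChannelConfig(flip_period=1.0, flip_dead_time=2.0)


class TestGenerateChannelTrace:
    def test_deterministic_under_seed(self, channel_config, barcode_model):
        kw = dict(
            config=channel_config,
            models=[barcode_model],
            schedule=synth.Schedule.constant({"B0": 0.5}),
            duration=60.0,
            seed=7,
        )
        a = synth.generate_channel_trace(**kw)
        b = synth.generate_channel_trace(**kw)
        assert np.array_equal(a.samples, b.samples)
        assert a.truth == b.truth

    def test_zero_concentration_zero_noise_is_pure_open_pore(
        self, channel_config, barcode_model
    ):
        trace = synth.generate_channel_trace(
            channel_config,
            [barcode_model],
            synth.Schedule.constant({"B0": 0.0}),
            duration=60.0,
            seed=1,
        )
        assert trace.truth == []
        open_mask = trace.samples > 0
        assert np.abs(trace.samples[open_mask].mean() - 220.0) < 0.5

    def test_event_count_within_poisson_band(self, channel_config, barcode_model):
        """Observed captures across seeded replicates stay inside the 99%
        band of the generator's own per-cycle capture probability."""
        lam = channel_config.capture_rate_per_uM * 0.5
        u = channel_config.flip_period - channel_config.flip_dead_time
        p = 1.0 - np.exp(-lam * u)
        n_cycles = int(600.0 / channel_config.flip_period)
        counts = []
        for seed in range(20):
            trace = synth.generate_channel_trace(
                channel_config,
                [barcode_model],
                synth.Schedule.constant({"B0": 0.5}),
                duration=600.0,
                seed=seed,
            )
            counts.append(sum(1 for t in trace.truth if t.label == "B0"))
        total = sum(counts)
        mean = 20 * n_cycles * p
        sd = np.sqrt(20 * n_cycles * p * (1 - p))
        assert abs(total - mean) < 2.58 * sd

    def test_capture_ends_coincide_with_flip_boundaries(self, short_trace):
        fs = short_trace.config.sampling_rate
        period_samples = short_trace.config.flip_period * fs
        for ev in short_trace.truth:
            if ev.label == "noise":
                continue
            assert ev.end_sample % period_samples == pytest.approx(0, abs=1)

    def test_event_levels_recover_model_mean(self, channel_config):
        model = synth.BarcodeSignalModel(
            "B1", 0.42, within_event_sd=0.02, level_sd=0.004
        )
        trace = synth.generate_channel_trace(
            channel_config,
            [model],
            synth.Schedule.constant({"B1": 0.8}),
            duration=600.0,
            seed=3,
        )
        means = [
            trace.samples[t.start_sample : t.end_sample].mean() / 220.0
            for t in trace.truth
        ]
        n = len(means)
        assert n > 10
        se = np.sqrt(0.004**2 + 0.02**2 / 1000) / np.sqrt(n)
        assert abs(np.mean(means) - 0.42) < max(3 * se, 0.003)

    def test_duration_must_cover_one_flip(self, channel_config, barcode_model):
        with pytest.raises(ValueError, match="flip"):
            synth.generate_channel_trace(
                channel_config,
                [barcode_model],
                synth.Schedule.constant({"B0": 0.5}),
                duration=5.0,
                seed=0,
            )


class TestArrayRun:
    def test_zero_channels_gives_empty_run(self, channel_config, barcode_model):
        run = synth.generate_array_run(
            0,
            synth.Schedule.constant({"B0": 0.5}),
            [barcode_model],
            channel_config,
            60.0,
            seed=0,
        )
        assert run.traces == []

    def test_event_count_scales_with_channel_count(self, channel_config, barcode_model):
        def total_events(n_ch, seed):
            run = synth.generate_array_run(
                n_ch,
                synth.Schedule.constant({"B0": 0.5}),
                [barcode_model],
                channel_config,
                300.0,
                seed=seed,
            )
            return sum(len(t.truth) for t in run.traces)

        small = total_events(3, 0)
        large = total_events(30, 0)
        ratio = large / small
        assert 6 < ratio < 16  # ~10x within Poisson error

    def test_unmapped_output_species_rejected(self):
        from dsdpore.circuits import build_seesaw, simulate

        traj = simulate(build_seesaw(0.5, 0.2, 2.0), 600.0, step=60.0)
        with pytest.raises(ValueError, match="unmapped"):
            synth.Schedule.from_trajectory(
                traj, {}, system=build_seesaw(0.5, 0.2, 2.0)
            )

    def test_trajectory_driven_counts_rise_with_output(self, channel_config):
        from dsdpore.circuits import build_seesaw, simulate

        system = build_seesaw(
            0.5, 0.2, 2.0, rates=dict(k_displace=4e-3, k_fuel=4e-3)
        )
        traj = simulate(system, 1800.0, step=30.0)
        model = synth.BarcodeSignalModel("B0", 0.3, within_event_sd=0.02)
        run = synth.generate_array_run(
            12,
            synth.Schedule.from_trajectory(traj, {"output": "B0"}),
            [model],
            channel_config,
            1800.0,
            seed=2,
        )
        fs = channel_config.sampling_rate
        counts = np.zeros(6)
        for trace in run.traces:
            for t in trace.truth:
                counts[min(int(t.start_sample / fs / 300.0), 5)] += 1
        # free output rises monotonically; early bins must see fewer captures
        assert counts[0] < counts[2] < counts[5]


class TestNoiseInjection:
    def test_zero_rate_returns_trace_unchanged(self, short_trace):
        out = synth.inject_noise_events(short_trace, rate=0.0, seed=1)
        assert out is short_trace

    def test_noise_marked_and_nonoverlapping(self, noisy_trace):
        labels = [t.label for t in noisy_trace.truth]
        assert "noise" in labels
        spans = sorted((t.start_sample, t.end_sample) for t in noisy_trace.truth)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_injected_durations_below_length_filter(self, noisy_trace):
        fs = noisy_trace.config.sampling_rate
        for t in noisy_trace.truth:
            if t.label == "noise":
                assert (t.end_sample - t.start_sample) / fs < 2.0

    def test_sub_millisecond_noise_invisible_to_detector(
        self, channel_config, barcode_model
    ):
        """Blockades shorter than 1 ms sit below the detector's duration
        floor and must never surface as events."""
        from dsdpore import extract as ex

        clean = synth.generate_channel_trace(
            channel_config,
            [barcode_model],
            synth.Schedule.constant({"B0": 0.0}),
            duration=120.0,
            seed=8,
        )
        spiked = synth.inject_noise_events(
            clean, rate=0.5, duration_range=(0.0002, 0.0008), seed=9
        )
        assert sum(1 for t in spiked.truth if t.label == "noise") > 20
        events, _ = ex.extract_channel(spiked)
        assert events == []


class TestEventWindows:
    def test_sampler_is_seeded_and_shaped(self, barcode_model):
        a = synth.sample_event_windows(barcode_model, 5, seed=9)
        b = synth.sample_event_windows(barcode_model, 5, seed=9)
        assert a.shape == (5, 20_000)
        assert np.array_equal(a, b)

    def test_flicker_produces_bimodal_signal(self):
        model = synth.BarcodeSignalModel(
            "F", 0.5, within_event_sd=0.01, level_sd=0.0,
            flicker_depth=0.1, flicker_rate=5.0,
        )
        w = synth.sample_event_windows(model, 1, seed=1)[0]
        lo = w < 0.45
        assert 0.1 < lo.mean() < 0.9  # both telegraph states visited


class TestTraceIO:
    def test_hdf5_round_trip(self, tmp_path, channel_config, barcode_model):
        run = synth.generate_array_run(
            2,
            synth.Schedule.constant({"B0": 0.5}),
            [barcode_model],
            channel_config,
            60.0,
            seed=5,
        )
        h5 = tmp_path / "run.h5"
        tsv = tmp_path / "truth.tsv"
        synth.write_run_hdf5(run, h5, truth_tsv=tsv)
        traces = synth.read_run_hdf5(h5, truth_tsv=tsv)
        assert len(traces) == 2
        for orig, back in zip(run.traces, traces):
            assert np.array_equal(orig.samples, back.samples)
            assert orig.truth == back.truth
            assert back.config == channel_config

    def test_csv_round_trip(self, tmp_path, short_trace):
        path = tmp_path / "trace.csv"
        synth.write_trace_csv(short_trace, path)
        back = synth.read_trace_csv(path, short_trace.config)
        assert np.allclose(back.samples, short_trace.samples, atol=5e-3)
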