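"""Generator contracts: species library, event synthesis, recordings,
labeled datasets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wingbeat as wb
from wingbeat.detect import DetectionParams, detect_events
from wingbeat.spectral import power_spectrum

from conftest import make_event, make_flyer


class TestSpeciesLibrary:
    def test_nine_profiles_two_jumpers(self, library):
        assert len(library) == 9
        assert sum(p.behaviour == "jumper" for p in library) == 2

    def test_overlapping_flyer_pair_exists(self, library):
        flyers = [p for p in library if p.behaviour == "flyer"]
        assert any(
            abs(a.f0_mean - b.f0_mean) < a.f0_sd + b.f0_sd
            for i, a in enumerate(flyers)
            for b in flyers[i + 1 :]
        )

    def test_library_is_pure(self):
        assert wb.default_species_library() == wb.default_species_library()

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            wb.SpeciesProfile(name="bad", f0_mean=0.0, f0_sd=1.0)
        with pytest.raises(ValueError):
            wb.SpeciesProfile(name="bad", f0_mean=100.0, f0_sd=1.0,
                              body_fraction=1.5)


class TestSimulateEvent:
    def test_flyer_peak_at_f0(self, sensor):
        ev = make_event(make_flyer(200.0), sensor, duration=0.1, seed=1)
        spec = power_spectrum(ev)
        mean = spec.channel_mean_band
        peak = 30 + np.argmax(mean[30:])
        assert abs(peak - 200.0) <= 10.0  # 1/0.1 s resolution

    def test_jumper_has_no_wbf_peak(self, sensor, library):
        jumper = next(p for p in library if p.behaviour == "jumper")
        ev = make_event(jumper, sensor, duration=0.1, seed=2)
        band = power_spectrum(ev).channel_mean_band[30:1000]
        assert band.max() <= 5.0 * np.median(band)

    def test_determinism_bitwise(self, sensor, library):
        for profile in library[:2] + library[-1:]:
            a = wb.simulate_event(profile, sensor, 0.08, seed=7)
            b = wb.simulate_event(profile, sensor, 0.08, seed=7)
            np.testing.assert_array_equal(a, b)
            c = wb.simulate_event(profile, sensor, 0.08, seed=8)
            assert not np.array_equal(a, c)

    def test_harmonic_decay_recovered(self, sensor):
        """Spectral fidelity: magnitude(2 f0) / magnitude(f0) matches the
        configured decay within 10% on a noiseless event."""
        for decay in (0.3, 0.5, 0.7):
            ev = make_event(make_flyer(150.0, decay=decay), sensor,
                            duration=0.2, seed=3)
            spec = power_spectrum(ev)
            mean = spec.channel_mean_band
            a1 = mean[145:156].max()
            a2 = mean[295:306].max()
            assert a2 / a1 == pytest.approx(decay, rel=0.10)

    def test_depol_ratio_recovered(self, sensor):
        profile = make_flyer(200.0, depol_ratio=(0.35, 0.6))
        ev = make_event(profile, sensor, duration=0.1, seed=4)
        band = power_spectrum(ev).band[:, 30:]
        integrated = band.sum(axis=1)
        assert integrated[1] / integrated[0] == pytest.approx(0.35, rel=0.10)
        assert integrated[3] / integrated[2] == pytest.approx(0.60, rel=0.10)

    def test_amplitude_sets_peak(self, sensor):
        ev = make_event(make_flyer(100.0), sensor, seed=5, amplitude=7.5)
        assert np.max(np.abs(ev.segment)) == pytest.approx(7.5)

    def test_rejects_nonpositive_duration(self, sensor, library):
        with pytest.raises(ValueError):
            wb.simulate_event(library[0], sensor, 0.0, seed=0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        duration=st.floats(min_value=0.02, max_value=0.2),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_shape_and_peak_properties(self, duration, seed):
        sensor = wb.SensorConfig()
        seg = wb.simulate_event(make_flyer(180.0), sensor, duration, seed)
        assert seg.shape == (4, int(round(duration * sensor.sample_rate)))
        assert np.max(np.abs(seg)) == pytest.approx(1.0)


class TestSimulateRecording:
    def test_zero_rate_gives_empty_truth(self, library, sensor):
        rec = wb.simulate_recording(library, 0.0, 10.0, 1.0, seed=1,
                                    sensor=sensor)
        assert rec.truth == []
        assert rec.n_samples == 200_000

    def test_background_noise_level(self, library, sensor):
        rec = wb.simulate_recording(library, 0.0, 10.0, 2.5, seed=1,
                                    sensor=sensor)
        assert np.std(rec.samples, axis=1) == pytest.approx(
            [2.5] * 4, rel=0.02
        )

    def test_determinism(self, library, sensor):
        a = wb.simulate_recording(library, 0.5, 5.0, 1.0, seed=9, sensor=sensor)
        b = wb.simulate_recording(library, 0.5, 5.0, 1.0, seed=9, sensor=sensor)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.truth == b.truth

    def test_detector_recovers_inserted_events(self, library, sensor):
        """At peak SNR 50 every truth interval is recovered by the
        default detector, one-to-one and overlapping."""
        rec = wb.simulate_recording(
            library, 0.4, 25.0, 1.0, seed=11, sensor=sensor, peak_snr=50.0
        )
        assert len(rec.truth) >= 3
        events = detect_events(rec, DetectionParams())
        assert len(events) == len(rec.truth)
        for (ts, te, _), ev in zip(rec.truth, events):
            assert ev.start < te and ev.end > ts  # overlap


class TestLabeledDataset:
    def test_counts_exact(self, library, sensor):
        ds = wb.simulate_labeled_dataset(library, 30, sensor=sensor, seed=2)
        assert len(ds) == 270
        assert set(ds.counts().values()) == {30}
        assert all(ev.label == lab for ev, lab in zip(ds.events, ds.labels))

    def test_duration_means_match_profiles(self, default_dataset, library):
        for profile in library:
            idx = default_dataset.indices_of(profile.name)
            durations = np.array(
                [default_dataset.events[i].duration for i in idx]
            )
            assert durations.mean() * 1000.0 == pytest.approx(
                profile.duration_mean, rel=0.20
            )

    def test_embed_mode_recovers_labeled_events(self, library, sensor):
        ds = wb.simulate_labeled_dataset(
            library[:2], 3, sensor=sensor, seed=3, peak_snr=50.0, embed=True
        )
        assert len(ds) == 6
        assert all(ev.n_samples > 0 for ev in ds.events)

    def test_rejects_zero_events(self, library, sensor):
        with pytest.raises(ValueError):
            wb.simulate_labeled_dataset(library, 0, sensor=sensor)


class TestSeparabilityDial:
    def test_wbf_accuracy_increases_with_f0_gap(self, sensor):
        """Widening the WBF gap between two species must raise the WBF
        method's mean held-out accuracy across the three settings."""
        from wingbeat import ForestConfig, OneVsAllExperiment, SplitSpec

        mean_acc = []
        for gap in (10.0, 60.0, 150.0):
            a = make_flyer(250.0, f0_sd=30.0, cv=0.1, name="a")
            b = make_flyer(250.0 + gap, f0_sd=30.0, cv=0.1, name="b")
            ds = wb.simulate_labeled_dataset([a, b], 120, sensor=sensor,
                                             seed=17)
            res = OneVsAllExperiment(
                ds,
                methods=("wbf",),
                n_folds=20,
                split=SplitSpec(target="", n_target_train=70,
                                n_other_train_each=70, n_test_each=40),
                forest_config=ForestConfig(n_estimators=100),
            ).fit(seed=5)
            mean_acc.append(res.folds_frame()["overall_accuracy"].mean())
        assert mean_acc[0] < mean_acc[1] < mean_acc[2]
        assert mean_acc[2] > 0.9
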