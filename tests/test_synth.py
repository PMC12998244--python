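import numpy as np
import pytest

from roarbout.f0 import F0Config, call_to_contour
from roarbout.synth import (
    BoutSpec,
    IndividualSpec,
    contour_template,
    default_type_specs,
    gen_bout,
    gen_contour,
    gen_dataset,
    load_calls,
    render_audio,
)

SPECS = default_type_specs()
STAGES = ("moan", "full_throated_roar", "intermediary_roar", "grunt")


class TestGenContour:
    def test_zero_noise_equals_template(self):
        from dataclasses import replace

        spec = replace(SPECS["full_throated_roar"], noise_hz=0.0,
                       duration_s=(1.0, 0.0), max_freq_hz=(320.0, 0.0))
        contour = gen_contour(spec, rng_seed=0)
        template = contour_template(spec, 1.0, 320.0)
        np.testing.assert_allclose(contour.values_hz, template)

    def test_same_seed_identical(self):
        a = gen_contour(SPECS["moan"], rng_seed=42)
        b = gen_contour(SPECS["moan"], rng_seed=42)
        np.testing.assert_array_equal(a.values_hz, b.values_hz)

    def test_peak_scale_signature_shifts_mean_peak(self):
        """Monte-Carlo: lions with peak scales 1.0 vs 1.3 differ in mean
        contour peak by ~30%."""
        spec = SPECS["full_throated_roar"]
        base = IndividualSpec("a", peak_scale=1.0)
        high = IndividualSpec("b", peak_scale=1.3)
        rng = np.random.default_rng(9)
        peaks = {ind.lion_id: [] for ind in (base, high)}
        for ind in (base, high):
            for _ in range(100):
                peaks[ind.lion_id].append(gen_contour(spec, ind, rng).values_hz.max())
        ratio = np.mean(peaks["b"]) / np.mean(peaks["a"])
        assert ratio == pytest.approx(1.3, abs=0.05)

    def test_arch_rises_then_falls(self):
        contour = gen_contour(SPECS["full_throated_roar"], rng_seed=1)
        peak_pos = np.argmax(contour.values_hz) / len(contour)
        assert 0.05 < peak_pos < 0.6  # asymmetric: peak in the first half


class TestGenBout:
    def test_requested_counts_in_stage_order(self):
        counts = {"moan": 2, "full_throated_roar": 3, "intermediary_roar": 2, "grunt": 8}
        anns, contours = gen_bout(BoutSpec(), SPECS, IndividualSpec("L"), 0,
                                  counts=counts)
        assert len(anns) == len(contours) == 15
        labels = [a.call_type for a in anns]
        expected = (["moan"] * 2 + ["full_throated_roar"] * 3
                    + ["intermediary_roar"] * 2 + ["grunt"] * 8)
        assert labels == expected

    def test_grunts_only(self):
        counts = {s: 0 for s in STAGES} | {"grunt": 4}
        anns, _ = gen_bout(BoutSpec(), SPECS, IndividualSpec("L"), 1, counts=counts)
        assert [a.call_type for a in anns] == ["grunt"] * 4

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            gen_bout(BoutSpec(), SPECS, IndividualSpec("L"), 0, counts={"moan": -1})

    @pytest.mark.parametrize("seed", range(20))
    def test_grammar_ordering_and_no_overlap(self, seed):
        """IRs come after FTRs and before grunts; annotations never overlap."""
        anns, _ = gen_bout(BoutSpec(), SPECS, IndividualSpec("L"), seed)
        stage_idx = [STAGES.index(a.call_type) for a in anns]
        assert stage_idx == sorted(stage_idx)
        for prev, nxt in zip(anns, anns[1:]):
            assert nxt.begin_s >= prev.end_s


class TestGenDataset:
    def test_corpus_shape_and_truth(self):
        ds = gen_dataset(5, 10, seed=1)
        truth = ds.truth()
        assert truth["lion_id"].nunique() == 5
        assert truth["bout_id"].nunique() == 50
        assert len(ds.annotations) == len(ds.contours) == len(truth)

    def test_fixed_seed_reproducible(self):
        a = gen_dataset(2, 3, seed=9).truth()
        b = gen_dataset(2, 3, seed=9).truth()
        assert a.equals(b)

    def test_counter_seeding_stable_under_subsetting(self):
        """Bout (i, j) regenerates identically whatever else is generated."""
        big = gen_dataset(3, 4, seed=5)
        small = gen_dataset(3, 2, seed=5)
        big_bout = [c for a, c in zip(big.annotations, big.contours)
                    if a.bout_id == "L2_b2"]
        small_bout = [c for a, c in zip(small.annotations, small.contours)
                      if a.bout_id == "L2_b2"]
        assert len(big_bout) == len(small_bout) > 0
        for x, y in zip(big_bout, small_bout):
            np.testing.assert_array_equal(x.values_hz, y.values_hz)

    def test_zero_separation_collapses_feature_means(self):
        ds = gen_dataset(2, 8, separation=0.0, seed=3)
        truth = ds.truth()
        means = truth.groupby("call_type")["max_freq_hz"].mean()
        assert means.max() - means.min() <= 15.0

    def test_roundtrip_disk_layout(self, tmp_path):
        ds = gen_dataset(2, 2, seed=4)
        ds.write(tmp_path)
        anns, contours = load_calls(tmp_path)
        assert len(anns) == len(ds.annotations)
        np.testing.assert_allclose(contours[0].values_hz, ds.contours[0].values_hz)
        assert (tmp_path / "selections").exists()


class TestRenderAudio:
    def test_flat_contour_round_trip(self):
        from roarbout.f0 import F0Contour

        flat = F0Contour(np.full(250, 150.0), 0.004 * np.arange(250))
        clip = render_audio(flat, harmonics=3, snr_db=40, seed=0)
        contour = call_to_contour(clip, F0Config())
        assert np.median(contour.values_hz) == pytest.approx(150.0, abs=1.5)

    def test_noise_only_mostly_gated(self):
        from roarbout.f0 import F0Contour

        flat = F0Contour(np.full(250, 150.0), 0.004 * np.arange(250))
        clip = render_audio(flat, snr_db=-40, seed=1)
        contour = call_to_contour(clip, F0Config())
        n_frames = (clip.n_samples - 128) // 64 + 1
        assert len(contour) <= 0.2 * n_frames

    def test_same_seed_identical_waveform(self):
        c = gen_contour(SPECS["intermediary_roar"], rng_seed=2)
        a = render_audio(c, seed=7)
        b = render_audio(c, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_aliasing_guard(self):
        from roarbout.f0 import F0Contour

        flat = F0Contour(np.full(50, 300.0), 0.004 * np.arange(50))
        with pytest.raises(ValueError, match="harmonic"):
            render_audio(flat, rate=1000, harmonics=3)
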