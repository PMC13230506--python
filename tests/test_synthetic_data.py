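import numpy as np
import pytest

from hbvision.corridor_decision import CorridorLabel
from hbvision.synthetic_data import (
    ANEMIA_THRESHOLD,
    CohortConfig,
    ConfigurationError,
    QolLink,
    RenderParams,
    SubgroupParams,
    assign_clinician_label,
    cohort_to_frame,
    generate_cohort,
    generate_qol,
    hue_for_hb,
    load_samples,
    render_visit_images,
    save_samples,
)

from conftest import tiny_subgroups


class TestGenerateCohort:
    def test_table5_counts(self):
        entries = generate_cohort(CohortConfig(seed=0))
        assert len(entries) == 551
        patients = [e for e in entries if e.subgroup in ("B", "C")]
        assert len(patients) == 367

    def test_empty_cohort(self):
        cfg = CohortConfig(
            subgroups={
                name: SubgroupParams(n=0, hb_median=p.hb_median, hb_range=p.hb_range)
                for name, p in tiny_subgroups().items()
            }
        )
        assert generate_cohort(cfg) == []

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_anemia_threshold_respected(self, seed):
        entries = generate_cohort(CohortConfig(seed=seed))
        b_values = [e.hb_true for e in entries if e.subgroup == "B"]
        c_values = [e.hb_true for e in entries if e.subgroup == "C"]
        assert max(b_values) < ANEMIA_THRESHOLD
        assert min(c_values) > ANEMIA_THRESHOLD

    def test_deterministic_given_seed(self):
        a = cohort_to_frame(generate_cohort(CohortConfig(seed=11)))
        b = cohort_to_frame(generate_cohort(CohortConfig(seed=11)))
        assert a.equals(b)

    def test_different_seeds_differ(self):
        a = cohort_to_frame(generate_cohort(CohortConfig(seed=1)))
        b = cohort_to_frame(generate_cohort(CohortConfig(seed=2)))
        assert not a["hb_true"].equals(b["hb_true"])

    @pytest.mark.parametrize("seed", [0, 5])
    def test_subgroup_medians_near_target(self, seed):
        # distributional check for n >= 100 per subgroup
        entries = generate_cohort(CohortConfig(seed=seed))
        targets = {"A": 8.6, "B": 5.2, "C": 7.9}
        for name, target in targets.items():
            values = [e.hb_true for e in entries if e.subgroup == name]
            assert len(values) >= 100
            assert abs(float(np.median(values)) - target) < 0.3

    def test_repeat_visits_share_patient_distinct_index(self):
        cfg = CohortConfig(
            subgroups=tiny_subgroups(20, 20, 20), visit_repeat_prob=0.5, seed=3
        )
        entries = generate_cohort(cfg)
        seen = {}
        for e in entries:
            key = (e.patient_id, e.visit_index)
            assert key not in seen, "duplicate (patient, visit)"
            seen[key] = e
        n_repeats = sum(1 for e in entries if e.visit_index > 0)
        assert n_repeats > 0

    def test_qol_subset_size_and_range(self):
        entries = generate_cohort(CohortConfig(seed=4))
        with_qol = [e for e in entries if e.qol_global_health is not None]
        assert len(with_qol) == round(47 / 551 * 551)
        for e in with_qol:
            assert 0 <= e.qol_global_health <= 100
            assert 0 <= e.qol_fatigue <= 100
            assert e.subgroup in ("B", "C")
            assert e.clinician_label in CorridorLabel

    def test_invalid_counts_raise(self):
        bad = tiny_subgroups()
        bad["A"] = SubgroupParams(n=-1, hb_median=8.6, hb_range=(6.5, 11.4))
        with pytest.raises(ConfigurationError):
            generate_cohort(CohortConfig(subgroups=bad))

    def test_unordered_range_raises(self):
        bad = tiny_subgroups()
        bad["A"] = SubgroupParams(n=5, hb_median=8.6, hb_range=(11.4, 6.5))
        with pytest.raises(ConfigurationError):
            generate_cohort(CohortConfig(subgroups=bad))


class TestGenerateQol:
    def test_zero_noise_exact_link(self):
        link = QolLink(gh_noise_sd=0.0, fatigue_noise_sd=0.0)
        gh, fatigue = generate_qol(6.0, link, 0)
        assert gh == pytest.approx(link.gh_intercept + link.gh_slope * 6.0)
        assert fatigue == pytest.approx(
            link.fatigue_intercept + link.fatigue_slope * 6.0
        )

    def test_clipping_at_extreme_hb(self):
        link = QolLink(gh_noise_sd=0.0, fatigue_noise_sd=0.0)
        gh, fatigue = generate_qol(50.0, link, 0)
        assert gh == 100.0
        assert fatigue == 0.0

    def test_same_seed_identical(self):
        assert generate_qol(6.0, QolLink(), 42) == generate_qol(6.0, QolLink(), 42)

    def test_positive_hb_required(self):
        with pytest.raises(ValueError):
            generate_qol(0.0, QolLink(), 0)

    def test_slope_recovery_zero_noise(self):
        # regressing gh on hb recovers the configured slope to machine tolerance
        link = QolLink(gh_noise_sd=0.0, fatigue_noise_sd=0.0, gh_slope=5.0, gh_intercept=30.0)
        hb = np.linspace(4.0, 9.0, 50)
        gh = np.array([generate_qol(h, link, 0)[0] for h in hb])
        slope, intercept = np.polyfit(hb, gh, 1)
        assert slope == pytest.approx(5.0, abs=1e-9)
        assert intercept == pytest.approx(30.0, abs=1e-9)

    def test_average_direction(self, rng):
        link = QolLink()
        lows = [generate_qol(4.0, link, int(s))[0] for s in rng.integers(0, 1e6, 200)]
        highs = [generate_qol(9.0, link, int(s))[0] for s in rng.integers(0, 1e6, 200)]
        assert np.mean(highs) > np.mean(lows)
        lows_f = [generate_qol(4.0, link, int(s))[1] for s in rng.integers(0, 1e6, 200)]
        highs_f = [generate_qol(9.0, link, int(s))[1] for s in rng.integers(0, 1e6, 200)]
        assert np.mean(highs_f) < np.mean(lows_f)


class TestClinicianLabel:
    def test_green_with_low_fatigue(self):
        assert assign_clinician_label(7.5, 5.0) is CorridorLabel.GREEN

    def test_red_below_cutoff_any_fatigue(self):
        for fatigue in (0.0, 50.0, 100.0):
            assert assign_clinician_label(4.0, fatigue) is CorridorLabel.RED

    def test_yellow_escalated_by_fatigue(self):
        assert assign_clinician_label(5.0, 60.0) is CorridorLabel.RED
        assert assign_clinician_label(5.0, 10.0) is CorridorLabel.YELLOW

    def test_monotone_in_hb(self):
        for fatigue in (0.0, 20.0, 45.0, 90.0):
            severities = [
                assign_clinician_label(hb, fatigue).severity
                for hb in np.linspace(3.5, 9.0, 40)
            ]
            assert all(a >= b for a, b in zip(severities, severities[1:]))

    def test_fatigue_out_of_range(self):
        with pytest.raises(ValueError):
            assign_clinician_label(5.0, 101.0)


def _zero_noise_params(**kwargs):
    return RenderParams(
        image_size=(64, 64),
        eyelid_images=1,
        fingernail_images=1,
        pixel_hue_noise_sd=0.0,
        image_hue_offset_sd=0.0,
        lighting_gain_sd=0.0,
        background_noise_sd=0.0,
        **kwargs,
    )


def _entry(hb):
    from hbvision.synthetic_data import SubjectEntry

    return SubjectEntry(
        patient_id="P0000", visit_index=0, subgroup="C", age=50.0, sex="female", hb_true=hb
    )


def _mean_roi_hue(sample):
    from hbvision.chromatic_features import rgb_to_hue

    hues, chromatic = rgb_to_hue(sample.pixels)
    mask = sample.ground_truth["true_mask"] & chromatic
    return float(hues[mask].mean())


class TestRenderVisitImages:
    def test_zero_noise_mean_hue_matches_link(self):
        params = _zero_noise_params()
        for hb in (4.0, 6.5, 9.0):
            for sample in render_visit_images(_entry(hb), params, 0):
                # uint8 quantization perturbs hue by < 1 degree
                assert _mean_roi_hue(sample) == pytest.approx(
                    hue_for_hb(hb, params), abs=1.0
                )

    def test_hue_monotone_in_hb(self):
        params = _zero_noise_params()
        low = render_visit_images(_entry(4.0), params, 0)[0]
        high = render_visit_images(_entry(9.0), params, 1)[0]
        assert _mean_roi_hue(high) < _mean_roi_hue(low)

    def test_coarse_mask_strictly_contains_true_roi(self):
        params = RenderParams(image_size=(64, 64), eyelid_images=2, fingernail_images=2)
        for sample in render_visit_images(_entry(7.0), params, 3):
            true_mask = sample.ground_truth["true_mask"]
            assert not (true_mask & ~sample.coarse_mask).any()
            assert sample.coarse_mask.sum() > true_mask.sum()

    def test_modalities_and_counts(self):
        params = RenderParams(image_size=(64, 64), eyelid_images=3, fingernail_images=2)
        samples = render_visit_images(_entry(7.0), params, 0)
        assert [s.modality for s in samples].count("eyelid") == 3
        assert [s.modality for s in samples].count("fingernail") == 2

    def test_pixel_range_and_dtype(self):
        for sample in render_visit_images(_entry(7.0), _zero_noise_params(), 0):
            assert sample.pixels.dtype == np.uint8
            assert sample.coarse_mask.any()

    def test_deterministic_given_seed(self):
        a = render_visit_images(_entry(7.0), RenderParams(image_size=(64, 64)), 9)
        b = render_visit_images(_entry(7.0), RenderParams(image_size=(64, 64)), 9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.pixels, y.pixels)
            np.testing.assert_array_equal(x.coarse_mask, y.coarse_mask)

    def test_requires_positive_hb(self):
        entry = _entry(7.0)
        entry.hb_true = -1.0
        with pytest.raises(ValueError):
            render_visit_images(entry, _zero_noise_params(), 0)


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path):
        samples = render_visit_images(_entry(7.0), RenderParams(image_size=(48, 48)), 0)
        save_samples(samples, tmp_path)
        loaded = load_samples(tmp_path)
        assert len(loaded) == len(samples)
        for orig, back in zip(samples, loaded):
            np.testing.assert_array_equal(orig.pixels, back.pixels)
            np.testing.assert_array_equal(orig.coarse_mask, back.coarse_mask)
            np.testing.assert_array_equal(
                orig.ground_truth["true_mask"], back.ground_truth["true_mask"]
            )
            assert back.ground_truth["hue_offset"] == pytest.approx(
                orig.ground_truth["hue_offset"]
            )

    def test_cohort_frame_columns(self, tiny_cohort_config):
        frame = cohort_to_frame(generate_cohort(tiny_cohort_config))
        assert {"patient_id", "visit_index", "hb_true", "subgroup"} <= set(frame.columns)
        assert len(frame) == 24
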