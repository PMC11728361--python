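from dataclasses import replace

import numpy as np
import pytest

from echotex.errors import GenerationError
from echotex.features import first_order_features, glcm_features, glcm_matrix
from echotex.synthetic import (
    DEFAULT_PROFILES,
    GradeProfile,
    SyntheticCohortConfig,
    generate_cohort,
    generate_image,
    sample_grade_ev,
)


class TestSampleGradeEv:
    def test_grade4_draws_match_published_moments(self):
        """10^5 draws reproduce the grade-4 EV mean and SD to ±0.05."""
        profile = DEFAULT_PROFILES[3]
        rng = np.random.default_rng(0)
        draws = np.array([sample_grade_ev(profile, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(26.85, abs=0.05)
        assert draws.std(ddof=1) == pytest.approx(4.06, abs=0.05)

    def test_truncation_untouched_for_calm_grades(self):
        # grades 2-4 have means >= 5 sigma from both bounds
        for profile in DEFAULT_PROFILES[1:]:
            assert profile.ev_mean - 5 * profile.ev_sd > 5.0
            assert profile.ev_mean + 5 * profile.ev_sd < 150.0

    def test_fixed_seed_reproduces_sequence(self):
        p = DEFAULT_PROFILES[0]
        a = [sample_grade_ev(p, np.random.default_rng(3)) for _ in range(1)]
        b = [sample_grade_ev(p, np.random.default_rng(3)) for _ in range(1)]
        assert a == b


class TestGenerateImage:
    def test_round_trip_hits_targets(self, small_config):
        rng = np.random.default_rng(1)
        img, truth = generate_image(4, small_config, rng)
        assert img.dtype == np.uint8
        assert abs(truth.ev_extracted - truth.ev_target) <= small_config.ev_tolerance
        assert abs(truth.ei_extracted - truth.ei_target) <= 2.0
        fo = first_order_features(img)
        assert fo.echovariation == pytest.approx(truth.ev_extracted)

    def test_independent_speckle_has_no_glcm_correlation(self):
        cfg = SyntheticCohortConfig(correlation_length=0.0, striation_amplitude=0.0)
        img, _ = generate_image(2, cfg, np.random.default_rng(5))
        f = glcm_features(glcm_matrix(img))
        assert abs(f.correlation) < 0.05

    def test_same_seed_byte_identical(self, small_config):
        a, _ = generate_image(3, small_config, np.random.default_rng(9))
        b, _ = generate_image(3, small_config, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_infeasible_sd_raises_naming_grade(self):
        # EV 50% of EI 240 needs SD 120 > sqrt(240*15) ~ 60: impossible in 8-bit
        profiles = (replace(DEFAULT_PROFILES[0], ei_mean=240.0, ev_mean=50.0, ev_sd=1e-6),) + DEFAULT_PROFILES[1:]
        cfg = SyntheticCohortConfig(profiles=profiles)
        with pytest.raises(GenerationError, match="grade 1"):
            generate_image(1, cfg, np.random.default_rng(0))


class TestGenerateCohort:
    def test_default_grade_counts(self, default_cohort):
        _, images, records, truths = default_cohort
        assert len(images) == 130
        counts = {g: sum(r.grade == g for r in records) for g in (1, 2, 3, 4)}
        assert counts == {1: 24, 2: 58, 3: 24, 4: 24}

    def test_smoke_scale_cohort(self, small_config):
        images, records, truths = generate_cohort(small_config)
        assert len(images) == 20
        assert {r.limb for r in records} == {"left", "right"}

    def test_determinism_and_seed_sensitivity(self, small_config):
        im1, rec1, _ = generate_cohort(small_config)
        im2, rec2, _ = generate_cohort(small_config)
        assert rec1 == rec2
        for k in im1:
            np.testing.assert_array_equal(im1[k], im2[k])
        im3, rec3, _ = generate_cohort(replace(small_config, seed=8))
        assert [r.image_id for r in rec3] == [r.image_id for r in rec1]  # schema
        assert any(not np.array_equal(im1[k], im3[k]) for k in im1)  # pixels

    def test_grade_monotone_ei_up_ev_down(self, default_cohort):
        _, _, _, truths = default_cohort
        ei = [np.mean([t.ei_extracted for t in truths if t.grade == g]) for g in (1, 2, 3, 4)]
        ev = [np.mean([t.ev_extracted for t in truths if t.grade == g]) for g in (1, 2, 3, 4)]
        assert all(a < b for a, b in zip(ei, ei[1:]))
        assert all(a > b for a, b in zip(ev, ev[1:]))

    def test_extracted_ev_tracks_targets(self, default_cohort):
        _, _, _, truths = default_cohort
        target = np.array([t.ev_target for t in truths])
        extracted = np.array([t.ev_extracted for t in truths])
        assert np.corrcoef(target, extracted)[0, 1] >= 0.99
        assert max(t.clip_fraction for t in truths) <= 0.02


class TestProfileValidation:
    def test_default_profiles_are_grade_monotone(self):
        eis = [p.ei_mean for p in DEFAULT_PROFILES]
        evs = [p.ev_mean for p in DEFAULT_PROFILES]
        assert eis == sorted(eis) and len(set(eis)) == 4
        assert evs == sorted(evs, reverse=True)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(grade=5, ev_mean=30, ev_sd=3, ei_mean=100, n=5),
            dict(grade=1, ev_mean=-1, ev_sd=3, ei_mean=100, n=5),
            dict(grade=1, ev_mean=30, ev_sd=3, ei_mean=300, n=5),
        ],
    )
    def test_invalid_profiles_rejected(self, kwargs):
        from echotex.errors import ValidationError

        with pytest.raises(ValidationError):
            GradeProfile(**kwargs)
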