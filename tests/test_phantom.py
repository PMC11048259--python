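"""Generator-level checks: speckle statistics, injury effect size,
subject effects, cohort reproducibility."""

import numpy as np
import pytest

from efastnet import phantom
from efastnet.phantom import (PhantomParams, render_bmode, render_mmode,
                              sample_subject_effects, speckle_field,
                              generate_cohort, site_mode)


class TestScanSites:
    def test_exactly_six_codes_with_derived_mode(self):
        assert len(phantom.SITE_CODES) == 6
        for code in ("RUQ", "BLD", "PTX_B", "HTX_B"):
            assert site_mode(code) == "B"
        for code in ("PTX_M", "HTX_M"):
            assert site_mode(code) == "M"

    def test_unknown_site_rejected(self):
        with pytest.raises(ValueError):
            site_mode("LUQ")


class TestSubjectEffects:
    def test_zero_sds_give_central_values(self):
        p = PhantomParams(gain_sd=0, grain_sd=0, depth_jitter_sd=0,
                          geometry_jitter_sd=0)
        eff = sample_subject_effects(p, 3)
        assert eff.gain_offset == 0.0
        assert eff.grain_scale == p.grain
        assert eff.depth_jitter == 0.0
        assert eff.geometry_jitter == (0.0, 0.0, 0.0, 0.0)

    def test_deterministic_for_fixed_seed(self, desk_params):
        assert (sample_subject_effects(desk_params, 5)
                == sample_subject_effects(desk_params, 5))

    def test_gain_offset_sd_matches_configuration(self):
        # Monte-Carlo: sample SD within 3 standard errors of the target SD
        p = PhantomParams(gain_sd=0.04)
        draws = np.array([sample_subject_effects(p, s).gain_offset
                          for s in range(100)])
        se = p.gain_sd / np.sqrt(2 * (len(draws) - 1))
        assert abs(draws.std(ddof=1) - p.gain_sd) < 3 * se

    def test_negative_seed_rejected(self, desk_params):
        with pytest.raises(ValueError):
            sample_subject_effects(desk_params, -1)


class TestSpeckleField:
    def test_zero_sigma_gives_zero_field(self, rng):
        assert not speckle_field(16, 16, 0.0, 1.0, rng).any()

    def test_rayleigh_mean_without_smoothing(self):
        # magnitude of i.i.d. complex Gaussian is Rayleigh(sigma):
        # mean sigma*sqrt(pi/2), sd sigma*sqrt((4-pi)/2)
        sigma = 0.2
        field = speckle_field(256, 256, sigma, 0.0, np.random.default_rng(0))
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt((4 - np.pi) / 2) / 256
        assert abs(field.mean() - expected) < 3 * se

    def test_fixed_seed_bit_identical(self):
        a = speckle_field(32, 32, 0.2, 1.5, np.random.default_rng(9))
        b = speckle_field(32, 32, 0.2, 1.5, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_invalid_dimensions_rejected(self, rng):
        with pytest.raises(ValueError):
            speckle_field(0, 16, 0.2, 1.0, rng)


class TestBModeRendering:
    @pytest.mark.parametrize("site", ["RUQ", "BLD", "PTX_B", "HTX_B"])
    def test_zero_severity_nullifies_injury(self, site, effects):
        p0 = PhantomParams(severity=0.0, size=64, base_seed=7)
        pos = render_bmode(site, "positive", p0, effects,
                           np.random.default_rng(11))
        neg = render_bmode(site, "negative", p0, effects,
                           np.random.default_rng(11))
        np.testing.assert_array_equal(pos.pixels, neg.pixels)

    def test_htxb_fluid_region_darker_than_band_above(self, desk_params,
                                                      effects):
        fr = render_bmode("HTX_B", "positive", desk_params, effects,
                          np.random.default_rng(3))
        mask = fr.mask.astype(bool)
        rows = np.flatnonzero(mask.any(axis=1))
        height = rows.max() - rows.min() + 1
        shift = height + 8  # equal-area band safely above the pleural line
        above = np.zeros_like(mask)
        above[rows - shift, :] = mask[rows, :]
        assert fr.pixels[mask].mean() < 0.5 * fr.pixels[above].mean()

    def test_default_render_size_is_512(self, effects):
        fr = render_bmode("RUQ", "negative", PhantomParams(), effects,
                          np.random.default_rng(0))
        assert fr.pixels.shape == (512, 512)

    def test_pixels_stay_in_unit_interval(self, desk_params, effects, rng):
        for site in ("RUQ", "BLD", "PTX_B", "HTX_B"):
            for lab in ("positive", "negative"):
                fr = render_bmode(site, lab, desk_params, effects, rng)
                assert fr.pixels.min() >= 0.0 and fr.pixels.max() <= 1.0

    def test_mmode_site_rejected(self, desk_params, effects, rng):
        with pytest.raises(ValueError):
            render_bmode("PTX_M", "positive", desk_params, effects, rng)


class TestMModeRendering:
    def test_default_duration_five_seconds(self, desk_params, effects, rng):
        cap = render_mmode("PTX_M", "negative", desk_params, effects, rng)
        assert cap.duration == 5.0
        assert cap.matrix.shape[1] == round(5.0 * cap.columns_per_second)

    def test_ptxm_positive_is_temporally_static(self, desk_params, effects):
        # barcode sign: column-to-column variation collapses below the line
        pos = render_mmode("PTX_M", "positive", desk_params, effects,
                           np.random.default_rng(4))
        neg = render_mmode("PTX_M", "negative", desk_params, effects,
                           np.random.default_rng(4))
        sub = pos.mask.astype(bool)
        var_pos = np.abs(np.diff(pos.matrix, axis=1))[sub[:, 1:]].mean()
        var_neg = np.abs(np.diff(neg.matrix, axis=1))[sub[:, 1:]].mean()
        assert var_pos < var_neg

    def test_zero_severity_nullifies_injury(self, effects):
        p0 = PhantomParams(severity=0.0, size=64, base_seed=7)
        for site in ("PTX_M", "HTX_M"):
            pos = render_mmode(site, "positive", p0, effects,
                               np.random.default_rng(2))
            neg = render_mmode(site, "negative", p0, effects,
                               np.random.default_rng(2))
            np.testing.assert_array_equal(pos.matrix, neg.matrix)

    def test_bmode_site_rejected(self, desk_params, effects, rng):
        with pytest.raises(ValueError):
            render_mmode("RUQ", "positive", desk_params, effects, rng)


class TestCohort:
    def test_empty_cohort(self, desk_params):
        assert generate_cohort(desk_params, 0, {"RUQ": 2}) == []

    def test_27_distinct_subjects(self, desk_params):
        cohort = generate_cohort(desk_params, 27, {"RUQ": 1})
        assert len({ds.subject_id for ds in cohort}) == 27

    def test_reproducible_from_base_seed(self, desk_params):
        a = generate_cohort(desk_params, 2, {"HTX_B": 2, "PTX_M": 1})
        b = generate_cohort(desk_params, 2, {"HTX_B": 2, "PTX_M": 1})
        for da, db in zip(a, b):
            for site in da.frames:
                for fa, fb in zip(da.frames[site], db.frames[site]):
                    pa = fa.pixels if hasattr(fa, "pixels") else fa.matrix
                    pb = fb.pixels if hasattr(fb, "pixels") else fb.matrix
                    np.testing.assert_array_equal(pa, pb)

    def test_negative_counts_rejected(self, desk_params):
        with pytest.raises(ValueError):
            generate_cohort(desk_params, 1, {"RUQ": -1})

    def test_every_frame_matches_container_subject(self, tiny_cohort):
        for ds in tiny_cohort:
            for item in ds.items():
                assert item.subject_id == ds.subject_id


def test_save_cohort_layout(tmp_path, tiny_cohort):
    manifest = phantom.save_cohort(tiny_cohort, tmp_path, severity=1.0)
    assert set(manifest.columns) == {"path", "site", "mode", "subject",
                                     "label", "severity"}
    assert len(manifest) == sum(len(list(ds.items())) for ds in tiny_cohort)
    first = tmp_path / manifest.iloc[0]["path"]
    assert first.exists()
    parts = first.relative_to(tmp_path).parts
    assert parts[0] in phantom.SITE_CODES and parts[2] in ("positive", "negative")
    assert (tmp_path / "manifest.csv").exists()
    assert (tmp_path / "manifest.json").exists()
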