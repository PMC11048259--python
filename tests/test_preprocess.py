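"""Cropping, resizing, rolling-window splitting, datastores, balanced
sampling, and augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from efastnet import phantom, preprocess
from efastnet.phantom import Frame, MModeCapture
from efastnet.preprocess import (AugmentPolicy, InsufficientDataError,
                                 apply_augment, augment_pixels,
                                 balanced_sample, build_datastore, crop_ui,
                                 expand_mmode, resize_frame,
                                 split_mmode_windows)


def _frame(px, subject="S0", label="negative", prov="p0", site="RUQ"):
    return Frame(np.asarray(px, dtype=np.float32), site, subject, label, prov)


class TestCrop:
    def test_zero_margins_identity(self, rng):
        fr = _frame(rng.random((16, 16)))
        np.testing.assert_array_equal(crop_ui(fr).pixels, fr.pixels)

    def test_margin_arithmetic(self, rng):
        fr = _frame(rng.random((512, 512)))
        out = crop_ui(fr, 10, 10, 10, 10)
        assert out.pixels.shape == (492, 492)
        assert out.provenance == fr.provenance

    def test_margins_consuming_frame_rejected(self, rng):
        fr = _frame(rng.random((16, 16)))
        with pytest.raises(ValueError):
            crop_ui(fr, top=16)


class TestResize:
    def test_constant_input_preserved(self):
        fr = _frame(np.full((20, 20), 0.3))
        out = resize_frame(fr, 40)
        np.testing.assert_allclose(out.pixels, 0.3, atol=1e-6)

    def test_already_target_untouched(self, rng):
        fr = _frame(rng.random((32, 32)))
        np.testing.assert_array_equal(resize_frame(fr, 32).pixels, fr.pixels)

    def test_default_target_512(self, rng):
        fr = _frame(rng.random((40, 40)))
        assert resize_frame(fr).pixels.shape == (512, 512)


class TestRollingWindow:
    def _capture(self, duration=5.0, cps=100.0):
        cols = round(duration * cps)
        mat = np.random.default_rng(0).random((32, cols)).astype(np.float32)
        return MModeCapture(mat, "PTX_M", "S0", "negative", "cap0",
                            duration=duration, columns_per_second=cps)

    def test_five_seconds_yield_25_sections(self):
        sections = split_mmode_windows(self._capture(), 1.0, 25)
        assert len(sections) == 25
        assert all(s.pixels.shape[1] == 100 for s in sections)

    def test_window_equal_duration_single_section(self):
        assert len(split_mmode_windows(self._capture(), 5.0, 25)) == 1

    def test_stride_formula_on_three_second_capture(self):
        # starts {0, 0.5, 1.0, 1.5, 2.0} s -> columns {0, 50, 100, 150, 200}
        cap = self._capture(duration=3.0)
        sections = split_mmode_windows(cap, 1.0, 5)
        cols = []
        for s in sections:
            for c0 in range(0, cap.matrix.shape[1] - 99):
                if np.array_equal(cap.matrix[:, c0:c0 + 100], s.pixels):
                    cols.append(c0)
                    break
        assert cols == [0, 50, 100, 150, 200]

    def test_constant_stride_and_provenance(self):
        sections = split_mmode_windows(self._capture(), 1.0, 25)
        assert [s.provenance for s in sections] == \
            [f"cap0/w{i}" for i in range(25)]

    def test_window_longer_than_duration_rejected(self):
        with pytest.raises(ValueError):
            split_mmode_windows(self._capture(), 6.0, 25)


class TestDatastore:
    def test_empty_cohort(self):
        assert build_datastore([]).total() == 0

    def test_count_conservation(self, tiny_cohort):
        store = build_datastore(tiny_cohort)
        expected = sum(len(list(ds.items())) for ds in tiny_cohort)
        assert store.total() == expected
        # brute-force recount per site
        for site in ("RUQ", "HTX_B"):
            manual = sum(
                1 for ds in tiny_cohort for it in ds.items() if it.site == site)
            by_key = sum(v for k, v in store.counts().items() if k[0] == site)
            assert by_key == manual

    def test_duplicate_provenance_rejected(self, desk_params, effects):
        fr = phantom.render_bmode("RUQ", "negative", desk_params, effects,
                                  np.random.default_rng(0))
        fr.subject_id = "S0"
        fr.provenance = "dup"
        ds = phantom.SubjectDataset("S0", "t", {"RUQ": [fr, fr]})
        with pytest.raises(ValueError, match="duplicate provenance"):
            build_datastore([ds])

    def test_mmode_captures_must_be_expanded_first(self, desk_params):
        cohort = phantom.generate_cohort(desk_params, 1, {"PTX_M": 1})
        with pytest.raises(TypeError):
            build_datastore(cohort)
        store = build_datastore(expand_mmode(cohort, target=32))
        assert store.total() == 2 * 25  # two captures x 25 sections


class TestBalancedSample:
    @pytest.fixture
    def store(self, tiny_cohort):
        return build_datastore(tiny_cohort)

    def test_zero_request_empty(self, store, rng):
        assert balanced_sample(store, "RUQ", ["S000"], 0, rng) == []

    def test_exact_balance(self, store, rng):
        out = balanced_sample(store, "RUQ", ["S000", "S001"], 3, rng)
        labels = [f.label for f in out]
        assert labels.count("positive") == 3 and labels.count("negative") == 3

    def test_no_frames_from_excluded_subjects(self, store, rng):
        out = balanced_sample(store, "RUQ", ["S001"], 4, rng)
        assert {f.subject_id for f in out} == {"S001"}

    def test_insufficient_data_reports_deficit(self, store, rng):
        with pytest.raises(InsufficientDataError) as err:
            balanced_sample(store, "RUQ", ["S000"], 99, rng)
        assert err.value.deficits == {"positive": 95, "negative": 95}


class _ScriptedRng:
    """Deterministic stand-in: .random() and .uniform() replay a script."""

    def __init__(self, randoms=(), uniforms=()):
        self._r = list(randoms)
        self._u = list(uniforms)

    def random(self):
        return self._r.pop(0)

    def uniform(self, lo, hi):
        return self._u.pop(0)


class TestAugment:
    def test_identity_policy_returns_same_pixels(self, rng):
        fr = _frame(rng.random((16, 16)))
        policy = AugmentPolicy(False, 0.0, (1.0, 1.0))
        np.testing.assert_array_equal(
            apply_augment(fr, policy, rng).pixels, fr.pixels)

    def test_double_reflection_is_involution(self, rng):
        px = rng.random((8, 8)).astype(np.float32)
        policy = AugmentPolicy(True, 0.0, (1.0, 1.0))
        script = _ScriptedRng(randoms=[0.0, 0.0], uniforms=[0.0, 1.0, 0.0, 1.0])
        once = augment_pixels(px, policy, script)
        twice = augment_pixels(once, policy, script)
        np.testing.assert_array_equal(twice, px)

    def test_90_degree_rotation_permutes_pixels(self):
        # 2x2 grid [[a,b],[c,d]] rotated 90 deg ccw -> [[b,d],[a,c]]
        px = np.array([[0.1, 0.2], [0.3, 0.4]], dtype=np.float32)
        policy = AugmentPolicy(False, 90.0, (1.0, 1.0))
        script = _ScriptedRng(uniforms=[90.0, 1.0])
        out = augment_pixels(px, policy, script)
        np.testing.assert_allclose(out, np.rot90(px, 1), atol=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_extents_and_range_preserved(self, seed):
        r = np.random.default_rng(seed)
        px = r.random((24, 24)).astype(np.float32)
        out = augment_pixels(px, preprocess.STAGE_POLICY, r)
        assert out.shape == px.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            AugmentPolicy(True, -1.0, (1.0, 1.0))
        with pytest.raises(ValueError):
            AugmentPolicy(True, 10.0, (1.2, 0.8))
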