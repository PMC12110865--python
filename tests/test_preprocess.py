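"""Preprocessing/augmentation tests: operator contracts, dataset expansion
arithmetic, stratified split, and the color-to-pH calibration round trip."""

import numpy as np
import pandas as pd
import pytest

from freshfusion.preprocess import (AugmentPolicy, apply_augment,
                                    augment_dataset, augment_image,
                                    color_scalar, equalize_histogram,
                                    extract_center_rgb, fit_ph_calibration,
                                    gamma_correct, normalize_rgb,
                                    PhCalibration, resize_image, rgb_to_ph,
                                    sample_augment_params, split_dataset)
from freshfusion.synthetic import (METADATA_COLUMNS, MultimodalDataset,
                                   ph_to_film_color)


class TestElementaryOps:
    def test_resize_to_512(self, rng):
        img = rng.random((1024, 768, 3))
        assert resize_image(img, 512).shape == (512, 512, 3)

    def test_resize_identity(self, rng):
        img = rng.random((512, 512, 3))
        assert np.array_equal(resize_image(img, 512), img)

    def test_resize_preserves_constant_color(self):
        img = np.full((100, 40, 3), 0.37)
        out = resize_image(img, 64)
        assert np.allclose(out, 0.37)

    def test_resize_rejects_empty(self):
        with pytest.raises(ValueError):
            resize_image(np.empty((0, 0, 3)))

    @pytest.mark.parametrize("value,expected", [(255, 1.0), (0, 0.0),
                                                (127.5, 0.5)])
    def test_normalize_rgb_linearity(self, value, expected):
        img = np.full((4, 4, 3), value, dtype=float)
        assert np.allclose(normalize_rgb(img), expected)

    def test_normalize_rgb_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            normalize_rgb(np.full((2, 2, 3), 300.0))

    def test_equalize_constant_image_unchanged(self):
        img = np.full((8, 8, 3), 0.4)
        assert np.allclose(equalize_histogram(img), img)

    def test_equalize_two_level_image_maps_to_cdf(self):
        # 25% of luminance at 0.2, 75% at 0.8 -> CDF values 0.25 and 1.0
        img = np.full((4, 4, 3), 0.8)
        img[0, :, :] = 0.2
        out = equalize_histogram(img)
        assert np.allclose(out[0], 0.25)
        assert np.allclose(out[1:], 1.0)

    def test_equalize_output_in_unit_range(self, rng):
        out = equalize_histogram(rng.random((16, 16, 3)))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_gamma_identity_and_example(self):
        img = np.full((2, 2, 3), 0.25)
        assert np.allclose(gamma_correct(img, 1.0), img)
        assert np.allclose(gamma_correct(img, 0.5), 0.5)

    def test_gamma_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gamma_correct(np.zeros((2, 2, 3)), 0.0)


class TestAugmentation:
    def test_sampled_parameters_respect_policy_ranges(self, rng):
        policy = AugmentPolicy()
        for _ in range(100):
            p = sample_augment_params(policy, rng)
            assert -15.0 <= p.rotation_deg <= 15.0
            assert 0.10 <= p.occlusion_frac <= 0.20
            assert 0.8 <= p.scale <= 1.2
            assert 0.5 <= p.gamma <= 1.5

    def test_augment_preserves_shape_and_range(self, rng):
        img = rng.random((48, 48, 3))
        out = augment_image(img, AugmentPolicy(), seed=5)
        assert out.shape == img.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_augment_deterministic_given_seed(self, rng):
        img = rng.random((40, 40, 3))
        a = augment_image(img, AugmentPolicy(), seed=9)
        b = augment_image(img, AugmentPolicy(), seed=9)
        assert np.array_equal(a, b)

    def test_occlusion_covers_requested_area(self, rng):
        img = np.ones((64, 64, 3))
        policy = AugmentPolicy(rotation_deg=0.0, hflip_prob=0.0,
                               scale_range=(1.0, 1.0), gamma_range=(1.0, 1.0))
        out = augment_image(img, policy, seed=3)
        occluded = np.isclose(out, 0.5).all(axis=2).mean()
        assert 0.08 <= occluded <= 0.22  # rectangle rounding tolerance

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            AugmentPolicy(hflip_prob=1.5)
        with pytest.raises(ValueError):
            AugmentPolicy(occlusion_area_frac=(0.0, 0.2))
        with pytest.raises(ValueError):
            AugmentPolicy(scale_range=(1.2, 0.8))


def _toy_dataset(n, labels=None, seed=0):
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = rng.choice(["fresh", "qualified", "inedible"], size=n)
    meta = pd.DataFrame({c: [""] * n for c in METADATA_COLUMNS})
    meta["image_path"] = [f"images/img_{i:06d}.png" for i in range(n)]
    meta["label"] = labels
    meta["ph"] = rng.uniform(6.0, 7.8, size=n)
    images = rng.random((n, 8, 8, 3)).astype(np.float32)
    return MultimodalDataset(images, meta, pd.DataFrame())


class TestDatasetExpansion:
    @pytest.mark.parametrize("n,copies", [(0, 1), (1, 1), (10, 1), (7, 3)])
    def test_output_count_is_input_times_one_plus_copies(self, n, copies):
        ds = _toy_dataset(n)
        out = augment_dataset(ds, AugmentPolicy(copies_per_image=copies))
        assert len(out) == n * (1 + copies)
        assert len(out.images) == len(out.meta)

    def test_originals_retained_and_provenance_linked(self):
        ds = _toy_dataset(5)
        out = augment_dataset(ds, AugmentPolicy(copies_per_image=1))
        assert np.array_equal(out.images[:5], ds.images)
        aug = out.meta.iloc[5:]
        assert (aug["source_image_path"].to_numpy()
                == ds.meta["image_path"].to_numpy()).all()

    def test_augmented_rows_inherit_split(self):
        ds = _toy_dataset(10)
        ds = split_dataset(ds, 0.8, seed=0)
        out = augment_dataset(ds, AugmentPolicy(copies_per_image=1))
        orig = out.meta.iloc[:10]["split"].to_numpy()
        aug = out.meta.iloc[10:]["split"].to_numpy()
        assert (orig == aug).all()


class TestSplit:
    def test_8020_arithmetic(self):
        ds = _toy_dataset(10, labels=["fresh"] * 10)
        out = split_dataset(ds, 0.8, seed=1)
        counts = out.meta["split"].value_counts()
        assert counts["train"] == 8 and counts["val"] == 2

    def test_stratified_within_one_sample_over_many_seeds(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(30, 120))
            ds = _toy_dataset(n, seed=seed)
            out = split_dataset(ds, 0.8, seed=seed)
            for label, group in out.meta.groupby("label"):
                n_train = (group["split"] == "train").sum()
                assert abs(n_train - 0.8 * len(group)) <= 1.0

    def test_deterministic_given_seed(self):
        ds = _toy_dataset(40)
        a = split_dataset(ds, 0.8, seed=4).meta["split"]
        b = split_dataset(ds, 0.8, seed=4).meta["split"]
        assert (a == b).all()

    def test_tiny_class_goes_to_train_with_warning(self):
        ds = _toy_dataset(11, labels=["fresh"] * 10 + ["inedible"])
        with pytest.warns(UserWarning):
            out = split_dataset(ds, 0.8, seed=0)
        row = out.meta[out.meta["label"] == "inedible"]
        assert (row["split"] == "train").all()

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_dataset(_toy_dataset(10), 1.0, seed=0)


class TestCenterWindow:
    def test_constant_image(self):
        img = np.full((120, 120, 3), 0.3)
        assert np.allclose(extract_center_rgb(img), (0.3, 0.3, 0.3))

    def test_window_indexing(self):
        img = np.zeros((512, 512, 3))
        img[206:306, 206:306] = 1.0  # exactly the centered 100x100 window
        assert np.allclose(extract_center_rgb(img, 100), 1.0)

    def test_window_larger_than_image(self):
        with pytest.raises(ValueError):
            extract_center_rgb(np.zeros((50, 50, 3)), 100)


class TestCalibration:
    def test_exact_cubic_interpolation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 0.5 * x ** 3 - x + 2
        cal = fit_ph_calibration(x, y)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_film_colors_fit_with_high_r2(self):
        ph = np.linspace(5.8, 8.6, 20)
        scalars = [color_scalar(ph_to_film_color(p)) for p in ph]
        cal = fit_ph_calibration(np.asarray(scalars), ph)
        assert cal.r_squared >= 0.98

    def test_round_trip_error_below_0p05_ph(self):
        ph = np.linspace(5.8, 8.6, 20)
        scalars = [color_scalar(ph_to_film_color(p)) for p in ph]
        cal = fit_ph_calibration(np.asarray(scalars), ph)
        for p in np.linspace(5.8, 8.6, 57):
            recovered = rgb_to_ph(cal, ph_to_film_color(p))
            assert abs(recovered - p) < 0.05

    def test_output_clamped_to_film_range(self):
        ph = np.linspace(5.8, 8.6, 10)
        scalars = np.asarray([color_scalar(ph_to_film_color(p)) for p in ph])
        cal = fit_ph_calibration(scalars, ph)
        assert 5.8 <= rgb_to_ph(cal, np.array([0.1, 0.9, 0.1])) <= 8.6

    def test_duplicate_scalars_rejected(self):
        with pytest.raises(ValueError):
            fit_ph_calibration(np.array([1.0, 1.0, 1.0, 1.0]),
                               np.array([6.0, 6.5, 7.0, 7.5]))

    def test_json_roundtrip(self, tmp_path):
        cal = fit_ph_calibration(np.array([0.0, 1.0, 2.0, 3.0]),
                                 np.array([6.0, 6.5, 7.0, 7.5]))
        path = tmp_path / "cal.json"
        cal.to_json(path)
        loaded = PhCalibration.from_json(path)
        assert np.allclose(loaded.coefficients, cal.coefficients)
        assert loaded.r_squared == cal.r_squared
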