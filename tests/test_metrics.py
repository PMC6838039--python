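"""Color-constancy metrics: NMI, NMH, AMCE, CD, population CV."""

import numpy as np
import pytest

from henorm import metrics, normalize, synthetic
from henorm.color import rgb_to_lab
from henorm.errors import InvalidInputError, UndefinedMetricError

from conftest import random_rgb


def brute_percentile(values, q):
    """Independent linear-interpolation percentile on sorted order statistics."""
    v = sorted(float(x) for x in values)
    if len(v) == 1:
        return v[0]
    pos = (len(v) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


class TestNmi:
    def test_uniform_image_is_one(self):
        img = np.full((8, 8, 3), 37, dtype=np.uint8)
        assert metrics.nmi(img) == pytest.approx(1.0)

    def test_known_order_statistics(self):
        vals = np.arange(1, 101, dtype=np.uint8)
        img = np.repeat(vals, 3).reshape(10, 10, 3)  # A(i) = 1..100
        assert metrics.nmi(img) == pytest.approx(50.5 / 95.05, abs=1e-12)

    def test_all_black_undefined(self):
        with pytest.raises(UndefinedMetricError):
            metrics.nmi(np.zeros((8, 8, 3), dtype=np.uint8))


class TestNmh:
    def test_uniform_blue_is_one(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[..., 2] = 255
        assert metrics.nmh(img) == pytest.approx(1.0)

    def test_uniform_chromatic_point_mass_is_one(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[..., 1] = 200
        img[..., 2] = 90
        assert metrics.nmh(img) == pytest.approx(1.0)

    def test_two_hue_mixture(self):
        # (85,255,0) has hue exactly 100 deg; (0,170,255) exactly 200 deg
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        img[:5] = (85, 255, 0)
        img[5:] = (0, 170, 255)
        assert metrics.nmh(img) == pytest.approx(150.0 / 200.0, abs=1e-12)

    def test_achromatic_image_undefined(self):
        with pytest.raises(UndefinedMetricError):
            metrics.nmh(np.full((8, 8, 3), 99, dtype=np.uint8))


class TestAmce:
    def test_identical_sets_give_zero(self, rng):
        imgs = [random_rgb(rng, 64, 64) for _ in range(3)]
        a, b = metrics.amce(imgs, list(imgs), window_size=16)
        assert a == 0.0 and b == 0.0

    def test_alpha_shift_measured(self, rng):
        # mid-range image so the opponent-channel shift stays inside the
        # 8-bit gamut (no clipping)
        img = rng.integers(110, 146, (128, 128, 3)).astype(np.uint8)
        lab = rgb_to_lab(img)
        shifted = lab.copy()
        shifted[..., 1] += 0.08
        from henorm.color import lab_to_rgb

        img2 = lab_to_rgb(shifted)
        assert not np.any((img2 == 0) | (img2 == 255))  # no gamut clipping
        a, b = metrics.amce([img], [img2], window_size=32)
        assert a == pytest.approx(0.08, abs=0.01)
        assert b < 0.01

    def test_matches_brute_force_pooling(self, rng):
        tars = [random_rgb(rng, 48, 72) for _ in range(2)]
        procs = [random_rgb(rng, 72, 48) for _ in range(3)]
        w = 16
        got = metrics.amce(tars, procs, window_size=w)
        for idx, val in zip((1, 2), got):
            pools = []
            for imgs in (tars, procs):
                means = []
                for img in imgs:
                    lab = rgb_to_lab(img)
                    H, W = lab.shape[:2]
                    for r in range(0, (H // w) * w, w):
                        for c in range(0, (W // w) * w, w):
                            means.append(lab[r : r + w, c : c + w, idx].mean())
                pools.append(means)
            n = min(len(pools[0]), len(pools[1]))
            expected = abs(
                np.mean(pools[0][:n]) - np.mean(pools[1][:n])
            )
            assert val == pytest.approx(expected, abs=1e-9)

    def test_empty_set_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            metrics.amce([], [random_rgb(rng)], window_size=8)

    def test_symmetry_under_swap(self, rng):
        a = [random_rgb(rng, 64, 64)]
        b = [random_rgb(rng, 64, 64)]
        assert metrics.amce(a, b, 16) == metrics.amce(b, a, 16)


class TestCd:
    def test_identical_images_zero(self, rng):
        img = random_rgb(rng, 64, 64)
        assert metrics.cd(img, img, window_size=16) == 0.0

    def test_contrast_stretch_positive(self, rng):
        base = rng.integers(80, 176, (64, 64, 3)).astype(np.uint8)
        mean = base.mean()
        stretched = np.clip((base.astype(float) - mean) * 1.5 + mean, 0, 255)
        assert not np.any((stretched <= 0) | (stretched >= 255))
        assert metrics.cd(stretched.astype(np.uint8), base, window_size=16) > 0

    def test_constant_image_nonpositive(self, rng):
        base = random_rgb(rng, 64, 64)
        const = np.full_like(base, 100)
        assert metrics.cd(const, base, window_size=16) <= 0

    def test_antisymmetry(self, rng):
        a, b = random_rgb(rng, 64, 64), random_rgb(rng, 64, 64)
        assert metrics.cd(a, b, 16) == pytest.approx(-metrics.cd(b, a, 16), abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            metrics.cd(random_rgb(rng, 32, 32), random_rgb(rng, 64, 64), 16)


class TestPopulationReport:
    def test_identical_images_have_zero_cv(self, rng):
        img = random_rgb(rng, 64, 64)
        rep = metrics.population_report([img] * 5, window_size=16)
        assert rep.cv("nmi") == pytest.approx(0.0, abs=1e-12)
        assert rep.cv("nmh") == pytest.approx(0.0, abs=1e-12)

    def test_cv_formula(self):
        vals = np.array([2.0, 4.0, 6.0])
        assert metrics._cv(vals) == pytest.approx(0.5)

    def test_cv_matches_brute_force_from_table(self, rng):
        imgs = [random_rgb(rng, 64, 64) for _ in range(6)]
        rep = metrics.population_report(imgs, window_size=16)
        for m in ("nmi", "nmh"):
            vals = rep.per_image[m].to_numpy(dtype=float)
            mean = sum(vals) / len(vals)
            std = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
            assert rep.summary.loc["cv", m] == pytest.approx(std / mean, abs=1e-12)

    def test_deterministic_ordering_by_id(self, rng):
        imgs = [random_rgb(rng, 32, 32) for _ in range(3)]
        ids = ["c", "a", "b"]
        rep = metrics.population_report(imgs, ids)
        assert list(rep.per_image.index) == ["a", "b", "c"]

    def test_undefined_metrics_recorded_missing(self, rng):
        imgs = [random_rgb(rng, 32, 32), np.zeros((32, 32, 3), dtype=np.uint8)]
        rep = metrics.population_report(imgs)
        assert rep.missing["nmi"] == 1
        assert np.isnan(rep.per_image["nmi"]).sum() == 1

    def test_mc_normalization_reduces_nmh_cv(self, small_params):
        data = synthetic.generate_multicenter(2, 4, small_params,
                                              stain_jitter_deg=15.0, seed=5)
        ref = synthetic.render(synthetic.generate_scene(small_params, seed=99))
        imgs = [im for _, im, _ in data]
        before = metrics.population_report(imgs, window_size=32)
        model = normalize.fit_reference(ref, "mc")
        after = metrics.population_report(
            [normalize.normalize(im, model) for im in imgs], window_size=32
        )
        assert after.cv("nmh") < before.cv("nmh")
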