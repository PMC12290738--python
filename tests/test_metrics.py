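"""Masked SSIM/PSNR, regional volumetry, rates, atrophy scenarios."""

import math

import numpy as np
import pytest

from longidiff.metrics import (MetricReport, aggregate_report,
                               annualized_atrophy_comparison, class_means_from,
                               error_rate, masked_mse, progression_gap,
                               progression_rate, psnr, region_volumes,
                               segment_by_intensity, ssim)


def _scalar_ssim_constant(a, b, data_range):
    """Independent scalar SSIM for two constant images: variance terms are
    zero so only the luminance term (2 mu_x mu_y + C1)/(mu_x^2 + mu_y^2 + C1)
    survives; the contrast/structure factor is C2/C2 = 1."""
    c1 = (0.01 * data_range) ** 2
    return (2 * a * b + c1) / (a * a + b * b + c1)


@pytest.fixture
def ball_mask():
    g = np.ogrid[0:24, 0:24, 0:24]
    return sum((x - 11.5) ** 2 for x in g) < 8.0 ** 2


class TestSSIM:
    def test_self_similarity_is_one(self, ball_mask, rng):
        v = rng.random((24, 24, 24))
        assert ssim(v, v, ball_mask) == pytest.approx(1.0)

    def test_symmetry(self, ball_mask, rng):
        x = rng.random((24, 24, 24))
        y = rng.random((24, 24, 24))
        assert ssim(x, y, ball_mask) == pytest.approx(
            ssim(y, x, ball_mask), abs=1e-12)

    def test_constant_offset_matches_scalar_oracle(self):
        mask = np.ones((20, 20, 20), dtype=bool)
        x = np.full((20, 20, 20), 0.25)
        y = x + 0.5
        expected = _scalar_ssim_constant(0.25, 0.75, 1.0)
        assert ssim(x, y, mask) == pytest.approx(expected, abs=1e-6)

    def test_invariant_to_changes_outside_mask(self, ball_mask, rng):
        x = rng.random((24, 24, 24))
        y = rng.random((24, 24, 24))
        base = ssim(x, y, ball_mask)
        x2 = x.copy()
        x2[~ball_mask] = 100.0 * rng.random((~ball_mask).sum())
        assert ssim(x2, y, ball_mask) == pytest.approx(base, abs=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ssim(np.zeros((8, 8, 8)), np.zeros((8, 8, 8)),
                 np.zeros((8, 8, 8), dtype=bool))


class TestPSNR:
    def test_worked_example(self):
        """Masked MSE of 0.25 with unit range gives 20 log10(1/0.5) dB."""
        mask = np.ones((10, 10, 10), dtype=bool)
        x = np.zeros((10, 10, 10))
        y = np.full((10, 10, 10), 0.5)
        assert psnr(x, y, mask) == pytest.approx(6.0206, abs=1e-4)

    def test_identical_images_are_infinite(self, rng):
        v = rng.random((8, 8, 8))
        assert psnr(v, v, np.ones_like(v, dtype=bool)) == math.inf

    def test_halving_mse_adds_3dB(self, rng):
        mask = np.ones((10, 10, 10), dtype=bool)
        x = np.zeros((10, 10, 10))
        y = np.full((10, 10, 10), 0.4)
        y2 = np.full((10, 10, 10), 0.4 / np.sqrt(2))
        assert psnr(x, y2, mask) - psnr(x, y, mask) == pytest.approx(
            10 * math.log10(2), abs=1e-9)

    def test_outside_mask_ignored(self, ball_mask, rng):
        x = rng.random((24, 24, 24))
        y = rng.random((24, 24, 24))
        x2 = x.copy()
        x2[~ball_mask] = -5.0
        assert psnr(x2, y, ball_mask) == pytest.approx(
            psnr(x, y, ball_mask), abs=1e-12)


class TestRegionVolumes:
    def test_counting(self):
        lm = np.zeros((10, 10, 10), dtype=int)
        lm.flat[:100] = 3
        assert region_volumes(lm, 1.0) == {3: 100.0}
        assert region_volumes(lm, 2.0) == {3: 200.0}

    def test_ellipsoid_volume_close_to_analytic(self):
        g = np.ogrid[0:48, 0:48, 0:48]
        a, b, c = 10.0, 8.0, 6.0
        inside = sum(((x - 23.5) / s) ** 2
                     for x, s in zip(g, (a, b, c))) <= 1.0
        vol = region_volumes(inside.astype(int))[1]
        analytic = 4.0 / 3.0 * math.pi * a * b * c
        assert vol == pytest.approx(analytic, rel=0.05)

    def test_background_only_rejected(self):
        with pytest.raises(ValueError, match="no nonzero"):
            region_volumes(np.zeros((4, 4, 4), dtype=int))


class TestRates:
    def test_error_rate_examples(self):
        y = {1: 100.0, 2: 50.0}
        assert error_rate(y, y) == {1: 0.0, 2: 0.0}
        assert error_rate({1: 90.0, 2: 50.0}, y)[1] == pytest.approx(0.1)
        assert error_rate({1: 110.0, 2: 50.0}, y)[1] == pytest.approx(0.1)

    def test_progression_examples(self):
        prev = {1: 100.0}
        assert progression_rate(prev, prev) == {1: 0.0}
        assert progression_rate({1: 95.0}, prev)[1] == pytest.approx(0.05)
        gap = progression_gap({1: 95.0}, {1: 96.0}, prev)
        assert gap[1] == pytest.approx(0.01)

    def test_scale_invariance(self):
        a = {1: 120.0, 2: 80.0}
        b = {1: 100.0, 2: 90.0}
        scaled = lambda d: {k: 3.5 * v for k, v in d.items()}
        assert error_rate(scaled(a), scaled(b)) == pytest.approx(
            error_rate(a, b))
        assert progression_rate(scaled(a), scaled(b)) == pytest.approx(
            progression_rate(a, b))

    def test_mismatched_regions_rejected(self):
        with pytest.raises(ValueError, match="region sets differ"):
            error_rate({1: 1.0}, {2: 1.0})


class TestAtrophyScenarios:
    def test_linear_decline_makes_doubling_exact(self):
        v0 = {1: 1000.0, 2: 500.0}
        v6 = {1: 950.0, 2: 480.0}      # linear: -50 and -20 per half year
        v12 = {1: 900.0, 2: 460.0}
        table = annualized_atrophy_comparison(v0, v6, v12, v12)
        assert np.allclose(table["dev_doubled"], 0.0)
        assert np.allclose(table["dev_imputed"], 0.0)

    def test_exponential_decline_biases_doubling_not_oracle(self):
        lam = 0.10  # per-visit decay
        traj = [{1: 1000.0 * math.exp(-lam * r)} for r in range(3)]
        table = annualized_atrophy_comparison(traj[0], traj[1], traj[2],
                                              traj[2])
        assert float(table["dev_doubled"].iloc[0]) > 0.0
        assert float(table["dev_imputed"].iloc[0]) == 0.0
        # doubled rate deviation equals (1 - e^{-lam})^2 analytically
        expected = (1.0 - math.exp(-lam)) ** 2
        assert float(table["dev_doubled"].iloc[0]) == pytest.approx(expected)

    def test_expanding_region_rates_signed(self):
        table = annualized_atrophy_comparison(
            {3: 100.0}, {3: 105.0}, {3: 110.0}, {3: 110.0})
        assert float(table["rate_complete"].iloc[0]) == pytest.approx(-0.1)


class TestAggregation:
    def test_single_report_sd_zero(self):
        rep = MetricReport(ssim=0.9, psnr_db=20.0)
        df = aggregate_report([rep])
        assert df.loc["mean", "ssim"] == pytest.approx(0.9)

    def test_two_report_mean(self):
        reps = [MetricReport(ssim=0.9, psnr_db=20.0),
                MetricReport(ssim=1.0, psnr_db=30.0)]
        df = aggregate_report(reps)
        assert df.loc["mean", "ssim"] == pytest.approx(0.95)
        assert df.loc["mean", "psnr_db"] == pytest.approx(25.0)
        assert aggregate_report(reps[::-1]).loc["mean", "ssim"] == \
            pytest.approx(0.95)

    def test_region_means_within_report_first(self):
        rep = MetricReport(ssim=1.0, psnr_db=30.0,
                           error_rate={1: 0.1, 2: 0.3})
        assert rep.mean_error_rate == pytest.approx(0.2)


class TestVolumeTables:
    def test_round_trip(self, tmp_path):
        from longidiff.metrics import read_volume_table, write_volume_table
        vols = {("sub-000", 0): {1: 473.1, 2: 231.8},
                ("sub-000", 1): {1: 405.7, 2: 198.7},
                ("sub-001", 0): {1: 460.0, 2: 240.0}}
        path = tmp_path / "volumes.tsv"
        write_volume_table(vols, path)
        back = read_volume_table(path)
        assert set(back) == set(vols)
        for key in vols:
            assert back[key] == pytest.approx(vols[key])

    def test_missing_columns_rejected(self, tmp_path):
        from longidiff.metrics import read_volume_table
        path = tmp_path / "bad.tsv"
        path.write_text("subject\tvisit\n a\t0\n")
        with pytest.raises(ValueError, match="columns"):
            read_volume_table(path)


class TestSegmentation:
    def test_nearest_mean_recovers_planted_labels(self, rng):
        mask = np.ones((16, 16, 16), dtype=bool)
        lm = np.zeros((16, 16, 16), dtype=int)
        lm[4:8, 4:8, 4:8] = 1
        img = np.where(lm == 1, 0.8, 0.3) + 0.02 * rng.standard_normal(lm.shape)
        cm = class_means_from(img, lm, mask)
        seg = segment_by_intensity(img, mask, cm)
        assert (seg == lm).mean() > 0.999
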