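"""MRI pathway: histograms, two-Gaussian fits, polarity, composition."""

import numpy as np
import pytest

from breastdensity import (
    MriVolume,
    PhantomSpec,
    TwoGaussianHistogramModel,
    VoxelGeometry,
    assign_gland_component,
    build_histogram,
    fit_two_gaussians,
    make_mri_phantom,
    mri_composition,
)
from breastdensity.mri_density import (
    GaussianComponent,
    MixtureFit,
    two_gaussian_curve,
)
from tests.conftest import sample_mixture_histogram


def small_volume(rng, protocol="3DGRE"):
    vol, truth = make_mri_phantom(
        PhantomSpec(shape=(24, 32, 32), gland_fraction=0.30, seed=13),
        protocol=protocol,
    )
    return vol, truth


class TestBuildHistogram:
    def test_mass_equals_masked_voxel_count(self, rng):
        vol, _ = small_volume(rng)
        centers, counts = build_histogram(vol)
        assert counts.sum() == vol.breast_mask.sum()
        vals = vol.voxels[vol.breast_mask]
        assert centers.min() >= vals.min() and centers.max() <= vals.max()

    def test_constant_volume_single_bin(self):
        voxels = np.full((4, 4, 4), 7.0)
        mask = np.ones_like(voxels, dtype=bool)
        vol = MriVolume(voxels, mask, VoxelGeometry(1.0, 1.0), "3DGRE")
        centers, counts = build_histogram(vol)
        assert centers.tolist() == [7.0] and counts.tolist() == [64]

    def test_matches_explicit_loop_tally(self, rng):
        vol, _ = small_volume(rng)
        centers, counts = build_histogram(vol, n_bins=32)
        vals = vol.voxels[vol.breast_mask]
        edges = np.linspace(vals.min(), vals.max(), 33)
        tally = [0] * 32
        for v in vals:
            k = min(int((v - edges[0]) / (edges[1] - edges[0])), 31)
            tally[k] += 1
        assert counts.tolist() == tally

    def test_empty_mask_rejected_at_construction(self):
        with pytest.raises(ValueError, match="empty"):
            MriVolume(
                np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool),
                VoxelGeometry(1.0, 1.0), "3DGRE",
            )


class TestTwoGaussianFit:
    def test_noise_free_self_fit_recovers_parameters(self):
        x = np.linspace(0, 1000, 200)
        true = (120.0, 300.0, 40.0, 80.0, 700.0, 60.0)
        y = two_gaussian_curve(x, true)
        fit = fit_two_gaussians((x, y), protocol="3DGRE", seed=0)
        assert fit.converged
        assert fit.rss == pytest.approx(0.0, abs=1e-10)
        got = (fit.gland, fit.adipose)  # 3DGRE: gland is the low-mean peak
        for comp, (a, m, s) in zip(got, [true[:3], true[3:]]):
            assert comp.amplitude == pytest.approx(a, rel=1e-6)
            assert comp.mean == pytest.approx(m, rel=1e-6)
            assert comp.sigma == pytest.approx(s, rel=1e-6)

    def test_sampled_mixture_fraction_recovered(self, rng):
        centers, counts, achieved = sample_mixture_histogram(
            rng, n=100_000, fraction_gland=0.30,
            mu_gland=300.0, mu_fat=700.0, sigma=60.0,
        )
        fit = fit_two_gaussians((centers, counts), protocol="3DGRE", seed=0)
        assert fit.converged
        assert fit.fraction_gland == pytest.approx(achieved, abs=0.02)

    def test_too_few_nonzero_bins_rejected(self):
        x = np.arange(5, dtype=float)
        y = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="nonzero bins"):
            fit_two_gaussians((x, y))

    def test_single_gaussian_histogram_flagged_degenerate_or_unconverged(
        self, rng
    ):
        vals = rng.normal(500.0, 50.0, 50_000)
        counts, edges = np.histogram(vals, bins=128)
        centers = 0.5 * (edges[:-1] + edges[1:])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            fit = fit_two_gaussians((centers, counts), protocol="3DGRE", seed=0)
        assert fit.degenerate or not fit.converged
        assert 0.0 <= fit.fraction_gland <= 1.0

    def test_fraction_invariant_under_intensity_rescaling(self, rng):
        centers, counts, _ = sample_mixture_histogram(
            rng, n=50_000, fraction_gland=0.40,
            mu_gland=200.0, mu_fat=600.0, sigma=50.0,
        )
        fit = fit_two_gaussians((centers, counts), protocol="3DGRE", seed=0)
        scaled = fit_two_gaussians(
            (centers * 3.0, counts), protocol="3DGRE", seed=0
        )
        assert scaled.fraction_gland == pytest.approx(
            fit.fraction_gland, abs=1e-6
        )
        assert scaled.gland.mean == pytest.approx(3.0 * fit.gland.mean, rel=1e-4)
        assert scaled.gland.sigma == pytest.approx(3.0 * fit.gland.sigma, rel=1e-4)

    def test_mean_recovery_over_many_seeded_histograms(self, rng):
        errors = []
        for i in range(20):
            r = np.random.default_rng(1000 + i)
            frac = float(r.uniform(0.15, 0.6))
            centers, counts, achieved = sample_mixture_histogram(
                r, n=40_000, fraction_gland=frac,
                mu_gland=300.0, mu_fat=700.0, sigma=90.0,  # >= 3 sigma apart
            )
            fit = fit_two_gaussians((centers, counts), protocol="3DGRE", seed=i)
            errors.append(abs(fit.fraction_gland - achieved))
        assert np.mean(errors) < 0.02

    def test_summary_reports_labeled_components(self, rng):
        centers, counts, _ = sample_mixture_histogram(
            rng, n=20_000, fraction_gland=0.3,
            mu_gland=300.0, mu_fat=700.0, sigma=50.0,
        )
        fit = TwoGaussianHistogramModel(centers, counts, "3DGRE").fit(seed=0)
        text = fit.summary()
        assert "gland" in text and "adipose" in text
        assert "fraction_gland" in text


class TestGlandAssignment:
    def _fit(self):
        low = GaussianComponent(10.0, 80.0, 5.0)
        high = GaussianComponent(20.0, 200.0, 5.0)
        return MixtureFit(adipose=high, gland=low, rss=0.0, converged=True)

    def test_3dgre_gland_is_low_mean_peak(self):
        fit = assign_gland_component(self._fit(), "3DGRE")
        assert fit.gland.mean == 80.0

    def test_stir_gland_is_high_mean_peak(self):
        fit = assign_gland_component(self._fit(), "STIR")
        assert fit.gland.mean == 200.0

    def test_override_wins_and_warns(self, caplog):
        with caplog.at_level("WARNING", logger="breastdensity.mri_density"):
            fit = assign_gland_component(
                self._fit(), "STIR", override_gland="low"
            )
        assert fit.gland.mean == 80.0
        assert "override" in caplog.text

    def test_equal_means_rejected(self):
        c = GaussianComponent(10.0, 100.0, 5.0)
        fit = MixtureFit(adipose=c, gland=c, rss=0.0, converged=True)
        with pytest.raises(ValueError, match="equal"):
            assign_gland_component(fit, "3DGRE")


class TestMriComposition:
    def test_voxel_count_arithmetic(self):
        voxels = np.zeros((100, 100, 100))
        voxels[:50] = 100.0  # irrelevant to the arithmetic below
        mask = np.ones_like(voxels, dtype=bool)
        vol = MriVolume(voxels, mask, VoxelGeometry(1.0, 1.0), "3DGRE")
        fit = MixtureFit(
            adipose=GaussianComponent(30.0, 700.0, 50.0),
            gland=GaussianComponent(10.0, 300.0, 50.0),
            rss=0.0, converged=True,
        )
        comp = mri_composition(vol, fit)
        assert comp.tv_ml == pytest.approx(1000.0)  # 1e6 voxels at 1 mm^3
        assert comp.gv_ml == pytest.approx(1000.0 * fit.fraction_gland)
        assert comp.gv_ml + comp.fv_ml == pytest.approx(comp.tv_ml, rel=1e-12)

    def test_zero_fraction_boundary(self):
        vol = MriVolume(
            np.ones((4, 4, 4)), np.ones((4, 4, 4), bool),
            VoxelGeometry(1.0, 1.0), "3DGRE",
        )
        fit = MixtureFit(
            adipose=GaussianComponent(10.0, 700.0, 50.0),
            gland=GaussianComponent(0.0, 300.0, 50.0),
            rss=0.0, converged=True,
        )
        comp = mri_composition(vol, fit)
        assert comp.gv_ml == 0.0 and comp.fv_ml == comp.tv_ml

    def test_unconverged_fit_rejected(self):
        vol = MriVolume(
            np.ones((4, 4, 4)), np.ones((4, 4, 4), bool),
            VoxelGeometry(1.0, 1.0), "STIR",
        )
        fit = MixtureFit(
            adipose=GaussianComponent(10.0, 700.0, 50.0),
            gland=GaussianComponent(5.0, 300.0, 50.0),
            rss=1.0, converged=False,
        )
        with pytest.raises(ValueError, match="converge"):
            mri_composition(vol, fit)

    def test_end_to_end_phantom_within_two_points(self, rng):
        for protocol in ("3DGRE", "STIR"):
            vol, truth = small_volume(rng, protocol)
            fit = fit_two_gaussians(
                build_histogram(vol), protocol=protocol, seed=0
            )
            comp = mri_composition(vol, fit)
            assert comp.method == protocol
            assert comp.pct_g == pytest.approx(
                100.0 * truth["fraction_gland"], abs=2.0
            )
            assert comp.tv_ml == pytest.approx(truth["tv_ml"], rel=1e-12)
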