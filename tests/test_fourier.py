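"""Fourier-domain observer: NPS, TTF, disk task spectrum, d' integral."""

import numpy as np
import pytest
from scipy.special import j1

from npwmf import (
    DiskFeature,
    ImageEnsemble,
    NoiseSpec,
    PhantomSpec,
    TaskTransferFunction,
    NoisePowerSpectrum,
    disk_image,
    disk_spectrum,
    dprime_fourier,
    estimate_nps,
    estimate_ttf,
    simulate_ensemble,
    background_roi_grid,
)


class TestDiskSpectrum:
    def test_dc_value_is_contrast_times_area(self):
        sp = disk_spectrum(DiskFeature((0.0, 0.0), 6.0, 10.0))
        assert sp(0.0) == pytest.approx(10.0 * np.pi * 9.0)

    def test_first_zero_at_bessel_root(self):
        # J1 first root 3.8317 -> rho = 3.8317 / (pi D) = 1.2197 / D
        D = 6.0
        sp = disk_spectrum(DiskFeature((0.0, 0.0), D, 10.0))
        rho0 = 3.8317059702 / (np.pi * D)
        assert abs(sp(rho0)) < 1e-6 * sp(0.0)
        assert sp(rho0 * 0.99) > 0 and sp(rho0 * 1.01) < 0

    def test_parseval_energy_matches_spatial_disk(self):
        # int |dF|^2 dnu (2D) = C^2 * disk area
        C, D = 10.0, 6.0
        sp = disk_spectrum(DiskFeature((0.0, 0.0), D, C))
        rho = np.linspace(0, 60, 400000)
        energy = np.trapezoid(sp(rho) ** 2 * 2 * np.pi * rho, rho)
        assert energy == pytest.approx(C**2 * np.pi * (D / 2) ** 2, rel=0.01)


def _noise_ensemble(model="white", std=10.0, n=16, shape=(96, 96), px=0.5, seed=4):
    spec = PhantomSpec(grid_shape=shape, pixel_size=px)
    return simulate_ensemble(spec, NoiseSpec(model=model, target_std=std), n, 1, seed)


class TestEstimateNps:
    def test_white_noise_spectrum_flat_at_sigma2_a(self):
        ens = _noise_ensemble(std=10.0)
        nps = estimate_nps(ens, roi_size=64)
        level = 10.0**2 * 0.5 * 0.5
        band = nps.values[2:28]
        assert band.mean() == pytest.approx(level, rel=0.05)

    def test_parseval_integral_matches_variance(self):
        ens = _noise_ensemble(model="parametric-ramp", std=8.0, n=20)
        nps = estimate_nps(ens, roi_size=64)
        var = (ens.pixels - ens.pixels.mean(axis=0, keepdims=True)).var() * 20 / 19
        assert nps.integral() == pytest.approx(var, rel=0.03)

    def test_matches_requested_radial_model_band_averaged(self):
        px, g = 0.5, 128
        ens = _noise_ensemble(model="parametric-ramp", std=10.0, n=30,
                              shape=(g, g), px=px, seed=8)
        nps = estimate_nps(ens, roi_size=64)
        fr = np.fft.fftfreq(g, px)
        rr = np.sqrt(fr[:, None] ** 2 + fr[None, :] ** 2)
        S = rr * np.exp(-((rr / 0.35) ** 2))
        truth = nps.radial_freq * np.exp(-((nps.radial_freq / 0.35) ** 2))
        truth = truth / S.mean() * 100 * px * px
        sel = slice(2, 30)
        ratio = nps.values[sel] / truth[sel]
        assert np.all(np.abs(ratio - 1) < 0.05)

    def test_zero_noise_gives_zero_spectrum(self):
        ens = _noise_ensemble(std=0.0, n=3)
        nps = estimate_nps(ens, roi_size=64)
        assert np.allclose(nps.values, 0.0)

    def test_requires_two_repeats(self):
        ens = _noise_ensemble(n=2)
        single = ImageEnsemble(ens.pixels[:1], ens.pixel_size)
        with pytest.raises(ValueError, match="2 repeats"):
            estimate_nps(single, roi_size=64)

    def test_roi_touching_feature_rejected(self):
        ens = _noise_ensemble(n=3, shape=(96, 96))
        mask = np.zeros((96, 96), bool)
        mask[10:20, 10:20] = True
        with pytest.raises(ValueError, match="touches"):
            estimate_nps(ens, 64, roi_corners=[(0, 0)], exclusion_masks=[mask])

    def test_background_grid_avoids_exclusions(self):
        mask = np.zeros((128, 128), bool)
        mask[:, :40] = True
        corners = background_roi_grid((128, 128), 64, [mask])
        assert corners and all(c >= 40 for _, c in corners)

    def test_csv_roundtrip(self, tmp_path):
        ens = _noise_ensemble(n=4)
        nps = estimate_nps(ens, roi_size=64)
        p = tmp_path / "nps.csv"
        nps.to_csv(p)
        back = NoisePowerSpectrum.from_csv(p, pixel_size=0.5)
        np.testing.assert_allclose(back.values, nps.values)


def _disk_ensemble(psf_mm, px=0.25, D=16.0, C=100.0, grid=160):
    c = (grid // 2) * px
    spec = PhantomSpec(grid_shape=(grid, grid), pixel_size=px,
                       features=(DiskFeature((c, c), D, C),), psf_sigma=psf_mm)
    return ImageEnsemble(disk_image(spec)[None, None], px), spec.features[0]


class TestEstimateTtf:
    def test_gaussian_psf_matches_closed_form(self):
        s = 1.0  # mm; 4 px, so the pixel aperture is negligible
        ens, feat = _disk_ensemble(s)
        ttf = estimate_ttf(ens, feat, min_cnr=0)
        ref = np.exp(-2 * np.pi**2 * s**2 * ttf.radial_freq**2)
        sel = ref >= 0.1
        assert np.all(np.abs(ttf.values[sel] - ref[sel]) < 0.03 * np.maximum(ref[sel], 0.1))

    def test_ideal_edge_near_unity_at_low_frequency(self):
        ens, feat = _disk_ensemble(0.0)
        ttf = estimate_ttf(ens, feat, min_cnr=0)
        nyq = 1 / (2 * 0.25)
        assert np.all(ttf.values[ttf.radial_freq <= 0.15 * nyq] > 0.97)
        assert np.all(ttf.values[ttf.radial_freq <= 0.5 * nyq] > 0.85)

    def test_contrast_independent_for_linear_images(self):
        ens1, feat1 = _disk_ensemble(0.8, C=50.0)
        ens2, feat2 = _disk_ensemble(0.8, C=100.0)
        t1 = estimate_ttf(ens1, feat1, min_cnr=0)
        t2 = estimate_ttf(ens2, feat2, min_cnr=0)
        np.testing.assert_allclose(t1.values, t2.values, atol=1e-9)

    def test_small_disk_rejected(self):
        ens, feat = _disk_ensemble(0.5, D=3.0)
        with pytest.raises(ValueError, match="too small"):
            estimate_ttf(ens, feat)

    def test_low_cnr_recommends_more_repeats(self, small_scene):
        spec, _ = small_scene
        big = PhantomSpec(grid_shape=(128, 128), pixel_size=0.469,
                          features=(DiskFeature((30.0, 30.0), 16.0, 5.0),),
                          psf_sigma=0.6)
        ens = simulate_ensemble(big, NoiseSpec(model="white", target_std=20.0), 2, 1, 1)
        with pytest.raises(ValueError, match="more repeats"):
            estimate_ttf(ens, big.features[0])


class TestDprimeFourier:
    def _flat(self, level, fmax=4.0, n=512):
        f = np.linspace(0, fmax, n)
        return NoisePowerSpectrum(f, np.full(n, level), 0.25, 0), TaskTransferFunction(
            f, np.ones(n)
        )

    def test_flat_nps_closed_form(self):
        # d'^2 = C^2 pi (D/2)^2 / N0 when T == 1 and the NPS is white
        C, D, N0 = 10.0, 6.0, 25.0
        nps, ttf = self._flat(N0)
        task = disk_spectrum(DiskFeature((0, 0), D, C))
        expected = np.sqrt(C**2 * np.pi * (D / 2) ** 2 / N0)
        assert dprime_fourier(nps, ttf, task) == pytest.approx(expected, rel=0.01)

    def test_contrast_homogeneity(self):
        nps, ttf = self._flat(25.0)
        d1 = dprime_fourier(nps, ttf, disk_spectrum(DiskFeature((0, 0), 6.0, 5.0)))
        d2 = dprime_fourier(nps, ttf, disk_spectrum(DiskFeature((0, 0), 6.0, 10.0)))
        assert d2 == pytest.approx(2 * d1, rel=1e-6)

    def test_grid_sampling_invariance(self):
        # same physical curves sampled on different grids agree closely
        task = disk_spectrum(DiskFeature((0, 0), 6.0, 10.0))
        d = []
        for fmax, n in [(2.0, 300), (4.0, 1200)]:
            f = np.linspace(0, fmax, n)
            nps = NoisePowerSpectrum(f, 25.0 * np.exp(-f), 0.25, 0)
            ttf = TaskTransferFunction(f, np.exp(-2 * np.pi**2 * 0.6**2 * f**2))
            d.append(dprime_fourier(nps, ttf, task))
        assert d[0] == pytest.approx(d[1], rel=0.02)

    def test_degenerate_nps_rejected(self):
        f = np.linspace(0, 2, 64)
        nps = NoisePowerSpectrum(f, np.zeros(64), 0.25, 0)
        ttf = TaskTransferFunction(f, np.ones(64))
        with pytest.raises(ValueError, match="NPS"):
            dprime_fourier(nps, ttf, disk_spectrum(DiskFeature((0, 0), 6.0, 10.0)))
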