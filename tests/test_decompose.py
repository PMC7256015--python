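"""Material decomposition: ML vs brute force, calibration, cross-talk."""

import numpy as np
import pytest

from spcct import config
from spcct.decompose import (
    _MLContext,
    conventional_sinogram,
    decompose_sinogram,
    effective_coefficients,
    effective_mu_water,
    fit_calibration,
    ml_decompose,
    ml_decompose_ray,
)
from spcct.forward import bin_weights, expected_counts, simulate_acquisition, Geometry
from spcct.phantoms import build_brain_slice, build_calibration_series, build_tube
from spcct.physics import mass_attenuation_at, load_attenuation_table


def _blank(spectrum, bins, flux=1e5):
    return bin_weights(spectrum, bins, flux).sum(axis=1)


def _grid_oracle(ctx, y, center, half_widths, n=121):
    """Brute-force likelihood maximizer on a local lattice around ``center``."""
    axes = [np.linspace(c - h, c + h, n) for c, h in zip(center, half_widths)]
    mesh = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([m.ravel() for m in mesh], axis=1)
    lam = np.clip(ctx.lam(grid), 1e-300, None)
    ll = (np.where(y > 0, y * np.log(lam), 0.0) - lam).sum(axis=1)
    return grid[np.argmax(ll)], np.array([a[1] - a[0] for a in axes])


class TestMaximumLikelihood:
    def test_noiseless_truth_recovered(self, spectrum, bins):
        blank = _blank(spectrum, bins)
        ctx = _MLContext(spectrum, bins, ("water", "gold"), None, blank)
        truth = np.array([3.0, 0.004])
        y = ctx.lam(truth[None])[0]
        a, conv = ml_decompose_ray(y, blank, spectrum, bins, ("water", "gold"))
        assert conv
        assert np.all(np.abs(a - truth) < 1e-6)

    def test_blank_counts_give_zero(self, spectrum, bins):
        blank = _blank(spectrum, bins)
        a, conv = ml_decompose_ray(blank, blank, spectrum, bins, ("water", "gold"))
        assert conv
        assert np.all(np.abs(a) < 1e-8)

    def test_matches_brute_force_grid_on_random_rays(self, spectrum, bins, rng):
        # >= 50 random noiseless water/gold rays: the Newton-type maximizer
        # must agree with an exhaustive likelihood search to grid resolution
        blank = _blank(spectrum, bins)
        basis = ("water", "gold")
        ctx = _MLContext(spectrum, bins, basis, None, blank)
        truths = np.stack(
            [rng.uniform(0.2, 4.0, 60), rng.uniform(0.0, 0.02, 60)], axis=1
        )
        y = ctx.lam(truths)
        a_hat, conv = ml_decompose(y, blank, spectrum, bins, basis)
        assert np.all(conv)
        for i in range(truths.shape[0]):
            best, step = _grid_oracle(
                ctx, y[i], a_hat[i], half_widths=(0.002, 0.0004), n=81
            )
            assert np.all(np.abs(a_hat[i] - best) <= step + 1e-12)

    def test_three_material_ray_matches_grid(self, spectrum, bins):
        blank = _blank(spectrum, bins)
        basis = ("water", "gold", "iodine")
        ctx = _MLContext(spectrum, bins, basis, None, blank)
        truth = np.array([5.0, 0.0, 0.005])
        y = ctx.lam(truth[None])[0]
        a_hat, conv = ml_decompose_ray(y, blank, spectrum, bins, basis)
        assert conv
        best, step = _grid_oracle(
            ctx, y, a_hat, half_widths=(0.002, 0.0004, 0.0004), n=41
        )
        assert np.all(np.abs(a_hat - best) <= step + 1e-12)

    def test_dead_ray_flagged(self, spectrum, bins):
        blank = _blank(spectrum, bins)
        a, conv = ml_decompose_ray(
            np.zeros(bins.n_bins), blank, spectrum, bins, ("water", "gold")
        )
        assert not conv
        assert np.all(a == 0)

    def test_asymptotically_unbiased(self, spectrum, bins):
        # 500 Poisson replicates of one ray at blank fluence 1e6
        blank = _blank(spectrum, bins, flux=1e6)
        basis = ("water", "gold")
        ctx = _MLContext(spectrum, bins, basis, None, blank)
        truth = np.array([2.5, 0.01])
        lam = ctx.lam(truth[None])[0]
        rng = np.random.default_rng(21)
        y = rng.poisson(lam, size=(500, bins.n_bins))
        a, conv = ml_decompose(y, blank, spectrum, bins, basis)
        assert conv.mean() > 0.99
        assert a[:, 1].mean() == pytest.approx(truth[1], rel=0.02)

    def test_noise_scales_with_inverse_sqrt_flux(self, spectrum, bins):
        basis = ("water", "gold")
        truth = np.array([2.5, 0.005])
        sds = []
        for flux in (1e4, 1e5):
            blank = _blank(spectrum, bins, flux=flux)
            ctx = _MLContext(spectrum, bins, basis, None, blank)
            lam = ctx.lam(truth[None])[0]
            rng = np.random.default_rng(5)
            y = rng.poisson(lam, size=(400, bins.n_bins))
            a, _ = ml_decompose(y, blank, spectrum, bins, basis)
            sds.append(a[:, 1].std())
        ratio = sds[0] / sds[1]
        assert 2.4 < ratio < 4.2  # ~sqrt(10)


class TestSinogramDecomposition:
    def test_zero_attenuation_sinogram(self, spectrum, bins, geometry, water_disk, acquire):
        empty = build_tube(0.0, "gold", 0.5)  # nearly no object
        empty.water[:] = 0.0
        sino = acquire(empty, noise=False)
        ms = decompose_sinogram(sino, spectrum)
        for m in ms.basis:
            assert np.all(np.abs(ms[m]) < 1e-8)

    def test_gold_only_phantom_has_no_iodine(self, spectrum, acquire):
        ph = build_tube(4.0, "gold", 12.0)
        ph.water[:] = 0.0  # pure gold suspension column
        sino = acquire(ph, noise=False)
        ms = decompose_sinogram(sino, spectrum)
        scale = np.abs(ms["gold"]).max()
        assert np.abs(ms["iodine"]).max() < 0.01 * scale

    def test_physics_and_calibrated_modes_agree(self, spectrum, bins, geometry, acquire):
        ph = build_tube(4.0, "gold", 12.0)
        sino = acquire(ph, noise=False)
        series = build_calibration_series([0, 5, 10], "gold", 12.0)
        series += build_calibration_series([5, 10], "iodine", 12.0)
        scans = [acquire(p, noise=False) for p in series]
        cal = fit_calibration(scans, series, geometry, basis=("water", "gold", "iodine"))
        phys = decompose_sinogram(sino, spectrum, mode="physics")
        calb = decompose_sinogram(sino, spectrum, mode="calibrated", calibration=cal)
        det = ph.shape[0] // 2
        a_p = phys["gold"][:, det]
        a_c = calb["gold"][:, det]
        assert np.abs(a_c - a_p).max() < 0.05 * np.abs(a_p).max()

    def test_unknown_mode_and_missing_calibration(self, spectrum, acquire, water_disk):
        sino = acquire(water_disk, noise=False)
        with pytest.raises(ValueError):
            decompose_sinogram(sino, spectrum, mode="magic")
        with pytest.raises(ValueError):
            decompose_sinogram(sino, spectrum, mode="calibrated")

    def test_basis_without_table_rejected(self, spectrum, acquire, water_disk):
        sino = acquire(water_disk, noise=False)
        with pytest.raises(ValueError):
            decompose_sinogram(sino, spectrum, basis=("water", "kryptonite"))

    def test_calcium_crosstalk_goes_to_iodine(self, spectrum, bins):
        # skull-crossing rays leak positively into the iodine basis while the
        # gold basis stays comparatively clean: the skull shows up in the
        # iodine image, not the gold image
        ph = build_brain_slice(0.0, 0.0, 0.0, 0.0, skull=True, grid_n=128)
        geo = Geometry(n_views=8, n_detectors=128)
        sino = simulate_acquisition(
            ph, spectrum, bins, geo, config.DEFAULT_FLUX, noise=False
        )
        ms = decompose_sinogram(sino, spectrum)
        crossing = ph.maps["calcium"].max(axis=0) > 0  # view-0 skull columns
        a_i = ms["iodine"][0, crossing]
        a_au = ms["gold"][0, crossing]
        assert a_i.mean() > 0
        assert np.abs(a_au).mean() < 0.5 * a_i.mean()


class TestCalibrationFit:
    def test_recovers_spectrum_weighted_coefficients(self, spectrum, bins, geometry, acquire):
        # thin-object limit: fitted slopes match the per-bin spectrum-weighted
        # mean attenuation oracle within 2 %
        series = build_calibration_series([0, 2, 5], "gold", 6.0)
        scans = [acquire(p, noise=False) for p in series]
        cal = fit_calibration(scans, series, geometry, basis=("water", "gold"))
        oracle = effective_coefficients(spectrum, bins, ("water", "gold"))
        assert np.abs(cal.coefficients / oracle - 1).max() < 0.02

    def test_gold_kedge_bin_ordering(self, spectrum, bins, geometry, acquire):
        series = build_calibration_series([0, 5, 10], "gold", 8.0)
        scans = [acquire(p, noise=False) for p in series]
        cal = fit_calibration(scans, series, geometry, basis=("water", "gold"))
        gold = cal.coefficients[:, 1]
        assert gold[3] > gold[1]  # bin [83,98) above the K edge exceeds [53,78)

    def test_degenerate_design_rejected(self, geometry, acquire):
        series = build_calibration_series([0, 0], "gold", 8.0)
        scans = [acquire(p, noise=False) for p in series]
        with pytest.raises(ValueError):
            fit_calibration(scans, series, geometry, basis=("water", "gold"))


class TestConventionalSinogram:
    def test_blank_and_unit_transmission(self, acquire, water_disk, spectrum, bins):
        sino = acquire(water_disk, noise=False)
        sino.counts = np.broadcast_to(sino.blank, sino.counts.shape).copy()
        assert np.allclose(conventional_sinogram(sino), 0.0)
        sino.counts = sino.counts / np.e
        assert np.allclose(conventional_sinogram(sino), 1.0)

    def test_water_disk_central_value(self, spectrum, bins, acquire):
        # polychromatic oracle: p_center = -ln(sum_b lam_b / sum_b blank_b)
        ph = build_tube(0.0, "gold", 12.0)
        sino = acquire(ph, noise=False)
        p = conventional_sinogram(sino)
        mu_eff = effective_mu_water(spectrum, bins)
        det = ph.shape[0] // 2
        assert p[0, det] == pytest.approx(mu_eff * 1.2, rel=0.03)
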