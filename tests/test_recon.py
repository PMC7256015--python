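"""FBP reconstruction: linearity, round-trip accuracy, HU convention."""

import numpy as np
import pytest

from spcct import config
from spcct.decompose import decompose_sinogram
from spcct.forward import Geometry, project_material
from spcct.phantoms import GeometryError, VoxelPhantom, build_tube
from spcct.quantify import background_annulus, measure_background_sd
from spcct.recon import (
    fbp,
    fbp_material,
    reconstruct_conventional,
    reconstruct_materials,
    to_hounsfield,
)


def _interior(diameter_mm, grid_n=64):
    # 1-voxel-eroded interior mask of a centered disk
    return build_tube(1.0, "gold", diameter_mm - 0.5, grid_n).maps["gold"] > 0


class TestFbp:
    def test_zero_sinogram_and_linearity(self, geometry):
        z = np.zeros((geometry.n_views, geometry.n_detectors))
        assert np.all(fbp(z, geometry) == 0)
        rng = np.random.default_rng(0)
        a = rng.random(z.shape)
        b = rng.random(z.shape)
        lhs = fbp(a + b, geometry)
        rhs = fbp(a, geometry) + fbp(b, geometry)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_uniform_disk_recovered_within_5pct(self, geometry):
        ph = build_tube(4.0, "gold", 10.0)
        sino = project_material(ph, geometry, "gold")
        img = fbp_material(sino, geometry, ph.voxel_size_um)
        assert img[_interior(10.0)].mean() == pytest.approx(4.0, rel=0.05)

    def test_geometry_mismatch_rejected(self, geometry):
        with pytest.raises(GeometryError):
            fbp(np.zeros((10, geometry.n_detectors)), geometry)
        with pytest.raises(GeometryError):
            fbp(np.zeros((2, 16)), Geometry(n_views=1, n_detectors=16))

    def test_unknown_filter(self, geometry):
        z = np.zeros((geometry.n_views, geometry.n_detectors))
        with pytest.raises(ValueError):
            fbp(z, geometry, filter_name="shepp")

    def test_hann_filter_smooths(self, geometry, acquire, spectrum):
        sino = acquire(build_tube(0.0, "gold", 12.0), seed=8)
        ms = decompose_sinogram(sino, spectrum)
        bg = background_annulus(64, 250.0)
        sd_ramp = measure_background_sd(fbp_material(ms["gold"], geometry, 250.0), bg)
        sd_hann = measure_background_sd(
            fbp_material(ms["gold"], geometry, 250.0, filter_name="hann"), bg
        )
        assert sd_hann < sd_ramp


class TestHounsfield:
    @pytest.mark.parametrize(
        "mu,expected", [(0.2, 0.0), (0.0, -1000.0), (0.4, 1000.0)]
    )
    def test_scale(self, mu, expected):
        assert to_hounsfield(np.array([mu]), 0.2)[0] == pytest.approx(expected)

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            to_hounsfield(np.zeros(3), 0.0)

    def test_water_near_zero_air_near_minus_1000(self, acquire, spectrum):
        sino = acquire(build_tube(0.0, "gold", 12.0), seed=5)
        hu = reconstruct_conventional(sino, spectrum, 250.0)
        assert abs(hu[_interior(12.0)].mean()) < 30.0
        air = np.zeros_like(hu, dtype=bool)
        air[2:6, 28:36] = True
        assert hu[air].mean() == pytest.approx(-1000.0, abs=40.0)


class TestRoundTrip:
    def test_noiseless_chain_recovers_concentrations(self, acquire, spectrum, geometry):
        # project -> ML decompose -> FBP recovers uniform regions within 5 %
        ph = build_tube(4.0, "gold", 10.0, 64)
        sino = acquire(ph, noise=False)
        images = reconstruct_materials(decompose_sinogram(sino, spectrum), geometry, 250.0)
        inner = _interior(10.0)
        assert images["gold"][inner].mean() == pytest.approx(4.0, rel=0.05)
        assert images["water"][inner].mean() == pytest.approx(1000.0, rel=0.05)


@pytest.fixture(scope="module")
def bicolor_images(acquire, spectrum, geometry):
    # disjoint gold and iodine deposits inside one water disk
    ph = build_tube(0.0, "gold", 12.0)
    gold = np.zeros(ph.shape)
    iodine = np.zeros(ph.shape)
    yy, xx = np.mgrid[0:64, 0:64]
    gold_region = (yy - 26) ** 2 + (xx - 32) ** 2 <= 9
    iodine_region = (yy - 38) ** 2 + (xx - 32) ** 2 <= 9
    # concentrations of the transplanted deposits: packed labeled cells
    # (~46 mg/mL gold) and labeled scaffold (~10 mg/mL iodine)
    gold[gold_region] = 45.7
    iodine[iodine_region] = 10.2
    phantom = VoxelPhantom(ph.water.copy(), {"gold": gold, "iodine": iodine}, 250.0)
    sino = acquire(phantom, seed=17)
    images = reconstruct_materials(decompose_sinogram(sino, spectrum), geometry, 250.0)
    return images, gold_region, iodine_region


class TestMaterialSpecificity:
    def test_material_images_separate_the_deposits(self, bicolor_images):
        images, gold_region, iodine_region = bicolor_images
        bg = background_annulus(64, 250.0) & ~gold_region & ~iodine_region
        sd_gold = measure_background_sd(images["gold"], bg)
        sd_iodine = measure_background_sd(images["iodine"], bg)
        # each map lights up its own deposit (region mean vs its SE) ...
        n = gold_region.sum()
        assert images["gold"][gold_region].mean() > 4 * sd_gold / np.sqrt(n)
        assert images["iodine"][iodine_region].mean() > 4 * sd_iodine / np.sqrt(n)
        # ... and stays silent at the other deposit
        assert abs(images["gold"][iodine_region].mean()) < 2 * sd_gold
        assert abs(images["iodine"][gold_region].mean()) < 2 * sd_iodine

    def test_conventional_cannot_separate_matched_deposits(self, acquire, spectrum):
        # equal-concentration gold and iodine tubes overlap within +/- 1 SD
        intervals = {}
        for el in ("gold", "iodine"):
            sino = acquire(build_tube(4.0, el, 12.0), seed=23)
            hu = reconstruct_conventional(sino, spectrum, 250.0)
            vals = hu[_interior(12.0)]
            intervals[el] = (vals.mean() - vals.std(), vals.mean() + vals.std())
        lo = max(intervals["gold"][0], intervals["iodine"][0])
        hi = min(intervals["gold"][1], intervals["iodine"][1])
        assert lo < hi
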