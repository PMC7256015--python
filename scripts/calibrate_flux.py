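"""One-off calibration of the default blank fluence.

Finds the blank fluence (expected counts per detector element per view,
summed over the spectrum) at which the reconstructed gold map of the default
water phantom has a background SD of 10 mg/mL.  Gold-map noise scales as
flux^-1/2, so the SD is measured at a reference fluence over seeded
replicates and scaled.  The resulting value is frozen as
``spcct.config.DEFAULT_FLUX``.

Run from the repository root:  python scripts/calibrate_flux.py
"""

import numpy as np

from spcct import config
from spcct.decompose import decompose_sinogram
from spcct.forward import simulate_acquisition
from spcct.phantoms import build_tube
from spcct.quantify import background_annulus, measure_background_sd
from spcct.recon import fbp_material

TARGET_SD = 10.0  # mg/mL
REFERENCE_FLUX = 40000.0
N_REPLICATES = 12
SEED = 20200422  # fixed once


def main() -> None:
    spectrum = config.default_spectrum()
    bins = config.default_bins()
    geometry = config.default_geometry()
    phantom = build_tube(0.0, "gold", config.DEFAULT_WATER_DISK_MM, config.DEFAULT_GRID_N)
    bg = background_annulus(config.DEFAULT_GRID_N, config.DEFAULT_VOXEL_UM)
    rng = np.random.default_rng(SEED)
    sds = []
    for i in range(N_REPLICATES):
        sino = simulate_acquisition(phantom, spectrum, bins, geometry, REFERENCE_FLUX, seed=rng)
        img = fbp_material(decompose_sinogram(sino, spectrum)["gold"], geometry,
                           config.DEFAULT_VOXEL_UM)
        sds.append(measure_background_sd(img, bg))
        print(f"replicate {i}: sigma_bg = {sds[-1]:.3f} mg/mL at flux {REFERENCE_FLUX:.0f}")
    sd_ref = float(np.sqrt(np.mean(np.square(sds))))
    flux = REFERENCE_FLUX * (sd_ref / TARGET_SD) ** 2
    print(f"pooled sigma_bg at reference flux: {sd_ref:.3f} mg/mL")
    print(f"calibrated flux for {TARGET_SD:.0f} mg/mL: {flux:.0f}")


if __name__ == "__main__":
    main()
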