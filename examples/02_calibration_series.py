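"""Tube calibration: recovered vs true concentration on K-edge images.

Simulates noisy scans of the gold tube series, decomposes and reconstructs
each, and regresses the recovered in-tube gold concentration on the truth.
"""

import numpy as np

from spcct import build_calibration_series, linreg, simulate_acquisition
from spcct import decompose_sinogram, reconstruct_materials
from spcct import config

GOLD_MM = [0, 10, 15, 20, 30, 40]

spectrum = config.default_spectrum()
bins = config.default_bins()
geometry = config.default_geometry()

series = build_calibration_series(GOLD_MM, "gold", tube_diameter_mm=12.0)
inner = build_calibration_series([1], "gold", tube_diameter_mm=9.0)[0].maps["gold"] > 0

truth, recovered = [], []
for i, phantom in enumerate(series):
    sino = simulate_acquisition(
        phantom, spectrum, bins, geometry, config.DEFAULT_FLUX, seed=100 + i
    )
    images = reconstruct_materials(
        decompose_sinogram(sino, spectrum), geometry, phantom.voxel_size_um
    )
    truth.append(phantom.maps["gold"].max())
    recovered.append(images["gold"][inner].mean())
    print(f"{GOLD_MM[i]:>3} mM: true {truth[-1]:6.3f}  recovered {recovered[-1]:6.3f} mg/mL")

fit = linreg(truth, recovered)
print(f"slope {fit.slope:.3f}, intercept {fit.intercept:.3f} mg/mL, R2 {fit.r_squared:.4f}")
# A slope near 1 and R2 near 1 mean the K-edge channel reads concentration
# quantitatively across the clinical contrast range.
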