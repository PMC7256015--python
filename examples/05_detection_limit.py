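"""Single-voxel detection limit of gold-labeled cells.

Places N labeled cells (128 pg gold each) into one 250 µm voxel and asks
how small N can be while the reconstructed gold-map voxel still exceeds a
4-sigma detection threshold reliably.  A coarse N grid keeps this demo
quick; scripts/acceptance.py runs the full 250-cell-step scan.
"""

import numpy as np

from spcct.quantify import detection_limit

res = detection_limit(seed=0, cell_grid=np.arange(2000, 12001, 1000))

print(f"gold-map background SD: {res.sigma_bg_mg_ml:.2f} mg/mL")
print(f"analytic 4-sigma contrast limit: {res.analytic_cells_per_voxel:.0f} cells/voxel")
print(f"empirical 95%-power limit:       {res.min_cells_per_voxel:.0f} cells/voxel")
print("detection rates:", {n: round(float(r), 2) for n, r in res.detection_rates.items()})
# The analytic figure (~4.9e3 cells at sigma = 10 mg/mL) is the number of
# cells whose single-voxel concentration equals 4 sigma.  Demanding 95 %
# detection power across replicates, and paying the point-spread recovery
# loss of ramp FBP, moves the empirical limit ~1.7x higher; see
# docs/methods.md for the breakdown.
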