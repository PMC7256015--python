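"""Bicolor brain slice: separating labeled cells from labeled scaffold.

Simulates a rat-head slice with a gold-labeled cell cluster inside an
iodine-labeled scaffold, plus a calcium skull, and shows that material
images separate all three while the conventional image cannot.
"""

import numpy as np

from spcct import build_brain_slice, simulate_acquisition
from spcct import decompose_sinogram, reconstruct_conventional, reconstruct_materials
from spcct import config
from spcct.forward import Geometry

spectrum = config.default_spectrum()
bins = config.default_bins()
geometry = Geometry(n_views=192, n_detectors=128)

phantom = build_brain_slice(
    cell_gold_mass_ug=48.0, cell_volume_ul=1.4,
    scaffold_iodine_mass_ug=50.0, scaffold_volume_ul=4.9,
    skull=True, grid_n=128,
)
sino = simulate_acquisition(
    phantom, spectrum, bins, geometry, config.DEFAULT_FLUX, seed=1
)
images = reconstruct_materials(
    decompose_sinogram(sino, spectrum), geometry, phantom.voxel_size_um
)
hu = reconstruct_conventional(sino, spectrum, phantom.voxel_size_um)

cells = phantom.maps["gold"] > 0
scaffold_only = (phantom.maps["iodine"] > 0) & ~cells
skull = phantom.maps["calcium"] > 0

print("region            gold map   iodine map   conventional (mean)")
for name, mask in (("cell cluster", cells), ("scaffold only", scaffold_only), ("skull", skull)):
    print(
        f"{name:<16} {images['gold'][mask].mean():8.1f} mg/mL"
        f" {images['iodine'][mask].mean():8.1f} mg/mL {hu[mask].mean():10.0f} HU"
    )
# The gold map lights up only the cell cluster and the iodine map only the
# scaffold, while both deposits and the skull are bright on the conventional
# image.  The skull also leaks into the iodine map (calcium/iodine
# cross-talk of the three-material basis) but stays out of the gold map.
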