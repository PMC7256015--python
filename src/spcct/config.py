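"""Shared default acquisition settings.

The defaults reproduce the acquisition used throughout: 120 kVp bremsstrahlung
beam with 2.5 mm Al filtration, the five counting thresholds 30/53/78/83/98
keV, 250 µm voxels, and desk-scale parallel-beam geometries.

``DEFAULT_FLUX`` is the blank fluence (expected counts per detector element
per view, summed over the spectrum).  It was calibrated once, with
``scripts/calibrate_flux.py``, so that the reconstructed gold map of the
default water phantom has a background SD of ≈ 10 mg/mL; the tube
current/time product of a real scan only enters a Poisson model through this
scalar.
"""

from __future__ import annotations

from .forward import Geometry
from .physics import EnergyBinSet, SourceSpectrum, build_source_spectrum

DEFAULT_KVP = 120.0
DEFAULT_FILTRATION_MM_AL = 2.5
DEFAULT_THRESHOLDS_KEV = (30.0, 53.0, 78.0, 83.0, 98.0)
DEFAULT_VOXEL_UM = 250.0

#: Blank fluence calibrated for a 10 mg/mL gold-map background SD on the
#: default 64-voxel water phantom (see scripts/calibrate_flux.py).
DEFAULT_FLUX = 26576.0

#: Desk-scale scan used for tubes, pellets and detection-limit studies.
DEFAULT_GRID_N = 64
DEFAULT_N_VIEWS = 96
DEFAULT_WATER_DISK_MM = 12.0


def default_spectrum() -> SourceSpectrum:
    return build_source_spectrum(DEFAULT_KVP, DEFAULT_FILTRATION_MM_AL)


def default_bins() -> EnergyBinSet:
    return EnergyBinSet(DEFAULT_THRESHOLDS_KEV, DEFAULT_KVP)


def default_geometry(grid_n: int = DEFAULT_GRID_N, n_views: int = DEFAULT_N_VIEWS) -> Geometry:
    return Geometry(n_views=n_views, n_detectors=grid_n)
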