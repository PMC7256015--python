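"""Multi-bin photon-counting acquisition model.

The acquisition chain is: discrete Radon transform of each material map
(parallel-beam, 2-D), polychromatic Beer–Lambert expected counts per energy
bin, and independent Poisson sampling.  The parallel-beam 360-view geometry
replaces the scanner's helical fan beam: ramp-filtered back-projection is
exact for it and the material-decomposition statistics per ray are the same.

Tube current and rotation time are absorbed into a single blank-fluence
scalar (photons per detector element per view, summed over the spectrum):
only the current × time product enters a Poisson counting model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import radon

from .phantoms import GeometryError, VoxelPhantom
from .physics import EnergyBinSet, SourceSpectrum, load_attenuation_table, mass_attenuation_at

__all__ = [
    "Geometry",
    "CountSinogram",
    "project_material",
    "project_basis",
    "bin_weights",
    "expected_counts",
    "sample_poisson",
    "simulate_acquisition",
]


@dataclass(frozen=True)
class Geometry:
    """2-D parallel-beam scan geometry.

    ``n_detectors`` must equal the phantom grid size (detector pitch equals
    the voxel pitch); views are spread uniformly over ``angular_span_deg``.
    """

    n_views: int = 360
    n_detectors: int = 384
    angular_span_deg: float = 180.0

    def __post_init__(self) -> None:
        if self.n_views < 1 or self.n_detectors < 1:
            raise ValueError("views and detectors must be positive")

    @property
    def thetas(self) -> np.ndarray:
        return np.linspace(0.0, self.angular_span_deg, self.n_views, endpoint=False)


@dataclass
class CountSinogram:
    """Photon counts per (view, detector, energy bin) plus the blank scan.

    ``counts`` holds integers after Poisson sampling or the real-valued
    expected counts for a noiseless acquisition.  ``blank`` is the expected
    per-bin count with no object in the beam (identical for every ray).
    """

    counts: np.ndarray
    blank: np.ndarray
    bins: EnergyBinSet
    geometry: Geometry

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.blank = np.asarray(self.blank, dtype=float)
        if self.counts.ndim != 3 or self.counts.shape[2] != self.bins.n_bins:
            raise ValueError("counts must have shape (views, detectors, bins)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.blank.shape != (self.bins.n_bins,) or np.any(self.blank <= 0):
            raise ValueError("blank must be positive in every bin")


def project_material(
    phantom: VoxelPhantom, geometry: Geometry, material: str
) -> np.ndarray:
    """Line integrals of one material map, g/cm², shape (views, detectors).

    Uses the rotate-and-sum discrete Radon transform; linear in the phantom.
    """
    if geometry.n_views < 1:
        raise ValueError("geometry has no views")
    grid = phantom.get_map(material)
    if grid.shape[0] != grid.shape[1] or grid.shape[0] != geometry.n_detectors:
        raise GeometryError(
            "detector count must match the (square) phantom grid size"
        )
    sino = radon(grid, theta=geometry.thetas, circle=True)  # (det, views)
    scale = phantom.voxel_size_cm  # path length per pixel
    if material == "water":
        return sino.T * scale  # g/mL × cm → g/cm²
    return sino.T * scale * 1e-3  # mg/mL × cm → g/cm²


def project_basis(phantom: VoxelPhantom, geometry: Geometry, materials) -> dict:
    """Line-integral sinograms for several materials (always include water)."""
    return {m: project_material(phantom, geometry, m) for m in materials}


def bin_weights(
    spectrum: SourceSpectrum, bins: EnergyBinSet, flux: float
) -> np.ndarray:
    """Per-bin spectral weights W_b(E) = S(E)·R_b(E), scaled to ``flux``.

    ``flux`` is the blank fluence: total expected counts per detector element
    per view summed over all bins.  Returns shape (n_bins, n_energies);
    blank_b = Σ_E W_b(E).
    """
    if flux <= 0:
        raise ValueError("flux must be positive")
    resp = bins.bin_response(spectrum.grid.energies)
    w = resp * spectrum.fluence[None, :]
    total = w.sum()
    if total <= 0:
        raise ValueError("spectrum carries no photons inside the bins")
    return w * (flux / total)


def expected_counts(
    line_integrals: dict,
    spectrum: SourceSpectrum,
    bins: EnergyBinSet,
    flux: float,
    tables: dict | None = None,
) -> tuple:
    """Polychromatic Beer–Lambert expected counts per bin.

    λ_b = Σ_E S(E)·R_b(E)·exp(−Σ_m (μ/ρ)_m(E)·A_m), evaluated on the
    spectrum's energy grid.  ``line_integrals`` maps material name to a
    (views, detectors) array in g/cm².  Returns ``(lam, blank)`` with
    ``lam`` shaped (views, detectors, n_bins).
    """
    mats = list(line_integrals)
    if not mats:
        raise ValueError("no materials to project")
    tables = tables or {m: load_attenuation_table(m) for m in mats}
    first = line_integrals[mats[0]]
    for m in mats:
        if np.any(line_integrals[m] < 0):
            raise ValueError(f"negative line integrals for {m!r}")
    energies = spectrum.grid.energies
    mu = np.stack([mass_attenuation_at(tables[m], energies) for m in mats])  # (M, E)
    a = np.stack([line_integrals[m].ravel() for m in mats], axis=1)  # (R, M)
    w = bin_weights(spectrum, bins, flux)  # (B, E)
    trans = np.exp(-np.clip(a @ mu, -50.0, None))  # (R, E)
    lam = trans @ w.T  # (R, B)
    blank = w.sum(axis=1)
    return lam.reshape(first.shape + (bins.n_bins,)), blank


def sample_poisson(lam: np.ndarray, seed) -> np.ndarray:
    """Independent Poisson draws of the expected counts, reproducible by seed."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("expected counts must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(lam).astype(np.int64)


def simulate_acquisition(
    phantom: VoxelPhantom,
    spectrum: SourceSpectrum,
    bins: EnergyBinSet,
    geometry: Geometry,
    flux: float,
    seed=None,
    noise: bool = True,
    tables: dict | None = None,
) -> CountSinogram:
    """Full forward simulation of one axial SPCCT scan of ``phantom``.

    Projects every material present in the phantom (plus water), forms the
    expected per-bin counts and, when ``noise`` is set, Poisson-samples them.
    A noiseless acquisition stores the expected counts directly.
    """
    materials = ["water"] + [m for m, g in phantom.maps.items() if np.any(g > 0)]
    line_integrals = project_basis(phantom, geometry, materials)
    lam, blank = expected_counts(line_integrals, spectrum, bins, flux, tables)
    if noise:
        if seed is None:
            raise ValueError("a seed is required for a noisy acquisition")
        counts = sample_poisson(lam, seed)
    else:
        counts = lam
    return CountSinogram(counts, blank, bins, geometry)
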