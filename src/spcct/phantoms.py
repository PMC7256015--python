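"""Voxelized digital phantoms: calibration tubes, cell pellets, brain slice.

Phantoms are 2-D axial slices on an isotropic grid (250 µm default, the
scanner's reconstructed voxel pitch).  Each phantom carries per-material
concentration maps in mg/mL plus a water-equivalent density map in g/mL.
A slice is one voxel thick, so in-slice region areas map to volumes through
the (250 µm)³ = 1.5625e-2 µL voxel volume.

Regions are rasterized center-of-voxel (a voxel belongs to a region iff its
center falls inside).  Mass-carrying regions (pellet, cell cluster, scaffold)
are built to the exact requested mass: whole voxels at the nominal
concentration plus one partial-concentration rim voxel absorbing the
remainder, which keeps the mass-bookkeeping identity exact rather than
discretization-limited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .physics import molar_to_mass_concentration

__all__ = [
    "GeometryError",
    "VoxelPhantom",
    "PelletSpec",
    "build_tube",
    "build_calibration_series",
    "build_pellet",
    "build_brain_slice",
]

MATERIALS = ("gold", "iodine", "gadolinium", "calcium")

#: Gold load per labeled macrophage, pg (ICP-OES mean of the labeling assay).
DEFAULT_PER_CELL_LOAD_PG = 128.0
#: Packed volume per cell, pL: 1e6 cells occupy 2.8 µL.
DEFAULT_PACKING_PL_PER_CELL = 2.8


class GeometryError(ValueError):
    """A requested region does not fit the phantom or scan geometry."""


@dataclass
class VoxelPhantom:
    """Voxel grid of basis-material concentration maps.

    Parameters
    ----------
    water:
        Water-equivalent density, g/mL, in [0, 1.2].
    maps:
        Per-material concentration grids, mg/mL, keyed by material name.
    voxel_size_um:
        Isotropic voxel pitch in micrometres.
    """

    water: np.ndarray
    maps: dict = field(default_factory=dict)
    voxel_size_um: float = 250.0

    def __post_init__(self) -> None:
        self.water = np.asarray(self.water, dtype=float)
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be positive")
        if np.any(self.water < 0) or np.any(self.water > 1.2):
            raise ValueError("water density must lie in [0, 1.2] g/mL")
        for name, grid in self.maps.items():
            grid = np.asarray(grid, dtype=float)
            if grid.shape != self.water.shape:
                raise ValueError(f"map {name!r} does not match the grid shape")
            if np.any(grid < 0):
                raise ValueError(f"map {name!r} has negative concentrations")
            self.maps[name] = grid

    @property
    def shape(self) -> tuple:
        return self.water.shape

    @property
    def voxel_size_cm(self) -> float:
        return self.voxel_size_um * 1e-4

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_cm**3

    @property
    def voxel_volume_ul(self) -> float:
        return self.voxel_volume_ml * 1e3

    def get_map(self, material: str) -> np.ndarray:
        """Concentration map for ``material`` (zeros when absent)."""
        if material == "water":
            return self.water
        return self.maps.get(material, np.zeros_like(self.water))

    def material_mass_ug(self, material: str) -> float:
        """Total elemental mass in the slice, µg (mg/mL × mL × 1000)."""
        return float(self.get_map(material).sum() * self.voxel_volume_ml * 1e3)


def _centers_mm(n: int, voxel_size_um: float) -> np.ndarray:
    s = voxel_size_um * 1e-3
    return (np.arange(n) - (n - 1) / 2.0) * s


def _disk_mask(grid_n, voxel_size_um, center_mm, radius_mm) -> np.ndarray:
    y = _centers_mm(grid_n, voxel_size_um)[:, None] - center_mm[0]
    x = _centers_mm(grid_n, voxel_size_um)[None, :] - center_mm[1]
    return y * y + x * x <= radius_mm * radius_mm


def _ellipse_mask(grid_n, voxel_size_um, center_mm, semi_mm) -> np.ndarray:
    y = _centers_mm(grid_n, voxel_size_um)[:, None] - center_mm[0]
    x = _centers_mm(grid_n, voxel_size_um)[None, :] - center_mm[1]
    return (y / semi_mm[0]) ** 2 + (x / semi_mm[1]) ** 2 <= 1.0


def _fill_exact_mass(
    target: np.ndarray,
    allowed: np.ndarray,
    center_mm,
    concentration: float,
    volume_ul: float,
    voxel_size_um: float,
) -> None:
    """Deposit ``concentration`` over exactly ``volume_ul`` of voxels.

    Voxels inside ``allowed`` are taken nearest-the-center first; the last
    voxel receives a fractional concentration so the total mass is exact.
    """
    if volume_ul <= 0:
        return
    vvox = (voxel_size_um * 1e-4) ** 3 * 1e3  # µL
    n_needed = volume_ul / vvox
    idx = np.argwhere(allowed)
    if idx.shape[0] < n_needed:
        raise GeometryError("region volume exceeds the available space")
    cy = _centers_mm(target.shape[0], voxel_size_um)
    cx = _centers_mm(target.shape[1], voxel_size_um)
    d2 = (cy[idx[:, 0]] - center_mm[0]) ** 2 + (cx[idx[:, 1]] - center_mm[1]) ** 2
    order = np.lexsort((idx[:, 1], idx[:, 0], d2))
    n_full = int(np.floor(n_needed))
    frac = n_needed - n_full
    sel = idx[order[:n_full]]
    target[sel[:, 0], sel[:, 1]] += concentration
    if frac > 1e-12:
        i, j = idx[order[n_full]]
        target[i, j] += concentration * frac


def build_tube(
    concentration_mg_ml: float,
    material: str,
    tube_diameter_mm: float = 8.0,
    grid_n: int = 64,
    voxel_size_um: float = 250.0,
) -> VoxelPhantom:
    """A single agarose-filled tube holding one material in suspension.

    The tube interior is water-equivalent (1.0 g/mL, agarose gel) with the
    material at ``concentration_mg_ml``; the exterior is air.
    """
    fov_mm = grid_n * voxel_size_um * 1e-3
    if tube_diameter_mm > fov_mm:
        raise GeometryError("tube does not fit inside the grid")
    interior = _disk_mask(grid_n, voxel_size_um, (0.0, 0.0), tube_diameter_mm / 2.0)
    water = np.where(interior, 1.0, 0.0)
    conc = np.where(interior, float(concentration_mg_ml), 0.0)
    return VoxelPhantom(water, {material: conc}, voxel_size_um)


def build_calibration_series(
    concentrations_mm,
    element: str,
    tube_diameter_mm: float = 8.0,
    grid_n: int = 64,
    voxel_size_um: float = 250.0,
) -> list:
    """Tube phantoms at the printed molar series for one element.

    One phantom per molar concentration; interior voxels carry the converted
    mg/mL value (e.g. 40 mM gold → 7.879 mg/mL).
    """
    out = []
    for mm in concentrations_mm:
        c = molar_to_mass_concentration(float(mm), element)
        out.append(build_tube(c, element, tube_diameter_mm, grid_n, voxel_size_um))
    return out


@dataclass(frozen=True)
class PelletSpec:
    """A spun-down pellet of labeled cells at the bottom of a tube."""

    cell_count: float
    per_cell_load_pg: float = DEFAULT_PER_CELL_LOAD_PG
    packing_volume_pl: float = DEFAULT_PACKING_PL_PER_CELL

    def __post_init__(self) -> None:
        if self.cell_count < 0:
            raise ValueError("cell count must be nonnegative")
        if self.per_cell_load_pg <= 0 or self.packing_volume_pl <= 0:
            raise ValueError("per-cell load and packing volume must be positive")

    @property
    def volume_ul(self) -> float:
        return self.cell_count * self.packing_volume_pl * 1e-6

    @property
    def concentration_mg_ml(self) -> float:
        # pg/pL ≡ mg/mL
        return self.per_cell_load_pg / self.packing_volume_pl

    @property
    def gold_mass_ug(self) -> float:
        return self.cell_count * self.per_cell_load_pg * 1e-6


def build_pellet(
    spec: PelletSpec,
    tube_diameter_mm: float = 8.0,
    grid_n: int = 64,
    voxel_size_um: float = 250.0,
) -> VoxelPhantom:
    """Tube phantom with a centered cell pellet of exact total gold mass."""
    phantom = build_tube(0.0, "gold", tube_diameter_mm, grid_n, voxel_size_um)
    interior = phantom.water > 0
    tube_volume_ul = interior.sum() * phantom.voxel_volume_ul
    if spec.volume_ul > tube_volume_ul:
        raise GeometryError("pellet volume exceeds the tube volume")
    gold = phantom.maps["gold"]
    _fill_exact_mass(
        gold, interior, (0.0, 0.0), spec.concentration_mg_ml, spec.volume_ul, voxel_size_um
    )
    return phantom


def build_brain_slice(
    cell_gold_mass_ug: float = 64.0,
    cell_volume_ul: float = 1.4,
    scaffold_iodine_mass_ug: float = 50.0,
    scaffold_volume_ul: float = 4.9,
    skull: bool = True,
    grid_n: int = 256,
    voxel_size_um: float = 250.0,
    head_semi_axes_mm: tuple = (11.0, 9.0),
    skull_calcium_mg_ml: float = 150.0,
) -> VoxelPhantom:
    """Axial rat-head slice: lesion cavity, labeled cells, labeled scaffold.

    The head is an ellipse of brain-equivalent tissue (1.04 g/mL) with an
    optional two-voxel calcium annulus standing in for the skull.  The lesion
    cavity (1.0 g/mL fluid) sits in the right striatum; the iodine-labeled
    scaffold occupies ``scaffold_volume_ul`` inside the cavity and the gold
    cell cluster of ``cell_volume_ul`` sits within/overlapping the scaffold.
    Monocolor configurations pass zero scaffold mass and volume.
    """
    for mass, vol, what in (
        (cell_gold_mass_ug, cell_volume_ul, "cell cluster"),
        (scaffold_iodine_mass_ug, scaffold_volume_ul, "scaffold"),
    ):
        if mass < 0 or vol < 0:
            raise ValueError(f"{what}: mass and volume must be nonnegative")
        if mass > 0 and vol == 0:
            raise ValueError(f"{what}: positive mass requires positive volume")

    fov_mm = grid_n * voxel_size_um * 1e-3
    if 2 * max(head_semi_axes_mm) > fov_mm:
        raise GeometryError("head ellipse does not fit inside the grid")

    head = _ellipse_mask(grid_n, voxel_size_um, (0.0, 0.0), head_semi_axes_mm)
    water = np.where(head, 1.04, 0.0)

    gold = np.zeros((grid_n, grid_n))
    iodine = np.zeros((grid_n, grid_n))
    calcium = np.zeros((grid_n, grid_n))

    if skull:
        t = 2 * voxel_size_um * 1e-3  # two-voxel annulus
        inner = _ellipse_mask(
            grid_n,
            voxel_size_um,
            (0.0, 0.0),
            (head_semi_axes_mm[0] - t, head_semi_axes_mm[1] - t),
        )
        calcium[head & ~inner] = skull_calcium_mg_ml
        water[head & ~inner] = 1.0

    # lesion cavity in the right hemisphere
    lesion_center = (-1.5, 2.5)
    lesion_radius = 3.0
    lesion = _disk_mask(grid_n, voxel_size_um, lesion_center, lesion_radius)
    water[lesion & head] = 1.0

    injectable = lesion & head
    capacity_ul = injectable.sum() * (voxel_size_um * 1e-4) ** 3 * 1e3
    if cell_volume_ul + scaffold_volume_ul > 0 and max(cell_volume_ul, scaffold_volume_ul) > capacity_ul:
        raise GeometryError("injected volume exceeds the lesion cavity")

    if scaffold_volume_ul > 0:
        _fill_exact_mass(
            iodine,
            injectable,
            lesion_center,
            scaffold_iodine_mass_ug / scaffold_volume_ul,
            scaffold_volume_ul,
            voxel_size_um,
        )
    if cell_volume_ul > 0:
        # cells sit inside / overlapping the scaffold, slightly off its center
        cell_center = (lesion_center[0] + 0.5, lesion_center[1] + 0.5)
        _fill_exact_mass(
            gold,
            injectable,
            cell_center,
            cell_gold_mass_ug / cell_volume_ul,
            cell_volume_ul,
            voxel_size_um,
        )

    maps = {"gold": gold, "iodine": iodine, "calcium": calcium}
    return VoxelPhantom(water, maps, voxel_size_um)
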