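"""Energy-dependent X-ray attenuation physics.

This module carries the spectral building blocks of the simulation: mass
attenuation tables with K-edge discontinuities for the contrast and tissue
materials, a polychromatic bremsstrahlung source spectrum, the photon-counting
detector's energy-bin partition, and the molar/mass concentration conversions
used when going from nanoparticle suspensions (mM of element) to the mg/mL
scale of material images.

Attenuation data are embedded as plain-text two-column tables (keV,
cm²/g) transcribed from NIST XCOM.  Interpolation is log-log linear and never
crosses a K edge: the edge energy appears twice in a table, once with the
below-edge limit and once with the above-edge limit, and a query exactly at
the edge resolves to the above-edge (right-continuous) value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "ATOMIC_MASS_G_PER_MOL",
    "K_EDGE_KEV",
    "EnergyGrid",
    "AttenuationTable",
    "SourceSpectrum",
    "EnergyBinSet",
    "load_attenuation_table",
    "mass_attenuation_at",
    "build_source_spectrum",
    "load_spectrum_file",
    "molar_to_mass_concentration",
    "mass_to_molar_concentration",
]

#: Standard atomic masses of the contrast elements, g/mol.
ATOMIC_MASS_G_PER_MOL = {
    "gold": 196.967,
    "iodine": 126.904,
    "gadolinium": 157.25,
    "calcium": 40.078,
}

#: K-shell binding energies, keV.  Water and calcium have no edge in the
#: diagnostic band (the Ca K edge at 4.04 keV lies below the tube spectrum).
K_EDGE_KEV = {
    "gold": 80.7249,
    "iodine": 33.1694,
    "gadolinium": 50.2391,
}

ALUMINUM_DENSITY_G_PER_CM3 = 2.699


@dataclass(frozen=True)
class EnergyGrid:
    """Discrete photon-energy axis (keV) for spectral integrals.

    The grid must be strictly increasing, start no lower than 10 keV, span at
    least [20, 120] keV and carry at least 200 samples so that narrow energy
    bins are resolved.
    """

    energies: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "energies", e)
        if e.ndim != 1 or e.size < 200:
            raise ValueError("energy grid needs >= 200 samples")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if e[0] < 10.0:
            raise ValueError("grid must not extend below 10 keV")
        if e[0] > 20.0 or e[-1] < 120.0:
            raise ValueError("grid must cover at least [20, 120] keV")

    @classmethod
    def default(cls, lo: float = 20.0, hi: float = 120.0, step: float = 0.5) -> "EnergyGrid":
        n = int(round((hi - lo) / step)) + 1
        return cls(np.linspace(lo, hi, n))

    @property
    def step(self) -> float:
        return float(self.energies[1] - self.energies[0])


@dataclass(frozen=True)
class AttenuationTable:
    """Tabulated mass attenuation μ/ρ(E) for one material.

    ``energies`` may contain one duplicated abscissa marking a K edge; the
    first of the pair holds the below-edge limit, the second the above-edge
    limit.
    """

    material: str
    energies: np.ndarray
    mu_over_rho: np.ndarray
    kedge_energy: float | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        v = np.asarray(self.mu_over_rho, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_over_rho", v)
        if e.shape != v.shape or e.ndim != 1 or e.size < 2:
            raise ValueError("energies and mu_over_rho must be matching 1-D arrays")
        if np.any(np.diff(e) < 0):
            raise ValueError("energies must be non-decreasing")
        if np.any(v <= 0):
            raise ValueError("mu_over_rho must be positive")

    def __call__(self, energy) -> np.ndarray | float:
        return mass_attenuation_at(self, energy)


def _parse_two_column(text: str) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        a, b = line.split()[:2]
        xs.append(float(a))
        ys.append(float(b))
    return np.asarray(xs), np.asarray(ys)


@lru_cache(maxsize=None)
def load_attenuation_table(material: str) -> AttenuationTable:
    """Load the packaged attenuation table for ``material``.

    Known materials: water, gold, iodine, gadolinium, calcium, aluminum.
    """
    name = material.lower()
    try:
        text = resources.files("spcct.data").joinpath(f"{name}.txt").read_text()
    except FileNotFoundError as exc:
        raise ValueError(f"no attenuation table for material {material!r}") from exc
    e, v = _parse_two_column(text)
    kedge = K_EDGE_KEV.get(name)
    return AttenuationTable(name, e, v, kedge)


def load_attenuation_file(path, material: str, kedge_energy: float | None = None) -> AttenuationTable:
    """Read a user-supplied two-column (keV, cm²/g) attenuation table."""
    with open(path) as fh:
        e, v = _parse_two_column(fh.read())
    return AttenuationTable(material, e, v, kedge_energy)


def mass_attenuation_at(table: AttenuationTable, energy) -> np.ndarray | float:
    """Log-log interpolate μ/ρ at ``energy`` (keV), preserving K edges.

    A query exactly at the edge energy returns the above-edge value
    (right-continuous convention).  Energies outside the tabulated range
    raise ``ValueError``.
    """
    e = np.asarray(energy, dtype=float)
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    E, V = table.energies, table.mu_over_rho
    if np.any(e < E[0]) or np.any(e > E[-1]):
        raise ValueError(
            f"energy outside [{E[0]}, {E[-1]}] keV for material {table.material!r}"
        )
    # side='right' lands the query after a duplicated edge abscissa, which is
    # what makes the edge right-continuous.
    idx = np.clip(np.searchsorted(E, e, side="right"), 1, E.size - 1)
    e0, e1 = E[idx - 1], E[idx]
    v0, v1 = V[idx - 1], V[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(e1 > e0, np.log(e / np.where(e0 > 0, e0, 1.0)) / np.log(e1 / e0), 1.0)
    t = np.clip(t, 0.0, 1.0)
    out = np.exp((1.0 - t) * np.log(v0) + t * np.log(v1))
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class SourceSpectrum:
    """Polychromatic tube output S(E): photons per keV per detector element.

    The absolute scale is arbitrary; the forward model normalizes the
    spectrum to a configured blank fluence.
    """

    grid: EnergyGrid
    fluence: np.ndarray
    kvp: float

    def __post_init__(self) -> None:
        f = np.asarray(self.fluence, dtype=float)
        object.__setattr__(self, "fluence", f)
        if f.shape != self.grid.energies.shape:
            raise ValueError("fluence must match the energy grid")
        if np.any(f < 0):
            raise ValueError("fluence must be nonnegative")
        if not np.any(f > 0):
            raise ValueError("spectrum carries no photons")
        if np.any(f[self.grid.energies > self.kvp] > 0):
            raise ValueError("fluence must vanish above the tube voltage")

    @property
    def mean_energy(self) -> float:
        e = self.grid.energies
        return float(np.sum(e * self.fluence) / np.sum(self.fluence))


def build_source_spectrum(
    kvp: float = 120.0,
    filtration_mm_al: float = 2.5,
    grid: EnergyGrid | None = None,
) -> SourceSpectrum:
    """Bremsstrahlung spectrum by Kramers' law with aluminum filtration.

    The unfiltered photon fluence is proportional to (kVp − E) up to the tube
    voltage; an aluminum filter of ``filtration_mm_al`` millimetres hardens
    the beam.  Characteristic tungsten lines are not modeled.  The scanner
    supports 80, 100 and 120 kVp.
    """
    if kvp not in (80.0, 100.0, 120.0, 80, 100, 120):
        raise ValueError("tube voltage must be 80, 100 or 120 kVp")
    if filtration_mm_al < 0:
        raise ValueError("filtration thickness must be nonnegative")
    grid = grid or EnergyGrid.default(hi=max(120.0, float(kvp)))
    e = grid.energies
    fluence = np.clip(kvp - e, 0.0, None)
    if filtration_mm_al > 0:
        al = load_attenuation_table("aluminum")
        mu = mass_attenuation_at(al, e) * ALUMINUM_DENSITY_G_PER_CM3  # 1/cm
        fluence = fluence * np.exp(-mu * filtration_mm_al / 10.0)
    return SourceSpectrum(grid, fluence, float(kvp))


def load_spectrum_file(path, kvp: float, grid: EnergyGrid | None = None) -> SourceSpectrum:
    """Load a tabulated spectrum from a two-column (keV, fluence) text file.

    Values are linearly interpolated onto ``grid`` (default grid when omitted)
    and clipped to zero above ``kvp``.
    """
    with open(path) as fh:
        e, f = _parse_two_column(fh.read())
    grid = grid or EnergyGrid.default(hi=max(120.0, float(kvp)))
    fl = np.interp(grid.energies, e, f, left=0.0, right=0.0)
    fl[grid.energies > kvp] = 0.0
    return SourceSpectrum(grid, fl, float(kvp))


@dataclass(frozen=True)
class EnergyBinSet:
    """Detector energy thresholds partitioning [t₁, kVp] into counting bins.

    Bins are contiguous half-open intervals [tᵢ, tᵢ₊₁), the last bin closed
    at ``upper_bound``.  The detector response is an ideal indicator per bin.
    """

    thresholds: tuple = (30.0, 53.0, 78.0, 83.0, 98.0)
    upper_bound: float = 120.0

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        object.__setattr__(self, "thresholds", t)
        if len(t) < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly ascending")
        if self.upper_bound <= t[-1]:
            raise ValueError("upper bound must exceed the last threshold")

    @property
    def n_bins(self) -> int:
        return len(self.thresholds)

    @property
    def edges(self) -> np.ndarray:
        return np.asarray(self.thresholds + (self.upper_bound,))

    def bin_response(self, energies) -> np.ndarray:
        """Indicator response R_b(E), shape (n_bins, n_energies)."""
        e = np.atleast_1d(np.asarray(energies, dtype=float))
        lo = self.edges[:-1][:, None]
        hi = self.edges[1:][:, None]
        resp = (e[None, :] >= lo) & (e[None, :] < hi)
        # the last bin is closed at the upper bound
        resp[-1] |= e[None, :][0] == self.upper_bound
        return resp.astype(float)


def molar_to_mass_concentration(molar_mm: float, element: str):
    """Convert an elemental molar concentration (mM) to mg/mL.

    mg/mL = mM × (atomic mass g/mol) / 1000.  The printed calibration series
    (up to 40 mM gold, 60 mM iodine) maps onto a common 0–8 mg/mL range.
    """
    molar = np.asarray(molar_mm, dtype=float)
    if np.any(molar < 0):
        raise ValueError("molar concentration must be nonnegative")
    try:
        mass = ATOMIC_MASS_G_PER_MOL[element.lower()]
    except KeyError as exc:
        raise ValueError(f"unknown element {element!r}") from exc
    out = molar * mass / 1000.0
    return float(out) if out.ndim == 0 else out


def mass_to_molar_concentration(mg_per_ml: float, element: str):
    """Inverse of :func:`molar_to_mass_concentration` (mg/mL → mM)."""
    c = np.asarray(mg_per_ml, dtype=float)
    if np.any(c < 0):
        raise ValueError("mass concentration must be nonnegative")
    try:
        mass = ATOMIC_MASS_G_PER_MOL[element.lower()]
    except KeyError as exc:
        raise ValueError(f"unknown element {element!r}") from exc
    out = c * 1000.0 / mass
    return float(out) if out.ndim == 0 else out
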