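"""End-to-end experiment orchestration.

An :class:`ExperimentConfig` bundles every stage parameter (phantom series,
acquisition, decomposition, reconstruction, quantification) into one
serializable object; :func:`run_experiment` executes the chain phantom →
acquire → decompose → reconstruct → quantify deterministically and writes a
self-describing artifact directory (sinograms/, images/, tables/,
report.json).

:func:`builtin_experiments` packages the study's named experiments: the
molar calibration series, the cell-pellet dilution series, the monocolor and
bicolor brain slices, and the single-voxel detection-limit study.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as cfg
from . import io
from .cohort import StudyDesign, cohort_table, generate_cohort
from .decompose import DEFAULT_BASIS, decompose_sinogram
from .forward import Geometry, simulate_acquisition
from .phantoms import (
    DEFAULT_PER_CELL_LOAD_PG,
    PelletSpec,
    build_brain_slice,
    build_calibration_series,
    build_pellet,
)
from .physics import EnergyBinSet, build_source_spectrum
from .quantify import (
    background_annulus,
    detection_limit,
    measure_background_sd,
    roi_mass,
    segment_roi,
)
from .recon import reconstruct_conventional, reconstruct_materials

__all__ = [
    "ExperimentConfig",
    "builtin_experiments",
    "BUILTIN_NAMES",
    "run_experiment",
    "run_pellet_series",
]

#: Printed molar calibration series (mM): 13 tubes in total.
GOLD_CALIBRATION_MM = (0, 10, 15, 20, 30, 40)
IODINE_CALIBRATION_MM = (0, 10, 15, 20, 30, 40, 60)
#: Printed pellet series (cells per pellet).
PELLET_CELL_COUNTS = (1e6, 0.5e6, 0.25e6, 0.125e6, 0)

BUILTIN_NAMES = ("calibration", "pellets", "monocolor", "bicolor", "detection_limit")


@dataclass
class ExperimentConfig:
    """Complete, serializable description of one experiment run."""

    name: str
    phantom: dict
    seed: int | None = 0
    noise: bool = True
    acquisition: dict = field(default_factory=dict)
    decomposition: dict = field(default_factory=dict)
    reconstruction: dict = field(default_factory=dict)
    quantification: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.acquisition = {
            "kvp": cfg.DEFAULT_KVP,
            "filtration_mm_al": cfg.DEFAULT_FILTRATION_MM_AL,
            "thresholds_kev": list(cfg.DEFAULT_THRESHOLDS_KEV),
            "flux": cfg.DEFAULT_FLUX,
            "n_views": cfg.DEFAULT_N_VIEWS,
            "grid_n": cfg.DEFAULT_GRID_N,
            "voxel_um": cfg.DEFAULT_VOXEL_UM,
            **self.acquisition,
        }
        self.decomposition = {"basis": list(DEFAULT_BASIS), "mode": "physics", **self.decomposition}
        self.reconstruction = {"filter": "ramp", **self.reconstruction}
        self.quantification = {
            "n_sigma": 2.0,
            "k": 4.0,
            "per_cell_load_pg": DEFAULT_PER_CELL_LOAD_PG,
            "bg_r_in_mm": 2.2,
            "bg_r_out_mm": 3.6,
            **self.quantification,
        }
        self.validate()

    def validate(self) -> None:
        if self.noise and self.seed is None:
            raise ValueError("config field 'seed' is required for a noisy acquisition")
        if "kind" not in self.phantom:
            raise ValueError("config field 'phantom.kind' is missing")
        if self.decomposition["mode"] not in ("physics", "calibrated"):
            raise ValueError("config field 'decomposition.mode' must be physics|calibrated")
        if self.reconstruction["filter"] not in ("ramp", "hann"):
            raise ValueError("config field 'reconstruction.filter' must be ramp|hann")
        for key in ("flux", "n_views", "grid_n", "voxel_um"):
            if self.acquisition[key] <= 0:
                raise ValueError(f"config field 'acquisition.{key}' must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    # -- stage objects -----------------------------------------------------
    def spectrum(self):
        return build_source_spectrum(
            self.acquisition["kvp"], self.acquisition["filtration_mm_al"]
        )

    def bins(self):
        return EnergyBinSet(tuple(self.acquisition["thresholds_kev"]), self.acquisition["kvp"])

    def geometry(self):
        return Geometry(
            n_views=int(self.acquisition["n_views"]),
            n_detectors=int(self.acquisition["grid_n"]),
        )


def builtin_experiments(name: str) -> ExperimentConfig:
    """Packaged configs reproducing the study's named experiments."""
    if name == "calibration":
        phantom = {
            "kind": "calibration",
            "series": [
                {"element": "gold", "concentrations_mM": list(GOLD_CALIBRATION_MM)},
                {"element": "iodine", "concentrations_mM": list(IODINE_CALIBRATION_MM)},
            ],
            "tube_diameter_mm": cfg.DEFAULT_WATER_DISK_MM,
        }
        return ExperimentConfig(name, phantom)
    if name == "pellets":
        phantom = {
            "kind": "pellets",
            "cell_counts": list(PELLET_CELL_COUNTS),
            "tube_diameter_mm": cfg.DEFAULT_WATER_DISK_MM,
        }
        return ExperimentConfig(name, phantom)
    if name == "monocolor":
        phantom = {
            "kind": "brain",
            "cell_gold_mass_ug": 48.0,
            "cell_volume_ul": 1.4,
            "scaffold_iodine_mass_ug": 0.0,
            "scaffold_volume_ul": 0.0,
            "skull": True,
        }
        return ExperimentConfig(
            name, phantom, acquisition={"grid_n": 128, "n_views": 192}
        )
    if name == "bicolor":
        phantom = {
            "kind": "brain",
            "cell_gold_mass_ug": 48.0,
            "cell_volume_ul": 1.4,
            "scaffold_iodine_mass_ug": 50.0,
            "scaffold_volume_ul": 4.9,
            "skull": True,
        }
        return ExperimentConfig(
            name, phantom, acquisition={"grid_n": 128, "n_views": 192}
        )
    if name == "detection_limit":
        return ExperimentConfig(name, {"kind": "detection_limit"})
    raise ValueError(f"unknown experiment {name!r}; valid names: {', '.join(BUILTIN_NAMES)}")


def _phantom_series(config: ExperimentConfig):
    """Materialize the configured phantom(s) as (label, phantom, truth) rows."""
    p = config.phantom
    grid_n = int(config.acquisition["grid_n"])
    voxel = config.acquisition["voxel_um"]
    kind = p["kind"]
    out = []
    if kind == "calibration":
        for series in p["series"]:
            phs = build_calibration_series(
                series["concentrations_mM"],
                series["element"],
                p.get("tube_diameter_mm", 8.0),
                grid_n,
                voxel,
            )
            for mm, ph in zip(series["concentrations_mM"], phs):
                out.append((f"{series['element']}_{mm}mM", ph, {"molar_mM": mm}))
    elif kind == "pellets":
        for n in p["cell_counts"]:
            spec = PelletSpec(n, config.quantification["per_cell_load_pg"])
            ph = build_pellet(spec, p.get("tube_diameter_mm", 8.0), grid_n, voxel)
            out.append(
                (
                    f"pellet_{int(n)}",
                    ph,
                    {"cells": n, "true_gold_ug": spec.gold_mass_ug},
                )
            )
    elif kind == "brain":
        ph = build_brain_slice(
            cell_gold_mass_ug=p["cell_gold_mass_ug"],
            cell_volume_ul=p["cell_volume_ul"],
            scaffold_iodine_mass_ug=p["scaffold_iodine_mass_ug"],
            scaffold_volume_ul=p["scaffold_volume_ul"],
            skull=p.get("skull", True),
            grid_n=grid_n,
            voxel_size_um=voxel,
        )
        out.append(("brain", ph, {"true_gold_ug": p["cell_gold_mass_ug"]}))
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return out


def run_experiment(config: ExperimentConfig, outdir) -> Path:
    """Execute the configured chain and write a deterministic artifact tree."""
    config.validate()
    outdir = Path(outdir)
    for sub in ("sinograms", "images", "tables"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    report = {
        "name": config.name,
        "config": config.to_dict(),
        "config_hash": io.config_hash(config.to_dict()),
        "seed": config.seed,
        "versions": _versions(),
    }

    if config.phantom["kind"] == "detection_limit":
        res = detection_limit(
            per_cell_load_pg=config.quantification["per_cell_load_pg"],
            k=config.quantification["k"],
            seed=config.seed or 0,
            flux=config.acquisition["flux"],
            grid_n=int(config.acquisition["grid_n"]),
            n_views=int(config.acquisition["n_views"]),
            voxel_size_um=config.acquisition["voxel_um"],
        )
        rows = [{"cells": n, "detection_rate": r} for n, r in res.detection_rates.items()]
        pd.DataFrame(rows).to_csv(outdir / "tables" / "detection_rates.csv", index=False)
        report["detection_limit"] = {
            "sigma_bg_mg_ml": res.sigma_bg_mg_ml,
            "empirical_cells": res.min_cells_per_voxel,
            "analytic_cells": res.analytic_cells_per_voxel,
            "converged": res.converged,
        }
        io.write_json(report, outdir / "report.json")
        return outdir

    spectrum, bins, geometry = config.spectrum(), config.bins(), config.geometry()
    basis = tuple(config.decomposition["basis"])
    voxel = config.acquisition["voxel_um"]
    grid_n = int(config.acquisition["grid_n"])
    bg = background_annulus(
        grid_n,
        voxel,
        config.quantification["bg_r_in_mm"],
        config.quantification["bg_r_out_mm"],
    )
    rows = []
    for i, (label, phantom, truth) in enumerate(_phantom_series(config)):
        sino = simulate_acquisition(
            phantom,
            spectrum,
            bins,
            geometry,
            config.acquisition["flux"],
            seed=np.random.default_rng(np.random.SeedSequence((config.seed or 0, i))),
            noise=config.noise,
        )
        msino = decompose_sinogram(sino, spectrum, basis=basis, mode=config.decomposition["mode"])
        images = reconstruct_materials(msino, geometry, voxel, config.reconstruction["filter"])
        conventional = reconstruct_conventional(sino, spectrum, voxel, config.reconstruction["filter"])

        io.save_tiff(np.transpose(sino.counts, (2, 0, 1)), outdir / "sinograms" / f"{label}_counts.tif")
        for m, img in images.items():
            io.save_nifti(img, voxel, outdir / "images" / f"{label}_{m}.nii.gz")
            io.save_tiff(img, outdir / "images" / f"{label}_{m}.tif", voxel)
        io.save_nifti(conventional, voxel, outdir / "images" / f"{label}_conventional.nii.gz")

        gold_img = images.get("gold")
        row = {"label": label, **truth}
        if gold_img is not None:
            sigma = measure_background_sd(gold_img, bg)
            roi = segment_roi(gold_img, sigma_bg=sigma, n_sigma=config.quantification["n_sigma"])
            q = roi_mass(gold_img, roi, voxel, config.quantification["per_cell_load_pg"])
            row.update(
                sigma_bg_mg_ml=sigma,
                roi_voxels=q.roi_voxels,
                roi_volume_ul=q.roi_volume_ul,
                est_gold_ug=q.mass_ug,
                est_cells=q.est_cells,
            )
        rows.append(row)

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "tables" / "quantification.csv", index=False)
    report["n_phantoms"] = len(rows)
    io.write_json(report, outdir / "report.json")
    return outdir


def run_pellet_series(
    seed: int = 0,
    cell_counts=PELLET_CELL_COUNTS,
    noise: bool = True,
    flux: float | None = None,
) -> pd.DataFrame:
    """Acquire → decompose → reconstruct → quantify the printed pellet series.

    Returns one row per pellet with the true and image-estimated gold mass;
    the regression of estimated on true mass is the in-vitro linearity check.
    """
    config = builtin_experiments("pellets")
    config.seed = seed
    config.noise = noise
    if flux is not None:
        config.acquisition["flux"] = flux
    config.phantom["cell_counts"] = list(cell_counts)

    spectrum, bins, geometry = config.spectrum(), config.bins(), config.geometry()
    voxel = config.acquisition["voxel_um"]
    grid_n = int(config.acquisition["grid_n"])
    bg = background_annulus(grid_n, voxel, 2.2, 3.6)
    rows = []
    for i, (label, phantom, truth) in enumerate(_phantom_series(config)):
        sino = simulate_acquisition(
            phantom,
            spectrum,
            bins,
            geometry,
            config.acquisition["flux"],
            seed=np.random.default_rng(np.random.SeedSequence((seed, i))),
            noise=noise,
        )
        msino = decompose_sinogram(sino, spectrum)
        gold_img = reconstruct_materials(msino, geometry, voxel)["gold"]
        sigma = measure_background_sd(gold_img, bg)
        roi = segment_roi(gold_img, sigma_bg=sigma)
        q = roi_mass(gold_img, roi, voxel)
        rows.append({**truth, "label": label, "est_gold_ug": q.mass_ug, "est_cells": q.est_cells})
    return pd.DataFrame(rows)


def run_cohort(design_name: str = "monocolor", n: int = 12, seed: int = 0) -> pd.DataFrame:
    """Generate a synthetic cohort table for a named design."""
    if design_name == "monocolor":
        design = StudyDesign.monocolor(n)
    elif design_name == "bicolor":
        design = StudyDesign.bicolor(max(1, n // 3))
    else:
        raise ValueError("design must be monocolor or bicolor")
    return cohort_table(generate_cohort(design, seed))


def _versions() -> dict:
    import numpy
    import scipy
    import skimage

    from . import __version__

    return {
        "spcct": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
    }
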