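"""Synthetic dual-scanner neck-lesion phantoms.

Generates a ground-truth activity map of spherical lesions on a uniform
background and simulates its observation by virtual PET scanners that differ
in voxel grid, reconstructed resolution, prompt-gamma-coincidence (PGC)
recovery and noise level.  The forward model per scanner is

    observed = pgc_factor * resample(blur(truth, fwhm), scanner grid) + noise

with isotropic Gaussian blur of the scanner's reconstructed resolution
(applied on the fine truth grid, edge-replicated borders), trilinear resampling
onto the scanner grid, and zero-mean Gaussian noise whose per-voxel SD is
``noise_coeff * sqrt(max(value, 0))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import ActivityVolume, Grid, save_volume
from .harmonize import gaussian_smooth, resample_to_grid

__all__ = [
    "LesionSpec",
    "ScannerModel",
    "build_ground_truth",
    "simulate_scan",
    "write_phantom_bundle",
    "sample_lesions",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "id",
    "center_x_mm",
    "center_y_mm",
    "center_z_mm",
    "diameter_mm",
    "ac_kbq_ml",
    "trachea_distance_mm",
]


@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion: center (mm), diameter (mm), activity concentration
    (kBq/mL) and distance to the trachea surface (mm)."""

    id: str
    center: tuple[float, float, float]
    diameter: float
    ac: float
    trachea_distance: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"lesion {self.id}: diameter must be > 0")
        if self.ac < 0:
            raise ValueError(f"lesion {self.id}: activity concentration must be >= 0")
        if self.trachea_distance < 0:
            raise ValueError(f"lesion {self.id}: trachea distance must be >= 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class ScannerModel:
    """A virtual scanner's imaging characteristics.

    Parameters
    ----------
    name : str
        Label used in manifests and reports.
    grid_spacing : tuple of float
        Reconstructed voxel size in mm.
    resolution_fwhm : float
        Isotropic reconstructed PET resolution (FWHM, mm).
    pgc_factor : float
        Fraction of the true activity concentration that is imaged; 124-I
        prompt-gamma coincidences bias imaged AC downward, e.g. 0.8 means a
        20% underestimation.  Must lie in (0, 1].
    noise_coeff : float
        Coefficient of the sqrt-intensity Gaussian noise model (>= 0); larger
        values emulate shorter emission times.
    emission_time : float
        Emission time per bed in minutes (metadata only).
    """

    name: str
    grid_spacing: tuple[float, float, float]
    resolution_fwhm: float
    pgc_factor: float
    noise_coeff: float = 0.0
    emission_time: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.pgc_factor <= 1.0):
            raise ValueError(f"pgc_factor must be in (0, 1], got {self.pgc_factor}")
        if self.resolution_fwhm < 0:
            raise ValueError("resolution_fwhm must be >= 0")
        if self.noise_coeff < 0:
            raise ValueError("noise_coeff must be >= 0")
        object.__setattr__(
            self, "grid_spacing", tuple(float(s) for s in self.grid_spacing)
        )


def build_ground_truth(
    lesions: list[LesionSpec], background_ac: float, grid: Grid
) -> ActivityVolume:
    """Paint spherical lesions onto a uniform background.

    Voxel membership is voxel-center-in-sphere: every voxel whose center lies
    within a lesion's radius carries that lesion's AC, all others the
    background AC.  Lesions must not overlap and must lie inside the grid
    extent.
    """
    if background_ac < 0:
        raise ValueError("background_ac must be >= 0")
    for i, a in enumerate(lesions):
        for b in lesions[i + 1 :]:
            gap = np.linalg.norm(np.subtract(a.center, b.center))
            if gap < a.radius + b.radius:
                raise ValueError(f"lesions {a.id!r} and {b.id!r} overlap")
    ext = grid.extent
    for les in lesions:
        for a in range(3):
            if les.center[a] - les.radius < ext[a][0] or les.center[a] + les.radius > ext[a][1]:
                raise ValueError(f"lesion {les.id!r} extends outside the grid")

    values = np.full(grid.shape, float(background_ac))
    ax = grid.axis_coordinates()
    for les in lesions:
        # restrict to the lesion's bounding box before the distance test
        lo = [int(np.ceil((les.center[a] - les.radius - grid.origin[a]) / grid.spacing[a])) for a in range(3)]
        hi = [int(np.floor((les.center[a] + les.radius - grid.origin[a]) / grid.spacing[a])) for a in range(3)]
        lo = [max(v, 0) for v in lo]
        hi = [min(h, s - 1) for h, s in zip(hi, grid.shape)]
        xs = ax[0][lo[0] : hi[0] + 1] - les.center[0]
        ys = ax[1][lo[1] : hi[1] + 1] - les.center[1]
        zs = ax[2][lo[2] : hi[2] + 1] - les.center[2]
        d2 = (
            xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
        )
        inside = d2 <= les.radius**2
        block = values[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        block[inside] = les.ac
    return ActivityVolume(grid, values, {"kind": "ground_truth"})


def _scanner_grid_for(truth_grid: Grid, scanner: ScannerModel) -> Grid:
    """Scanner grid covering the truth extent, sharing the truth origin."""
    shape = tuple(
        max(1, int(np.floor((truth_grid.extent[a][1] - truth_grid.origin[a]) / scanner.grid_spacing[a])) + 1)
        for a in range(3)
    )
    return Grid(shape, scanner.grid_spacing, truth_grid.origin)


def simulate_scan(
    truth: ActivityVolume,
    scanner: ScannerModel,
    seed: int,
    scanner_grid: Grid | None = None,
) -> ActivityVolume:
    """Forward-simulate one scanner's observation of a ground-truth map.

    Deterministic for a fixed seed.  The truth grid must be at least as fine
    as the scanner grid on every axis.
    """
    if scanner_grid is None:
        scanner_grid = _scanner_grid_for(truth.grid, scanner)
    for a in range(3):
        if truth.grid.spacing[a] > scanner_grid.spacing[a] + 1e-9:
            raise ValueError(
                "truth grid must be at least as fine as the scanner grid "
                f"(axis {a}: {truth.grid.spacing[a]} > {scanner_grid.spacing[a]} mm)"
            )
    blurred = gaussian_smooth(truth, scanner.resolution_fwhm)
    native = resample_to_grid(blurred, scanner_grid)
    values = native.values * scanner.pgc_factor
    if scanner.noise_coeff > 0:
        rng = np.random.default_rng(seed)
        sd = scanner.noise_coeff * np.sqrt(np.maximum(values, 0.0))
        values = values + sd * rng.standard_normal(values.shape)
    return ActivityVolume(
        scanner_grid,
        values,
        {
            "kind": "observed",
            "scanner": scanner.name,
            "resolution_fwhm_mm": scanner.resolution_fwhm,
            "pgc_factor": scanner.pgc_factor,
            "noise_coeff": scanner.noise_coeff,
            "seed": int(seed),
        },
    )


def lesions_to_frame(lesions: list[LesionSpec]) -> pd.DataFrame:
    rows = [
        {
            "id": l.id,
            "center_x_mm": l.center[0],
            "center_y_mm": l.center[1],
            "center_z_mm": l.center[2],
            "diameter_mm": l.diameter,
            "ac_kbq_ml": l.ac,
            "trachea_distance_mm": l.trachea_distance,
        }
        for l in lesions
    ]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def lesions_from_frame(df: pd.DataFrame) -> list[LesionSpec]:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lesion manifest missing columns: {missing}")
    return [
        LesionSpec(
            id=str(r["id"]),
            center=(r["center_x_mm"], r["center_y_mm"], r["center_z_mm"]),
            diameter=float(r["diameter_mm"]),
            ac=float(r["ac_kbq_ml"]),
            trachea_distance=float(r["trachea_distance_mm"]),
        )
        for _, r in df.iterrows()
    ]


def read_lesion_manifest(path) -> list[LesionSpec]:
    return lesions_from_frame(pd.read_csv(path))


def write_phantom_bundle(
    truth: ActivityVolume,
    observed_pairs: dict[str, ActivityVolume],
    lesions: list[LesionSpec],
    directory,
) -> Path:
    """Write truth + observed volumes (NIfTI), the lesion manifest (CSV) and
    a JSON manifest of scanner metadata and seeds; returns the JSON path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = {}
    truth_path = directory / "truth.nii.gz"
    save_volume(truth, truth_path)
    entries["truth"] = {"file": truth_path.name}
    for label, vol in observed_pairs.items():
        p = directory / f"{label}.nii.gz"
        save_volume(vol, p)
        entries[label] = {"file": p.name, **vol.meta}
    lesion_path = directory / "lesions.csv"
    lesions_to_frame(lesions).to_csv(lesion_path, index=False)
    manifest = {
        "coordinate_convention": "world mm, RAS-like axes, voxel-center origin",
        "volumes": entries,
        "lesion_manifest": lesion_path.name,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def sample_lesions(
    n: int,
    grid: Grid,
    rng: np.random.Generator,
    diameter_range: tuple[float, float] = (5.0, 20.0),
    ac_range: tuple[float, float] = (0.2, 800.0),
    margin: float = 25.0,
    min_gap: float = 6.0,
    max_attempts: int = 20000,
) -> list[LesionSpec]:
    """Randomly place non-overlapping spherical lesions inside a grid.

    Diameters are uniform on ``diameter_range``; ACs log-uniform on
    ``ac_range`` (lesion ACs in neck studies span more than three decades);
    trachea distances uniform on [0, 30] mm so both proximity classes are
    populated.  ``margin`` keeps lesion surfaces away from the grid border
    (so scanner blur does not interact with the edge) and ``min_gap``
    separates lesion surfaces from each other.
    """
    ext = grid.extent
    lesions: list[LesionSpec] = []
    attempts = 0
    while len(lesions) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} lesions after {max_attempts} attempts; "
                "enlarge the grid or reduce n"
            )
        d = rng.uniform(*diameter_range)
        r = d / 2.0
        center = tuple(
            rng.uniform(ext[a][0] + margin + r, ext[a][1] - margin - r) for a in range(3)
        )
        ok = True
        for other in lesions:
            if np.linalg.norm(np.subtract(center, other.center)) < r + other.radius + min_gap:
                ok = False
                break
        if not ok:
            continue
        ac = float(np.exp(rng.uniform(np.log(ac_range[0]), np.log(ac_range[1]))))
        dist = float(rng.uniform(0.0, 30.0))
        lesions.append(
            LesionSpec(
                id=f"L{len(lesions) + 1:02d}",
                center=center,
                diameter=float(d),
                ac=ac,
                trachea_distance=dist,
            )
        )
    return lesions
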