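"""Per-lesion activity-concentration measurements on paired volumes.

Two AC readouts per lesion per volume: the maximum AC (hottest voxel within a
search neighbourhood of the lesion seed) and the average AC within a 7-mm
spherical VOI centered on that hottest voxel — the sphere diameter matches
the harmonized PET resolution.  Paired records additionally carry the
percentage difference of the test (MR-based) versus reference (CT-based)
readout, the trachea-proximity class, and a low-AC exclusion flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grid import ActivityVolume
from .phantom import LesionSpec

__all__ = [
    "LesionMeasurement",
    "PairedLesionRecord",
    "locate_max",
    "sphere_mean",
    "percent_difference",
    "classify_proximity",
    "apply_exclusion",
    "measure_pair",
    "measure_lesion",
    "records_to_frame",
]

#: VOI diameter (mm) for the average AC, equal to the harmonized resolution.
DEFAULT_VOI_DIAMETER = 7.0
#: Default max-search radius (mm) around the lesion seed.
DEFAULT_SEARCH_RADIUS = 10.0
#: Trachea adjacency threshold (mm); distance <= 5 mm counts as adjacent.
ADJACENCY_THRESHOLD = 5.0


@dataclass(frozen=True)
class LesionMeasurement:
    lesion_id: str
    max_ac: float
    max_position: tuple[float, float, float]
    avg_ac: float


@dataclass(frozen=True)
class PairedLesionRecord:
    lesion_id: str
    ref_max_ac: float
    ref_avg_ac: float
    test_max_ac: float
    test_avg_ac: float
    pct_diff_max: float
    pct_diff_avg: float
    proximity: str
    excluded: bool = False


def _voxels_within(volume: ActivityVolume, center, radius: float):
    """Indices (n, 3) and squared distances of voxel centers within radius of
    a world-mm point, restricted to the bounding box first."""
    grid = volume.grid
    center = np.asarray(center, dtype=float)
    lo, hi = [], []
    for a in range(3):
        lo.append(max(0, int(np.ceil((center[a] - radius - grid.origin[a]) / grid.spacing[a]))))
        hi.append(min(grid.shape[a] - 1, int(np.floor((center[a] + radius - grid.origin[a]) / grid.spacing[a]))))
    if any(l > h for l, h in zip(lo, hi)):
        return np.empty((0, 3), dtype=int), np.empty(0)
    ax = grid.axis_coordinates()
    xs = ax[0][lo[0] : hi[0] + 1] - center[0]
    ys = ax[1][lo[1] : hi[1] + 1] - center[1]
    zs = ax[2][lo[2] : hi[2] + 1] - center[2]
    d2 = xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
    mask = d2 <= radius**2
    idx = np.argwhere(mask)
    idx += np.asarray(lo)
    return idx, d2[mask]


def locate_max(
    volume: ActivityVolume, seed, search_radius: float = DEFAULT_SEARCH_RADIUS
) -> tuple[tuple[float, float, float], float]:
    """Position (world mm) and value of the hottest voxel within
    ``search_radius`` of ``seed``.

    Ties are broken by smallest distance to the seed, then by lexicographic
    voxel index order.
    """
    if search_radius <= 0:
        raise ValueError("search_radius must be > 0")
    idx, d2 = _voxels_within(volume, seed, search_radius)
    if len(idx) == 0:
        raise ValueError(f"no voxel center within {search_radius} mm of seed {tuple(seed)}")
    vals = volume.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    # sort by (-value, distance, i, j, k); the first row wins
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2, -vals))
    best = idx[order[0]]
    pos = tuple(volume.grid.world_coordinates(best))
    return pos, float(volume.values[tuple(best)])


def sphere_mean(
    volume: ActivityVolume, center, diameter: float = DEFAULT_VOI_DIAMETER
) -> float:
    """Unweighted mean over voxels whose centers lie within diameter/2 of
    ``center`` (Euclidean distance in mm)."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    idx, _ = _voxels_within(volume, center, diameter / 2.0)
    if len(idx) == 0:
        raise ValueError(
            f"no voxel centers inside a {diameter} mm sphere at {tuple(center)}; grid too coarse"
        )
    return float(volume.values[idx[:, 0], idx[:, 1], idx[:, 2]].mean())


def percent_difference(test_ac: float, ref_ac: float) -> float:
    """100 * (test - ref) / ref; the reference AC must be positive."""
    if ref_ac <= 0:
        raise ValueError(f"reference AC must be > 0, got {ref_ac}")
    return 100.0 * (test_ac - ref_ac) / ref_ac


def classify_proximity(trachea_distance: float) -> str:
    """'adjacent' when the trachea-surface distance is <= 5 mm, else 'distant'."""
    if trachea_distance < 0:
        raise ValueError("trachea_distance must be >= 0")
    return "adjacent" if trachea_distance <= ADJACENCY_THRESHOLD else "distant"


def measure_lesion(
    volume: ActivityVolume,
    lesion: LesionSpec,
    search_radius: float = DEFAULT_SEARCH_RADIUS,
    voi_diameter: float = DEFAULT_VOI_DIAMETER,
) -> LesionMeasurement:
    """Max-AC and sphere-averaged AC for one lesion on one volume.

    The VOI is centered at this volume's own max position, so paired volumes
    may use slightly different sphere centers.
    """
    pos, max_ac = locate_max(volume, lesion.center, search_radius)
    avg = sphere_mean(volume, pos, voi_diameter)
    return LesionMeasurement(lesion.id, max_ac, pos, avg)


def measure_pair(
    ref_volume: ActivityVolume,
    test_volume: ActivityVolume,
    lesions: list[LesionSpec],
    search_radius: float = DEFAULT_SEARCH_RADIUS,
    voi_diameter: float = DEFAULT_VOI_DIAMETER,
    exclusion_threshold: float = 1.0,
) -> list[PairedLesionRecord]:
    """Measure every lesion independently on both volumes and pair the
    readouts; volumes must be co-registered (shared world coordinates)."""
    records = []
    for les in lesions:
        ref = measure_lesion(ref_volume, les, search_radius, voi_diameter)
        test = measure_lesion(test_volume, les, search_radius, voi_diameter)
        records.append(
            PairedLesionRecord(
                lesion_id=les.id,
                ref_max_ac=ref.max_ac,
                ref_avg_ac=ref.avg_ac,
                test_max_ac=test.max_ac,
                test_avg_ac=test.avg_ac,
                pct_diff_max=percent_difference(test.max_ac, ref.max_ac),
                pct_diff_avg=percent_difference(test.avg_ac, ref.avg_ac),
                proximity=classify_proximity(les.trachea_distance),
            )
        )
    return apply_exclusion(records, exclusion_threshold)


def apply_exclusion(
    records: list[PairedLesionRecord], threshold: float = 1.0
) -> list[PairedLesionRecord]:
    """Flag (never delete) records whose reference avg-AC is at or below the
    low-AC threshold; downstream summaries report both with and without."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return [replace(r, excluded=r.ref_avg_ac <= threshold) for r in records]


def records_to_frame(records: list[PairedLesionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lesion_id": r.lesion_id,
                "ref_max_ac": r.ref_max_ac,
                "ref_avg_ac": r.ref_avg_ac,
                "test_max_ac": r.test_max_ac,
                "test_avg_ac": r.test_avg_ac,
                "pct_diff_max": r.pct_diff_max,
                "pct_diff_avg": r.pct_diff_avg,
                "proximity": r.proximity,
                "excluded": r.excluded,
            }
            for r in records
        ]
    )
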