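"""Grid-based binding-pocket volume calculation.

The pocket volume of a receptor structure is measured by filling a
user-specified inclusion region (a union of spheres) with an axis-aligned
lattice of points (0.5 A spacing by default), then

1. carving away points within any receptor atom's van der Waals radius plus
   a pad (1.09 A by default),
2. removing points outside the convex hull of the pocket-lining receptor
   atoms, and
3. removing lattice components not contiguous (26-neighbourhood) with the
   main pocket.

The retained point count times the lattice cell volume is the pocket volume
in cubic angstroms. Group-wise volume comparisons use a two-sided rank-sum
test of median differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.stats import mannwhitneyu

from .structures import Structure

#: Van der Waals radii in angstroms (Bondi-style table with common metals).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "SE": 1.90, "BR": 1.85, "I": 1.98,
    "FE": 2.05, "MO": 2.10, "V": 2.05, "MG": 1.73, "MN": 2.05,
    "ZN": 1.39, "CU": 1.40, "NI": 1.63, "CO": 2.00, "CA": 2.31,
    "NA": 2.27, "K": 2.75,
}


@dataclass(frozen=True)
class InclusionRegion:
    """Union of spheres defining where pocket grid points may exist."""

    spheres: tuple[tuple[tuple[float, float, float], float], ...]

    def __post_init__(self):
        if not self.spheres:
            raise ValueError("inclusion region needs at least one sphere")
        for center, radius in self.spheres:
            if radius <= 0:
                raise ValueError(f"sphere radius must be positive, got {radius}")
            if len(center) != 3:
                raise ValueError("sphere centers must be 3D")

    @classmethod
    def sphere(cls, center, radius: float) -> "InclusionRegion":
        return cls(((tuple(float(c) for c in center), float(radius)),))

    @classmethod
    def from_dict(cls, payload: dict) -> "InclusionRegion":
        return cls(tuple((tuple(s["center"]), float(s["radius"]))
                         for s in payload["spheres"]))

    def to_dict(self) -> dict:
        return {"spheres": [{"center": list(c), "radius": r}
                            for c, r in self.spheres]}

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        centers = np.array([c for c, _ in self.spheres])
        radii = np.array([r for _, r in self.spheres])
        return (centers - radii[:, None]).min(axis=0), \
               (centers + radii[:, None]).max(axis=0)

    def distance_to(self, points: np.ndarray) -> np.ndarray:
        """Signed-ish distance: min over spheres of (|p - center| - radius)."""
        d = np.full(len(points), np.inf)
        for center, radius in self.spheres:
            d = np.minimum(d, np.linalg.norm(points - np.asarray(center),
                                             axis=1) - radius)
        return d


@dataclass(frozen=True)
class PocketConfig:
    """Lattice and filter parameters for pocket-volume calculation."""

    grid_spacing: float = 0.5
    vdw_pad: float = 1.09
    vdw_table: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    vdw_fallback: float | None = 1.80
    hull_filter: bool = True
    hull_shell: float = 8.0
    contiguity_filter: bool = True
    contiguity_seed: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.vdw_pad < 0:
            raise ValueError("vdw_pad must be non-negative")

    def radius_of(self, element: str) -> float:
        r = self.vdw_table.get(element.upper())
        if r is None:
            r = self.vdw_fallback
        if r is None:
            raise KeyError(f"no van der Waals radius for element {element!r} "
                           "and no fallback configured")
        return r


@dataclass
class PocketResult:
    """Retained grid points and the volume they represent."""

    points: np.ndarray
    grid_spacing: float
    stage_counts: dict[str, int]

    @property
    def volume(self) -> float:
        return len(self.points) * self.grid_spacing ** 3

    def to_dict(self) -> dict:
        return {"volume_A3": self.volume,
                "grid_spacing_A": self.grid_spacing,
                "stage_counts": dict(self.stage_counts)}


def generate_grid(region: InclusionRegion,
                  config: PocketConfig | None = None) -> np.ndarray:
    """Lattice points inside the inclusion region.

    The lattice is anchored at the region's bounding-box minimum so results
    are reproducible for a given region and spacing.
    """
    config = config or PocketConfig()
    lo, hi = region.bounding_box()
    s = config.grid_spacing
    axes = [np.arange(lo[k], hi[k] + 0.5 * s, s) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    inside = region.distance_to(grid) <= 0.0
    return grid[inside]


def _receptor_mask(structure: Structure) -> np.ndarray:
    mask = np.ones(len(structure), dtype=bool)
    if structure.cofactor_selector is not None:
        mask &= ~structure.cofactor_mask()
    return mask


def carve(points: np.ndarray, structure: Structure,
          config: PocketConfig | None = None) -> np.ndarray:
    """Remove points within vdW radius + pad of any receptor atom.

    The cofactor group (if a selector is set) is not part of the receptor:
    the pocket being measured is the space it occupies.
    """
    config = config or PocketConfig()
    if len(points) == 0:
        return points
    mask = _receptor_mask(structure)
    if not mask.any():
        return points
    coords = structure.coords[mask]
    elements = structure.elements[mask]
    keep = np.ones(len(points), dtype=bool)
    tree = cKDTree(points)
    for element in np.unique(elements):
        r = config.radius_of(str(element)) + config.vdw_pad
        for idx in tree.query_ball_point(coords[elements == element], r):
            keep[idx] = False
    return points[keep]


def hull_filter(points: np.ndarray, structure: Structure,
                region: InclusionRegion | None = None,
                config: PocketConfig | None = None) -> np.ndarray:
    """Remove points outside the convex hull of the pocket-lining atoms.

    Lining atoms are receptor atoms within ``hull_shell`` (default 8 A) of
    the inclusion region; with no region given, all receptor atoms define
    the hull.
    """
    config = config or PocketConfig()
    if len(points) == 0:
        return points
    mask = _receptor_mask(structure)
    coords = structure.coords[mask]
    if region is not None:
        coords = coords[region.distance_to(coords) <= config.hull_shell]
    if len(coords) < 4:
        raise ValueError("convex hull needs >= 4 pocket-lining atoms")
    try:
        hull = Delaunay(coords)
    except QhullError as exc:
        raise ValueError(f"degenerate (coplanar?) hull atoms: {exc}") from exc
    return points[hull.find_simplex(points) >= 0]


def contiguity_filter(points: np.ndarray,
                      config: PocketConfig | None = None) -> np.ndarray:
    """Keep one 26-connected lattice component.

    The component containing ``contiguity_seed`` is kept when configured and
    non-empty; otherwise the largest component, ties broken toward the
    component holding the lowest-coordinate point.
    """
    config = config or PocketConfig()
    if len(points) == 0:
        return points
    s = config.grid_spacing
    origin = points.min(axis=0)
    idx = np.rint((points - origin) / s).astype(int)
    shape = idx.max(axis=0) + 1
    lattice = np.zeros(shape, dtype=bool)
    lattice[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    labels, n_comp = ndimage.label(lattice, structure=np.ones((3, 3, 3)))
    if n_comp <= 1:
        return points
    point_labels = labels[idx[:, 0], idx[:, 1], idx[:, 2]]

    chosen = 0
    if config.contiguity_seed is not None:
        seed_idx = np.rint((np.asarray(config.contiguity_seed) - origin) / s
                           ).astype(int)
        if np.all(seed_idx >= 0) and np.all(seed_idx < shape):
            chosen = int(labels[tuple(seed_idx)])
    if chosen == 0:
        sizes = np.bincount(point_labels)
        sizes[0] = 0
        best = sizes.max()
        candidates = np.flatnonzero(sizes == best)
        if len(candidates) == 1:
            chosen = int(candidates[0])
        else:
            # tie: component containing the lexicographically smallest point
            order = np.lexsort((points[:, 2], points[:, 1], points[:, 0]))
            for i in order:
                if point_labels[i] in candidates:
                    chosen = int(point_labels[i])
                    break
    return points[point_labels == chosen]


def pocket_volume(structure: Structure, region: InclusionRegion,
                  config: PocketConfig | None = None) -> PocketResult:
    """Full pipeline: generate -> carve -> hull filter -> contiguity -> volume."""
    config = config or PocketConfig()
    pts = generate_grid(region, config)
    counts = {"grid": len(pts)}
    pts = carve(pts, structure, config)
    counts["carve"] = len(pts)
    if config.hull_filter and len(pts):
        pts = hull_filter(pts, structure, region, config)
    counts["hull"] = len(pts)
    if config.contiguity_filter and len(pts):
        pts = contiguity_filter(pts, config)
    counts["contiguity"] = len(pts)
    return PocketResult(pts, config.grid_spacing, counts)


def compare_volume_groups(volume_sets: dict[str, list[float]]) -> dict:
    """Group summaries plus pairwise two-sided rank-sum median-difference tests.

    Returns a dict with per-group ``mean``, ``sd`` (population), ``min``,
    ``max``, ``n``, and a ``pairwise`` table of Mann-Whitney U statistics and
    two-sided p-values (exact for small samples without ties).
    """
    if len(volume_sets) < 2:
        raise ValueError("need at least two groups to compare")
    groups = {}
    for name, values in volume_sets.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        groups[name] = {"n": int(v.size), "mean": float(v.mean()),
                        "sd": float(v.std()), "min": float(v.min()),
                        "max": float(v.max()), "median": float(np.median(v))}
    pairwise = {}
    names = list(volume_sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = mannwhitneyu(volume_sets[a], volume_sets[b],
                               alternative="two-sided")
            pairwise[f"{a}|{b}"] = {
                "U": float(res.statistic), "p": float(res.pvalue),
                "median_difference": float(groups[a]["median"]
                                           - groups[b]["median"])}
    return {"groups": groups, "pairwise": pairwise}
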