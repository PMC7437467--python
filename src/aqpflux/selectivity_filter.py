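"""Selectivity-filter "central area": the projected quadrilateral spanned by
one representative atom from each of four pore-lining residues.

For aquaporin Z the filter is delimited by F43, H174, T183 and R189.  Per
frame, the centre point of the four residues is the mean of their centroids;
for each residue the atom closest to that centre is picked (deterministic
tie-break: lowest atom index).  The four picked positions are projected onto
the plane perpendicular to the channel axis, ordered by polar angle about
their projected centroid (which guarantees a simple quadrilateral), and the
area follows from the shoelace formula.  The area series is summarised as a
relative-frequency histogram with bin edges starting at 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import SelectionError, SpecError
from .io_trajectory import Topology, Trajectory, select

__all__ = [
    "FilterSpec",
    "AreaSeries",
    "pick_filter_atoms",
    "central_area",
    "area_series",
    "area_histogram",
    "DEFAULT_BIN_WIDTH_A2",
]

DEFAULT_BIN_WIDTH_A2 = 0.5


@dataclass(frozen=True)
class FilterSpec:
    """Four residues (chain, residue number) and the channel axis."""

    residues: tuple[tuple[str, int], ...]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.residues) != 4:
            raise SpecError("a selectivity filter has exactly four residues")
        norm = float(np.linalg.norm(self.axis))
        if abs(norm - 1.0) > 1e-8:
            object.__setattr__(
                self, "axis", tuple(np.asarray(self.axis, dtype=float) / norm)
            )

    def residue_atom_sets(self, topology: Topology) -> list[np.ndarray]:
        sets = []
        for chain, resnum in self.residues:
            ids = select(
                topology, {"chain_id": chain, "residue_number": resnum}
            )
            if ids.size == 0:
                raise SelectionError(
                    f"residue {chain}:{resnum} selects no atoms"
                )
            sets.append(ids)
        return sets


@dataclass
class AreaSeries:
    """Per-frame central area (Å²) and the atom picked per residue per frame."""

    time_ps: np.ndarray
    area: np.ndarray
    picked_ids: np.ndarray  # (n_frames, 4)


def pick_filter_atoms(
    trajectory: Trajectory, frame: int, residue_atom_sets: Sequence[np.ndarray]
) -> np.ndarray:
    """One representative atom per residue: the atom closest to the centre
    point (mean of the four residue centroids); ties go to the lowest index."""
    coords = trajectory.coords[frame].astype(np.float64)
    centroids = []
    for ids in residue_atom_sets:
        ids = np.asarray(ids, dtype=np.int64)
        if ids.size == 0:
            raise SelectionError("a filter residue selects no atoms")
        centroids.append(coords[ids].mean(axis=0))
    center = np.mean(centroids, axis=0)
    picked = []
    for ids in residue_atom_sets:
        ids = np.asarray(ids, dtype=np.int64)
        dist = np.linalg.norm(coords[ids] - center, axis=1)
        picked.append(ids[int(np.argmin(dist))])  # argmin is first-lowest on ties
    return np.asarray(picked, dtype=np.int64)


def _plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def central_area(
    points: np.ndarray, axis: Sequence[float] = (0.0, 0.0, 1.0)
) -> float:
    """Area (Å²) of the quadrilateral the four points span in the plane
    perpendicular to ``axis``.

    Vertices are ordered by polar angle about their projected centroid, so
    the input order is irrelevant; four collinear projections give area 0.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.shape != (4, 3):
        raise SpecError(f"central_area expects four 3D points; got {points.shape}")
    axis = np.asarray(axis, dtype=np.float64)
    u, v = _plane_basis(axis)
    xy = np.column_stack([points @ u, points @ v])
    centroid = xy.mean(axis=0)
    order = np.argsort(np.arctan2(xy[:, 1] - centroid[1], xy[:, 0] - centroid[0]))
    p = xy[order]
    x, y = p[:, 0], p[:, 1]
    return float(
        0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    )


def area_series(
    trajectory: Trajectory,
    topology: Topology,
    spec: FilterSpec,
    repick_every_frame: bool = True,
) -> AreaSeries:
    """Central-area time series for one monomer.

    By default the representative atom is re-picked every frame; with
    ``repick_every_frame=False`` the frame-0 picks are reused throughout
    (useful for stability comparisons).
    """
    sets = spec.residue_atom_sets(topology)
    axis = np.asarray(spec.axis, dtype=np.float64)
    n_frames = trajectory.n_frames
    areas = np.empty(n_frames)
    picked = np.empty((n_frames, 4), dtype=np.int64)
    fixed = None if repick_every_frame else pick_filter_atoms(trajectory, 0, sets)
    for f in range(n_frames):
        ids = pick_filter_atoms(trajectory, f, sets) if fixed is None else fixed
        picked[f] = ids
        areas[f] = central_area(
            trajectory.coords[f, ids].astype(np.float64), axis
        )
    return AreaSeries(time_ps=trajectory.time_ps, area=areas, picked_ids=picked)


def area_histogram(
    areas: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH_A2
) -> tuple[np.ndarray, np.ndarray]:
    """Relative-frequency histogram of areas; edges start at 0, masses sum to 1.

    Returns (edges, rel_freq) with len(edges) = len(rel_freq) + 1.
    """
    areas = np.asarray(areas, dtype=np.float64)
    if areas.size == 0:
        raise SpecError("area histogram needs at least one value")
    if bin_width <= 0:
        raise SpecError("bin width must be positive")
    n_bins = max(1, int(np.ceil((areas.max() + 1e-12) / bin_width)))
    edges = np.arange(n_bins + 1, dtype=np.float64) * bin_width
    counts, _ = np.histogram(areas, bins=edges)
    return edges, counts / areas.size
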