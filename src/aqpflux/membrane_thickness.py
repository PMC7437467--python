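"""Bilayer hydrophobic thickness from phosphorus atoms and its protein-adjacent
deformation.

Hydrophobic thickness is proxied by the phosphorus-to-phosphorus distance
d_P−P between the two leaflets, computed as the difference between the mean
z of upper-leaflet and lower-leaflet P atoms (leaflet-mean rather than
nearest-neighbour pairing: robust when a region holds only a handful of
lipids).  The protein-adjacent deformation is

    Δd_P−P,adj = d_P−P,origin − d_P−P,deform

where d_P−P,deform is measured on the annular shell of lipids laterally
within a cutoff of the protein (default 5 Å) and d_P−P,origin on a
protein-free reference — either a separate reference trajectory or a stated
constant.  Compression of the adjacent bilayer gives Δd > 0.

The default averaging schedule evaluates the thickness five times at 1-ns
spacing over the first 5 ns, each evaluation a block average of the frames
within ±half the spacing of the block centre, and reports the mean of the
five values; the schedule is fully configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientDataError, SelectionError, StructureError
from .io_trajectory import Trajectory

__all__ = [
    "LeafletAssignment",
    "ThicknessSchedule",
    "ThicknessRecord",
    "assign_leaflets",
    "thickness",
    "adjacent_shell",
    "delta_thickness",
    "DEFAULT_SHELL_CUTOFF_A",
]

DEFAULT_SHELL_CUTOFF_A = 5.0


@dataclass
class LeafletAssignment:
    """Partition of P atoms into upper/lower leaflets by the bilayer midplane."""

    p_ids: np.ndarray
    upper: np.ndarray  # boolean mask aligned with p_ids
    midplane_z: float

    @property
    def upper_ids(self) -> np.ndarray:
        return self.p_ids[self.upper]

    @property
    def lower_ids(self) -> np.ndarray:
        return self.p_ids[~self.upper]


@dataclass(frozen=True)
class ThicknessSchedule:
    """Evaluation schedule: ``n_points`` block averages spaced ``spacing_ps``
    apart; block k averages the frames in [k·spacing, (k+1)·spacing) — i.e.
    each evaluation is centred at (k + 1/2)·spacing and spans ±spacing/2,
    with shared boundary frames assigned to the later block."""

    n_points: int = 5
    spacing_ps: float = 1000.0

    @property
    def span_ps(self) -> float:
        return self.n_points * self.spacing_ps

    def blocks(self, time_ps: np.ndarray) -> list[np.ndarray]:
        """Frame indices per block; raises if the trajectory is too short."""
        if time_ps[-1] + 1e-9 < (self.n_points - 1) * self.spacing_ps:
            raise InsufficientDataError(
                f"trajectory spans {time_ps[-1]} ps, schedule needs "
                f"~{self.span_ps} ps"
            )
        out = []
        for k in range(self.n_points):
            lo = k * self.spacing_ps
            hi = (k + 1) * self.spacing_ps
            mask = (time_ps >= lo - 1e-9) & (time_ps < hi - 1e-9)
            if k == self.n_points - 1:  # close the final block
                mask |= np.abs(time_ps - hi) <= 1e-9
            idx = np.nonzero(mask)[0]
            if idx.size == 0:
                raise InsufficientDataError(f"schedule block {k} contains no frames")
            out.append(idx)
        return out


@dataclass
class ThicknessRecord:
    """Δd_P−P,adj with its per-block values and the shell cutoff used."""

    d_origin: float
    d_deform: float
    per_point_origin: np.ndarray
    per_point_deform: np.ndarray
    cutoff: float

    @property
    def delta_adj(self) -> float:
        return self.d_origin - self.d_deform

    @property
    def per_point_delta(self) -> np.ndarray:
        return self.per_point_origin - self.per_point_deform

    @property
    def delta_stderr(self) -> float:
        """Standard error of Δd over the schedule blocks."""
        d = self.per_point_delta
        if len(d) < 2:
            return float("nan")
        return float(np.std(d, ddof=1) / np.sqrt(len(d)))

    def to_dict(self) -> dict:
        return {
            "d_origin_A": self.d_origin,
            "d_deform_A": self.d_deform,
            "delta_adj_A": self.delta_adj,
            "delta_stderr_A": self.delta_stderr,
            "per_point_delta_A": self.per_point_delta.tolist(),
            "shell_cutoff_A": self.cutoff,
        }


def assign_leaflets(
    trajectory: Trajectory, frame: int, p_ids: np.ndarray
) -> LeafletAssignment:
    """Split P atoms at the bilayer midplane (mean z of the selection)."""
    p_ids = np.asarray(p_ids, dtype=np.int64)
    if p_ids.size < 2:
        raise SelectionError("leaflet assignment needs at least two P atoms")
    z = trajectory.coords[frame, p_ids, 2].astype(np.float64)
    mid = float(z.mean())
    if np.any(z == mid):
        raise StructureError("P atom exactly on the bilayer midplane")
    upper = z > mid
    if upper.all() or (~upper).all():
        raise StructureError("degenerate bilayer: all P atoms on one side")
    return LeafletAssignment(p_ids=p_ids, upper=upper, midplane_z=mid)


def thickness(
    trajectory: Trajectory,
    frame: int,
    p_ids: np.ndarray,
    region: np.ndarray | None = None,
) -> float:
    """d_P−P of one frame: leaflet-mean z difference within ``region``.

    Leaflets are assigned from the full P selection so a one-sided region
    still refers to the global midplane; ``region`` (a subset of ``p_ids``)
    restricts which atoms enter the means.
    """
    assignment = assign_leaflets(trajectory, frame, p_ids)
    if region is None:
        region = assignment.p_ids
    region = np.asarray(region, dtype=np.int64)
    in_region = np.isin(assignment.p_ids, region)
    z = trajectory.coords[frame, assignment.p_ids, 2].astype(np.float64)
    up = assignment.upper & in_region
    lo = ~assignment.upper & in_region
    if not up.any() or not lo.any():
        raise InsufficientDataError("region leaves a leaflet empty")
    return float(z[up].mean() - z[lo].mean())


def adjacent_shell(
    trajectory: Trajectory,
    frame: int,
    p_ids: np.ndarray,
    protein_ids: np.ndarray,
    cutoff: float = DEFAULT_SHELL_CUTOFF_A,
) -> np.ndarray:
    """P atoms whose minimum lateral (xy, minimum-image) distance to any
    protein atom is ≤ cutoff.  An empty shell is returned with a warning."""
    p_ids = np.asarray(p_ids, dtype=np.int64)
    protein_ids = np.asarray(protein_ids, dtype=np.int64)
    if protein_ids.size == 0:
        raise SelectionError("empty protein selection")
    pxy = trajectory.coords[frame, p_ids, :2].astype(np.float64)
    qxy = trajectory.coords[frame, protein_ids, :2].astype(np.float64)
    d = pxy[:, None, :] - qxy[None, :, :]
    if trajectory.box is not None:
        l = trajectory.box[frame, :2]
        d -= l * np.round(d / l)
    min_dist = np.sqrt((d**2).sum(axis=2)).min(axis=1)
    shell = p_ids[min_dist <= cutoff]
    if shell.size == 0:
        warnings.warn(
            f"adjacent shell empty at cutoff {cutoff} Å", stacklevel=2
        )
    return shell


def _scheduled_thickness(
    trajectory: Trajectory,
    p_ids: np.ndarray,
    schedule: ThicknessSchedule,
    region_for_frame,
) -> np.ndarray:
    """Block-averaged thickness per schedule point."""
    values = []
    for idx in schedule.blocks(trajectory.time_ps):
        per_frame = [
            thickness(trajectory, f, p_ids, region_for_frame(f)) for f in idx
        ]
        values.append(float(np.mean(per_frame)))
    return np.asarray(values)


def delta_thickness(
    trajectory: Trajectory,
    p_ids: np.ndarray,
    protein_ids: np.ndarray,
    cutoff: float = DEFAULT_SHELL_CUTOFF_A,
    reference: "Trajectory | float" = None,
    reference_p_ids: np.ndarray | None = None,
    schedule: ThicknessSchedule = ThicknessSchedule(),
) -> ThicknessRecord:
    """Δd_P−P,adj on the block-average schedule.

    ``reference`` is either a protein-free trajectory (d_origin computed on
    its full bilayer with the same schedule) or a constant d_origin in Å.
    ``reference_p_ids`` defaults to ``p_ids`` (valid when the reference
    shares the topology's atom ordering).
    """
    if reference is None:
        raise SelectionError(
            "reference required: a protein-free trajectory or a constant d_origin"
        )
    deform = _scheduled_thickness(
        trajectory,
        p_ids,
        schedule,
        lambda f: adjacent_shell(trajectory, f, p_ids, protein_ids, cutoff),
    )
    if isinstance(reference, Trajectory):
        ref_ids = p_ids if reference_p_ids is None else np.asarray(reference_p_ids)
        origin = _scheduled_thickness(reference, ref_ids, schedule, lambda f: None)
    else:
        origin = np.full_like(deform, float(reference))
    return ThicknessRecord(
        d_origin=float(origin.mean()),
        d_deform=float(deform.mean()),
        per_point_origin=origin,
        per_point_deform=deform,
        cutoff=cutoff,
    )
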