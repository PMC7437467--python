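"""Per-channel water occupancy and the collective transport coordinate n(t).

The channel is modelled as a finite cylinder aligned with z.  The collective
coordinate accumulates, per frame interval, the summed z-displacements of the
waters inside the channel, in units of the channel length L:

    n(t_{k+1}) = n(t_k) + sum_{i in s(t_k) ∩ s(t_{k+1})} dz_i / L,   n(0) = 0.

A single water traversing the full channel length contributes exactly ±1, so
n counts net permeation events; treated as a 1D random walk it yields the
osmotic diffusivity D_n (see :mod:`aqpflux.diffusion`).  Counting an interval
only for waters inside at BOTH endpoints is symmetric in time, avoids
double-counting entry/exit displacement, and preserves the ±1-per-permeation
identity in the channel interior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientDataError, SelectionError, SpecError
from .io_trajectory import Trajectory, unwrapped_dz

__all__ = [
    "ChannelSpec",
    "OccupancySeries",
    "CollectiveCoordinateSeries",
    "occupancy",
    "collective_coordinate",
    "occupancy_count_series",
]


@dataclass(frozen=True)
class ChannelSpec:
    """Geometric definition of one monomer channel.

    The axis is +z; ``center_xy`` fixes the pore axis position, ``z_min`` /
    ``z_max`` the channel extent (L = z_max - z_min) and ``radius`` the
    cylinder radius, all in Å.
    """

    channel_id: str
    center_xy: tuple[float, float]
    z_min: float
    z_max: float
    radius: float = 4.0

    def __post_init__(self) -> None:
        if not self.z_max > self.z_min:
            raise SpecError(
                f"channel {self.channel_id!r}: z_max ({self.z_max}) must exceed "
                f"z_min ({self.z_min})"
            )
        if not self.radius > 0:
            raise SpecError(f"channel {self.channel_id!r}: radius must be positive")

    @property
    def length(self) -> float:
        """Channel length L in Å."""
        return self.z_max - self.z_min


@dataclass
class OccupancySeries:
    """Per-frame channel membership for a water selection.

    ``inside`` is a boolean (n_frames, n_waters) matrix; column order follows
    ``water_ids``.
    """

    channel_id: str
    water_ids: np.ndarray
    inside: np.ndarray
    time_ps: np.ndarray

    def members(self, frame: int) -> np.ndarray:
        """Atom ids of the waters inside the channel at ``frame``."""
        return self.water_ids[self.inside[frame]]

    @property
    def counts(self) -> np.ndarray:
        return self.inside.sum(axis=1)


@dataclass
class CollectiveCoordinateSeries:
    """The dimensionless collective coordinate n(t) of one channel; n(0) = 0."""

    channel_id: str
    time_ps: np.ndarray
    n: np.ndarray

    @property
    def dt_frame(self) -> float:
        return float(self.time_ps[1] - self.time_ps[0])


def occupancy(
    trajectory: Trajectory, water_ids: np.ndarray, channel: ChannelSpec
) -> OccupancySeries:
    """Determine which waters are inside the channel cylinder at each frame.

    Membership: lateral (minimum-image x,y) distance to the axis ≤ radius and
    z_min ≤ z ≤ z_max, both boundaries inclusive.
    """
    water_ids = np.asarray(water_ids, dtype=np.int64)
    if water_ids.size == 0:
        raise SelectionError("empty water selection")
    xyz = trajectory.coords[:, water_ids, :].astype(np.float64)
    dx = xyz[:, :, 0] - channel.center_xy[0]
    dy = xyz[:, :, 1] - channel.center_xy[1]
    if trajectory.box is not None:
        lx = trajectory.box[:, 0][:, None]
        ly = trajectory.box[:, 1][:, None]
        dx -= lx * np.round(dx / lx)
        dy -= ly * np.round(dy / ly)
    lateral2 = dx * dx + dy * dy
    z = xyz[:, :, 2]
    inside = (lateral2 <= channel.radius**2) & (z >= channel.z_min) & (z <= channel.z_max)
    return OccupancySeries(
        channel_id=channel.channel_id,
        water_ids=water_ids,
        inside=inside,
        time_ps=trajectory.time_ps,
    )


def collective_coordinate(
    trajectory: Trajectory, water_ids: np.ndarray, channel: ChannelSpec
) -> CollectiveCoordinateSeries:
    """Accumulate n(t) for one channel from unwrapped water displacements."""
    if trajectory.n_frames < 2:
        raise InsufficientDataError("collective coordinate needs at least two frames")
    occ = occupancy(trajectory, water_ids, channel)
    disp = unwrapped_dz(trajectory, occ.water_ids)
    both = occ.inside[:-1] & occ.inside[1:]
    increments = np.where(both, disp.dz, 0.0).sum(axis=1) / channel.length
    n = np.concatenate([[0.0], np.cumsum(increments)])
    return CollectiveCoordinateSeries(
        channel_id=channel.channel_id, time_ps=trajectory.time_ps, n=n
    )


def occupancy_count_series(occ: OccupancySeries) -> np.ndarray:
    """Number of waters inside the channel per frame."""
    return occ.counts
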