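"""Synthetic trajectory generators with analytically known ground truth.

Three harnesses, one per analysis chain:

* **Channel water** — independent waters performing 1D Brownian motion along
  z inside cylindrical channels.  In the default ``periodic`` boundary mode
  the channel spans the full periodic box height, so the occupancy set is
  constant AND every water remains a free (unbounded) random walk; the
  collective coordinate then has the exact closed-form diffusivity
  D_n = N_w·D_w/L² (variance additivity of independent increments divided by
  L²).  A ``reflective`` mode confines waters between hard channel ends; its
  per-water MSD saturates on the scale L²/D, so the closed form holds only
  for lags ≪ L²/D and the mode is meant for qualitative boundary-bookkeeping
  checks, not parameter recovery.
* **Bilayer** — two square lattices of phosphorus atoms at z = ±d0/2 around a
  central cylindrical dummy protein; both leaflets are displaced inward by
  (A/2)·exp(−(r−r_prot)²/(2σ²)) with r the lateral distance to the protein
  surface, plus per-frame Gaussian z-noise.  A protein-free, undeformed
  reference trajectory is produced alongside, and the planted truth
  Δd_expected(cutoff) is the average of the analytic deformation profile
  over the noise-free lattice sites inside the shell.
* **Filter** — four marker atoms on square corners whose area switches
  between two target values via a symmetric two-state Markov chain, with
  Gaussian vertex jitter; the per-frame state labels are emitted.

All generators are bit-reproducible given (config, seed) and write through
:mod:`aqpflux.io_trajectory` formats unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collective_coordinate import ChannelSpec
from .exceptions import SpecError
from .io_trajectory import Topology, Trajectory

__all__ = [
    "ChannelWaterConfig",
    "BilayerConfig",
    "FilterConfig",
    "ChannelWaterSystem",
    "BilayerSystem",
    "FilterSystem",
    "gen_channel_water",
    "gen_bilayer",
    "gen_filter",
]


# --------------------------------------------------------------------------
# channel water
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelWaterConfig:
    """Brownian channel-water generator settings (defaults match the
    package's standard validation conditions)."""

    n_channels: int = 4
    n_waters_per_channel: int = 8
    channel_length: float = 20.0  # Å
    radius: float = 4.0  # Å
    d_water: float = 0.2  # Å²/ps
    dt_frame: float = 1.0  # ps
    n_frames: int = 200_000
    boundary: str = "periodic"  # or "reflective"
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "n_channels",
            "n_waters_per_channel",
            "channel_length",
            "radius",
            "dt_frame",
            "n_frames",
        ):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if self.d_water < 0:
            raise SpecError("d_water must be non-negative")
        if self.boundary not in ("periodic", "reflective"):
            raise SpecError("boundary must be 'periodic' or 'reflective'")


@dataclass
class ChannelWaterSystem:
    topology: Topology
    trajectory: Trajectory
    channels: list[ChannelSpec]
    water_ids_per_channel: list[np.ndarray]
    truth: dict


def _reflect(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by specular reflection."""
    span = hi - lo
    z = np.mod(z - lo, 2 * span)
    z = np.where(z > span, 2 * span - z, z)
    return z + lo


def gen_channel_water(config: ChannelWaterConfig) -> ChannelWaterSystem:
    """Generate Brownian channel waters with closed-form D_n truth.

    Channels sit on a lateral grid; each holds ``n_waters_per_channel``
    independent waters with z-increments Normal(0, 2·D_w·dt) and a small
    lateral jitter that keeps them well inside the radius.  Truth:
    D_n_expected = N_w·D_w/L² (exact in periodic mode; short-lag-only in
    reflective mode).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pitch = 6.0 * cfg.radius
    per_row = int(np.ceil(np.sqrt(cfg.n_channels)))
    lx = ly = per_row * pitch
    centers = [
        ((i % per_row + 0.5) * pitch, (i // per_row + 0.5) * pitch)
        for i in range(cfg.n_channels)
    ]
    if cfg.boundary == "periodic":
        z_min, z_max = 0.0, cfg.channel_length
        lz = cfg.channel_length
    else:
        margin = 2.0
        z_min, z_max = margin, margin + cfg.channel_length
        lz = cfg.channel_length + 2 * margin

    n_w = cfg.n_waters_per_channel
    n_atoms = cfg.n_channels * n_w
    step_sigma = np.sqrt(2.0 * cfg.d_water * cfg.dt_frame)
    coords = np.empty((cfg.n_frames, n_atoms, 3), dtype=np.float32)

    channels: list[ChannelSpec] = []
    water_ids: list[np.ndarray] = []
    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWX"
    names, resnames, resnums, chains = [], [], [], []
    for c, (cx, cy) in enumerate(centers):
        ids = np.arange(c * n_w, (c + 1) * n_w)
        water_ids.append(ids)
        channels.append(
            ChannelSpec(
                channel_id=f"M{c + 1}",
                center_xy=(cx, cy),
                z_min=z_min,
                z_max=z_max,
                radius=cfg.radius,
            )
        )
        # lateral home positions well inside the radius, frozen per water
        ang = rng.uniform(0, 2 * np.pi, n_w)
        rad = cfg.radius * 0.4 * np.sqrt(rng.uniform(0, 1, n_w))
        home = np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
        jitter = rng.normal(0.0, 0.15 * cfg.radius, size=(cfg.n_frames, n_w, 2))
        lateral = home[None, :, :] + jitter
        # clip lateral excursions so occupancy never flickers at the wall
        off = lateral - np.array([cx, cy])
        norm = np.linalg.norm(off, axis=2, keepdims=True)
        cap = 0.9 * cfg.radius
        scale = np.where(norm > cap, cap / np.maximum(norm, 1e-12), 1.0)
        lateral = np.array([cx, cy]) + off * scale
        coords[:, ids, 0] = lateral[:, :, 0]
        coords[:, ids, 1] = lateral[:, :, 1]

        z0 = rng.uniform(z_min, z_max, n_w)
        steps = rng.normal(0.0, step_sigma, size=(cfg.n_frames - 1, n_w))
        z = np.vstack([z0, z0 + np.cumsum(steps, axis=0)])
        if cfg.boundary == "periodic":
            z = np.mod(z, lz)
        else:
            z = _reflect(z, z_min, z_max)
        coords[:, ids, 2] = z

        for w in range(n_w):
            names.append("OH2")
            resnames.append("TIP3")
            resnums.append(w + 1)
            chains.append(chain_letters[c % len(chain_letters)])

    topo = Topology(
        atom_name=names, residue_name=resnames, residue_number=resnums, chain_id=chains
    )
    box = np.tile([lx, ly, lz], (cfg.n_frames, 1))
    traj = Trajectory(coords=coords, box=box, dt_frame=cfg.dt_frame)
    truth = {
        "D_n_expected_per_ps": n_w * cfg.d_water / cfg.channel_length**2,
        "boundary": cfg.boundary,
        "exact": cfg.boundary == "periodic",
        "seed": cfg.seed,
    }
    return ChannelWaterSystem(
        topology=topo,
        trajectory=traj,
        channels=channels,
        water_ids_per_channel=water_ids,
        truth=truth,
    )


# --------------------------------------------------------------------------
# bilayer
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BilayerConfig:
    """Deformed-bilayer generator settings.

    The 8-Å lattice spacing corresponds to ~64 Å² per lipid, a realistic
    phospholipid area; ``amplitude`` is the total thickness reduction A at
    the protein surface and ``decay_width`` the lateral Gaussian decay σ.
    """

    lipids_per_leaflet: int = 256
    lattice_spacing: float = 8.0  # Å
    d0: float = 38.0  # unperturbed P–P thickness, Å
    protein_radius: float = 10.0  # Å
    amplitude: float = 4.0  # A, Å
    decay_width: float = 3.0  # σ, Å
    z_noise: float = 0.5  # σ_z, Å
    n_frames: int = 50
    dt_frame: float = 100.0  # ps → 50 frames span the 5-ns schedule
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.d0 > self.amplitude >= 0:
            raise SpecError("need d0 > amplitude >= 0")
        if self.decay_width <= 0:
            raise SpecError("decay_width must be positive")
        side = int(np.ceil(np.sqrt(self.lipids_per_leaflet))) * self.lattice_spacing
        if self.protein_radius >= side / 2:
            raise SpecError("protein radius must be below half the box side")


@dataclass
class BilayerSystem:
    topology: Topology
    trajectory: Trajectory
    reference: Trajectory
    p_ids: np.ndarray
    protein_ids: np.ndarray
    leaflet_labels: np.ndarray  # +1 upper / -1 lower, aligned with p_ids
    site_radial_dist: np.ndarray  # lateral distance of each P site to protein surface
    truth: dict

    def delta_expected(self, cutoff: float) -> float:
        """Shell average of the analytic deformation profile (numeric
        integration over the discrete lattice sites within the cutoff)."""
        cfg = self.truth["config"]
        in_shell = self.site_radial_dist <= cutoff
        if not in_shell.any():
            raise SpecError(f"no lattice sites within cutoff {cutoff} Å")
        prof = cfg.amplitude * np.exp(
            -(self.site_radial_dist[in_shell] ** 2) / (2 * cfg.decay_width**2)
        )
        return float(prof.mean())


def gen_bilayer(config: BilayerConfig) -> BilayerSystem:
    """Generate a deformed two-leaflet P-atom bilayer plus its protein-free
    reference, with the analytic Δd truth attached."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    per_side = int(np.ceil(np.sqrt(cfg.lipids_per_leaflet)))
    box_side = per_side * cfg.lattice_spacing
    grid = (np.arange(per_side) + 0.5) * cfg.lattice_spacing
    gx, gy = np.meshgrid(grid, grid, indexing="ij")
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    center = np.array([box_side / 2, box_side / 2])
    r_axis = np.linalg.norm(xy - center, axis=1)
    keep = r_axis > cfg.protein_radius + 0.5  # protein occupies the centre
    xy = xy[keep]
    r_surface = r_axis[keep] - cfg.protein_radius
    n_per_leaflet = xy.shape[0]

    deform = (cfg.amplitude / 2.0) * np.exp(
        -(r_surface**2) / (2 * cfg.decay_width**2)
    )
    z_upper = cfg.d0 / 2.0 - deform
    z_lower = -cfg.d0 / 2.0 + deform

    # dense protein ring: 180 atoms × 3 z-levels keeps the lateral distance
    # to the cylinder surface accurate to < 0.01 Å
    n_ring, n_levels = 180, 3
    ang = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    ring = center + cfg.protein_radius * np.column_stack([np.cos(ang), np.sin(ang)])
    prot_xy = np.tile(ring, (n_levels, 1))
    prot_z = np.repeat(np.linspace(-cfg.d0 / 4, cfg.d0 / 4, n_levels), n_ring)

    n_p = 2 * n_per_leaflet
    n_prot = prot_xy.shape[0]
    n_atoms = n_p + n_prot

    names = ["P"] * n_p + ["C"] * n_prot
    resnames = ["POPC"] * n_p + ["PRT"] * n_prot
    resnums = list(range(1, n_p + 1)) + [1] * n_prot
    chains = ["U"] * n_per_leaflet + ["L"] * n_per_leaflet + ["X"] * n_prot
    topo = Topology(
        atom_name=names, residue_name=resnames, residue_number=resnums, chain_id=chains
    )

    base = np.empty((n_atoms, 3))
    base[:n_per_leaflet, :2] = xy
    base[:n_per_leaflet, 2] = z_upper
    base[n_per_leaflet:n_p, :2] = xy
    base[n_per_leaflet:n_p, 2] = z_lower
    base[n_p:, :2] = prot_xy
    base[n_p:, 2] = prot_z

    coords = np.tile(base, (cfg.n_frames, 1, 1))
    coords[:, :n_p, 2] += rng.normal(0.0, cfg.z_noise, size=(cfg.n_frames, n_p))

    ref_base = base[:n_p].copy()
    ref_base[:n_per_leaflet, 2] = cfg.d0 / 2.0
    ref_base[n_per_leaflet:, 2] = -cfg.d0 / 2.0
    ref_coords = np.tile(ref_base, (cfg.n_frames, 1, 1))
    ref_coords[:, :, 2] += rng.normal(0.0, cfg.z_noise, size=(cfg.n_frames, n_p))

    lz = 2 * cfg.d0
    box = np.tile([box_side, box_side, lz], (cfg.n_frames, 1))
    traj = Trajectory(coords=coords.astype(np.float32), box=box, dt_frame=cfg.dt_frame)
    ref = Trajectory(
        coords=ref_coords.astype(np.float32), box=box.copy(), dt_frame=cfg.dt_frame
    )

    labels = np.concatenate([np.ones(n_per_leaflet), -np.ones(n_per_leaflet)])
    system = BilayerSystem(
        topology=topo,
        trajectory=traj,
        reference=ref,
        p_ids=np.arange(n_p),
        protein_ids=np.arange(n_p, n_atoms),
        leaflet_labels=labels,
        site_radial_dist=np.concatenate([r_surface, r_surface]),
        truth={"config": cfg, "seed": cfg.seed},
    )
    system.truth["delta_expected_at_default_cutoff"] = system.delta_expected(5.0)
    return system


# --------------------------------------------------------------------------
# selectivity filter
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Two-state filter-area generator settings (mode areas echo the two
    observed flexibility states near 5 and 9 Å²)."""

    area_low: float = 5.0  # Å²
    area_high: float = 9.0  # Å²
    switch_prob: float = 0.02  # per frame, symmetric
    jitter: float = 0.1  # Å, per-vertex Gaussian
    n_frames: int = 5000
    dt_frame: float = 10.0  # ps
    seed: int = 42

    def __post_init__(self) -> None:
        if self.area_low <= 0 or self.area_high <= 0:
            raise SpecError("mode areas must be positive")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise SpecError("switch probability must lie in [0, 1]")


@dataclass
class FilterSystem:
    topology: Topology
    trajectory: Trajectory
    state_labels: np.ndarray  # 0 = low-area state, 1 = high-area state
    truth: dict


# the four pore-lining residues of the aquaporin Z selectivity filter
_FILTER_RESIDUES = (("PHE", 43, "CA"), ("HIS", 174, "CA"), ("THR", 183, "CA"), ("ARG", 189, "CA"))


def gen_filter(config: FilterConfig) -> FilterSystem:
    """Four marker atoms on a square whose area flips between two modes."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    flips = rng.uniform(size=cfg.n_frames - 1) < cfg.switch_prob
    states = np.empty(cfg.n_frames, dtype=np.int64)
    states[0] = 0
    for i, f in enumerate(flips, start=1):
        states[i] = states[i - 1] ^ int(f)
    side = np.sqrt(np.where(states == 0, cfg.area_low, cfg.area_high))
    corners = np.array(
        [[-0.5, -0.5], [0.5, -0.5], [0.5, 0.5], [-0.5, 0.5]]
    )  # unit square
    coords = np.zeros((cfg.n_frames, 4, 3))
    coords[:, :, :2] = corners[None, :, :] * side[:, None, None]
    coords[:, :, :2] += rng.normal(0.0, cfg.jitter, size=(cfg.n_frames, 4, 2))
    coords[:, :, 2] = rng.normal(0.0, cfg.jitter, size=(cfg.n_frames, 4))
    coords[:, :, :2] += 25.0  # keep coordinates positive for PDB friendliness

    topo = Topology(
        atom_name=[a for _, _, a in _FILTER_RESIDUES],
        residue_name=[r for r, _, _ in _FILTER_RESIDUES],
        residue_number=[n for _, n, _ in _FILTER_RESIDUES],
        chain_id=["A"] * 4,
    )
    box = np.array([50.0, 50.0, 50.0])
    traj = Trajectory(
        coords=coords.astype(np.float32),
        box=np.tile(box, (cfg.n_frames, 1)),
        dt_frame=cfg.dt_frame,
    )
    truth = {
        "modes_A2": (cfg.area_low, cfg.area_high),
        "stationary_distribution": (0.5, 0.5) if cfg.switch_prob > 0 else (1.0, 0.0),
        "seed": cfg.seed,
    }
    return FilterSystem(
        topology=topo, trajectory=traj, state_labels=states, truth=truth
    )
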