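"""Agent-based synthetic spheroid trajectories and quantification images.

The simulator emulates a mixed-population spheroid motility experiment: two
cell populations inside an elliptical core, one persistent and biased toward
the matrix interface (an Ornstein–Uhlenbeck persistent random walk on
velocity with an added outward radial drift, "sticky" at the boundary), the
other diffusive (short velocity decorrelation time, no drift).  With a fixed
seed every output is byte-identical, so downstream statistics (ΔDI sign,
MSD exponents, compartment occupancy) can be tested against a known
construction.

The OU velocity process per component is

    dv = -(v/τ) dt + (σ/√τ) √2 dW,      σ² = s²/2 per component,

which gives a stationary speed scale s (``PopulationParams.speed``) and a
velocity autocorrelation exp(−t/τ) with persistence time τ.  Its MSD crosses
over from ballistic (~s²t²) at t ≪ τ to diffusive (~2·s²τ·t per axis... in
2D: 4Dt with D = s²τ/2) at t ≫ τ, so both α → 2 and α → 1 regimes are
reachable by choosing τ against the observation window.

Image fixtures: bright-background gelatin images with dark degradation holes
of known rasterized area, and blob images for area quantification, each with
exact ground truth returned alongside the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .geometry import SpheroidGeometry
from .tracks import Spot, Track

__all__ = [
    "PopulationParams",
    "SimulationConfig",
    "SyntheticImageSpec",
    "ConfigurationError",
    "simulate_spheroid_population",
    "brownian_polar_tracks",
    "generate_degradation_image",
    "generate_blob_image",
    "generate_trackmate_fixture",
]

BoundaryMode = Literal["sticky", "reflecting", "absorbing-free"]
Placement = Literal["uniform", "core-only", "edge-only"]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class PopulationParams:
    """Motility parameters for one simulated cell population.

    Parameters
    ----------
    name : str
        Population label carried onto every track.
    n_cells : int
    speed : float
        Stationary root-mean-square speed of the OU walk, µm/min.
    persistence_time : float
        Velocity decorrelation time τ, min.  τ much shorter than the
        observation window gives diffusive motion; τ comparable to it gives
        persistent, super-diffusive-looking motion.
    radial_bias : float
        Dimensionless strength of the constant outward drift; the drift
        speed is ``radial_bias * speed``.  0 disables drift.
    boundary_mode : {"sticky", "reflecting", "absorbing-free"}
        Behavior at the spheroid–matrix interface: *sticky* projects the
        outward velocity component onto the boundary tangent (the cell stays
        in the edge ring), *reflecting* mirrors it, *absorbing-free* lets
        cells leave the core.
    initial_placement : {"uniform", "core-only", "edge-only"}
        Seeding region; *core-only* places cells deeper than 30 µm from the
        interface, *edge-only* within that ring.
    """

    name: str
    n_cells: int
    speed: float
    persistence_time: float
    radial_bias: float = 0.0
    boundary_mode: BoundaryMode = "sticky"
    initial_placement: Placement = "uniform"

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")
        if self.speed < 0:
            raise ConfigurationError("speed must be >= 0")
        if self.persistence_time <= 0:
            raise ConfigurationError("persistence_time must be > 0")
        if self.radial_bias < 0:
            raise ConfigurationError("radial_bias must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the two-population spheroid simulator.

    ``mixing_ratio``, when given as (nA, nB), overrides the per-population
    cell counts while keeping the total, e.g. (1, 50) for a 1:50 mix.
    Defaults mirror the assay's recording scheme: 10-min frames over 44 h.
    """

    geometry: SpheroidGeometry
    populations: tuple[PopulationParams, ...]
    dt: float = 10.0  # min
    duration: float = 2640.0  # min (44 h)
    seed: int = 0
    mixing_ratio: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.duration < self.dt:
            raise ConfigurationError("duration must be >= dt")
        if self.mixing_ratio is not None and len(self.populations) != 2:
            raise ConfigurationError("mixing_ratio requires exactly 2 populations")

    def effective_counts(self) -> list[int]:
        counts = [p.n_cells for p in self.populations]
        if self.mixing_ratio is not None:
            total = sum(counts)
            ra, rb = self.mixing_ratio
            na = round(total * ra / (ra + rb))
            counts = [na, total - na]
        return counts


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Specification of a synthetic quantification image.

    ``hole_specs`` are (center_xy_px, radius_px, depth) discs subtracted from
    a bright background (degradation fixtures).  Holes must lie within the
    image; overlaps are allowed and ground truth is the union area.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.0  # µm/px
    background_level: int = 10000
    hole_specs: tuple[tuple[tuple[float, float], float, float], ...] = ()
    n_cells_drawn: int = 0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        h, w = self.shape
        for (cx, cy), radius, _depth in self.hole_specs:
            if radius <= 0:
                raise ConfigurationError("hole radius must be > 0")
            if not (0 <= cx < w and 0 <= cy < h):
                raise ConfigurationError(f"hole center ({cx}, {cy}) outside image")


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

def _place_cells(
    rng: np.random.Generator,
    n: int,
    geom: SpheroidGeometry,
    placement: Placement,
    ring_width: float = 30.0,
) -> np.ndarray:
    """Rejection-sample initial positions in the requested region (local frame)."""
    from .geometry import _dist_to_ellipse_first_quadrant

    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(4 * (n - filled), 16)
        cand = rng.uniform(-1, 1, size=(m, 2)) * [geom.a, geom.b]
        inside = (cand[:, 0] / geom.a) ** 2 + (cand[:, 1] / geom.b) ** 2 < 1.0
        cand = cand[inside]
        if placement != "uniform" and len(cand):
            d = _dist_to_ellipse_first_quadrant(
                np.abs(cand[:, 0]), np.abs(cand[:, 1]), geom.a, geom.b
            )
            cand = cand[d > ring_width] if placement == "core-only" else cand[d <= ring_width]
        take = min(len(cand), n - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return out


def _boundary_normal(pos: np.ndarray, geom: SpheroidGeometry) -> np.ndarray:
    """Outward normal direction of the level set (x/a)²+(y/b)²=1 (local frame)."""
    g = np.column_stack([pos[:, 0] / geom.a**2, pos[:, 1] / geom.b**2])
    norm = np.linalg.norm(g, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return g / norm


def simulate_spheroid_population(
    config: SimulationConfig,
) -> tuple[list[Track], SpheroidGeometry]:
    """Simulate all populations; returns tracks (µm, min) and the geometry.

    Each cell follows the OU persistent random walk with optional outward
    drift; positions are stepped by Euler–Maruyama at ``config.dt``.  For
    sticky/reflecting boundary modes no position ever leaves the core
    ellipse.  Determinism: one ``Philox`` stream per cell keyed by
    (master seed, global cell index), so results are independent of
    vectorization or population order.
    """
    geom = config.geometry
    counts = config.effective_counts()
    n_steps = int(np.floor(config.duration / config.dt))
    dt = config.dt

    tracks: list[Track] = []
    cell_index = 0
    for pop, n_cells in zip(config.populations, counts):
        if n_cells == 0:
            continue
        # placement stream keyed by first global cell index of the population
        rng_place = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1, cell_index))
        )
        pos0 = _place_cells(rng_place, n_cells, geom, pop.initial_placement)
        sigma = pop.speed / np.sqrt(2.0)  # per-component stationary sd
        tau = pop.persistence_time
        drift_speed = pop.radial_bias * pop.speed

        for i in range(n_cells):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(2, cell_index))
            )
            pos = pos0[i].copy()
            vel = rng.normal(0.0, sigma, size=2) if pop.speed > 0 else np.zeros(2)
            traj = np.empty((n_steps + 1, 2))
            traj[0] = pos
            decay = np.exp(-dt / tau)
            kick_sd = sigma * np.sqrt(1.0 - decay**2)
            for k in range(1, n_steps + 1):
                if pop.speed > 0:
                    vel = vel * decay + rng.normal(0.0, kick_sd, size=2)
                step = vel.copy()
                if drift_speed > 0:
                    nrm = _boundary_normal(pos[None, :], geom)[0]
                    step = step + drift_speed * nrm
                new = pos + step * dt
                if pop.boundary_mode != "absorbing-free":
                    inside = (new[0] / geom.a) ** 2 + (new[1] / geom.b) ** 2 <= 1.0
                    if not inside:
                        n_hat = _boundary_normal(new[None, :], geom)[0]
                        if pop.boundary_mode == "sticky":
                            # damp the outward component; slide along tangent
                            v_out = step @ n_hat
                            step = step - max(v_out, 0.0) * n_hat
                            vel = vel - max(vel @ n_hat, 0.0) * n_hat
                        else:  # reflecting
                            step = step - 2.0 * (step @ n_hat) * n_hat
                            vel = vel - 2.0 * (vel @ n_hat) * n_hat
                        new = pos + step * dt
                        # project back if still (numerically) outside
                        q = (new[0] / geom.a) ** 2 + (new[1] / geom.b) ** 2
                        if q > 1.0:
                            new = new / np.sqrt(q)
                pos = new
                traj[k] = pos
            # rotate/translate local-frame trajectory into lab coordinates
            c, s = np.cos(geom.phi0_axis), np.sin(geom.phi0_axis)
            rot = np.array([[c, -s], [s, c]])
            lab = traj @ rot.T + np.asarray(geom.center)
            spots = [
                Spot(frame=k, t=k * dt, x=float(lab[k, 0]), y=float(lab[k, 1]))
                for k in range(n_steps + 1)
            ]
            tracks.append(
                Track(
                    track_id=f"{pop.name}_{i:04d}",
                    spots=spots,
                    population=pop.name,
                )
            )
            cell_index += 1
    return tracks, geom


def brownian_polar_tracks(
    n_tracks: int,
    diffusion: float = 1.0,
    dt: float = 10.0,
    duration: float = 2640.0,
    seed: int = 0,
    r0: float = 100.0,
):
    """1D Brownian walks in the radial coordinate, as ready-made PolarTracks.

    Ground truth: ⟨(r−r0)²⟩ = 2·D·t with ``D = diffusion`` in µm²/min, so a
    power-law fit should recover α ≈ 1 and Γ ≈ 2D.  The walk starts at
    ``r0`` (far from 0, so the r ≥ 0 fold is never hit at desk-scale D) and
    ϕ stays 0.  Used as the known-answer input for diffusion-coefficient
    recovery tests.
    """
    from .motility import PolarTrack

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(5,))
    )
    n_steps = int(np.floor(duration / dt))
    t = np.arange(n_steps + 1) * dt
    steps = rng.normal(0.0, np.sqrt(2.0 * diffusion * dt), size=(n_tracks, n_steps))
    r = r0 + np.concatenate(
        [np.zeros((n_tracks, 1)), np.cumsum(steps, axis=1)], axis=1
    )
    return [
        PolarTrack(track_id=f"bm_{i:04d}", t=t, r=np.abs(r[i]), phi=np.zeros_like(t))
        for i in range(n_tracks)
    ]


# ---------------------------------------------------------------------------
# Image fixtures
# ---------------------------------------------------------------------------

def _rasterize_discs(
    shape: tuple[int, int],
    discs: Sequence[tuple[tuple[float, float], float]],
) -> np.ndarray:
    """Boolean union of discs; a pixel (row, col) is in a disc when its
    center (col, row) lies within the radius."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for (cx, cy), radius in discs:
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return mask


def generate_degradation_image(
    spec: SyntheticImageSpec, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Synthetic gelatin-degradation image plus exact ground-truth hole area.

    Dark discs ("holes") are stamped onto a bright uniform background,
    optionally with Gaussian noise.  Returns the 16-bit image and the union
    area of the rasterized holes in px².
    """
    h, w = spec.shape
    img = np.full(spec.shape, float(spec.background_level))
    union = _rasterize_discs(spec.shape, [(c, r) for c, r, _d in spec.hole_specs])
    for center, radius, depth in spec.hole_specs:
        disc = _rasterize_discs(spec.shape, [(center, radius)])
        img[disc] = np.minimum(img[disc], spec.background_level - depth)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    return img, float(union.sum())


def generate_blob_image(
    spec: SyntheticImageSpec, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Bright blobs (nuclei-like) on a dark background with exact area.

    Reuses ``hole_specs`` as (center, radius, intensity) for bright discs.
    """
    img = np.zeros(spec.shape, dtype=float)
    union = _rasterize_discs(spec.shape, [(c, r) for c, r, _d in spec.hole_specs])
    for center, radius, intensity in spec.hole_specs:
        disc = _rasterize_discs(spec.shape, [(center, radius)])
        img[disc] = np.maximum(img[disc], intensity)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(4,)))
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    return img, float(union.sum())


def generate_trackmate_fixture(
    tracks: list[Track],
    path,
    drop_frames: dict | None = None,
) -> None:
    """Write tracks as a TrackMate-dialect XML fixture.

    ``drop_frames`` maps track_id to frame indices whose spots are omitted,
    creating gaps for the reader's gap-closing to fill.
    """
    from .tracks import write_trackmate_xml

    if not tracks:
        raise ValueError("tracks must be non-empty")
    write_trackmate_xml(tracks, path, drop=drop_frames)
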