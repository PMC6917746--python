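"""Synthetic gastrulating-embryo generator.

Produces ground-truth single-cell trajectories, germlayer identities,
expression traces, and toy image stacks with the statistical structure the
downstream analysis assumes, so the whole pipeline is testable without
light-sheet data.

The model: cells occupy a thin shell (≈50 µm) just under the surface of a
sphere of radius ≈350 µm (the embryo, inside a ≈550 µm chorion). They are
advected along meridians by a time-dependent epiboly rate and along
parallels toward the dorsal midline by a convergence rate. A configurable
fraction of mesendoderm cells near the shield internalizes: a radial
inward step of ``internalize_depth`` followed by a drift back toward the
animal pole. Expression reporters switch on at fixed onsets (mezzo in
mesendoderm from ≈4.5 hpf, sox17 in endoderm from ≈6.5 hpf) with a
first-order rise. Observed tracks add Gaussian positional noise and may be
fragmented into tracklets; the un-noised, un-fragmented truth is returned
alongside.

Randomness uses one counter-derived substream per cell, so cell k's
trajectory is invariant under changes of ``n_cells`` above k.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import SphericalFrame, to_cartesian
from .preprocess import VoxelStack
from .tracks import Track, TrackSet

__all__ = [
    "EmbryoSimConfig",
    "GroundTruth",
    "default_epiboly_rate",
    "default_convergence_rate",
    "simulate_embryo_tracks",
    "render_channel_stacks",
    "render_transmission_stack",
]


def default_epiboly_rate(t_hpf: np.ndarray) -> np.ndarray:
    """Epiboly rate profile (rad/h): bump peaking around 5–9 hpf, decaying
    toward the end of gastrulation. Illustrative magnitude (~0.45 rad/h
    peak spreads the blastoderm over the yolk in ~6 h)."""
    t = np.asarray(t_hpf, dtype=float)
    return 0.45 * np.exp(-0.5 * ((t - 7.0) / 2.0) ** 2)


def default_convergence_rate(t_hpf: np.ndarray) -> np.ndarray:
    """Dorsal convergence rate profile (rad/h): bump peaking around
    8–12 hpf."""
    t = np.asarray(t_hpf, dtype=float)
    return 0.30 * np.exp(-0.5 * ((t - 10.0) / 2.0) ** 2)


@dataclass
class EmbryoSimConfig:
    """Parameters of the synthetic embryo.

    Rates may be constants (rad/h) or callables of time (hpf). Onsets and
    the internalization window are in hpf; lengths in µm.
    """

    n_cells: int = 500
    embryo_radius: float = 350.0
    chorion_radius: float = 550.0
    shell_band: float = 50.0
    frame_interval: float = 120.0  # seconds
    t_start: float = 4.0
    t_end: float = 14.0
    epiboly_rate: object = None  # default: default_epiboly_rate
    convergence_rate: object = None  # default: default_convergence_rate
    mesendoderm_fraction: float = 0.4
    endoderm_fraction: float = 0.2  # of mesendoderm lineage, after sox17 onset
    internalize_fraction: float = 0.25
    internalize_depth: float = 30.0
    internalize_start: float = 5.5
    internalize_duration: float = 0.5
    animal_drift_rate: float = 0.25  # rad/h toward animal pole after internalizing
    noise_sd: float = 1.0
    mezzo_onset: float = 4.5
    sox17_onset: float = 6.5
    expression_tau: float = 0.5  # first-order rise time constant, h
    fragment_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embryo_radius >= self.chorion_radius:
            raise ValueError("embryo_radius must be < chorion_radius")
        if not 0.0 <= self.internalize_fraction <= 1.0:
            raise ValueError("internalize_fraction must be in [0, 1]")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.epiboly_rate is None:
            self.epiboly_rate = default_epiboly_rate
        if self.convergence_rate is None:
            self.convergence_rate = default_convergence_rate

    def times_hpf(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) * 3600.0 / self.frame_interval)) + 1
        return self.t_start + np.arange(n) * self.frame_interval / 3600.0

    def rate_at(self, which: str, t: np.ndarray) -> np.ndarray:
        fn = self.epiboly_rate if which == "epiboly" else self.convergence_rate
        vals = np.asarray(fn(t) if callable(fn) else np.full_like(np.asarray(t, float), float(fn)), dtype=float)
        if np.any(np.isnan(vals)):
            raise ValueError(f"{which}_rate evaluates to NaN")
        return vals


@dataclass
class GroundTruth:
    """Everything the simulator knows that a tracker would not."""

    true_tracks: TrackSet  # complete, un-fragmented, noise-free
    fate: np.ndarray  # final layer per cell: epiblast/mesendoderm/endoderm
    internalized: np.ndarray  # bool per cell
    flow_params: dict  # arrays: t_hpf, epiboly_rate, convergence_rate
    fragment_base: dict  # observed fragment cell_id -> true cell index

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "fate": list(map(str, self.fate)),
                    "internalized": [bool(b) for b in self.internalized],
                    "flow_params": {
                        k: np.asarray(v).tolist() for k, v in self.flow_params.items()
                    },
                    "fragment_base": {
                        str(k): int(v) for k, v in self.fragment_base.items()
                    },
                },
                indent=1,
            )
        )


def _simulate_cell(cfg: EmbryoSimConfig, i: int, times: np.ndarray,
                   epi_rate: np.ndarray, conv_rate: np.ndarray):
    """One cell: spherical-coordinate advection in the canonical frame."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
    # initial position: uniform-area on the animal cap, within the shell band
    r0 = cfg.embryo_radius - cfg.shell_band * rng.random()
    phi = float(np.arcsin(-rng.random()))  # in [-pi/2, 0): blastoderm cap
    theta = float(rng.uniform(-np.pi, np.pi))
    meso = rng.random() < cfg.mesendoderm_fraction
    endo = bool(meso and (rng.random() < cfg.endoderm_fraction))
    internalize = bool(meso and (rng.random() < cfg.internalize_fraction))
    if internalize:
        # internalizers sit near the shield (longitude ~ 0) close to the margin
        theta = float(np.clip(rng.normal(0.0, np.pi / 10.0), -np.pi / 4, np.pi / 4))
        phi = float(rng.uniform(-0.3, -0.05))

    n = len(times)
    dt_h = cfg.frame_interval / 3600.0
    r_arr = np.empty(n)
    th_arr = np.empty(n)
    ph_arr = np.empty(n)
    r = r0
    t_int0 = cfg.internalize_start
    t_int1 = cfg.internalize_start + cfg.internalize_duration
    for k, t in enumerate(times):
        r_arr[k], th_arr[k], ph_arr[k] = r, theta, phi
        if k == n - 1:
            break
        in_step = internalize and t_int0 <= t < t_int1
        post = internalize and t >= t_int1
        if in_step:
            r -= cfg.internalize_depth * dt_h / cfg.internalize_duration
        elif post:
            phi = max(phi - cfg.animal_drift_rate * dt_h, -np.pi / 2 + 1e-3)
        else:
            phi = min(phi + epi_rate[k] * dt_h, np.pi / 2 - 1e-3)
        step = conv_rate[k] * dt_h
        if step != 0.0 and theta != 0.0:
            theta -= np.sign(theta) * min(abs(step), abs(theta))
    noise = (
        rng.normal(0.0, cfg.noise_sd, size=(n, 3)) if cfg.noise_sd > 0 else np.zeros((n, 3))
    )
    cuts = rng.random(n - 1) < cfg.fragment_prob if cfg.fragment_prob > 0 else np.zeros(n - 1, bool)
    return r_arr, th_arr, ph_arr, noise, cuts, meso, endo, internalize


def simulate_embryo_tracks(
    cfg: EmbryoSimConfig,
) -> tuple[TrackSet, GroundTruth]:
    """Simulate the embryo; returns (observed TrackSet, GroundTruth).

    The observed set carries positional noise and fragmentation; the
    ground truth carries complete noise-free tracks, per-cell fates and
    internalization flags, the programmed flow profiles, and the mapping
    from observed fragment ids back to true cells.
    """
    frame = SphericalFrame.canonical(cfg.embryo_radius)
    times = cfg.times_hpf()
    epi_rate = cfg.rate_at("epiboly", times)
    conv_rate = cfg.rate_at("convergence", times)
    n_frames = len(times)

    obs_tracks: list = []
    true_tracks: list = []
    fate = np.empty(cfg.n_cells, dtype=object)
    internalized = np.zeros(cfg.n_cells, dtype=bool)
    fragment_base: dict = {}

    for i in range(cfg.n_cells):
        r_arr, th_arr, ph_arr, noise, cuts, meso, endo, intern = _simulate_cell(
            cfg, i, times, epi_rate, conv_rate
        )
        fate[i] = "endoderm" if endo else ("mesendoderm" if meso else "epiblast")
        internalized[i] = intern

        true_pos = to_cartesian(r_arr, th_arr, ph_arr, frame)
        layers = np.empty(n_frames, dtype=object)
        mezzo = np.zeros(n_frames)
        sox17 = np.zeros(n_frames)
        for k, t in enumerate(times):
            if endo and t >= cfg.sox17_onset:
                layers[k] = "endoderm"
            elif meso and t >= cfg.mezzo_onset:
                layers[k] = "mesendoderm"
            else:
                layers[k] = "epiblast"
        if meso:
            dt_on = np.maximum(times - cfg.mezzo_onset, 0.0)
            mezzo = np.where(
                times >= cfg.mezzo_onset, 1.0 - np.exp(-dt_on / cfg.expression_tau), 0.0
            )
        if endo:
            dt_on = np.maximum(times - cfg.sox17_onset, 0.0)
            sox17 = np.where(
                times >= cfg.sox17_onset, 1.0 - np.exp(-dt_on / cfg.expression_tau), 0.0
            )
        expression = {"mezzo": mezzo, "sox17": sox17}
        frames = np.arange(n_frames)
        true_tracks.append(
            Track(
                cell_id=i, frames=frames, positions=true_pos, layers=layers,
                expression=expression,
            )
        )

        obs_pos = true_pos + noise
        cut_idx = np.flatnonzero(cuts) + 1
        bounds = [0, *cut_idx.tolist(), n_frames]
        for j in range(len(bounds) - 1):
            lo, hi = bounds[j], bounds[j + 1]
            cid = i if j == 0 else cfg.n_cells * j + i
            fragment_base[cid] = i
            obs_tracks.append(
                Track(
                    cell_id=cid,
                    frames=frames[lo:hi],
                    positions=obs_pos[lo:hi],
                    layers=layers[lo:hi],
                    expression={k: v[lo:hi] for k, v in expression.items()},
                )
            )

    obs = TrackSet(obs_tracks, cfg.frame_interval, cfg.t_start, f"sim-seed{cfg.seed}")
    truth = GroundTruth(
        true_tracks=TrackSet(
            true_tracks, cfg.frame_interval, cfg.t_start, f"sim-seed{cfg.seed}-truth"
        ),
        fate=fate,
        internalized=internalized,
        flow_params={
            "t_hpf": times, "epiboly_rate": epi_rate, "convergence_rate": conv_rate
        },
        fragment_base=fragment_base,
    )
    return obs, truth


# ---------------------------------------------------------------------------
# Toy image rendering


def _positions_at_frame(trackset: TrackSet, frame_index: int):
    pos, layers = [], []
    for t in trackset:
        hit = np.flatnonzero(t.frames == frame_index)
        if hit.size:
            pos.append(t.positions[hit[0]])
            layers.append(str(t.layers[hit[0]]))
    if not pos:
        return np.empty((0, 3)), []
    return np.asarray(pos), layers


def _render_blobs(
    coords_vox: np.ndarray, shape: tuple, sigma_vox: float, amplitude: float
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    if coords_vox.shape[0]:
        idx = np.round(coords_vox).astype(int)
        np.add.at(img, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
        peak = 1.0 / (np.sqrt(2.0 * np.pi) * sigma_vox) ** 3
        img *= amplitude / peak
    return img


def render_channel_stacks(
    trackset: TrackSet,
    frame_index: int,
    voxel_size: float,
    shape: tuple,
    amplitude: float = 200.0,
    nuclear_sigma_um: float = 3.0,
    cyto_sigma_um: float = 7.0,
    background: float = 0.0,
    poisson_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[VoxelStack, VoxelStack, VoxelStack]:
    """Render the three reporter channels for one frame.

    Channel 3 (ubiquitous histone): nuclear Gaussian blobs at all cell
    positions. Channel 2 (mezzo, cytoplasmic): broader blobs at
    mesendoderm + endoderm positions. Channel 1 (sox17): nuclear blobs at
    endoderm positions. The embryo centre maps to the stack centre.
    """
    pos, layers = _positions_at_frame(trackset, frame_index)
    if pos.shape[0] == 0 and not any(t.frames[0] <= frame_index <= t.frames[-1] for t in trackset):
        if len(trackset) and not any(
            frame_index in t.frames for t in trackset
        ):
            raise ValueError(f"frame {frame_index} not present in any track")
    shape = tuple(int(s) for s in shape)
    origin = -0.5 * np.asarray(shape) * voxel_size  # µm, (z, y, x)
    coords = (pos[:, ::-1] - origin) / voxel_size if pos.shape[0] else pos
    for ax, name in enumerate("zyx"):
        if pos.shape[0] and (
            np.any(coords[:, ax] < 1) or np.any(coords[:, ax] > shape[ax] - 2)
        ):
            raise ValueError(
                f"stack too small along {name}: cells fall outside "
                f"{shape[ax]} voxels at {voxel_size} µm"
            )
    nuc_sigma = nuclear_sigma_um / voxel_size
    cyto_sigma = cyto_sigma_um / voxel_size
    is_meso = np.array([l in ("mesendoderm", "endoderm") for l in layers], bool)
    is_endo = np.array([l == "endoderm" for l in layers], bool)
    ch3 = _render_blobs(coords, shape, nuc_sigma, amplitude) + background
    ch2 = _render_blobs(coords[is_meso], shape, cyto_sigma, amplitude) + background
    ch1 = _render_blobs(coords[is_endo], shape, nuc_sigma, amplitude) + background
    if poisson_noise:
        rng = rng or np.random.default_rng(0)
        ch1, ch2, ch3 = (rng.poisson(c).astype(float) for c in (ch1, ch2, ch3))
    vs = voxel_size
    return (
        VoxelStack(ch1, vs, "sox17"),
        VoxelStack(ch2, vs, "mezzo"),
        VoxelStack(ch3, vs, "histone"),
    )


def render_transmission_stack(
    cfg: EmbryoSimConfig,
    voxel_size: float,
    shape: tuple,
    amplitude: float = 100.0,
    shell_sigma_um: float | None = None,
    background: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> VoxelStack:
    """Two noisy spherical surface shells on a flat background.

    Mimics the in-focus edges of a focus-filtered transmission stack: the
    embryo surface at ``cfg.embryo_radius`` and the chorion at
    ``cfg.chorion_radius``, each a Gaussian ridge of width
    ``shell_sigma_um`` (default: one voxel).
    """
    shape = tuple(int(s) for s in shape)
    half_extent = 0.5 * min(shape) * voxel_size
    for name, radius in (("embryo", cfg.embryo_radius), ("chorion", cfg.chorion_radius)):
        if radius >= half_extent:
            raise ValueError(
                f"{name} radius {radius} µm does not fit: half-extent is "
                f"{half_extent} µm"
            )
    if shell_sigma_um is None:
        shell_sigma_um = voxel_size
    center = 0.5 * np.asarray(shape) * voxel_size
    axes = [(np.arange(n) + 0.5) * voxel_size - c for n, c in zip(shape, center)]
    dist = np.sqrt(
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    img = background + amplitude * (
        np.exp(-0.5 * ((dist - cfg.embryo_radius) / shell_sigma_um) ** 2)
        + np.exp(-0.5 * ((dist - cfg.chorion_radius) / shell_sigma_um) ** 2)
    )
    if noise_sd > 0:
        rng = rng or np.random.default_rng(cfg.seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
        img = np.clip(img, 0.0, None)
    return VoxelStack(img.astype(np.float32), voxel_size, "transmission")
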