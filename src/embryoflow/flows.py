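"""Tissue-scale flow fields and cross-layer motion statistics.

Single-cell displacements are aggregated on a regular grid over the
Mercator projection of the embryo surface (default 40×40 cells, 10 time
intervals), yielding per-interval vector fields of the local mean motion
direction with observation counts as weights. On these fields the module
computes:

* multi-embryo averaging,
* circular correlation of flow directions between germlayers,
* decomposition of motion into epiboly and convergence proportions with
  observation-weighted per-interval summaries,
* density-weighted streamlines (RK2 integration, widths corrected for the
  Mercator sec²(phi) area inflation),
* local single-cell motion correlation between neighbouring cells
  (Spearman, per spherical component), and
* residual motion of the mesendoderm relative to the surrounding epiblast.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde, spearmanr

from .geometry import (
    DEFAULT_PHI_MAX,
    SphericalFrame,
    area_factor,
    mercator_project,
    to_spherical,
)
from .tracks import TrackSet

__all__ = [
    "GridSpec",
    "FlowField",
    "DecompositionResult",
    "build_flow_field",
    "average_flow_fields",
    "circular_correlation",
    "reference_directions_uv",
    "decompose_movement",
    "density_weighted_streamlines",
    "local_motion_correlation",
    "relative_layer_motion",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular grid over the Mercator plane plus a time binning."""

    n_u: int = 40
    n_v: int = 40
    n_intervals: int = 10
    u_range: tuple = (-np.pi, np.pi)
    v_range: tuple = None
    frame_range: tuple = (0, 0)

    def __post_init__(self) -> None:
        if self.v_range is None:
            v_max = float(np.log(np.tan(np.pi / 4.0 + DEFAULT_PHI_MAX / 2.0)))
            object.__setattr__(self, "v_range", (-v_max, v_max))

    def cell_of(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        iu = np.clip(
            ((u - self.u_range[0]) / (self.u_range[1] - self.u_range[0]) * self.n_u)
            .astype(int),
            0,
            self.n_u - 1,
        )
        iv = np.clip(
            ((v - self.v_range[0]) / (self.v_range[1] - self.v_range[0]) * self.n_v)
            .astype(int),
            0,
            self.n_v - 1,
        )
        return iu, iv

    def interval_of(self, frames: np.ndarray) -> np.ndarray:
        lo, hi = self.frame_range
        span = max((hi - lo + 1) / self.n_intervals, 1e-9)
        return np.clip(((np.asarray(frames) - lo) / span).astype(int), 0, self.n_intervals - 1)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        u = self.u_range[0] + (np.arange(self.n_u) + 0.5) * (
            self.u_range[1] - self.u_range[0]
        ) / self.n_u
        v = self.v_range[0] + (np.arange(self.n_v) + 0.5) * (
            self.v_range[1] - self.v_range[0]
        ) / self.n_v
        return u, v

    def layout_equal(self, other: "GridSpec") -> bool:
        return (
            self.n_u == other.n_u
            and self.n_v == other.n_v
            and self.n_intervals == other.n_intervals
            and np.allclose(self.u_range, other.u_range)
            and np.allclose(self.v_range, other.v_range)
        )


@dataclass
class FlowField:
    """Gridded spatio-temporal flow field.

    ``vectors[t, iv, iu]`` is the unit mean direction in the (u, v) plane
    (zero where undefined), ``magnitude`` the resultant length of the mean
    of the assigned unit displacements (1 = perfectly coherent cell), and
    ``weights`` the observation count.
    """

    grid: GridSpec
    vectors: np.ndarray  # (T, n_v, n_u, 2)
    magnitude: np.ndarray  # (T, n_v, n_u)
    weights: np.ndarray  # (T, n_v, n_u) int

    def __post_init__(self) -> None:
        t, nv, nu = self.weights.shape
        if self.vectors.shape != (t, nv, nu, 2):
            raise ValueError("vectors shape inconsistent with weights")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    def save(self, base: str | Path) -> None:
        base = Path(base)
        base.parent.mkdir(parents=True, exist_ok=True)
        spec = dataclasses.asdict(self.grid)
        spec = {k: (list(v) if isinstance(v, tuple) else v) for k, v in spec.items()}
        base.with_suffix(".json").write_text(json.dumps(spec))
        np.savez(
            base.with_suffix(".npz"),
            vectors=self.vectors,
            magnitude=self.magnitude,
            weights=self.weights,
        )

    @classmethod
    def load(cls, base: str | Path) -> "FlowField":
        base = Path(base)
        spec = json.loads(base.with_suffix(".json").read_text())
        spec = {k: (tuple(v) if isinstance(v, list) else v) for k, v in spec.items()}
        arrays = np.load(base.with_suffix(".npz"))
        return cls(GridSpec(**spec), arrays["vectors"], arrays["magnitude"], arrays["weights"])


def _displacements_uv(trackset: TrackSet, frame: SphericalFrame):
    """Per-track consecutive-frame displacements in the Mercator plane.

    Returns arrays (u0, v0, du, dv, start_frames). Displacements whose
    endpoints straddle the ±π longitude seam are wrapped.
    """
    u0s, v0s, dus, dvs, f0s = [], [], [], [], []
    for t in trackset:
        if len(t) < 2:
            continue
        _, theta, phi, _ = to_spherical(t.positions, frame)
        u, v = mercator_project(theta, phi)
        du = np.diff(u)
        du = (du + np.pi) % (2.0 * np.pi) - np.pi  # wrap the longitude seam
        dv = np.diff(v)
        consecutive = np.diff(t.frames) == 1
        u0s.append(u[:-1][consecutive])
        v0s.append(v[:-1][consecutive])
        dus.append(du[consecutive])
        dvs.append(dv[consecutive])
        f0s.append(t.frames[:-1][consecutive])
    if not u0s:
        z = np.empty(0)
        return z, z, z, z, z.astype(int)
    return (
        np.concatenate(u0s),
        np.concatenate(v0s),
        np.concatenate(dus),
        np.concatenate(dvs),
        np.concatenate(f0s),
    )


def build_flow_field(
    trackset: TrackSet,
    frame: SphericalFrame,
    grid: GridSpec | None = None,
) -> FlowField:
    """Grid the unit-normalized displacements of a track set.

    Each consecutive-frame displacement is unit-normalized in the Mercator
    plane and assigned to the grid cell of its start point and the time
    interval of its start frame; the per-cell vector is the mean of the
    assigned unit vectors (direction stored unit-length, resultant length
    in ``magnitude``), the weight is the count. The summed weights equal
    the number of non-degenerate consecutive displacements.
    """
    if grid is None:
        grid = GridSpec(frame_range=trackset.frame_range())
    u0, v0, du, dv, f0 = _displacements_uv(trackset, frame)
    norm = np.hypot(du, dv)
    ok = norm > 0
    u0, v0, du, dv, f0, norm = u0[ok], v0[ok], du[ok] / norm[ok], dv[ok] / norm[ok], f0[ok], norm[ok]
    iu, iv = grid.cell_of(u0, v0)
    it = grid.interval_of(f0)

    sums = np.zeros((grid.n_intervals, grid.n_v, grid.n_u, 2))
    weights = np.zeros((grid.n_intervals, grid.n_v, grid.n_u), dtype=int)
    np.add.at(sums, (it, iv, iu, np.zeros_like(it)), du)
    np.add.at(sums, (it, iv, iu, np.ones_like(it)), dv)
    np.add.at(weights, (it, iv, iu), 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_vec = sums / np.maximum(weights, 1)[..., None]
    magnitude = np.linalg.norm(mean_vec, axis=-1)
    unit = np.where(magnitude[..., None] > 0, mean_vec / np.maximum(magnitude, 1e-300)[..., None], 0.0)
    unit[weights == 0] = 0.0
    magnitude = np.where(weights > 0, magnitude, 0.0)
    return FlowField(grid=grid, vectors=unit, magnitude=magnitude, weights=weights)


def average_flow_fields(fields: list) -> FlowField:
    """Average per-embryo flow fields cell by cell.

    The per-cell vector is the renormalized mean of the embryo unit
    vectors (cells where they cancel are flagged incoherent: zero vector,
    zero magnitude); weights are summed. All fields must share the grid
    layout.
    """
    if not fields:
        raise ValueError("need at least one field")
    first = fields[0]
    for f in fields[1:]:
        if not first.grid.layout_equal(f.grid):
            raise ValueError("flow-field grid/interval layouts differ")
    present = np.stack([f.weights > 0 for f in fields])
    vecs = np.stack([f.vectors for f in fields])
    n_present = present.sum(axis=0)
    mean_vec = np.where(
        n_present[..., None] > 0,
        vecs.sum(axis=0) / np.maximum(n_present, 1)[..., None],
        0.0,
    )
    magnitude = np.linalg.norm(mean_vec, axis=-1)
    unit = np.where(
        magnitude[..., None] > 1e-12, mean_vec / np.maximum(magnitude, 1e-300)[..., None], 0.0
    )
    weights = np.sum([f.weights for f in fields], axis=0)
    return FlowField(
        grid=first.grid,
        vectors=unit,
        magnitude=np.where(n_present > 0, magnitude, 0.0),
        weights=weights,
    )


def circular_correlation(field_a: FlowField, field_b: FlowField) -> pd.DataFrame:
    """Circular correlation of two flow fields, per time interval.

    With the circular means set to zero (directions on the projected
    sphere have no unambiguous mean), the correlation of the direction
    angles α, β over paired populated sites reduces to

        rho = Σ w sin(α) sin(β) / sqrt(Σ w sin²(α) · Σ w sin²(β)),

    with per-site weight w = min(w_A, w_B). rho is 1 for identical fields
    and −1 for fields rotated by π. Intervals where either field has zero
    sin-variance are NaN (flagged undefined).
    """
    if not field_a.grid.layout_equal(field_b.grid):
        raise ValueError("flow-field layouts differ")
    rows = []
    for t in range(field_a.grid.n_intervals):
        both = (field_a.weights[t] > 0) & (field_b.weights[t] > 0)
        n_sites = int(np.count_nonzero(both))
        if n_sites == 0:
            rows.append({"interval": t, "rho": np.nan, "n_sites": 0})
            continue
        va = field_a.vectors[t][both]
        vb = field_b.vectors[t][both]
        w = np.minimum(field_a.weights[t][both], field_b.weights[t][both]).astype(float)
        alpha = np.arctan2(va[:, 1], va[:, 0])
        beta = np.arctan2(vb[:, 1], vb[:, 0])
        sa, sb = np.sin(alpha), np.sin(beta)
        denom = np.sqrt(np.sum(w * sa**2) * np.sum(w * sb**2))
        rho = float(np.sum(w * sa * sb) / denom) if denom > 0 else np.nan
        rows.append({"interval": t, "rho": rho, "n_sites": n_sites})
    return pd.DataFrame(rows)


def reference_directions_uv(grid: GridSpec) -> dict:
    """Epiboly / convergence reference directions at grid-cell centres,
    expressed in the Mercator tangent plane.

    The projection is conformal and maps meridians to vertical lines, so
    pure epiboly (animal→vegetal, increasing latitude) is (0, +1)
    everywhere, and pure convergence (along parallels toward the dorsal
    midline u = 0) is (−sign(u), 0), degenerate on u ∈ {0, ±π}.
    """
    u_c, v_c = grid.cell_centers()
    uu = np.broadcast_to(u_c[None, :], (grid.n_v, grid.n_u))
    epi = np.zeros((grid.n_v, grid.n_u, 2))
    epi[..., 1] = 1.0
    conv = np.zeros((grid.n_v, grid.n_u, 2))
    conv[..., 0] = -np.sign(uu)
    degenerate_conv = np.isclose(uu, 0.0) | np.isclose(np.abs(uu), np.pi)
    conv[degenerate_conv] = 0.0
    return {"epi": epi, "conv": conv, "conv_degenerate": degenerate_conv}


@dataclass
class DecompositionResult:
    """Epiboly/convergence decomposition of a flow field.

    ``s_*`` are the projections of the unit flow direction onto the unit
    reference directions (cosine of the angle); ``p_*`` the proportions
    p = 1 − (2/π)·arccos(s) for s > 0 else 0; ``o_*`` the per-interval
    means of p weighted by observation count.
    """

    s_epi: np.ndarray
    s_conv: np.ndarray
    p_epi: np.ndarray
    p_conv: np.ndarray
    o_epi: np.ndarray
    o_conv: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval": np.arange(len(self.o_epi)),
                "o_epi": self.o_epi,
                "o_conv": self.o_conv,
            }
        )


def proportion_from_projection(s: np.ndarray) -> np.ndarray:
    """Map a projection s = cos(angle) to a movement proportion in [0, 1].

    p = 1 − (2/π)·arccos(s) for s > 0, else 0: a flow parallel to the
    reference scores 1, orthogonal or opposing flow scores 0, a 45° angle
    scores exactly 1/2.
    """
    s = np.clip(np.asarray(s, dtype=float), -1.0, 1.0)
    p = 1.0 - (2.0 / np.pi) * np.arccos(s)
    return np.where(s > 0, p, 0.0)


def decompose_movement(field: FlowField, refs: dict | None = None) -> DecompositionResult:
    """Decompose a flow field into epiboly and convergence proportions.

    Per populated site the unit flow direction is projected onto the unit
    reference directions; sites with a degenerate convergence reference
    (on the dorsal midline or the ventral seam) are excluded from the
    convergence summary. The per-interval summary o(t) is the mean of p
    across sites weighted by observation count — a convex combination of
    the site proportions.
    """
    if refs is None:
        refs = reference_directions_uv(field.grid)
    T = field.grid.n_intervals
    s_epi = np.einsum("tijk,ijk->tij", field.vectors, refs["epi"])
    s_conv = np.einsum("tijk,ijk->tij", field.vectors, refs["conv"])
    p_epi = proportion_from_projection(s_epi)
    p_conv = proportion_from_projection(s_conv)
    populated = field.weights > 0
    w = field.weights.astype(float)

    o_epi = np.full(T, np.nan)
    o_conv = np.full(T, np.nan)
    conv_ok = ~refs["conv_degenerate"]
    for t in range(T):
        m = populated[t]
        if m.any():
            o_epi[t] = np.sum(p_epi[t][m] * w[t][m]) / np.sum(w[t][m])
        mc = m & conv_ok
        if mc.any():
            o_conv[t] = np.sum(p_conv[t][mc] * w[t][mc]) / np.sum(w[t][mc])
    return DecompositionResult(
        s_epi=s_epi, s_conv=s_conv, p_epi=p_epi, p_conv=p_conv,
        o_epi=o_epi, o_conv=o_conv,
    )


def density_weighted_streamlines(
    field: FlowField,
    interval: int,
    step_fraction: float = 0.25,
    max_steps: int = 200,
    width_scale: float = 1.0,
) -> list:
    """Integrate streamlines through one interval of the field (RK2).

    Seeds are placed at all populated cell centres; integration steps a
    quarter cell width, looks directions up at the nearest cell, and
    terminates on leaving the grid or entering an empty cell. The width of
    each streamline is scaled by the start cell's observation count
    corrected for the Mercator area inflation — the count is divided by
    the cell's true surface area (projected area / sec²(phi) at the cell
    centre) — so widths reflect true surface densities, not projected
    ones: a uniformly populated sphere yields uniform widths across
    latitude rows.
    """
    grid = field.grid
    u_c, v_c = grid.cell_centers()
    du_cell = (grid.u_range[1] - grid.u_range[0]) / grid.n_u
    step = step_fraction * du_cell
    vecs = field.vectors[interval]
    weights = field.weights[interval]

    def sample(p):
        if not (grid.u_range[0] <= p[0] < grid.u_range[1]) or not (
            grid.v_range[0] <= p[1] < grid.v_range[1]
        ):
            return None
        iu, iv = grid.cell_of(np.array([p[0]]), np.array([p[1]]))
        if weights[iv[0], iu[0]] == 0:
            return None
        return vecs[iv[0], iu[0]]

    streamlines = []
    for iv in range(grid.n_v):
        phi_c = 2.0 * np.arctan(np.exp(v_c[iv])) - np.pi / 2.0
        correction = float(area_factor(phi_c))
        for iu in range(grid.n_u):
            if weights[iv, iu] == 0:
                continue
            pts = [np.array([u_c[iu], v_c[iv]])]
            p = pts[0].copy()
            for _ in range(max_steps):
                d1 = sample(p)
                if d1 is None:
                    break
                mid = p + 0.5 * step * d1
                d2 = sample(mid)
                if d2 is None:
                    break
                p = p + step * d2
                pts.append(p.copy())
            streamlines.append(
                {
                    "points": np.asarray(pts),
                    "width": width_scale * weights[iv, iu] * correction,
                    "start_cell": (iv, iu),
                    "count": int(weights[iv, iu]),
                }
            )
    return streamlines


# ---------------------------------------------------------------------------
# Local single-cell motion statistics


def _segment_motion(trackset: TrackSet, f0: int, window_frames: int):
    """End-to-end motion vectors over [f0, f0+window] per cell.

    Returns (start positions, end positions, cell ids) for cells sampled
    at both endpoints of the window.
    """
    p0, p1, ids = [], [], []
    for t in trackset:
        i0 = np.flatnonzero(t.frames == f0)
        i1 = np.flatnonzero(t.frames == f0 + window_frames)
        if i0.size and i1.size:
            p0.append(t.positions[i0[0]])
            p1.append(t.positions[i1[0]])
            ids.append(t.cell_id)
    if not p0:
        return np.empty((0, 3)), np.empty((0, 3)), []
    return np.asarray(p0), np.asarray(p1), ids


def _spherical_components(p0: np.ndarray, p1: np.ndarray, frame: SphericalFrame):
    """Physical (µm) motion components along r, parallels, meridians."""
    r0, th0, ph0, _ = to_spherical(p0, frame)
    r1, th1, ph1, _ = to_spherical(p1, frame)
    r_mid = 0.5 * (np.atleast_1d(r0) + np.atleast_1d(r1))
    dth = (np.atleast_1d(th1 - th0) + np.pi) % (2 * np.pi) - np.pi
    d_r = np.atleast_1d(r1 - r0)
    d_theta = r_mid * np.cos(0.5 * (np.atleast_1d(ph0) + np.atleast_1d(ph1))) * dth
    d_phi = r_mid * np.atleast_1d(ph1 - ph0)
    return np.column_stack([d_r, d_theta, d_phi])


def local_motion_correlation(
    tracks_a: TrackSet,
    tracks_b: TrackSet,
    frame: SphericalFrame,
    k: int = 6,
    window_s: float = 600.0,
    eval_every: int = 1,
) -> pd.DataFrame:
    """Spearman correlation of local motion with the neighbourhood mean.

    For each cell in A the end-to-end motion vector over a 10-minute
    window is compared against the mean motion of its k = 6 nearest
    neighbours in B (3D Euclidean search at the window start; the cell
    itself is excluded when A is B). Both vectors are split into
    spherical components (radial, along-parallel, along-meridian) and the
    per-frame Spearman rank correlation over all (cell, neighbourhood)
    pairs is reported per component. Zero-variance components are NaN.
    """
    window_frames = max(int(round(window_s / tracks_a.frame_interval)), 1)
    lo, hi = tracks_a.frame_range()
    same = tracks_a is tracks_b
    rows = []
    for f0 in range(lo, hi - window_frames + 1, eval_every):
        a0, a1, a_ids = _segment_motion(tracks_a, f0, window_frames)
        b0, b1, b_ids = _segment_motion(tracks_b, f0, window_frames)
        n_needed = k + 1 if same else k
        if len(a_ids) == 0 or len(b_ids) < n_needed:
            continue
        tree = cKDTree(b0)
        comp_a = _spherical_components(a0, a1, frame)
        comp_b = _spherical_components(b0, b1, frame)
        _, idx = tree.query(a0, k=n_needed)
        idx = np.atleast_2d(idx)
        if same:
            # drop the self-match (distance 0 to the identical point)
            neigh = np.empty((len(a_ids), k), dtype=int)
            for i in range(len(a_ids)):
                row = [j for j in idx[i] if b_ids[j] != a_ids[i]][:k]
                neigh[i] = row
        else:
            neigh = idx[:, :k]
        mean_b = comp_b[neigh].mean(axis=1)
        record = {"frame": f0, "n_pairs": len(a_ids)}
        for ci, name in enumerate(("r", "theta", "phi")):
            x, y = comp_a[:, ci], mean_b[:, ci]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                record[f"rho_{name}"] = np.nan
            else:
                record[f"rho_{name}"] = float(spearmanr(x, y).statistic)
        rows.append(record)
    return pd.DataFrame(rows)


def relative_layer_motion(
    meso: TrackSet,
    epi: TrackSet,
    frame: SphericalFrame,
    k: int = 6,
    window_s: float = 600.0,
    neighbor_cutoff: float = 100.0,
    grid: GridSpec | None = None,
    eval_every: int = 1,
) -> dict:
    """Residual motion of mesendoderm cells relative to nearby epiblast.

    Per mesendoderm cell and 10-minute window, the difference between its
    motion vector and the mean motion of its k = 6 nearest epiblast
    neighbours, in spherical components (µm). Cells without an epiblast
    neighbour within ``neighbor_cutoff`` µm are excluded (count reported).
    Residuals are averaged on the Mercator grid, and the radial components
    are summarized as a Gaussian-kernel density per time interval.

    Returns dict with ``residuals`` (tidy frame), ``grid_map`` (per-cell
    mean residual components and counts), ``radial_kde`` (per interval),
    and ``n_excluded``.
    """
    window_frames = max(int(round(window_s / meso.frame_interval)), 1)
    lo, hi = meso.frame_range()
    if grid is None:
        grid = GridSpec(frame_range=(lo, hi))
    rows = []
    n_excluded = 0
    for f0 in range(lo, hi - window_frames + 1, eval_every):
        m0, m1, m_ids = _segment_motion(meso, f0, window_frames)
        e0, e1, _ = _segment_motion(epi, f0, window_frames)
        if len(m_ids) == 0 or len(e0) < k:
            continue
        tree = cKDTree(e0)
        dists, idx = tree.query(m0, k=k)
        dists = np.atleast_2d(dists)
        idx = np.atleast_2d(idx)
        comp_m = _spherical_components(m0, m1, frame)
        comp_e = _spherical_components(e0, e1, frame)
        has_neighbor = dists[:, 0] <= neighbor_cutoff
        n_excluded += int(np.count_nonzero(~has_neighbor))
        mean_e = comp_e[idx].mean(axis=1)
        resid = comp_m - mean_e
        _, th, ph, _ = to_spherical(m0, frame)
        u, v = mercator_project(th, ph)
        for i in np.flatnonzero(has_neighbor):
            rows.append(
                {
                    "frame": f0,
                    "cell_id": m_ids[i],
                    "u": u[i],
                    "v": v[i],
                    "d_r": resid[i, 0],
                    "d_theta": resid[i, 1],
                    "d_phi": resid[i, 2],
                }
            )
    residuals = pd.DataFrame(rows)
    out = {"residuals": residuals, "n_excluded": n_excluded, "grid": grid}
    if residuals.empty:
        out["grid_map"] = None
        out["radial_kde"] = {}
        return out

    iu, iv = grid.cell_of(residuals["u"].to_numpy(), residuals["v"].to_numpy())
    it = grid.interval_of(residuals["frame"].to_numpy())
    sums = np.zeros((grid.n_intervals, grid.n_v, grid.n_u, 3))
    counts = np.zeros((grid.n_intervals, grid.n_v, grid.n_u), dtype=int)
    comp = residuals[["d_r", "d_theta", "d_phi"]].to_numpy()
    for ci in range(3):
        np.add.at(sums, (it, iv, iu, np.full_like(it, ci)), comp[:, ci])
    np.add.at(counts, (it, iv, iu), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        grid_map = np.where(counts[..., None] > 0, sums / np.maximum(counts, 1)[..., None], np.nan)
    out["grid_map"] = {"mean": grid_map, "count": counts}

    radial_kde = {}
    for t in range(grid.n_intervals):
        vals = comp[it == t, 0]
        if len(vals) >= 5 and np.ptp(vals) > 0:
            radial_kde[t] = gaussian_kde(vals)
    out["radial_kde"] = radial_kde
    return out
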