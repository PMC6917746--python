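"""Trajectory visualization exports: edge bundling, space-time plots,
and the interactive-viewer JSON.

Edge bundling pulls spatially compatible polylines toward each other so
that plotting tens of thousands of overlapping cell tracks reveals the
main migration streams instead of a uniform hairball. The implementation
follows the force-directed formulation: polylines are resampled to a
common vertex count, pairwise compatibility is scored by angle, scale,
position and visibility of the end-to-end chords, and interior vertices
move under polyline-internal spring forces plus attraction between
compatible pairs over several cycles with a halving step size. Endpoints
never move. Bundling is applied within spatial pre-clusters only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import SphericalFrame, mercator_project, to_spherical
from .tracks import TrackSet

__all__ = [
    "BundleParams",
    "resample_polyline",
    "edge_bundle",
    "export_spacetime",
    "export_web_json",
    "read_web_json",
]


@dataclass
class BundleParams:
    """Force-directed bundling schedule.

    ``n_cycles`` cycles of ``iterations`` relaxation steps each; the step
    size halves and the attraction stiffens every cycle (vertex count
    fixed after initial resampling to ``n_vertices``). Pairs bundle only
    if their chord compatibility reaches ``compatibility_threshold``.
    ``transparency`` is the rendering default (0.95: heavy overplotting
    still shows the main paths plus outlier silhouettes).
    """

    n_cycles: int = 6
    iterations: int = 30
    step_size: float = 0.04
    compatibility_threshold: float = 0.6
    n_vertices: int = 33
    spring_constant: float = 0.5
    transparency: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.compatibility_threshold <= 1.0:
            raise ValueError("compatibility_threshold must be in [0, 1]")


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to n vertices, uniform in arc length."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] == 1:
        return np.repeat(pts, n, axis=0)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(pts[:1], n, axis=0)
    targets = np.linspace(0.0, s[-1], n)
    out = np.empty((n, pts.shape[1]))
    for d in range(pts.shape[1]):
        out[:, d] = np.interp(targets, s, pts[:, d])
    return out


def _chord_compatibility(p: np.ndarray, q: np.ndarray) -> float:
    """Holten-style compatibility of two polylines from their chords."""
    cp = p[-1] - p[0]
    cq = q[-1] - q[0]
    lp, lq = np.linalg.norm(cp), np.linalg.norm(cq)
    if lp == 0 or lq == 0:
        return 0.0
    c_angle = abs(float(cp @ cq)) / (lp * lq)
    l_avg = 0.5 * (lp + lq)
    c_scale = 2.0 / (l_avg / min(lp, lq) + max(lp, lq) / l_avg)
    mid_p = 0.5 * (p[0] + p[-1])
    mid_q = 0.5 * (q[0] + q[-1])
    c_pos = l_avg / (l_avg + float(np.linalg.norm(mid_p - mid_q)))

    def visibility(a0, a1, b0, b1):
        d = a1 - a0
        denom = float(d @ d)
        if denom == 0:
            return 0.0
        t0 = float((b0 - a0) @ d) / denom
        t1 = float((b1 - a0) @ d) / denom
        i0 = a0 + t0 * d
        i1 = a0 + t1 * d
        im = 0.5 * (i0 + i1)
        bm = 0.5 * (b0 + b1)
        seg = float(np.linalg.norm(i1 - i0))
        if seg == 0:
            return 0.0
        return max(0.0, 1.0 - 2.0 * float(np.linalg.norm(bm - im)) / seg)

    c_vis = min(
        visibility(p[0], p[-1], q[0], q[-1]), visibility(q[0], q[-1], p[0], p[-1])
    )
    return c_angle * c_scale * c_pos * c_vis


def _bundle_group(lines: list, params: BundleParams) -> list:
    n = len(lines)
    if n < 2:
        return [l.copy() for l in lines]
    comp = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp[i, j] = comp[j, i] = _chord_compatibility(lines[i], lines[j])
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if comp[i, j] >= params.compatibility_threshold
    ]
    out = [l.copy() for l in lines]
    step = params.step_size
    for _ in range(params.n_cycles):
        for _ in range(params.iterations):
            forces = [np.zeros_like(l) for l in out]
            for l, f in zip(out, forces):
                # spring: pull interior vertices toward neighbour midpoints
                f[1:-1] += params.spring_constant * (l[2:] + l[:-2] - 2.0 * l[1:-1])
            for i, j in pairs:
                delta = out[j] - out[i]
                dist = np.linalg.norm(delta, axis=1, keepdims=True)
                attraction = comp[i, j] * delta / np.maximum(dist, 1e-9)
                forces[i][1:-1] += attraction[1:-1]
                forces[j][1:-1] -= attraction[1:-1]
            for l, f in zip(out, forces):
                l[1:-1] += step * f[1:-1]
        step *= 0.5
    return out


def edge_bundle(
    polylines: list,
    params: BundleParams | None = None,
    n_clusters: int = 1,
    random_state: int = 0,
) -> list:
    """Bundle spatially compatible polylines.

    Polylines (arrays of shape (m, d), d = 2 or 3) are resampled to
    ``params.n_vertices`` vertices, pre-clustered into ``n_clusters``
    spatial groups (k-means on resampled coordinates) and bundled within
    each group. Endpoints are pinned; the polyline count is preserved;
    the result is deterministic for a given input order and parameters.
    A single polyline is returned unchanged (after resampling).
    """
    if not polylines:
        raise ValueError("need at least one polyline")
    params = params or BundleParams()
    lines = [resample_polyline(p, params.n_vertices) for p in polylines]
    if len(lines) == 1:
        return lines
    if n_clusters > 1:
        from sklearn.cluster import KMeans

        X = np.stack([l.ravel() for l in lines])
        labels = KMeans(
            n_clusters=min(n_clusters, len(lines)), n_init=10, random_state=random_state
        ).fit_predict(X)
    else:
        labels = np.zeros(len(lines), dtype=int)
    out: list = [None] * len(lines)
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        bundled = _bundle_group([lines[i] for i in members], params)
        for i, b in zip(members, bundled):
            out[i] = b
    return out


def export_spacetime(
    trackset: TrackSet, frame: SphericalFrame, reference_point: np.ndarray | None = None
) -> dict:
    """Mercator space-time polylines: per track (u, v, t_hpf) vertices.

    Includes a vertical reference line — the space-time track of a
    stationary object — at ``reference_point`` (default: the dorsal
    equator point of the frame).
    """
    tracks_out = []
    for t in trackset:
        _, theta, phi, _ = to_spherical(t.positions, frame)
        u, v = mercator_project(theta, phi)
        tracks_out.append(
            {
                "cell_id": int(t.cell_id),
                "u": np.asarray(u),
                "v": np.asarray(v),
                "t_hpf": trackset.time_hpf(t.frames),
            }
        )
    if reference_point is None:
        reference_point = frame.center + frame.radius * frame.dorsal_axis
    _, th_ref, ph_ref, _ = to_spherical(np.asarray(reference_point), frame)
    u_ref, v_ref = mercator_project(np.array([th_ref]), np.array([ph_ref]))
    lo, hi = trackset.frame_range()
    t_ref = trackset.time_hpf(np.array([lo, hi]))
    return {
        "tracks": tracks_out,
        "reference": {
            "u": np.array([u_ref[0], u_ref[0]]),
            "v": np.array([v_ref[0], v_ref[0]]),
            "t_hpf": t_ref,
        },
    }


def export_web_json(
    trackset: TrackSet,
    frame: SphericalFrame,
    path: str | Path | None = None,
    downsample_factor: int = 5,
    expression_key: str = "mezzo",
) -> dict:
    """Viewer JSON: decimated Mercator trajectories with expression.

    Each track becomes ``[[u, v, t_hpf, expr], ...]`` with every
    ``downsample_factor``-th vertex kept (endpoints always preserved; a
    factor of 1 is lossless). Expression values outside [0, 1] are
    clipped with a warning. The schema round-trips through
    :func:`read_web_json`.
    """
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    tracks_out = []
    clipped = False
    for t in trackset:
        n = len(t)
        keep = np.arange(0, n, downsample_factor)
        if keep[-1] != n - 1:
            keep = np.append(keep, n - 1)
        _, theta, phi, _ = to_spherical(t.positions[keep], frame)
        u, v = mercator_project(theta, phi)
        expr = np.asarray(
            t.expression.get(expression_key, np.zeros(n)), dtype=float
        )[keep]
        if np.any((expr < 0) | (expr > 1)):
            clipped = True
            expr = np.clip(expr, 0.0, 1.0)
        t_hpf = trackset.time_hpf(t.frames[keep])
        tracks_out.append(
            {
                "cell_id": int(t.cell_id),
                "points": np.column_stack(
                    [np.atleast_1d(u), np.atleast_1d(v), t_hpf, expr]
                ).tolist(),
            }
        )
    if clipped:
        warnings.warn("expression values outside [0, 1] were clipped")
    doc = {
        "schema": "embryoflow-viewer/1",
        "downsample_factor": int(downsample_factor),
        "expression": expression_key,
        "tracks": tracks_out,
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc))
    return doc


def read_web_json(path: str | Path) -> dict:
    """Validating reader for the viewer JSON schema."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "embryoflow-viewer/1":
        raise ValueError(f"unknown schema: {doc.get('schema')!r}")
    for tr in doc["tracks"]:
        pts = np.asarray(tr["points"], dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 4:
            raise ValueError(f"track {tr.get('cell_id')}: points must be (n, 4)")
        if np.any(np.diff(pts[:, 2]) < 0):
            raise ValueError(f"track {tr.get('cell_id')}: time must be non-decreasing")
        if np.any((pts[:, 3] < 0) | (pts[:, 3] > 1)):
            raise ValueError(f"track {tr.get('cell_id')}: expression outside [0, 1]")
    return doc
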