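"""Embryo-centric spherical coordinates and map projections.

The embryo is modelled as a sphere. Positions are expressed in a
:class:`SphericalFrame` whose polar axis runs through the animal pole and
whose zero meridian passes through the dorsal midline (the shield):

* ``r`` — radial distance from the embryo centre (µm),
* ``theta`` — longitude in (−π, π], 0 at the dorsal midline; motion along
  parallels (constant latitude) corresponds to dorsal convergence,
* ``phi`` — latitude in [−π/2, π/2], −π/2 at the animal pole and +π/2 at
  the vegetal pole; motion along meridians corresponds to epiboly.

A conformal Mercator projection maps the sphere to the plane for gridded
flow-field analysis; areas inflate by sec²(phi), which callers must divide
out when densities matter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import svd

__all__ = [
    "SphericalFrame",
    "ReferenceFields",
    "DEFAULT_PHI_MAX",
    "to_spherical",
    "to_cartesian",
    "align_positions",
    "rotation_from_landmarks",
    "mercator_project",
    "mercator_unproject",
    "area_factor",
    "reference_fields",
]

#: Latitude clamp for the Mercator projection: 85° keeps v finite.
DEFAULT_PHI_MAX = np.deg2rad(85.0)


@dataclass(frozen=True)
class SphericalFrame:
    """Embryo-centric coordinate frame.

    Parameters
    ----------
    center : (3,) array
        Embryo centre in stage coordinates (µm).
    radius : float
        Nominal embryo radius (µm).
    animal_axis : (3,) unit vector
        Points from the centre toward the animal pole.
    dorsal_axis : (3,) unit vector
        Orthogonal to ``animal_axis``; defines longitude zero (shield).
    """

    center: np.ndarray
    radius: float
    animal_axis: np.ndarray
    dorsal_axis: np.ndarray

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float).reshape(3)
        a = np.asarray(self.animal_axis, dtype=float).reshape(3)
        d = np.asarray(self.dorsal_axis, dtype=float).reshape(3)
        if not np.all(np.isfinite(center)):
            raise ValueError("frame center must be finite")
        if self.radius <= 0:
            raise ValueError(f"frame radius must be positive, got {self.radius}")
        if abs(np.linalg.norm(a) - 1.0) > 1e-9:
            raise ValueError("animal_axis must be a unit vector")
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("dorsal_axis must be a unit vector")
        if abs(float(a @ d)) > 1e-9:
            raise ValueError("animal_axis and dorsal_axis must be orthogonal")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "animal_axis", a)
        object.__setattr__(self, "dorsal_axis", d)

    @property
    def lateral_axis(self) -> np.ndarray:
        """Third basis vector, animal × dorsal (right-handed)."""
        return np.cross(self.animal_axis, self.dorsal_axis)

    @classmethod
    def canonical(cls, radius: float = 350.0) -> "SphericalFrame":
        """Frame at the origin with animal pole on +z, dorsal on +x."""
        return cls(
            center=np.zeros(3),
            radius=radius,
            animal_axis=np.array([0.0, 0.0, 1.0]),
            dorsal_axis=np.array([1.0, 0.0, 0.0]),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "center": self.center.tolist(),
                "radius": float(self.radius),
                "animal_axis": self.animal_axis.tolist(),
                "dorsal_axis": self.dorsal_axis.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SphericalFrame":
        d = json.loads(text)
        return cls(
            center=np.array(d["center"]),
            radius=float(d["radius"]),
            animal_axis=np.array(d["animal_axis"]),
            dorsal_axis=np.array(d["dorsal_axis"]),
        )


def _frame_basis(frame: SphericalFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return frame.animal_axis, frame.dorsal_axis, frame.lateral_axis


def to_spherical(
    points: np.ndarray, frame: SphericalFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Convert Cartesian positions (µm) to embryo-centric (r, theta, phi).

    Returns
    -------
    r, theta, phi : arrays
        Radius (µm), longitude in (−π, π], latitude in [−π/2, π/2].
    degenerate : bool array
        True where the point coincides with the centre (angles undefined,
        reported as 0).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    a, d, e = _frame_basis(frame)
    q = p - frame.center
    r = np.linalg.norm(q, axis=-1)
    degenerate = r == 0.0
    safe_r = np.where(degenerate, 1.0, r)
    # phi = -pi/2 at the animal pole (q parallel to animal_axis)
    sin_phi = np.clip(-(q @ a) / safe_r, -1.0, 1.0)
    phi = np.arcsin(sin_phi)
    theta = np.arctan2(q @ e, q @ d)
    theta = np.where(degenerate, 0.0, theta)
    phi = np.where(degenerate, 0.0, phi)
    if np.ndim(points) == 1:
        return r[0], theta[0], phi[0], bool(degenerate[0])
    return r, theta, phi, degenerate


def to_cartesian(
    r: np.ndarray, theta: np.ndarray, phi: np.ndarray, frame: SphericalFrame
) -> np.ndarray:
    """Inverse of :func:`to_spherical`."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    a, d, e = _frame_basis(frame)
    cos_phi = np.cos(phi)
    q = (
        np.multiply.outer(r * cos_phi * np.cos(theta), d)
        + np.multiply.outer(r * cos_phi * np.sin(theta), e)
        - np.multiply.outer(r * np.sin(phi), a)
    )
    return frame.center + q


def align_positions(
    positions: np.ndarray, center: np.ndarray, rotation: np.ndarray
) -> np.ndarray:
    """Centre positions on ``center`` then apply an orthonormal rotation.

    Replaces the manual alignment to a reference embryo with an explicit
    transform; estimate ``rotation`` with :func:`rotation_from_landmarks`.
    Pairwise distances are preserved.
    """
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {rotation.shape}")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-9):
        raise ValueError("rotation is not orthonormal (R @ R.T != I)")
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-9):
        raise ValueError(
            f"rotation determinant must be +1, got {np.linalg.det(rotation):.6f}"
        )
    q = np.asarray(positions, dtype=float) - np.asarray(center, dtype=float)
    return q @ rotation.T


def rotation_from_landmarks(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation mapping centred source landmarks onto target.

    Orthogonal Procrustes with a proper-rotation constraint (Kabsch). At
    least three non-collinear landmark pairs are required.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.shape[0] < 3:
        raise ValueError("need >= 3 landmark pairs of identical shape")
    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    h = src_c.T @ tgt_c
    if np.linalg.matrix_rank(h) < 2:
        raise ValueError("landmarks are collinear; rotation is underdetermined")
    u, _, vt = svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, sign])
    return vt.T @ diag @ u.T


class ClampLog:
    """Counts latitude values clipped by the Mercator clamp."""

    def __init__(self) -> None:
        self.n_clamped = 0
        self.n_total = 0

    def record(self, clamped_mask: np.ndarray) -> None:
        self.n_clamped += int(np.count_nonzero(clamped_mask))
        self.n_total += int(np.size(clamped_mask))


def mercator_project(
    theta: np.ndarray,
    phi: np.ndarray,
    phi_max: float = DEFAULT_PHI_MAX,
    clamp_log: ClampLog | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Conformal Mercator projection u = theta, v = ln tan(π/4 + phi/2).

    Latitudes beyond ``phi_max`` are clamped (and counted in ``clamp_log``
    if given) so v stays finite near the poles.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    clamped = np.abs(phi) > phi_max
    if clamp_log is not None:
        clamp_log.record(clamped)
    phi_c = np.clip(phi, -phi_max, phi_max)
    # arctanh(sin phi) == ln tan(pi/4 + phi/2), exact (and odd) at phi = 0
    v = np.arctanh(np.sin(phi_c))
    return theta + 0.0, v


def mercator_unproject(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse Mercator: theta = u, phi = 2·atan(e^v) − π/2."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    phi = np.arcsin(np.tanh(v))
    return u + 0.0, phi


def area_factor(phi: np.ndarray) -> np.ndarray:
    """Mercator area inflation sec²(phi).

    A patch of true surface area A at latitude phi occupies projected
    area A·sec²(phi). Sample counts collected on the projection are
    converted to true surface densities by dividing by the patch's true
    area, i.e. multiplying the count per projected area by this factor.
    """
    return 1.0 / np.cos(np.asarray(phi, dtype=float)) ** 2


def corrected_band_counts(
    phi_samples: np.ndarray, n_bands: int, phi_max: float = 1.2
) -> tuple[np.ndarray, np.ndarray]:
    """Latitude-band sample counts corrected for Mercator area inflation.

    Samples are binned in equal-width Mercator-v bands over
    [−phi_max, phi_max]; each band count is converted to a count per unit
    true surface area using ``area_factor`` at the band centre. For
    uniformly distributed points on the sphere the corrected counts are
    uniform up to Monte-Carlo noise. Returns (corrected counts,
    Monte-Carlo standard deviations on the same scale).
    """
    phi_samples = np.asarray(phi_samples, dtype=float)
    keep = np.abs(phi_samples) < phi_max
    _, v = mercator_project(np.zeros(np.count_nonzero(keep)), phi_samples[keep])
    v_max = float(np.arctanh(np.sin(phi_max)))
    edges = np.linspace(-v_max, v_max, n_bands + 1)
    counts, _ = np.histogram(v, bins=edges)
    centers_phi = np.arcsin(np.tanh(0.5 * (edges[:-1] + edges[1:])))
    factor = area_factor(centers_phi)
    return counts * factor, np.sqrt(np.maximum(counts, 1.0)) * factor


@dataclass(frozen=True)
class ReferenceFields:
    """Unit reference vector fields for the two morphogenetic movements.

    ``epi(x)`` points along meridians toward the vegetal pole (pure
    epiboly); ``conv(x)`` points along parallels toward the dorsal midline
    theta = 0 (pure convergence). Both are tangent to the sphere. ``epi``
    is undefined at the poles and ``conv`` on the meridians theta ∈ {0, π};
    there a zero vector is returned and the degeneracy flagged.
    """

    frame: SphericalFrame

    def epi(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        _, theta, phi, degen = _angles(points, self.frame)
        a, d, e = _frame_basis(self.frame)
        # d/dphi of the embedding, normalized (norm = r)
        vec = (
            -np.multiply.outer(np.sin(phi) * np.cos(theta), d)
            - np.multiply.outer(np.sin(phi) * np.sin(theta), e)
            - np.multiply.outer(np.cos(phi), a)
        )
        at_pole = np.isclose(np.abs(phi), np.pi / 2.0) | degen
        vec[at_pole] = 0.0
        return vec, at_pole

    def conv(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        _, theta, phi, degen = _angles(points, self.frame)
        a, d, e = _frame_basis(self.frame)
        # d/dtheta of the embedding has norm r·cos(phi); unit tangent:
        east = -np.multiply.outer(np.sin(theta), d) + np.multiply.outer(
            np.cos(theta), e
        )
        sign = -np.sign(theta)  # toward decreasing |theta|
        vec = east * sign[..., None]
        degenerate = (
            np.isclose(theta, 0.0)
            | np.isclose(np.abs(theta), np.pi)
            | np.isclose(np.abs(phi), np.pi / 2.0)
            | degen
        )
        vec[degenerate] = 0.0
        return vec, degenerate


def _angles(points, frame):
    p = np.atleast_2d(np.asarray(points, dtype=float))
    r, theta, phi, degen = to_spherical(p, frame)
    return r, theta, phi, degen


def reference_fields(frame: SphericalFrame) -> ReferenceFields:
    """Construct the pure-epiboly / pure-convergence reference fields."""
    return ReferenceFields(frame)
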