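"""Image-side preprocessing for shell-acquired light-sheet stacks.

Covers the pipeline from a transmission stack to tracked, layer-separated
nuclei:

* plane-wise difference-of-Gaussians focus filtering,
* an EM-style two-sphere fit locating the embryo and chorion surfaces,
* a spherical shell mask with a compact masked storage format (one index
  table shared by all timepoints, per-timepoint intensity blobs),
* nucleus detection by smoothed local maxima with a saddle-prominence
  criterion,
* rigid time-lapse registration by Iterative Closest Point,
* channel subtraction separating germlayer nuclei, and
* windowed expression readout with global min-max normalization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "VoxelStack",
    "SphereFit",
    "ShellMask",
    "ShellMaskStore",
    "dog_filter",
    "fit_two_spheres",
    "shell_mask",
    "masked_write",
    "masked_read",
    "detect_nuclei",
    "rigid_register",
    "subtract_channels",
    "assign_layers",
    "window_means",
    "expression_readout",
]


@dataclass
class VoxelStack:
    """A 3D image with voxel spacing metadata.

    ``data`` is indexed (z, y, x); ``voxel_size`` is µm per axis, either a
    scalar (isotropic) or a (z, y, x) triple.
    """

    data: np.ndarray
    voxel_size: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D, got shape {self.data.shape}")
        vs = np.asarray(self.voxel_size, dtype=float)
        if vs.ndim == 0:
            vs = np.full(3, float(vs))
        if vs.shape != (3,) or np.any(vs <= 0):
            raise ValueError("voxel_size must be positive, scalar or length-3")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def physical_extent(self) -> np.ndarray:
        """Physical size per axis in µm (z, y, x)."""
        return np.asarray(self.data.shape) * self.voxel_size

    def voxel_centers_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis coordinate vectors of voxel centres in µm."""
        return tuple(
            (np.arange(n) + 0.5) * s for n, s in zip(self.data.shape, self.voxel_size)
        )

    def save_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(
            str(path),
            self.data,
            metadata={
                "voxel_size_um": self.voxel_size.tolist(),
                "channel": self.channel,
            },
        )

    @classmethod
    def load_tiff(cls, path: str | Path) -> "VoxelStack":
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        return cls(
            data=data,
            voxel_size=np.asarray(meta.get("voxel_size_um", 1.0)),
            channel=str(meta.get("channel", "")),
        )


@dataclass
class SphereFit:
    """Result of fitting one sphere model to foreground voxels."""

    center: np.ndarray  # µm, (z, y, x)
    radius: float
    n_inliers: int = 0
    converged: bool = False
    iterations: int = 0
    message: str = ""

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.converged and self.radius <= 0:
            raise ValueError("converged fit must have positive radius")


# ---------------------------------------------------------------------------
# Focus filtering


def dog_filter(stack: VoxelStack, sigma: float = 1.0) -> VoxelStack:
    """Plane-wise difference-of-Gaussians focus filter.

    I' = |I − G_sigma * I| with a 2D Gaussian applied per z-plane; in-focus
    edges (high local contrast) survive, defocused regions vanish. The
    default sigma of 1 voxel matches routine transmission-stack use.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    data = np.asarray(stack.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("stack contains non-finite voxels")
    blurred = ndimage.gaussian_filter(data, sigma=(0.0, sigma, sigma))
    return VoxelStack(np.abs(data - blurred), stack.voxel_size, stack.channel)


# ---------------------------------------------------------------------------
# Two-sphere EM fit


def _algebraic_sphere_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares (Kåsa) sphere fit; raises on < 4 non-coplanar points."""
    if points.shape[0] < 4:
        raise ValueError("sphere fit needs at least 4 points")
    a = np.column_stack([2.0 * points, np.ones(points.shape[0])])
    if np.linalg.matrix_rank(a) < 4:
        raise ValueError("sphere fit needs non-coplanar points")
    b = np.sum(points**2, axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(max(sol[3] + center @ center, 0.0)))
    return center, radius


def _surface_sse(points: np.ndarray, center: np.ndarray, radius: float) -> float:
    d = np.linalg.norm(points - center, axis=1)
    return float(np.sum((d - radius) ** 2))


def _refine_geometric(
    points: np.ndarray, center: np.ndarray, radius: float, n_steps: int = 5
) -> tuple[np.ndarray, float]:
    """A few fixed-point steps minimizing the geometric surface distance."""
    c = center.copy()
    for _ in range(n_steps):
        diff = points - c
        d = np.linalg.norm(diff, axis=1)
        d = np.where(d == 0, 1e-12, d)
        radius = float(d.mean())
        # gradient step of sum (d - R)^2 wrt c has closed-form fixed point
        c = points.mean(axis=0) - radius * (diff / d[:, None]).mean(axis=0)
    return c, float(np.linalg.norm(points - c, axis=1).mean())


def fit_two_spheres(
    filtered: VoxelStack,
    threshold: float | None = None,
    init_radii: tuple[float, float] = (350.0, 550.0),
    max_iter: int = 50,
    threshold_percentile: float = 99.5,
) -> tuple[SphereFit, SphereFit]:
    """EM-style fit of two concentric-ish spheres to foreground voxels.

    After 3×3 plane-wise median filtering, voxels above ``threshold``
    (default: the ``threshold_percentile`` of the filtered image — the
    foreground cut is data dependent and should be tuned per acquisition)
    are treated as surface samples. Both sphere models start at the image
    centre with the given initial radii (embryo ≈ 350 µm, chorion ≈ 550 µm).
    The E-step assigns each voxel to the sphere whose *surface* is nearest
    (ties to the smaller sphere); the M-step refits each sphere by
    least squares. Iterates until assignments are stable or ``max_iter``.
    The summed squared surface distance never increases: an M-step that
    would worsen it is rejected for that sphere.

    Returns the two fits ordered by radius ascending (embryo first).
    """
    med = ndimage.median_filter(np.asarray(filtered.data, dtype=float), size=(1, 3, 3))
    if threshold is None:
        threshold = float(np.percentile(med, threshold_percentile))
    fg = np.argwhere(med > threshold)
    if fg.shape[0] < 20:
        raise ValueError(
            f"threshold {threshold:g} yields only {fg.shape[0]} foreground voxels; "
            "need >= 10 per sphere"
        )
    points = (fg + 0.5) * filtered.voxel_size  # µm, (z, y, x)

    center0 = 0.5 * filtered.physical_extent()
    centers = [center0.copy(), center0.copy()]
    radii = sorted(float(r) for r in init_radii)
    fits_ok = [True, True]
    message = ["", ""]
    prev_assign = None
    prev_sse = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        dists = np.stack(
            [
                np.abs(np.linalg.norm(points - c, axis=1) - r)
                for c, r in zip(centers, radii)
            ],
            axis=1,
        )
        assign = np.argmin(dists, axis=1)  # argmin → index 0 (embryo) on ties
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        prev_assign = assign
        for k in range(2):
            pts_k = points[assign == k]
            if pts_k.shape[0] < 4:
                fits_ok[k] = False
                message[k] = f"empty/degenerate assignment at iteration {it}"
                continue
            try:
                c_new, r_new = _algebraic_sphere_fit(pts_k)
                c_new, r_new = _refine_geometric(pts_k, c_new, r_new)
            except ValueError as exc:
                fits_ok[k] = False
                message[k] = f"{exc} at iteration {it}"
                continue
            if _surface_sse(pts_k, c_new, r_new) <= _surface_sse(
                pts_k, centers[k], radii[k]
            ):
                centers[k], radii[k] = c_new, r_new
        sse = sum(
            _surface_sse(points[assign == k], centers[k], radii[k]) for k in range(2)
        )
        if sse > prev_sse + 1e-6:  # safeguarded: should not happen
            break
        prev_sse = sse

    counts = [int(np.sum(prev_assign == k)) for k in range(2)]
    fits = [
        SphereFit(
            center=centers[k],
            radius=radii[k],
            n_inliers=counts[k],
            converged=fits_ok[k],
            iterations=it,
            message=message[k],
        )
        for k in range(2)
    ]
    fits.sort(key=lambda f: f.radius)
    return fits[0], fits[1]


# ---------------------------------------------------------------------------
# Shell mask and masked storage format


@dataclass
class ShellMask:
    """Spherical band selecting voxels near the fitted embryo surface.

    ``index_table`` holds the linear (z-major C-order) voxel indices of
    the band, strictly increasing; it is stored once and shared by all
    timepoints of a masked acquisition.
    """

    sphere: SphereFit
    band: tuple  # (inner, outer) signed distance to surface, µm
    stack_shape: tuple
    voxel_size: np.ndarray
    index_table: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.band[0] >= self.band[1] and not (self.band[0] == self.band[1]):
            raise ValueError("band inner must be < outer")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(-1)
        if self.voxel_size.shape == (1,):
            self.voxel_size = np.full(3, self.voxel_size[0])
        if self.index_table is not None:
            self.index_table = np.asarray(self.index_table, dtype=np.uint32)
            if self.index_table.size and np.any(np.diff(self.index_table.astype(np.int64)) <= 0):
                raise ValueError("index table must be strictly increasing")

    @property
    def n_voxels(self) -> int:
        return 0 if self.index_table is None else int(self.index_table.size)

    def fraction(self) -> float:
        return self.n_voxels / float(np.prod(self.stack_shape))


def shell_mask(
    fit: SphereFit,
    band: tuple = (-150.0, 150.0),
    stack_shape: tuple = None,
    voxel_size: float | np.ndarray = 1.0,
) -> ShellMask:
    """Build the shell mask: voxels whose signed distance to the fitted
    sphere surface lies inside ``band`` (default a 300 µm thick shell,
    ±150 µm around the surface).
    """
    if not fit.converged:
        raise ValueError("sphere fit did not converge; refusing to build mask")
    vs = np.asarray(voxel_size, dtype=float)
    if vs.ndim == 0:
        vs = np.full(3, float(vs))
    zc, yc, xc = (
        (np.arange(n) + 0.5) * s for n, s in zip(stack_shape, vs)
    )
    dz = zc - fit.center[0]
    dy = yc - fit.center[1]
    dx = xc - fit.center[2]
    dist = np.sqrt(
        dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
    )
    signed = dist - fit.radius
    inside = (signed >= band[0]) & (signed < band[1])
    idx = np.flatnonzero(inside.ravel(order="C")).astype(np.uint32)
    return ShellMask(
        sphere=fit, band=tuple(band), stack_shape=tuple(stack_shape),
        voxel_size=vs, index_table=idx,
    )


class ShellMaskStore:
    """Masked acquisition storage: JSON header + binary index + blobs.

    Layout under a base directory::

        header.json   shape, dtype, band, sphere, endianness
        index.idx     uint32 little-endian linear voxel indices (once)
        t_0000.blob   concatenated intensities of masked voxels, frame 0
        ...

    Write∘read is lossless on masked voxels; unmasked voxels are
    reconstituted with a declared fill value.
    """

    def __init__(self, base: str | Path, mask: ShellMask, dtype: str = "uint16"):
        self.base = Path(base)
        self.mask = mask
        self.dtype = np.dtype(dtype)

    def save_header(self) -> None:
        self.base.mkdir(parents=True, exist_ok=True)
        header = {
            "shape": list(self.mask.stack_shape),
            "dtype": self.dtype.name,
            "endianness": "little",
            "band": list(self.mask.band),
            "voxel_size_um": self.mask.voxel_size.tolist(),
            "sphere": {
                "center_um": self.mask.sphere.center.tolist(),
                "radius_um": float(self.mask.sphere.radius),
            },
            "n_voxels": self.mask.n_voxels,
        }
        (self.base / "header.json").write_text(json.dumps(header, indent=1))
        self.mask.index_table.astype("<u4").tofile(self.base / "index.idx")

    @classmethod
    def open(cls, base: str | Path) -> "ShellMaskStore":
        base = Path(base)
        header = json.loads((base / "header.json").read_text())
        idx = np.fromfile(base / "index.idx", dtype="<u4")
        fit = SphereFit(
            center=np.asarray(header["sphere"]["center_um"]),
            radius=float(header["sphere"]["radius_um"]),
            converged=True,
        )
        mask = ShellMask(
            sphere=fit,
            band=tuple(header["band"]),
            stack_shape=tuple(header["shape"]),
            voxel_size=np.asarray(header["voxel_size_um"]),
            index_table=idx,
        )
        return cls(base, mask, dtype=header["dtype"])

    def _blob_path(self, t: int) -> Path:
        return self.base / f"t_{t:04d}.blob"

    def write_timepoint(self, stack: VoxelStack, t: int) -> None:
        if tuple(stack.data.shape) != tuple(self.mask.stack_shape):
            raise ValueError(
                f"stack shape {stack.data.shape} != mask shape {self.mask.stack_shape}"
            )
        flat = np.ascontiguousarray(stack.data).ravel(order="C")
        blob = flat[self.mask.index_table.astype(np.int64)].astype(
            self.dtype.newbyteorder("<")
        )
        blob.tofile(self._blob_path(t))

    def read_timepoint(self, t: int, fill=0) -> VoxelStack:
        blob = np.fromfile(self._blob_path(t), dtype=self.dtype.newbyteorder("<"))
        if blob.size != self.mask.n_voxels:
            raise ValueError(
                f"corrupt blob: {blob.size} values but index table has "
                f"{self.mask.n_voxels}"
            )
        flat = np.full(int(np.prod(self.mask.stack_shape)), fill, dtype=self.dtype)
        flat[self.mask.index_table.astype(np.int64)] = blob
        return VoxelStack(
            flat.reshape(self.mask.stack_shape), self.mask.voxel_size
        )


def masked_write(stack: VoxelStack, mask: ShellMask, base: str | Path) -> None:
    """Write one stack through a shell mask (header + index + one blob)."""
    store = ShellMaskStore(base, mask, dtype=str(stack.data.dtype))
    store.save_header()
    store.write_timepoint(stack, 0)


def masked_read(base: str | Path, fill=0) -> VoxelStack:
    """Read back a single-timepoint masked stack; unmasked voxels = fill."""
    return ShellMaskStore.open(base).read_timepoint(0, fill=fill)


# ---------------------------------------------------------------------------
# Nucleus detection


def detect_nuclei(
    stack: VoxelStack,
    sigma: float = 1.0,
    threshold: float = 150.0,
    min_prominence: float = 30.0,
) -> np.ndarray:
    """Detect nucleus centres as prominent smoothed local maxima.

    The stack is Gaussian-smoothed (sigma voxels), then local maxima above
    ``threshold`` are kept if they rise at least ``min_prominence`` gray
    levels above the saddle to any retained neighbouring maximum
    (h-maxima). Returns an (n, 4) array of (z, y, x) in µm plus peak
    intensity, sorted by intensity descending.
    """
    from skimage.morphology import h_maxima

    data = np.asarray(stack.data, dtype=float)
    smoothed = ndimage.gaussian_filter(data, sigma=sigma)
    peaks_mask = h_maxima(smoothed, min_prominence)
    labels, n_lab = ndimage.label(peaks_mask)
    if n_lab == 0:
        return np.empty((0, 4))
    out = []
    for lab in range(1, n_lab + 1):
        coords = np.argwhere(labels == lab)
        vals = smoothed[tuple(coords.T)]
        peak = coords[np.argmax(vals)]
        inten = float(vals.max())
        if inten > threshold:
            pos = (peak + 0.5) * stack.voxel_size
            out.append([pos[0], pos[1], pos[2], inten])
    if not out:
        return np.empty((0, 4))
    arr = np.asarray(out)
    return arr[np.argsort(-arr[:, 3])]


# ---------------------------------------------------------------------------
# Rigid time-lapse registration (ICP)


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping src onto dst, det(R)=+1."""
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    h = src_c.T @ dst_c
    if np.linalg.matrix_rank(h) < 2:
        raise ValueError("degenerate geometry: correspondence matrix rank < 2")
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = dst.mean(axis=0) - r @ src.mean(axis=0)
    return r, t


def rigid_register(
    points_t: np.ndarray,
    points_t1: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
    trim_fraction: float = 0.0,
) -> dict:
    """ICP rigid registration mapping ``points_t`` onto ``points_t1``.

    Alternates nearest-neighbour correspondence with a least-squares rigid
    solve (SVD, proper rotation enforced) until the RMS residual changes
    by less than ``tol`` or ``max_iter`` is reached. With
    ``trim_fraction`` > 0 the worst matches are dropped each iteration
    (robustness to detection outliers between consecutive timepoints).

    Returns dict with rotation ``R``, translation ``t``, ``rms``,
    ``iterations``, ``converged``.
    """
    src = np.asarray(points_t, dtype=float)
    dst = np.asarray(points_t1, dtype=float)
    if src.shape[0] < 3 or dst.shape[0] < 3:
        raise ValueError("need >= 3 points in each set")
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must be in [0, 1)")
    tree = cKDTree(dst)
    r_total = np.eye(3)
    t_total = np.zeros(3)
    cur = src.copy()
    prev_rms = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dists, idx = tree.query(cur)
        keep = np.arange(len(cur))
        if trim_fraction > 0:
            n_keep = max(int(np.ceil((1.0 - trim_fraction) * len(cur))), 3)
            keep = np.argsort(dists)[:n_keep]
        r_step, t_step = _kabsch(cur[keep], dst[idx[keep]])
        cur = cur @ r_step.T + t_step
        r_total = r_step @ r_total
        t_total = r_step @ t_total + t_step
        rms = float(np.sqrt(np.mean(dists[keep] ** 2)))
        if abs(prev_rms - rms) < tol:
            converged = True
            break
        prev_rms = rms
    dists, idx = tree.query(cur)
    return {
        "R": r_total,
        "t": t_total,
        "rms": float(np.sqrt(np.mean(dists**2))),
        "iterations": it,
        "converged": converged,
    }


# ---------------------------------------------------------------------------
# Channel subtraction


def _foreground_percentile(data: np.ndarray, q: float) -> float:
    fg = data[data > 0]
    return float(np.percentile(fg, q)) if fg.size else 0.0


def subtract_channels(
    ch1: VoxelStack,
    ch2: VoxelStack,
    ch3: VoxelStack,
    nucleus_radius: int = 2,
    scale_percentile: float = 99.9,
) -> dict:
    """Separate germlayer nuclei by channel subtraction.

    Channel semantics: ch1 endoderm nuclei, ch2 mesendoderm cytoplasm,
    ch3 all nuclei. Because ch2 is cytoplasmic it is first morphologically
    closed with a nucleus-sized structuring element so it covers nuclear
    footprints, then rescaled so its bright foreground (99.9th percentile)
    matches ch3 before subtracting:

        epiblast    = clamp0(ch3 − s·close(ch2))
        mesendoderm = clamp0(ch3 − epiblast)
        mesoderm    = clamp0(mesendoderm − s'·ch1)
        endoderm    = ch1 (used as is)

    Returns dict of VoxelStacks keyed by layer name.
    """
    shapes = {s.data.shape for s in (ch1, ch2, ch3)}
    if len(shapes) != 1:
        raise ValueError(
            "channel shapes differ: "
            f"ch1={ch1.data.shape}, ch2={ch2.data.shape}, ch3={ch3.data.shape}"
        )
    d1 = np.asarray(ch1.data, dtype=float)
    d2 = np.asarray(ch2.data, dtype=float)
    d3 = np.asarray(ch3.data, dtype=float)

    if nucleus_radius > 0 and np.any(d2 > 0):
        from skimage.morphology import ball, closing

        d2 = closing(d2, ball(nucleus_radius))

    p3 = _foreground_percentile(d3, scale_percentile)
    p2 = _foreground_percentile(d2, scale_percentile)
    p1 = _foreground_percentile(d1, scale_percentile)
    s = p3 / p2 if p2 > 0 else 0.0

    epiblast = np.clip(d3 - s * d2, 0.0, None)
    mesendoderm = np.clip(d3 - epiblast, 0.0, None)
    s1 = (
        _foreground_percentile(mesendoderm, scale_percentile) / p1 if p1 > 0 else 0.0
    )
    mesoderm = np.clip(mesendoderm - s1 * d1, 0.0, None)
    vs = ch3.voxel_size
    return {
        "epiblast": VoxelStack(epiblast, vs, "epiblast"),
        "mesendoderm": VoxelStack(mesendoderm, vs, "mesendoderm"),
        "mesoderm": VoxelStack(mesoderm, vs, "mesoderm"),
        "endoderm": VoxelStack(d1, ch1.voxel_size, "endoderm"),
    }


def assign_layers(layer_stacks: dict, positions_um: np.ndarray) -> list:
    """Classify cell positions into germlayers from separated stacks.

    Scores each position by the windowed mean intensity of the epiblast,
    mesendoderm, and endoderm stacks. An endoderm signal comparable to the
    mesendoderm signal (endoderm nuclei appear in both) wins; otherwise
    the larger of epiblast vs mesendoderm decides.
    """
    epi = window_means(layer_stacks["epiblast"], positions_um)
    meso = window_means(layer_stacks["mesendoderm"], positions_um)
    endo = window_means(layer_stacks["endoderm"], positions_um)
    labels = []
    for e, m, n in zip(epi, meso, endo):
        if n > 0.5 * max(m, 1e-12) and n > e:
            labels.append("endoderm")
        elif m > e:
            labels.append("mesendoderm")
        else:
            labels.append("epiblast")
    return labels


# ---------------------------------------------------------------------------
# Expression readout


def window_means(
    stack: VoxelStack, positions_um: np.ndarray, window: int = 3
) -> np.ndarray:
    """Mean intensity in a window×window×window voxel box around each
    position (µm); boxes are truncated at stack edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    data = np.asarray(stack.data, dtype=float)
    pos = np.atleast_2d(np.asarray(positions_um, dtype=float))
    out = np.empty(pos.shape[0])
    for i, p in enumerate(pos):
        vox = np.floor(p / stack.voxel_size).astype(int)
        lo = np.maximum(vox - half, 0)
        hi = np.minimum(vox + half + 1, np.asarray(data.shape))
        if np.any(lo >= hi):
            out[i] = np.nan
            continue
        out[i] = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].mean()
    return out


def expression_readout(
    stacks: list, positions_per_stack: list, window: int = 3
) -> list:
    """Windowed expression readout with global min-max normalization.

    ``stacks[i]`` is the reporter stack for frame i and
    ``positions_per_stack[i]`` the tracked cell positions (µm) at that
    frame. Raw window means are normalized to [0, 1] using the minimum
    and maximum across *all* frames and positions of the run. A constant
    signal (max = min) yields all zeros with a warning.
    """
    raw = [
        window_means(s, p, window) for s, p in zip(stacks, positions_per_stack)
    ]
    allv = np.concatenate([r[np.isfinite(r)] for r in raw]) if raw else np.array([])
    if allv.size == 0:
        return raw
    vmin, vmax = float(allv.min()), float(allv.max())
    if vmax == vmin:
        warnings.warn("expression signal is constant; normalized values set to 0")
        return [np.zeros_like(r) for r in raw]
    return [(r - vmin) / (vmax - vmin) for r in raw]
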