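"""Single-cell track containers and trajectory statistics.

A :class:`Track` is one cell's time series of 3D positions (µm) with a
germlayer label and optional expression traces; a :class:`TrackSet` bundles
tracks sharing a frame interval. Statistics implemented here:

* straightness index (end-to-end distance over path length),
* SI-vs-position scatter with 90% prediction ellipses,
* per-frame relative cell counts and normalized mean radial positions,
* average change in radius / latitude over 10-minute pieces,
* shield-region filtering and latitude-profile clustering,
* greedy aggregation of fragmented tracklets into long-term tracks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .geometry import SphericalFrame, to_spherical

__all__ = [
    "Track",
    "TrackSet",
    "LAYERS",
    "straightness_index",
    "prediction_ellipse",
    "si_position_analysis",
    "relative_cell_counts",
    "mean_radial_position",
    "radius_latitude_change",
    "filter_tracks_region",
    "cluster_latitude_profiles",
    "aggregate_long_tracks",
]

#: Germlayer labels, exhaustive and exclusive at each frame.
LAYERS = ("epiblast", "mesendoderm", "endoderm")


@dataclass
class Track:
    """One cell's trajectory.

    ``layers`` may vary per frame (a blastoderm cell becomes mesendoderm
    at marker onset); ``layer`` reports the label at the last frame.
    """

    cell_id: int
    frames: np.ndarray
    positions: np.ndarray
    layers: np.ndarray
    parent_id: int = -1
    expression: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.frames.ndim != 1 or self.positions.shape != (len(self.frames), 3):
            raise ValueError("positions must be (n_frames, 3)")
        if len(self.frames) < 1:
            raise ValueError("track must contain at least one frame")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if isinstance(self.layers, str):
            self.layers = np.full(len(self.frames), self.layers, dtype=object)
        else:
            self.layers = np.asarray(self.layers, dtype=object)
        if len(self.layers) != len(self.frames):
            raise ValueError("layers must have one label per frame")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def layer(self) -> str:
        return str(self.layers[-1])

    def slice_frames(self, frame_lo: int, frame_hi: int) -> "Track | None":
        """Sub-track restricted to frames in [frame_lo, frame_hi]; None if empty."""
        sel = (self.frames >= frame_lo) & (self.frames <= frame_hi)
        if not np.any(sel):
            return None
        return Track(
            cell_id=self.cell_id,
            frames=self.frames[sel],
            positions=self.positions[sel],
            layers=self.layers[sel],
            parent_id=self.parent_id,
            expression={k: np.asarray(v)[sel] for k, v in self.expression.items()},
        )


@dataclass
class TrackSet:
    """A collection of tracks sharing a frame clock."""

    tracks: list
    frame_interval: float  # seconds
    t_start_hpf: float = 4.0
    embryo_id: str = "synthetic-0"

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        ids = [t.cell_id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise ValueError("cell_ids must be unique within a TrackSet")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def time_hpf(self, frames: np.ndarray) -> np.ndarray:
        return self.t_start_hpf + np.asarray(frames) * self.frame_interval / 3600.0

    def frame_range(self) -> tuple[int, int]:
        lo = min(int(t.frames[0]) for t in self.tracks)
        hi = max(int(t.frames[-1]) for t in self.tracks)
        return lo, hi

    def select_layer(self, layer: str) -> "TrackSet":
        """Tracks whose final label matches ``layer``."""
        return dataclasses.replace(
            self, tracks=[t for t in self.tracks if t.layer == layer]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            n = len(t)
            block = {
                "frame": t.frames,
                "time_hpf": self.time_hpf(t.frames),
                "cell_id": np.full(n, t.cell_id),
                "parent_id": np.full(n, t.parent_id),
                "x_um": t.positions[:, 0],
                "y_um": t.positions[:, 1],
                "z_um": t.positions[:, 2],
                "layer": t.layers,
            }
            for key in ("mezzo", "sox17"):
                block[key] = np.asarray(
                    t.expression.get(key, np.zeros(n)), dtype=float
                )
            rows.append(pd.DataFrame(block))
        if not rows:
            return pd.DataFrame(
                columns=[
                    "frame", "time_hpf", "cell_id", "parent_id",
                    "x_um", "y_um", "z_um", "layer", "mezzo", "sox17",
                ]
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        frame_interval: float,
        t_start_hpf: float = 4.0,
        embryo_id: str = "external",
    ) -> "TrackSet":
        tracks = []
        for cell_id, g in df.sort_values("frame").groupby("cell_id", sort=True):
            expression = {
                k: g[k].to_numpy(dtype=float) for k in ("mezzo", "sox17") if k in g
            }
            tracks.append(
                Track(
                    cell_id=int(cell_id),
                    frames=g["frame"].to_numpy(),
                    positions=g[["x_um", "y_um", "z_um"]].to_numpy(),
                    layers=g["layer"].to_numpy(dtype=object),
                    parent_id=int(g["parent_id"].iloc[0]) if "parent_id" in g else -1,
                    expression=expression,
                )
            )
        return cls(tracks, frame_interval, t_start_hpf, embryo_id)

    @classmethod
    def from_csv(
        cls, path: str | Path, frame_interval: float, t_start_hpf: float = 4.0
    ) -> "TrackSet":
        return cls.from_dataframe(
            pd.read_csv(path), frame_interval, t_start_hpf, embryo_id=str(path)
        )


# ---------------------------------------------------------------------------
# Straightness


def straightness_index(track: Track) -> float:
    """End-to-end distance divided by path length, in [0, 1].

    NaN for stationary tracks (zero path length) — callers exclude those
    from aggregates — and for single-frame tracks.
    """
    if len(track) < 2:
        return float("nan")
    steps = np.diff(track.positions, axis=0)
    path = float(np.sum(np.linalg.norm(steps, axis=1)))
    if path == 0.0:
        return float("nan")
    end_to_end = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    return end_to_end / path


def prediction_ellipse(
    points: np.ndarray, coverage: float = 0.90
) -> dict:
    """Prediction ellipse for a bivariate-normal sample.

    The ellipse encloses the region where ``coverage`` of *new* draws from
    the fitted normal would fall: Mahalanobis radius sqrt(chi2.ppf(coverage, 2)).
    Returns mean, covariance, radius, and semi-axes (sqrt eigenvalues × radius).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a prediction ellipse")
    mean = pts.mean(axis=0)
    cov = np.cov(pts.T)
    radius = float(np.sqrt(chi2.ppf(coverage, df=2)))
    eigvals, eigvecs = np.linalg.eigh(cov)
    return {
        "mean": mean,
        "cov": cov,
        "radius": radius,
        "semi_axes": np.sqrt(np.maximum(eigvals, 0.0)) * radius,
        "axes": eigvecs,
        "coverage": coverage,
    }


def si_position_analysis(
    trackset: TrackSet,
    frame: SphericalFrame,
    window_frames: int = 10,
    coverage: float = 0.90,
) -> tuple[pd.DataFrame, dict]:
    """SI of short track windows vs. position at the window midpoint.

    Tracks are subdivided into non-overlapping windows of ``window_frames``
    aligned to track start (10 frames ≈ 20 min at 2-min sampling). For each
    window the SI and the spherical coordinates at the midpoint are
    recorded. Per layer and per coordinate (r, theta, phi), a prediction
    ellipse of the (coordinate, SI) scatter is fitted; layers with fewer
    than 3 windows are flagged with ``None``.
    """
    records = []
    for t in trackset:
        n_windows = len(t) // window_frames
        for w in range(n_windows):
            seg = Track(
                cell_id=t.cell_id,
                frames=t.frames[w * window_frames : (w + 1) * window_frames],
                positions=t.positions[w * window_frames : (w + 1) * window_frames],
                layers=t.layers[w * window_frames : (w + 1) * window_frames],
            )
            si = straightness_index(seg)
            if not np.isfinite(si):
                continue
            mid = seg.positions[len(seg) // 2]
            r, theta, phi, _ = to_spherical(mid, frame)
            records.append(
                {
                    "cell_id": t.cell_id,
                    "window": w,
                    "layer": seg.layer,
                    "si": si,
                    "r": r,
                    "theta": theta,
                    "phi": phi,
                }
            )
    df = pd.DataFrame(records)
    ellipses: dict = {}
    if df.empty:
        return df, ellipses
    for layer, g in df.groupby("layer"):
        ellipses[layer] = {}
        for coord in ("r", "theta", "phi"):
            pts = g[[coord, "si"]].to_numpy()
            ellipses[layer][coord] = (
                prediction_ellipse(pts, coverage) if len(pts) >= 3 else None
            )
    return df, ellipses


# ---------------------------------------------------------------------------
# Counts and radial stratification


def relative_cell_counts(trackset: TrackSet) -> pd.DataFrame:
    """Per-frame germlayer fractions of the total cell count.

    Fractions over {epiblast, mesendoderm, endoderm} sum to exactly 1 at
    every frame with at least one cell; frames with zero cells are NaN.
    """
    lo, hi = trackset.frame_range()
    frames = np.arange(lo, hi + 1)
    counts = {layer: np.zeros(len(frames), dtype=int) for layer in LAYERS}
    for t in trackset:
        idx = t.frames - lo
        for i, layer in zip(idx, t.layers):
            counts[str(layer)][i] += 1
    total = sum(counts.values())
    out = {"frame": frames, "total": total}
    with np.errstate(invalid="ignore", divide="ignore"):
        for layer in LAYERS:
            out[layer] = np.where(total > 0, counts[layer] / np.maximum(total, 1), np.nan)
    return pd.DataFrame(out)


def mean_radial_position(
    trackset: TrackSet,
    frame: SphericalFrame,
    reference_layer: str = "mesendoderm",
) -> pd.DataFrame:
    """Per-frame mean radius of each layer, normalized by the reference layer.

    Frames where the reference layer is empty yield NaN (flagged gap).
    """
    lo, hi = trackset.frame_range()
    frames = np.arange(lo, hi + 1)
    sums = {layer: np.zeros(len(frames)) for layer in LAYERS}
    ns = {layer: np.zeros(len(frames), dtype=int) for layer in LAYERS}
    for t in trackset:
        r, _, _, _ = to_spherical(t.positions, frame)
        idx = t.frames - lo
        for i, layer, ri in zip(idx, t.layers, np.atleast_1d(r)):
            sums[str(layer)][i] += ri
            ns[str(layer)][i] += 1
    out = {"frame": frames}
    with np.errstate(invalid="ignore", divide="ignore"):
        means = {
            layer: np.where(ns[layer] > 0, sums[layer] / np.maximum(ns[layer], 1), np.nan)
            for layer in LAYERS
        }
        ref = means[reference_layer]
        for layer in LAYERS:
            out[layer] = means[layer] / ref
        out["reference_mean_r"] = ref
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Radius / latitude drift


def radius_latitude_change(
    trackset: TrackSet,
    frame: SphericalFrame,
    piece_duration_s: float = 600.0,
) -> pd.DataFrame:
    """Per-track mean change in radius and latitude over 10-min pieces.

    Each track is cut into non-overlapping pieces of ``piece_duration_s``;
    per piece the last-minus-first r and phi are taken, then averaged per
    track. Tracks shorter than one piece are excluded (reported via the
    ``n_pieces`` column being absent for them; the count of exclusions is
    stored in ``df.attrs['n_excluded']``).
    """
    piece_frames = max(int(round(piece_duration_s / trackset.frame_interval)), 1)
    records = []
    n_excluded = 0
    for t in trackset:
        n_pieces = (len(t) - 1) // piece_frames
        if n_pieces < 1:
            n_excluded += 1
            continue
        r, _, phi, _ = to_spherical(t.positions, frame)
        dr, dphi = [], []
        for p in range(n_pieces):
            i0, i1 = p * piece_frames, (p + 1) * piece_frames
            dr.append(r[i1] - r[i0])
            dphi.append(phi[i1] - phi[i0])
        records.append(
            {
                "cell_id": t.cell_id,
                "layer": t.layer,
                "mean_dr": float(np.mean(dr)),
                "mean_dphi": float(np.mean(dphi)),
                "n_pieces": n_pieces,
            }
        )
    df = pd.DataFrame(records)
    df.attrs["n_excluded"] = n_excluded
    return df


# ---------------------------------------------------------------------------
# Region filtering and clustering


def filter_tracks_region(
    trackset: TrackSet,
    frame: SphericalFrame,
    theta_range: tuple[float, float] = (-np.pi / 8, np.pi / 8),
    time_range: tuple[int, int] | None = None,
    completeness: str = "full",
) -> TrackSet:
    """Retain tracks inside a longitude window (shield region by default).

    ``completeness='full'`` drops tracks that do not span the whole
    ``time_range`` (incomplete tracks are excluded from long-term
    analysis); ``'partial'`` keeps any overlap. The angular predicate
    requires every retained position to lie within ``theta_range``.
    """
    if completeness not in ("full", "partial"):
        raise ValueError("completeness must be 'full' or 'partial'")
    lo, hi = time_range if time_range is not None else trackset.frame_range()
    kept = []
    for t in trackset:
        sub = t.slice_frames(lo, hi)
        if sub is None:
            continue
        if completeness == "full" and not (
            sub.frames[0] == lo and sub.frames[-1] == hi
            and len(sub) == hi - lo + 1
        ):
            continue
        _, theta, _, _ = to_spherical(sub.positions, frame)
        if np.all((theta >= theta_range[0]) & (theta <= theta_range[1])):
            kept.append(sub)
    return dataclasses.replace(trackset, tracks=kept)


def cluster_latitude_profiles(
    trackset: TrackSet,
    frame: SphericalFrame,
    k: int = 3,
    random_state: int = 0,
    smooth_window: int = 5,
) -> dict:
    """K-means clustering of per-frame latitude profiles.

    All tracks must span a common frame window (apply
    :func:`filter_tracks_region` with ``completeness='full'`` first).
    Returns per-track labels, per-cluster 3D centroid trajectories
    (frame-wise mean position), and the index of the cluster whose
    centroid latitude reverses direction (sign change of the smoothed
    dphi/dt) — the internalize-then-animal-ward population.
    """
    from sklearn.cluster import KMeans

    tracks = list(trackset)
    if k > len(tracks):
        raise ValueError(f"k={k} exceeds number of tracks ({len(tracks)})")
    lengths = {len(t) for t in tracks}
    if len(lengths) != 1:
        raise ValueError("tracks must span a common window; run the completeness filter")
    profiles = []
    for t in tracks:
        _, _, phi, _ = to_spherical(t.positions, frame)
        profiles.append(phi)
    X = np.asarray(profiles)
    km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
    labels = km.fit_predict(X)

    centroids = []
    reversing = []
    for c in range(k):
        members = [t for t, lab in zip(tracks, labels) if lab == c]
        if not members:  # k-means may collapse clusters on duplicate input
            centroids.append(None)
            reversing.append(False)
            continue
        centroid = np.mean([t.positions for t in members], axis=0)
        centroids.append(centroid)
        _, _, phi_c, _ = to_spherical(centroid, frame)
        reversing.append(_reverses_direction(phi_c, smooth_window))
    return {
        "labels": labels,
        "centroids": centroids,
        "reversing": np.asarray(reversing),
        "reversing_cluster": int(np.argmax(reversing)) if any(reversing) else None,
    }


def _reverses_direction(phi: np.ndarray, smooth_window: int) -> bool:
    """True if the smoothed latitude velocity changes sign."""
    if len(phi) < smooth_window + 2:
        return False
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(phi, kernel, mode="valid")
    dphi = np.diff(smoothed)
    dphi = dphi[np.abs(dphi) > 1e-12]
    if len(dphi) == 0:
        return False
    return bool(np.any(np.sign(dphi[:-1]) != np.sign(dphi[1:])))


# ---------------------------------------------------------------------------
# Tracklet aggregation


def aggregate_long_tracks(
    trackset: TrackSet, gap_frames: int = 3, link_radius: float = 15.0
) -> TrackSet:
    """Greedily link tracklet ends to nearby tracklet starts.

    A fragment's end may be linked to another fragment's start if the
    start follows within ``gap_frames`` frames and lies within
    ``link_radius`` µm. Candidates are chosen by smallest distance, ties
    by lower cell_id; each fragment is used at most once, so the result is
    deterministic for a given input. Gap frames between linked fragments
    are left unsampled (frames stay strictly increasing). Unlinked
    fragments pass through unchanged.
    """
    frags = sorted(trackset.tracks, key=lambda t: (t.frames[0], t.cell_id))
    starts = [(t.frames[0], t.positions[0], i) for i, t in enumerate(frags)]
    used_as_successor = set()
    successor = {}

    for i, t in enumerate(frags):
        end_frame = t.frames[-1]
        end_pos = t.positions[-1]
        best = None
        for f0, p0, j in starts:
            if j == i or j in used_as_successor:
                continue
            dt = f0 - end_frame
            if dt < 1 or dt > gap_frames:
                continue
            dist = float(np.linalg.norm(p0 - end_pos))
            if dist > link_radius:
                continue
            key = (dist, frags[j].cell_id)
            if best is None or key < best[0]:
                best = (key, j)
        if best is not None:
            successor[i] = best[1]
            used_as_successor.add(best[1])

    merged = []
    heads = [i for i in range(len(frags)) if i not in used_as_successor]
    for i in heads:
        chain = [frags[i]]
        j = i
        while j in successor:
            j = successor[j]
            chain.append(frags[j])
        if len(chain) == 1:
            merged.append(chain[0])
        else:
            merged.append(
                Track(
                    cell_id=chain[0].cell_id,
                    frames=np.concatenate([t.frames for t in chain]),
                    positions=np.concatenate([t.positions for t in chain]),
                    layers=np.concatenate([t.layers for t in chain]),
                    parent_id=chain[0].parent_id,
                    expression={
                        key: np.concatenate(
                            [np.asarray(t.expression.get(key, np.zeros(len(t))))
                             for t in chain]
                        )
                        for key in chain[0].expression
                    },
                )
            )
    return dataclasses.replace(trackset, tracks=merged)
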