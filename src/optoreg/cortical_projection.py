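"""Scalp-to-cortex projection and source-detector channel construction.

Scalp-level optode positions in MNI space are pulled down onto a cortical
surface mesh, and measurement channels are formed from source-detector
pairs whose scalp separation falls within a tolerance band around the
nominal separation (28 mm by default). The channel position is the
midpoint of its optode pair; in cortical space the scalp midpoint is
projected onto the cortex (the alternative order — mean of the projected
endpoints — is available via ``midpoint_mode``).

Two projection methods are provided:

``closest``
    Euclidean closest point over all mesh triangles; ties broken by the
    lowest face index.
``ray``
    Intersection of the segment from the point to the mesh centroid with
    the nearest intersected triangle. Points whose segment misses the mesh
    produce a per-point error record instead of aborting the run.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry_io import (
    OptodeSet,
    Point3,
    PointTable,
    SurfaceMesh,
    check_same_frame,
)

PROJECTION_METHODS = ("closest", "ray")

DEFAULT_SEPARATION_MM = 28.0
DEFAULT_SEPARATION_TOL = 0.2


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray,
                               chunk: int = 256):
    """Closest points on a triangle soup for each query point.

    Parameters
    ----------
    points : (n, 3) array
    triangles : (m, 3, 3) array of triangle corners

    Returns
    -------
    closest : (n, 3) array — closest point on the surface per query
    distance : (n,) array
    face_index : (n,) int array — index of the winning triangle (lowest
        index wins ties)
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    triangles = np.asarray(triangles, dtype=float)
    if triangles.size == 0:
        raise ValidationError("cannot project onto an empty mesh")
    n = len(points)
    closest = np.empty((n, 3))
    dist = np.empty(n)
    face = np.empty(n, dtype=np.int64)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        c, d, f = _closest_block(points[sl], triangles)
        closest[sl], dist[sl], face[sl] = c, d, f
    return closest, dist, face


def _closest_block(p: np.ndarray, tri: np.ndarray):
    """Vectorised point/triangle closest point (Ericson's region test).

    Broadcasts all points in the block against all triangles; memory is
    O(len(p) * len(tri)).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]          # (m, 3)
    ab = b - a
    ac = c - a
    pa = p[:, None, :] - a[None, :, :]                 # (n, m, 3)

    d1 = np.einsum("mk,nmk->nm", ab, pa)
    d2 = np.einsum("mk,nmk->nm", ac, pa)
    pb = p[:, None, :] - b[None, :, :]
    d3 = np.einsum("mk,nmk->nm", ab, pb)
    d4 = np.einsum("mk,nmk->nm", ac, pb)
    pc = p[:, None, :] - c[None, :, :]
    d5 = np.einsum("mk,nmk->nm", ab, pc)
    d6 = np.einsum("mk,nmk->nm", ac, pc)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    denom = va + vb + vc
    # interior barycentric coordinates (guard zero for degenerate regions)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_face = np.where(denom != 0, vb / denom, 0.0)
        w_face = np.where(denom != 0, vc / denom, 0.0)
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        den_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)

    # start from the face projection, then overwrite edge/vertex regions
    cand = (a[None] + v_face[..., None] * ab[None] + w_face[..., None] * ac[None])

    # Ericson's sequence of exclusive region tests:
    r_a = (d1 <= 0) & (d2 <= 0)
    r_b = (d3 >= 0) & (d4 <= d3)
    r_c = (d6 >= 0) & (d5 <= d6)
    r_ab = (~r_a) & (~r_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    r_ac = (~r_a) & (~r_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    r_bc = (~r_b) & (~r_c) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    w_bc_cl = np.clip(w_bc, 0.0, 1.0)
    cand = np.where(r_bc[..., None], b[None] + w_bc_cl[..., None] * (c - b)[None], cand)
    cand = np.where(r_ac[..., None],
                    a[None] + np.clip(w_ac, 0, 1)[..., None] * ac[None], cand)
    cand = np.where(r_ab[..., None],
                    a[None] + np.clip(v_ab, 0, 1)[..., None] * ab[None], cand)
    cand = np.where(r_c[..., None], np.broadcast_to(c[None], cand.shape), cand)
    cand = np.where(r_b[..., None], np.broadcast_to(b[None], cand.shape), cand)
    cand = np.where(r_a[..., None], np.broadcast_to(a[None], cand.shape), cand)

    d2_all = np.sum((p[:, None, :] - cand) ** 2, axis=2)
    face = np.argmin(d2_all, axis=1)  # argmin returns the lowest tied index
    rows = np.arange(len(p))
    return cand[rows, face], np.sqrt(d2_all[rows, face]), face


def _ray_hits(origins: np.ndarray, target: np.ndarray, triangles: np.ndarray):
    """Möller–Trumbore: nearest intersection of segments origin→target."""
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    e1 = b - a
    e2 = c - a
    dirs = target[None, :] - origins                       # (n, 3)
    eps = 1e-12
    hit_pts = np.full((len(origins), 3), np.nan)
    hit_face = np.full(len(origins), -1, dtype=np.int64)
    for i, (o, d) in enumerate(zip(origins, dirs)):
        pvec = np.cross(d, e2)
        det = np.einsum("mk,mk->m", e1, pvec)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = o - a
        u = np.einsum("mk,mk->m", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = np.einsum("k,mk->m", d, qvec) * inv
        t = np.einsum("mk,mk->m", e2, qvec) * inv
        valid = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & \
            (t >= -eps) & (t <= 1 + eps)
        if valid.any():
            t_valid = np.where(valid, t, np.inf)
            f = int(np.argmin(t_valid))
            hit_face[i] = f
            hit_pts[i] = o + t_valid[f] * d
    return hit_pts, hit_face


@dataclass
class ProjectionResult:
    """Projected points plus per-point provenance and failures."""

    points: PointTable
    face_indices: np.ndarray
    distances: np.ndarray
    method: str
    errors: list[tuple[str, str]] = field(default_factory=list)

    @property
    def failed_ids(self) -> list[str]:
        return [pid for pid, _ in self.errors]


def project_to_surface(points: PointTable, surface: SurfaceMesh,
                       method: str = "closest") -> ProjectionResult:
    """Project every point onto ``surface``.

    Points and mesh must share a frame. With ``method="ray"`` a point whose
    segment to the mesh centroid misses every triangle keeps its input
    position and is reported in ``result.errors``; the run continues.
    """
    if method not in PROJECTION_METHODS:
        raise ValidationError(f"unknown projection method {method!r}")
    check_same_frame(points, surface)
    if surface.n_faces == 0:
        raise ValidationError("cannot project onto an empty mesh")
    tri = surface.triangles()
    if method == "closest":
        closest, dist, face = closest_point_on_triangles(points.coords, tri)
        return ProjectionResult(points.with_coords(closest), face, dist, method)
    hit_pts, hit_face = _ray_hits(points.coords, surface.centroid(), tri)
    errors = []
    out = points.coords.copy()
    dist = np.zeros(len(points))
    for i, pid in enumerate(points.ids):
        if hit_face[i] < 0:
            errors.append((pid, "segment to mesh centroid intersects no triangle"))
        else:
            out[i] = hit_pts[i]
            dist[i] = np.linalg.norm(points.coords[i] - hit_pts[i])
    return ProjectionResult(points.with_coords(out), hit_face, dist, method, errors)


# ---------------------------------------------------------------------------
# Channels


@dataclass
class Channel:
    channel: str
    source: str
    detector: str
    separation_mm: float
    midpoint: Point3 | None = None

    def __post_init__(self):
        if self.separation_mm <= 0:
            raise ValidationError(
                f"channel {self.channel}: separation must be positive"
            )


@dataclass
class ChannelTable:
    channels: list[Channel] = field(default_factory=list)

    def __post_init__(self):
        pairs = [(c.source, c.detector) for c in self.channels]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate source-detector pair in channel table")

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self):
        return iter(self.channels)

    def ids(self) -> list[str]:
        return [c.channel for c in self.channels]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.channels:
            m = c.midpoint
            rows.append({
                "channel": c.channel, "source": c.source, "detector": c.detector,
                "separation_mm": c.separation_mm,
                "x": m.x if m else np.nan,
                "y": m.y if m else np.nan,
                "z": m.z if m else np.nan,
            })
        return pd.DataFrame(
            rows, columns=["channel", "source", "detector", "separation_mm",
                           "x", "y", "z"])

    def to_csv(self, path, metadata: dict | None = None) -> Path:
        path = Path(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            for k, v in (metadata or {}).items():
                fh.write(f"# {k}: {v}\n")
            self.to_frame().to_csv(fh, index=False)
        return path


def _channel_id(i: int, width: int = 2) -> str:
    return f"CH{i + 1:0{width}d}"


def pair_channels(optodes: OptodeSet, nominal_sep: float = DEFAULT_SEPARATION_MM,
                  tol: float = DEFAULT_SEPARATION_TOL) -> ChannelTable:
    """All source-detector pairs within ``nominal_sep * (1 ± tol)``.

    Channel ids are assigned in (source id, detector id) lexicographic
    order. An empty table is a valid result.
    """
    if nominal_sep <= 0:
        raise ValidationError("nominal separation must be positive")
    if not 0 < tol < 1:
        raise ValidationError("tolerance must be a fraction in (0, 1)")
    lo, hi = nominal_sep * (1 - tol), nominal_sep * (1 + tol)
    pairs = []
    for s in optodes.sources():
        for d in optodes.detectors():
            sep = s.position.distance_to(d.position)
            if lo <= sep <= hi:
                pairs.append((s.id, d.id, sep))
    pairs.sort(key=lambda p: (p[0], p[1]))
    width = max(2, len(str(len(pairs))))
    return ChannelTable([
        Channel(_channel_id(i, width), s, d, sep)
        for i, (s, d, sep) in enumerate(pairs)
    ])


def read_pairing(path) -> list[tuple[str, str, str]]:
    """Read a user-supplied pairing override CSV: channel,source,detector."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(
                line for line in fh if not line.startswith("#")):
            rows.append((row["channel"].strip(), row["source"].strip(),
                         row["detector"].strip()))
    return rows


def pair_channels_from_file(optodes: OptodeSet, path) -> ChannelTable:
    """Build a channel table from an explicit pairing file (no distance filter)."""
    table = optodes.to_point_table()
    channels = []
    for name, s, d in read_pairing(path):
        sep = float(np.linalg.norm(table.position(s) - table.position(d)))
        channels.append(Channel(name, s, d, sep))
    return ChannelTable(channels)


def channel_midpoints(channels: ChannelTable, positions: PointTable,
                      space: str = "scalp", cortex: SurfaceMesh | None = None,
                      midpoint_mode: str = "project-midpoint") -> PointTable:
    """Channel positions as source-detector midpoints.

    ``space="scalp"`` returns the arithmetic midpoints of the given
    positions. ``space="cortical"`` requires ``cortex`` and, by default,
    projects the scalp midpoint onto the cortical mesh
    (``midpoint_mode="project-midpoint"``); with
    ``midpoint_mode="mean-of-projected"`` the endpoints are projected first
    and their mean re-projected onto the cortex.
    """
    if space not in ("scalp", "cortical"):
        raise ValidationError(f"unknown channel space {space!r}")
    if midpoint_mode not in ("project-midpoint", "mean-of-projected"):
        raise ValidationError(f"unknown midpoint mode {midpoint_mode!r}")
    endpoint_ids: list[str] = []
    for c in channels:
        for oid in (c.source, c.detector):
            if oid not in endpoint_ids:
                endpoint_ids.append(oid)
    endpoints = positions.subset(endpoint_ids)  # raises on missing id

    if space == "cortical":
        if cortex is None:
            raise ValidationError("cortical midpoints require a cortex mesh")
        check_same_frame(positions, cortex)
        if midpoint_mode == "mean-of-projected":
            endpoints = project_to_surface(endpoints, cortex).points

    mids = np.array([
        0.5 * (endpoints.position(c.source) + endpoints.position(c.detector))
        for c in channels
    ]).reshape(-1, 3)
    out = PointTable(channels.ids(), mids, positions.frame)
    if space == "cortical":
        out = project_to_surface(out, cortex).points
    return out


def attach_midpoints(channels: ChannelTable, midpoints: PointTable) -> ChannelTable:
    """Return a copy of ``channels`` with midpoint positions filled in."""
    return ChannelTable([
        Channel(c.channel, c.source, c.detector, c.separation_mm,
                midpoints.point(c.channel))
        for c in channels
    ])
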