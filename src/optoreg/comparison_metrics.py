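"""Validation statistics for comparing registration methods.

Implements the four dispersion/agreement metrics used to compare a
photogrammetric registration against an MRI-based one:

* per-point displacement between two registered coordinate sets (per-axis
  absolute differences and Euclidean distance),
* the composite standard deviation Csd = sqrt(sdx^2 + sdy^2 + sdz^2) of a
  group of participants, per point,
* per-axis mean displacement summaries,
* the volumetric overlap of two equal spheres (default radius 20 mm)
  centred on the channel positions reported by each method.

Reports mirror the conventional table layout: coordinates rounded to
integers and distances to one decimal; raw values are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry_io import Point3, PointTable, check_same_frame

DEFAULT_OVERLAP_RADIUS_MM = 20.0


@dataclass
class DisplacementRecord:
    """Per-point difference between two registered positions (all mm, >= 0)."""

    id: str
    dx: float
    dy: float
    dz: float
    d: float


@dataclass
class OverlapResult:
    channel: str
    separation_mm: float
    fraction: float


@dataclass
class GroupPositions:
    """Point tables for several participants covering the same id set."""

    participants: dict[str, PointTable] = field(default_factory=dict)

    def __post_init__(self):
        if not self.participants:
            raise ValidationError("group must contain at least one participant")
        tables = list(self.participants.values())
        check_same_frame(*tables)
        ref = tables[0].ids
        for pid, table in self.participants.items():
            if sorted(table.ids) != sorted(ref):
                raise ValidationError(
                    f"participant {pid!r} covers a different id set"
                )

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def frame(self) -> str:
        return next(iter(self.participants.values())).frame

    @property
    def point_ids(self) -> list[str]:
        return list(next(iter(self.participants.values())).ids)

    def stacked(self) -> np.ndarray:
        """(n_participants, n_points, 3) array in a consistent id order."""
        ids = self.point_ids
        return np.stack([
            t.subset(ids).coords for t in self.participants.values()
        ])

    def mean_table(self) -> PointTable:
        return PointTable(self.point_ids, self.stacked().mean(axis=0), self.frame)


def displacement(a: PointTable, b: PointTable) -> list[DisplacementRecord]:
    """Per-id displacement between two point tables with identical id sets."""
    check_same_frame(a, b)
    if sorted(a.ids) != sorted(b.ids):
        only_a = sorted(set(a.ids) - set(b.ids))
        only_b = sorted(set(b.ids) - set(a.ids))
        raise ValidationError(
            f"id mismatch between tables (only in a: {only_a}, only in b: {only_b})"
        )
    records = []
    for pid in a.ids:
        diff = np.abs(a.position(pid) - b.position(pid))
        records.append(DisplacementRecord(
            pid, float(diff[0]), float(diff[1]), float(diff[2]),
            float(np.linalg.norm(diff)),
        ))
    return records


def displacement_table(a: PointTable, b: PointTable,
                       rounded: bool = False) -> pd.DataFrame:
    """Table-style displacement report (one row per id).

    With ``rounded=True`` coordinates are rounded to integers and distances
    to one decimal, mirroring the conventional report layout.
    """
    records = displacement(a, b)
    rows = []
    for r in records:
        pa, pb = a.position(r.id), b.position(r.id)
        rows.append({
            "id": r.id,
            "a_x": pa[0], "a_y": pa[1], "a_z": pa[2],
            "b_x": pb[0], "b_y": pb[1], "b_z": pb[2],
            "dx": r.dx, "dy": r.dy, "dz": r.dz, "d": r.d,
        })
    df = pd.DataFrame(rows)
    if rounded:
        for col in ("a_x", "a_y", "a_z", "b_x", "b_y", "b_z"):
            df[col] = df[col].round(0).astype(int)
        for col in ("dx", "dy", "dz", "d"):
            df[col] = df[col].round(1)
    return df


def axis_displacement_summary(records: list[DisplacementRecord]) -> tuple[float, float, float]:
    """Mean per-axis absolute displacement (mean dx, mean dy, mean dz)."""
    if not records:
        raise ValidationError("cannot summarise an empty displacement set")
    dx = float(np.mean([r.dx for r in records]))
    dy = float(np.mean([r.dy for r in records]))
    dz = float(np.mean([r.dz for r in records]))
    return dx, dy, dz


def composite_sd(group: GroupPositions) -> dict[str, float]:
    """Composite standard deviation per point id across participants.

    Per id, the sample standard deviation (n-1 denominator) along each axis
    is combined as sqrt(sdx^2 + sdy^2 + sdz^2). Requires >= 2 participants.
    """
    if len(group) < 2:
        raise ValidationError("composite SD requires at least 2 participants")
    stacked = group.stacked()                       # (p, n, 3)
    sd = stacked.std(axis=0, ddof=1)                # (n, 3)
    csd = np.sqrt(np.sum(sd**2, axis=1))
    return dict(zip(group.point_ids, csd.astype(float)))


def composite_sd_table(group: GroupPositions) -> pd.DataFrame:
    if len(group) < 2:
        raise ValidationError("composite SD requires at least 2 participants")
    stacked = group.stacked()
    sd = stacked.std(axis=0, ddof=1)
    return pd.DataFrame({
        "id": group.point_ids,
        "sdx": sd[:, 0], "sdy": sd[:, 1], "sdz": sd[:, 2],
        "csd": np.sqrt(np.sum(sd**2, axis=1)),
    })


def overlap_fraction(separation: float | np.ndarray,
                     radius: float = DEFAULT_OVERLAP_RADIUS_MM):
    """Lens volume of two equal spheres divided by one sphere's volume.

    For centre separation d <= 2R the intersection of two radius-R spheres
    is a lens of volume pi (4R + d)(2R - d)^2 / 12; dividing by
    (4/3) pi R^3 gives (4R + d)(2R - d)^2 / (16 R^3). Zero beyond 2R, one
    at d = 0.
    """
    if radius <= 0:
        raise ValidationError("sphere radius must be positive")
    d = np.asarray(separation, dtype=float)
    if np.any(d < 0):
        raise ValidationError("separation must be non-negative")
    frac = np.where(
        d >= 2 * radius,
        0.0,
        (4 * radius + d) * (2 * radius - d) ** 2 / (16 * radius**3),
    )
    return float(frac) if np.isscalar(separation) else frac


def channel_overlap(center_a: Point3, center_b: Point3,
                    radius: float = DEFAULT_OVERLAP_RADIUS_MM,
                    channel: str = "") -> OverlapResult:
    """Sphere-overlap agreement between two estimates of one channel position."""
    sep = center_a.distance_to(center_b)
    return OverlapResult(channel, sep, overlap_fraction(sep, radius))


def overlap_table(a: PointTable, b: PointTable,
                  radius: float = DEFAULT_OVERLAP_RADIUS_MM) -> pd.DataFrame:
    """Per-channel overlap report between two channel-position tables."""
    check_same_frame(a, b)
    if sorted(a.ids) != sorted(b.ids):
        raise ValidationError("channel id mismatch between tables")
    rows = []
    for cid in a.ids:
        sep = float(np.linalg.norm(a.position(cid) - b.position(cid)))
        rows.append({
            "channel": cid,
            "separation_mm": sep,
            "overlap_fraction": overlap_fraction(sep, radius),
        })
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path, metadata: dict | None = None) -> Path:
    """Write a CSV report with a commented metadata header block."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)
    return path
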