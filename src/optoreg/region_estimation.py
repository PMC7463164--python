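"""Monte-Carlo estimation of the brain regions sampled by each channel.

For every channel position, points are drawn uniformly from a ball
(default r = 10 mm, n = 10,000 samples) centred on the channel, mapped
into voxel space of an integer parcellation volume, and tabulated by
region label. Regions covering at least ``min_fraction`` of the samples
are flagged as detected.

Sampling is uniform in the ball via an inverse-CDF radius (u^(1/3)
scaling) rather than rejection, so a fixed seed yields a fixed sample
count and identical results across runs. Label lookup is nearest-voxel
(labels are categorical; interpolation would be meaningless); points
outside the grid map to the background label 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry_io import MNI, Point3, PointTable

DEFAULT_SAMPLE_RADIUS_MM = 10.0
DEFAULT_SAMPLE_COUNT = 10_000
DEFAULT_MIN_FRACTION = 0.05

BACKGROUND_LABEL = 0
BACKGROUND_NAME = "background"


@dataclass
class ParcellationAtlas:
    """Integer label volume with a voxel-to-world affine and label names."""

    data: np.ndarray            # 3-D integer grid
    affine: np.ndarray          # (4, 4) voxel -> world (mm)
    labels: dict[int, str]      # nonzero label id -> region name

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError("atlas grid must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValidationError("atlas grid must hold integer labels")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(self.affine[:3, :3])) <= 1e-12:
            raise ValidationError("voxel-to-world affine is singular")
        self.labels = {int(k): str(v) for k, v in self.labels.items()
                       if int(k) != BACKGROUND_LABEL}
        present = set(np.unique(self.data).tolist()) - {BACKGROUND_LABEL}
        unnamed = sorted(present - set(self.labels))
        if unnamed:
            raise ValidationError(f"atlas labels without names: {unnamed}")

    def name_of(self, label: int) -> str:
        return BACKGROUND_NAME if label == BACKGROUND_LABEL else self.labels[label]

    def to_nifti(self, volume_path, labels_path=None) -> Path:
        img = nib.Nifti1Image(self.data.astype(np.int16), self.affine)
        nib.save(img, str(volume_path))
        if labels_path is not None:
            Path(labels_path).write_text(
                json.dumps({str(k): v for k, v in self.labels.items()}, indent=2)
                + "\n",
                encoding="utf-8",
            )
        return Path(volume_path)

    @classmethod
    def from_nifti(cls, volume_path, labels_path) -> "ParcellationAtlas":
        img = nib.load(str(volume_path))
        data = np.asarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded):
                raise ValidationError(
                    f"{volume_path}: label volume holds non-integer values"
                )
            data = rounded.astype(np.int32)
        labels = json.loads(Path(labels_path).read_text(encoding="utf-8"))
        return cls(data, img.affine, {int(k): v for k, v in labels.items()})


@dataclass
class RegionEstimate:
    """Detected-region listing for one channel."""

    channel: str
    regions: list[tuple[str, float]]        # sorted by descending fraction
    background_fraction: float
    detected: list[str] = field(default_factory=list)


@dataclass
class RegionTable:
    estimates: list[RegionEstimate]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        for e in self.estimates:
            total = sum(f for _, f in e.regions) + e.background_fraction
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"channel {e.channel}: fractions sum to {total}, not 1"
                )
            fracs = [f for _, f in e.regions]
            if any(fracs[i] < fracs[i + 1] for i in range(len(fracs) - 1)):
                raise ValidationError(
                    f"channel {e.channel}: regions not sorted by fraction"
                )

    def __iter__(self):
        return iter(self.estimates)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.estimates:
            for name, frac in e.regions:
                rows.append({
                    "channel": e.channel, "region": name,
                    "fraction": frac, "detected": name in e.detected,
                })
            rows.append({
                "channel": e.channel, "region": BACKGROUND_NAME,
                "fraction": e.background_fraction, "detected": False,
            })
        return pd.DataFrame(rows,
                            columns=["channel", "region", "fraction", "detected"])

    def to_csv(self, path) -> Path:
        path = Path(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            for k, v in sorted(self.params.items()):
                fh.write(f"# {k}: {v}\n")
            self.to_frame().to_csv(fh, index=False)
        return path


def sample_sphere_uniform(center: Point3 | np.ndarray, r: float, n: int,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` points uniformly from the closed ball of radius ``r``.

    Directions are isotropic (normalised Gaussians) and radii follow the
    inverse-CDF law r * u^(1/3), giving uniform density in the ball.
    Deterministic for a fixed integer seed.
    """
    if r <= 0:
        raise ValidationError("sampling radius must be positive")
    if n < 1:
        raise ValidationError("sample count must be >= 1")
    c = center.as_array() if isinstance(center, Point3) else np.asarray(center, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = r * rng.uniform(size=n) ** (1.0 / 3.0)
    return c + direction * radius[:, None]


def label_points(points: np.ndarray, atlas: ParcellationAtlas) -> np.ndarray:
    """Nearest-voxel label for each world-space point (0 outside the grid).

    World coordinates are mapped through the inverse voxel affine and
    rounded half-up per axis (floor(v + 0.5)), a fixed tie rule that keeps
    boundary points stable across runs.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    inv = np.linalg.inv(atlas.affine)
    voxels = points @ inv[:3, :3].T + inv[:3, 3]
    idx = np.floor(voxels + 0.5).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < np.array(atlas.data.shape)), axis=1)
    labels = np.full(len(points), BACKGROUND_LABEL, dtype=atlas.data.dtype)
    ii = idx[inside]
    labels[inside] = atlas.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    return labels


def estimate_channel_regions(center: np.ndarray, atlas: ParcellationAtlas,
                             r: float, n: int, rng: np.random.Generator,
                             min_fraction: float,
                             normalize: str = "all") -> tuple[list, float, list]:
    samples = sample_sphere_uniform(np.asarray(center), r, n, rng)
    labels = label_points(samples, atlas)
    counts = pd.Series(labels).value_counts()
    n_background = int(counts.get(BACKGROUND_LABEL, 0))
    denom = n - n_background if normalize == "labeled" else n
    regions = []
    for label, count in counts.items():
        if label == BACKGROUND_LABEL:
            continue
        frac = count / denom if denom else 0.0
        regions.append((atlas.name_of(int(label)), float(frac)))
    regions.sort(key=lambda x: (-x[1], x[0]))
    background_fraction = (0.0 if normalize == "labeled" else n_background / n)
    detected = [name for name, frac in regions if frac >= min_fraction]
    return regions, background_fraction, detected


def region_table(channels: PointTable, atlas: ParcellationAtlas,
                 r: float = DEFAULT_SAMPLE_RADIUS_MM,
                 n: int = DEFAULT_SAMPLE_COUNT,
                 seed: int = 0,
                 min_fraction: float = DEFAULT_MIN_FRACTION,
                 normalize: str = "all") -> RegionTable:
    """Monte-Carlo region tabulation for every channel position.

    ``normalize="all"`` keeps background (non-brain) samples in the
    denominator; ``normalize="labeled"`` restricts fractions to labelled
    samples only. One sub-stream of ``seed`` is spawned per channel so the
    result for a channel does not depend on how many channels precede it.
    """
    if channels.frame != MNI:
        raise ValidationError("channel positions must be in the MNI frame")
    if normalize not in ("all", "labeled"):
        raise ValidationError(f"unknown normalization {normalize!r}")
    if not 0 <= min_fraction < 1:
        raise ValidationError("min_fraction must be in [0, 1)")
    root = np.random.default_rng(seed)
    streams = root.spawn(len(channels))
    estimates = []
    for (cid, center), rng in zip(channels, streams):
        regions, background, detected = estimate_channel_regions(
            center, atlas, r, n, rng, min_fraction, normalize)
        # under "labeled" normalization an all-background ball must still sum to 1
        if normalize == "labeled" and not regions:
            background = 1.0
        estimates.append(RegionEstimate(cid, regions, background, detected))
    params = {"r_mm": r, "n_samples": n, "seed": seed,
              "min_fraction": min_fraction, "normalize": normalize}
    return RegionTable(estimates, params)
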