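"""Synthetic heads, caps, atlases and multi-participant sessions.

Everything downstream of photo reconstruction can be exercised without any
external data: heads are nested ellipsoid meshes with the five fiducials at
their poles, caps are triangular-lattice optode layouts draped onto the
scalp, sessions simulate per-participant cap placement jitter, an MRI
"supine shift", and photo-frame measurement noise under a known ground-truth
photo-to-MNI affine, and atlases are label volumes with analytically known
region geometry.

The default head is scaled so its horizontal circumference matches the
~56 cm adult average; the default cap reproduces the 6-source/12-detector,
23-channel, 28-mm-separation layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ellipe

from .comparison_metrics import GroupPositions
from .cortical_projection import (
    DEFAULT_SEPARATION_MM,
    DEFAULT_SEPARATION_TOL,
    pair_channels,
    project_to_surface,
)
from .errors import CapPackingError, ValidationError
from .geometry_io import (
    MNI,
    PHOTO,
    LandmarkSet,
    Optode,
    OptodeSet,
    Point3,
    PointTable,
    SurfaceMesh,
)
from .registration import AffineTransform, apply_affine, invert_affine
from .region_estimation import ParcellationAtlas

#: Semi-axes giving a horizontal (x-y) circumference of ~56 cm and a
#: nasion-over-vertex-to-inion arc of ~28 cm.
DEFAULT_SEMI_AXES = (85.0, 95.0, 80.0)


# ---------------------------------------------------------------------------
# Heads


@dataclass
class SyntheticHeadSpec:
    semi_axes: tuple[float, float, float] = DEFAULT_SEMI_AXES
    cortex_shrink: float = 0.8
    subdivisions: int = 3
    seed: int = 0

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise ValidationError("semi-axes must be positive")
        if not 0 < self.cortex_shrink < 1:
            raise ValidationError("cortex shrink factor must be in (0, 1)")
        if self.subdivisions < 0:
            raise ValidationError("subdivision level must be >= 0")


@dataclass
class SyntheticHead:
    scalp: SurfaceMesh
    cortex: SurfaceMesh
    landmarks: LandmarkSet
    spec: SyntheticHeadSpec

    def nasion_inion_arc(self) -> float:
        """Analytic scalp arc nasion -> cz -> inion (half the y-z ellipse)."""
        _, b, c = self.spec.semi_axes
        return 0.5 * ellipse_perimeter(b, c)


def ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter via the complete elliptic integral."""
    big, small = max(a, b), min(a, b)
    m = 1.0 - (small / big) ** 2
    return float(4.0 * big * ellipe(m))


def icosphere(subdivisions: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere (vertices, faces) by icosahedron subdivision."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v) for v in verts]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = np.array(verts[i]) + np.array(verts[j])
                m /= np.linalg.norm(m)
                verts.append(tuple(m))
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.array(verts, dtype=float), np.array(faces, dtype=np.int64)


def make_head(spec: SyntheticHeadSpec | None = None) -> SyntheticHead:
    """Nested ellipsoid scalp/cortex meshes with fiducials at the poles.

    The cortex is the scalp scaled toward the origin by the shrink factor.
    Landmarks: nasion at the anterior pole (+y), inion posterior (-y), cz at
    the apex (+z), lpa/rpa at the lateral poles (-x left, +x right), in the
    MNI axis convention.
    """
    spec = spec or SyntheticHeadSpec()
    verts, faces = icosphere(spec.subdivisions)
    axes = np.array(spec.semi_axes)
    scalp = SurfaceMesh(verts * axes, faces, MNI)
    cortex = SurfaceMesh(verts * axes * spec.cortex_shrink, faces, MNI)
    a, b, c = spec.semi_axes
    landmarks = LandmarkSet({
        "nasion": Point3(0.0, b, 0.0, MNI),
        "inion": Point3(0.0, -b, 0.0, MNI),
        "cz": Point3(0.0, 0.0, c, MNI),
        "lpa": Point3(-a, 0.0, 0.0, MNI),
        "rpa": Point3(a, 0.0, 0.0, MNI),
    })
    return SyntheticHead(scalp, cortex, landmarks, spec)


# ---------------------------------------------------------------------------
# Caps

#: Triangular-lattice diamond (row lengths) and the source site indices that
#: give exactly 23 unit-distance source-detector pairs with no two sources
#: adjacent. Second-neighbour lattice distance is sqrt(3), so unwanted pairs
#: sit far outside the +/-20% separation band.
_DEFAULT_ROWS = (3, 4, 4, 4, 3)
_DEFAULT_SOURCE_SITES = (2, 3, 6, 9, 11, 14)
_DEFAULT_CHANNELS = 23


def cap_lattice(n_sources: int = 6, n_detectors: int = 12,
                sep: float = DEFAULT_SEPARATION_MM) -> tuple[np.ndarray, list[str]]:
    """Planar triangular-lattice cap layout.

    Returns (n, 2) planar coordinates (scaled by ``sep``; all pairwise
    distances scale linearly with ``sep``) and the role of each site. The
    6/12 default uses a fixed layout with exactly 23 unit-separation
    source-detector pairs; other counts fill the same lattice greedily and
    carry no channel-count guarantee.
    """
    if n_sources <= 0 or n_detectors <= 0:
        raise ValidationError("optode counts must be positive")
    if sep <= 0:
        raise ValidationError("separation must be positive")
    n = n_sources + n_detectors
    if n_sources == 6 and n_detectors == 12:
        rows, source_sites = _DEFAULT_ROWS, set(_DEFAULT_SOURCE_SITES)
    else:
        ncols = int(np.ceil(np.sqrt(n)))
        rows = []
        remaining = n
        while remaining > 0:
            take = min(ncols, remaining)
            rows.append(take)
            remaining -= take
        # spread sources evenly across the site sequence
        stride = n / n_sources
        source_sites = {int(round(i * stride)) for i in range(n_sources)}
        while len(source_sites) < n_sources:
            source_sites.add(max(source_sites) + 1)
        source_sites = {s for s in sorted(source_sites)[:n_sources]}
    sites = []
    for r, count in enumerate(rows):
        for col in range(count):
            sites.append((col + 0.5 * (r % 2), r * np.sqrt(3.0) / 2.0))
    if len(sites) < n:
        raise CapPackingError(
            f"lattice of {len(sites)} sites cannot hold {n} optodes")
    coords = np.array(sites[:n]) * sep
    coords -= coords.mean(axis=0)
    roles = ["source" if i in source_sites else "detector" for i in range(n)]
    return coords, roles


def _intended_pairs(coords: np.ndarray, roles: list[str],
                    sep: float) -> list[tuple[int, int]]:
    """Source-detector site pairs at (planar) lattice distance ``sep``."""
    pairs = []
    for i in range(len(coords)):
        for j in range(len(coords)):
            if roles[i] == "source" and roles[j] == "detector":
                if abs(np.linalg.norm(coords[i] - coords[j]) - sep) < 1e-6 * sep:
                    pairs.append((i, j))
    return pairs


def _drape_on_scalp(planar: np.ndarray, head: SyntheticHead) -> np.ndarray:
    """Map planar patch coordinates onto the left-lateral scalp surface.

    Uses the exponential map on a sphere centred at the origin (pole at the
    left preauricular direction, u toward anterior, v toward dorsal), pushes
    points radially onto the scalp ellipsoid, then snaps them to the mesh by
    closest-point projection so every optode lies exactly on the surface.
    """
    lpa = head.landmarks.points["lpa"].as_array()
    radius = np.linalg.norm(lpa)
    pole = lpa / radius
    e_u = np.array([0.0, 1.0, 0.0])   # anterior
    e_v = np.array([0.0, 0.0, 1.0])   # dorsal
    out = np.empty((len(planar), 3))
    for i, (u, v) in enumerate(planar):
        s = float(np.hypot(u, v))
        if s < 1e-12:
            direction = pole
        else:
            tangent = (u * e_u + v * e_v) / s
            ang = s / radius
            direction = np.cos(ang) * pole + np.sin(ang) * tangent
        # radial push onto the ellipsoid, then snap to the actual mesh
        axes = np.array(head.spec.semi_axes)
        t = 1.0 / np.sqrt(np.sum((direction / axes) ** 2))
        out[i] = direction * t
    table = PointTable([str(i) for i in range(len(out))], out, MNI)
    return project_to_surface(table, head.scalp).points.coords


def make_cap(head: SyntheticHead, n_sources: int = 6, n_detectors: int = 12,
             sep: float = DEFAULT_SEPARATION_MM, seed: int = 0) -> OptodeSet:
    """Drape a lattice cap onto the left-lateral scalp patch.

    The planar lattice is rescaled (a few fixed-point iterations) so that
    the intended source-detector pairs average the nominal separation after
    draping; for the 6/12 default the result is verified to yield exactly
    23 channels at ``pair_channels(sep, tol=0.2)`` and a
    :class:`CapPackingError` is raised otherwise.
    """
    planar, roles = cap_lattice(n_sources, n_detectors, sep)
    pairs = _intended_pairs(planar, roles, sep)
    scale = 1.0
    coords = _drape_on_scalp(planar, head)
    for _ in range(4):
        if not pairs:
            break
        mean_sep = float(np.mean([
            np.linalg.norm(coords[i] - coords[j]) for i, j in pairs]))
        scale *= sep / mean_sep
        coords = _drape_on_scalp(planar * scale, head)

    n_s = n_d = 0
    optodes = []
    for role, xyz in zip(roles, coords):
        if role == "source":
            n_s += 1
            oid = f"S{n_s}"
        else:
            n_d += 1
            oid = f"D{n_d:02d}"
        optodes.append(Optode(oid, role, Point3.from_array(xyz, MNI)))
    cap = OptodeSet(optodes)

    if n_sources == 6 and n_detectors == 12 and sep == DEFAULT_SEPARATION_MM:
        n_channels = len(pair_channels(cap, sep, DEFAULT_SEPARATION_TOL))
        if n_channels != _DEFAULT_CHANNELS:
            raise CapPackingError(
                f"default cap produced {n_channels} channels, "
                f"expected {_DEFAULT_CHANNELS}")
    return cap


# ---------------------------------------------------------------------------
# Sessions


def default_photo_affine() -> AffineTransform:
    """A fixed, well-conditioned ground-truth photo-to-MNI affine.

    Rotation of 20 degrees about a skew axis, anisotropic scale around 0.5
    (photogrammetric reconstructions carry arbitrary global scale), and a
    translation; condition number is far below the fit-recovery limit.
    """
    ang = np.deg2rad(20.0)
    axis = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    rot = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)
    linear = rot @ np.diag([2.0, 2.1, 1.9])
    translation = np.array([12.0, -35.0, 20.0])
    return AffineTransform(linear, translation, 0.0, PHOTO, MNI)


@dataclass
class SessionSpec:
    n_participants: int = 10
    jitter_sd: float = 3.0          # per-axis cap placement jitter (mm)
    shift: tuple[float, float, float] = (0.0, 5.0, 5.0)  # MRI supine shift (mm)
    noise_sd: float = 1.0           # per-axis measurement noise (mm)
    affine: AffineTransform = field(default_factory=default_photo_affine)
    post_shift_fraction: float = 0.0  # residual shift left in the post session
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValidationError("participant count must be >= 1")
        if self.jitter_sd < 0 or self.noise_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")


@dataclass
class PORObservation:
    """One participant's photo-frame session: landmarks plus optode picks."""

    landmarks: LandmarkSet
    optodes: PointTable


@dataclass
class SimulatedSessions:
    """Ground truth and per-session observations for a simulated cohort."""

    ground_truth: GroupPositions          # true per-participant MNI placements
    mri_truth: GroupPositions             # placements under the supine shift
    por_pre: dict[str, PORObservation]    # photo frame
    por_post: dict[str, PORObservation]   # photo frame
    mri: GroupPositions                   # MNI frame, noisy observations
    template_landmarks: LandmarkSet       # MNI fiducials for registration
    true_affine: AffineTransform
    spec: SessionSpec

    @property
    def participant_ids(self) -> list[str]:
        return list(self.ground_truth.participants)


def _tangent_jitter(coords: np.ndarray, scalp: SurfaceMesh, sd: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Jitter points in the local scalp tangent plane, then re-project.

    Caps slide on heads rather than floating off them, so the radial jitter
    component is removed before re-projection.
    """
    if sd == 0:
        return coords.copy()
    table = PointTable([str(i) for i in range(len(coords))], coords, scalp.frame)
    proj = project_to_surface(table, scalp)
    normals = scalp.face_normals()[proj.face_indices]
    g = rng.normal(scale=sd, size=coords.shape)
    tangent = g - (np.sum(g * normals, axis=1, keepdims=True)) * normals
    moved = table.with_coords(proj.points.coords + tangent)
    return project_to_surface(moved, scalp).points.coords


def _reproject(coords: np.ndarray, scalp: SurfaceMesh) -> np.ndarray:
    table = PointTable([str(i) for i in range(len(coords))], coords, scalp.frame)
    return project_to_surface(table, scalp).points.coords


def simulate_sessions(head: SyntheticHead, cap: OptodeSet,
                      spec: SessionSpec | None = None) -> SimulatedSessions:
    """Simulate pre-POR, MRI and post-POR sessions for a cohort.

    Per participant the true cap placement is the nominal cap jittered in
    the scalp tangent plane and re-projected. The MRI session adds the
    supine shift vector before re-projection (plus MNI-frame measurement
    noise); the POR sessions observe the placement in the photo frame (the
    inverse of the ground-truth affine) with measurement noise on both
    landmarks and optodes. With all noise terms zero the full pipeline
    closes on the ground truth exactly.
    """
    spec = spec or SessionSpec()
    rng = np.random.default_rng(spec.seed)
    ids = cap.ids()
    inverse = invert_affine(spec.affine)
    shift = np.asarray(spec.shift, dtype=float)

    truths, mri_truths, mri_obs = {}, {}, {}
    por_pre, por_post = {}, {}
    template = head.landmarks
    template_coords = template.coords()

    def noisy(coords):
        if spec.noise_sd == 0:
            return coords
        return coords + rng.normal(scale=spec.noise_sd, size=coords.shape)

    def observe_photo(placement_mni: np.ndarray) -> PORObservation:
        mni_table = PointTable(ids, placement_mni, MNI)
        photo = apply_affine(inverse, mni_table)
        lm_photo = inverse.transform(template_coords)
        return PORObservation(
            LandmarkSet.from_arrays(noisy(lm_photo), PHOTO),
            photo.with_coords(noisy(photo.coords)),
        )

    for p in range(spec.n_participants):
        pid = f"P{p + 1:02d}"
        placement = _tangent_jitter(
            cap.to_point_table().coords, head.scalp, spec.jitter_sd, rng)
        truths[pid] = PointTable(ids, placement, MNI)

        mri_placement = _reproject(placement + shift, head.scalp)
        mri_truths[pid] = PointTable(ids, mri_placement, MNI)
        mri_obs[pid] = PointTable(ids, noisy(mri_placement), MNI)

        por_pre[pid] = observe_photo(placement)
        post_placement = placement
        if spec.post_shift_fraction:
            post_placement = _reproject(
                placement + spec.post_shift_fraction * shift, head.scalp)
        por_post[pid] = observe_photo(post_placement)

    return SimulatedSessions(
        GroupPositions(truths), GroupPositions(mri_truths),
        por_pre, por_post, GroupPositions(mri_obs),
        template, spec.affine, spec,
    )


def register_session(observations: dict[str, PORObservation],
                     template_landmarks: LandmarkSet) -> GroupPositions:
    """Register every participant's photo-frame session into MNI space."""
    from .registration import register_optodes

    registered = {}
    for pid, obs in observations.items():
        registered[pid], _ = register_optodes(
            obs.landmarks, template_landmarks, obs.optodes)
    return GroupPositions(registered)


# ---------------------------------------------------------------------------
# Atlases

ATLAS_GEOMETRIES = ("half-spaces", "nested-shells", "voronoi")


def make_atlas(geometry: str = "half-spaces",
               shape: tuple[int, int, int] = (64, 64, 64),
               labels: list[str] | None = None,
               seed: int = 0,
               extent: float = 90.0) -> ParcellationAtlas:
    """Synthetic parcellation volumes with known region geometry.

    ``half-spaces``: label 1 where x < 0, label 2 where x >= 0 (analytic
    50/50 split for any ball centred on the x = 0 plane).
    ``nested-shells``: concentric radial shells with analytic volumes;
    background outside the outer radius.
    ``voronoi``: nearest of k seeded sites (k = number of labels,
    default 5); deterministic for a fixed seed.

    The voxel-to-world affine maps the grid onto the cube
    [-extent, extent]^3 (mm).
    """
    if geometry not in ATLAS_GEOMETRIES:
        raise ValidationError(f"unknown atlas geometry {geometry!r}")
    shape = tuple(int(s) for s in shape)
    spacing = [2.0 * extent / (s - 1) for s in shape]
    affine = np.diag(spacing + [1.0])
    affine[:3, 3] = -extent
    grids = np.meshgrid(*[
        np.linspace(-extent, extent, s) for s in shape
    ], indexing="ij")
    x, y, z = grids

    if geometry == "half-spaces":
        names = labels or ["left-region", "right-region"]
        if len(names) != 2:
            raise ValidationError("half-spaces geometry takes exactly 2 labels")
        data = np.where(x < 0, 1, 2).astype(np.int16)
    elif geometry == "nested-shells":
        names = labels or ["core", "mid-shell", "outer-shell"]
        radius = np.sqrt(x**2 + y**2 + z**2)
        bounds = np.linspace(0, extent, len(names) + 1)[1:]
        data = np.zeros(shape, dtype=np.int16)
        for i, rb in enumerate(reversed(bounds)):
            data[radius <= rb] = len(names) - i
    else:  # voronoi
        names = labels or [f"cell-{i + 1}" for i in range(5)]
        rng = np.random.default_rng(seed)
        sites = rng.uniform(-extent, extent, size=(len(names), 3))
        pts = np.stack([x, y, z], axis=-1)
        d2 = np.sum((pts[..., None, :] - sites) ** 2, axis=-1)
        data = (np.argmin(d2, axis=-1) + 1).astype(np.int16)

    return ParcellationAtlas(
        data, affine, {i + 1: n for i, n in enumerate(names)})


def shell_bounds(n_shells: int, extent: float = 90.0) -> np.ndarray:
    """Outer radii of the nested-shells geometry, for analytic checks."""
    return np.linspace(0, extent, n_shells + 1)[1:]
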