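"""Landmark-based affine registration between the photo and MNI frames.

The transform is the 12-parameter affine (3x3 linear part plus translation)
that minimises the summed squared residuals over the five fiducial
correspondences — 15 equations for 12 unknowns, solved by ordinary least
squares. Because an affine absorbs global scale, the scale ambiguity
inherent to photogrammetric reconstruction drops out of the registered
coordinates.

A negative determinant means the source reconstruction is mirrored; the fit
still succeeds but is flagged with a warning, as is an RMS residual above
``RMS_WARN_MM`` (half the nominal 28 mm optode separation), which usually
indicates mis-picked landmarks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateFitError, FrameMismatchError, ValidationError
from .geometry_io import LANDMARK_NAMES, MNI, LandmarkSet, PointTable

#: fit_rms above this (mm) triggers a landmark-quality warning.
RMS_WARN_MM = 10.0


class RegistrationWarning(UserWarning):
    """Non-fatal issue detected while fitting a transform."""


@dataclass
class AffineTransform:
    """p_target = linear @ p_source + translation."""

    linear: np.ndarray       # (3, 3), unitless
    translation: np.ndarray  # (3,), mm
    fit_rms: float = 0.0     # mm, RMS residual of the landmark fit
    source_frame: str = "photo"
    target_frame: str = MNI

    def __post_init__(self):
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.linear)) <= 1e-9:
            raise DegenerateFitError("affine linear part is singular")
        if self.fit_rms < 0:
            raise ValidationError("fit_rms must be non-negative")

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.linear))

    @property
    def is_mirrored(self) -> bool:
        return self.determinant < 0

    def matrix4(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.linear
        m[:3, 3] = self.translation
        return m

    def transform(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.linear.T + self.translation

    def to_json(self, path=None) -> str:
        payload = {
            "linear": self.linear.tolist(),
            "translation": self.translation.tolist(),
            "fit_rms": self.fit_rms,
            "source_frame": self.source_frame,
            "target_frame": self.target_frame,
            "determinant": self.determinant,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path) -> "AffineTransform":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            np.array(payload["linear"]),
            np.array(payload["translation"]),
            float(payload.get("fit_rms", 0.0)),
            payload.get("source_frame", "photo"),
            payload.get("target_frame", MNI),
        )

    @classmethod
    def identity(cls, source_frame: str = "photo", target_frame: str = MNI):
        return cls(np.eye(3), np.zeros(3), 0.0, source_frame, target_frame)


def fit_affine(source: LandmarkSet, target: LandmarkSet) -> AffineTransform:
    """Least-squares affine mapping ``source`` landmarks onto ``target``.

    Landmarks are matched by canonical name. Raises
    :class:`DegenerateFitError` when the source set is coplanar (the
    LandmarkSet constructor already enforces this, so the check here guards
    hand-built sets) and :class:`FrameMismatchError` when both sets share a
    frame that makes the fit a no-op mistake (identical frames are allowed
    only when they genuinely coincide, e.g. MNI→MNI session comparison, so
    no error is raised for that case).
    """
    if source.coplanar():
        raise DegenerateFitError("source landmarks are coplanar")
    src = source.coords()
    dst = target.coords()
    # design matrix rows [x y z 1]; solve for the (4, 3) parameter block
    design = np.hstack([src, np.ones((len(LANDMARK_NAMES), 1))])
    params, *_ = np.linalg.lstsq(design, dst, rcond=None)
    linear = params[:3].T
    translation = params[3]
    residuals = design @ params - dst
    fit_rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    tf = AffineTransform(linear, translation, fit_rms, source.frame, target.frame)
    if tf.is_mirrored:
        warnings.warn(
            f"fitted affine has negative determinant ({tf.determinant:.4g}); "
            "the source reconstruction appears mirrored",
            RegistrationWarning,
            stacklevel=2,
        )
    if fit_rms > RMS_WARN_MM:
        warnings.warn(
            f"landmark fit RMS {fit_rms:.2f} mm exceeds {RMS_WARN_MM} mm; "
            "check landmark picking",
            RegistrationWarning,
            stacklevel=2,
        )
    return tf


def apply_affine(tf: AffineTransform, points: PointTable) -> PointTable:
    """Map a point table through ``tf``; output is tagged with the target frame."""
    if points.frame != tf.source_frame:
        raise FrameMismatchError(
            f"points are in frame {points.frame!r} but transform expects "
            f"{tf.source_frame!r}"
        )
    return PointTable(list(points.ids), tf.transform(points.coords), tf.target_frame)


def invert_affine(tf: AffineTransform) -> AffineTransform:
    """The inverse map; fit_rms is carried over unchanged."""
    inv = np.linalg.inv(tf.linear)
    return AffineTransform(
        inv, -inv @ tf.translation, tf.fit_rms, tf.target_frame, tf.source_frame
    )


def register_optodes(
    landmarks: LandmarkSet,
    template_landmarks: LandmarkSet,
    optodes: PointTable,
) -> tuple[PointTable, AffineTransform]:
    """Fit the landmark affine and carry ``optodes`` into the template frame.

    This is the core registration step of the pipeline: photo-frame
    landmarks are matched against the template (MNI) landmarks, and the
    resulting transform is applied to the photo-frame optode positions.
    """
    tf = fit_affine(landmarks, template_landmarks)
    return apply_affine(tf, optodes), tf
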