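"""Rigid template registration and scalar-field transfer.

Per-subject articular patches are rigidly aligned to a template patch with
iterative closest point (point-to-point, Kabsch update), and measurement
fields are resampled onto template vertices by closest-point barycentric
interpolation.  Non-rigid matching is deliberately out of scope: synthetic
cohorts are generated with exact vertex correspondence, so rigid alignment
plus closest-point transfer is sufficient to validate the statistics layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .proximity import MeshProximity
from .surface import JointPatch, ScalarField, SurfaceMesh

__all__ = [
    "RigidTransform",
    "RegistrationError",
    "TemplateAtlas",
    "kabsch",
    "icp_rigid",
    "transfer_field",
]

log = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    """ICP diverged or the surfaces cannot be brought into correspondence."""


@dataclass
class RigidTransform:
    """Proper rigid transform: x -> rotation @ x + translation (mm)."""

    rotation: np.ndarray = dc_field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be a proper rotation (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(
        cls, axis: np.ndarray, angle_deg: float, translation: np.ndarray | None = None
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        a = np.deg2rad(angle_deg)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        r = np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)
        return cls(r, np.zeros(3) if translation is None else translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: SurfaceMesh) -> SurfaceMesh:
        return mesh.transformed(self.rotation, self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self . other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @property
    def angle_deg(self) -> float:
        """Rotation magnitude in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    def save(self, path: str | Path) -> None:
        np.savetxt(str(path), self.to_matrix(), fmt="%.12g")

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_matrix(np.loadtxt(str(path)))


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping paired source points onto target."""
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    cs, ct = source.mean(axis=0), target.mean(axis=0)
    h = (source - cs).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, ct - r @ cs)


def icp_rigid(
    source: SurfaceMesh,
    target: SurfaceMesh,
    max_iter: int = 100,
    tol: float = 1e-4,
    fail_threshold: float = 2.0,
) -> RigidTransform:
    """Iterative closest point with point-to-point Kabsch updates.

    Starts from centroid alignment; stops when the RMS correspondence
    distance changes by less than ``tol`` mm or after ``max_iter`` rounds.
    Correspondences are closest points on the target *surface* (not nearest
    vertices), which avoids the lattice-locking local minima that vertex
    correspondences exhibit for in-plane motion of regularly meshed patches.
    Raises :class:`RegistrationError` when the RMS increases five times in a
    row (divergence) or the converged RMS exceeds ``fail_threshold`` mm,
    which indicates surfaces that do not actually overlap.
    """
    query = MeshProximity(target.vertices, target.faces)
    current = RigidTransform(np.eye(3), target.vertices.mean(0) - source.vertices.mean(0))
    pts = current.apply(source.vertices)
    history: list[float] = []
    rises = 0
    prev = np.inf
    for _ in range(max_iter):
        closest, dist, _, _ = query.query(pts)
        rms = float(np.sqrt(np.mean(dist**2)))
        history.append(rms)
        if rms > prev + 1e-12:
            rises += 1
            if rises >= 5:
                raise RegistrationError(
                    f"registration failed: RMS increased 5 consecutive iterations "
                    f"(history tail {history[-6:]})"
                )
        else:
            rises = 0
        if abs(prev - rms) < tol:
            break
        prev = rms
        step = kabsch(pts, closest)
        current = step.compose(current)
        pts = current.apply(source.vertices)
    final = history[-1] if history else np.inf
    if final > fail_threshold:
        raise RegistrationError(
            f"registration failed: converged RMS {final:.3f} mm exceeds "
            f"fail_threshold {fail_threshold:.3f} mm (surfaces do not overlap)"
        )
    return current


def transfer_field(
    source_patch: JointPatch,
    field: ScalarField,
    template_patch: JointPatch,
    transform: RigidTransform | None = None,
    cutoff: float = 2.0,
) -> ScalarField:
    """Resample a source field onto template vertices.

    Each template vertex takes the barycentric interpolation of the field at
    its closest point on the (transformed) source patch; template vertices
    farther than ``cutoff`` mm from the source surface, or supported by any
    invalid source vertex, are masked.
    """
    if transform is None:
        transform = RigidTransform.identity()
    src = transform.apply_mesh(source_patch.submesh)
    query = MeshProximity(src.vertices, src.faces)
    _, dist, tri_id, bary = query.query(template_patch.submesh.vertices)
    corner_vals = field.values[src.faces[tri_id]]
    corner_ok = field.mask[src.faces[tri_id]]
    values = np.einsum("ij,ij->i", bary, corner_vals)
    mask = (dist <= cutoff) & corner_ok.all(axis=1) & np.isfinite(values)
    n_dropped = int((~mask).sum())
    if n_dropped:
        log.info("transfer_field: %d template vertices masked (cutoff %.2f mm)", n_dropped, cutoff)
    return ScalarField(np.where(mask, values, 0.0), mask)


@dataclass
class TemplateAtlas:
    """Template patches plus per-subject fields resampled onto their vertices."""

    patches: dict[str, JointPatch]
    stacked: dict[str, list[ScalarField]] = dc_field(default_factory=dict)
    record_labels: dict[str, list[str]] = dc_field(default_factory=dict)

    def add_field(self, label: str, field: ScalarField, record: str = "") -> None:
        patch = self.patches[label]
        if len(field) != patch.n_vertices:
            raise ValueError(f"field length does not match template patch {label!r}")
        self.stacked.setdefault(label, []).append(field)
        self.record_labels.setdefault(label, []).append(record)

    def stacked_arrays(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(values, mask) arrays of shape (n_records, n_vertices)."""
        fields = self.stacked[label]
        vals = np.stack([np.where(f.mask, f.values, np.nan) for f in fields])
        mask = np.stack([f.mask for f in fields])
        return vals, mask

    def to_csv(self, label: str, path: str | Path) -> None:
        """CSV matrix: rows = template vertices, columns = records."""
        import pandas as pd

        vals, _ = self.stacked_arrays(label)
        pd.DataFrame(vals.T, columns=self.record_labels[label]).to_csv(path, index_label="vertex")
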