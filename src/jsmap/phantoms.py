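"""Synthetic articulating-joint phantoms and cohort simulation.

Real weight-bearing CT of the ankle is not redistributable, so the package
ships a generator that emulates the measurement situation instead: two
opposing cortical-bone surfaces separated by a known gap field g(u, v) in
the 1.9-2.9 mm range, rasterized into isotropic voxel volumes (0.37 mm
default) with Gaussian point-spread blur and additive intensity noise.
Cohorts add between-subject gap variation, repeat "visits" with fresh noise
and small pose changes, operator-dependent patch-perimeter variation, and a
per-vertex slope linking plantarflexion angle to the true gap.

The opposing surface is built by offsetting the reference surface along its
normals, so every reference vertex has an exact ground-truth gap and exact
template correspondence — the property the statistics layer is validated
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import dijkstra
from scipy import sparse

from .raster import voxelize_solid
from .register import RigidTransform
from .surface import JointPatch, ScalarField, SurfaceMesh, patch_submesh, smooth_field
from .volume import VoxelVolume

__all__ = [
    "GapField",
    "PhantomSpec",
    "JointPhantom",
    "CohortSpec",
    "CohortRecord",
    "CohortData",
    "PhantomSpecError",
    "make_joint_phantom",
    "rasterize_ct",
    "perturb_perimeter",
    "simulate_cohort",
    "simulate_field_cohort",
    "anterior_effect_map",
]

FACET_LABELS = ("talonavicular", "dome-medial", "lateral-gutter", "posterior-subtalar")


class PhantomSpecError(ValueError):
    """Invalid phantom or cohort specification."""


@dataclass
class GapField:
    """Parametric gap g(u, v) >= 0 in mm over the reference surface.

    kinds:
      constant     params: value
      ramp         params: lo, hi  (linear in u across the core extent)
      bump         params: base, amplitude, width (radial Gaussian bump)
    """

    kind: Literal["constant", "ramp", "bump"] = "constant"
    value: float = 2.0
    lo: float = 1.9
    hi: float = 2.9
    base: float = 2.0
    amplitude: float = 0.5
    width: float = 5.0

    def evaluate(self, u: np.ndarray, v: np.ndarray, extent: float) -> np.ndarray:
        u = np.asarray(u, float)
        v = np.asarray(v, float)
        if self.kind == "constant":
            return np.full_like(u, float(self.value))
        if self.kind == "ramp":
            return self.lo + (self.hi - self.lo) * (u / extent + 0.5)
        if self.kind == "bump":
            r2 = u**2 + v**2
            return self.base + self.amplitude * np.exp(-0.5 * r2 / self.width**2)
        raise PhantomSpecError(f"unknown gap field kind {self.kind!r}")


@dataclass
class PhantomSpec:
    """Geometry of one synthetic articulating joint.

    ``extent`` is the side length (mm) of the measured articular patch; the
    bone surfaces and bodies extend a further ``rim`` mm on each side so
    that intensity profiles near the patch edge stay inside bone, as they
    would against real anatomy.  ``shell`` is the cortical body thickness.
    """

    geometry: Literal["parallel-slabs", "ball-and-socket", "saddle"] = "parallel-slabs"
    extent: float = 20.0
    gap_field: GapField = dc_field(default_factory=GapField)
    mesh_resolution: float = 1.0
    rim: float = 3.0
    shell: float = 5.0
    pose: RigidTransform | None = None
    sphere_radius: float = 30.0
    saddle_scale: float = 50.0

    def __post_init__(self) -> None:
        if self.mesh_resolution <= 0:
            raise PhantomSpecError("mesh_resolution must be > 0")
        if self.extent <= 0:
            raise PhantomSpecError("extent must be > 0")
        if self.shell < 2.0:
            raise PhantomSpecError("cortical shell must be >= 2 mm")


@dataclass
class JointPhantom:
    """Reference/opposing articular surfaces with exact per-vertex truth.

    ``reference`` normals point across the gap toward the opposing bone.
    ``reference_body`` / ``opposing_body`` are the closed solids consumed by
    :func:`rasterize_ct`.  ``patch_mask`` flags the core articular region
    (the measured patch) on the reference surface.
    """

    reference: SurfaceMesh
    opposing: SurfaceMesh
    truth: ScalarField
    reference_body: SurfaceMesh
    opposing_body: SurfaceMesh
    patch_mask: np.ndarray
    spec: PhantomSpec

    def patch(self, label: str = "articular") -> JointPatch:
        return patch_submesh(self.reference, self.patch_mask, label)


def _grid_surface(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Parameter grid (u, v), positions and unit normals for the geometry."""
    total = spec.extent + 2.0 * spec.rim
    n = max(2, int(round(total / spec.mesh_resolution))) + 1
    coords = np.linspace(-total / 2.0, total / 2.0, n)
    uu, vv = np.meshgrid(coords, coords, indexing="ij")
    u, v = uu.ravel(), vv.ravel()
    if spec.geometry == "parallel-slabs":
        p = np.column_stack([u, v, np.zeros_like(u)])
        nrm = np.tile([0.0, 0.0, 1.0], (len(u), 1))
    elif spec.geometry == "ball-and-socket":
        r = spec.sphere_radius
        if total / 2.0 * np.sqrt(2.0) >= r:
            raise PhantomSpecError("extent too large for sphere_radius")
        h = np.sqrt(r**2 - u**2 - v**2)
        p = np.column_stack([u, v, h - r])
        nrm = np.column_stack([u, v, h]) / r
    elif spec.geometry == "saddle":
        c = spec.saddle_scale
        p = np.column_stack([u, v, (u**2 - v**2) / (2.0 * c)])
        nrm = np.column_stack([-u / c, v / c, np.ones_like(u)])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    else:
        raise PhantomSpecError(f"unknown geometry {spec.geometry!r}")
    return u, v, p, nrm, coords


def _grid_faces(n: int) -> np.ndarray:
    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    return np.concatenate([np.column_stack([a, b, c]), np.column_stack([a, c, d])])


def _closed_body(top: np.ndarray, bottom: np.ndarray, faces: np.ndarray) -> SurfaceMesh:
    """Closed solid between two congruent grid sheets."""
    n = len(top)
    verts = np.vstack([top, bottom])
    top_faces = faces
    bot_faces = faces[:, ::-1] + n
    # boundary edges = edges used by exactly one face
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[counts[inv] == 1]
    walls = np.concatenate(
        [
            np.column_stack([boundary[:, 1], boundary[:, 0], boundary[:, 0] + n]),
            np.column_stack([boundary[:, 1], boundary[:, 0] + n, boundary[:, 1] + n]),
        ]
    )
    return SurfaceMesh(verts, np.vstack([top_faces, bot_faces, walls]))


def make_joint_phantom(
    spec: PhantomSpec,
    gap_override: np.ndarray | None = None,
) -> JointPhantom:
    """Build a phantom: reference surface, normal-offset opposing surface,
    exact truth field and closed cortical bodies.

    ``gap_override`` replaces the parametric gap with explicit per-vertex
    values on the reference grid (used by the cohort simulator).
    """
    u, v, p, nrm, coords = _grid_surface(spec)
    n = len(coords)
    faces = _grid_faces(n)
    if gap_override is not None:
        g = np.asarray(gap_override, dtype=float).ravel()
        if g.shape != u.shape:
            raise PhantomSpecError("gap_override must have one value per grid vertex")
    else:
        g = spec.gap_field.evaluate(u, v, spec.extent)
    if np.any(g <= 0):
        raise PhantomSpecError("gap_field must be strictly positive everywhere")

    reference = SurfaceMesh(p, faces, nrm)
    opposing = SurfaceMesh(p + g[:, None] * nrm, faces[:, ::-1].copy(), -nrm)
    reference_body = _closed_body(p, p - spec.shell * nrm, faces)
    opposing_body = _closed_body(p + (g + spec.shell)[:, None] * nrm, p + g[:, None] * nrm, faces)
    truth = ScalarField(g.copy(), np.ones(len(g), dtype=bool))
    half = spec.extent / 2.0 + 1e-9
    patch_mask = (np.abs(u) <= half) & (np.abs(v) <= half)

    if spec.pose is not None:
        t = spec.pose
        reference = t.apply_mesh(reference)
        opposing = t.apply_mesh(opposing)
        reference_body = t.apply_mesh(reference_body)
        opposing_body = t.apply_mesh(opposing_body)
    return JointPhantom(reference, opposing, truth, reference_body, opposing_body, patch_mask, spec)


# ----------------------------------------------------------------------
# CT-like rasterization


def rasterize_ct(
    pair: JointPhantom | tuple[SurfaceMesh, SurfaceMesh],
    spacing: float = 0.37,
    psf_sigma: float = 0.5,
    noise_sd: float = 20.0,
    bone_intensity: float = 1000.0,
    background_intensity: float = 0.0,
    seed: int | None = None,
    supersample: int = 4,
    margin: float = 4.0,
) -> VoxelVolume:
    """Rasterize two closed bone bodies into a CT-like volume.

    Voxel intensity is ``background + (bone - background) * occupancy``
    where occupancy is the fraction of the voxel inside either body
    (estimated on a ``supersample``-times finer grid; ``supersample=1``
    degenerates to binary centre sampling).  The result is convolved with
    an isotropic Gaussian PSF of SD ``psf_sigma`` mm and i.i.d. Gaussian
    noise of SD ``noise_sd`` is added.  Deterministic given ``seed``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if psf_sigma < 0:
        raise ValueError("psf_sigma must be >= 0")
    if isinstance(pair, JointPhantom):
        bodies = (pair.reference_body, pair.opposing_body)
    else:
        bodies = pair
    all_verts = np.vstack([b.vertices for b in bodies])
    lo = all_verts.min(axis=0) - margin
    hi = all_verts.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    origin = lo
    ss = int(supersample)
    if ss < 1:
        raise ValueError("supersample must be >= 1")
    fine_spacing = spacing / ss
    fine_origin = origin - spacing / 2.0 + fine_spacing / 2.0
    fine_shape = tuple(s * ss for s in shape)
    occ = np.zeros(fine_shape, dtype=bool)
    for b in bodies:
        occ |= voxelize_solid(b.vertices, b.faces, fine_origin, fine_spacing, fine_shape)
    if ss > 1:
        frac = occ.reshape(shape[0], ss, shape[1], ss, shape[2], ss).mean(axis=(1, 3, 5))
    else:
        frac = occ.astype(float)
    img = background_intensity + (bone_intensity - background_intensity) * frac
    if psf_sigma > 0:
        img = gaussian_filter(img, sigma=psf_sigma / spacing, mode="nearest")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return VoxelVolume(img, spacing, origin)


# ----------------------------------------------------------------------
# operator perimeter simulation


def _smooth_random_field(mesh: SurfaceMesh, rng: np.random.Generator, iterations: int = 10) -> np.ndarray:
    """Unit-SD smooth random field on mesh vertices (umbrella-filtered noise)."""
    raw = ScalarField(rng.standard_normal(mesh.n_vertices))
    sm = smooth_field(raw, mesh, iterations=iterations, weight=1.0).values
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def perturb_perimeter(
    mask: np.ndarray,
    mesh: SurfaceMesh,
    magnitude: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Erode/dilate a patch boundary by a smooth random signed offset.

    The boundary moves in or out by a smooth field with RMS amplitude
    ``magnitude`` mm along the surface; the interior far from the boundary
    is unchanged.  Emulates inter-operator variation in manual perimeter
    segmentation.  ``magnitude = 0`` returns the mask unchanged.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    mask = np.asarray(mask, dtype=bool).ravel()
    if magnitude == 0 or mask.all() or not mask.any():
        return mask.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # weighted vertex graph for geodesic-ish distances
    f = mesh.faces
    i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    w = np.linalg.norm(mesh.vertices[i] - mesh.vertices[j], axis=1)
    n = mesh.n_vertices
    g = sparse.coo_matrix((w, (i, j)), shape=(n, n))
    g = g.maximum(g.T).tocsr()
    idx_in = np.flatnonzero(mask)
    idx_out = np.flatnonzero(~mask)
    d_to_out = dijkstra(g, indices=idx_out, min_only=True)
    d_to_in = dijkstra(g, indices=idx_in, min_only=True)
    signed = np.where(mask, d_to_out, -d_to_in)
    offset = magnitude * _smooth_random_field(mesh, rng)
    return signed > offset


# ----------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortSpec:
    """Study design for a simulated repeat-imaging cohort.

    Defaults follow the emulated study conditions: 23 subjects, two visits
    within months of each other, two operators, per-subject plantarflexion
    angles with SD ~9 degrees, image noise SD 20 on a bone contrast of
    1000, and ~0.1 mm per-vertex measurement noise at the field level.
    """

    n_subjects: int = 23
    visits: int = 2
    operators: int = 2
    gap_base: PhantomSpec = dc_field(default_factory=PhantomSpec)
    between_subject_sd: float = 0.5  # mm, smooth random gap modulation
    visit_noise_sd: float = 20.0  # image intensity noise per visit
    measurement_noise_sd: float = 0.1  # mm, field-level per-vertex noise
    visit_pose_jitter: tuple[float, float] = (2.0, 1.0)  # max rot deg, max trans mm
    angle_values: np.ndarray | None = None  # per-subject plantarflexion, deg
    angle_visit_values: np.ndarray | None = None  # (n_subjects, visits) override
    interval_values: np.ndarray | None = None  # per-subject days override
    angle_sd: float = 9.3
    effect_map: np.ndarray | None = None  # mm per degree, per reference-grid vertex
    perimeter_jitter: float = 1.0  # mm
    interval_mean: float = 74.0  # days between visits
    interval_sd: float = 29.6
    min_gap: float = 0.2  # mm, floor applied to the true gap
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise PhantomSpecError("n_subjects must be >= 2")
        for name in ("between_subject_sd", "visit_noise_sd", "measurement_noise_sd",
                     "perimeter_jitter", "angle_sd", "interval_sd"):
            if getattr(self, name) < 0:
                raise PhantomSpecError(f"{name} must be >= 0")
        if self.angle_values is not None:
            self.angle_values = np.asarray(self.angle_values, dtype=float).ravel()
            if len(self.angle_values) != self.n_subjects:
                raise PhantomSpecError("angle_values length must equal n_subjects")
        if self.angle_visit_values is not None:
            self.angle_visit_values = np.asarray(self.angle_visit_values, dtype=float)
            if self.angle_visit_values.shape != (self.n_subjects, self.visits):
                raise PhantomSpecError("angle_visit_values must be (n_subjects, visits)")
        if self.interval_values is not None:
            self.interval_values = np.asarray(self.interval_values, dtype=float).ravel()
            if len(self.interval_values) != self.n_subjects:
                raise PhantomSpecError("interval_values length must equal n_subjects")


@dataclass
class CohortRecord:
    subject: int
    visit: int
    operator: int
    field: ScalarField | None = None  # measured/emulated JSW on the template
    phantom: JointPhantom | None = None
    volume: VoxelVolume | None = None
    patch_mask: np.ndarray | None = None  # operator's perimeter on the reference mesh


@dataclass
class CohortData:
    """Simulated cohort with ground truth on a shared template patch."""

    template: JointPatch
    records: list[CohortRecord]
    ground_truth: np.ndarray  # (n_subjects, visits, n_template_vertices), mm
    covariates: pd.DataFrame  # subject, visit, operator, angle_deg, interval_days, seed
    spec: CohortSpec

    def record(self, subject: int, visit: int, operator: int) -> CohortRecord:
        for r in self.records:
            if (r.subject, r.visit, r.operator) == (subject, visit, operator):
                return r
        raise KeyError((subject, visit, operator))


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(t) for t in tags]])


def anterior_effect_map(spec: PhantomSpec, slope: float = 0.1) -> np.ndarray:
    """Per-vertex angle slope (mm/deg): ``slope`` on the anterior (u > extent/4)
    core region, zero elsewhere.  Emulates gap widening with plantarflexion
    at the anterior aspect of a facet."""
    u, v, _, _, _ = _grid_surface(spec)
    half = spec.extent / 2.0 + 1e-9
    core = (np.abs(u) <= half) & (np.abs(v) <= half)
    return np.where(core & (u > spec.extent / 4.0), slope, 0.0)


def _subject_truths(spec: CohortSpec, ref: SurfaceMesh, angles_sv: np.ndarray) -> np.ndarray:
    """True per-vertex gap for every (subject, visit) on the reference grid."""
    u, v, _, _, _ = _grid_surface(spec.gap_base)
    base = spec.gap_base.gap_field.evaluate(u, v, spec.gap_base.extent)
    effect = np.zeros_like(base) if spec.effect_map is None else np.asarray(spec.effect_map, float).ravel()
    if effect.shape != base.shape:
        raise PhantomSpecError("effect_map must have one value per reference-grid vertex")
    mean_angle = angles_sv.mean()
    out = np.empty((spec.n_subjects, spec.visits, len(base)))
    for s in range(spec.n_subjects):
        if spec.between_subject_sd > 0:
            modul = spec.between_subject_sd * _smooth_random_field(ref, _rng(spec.seed, 11, s))
        else:
            modul = 0.0
        for vi in range(spec.visits):
            g = base + modul + effect * (angles_sv[s, vi] - mean_angle)
            if np.any(g < spec.min_gap):
                g = np.maximum(g, spec.min_gap)
            out[s, vi] = g
    return out


def _cohort_frame(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-subject angles/intervals and per-(subject, visit) angles."""
    rng = _rng(spec.seed, 3)
    if spec.angle_values is None:
        angles = rng.normal(0.0, spec.angle_sd, spec.n_subjects)
    else:
        angles = spec.angle_values.copy()
    if spec.interval_values is None:
        intervals = np.maximum(7.0, rng.normal(spec.interval_mean, spec.interval_sd, spec.n_subjects))
    else:
        intervals = spec.interval_values.copy()
    max_rot = spec.visit_pose_jitter[0]
    if spec.angle_visit_values is not None:
        angles_sv = spec.angle_visit_values.copy()
    else:
        angles_sv = np.empty((spec.n_subjects, spec.visits))
        for s in range(spec.n_subjects):
            for vi in range(spec.visits):
                jr = _rng(spec.seed, 5, s, vi)
                angles_sv[s, vi] = angles[s] + (jr.uniform(-max_rot, max_rot) if max_rot > 0 else 0.0)
    rows = []
    for s in range(spec.n_subjects):
        for vi in range(spec.visits):
            for o in range(spec.operators):
                rows.append(
                    dict(subject=s, visit=vi, operator=o,
                         angle_deg=angles_sv[s, vi], interval_days=intervals[s], seed=spec.seed)
                )
    return angles_sv, intervals, pd.DataFrame(rows)


def _operator_masks(spec: CohortSpec, ref: SurfaceMesh, core_mask: np.ndarray) -> np.ndarray:
    """(n_subjects, operators, n_ref_vertices) perimeter masks.

    Operator 0 is the reference segmentation (the core patch); further
    operators perturb the perimeter by ``perimeter_jitter`` mm."""
    masks = np.empty((spec.n_subjects, spec.operators, ref.n_vertices), dtype=bool)
    for s in range(spec.n_subjects):
        for o in range(spec.operators):
            if o == 0 or spec.perimeter_jitter == 0:
                masks[s, o] = core_mask
            else:
                masks[s, o] = perturb_perimeter(
                    core_mask, ref, spec.perimeter_jitter, _rng(spec.seed, 17, s, o)
                )
    return masks


def simulate_field_cohort(spec: CohortSpec) -> CohortData:
    """Simulate measured JSW fields directly on the template (no imaging).

    Each record's field is the subject/visit true gap plus i.i.d. per-vertex
    Gaussian noise of SD ``measurement_noise_sd`` mm, restricted to the
    operator's perimeter.  Used for statistics calibration where hundreds
    of cohort realisations are needed.  Reproducible given ``spec.seed``.
    """
    base_phantom = make_joint_phantom(spec.gap_base)
    ref = base_phantom.reference
    template = base_phantom.patch("template")
    angles_sv, _, cov = _cohort_frame(spec)
    truths = _subject_truths(spec, ref, angles_sv)
    masks = _operator_masks(spec, ref, base_phantom.patch_mask)
    pidx = template.parent_index
    records: list[CohortRecord] = []
    gt = truths[:, :, pidx]
    for s in range(spec.n_subjects):
        for vi in range(spec.visits):
            for o in range(spec.operators):
                noise_rng = _rng(spec.seed, 7, s, vi, o)
                vals = truths[s, vi, pidx]
                if spec.measurement_noise_sd > 0:
                    vals = vals + noise_rng.normal(0, spec.measurement_noise_sd, len(pidx))
                m = masks[s, o, pidx]
                records.append(
                    CohortRecord(s, vi, o, field=ScalarField(np.where(m, vals, 0.0), m))
                )
    return CohortData(template, records, gt, cov, spec)


def simulate_cohort(
    spec: CohortSpec,
    spacing: float = 0.37,
    psf_sigma: float = 0.5,
    supersample: int = 4,
    rasterize: bool = True,
) -> CohortData:
    """Simulate the full imaging cohort: per (subject, visit) a posed phantom
    pair rasterized into a CT-like volume; per operator a perimeter mask.

    Measurement (profile fitting) is performed downstream by
    :func:`jsmap.mapping.map_jsw`; the two operators of a visit share the
    volume and differ only in the patch perimeter, as in a repeat-analysis
    study.  Reproducible given ``spec.seed``.
    """
    base_phantom = make_joint_phantom(spec.gap_base)
    ref = base_phantom.reference
    template = base_phantom.patch("template")
    angles_sv, _, cov = _cohort_frame(spec)
    truths = _subject_truths(spec, ref, angles_sv)
    masks = _operator_masks(spec, ref, base_phantom.patch_mask)
    pidx = template.parent_index
    gt = truths[:, :, pidx]
    max_rot, max_trans = spec.visit_pose_jitter
    records: list[CohortRecord] = []
    for s in range(spec.n_subjects):
        for vi in range(spec.visits):
            pr = _rng(spec.seed, 13, s, vi)
            if max_rot > 0 or max_trans > 0:
                axis = pr.standard_normal(3)
                pose = RigidTransform.from_axis_angle(
                    axis, pr.uniform(-max_rot, max_rot), pr.uniform(-max_trans, max_trans, 3)
                )
            else:
                pose = None
            pspec = PhantomSpec(
                geometry=spec.gap_base.geometry,
                extent=spec.gap_base.extent,
                gap_field=spec.gap_base.gap_field,
                mesh_resolution=spec.gap_base.mesh_resolution,
                rim=spec.gap_base.rim,
                shell=spec.gap_base.shell,
                pose=pose,
                sphere_radius=spec.gap_base.sphere_radius,
                saddle_scale=spec.gap_base.saddle_scale,
            )
            phantom = make_joint_phantom(pspec, gap_override=truths[s, vi])
            if rasterize:
                noise_seed = int(_rng(spec.seed, 19, s, vi).integers(0, 2**31 - 1))
                volume = rasterize_ct(
                    phantom,
                    spacing=spacing,
                    psf_sigma=psf_sigma,
                    noise_sd=spec.visit_noise_sd,
                    seed=noise_seed,
                    supersample=supersample,
                )
            else:
                volume = None
            for o in range(spec.operators):
                records.append(
                    CohortRecord(s, vi, o, phantom=phantom, volume=volume,
                                 patch_mask=masks[s, o])
                )
    return CohortData(template, records, gt, cov, spec)
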