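"""The measurement core: shadow casting and sub-voxel joint space width.

For every vertex of the reference (e.g. talar) articular surface a ray is
cast along the outward vertex normal.  Vertices whose ray first meets the
opposing bone within ``t_max`` form the "shadow" patch — the articulating
region.  At each such vertex an intensity profile is sampled from the CT
volume along the normal and a blurred two-edge model is fitted:

    y(t) = b + (A1 - b) * Phi((e1 - t) / s) + (A2 - b) * Phi((t - e2) / s)

with Phi the standard normal CDF: bone plateau A1, background b in the
joint space, bone plateau A2, both edges blurred by the imaging PSF (SD
``s``).  The joint space width is e2 - e1, localising both bone edges well
below the voxel size because the whole profile constrains each edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares
from scipy.special import ndtr

from .rays import first_hit_distance
from .surface import JointPatch, ScalarField, SurfaceMesh, smooth_field
from .volume import VoxelVolume

__all__ = [
    "Profile",
    "ProfileFit",
    "JSWMap",
    "MapParams",
    "cast_shadow",
    "extract_profile",
    "fit_blur_model",
    "map_jsw",
    "ray_distance_oracle",
]


@dataclass
class Profile:
    """Uniformly sampled intensity profile along a measurement ray.

    ``positions`` are in mm, zero at the reference vertex, positive toward
    the opposing bone; intensities come from trilinear interpolation.
    """

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float).ravel()
        self.intensities = np.asarray(self.intensities, float).ravel()
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities must have equal length")
        if len(self.positions) < 20:
            raise ValueError("profile needs at least 20 samples")
        d = np.diff(self.positions)
        if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
            raise ValueError("positions must be strictly increasing with uniform step")

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass
class ProfileFit:
    """Result of the blurred two-edge model fit.

    jsw = e2 - e1 (mm); ``converged`` is False when the optimiser failed or
    the profile showed no opposing bone edge (``failure`` gives the reason).
    """

    b: float = np.nan
    a1: float = np.nan
    a2: float = np.nan
    e1: float = np.nan
    e2: float = np.nan
    s: float = np.nan
    rms_residual: float = np.nan
    converged: bool = False
    failure: str = ""

    @property
    def jsw(self) -> float:
        return self.e2 - self.e1


@dataclass
class MapParams:
    """Measurement parameters for :func:`map_jsw`.

    Units mm throughout.  ``forward`` defaults to ``t_max + 4``.
    """

    t_max: float = 6.0
    back: float = 4.0
    forward: float | None = None
    step: float = 0.1
    psf_bounds: tuple[float, float] = (0.2, 1.5)
    smooth_iterations: int = 5
    smooth_weight: float = 0.5
    fit_margin: float = 2.0

    def __post_init__(self) -> None:
        if self.forward is None:
            self.forward = self.t_max + 4.0


@dataclass
class JSWMap:
    """Per-vertex joint space width on a patch, with fit quality."""

    field: ScalarField
    rms_residual: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    converged: np.ndarray = dc_field(default_factory=lambda: np.empty(0, dtype=bool))
    patch: JointPatch | None = None


def _two_edge_model(t: np.ndarray, b: float, a1: float, a2: float,
                    e1: float, gap: float, s: float) -> np.ndarray:
    return b + (a1 - b) * ndtr((e1 - t) / s) + (a2 - b) * ndtr((t - e1 - gap) / s)


def cast_shadow(reference: SurfaceMesh, opposing: SurfaceMesh, t_max: float) -> np.ndarray:
    """Flag reference vertices whose outward-normal ray first meets the
    opposing surface within (0, t_max] mm — the articulating "shadow".

    Degenerate (non-finite) normals yield an unflagged vertex, never a
    global failure.
    """
    t = first_hit_distance(reference.vertices, reference.normals,
                           opposing.vertices, opposing.faces)
    return (t > 0) & (t <= t_max)


def extract_profile(
    volume: VoxelVolume,
    start: np.ndarray,
    direction: np.ndarray,
    back: float,
    forward: float,
    step: float,
) -> Profile:
    """Sample the volume from ``-back`` to ``+forward`` mm along a unit ray.

    Raises the volume's out-of-bounds error (naming the offending endpoint)
    when the segment exits the grid.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    n_back = int(round(back / step))
    n_fwd = int(round(forward / step))
    t = np.arange(-n_back, n_fwd + 1) * step
    pts = np.asarray(start, float)[None, :] + t[:, None] * direction[None, :]
    return Profile(t, volume.sample(pts))


def fit_blur_model(
    profile: Profile,
    psf_bounds: tuple[float, float] = (0.2, 1.5),
    fit_margin: float = 2.0,
    min_edge_contrast: float = 0.2,
    fix_b: float | None = None,
    fix_s: float | None = None,
) -> ProfileFit:
    """Least-squares fit of the blurred two-edge model to a profile.

    The fit is performed over (b, A1, A2, e1, gap, s) with gap >= 0 and s
    constrained to ``psf_bounds``; initial edge positions come from the
    extrema of the smoothed derivative, and the fitted window is trimmed to
    ``[e1 - fit_margin, e2 + fit_margin]`` so that finite bone thickness
    beyond the plateaus does not bias the plateaus.  A profile without a
    second intensity rise (no opposing bone along the ray) returns a
    non-converged fit flagged "no opposing edge".

    When the gap is small relative to the blur the two edges merge and
    (gap, b, s) become jointly degenerate: almost-identical profiles arise
    from a narrower gap with a denser background or a wider blur.  The
    background level and the PSF width are properties of the tissue and the
    scanner, not of the individual ray, so callers measuring many profiles
    calibrate them globally and pass ``fix_b``/``fix_s`` to pin them (see
    :func:`map_jsw`); with both fixed the edge pair is identifiable well
    below the voxel size.
    """
    t, y = profile.positions, profile.intensities
    n = len(t)
    ys = gaussian_filter1d(y, sigma=max(1.0, 0.3 / profile.step))
    d = np.gradient(ys, t)
    # edge candidates: prominent local extrema of the smoothed derivative.
    # The ray is anchored at the reference bone surface, so the reference
    # edge e1 is the prominent *falling* edge nearest t = 0; the opposing
    # edge e2 is the first prominent *rising* edge after it.
    thresh = 0.25 * float(np.abs(d).max())
    if thresh <= 0:
        return ProfileFit(converged=False, failure="no plateau structure")
    interior = np.arange(1, n - 1)
    local_min = interior[(d[interior] <= d[interior - 1]) & (d[interior] <= d[interior + 1])
                         & (d[interior] < -thresh)]
    local_max = interior[(d[interior] >= d[interior - 1]) & (d[interior] >= d[interior + 1])
                         & (d[interior] > thresh)]
    if len(local_min) == 0:
        return ProfileFit(converged=False, failure="no plateau structure")
    i1 = int(local_min[np.argmin(np.abs(t[local_min]))])
    rising_after = local_max[local_max > i1]
    if len(rising_after) == 0:
        return ProfileFit(converged=False, failure="no opposing edge")
    i2 = int(rising_after[0])
    e1_0, e2_0 = float(t[i1]), float(t[i2])
    trough = float(ys[i1 : i2 + 1].min())
    a1_0 = float(ys[: max(i1, 1)].max())
    a2_0 = float(ys[i2 : min(i2 + int(fit_margin / profile.step) + 1, n)].max())
    if (a2_0 - trough) < min_edge_contrast * max(a1_0 - trough, 1e-12):
        return ProfileFit(converged=False, failure="no opposing edge")
    window = (t >= e1_0 - fit_margin) & (t <= e2_0 + fit_margin)
    tw, yw = t[window], y[window]
    if len(tw) < 10:
        return ProfileFit(converged=False, failure="window too short")
    # plateau structure check on the fitted window
    q = len(tw) // 4
    if q >= 1 and not (
        yw[:q].mean() > yw[q : 3 * q].mean() and yw[3 * q :].mean() > yw[q : 3 * q].mean()
    ):
        return ProfileFit(converged=False, failure="no plateau structure")
    s_lo, s_hi = psf_bounds
    s0 = float(np.clip(0.5, s_lo, s_hi)) if fix_s is None else float(fix_s)
    b0 = float(trough) if fix_b is None else float(fix_b)
    gap0 = max(e2_0 - e1_0, 0.05)
    x0_full = np.array([b0, a1_0, a2_0, e1_0, gap0, s0])
    span = float(t[-1] - t[0])
    scale = max(a1_0 - trough, 1.0)
    lb_full = np.array([trough - 2 * scale, trough, trough, t[0], 0.0, s_lo])
    ub_full = np.array([a1_0 + 2 * scale, a1_0 + 2 * scale, a2_0 + 2 * scale, t[-1], span, s_hi])
    xscale_full = np.array([scale, scale, scale, 1.0, 1.0, 0.3])
    free = np.ones(6, dtype=bool)
    free[0] = fix_b is None
    free[5] = fix_s is None
    x0_full = np.clip(x0_full, lb_full, ub_full)
    x0_full[0], x0_full[5] = b0, s0  # fixed values may sit outside the free bounds
    params = x0_full.copy()

    def residual(p: np.ndarray) -> np.ndarray:
        params[free] = p
        return _two_edge_model(tw, *params) - yw

    try:
        res = least_squares(residual, x0_full[free],
                            bounds=(lb_full[free], ub_full[free]), method="trf",
                            x_scale=xscale_full[free])
    except Exception as exc:  # pragma: no cover - optimiser pathologies
        return ProfileFit(converged=False, failure=f"optimiser error: {exc}")
    params[free] = res.x
    b, a1, a2, e1, gap, s = params
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return ProfileFit(
        b=float(b), a1=float(a1), a2=float(a2), e1=float(e1), e2=float(e1 + gap),
        s=float(s), rms_residual=rms, converged=bool(res.success), failure="",
    )


def map_jsw(
    volume: VoxelVolume,
    patch: JointPatch,
    opposing: SurfaceMesh,
    params: MapParams | None = None,
) -> JSWMap:
    """Measure JSW at every patch vertex inside the opposing bone's shadow.

    Per flagged vertex: profile along the vertex normal, blurred two-edge
    fit, JSW = e2 - e1; failed fits are masked; the field is finally
    smoothed with the masked umbrella operator.  A warning is raised when
    more than half of the attempted fits fail.

    Fitting is two-pass: a first pass with all parameters free, then a
    global calibration of the background level and PSF width (medians over
    confidently separated first-pass fits, gap > 2 s) which are properties
    of the image rather than of a single ray, and a second pass with both
    fixed — this keeps narrow gaps identifiable below the voxel size.
    """
    if params is None:
        params = MapParams()
    sub = patch.submesh
    flags = cast_shadow(sub, opposing, params.t_max)
    n = sub.n_vertices
    jsw = np.full(n, np.nan)
    rms = np.full(n, np.nan)
    conv = np.zeros(n, dtype=bool)
    n_attempt = 0
    n_fail = 0
    lo = volume.origin
    hi = volume.origin + (np.array(volume.shape) - 1) * volume.spacing
    profiles: dict[int, Profile] = {}
    for v in np.flatnonzero(flags):
        origin = sub.vertices[v]
        direction = sub.normals[v]
        # clip the window to the volume bounds along this ray
        back, fwd = params.back, float(params.forward)
        for k in range(3):
            if direction[k] > 1e-12:
                fwd = min(fwd, (hi[k] - origin[k]) / direction[k])
                back = min(back, (origin[k] - lo[k]) / direction[k])
            elif direction[k] < -1e-12:
                fwd = min(fwd, (lo[k] - origin[k]) / direction[k])
                back = min(back, (origin[k] - hi[k]) / direction[k])
        back = max(0.0, np.floor(back / params.step) * params.step - params.step)
        fwd = max(0.0, np.floor(fwd / params.step) * params.step - params.step)
        n_attempt += 1
        if (back + fwd) / params.step < 20:
            n_fail += 1
            continue
        profiles[v] = extract_profile(volume, origin, direction, back, fwd, params.step)

    first_pass: dict[int, ProfileFit] = {
        v: fit_blur_model(p, params.psf_bounds, params.fit_margin) for v, p in profiles.items()
    }
    separated = [
        f for f in first_pass.values()
        if f.converged and f.jsw > 2.0 * f.s and 0.0 <= f.jsw <= params.t_max
    ]
    if len(separated) >= 5:
        b_cal = float(np.median([f.b for f in separated]))
        s_cal = float(np.median([f.s for f in separated]))
    else:
        b_cal = s_cal = None  # calibration unavailable: keep free fits
    for v, prof in profiles.items():
        fit = first_pass[v]
        if b_cal is not None:
            refit = fit_blur_model(prof, params.psf_bounds, params.fit_margin,
                                   fix_b=b_cal, fix_s=s_cal)
            if refit.converged:
                fit = refit
        if fit.converged and 0.0 <= fit.jsw <= params.t_max:
            jsw[v] = fit.jsw
            rms[v] = fit.rms_residual
            conv[v] = True
        else:
            n_fail += 1
    if n_attempt and n_fail > 0.5 * n_attempt:
        warnings.warn(
            f"map_jsw: {n_fail}/{n_attempt} profile fits failed", RuntimeWarning
        )
    mask = conv.copy()
    field = ScalarField(np.where(mask, jsw, 0.0), mask)
    if params.smooth_iterations > 0:
        field = smooth_field(field, sub, params.smooth_iterations, params.smooth_weight)
    return JSWMap(field, rms, conv, patch)


def ray_distance_oracle(
    patch: JointPatch,
    opposing: SurfaceMesh,
    t_max: float = np.inf,
) -> JSWMap:
    """Brute-force mesh-to-mesh JSW: first ray-surface intersection distance
    along each vertex normal, no image involvement.  Vertices whose ray
    misses within ``t_max`` are masked."""
    sub = patch.submesh
    t = first_hit_distance(sub.vertices, sub.normals, opposing.vertices, opposing.faces)
    mask = np.isfinite(t) & (t > 0) & (t <= t_max)
    field = ScalarField(np.where(mask, t, 0.0), mask)
    return JSWMap(field, np.full(sub.n_vertices, 0.0), mask, patch)
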