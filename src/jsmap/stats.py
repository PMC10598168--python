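"""Cohort statistics: Bland-Altman maps, paired t, landmark angles, and
permutation-based statistical parametric mapping (SPM) on surfaces.

Reproducibility (two operators, same scan) and repeatability (two visits,
same operator) are summarised vertex-wise as Bland-Altman bias and 95%
limits of agreement, LOA = 1.96 x SD of the paired differences; the LOA is
the smallest detectable difference of the measurement chain.  The relation
between a per-subject covariate (talocrural angulation, i.e. degree of
plantarflexion) and the JSW distribution is mapped with a vertex-wise F
test, with family-wise error controlled by max-statistic permutation of
the covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .surface import JointPatch, ScalarField, patch_mean

__all__ = [
    "BlandAltmanMap",
    "SPMResult",
    "TTestResult",
    "bland_altman_map",
    "paired_t",
    "sagittal_angle",
    "spm_f_map",
    "cohort_summary",
    "load_ankle_cohort",
    "stack_fields",
]


def stack_fields(fields: list[ScalarField]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-subject fields into (n_subjects, n_vertices) value/mask arrays."""
    n = len(fields[0])
    for k, f in enumerate(fields):
        if len(f) != n:
            raise ValueError(f"field for subject {k} has length {len(f)}, expected {n}")
    vals = np.stack([np.where(f.mask, f.values, np.nan) for f in fields])
    mask = np.stack([f.mask for f in fields])
    return vals, mask


def _as_stacked(fields) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(fields, (list, tuple)):
        return stack_fields(list(fields))
    vals = np.asarray(fields, dtype=float)
    if vals.ndim != 2:
        raise ValueError("stacked fields must be a 2-D (subjects x vertices) array")
    return vals, np.isfinite(vals)


@dataclass
class BlandAltmanMap:
    """Vertex-wise agreement between paired measurement sets A and B.

    bias(v) = mean over subjects of (B - A); loa(v) = 1.96 x SD (n-1) of the
    same differences.  ``patch_bias``/``patch_loa`` are Bland-Altman numbers
    computed from per-subject *patch means* (the headline, Table-style
    summary); ``surface_mean_loa`` is the area-less average of the
    vertex-wise LOA map, emitted because "surface averaged" summaries are
    used both ways in practice.
    """

    bias: ScalarField
    loa: ScalarField
    n_pairs: np.ndarray
    patch_bias: float | None = None
    patch_loa: float | None = None
    surface_mean_bias: float | None = None
    surface_mean_loa: float | None = None


def bland_altman_map(
    fields_a,
    fields_b,
    patch: JointPatch | None = None,
) -> BlandAltmanMap:
    """Vertex-wise Bland-Altman statistics for paired field sets (B - A).

    Vertices valid in fewer than 2 pairs are masked.  When ``patch`` is
    given, per-subject patch means feed scalar Bland-Altman summaries.
    """
    va, ma = _as_stacked(fields_a)
    vb, mb = _as_stacked(fields_b)
    if va.shape[0] != vb.shape[0]:
        raise ValueError(
            f"paired sets differ in subject count: {va.shape[0]} vs {vb.shape[0]}"
        )
    if va.shape != vb.shape:
        raise ValueError(f"stacked field shapes differ: {va.shape} vs {vb.shape}")
    both = ma & mb
    diff = np.where(both, vb - va, np.nan)
    n = both.sum(axis=0)
    valid = n >= 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bias = np.nanmean(diff, axis=0)
        sd = np.nanstd(diff, axis=0, ddof=1)
    loa = 1.96 * sd
    bias_f = ScalarField(np.where(valid, bias, 0.0), valid)
    loa_f = ScalarField(np.where(valid, loa, 0.0), valid)
    out = BlandAltmanMap(bias_f, loa_f, n)
    if valid.any():
        out.surface_mean_bias = float(bias[valid].mean())
        out.surface_mean_loa = float(loa[valid].mean())
    if patch is not None:
        pm_a, pm_b = [], []
        for s in range(va.shape[0]):
            fa = ScalarField(np.where(ma[s], va[s], 0.0), ma[s])
            fb = ScalarField(np.where(mb[s], vb[s], 0.0), mb[s])
            pm_a.append(patch_mean(fa, patch))
            pm_b.append(patch_mean(fb, patch))
        d = np.asarray(pm_b) - np.asarray(pm_a)
        out.patch_bias = float(d.mean())
        out.patch_loa = float(1.96 * d.std(ddof=1))
    return out


@dataclass
class TTestResult:
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p: float


def paired_t(differences) -> TTestResult:
    """Two-sided one-sample Student t on paired differences.

    t = mean / (sd / sqrt(n)), n-1 degrees of freedom.  All-zero input
    gives t = 0, p = 1; zero variance with nonzero mean gives p = 0 with a
    warning (the conventional degenerate limit).
    """
    d = np.asarray(differences, dtype=float).ravel()
    if len(d) < 2:
        raise ValueError("need at least 2 paired differences")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, 0.0, 0.0, df, 1.0)
        warnings.warn("zero variance with nonzero mean: p = 0 by convention", RuntimeWarning)
        return TTestResult(mean, 0.0, np.inf if mean > 0 else -np.inf, df, 0.0)
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(mean, sd, float(t), df, p)


def sagittal_angle(
    tibia_shaft_centre,
    dome_centre,
    head_centre,
    sagittal_normal=(1.0, 0.0, 0.0),
) -> float:
    """Talocrural angulation from three landmarks, in degrees.

    The segments dome->tibial shaft centre and dome->talar head centre are
    projected onto the plane orthogonal to ``sagittal_normal``; the return
    value is the angle between them at the dome centre, in (0, 180].
    Angle differences between visits are computed by the caller.
    """
    n = np.asarray(sagittal_normal, float)
    n = n / np.linalg.norm(n)
    a = np.asarray(tibia_shaft_centre, float) - np.asarray(dome_centre, float)
    b = np.asarray(head_centre, float) - np.asarray(dome_centre, float)
    if np.allclose(a, 0) or np.allclose(b, 0):
        raise ValueError("degenerate landmarks: points coincide")
    a = a - np.dot(a, n) * n
    b = b - np.dot(b, n) * n
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("degenerate landmarks: segment vanishes after projection")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class SPMResult:
    """Vertex-wise F map with family-wise-corrected permutation p-values."""

    f: ScalarField
    p_corrected: ScalarField
    significant: np.ndarray
    n_permutations: int
    alpha: float
    p_uncorrected: np.ndarray | None = None


def _f_stats(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """F statistic of the slope in y = b0 + b1 x + e, per column of y."""
    n = len(x)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = y - y.mean(axis=0)
    sxy = xc @ yc
    syy = np.einsum("ij,ij->j", yc, yc)
    sse = syy - sxy**2 / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (sxy**2 / sxx) / (sse / (n - 2))
    f = np.where(syy <= 0, 0.0, f)  # constant field at a vertex -> F = 0
    f = np.where(np.isfinite(f), f, np.inf)
    return np.maximum(f, 0.0)


def spm_f_map(
    fields,
    covariate,
    n_permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> SPMResult:
    """Statistical parametric mapping of a covariate effect on a surface.

    Per vertex, the F statistic (1, n-2 df) for the slope of
    JSW = b0 + b1 * covariate + e.  Family-wise error across vertices is
    controlled by max-statistic permutation: the covariate is permuted
    ``n_permutations`` times, the maximum F over valid vertices recorded,
    and p_corrected(v) = (1 + #{max-F >= F(v)}) / (n_permutations + 1)
    (the observed statistic is included in its own null).  Deterministic
    given ``seed``.
    """
    vals, mask = _as_stacked(fields)
    x = np.asarray(covariate, dtype=float).ravel()
    n = vals.shape[0]
    if len(x) != n:
        raise ValueError("covariate length must equal the number of subjects")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.std(x) == 0:
        raise ValueError("covariate has zero variance")
    valid = mask.all(axis=0)
    y = vals[:, valid]
    f_valid = _f_stats(y, x)
    n_vert = vals.shape[1]
    f_all = np.zeros(n_vert)
    f_all[valid] = f_valid
    rng = np.random.default_rng(seed)
    max_f = np.empty(n_permutations)
    for k in range(n_permutations):
        max_f[k] = _f_stats(y, rng.permutation(x)).max() if valid.any() else 0.0
    exceed = (max_f[None, :] >= f_valid[:, None]).sum(axis=1)
    p_corr_valid = (1.0 + exceed) / (n_permutations + 1.0)
    p_all = np.ones(n_vert)
    p_all[valid] = p_corr_valid
    p_f = ScalarField(np.where(valid, p_all, 1.0), valid)
    f_f = ScalarField(np.where(valid, np.where(np.isfinite(f_all), f_all, 0.0), 0.0),
                      valid & np.isfinite(f_all))
    significant = valid & (p_all < alpha)
    p_unc = np.ones(n_vert)
    with np.errstate(invalid="ignore"):
        p_unc[valid] = sps.f.sf(f_valid, 1, n - 2)
    return SPMResult(f_f, p_f, significant, n_permutations, alpha, p_unc)


# ----------------------------------------------------------------------
# cohort table


def load_ankle_cohort() -> pd.DataFrame:
    """The shipped 23-participant demographic table (repeat ankle WBCT
    cohort): age, sex, side, metalwork, interval between visits in days and
    sagittal talocrural angle difference in degrees."""
    with resources.files("jsmap.data").joinpath("ankle_cohort.csv").open() as fh:
        return pd.read_csv(fh, keep_default_na=False, na_values=[""])


def cohort_summary(table: pd.DataFrame) -> dict:
    """Means, SDs (n-1) and ranges of the numeric columns plus sex/side counts.

    Raises on missing numeric cells, naming the offending row; with a
    single row SDs are reported as NaN (not available).
    """
    if len(table) == 0:
        raise ValueError("table is empty")
    out: dict = {"n": int(len(table))}
    for col in ("age_years", "interval_days", "angle_delta_deg"):
        if col not in table.columns:
            continue
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            row = table.index[vals.isna()][0]
            raise ValueError(f"missing numeric value in column {col!r} at row {row}")
        out[col] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    for col in ("sex", "side"):
        if col in table.columns:
            out[col] = {str(k): int(v) for k, v in table[col].value_counts().items()}
    return out
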