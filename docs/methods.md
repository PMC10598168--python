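# Methods

`jsmap` measures joint space width (JSW) — the distance between two opposing
subchondral bone surfaces — at every vertex of an articular surface mesh from
a CT-like intensity volume, and provides the statistics used to qualify such
maps: inter-operator reproducibility and test–retest repeatability as
vertex-wise Bland–Altman fields, and covariate effects (joint angulation) as
permutation-corrected statistical parametric maps. This note records the
models, the parameters that matter, and the design choices made where more
than one reasonable construction existed.

## Measurement model

### Shadow casting

The articulating region of the reference bone is found by casting a ray from
every vertex along its outward unit normal: a vertex belongs to the "shadow"
patch when the ray's first intersection with the opposing surface lies within
`(0, t_max]` (default `t_max = 6 mm`). Intersection uses a vectorised
Möller–Trumbore test over all triangles; ties among multiple hits resolve to
the nearest positive distance. Rays are cast along vertex normals rather than
along nearest-point directions because the normal direction is deterministic,
independent of the opposing mesh's tessellation, and matches the projection
geometry of casting the opposing bone's silhouette onto the reference
surface. Degenerate (zero or non-finite) normals invalidate the single vertex,
never the map.

### Intensity profiles and the blurred two-edge model

Along each shadowed vertex's normal an intensity profile is sampled by
trilinear interpolation (default window 4 mm into the reference bone to
`t_max + 4 mm` beyond it, step 0.1 mm; the window is clipped to the volume).
The profile across a joint space is modelled as two Gaussian-blurred edges:

    y(t) = b + (A1 − b)·Φ((e1 − t)/s) + (A2 − b)·Φ((t − e2)/s)

with Φ the standard normal CDF, `A1`/`A2` the two bone plateau intensities,
`b` the background (joint-space tissue) intensity, `e1`/`e2` the edge
positions and `s` the point-spread blur SD. The JSW at the vertex is
`e2 − e1`. Because the whole profile constrains each edge, edge positions are
recovered well below the voxel size, which is the point of fitting a model
rather than thresholding a segmentation.

Fitting is trust-region least squares over `(b, A1, A2, e1, gap = e2−e1, s)`
with `gap ≥ 0` and `s` bounded to `psf_bounds` (default 0.2–1.5 mm). Initial
edge estimates are the prominent extrema of the smoothed derivative; since
the ray is anchored at the reference surface, `e1` is initialised at the
prominent falling edge nearest `t = 0` and `e2` at the first prominent rising
edge after it. The fitted window is trimmed to `[e1 − 2, e2 + 2] mm` so the
finite thickness of real (or synthetic) cortices beyond the plateaus does not
bias the plateau estimates. A profile with no second rise (no opposing bone
along the ray — typical at patch margins) is flagged `no opposing edge` and
the vertex is masked rather than failing the map.

**Identifiability and global calibration.** When the gap is small relative to
the blur (`gap ≲ 2s`) the two edges merge and `(gap, b, s)` become jointly
near-degenerate: a narrower gap with a denser background, or a wider blur,
produces an almost identical profile. Numerically, the profiled residual over
`gap ∈ [0.1, 0.5] mm` for a true 0.3 mm gap is flat to below realistic noise
levels. The background density and the PSF width are, however, properties of
the tissue and the scanner, not of an individual ray, so `map_jsw` fits in
two passes: all parameters free, then `b` and `s` pinned to their medians
over confidently separated first-pass fits (`gap > 2s`, at least 5 of them)
and every profile refitted. With nuisance parameters fixed, a 0.3 mm gap at
`s = 0.5 mm` and noise SD 20 (on a bone contrast of 1000) is recovered with a
median absolute error of ~0.006 mm, versus ~0.45 mm with everything free.

### Map assembly and smoothing

Failed or out-of-range fits (`jsw ∉ [0, t_max]`) are masked; a map-level
warning is raised when more than half the attempted fits fail. The JSW field
is then smoothed with an iterated masked umbrella operator: each iteration
replaces a valid vertex's value with `(1−w)·value + w·mean(valid 1-ring
neighbours)` (defaults `w = 0.5`, 5 iterations). Masked vertices neither
contribute to nor receive averages; `w = 0` is the identity. The bandwidth is
mesh-resolution-aware by construction and the operator has testable fixed
points (constants). Smoothing is applied on the native patch before
registration; applying it after transfer would mix interpolation error into
the neighbourhood averages.

Patch summaries are area-weighted vertex means with barycentric lumping
(each vertex weighted by one third of its incident face areas), which is
robust on irregular triangulations and exactly linear in the field.

## Synthetic phantoms and the simulated study

Clinical weight-bearing CT cannot be redistributed, so validation runs on
phantoms with exact ground truth. A parametric reference surface (parallel
slab, spherical cap, or saddle — the saddle resembling a trochlear facet) is
meshed on a regular grid; the opposing surface is the reference offset along
its normals by a gap field `g(u, v) > 0` (constant, linear ramp 1.9→2.9 mm,
or radial bump — the range bracketing typical ankle facet JSW). Offsetting
along normals gives every reference vertex an exact truth value and exact
template correspondence, which is what lets the registration and statistics
layers be validated independently of segmentation. Both surfaces are
thickened into closed "cortical" bodies (default shell 5 mm, so profile
windows stay inside bone) that extend a `rim` (default 3 mm) beyond the
measured patch, as real bone extends past a facet.

### CT-like rasterization

Bodies are rasterized by counting ray crossings per voxel column (parity
test, with a sub-nanometre irrational grid jitter so rays never hit mesh
edges exactly; an odd crossing count reports a non-closed surface). Voxel
intensity is `background + contrast × occupancy fraction`, with the fraction
estimated on a `supersample×` finer grid (default 4) — the partial-volume
model of CT. Pure binary centre-sampling (`supersample = 1`) is available but
quantises each edge to the half-voxel grid (±0.19 mm at 0.37 mm voxels),
which would swamp the sub-voxel accuracy this method achieves; partial volume
is both the physically correct forward model and the one that preserves edge
information. The grid is blurred with an isotropic Gaussian PSF (default
`psf_sigma = 0.5 mm`, on the order of the 0.37 mm default voxel) and i.i.d.
Gaussian intensity noise (default SD 20, i.e. 2% of bone contrast) is added.
No published noise or PSF figures exist for the emulated scanner; these
defaults are stated assumptions, exposed in the configuration. The effective
profile blur is therefore `sqrt(psf² + Δ²/12)` plus a small trilinear
term — all absorbed by the fitted `s`.

### Cohort simulation

`CohortSpec` describes the emulated study: `n_subjects = 23`, 2 visits within
months (interval ~N(74, 29.6²) days), 2 operators, per-subject plantarflexion
angles ~N(0, 9.3²) degrees. Per subject, the gap field is modulated by a
smooth random field (umbrella-filtered white noise, SD `between_subject_sd`,
default 0.5 mm) and optionally shifted by a per-vertex slope `effect_map`
(mm/degree) times the centred visit angle — the injected angulation effect
(default 0.1 mm/deg on the anterior region in the pipeline). Per visit: a
fresh noise realisation and a small rigid pose jitter (≤2°, ≤1 mm). Per
operator: the patch perimeter is eroded/dilated by a smooth random signed
offset with RMS `perimeter_jitter` (default 1 mm), emulating manual
segmentation differences; the interior far from the boundary is untouched.
All randomness derives from one seed split by `(purpose, subject, visit,
operator)`, so adding subjects never changes earlier subjects' draws and
every simulation is bit-reproducible.

Two generators share this specification: `simulate_cohort` produces the full
imaging chain (phantom pair + volume per subject-visit), used by the
pipeline; `simulate_field_cohort` emulates the *measured* fields directly as
truth + i.i.d. per-vertex noise (default 0.1 mm), for statistical
calibrations that need hundreds of cohort realisations. What the field-level
generator does not model — spatially correlated measurement error, fit
failures at margins, registration error — is exercised by the imaging-level
tests instead; passing field-level calibrations therefore validates the
statistics, not the whole chain.

## Registration and transfer

Per-subject patches are aligned to the template by point-to-point ICP with
Kabsch updates, starting from centroid alignment. Correspondences are closest
points on the target *surface*, not nearest vertices: identical regular
meshes under in-plane motion lattice-lock nearest-vertex ICP into local
minima (an unrecovered 5° was observed), while surface correspondences
recover 5°/(1, 2, 0.5) mm to better than 0.1°/0.01 mm. Registration is
declared failed when the RMS rises five consecutive iterations or the
converged RMS exceeds `fail_threshold` (default 2 mm) — surfaces that cannot
correspond. A perfectly flat patch is rotationally under-constrained for any
rigid registration; the pipeline's phantoms default to saddle geometry partly
for this reason. Fields are transferred by barycentric interpolation at the
closest point on the transformed source patch; template vertices farther than
`cutoff` (default 2 mm) are masked. Non-rigid registration is out of scope:
synthetic cohorts carry exact correspondence, so rigid + closest-point
transfer suffices to validate the statistics; real-data non-rigid matching is
an extension point.

## Statistics

**Bland–Altman maps.** For paired measurement sets (operator 1 vs 2 at visit
1 for reproducibility; visit 2 vs 1 for one operator for repeatability), per
vertex: bias = mean of differences, LOA = 1.96 × SD (n−1 denominator) of the
differences, over subjects valid in both; vertices with fewer than two valid
pairs are masked. The LOA is the smallest detectable difference of the chain.
Patch-level summaries are computed from per-subject *patch means* (reduce
first, then Bland–Altman) — the headline numbers — while the plain average of
the vertex-wise LOA map is also emitted, since "surface averaged" is used
both ways in practice and the two differ: patch means average out
vertex-level noise, so their LOA is far smaller.

**Paired t.** `t = mean/(sd/√n)`, two-sided p from Student t with n−1 df;
all-zero differences give `t = 0, p = 1`; zero variance with nonzero mean
gives `p = 0` with a warning.

**Talocrural angle.** The two landmark segments (dome→tibial shaft centre,
dome→talar head centre) are projected onto the plane orthogonal to a
configurable sagittal normal (default the scanner x-axis) and the angle
between them taken at the dome. Visit differences are computed by the caller.

**SPM.** Per vertex, the F statistic (1, n−2 df; F = t² of the slope) for the
linear model `JSW = β0 + β1·angle + ε` over subjects. Family-wise error is
controlled by max-statistic permutation: the covariate is permuted
`n_permutations` times (default 999; 199 in the demo), the maximum F over
valid vertices recorded, and `p_corrected(v) = (1 + #{max-F ≥ F(v)}) /
(n_permutations + 1)` — the observed statistic counts in its own null, so p
is never zero and is bounded below by `1/(n_permutations+1)`. Permutation was
chosen over random-field theory because its family-wise error rate is exactly
testable by simulation (measured 0.052 over 500 null cohorts at α = 0.05)
and it needs no smoothness assumptions on a curved surface. Vertices missing
in any subject are excluded from the model and from the max statistic.

## Pipeline

`run_pipeline` chains simulate → measure → register → stats → report with a
JSON manifest recording parameters, seed and a SHA-256 checksum of every
artefact; deterministic stages reproduce checksums on rerun. The default
configuration simulates four facets as independent phantoms with gap means
and between-subject SDs of 1.91 ± 0.36, 2.73 ± 0.51, 2.84 ± 0.62 and
2.65 ± 0.60 mm (talonavicular, dome-medial, lateral gutter, posterior
subtalar — typical ankle values), n = 23 subjects, 2 visits, 2 operators.
Within a run all facets share the cohort-level draws (angles, intervals,
visit jitter), as they would for one set of ankles. The demo uses a 14 mm
patch at 1.4 mm mesh resolution with supersample 3 — sizes chosen so a full
end-to-end run completes in minutes on one core while the acceptance-grade
accuracy checks run at finer settings. Report numbers are fixed to two
decimal places in mm. Operators of the same visit share the volume (they
re-analyse the same scan); measurement fits are computed once on the union of
the operator perimeters and then restricted and smoothed per operator patch.

## Numerical choices and degenerate inputs

- Vertex/face indices are 0-based; positions in mm, right-handed frame.
- Non-manifold meshes load with a warning; connectivity is face-derived.
- `patch_submesh` keeps faces whose three vertices are all selected and
  returns the largest connected component by face count; a mask spanning no
  complete face is an error.
- Profile fits report `converged` and RMS residual per vertex; `map_jsw`
  masks failures instead of propagating exceptions.
- The permutation p-value convention (`+1` in numerator and denominator)
  avoids zero p-values; `F = 0` is assigned at vertices with constant fields.
- Gap fields must be strictly positive; simulated true gaps are floored at
  0.2 mm after modulation.
- Seeds are integers below 2³¹; every public simulation function is
  deterministic given its seed.

## Known limitations

- The phantom bone model is homogeneous (no trabecular texture, beam
  hardening, metal artefact or scanner kernel effects), so absolute accuracy
  figures here are upper bounds on clinical performance.
- The field-level cohort generator assumes independent per-vertex
  measurement noise; spatially correlated errors would widen vertex-wise LOA
  relative to its closed-form calibration.
- Rigid-only registration assumes shape differences are small; across real
  subjects a non-rigid step would precede transfer.
- The blur-model calibration (fixed `b`, `s`) assumes one background density
  and one PSF per map; joints with strongly varying intra-articular tissue
  density violate this.
- Flat articular patches leave in-plane rotation weakly determined in
  registration regardless of correspondence scheme.
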