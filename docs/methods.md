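# Methods

## The measurement problem

The hippocampus and adjacent medial temporal cortex form a thin, convoluted
gray-matter sheet whose subfields (CA fields, dentate gyrus, subiculum,
entorhinal/perirhinal/parahippocampal cortices, fusiform gyrus) are a few
millimetres wide. Volumetry at this scale mixes subfields; cortical
unfolding instead flattens the sheet into 2D so that subregions become
contiguous map regions and thickness can be measured per location.
`hippoflat` implements that unfolding pipeline and the downstream
gene–environment statistics, and — because clinical MRI from such cohorts is
not deposited — ships generators for volumetric phantoms and subject cohorts
so every stage is testable against known truth.

## Imaging pipeline

**Substrate.** Segmented 3D label volumes (background/WM/CSF/GM, subregion
codes 10–16 on GM) with per-axis spacing, read and written as NIfTI-1 via
nibabel. The emulated acquisition is a high-resolution oblique-coronal
protocol: 0.39×0.39 mm in-plane, 3 mm slices.

**Interpolation.** Only the through-plane axis is upsampled (nearest
neighbour — labels are categorical), by an integer factor; factor 7 takes
3 mm slices to ≈0.43 mm, near-isotropic. In-plane interpolation is not
performed: from the stated in-plane resolution it is neither needed nor
compatible with a "≈0.4 mm" target voxel.

**Layer growing.** GM voxels face-adjacent to WM form layer 0; layer k+1 is
the unassigned GM adjacent to layer k. Face (6-neighbour) connectivity is
the default for growth because it keeps each layer one voxel thin;
connectivity is configurable. The hop index equals BFS distance from the WM
interface (verified against an independent queue-based BFS oracle). GM
unreachable from the interface is counted, reported and excluded; phantoms
produce zero. Note that the face-connectivity hop metric is an L1-type
distance: where the sheet normal is oblique to the grid, layer counts exceed
thickness/spacing; under face+edge+corner connectivity the hop metric is
Chebyshev-like and layer counts track the through-sheet voxel count.

**Unfolding.** The assigned GM voxels form a weighted graph (26-neighbour
connectivity for geodesics, independent of the growth connectivity; edge
weights are Euclidean center-to-center distances under the anisotropic
spacing). Geodesic distances are Dijkstra shortest paths
(`scipy.sparse.csgraph`). Classical (Torgerson) metric MDS embeds a landmark
subset: double-center the squared-distance matrix, take the top-2 eigenpairs,
scale by √eigenvalue. Landmarks (default 500) are farthest-point sampled
from a seeded start, which reuses each Dijkstra run for the out-of-sample
step. All remaining voxels are placed by least-squares trilateration against
the landmark coordinates (differencing the squared-distance equations
against their mean; exact for distances consistent with a planar
configuration). Axis order and signs follow a fixed convention (eigenvalue
order; first nonzero coordinate positive) so maps reproduce bit-for-bit.
A distance matrix whose most negative eigenvalue rivals the second retained
axis has no faithful 2D representation and raises a diagnostic error rather
than embedding silently.

Flat-map coordinates are binned into square pixels (default 0.4 mm,
matching the interpolated voxel scale) covering the bounding box; every
mapped voxel lands in exactly one pixel, and a pixel aggregates its column
of voxels across layers. Subregion labels project by per-pixel majority
vote with ties broken by the fixed order CA23DG > CA1 > SUB > ERC > PRC >
PHC > FUS (anterior CADG is part of CA23DG by labeling convention).
Distortion diagnostics over landmark pairs: stress-1
(√(Σ(d_g−d_e)²/Σd_g²)) and the Pearson correlation between geodesic and
embedded distances.

**Thickness.** Per GM voxel, the anisotropic Euclidean distance transform
(`scipy.ndimage`) gives the distance to the closest non-GM voxel
(center-to-center). Per pixel, thickness is twice the maximum distance over
the corresponding voxels across layers; per subregion, the arithmetic mean
over its pixels; values are raw — no covariate adjustment at the
measurement stage.

Two conventions are shipped because the center-to-center definition carries
a systematic ≈one-voxel offset on discrete sheets: `literal` doubles the
maximum distance as stated, `boundary_corrected` subtracts one voxel
spacing. On an axis-aligned slab of n voxels at spacing s the literal value
is (n+1)s for odd n and ns for even n, so the correction is exact at odd
counts and conservative at even ones; both conventions sit within one
spacing of the geometric truth. The subtracted spacing is the smallest
mapped EDT value, i.e. one center-to-center step along the sheet normal —
on the near-isotropic grids the pipeline produces this equals the minimum
voxel spacing.

*Column correspondence.* The per-pixel maximum is taken over voxels binned
within ±2 pixels of each occupied pixel (`capture_radius_px`, exposed).
Under metric distortion the flat positions of one 3D column disperse by
roughly stress × thickness; with strict per-pixel binning the deepest voxel
of a column is regularly lost to a neighbouring pixel and curved sheets are
systematically underestimated (up to ~1.3 voxel spacings on graded
C-sheets). The 2-pixel window covers that dispersion for sheets up to 4 mm
at 0.4 mm pixels, while contamination across band boundaries stays below
one spacing because bands are an order of magnitude wider than the window.

## Phantoms

Three geometries, all bounded by WM on one side and CSF on the other, with
a 2-voxel background margin: a flat slab (normal along axis 0), a
cylindrical shell (annulus extruded along axis 2) and a folded C-sheet (a
270° sector of the shell, emulating the folded hippocampal sheet). The
shell carries a narrow (≈3-voxel) angular cut: a closed tube has no
isometric planar unrolling, so the cut — like the anatomical cut that makes
the real sheet unfoldable — keeps the phantom developable; its ground truth
is unaffected. Subregion bands partition the sheet along its length (slab
axis 1, shell/C angle) in the fixed anatomical order; per-band thickness may
vary (the graded phantom). Ground truth records the realised discrete
thickness for slabs (voxel count × spacing) and the nominal band thickness
for curved shells.

Because thickness is a distance to *any* non-GM tissue, voxels near the cut
edge of a finite sheet see a spuriously close boundary. Phantoms therefore
surround the banded region with unlabeled plain-GM "flanks" (width ≥ half
the maximal thickness plus one voxel): the flanks take part in layering,
unfolding and the EDT — as real cortex continuing beyond a region of
interest does — but contribute no labeled pixels, so subregion means are
free of rim truncation bias.

Sheet thickness must span at least two voxels along the sheet-normal axis
(for the realistic anisotropic acquisition the normal lies in-plane, so
3 mm slices do not forbid 2–3 mm sheets). An optional `label_noise_fraction`
reassigns that fraction of banded voxels to a random other band.

Recovery characteristics at 0.4 mm isotropic voxels (boundary-corrected):
flat slabs recover truth exactly away from parity effects; cut shells and
C-sheets carry a deterministic negative bias of up to one voxel spacing,
the sum of EDT quantisation on curved boundaries (the innermost/outermost
GM centers sit up to half a voxel inside the nominal radii) and residual
column dispersion. All phantom configurations in the shipped studies stay
within max(one voxel spacing, 5%) of truth; stress-1 stays ≤0.05 and the
distance correlation ≥0.99 for developable phantoms of cortical (≈2 mm)
thickness, with stress growing toward 0.08–0.09 for 4 mm sheets (the
thickness dimension and the inner/outer arc-length mismatch are genuinely
non-planar structure).

## Cohort generator

The cohort emulates a 58-patient mildly-impaired Alzheimer's sample with
two education groups (n = 32 lower, 26 higher). Exact-by-construction
marginals per group: female counts (18/9), APOE genotype counts (2/3: 2+1,
3/3: 12+6, 3/4: 13+14, 4/4: 5+5), family-history counts (9/13), and 4
subjects flagged as missing the MRI sequence (chosen uniformly at random;
their thickness values are simulated but excluded from analysis). Family
history is shuffled independently of genotype within groups — risk-level
stratum sizes are therefore random, the reading consistent with
genotype × FH independence. Age and MMSE are Gaussian per group (71.8±7.0 /
73.8±6.3 years; 21.1±5.2 / 24.7±4.2 points, MMSE clipped to 0–30 and
carried as metadata only — no modelled link to thickness).

**Education.** Lower-group years are uniform integers on {10..13} (mean
11.5, SD 1.12), higher-group on {14..19} (mean 16.5, SD 1.71) — close to
the emulated group summaries (11.5±1.2, 16.2±1.7) while keeping the two
supports disjoint, so the "below/above cohort mean" allocation rule
reproduces the fixed group sizes for every seed. The draw is additionally
conditioned (seeded rejection, ~8% rejection rate) on the realised cohort
mean falling between the supports. The mixture SD is analytic:
σ_e = 2.86 years, the scale used in the slope calibration below.

**Thickness model.** For subregion i and a subject with education E and
risk level ℓ:

```
T_i = base_i + s_{ℓ,i} · (E − Ē) + σ(√c · Z_shared + √(1−c) · Z_i)
```

with base thickness 2.05–2.50 mm per subregion (cohort-wide mean ≈2.2–2.3
mm), residual SD σ = 0.15 mm, and a noise component `Z_shared` common to
all seven subregions. Slopes are not free parameters: they are derived from
target education–thickness Pearson correlations per stratum via
s = g(r)·σ/σ_e with g(r) = r/√(1−r²). Targets: zero everywhere at low
risk; at high risk CA23DG 0.63, CA1 0 (no association), SUB 0.47, ERC 0.58,
PRC 0.73, PHC 0.72, FUS 0.61; at intermediate risk PHC 0.45 and ERC 0.44
with weak 0.25 trends elsewhere (0.10 for CA1). The shared-noise fraction c
resolves an inconsistency that independent noise would create: with
per-region targets fixed, the correlation of the 7-region mean is
r_comb = ḡ/√(ḡ² + c + (1−c)/7), which at c = 0 would give 0.88 against a
configured combined target of 0.77. Solving gives c = (7A−1)/6 with
A = ḡ²(1/r²_comb − 1), i.e. c ≈ 0.23 — anatomically plausible correlated
residuals across neighbouring regions. The implied intermediate combined
correlation (≈0.46) is left to follow from the same c rather than being
forced separately.

At 2000 high-risk subjects the sampled r lies within ±0.05 of each target
(sampling SE ≈ 0.014); at n = 58 the per-draw scatter is large, which is
the point of the calibration study.

## Statistical analysis

"Mixed general linear models" over two between-subject factors and two
covariates is implemented as a fixed-effects ANCOVA — the reported residual
df (46 at n = 54 with 8 design columns) identify that design exactly, and
no random effect is specified anywhere. Sum-to-zero factor coding with
partial (Type III) F tests per term: order-independent and valid under the
unbalanced cells a random risk allocation produces. The design matrix and
partial-F machinery are implemented directly (and cross-checked in the test
suite against statsmodels' sum-coded `anova_lm(typ=3)` to 1e-8); empty
education × risk cells raise a named rank-deficiency error. Post-hoc:
Pearson r per risk stratum × subregion with two-sided p from the t
transform (df = n−2); strata under 3 subjects are flagged not estimable.
Demographic comparisons: Pearson chi-square without continuity correction
(df = 1) for 2×2 category-vs-group tables, pooled two-sample t tests from
group summaries for continuous rows. No multiple-testing correction
anywhere, mirroring the emulated analysis (α = 0.05, per-test p reported
raw). The education-group tie rule (years exactly at the mean) assigns
"higher".

Monte-Carlo calibration: under null cohorts (all slopes zero) the
interaction F test rejects at 0.05 within Monte-Carlo error over 2000
replicates (the test is conditionally exact under Gaussian noise, so this
checks the machinery, not an approximation); with calibrated slopes at 10×
cohort size power is ≈1. Replicates whose random risk allocation empties a
design cell (rare at n = 58) are redrawn, since the interaction is
untestable there.

## Pipeline scale and defaults

The orchestrated demo (`pipeline.PipelineConfig` defaults) runs 8 subjects
on 48×48×12 grids at 0.6×0.6×1.8 mm with factor-3 interpolation, 200
landmarks and 0.6 mm pixels — coarse enough to run a full
simulate→upsample→layer→unfold→thickness→stats pass in a couple of minutes
while exhibiting every behaviour of the fidelity-scale settings
(`configs/fidelity.yaml`: 0.39×0.39×3 mm, factor 7, 500 landmarks), which
are provided but not exercised by the test suite. Phantom studies in tests
and the acceptance script use 0.4 mm isotropic grids of 24–52 voxels per
side and 300 landmarks; at these sizes landmark MDS is within 1% of the
full eigendecomposition for downstream means. Every output file carries the
seed and a hash of the scientific configuration; reruns at a fixed seed are
checksum-identical.

## What the synthetic data do and do not show

The phantoms have exact labels, no intensity information, no segmentation
error and smooth analytic geometry; the cohorts have Gaussian residuals,
exact categorical marginals and a linear education effect. Passing tests
therefore demonstrate that the *machinery* — interpolation, layering,
flattening, thickness measurement, model arithmetic — is correct and
calibrated, not that the pipeline is robust to motion artefacts, manual
segmentation variability, partial-volume effects, or non-linear
dose–response in real patients. Patient-derived quantities (group thickness
means of 2.28/2.20 mm, the stratified correlations) enter only as generator
calibration targets, never as correctness tests. Known limitations: curved
sheets carry a deterministic sub-voxel negative thickness bias; stress
grows with sheet thickness; the closed-tube topology is out of reach of any
planar embedding (hence the cut); layer counts depend on the growth
connectivity on oblique normals.
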