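# Methods

`stereocol` quantifies a 3D population of cells — in the motivating
application, layer III pyramidal neurons of the dorsolateral prefrontal
cortex (BA46) — three complementary ways: design-based stereology for
population totals and per-cell size/shape, voxel morphometry of segmented
image stacks, and second-order spatial statistics of cell centroids. All of
it is validated against a synthetic-data module with known ground truth.
This note records the models, the estimators, the numerical choices, and
what the synthetic validation does and does not establish.

## Coordinate and unit conventions

All lengths are micrometres. The observation window is an axis-aligned box
`[0,lx]×[0,ly]×[0,lz]` with the **x-axis perpendicular to the pial surface**,
so cortical minicolumns run along x. Voxel pitches are given in nanometres
(the native unit of the imaging hardware, e.g. 272×272×900 nm) and converted
once at ingestion; voxel `(i,j,k)` has its centre at `((i+0.5)vx, (j+0.5)vy,
(k+0.5)vz)` µm. Densities are reported per mm³ (`N/V × 10⁹` for V in µm³).
A single integer seed drives every stochastic component; independent streams
are split off by hashing a path of stage/subject labels into a
`SeedSequence` spawn key, so adding or reordering stages leaves unrelated
streams untouched.

## Stereological estimators

**Cavalieri volume.** `V = T · (a/p) · ΣP` from systematic parallel sections
a distance `T` apart carrying a square point grid with area `a/p` per point;
section phase and grid offset are uniformly random, which is what makes the
estimator unbiased. `T` is interpreted as the spacing between the *analysed*
sections, so the formula carries no extra subsampling factor; slab
subsampling belongs to the count estimator below. (With 300 nm cuts and
every third section analysed, the effective spacing is 900 nm.)

**Optical fractionator.** `N = (1/ssf)(1/bsf)(1/asf)(1/hsf) · ΣQ⁻`: cells
counted in optical disectors, divided by the sampling fractions at the slab,
section, area and height levels. The equivalent component form is
`N = 2 · (T/MA) · (A/a) · (t_Q⁻/h) · ΣQ⁻`, the leading 2 being the inverse
slab sampling fraction for every-second-slab sampling. When a design record
carries both forms they must agree to 1e-9 relative or the estimator refuses
to guess.

**Volume tensors.** For a cell `X` and a reference point (the nucleolus),
`T_k(X) = (1/k!) ∫_X x⊗…⊗x dx` with `x` relative to the reference. Rank 0 is
the volume; rank1/rank0 is the centre of mass, whose norm is the **nucleus
displacement**; the centred second moment `M = 2·rank2/rank0 − c cᵀ` is the
covariance of the uniform distribution on `X`. The shape summary is the
ellipsoid whose covariance matches `M` (semi-axes `√(5λᵢ)` along the
eigenvectors), rescaled isotropically so its volume equals rank 0 exactly;
for data that are themselves ellipsoidal the rescale factor is 1, and for
arbitrary shapes the summary preserves rank-2 anisotropy while matching
rank-0 volume (the two cannot both be matched exactly off the ellipsoid
family). The **elongation index** is the ratio of the longest to the
shortest fitted semi-axis (≥ 1 by construction; alternative ratios can be
formed from the reported semi-axes). Displacement is reported as a norm;
its direction is available from the centroid vector.

**Rotator probe.** The Monte-Carlo rotator measures boundary distances
ρ(ω) along half-lines through the reference point. Writing the tensor
integral in spherical coordinates, `T_k = (1/k!) ∫_{S²} ω⊗k ρ(ω)^{k+3}/(k+3)
dω`; a vertical plane through the reference at uniform azimuth φ ∈ [0,π)
carries the in-plane direction density `|sin ψ|/4` (ψ the angle from the
vertical axis). Half-lines are placed by systematic inverse-CDF sampling of
that density — `n` half-lines at `F⁻¹((u₀+j)/n)` with one uniform `u₀` per
plane — giving an estimator that is unbiased for ranks 0–2 and *exact* for
rank 0 on a ball from a single plane (all ρ equal). Convergence is the
Monte-Carlo rate: quadrupling the number of planes halves the error. The
implementation measures a single boundary crossing per half-line, which is
exact for star-shaped cells (any ellipsoid containing its reference); for
non-convex cells the natural extension is the total intercept moment, not
implemented here.

## Voxel morphometry

Per labelled cell: volume = voxel count × voxel volume; equivalent diameter
`(6V/π)^{1/3}`; centroid = mean physical voxel-centre coordinate;
orientation = angle between the principal eigenvector of the
physical-coordinate covariance and the x-axis, folded to [0°, 90°] since
axes are undirected; sphericity `π^{1/3}(6V)^{2/3}/A`.

The surface area `A` comes from a marching-cubes iso-surface at the
physical (anisotropic) voxel spacing — voxel-face counting overestimates
area by up to ~50% and was rejected. On strongly anisotropic grids the raw
binary iso-surface still carries a staircase along the coarse axis
(z-pitch ≈ 3.3× the in-plane pitch) that inflates area by ~17% regardless of
object size, so the mask is regularised with a Gaussian at the physical
pitch scale (σ = max pitch, default) before meshing. The trade is a small
curvature loss at small radii: digitized-ball sphericity is ≈1.017 at
r = 10 µm, 1.004 at 20 µm, 1.0005 at 40 µm — it converges to 1 from
*above* as radius/pitch grows, and values slightly above 1 are possible
for small cells (bounded by ~1.1 in practice). Connectivity for component
labelling defaults to 26 (favouring merging over splitting for near-tangent
somata); anisotropy is always handled by scaling coordinates, never by
resampling the grid. Labels with fewer than 4 voxels keep their volume and
centroid but are flagged unreliable with undefined orientation/sphericity.
The "diameter" reported is the equivalent-spherical diameter (not a Feret
diameter).

## Spatial point-pattern statistics

**Cylindrical K.** For direction d, radius r and half-length t,
`K̂(r,t) = λ̂⁻² Σ_{i≠j} 1[pair in cylinder] / |W ∩ W_shift|` with the
translation edge correction `|W ∩ W_shift| = Π(L − |Δ|)` and
`λ̂² = n(n−1)/|W|²` (ratio-unbiased under CSR; the translation correction
suits a thin rectangular biopsy window better than border methods). Under
CSR `E K̂(r,t) = 2πr²t`, the cylinder volume. The default grid scans the
minicolumn detection radii r = 5–20 µm at fixed half-length t = 50 µm; the
half-length is an explicit configuration choice, not an estimate of any
anatomical quantity. Ripley's 3D K is the same estimator with balls
(`(4/3)πr³` under CSR). The empty-space function F (distances from a
regular 12³ lattice of test points) and nearest-neighbour function G use
minus-sampling border correction; under CSR both equal
`1 − exp(−λ(4/3)πr³)`.

**Global envelopes.** A pattern is tested against CSR by simulating
`n_sim` binomial patterns with the observed count (conditioning on n
removes count variance), computing the three directional K-curves of each,
and concatenating them into one functional statistic so the test is
simultaneous over directions and radii. Curves are ranked pointwise from
both tails; ties (ubiquitous where K̂ ≡ 0) are broken by the extreme rank
length (ERL): each curve's sorted vector of pointwise ranks, compared
lexicographically. The p-value is the exact Monte-Carlo fraction of curves
at least as ERL-extreme as the observed one. The displayed envelope is
ERL-induced — the ⌊α(m+1)⌋ most extreme curves are set aside and the band
is the pointwise min/max of the rest — so "the observed curve exits the
band" coincides with p ≤ α. (The classical order-k rank band degenerates to
the min/max band at these simulation counts because tens of curves are
pointwise-extreme somewhere along 21 grid points.)

**Classification.** Per direction: clustered if the observed curve exits
above its band segment, repulsive if below, random if inside. Cylinder
clusters along one axis raise K in *all* directions, with the on-axis curve
highest; the pattern verdict is therefore "clustered, columnar in d" for
the direction with the strictly largest exceedance among those exiting
above.

## Group inference

Per-subject K-curves (CSR expectation subtracted) are combined into
weighted group means, default weight `w_i = n_i` (the subject's point
count), since the variance of K̂ shrinks with the number of pairs; the
weight function is pluggable and always recorded in the output. The group
test statistic concatenates each group's weighted-mean deviation from the
overall weighted mean; its null distribution comes from permuting subject
group labels uniformly at random (weights travel with subjects; the
observed labelling is included among the permutations), with a separate
envelope and ERL p-value per direction, mirroring one test per axis. The
reference count is 8000 permutations; calibration experiments here use 999
to keep the validation suite fast, which only coarsens the p-value grid.
Scalar endpoints (volume, diameter, orientation, sphericity, elongation,
displacement, counts) are compared with a classical one-way ANOVA; pairwise
post-hoc comparisons are pooled-variance t-tests (Welch selectable) with
Bonferroni multiplication by the number of pairs (6 for four groups),
capped at 1. Degenerate inputs (all groups constant and equal) define F = 0,
p = 1.

## Synthetic data: what it emulates, and what it does not

* `simulate_csr` — binomial (fixed n) or homogeneous Poisson patterns: the
  null model.
* `simulate_columnar` — a Poisson line cluster process: parent lines
  parallel to x at Poisson (y,z) positions spanning the window (the
  columns of interest traverse the layer), each with Poisson-many daughters
  uniform in x and displaced in (y,z) by an isotropic Gaussian
  (`column_sd`). Daughters falling outside the window are discarded. A
  `background_fraction` f thins daughters by (1−f) and adds a CSR component
  of matching expectation, so the expected total count does not depend on
  f. As `column_sd → ∞` the pattern converges to CSR. Defaults
  (`line_intensity = 5·10⁻⁴ µm⁻²`, `points_per_line = 20`,
  `column_sd = 3 µm`, 200³ µm³ window → ≈400 points) give column widths at
  the small end of the 5–20 µm detection range and subject-scale point
  counts; they are chosen for testability, not as anatomical claims.
* `simulate_hardcore` — Matérn type-II thinning with proposals in the
  r-dilated window (clipped back after thinning), so the output is the
  stationary process restricted to the window and the closed-form retained
  intensity `(1−e^{−λ_p v})/v` holds exactly.
* `place_population` / `voxelize_cells` — pairwise-disjoint triaxial
  ellipsoids (long axis 7–12 µm, short axes 4–7 µm by default,
  approximating layer-III somata) with a nucleolus placed uniformly in the
  cell shrunk to 30% about its centre; disjointness enforced conservatively
  by bounding spheres; rasterisation marks voxels whose centre falls inside
  a cell.
* Counting-study simulators reproduce the actual sampling mechanisms
  (random section phase and grid offset for Cavalieri; independent
  Bernoulli inclusion at the product of the sampling fractions for the
  fractionator), so the unbiasedness checks exercise the same randomness the
  real designs rely on.

None of this emulates image noise, the point-spread function, segmentation
errors, dendritic morphology, tissue shrinkage or section registration
errors. Passing tests therefore establish the *estimators'* correctness on
clean geometry — unbiasedness, calibration, convergence — not robustness of
any upstream imaging pipeline.

## Validation sizes and numerical choices

The validation suite uses problem sizes chosen to make Monte-Carlo noise
small relative to each tolerance while keeping a full run short: 500 random
designs for Cavalieri (1% tolerance), 2000 for the fractionator (3 SE),
10⁴ planes for the rotator (1%), 500 CSR simulations for the closed-form
means (3 SE), 200 replicates at n = 100 points for envelope type-I
calibration (band 2–8%), 201 per-direction tests for group-test
calibration, and 20 replicates for power (threshold 80%; measured power is
near 100% at `column_sd = 3 µm`). Envelope reference curves are computed in
a batched float32 path — their only use is ranking, where 10⁻⁷ relative
precision is far below Monte-Carlo noise; all per-pattern estimators are
float64. Other numerics: ellipsoid ray lengths solve the quadratic in
axis-scaled body coordinates (the positive root always exists for an
interior origin); eigenvalues of the centred second moment are clamped at
−10⁻⁹ relative before the PSD error fires, absorbing roundoff; the
fractionator/ Cavalieri design records validate their invariants
(`h ≤ t_Q`, `a ≤ A`, `MA ≤ T`, fractions in (0,1]) at construction.

## Known limitations

* The rotator handles one boundary crossing per half-line (star-shaped
  cells); total intercept moments for non-convex somata are future work.
* The ERL-induced envelope's band exit and p ≤ α can disagree in
  pathological tie configurations (everything identical); the p-value is
  authoritative.
* Variance predictors (CE formulas) for the stereological estimators are
  out of scope; only empirical Monte-Carlo variance is reported.
* The cylinder half-length grid is a configuration constant; no attempt is
  made to estimate an optimal cylinder aspect from data.
* `run_study` re-executes stages rather than caching them; stage outputs
  are plain CSV/JSON so any stage can be inspected or rerun independently,
  and identical config + seed reproduces identical numeric payloads.
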