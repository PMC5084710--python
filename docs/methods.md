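# Methods

This note records the models, conventions and design decisions behind
apexkit, in the order the pipelines run. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and volumes

Volumes are multi-page grayscale TIFFs indexed `(z, y, x)` (page = z
slice), with per-axis voxel sizes in μm given in the same order; voxel
centres sit at `(index + 0.5) × spacing`, so sub-voxel centroids are
unambiguous. All physical coordinates in output tables are `(x, y, z)` μm.
Exterior / unsegmented space must carry the background label (default 0).
Anisotropic spacing is honoured throughout: face areas use the spacing
product of the two in-face axes, and centroids scale linearly with each
axis's spacing (tested as a property).

## Facets and the new-wall call

A facet is the set of 6-connected voxel faces shared by one unordered
label pair; all shared faces are merged into one facet because two
adjacent cells share one biological wall. Pairs with fewer than
`min_face_elements` (default 5) faces are discarded as segmentation noise.
Facet area is the summed physical face area; the centroid is the
area-weighted mean of face midpoints; the signal density is the
area-weighted mean over faces of the mean intensity of the two flanking
voxels — the recorded operationalisation of "stain density", since the
wall signal lives in the voxels on either side of the interface.

A facet is called a new wall iff its density is within a relative
`tie_tol` (default 1e-9, i.e. exact ties only) of the minimum density over
the eligible facets of **both** adjacent cells. Ties call every tied
facet; facets touching the background are never called. Only within-cell
density ranks matter, so the call set is invariant under any global
increasing affine rescaling of the image (tested).

## Wall orientation

The best-fitting plane of a facet is estimated from its face midpoints:
the normal is the eigenvector of the smallest eigenvalue of the centered
second-moment matrix, the centroid is the mean point, and `planarity` =
λ₀/λ₁ (0 for coplanar points). Fits with fewer than `min_points` (default
4) points or rank < 2 are degenerate; such facets keep NaN angles —
undefined is always encoded as NaN, never as 0.

Both orientation angles are measured on the plane **normal** and folded
into [0°, 90°] (a normal has no sign):

* angle to the main axis = `arccos |n·a|` — a transversal wall
  (perpendicular to the stem axis, the rib-meristem signature) scores near
  0°, a wall containing the axis 90°. Descriptions of wall orientation
  sometimes quote the angle of the *plane* instead; that is the
  complement, and the normal convention is used consistently here because
  it gives transversal walls a distinct low-angle class.
* radial angle = `arccos |n·r̂|`, with **r̂** the unit component of
  (centroid − summit) orthogonal to the axis. A wall facing the central
  axis scores near 0°; anticlinal walls range from small to large radial
  angles depending on whether they face the axis; "radially oriented"
  walls (containing the radial direction) score near 90°. The radial angle
  is undefined (NaN) within `min_radius` (default 1 μm) of the axis.

Depth below the summit is axial — `depth = (summit − p)·a` — rather than
Euclidean distance to the summit; the two differ only near the summit at
large radius, and axial depth composes cleanly with the radius coordinate.
The reference frame (summit + unit axis) is user input per apex; a default
can be derived from a volume as the mean centre of the highest tissue
voxels along a user axis.

## Zonation and distribution comparisons

The standard regions in (depth, radius) μm windows: AR `[0,30)×[0,40)`,
RC `[30,60)×[0,40)`, RP `[30,60)×[40,50)`. Windows are half-open so the
shared 30 μm and 40 μm boundaries belong to the deeper/outer region;
classification is total and deterministic (first matching window wins,
with a warning for overlapping user-defined regions). Angle values are
pooled across apices per group; per-apex breakdowns can be produced by
passing per-apex groups.

The Mann–Whitney U test is two-sided and returns (U of sample 1, p). For
`min(n₁, n₂) ≤ 8` the p-value is computed exactly by enumerating all
C(n₁+n₂, min) group assignments over pooled midranks; doubled midranks are
integers, so tie handling and the two-sided count
`P(|U − n₁n₂/2| ≥ |u_obs − n₁n₂/2|)` are exact (the permutation
distribution of U is symmetric about n₁n₂/2, with or without ties). For
larger samples the tie-corrected normal approximation with continuity
correction is used. No multiple-testing correction is applied across the
region × metric grid by default, matching how such comparisons are
conventionally reported; callers can correct externally.

Boxplot summaries use the Hazen quantile rule (linear interpolation with
`h = np + 1/2`) for the median and quartiles — the convention is fixed and
documented because quartile values are reported verbatim — with whiskers
at the most extreme data within 1.5×IQR of the quartiles and everything
beyond listed as outliers.

## Clonal sectors

Sectors are recorded as one landmark per cell (μm, xyz) plus a per-apex
frame. Alignment is the rigid map translate(summit→origin) followed by the
minimal rotation taking the axis onto +z (about the mutual perpendicular;
an exactly antiparallel axis maps by a half-turn about x). Azimuth is left
untouched because no azimuthal landmark exists.

Per sector: centre of mass = mean landmark; principal ("main") axis =
direction of greatest scatter of the landmarks (second-moment
eigen-decomposition, sign-folded); vertical angle = `arccos |axis_z|`;
radial angle = angle between the principal axis and r̂ at the centre of
mass (undefined within 1 μm of the stem axis); cell count = number of
landmarks; length = extent (max − min) of landmark projections on the
principal axis — projection extent was chosen over farthest-pair distance
as the more robust reading of "main-axis length"; the two coincide for
straight clones. A single-point sector has an undefined axis, NaN angles
and zero length. Growth *rate* is deliberately not computed: the input is
a single time point, so cell count and length are the size measures.

Projections for plotting: the vertical view drops z; the radial view maps
each sector onto the plane through its centre of mass and the stem axis,
as signed (r, z) with the sign keyed to the centre of mass's x-coordinate
so left/right placement matches the vertical view.

## Consensus peaks, attribution, enrichment

narrowPeak/BED coordinates are 0-based half-open; GFF3 is read 1-based
closed and converted on input (start − 1). Consensus selection uses
coverage semantics per replicate (q-passing peaks merged; q ≤ q_max means
−log₁₀ q ≥ −log₁₀ q_max within 1e-9), a sweep-line 3-way intersection,
a minimum intersection length (default 50 nt), and exclusion of any
interval with ≥ 1 nt overlap with any control peak — controls are used as
called, with no q threshold, which is the conservative reading of "not
detected in any control". The region centre is `(start + end) // 2`.

Attribution anchors at the region **centre** (deterministic; an
any-overlap mode was considered and rejected because a wide region could
then serve arbitrarily many genes): region → gene g iff the centre lies in
the strand-adjusted window `[CDS_start − 3000, CDS_end + 1500]` (swapped
for − strand) and no other gene's CDS lies entirely in the open interval
between the centre and the nearer CDS edge (strand-agnostic — an
intervening coding unit in either orientation separates a peak from the
gene behind it). A region may serve several flanking genes.

Positional enrichment classifies each centre as promoter (between the
extended-span edge and the transcript start, 5′), transcribed (within the
transcript span) or downstream (3′), with transcribed taking precedence
where genes overlap. The null places the same number of centres uniformly
at random within the union of the attributed genes' extended spans —
deliberately *within the target set*, so the test asks "where within its
target genes does the factor sit", not "is it near genes at all". The
statistic is the promoter+downstream count and
`p = (1 + #{sim ≥ obs}) / (n_sims + 1)` (never below 1/(n_sims+1); seeded
and reproducible). Default 10,000 simulations. Position histograms
relative to the transcript start are emitted for plotting.

Motif inputs are the centre ± 75 nt observed windows and a seeded control
set of 10× as many random windows of the same width (length-weighted
across chromosomes, clipped at chromosome bounds with a warning). Gene-set
overlaps use the two-sided Fisher exact test on the 2×2 membership table.

## Synthetic study conditions

The generators aim for *detectability structure* — inputs whose ground
truth the analysis rules can, in principle, recover exactly — not for
biophysical realism.

**Meristem volumes.** The tissue mask is a paraboloid-capped cylinder
(default radius 55 μm, height 66 μm, cap drop 25 μm — large enough to
contain all three zonation windows). Cells are the nearest-seed partition
of the mask at a target diameter of 8 μm, sampled at 1 μm isotropic
spacing: a deliberate resolution choice, since coarser z-steps quantise
shallow transversal wall tilts (< 6°) to exactly 0° and misrepresent the
planted orientation distributions. Selected mothers (default 30/40/30 in
AR/RC/RP, i.e. 100 divisions) are split by a plane through their centroid
with a normal drawn from the region's orientation distribution —
folded-normal on the angle to the axis (transversal, mean 0° ± 10°, in the
core; anticlinal, mean 90° ± 10°, with uniform azimuth in the apical
region and periphery, so peripheral radial angles spread over [0°, 90°]).

Wall intensity encodes wall age. Old walls follow a linear age potential
of the two cells' centroids — predominantly "deeper is older/brighter"
(range `age_gain` = 4.5× above the 0.9× floor), with a small generic
lateral tilt to break ties. A linear potential has a unique local minimum
on the cell-adjacency graph (the summit cell), and the generator always
divides that cell, so each undivided cell's weakest wall points strictly
"uphill" toward younger tissue and no two undivided cells are mutually
weakest. Planted walls carry `intensity_ratio` (default 0.5) times the
*local* mature level, so `ratio = 1` is a true information-free negative
control (recovery collapses; the test suite asserts this). Voxels are
painted dimmest-wall-wins where several walls meet (a thin new wall keeps
its junction voxels); the residual junction contamination is then removed
by a brightening pass that raises any old wall the weakest-wall rule
would call — or that would undercut a planted wall — including a guard
margin of `guard_k` = 2.5 standard errors of the configured voxel noise
(σ = 10 % of the old-wall level by default). With zero noise the guard
collapses and the pass reproduces the exact call rule, which is what makes
noise-free recovery of the planted set exact by construction. Gaussian
voxel noise is added last.

Consequently, a passing detection benchmark shows that the weakest-wall
rule, facet measurement and plane fitting are implemented correctly and
are robust at the configured noise and resolution. It does **not** show
that the rule separates recent from slightly-older divisions in real
tissue, where wall ages form a continuum and every cell has a "most
recent" wall — on real data the method also reports older low-intensity
walls, and time-lapse validation remains the arbiter.

**Sectors.** Chains of one landmark per cell (4–10 cells, 4 μm steps)
along planted directions (vertical in RC, tangential in AR, 25° in RP,
±8° jitter), with 1 μm landmark jitter, grown in randomly posed apex
frames (summit offsets, ≤ 15° axis tilt) so alignment is exercised. Truth
values are the measurements of the noise-free chains. At this jitter and
sector length, per-sector angle errors have a standard deviation of
several degrees, so recovery is asserted at the median across sectors;
cell counts are exact per sector.

**Toy genomes.** Random sequence (default 2 × 100 kb), non-overlapping
strand-assigned gene models spaced so neighbouring promoter/downstream
windows do not collide, and true binding sites sampled directly from the
zone segments (default bias 60/20/20 promoter/transcribed/downstream,
≥ peak-width separation). Each treatment replicate re-emits every site
with ±20 nt jitter and a passing q (uniform in [3, 30] on the −log₁₀
scale); replicate-specific noise peaks and independent control peaks are
confined to a reserved gene-free tail of each chromosome, in slots spaced
so no cross-replicate 50-nt overlap can arise — which is what gives the
consensus rules an exact known answer (with zero jitter, recovery is
site-for-site). Real control libraries of course do overlap real signal;
the exclusion rule itself is exercised separately on constructed cases.

All generators are bit-reproducible from their seed; every stochastic
test and the acceptance script derive their randomness from explicit
seeds.

## Numerical choices and degenerate inputs

Rank-deficiency in plane fits is declared at λ₁ ≤ 1e-12·λ₂; unit-axis
normalisation tolerates any nonzero input vector; exact Mann–Whitney
enumeration is capped at 5×10⁶ assignments (beyond that the approximation
is used); Monte Carlo p-values are bounded below by 1/(n_sims+1) by
construction; empty facet lists write header-only tables; undefined
angles are NaN end to end. The Mann–Whitney exact path, the consensus
sweep, the Fisher table and the quantile rule are each validated against
independent oracles (full permutation enumeration, per-base coverage
masks, hypergeometric sums, and frozen hand-computed examples) in the test
suite.

## Known limitations

* The new/old wall call is binary; wall age beyond that is not estimated,
  and mother/daughter matching across time points is out of scope.
* The summit/axis frame is user input (or a simple highest-tissue
  heuristic); no curvature-based summit detection is attempted.
* Consensus selection implements the n-of-n replicate rule only.
* The enrichment null is confined to attributed genes' spans; it does not
  test genome-wide association with genes.
* The synthetic tissue is a static tessellation with planted divisions,
  not a growth simulation; conclusions about real-image performance are
  limited accordingly (see above).
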