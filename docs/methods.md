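# Methods

This note documents the models, parameter choices and numerical
decisions behind the package, in the order the pipeline runs them.

## Synthetic vascular phantoms

**Growth model.** A sample is a forest of stochastic binary branching
trees grown into one shared collision field. Each bifurcation draws a
flow split u ~ U(0.35, 0.65) and assigns child radii by Murray's law,
r_child = r_parent·u^(1/m) with exponent m = 3; children falling below
the minimum radius are not generated. Segments are straight, with the
drawn length scaled by calibre as (r/r_root)^0.7 — distal branches are
proportionally shorter, which both matches vascular morphometry and
lets thin branches fill inter-vessel gaps. Sibling branches leave on
opposite azimuths around the parent axis at 0.6–1.2× the nominal
branch angle (40°), so daughter tubes separate cleanly at the
junction.

Two structural guarantees make ground truth meaningful:

- *No self-intersection.* Every proposed segment is tested against all
  existing centerline samples (KD-tree) and must keep a 4 μm surface
  clearance; colliding proposals are redrawn, then dropped. Recovered
  topology is therefore well defined.
- *No sub-spur branches.* A segment must be at least 4.5× its radius
  long (2.25× its diameter, and never shorter than two voxels). The
  spur-pruning stage of vectorization removes terminal branches shorter
  than 2× their diameter; the margin guarantees no real branch is ever
  prunable, so exact topology recovery is a fair test.

**Forest density.** Trees (first at the root calibre of 25 μm,
subsequent roots drawn at 55–100% of it) are added until the centerline
length density reaches 2.8×10⁻⁴ μm/μm³, which puts typical
inter-vessel gaps near 100 μm. This density is what the
cavity-extraction construction assumes (see below); it is a property of
the phantom's resolved vessel population, not of real capillary-dense
tissue.

**Condition templates.** With field size F (minimum volume extent, in
μm), the focus sits at the volume centre with radius 0.20 F. Acute
templates attach extra microvessels (radius U(5, 10) μm, length
U(50, 90) μm) at random points of existing vessels inside the penumbral
shell (between one and two focal radii — never inside the focus),
at 4×10⁻⁶ vessels per μm³ of shell, scaled by the condition multiplier:
0 (sham), 1.0 (4 h), 1.5 (6 h). Each attachment splits its host branch,
so it adds two branches and two nodes — this is what drives the
branch/node-count peak at 6 h. Chronic templates instead carve all
geometry within a cavity radius of 0.34 F (3 d) or 0.46 F (18 d);
attachment multipliers return to 0. Template magnitudes were fixed once
to reproduce the qualitative ordering of the experimental time course
(counts: sham < 4h < 6h, falling by 3 d/18 d; cavity growing from 3 d
to 18 d); no absolute counts are claimed.

**Imaging model.** Vessels render as flat-capped tubes (union of finite
cylinders per straight run, a ball at interior bends) at intensity 100
on a parenchyma of 20, blurred with a 2.6 μm Gaussian PSF, plus
additive Gaussian noise (default σ = 8, i.e. contrast-to-noise 10;
recovery experiments also use σ = 16, CNR 5). Flat caps matter: ball-
stamped capsules would extend the mask one radius past every branch
tip and bias recovered lengths by ~+2r per terminal branch. An optional
concentric sinusoidal modulation emulates ring artifacts (off by
default). All draws for one sample come from a single seeded generator,
so identical specs give bit-identical volumes and ground truth.

**What the phantoms do not emulate.** No capillary bed below 5 μm
radius, no anastomoses (the truth is always a forest), no phase-contrast
edge enhancement, no beam-hardening or real ring artifacts, no
anisotropic PSF, no partial-volume texture in the parenchyma. Passing
recovery tests therefore demonstrates correctness of the measurement
chain on resolvable, tube-like, additive-noise data — not performance
on real reconstructions.

## Vessel enhancement

Frangi-type vesselness with α = β = 0.5 and c resolved per scale to
half the maximum Hessian Frobenius norm ("auto"), which makes the
response exactly invariant to positive intensity scaling. Scales are
σ = r/√2 for target radii {5, 7.5, 10, 15, 20} μm, snapped up to the
voxel spacing (σ = r/√2 is the scale at which a tube of radius r
maximizes the γ-normalized response; γ = 2 throughout). Boundary
handling is mirror reflection. Second derivatives come from sampled-
Gaussian kernels with the DC term removed exactly — scipy's truncated
kernels leak ~10⁻⁴ of the input level into the response, which would
break the zero-response-on-constant contract. Eigenvalues are computed
with batched symmetric diagonalization and sorted by magnitude.

## Segmentation

**Threshold.** Iterative intermeans (ISODATA): t ← (mean below + mean
above)/2 from the global mean, to |Δt| < 10⁻⁶ (relative to the
intensity range) or 100 iterations. The procedure commutes exactly with
affine intensity maps. A constant image has no threshold and is an
error; an already-binary response maps to itself (threshold at half the
positive level). The automatic threshold replaces manual selection for
reproducibility; a manual override is exposed.

**Mask construction.** Response > threshold (computed on the positive-
response support), then, when the raw volume is supplied, intersection
with raw > (background + vessel)/2, the two levels estimated as medians
outside/inside the vesselness mask. This half-max refinement trims the
~one-scale axial overhang of the vesselness response at tube ends; a
half-max cut is exactly the true boundary of a blurred two-level
object. Enclosed cavities (single-voxel noise dips inside vessels) are
filled — topology-preserving thinning would otherwise wrap closed
surfaces around them — and 26-connected components below 27 voxels are
removed. All parameters land in the mask's provenance record.

**Brain mask.** Otsu binarization, ball-closing at 250 μm, hole
filling, largest component. On real reconstructions Otsu separates
tissue from the empty field of view; on phantoms, where parenchyma and
exterior share one gray level, it picks up the vessels and the closing
recovers the vascularized territory.

**Ischemic cavity.** The cavity *core* is brain tissue farther than the
closing radius from any vessel. The largest 26-connected core component
is dilated back by the closing radius (the core sits exactly that far
inside the cavity rim), re-intersected with brain ∧ ¬vessels, and kept
if it reaches the minimum volume. Selecting the component on the core
is essential: the complement of a morphological closing equals
core ⊕ ball(r), so scattered inter-vessel pockets inflate and merge if
the component is chosen after dilation. Ball operations use exact
Euclidean distance transforms. Defaults on `extract_cavity` are 60 μm
closing and 10⁶ μm³ minimum — suited to capillary-resolved data where
inter-vessel gaps are tens of μm. The pipeline's phantom-analysis
defaults are 130 μm and 10⁷ μm³, because the phantom's resolved network
has ~100 μm gaps; both scales sit between the largest interstitial gap
and the smallest template cavity (170 μm radius at the default 96³
field).

## Skeletonization and vectorization

Thinning uses the parallel topology-preserving 3D algorithm of
scikit-image; radii are Euclidean-distance-transform values at skeleton
voxels. Thinning retracts centerlines ~one radius from free tube ends,
so each endpoint is marched outward along its terminal direction while
still inside the mask (tip extension); with flat-capped tubes this
restores the centerline to the cap. If a perfectly symmetric object
erodes away entirely (the medial axis can fall between voxels), the
deepest voxel per component is kept.

Vectorization:

- *Adjacency.* 26-adjacency with redundant diagonal edges removed — a
  diagonal step is dropped when an intermediate skeleton voxel shortcuts
  it. Raw 26-adjacency creates spurious triangles (false junctions and
  loops) along staircase chains.
- *Nodes.* Voxels with one pruned-adjacency neighbour are endpoints,
  with ≥3 are junction candidates; 26-adjacent candidates merge into a
  single node at their centroid. Isolated voxels become degree-0
  endpoint nodes; a pure cycle becomes one branch on a single flagged
  degree-2 junction node.
- *Branches.* Degree-2 chains traced between nodes, in canonical
  (lexicographic) voxel order, so identical masks give identical
  graphs. Branch length sums per-step chamfer weights 0.9016 / 1.289 /
  1.615 (axis / face / body diagonal, × spacing): the naive 1 / √2 / √3
  weights overestimate digitized straight lines by ~9% on average,
  which would consume the length-accuracy budget by itself. Branch
  diameter is 2× the median distance-transform radius over interior
  path voxels (median, to resist junction inflation).
- *Cleanup.* Cycles whose circumference is under 8× the thickest cycle
  branch's diameter are contracted into one junction — noise tunnels
  through thick junction regions make thinning keep small handles
  (circumference ~π × diameter), while a genuine vascular ring is far
  longer relative to its calibre. Terminal branches shorter than
  prune_factor (default 2) × their own diameter are removed as thinning
  spurs and the skeleton re-vectorized once. Any junction node left
  with degree 2 is dissolved by merging its two branches.

Diameter filtering (e.g. the < 30 μm microvessel subset) keeps branches
in [min, max), recomputes degrees and drops orphaned nodes. Morphometry
is computed over all branches by default.

## Morphometry and statistics

Branch calibre histogram bins are fixed at <10, 10–20, 20–50 and
>50 μm; counts always sum to the branch count. Mean branch length is
the per-branch arithmetic mean. Vascular volume fraction is vessel
voxels over brain-mask voxels. Group comparison is classical one-way
fixed-effects ANOVA (sums of squares computed directly; p from the F
distribution) followed by Tukey HSD over all group pairs via the
studentized range (statsmodels), at α = 0.05. Degenerate inputs are
explicit: identical groups give F = 0, p = 1; zero within-group
variance with distinct means reports F = ∞, p = 0, flagged; a
single-group input degenerates to means only, flagged, with no test.
The diameter pseudocolor table maps calibre linearly onto a blue→red
gradient over 10–50 μm, clamped at the ends.

## Problem sizes

The default analysis field is 96³ voxels at 5.2 μm (a 500 μm cube);
the cohort study is five conditions × three replicates, per-sample
seeds derived by hashing (global seed, condition, replicate).
Recovery experiments use 80³ fields with one- or two-generation trees
(radii ≥ 3 voxels) for exact-topology checks, and 96³ fields for cavity
recovery. These sizes keep a full cohort under ~2 minutes per run on
one CPU while leaving every tested property — rank orderings, relative
tolerances, exact topology — size-independent.

## Known limitations

- The measurement chain is validated on phantoms only; real
  reconstructions add artifacts (phase fringes, rings, streaks) that
  the imaging model does not produce.
- Radius estimates inherit the segmentation's bias: the vesselness
  support runs slightly inside the true wall, so calibres in noisy
  volumes read ~5–15% thin. Trend comparisons are unaffected.
- Near-touching vessels (< ~1 voxel apart after blur) can fuse in the
  mask and appear as anastomoses; phantom clearance keeps this rare but
  noise can still bridge gaps.
- The cavity construction assumes one dominant vessel-free region well
  separated in scale from interstitial gaps; multiple cavities would be
  reported as the largest one only.
- Anisotropic voxels are not supported anywhere in the pipeline.
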