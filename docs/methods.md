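# Methods

This note documents the models, conventions and numerical choices behind
`phylomorph`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and which decisions were genuinely open.

## Voxel volumes and skeletonization

Volumes are 3D boolean occupancy grids with per-axis physical spacing in
mm; all geometry (radii, lengths, angles, spacings) is computed in mm,
never in voxel counts, because CT stacks of colonies are typically
anisotropic (z pitch several times the xy pitch).

`skeletonize` reduces the foreground to its largest 26-connected
component, resamples to isotropic voxels at the finest axis pitch (3D
thinning assumes isotropy), thins with the topology-preserving 3D
algorithm of scikit-image, and assigns each skeleton voxel the Euclidean
distance to the nearest background voxel as its inscribed radius.

Two numerical details matter:

- **Lattice-symmetry guard.** Topology-preserving thinning can contract a
  perfectly lattice-symmetric tube to nothing: in a symmetric even-width
  cross-section no voxel ever becomes a curve endpoint, so the end caps
  erode straight through the limb. Real scans never exhibit this, but
  synthetic axis-aligned cylinders do. Thinning is therefore retried with
  different fixed sub-voxel resampling offsets until no foreground voxel
  is farther from the skeleton than about 2.5 maximal inscribed radii
  (ordinary tip retraction is roughly one local radius); the best attempt
  is kept. The offset sequence is a package constant, so results are
  deterministic.
- **Ridge snapping.** The thinned line can sit ~1 voxel off the true
  medial axis, which would bias radii low; per-point radii therefore take
  the maximum of the distance transform over the 3×3×3 neighborhood.

The voxel skeleton is converted to a branch graph. Thinning leaves small
clumps of junction voxels (and voxel-scale loops) around each true
bifurcation, so 26-adjacent junction voxels are clustered into one node,
and two junction clusters joined by a path shorter than the local
inscribed radius are merged — they lie inside a single junction ball.
Terminal branches shorter than the prune length are removed iteratively;
the default prune length is **2 × the median branch diameter**, which
suppresses corallite-scale surface spurs while keeping true branches.
Pass-through nodes left by pruning are merged away. A skeleton with
cycles after pruning is flagged (`is_tree=False`) with a warning rather
than an error: the colony is then not tree-like and branch measures should
be interpreted with care.

The **basal** node is the skeleton tip with the lowest coordinate along
the growth axis (+y by convention); branches are oriented away from it.

## Branch measures

For each oriented branch: `da` is the inscribed diameter at the proximal
(parent-side) end; `db` is taken one local diameter distal to the junction
along the child centerline ("after branching" is not otherwise
quantified); `dc` is the diameter at the tip (tip branches only); `rb` is
the centerline arc length; `g_angle` is the angle between the branch axis
and +y; `b_angle` is the angle between the axes of the two branches
emerging from the same junction (undefined for the basal branch). Branch
axes come from a total-least-squares line fit to the centerline, which is
robust to voxel jaggedness; an endpoint-chord alternative would differ
only at strongly curved branches. `br_spacing` is the distance from a tip
to the nearest centerline point of another branch. The centerline (rather
than surface) target makes ground truth exact in the simulator and is
stated here because the two conventions differ by about one branch radius.

Colony traits: **thickness** = mean representative branch diameter, where
the representative diameter of a branch is the mean inscribed diameter
over its interior (excluding half a median diameter at each end, the part
inflated by junction balls); **spacing** = mean `br_spacing` over tip
branches; **length/thickness ratio** = mean of `rb` divided by the
branch's representative diameter. Which of da/db/dc (or the interior
mean) represents a branch, and mean vs median aggregation, are config
switches (`diameter=`, `statistic=`); the interior mean is the default as
the least junction-biased choice. Traits are standardized per trait to
zero mean and unit **sample (n−1)** standard deviation — with two colonies
a standardized column is (−1/√2, +1/√2) — and the convention is recorded
in every provenance log. Morphological distances are plain Euclidean in
the standardized 3-trait space.

## Genetic distances

p-distance = differing sites / comparable sites with pairwise deletion of
gaps and N (the standard convention; intron alignments contain indels).
IUPAC ambiguity codes other than N are masked as N with a warning.
Diploid samples: the single allele of a homozygote is duplicated so every
sample carries two alleles, and the distance between two samples is the
mean of the four inter-allele comparisons. The self-comparison of a
heterozygote would average to half its inter-allele distance; the matrix
diagonal is instead defined as 0, which clustering and permutation
machinery require.

## Trees

The morphological dendrogram uses unweighted average linkage (UPGMA) with
merge heights equal to half the between-cluster average distance, so leaf-
to-leaf path lengths equal cophenetic distances. Ties are broken by the
lexicographic order of the candidate clusters' member labels, making the
tree deterministic across platforms. The weighted (WPGMA) variant was
considered and rejected as the less common reading of "average linkage".

Topological distances set every branch length to 1 and count edges on the
leaf-to-leaf path in the **rooted** tree as parsed: the root is an
ordinary path vertex, so a path through the root traverses both of its
incident edges. Users who prefer unrooted edge counts can unroot
explicitly before calling. Allele-level distances collapse to sample
level by averaging over allele pairs; duplicating a homozygote's allele
leaves the mean unchanged, so the duplication rule and the plain mean
coincide.

## Congruence tests

Mantel: Z = Σ_{i<j} d1ᵢⱼ d2ᵢⱼ over the row-major upper triangles of two
label-aligned matrices; r is the Pearson correlation of the same vectors;
the null permutes the objects (rows and columns simultaneously) of the
second matrix. The reported t is the permutation-standardized deviate
(Z − mean)/sd of the null with population (ddof=0) sd — a closed-form
moment version exists but adds assumptions without changing the deviate's
meaning. Default tail is one-sided "greater": congruence is a directional
hypothesis.

CADM: distances are ranked within each matrix (mid-ranks for ties) and
concordance is the tie-corrected Kendall W; the global null permutes every
matrix independently (a fixed-reference variant is available via
`permute_all=False`); a posteriori, matrix k is scored by the Pearson
correlation between its ranks and the mean ranks of the other matrices,
permuting matrix k only. For m = 2 the identity W = (1+ρ)/2 holds exactly
whenever the two rank rows carry equal tie corrections (always true for
tie-free continuous matrices); with unequal tie patterns the tie-corrected
denominator uses the arithmetic rather than geometric mean of the rank
variances and the identity is approximate.

All permutation p-values use (1 + count ≥ observed)/(1 + n_perm), so the
smallest attainable p is 1/(n_perm+1); the default n_perm is 1000.
Exhaustive enumeration over all n! object permutations is available for
small n (for CADM with m = 2, permuting a single matrix enumerates the
null exactly because W is invariant under simultaneous relabeling).

## Synthetic data

The colony generator grows a strictly binary tree of straight capsule
segments: children deflect by half the inter-child `branch_angle` (plus
Gaussian jitter) on either side of the parent axis, within a plane whose
orientation is redrawn per junction. If a `spacing_target` is given it
overrides the angle via angle = 2·arcsin(target/(2·child length)).
Per-segment radii, lengths, realized inter-child angles, growth angles and
tip spacings are recorded as ground truth, so every downstream measure has
an exact expected value. Parameter sets whose non-adjacent segments
overlap beyond a configured fraction are rejected as degenerate.
Rasterization marks a voxel foreground iff its center lies within the
segment radius of a centerline (capsule geometry in mm, honoring
anisotropic spacing) and pads the volume with background.

Sequences evolve site-i.i.d. under Jukes–Cantor along a **star** species
tree: every species splits at the root, so the expected p-distance between
alleles of different species has the closed form 3/4·(1 − exp(−4/3·d))
with d the tip-to-tip divergence — the property the calibration tests
exploit. Allele lineages within a species coalesce at 5% of the
divergence below the species ancestor (default). Heterozygotes draw two
alleles; homozygotes store one; each hybrid sample takes allele 1 from its
nominal species and allele 2 from another species' lineage (one allele per
parental species, no recombination). The generator does not model coral
growth, selection, recombination or coalescent stochasticity in tree
shape; passing tests demonstrate correctness of the measurement and
testing machinery on tree-like geometry and clock-like sequences, not
robustness to real CT noise, encrusting bases, anastomosing branches or
rate variation.

`generate_congruent_dataset` couples the two sides: 3 traits per sample
from species-specific normals with unit within-species sd and mean
separation `effect_size` (in sd units) in random directions, and a genetic
matrix simulated on the same species assignment (default divergence 0.05
substitutions/site, heterozygosity 0.4, 400 sites — values typical of a
variable nuclear intron among recently diverged congeners). With
`effect_size=0` the matrices are independent, giving the type-I
calibration condition; at 5 sd the congruence tests have essentially full
power at n = 15.

## Problem sizes used in the test battery

Calibration and power checks use 500 null replicates and 200 power
replicates at n = 15 objects with 999 permutations; oracle comparisons use
500 random trees (≤ 12 leaves) and 200 random matrices (≤ 6 labels);
morphometric recovery uses cylinders of radius 2–8 mm at 0.33 × 0.33 ×
1.50 mm spacing and three-generation colonies at 0.5 × 0.5 × 1.5 mm.
These sizes give stable statistics (binomial se of a 5% rate at 500 reps
is ~1%) while keeping the suite quick on a single CPU.

## Known limitations

- Thinning-based skeletons retract tips by about one branch radius, so
  `rb` of tip branches and tip positions are short by that amount;
  spacing measurements inherit ~1 voxel pitch of jitter.
- `db`'s "one diameter past the junction" offset is a convention, not a
  measurement-theoretic optimum.
- The star species tree has no topology signal; tests of tree-shape
  recovery beyond species-level clustering are out of scope.
- Mantel/CADM assume exchangeable objects under the null; phylogenetic
  autocorrelation within species makes the tests anti-conservative for
  inference beyond the synthetic calibration conditions.
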