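# Methods

## The descriptor system

Two contacting aromatic rings are described by three numbers. Let n₁, n₂ be
the fitted unit normals, c₁, c₂ the ring centroids, and
θ = arccos |n₁·n₂| ∈ [0°, 90°] the plain angle between the planes.

**Interplanar dihedral α.** The plain θ cannot distinguish an acute from an
obtuse arrangement — sliding one ring across the other turns a 50° contact
into a 130° one without changing θ. α restores that distinction: let L be the
intersection line of the two ring planes and w_k the in-plane unit vector
from the point of L nearest to c_k toward c_k; then α = ∠(w₁, w₂) ∈ [0°, 180°].
α is symmetric in the rings, invariant under rigid motions, independent of the
(arbitrary) normal signs, and always equals θ or 180° − θ. For the canonical
construction — ring 1 in z = 0 at the origin, ring 2 tilted by Ry(α₀) and
shifted by (Δx, Δy, h) — the closed form is

    α = arccos( sign(Δx + h·cot α₀) · cos α₀ ),

i.e. α = α₀ on the acute side of the switching boundary Δx = −h·cot α₀ and
180° − α₀ beyond it, independent of Δy. The implementation is validated
against this rule over a dense parameter grid (tolerance 10⁻⁶ degrees off the
boundary).

Degenerate branches: sin θ < 10⁻⁶ (planes effectively parallel) and a ring
center within 10⁻⁶ Å of L both fall back to α = θ. Both thresholds sit far
below coordinate precision (PDB files carry 10⁻³ Å).

**Central plane.** The plane through L and the midpoint M of the centers; for
parallel rings, the mid-plane. If M itself lies on L (measure-zero), the
plane spanned by L and the dihedral bisector is used. Note this plane
contains the dihedral bisector only approximately in general; the
through-L-and-M construction is the one implemented.

**β and d.** β is the angle between the two guiding vectors — unit vectors
from each ring centroid toward its Cγ, i.e. toward the stem that connects
ring to backbone — after orthogonal projection onto the central plane
(β ≈ 0° cis, 180° trans; undefined, reported as NaN, when a guide is parallel
to the central-plane normal). d is the distance between the projections of
the two centroids onto the central plane; projection is non-expansive, so
d ≤ |c₂ − c₁| always.

**Ring fitting.** Centers and normals come from a total-least-squares plane
fit (SVD of the centered ring coordinates). Phe/Tyr use the six benzene
carbons; His the five imidazole heavy atoms; Trp all nine indole heavy atoms
(indole is planar, and fitting the full system avoids choosing between the
five- and six-membered sub-rings). Rings with RMS out-of-plane deviation
above 0.25 Å, or missing any required atom or CB/CG, are skipped with a
warning.

## Contact definition and classes

A pair is a contact when the centroid distance is strictly below 7 Å.
Same-chain pairs must be separated by at least two positions on the chain
*ordinals* (order of appearance, robust to author-numbering gaps and
insertion codes); |i−j| = 2 contacts are flagged as through-one-residue
neighbours. Inter-chain pairs are included by default and can be switched
off. Orientation classes partition [0°, 180°] with lower-closed bins:
parallel (α < 15° or α ≥ 165°), [15, 45), [45, 75), perpendicular [75, 105),
[105, 135), [135, 165).

## The reference enumeration

The null model asks how often each orientation class occurs when two ideal
Phe side groups are placed in contact with no interaction beyond hard-sphere
sterics. The template is a regular hexagon with C–C 1.39 Å in z = 0, centroid
at the origin, CG on +x and CB 1.52 Å beyond CG (idealized standard
geometry). Ring 2 is the template rotated by m about the origin and shifted
by v, so the center distance is exactly |v|.

*Rotations.* Two modes. (a) Grid + sift: all Euler products Rz·Ry·Rx at a
fixed step are thinned by keying each matrix on the nearest quasi-uniform
sphere point (Fibonacci spiral) to each of its three axis images and keeping,
per key, the matrix closest to its key points. The spiral point count is
4π/s² for requested spacing s (≈ 6 600 points at 2.5°, with a floor of 8 so
even the coarsest request covers all axis directions), and the median
nearest-neighbour spacing tracks s within 15%. (b) Uniform random: normalized
Gaussian quaternions, exactly uniform on SO(3) and cleanly seedable — the
preferred desk-scale estimator, since the class fractions are
resolution-independent statistics.

*Translations.* The lattice step·(i, j, k) strictly inside |v| < 7 Å
(11 459 vectors at 0.5 Å). Strict boundaries are used everywhere — the
contact cutoff, the lattice, and the ball overlap rule below.

*Steric filter.* Each side-chain atom (six ring carbons + CB) is a 1.75 Å
ball; the entire backbone is one 3 Å ball on the Cγ–Cβ line, 3 Å beyond Cβ on
the side away from the ring (the physically sensible of the two positions the
line admits). A conformation is forbidden iff any inter-residue ball pair has
center distance strictly below the radius sum. About 30% of conformations
survive; survival barely changes the parallel and perpendicular fractions but
depletes the obtuse bins, and it makes trans guiding-vector arrangements
dominate among parallel pairs (cis stacking aligns the two backbone balls and
clashes).

*Scale.* The histogram pass streams one rotation at a time with vectorized
kernels over the whole lattice, so memory is flat in the conformation count;
full-scale runs (~10¹⁰ conformations) are supported in principle, and
overlap-allowed totals are available without iteration as
n_rotations × n_vectors. Tests and the acceptance script use scaled runs —
5 000 rotations × a 0.875 Å lattice (2 103 vectors, ≈ 10⁷ conformations) —
which reproduce the class fractions to well under a percentage point of
Monte-Carlo scatter.

Analytic anchors: under exactly uniform rotations θ has density sin θ, so
P(parallel) = 1 − cos 15° ≈ 3.41% and P(perpendicular) = cos 75° ≈ 25.88%;
both class memberships depend only on θ, hence only on the rotation, which
the tests exploit (translation independence). The position-dependent α splits
each sine-symmetric θ mass between acute and obtuse: among *contacting*
centers the acute side of the intersection line is the larger one, so
P(α < 90°) > P(α > 90°) — e.g. the [15°, 45°) bin holds ≈ 22% of
conformations versus ≈ 3–5% in its mirror [135°, 165°).

## Pair-type statistics

Frequencies P_A are estimated over pair members (2·N_sum slots), not over all
residues in the structures. Expected counts are 2·N_sum·P_A·P_B for hetero
and N_sum·P_A² for homo pairs — the multinomial convention under which the
expectations sum to N_sum exactly. Density histograms divide by total count
and bin width and support explicit widths for classes that span disjoint
ranges (the parallel class covers 30° split across both ends of the α range).
A population ratio r corresponds to ΔE = RT·ln r with
R = 1.987×10⁻³ kcal/(mol·K) at 298.15 K; a two-fold ratio is ≈ 0.41 kcal/mol,
below the resolution of conventional force fields.

## Chain clustering

Identity is Id = I/(L₁+L₂−I)×100 from a precomputed pairwise alignment table;
absent pairs count as identity 0 and therefore always veto. Chains that match
perfectly collapse first (connected components of Id = 100). Clustering then
repeatedly merges the pair of clusters with the highest *average*
cross-identity, subject to a complete-linkage veto: no merge may put two
chains with identity below the threshold into one cluster. Ties on the
average break lexicographically on the smallest chain id per cluster, making
the procedure deterministic. Each lower threshold is seeded with the previous
partition, which guarantees nesting (every 75% cluster lies inside one 50%
cluster, and so on). The mean over all cross pairs is used as the
"average" — an unweighted choice; a size-weighted variant would also be
defensible. Representatives are chosen by best (smallest) resolution, ties
lexicographic.

Structure-level dataset filters: X-ray method, resolution strictly better
than 3 Å (entries lacking a resolution are rejected), ≥ 40 residues.

## Synthetic data

The fixture generator produces (a) two-Phe PDB structures from the
rotate-then-translate construction, whose exact α is known from the closed
form above (recovered to 10⁻⁶ degrees on in-memory geometry and to 0.05°
through PDB round-trip, the difference being the format's fixed-width
coordinate truncation); (b) boxes of randomly placed and oriented aromatic
residues, one per chain so that every pair is contact-eligible and a plain
O(n²) distance count is the oracle; and (c) block-structured identity tables
with a planted partition. The fixtures use idealized planar templates and
crude backbone placement: they exercise the geometry, bookkeeping and
clustering exactly, but say nothing about realistic protein packing,
secondary structure, or coordinate noise beyond the fit tolerances — passing
tests validate the machinery, not any biological claim.

## Known limitations

- PDB format only (first MODEL; altlocs resolved to highest occupancy, ties
  preferring 'A'); no mmCIF, no assembly expansion.
- Aromatic ligands (HETATM) are ignored; only the four standard aromatic
  residue types contribute rings.
- The guiding-line-distance reading of d (distance between the two guide
  *lines*) is not implemented; d is the projected-center shift.
- The enumeration uses a Phe template only; no per-type templates, hydrogens
  or energy model.
- β-strand-bridge neighbour detection is out of scope; only the |i−j| = 2
  flag is provided.
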