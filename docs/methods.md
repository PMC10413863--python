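# Methods

## Probe engine

A probe instance of radius `r_p` is a sphere tangent simultaneously to three
atoms, `|x − c_i| = r_i + r_p` for each triplet atom `i`, that clashes with
no other atom (`|x − c_k| ≥ r_k + r_p − tol` for all `k`).  The tangency
system is solved by trilateration in an orthonormal frame of the triplet; it
yields two mirror solutions on opposite sides of the plane through the three
atom centers.  Collinear triplets and grazing (double-root) configurations
are skipped.  Candidate triplets are restricted by the necessary pair
condition `|c_i − c_j| < r_i + r_j + 2 r_p` using a k-d tree; clash tests run
as nearest-neighbour queries per distinct vdW radius.  Probes whose centers
coincide within `tol` are merged keeping the lexicographically smallest
triplet, and output order (triplet, then side) fixes ids deterministically.

Defaults: ladder 1.4 → 3.0 Å in δ = 0.1 Å steps (17 levels); `tol` = 1e−3 Å.
The trimming plane is the plane through the three atom centers with a
deterministic canonical normal; the probe's `side` is its sign relative to
that plane, and `side × normal` is the outward direction used for entrances.
Only triplet-tangent ("fixed") probes are generated; toroidal two-atom
rolling contacts are not probe instances in this scheme.  An external SES
engine can replace the internal one through the probe TSV dump/import
format.

## Clustering events and the merge tree

Merging happens only between probes of equal radius or radii differing by a
single δ:

* **bottleneck** (equal or δ-differing): same triplet, opposite sides, the
  in-plane projections of both centers coincide (tolerance 0.1 Å) and fall
  inside the triangle of atom centers — a narrowing sealed from both sides.
* **radial shift** (δ-differing): same triplet and side.  Maximal runs over
  consecutive levels form chains; the chain length is its *depth index*.
  Chains with depth ≥ 4 (the significant-alignment threshold) mark
  pseudo-mouths; their per-cluster depth indices form the persistence list.
* **lateral** (equal radius): probes tangent to the same two atoms, on the
  same side of each trimming plane, with center distance ≤ γ.
* **pyramidal** (δ-differing): probes not sharing a full triplet with center
  distance ≤ β.

γ and β are read as **center-to-center distances**, not surface gaps.  This
is a deliberate design choice: adjacent SES probes overlap almost everywhere
on any molecular surface, so a surface-gap reading would let the optimal
setting (γ = 0, β = 0.9 Å) merge every neighbouring pair and percolate the
whole surface into one cluster — the exact failure mode these two caps exist
to control.  Under the center-distance reading β genuinely bounds how far
aggregation can spread, and γ = 0 sits at the "no lateral merging" end of
its axis, consistent with larger γ producing fewer, larger pockets.

Passes follow the ladder: per level, same-radius bottlenecks then lateral;
between consecutive levels, bottlenecks then pyramidal + radial shift.
Within a pass, candidate pairs are processed in ascending distance (ties by
probe ids), so the run is deterministic.  Merges are union-find; each merge
creates a binary tree node recording the event and the two cluster sizes
before merging.  Because all four predicates are pairwise-geometric and
independent of cluster state, the final partition equals the transitive
closure of the pairwise event relation — the property the oracle-equivalence
test checks exhaustively on small fixtures.  After construction the forest
is indexed so that every node covers a contiguous leaf interval, making
membership and subset queries cheap without per-node member sets.

## Pockets, subpockets, entrances

A node qualifies as a pocket when it has ≥ 100 member spheres and owns at
least one significant chain; maximal qualifying nodes are pockets, minimal
qualifying strict descendants are subpockets, and a pocket with subpockets
is a master.  Terminal probes of significant chains with radius > 2.4 Å are
single-linkage clustered under the power-distance orthogonality rule
`d² ≤ r_i² + r_j²` into entrances, each carrying the arithmetic mean of
member centers, an effective radius (mean center spread + mean radius), the
mean chain depth, and the mean outward terminal normal.  A pocket with no
qualifying terminal is buried; a subpocket is buried when its terminal
radius falls below the separate 2.5 Å threshold (the two constants are kept
distinct and configurable).

## Descriptors

Seventeen geometric/clustering entries: entrance count, buried flag, mean
entrance radius, member-weighted entrance depth normalised by the alignment
threshold (1 = minimal pseudo-mouth), bottleneck count and mean radius,
size-weighted mean radius of large aggregations (merges where the smaller
cluster is ≥ 1/5 of the larger and both exceed 10 spheres), mold volume,
sphere count, aggregation/persistence/clustering scores (list length and
persistence sum normalised by size, and their sum), large-aggregation score,
volume-per-sphere ratio, Wadell sphericity ψ = π^{1/3}(6V)^{2/3}/A,
ramification (standard deviation of the persistence list) and protrusion
(un-normalised entrance depth − mean persistence − ramification).  Features
derived from an empty persistence list or absent entrances default to 0.

Twenty-two chemical entries: the fraction of each amino acid among the
distinct residues with at least one atom tangent to a member probe (they sum
to 1), plus hydrophobic and hydrophilic scores from a bundled binary
classification (glycine neutral: counted in the denominator, in neither
class).  The table is config-overridable.

Pocket volume and area come from the union of member spheres: the signed
distance field is sampled on a regular grid (default 0.3 Å), the zero
isosurface extracted by marching cubes, and vertices snapped radially onto
the nearest sphere surface, which removes the interpolation bias and leaves
only the chordal faceting term (≈ −2% at 0.2 Å on unit spheres, converging
as the grid refines).  The mesh doubles as the exported pocket mold.

## Ranking

Isolation forests are fitted with scikit-learn: no bootstrap, subsample 256,
10,000 trees at deployment (tests and the bundled training path use 200 —
statistically equivalent score contracts at far lower cost; the score is an
average over trees whose variance at 200 trees is already well below the
decision scale of the rankings exercised here).  Training rows are hitting
pockets only, replicated `max(1, round(10 × PC))` times (PC as a fraction)
to bias toward tight pockets, and split into "large" (masters with more than
one subpocket) and "small" (everything else, subpockets included)
populations, two feature blocks each — four forests.  The large-population
pair scores every top-level pocket (final score = mean of geometric and
chemical anomaly scores, ascending order, ties by larger volume then id);
the small-population pair orders subpockets within their master.  If a
population has no training rows its forests fall back to the other
population's pair.

The anomaly law `s = 2^{−E(h)/c(n))}` is cross-checked against an
independent re-implementation that walks every tree and re-applies the
below-leaf extension `c(leaf size)`; both routes agree to 1e−8.

For the single-pocket protocol each master is replaced by its ≤ 3 top
subpockets, scored by a penalised master score.  The penalty law is
`s_R = 1 − (1 − s)/R` for subrank `R`: identity at R = 1, non-improving and
bounded by 1 as R grows, and "proportional to the subranking" in the 1/R
sense.  The exact published expression was not recoverable from the source
text, so this form was chosen to satisfy the two stated contracts, which are
the only properties tests rely on.

## Evaluation

Contact = center distance < 5 Å between heavy atoms.  LC = ligand heavy
atoms contacting the pocket over those contacting the whole protein;
PC = pocket heavy atoms contacting the ligand over all pocket atoms; both
×100 and rounded *up* at 0.1% resolution (the ceiling reading is taken
literally).  Hit: LC ≥ 50 and PC ≥ 20 (inclusive).  A ligand contacting no
protein atom has undefined LC, is never a hit and is excluded from
normalisation with a warning.  Residue mode replaces atoms by residues on
the protein side (a residue is in contact if any heavy-atom pair is within
cutoff; pocket residues come from tangent atoms); a residue-set variant
supports apo evaluation after mapping binding residues through global
sequence alignment (affine gaps, exact residue identity required) and
keeping only solvent-exposed ones.  Rank of a site = number of non-matching
pockets above the first match; Top-N rates are normalised per
structure–ligand pair.  Mean LC/PC are averaged over the first matching
pocket of each site.  Nested evaluation credits a master when any of its
top-3 subpockets matches.

## Synthetic fixtures and the grid oracle

Fixtures place atoms on jittered quasi-uniform lattices: a two-layer hollow
shell (cavity radius 2.7 Å, mouth 3.6 Å, atom radius 1.5 Å, spacing 1.5 Å),
a two-layer open tube (bore 2.2 Å — deliberately below the 2.4 Å entrance
threshold so only the two open ends qualify as mouths), a three-layer slab
with a hemispherical dimple, and a solid convex blob whose pseudo-ligand is
parked on the surface and flagged shallow.  Walls are two atom layers thick
because a single layer lets mirror probes exist on both sides of the same
triplet, which the bottleneck rule would merge straight through the
material.  The cavity is kept smaller than the 3 Å probe: the oracle's SES
test is morphological (no path connectivity), so a void that could *contain*
a 3 Å sphere would not register as enclosed.  Residue names cycle through
the 20 amino acids so chemical descriptors are exercised; generation is
deterministic under the seed.

These fixtures emulate wall curvature, mouths, channels and burial, not real
protein chemistry: bonded-atom geometry, heterogeneous radii, rotamers and
crystal contacts are absent, so passing tests demonstrate the geometric and
statistical machinery, not benchmark performance on real structures.

The oracle flags grid points inside the 3.0 Å SES but outside the 1.4 Å SES
via erosion/dilation of the distance field: a point is outside the r-SES iff
it lies within r of a grid point whose clearance is at least r.  Both steps
are compensated by half a voxel (a valid probe center can sit anywhere
within half a grid step of a sample), which stabilises the flagged volume to
< 10% change per grid halving on the shell.  Cross-checks voxelise a
pocket's probe spheres on the oracle grid and compare by Jaccard index; the
shell fixture's cavity pocket scores ≈ 0.8 at 0.4 Å spacing.

## Problem sizes and numerical choices

Fixtures run at a few hundred atoms and 7,000–10,000 probes across the
17-level ladder, chosen so a full detect–train–rank cycle on the three
cavity-bearing fixtures completes in a few minutes on one CPU while still
producing qualifying pockets (≥ 100 spheres) under the deployment
thresholds.  Forests in tests use 200 trees; the oracle-equivalence check
runs on ≤ 200-probe structures where the exhaustive pairwise predicate is
affordable.  Degenerate inputs are handled explicitly: empty persistence
lists and entrance sets zero their features, identical training rows give
s = 0.5 exactly (no split exists), empty probe lists and empty training sets
raise, and undefined-LC sites are flagged rather than scored.
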