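# Methods

This note documents the models, parameter choices and numerical details
behind `soltrack`, and what the synthetic validation does and does not
demonstrate about real trajectories.

## Tracking model

A solvent molecule is represented by a single probe atom (the water
oxygen: the first atom of each residue in the solvent selection) and its
identity is the residue id. Per frame, two membership tests apply:

- **scope** — interior of the convex hull of the scope selection
  (default `name CA`), built with Qhull and tested via the half-space
  equations `A·x + b ≤ τ` with τ = 1e−9, so the boundary counts as
  inside. Two spherical prefilters (inscribed/circumscribed radius about
  the hull centroid) resolve points far from the boundary without facet
  tests. The hull is rebuilt per frame; identical consecutive scope
  coordinates (rigid or static systems) reuse the cached hull.
- **object** — one sphere of radius 4.0 Å (configurable) at the centre of
  geometry of *all* atoms of the object residues, recomputed per frame.
  Using all atoms rather than Cα only is a deliberate choice (the object
  is a solvation region, not a tunnel start point); `atoms="CA"` is
  available.

A raw path is a maximal run of consecutive in-scope frames containing at
least one in-object frame. `gap_tolerance` (default 0 frames) controls
whether brief scope exits split a path; with the default, a scope exit
terminates the path and a later object visit starts a new one. Object
membership only counts while in scope. Sample labels partition each path
exhaustively: incoming / object / re-entry / outgoing. Re-entry samples
belong to the path but never produce inlets — inlets are strictly surface
crossings. A terminus coinciding with the first/last trajectory frame
without a boundary crossing is labelled N and yields no inlet, giving the
bookkeeping identity `#inlets = 2·#paths − #N-termini`.

**Surface trimming.** The convex hull overestimates the molecular
surface, so each crossing terminus is trimmed: a cutting sphere is
centred at the crossing with radius `max(d_nearest − vdW_nearest,
r_min)`, where `d_nearest` is the distance to the nearest barber-selection
atom (default: all protein atoms) in the crossing's own frame, and
`r_min = 0.5 Å` avoids degenerate spheres. Consecutive head (incoming)
and tail (outgoing) samples strictly inside a cutting sphere are dropped;
object samples are never removed. This nearest-atom-sphere rule is the
minimal geometry consistent with "trim to the surface using all protein
atoms with van der Waals correction"; with fixed crossings it is
idempotent. Van der Waals radii come from a bundled Bondi-style element
table (unknown elements: 1.5 Å with a warning).

Trajectories are assumed whole-molecule imaged; periodic boundary
conditions are *not* unwrapped. Coordinates are Å, frames 0-based,
residue ids 1-based as in PDB.

## Inlet clustering and flux

Entry and exit inlets are pooled (an entrance area is also an exit area)
and clustered with DBSCAN, eps = 2.5 Å, min_samples = 3. The defaults
separate tunnel mouths a few Å apart while flagging stray crossings as
outliers; both are exposed. Cluster labels are canonicalised by
descending size (ties: centroid lexicographic order), so the labelling is
deterministic and permutation-invariant; outlier membership of DBSCAN
border points can in principle depend on input order, but inlet clouds at
distinct mouths are far beyond eps apart in practice.

The flux table counts each path once at (entry label, exit label) over
{C1…, OUTLIER, N}. Derived views: per-pair path shares (sum to 100% over
all paths) and per-label inlet shares (entries + exits, N excluded, sum
to 100%). Row/column sums reconstruct per-label inlet counts exactly.
An empty path list yields a zero table flagged `empty` with shares
reported as 0.

## Pockets, cavities, hot-spots, trapping

All path samples (every segment type, unless a segment filter is given)
are binned on a regular grid, spacing 1.0 Å by default, bounds = sample
bounding box padded by one voxel. The outer pocket is every visited
voxel; the inner pocket keeps voxels with count ≥ threshold, default =
mean of the nonzero counts — a parameter-free proxy for "easily
accessible" that suppresses transiently visited boundary slivers.
Components use 26-connectivity; volumes are #voxels·Δ³. Wall residues
are residues with ≥ 1 atom within 4.5 Å of ≥ 1 member-voxel centre,
unioned over 10 evenly spaced frames (cavity identity is reported by
volume rank; naming is the user's).

Two estimator facts worth knowing, both measured on the closed-shell
benchmark below: (i) the *outer* (purely geometric) volume converges
monotonically to the accessible volume as spacing shrinks (errors
81% → 40% → 19% over 2/1/0.5 Å); (ii) the *inner* volume is accurate at
1 Å (−7% against the analytic cavity volume) but needs enough samples per
voxel — at 0.5 Å with the same run the per-voxel statistics thin out
8-fold and the occupancy threshold misclassifies more voxels (−22%).
Report both; trust the inner estimate only when mean nonzero occupancy is
well above ~100 counts/voxel.

A hot-spot is a voxel whose count reaches the 95th percentile of nonzero
counts, is ≥ all 26 neighbours and exceeds at least one of them (a flat
field has no hot-spot). Out-of-grid neighbours are handled by edge
replication, so a uniformly filled grid stays hot-spot-free. Wall
residues attach per hot-spot with the same cutoff. Trapped-molecule
reports measure, per path, the longest run of consecutive samples inside
a voxel region before the first object entry and after the last object
exit, in ps via the frame cadence.

## Conservation scoring

Schneider entropy per MSA column: H = (−Σₐ pₐ ln pₐ)/ln 20 with
frequencies over non-gap letters; gaps are excluded from the frequencies
and all-gap columns are reported missing (NaN). The ln 20 normalisation
is used regardless of sequence count so scores are comparable across
MSAs; `normalization="nseq"` (ln min(N, 20)) is available. The natural
log basis cancels in the normalisation.

Structure residues map to alignment columns through the reference row:
the structure sequence must occur contiguously in the ungapped reference;
gap columns are skipped and a letter mismatch raises an error naming the
residue. Cavity wall-residue entropies are compared against all other
mapped residues with the two-sample KS test; D is the supremum ECDF
distance and the p-value uses the asymptotic Kolmogorov distribution with
effective size n₁n₂/(n₁+n₂) (small-sample exact tables are deliberately
not used; at the α = 0.005 default the asymptotic test is conservative —
measured type-I error ≈ 0.005 over 200 i.i.d. replicates). Unmappable
residues are excluded with a warning; an empty cavity list is an error.

## Synthetic benchmark systems

`ToySystemSpec` builds a pseudo-protein shell: one-atom residues (named
CA so the default scope selection applies) on Fibonacci-sphere lattices
(spacing 1.8 Å, layers every 1.44 Å radially) between the inner and outer
wall radii, with cylindrical channels carved where atom centres fall
within the bore of a channel axis. Defaults: cavity radius 6 Å, shell
thickness 3 Å, atom radius 1.5 Å, probe radius 1.0 Å. The inner wall is
placed at cavity_radius + atom_radius + probe_radius, so the hard-core
rule below confines particle centres to ≈ the stated cavity radius and
the analytic ground-truth volume 4/3·π·r³ is meaningful (measured centre
excursions reach ~6.25 Å through lattice gaps, a ~+4% volume bulge).

Dynamics: particles start uniformly in the cavity; each frame proposes an
isotropic Gaussian step (σ = 0.8 Å per axis, 1 ps cadence) rejected if
the endpoint comes within atom_radius + probe_radius of any pseudo-atom
or beyond a confining world sphere (outer radius + 8 Å) that lets escaped
particles return and sustain flux. This is hard-core rejection, not
Langevin dynamics: no forces, momenta, hydrodynamics or water structure.
It produces exactly the features downstream code consumes — confinement,
channel flux, occupancy gradients — so passing tests demonstrate correct
*bookkeeping and geometry*, not force-field realism. Channel mouths in
the ground truth sit at the inner-wall opening (axis × inner radius):
surface trimming pulls inlets about one cutting radius below the hull
cap, and measured inlet-cluster centroids land within ~0.5 Å of this
point. A channel bore of ~4 Å leaves an effective free bore of ~1.5 Å
after the 2.5 Å hard-core clearance — wide enough for steady traffic,
narrow enough that mouths stay distinct.

Toy MSAs draw each column's letter frequencies from a symmetric Dirichlet
over the 20 amino acids (concentration 0.05 for planted conserved
columns — near one-hot — and 5.0 otherwise, near uniform), then sample
letters i.i.d. per sequence; 312 sequences by default in the validation
runs, matching a realistic homolog-family depth.

## Problem sizes used in validation

Chosen so each estimate is statistically comfortable: cluster recovery
uses 50 particles × 20 000 frames on a three-channel system (~200
inlets); volume recovery uses 60 particles × 8 000 frames (~480 000
samples, ≈ 380 counts/voxel at 1 Å); the KS type-I rate uses 200
replicates of a 312 × 100 i.i.d. MSA; hull membership is checked against
a linear-programming oracle on 1000 queries; determinism re-runs the full
pipeline twice and compares artifacts byte-for-byte.

## Known limitations

- The convex-hull scope is a crude surface; molecules in deep surface
  grooves count as "inside". Auto-Barber mitigates but its sphere rule is
  a reconstruction, not a published algorithm.
- Waters are tracked as single points; hydrogen positions and orientation
  are ignored.
- No PBC unwrapping: supply whole-molecule-imaged trajectories.
- Inner-pocket volumes are occupancy-threshold estimates; see the sample
  size caveat above. Absolute cavity volumes from real trajectories
  additionally depend on simulation length and force field.
- DBSCAN parameters are system-dependent: eps should be of the order of
  the mouth radius, and results should be checked against the outlier
  fraction.
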