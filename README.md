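# soltrack

Solvent-molecule tracking through molecular-dynamics trajectories:
per-molecule paths, surface inlets, inter-cluster water flux, pockets,
hot-spots and the evolutionary conservation of cavity residues.

## What problem this solves

Enzymes with buried active sites exchange water (and substrates) with the
bulk through tunnels and internal cavities. Geometry-based tunnel finders
describe static channels; `soltrack` instead uses the solvent itself as a
molecular probe. Every water molecule that visits a region of interest is
traced through the trajectory, and the ensemble of traces is distilled
into the quantities a protein engineer cares about: where molecules enter
and leave, how much traffic each entrance carries, which internal volumes
are water-accessible, where waters get trapped, and whether the residues
lining those compartments are evolutionarily conserved.

The package is for structural bioinformaticians and enzyme engineers who
already have trajectories (e.g. from AMBER/GROMACS runs of an epoxide
hydrolase-like enzyme) and want a scriptable, testable analysis layer.

## Model and definitions

- **object** — the tracked region: a sphere of radius *r* (default 4 Å)
  around the centre of geometry of the active-site residues, recomputed
  per frame. A molecule must visit the object to be traced.
- **scope** — the tracking limit: the interior of the convex hull of the
  protein's Cα atoms (closed hull, recomputed per frame). A *raw path* is
  a maximal run of consecutive in-scope frames containing ≥ 1 object
  visit, partitioned into **incoming** (before the first object visit),
  **object**, **re-entry** (between object visits) and **outgoing**
  segments. Termini that never cross the scope boundary are labelled *N*
  (path end detected inside the protein).
- **Auto-Barber trimming** — the convex hull overestimates the surface,
  so each crossing point *c* defines a cutting sphere of radius
  max(‖c − a‖ − vdW(a), r_min) for the nearest protein atom *a*; head and
  tail samples inside cutting spheres are removed. The retained endpoints
  are the **inlets**.
- **flux** — inlets are pooled and clustered with DBSCAN (eps 2.5 Å,
  min_samples 3); each path contributes one count at (entry cluster, exit
  cluster) over labels {C1…, OUTLIER, N}. Inlet percentages exclude N.
- **pockets** — all path samples are binned on a voxel grid (spacing
  1 Å). The *outer pocket* is every visited voxel (maximal explored
  space); the *inner pocket* keeps voxels with occupancy ≥ a threshold
  (default: mean nonzero count) — the easily accessible volume. Connected
  components (26-connectivity) are cavities with volume = #voxels·Δ³ and
  wall residues within 4.5 Å. **Hot-spots** are strict local density
  maxima above the 95th percentile of nonzero counts.
- **conservation** — per-column Schneider entropy of an MSA,
  H = (−Σₐ pₐ ln pₐ)/ln 20 ∈ [0, 1] over non-gap letters; cavity-residue
  entropies are compared to the remainder of the protein with a
  two-sample Kolmogorov–Smirnov test (asymptotic p, α = 0.005).

A synthetic generator (`soltrack.synthetic`) builds shell "proteins" with
channels and a spherical cavity of known analytic volume, plus toy MSAs
with planted conserved columns, so every stage is validated against exact
ground truth — no trajectories or downloads needed.

## Worked example

`examples/01_track_toy_system.py` builds a three-channel toy protein
(bores 5.0/4.0/3.2 Å), diffuses 40 particles for 8000 frames and runs the
tracking chain:

```
78 paths traced, 114 surface inlets
clusters (by size): {'C1': 74, 'C2': 32, 'C3': 8}, 0 outlier inlets
  C1: centroid ( -0.23,  0.51,  7.63), 1.03 A from the nearest channel mouth
  C2: centroid (  8.63,  0.40,  0.23), 0.48 A from the nearest channel mouth
  C3: centroid (  0.24,  8.38,  0.01), 0.27 A from the nearest channel mouth
...
inlet shares (%, N excluded):
C1         64.9
C2         28.1
C3          7.0
```

The three inlet clusters recover the three channel mouths, and the inlet
shares rank with the channel bores — the wide channel carries the
majority of the traffic, the narrow one a few percent, mirroring how a
main tunnel dominates the water exchange of a buried active site.
`examples/02_pockets_and_hotspots.py` confines particles to a closed 6 Å
cavity and reports an inner-pocket volume of 840 Å³ vs the analytic
904.78 Å³ (−7.2%); `examples/03_cavity_conservation.py` rejects the KS
null (D = 1.0, p < 0.005) for a cavity drawn from planted conserved
columns. `examples/04_full_pipeline.py` and the `soltrack` CLI
(`track` / `cluster` / `pockets` / `evolution` / `simulate` / `all`) run
every stage from one INI config and write the full artifact bundle
(paths/inlets/flux CSVs, JSON summary, OpenDX density grid, cavity and
hot-spot reports, entropy and conservation tables).

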