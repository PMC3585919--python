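# Methods

`locsurf` predicts where a small-molecule ligand can bind a protein by
comparing *functional surfaces*: once the solvent-excluded surface mesh and
its per-vertex physico-chemical descriptors are computed, the atomic
coordinates behind the surface play no further role. This note records the
model, its assumptions, the tunable parameters, and the numerical choices a
maintainer would want to know.

## The descriptor

Every mesh vertex ("surface sample") carries a 40-component vector:

| block | features |
|---|---|
| 1 | visibility: fraction of the outward hemisphere from which the point can be seen |
| 2–13 | Euclidean distance (Å) to the nearest atom of 12 chemical categories (backbone C/CA, aromatic sidechain, aliphatic sidechain, backbone N, backbone O, sidechain S, amide N, amide O, tryptophan sidechain, hydroxyl, charged O, charged N) |
| 14–28 | patch anisotropy, curvature, curvature variance at the 5 scales 1.6/3.2/4.8/6.4/8 Å |
| 29–38 | patch-averaged Kyte–Doolittle hydropathy and electrostatic potential at the same scales |
| 39–40 | distance to the nearest hydrogen-bond donor / acceptor |

The scale ladder spans atom-sized (1.6 Å) through residue-sized to
small-pocket-sized (8 Å) neighbourhoods. A patch is a geodesic disc: all
vertices within the given along-surface distance of the sample.

**Sampling density.** Meshes are expected at ≈3 vertices/Å², the density at
which a 1.6 Å geodesic disc always holds the ≥6 vertices needed for a
well-posed quadric fit. The parametric fixture generator hits this density
exactly up to rounding (Fibonacci lattice + convex hull for spheres).

**Geodesics.** Distances on the mesh are Dijkstra shortest paths on the edge
graph augmented with corner-cut shortcut edges: for every adjacent triangle
pair, and for every four-triangle strip, the patch is unfolded into a plane
and the two opposite vertices joined when the straight segment crosses the
shared edge(s). Two unfolding levels make flat-surface distances exact for
all lattice directions up to √7·spacing (worst-case overestimate
1/cos 9.6° ≈ 1.4%) and keep sphere distances within 5% of great-circle arcs
at density 3. A pure edge-graph mode (`method="dijkstra"`) remains available
as a degraded fallback; it upper-bounds the corner-cut distances.

**Patch shape.** At each vertex a quadratic height field
h = ax² + bxy + cy² is fitted (vertex-area-weighted least squares) over the
1.6 Å disc, in geodesic-polar coordinates of the tangent frame (radial
coordinate = geodesic distance, direction = tangent projection; height along
the inward normal, so convex bulges are positive and pockets negative).
Principal curvatures κ₁ ≥ κ₂ come from the fitted second fundamental form
[[2a, b], [b, 2c]]; anisotropy is (κ₁−κ₂)/(|κ₁|+|κ₂|+10⁻⁸) clamped to
[0, 1]. Larger-scale curvature and anisotropy are **area-weighted patch
averages of the per-vertex values**, and curvature variance is the patch
variance of the per-vertex mean curvature. A per-scale quadric re-fit was
rejected deliberately: a single tangent-frame height field stops being
injective once the patch approaches a hemisphere (an 8 Å disc on a 2 Å
sphere covers the whole sphere), and its least-squares curvature is biased
by >50% there, while the averaging construction reproduces the closed forms
on sphere/plane/cylinder fixtures within 10% at *all* five scales. What is
lost is genuinely non-local shape (e.g. a wide pocket assembled from
individually flat facets reads as flat); the visibility feature carries
most of that signal instead.

**Visibility** casts 64 (configurable) cosine-weighted rays per vertex from
a deterministic Fibonacci lattice in the normal's tangent frame and reports
the escaping fraction, with a hand-rolled batched Möller–Trumbore
intersector. Note the discretized estimate is only rotation-invariant to
within the ray budget (±1–2 ray weights); all other features are invariant
to rigid motions up to float rounding.

**Chemistry.** Atom→category rules are the standard heavy-atom assignments
(donors inferred from N–H/O–H bearers since hydrogens are usually absent;
proline backbone N excluded; histidine counted both aromatic and charged-N;
hydroxyls both donate and accept). A category absent from a structure yields
a capped sentinel distance of 20 Å, keeping features bounded. Hydropathy is
transferred to the surface by nearest heavy atom (ties broken to the lower
serial) and patch-averaged. Electrostatics come from an APBS-style OpenDX
grid sampled by trilinear interpolation; without a grid a flagged fallback
uses a Coulomb sum with distance-dependent dielectric ε(r)=4r and crude
formal-type partial charges — adequate because features are z-scored and
used comparatively, not physically.

**Normalization.** Features mix units, so they are z-scored against a
reference corpus (per-feature mean/sd pooled over all vertices of a set of
reference surfaces; the original study used 100 random PDB proteins). Stats
are explicit versioned inputs carrying an id; every normalized surface
records the id it was normalized with, and model/surface id mismatches are
errors. Standard deviations are floored at 10⁻⁶: corpus-constant features
scale toward 0 instead of exploding.

## Training

Per-ligand models decompose into moieties (chemist-specified rigid
fragments) and then into atoms. The two working assumptions are that each
ligand atom prefers a distinct surface micro-environment and that this
micro-environment is consistent across binding partners. For each atom:
vertices within 1.6 Å of the *van der Waals surface* of the bound atom
(boundary inclusive) are positives — surface-referenced to match the
evaluation ground truth; an equal-sized uniform random sample of the
remaining vertices are negatives (more negatives do not help and slow
training). The classifier is an RBF-kernel SVM with Platt-sigmoid
probability calibration via internal 5-fold CV; hyperparameters default to
C = 1, γ = 1/(40·pooled feature variance) and are recorded in the model
file. Corpus selection takes at most one example per homology cluster
(cluster file is an input; BLASTCLUST-style), uniformly at random under a
seed.

Alongside the classifiers, the minimum and maximum Euclidean distance of
every atom pair over the training conformers is stored. Tight bounds mean a
rigid fragment; wide bounds encode observed flexibility.

## Sample grouping

Dense meshes over-sample smooth regions. Before prediction, samples are
grouped per atom under that atom's *important features* — the descriptor
components whose variance over the atom's positives is below the normalized
background of 1 (strict inequality). The greedy pass sweeps disc radii
4 → 2 → 1 → 0.5 Å (halving schedule, configurable); at each radius every
unassigned vertex's geodesic disc is scored by the mean pairwise RMS
masked-feature distance of its members (exact up to 200-member discs, a
seeded 200-pair subsample beyond), and discs with score < T = 0.5 are
accepted in ascending score order, skipping any disc sharing a sample with
an accepted one (ties break on lowest center id). Accepted members collapse
onto the center, which keeps the disc radius. Leftovers join an edge-adjacent
disc when within T of its center, else stand alone with radius 0. T = 0.5
means "half a corpus standard deviation"; 0.25 is the stricter published
alternative and is available via `GroupingParams`. On smooth surfaces the
reduction is 5–60×, which matters because field combination is quadratic in
sample count.

## Prediction

Each atom classifier scores its own representatives (P_A). Fields then
confirm each other: for sample s of atom A and partner B, the confirmation
is the mean of P_B over B-samples whose Euclidean distance to s lies in the
observed [min, max] window for the pair, relaxed by the partner sample's
disc radius; an empty window is disconfirming (0), and pairs whose minimum
bound exceeds 15 Å are never combined. The confirmed field is
PC_A = P_A × (arithmetic mean over contributing partners of their
confirmations) — the product form was chosen over replacement because it
yields the provable bound PC_A ≤ P_A and demotes unpartnered peaks without
promoting anything; a geometric-mean combiner is available. Averaging inside
the window (not max) keeps isolated spurious peaks from vouching for each
other. Range queries are exact vectorized distance evaluations, bit-identical
to the brute-force triple loop (tested over 100 seeded configurations).
Confirmed fields expand back to all vertices (members inherit their
representative's value) and merge by pointwise maximum into the moiety field
and then the ligand field — a partial-match heuristic: one well-predicted
moiety suffices, at the cost of confusing ligands that share moieties.

## Evaluation

A vertex is an interface point when within 1.6 Å of the vdW surface of any
bound-ligand atom. ROC curves use the standard sweep with trapezoidal area;
precision–recall areas use step-wise interpolation (trapezoids are
optimistic for PR), and ties — common after group expansion — cross
thresholds together. Multi-ligand benchmarking produces a matrix of PR areas
(model × case).

## Synthetic data

The fixture generator supplies both oracle geometry and end-to-end truth:

* Parametric meshes (sphere, plane, cylinder, saddle, hemispherical
  pocket-in-plane) at exact density with analytic curvatures attached.
* Synthetic complexes: ~60 pseudo-protein atoms with category-bearing
  names inside a radius-4 Å spherical surface (~600 vertices at density 3);
  a two-atom pseudo-ligand posed 0.5 Å off the surface at a requested
  spacing; raw descriptors computed by the real pipeline; then a planted
  "signature" — by default +2 sd on 5 designated features per atom, disjoint
  between the atoms — added at the vertices within 1.6 Å of each ligand
  atom's vdW surface. The shift is measured in the generating surface's own
  per-feature sd, which tracks the pooled corpus sd to within a few percent.
  Corpora draw child seeds from a master seed and jitter the ligand spacing
  in a declared window (default 3.5–4.5 Å) so distance-bound recovery is
  testable against known generative bounds.

The study conditions for the end-to-end checks are 20 training and 5 test
complexes with the +2σ/5-feature signature. What passing shows: the pipeline
recovers planted, consistent micro-environments and suppresses single-atom
decoys via distance confirmation. What it does not show: performance on real
PDB complexes, where micro-environments are noisier, homology structure is
real, electrostatics come from Poisson–Boltzmann solvers, and ligand
chemistry is not two tagged pseudo-atoms.

## Numerical choices and degenerate inputs

* Quadric fits require ≥6 patch members (center + 5); sparser meshes raise
  an under-constrained error naming the vertex.
* Isolated vertices are rejected for geodesic queries; orphaned vertices are
  dropped by the pocket fixture's sliver filter.
* Anisotropy's ε = 10⁻⁸ guard makes flat patches read 0 rather than 0/0.
* The Coulomb fallback clamps inter-distances at 1 Å to avoid singularities.
* All randomness (negative draws, corpus subsampling, pair subsampling,
  fixture generation) flows from explicit integer seeds; fixture generation
  is bit-reproducible.
* Probability fields clamp to [0,1] after float arithmetic.

## Problem sizes

Tests and the acceptance script run on fixture meshes of ~300–2400 vertices
and corpora of 25 complexes (~600 vertices each), sizes at which every
brute-force oracle (pairwise certificates, triple-loop confirmation,
exhaustive threshold sweeps) is exact and cheap; the library itself is
vectorized and handles protein-scale meshes (tens of thousands of vertices)
through the same code paths.

## Known limitations

* Curvature at large scales is smoothed small-scale curvature, not a true
  large-scale quadric (see above); deep narrow geometry is carried mostly by
  visibility.
* The corner-cut graph underestimates geodesics slightly on coarse convex
  meshes (inscribed-polyhedron effect, ~1–3% at density 3).
* Moiety decomposition is manual input; no automatic fragmenting.
* Homology clustering, surface tessellation (MSMS) and Poisson–Boltzmann
  grids (APBS) are consumed as files, never computed.
* The max-merge over moieties cannot distinguish ligands sharing all their
  moieties (e.g. ADP within ATP).
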