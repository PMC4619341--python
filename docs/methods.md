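# Methods

## The model

A SAPN building block is one peptide chain with two coiled-coil-forming
helices joined by a short linker.  In the assembled T=1 particle the
pentamer-forming helix lies along a fivefold axis of the icosahedral
rotation group and the trimer-forming helix along an adjacent threefold
axis, so the ideal hinge angle of the monomer is the inter-axis angle of
that pair.  The package computes this angle from exact geometry — a vertex
direction and an adjacent face-center direction of a regular icosahedron
built on golden-ratio coordinates — rather than hard-coding it; it
evaluates to 37.377° (37.4° at one decimal).  Flexible linkers realize
larger angles; the deviation of a model's fitted inter-helical angle from
the ideal is the geometric score used to rank designs.

### Icosahedral machinery

The rotation group is generated from one 72° rotation about a vertex axis
and one 120° rotation about an adjacent face axis and closed under
composition (deduplication at 1e-9), giving exactly 60 orthogonal
operators with determinant +1 and the class structure
1 + 6·4 + 10·2 + 15·1.  The default orientation convention places the
twofold axis that lies on the reference fivefold→threefold great circle
along +z and the reference pair in the +x half of the xz-plane; the
convention is explicit because no standard setting exists for this
application, and a raw golden-ratio frame is available as `"golden"`.

The asymmetric unit is the spherical kite fivefold–twofold–threefold–
twofold: four planes through the origin, each containing two consecutive
kite axes, with inward normals chosen so the fivefold/threefold bisector
is interior.  The two bounding twofold axes are identified by their
characteristic angles to the reference pair (31.72° to the vertex, 20.91°
to the face center), themselves consequences of icosahedral geometry.
Points on a cutting plane (within τ = 1e-9 on the unit sphere) are
classified `boundary`; for partitioning, every atom is assigned to the
lowest-index rotation whose closed wedge image contains it, which makes
the 60 images an exact partition of space (verified by the tiling tests).
Face-adjacent neighbor operators — the images a symmetry-reduced
interaction calculation must consider — are found by reflecting an
interior point across each bounding plane and locating the image that
contains the reflection; there are exactly four.

### Coiled-coil generation and axis fitting

Backbone traces follow the Crick parameterization: residue *i* sits at
superhelical phase ω₀·i and minor-helix phase ω₁·i, with ω₁ = 2π/3.5 per
residue, axial rise 1.495 Å/residue, CA minor radius 2.26 Å (which makes
consecutive CA–CA distances ≈ 3.8 Å), superhelix radii 8.6 Å (pentamer)
and 6.7 Å (trimer), and left-handed pitch −200 Å.  These are canonical
literature values for α-helical coiled coils, recorded as overridable
defaults.  Bundle chain
*k* is generated as the exact rotation of chain 0 by 2πk/order, so Cₙ
symmetry holds to machine precision.  CA-only mode is the contract
surface; the full-backbone mode places N/C/O at idealized offsets in the
local frame of the CA trace and is cosmetic, for visual inspection of
exported files only.

Helix axes are fitted by total least squares (principal component) on the
CA trace after a 4-residue sliding-window average — approximately one
helical turn, which cancels the helical wobble.  The direction sign
follows the N→C convention.  Inputs with no radial wobble (collinear
points) are flagged degenerate with a warning.  For generated helices the
fit recovers the construction axis to well under 1°.

### Monomer construction and assembly

The two bundle axes of the monomer are lines through the origin — the
future particle center — separated by the target angle.  Each domain is
drawn as a *straight* α-helix parallel to its bundle axis at the bundle's
superhelix radius, facing the other domain.  Drawing the strand straight
(rather than supercoiled) keeps its fitted axis exactly parallel to the
oligomerization axis and the chain azimuthally compact, which is what
makes one chain fall cleanly inside one asymmetric-unit wedge; the
supercoil matters for multi-heptad bundles, not for the one- to
two-heptad arcs of a single building block.  The linker is a quadratic
Bézier arc bulged radially outward, sampled at equal arc length
(~3.8 Å/residue); a linker too short to span the hinge gap is rejected
with the required minimum length.  The hinge is purely geometric — a
pivot at the linker glycine nearest the linker center — with no loop
closure or backbone chemistry, because the comparable design quantity is
the axis angle, not linker torsions.  Re-hinging rotates the trimer side
about the pivot around the mutual perpendicular of the two fitted axes,
so the inter-axis angle changes by exactly the applied increment and
re-hinging to the current angle is the identity.

The hinge-proximal helix ends sit at an axial clearance of 18 Å from the
center, the smallest value at which no two chains of the expanded 60-mer
approach closer than 3.5 Å CA–CA (the bundle axes converge at the center,
so smaller clearances interpenetrate).  N-terminal tag residues (the
His-tag of the expression constructs) are appended outward from the
pentamer N-terminus either as a compact spiral with 1.6 Å net rise per
residue (`"coil"`, the default — a stand-in for a random-coil tag) or as
a fully extended 3.5 Å/residue strand (`"extended"`, the maximal-diameter
case); with these choices the full-length 2.5HR particle measures
21.7 nm and 28.5 nm respectively, bracketing the compact and
fully-extended regimes.

Assembly maps the two bundle axes onto the reference fivefold/threefold
pair (rejecting monomers whose angle differs by more than 0.5° or whose
bundle axes miss each other by more than 2 Å, since such a chain cannot
meet both particle axes simultaneously) and applies all 60 operators.
Particle invariants — identical internal geometry of all chains, equal
pentamer-centroid radii, 5/3 nearest-axis clustering, exact
re-expansion of the asymmetric unit — hold by construction and are
asserted in tests.

### Metrics

RMSD uses the Kabsch algorithm (SVD with a determinant correction to
enforce a proper rotation) on CA atoms matched by residue index; the
implementation is cross-checked in tests against an exhaustive
rotation-grid search and against an independent library routine.  The
radius of gyration is mass-weighted about the center of mass (equal
masses by default for CA traces).  Inter-helical angles are reported in
both conventions — undirected (folded into [0°, 90°], appropriate for
axes without arrows) and directed N→C (0°–180°) — because either reading
is consistent with observed values below 90°.

A trajectory is labeled **converging** when both tail-window means (last
25 % of frames) satisfy RMSD ≤ 7 Å and RGYR ≤ 17.1 Å, and **diverging**
otherwise.  The RMSD bound is the characteristic late-time spread of converging
designs; the RGYR bound is the midpoint of the two reference cluster values (16.2 Å
converging, 18 Å diverging) — an interpolation, flagged as such.  The
tail window reflects that cluster membership is judged by late-time
behavior; raising either threshold can only move labels toward
converging (monotonicity, property-tested).

## Synthetic data

Force-field MD is out of scope, so trajectories for testing and
demonstration come from a seeded generator with two modes: per-frame
Gaussian coordinate jitter about the base model (non-cumulative —
emulating a stably folded, converging design) and cumulative
hinge-opening rotation of the trimer-side residues about the linker
pivot (emulating a diverging design).  Frame 0 is always the base model,
and identical seeds give bit-identical trajectories.  What this does
*not* emulate: force-field physics, solvent or salt effects, helix
unfolding, or sequence dependence of the dynamics — so a passing
classifier test shows the pipeline and thresholds behave as specified on
trajectories with the stipulated late-time statistics, not that real MD
of these peptides would reproduce them.  On the compact 36-residue
building block, pure hinge opening saturates near 7.8 Å RMSD (around a
150° opening), so the diverging demonstrations use a sustained
6°/frame ramp; the absolute RGYR of these CA-only models (~7 Å) is well
below the all-atom scale of the classifier's RGYR threshold, which
therefore only discriminates on series supplied on that scale.

## Packaged designs

The construct family (peptide 1 and its ten mutants; the
His-tagged 2HR/2.5HR/3HR truncation series) ships as a **synthetic
reconstruction**: the experimentally studied sequences are not available
in machine-readable form, so the fixtures were engineered once to satisfy
every documented constraint — the 36-residue mini chain with E7, T15, G19, S23, E27, R30
and E34 at the positions the mutation names imply; overall charge −2 for
peptide 2; a terminal arginine before the engineered stop codon; the
three constructs differing only by trimer truncation (14/18/21 trimer
residues for 2/2.5/3 heptads, taking "2.5 heptads" as 18 residues); and
ProtParam average masses of 9805.7 Da (2.5HR) and 10251.3 Da (3HR).
Peptides 2–11 are generated from peptide 1 by their defining mutation
lists.  Sequence-dependent tests are therefore
fixture-dependent: they validate the bookkeeping code against these
reconstructed sequences, and a transcription difference from the real
constructs would surface there, not as a code defect.

## Numerical choices

* Group closure and orthogonality: 1e-9 (operators), det to 1e-12.
* Wedge boundary tolerance τ = 1e-9 on unit-sphere points; boundary
  tie-break to the lowest-index image.
* Axis-fit smoothing window: 4 residues; degeneracy when mean radial
  wobble < 0.05 Å.
* Monomer feasibility: angle mismatch ≤ 0.5°, bundle-axis miss ≤ 2 Å.
* Disulfide proxy: CA–CA ≤ 7.5 Å (side chains are not modeled).
* Units: Å internally everywhere; nm only at the diameter reporting
  boundary.  Charges are formal, neutral-pH convention.  Masses are
  ProtParam average masses plus one water (18.01524 Da).
* Problem sizes: the test suite and the acceptance script run the mini
  (36-residue) constructs for assembly checks — 2160 CA atoms per
  particle — and 10⁶ Monte-Carlo samples for the wedge solid angle,
  sizes at which every geometric assertion is already exact or
  statistically decisive.

## Known limitations

Models are CA-only idealizations: no side chains, rotamers, or packing
scores, and the full-backbone export is cosmetic.  Absolute coordinates
of real SAPN models built from crystal-structure templates will differ;
only symmetry- and angle-level quantities are comparable.  The charge
model ignores pKa shifts and pH, and the diameter depends on the chosen
tag representation.  Quasi-equivalent (T > 1) lattices, reflections
(the order-120 achiral group), and crystallographic space groups are out
of scope.
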