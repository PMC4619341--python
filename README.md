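# sapn

Design machinery for **self-assembling peptide nanoparticles (SAPNs)** —
T=1 icosahedral particles in which 60 copies of a single fusion peptide
co-assemble.  Each chain carries an N-terminal helix that oligomerizes as a
pentameric coiled coil along a fivefold axis and a C-terminal helix that
oligomerizes as a trimeric coiled coil along an adjacent threefold axis,
joined by a short helix-turn-helix linker with a central glycine hinge.
The package is for structural bioinformaticians and protein designers who
want to generate, symmetrize, dissect and rank such designs without a
molecular-dynamics engine.

## What it computes

* **Construct bookkeeping** — domain ranges, `S23T`-style point mutations,
  heptad registers (`abcdefg`), formal charges per domain (D/E = −1,
  K/R = +1, His and termini 0) with the charge-complementarity rule
  (oppositely charged pentamer and trimer domains attract, favouring
  assembly), and ProtParam-convention average masses.
* **Coiled-coil models** — Crick-parameterized CA (or cosmetic backbone)
  traces: minor helix at ω₁ = 360°/3.5 per residue, rise 1.495 Å/residue,
  superhelix radius 8.6 Å (pentamer) / 6.7 Å (trimer), left-handed pitch
  −200 Å; exact Cₙ bundles; total-least-squares helix-axis fitting.
* **Icosahedral symmetry** — the 60 proper rotations generated from one
  fivefold and one adjacent threefold rotation (class equation
  1 + 6·4 + 10·2 + 15·1 = 60), all axis sets, and the wedge-shaped
  asymmetric unit bounded by the four planes through consecutive
  5–2–3–2 axes, exactly 1/60 of space.  The adjacent fivefold/threefold
  inter-axis angle, arccos-exact at 37.38°, is the ideal inter-helical
  angle of the building block.
* **Assembly** — a monomer hinged at a target inter-helical angle, rigid
  expansion to the 60-chain particle (chain *k* is exactly *R·k* chain 0),
  nearest-axis clustering checks (5 pentamer helices per fivefold axis,
  3 trimer helices per threefold), asymmetric-unit extraction, particle
  diameter, and a CA–CA disulfide feasibility check (≤ 7.5 Å).
* **Metrics** — Kabsch superposition RMSD, mass-weighted radius of
  gyration, undirected/directed inter-helical angles, and the
  converging/diverging trajectory classifier (tail-window means against
  RMSD ≤ 7 Å and RGYR ≤ 17.1 Å).

Packaged designs (`sapn.designs`) include the 36-residue mini-peptide
family (peptide 1 plus ten mutants such as `T15C/S23C/R30E`) and the
His-tagged 2HR/2.5HR/3HR expression constructs.  The sequences are
synthetic reconstructions engineered to satisfy the documented constraints
(lengths, mutation positions, charges, molecular weights); see
`src/sapn/data/constructs_synthetic.yaml`.

## Worked example

Inspect a design, build its nanoparticle, and cut out the asymmetric unit:

```sh
$ sapn construct report peptide-2
construct peptide-2 (36 aa)
  sequence       WKALKAELWQALAATLQSGSELTAIEELARILDELR
  average mass   4038.7 Da
  charges (formal charge, neutral-pH convention)
    pentamer +1  trimer -3  linker +0  tag +0  total -2  -> attract
  pentamer register  abcdefgabcdef
    a/d hydrophobic fraction 1.00
  trimer register  abcdefgabcdefgab
    a/d hydrophobic fraction 0.80
  mutations      S23T

$ sapn build-particle --construct peptide-8 --out p8.cif
wrote 60-chain particle to p8.cif
  inter-helical angle 37.38 deg
  diameter 8.2 nm (mean 5.8 nm)

$ sapn asu --in p8.cif
36 of 2160 atoms in the asymmetric unit; 1 chain(s) majority-inside: ['A0']
```

Reading the numbers: peptide 2 carries the S23T mutation on the trimeric
side and a total formal charge of −2, with oppositely charged domains
(+1/−3) that attract across the linker.  The particle is built with the
hinge at 37.38°, the exact angle between adjacent fivefold and threefold
axes of an icosahedron, and expands to 60 identical chains (2160 CA atoms).
The wedge-shaped asymmetric unit holds exactly one chain-worth of atoms
(36 = 2160/60) and exactly one chain lies majority-inside it — the wedge
plus the symmetry operators regenerate the whole particle.

The same workflow is available as a library:

```python
from sapn import build_monomer, assemble_particle, make_frame, build_wedge
from sapn.designs import mini_peptide

frame = make_frame()
particle = assemble_particle(build_monomer(mini_peptide(8)), frame)
print(particle.n_chains, round(particle.diameter_nm, 1))  # 60 8.2
```

Pseudo-trajectories for exercising the metrics layer come from
`sapn simulate-traj` / `sapn.synthetic` (seeded Gaussian jitter, optional
cumulative hinge-opening drift) and are scored with `sapn analyze`.

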