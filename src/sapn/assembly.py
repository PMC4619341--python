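"""Build the pentamer–trimer building block and expand it to the 60-mer.

The SAPN building block is a single chain whose N-terminal helix runs along
a fivefold axis of the icosahedron (as one strand of a pentameric coiled
coil) and whose C-terminal helix runs along an adjacent threefold axis (one
strand of a trimeric coiled coil), hinged at the linker.  The inter-helical
angle therefore targets the fivefold/threefold inter-axis angle, 37.4°;
flexible linkers realize larger angles, which is the design
observable this module makes computable.

The hinge is treated purely geometrically (a pivot at the central linker
residue); no loop closure or backbone chemistry is attempted, because the
comparable design quantity is the axis angle, not linker torsions.

Expansion applies the 60 icosahedral rotation operators to the one chain,
so particle symmetry is exact by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constructs import Construct
from .coiledcoil import (
    CrickParams,
    HelixAxis,
    PENTAMER_PARAMS,
    TRIMER_PARAMS,
    _ca_trace,
    fit_helix_axis,
    three_letter,
)
from .icosa import IcosahedralFrame, Wedge, assign_to_wedge_images, axis_angle
from .structure import Structure

__all__ = [
    "MonomerModel",
    "ParticleModel",
    "AsymmetricUnit",
    "DiameterReport",
    "build_monomer",
    "rehinge",
    "assemble_particle",
    "particle_diameter",
    "extract_asymmetric_unit",
    "validate_disulfide",
    "domain_cluster_counts",
    "particle_chain_names",
]

#: CA-CA spacing targets (Å): helical linker path and extended tag strand.
_LINKER_SPACING = 3.8
_TAG_SPACING = 3.5

#: Compact random-coil tag stand-in: a loose spiral with ~1.6 Å net rise
#: per residue (vs 3.5 Å fully extended), keeping CA-CA steps near 3.8 Å.
_TAG_COIL_RISE = 1.6
_TAG_COIL_RADIUS = 1.9
_TAG_COIL_TURN = 2.2  # radians per residue

#: CA-CA distance proxy for a feasible disulfide bond (side chains are not
#: modeled, so the standard coarse cutoff on CA separation stands in).
DISULFIDE_CA_CUTOFF = 7.5


@dataclass
class MonomerModel:
    """One nanoparticle peptide chain with its fitted and bundle axes.

    ``pentamer_axis``/``trimer_axis`` are the helix axes fitted to the
    chain's own CA trace; ``pentamer_bundle_axis``/``trimer_bundle_axis``
    are the oligomerization axes of the coiled-coil bundles the domains
    belong to (the chain sits at the superhelix radius from them).  In the
    assembled particle the bundle axes coincide with a fivefold and an
    adjacent threefold icosahedral axis; both point outward from the
    particle center.
    """

    structure: Structure
    pentamer_axis: HelixAxis
    trimer_axis: HelixAxis
    pentamer_bundle_axis: HelixAxis
    trimer_bundle_axis: HelixAxis
    target_angle: float
    linker_residues: tuple[int, int]
    construct: Construct

    @property
    def realized_angle(self) -> float:
        """Undirected angle between the fitted domain axes, degrees."""
        return axis_angle(self.pentamer_axis.direction, self.trimer_axis.direction)


@dataclass
class ParticleModel:
    """The complete 60-chain particle: one chain per rotation operator."""

    structure: Structure          # 60 chains
    frame: IcosahedralFrame
    monomer: MonomerModel
    diameter_nm: float            # 2 x max CA distance from center
    mean_diameter_nm: float       # 2 x mean radial CA distance

    @property
    def n_chains(self) -> int:
        return len(self.structure.chains)


def particle_chain_names(n: int = 60) -> list[str]:
    """Two-character chain names A0..F9 for the 60 symmetry copies."""
    return [f"{'ABCDEF'[i // 10]}{i % 10}" for i in range(n)]


# ---------------------------------------------------------------------------
# monomer construction

def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular
        p = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, p)
        v /= np.linalg.norm(v)
        return _rodrigues(v, np.pi)
    v = v / np.linalg.norm(v)
    return _rodrigues(v, np.arccos(np.clip(c, -1.0, 1.0)))


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _place_domain(
    chain: Structure,
    target_dir: np.ndarray,
    *,
    flip: bool,
    face_dir: np.ndarray,
    offset_radius: float,
    anchor: str,
    clearance: float,
) -> Structure:
    """Rigidly place one coiled-coil strand next to its bundle axis.

    The bundle (oligomerization) axis is the line through the origin along
    ``target_dir``; the chain's own fitted helix axis is made parallel to
    it (N→C along −``target_dir`` when ``flip``) at perpendicular distance
    ``offset_radius`` in the direction ``face_dir``, then slid so the
    anchor residue's axial coordinate equals ``clearance``.
    """
    t = target_dir / np.linalg.norm(target_dir)
    ax = fit_helix_axis(chain.ca_coords())
    want = -t if flip else t
    R1 = _minimal_rotation(ax.direction, want)
    out = chain.transformed(R=R1)
    p = R1 @ ax.point

    f = face_dir - np.dot(face_dir, t) * t
    f /= np.linalg.norm(f)
    # helix axis line -> the parallel line through offset_radius * f
    out = out.transformed(t=offset_radius * f - (p - np.dot(p, t) * t))

    ca = out.ca_coords()
    anchor_ca = ca[0] if anchor == "first" else ca[-1]
    out = out.transformed(t=(clearance - np.dot(anchor_ca, t)) * t)
    return out


def _linker_path(a: np.ndarray, b: np.ndarray, n_points: int, spacing: float) -> np.ndarray:
    """CA positions bridging a→b: an outward-bulged arc of ~equal spacing.

    A quadratic Bézier with its control point pushed radially outward (away
    from the particle center at the origin) is stretched until its arc
    length matches ``(n_points + 1) * spacing``, then sampled at equal arc
    length.  Returns the ``n_points`` interior positions.
    """
    target_len = (n_points + 1) * spacing
    chord = float(np.linalg.norm(b - a))
    mid = (a + b) / 2.0
    out_dir = mid / np.linalg.norm(mid) if np.linalg.norm(mid) > 1e-9 else np.array([1.0, 0.0, 0.0])

    def bezier(push: float, m: int = 400) -> np.ndarray:
        ctrl = mid + push * out_dir
        s = np.linspace(0.0, 1.0, m)[:, None]
        return (1 - s) ** 2 * a + 2 * s * (1 - s) * ctrl + s**2 * b

    def arclen(P: np.ndarray) -> float:
        return float(np.linalg.norm(np.diff(P, axis=0), axis=1).sum())

    lo, hi = 0.0, max(target_len, chord)
    if arclen(bezier(0.0)) >= target_len:
        push = 0.0
    else:
        while arclen(bezier(hi)) < target_len:
            hi *= 2.0
        for _ in range(60):
            push = (lo + hi) / 2.0
            if arclen(bezier(push)) < target_len:
                lo = push
            else:
                hi = push
        push = (lo + hi) / 2.0

    P = bezier(push, m=2000)
    seg = np.linalg.norm(np.diff(P, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.linspace(0.0, total, n_points + 2)[1:-1]
    idx = np.searchsorted(cum, targets)
    idx = np.clip(idx, 1, len(P) - 1)
    w = (targets - cum[idx - 1]) / np.maximum(cum[idx] - cum[idx - 1], 1e-12)
    return P[idx - 1] + w[:, None] * (P[idx] - P[idx - 1])


def build_monomer(
    construct: Construct,
    params5: CrickParams = PENTAMER_PARAMS,
    params3: CrickParams = TRIMER_PARAMS,
    target_angle: float | None = None,
    *,
    hinge_clearance: float = 18.0,
    include_tag: str = "coil",
) -> MonomerModel:
    """Build one nanoparticle peptide chain at a target inter-helical angle.

    The pentamer bundle axis is the line through the origin along +z, the
    trimer bundle axis the line through the origin at ``target_angle`` from
    +z; the two bundle axes intersect at the origin — the future particle
    center — which is what lets the icosahedral expansion close.  Each
    domain is drawn as a straight α-helix parallel to its bundle axis at
    the bundle's superhelix radius (N-terminus outward for the pentamer,
    C-terminus outward for the trimer), facing the other domain so the
    linker can bridge the two hinge-proximal ends.

    ``target_angle`` defaults to the exact fivefold/threefold inter-axis
    angle of the icosahedron (37.377°).  ``include_tag`` controls residues
    preceding the pentamer domain (a His-tag): ``"coil"`` (default) appends
    them as a compact random-coil-like spiral continuing outward,
    ``"extended"`` as a fully extended strand (the maximal-diameter case),
    ``"omit"`` drops them.  ``hinge_clearance`` (Å) is the axial distance
    from the particle center at which the hinge-proximal helix ends sit;
    the default is the smallest value at which no two chains of the 60-mer
    come closer than 3.5 Å CA–CA.
    """
    if target_angle is None:
        # exact adjacent fivefold/threefold angle, computed not hard-coded
        from .icosa import make_frame
        target_angle = axis_angle(*make_frame().reference_pair)
    if not (0.0 < target_angle < 90.0):
        raise ValueError(f"target_angle must be in (0°, 90°), got {target_angle}")
    if include_tag not in ("coil", "extended", "omit"):
        raise ValueError("include_tag must be 'coil', 'extended' or 'omit'")

    theta = np.deg2rad(target_angle)
    u5 = np.array([0.0, 0.0, 1.0])
    u3 = np.array([np.sin(theta), 0.0, np.cos(theta)])

    seq5 = construct.pentamer_sequence
    seq3 = construct.trimer_sequence
    seq_l = construct.linker_sequence
    n_l = len(seq_l)

    # single strands are drawn straight (no supercoil) and parallel to the
    # bundle axis; the bundle radius enters as the placement offset
    straight5 = replace(params5, superhelix_radius=0.0, superhelix_pitch=np.inf)
    straight3 = replace(params3, superhelix_radius=0.0, superhelix_pitch=np.inf)
    chain5 = Structure.from_ca(
        _ca_trace(len(seq5), straight5), chain="A", resnames=three_letter(seq5),
        start_resseq=construct.pentamer_range[0],
    )
    chain3 = Structure.from_ca(
        _ca_trace(len(seq3), straight3), chain="A", resnames=three_letter(seq3),
        start_resseq=construct.trimer_range[0],
    )

    # pentamer: N outward along +z, C at the hinge; faces the trimer side
    face5 = u3 - np.dot(u3, u5) * u5
    pent = _place_domain(
        chain5, u5, flip=True, face_dir=face5,
        offset_radius=params5.superhelix_radius, anchor="last",
        clearance=hinge_clearance,
    )
    # trimer: N at the hinge, C outward along u3; faces the pentamer side
    face3 = u5 - np.dot(u5, u3) * u3
    trim = _place_domain(
        chain3, u3, flip=False, face_dir=face3,
        offset_radius=params3.superhelix_radius, anchor="first",
        clearance=hinge_clearance,
    )

    a = pent.ca_coords()[-1]
    b = trim.ca_coords()[0]
    gap = float(np.linalg.norm(b - a))
    max_span = (n_l + 1) * (_LINKER_SPACING + 0.1)
    if gap > max_span:
        need = int(np.ceil(gap / _LINKER_SPACING)) - 1
        raise ValueError(
            f"linker of {n_l} residues cannot span the {gap:.1f} Å hinge gap; "
            f"at least {need} residues are required"
        )
    link_ca = _linker_path(a, b, n_l, _LINKER_SPACING)
    linker = Structure.from_ca(
        link_ca, chain="A", resnames=three_letter(seq_l),
        start_resseq=construct.linker_range[0],
    )

    parts = []
    tag = construct.tag_sequence
    if tag and include_tag != "omit":
        n_tag = len(tag)
        first_ca = pent.ca_coords()[0]
        # residue 1 farthest out, running inward to meet the pentamer N-terminus
        k = np.arange(n_tag, 0, -1)[:, None]
        if include_tag == "extended":
            offsets = k * _TAG_SPACING * u5
        else:  # compact random-coil stand-in: a loose spiral along the axis
            e1 = face5 / np.linalg.norm(face5)
            e2 = np.cross(u5, e1)
            phase = _TAG_COIL_TURN * k
            offsets = (
                k * _TAG_COIL_RISE * u5
                + _TAG_COIL_RADIUS * np.sin(phase) * e1
                + _TAG_COIL_RADIUS * np.cos(phase) * e2
            )
        tag_struct = Structure.from_ca(
            first_ca + offsets, chain="A", resnames=three_letter(tag), start_resseq=1,
        )
        parts.append(tag_struct)
    parts += [pent, linker, trim]
    chain = Structure.concat(parts)

    pax = fit_helix_axis(chain.select(resseq_range=construct.pentamer_range).ca_coords())
    tax = fit_helix_axis(chain.select(resseq_range=construct.trimer_range).ca_coords())
    realized = axis_angle(pax.direction, tax.direction)
    if abs(realized - target_angle) > 0.5:
        raise RuntimeError(
            f"hinge construction failed: realized angle {realized:.2f}° "
            f"vs target {target_angle:.2f}°"
        )
    span5 = (len(seq5) - 1) * params5.rise_per_residue
    span3 = (len(seq3) - 1) * params3.rise_per_residue
    return MonomerModel(
        structure=chain,
        pentamer_axis=pax,
        trimer_axis=tax,
        pentamer_bundle_axis=HelixAxis(np.zeros(3), u5, span5),
        trimer_bundle_axis=HelixAxis(np.zeros(3), u3, span3),
        target_angle=float(target_angle),
        linker_residues=construct.linker_range,
        construct=construct,
    )


def rehinge(monomer: MonomerModel, target_angle: float) -> MonomerModel:
    """Rotate the trimer side about the hinge pivot to a new axis angle.

    The pivot is the CA of the central linker residue; the rotation axis is
    perpendicular to both fitted helix axes, so the inter-axis angle changes
    by exactly the applied increment.  Re-hinging to the current realized
    angle is the identity.
    """
    if not (0.0 < target_angle < 90.0):
        raise ValueError(f"target_angle must be in (0°, 90°), got {target_angle}")
    from .synthetic import hinge_pivot_residue

    current = monomer.realized_angle
    delta = np.deg2rad(target_angle - current)
    st = monomer.structure

    def _resname(r: int) -> str:
        sel = st.select(resseq_range=(r, r))
        return str(sel.resname[0]) if len(sel) else ""

    pivot_res = hinge_pivot_residue(monomer.linker_residues, _resname)
    pivot = st.select(resseq_range=(pivot_res, pivot_res)).ca_coords()[0]

    d5 = monomer.pentamer_axis.direction
    d3 = monomer.trimer_axis.direction
    n = np.cross(d5, d3)
    if np.linalg.norm(n) < 1e-9:
        raise ValueError("cannot rehinge: domain axes are collinear")
    n /= np.linalg.norm(n)
    # sign: opening the hinge moves d3 away from the d5 line
    R_try = _rodrigues(n, delta)
    if abs(axis_angle(d5, R_try @ d3) - target_angle) > abs(
        axis_angle(d5, _rodrigues(n, -delta) @ d3) - target_angle
    ):
        R_try = _rodrigues(n, -delta)

    moving = st.resseq > pivot_res
    coords = st.coords.copy()
    coords[moving] = (coords[moving] - pivot) @ R_try.T + pivot
    out = st.copy()
    out.coords = coords

    pax = fit_helix_axis(out.select(resseq_range=monomer.construct.pentamer_range).ca_coords())
    tax = fit_helix_axis(out.select(resseq_range=monomer.construct.trimer_range).ca_coords())
    # the trimer bundle axis rides along with the trimer domain
    tb = monomer.trimer_bundle_axis
    tb_new = HelixAxis(
        R_try @ (tb.point - pivot) + pivot, R_try @ tb.direction, tb.length,
    )
    return MonomerModel(
        structure=out,
        pentamer_axis=pax,
        trimer_axis=tax,
        pentamer_bundle_axis=monomer.pentamer_bundle_axis,
        trimer_bundle_axis=tb_new,
        target_angle=float(target_angle),
        linker_residues=monomer.linker_residues,
        construct=monomer.construct,
    )


# ---------------------------------------------------------------------------
# particle assembly

def _triad(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    e1 = u / np.linalg.norm(u)
    w = v - np.dot(v, e1) * e1
    e2 = w / np.linalg.norm(w)
    return np.column_stack([e1, e2, np.cross(e1, e2)])


def assemble_particle(monomer: MonomerModel, frame: IcosahedralFrame) -> ParticleModel:
    """Expand one building block into the 60-chain icosahedral particle.

    A rigid pre-transform (computed internally) carries the monomer's
    pentamer bundle axis onto the frame's reference fivefold axis and its
    trimer bundle axis onto the adjacent threefold axis (both outward),
    with the bundle-axis crossing point at the particle center.  The 60
    rotation operators then produce the chains; chain k is exactly
    ``R_k · chain_0``.
    """
    v5, v3 = frame.reference_pair
    ref_angle = axis_angle(v5, v3)
    out5 = monomer.pentamer_bundle_axis.direction
    out3 = monomer.trimer_bundle_axis.direction
    mono_angle = axis_angle(out5, out3)
    if abs(mono_angle - ref_angle) > 0.5:
        raise ValueError(
            f"monomer inter-helical angle {mono_angle:.2f}° does not match the "
            f"icosahedral fivefold/threefold angle {ref_angle:.2f}°; re-hinge first"
        )

    # crossing point of the two bundle axis lines (closest-approach midpoint)
    p5, d5 = monomer.pentamer_bundle_axis.point, out5
    p3, d3 = monomer.trimer_bundle_axis.point, out3
    n = np.cross(d5, d3)
    nn = np.dot(n, n)
    t5 = np.dot(np.cross(p3 - p5, d3), n) / nn
    t3 = np.dot(np.cross(p3 - p5, d5), n) / nn
    q5 = p5 + t5 * d5
    q3 = p3 + t3 * d3
    miss = float(np.linalg.norm(q5 - q3))
    if miss > 2.0:
        raise ValueError(
            f"monomer helix axes miss each other by {miss:.1f} Å; the two "
            "domains cannot simultaneously meet a fivefold and a threefold "
            "axis through the particle center"
        )
    X = (q5 + q3) / 2.0

    R_align = _triad(v5, v3) @ _triad(out5, out3).T
    chain0 = monomer.structure.transformed(R=R_align, t=-R_align @ X)

    names = particle_chain_names()
    parts = [
        chain0.transformed(R=R).with_chain(names[k])
        for k, R in enumerate(frame.rotations)
    ]
    particle = Structure.concat(parts)
    rep = particle_diameter_from_structure(particle)
    return ParticleModel(
        structure=particle,
        frame=frame,
        monomer=monomer,
        diameter_nm=rep.diameter_nm,
        mean_diameter_nm=rep.mean_diameter_nm,
    )


@dataclass(frozen=True)
class DiameterReport:
    diameter_nm: float        # 2 x max CA radial distance
    mean_diameter_nm: float   # 2 x mean CA radial distance


def particle_diameter_from_structure(structure: Structure) -> DiameterReport:
    ca = structure.ca_coords()
    center = ca.mean(axis=0)
    r = np.linalg.norm(ca - center, axis=1)
    return DiameterReport(float(2.0 * r.max() / 10.0), float(2.0 * r.mean() / 10.0))


def particle_diameter(particle: ParticleModel) -> DiameterReport:
    """Particle size in nm: 2 × max (and 2 × mean) CA distance from center."""
    return particle_diameter_from_structure(particle.structure)


def domain_cluster_counts(particle: ParticleModel, which: str = "pentamer") -> np.ndarray:
    """Chains per symmetry axis, by nearest-axis assignment of domain centroids.

    Each chain's pentamer-domain (or trimer-domain) CA centroid is assigned
    to the nearest directed fivefold (threefold) axis.  A correctly
    assembled particle puts exactly 5 pentamer helices on each of the 12
    vertex directions and exactly 3 trimer helices on each of the 20 face
    directions.
    """
    rng_map = {
        "pentamer": particle.monomer.construct.pentamer_range,
        "trimer": particle.monomer.construct.trimer_range,
    }
    axes = (
        particle.frame.fivefold_directed if which == "pentamer"
        else particle.frame.threefold_directed
    )
    lo, hi = rng_map[which]
    counts = np.zeros(len(axes), dtype=int)
    for name in particle.structure.chains:
        dom = particle.structure.select(chain=name, resseq_range=(lo, hi))
        c = dom.ca_coords().mean(axis=0)
        c /= np.linalg.norm(c)
        counts[int(np.argmax(axes @ c))] += 1
    return counts


@dataclass
class AsymmetricUnit:
    """Atoms of the wedge image at the identity operator, plus bookkeeping."""

    structure: Structure
    per_atom_image: np.ndarray     # (n_atoms,) rotation index owning each atom
    majority_chains: list[str]     # chains with > 50 % of atoms in the wedge

    @property
    def n_majority(self) -> int:
        return len(self.majority_chains)


def extract_asymmetric_unit(particle: ParticleModel, wedge: Wedge) -> AsymmetricUnit:
    """Cut the asymmetric unit out of an assembled, centered particle.

    Every atom is assigned to exactly one of the 60 wedge images (boundary
    tie-break to the lowest-index image), so re-expanding the extracted
    atoms with the 60 operators reconstructs the particle's atom set as a
    partition.  Also reports which chains are majority-inside the identity
    wedge — for a proper T=1 particle, exactly one.
    """
    st = particle.structure
    if len(st) == 0:
        return AsymmetricUnit(st.copy(), np.empty(0, dtype=int), [])
    center = st.coords.mean(axis=0)
    if np.linalg.norm(center) > 1.0:
        raise ValueError(
            f"particle is off-center by {np.linalg.norm(center):.2f} Å; "
            "re-center it at the origin before extracting the asymmetric unit"
        )
    images = assign_to_wedge_images(st.coords, wedge, particle.frame)
    identity_idx = int(
        np.argmin([np.max(np.abs(R - np.eye(3))) for R in particle.frame.rotations])
    )
    inside = images == identity_idx
    majority = []
    for name in st.chains:
        m = st.chain == name
        if inside[m].mean() > 0.5:
            majority.append(name)
    return AsymmetricUnit(st.mask(inside), images, majority)


def validate_disulfide(
    monomer: MonomerModel, pair: tuple[int, int]
) -> tuple[float, bool]:
    """CA–CA distance of a residue pair and disulfide feasibility.

    Feasible iff the CA–CA distance is ≤ 7.5 Å, the usual coarse proxy when
    side chains are not modeled.  A non-cysteine pair triggers a warning
    but the distance is still computed.
    """
    st = monomer.structure
    cas = []
    for r in pair:
        sel = st.select(resseq_range=(r, r), atom_name="CA")
        if len(sel) == 0:
            raise ValueError(f"residue {r} not present in the monomer model")
        if sel.resname[0] != "CYS":
            warnings.warn(
                f"residue {r} is {sel.resname[0]}, not CYS; computing the "
                "distance anyway", stacklevel=2,
            )
        cas.append(sel.coords[0])
    d = float(np.linalg.norm(cas[0] - cas[1]))
    return d, d <= DISULFIDE_CA_CUTOFF
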