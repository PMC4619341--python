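"""Parametric α-helix and coiled-coil backbone generation (Crick model).

A coiled-coil chain is described by two superimposed circular motions: the
minor helix (the α-helix itself, ~3.5 residues per turn, rise ~1.5 Å per
residue) winding around a superhelical axis at radius R0 with pitch P.  A
negative pitch encodes the usual left-handed supercoil.  An oligomer of
order *n* is generated by rotating one chain by exact multiples of 360°/n
about the superhelical axis, which makes the Cn symmetry of the bundle
exact to machine precision — a property the icosahedral assembly machinery
relies on.

The design-ranking quantities (inter-helical angles, RMSD, radius of
gyration) are all computable from CA traces, so CA-only generation is the
contract surface; full-backbone mode is cosmetic for PDB export.

Default parameters are canonical literature values for α-helical coiled
coils: rise 1.495 Å/residue, 102.86°/residue minor-helix rotation
(3.5 residues/turn), superhelix radius 8.6 Å for pentamers and 6.7 Å for
trimers, left-handed superhelical pitch of 200 Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .structure import Structure

__all__ = [
    "CrickParams",
    "HelixAxis",
    "PENTAMER_PARAMS",
    "TRIMER_PARAMS",
    "ideal_helix",
    "coiled_coil_bundle",
    "fit_helix_axis",
]

#: CA distance from the α-helix axis (Å); gives consecutive CA-CA ≈ 3.8 Å.
CA_MINOR_RADIUS = 2.26

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def three_letter(seq: str) -> list[str]:
    return [_AA3.get(aa, "UNK") for aa in seq]


@dataclass(frozen=True)
class CrickParams:
    """Geometric parameters of one coiled-coil bundle.

    ``superhelix_pitch`` is the axial distance (Å) per full superhelical
    turn; its sign encodes handedness (negative = left-handed).
    ``phase_offset`` (degrees) is the minor-helix phase of residue 1.
    """

    oligomer_order: int = 1
    superhelix_radius: float = 0.0        # Å
    residues_per_turn: float = 3.5        # minor-helix frequency
    rise_per_residue: float = 1.495       # Å along the superhelical axis
    superhelix_pitch: float = -200.0      # Å, negative = left-handed
    phase_offset: float = 0.0             # degrees

    def __post_init__(self) -> None:
        if self.oligomer_order < 1:
            raise ValueError("oligomer_order must be >= 1")
        if self.superhelix_radius < 0:
            raise ValueError("superhelix_radius must be >= 0")
        if self.rise_per_residue <= 0:
            raise ValueError("rise_per_residue must be > 0")
        if self.residues_per_turn <= 0:
            raise ValueError("residues_per_turn must be > 0")

    @property
    def minor_omega(self) -> float:
        """Minor-helix rotation per residue, radians (positive)."""
        return 2.0 * np.pi / self.residues_per_turn

    @property
    def super_omega(self) -> float:
        """Superhelix rotation per residue, radians (signed by handedness)."""
        if self.superhelix_radius == 0.0 or np.isinf(self.superhelix_pitch):
            return 0.0
        return 2.0 * np.pi * self.rise_per_residue / self.superhelix_pitch

    @property
    def pitch_angle(self) -> float:
        """Tilt of the minor-helix axis away from the bundle axis, radians."""
        if self.superhelix_radius == 0.0 or np.isinf(self.superhelix_pitch):
            return 0.0
        return np.arctan(2.0 * np.pi * self.superhelix_radius / abs(self.superhelix_pitch))


PENTAMER_PARAMS = CrickParams(oligomer_order=5, superhelix_radius=8.6)
TRIMER_PARAMS = CrickParams(oligomer_order=3, superhelix_radius=6.7)


def _ca_trace(n_residues: int, params: CrickParams, superhelix_phase: float = 0.0) -> np.ndarray:
    """Crick-parameterized CA coordinates of one chain along +z.

    Residue i sits at superhelix phase ``θ_i = ω0 i + superhelix_phase`` and
    minor phase ``ψ_i = ω1 i + phase_offset``; a pure α-helix falls out of
    the same equations at superhelix radius 0.
    """
    i = np.arange(n_residues, dtype=float)
    r0 = params.superhelix_radius
    r1 = CA_MINOR_RADIUS
    w0 = params.super_omega
    w1 = params.minor_omega
    alpha = np.sign(params.superhelix_pitch) * params.pitch_angle
    theta = w0 * i + superhelix_phase
    psi = w1 * i + np.deg2rad(params.phase_offset)
    ca, sa = np.cos(alpha), np.sin(alpha)
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(psi), np.sin(psi)
    x = r0 * ct + r1 * (ct * cp - ca * st * sp)
    y = r0 * st + r1 * (st * cp + ca * ct * sp)
    z = params.rise_per_residue * i - r1 * sa * sp
    return np.column_stack([x, y, z])


def _add_backbone(ca: np.ndarray, resnames, chain: str) -> Structure:
    """Decorate a CA trace with approximate N/C/O positions.

    The peptide-plane atoms are placed in the local Frenet-like frame of
    the CA trace with idealized offsets.  Purely cosmetic — good enough for
    visual inspection of exported PDB files, not for chemistry.
    """
    n = len(ca)
    tang = np.gradient(ca, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    center = ca.mean(axis=0)
    radial = ca - center
    radial -= (radial * tang).sum(axis=1, keepdims=True) * tang
    nrm = np.linalg.norm(radial, axis=1, keepdims=True)
    nrm[nrm < 1e-9] = 1.0
    radial /= nrm
    binorm = np.cross(tang, radial)

    atoms, names = [], []
    for i in range(n):
        pos_n = ca[i] - 1.32 * tang[i] - 0.55 * radial[i]
        pos_c = ca[i] + 1.35 * tang[i] - 0.45 * radial[i]
        pos_o = pos_c + 1.10 * binorm[i] - 0.55 * radial[i]
        atoms += [pos_n, ca[i], pos_c, pos_o]
        names += ["N", "CA", "C", "O"]
    coords = np.asarray(atoms)
    elements = [nm[0] for nm in names]
    return Structure(
        chain=np.full(4 * n, chain, dtype=object),
        resseq=np.repeat(np.arange(1, n + 1), 4),
        resname=np.repeat(np.asarray(resnames, dtype=object), 4),
        atom_name=np.asarray(names, dtype=object),
        element=np.asarray(elements, dtype=object),
        coords=coords,
    )


def ideal_helix(
    n_residues: int,
    params: CrickParams | None = None,
    *,
    sequence: str | None = None,
    mode: str = "ca",
    chain: str = "A",
) -> Structure:
    """Generate an idealized straight α-helix along +z.

    With superhelix radius 0 the axial rise per residue equals
    ``params.rise_per_residue`` exactly and consecutive CA-CA distances are
    ≈ 3.8 Å.  ``mode`` is ``"ca"`` (contract surface) or ``"backbone"``
    (cosmetic N/CA/C/O for export).
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if params is None:
        params = CrickParams()
    ca = _ca_trace(n_residues, params)
    resnames = three_letter(sequence) if sequence else np.full(n_residues, "ALA")
    if sequence is not None and len(sequence) != n_residues:
        raise ValueError("sequence length does not match n_residues")
    if mode == "ca":
        return Structure.from_ca(ca, chain=chain, resnames=resnames)
    elif mode == "backbone":
        if n_residues < 3:
            raise ValueError("backbone mode needs >= 3 residues")
        return _add_backbone(ca, resnames, chain)
    raise ValueError(f"unknown mode {mode!r}")


_CHAIN_IDS = "ABCDEFG"


def coiled_coil_bundle(
    domain_sequence: str,
    params: CrickParams,
    *,
    mode: str = "ca",
) -> tuple[Structure, "HelixAxis"]:
    """Generate a Cn-symmetric coiled-coil bundle along +z.

    Chain k is the exact image of chain 0 under rotation by k·360°/order
    about the bundle axis, so the bundle symmetry holds to machine
    precision.  Returns the bundle and its axis (through the origin,
    pointing N→C along +z).
    """
    order = params.oligomer_order
    if not (1 <= order <= 7):
        raise ValueError(f"unsupported oligomer order {order} (expected 1..7)")
    n = len(domain_sequence)
    if n < 1:
        raise ValueError("empty domain sequence")
    resnames = three_letter(domain_sequence)
    if mode == "ca":
        chain0 = Structure.from_ca(_ca_trace(n, params), chain="A", resnames=resnames)
    else:
        chain0 = _add_backbone(_ca_trace(n, params), resnames, "A")

    parts = [chain0]
    for k in range(1, order):
        ang = 2.0 * np.pi * k / order
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        parts.append(chain0.transformed(R).with_chain(_CHAIN_IDS[k]))
    bundle = Structure.concat(parts)
    length = (n - 1) * params.rise_per_residue
    axis = HelixAxis(point=np.array([0.0, 0.0, length / 2.0]),
                     direction=np.array([0.0, 0.0, 1.0]),
                     length=length)
    return bundle, axis


@dataclass(frozen=True)
class HelixAxis:
    """A fitted (or constructed) helix axis: point, unit direction, length.

    Direction follows the N→C convention of the underlying chain.
    ``degenerate`` is set when the input had no helical wobble (collinear
    points), in which case the direction is still the best-fit line.
    """

    point: np.ndarray
    direction: np.ndarray
    length: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        nd = np.linalg.norm(d)
        if nd == 0:
            raise ValueError("axis direction must be nonzero")
        object.__setattr__(self, "direction", d / nd)
        if self.length < 0:
            raise ValueError("length must be >= 0")

    def transformed(self, R: np.ndarray = None, t: np.ndarray = None) -> "HelixAxis":
        p, d = self.point, self.direction
        if R is not None:
            R = np.asarray(R, dtype=float)
            p, d = R @ p, R @ d
        if t is not None:
            p = p + np.asarray(t, dtype=float)
        return HelixAxis(p, d, self.length, self.degenerate)


_SMOOTH_WINDOW = 4  # residues; ~one α-helical turn, cancels helical wobble


def fit_helix_axis(backbone_coords: np.ndarray) -> HelixAxis:
    """Fit the axis of a helical CA trace.

    A sliding-window average over ~one helical turn collapses the CA wobble
    onto the axis; a total-least-squares line (principal component) through
    the smoothed points is the axis.  Direction points from the N- toward
    the C-terminus.  For an ideally generated helix the fitted direction
    matches the generating axis to well under 1°.
    """
    X = np.asarray(backbone_coords, dtype=float).reshape(-1, 3)
    n = len(X)
    if n < 5:
        raise ValueError(f"need >= 5 CA positions to fit a helix axis, got {n}")
    w = min(_SMOOTH_WINDOW, n - 1)
    kernel = np.ones(w) / w
    sm = np.column_stack([np.convolve(X[:, j], kernel, mode="valid") for j in range(3)])
    centroid = sm.mean(axis=0)
    _, _, Vt = np.linalg.svd(sm - centroid)
    d = Vt[0]
    if np.dot(d, sm[-1] - sm[0]) < 0:
        d = -d
    proj = (X - centroid) @ d
    length = float(proj.max() - proj.min())
    radial = (X - centroid) - np.outer(proj, d)
    degenerate = bool(np.mean(np.linalg.norm(radial, axis=1)) < 0.05)
    if degenerate:
        warnings.warn(
            "input points are (near-)collinear: no helical wobble; "
            "axis fit is degenerate", stacklevel=2,
        )
    return HelixAxis(point=centroid, direction=d, length=length, degenerate=degenerate)
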