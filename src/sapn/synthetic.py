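"""Synthetic pseudo-trajectory generation.

Force-field molecular dynamics of the building block is out of scope here;
what the metrics layer needs for testing and demonstration is trajectories
with the two qualitative behaviors the design loop distinguishes: stable
designs fluctuate around their starting model (converging), and unstable
ones progressively open the linker hinge and drift away (diverging).  The
generator emulates exactly those two modes — per-frame Gaussian coordinate
noise, optionally plus a cumulative hinge-opening rotation of the
trimer-side residues about the central linker glycine.

What this does *not* emulate: real force-field physics, solvent/salt
effects, helix unfolding, or any sequence dependence of the dynamics.
Trajectory generation is seed-deterministic (same spec, same frames,
bit for bit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Structure

__all__ = ["SyntheticTrajectorySpec", "generate_synthetic_trajectory", "hinge_pivot_residue"]


def hinge_pivot_residue(linker_range: tuple[int, int], resname_of=None) -> int:
    """Pivot residue of the hinge: the linker glycine nearest the center.

    Falls back to the central linker residue when no glycine is present.
    ``resname_of`` maps a residue number to its three-letter name.
    """
    lo, hi = linker_range
    center = (lo + hi) / 2.0
    if resname_of is not None:
        glycines = [r for r in range(lo, hi + 1) if resname_of(r) == "GLY"]
        if glycines:
            return min(glycines, key=lambda r: abs(r - center))
    return int(round(center))


@dataclass
class SyntheticTrajectorySpec:
    """Recipe for one pseudo-trajectory.

    ``noise_sigma`` is the per-frame, per-coordinate Gaussian displacement
    (Å) around the base model (non-cumulative — thermal jitter).
    ``drift_mode`` ``"hinge_opening"`` additionally rotates all residues
    after ``pivot_residue`` by a cumulative ``drift_deg_per_frame`` degrees
    per frame about the hinge, emulating a diverging design.  Frame 0 is
    always the base model itself.
    """

    base_model: Structure
    n_frames: int
    noise_sigma: float = 0.0
    drift_mode: str = "none"              # "none" | "hinge_opening"
    drift_deg_per_frame: float = 2.0
    pivot_residue: int | None = None      # default: central residue
    hinge_axis: np.ndarray | None = None  # default: least principal axis
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.drift_mode not in ("none", "hinge_opening"):
            raise ValueError(f"unknown drift_mode {self.drift_mode!r}")


def _default_hinge(base: Structure, pivot: int) -> np.ndarray:
    """Rotation axis for hinge opening: perpendicular to both arm axes."""
    before = base.coords[base.resseq <= pivot]
    after = base.coords[base.resseq > pivot]

    def principal(X: np.ndarray) -> np.ndarray:
        _, _, Vt = np.linalg.svd(X - X.mean(axis=0))
        return Vt[0]

    n = np.cross(principal(before), principal(after))
    nn = np.linalg.norm(n)
    if nn < 1e-6:  # arms collinear: any perpendicular to the common axis
        d = principal(base.coords)
        n = np.cross(d, [1.0, 0.0, 0.0])
        if np.linalg.norm(n) < 1e-6:
            n = np.cross(d, [0.0, 1.0, 0.0])
        nn = np.linalg.norm(n)
    return n / nn


def generate_synthetic_trajectory(spec: SyntheticTrajectorySpec) -> list[Structure]:
    """Generate a multi-frame pseudo-trajectory from a base model."""
    base = spec.base_model
    rng = np.random.default_rng(spec.seed)
    pivot = spec.pivot_residue
    if pivot is None:
        pivot = int(round((base.resseq.min() + base.resseq.max()) / 2.0))
    moving = base.resseq > pivot
    if spec.drift_mode == "hinge_opening":
        sel = base.select(resseq_range=(pivot, pivot), atom_name="CA")
        if len(sel) == 0:
            raise ValueError(f"pivot residue {pivot} has no CA atom")
        pivot_ca = sel.coords[0]
        axis = spec.hinge_axis
        axis = _default_hinge(base, pivot) if axis is None else np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)

    frames = [base.copy()]
    for f in range(1, spec.n_frames):
        coords = base.coords.copy()
        if spec.drift_mode == "hinge_opening":
            ang = np.deg2rad(spec.drift_deg_per_frame * f)
            c, s = np.cos(ang), np.sin(ang)
            K = np.array([
                [0.0, -axis[2], axis[1]],
                [axis[2], 0.0, -axis[0]],
                [-axis[1], axis[0], 0.0],
            ])
            R = np.eye(3) + s * K + (1.0 - c) * (K @ K)
            coords[moving] = (coords[moving] - pivot_ca) @ R.T + pivot_ca
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
        fr = base.copy()
        fr.coords = coords
        frames.append(fr)
    return frames
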