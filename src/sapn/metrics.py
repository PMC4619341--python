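"""Structural metrics used to rank peptide nanoparticle designs.

Designs are judged on three observables computed over (pseudo-)trajectories
of the building-block peptide: the least-squares superposition RMSD against
a reference model, the radius of gyration (overall size/compactness), and
the inter-helical angle between the pentamer and trimer domains, whose
ideal value is the icosahedral fivefold/threefold axis angle.  Trajectories
whose late-time RMSD and radius of gyration stay low are *converging*
(stably folded building block); the rest are *diverging*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coiledcoil import fit_helix_axis
from .structure import Structure

__all__ = [
    "TrajectoryMetrics",
    "kabsch_superpose",
    "rmsd",
    "radius_of_gyration",
    "interhelical_angle",
    "classify_convergence",
    "analyze_trajectory",
    "RMSD_THRESHOLD",
    "RGYR_THRESHOLD",
    "TAIL_FRACTION",
]

#: Convergence thresholds.  The RMSD bound (7 Å) is the characteristic
#: late-time spread of a converging design; the radius-of-gyration bound is
#: the midpoint of the two reference cluster values, 16.2 Å (converging)
#: and 18 Å (diverging) — an interpolation, flagged as such.
RMSD_THRESHOLD = 7.0
RGYR_THRESHOLD = (16.2 + 18.0) / 2.0
TAIL_FRACTION = 0.25


def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of Y onto X (Kabsch algorithm).

    Returns ``(R, t, rmsd)`` with the proper rotation (det = +1) and
    translation minimizing ``|X - (Y R^T + t)|``; ``rmsd`` is the residual
    root-mean-square deviation in Å.  Points are matched by order.
    """
    X = np.asarray(X, dtype=float).reshape(-1, 3)
    Y = np.asarray(Y, dtype=float).reshape(-1, 3)
    if X.shape != Y.shape:
        raise ValueError(f"point counts differ: {X.shape[0]} vs {Y.shape[0]}")
    if len(X) < 3:
        raise ValueError("need at least 3 matched points for superposition")
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - cx, Y - cy
    H = Y0.T @ X0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cx - R @ cy
    diff = X - (Y @ R.T + t)
    return R, t, float(np.sqrt((diff**2).sum() / len(X)))


def rmsd(X: np.ndarray, Y: np.ndarray, *, superpose: bool = True) -> float:
    """RMSD between matched point sets, optionally after superposition."""
    if superpose:
        return kabsch_superpose(X, Y)[2]
    X = np.asarray(X, float).reshape(-1, 3)
    Y = np.asarray(Y, float).reshape(-1, 3)
    if X.shape != Y.shape:
        raise ValueError(f"point counts differ: {X.shape[0]} vs {Y.shape[0]}")
    return float(np.sqrt(((X - Y) ** 2).sum() / len(X)))


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration in Å.

    ``sqrt( Σ m_i |r_i − r_cm|² / Σ m_i )`` about the mass-weighted center
    of mass; equal masses by default.
    """
    X = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(X) < 1:
        raise ValueError("need at least one point")
    if masses is None:
        m = np.ones(len(X))
    else:
        m = np.asarray(masses, dtype=float)
        if m.shape != (len(X),):
            raise ValueError("masses must match point count")
        if np.any(m <= 0):
            raise ValueError("masses must be positive")
    cm = (m[:, None] * X).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((X - cm) ** 2).sum(axis=1)).sum() / m.sum()))


def interhelical_angle(
    model: Structure,
    pentamer_range: tuple[int, int],
    trimer_range: tuple[int, int],
) -> tuple[float, float]:
    """Angle between the fitted pentamer and trimer helix axes, degrees.

    Returns ``(undirected, directed)``: the undirected convention folds the
    angle into [0°, 90°] (axes have no arrow), while the directed one uses
    the N→C directions of both fitted axes and ranges over (0°, 180°).
    """
    ax5 = fit_helix_axis(model.select(resseq_range=pentamer_range).ca_coords())
    ax3 = fit_helix_axis(model.select(resseq_range=trimer_range).ca_coords())
    c = float(np.clip(np.dot(ax5.direction, ax3.direction), -1.0, 1.0))
    directed = float(np.degrees(np.arccos(c)))
    undirected = directed if directed <= 90.0 else 180.0 - directed
    return undirected, directed


@dataclass
class TrajectoryMetrics:
    """Per-frame RMSD/RGYR series of one pseudo-trajectory, plus label."""

    frame_times: np.ndarray      # ns
    rmsd_series: np.ndarray      # Å, vs the stated reference
    rgyr_series: np.ndarray      # Å
    final_interhelical_angle: float | None = None  # degrees, undirected
    label: str | None = None     # "converging" | "diverging"

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.rmsd_series = np.asarray(self.rmsd_series, dtype=float)
        self.rgyr_series = np.asarray(self.rgyr_series, dtype=float)
        n = len(self.frame_times)
        if len(self.rmsd_series) != n or len(self.rgyr_series) != n:
            raise ValueError("series lengths must equal the frame count")


def classify_convergence(
    metrics: TrajectoryMetrics,
    rmsd_threshold: float = RMSD_THRESHOLD,
    rgyr_threshold: float = RGYR_THRESHOLD,
    tail_fraction: float = TAIL_FRACTION,
) -> str:
    """Label a trajectory ``converging`` or ``diverging``.

    Converging iff the mean RMSD *and* mean radius of gyration over the
    tail window (the last ``tail_fraction`` of frames) stay at or below
    their thresholds.  The tail window is used because cluster membership
    is judged by late-time behavior, not the initial relaxation.
    """
    n = len(metrics.rmsd_series)
    if n == 0:
        raise ValueError("empty trajectory")
    if not (0.0 < tail_fraction <= 1.0):
        raise ValueError("tail_fraction must be in (0, 1]")
    k = max(1, int(np.ceil(tail_fraction * n)))
    tail_rmsd = float(metrics.rmsd_series[-k:].mean())
    tail_rgyr = float(metrics.rgyr_series[-k:].mean())
    if tail_rmsd <= rmsd_threshold and tail_rgyr <= rgyr_threshold:
        return "converging"
    return "diverging"


def analyze_trajectory(
    frames: list[Structure],
    reference: Structure,
    *,
    frame_times: np.ndarray | None = None,
    pentamer_range: tuple[int, int] | None = None,
    trimer_range: tuple[int, int] | None = None,
    rmsd_threshold: float = RMSD_THRESHOLD,
    rgyr_threshold: float = RGYR_THRESHOLD,
    tail_fraction: float = TAIL_FRACTION,
) -> TrajectoryMetrics:
    """Compute RMSD/RGYR series (CA atoms) of a trajectory vs a reference.

    CA atoms are matched by residue index against the reference.  If the
    domain ranges are given, the inter-helical angle of the final frame is
    included.  The convergence label is assigned from the tail window.
    """
    if not frames:
        raise ValueError("empty trajectory")
    ref_ca = reference.ca()
    ref_xyz = ref_ca.coords
    rmsds, rgyrs = [], []
    for fr in frames:
        ca = fr.ca()
        if len(ca) != len(ref_ca) or not np.array_equal(ca.resseq, ref_ca.resseq):
            raise ValueError("frame CA atoms do not match the reference by residue")
        rmsds.append(kabsch_superpose(ref_xyz, ca.coords)[2])
        rgyrs.append(radius_of_gyration(ca.coords))
    if frame_times is None:
        frame_times = np.arange(len(frames), dtype=float)
    angle = None
    if pentamer_range is not None and trimer_range is not None:
        angle = interhelical_angle(frames[-1], pentamer_range, trimer_range)[0]
    out = TrajectoryMetrics(
        frame_times=frame_times,
        rmsd_series=np.asarray(rmsds),
        rgyr_series=np.asarray(rgyrs),
        final_interhelical_angle=angle,
    )
    out.label = classify_convergence(out, rmsd_threshold, rgyr_threshold, tail_fraction)
    return out
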