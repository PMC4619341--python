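"""Exact icosahedral rotation-group machinery.

The rotation group *I* of a regular icosahedron has order 60: the
identity, 24 fivefold rotations about the 6 vertex axes, 20 threefold
rotations about the 10 face axes, and 15 twofold rotations about the edge
axes (class equation 1 + 6·4 + 10·2 + 15·1 = 60).  A T=1 peptide
nanoparticle is one building block expanded by all 60 operators.

The wedge-shaped asymmetric unit is 1/60 of space: the cone bounded by the
four planes through the origin spanned by consecutive axes of the spherical
kite fivefold–twofold–threefold–twofold.  Symmetry-reduced simulation of a
particle needs only the contents of this wedge plus its face-adjacent
symmetry images.

All axes are unit vectors; one representative per antipodal pair is stored
(axes are undirected).  The adjacent fivefold/threefold inter-axis angle,
arctan-exact at 37.377° (≈37.4°), is the geometric target for the
pentamer–trimer hinge of the peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "IcosahedralFrame",
    "Wedge",
    "make_frame",
    "axis_angle",
    "build_wedge",
    "classify_point",
    "wedge_neighbors",
    "assign_to_wedge_images",
    "wedge_mc_fraction",
    "rotation_order",
]

_TOL = 1e-9


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _dedupe_axes(directions: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """One unit representative per antipodal axis pair (deterministic sign)."""
    out: list[np.ndarray] = []
    for d in directions:
        d = d / np.linalg.norm(d)
        # canonical sign: first nonzero component positive
        for c in d:
            if abs(c) > tol:
                if c < 0:
                    d = -d
                break
        if not any(np.allclose(d, e, atol=tol) for e in out):
            out.append(d)
    return np.asarray(out)


def _icosahedron_vertices() -> np.ndarray:
    """The 12 vertices of a regular icosahedron (golden-ratio frame)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = []
    for a, b in [(1.0, phi)]:
        for s1 in (+1, -1):
            for s2 in (+1, -1):
                verts.append((0.0, s1 * a, s2 * b))
                verts.append((s1 * a, s2 * b, 0.0))
                verts.append((s2 * b, 0.0, s1 * a))
    V = np.asarray(verts)
    return V / np.linalg.norm(V, axis=1, keepdims=True)


def _close_group(generators: list[np.ndarray], tol: float = _TOL) -> np.ndarray:
    """Close a set of rotation matrices under composition (BFS)."""
    ops: list[np.ndarray] = [np.eye(3)]

    def _find(M: np.ndarray) -> bool:
        return any(np.max(np.abs(M - O)) < 1e-6 for O in ops)

    frontier = [g for g in generators if not _find(g)]
    ops.extend(frontier)
    while frontier:
        new: list[np.ndarray] = []
        for A in frontier:
            for B in generators:
                for M in (A @ B, B @ A):
                    if not _find(M):
                        ops.append(M)
                        new.append(M)
        frontier = new
        if len(ops) > 120:  # safety: should never exceed 60 for valid generators
            raise RuntimeError("group closure exceeded expected order")
    return np.asarray(ops)


def rotation_order(R: np.ndarray, tol: float = 1e-6) -> int:
    """Order of a rotation operator (1, 2, 3 or 5 for icosahedral elements)."""
    M = np.eye(3)
    for k in range(1, 61):
        M = M @ R
        if np.max(np.abs(M - np.eye(3))) < tol:
            return k
    raise ValueError("operator order exceeds 60; not an icosahedral rotation")


@dataclass(frozen=True)
class IcosahedralFrame:
    """Axes, the 60 rotation operators, and a reference adjacent axis pair.

    ``fivefold_axes`` (6, 3), ``threefold_axes`` (10, 3) and
    ``twofold_axes`` (15, 3) hold one unit vector per antipodal pair.
    ``reference_pair`` is one fivefold axis and an adjacent threefold axis
    (the 37.4° pair), both directed into the same hemisphere.
    """

    fivefold_axes: np.ndarray
    threefold_axes: np.ndarray
    twofold_axes: np.ndarray
    rotations: np.ndarray          # (60, 3, 3)
    reference_pair: tuple[np.ndarray, np.ndarray]

    @property
    def fivefold_directed(self) -> np.ndarray:
        """All 12 directed vertex directions (both antipodes)."""
        return np.vstack([self.fivefold_axes, -self.fivefold_axes])

    @property
    def threefold_directed(self) -> np.ndarray:
        """All 20 directed face-center directions."""
        return np.vstack([self.threefold_axes, -self.threefold_axes])


def make_frame(orientation_convention: str = "default") -> IcosahedralFrame:
    """Construct the icosahedral frame: axes and all 60 rotation operators.

    The group is generated from one fivefold rotation (72° about a vertex)
    and one adjacent threefold rotation (120° about a face center) and
    closed under composition.

    Conventions:

    * ``"default"`` — the twofold axis on the great circle through the
      reference fivefold/threefold pair lies along +z, and the pair itself
      lies in the +x half of the xz-plane.
    * ``"golden"`` — the raw golden-ratio vertex frame (vertices at cyclic
      permutations of (0, ±1, ±φ)).
    """
    V = _icosahedron_vertices()

    # edges: closest vertex pairs; faces: mutually adjacent triples
    d2 = np.linalg.norm(V[:, None, :] - V[None, :, :], axis=-1)
    edge_len = np.min(d2[d2 > 1e-9])
    adj = np.abs(d2 - edge_len) < 1e-9
    edges = [(i, j) for i, j in combinations(range(12), 2) if adj[i, j]]
    faces = [
        (i, j, k)
        for i, j, k in combinations(range(12), 3)
        if adj[i, j] and adj[j, k] and adj[i, k]
    ]
    assert len(edges) == 30 and len(faces) == 20

    face_centers = np.asarray([V[list(f)].mean(axis=0) for f in faces])
    face_centers /= np.linalg.norm(face_centers, axis=1, keepdims=True)
    edge_mids = np.asarray([(V[i] + V[j]) / 2.0 for i, j in edges])
    edge_mids /= np.linalg.norm(edge_mids, axis=1, keepdims=True)

    # reference pair: vertex 0 and one face containing it
    v5 = V[0]
    f_idx = next(i for i, f in enumerate(faces) if 0 in f)
    v3 = face_centers[f_idx]
    # the twofold on the v5->v3 great circle: midpoint of the face edge opposite v5
    opp = [k for k in faces[f_idx] if k != 0]
    t2 = (V[opp[0]] + V[opp[1]]) / 2.0
    t2 /= np.linalg.norm(t2)

    if orientation_convention == "default":
        # map t2 -> +z, then spin about z to put v5 (and v3) in the +x half-plane
        z = np.array([0.0, 0.0, 1.0])
        axis = np.cross(t2, z)
        na = np.linalg.norm(axis)
        if na < 1e-12:
            R1 = np.eye(3) if t2[2] > 0 else _rotation_about([1.0, 0.0, 0.0], np.pi)
        else:
            R1 = _rotation_about(axis / na, np.arccos(np.clip(np.dot(t2, z), -1, 1)))
        v5r = R1 @ v5
        spin = -np.arctan2(v5r[1], v5r[0])
        R_conv = _rotation_about(z, spin) @ R1
    elif orientation_convention == "golden":
        R_conv = np.eye(3)
    else:
        raise ValueError(f"unknown orientation convention {orientation_convention!r}")

    V = V @ R_conv.T
    face_centers = face_centers @ R_conv.T
    edge_mids = edge_mids @ R_conv.T
    v5, v3 = R_conv @ v5, R_conv @ v3

    g5 = _rotation_about(v5, 2.0 * np.pi / 5.0)
    g3 = _rotation_about(v3, 2.0 * np.pi / 3.0)
    rotations = _close_group([g5, g3])
    assert rotations.shape == (60, 3, 3)

    return IcosahedralFrame(
        fivefold_axes=_dedupe_axes(V),
        threefold_axes=_dedupe_axes(face_centers),
        twofold_axes=_dedupe_axes(edge_mids),
        rotations=rotations,
        reference_pair=(v5, v3),
    )


def axis_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees, in [0, 90], between two undirected axes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("axis vectors must be nonzero")
    c = abs(np.dot(a, b) / (na * nb))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class Wedge:
    """The asymmetric-unit cone: four oriented planes through the origin.

    ``planes`` holds the inward unit normals, in the cutting order
    fivefold–twofold, twofold–threefold, threefold–twofold,
    twofold–fivefold.  ``apex_axes`` are the directed bounding axes
    (fivefold, twofold, threefold, twofold) of the spherical kite.
    """

    planes: np.ndarray     # (4, 3) inward unit normals
    apex_axes: np.ndarray  # (4, 3) directed axes: 5f, 2f, 3f, 2f

    @property
    def bisector(self) -> np.ndarray:
        """Unit direction midway between the fivefold and threefold apexes."""
        b = self.apex_axes[0] + self.apex_axes[2]
        return b / np.linalg.norm(b)


def build_wedge(
    frame: IcosahedralFrame,
    fivefold: np.ndarray | None = None,
    threefold: np.ndarray | None = None,
) -> Wedge:
    """Build the wedge-shaped asymmetric unit of the icosahedral group.

    By default the frame's reference fivefold/threefold pair is used; an
    explicit non-adjacent pair is rejected.  The two twofold axes adjacent
    to both chosen axes complete the kite; the four cutting planes each
    contain two consecutive kite axes, with inward normals chosen so the
    fivefold/threefold bisector lies inside.
    """
    v5 = np.asarray(frame.reference_pair[0] if fivefold is None else fivefold, float)
    v3 = np.asarray(frame.reference_pair[1] if threefold is None else threefold, float)
    v5 = v5 / np.linalg.norm(v5)
    v3 = v3 / np.linalg.norm(v3)
    # adjacency = minimal fivefold/threefold inter-axis angle (~37.38°)
    if axis_angle(v5, v3) > 38.0:
        raise ValueError(
            f"fivefold/threefold axes are not adjacent "
            f"(angle {axis_angle(v5, v3):.2f}° > 37.38°)"
        )
    if np.dot(v5, v3) < 0:  # direct into a common hemisphere
        v3 = -v3

    bis = v5 + v3
    bis /= np.linalg.norm(bis)
    # the two twofold axes bounding the kite touch both the vertex (31.72°)
    # and the face center (20.91°)
    twofolds = []
    for t in frame.twofold_axes:
        if axis_angle(t, v5) < 32.5 and axis_angle(t, v3) < 21.5:
            td = t if np.dot(t, bis) > 0 else -t
            twofolds.append(td)
    if len(twofolds) != 2:
        raise ValueError("could not locate the two bounding twofold axes")
    e1, e2 = twofolds
    if np.dot(np.cross(v5, v3), e1) < 0:  # deterministic ordering of E1/E2
        e1, e2 = e2, e1

    apex = np.asarray([v5, e1, v3, e2])
    planes = []
    for i in range(4):
        n = np.cross(apex[i], apex[(i + 1) % 4])
        n /= np.linalg.norm(n)
        if np.dot(n, bis) < 0:
            n = -n
        planes.append(n)
    return Wedge(planes=np.asarray(planes), apex_axes=apex)


def classify_point(p: np.ndarray, wedge: Wedge, tol: float = _TOL) -> str:
    """Classify a point as ``inside``, ``boundary`` or ``outside`` the wedge.

    The wedge is a cone from the origin, so only the direction of ``p``
    matters; the boundary tolerance ``tol`` applies to unit-sphere points.
    """
    p = np.asarray(p, dtype=float)
    norm = np.linalg.norm(p)
    if not np.isfinite(norm):
        raise ValueError("point must be finite")
    if norm < tol:
        return "boundary"  # the apex itself lies on every plane
    d = wedge.planes @ (p / norm)
    if np.all(d > tol):
        return "inside"
    if np.all(d >= -tol):
        return "boundary"
    return "outside"


def wedge_neighbors(wedge: Wedge, frame: IcosahedralFrame) -> list[np.ndarray]:
    """The non-identity operators whose wedge image is face-adjacent.

    For each bounding plane, the interior reference point is reflected
    across the plane and the (unique) rotation whose wedge image contains
    the reflected point is the neighbor across that plane.  Symmetry-reduced
    interaction calculations need exactly these images.
    """
    c = wedge.bisector
    found: list[np.ndarray] = []
    for n in wedge.planes:
        c_ref = c - 2.0 * np.dot(n, c) * n
        for R in frame.rotations:
            if np.max(np.abs(R - np.eye(3))) < 1e-9:
                continue
            if classify_point(R.T @ c_ref, wedge, tol=1e-7) == "inside":
                if not any(np.max(np.abs(R - F)) < 1e-6 for F in found):
                    found.append(R)
                break
    return found


def assign_to_wedge_images(
    points: np.ndarray, wedge: Wedge, frame: IcosahedralFrame, tol: float = _TOL
) -> np.ndarray:
    """Partition points among the 60 wedge images.

    Returns, for each point, the index k of the rotation whose wedge image
    contains it.  Boundary points (within ``tol`` of a cutting plane) are
    assigned deterministically to the lowest-index image whose closed wedge
    contains them, so the 60 images partition space exactly.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    norms = np.linalg.norm(P, axis=1, keepdims=True)
    norms[norms < tol] = 1.0
    U = P / norms
    n_pts = len(U)
    assigned = np.full(n_pts, -1, dtype=int)
    for k, R in enumerate(frame.rotations):
        todo = assigned < 0
        if not np.any(todo):
            break
        # point p is in R·wedge iff R^T p is in the wedge (closed, tolerance)
        d = (U[todo] @ R) @ wedge.planes.T   # rows: (R^T u) · n
        inside = np.all(d >= -tol, axis=1)
        idx = np.flatnonzero(todo)[inside]
        assigned[idx] = k
    if np.any(assigned < 0):
        raise RuntimeError("some points fell outside all 60 wedge images")
    return assigned


def wedge_mc_fraction(
    wedge: Wedge, n_samples: int = 1_000_000, seed: int = 0
) -> float:
    """Monte-Carlo estimate of the wedge's solid-angle fraction.

    Uniform random unit vectors are classified against the wedge; the
    strict-inside fraction estimates the solid angle divided by 4π, which
    is exactly 1/60 for the icosahedral asymmetric unit.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_samples, 3))
    X /= np.linalg.norm(X, axis=1, keepdims=True)
    d = X @ wedge.planes.T
    inside = np.all(d > _TOL, axis=1)
    return float(inside.mean())
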