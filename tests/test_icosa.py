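"""Icosahedral rotation group, axes, and the wedge asymmetric unit."""

from collections import Counter

import numpy as np
import pytest

from sapn.icosa import (
    assign_to_wedge_images,
    axis_angle,
    build_wedge,
    classify_point,
    make_frame,
    rotation_order,
    wedge_mc_fraction,
    wedge_neighbors,
)


# ---------------------------------------------------------------------------
# the group

def test_group_has_sixty_proper_rotations(frame):
    R = frame.rotations
    assert R.shape == (60, 3, 3)
    for M in R:
        assert np.abs(M @ M.T - np.eye(3)).max() < 1e-12
        assert np.linalg.det(M) == pytest.approx(1.0, abs=1e-12)


def test_group_is_closed_with_unique_identity(frame):
    R = frame.rotations
    ident = [k for k, M in enumerate(R) if np.abs(M - np.eye(3)).max() < 1e-9]
    assert len(ident) == 1
    # closure + inverses, spot-checked on a deterministic subset
    rng = np.random.default_rng(0)
    idx = rng.integers(0, 60, size=(40, 2))
    for i, j in idx:
        P = R[i] @ R[j]
        assert any(np.abs(P - M).max() < 1e-9 for M in R)
    for M in R[::7]:
        assert any(np.abs(M.T - N).max() < 1e-9 for N in R)


def test_axis_counts_by_eigen_analysis(frame):
    # brute force: classify every operator by its rotation order, then count
    # distinct axes of each order from the operators' rotation axes
    orders = Counter(rotation_order(M) for M in frame.rotations)
    assert orders == {1: 1, 2: 15, 3: 20, 5: 24}
    # class equation: 6*4 + 10*2 + 15*1 + 1 = 60
    assert 6 * 4 + 10 * 2 + 15 * 1 + 1 == 60 == len(frame.rotations)
    assert len(frame.fivefold_axes) == 6
    assert len(frame.threefold_axes) == 10
    assert len(frame.twofold_axes) == 15

    def axes_of_order(n):
        found = []
        for M in frame.rotations:
            if rotation_order(M) != n:
                continue
            w, v = np.linalg.eig(M)
            ax = np.real(v[:, np.argmin(np.abs(w - 1.0))])
            ax /= np.linalg.norm(ax)
            if not any(abs(abs(np.dot(ax, f))) > 1 - 1e-6 for f in found):
                found.append(ax)
        return found

    assert len(axes_of_order(5)) == 6
    assert len(axes_of_order(3)) == 10
    assert len(axes_of_order(2)) == 15


def test_orientation_convention_places_twofold_on_z():
    f = make_frame("default")
    assert any(abs(abs(t[2]) - 1.0) < 1e-9 for t in f.twofold_axes)
    v5, v3 = f.reference_pair
    assert v5[1] == pytest.approx(0.0, abs=1e-9) and v5[0] > 0
    assert v3[1] == pytest.approx(0.0, abs=1e-9) and v3[0] > 0
    with pytest.raises(ValueError):
        make_frame("no-such-convention")


# ---------------------------------------------------------------------------
# axis angles

def test_axis_angle_reference_pair_is_37_4(frame):
    assert round(axis_angle(*frame.reference_pair), 1) == 37.4


def test_axis_angle_between_adjacent_fivefolds(frame):
    # arccos(1/sqrt(5)) = 63.43 deg, from the icosahedron's vertex geometry
    angles = sorted(
        axis_angle(frame.fivefold_axes[0], v) for v in frame.fivefold_axes[1:]
    )
    assert angles[0] == pytest.approx(63.43, abs=0.005)
    assert angles[0] == pytest.approx(np.degrees(np.arccos(1 / np.sqrt(5))), abs=1e-9)


def test_axis_angle_degenerate_and_invalid_inputs():
    assert axis_angle([0, 0, 2], [0, 0, 5]) == pytest.approx(0.0)
    assert axis_angle([1, 0, 0], [-1, 0, 0]) == pytest.approx(0.0)  # undirected
    assert axis_angle([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)
    with pytest.raises(ValueError):
        axis_angle([0, 0, 0], [1, 0, 0])


def test_axis_angle_symmetric_and_negation_invariant(frame, rng):
    for _ in range(20):
        a, b = rng.normal(size=(2, 3))
        assert axis_angle(a, b) == pytest.approx(axis_angle(b, a))
        assert axis_angle(-a, b) == pytest.approx(axis_angle(a, b))


# ---------------------------------------------------------------------------
# the wedge

def test_wedge_planes_contain_their_bounding_axes(wedge):
    for i in range(4):
        n = wedge.planes[i]
        a = wedge.apex_axes[i]
        b = wedge.apex_axes[(i + 1) % 4]
        assert abs(np.dot(n, a)) < 1e-12 and abs(np.dot(n, b)) < 1e-12


def test_wedge_reference_points(wedge):
    assert classify_point(wedge.bisector, wedge) == "inside"
    assert classify_point(wedge.apex_axes[0], wedge) == "boundary"
    assert classify_point(-wedge.bisector, wedge) == "outside"
    # a point exactly on a cutting plane
    p = wedge.apex_axes[0] + wedge.apex_axes[1]
    assert classify_point(p, wedge) == "boundary"


def test_wedge_rejects_non_adjacent_pair(frame):
    v5 = frame.fivefold_axes[0]
    far = max(frame.threefold_axes, key=lambda v: axis_angle(v5, v))
    with pytest.raises(ValueError, match="not adjacent"):
        build_wedge(frame, fivefold=v5, threefold=far)


def test_wedge_solid_angle_fraction_monte_carlo(wedge):
    n = 200_000
    frac = wedge_mc_fraction(wedge, n, seed=11)
    p = 1.0 / 60.0
    sigma = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 3 * sigma


def test_sixty_wedge_images_tile_the_sphere(frame, wedge, rng):
    pts = rng.normal(size=(20_000, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    counts = np.zeros(len(pts), dtype=int)
    for R in frame.rotations:
        counts += np.all((pts @ R) @ wedge.planes.T > 1e-9, axis=1)
    assert np.all(counts == 1)


def test_rotating_an_interior_point_lands_inside_exactly_once(frame, wedge):
    p = wedge.bisector
    images = [R @ p for R in frame.rotations]
    assert len({tuple(np.round(q, 9)) for q in images}) == 60
    inside = [q for q in images if classify_point(q, wedge) == "inside"]
    assert len(inside) == 1


def test_partition_assignment_is_exhaustive_and_unique(frame, wedge, rng):
    pts = rng.normal(size=(2_000, 3)) * 10.0
    img = assign_to_wedge_images(pts, wedge, frame)
    assert img.shape == (2_000,)
    assert np.all((img >= 0) & (img < 60))


def test_wedge_has_four_face_neighbors(frame, wedge):
    nbrs = wedge_neighbors(wedge, frame)
    assert len(nbrs) == 4
    for R in nbrs:
        assert np.abs(R - np.eye(3)).max() > 1e-6  # identity excluded
        # face adjacency: the rotated wedge shares one bounding plane
        shared = any(
            min(np.abs(n - R @ m).max(), np.abs(n + R @ m).max()) < 1e-9
            for n in wedge.planes
            for m in wedge.planes
        )
        assert shared
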