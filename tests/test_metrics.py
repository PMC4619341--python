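"""Superposition RMSD, radius of gyration, angles, convergence labels."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sapn.coiledcoil import CrickParams, _ca_trace
from sapn.metrics import (
    TrajectoryMetrics,
    classify_convergence,
    interhelical_angle,
    kabsch_superpose,
    radius_of_gyration,
    rmsd,
)
from sapn.structure import Structure


def _random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=int(seed)).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return R, t


# ---------------------------------------------------------------------------
# Kabsch superposition

def test_identical_sets_have_zero_rmsd(rng):
    X = rng.normal(size=(15, 3))
    _, _, r = kabsch_superpose(X, X)
    assert r == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_rigidly_moved_sets_superpose_to_zero(seed, rng):
    X = rng.normal(size=(25, 3)) * 10
    R, t = _random_rigid(seed)
    Rhat, that, r = kabsch_superpose(X, X @ R.T + t)
    assert r < 1e-9
    assert np.linalg.det(Rhat) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_matches_rotation_grid_oracle():
    # tiny 4-point problem: exhaustive search over a rotation grid must not
    # beat the analytic optimum by more than the grid resolution allows
    X = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 0, 3.8]])
    rng = np.random.default_rng(7)
    Y = X + rng.normal(scale=1.0, size=X.shape)
    _, _, r_opt = kabsch_superpose(X, Y)

    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    best = np.inf
    grid = np.linspace(0, 2 * np.pi, 25, endpoint=False)
    half = np.linspace(0, np.pi, 13)
    for a in grid:
        for b in half:
            for c in grid:
                R = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
                best = min(best, np.sqrt(((Xc - Yc @ R.T) ** 2).sum() / len(X)))
    assert r_opt <= best + 1e-12          # analytic optimum is never worse
    assert best - r_opt < 0.15            # and the grid comes close to it


def test_kabsch_matches_scipy_align_vectors(rng):
    # independent route: scipy's align_vectors on the centered clouds
    X = rng.normal(size=(30, 3)) * 5
    Y = rng.normal(size=(30, 3)) * 5
    _, _, r_ours = kabsch_superpose(X, Y)
    rot, rssd = Rotation.align_vectors(X - X.mean(axis=0), Y - Y.mean(axis=0))
    assert r_ours == pytest.approx(rssd / np.sqrt(len(X)), abs=1e-9)


def test_superposition_never_increases_rmsd(rng):
    X = rng.normal(size=(20, 3)) * 8
    Y = rng.normal(size=(20, 3)) * 8
    assert rmsd(X, Y) <= rmsd(X, Y, superpose=False) + 1e-12


@pytest.mark.parametrize("X, Y, match", [
    (np.zeros((4, 3)), np.zeros((5, 3)), "differ"),
    (np.zeros((2, 3)), np.zeros((2, 3)), "at least 3"),
])
def test_kabsch_input_validation(X, Y, match):
    with pytest.raises(ValueError, match=match):
        kabsch_superpose(X, Y)


# ---------------------------------------------------------------------------
# radius of gyration

def test_rgyr_closed_forms(rng):
    assert radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0
    # dumbbell: two equal masses separated by d -> d/2
    assert radius_of_gyration([[0, 0, 0], [0, 0, 7.0]]) == pytest.approx(3.5)
    # spherical shell of radius 16.2 -> 16.2 exactly (all radii equal);
    # antipodal pairs pin the center of mass to the sphere center
    pts = rng.normal(size=(400, 3))
    pts = 16.2 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
    pts = np.vstack([pts, -pts])
    assert radius_of_gyration(pts) == pytest.approx(16.2, abs=1e-9)


def test_rgyr_mass_weighting_moves_center():
    coords = [[0.0, 0, 0], [0, 0, 10.0]]
    heavy_left = radius_of_gyration(coords, masses=[3.0, 1.0])
    # cm at 2.5: sqrt((3*2.5^2 + 1*7.5^2)/4)
    assert heavy_left == pytest.approx(np.sqrt((3 * 2.5**2 + 7.5**2) / 4.0))


def test_rgyr_rigid_invariance_and_exact_scaling(rng):
    X = rng.normal(size=(50, 3)) * 6
    R, t = _random_rigid(9)
    assert radius_of_gyration(X @ R.T + t) == pytest.approx(
        radius_of_gyration(X), abs=1e-9
    )
    assert radius_of_gyration(2.5 * X) == pytest.approx(
        2.5 * radius_of_gyration(X), abs=1e-9
    )


def test_rgyr_rejects_bad_input():
    with pytest.raises(ValueError):
        radius_of_gyration(np.zeros((0, 3)))
    with pytest.raises(ValueError, match="positive"):
        radius_of_gyration([[0, 0, 0], [1, 1, 1]], masses=[1.0, -1.0])


# ---------------------------------------------------------------------------
# inter-helical angle

def _two_helix_model(crossing_deg):
    h1 = _ca_trace(18, CrickParams())
    th = np.deg2rad(crossing_deg)
    R = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0], [-np.sin(th), 0, np.cos(th)]])
    h2 = h1 @ R.T + np.array([25.0, 0, 0])
    return Structure.concat([
        Structure.from_ca(h1, start_resseq=1),
        Structure.from_ca(h2, start_resseq=21),
    ])


@pytest.mark.parametrize("angle", [20.0, 60.0, 85.0])
def test_interhelical_angle_recovers_generator_crossing(angle):
    st = _two_helix_model(angle)
    und, drc = interhelical_angle(st, (1, 18), (21, 38))
    assert und == pytest.approx(angle, abs=0.5)


def test_collinear_domains_give_zero_angle():
    st = _two_helix_model(0.0)
    und, _ = interhelical_angle(st, (1, 18), (21, 38))
    assert und == pytest.approx(0.0, abs=0.5)


def test_interhelical_angle_symmetric_and_rigid_invariant(rng):
    st = _two_helix_model(47.0)
    a1, _ = interhelical_angle(st, (1, 18), (21, 38))
    a2, _ = interhelical_angle(st, (21, 38), (1, 18))
    assert a1 == pytest.approx(a2, abs=1e-9)
    R, t = _random_rigid(13)
    a3, _ = interhelical_angle(st.transformed(R=R, t=t), (1, 18), (21, 38))
    assert a3 == pytest.approx(a1, abs=1e-6)


def test_directed_convention_spans_obtuse_angles():
    # anti-aligned helices: undirected angle folds to < 90, directed does not
    h1 = _ca_trace(18, CrickParams())
    h2 = (h1 @ np.diag([1.0, -1.0, -1.0])) + np.array([25.0, 0, 0])  # flipped
    st = Structure.concat([
        Structure.from_ca(h1, start_resseq=1),
        Structure.from_ca(h2, start_resseq=21),
    ])
    und, drc = interhelical_angle(st, (1, 18), (21, 38))
    assert drc == pytest.approx(180.0, abs=1.0)
    assert und == pytest.approx(0.0, abs=1.0)


# ---------------------------------------------------------------------------
# convergence classification

def _const_metrics(r, g, n=20):
    return TrajectoryMetrics(
        frame_times=np.arange(n) * 0.1,
        rmsd_series=np.full(n, float(r)),
        rgyr_series=np.full(n, float(g)),
    )


def test_printed_cluster_exemplars_are_labeled_correctly():
    # converging cluster: RMSD within 7 A, RGYR 16.2 A
    assert classify_convergence(_const_metrics(5.0, 16.2)) == "converging"
    # diverging cluster: RMSD about 10 A, RGYR 18 A
    assert classify_convergence(_const_metrics(10.0, 18.0)) == "diverging"


def test_either_metric_alone_can_diverge():
    assert classify_convergence(_const_metrics(10.0, 16.2)) == "diverging"
    assert classify_convergence(_const_metrics(5.0, 18.0)) == "diverging"


def test_classification_uses_the_tail_window():
    n = 20
    m = TrajectoryMetrics(
        frame_times=np.arange(n) * 0.1,
        rmsd_series=np.concatenate([np.full(15, 12.0), np.full(5, 3.0)]),
        rgyr_series=np.full(n, 16.0),
    )
    # early excursion is forgiven; the tail is quiet
    assert classify_convergence(m, tail_fraction=0.25) == "converging"
    assert classify_convergence(m, tail_fraction=1.0) == "diverging"


def test_classifier_is_monotone_in_thresholds(rng):
    for _ in range(20):
        m = _const_metrics(rng.uniform(0, 15), rng.uniform(10, 25))
        if classify_convergence(m, 7.0, 17.1) == "converging":
            assert classify_convergence(m, 8.0, 18.0) == "converging"


def test_empty_series_rejected():
    with pytest.raises(ValueError, match="empty"):
        classify_convergence(_const_metrics(1, 1, n=0))
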