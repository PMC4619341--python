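"""Monomer construction, 60-fold expansion, and asymmetric-unit extraction."""

import numpy as np
import pytest

from sapn.assembly import (
    assemble_particle,
    build_monomer,
    domain_cluster_counts,
    extract_asymmetric_unit,
    particle_diameter,
    particle_diameter_from_structure,
    rehinge,
    validate_disulfide,
)
from sapn.designs import full_length_construct, mini_peptide
from sapn.icosa import axis_angle
from sapn.metrics import kabsch_superpose, rmsd
from sapn.structure import Structure


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


# ---------------------------------------------------------------------------
# monomer

def test_monomer_realizes_target_angle():
    m = build_monomer(mini_peptide(1), target_angle=37.4)
    assert m.realized_angle == pytest.approx(37.4, abs=0.5)


def test_default_target_is_the_exact_icosahedral_angle(monomer, frame):
    assert monomer.target_angle == pytest.approx(
        axis_angle(*frame.reference_pair), abs=1e-9
    )
    assert monomer.realized_angle == pytest.approx(monomer.target_angle, abs=0.5)


def test_rehinge_to_current_angle_is_identity(monomer):
    again = rehinge(monomer, monomer.realized_angle)
    assert np.abs(again.structure.coords - monomer.structure.coords).max() < 1e-9


def test_rehinge_reaches_requested_angle(monomer):
    opened = rehinge(monomer, 60.0)
    assert opened.realized_angle == pytest.approx(60.0, abs=0.5)


def test_wider_hinge_gives_larger_end_to_end_distance(monomer):
    def end_to_end(m):
        ca = m.structure.ca_coords()
        return np.linalg.norm(ca[-1] - ca[0])

    wide = rehinge(monomer, 89.0)
    assert end_to_end(wide) > end_to_end(monomer)


def test_monomer_rejects_too_short_linker():
    from sapn.constructs import Construct

    # a 1-residue linker cannot span the hinge gap at a wide clearance
    c = Construct("tiny-linker", "WKALKAELWQALA" + "G" + "ELSAIEELARILDELR",
                  (1, 13), (14, 14), (15, 30))
    with pytest.raises(ValueError, match="linker"):
        build_monomer(c, hinge_clearance=60.0)


def test_monomer_rejects_out_of_range_angles(peptide1):
    with pytest.raises(ValueError, match="target_angle"):
        build_monomer(peptide1, target_angle=120.0)


# ---------------------------------------------------------------------------
# particle

def test_particle_has_sixty_chains(particle):
    assert particle.n_chains == 60


def test_every_chain_is_the_rotated_image_of_chain_zero(particle):
    st = particle.structure
    names = st.chains
    c0 = st.select(chain=names[0]).coords
    for k, R in enumerate(particle.frame.rotations):
        ck = st.select(chain=names[k]).coords
        assert rmsd(ck, c0 @ R.T, superpose=False) < 1e-6


def test_chains_have_identical_internal_geometry(particle):
    st = particle.structure
    names = st.chains
    d0 = np.linalg.norm(np.diff(st.select(chain=names[0]).coords, axis=0), axis=1)
    for cn in names[1::13]:
        dk = np.linalg.norm(np.diff(st.select(chain=cn).coords, axis=0), axis=1)
        assert np.abs(dk - d0).max() < 1e-6


def test_pentamer_centroid_radii_identical_across_chains(particle):
    st = particle.structure
    lo, hi = particle.monomer.construct.pentamer_range
    radii = [
        np.linalg.norm(st.select(chain=cn, resseq_range=(lo, hi)).ca_coords().mean(axis=0))
        for cn in st.chains
    ]
    assert np.ptp(radii) < 1e-6


def test_five_pentamer_helices_per_fivefold_axis(particle):
    counts = domain_cluster_counts(particle, "pentamer")
    assert counts.shape == (12,)
    assert set(counts) == {5}


def test_three_trimer_helices_per_threefold_axis(particle):
    counts = domain_cluster_counts(particle, "trimer")
    assert counts.shape == (20,)
    assert set(counts) == {3}


def test_interhelical_angle_preserved_in_every_chain(particle):
    from sapn.metrics import interhelical_angle

    st = particle.structure
    c = particle.monomer.construct
    for cn in st.chains[::15]:
        chain = st.select(chain=cn)
        angle, _ = interhelical_angle(chain, c.pentamer_range, c.trimer_range)
        assert angle == pytest.approx(particle.monomer.realized_angle, abs=0.1)


def test_mismatched_monomer_angle_is_rejected(frame):
    m = build_monomer(mini_peptide(1), target_angle=50.0)
    with pytest.raises(ValueError, match="does not match"):
        assemble_particle(m, frame)


# ---------------------------------------------------------------------------
# diameter

def test_diameter_of_a_spherical_shell_is_twice_the_radius():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(250, 3))
    pts = 105.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)  # 10.5 nm radius
    pts = np.vstack([pts, -pts])  # antipodal pairs: centroid exactly at center
    st = Structure.from_ca(pts)
    rep = particle_diameter_from_structure(st)
    assert rep.diameter_nm == pytest.approx(21.0, abs=0.01)
    assert rep.mean_diameter_nm == pytest.approx(21.0, abs=0.01)


def test_diameter_invariant_under_rigid_motion(particle):
    rep0 = particle_diameter(particle)
    R = _rotation([1, 2, 3], 1.1)
    moved = particle.structure.transformed(R=R, t=np.array([100.0, -50.0, 25.0]))
    rep1 = particle_diameter_from_structure(moved)
    assert rep1.diameter_nm == pytest.approx(rep0.diameter_nm, abs=1e-9)
    assert rep1.mean_diameter_nm == pytest.approx(rep0.mean_diameter_nm, abs=1e-9)


def test_full_length_particle_diameter_in_sanity_band(frame):
    c = full_length_construct("2.5HR")
    p = assemble_particle(build_monomer(c), frame)
    assert 15.0 < p.diameter_nm < 27.0
    # the fully extended His-tag sets the upper, larger bound
    p_ext = assemble_particle(build_monomer(c, include_tag="extended"), frame)
    assert p_ext.diameter_nm > p.diameter_nm


# ---------------------------------------------------------------------------
# asymmetric unit

def test_exactly_one_chain_majority_inside_the_wedge(particle, wedge):
    asu = extract_asymmetric_unit(particle, wedge)
    assert asu.n_majority == 1


def test_wedge_partition_reconstructs_the_particle(particle, wedge):
    asu = extract_asymmetric_unit(particle, wedge)
    # the 60 wedge images partition the atoms: counts sum to the total and
    # the identity image holds exactly one chain-worth of atoms
    n_atoms = len(particle.structure)
    assert len(asu.per_atom_image) == n_atoms
    counts = np.bincount(asu.per_atom_image, minlength=60)
    assert counts.sum() == n_atoms
    assert len(asu.structure) == n_atoms // 60


def test_empty_particle_gives_empty_asymmetric_unit(particle, wedge):
    import dataclasses

    empty = dataclasses.replace(
        particle, structure=particle.structure.mask(np.zeros(len(particle.structure), bool))
    )
    asu = extract_asymmetric_unit(empty, wedge)
    assert len(asu.structure) == 0 and asu.n_majority == 0


def test_off_center_particle_rejected(particle, wedge):
    import dataclasses

    shifted = dataclasses.replace(
        particle, structure=particle.structure.transformed(t=np.array([5.0, 0, 0]))
    )
    with pytest.raises(ValueError, match="off-center"):
        extract_asymmetric_unit(shifted, wedge)


# ---------------------------------------------------------------------------
# disulfide validation

def test_disulfide_distance_across_the_hinge():
    m = build_monomer(mini_peptide(3))  # carries T15C/S23C
    d, feasible = validate_disulfide(m, (15, 23))
    assert d > 0 and np.isfinite(d)
    assert feasible == (d <= 7.5)


def test_same_residue_disulfide_is_trivially_feasible():
    m = build_monomer(mini_peptide(3))
    d, feasible = validate_disulfide(m, (15, 15))
    assert d == 0.0 and feasible


def test_chain_end_pair_is_infeasible_and_warns(monomer):
    with pytest.warns(UserWarning, match="not CYS"):
        d, feasible = validate_disulfide(monomer, (1, 36))
    assert d > 7.5 and not feasible
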