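import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from actokin.geometry import (
    HBondCriteria,
    backbone_dihedrals,
    ca_angle,
    contact_profile,
    dihedral,
    domain_rotation,
    hbond_population,
    pocket_sphere_volume,
    superpose,
)
from actokin.pdbio import (
    CoordinateTrajectory,
    StructureModel,
    read_structure,
    write_structure,
)
from actokin.synth import (
    build_peptide,
    generate_trajectory,
    make_shell_model,
    make_template_model,
)
from helpers_geometry import cloud_model as _cloud_model
from helpers_geometry import quaternion_superpose_rmsd


def _random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def test_read_minimal_two_atom_file(tmp_path):
    pdb = tmp_path / "mini.pdb"
    pdb.write_text(
        "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00"
        "           C\n"
        "ATOM      2  CB  GLY A   1       4.500  -1.250   0.125  1.00  0.00"
        "           C\n"
        "END\n"
    )
    m = read_structure(pdb)
    assert len(m) == 2
    assert np.allclose(m.coords[0], [1.0, 2.0, 3.0], atol=1e-3)
    assert np.allclose(m.coords[1], [4.5, -1.25, 0.125], atol=1e-3)
    assert m.resnum[0] == 1 and m.name[1] == "CB"


def test_altloc_highest_occupancy_retained(tmp_path):
    pdb = tmp_path / "alt.pdb"
    pdb.write_text(
        "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.60  0.00"
        "           C\n"
        "ATOM      2  CA BGLY A   1       9.000   9.000   9.000  0.40  0.00"
        "           C\n"
        "END\n"
    )
    m = read_structure(pdb)
    assert len(m) == 1
    assert np.allclose(m.coords[0], [0, 0, 0], atol=1e-3)  # A (occ 0.6) kept


def test_multi_model_file_yields_trajectory(tmp_path, template):
    path = tmp_path / "traj.pdb"
    traj = generate_trajectory(3, template, seed=1)
    write_structure(traj, path)
    back = read_structure(path)
    assert isinstance(back, CoordinateTrajectory)
    assert len(back) == 3
    assert back[0].atom_keys() == back[2].atom_keys()
    assert np.allclose(back[1].coords, traj[1].coords, atol=1e-3)


def test_malformed_record_reports_line_number(tmp_path):
    pdb = tmp_path / "bad.pdb"
    pdb.write_text(
        "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00\n"
        "ATOM      2  CB  GLY A   1       4.500   x.250\n"
        "END\n"
    )
    with pytest.raises(ValueError, match=":2"):
        read_structure(pdb)


def test_empty_file_rejected(tmp_path):
    pdb = tmp_path / "empty.pdb"
    pdb.write_text("HEADER    NOTHING\nEND\n")
    with pytest.raises(ValueError):
        read_structure(pdb)


def test_selection_grammar(template):
    assert template.select("A:1-20@CA").sum() == 20
    assert template.select("A:5").sum() == 4  # N, CA, C, O
    assert template.select("A:*@CA").sum() == 32
    assert template.select("A:5@CA,A:10@CA").sum() == 2
    with pytest.raises(ValueError, match="bad selection"):
        template.select("nonsense")


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def test_superpose_identity_and_rigid_invariance(template):
    assert superpose(template, template).rmsd == pytest.approx(0.0, abs=1e-12)
    R, t = _random_rigid(3)
    moved = template.transformed(R, t)
    s = superpose(moved, template)
    assert s.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(s.rotation) == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(s.apply(moved.coords), template.coords, atol=1e-9)


@pytest.mark.parametrize("n_atoms", [4, 20, 100, 500])
def test_superpose_rmsd_matches_quaternion_oracle(n_atoms):
    rng = np.random.default_rng(n_atoms)
    a = rng.uniform(-10, 10, (n_atoms, 3))
    b = a + rng.normal(0, 0.8, (n_atoms, 3))
    R, t = _random_rigid(n_atoms + 1)
    mobile = _cloud_model(a @ R.T + t)
    target = _cloud_model(b)
    got = superpose(mobile, target).rmsd
    assert got == pytest.approx(quaternion_superpose_rmsd(a @ R.T + t, b),
                                abs=1e-9)


def test_superpose_fit_selection_rmsd_not_larger(template):
    rng = np.random.default_rng(9)
    noisy = template.copy()
    noisy.coords = noisy.coords + rng.normal(0, 0.5, noisy.coords.shape)
    fit_all = superpose(noisy, template)
    fit_core = superpose(noisy, template, "A:1-20")
    # restricting the evaluation to the atoms used for fitting can only
    # lower (or keep) the RMSD relative to fitting on those same atoms
    sel = template.select("A:1-20")
    moved = fit_all.apply(noisy.coords[sel])
    rmsd_all_on_core = float(np.sqrt(np.mean(
        np.sum((moved - template.coords[sel]) ** 2, axis=1))))
    assert fit_core.rmsd <= rmsd_all_on_core + 1e-12


def test_superpose_unmatched_residues_listed():
    a = _cloud_model(np.eye(3) * 2)
    b = a.subset(np.array([True, True, False]))
    b = _cloud_model(b.coords)  # renumbered 1..2
    with pytest.raises(ValueError, match="unmatched"):
        superpose(a, b)


# ---------------------------------------------------------------------------
# angles and dihedrals
# ---------------------------------------------------------------------------

def test_ca_angle_basic_geometries():
    def ca_model(points):
        m = _cloud_model(points)
        m.name = np.array(["CA"] * len(points), dtype=object)
        return m

    collinear = ca_model([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
    assert ca_angle(collinear, (1, 2, 3)) == pytest.approx(180.0, abs=1e-9)
    right = ca_model([[1, 0, 0], [0, 0, 0], [0, 1, 0]])
    assert ca_angle(right, (1, 2, 3)) == pytest.approx(90.0, abs=1e-9)
    with pytest.raises(ValueError, match="no Cα"):
        ca_angle(right, (1, 2, 99))


def test_planted_relay_style_kink_angle(template):
    """A 145° bend planted at a residue triple — the pre-powerstroke-like
    relay geometry — is read back exactly."""
    traj = generate_trajectory(
        5, template,
        {"angle": {"residues": (3, 10, 17), "chain": "A", "degrees": 145.0}},
        seed=2,
    )
    for frame in traj.frames:
        assert ca_angle(frame, (3, 10, 17), "A") == pytest.approx(145.0,
                                                                  abs=0.1)


def test_dihedral_of_ideal_helix_and_extended_chain():
    helix = build_peptide([-57.0] * 8, [-47.0] * 8)
    vals = backbone_dihedrals(helix, "A")
    assert vals[0][1] is None          # first residue: undefined phi
    assert vals[-1][2] is None         # last residue: undefined psi
    for _, phi, psi in vals[1:-1]:
        assert phi == pytest.approx(-57.0, abs=2.0)
        assert psi == pytest.approx(-47.0, abs=2.0)
    ext = backbone_dihedrals(build_peptide([180.0] * 5, [180.0] * 5), "A")
    for _, phi, psi in ext[1:-1]:
        assert abs(phi) == pytest.approx(180.0, abs=1e-6)
        assert abs(psi) == pytest.approx(180.0, abs=1e-6)


def test_dihedrals_undefined_across_chain_break():
    a = build_peptide([-57.0] * 4, [-47.0] * 4)
    b = build_peptide([-57.0] * 4, [-47.0] * 4, start_resnum=10)
    b.coords = b.coords + 50.0  # far away: no peptide bond
    from actokin.synth import _concat_models
    m = _concat_models([a, b])
    vals = {rn: (phi, psi) for rn, phi, psi in backbone_dihedrals(m, "A")}
    assert vals[3][0] is not None      # phi defined within first segment
    assert vals[4][1] is None          # psi spanning the break
    assert vals[10][0] is None         # phi spanning the break
    assert vals[11][0] is not None     # second segment internally intact


def test_dihedral_sign_convention():
    # a +90° torsion built by hand
    p0, p1, p2 = np.array([1.0, 0, 0]), np.zeros(3), np.array([0, 1.0, 0])
    p3 = np.array([0, 1.0, 1.0])
    assert dihedral(p0, p1, p2, p3) == pytest.approx(-90.0, abs=1e-9) or \
        dihedral(p0, p1, p2, p3) == pytest.approx(90.0, abs=1e-9)
    # trans is exactly 180, reported in (-180, 180]
    p3t = np.array([-1.0, 1.0, 0.0])
    assert dihedral(p0, p1, p2, p3t) == 180.0


# ---------------------------------------------------------------------------
# H-bonds and contacts
# ---------------------------------------------------------------------------

def _pair_traj(distances):
    frames = []
    for i, d in enumerate(distances):
        m = _cloud_model([[0, 0, 0], [d, 0, 0]])
        m.name = np.array(["O", "N"], dtype=object)
        m.element = np.array(["O", "N"], dtype=object)
        m.resnum = np.array([1, 2])
        m.model_id = i + 1
        frames.append(m)
    return CoordinateTrajectory(frames)


def test_hbond_population_trivial_bounds():
    always = _pair_traj([2.8] * 10)
    pop, pairs = hbond_population(always, "A:1@O", "A:2@N")
    assert pop == 1.0
    assert pairs[(("A", 1, "O"), ("A", 2, "N"))] == 1.0
    never = _pair_traj([4.5] * 10)
    assert hbond_population(never, "A:1@O", "A:2@N")[0] == 0.0


def test_hbond_population_equals_frame_average_oracle():
    rng = np.random.default_rng(8)
    dists = rng.uniform(2.5, 4.5, 200)
    traj = _pair_traj(dists)
    pop, _ = hbond_population(traj, "A:1@O", "A:2@N")
    assert pop == pytest.approx(np.mean(dists <= 3.5), abs=1e-12)


def test_planted_occupancy_recovered_exactly(template):
    traj = generate_trajectory(
        1000, template,
        {"hbond": {"donor": "A:5@O", "acceptor": "A:15@N",
                   "occupancy": 0.55}},
        seed=4,
    )
    pop, _ = hbond_population(traj, "A:5@O", "A:15@N")
    assert pop == pytest.approx(0.550, abs=1e-12)


def test_hbond_criteria_validation_and_empty_selection(template):
    with pytest.raises(ValueError, match="cutoff"):
        HBondCriteria(distance_cutoff=5.5)
    traj = CoordinateTrajectory([template])
    with pytest.raises(ValueError, match="empty donor"):
        hbond_population(traj, "B:1@O", "A:2@N")


def test_contact_profile_classification():
    m = _cloud_model([[0, 0, 0], [3.0, 0, 0], [0, 2.8, 0]])
    m.name = np.array(["NH1", "CB", "O"], dtype=object)
    m.element = np.array(["N", "C", "O"], dtype=object)
    m.resnum = np.array([788, 730, 731])
    cs = contact_profile(m, ("A", 788), cutoff=3.5)
    assert [c.kind for c in cs] == ["hbond", "vdW"]   # sorted by distance
    assert cs[0].distance == pytest.approx(2.8)
    assert cs[1].distance == pytest.approx(3.0)
    with pytest.raises(ValueError, match="absent"):
        contact_profile(m, ("A", 999))


def test_contact_profile_matches_brute_force_scan():
    rng = np.random.default_rng(12)
    m = _cloud_model(rng.uniform(0, 25, (500, 3)))
    m.resnum = rng.integers(1, 60, 500)
    # rebuild with unique atom keys
    m.name = np.array([f"C{i}" for i in range(500)], dtype=object)
    cutoff = 4.0
    got = contact_profile(m, ("A", 30), cutoff=cutoff)
    own = (m.resnum == 30)
    expected = []
    for i in np.nonzero(own)[0]:
        for j in np.nonzero(~own)[0]:
            d = np.linalg.norm(m.coords[i] - m.coords[j])
            if d <= cutoff:
                expected.append((round(d, 9), m.name[j]))
    assert sorted((round(c.distance, 9), c.partner_atom[2]) for c in got) \
        == sorted(expected)


# ---------------------------------------------------------------------------
# domain rotation and pocket volume
# ---------------------------------------------------------------------------

def test_domain_rotation_identity_and_plant(template):
    assert domain_rotation(template, template, "A:1-20", "A:101-112") \
        == pytest.approx(0.0, abs=1e-6)
    traj = generate_trajectory(
        50, template,
        {"rotation": {"selection": "A:101-112", "degrees": 27.0}},
        seed=6,
    )
    got = domain_rotation(traj[0], traj[-1], "A:1-20", "A:101-112")
    assert got == pytest.approx(27.0, abs=0.1)


def test_domain_rotation_half_turn(template):
    traj = generate_trajectory(
        2, template,
        {"rotation": {"selection": "A:101-112", "degrees": 180.0}},
        seed=7,
    )
    got = domain_rotation(traj[0], traj[1], "A:1-20", "A:101-112")
    assert got == pytest.approx(180.0, abs=0.1)


def test_pocket_sphere_volume_closed_form():
    r, v = pocket_sphere_volume(make_shell_model(9.0), "A:999@CEN")
    assert r == pytest.approx(9.0, abs=1e-9)
    assert v == pytest.approx(3053.6, abs=0.1)
    r, v = pocket_sphere_volume(make_shell_model(5.50), "A:999@CEN")
    assert v == pytest.approx(696.9, abs=0.1)


def test_pocket_volume_zero_when_center_on_atom():
    shell = make_shell_model(6.0)
    # pick a shell atom itself as the center: nearest wall at 0 distance is
    # excluded (it's selected), the next shell atom is > 0 away, so use probe
    m = shell
    r, v = pocket_sphere_volume(m, "A:999@CEN", probe=6.0)
    assert r == 0.0 and v == 0.0


# ---------------------------------------------------------------------------
# rigid-motion invariance of every metric
# ---------------------------------------------------------------------------

def test_all_metrics_invariant_under_global_rigid_motion(template):
    R, t = _random_rigid(42)
    traj = generate_trajectory(
        40, template,
        {"rotation": {"selection": "A:101-112", "degrees": 27.0},
         "hbond": {"donor": "A:5@O", "acceptor": "A:15@N",
                   "occupancy": 0.4}},
        seed=10,
    )
    moved = CoordinateTrajectory([f.transformed(R, t) for f in traj.frames])

    a0 = ca_angle(traj[0], (3, 10, 17), "A")
    assert ca_angle(moved[0], (3, 10, 17), "A") == pytest.approx(a0,
                                                                 abs=1e-9)
    d0 = backbone_dihedrals(traj[0], "A")
    d1 = backbone_dihedrals(moved[0], "A")
    for (_, p0, s0), (_, p1, s1) in zip(d0, d1):
        if p0 is not None:
            assert p1 == pytest.approx(p0, abs=1e-6)
    p0 = hbond_population(traj, "A:5@O", "A:15@N")[0]
    assert hbond_population(moved, "A:5@O", "A:15@N")[0] == p0
    rot0 = domain_rotation(traj[0], traj[-1], "A:1-20", "A:101-112")
    rot1 = domain_rotation(moved[0], moved[-1], "A:1-20", "A:101-112")
    assert rot1 == pytest.approx(rot0, abs=1e-6)
    s = superpose(moved[0], traj[0])
    assert s.rmsd == pytest.approx(0.0, abs=1e-9)
    c0 = contact_profile(traj[0], ("A", 5), cutoff=4.0)
    c1 = contact_profile(moved[0], ("A", 5), cutoff=4.0)
    assert [round(c.distance, 6) for c in c0] \
        == [round(c.distance, 6) for c in c1]
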