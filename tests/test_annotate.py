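import numpy as np
import pytest

from kjunction.annotate import (ATOM_SETS, AssignmentError, KTurnAssignment,
                                MissingAtomError, assign_roles,
                                classify_n_class, measure_contact,
                                superpose_roles)
from kjunction.fixtures import HelixSpec, build_ideal_duplex, build_two_helix_scene
from kjunction.search import default_pattern, scan_structure
from kjunction.structure_io import Nucleotide, StructureModel

from conftest import random_rigid

ROLE_SEQUENCE = ("-1n", "L1", "2b", "1n", "2n")


def _role_map(model, count=5):
    """Arbitrary injective role map over the first residues of a model."""
    return KTurnAssignment({role: model.nucleotides[i]
                            for i, role in enumerate(ROLE_SEQUENCE[:count])})


@pytest.fixture(scope="module")
def ga_scene():
    """Kinked two-helix scene whose NC helix carries a trans G.A pair."""
    pattern = default_pattern()
    nc = HelixSpec("GGGGGGGG", strand2="CCCCCCCA", chain1="C", chain2="D")
    scene, _ = build_two_helix_scene(HelixSpec("GGCAUCGAUGCU"), nc,
                                     pattern.entries[0], anchor_a=5, anchor_b=0)
    return scene


def test_assign_roles_finds_ga_pair(ga_scene):
    hits = scan_structure(ga_scene, default_pattern())
    assert hits
    asn = assign_roles(ga_scene, hits[0])
    keys = {asn.roles["1b"].key, asn.roles["1n"].key}
    assert keys == {("C", "1"), ("D", "8")}
    assert {"-1b", "-1n"} <= set(asn.roles)
    assert not asn.complete_core  # only one purine-purine pair grafted


def test_assign_roles_fails_on_plain_wc_scene(planted_scene, pattern):
    hits = scan_structure(planted_scene, pattern)
    with pytest.raises(AssignmentError, match="candidates considered"):
        assign_roles(planted_scene, hits[0])


def test_assign_roles_override_wins(ga_scene, pattern):
    hits = scan_structure(ga_scene, pattern)
    override = {"1b": ("D", "8"), "1n": ("C", "1")}
    asn = assign_roles(ga_scene, hits[0], override=override)
    assert asn.roles["1b"].key == ("D", "8")
    assert asn.roles["1n"].key == ("C", "1")


def test_role_map_must_be_injective(duplex):
    nt = duplex.nucleotides[0]
    with pytest.raises(ValueError):
        KTurnAssignment({"1b": nt, "1n": nt})


def test_measure_contact_symmetric_and_zero_on_self(duplex):
    asn = _role_map(duplex)
    d1 = measure_contact(duplex, asn, ("-1n", "O2'"), ("2b", "N1"))
    d2 = measure_contact(duplex, asn, ("2b", "N1"), ("-1n", "O2'"))
    assert d1 == d2 > 0
    assert measure_contact(duplex, asn, ("L1", "C1'"), ("L1", "C1'")) == 0.0


def test_measure_contact_missing_atom_names_the_culprit(duplex):
    asn = _role_map(duplex)
    with pytest.raises(MissingAtomError, match="N6"):
        # role -1n is a G here: it has no N6
        measure_contact(duplex, asn, ("-1n", "N6"), ("2b", "N1"))
    with pytest.raises(MissingAtomError, match="3b"):
        measure_contact(duplex, asn, ("3b", "O2'"), ("2b", "N1"))


@pytest.mark.parametrize("target", ["N1", "N3"])
def test_n_class_follows_nearer_acceptor_nitrogen(duplex, target):
    """Moving the 2b adenine so that one ring nitrogen sits 2.9-3.0 A
    from the -1n O2' (the other farther) must flip the classification."""
    donor = duplex.get("A", "5")          # a U: supplies O2'
    adenine = duplex.get("A", "4")        # an A: supplies N1/N3
    o2 = donor.coord("O2'")
    w = adenine.coord("N1") - adenine.coord("N3")
    w /= np.linalg.norm(w)
    probe = adenine.coord(target)
    direction = -w if target == "N1" else w
    shift = o2 + 2.95 * direction - probe
    moved = Nucleotide("X", "1", "A",
                       {n: type(a)(a.name, a.element, a.position + shift)
                        for n, a in adenine.atoms.items()}, "A")
    model = StructureModel("synthetic-core", [donor, moved])
    asn = KTurnAssignment({"-1n": donor, "2b": moved})
    report = classify_n_class(model, asn)
    assert report.n_class == target
    other = "N3" if target == "N1" else "N1"
    assert (report.distance(f"-1n O2' - 2b {target}")
            < report.distance(f"-1n O2' - 2b {other}"))


def test_contact_report_lists_every_standard_label(duplex):
    asn = _role_map(duplex)  # most roles absent
    report = classify_n_class(duplex, asn)
    labels = [lab for lab, *_ in report.contacts]
    assert len(labels) == 8
    statuses = {s for *_, s in report.contacts}
    assert "missing" in statuses  # absent roles flagged, never dropped


def test_superpose_self_is_zero(duplex):
    asn = _role_map(duplex)
    rmsd, rot, trans = superpose_roles(duplex, asn, duplex, asn)
    assert rmsd < 1e-9
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
    assert np.linalg.det(rot) == pytest.approx(1.0)


def test_superpose_recovers_random_rigid_motion(duplex):
    rng = np.random.default_rng(3)
    rot, trans = random_rigid(rng)
    moved = duplex.transformed(rot, trans)
    asn_m = _role_map(moved)
    asn_r = _role_map(duplex)
    rmsd, rhat, that = superpose_roles(moved, asn_m, duplex, asn_r)
    assert rmsd < 1e-6
    np.testing.assert_allclose(rhat @ rot, np.eye(3), atol=1e-6)


def test_superpose_symmetric_rmsd(duplex):
    rng = np.random.default_rng(4)
    rot, trans = random_rigid(rng)
    # different conformation, not a pure rigid copy: jitter the atoms
    jittered = duplex.transformed(rot, trans)
    for nt in jittered.nucleotides:
        for atom in nt.atoms.values():
            atom.position = atom.position + rng.normal(0, 0.3, 3)
    a1, a2 = _role_map(jittered), _role_map(duplex)
    r_ab, *_ = superpose_roles(jittered, a1, duplex, a2)
    r_ba, *_ = superpose_roles(duplex, a2, jittered, a1)
    assert r_ab == pytest.approx(r_ba, abs=1e-9)


def test_subset_fit_beats_full_fit_on_the_subset(duplex):
    """Kabsch optimality: evaluating a role subset under its own optimal
    transform never exceeds evaluating it under the full-set optimum."""
    rng = np.random.default_rng(5)
    rot, trans = random_rigid(rng)
    jittered = duplex.transformed(rot, trans)
    for nt in jittered.nucleotides:
        for atom in nt.atoms.values():
            atom.position = atom.position + rng.normal(0, 0.4, 3)
    a_m, a_r = _role_map(jittered), _role_map(duplex)
    _, r_full, t_full = superpose_roles(jittered, a_m, duplex, a_r)
    subset = ROLE_SEQUENCE[:3]
    rmsd_sub, *_ = superpose_roles(jittered, a_m, duplex, a_r, roles=subset)

    xyz_m, xyz_r = [], []
    for role in subset:
        for atom in ATOM_SETS["backbone"]:
            xyz_m.append(a_m.roles[role].coord(atom))
            xyz_r.append(a_r.roles[role].coord(atom))
    xyz_m, xyz_r = np.array(xyz_m), np.array(xyz_r)
    moved = xyz_m @ r_full.T + t_full
    rmsd_fullfit = np.sqrt(np.mean(np.sum((moved - xyz_r) ** 2, axis=1)))
    assert rmsd_sub <= rmsd_fullfit + 1e-12


def test_superpose_underdetermined_raises(duplex):
    asn = _role_map(duplex, count=1)
    with pytest.raises(ValueError, match="underdetermined"):
        superpose_roles(duplex, asn, duplex, asn, roles=("-1n",),
                        atom_set=("P",))


def test_trace_atom_set_uses_fewer_atoms(duplex):
    asn = _role_map(duplex)
    r_back, *_ = superpose_roles(duplex, asn, duplex, asn, atom_set="backbone")
    r_trace, *_ = superpose_roles(duplex, asn, duplex, asn, atom_set="trace")
    assert r_back < 1e-9 and r_trace < 1e-9
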