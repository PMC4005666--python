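import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kjunction.fixtures import HelixSpec, build_ideal_duplex, build_two_helix_scene
from kjunction.pairing import RelativeTransform
from kjunction.search import (SearchPattern, SelectionError, default_pattern,
                              interaxis_angle_deg, pattern_from_reference,
                              scan_structure, transform_deviation,
                              write_hits_pseudoatoms)
from kjunction.structure_io import load_structure

from conftest import random_rigid

SEQ_A, SEQ_B = "GGCAUCGAUGCU", "GCGAUCGAUCGC"


def _planted(t, anchor=5):
    scene, _ = build_two_helix_scene(HelixSpec(SEQ_A), HelixSpec(SEQ_B), t,
                                     anchor_a=anchor, anchor_b=anchor)
    return scene


def test_planted_scene_gives_one_exact_hit(pattern, planted_scene):
    hits = scan_structure(planted_scene, pattern)
    assert len(hits) == 1
    assert hits[0].translation_dev < 1e-6
    assert hits[0].rotation_dev < 1e-6
    chains_c = {c for c, _ in hits[0].c_segment.nucleotide_keys()}
    chains_nc = {c for c, _ in hits[0].nc_segment.nucleotide_keys()}
    assert chains_c == {"A", "B"} and chains_nc == {"C", "D"}


def test_straight_duplex_is_negative_control(pattern, duplex):
    assert scan_structure(duplex, pattern) == []


def test_tolerance_boundary_sweep(pattern):
    # perturb about the axis that changes the inter-helix angle itself:
    # no screw re-anchoring along either helix can compensate for that
    t = pattern.entries[0]
    x = np.array([1.0, 0.0, 0.0])
    w = np.cross(x, t.matrix @ x)
    w /= np.linalg.norm(w)

    def kinked(extra_deg):
        rot = Rotation.from_rotvec(np.radians(extra_deg) * w) * t.rotation
        return RelativeTransform(t.translation, rot)

    assert scan_structure(_planted(kinked(pattern.rotation_tol + 10)),
                          pattern) == []
    hits = scan_structure(_planted(kinked(pattern.rotation_tol / 2)), pattern)
    assert len(hits) == 1
    assert hits[0].rotation_dev <= pattern.rotation_tol / 2 + 1e-6


def test_enlarging_tolerances_never_loses_a_raw_match(pattern, planted_scene):
    small = pattern.with_tolerances(2.0, 15.0)
    large = pattern.with_tolerances(4.0, 30.0)
    raw_small = scan_structure(planted_scene, small, dedupe=False)
    raw_large = scan_structure(planted_scene, large, dedupe=False)
    keys_small = {(h.c_segment.key, h.nc_segment.key) for h in raw_small}
    keys_large = {(h.c_segment.key, h.nc_segment.key) for h in raw_large}
    assert keys_small <= keys_large


def test_scan_rigid_motion_invariant(pattern, planted_scene):
    base = scan_structure(planted_scene, pattern)
    rng = np.random.default_rng(11)
    rot, trans = random_rigid(rng)
    moved = planted_scene.transformed(rot, trans)
    hits = scan_structure(moved, pattern)
    assert len(hits) == len(base) == 1
    assert abs(hits[0].translation_dev - base[0].translation_dev) < 1e-6
    assert abs(hits[0].rotation_dev - base[0].rotation_dev) < 1e-6


def test_pattern_from_reference_recovers_planted_transform(pattern):
    t = pattern.entries[0]
    scene = _planted(t, anchor=5)
    built = pattern_from_reference(scene, c_selector="A:6-7,B:5-7",
                                   nc_selector="C:6-7,D:5-7")
    # the A:6-7 x B segment is unique, likewise on the NC side
    devs = [transform_deviation(e, t) for e in built.entries]
    assert min(dt for dt, _ in devs) < 1e-6
    assert min(dr for _, dr in devs) < 1e-6


def test_pattern_selector_errors(duplex):
    with pytest.raises(SelectionError):
        pattern_from_reference(duplex, "A:1-2", "Q:1-2")
    with pytest.raises(SelectionError):
        pattern_from_reference(duplex, "bogus", "A:1-2")


def test_self_pattern_on_duplex_is_near_pure_twist(duplex):
    built = pattern_from_reference(duplex, "A:1-12,B:1-12", "A:1-12,B:1-12",
                                   translation_tol=4, rotation_tol=25)
    for entry in built.entries:
        axis_angle = np.degrees(np.arccos(np.clip(
            abs(entry.matrix[0, 0]), -1, 1)))
        assert axis_angle < 5.0  # candidate axis stays aligned with reference


def test_pseudoatom_output_roundtrip(tmp_path, pattern, planted_scene):
    hits = scan_structure(planted_scene, pattern)
    path = tmp_path / "hits.pdb"
    write_hits_pseudoatoms(hits, path)
    reloaded = load_structure(path, format="pdb")
    assert len(reloaded.nucleotides) == 2 * len(hits)
    assert all(len(nt.atoms) == 4 for nt in reloaded.nucleotides)
    seg = hits[0].c_segment
    nt = reloaded.nucleotides[0]
    np.testing.assert_allclose(nt.coord("ORI"), seg.origin, atol=1e-3)
    np.testing.assert_allclose(nt.coord("AXI") - nt.coord("ORI"),
                               5.0 * seg.axis, atol=2e-3)


def test_pseudoatom_output_with_no_hits_is_valid_pdb(tmp_path):
    path = tmp_path / "empty.pdb"
    write_hits_pseudoatoms([], path)
    text = path.read_text()
    assert text.startswith("REMARK") and "END" in text


def test_pattern_json_roundtrip(tmp_path, pattern):
    path = tmp_path / "pat.json"
    pattern.to_json(path)
    back = SearchPattern.from_json(path)
    assert back.translation_tol == pattern.translation_tol
    dt, dr = transform_deviation(back.entries[0], pattern.entries[0])
    assert dt < 1e-9 and dr < 1e-9


@pytest.mark.parametrize("n_scenes", [50])
def test_planted_motif_recovery_study(pattern, n_scenes):
    """100% recall on planted scenes under random global poses; zero
    hits when the planted transform deviates by at least twice the
    tolerance in both translation and rotation."""
    rng = np.random.default_rng(20140214)
    t = pattern.entries[0]
    recalled = 0
    for _ in range(n_scenes):
        scene = _planted(t, anchor=int(rng.integers(1, 10)))
        rot, trans = random_rigid(rng)
        hits = scan_structure(scene.transformed(rot, trans), pattern)
        recalled += bool(hits)
    assert recalled == n_scenes

    # negatives: random transforms whose helix-helix angle differs from
    # the pattern's by at least twice the rotation tolerance (modulo the
    # 0/180 flip), which no anchor shift or segment flip can bridge
    angle_pat = interaxis_angle_deg(t)
    false_hits = 0
    made = 0
    while made < n_scenes:
        cand = RelativeTransform(
            rng.uniform(-20, 20, 3),
            Rotation.random(random_state=np.random.RandomState(
                rng.integers(2**31))))
        ang = interaxis_angle_deg(cand)
        gap = min(abs(ang - angle_pat), abs(180 - ang - angle_pat))
        if gap < 2 * pattern.rotation_tol:
            continue
        made += 1
        scene = _planted(cand, anchor=int(rng.integers(1, 10)))
        false_hits += len(scan_structure(scene, pattern))
    assert false_hits == 0
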