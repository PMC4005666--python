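"""Synthetic RNA coordinate scenes for offline testing and calibration.

Real motif searches run on deposited coordinate files; everything in
this module exists so that pair detection, frame construction, scanning
and superposition can be exercised without any download:

* :func:`build_ideal_duplex` stacks idealized Watson-Crick (or wobble)
  base pairs with a fixed rise and twist about the z axis.  Nucleotide
  geometry comes from the chemical component dictionary templates
  shipped with biotite; the two bases of each pair are posed against
  each other by a small deterministic least-squares refinement that
  drives the canonical donor-acceptor distances to standard values.
* :func:`build_two_helix_scene` places a second duplex at a prescribed
  relative transform between chosen helix segments, closing the loop
  between scene construction and the measurement code.

The duplexes are geometrically idealized, not chemically refined: each
residue is internally correct, base pairs and stacking are regular, but
inter-residue backbone connectivity is not energy-minimised.  That is
sufficient (and intended) for validating the geometric search.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

import biotite.structure.info as struc_info

from .pairing import (RelativeTransform, detect_base_pairs,
                      enumerate_helix_segments, relative_transform)
from .structure_io import (BACKBONE_ATOMS, BASE_ATOMS, RING_ATOMS, Atom,
                           Nucleotide, StructureModel)

#: Textbook A-form helical parameters.
A_FORM_RISE = 2.81    # angstrom per base pair
A_FORM_TWIST = 32.7   # degrees per base pair

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Target donor-acceptor distances used when posing the idealized pairs.
#: The G.A entry is the trans sugar(G).Hoogsteen(A) pair of the k-turn
#: core (not detected as WC; used to graft non-canonical pairs).
_HBOND_TARGETS = {
    ("A", "U"): ((("N6", "O4"), 2.95), (("N1", "N3"), 2.82)),
    ("G", "C"): ((("O6", "N4"), 2.91), (("N1", "N3"), 2.95), (("N2", "O2"), 2.86)),
    ("G", "U"): ((("O6", "N3"), 2.83), (("N1", "O2"), 2.79)),
    ("G", "A"): ((("N3", "N6"), 3.00), (("N2", "N7"), 3.05)),
}

#: Canonical WC-edge atoms, used to aim the initial pose.
_EDGE_ATOMS = {"A": ("N6", "N1"), "U": ("O4", "N3"),
               "G": ("O6", "N1", "N2"), "C": ("N4", "N3", "O2")}

#: Per-combo overrides: pairing edges and whether the glycosidic bonds
#: are trans (parallel base normals) rather than cis (antiparallel).
_PAIR_EDGES: dict[tuple[str, str], tuple[tuple[str, ...], tuple[str, ...]]] = {
    ("G", "A"): (("N3", "N2"), ("N6", "N7")),  # sugar edge vs Hoogsteen edge
}
_TRANS_PAIRS = {("G", "A")}


@dataclass
class HelixSpec:
    """One duplex: sequence of strand 1, helical parameters and scene pose."""

    sequence: str
    rise: float = A_FORM_RISE
    twist: float = A_FORM_TWIST
    chain1: str = "A"
    chain2: str = "B"
    strand2: str | None = None   # override auto-complement (e.g. for wobble)
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("T", "U")
        if not self.sequence:
            raise ValueError("helix sequence must be non-empty")
        if any(b not in "ACGU" for b in self.sequence):
            raise ValueError(f"invalid base in sequence {self.sequence!r}")
        if not self.rise > 0:
            raise ValueError("rise must be positive")
        if not 0 < self.twist < 360:
            raise ValueError("twist must be in (0, 360) degrees")
        if self.strand2 is None:
            self.strand2 = "".join(COMPLEMENT[b] for b in reversed(self.sequence))
        if len(self.strand2) != len(self.sequence):
            raise ValueError("strand2 length must match sequence length")


@lru_cache(maxsize=8)
def _template_residue(base: str) -> dict[str, np.ndarray]:
    """Idealized heavy-atom coordinates for one ribonucleotide."""
    arr = struc_info.residue(base)
    wanted = set(BACKBONE_ATOMS) | set(BASE_ATOMS[base])
    coords = {}
    for name, xyz in zip(arr.atom_name, arr.coord):
        if name in wanted:
            coords[name] = np.asarray(xyz, dtype=float)
    missing = wanted - set(coords)
    if missing:  # pragma: no cover - CCD templates are complete
        raise RuntimeError(f"template {base} missing atoms {missing}")
    return coords


def _ring_normal(coords: dict[str, np.ndarray], base: str) -> np.ndarray:
    ring = [coords[a] for a in RING_ATOMS[base]]
    centroid = np.mean(ring, axis=0)
    vec = np.zeros(3)
    for i in range(len(ring)):
        vec += np.cross(ring[i] - centroid, ring[(i + 1) % len(ring)] - centroid)
    return vec / np.linalg.norm(vec)


def _edge_frame(coords: dict[str, np.ndarray], base: str,
                edge_atoms: tuple[str, ...] | None = None):
    """(edge centroid, outward unit vector, in-plane perp, normal)."""
    normal = _ring_normal(coords, base)
    ring_centroid = np.mean([coords[a] for a in RING_ATOMS[base]], axis=0)
    edge = np.mean([coords[a] for a in edge_atoms or _EDGE_ATOMS[base]], axis=0)
    out = edge - ring_centroid
    out -= np.dot(out, normal) * normal
    out /= np.linalg.norm(out)
    perp = np.cross(normal, out)
    return edge, out, perp, normal


@lru_cache(maxsize=16)
def _paired_templates(base1: str, base2: str):
    """Coordinates of an idealized (base1, base2) pair in a common frame.

    base1 keeps its template coordinates; base2 is posed by least squares
    so the canonical hydrogen bonds reach their target lengths with the
    base planes antiparallel and roughly coplanar.
    """
    combo = (base1, base2)
    if combo not in _HBOND_TARGETS:
        if (base2, base1) in _HBOND_TARGETS:
            c2, c1 = _paired_templates(base2, base1)
            return c1, c2
        raise ValueError(f"{base1}-{base2} is not a standard WC/wobble pair")
    t1 = _template_residue(base1)
    t2 = _template_residue(base2)
    edges = _PAIR_EDGES.get(combo, (None, None))
    trans_pair = combo in _TRANS_PAIRS
    e1, u1, v1, n1 = _edge_frame(t1, base1, edges[0])
    e2, u2, v2, n2 = _edge_frame(t2, base2, edges[1])
    # initial guess: face the pairing edges; cis pairs have antiparallel
    # base normals, trans pairs parallel ones
    if trans_pair:
        r_target = np.column_stack([-u1, -v1, n1])
    else:
        r_target = np.column_stack([-u1, v1, -n1])
    r_source = np.column_stack([u2, v2, n2])
    rot0 = r_target @ r_source.T
    shift0 = e1 + 2.9 * u1 - rot0 @ e2

    names2 = sorted(t2)
    base_xyz2 = np.array([t2[a] for a in names2])
    idx2 = {a: i for i, a in enumerate(names2)}
    targets = _HBOND_TARGETS[combo]
    n2_0 = n2

    def residuals(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix() @ rot0
        shift = shift0 + params[3:]
        moved = base_xyz2 @ rot.T + shift
        res = []
        for (a1, a2), target in targets:
            d = np.linalg.norm(t1[a1] - moved[idx2[a2]])
            res.append(3.0 * (d - target))
        sign = -1.0 if trans_pair else 1.0
        res.extend(2.0 * (rot @ n2_0 + sign * n1))       # plane coalignment
        d_c1 = np.linalg.norm(t1["C1'"] - moved[idx2["C1'"]])
        res.append(0.5 * (d_c1 - 10.4))                  # C1'-C1' near canonical
        return np.array(res)

    sol = least_squares(residuals, np.zeros(6), xtol=1e-12, ftol=1e-12)
    rot = Rotation.from_rotvec(sol.x[:3]).as_matrix() @ rot0
    shift = shift0 + sol.x[3:]
    c2 = {a: rot @ xyz + shift for a, xyz in t2.items()}
    return dict(t1), c2


def _pair_in_standard_pose(base1: str, base2: str):
    """Pair templates re-posed so the C1' midpoint is at the origin,
    C1'(1)->C1'(2) lies along +y and the mean base normal along +z."""
    c1, c2 = _paired_templates(base1, base2)
    p1, p2 = c1["C1'"], c2["C1'"]
    mid = 0.5 * (p1 + p2)
    y = p2 - p1
    y /= np.linalg.norm(y)
    sign = 1.0 if {(base1, base2), (base2, base1)} & _TRANS_PAIRS else -1.0
    n = _ring_normal(c1, base1) + sign * _ring_normal(c2, base2)
    n -= np.dot(n, y) * y
    z = n / np.linalg.norm(n)
    x = np.cross(y, z)
    rot = np.column_stack([x, y, z]).T       # world -> standard pose
    out1 = {a: rot @ (xyz - mid) for a, xyz in c1.items()}
    out2 = {a: rot @ (xyz - mid) for a, xyz in c2.items()}
    return out1, out2


def _make_nucleotide(chain: str, number: int, base: str,
                     coords: dict[str, np.ndarray],
                     rotation: np.ndarray, translation: np.ndarray,
                     is_chain_start: bool) -> Nucleotide:
    nt = Nucleotide(chain_id=chain, number=str(number), base=base,
                    resname=base, is_chain_start=is_chain_start)
    for name, xyz in coords.items():
        nt.atoms[name] = Atom(name=name, element=name.strip("'0123456789")[0],
                              position=rotation @ xyz + translation)
    return nt


def build_ideal_duplex(spec: HelixSpec, source_id: str = "fixture-duplex",
                       ) -> StructureModel:
    """Stack idealized base pairs into a regular duplex along +z.

    Pair *i* (0-based) of strand-1 residue ``i+1`` sits at height
    ``i * rise`` rotated by ``i * twist`` about z, with its C1' midpoint
    on the axis.  Strand 2 runs antiparallel; residue *j* of chain 2
    pairs with residue ``n + 1 - j`` of chain 1.  Every nucleotide is
    complete, so any duplex of >= 5 bp is eligible for scanning.
    """
    n = len(spec.sequence)
    strand1: list[Nucleotide] = []
    strand2: list[Nucleotide] = []
    for i, b1 in enumerate(spec.sequence):
        b2 = spec.strand2[n - 1 - i]
        tpl1, tpl2 = _pair_in_standard_pose(b1, b2)
        step = Rotation.from_euler("z", i * spec.twist, degrees=True).as_matrix()
        rot = spec.rotation @ step
        trans = spec.rotation @ np.array([0.0, 0.0, i * spec.rise]) + spec.translation
        strand1.append(_make_nucleotide(spec.chain1, i + 1, b1, tpl1,
                                        rot, trans, i == 0))
        strand2.append(_make_nucleotide(spec.chain2, n - i, b2, tpl2,
                                        rot, trans, i == n - 1))
    model = StructureModel(source_id=source_id)
    model.nucleotides = strand1 + list(reversed(strand2))
    return model


def duplex_segments(model: StructureModel, pairing_cfg=None, stacking_cfg=None):
    """Convenience: detected pairs and helix segments of a model."""
    pairs = detect_base_pairs(model, pairing_cfg)
    return pairs, enumerate_helix_segments(pairs, model, stacking_cfg)


def build_two_helix_scene(spec_a: HelixSpec, spec_b: HelixSpec,
                          transform: RelativeTransform,
                          anchor_a: int = 0, anchor_b: int = 0,
                          source_id: str = "fixture-scene",
                          ) -> tuple[StructureModel, bool]:
    """Two duplexes with a prescribed segment-to-segment relative pose.

    Helix B is rigidly moved so that the relative transform from segment
    ``anchor_a`` of helix A to segment ``anchor_b`` of helix B equals
    ``transform`` (loop closure better than 1e-3 by construction).

    Returns ``(model, clash)`` where ``clash`` flags any inter-helix
    heavy-atom contact below 2.0 angstrom.
    """
    if spec_b.chain1 in (spec_a.chain1, spec_a.chain2):
        spec_b = HelixSpec(spec_b.sequence, spec_b.rise, spec_b.twist,
                           chain1="C", chain2="D", strand2=spec_b.strand2)
    model_a = build_ideal_duplex(spec_a, source_id + "-A")
    model_b0 = build_ideal_duplex(spec_b, source_id + "-B")
    _, segs_a = duplex_segments(model_a)
    _, segs_b = duplex_segments(model_b0)
    if not segs_a or not segs_b:
        raise ValueError("helix too short to define an anchor segment")
    f_a = segs_a[anchor_a]
    f_b0 = segs_b[anchor_b]
    # desired world pose of B's anchor frame
    r_target = f_a.rotation @ transform.matrix
    o_target = f_a.origin + f_a.rotation @ transform.translation
    # rigid motion taking B's current anchor onto the target
    r_move = r_target @ f_b0.rotation.T
    t_move = o_target - r_move @ f_b0.origin
    model_b = model_b0.transformed(r_move, t_move)

    scene = StructureModel(source_id=source_id)
    scene.nucleotides = list(model_a.nucleotides) + list(model_b.nucleotides)

    xyz_a = np.array([a.position for nt in model_a.nucleotides
                      for a in nt.atoms.values()])
    xyz_b = np.array([a.position for nt in model_b.nucleotides
                      for a in nt.atoms.values()])
    from scipy.spatial import cKDTree
    dmin = float(cKDTree(xyz_a).query(xyz_b, k=1)[0].min())
    return scene, dmin < 2.0


def measure_scene_transform(scene: StructureModel, anchor_a: int = 0,
                            anchor_b: int = 0) -> RelativeTransform:
    """Re-measure the A->B anchor transform of a two-helix scene.

    Segments are partitioned into connected helices by chain membership:
    the first two chains are helix A, the rest helix B.
    """
    pairs = detect_base_pairs(scene)
    chains = []
    for nt in scene.nucleotides:
        if nt.chain_id not in chains:
            chains.append(nt.chain_id)
    chains_a = set(chains[:2])
    pairs_a = [p for p in pairs if p.nt1.chain_id in chains_a]
    pairs_b = [p for p in pairs if p.nt1.chain_id not in chains_a]
    segs_a = enumerate_helix_segments(pairs_a, scene)
    segs_b = enumerate_helix_segments(pairs_b, scene)
    return relative_transform(segs_a[anchor_a], segs_b[anchor_b])
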