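"""K-turn / k-junction annotation.

Once the geometric scan has located a candidate motif, this module maps
the structural-role nomenclature onto nucleotides, measures the
canonical core contacts, classifies the structure as N1 or N3, and
superposes motifs onto each other.

Role labels follow the standard k-turn scheme: the bulged strand runs
... -2b, -1b, L1 (L1.1) L2 L3, 1b, 2b, 3b ... and the non-bulged strand
... -2n, -1n | 1n, 2n, 3n ...; "b"/"n" mark the bulged and non-bulged
strands, negative numbers the canonical (C) helix, positive numbers the
non-canonical (NC) helix with its tandem purine-purine pairs at 1b.1n
and 2b.2n, and L the loop.  Roles are assigned by 3D position, not by
primary sequence, so insertions between 1b and 2b (as in the riboswitch
k-junctions) are handled naturally.

The class-defining contact is the -1n O2' hydrogen bond, accepted by
either N1 or N3 of the conserved adenine at 2b; whichever nitrogen is
closer determines the N1/N3 class.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from .pairing import BasePair, base_normal, detect_base_pairs
from .search import MotifHit
from .structure_io import Nucleotide, StructureModel

ROLE_LABELS = ("-2b", "-2n", "-1b", "-1n", "L1", "L1.1", "L2", "L3",
               "1b", "1n", "2b", "2n", "3b", "3n", "5b", "5n")

CORE_ROLES = ("-1n", "L1", "1b", "1n", "2b", "2n")

#: Named backbone atom sets for superposition.
ATOM_SETS = {
    # full backbone plus ribose ring
    "backbone": ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'",
                 "C2'", "C1'", "O4'"),
    # phosphate + sugar trace only
    "trace": ("P", "O5'", "C5'", "C4'", "C3'", "O3'"),
}

#: The standard contact set measured for every annotated k-turn.
#: (label, donor role, donor atom, acceptor role, acceptor atom)
STANDARD_CONTACTS = (
    ("L1 O2' - 1n N1", "L1", "O2'", "1n", "N1"),
    ("L1 O2' - 1n N3", "L1", "O2'", "1n", "N3"),
    ("-1n O2' - 2b N1", "-1n", "O2'", "2b", "N1"),
    ("-1n O2' - 2b N3", "-1n", "O2'", "2b", "N3"),
    ("2b N6 - 2n N3", "2b", "N6", "2n", "N3"),
    ("2b N6 - 2n N7", "2b", "N6", "2n", "N7"),
    ("-2n O2' - 3b O2'", "-2n", "O2'", "3b", "O2'"),
    ("L3 O2' - L2 proS-OP", "L3", "O2'", "L2", "OP2"),
)

HBOND_BONDED_MAX = 3.5      # heavy-atom distance labelled "bonded"
HBOND_BORDERLINE_MAX = 4.0  # ... and "borderline" up to here


class AssignmentError(ValueError):
    """Role assignment failed; the message lists candidates considered."""


class MissingAtomError(KeyError):
    """A contact endpoint does not exist in the assigned nucleotide."""


@dataclass
class KTurnAssignment:
    """Mapping of structural roles to nucleotides."""

    roles: dict[str, Nucleotide]
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [nt.key for nt in self.roles.values()]
        if len(set(keys)) != len(keys):
            raise ValueError("role map is not injective")

    @property
    def complete_core(self) -> bool:
        return all(r in self.roles for r in CORE_ROLES)

    def to_dict(self) -> dict:
        return {role: f"{nt.chain_id}:{nt.number}:{nt.base}"
                for role, nt in self.roles.items()}


@dataclass
class ContactReport:
    """Measured core contacts plus the N1/N3 classification."""

    contacts: list[tuple[str, float | None, str]]  # (label, distance, status)
    n_class: str  # "N1", "N3" or "undetermined"
    diagnostics: list[str] = field(default_factory=list)

    def distance(self, label: str) -> float | None:
        for lab, d, _ in self.contacts:
            if lab == label:
                return d
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "n_class": self.n_class,
            "contacts": [
                {"label": lab,
                 "distance_A": None if d is None else round(d, 1),
                 "status": status}
                for lab, d, status in self.contacts],
            "diagnostics": self.diagnostics,
        }


def _purine_purine_pairs(model: StructureModel,
                         wc_pairs: list[BasePair]) -> list[tuple[Nucleotide, Nucleotide]]:
    """Candidate non-WC purine-purine pairs (e.g. trans sugar/Hoogsteen G.A).

    Loose geometric criteria: both purines, C1'-C1' within 8.5-13.0 A,
    at least one base-base N/O contact <= 3.5 A, roughly parallel planes.
    """
    paired = {nt.key for p in wc_pairs for nt in p.nucleotides()}
    purines = [nt for nt in model.rna if nt.base in "AG"
               and "C1'" in nt.atoms]
    edge_atoms = {"A": ("N1", "N3", "N6", "N7"), "G": ("N1", "N2", "N3", "O6", "N7")}
    found = []
    for i in range(len(purines)):
        for j in range(i + 1, len(purines)):
            a, b = purines[i], purines[j]
            if a.key in paired and b.key in paired:
                continue
            d = np.linalg.norm(a.coord("C1'") - b.coord("C1'"))
            if not 8.5 <= d <= 13.0:
                continue
            try:
                contacts = [
                    (x, y)
                    for x in edge_atoms[a.base] for y in edge_atoms[b.base]
                    if np.linalg.norm(a.coord(x) - b.coord(y)) <= 3.5
                ]
                if not contacts:
                    continue
                ang = np.degrees(np.arccos(np.clip(
                    abs(float(np.dot(base_normal(a), base_normal(b)))), -1, 1)))
            except KeyError:
                continue
            if ang > 65.0:
                continue
            found.append((a, b))
    return found


def _seq_index(model: StructureModel, nt: Nucleotide) -> int:
    for i, other in enumerate(model.nucleotides):
        if other.key == nt.key:
            return i
    raise KeyError(nt.key)


def _neighbor(model: StructureModel, nt: Nucleotide, offset: int) -> Nucleotide | None:
    idx = _seq_index(model, nt) + offset
    if 0 <= idx < len(model.nucleotides):
        cand = model.nucleotides[idx]
        if cand.chain_id == nt.chain_id:
            return cand
    return None


def assign_roles(model: StructureModel, hit: MotifHit,
                 override: dict[str, tuple[str, str]] | None = None,
                 ) -> KTurnAssignment:
    """Assign k-turn role labels to the nucleotides around a motif hit.

    Heuristic: the tandem non-WC purine-purine pairs stacked at the end
    of the NC segment facing the C segment become 1b.1n and 2b.2n (1
    being nearer the strand exchange); the C-helix pair closest to the
    kink becomes -1b/-1n, the next -2b/-2n; loop nucleotides are the
    bulged-strand residues between -1b and 1b, labelled L1.. by their
    position (L1 over the C-helix end, L2 stacked on the NC helix, L3
    solvent-directed).  An explicit ``override`` map of
    role -> (chain, number) wins over the heuristic.
    """
    if override:
        roles = {}
        for role, (chain, number) in override.items():
            if role not in ROLE_LABELS:
                raise ValueError(f"unknown role label {role!r}")
            roles[role] = model.get(chain, number)
        return KTurnAssignment(roles, notes=["roles from explicit override"])

    wc_pairs = detect_base_pairs(model)
    candidates = _purine_purine_pairs(model, wc_pairs)
    nc_keys = hit.nc_segment.nucleotide_keys()
    c_origin = hit.c_segment.origin

    def dist_to_c(pair: tuple[Nucleotide, Nucleotide]) -> float:
        mid = 0.5 * (pair[0].coord("C1'") + pair[1].coord("C1'"))
        return float(np.linalg.norm(mid - c_origin))

    near = [p for p in candidates
            if min(np.linalg.norm(p[0].coord("C1'") - model.get(*k).coord("C1'"))
                   for k in nc_keys) < 14.0]
    if not near:
        considered = [f"{a.chain_id}{a.number}{a.base}.{b.chain_id}{b.number}{b.base}"
                      for a, b in candidates] or ["none"]
        raise AssignmentError(
            "no non-WC purine-purine pair found near the NC segment; "
            f"candidates considered: {', '.join(considered)}")
    near.sort(key=dist_to_c)
    pair1 = near[0]                     # closest to the strand exchange: 1b.1n
    pair2 = near[1] if len(near) > 1 else None

    # -1b/-1n: C-helix WC pair nearest the kink
    c_keys = hit.c_segment.nucleotide_keys()
    c_pairs = [p for p in wc_pairs
               if p.nt1.key in c_keys and p.nt2.key in c_keys]
    mid1 = 0.5 * (pair1[0].coord("C1'") + pair1[1].coord("C1'"))
    c_pairs.sort(key=lambda p: float(np.linalg.norm(p.origin - mid1)))
    if not c_pairs:
        raise AssignmentError("C segment contributes no Watson-Crick pair")
    m1 = c_pairs[0]
    m2 = c_pairs[1] if len(c_pairs) > 1 else None

    # orient 1b vs 1n: 1n lies on the strand that continues from the C helix
    def strand_links_c(nt: Nucleotide) -> bool:
        for off in (-2, -1, 1, 2):
            nb = _neighbor(model, nt, off)
            if nb is not None and nb.key in c_keys:
                return True
        return False

    a, b = pair1
    nt_1n, nt_1b = (a, b) if strand_links_c(a) else (b, a)
    roles: dict[str, Nucleotide] = {"1b": nt_1b, "1n": nt_1n}
    notes = []
    if pair2 is not None:
        a2, b2 = pair2
        # 2b continues the bulged strand of 1b
        if a2.chain_id == nt_1b.chain_id and b2.chain_id != nt_1b.chain_id:
            roles["2b"], roles["2n"] = a2, b2
        elif b2.chain_id == nt_1b.chain_id and a2.chain_id != nt_1b.chain_id:
            roles["2b"], roles["2n"] = b2, a2
        else:
            d_a2 = np.linalg.norm(a2.coord("C1'") - nt_1b.coord("C1'"))
            d_b2 = np.linalg.norm(b2.coord("C1'") - nt_1b.coord("C1'"))
            roles["2b"], roles["2n"] = (a2, b2) if d_a2 <= d_b2 else (b2, a2)
    else:
        notes.append("single purine-purine pair: 2b/2n unassigned")

    # C-helix: -1n shares the strand of 1n
    if m1.nt1.chain_id == nt_1n.chain_id:
        roles["-1n"], roles["-1b"] = m1.nt1, m1.nt2
    else:
        roles["-1n"], roles["-1b"] = m1.nt2, m1.nt1
    if m2 is not None:
        if m2.nt1.chain_id == roles["-1n"].chain_id:
            roles["-2n"], roles["-2b"] = m2.nt1, m2.nt2
        else:
            roles["-2n"], roles["-2b"] = m2.nt2, m2.nt1

    # loop: bulged-strand residues between -1b and 1b in file order
    i_b = _seq_index(model, nt_1b)
    i_mb = _seq_index(model, roles["-1b"])
    if roles["-1b"].chain_id == nt_1b.chain_id and 0 < i_b - i_mb <= 6:
        loop = model.nucleotides[i_mb + 1:i_b]
        labels = {3: ("L1", "L2", "L3"), 4: ("L1", "L1.1", "L2", "L3")}
        if len(loop) in labels:
            for lab, nt in zip(labels[len(loop)], loop):
                roles[lab] = nt
        else:
            notes.append(f"loop of {len(loop)} nt left unlabelled")
    else:
        notes.append("loop not identified from sequence context")

    return KTurnAssignment(roles, notes)


def measure_contact(model: StructureModel, assignment: KTurnAssignment,
                    donor: tuple[str, str], acceptor: tuple[str, str]) -> float:
    """Heavy-atom distance between two role/atom endpoints, in angstrom."""
    out = []
    for role, atom in (donor, acceptor):
        if role not in assignment.roles:
            raise MissingAtomError(f"role {role!r} not assigned")
        nt = assignment.roles[role]
        if atom not in nt.atoms:
            raise MissingAtomError(
                f"atom {atom!r} missing from role {role} "
                f"({nt.chain_id}{nt.number} {nt.resname})")
        out.append(nt.coord(atom))
    return float(np.linalg.norm(out[0] - out[1]))


def _status(d: float) -> str:
    if d <= HBOND_BONDED_MAX:
        return "bonded"
    if d <= HBOND_BORDERLINE_MAX:
        return "borderline"
    return "apart"


def classify_n_class(model: StructureModel,
                     assignment: KTurnAssignment) -> ContactReport:
    """Measure the standard contact table and decide the N1/N3 class.

    The class is set by whichever of 2b N1 / 2b N3 lies nearer the -1n
    O2' donor; it is undetermined when those atoms are not measurable.
    Every standard contact label appears in the report, flagged
    "missing" rather than silently dropped when atoms are absent.
    """
    contacts: list[tuple[str, float | None, str]] = []
    diagnostics: list[str] = []
    for label, r1, a1, r2, a2 in STANDARD_CONTACTS:
        try:
            d = measure_contact(model, assignment, (r1, a1), (r2, a2))
            contacts.append((label, d, _status(d)))
        except MissingAtomError as exc:
            contacts.append((label, None, "missing"))
            diagnostics.append(str(exc))
    by_label = {lab: d for lab, d, _ in contacts}
    d_n1 = by_label.get("-1n O2' - 2b N1")
    d_n3 = by_label.get("-1n O2' - 2b N3")
    if d_n1 is None or d_n3 is None:
        n_class = "undetermined"
        diagnostics.append("-1n O2' to 2b N1/N3 not measurable")
    else:
        n_class = "N1" if d_n1 <= d_n3 else "N3"
    return ContactReport(contacts, n_class, diagnostics)


def superpose_roles(mobile: StructureModel, mobile_assignment: KTurnAssignment,
                    reference: StructureModel,
                    reference_assignment: KTurnAssignment,
                    roles: tuple[str, ...] = ("-1n", "L1", "2b", "1n", "2n"),
                    atom_set: str = "backbone",
                    ) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition over matched role atoms.

    Returns ``(rmsd, rotation, translation)`` where the transform maps
    mobile coordinates onto the reference (Kabsch; proper rotation).
    Only atoms present in both structures for a requested role are used;
    fewer than three matched atoms is an error.
    """
    atoms = ATOM_SETS[atom_set] if isinstance(atom_set, str) else tuple(atom_set)
    xyz_m, xyz_r = [], []
    for role in roles:
        if role not in mobile_assignment.roles or role not in reference_assignment.roles:
            raise MissingAtomError(f"role {role!r} not assigned in both structures")
        nt_m = mobile_assignment.roles[role]
        nt_r = reference_assignment.roles[role]
        for atom in atoms:
            if atom in nt_m.atoms and atom in nt_r.atoms:
                xyz_m.append(nt_m.coord(atom))
                xyz_r.append(nt_r.coord(atom))
    if len(xyz_m) < 3:
        raise ValueError(
            f"only {len(xyz_m)} matched atoms; superposition underdetermined")
    xyz_m = np.array(xyz_m)
    xyz_r = np.array(xyz_r)
    cm, cr = xyz_m.mean(axis=0), xyz_r.mean(axis=0)
    # Kabsch: SVD of the covariance, sign-corrected to a proper rotation
    h = (xyz_m - cm).T @ (xyz_r - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rmat = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = cr - rmat @ cm
    moved = (xyz_m - cm) @ rmat.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((moved - xyz_r) ** 2, axis=1))))
    return rmsd, rmat, translation
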