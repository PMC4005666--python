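"""Base-pair detection, minimal helix segments and their coordinate frames.

The motif search abstracts double-helical RNA to rigid frames: every
stacked pair of Watson-Crick (or G.U wobble) base pairs becomes a
*helix segment* carrying an origin (the C1'-C1' midpoint of its first
pair) and a right-handed orthonormal triad

* ``axis``      - from the first pair's C1' midpoint to the second's,
* ``hbond_dir`` - the first pair's C1'(strand1) -> C1'(strand2) vector
  projected onto the plane perpendicular to the axis,
* ``normal``    - ``axis x hbond_dir``.

Relative position and orientation of one segment expressed in the frame
of another is the quantity the k-turn search pattern is built from; it
is invariant under any global rigid motion of the structure.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .config import PairingConfig, StackingConfig
from .structure_io import RING_ATOMS, Nucleotide, StructureModel

#: Canonical donor-acceptor atom pairs per base combination (first base,
#: second base).  G.U lists exactly the two wobble hydrogen bonds.
WC_HBOND_ATOMS: dict[tuple[str, str], tuple[tuple[str, str], ...]] = {
    ("A", "U"): (("N6", "O4"), ("N1", "N3")),
    ("G", "C"): (("O6", "N4"), ("N1", "N3"), ("N2", "O2")),
    ("G", "U"): (("O6", "N3"), ("N1", "O2")),
}
for (_b1, _b2), _atoms in list(WC_HBOND_ATOMS.items()):
    WC_HBOND_ATOMS[(_b2, _b1)] = tuple((a2, a1) for a1, a2 in _atoms)


class DegenerateFrameError(ValueError):
    """Segment geometry too degenerate to define an orthonormal triad."""


def base_normal(nt: Nucleotide) -> np.ndarray:
    """Unit normal of the base plane, signed by the ring's cyclic atom order."""
    ring = RING_ATOMS[nt.base]
    pts = np.array([nt.coord(a) for a in ring])
    centroid = pts.mean(axis=0)
    # polygon area vector: orientation follows the fixed ring ordering
    vec = np.zeros(3)
    for i in range(len(pts)):
        vec += np.cross(pts[i] - centroid, pts[(i + 1) % len(pts)] - centroid)
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        raise DegenerateFrameError(f"degenerate base plane in {nt!r}")
    return vec / norm


@dataclass
class BasePair:
    """A detected Watson-Crick or wobble pair; nt1 precedes nt2 canonically."""

    nt1: Nucleotide
    nt2: Nucleotide
    kind: str  # "WC" or "wobble"
    hbonds: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self._order_key(self.nt2) < self._order_key(self.nt1):
            self.nt1, self.nt2 = self.nt2, self.nt1
            self.hbonds = [(a2, a1, d) for a1, a2, d in self.hbonds]

    @staticmethod
    def _order_key(nt: Nucleotide) -> tuple:
        num = nt.number
        icode = ""
        if num and num[-1].isalpha():
            num, icode = num[:-1], num[-1]
        return (nt.chain_id, int(num), icode)

    @property
    def key(self) -> tuple:
        return (self.nt1.key, self.nt2.key)

    @property
    def sort_key(self) -> tuple:
        return (self._order_key(self.nt1), self._order_key(self.nt2))

    @property
    def origin(self) -> np.ndarray:
        """Midpoint of the two C1' atoms."""
        return 0.5 * (self.nt1.coord("C1'") + self.nt2.coord("C1'"))

    @property
    def c1_vector(self) -> np.ndarray:
        """C1'(nt1) -> C1'(nt2)."""
        return self.nt2.coord("C1'") - self.nt1.coord("C1'")

    @property
    def score(self) -> float:
        """Summed hydrogen-bond quality (larger = better)."""
        return sum(max(0.0, 3.5 - d) for *_ , d in self.hbonds)

    def nucleotides(self) -> tuple[Nucleotide, Nucleotide]:
        return (self.nt1, self.nt2)


def _candidate_pair(nt1: Nucleotide, nt2: Nucleotide,
                    cfg: PairingConfig) -> BasePair | None:
    combo = (nt1.base, nt2.base)
    atoms = WC_HBOND_ATOMS.get(combo)
    if atoms is None:
        return None
    try:
        d_c1 = float(np.linalg.norm(nt1.coord("C1'") - nt2.coord("C1'")))
    except KeyError:
        return None
    if not cfg.c1_c1_min <= d_c1 <= cfg.c1_c1_max:
        return None
    hbonds = []
    try:
        for a1, a2 in atoms:
            d = float(np.linalg.norm(nt1.coord(a1) - nt2.coord(a2)))
            if cfg.hbond_min <= d <= cfg.hbond_max:
                hbonds.append((a1, a2, d))
        n1, n2 = base_normal(nt1), base_normal(nt2)
    except (KeyError, DegenerateFrameError):
        return None
    needed = len(atoms) if combo in (("G", "U"), ("U", "G")) else cfg.min_hbonds
    if len(hbonds) < needed:
        return None
    cosang = abs(float(np.dot(n1, n2)))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if angle > cfg.normal_angle_max:
        return None
    kind = "wobble" if combo in (("G", "U"), ("U", "G")) else "WC"
    return BasePair(nt1, nt2, kind, hbonds)


def detect_base_pairs(model: StructureModel,
                      config: PairingConfig | None = None) -> list[BasePair]:
    """Find all standard Watson-Crick pairs plus the G.U wobble pair.

    Candidates must be complementary, have a C1'-C1' separation in the
    configured window, at least two canonical donor-acceptor contacts
    within the hydrogen-bond cutoff (both wobble contacts for G.U), and
    near-parallel base planes.  Conflicts are resolved greedily by
    hydrogen-bond score so each nucleotide joins at most one pair.
    """
    cfg = config or PairingConfig()
    nts = model.rna
    coords = []
    for nt in nts:
        try:
            coords.append(nt.coord("C1'"))
        except KeyError:
            coords.append(None)
    candidates: list[BasePair] = []
    for i in range(len(nts)):
        if coords[i] is None:
            continue
        for j in range(i + 1, len(nts)):
            if coords[j] is None:
                continue
            # cheap distance prefilter before full geometric checks
            if abs(coords[i][0] - coords[j][0]) > cfg.c1_c1_max:
                continue
            pair = _candidate_pair(nts[i], nts[j], cfg)
            if pair is not None:
                candidates.append(pair)
    candidates.sort(key=lambda p: (-p.score, p.sort_key))
    used: set[tuple[str, str]] = set()
    accepted = []
    for pair in candidates:
        if pair.nt1.key in used or pair.nt2.key in used:
            continue
        used.update((pair.nt1.key, pair.nt2.key))
        accepted.append(pair)
    accepted.sort(key=lambda p: p.sort_key)
    return accepted


@dataclass
class HelixSegmentFrame:
    """Two stacked base pairs abstracted to an origin plus orthonormal triad."""

    pair1: BasePair
    pair2: BasePair
    origin: np.ndarray
    axis: np.ndarray
    hbond_dir: np.ndarray
    normal: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with columns (axis, hbond_dir, normal)."""
        return np.column_stack([self.axis, self.hbond_dir, self.normal])

    @property
    def key(self) -> tuple:
        return (self.pair1.key, self.pair2.key)

    def nucleotide_keys(self) -> frozenset:
        return frozenset(nt.key for pair in (self.pair1, self.pair2)
                         for nt in pair.nucleotides())

    def flipped(self) -> "HelixSegmentFrame":
        """The same physical segment read in the opposite direction."""
        return frame_from_segment(self.pair2, self.pair1)


def frame_from_segment(pair1: BasePair, pair2: BasePair) -> HelixSegmentFrame:
    """Build the four-vector frame anchored on ``pair1``.

    Raises :class:`DegenerateFrameError` when the two pair origins are
    nearly coincident or the C1'-C1' vector is parallel to the axis.
    """
    origin = pair1.origin
    axis_raw = pair2.origin - origin
    length = float(np.linalg.norm(axis_raw))
    if length < 0.5:
        raise DegenerateFrameError(
            f"pair origins {length:.2f} A apart; axis undefined")
    axis = axis_raw / length
    c1 = pair1.c1_vector
    proj = c1 - np.dot(c1, axis) * axis
    pnorm = float(np.linalg.norm(proj))
    if pnorm < np.linalg.norm(c1) * np.sin(np.radians(1.0)):
        raise DegenerateFrameError("C1'-C1' vector parallel to helix axis")
    hbond_dir = proj / pnorm
    normal = np.cross(axis, hbond_dir)
    normal /= np.linalg.norm(normal)
    # re-orthogonalise to guard against accumulated rounding
    hbond_dir = np.cross(normal, axis)
    hbond_dir /= np.linalg.norm(hbond_dir)
    return HelixSegmentFrame(pair1, pair2, origin, axis, hbond_dir, normal)


def _pair_twist(p1: BasePair, p2: BasePair, axis: np.ndarray) -> float:
    """Angle between the two C1'-C1' vectors projected perpendicular to axis."""
    def proj(v: np.ndarray) -> np.ndarray:
        w = v - np.dot(v, axis) * axis
        n = np.linalg.norm(w)
        if n < 1e-9:
            raise DegenerateFrameError("pair vector parallel to axis")
        return w / n
    u1, u2 = proj(p1.c1_vector), proj(p2.c1_vector)
    cosang = np.clip(np.dot(u1, u2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def enumerate_helix_segments(pairs: list[BasePair],
                             model: StructureModel | None = None,
                             config: StackingConfig | None = None,
                             ) -> list[HelixSegmentFrame]:
    """All stacked two-pair segments, in canonical order.

    Two pairs stack when their C1'-midpoints are within the separation
    cutoff and the inter-pair twist lies inside the configured window.
    Pairs need not be sequence-adjacent, so stacking across a strand
    exchange (as at a junction) is allowed.  One canonical orientation
    per segment is returned; the scan flips candidates as needed.
    """
    cfg = config or StackingConfig()
    segments: list[HelixSegmentFrame] = []
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            p1, p2 = pairs[i], pairs[j]
            sep = np.linalg.norm(p2.origin - p1.origin)
            if not 1e-6 < sep <= cfg.max_pair_separation:
                continue
            axis = (p2.origin - p1.origin) / sep
            try:
                # accept either strand correspondence: antiparallel pairs may
                # list strands in swapped order across a strand exchange
                twist = _pair_twist(p1, p2, axis)
                twist = min(twist, 180.0 - twist)
                if not cfg.twist_min <= twist <= cfg.twist_max:
                    continue
                segments.append(frame_from_segment(p1, p2))
            except DegenerateFrameError:
                continue
    segments.sort(key=lambda s: (s.pair1.sort_key, s.pair2.sort_key))
    return segments


@dataclass
class RelativeTransform:
    """Pose of one segment frame expressed in another's coordinates."""

    translation: np.ndarray      # (3,) in reference-frame coordinates, angstrom
    rotation: Rotation           # maps reference triad onto candidate triad

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, float)
        if not isinstance(self.rotation, Rotation):
            self.rotation = Rotation.from_matrix(np.asarray(self.rotation, float))

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    def compose(self, other: "RelativeTransform") -> "RelativeTransform":
        """self followed by other (frame composition)."""
        return RelativeTransform(
            self.translation + self.matrix @ other.translation,
            self.rotation * other.rotation,
        )

    def inverse(self) -> "RelativeTransform":
        inv = self.rotation.inv()
        return RelativeTransform(-(inv.as_matrix() @ self.translation), inv)

    def rotation_angle_deg(self) -> float:
        return float(np.degrees(self.rotation.magnitude()))

    def to_dict(self) -> dict:
        return {"translation": self.translation.tolist(),
                "quaternion_xyzw": self.rotation.as_quat().tolist()}

    @classmethod
    def from_dict(cls, raw: dict) -> "RelativeTransform":
        if "quaternion_xyzw" in raw:
            rot = Rotation.from_quat(raw["quaternion_xyzw"])
        elif "rotvec_deg" in raw:
            rot = Rotation.from_rotvec(np.asarray(raw["rotvec_deg"], float),
                                       degrees=True)
        else:
            rot = Rotation.from_matrix(np.asarray(raw["rotation"], float))
        return cls(np.asarray(raw["translation"], float), rot)


def relative_transform(reference: HelixSegmentFrame,
                       candidate: HelixSegmentFrame) -> RelativeTransform:
    """Candidate pose in the reference frame; rigid-motion invariant."""
    r_ref = reference.rotation
    translation = r_ref.T @ (candidate.origin - reference.origin)
    rotation = Rotation.from_matrix(r_ref.T @ candidate.rotation)
    return RelativeTransform(translation, rotation)


def pairs_to_table(pairs: list[BasePair]):
    """Pair list as a pandas DataFrame (for CSV export)."""
    import pandas as pd

    rows = []
    for p in pairs:
        rows.append({
            "chain1": p.nt1.chain_id, "number1": p.nt1.number, "base1": p.nt1.base,
            "chain2": p.nt2.chain_id, "number2": p.nt2.number, "base2": p.nt2.base,
            "kind": p.kind,
            "n_hbonds": len(p.hbonds),
            "min_hbond_A": round(min(d for *_, d in p.hbonds), 3),
        })
    return pd.DataFrame(rows)
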