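"""K-turn motif search: pattern definition and structure scanning.

A search pattern is one or more reference relative transforms (the pose
of a non-canonical-helix segment expressed in the frame of a
canonical-helix segment) plus tolerances.  Scanning a structure tests
every ordered pair of helix segments, in all four relative strand
orientations, against every pattern entry; a segment pair is a hit when
its translation deviates by no more than the translation tolerance
(Euclidean, in the reference frame) and its rotation by no more than
the rotation tolerance (angle of the composed rotation).

Overlapping raw matches are merged into one reported hit per contiguous
region (segments sharing a base pair on both the reference and the
candidate side are considered the same physical match), keeping the
orientation with the smallest combined deviation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .config import SearchConfig, StackingConfig
from .pairing import (BasePair, HelixSegmentFrame, RelativeTransform,
                      detect_base_pairs, enumerate_helix_segments,
                      relative_transform)
from .structure_io import StructureModel, write_pdb, Nucleotide, Atom


class SelectionError(ValueError):
    """A residue-range selector resolved to no helix segment."""


@dataclass
class SearchPattern:
    """Reference relative transform(s) with matching tolerances."""

    entries: list[RelativeTransform]
    translation_tol: float = 4.0   # angstrom
    rotation_tol: float = 25.0     # degrees
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("pattern needs at least one entry")
        if self.translation_tol <= 0 or self.rotation_tol <= 0:
            raise ValueError("tolerances must be positive")

    def with_tolerances(self, translation_tol: float | None = None,
                        rotation_tol: float | None = None) -> "SearchPattern":
        return SearchPattern(
            self.entries,
            translation_tol if translation_tol is not None else self.translation_tol,
            rotation_tol if rotation_tol is not None else self.rotation_tol,
            list(self.provenance),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "translation_tol": self.translation_tol,
            "rotation_tol": self.rotation_tol,
            "provenance": self.provenance,
            "entries": [e.to_dict() for e in self.entries],
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SearchPattern":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_dict(cls, raw: dict) -> "SearchPattern":
        return cls(
            entries=[RelativeTransform.from_dict(e) for e in raw["entries"]],
            translation_tol=raw.get("translation_tol", 4.0),
            rotation_tol=raw.get("rotation_tol", 25.0),
            provenance=raw.get("provenance", []),
        )


def default_pattern() -> SearchPattern:
    """The pattern shipped with the package.

    Derived from a synthetic canonical k-turn geometry (ideal
    coordinates, see the packaged JSON's provenance field), so scanning
    works offline; patterns from real reference structures can be built
    with :func:`pattern_from_reference`.
    """
    ref = resources.files("kjunction.data").joinpath(
        "kturn_pattern_synthetic.json")
    return SearchPattern.from_dict(json.loads(ref.read_text()))


def parse_selector(selector: str) -> list[tuple[str, int, int]]:
    """Parse 'CHAIN:START-END[,CHAIN:START-END...]' (author numbering,
    inclusive).  A segment matches when every one of its nucleotides
    falls inside one of the listed ranges."""
    ranges = []
    for part in selector.split(","):
        chain, _, span = part.strip().partition(":")
        lo, _, hi = span.partition("-")
        try:
            ranges.append((chain, int(lo), int(hi or lo)))
        except ValueError:
            raise SelectionError(f"bad selector {part!r}") from None
    return ranges


def _segment_in_selection(seg: HelixSegmentFrame,
                          ranges: list[tuple[str, int, int]]) -> bool:
    for key_chain, number in seg.nucleotide_keys():
        num = int(number[:-1]) if number[-1].isalpha() else int(number)
        if not any(key_chain == chain and lo <= num <= hi
                   for chain, lo, hi in ranges):
            return False
    return True


def pattern_from_reference(model: StructureModel, c_selector: str,
                           nc_selector: str,
                           translation_tol: float = 4.0,
                           rotation_tol: float = 25.0,
                           stacking: StackingConfig | None = None,
                           ) -> SearchPattern:
    """Record the C->NC segment transforms of a known k-turn structure.

    One entry is produced per (C segment, NC segment) combination that
    resolves inside the two residue-range selectors.
    """
    pairs = detect_base_pairs(model)
    segments = enumerate_helix_segments(pairs, model, stacking)
    c_sel = parse_selector(c_selector)
    nc_sel = parse_selector(nc_selector)
    c_segs = [s for s in segments if _segment_in_selection(s, c_sel)]
    nc_segs = [s for s in segments if _segment_in_selection(s, nc_sel)]
    if not c_segs:
        raise SelectionError(f"no helix segment inside {c_selector!r}")
    if not nc_segs:
        raise SelectionError(f"no helix segment inside {nc_selector!r}")
    entries = []
    provenance = []
    for cs in c_segs:
        for ns in nc_segs:
            if cs.key == ns.key:
                continue
            entries.append(relative_transform(cs, ns))
            provenance.append(
                f"{model.source_id}: C={cs.key} NC={ns.key}")
    if not entries:
        raise SelectionError("selectors resolve to a single shared segment")
    return SearchPattern(entries, translation_tol, rotation_tol, provenance)


@dataclass
class MotifHit:
    """A segment pair matching the pattern geometry."""

    c_segment: HelixSegmentFrame
    nc_segment: HelixSegmentFrame
    observed: RelativeTransform
    translation_dev: float
    rotation_dev: float
    matched_entry: int

    @property
    def combined_dev(self) -> float:
        return self.translation_dev + self.rotation_dev / 10.0

    def normalized_dev(self, pattern: SearchPattern) -> float:
        return max(self.translation_dev / pattern.translation_tol,
                   self.rotation_dev / pattern.rotation_tol)


def interaxis_angle_deg(t: RelativeTransform) -> float:
    """Angle between the reference helix axis and the candidate helix
    axis implied by a transform, in degrees.

    Re-anchoring a segment one base-pair step along its helix is a screw
    motion about that helix's axis, so this angle (modulo the 0/180
    flip ambiguity) is invariant across all segment-pair combinations
    between the same two helices - a useful ground truth for scan tests.
    """
    v = t.matrix @ np.array([1.0, 0.0, 0.0])
    return float(np.degrees(np.arccos(np.clip(v[0], -1.0, 1.0))))


def transform_deviation(observed: RelativeTransform,
                        entry: RelativeTransform) -> tuple[float, float]:
    """(translation deviation in angstrom, rotation deviation in degrees)."""
    dt = float(np.linalg.norm(observed.translation - entry.translation))
    dr = float(np.degrees((observed.rotation * entry.rotation.inv()).magnitude()))
    return dt, dr


def _raw_matches(segments: list[HelixSegmentFrame], pattern: SearchPattern,
                 ) -> list[MotifHit]:
    flips: dict[tuple, HelixSegmentFrame] = {}

    def oriented(seg: HelixSegmentFrame) -> list[HelixSegmentFrame]:
        if seg.key not in flips:
            flips[seg.key] = seg.flipped()
        return [seg, flips[seg.key]]

    hits = []
    for i, s1 in enumerate(segments):
        for j, s2 in enumerate(segments):
            if i == j or s1.nucleotide_keys() & s2.nucleotide_keys():
                continue
            best = None
            for c_seg in oriented(s1):
                for nc_seg in oriented(s2):
                    observed = relative_transform(c_seg, nc_seg)
                    for k, entry in enumerate(pattern.entries):
                        dt, dr = transform_deviation(observed, entry)
                        if (dt <= pattern.translation_tol
                                and dr <= pattern.rotation_tol):
                            hit = MotifHit(c_seg, nc_seg, observed, dt, dr, k)
                            if best is None or hit.combined_dev < best.combined_dev:
                                best = hit
            if best is not None:
                hits.append(best)
    return hits


def _pair_keys(seg: HelixSegmentFrame) -> frozenset:
    return frozenset((seg.pair1.key, seg.pair2.key))


def scan_structure(model: StructureModel, pattern: SearchPattern,
                   stacking: StackingConfig | None = None,
                   pairing=None, dedupe: bool = True) -> list[MotifHit]:
    """Scan all helix-segment pairs of a model against a pattern.

    Raw matches whose segments share base pairs on both sides are merged
    (union-find) into one hit, keeping the representative with minimal
    combined deviation; hits are returned ordered by deviation.
    """
    pairs = detect_base_pairs(model, pairing)
    segments = enumerate_helix_segments(pairs, model, stacking)
    hits = _raw_matches(segments, pattern)
    if not dedupe:
        return sorted(hits, key=lambda h: h.combined_dev)

    parent = list(range(len(hits)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(hits)):
        for b in range(a + 1, len(hits)):
            ha, hb = hits[a], hits[b]
            if (_pair_keys(ha.c_segment) & _pair_keys(hb.c_segment)
                    and _pair_keys(ha.nc_segment) & _pair_keys(hb.nc_segment)):
                parent[find(a)] = find(b)
    clusters: dict[int, MotifHit] = {}
    for idx, hit in enumerate(hits):
        root = find(idx)
        if root not in clusters or hit.combined_dev < clusters[root].combined_dev:
            clusters[root] = hit
    return sorted(clusters.values(), key=lambda h: h.combined_dev)


def hits_to_table(hits: list[MotifHit]):
    """Hit list as a pandas DataFrame for CSV export."""
    import pandas as pd

    rows = []
    for i, h in enumerate(hits):
        def span(seg: HelixSegmentFrame) -> str:
            keys = sorted(seg.nucleotide_keys())
            return "+".join(f"{c}{n}" for c, n in keys)
        rows.append({
            "hit": i,
            "c_segment": span(h.c_segment),
            "nc_segment": span(h.nc_segment),
            "translation_dev_A": round(h.translation_dev, 3),
            "rotation_dev_deg": round(h.rotation_dev, 3),
            "matched_entry": h.matched_entry,
        })
    columns = ["hit", "c_segment", "nc_segment", "translation_dev_A",
               "rotation_dev_deg", "matched_entry"]
    return pd.DataFrame(rows, columns=columns)


PSEUDO_ATOM_SCALE = 5.0  # angstrom offset of the triad pseudo-atoms


def write_hits_pseudoatoms(hits: list[MotifHit], path: str | Path) -> None:
    """Write matched segment frames as pseudo-atom residues in PDB format.

    Each matched segment becomes one residue of four pseudo-atoms: the
    origin plus one atom 5 angstrom along each triad vector.  Chain 'Z',
    residue numbers 2*hit+1 (C segment) and 2*hit+2 (NC segment).
    """
    model = StructureModel(source_id="motif-hits")
    for i, hit in enumerate(hits):
        for j, seg in enumerate((hit.c_segment, hit.nc_segment)):
            nt = Nucleotide(chain_id="Z", number=str(2 * i + 1 + j),
                            base=None, resname="SEG")
            positions = {
                "ORI": seg.origin,
                "AXI": seg.origin + PSEUDO_ATOM_SCALE * seg.axis,
                "HBD": seg.origin + PSEUDO_ATOM_SCALE * seg.hbond_dir,
                "NRM": seg.origin + PSEUDO_ATOM_SCALE * seg.normal,
            }
            for name, pos in positions.items():
                nt.atoms[name] = Atom(name=name, element="X", position=pos)
            model.nucleotides.append(nt)
    if not model.nucleotides:
        # valid empty-model PDB so downstream tooling still parses it
        Path(path).write_text("REMARK   3 kjunction scan: no motif hits\nEND\n")
        return
    write_pdb(model, path)
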