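"""Reading and writing RNA coordinate files.

PDB and mmCIF parsing is delegated to gemmi; this module reduces a
coordinate file to a flat, uniform model of nucleotides and atoms that
the geometry code operates on.  Only the first model of multi-model
files is used, alternate locations are resolved to the highest-occupancy
conformer, and non-RNA content (ligands, ions, waters, protein) can be
stripped with :func:`filter_to_rna`.

A structure is *eligible* for motif scanning when it contains at least
ten complete nucleotides; completeness means every expected heavy atom
of the parent ribonucleotide is present (the 5' phosphate group is not
required of a chain's first residue, and OP3 is never required).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

ELIGIBILITY_MIN_COMPLETE = 10

#: Heavy atoms of the ribose-phosphate moiety (OP3 deliberately absent).
BACKBONE_ATOMS = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'",
    "O2'", "C1'",
)
PHOSPHATE_ATOMS = ("P", "OP1", "OP2")

#: Heavy atoms of each nucleobase.
BASE_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}

#: Ring atoms in cyclic order; used for base-plane fitting and a
#: consistently signed plane normal.
RING_ATOMS = {
    "A": ("N9", "C4", "N3", "C2", "N1", "C6", "C5", "N7", "C8"),
    "G": ("N9", "C4", "N3", "C2", "N1", "C6", "C5", "N7", "C8"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: Residue names accepted as RNA, mapped to the parent base.  Covers the
#: standard four plus common modified nucleotides found in ribosomal RNA.
RNA_RESIDUE_MAP = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U", "URI": "U",
    "PSU": "U", "5MU": "U", "4SU": "U", "H2U": "U", "UR3": "U", "OMU": "U",
    "5MC": "C", "OMC": "C", "4OC": "C",
    "1MA": "A", "2MA": "A", "MA6": "A", "6MZ": "A", "OMA": "A", "A2M": "A",
    "OMG": "G", "2MG": "G", "7MG": "G", "M2G": "G", "1MG": "G", "G7M": "G",
    "YG": "G", "QUO": "G",
}


class StructureError(Exception):
    """Raised for unreadable files or empty models."""


@dataclass
class Atom:
    """A single (heavy or hydrogen) atom with PDB-style naming."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), angstrom
    occupancy: float = 1.0
    alt_id: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Nucleotide:
    """One residue: author chain/number identity plus its atoms.

    ``base`` is the one-letter parent base for RNA residues and ``None``
    for anything not (yet) recognised as RNA; ``resname`` keeps the
    original residue name so non-RNA content survives a round trip.
    """

    chain_id: str
    number: str              # author residue number + insertion code
    base: str | None
    atoms: dict[str, Atom] = field(default_factory=dict)
    resname: str = ""
    is_chain_start: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain_id, self.number)

    @property
    def complete(self) -> bool:
        """True iff all expected heavy atoms of the parent base are present."""
        if self.base is None:
            return False
        expected = set(BACKBONE_ATOMS) | set(BASE_ATOMS[self.base])
        if self.is_chain_start:
            expected -= set(PHOSPHATE_ATOMS)
        return expected <= set(self.atoms)

    def coord(self, atom_name: str) -> np.ndarray:
        try:
            return self.atoms[atom_name].position
        except KeyError:
            raise KeyError(
                f"atom {atom_name!r} missing from residue "
                f"{self.chain_id}{self.number} ({self.resname})"
            ) from None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Nucleotide {self.chain_id}{self.number} {self.resname}>"


@dataclass
class StructureModel:
    """An ordered collection of residues from one coordinate-file model."""

    source_id: str
    nucleotides: list[Nucleotide] = field(default_factory=list)
    model_index: int = 1

    @property
    def rna(self) -> list[Nucleotide]:
        return [nt for nt in self.nucleotides if nt.base is not None]

    @property
    def n_complete(self) -> int:
        return sum(nt.complete for nt in self.nucleotides)

    @property
    def eligible(self) -> bool:
        return self.n_complete >= ELIGIBILITY_MIN_COMPLETE

    def get(self, chain_id: str, number: str | int) -> Nucleotide:
        key = (chain_id, str(number))
        for nt in self.nucleotides:
            if nt.key == key:
                return nt
        raise KeyError(f"no residue {chain_id}{number} in {self.source_id}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every atom moved by x -> R x + t."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = StructureModel(self.source_id, [], self.model_index)
        for nt in self.nucleotides:
            copy = Nucleotide(nt.chain_id, nt.number, nt.base, {},
                              nt.resname, nt.is_chain_start)
            for name, atom in nt.atoms.items():
                copy.atoms[name] = Atom(atom.name, atom.element,
                                        rotation @ atom.position + translation,
                                        atom.occupancy, atom.alt_id)
            out.nucleotides.append(copy)
        return out


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by altloc label."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occ, -ord(atom.altloc or "A")) > (prev.occ, -ord(prev.altloc or "A")):
            by_name[atom.name] = atom
    return list(by_name.values())


def load_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is read.  All residues are kept (RNA or not);
    apply :func:`filter_to_rna` before geometric analysis.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = {"pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no coordinate model found")

    model = StructureModel(source_id=st.name or path.stem)
    gmodel = st[0]
    for chain in gmodel:
        for i, residue in enumerate(chain):
            number = f"{residue.seqid.num}{residue.seqid.icode}".strip()
            resname = residue.name.strip()
            nt = Nucleotide(
                chain_id=chain.name,
                number=number,
                base=RNA_RESIDUE_MAP.get(resname),
                resname=resname,
                is_chain_start=(i == 0),
            )
            for atom in _resolve_altlocs(residue):
                nt.atoms[atom.name] = Atom(
                    name=atom.name,
                    element=atom.element.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    alt_id=atom.altloc or "",
                )
            if nt.atoms:
                model.nucleotides.append(nt)
    if not model.nucleotides:
        raise StructureError(f"{path}: model contains no residues")
    return model


def filter_to_rna(model: StructureModel) -> StructureModel:
    """Drop everything whose residue name does not map to A/C/G/U.

    Ligands, ions, waters and protein are removed; modified nucleotides
    are renamed to their parent base.  Idempotent.
    """
    kept: list[Nucleotide] = []
    dropped = 0
    for nt in model.nucleotides:
        if nt.base is None:
            dropped += 1
            continue
        kept.append(nt)
    if dropped:
        logger.info("filter_to_rna(%s): removed %d non-RNA residues, kept %d",
                    model.source_id, dropped, len(kept))
    # re-derive chain starts within the surviving residues
    seen_chains: set[str] = set()
    out = StructureModel(model.source_id, [], model.model_index)
    for nt in kept:
        copy = Nucleotide(nt.chain_id, nt.number, nt.base, dict(nt.atoms),
                          nt.resname, is_chain_start=nt.chain_id not in seen_chains)
        seen_chains.add(nt.chain_id)
        out.nucleotides.append(copy)
    return out


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a single-model PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = model.source_id
    gmodel = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for nt in model.nucleotides:
        chain = chains.get(nt.chain_id)
        if chain is None:
            chain = gemmi.Chain(nt.chain_id)
            chains[nt.chain_id] = chain
        res = gemmi.Residue()
        res.name = nt.resname or (nt.base or "UNK")
        num = nt.number
        if num and num[-1].isalpha():
            res.seqid = gemmi.SeqId(int(num[:-1]), num[-1])
        else:
            res.seqid = gemmi.SeqId(int(num), " ")
        for atom in nt.atoms.values():
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element or atom.name[0])
            ga.pos = gemmi.Position(*atom.position)
            ga.occ = atom.occupancy
            res.add_atom(ga)
        chain.add_residue(res)
    for chain in chains.values():
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)
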