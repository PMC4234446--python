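"""Protein-DNA interface residues from complex structures.

The residues through which a transcription factor reads its binding site are
those close to the DNA bases in a co-crystal structure.  Following common
practice for structure-derived footprints, a protein residue is part of the
DNA-binding interface when at least one of its heavy atoms lies within a
distance cutoff (default 4.5 A, inclusive) of at least one *base-moiety*
atom of the DNA - backbone phosphate and sugar contacts are ignored because
they are largely sequence-unspecific.

Interface similarity between an annotated TF and a candidate homolog is the
percentage of annotated interface positions that align (not to a gap) to a
residue with a positive substitution-matrix score (BLOSUM62 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio.Align import substitution_matrices

from .errors import StructureError, ValidationError

#: Base-moiety atom names shared across the four deoxynucleotides.
BASE_ATOMS = {"N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
              "N2", "N4", "N6", "O2", "O4", "O6"}

DNA_RESIDUES = ("DA", "DC", "DG", "DT")

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


@dataclass
class Atom:
    name: str
    x: float
    y: float
    z: float
    element: str = ""

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    chain: str
    number: int
    name: str  # 3-letter amino-acid code or DA/DC/DG/DT
    atoms: list[Atom]

    @property
    def one_letter(self) -> str:
        return _AA3TO1.get(self.name, "X")


@dataclass
class ComplexStructure:
    """Protein and DNA residues of one protein-DNA complex."""

    protein_residues: list[Residue]
    dna_residues: list[Residue]

    def __post_init__(self):
        if not self.protein_residues:
            raise StructureError("no protein chain in structure")
        if not self.dna_residues:
            raise StructureError("no nucleic chain in structure")

    @property
    def protein_sequence(self) -> str:
        return "".join(r.one_letter for r in self.protein_residues)


@dataclass
class InterfaceAnnotation:
    """DNA-contacting residue positions (0-based) of one TF sequence."""

    tf_id: str
    positions: tuple[int, ...]

    def __post_init__(self):
        self.positions = tuple(sorted(set(int(p) for p in self.positions)))


@dataclass
class SubstitutionMatrix:
    """Symmetric amino-acid scoring table (thin wrapper over Biopython)."""

    name: str
    scores: object  # Bio.Align.substitution_matrices.Array

    def score(self, a: str, b: str) -> float:
        try:
            return float(self.scores[a, b])
        except (KeyError, IndexError):
            raise ValidationError(f"residue pair ({a!r}, {b!r}) not in "
                                  f"matrix {self.name}")

    @property
    def alphabet(self) -> str:
        return str(self.scores.alphabet)


def blosum62() -> SubstitutionMatrix:
    return SubstitutionMatrix("BLOSUM62",
                              substitution_matrices.load("BLOSUM62"))


# ---------------------------------------------------------------------------
# Parsing and interface derivation
# ---------------------------------------------------------------------------

def parse_structure(pdb_text: str) -> ComplexStructure:
    """Parse PDB-format ATOM/HETATM records into a protein-DNA complex.

    Only the first model is used; alternate locations other than blank/'A'
    are dropped.  Residues are classified by residue name: the four
    deoxynucleotides go to the DNA side, standard amino acids (plus MSE) to
    the protein side; anything else (waters, ions, ligands) is ignored.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise StructureError("no models in structure")
    protein, dna = [], []
    model = structure[0]
    for chain in model:
        for res in chain:
            atoms = []
            for atom in res:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                atoms.append(Atom(name=atom.name, x=atom.pos.x, y=atom.pos.y,
                                  z=atom.pos.z, element=atom.element.name))
            if not atoms:
                continue
            residue = Residue(chain=chain.name, number=res.seqid.num,
                              name=res.name.strip(), atoms=atoms)
            if residue.name in DNA_RESIDUES:
                dna.append(residue)
            elif residue.name in _AA3TO1:
                protein.append(residue)
    return ComplexStructure(protein_residues=protein, dna_residues=dna)


def dna_base_atoms(residue: Residue) -> list[Atom]:
    """Atoms of the nitrogen-base moiety (sugar and phosphate excluded)."""
    if residue.name not in DNA_RESIDUES:
        raise ValidationError(f"not a DNA residue: {residue.name!r}")
    return [a for a in residue.atoms if a.name in BASE_ATOMS]


def interface_residues(c: ComplexStructure, cutoff: float = 4.5,
                       tf_id: str = "") -> InterfaceAnnotation:
    """Protein residues with a heavy atom within ``cutoff`` A (inclusive)
    of at least one DNA base atom, as 0-based protein-sequence positions."""
    base_coords = []
    for res in c.dna_residues:
        base_coords.extend(a.coords for a in dna_base_atoms(res))
    positions = []
    if base_coords:
        base = np.array(base_coords)
        for i, res in enumerate(c.protein_residues):
            heavy = np.array([a.coords for a in res.atoms
                              if not a.is_hydrogen])
            if heavy.size == 0:
                continue
            d2 = ((heavy[:, None, :] - base[None, :, :]) ** 2).sum(axis=2)
            if d2.min() <= cutoff * cutoff:
                positions.append(i)
    return InterfaceAnnotation(tf_id=tf_id, positions=tuple(positions))


def interface_similarity(db_tf_seq: str, candidate_seq: str,
                         annotation: InterfaceAnnotation,
                         alignment, matrix: SubstitutionMatrix | None = None
                         ) -> float:
    """Percent of interface positions conserved in an aligned candidate.

    ``alignment`` maps database-TF positions to candidate positions (see
    :class:`cisbind.tf_prediction.ProteinAlignment`); a position counts as
    conserved when it is aligned to a residue (not a gap) whose substitution
    score against the database residue is strictly positive.
    """
    if not annotation.positions:
        raise ValidationError("no interface annotated")
    if max(annotation.positions) >= len(db_tf_seq):
        raise ValidationError("interface positions outside the TF sequence")
    if matrix is None:
        matrix = blosum62()
    mapping = alignment.query_to_target()
    conserved = 0
    for pos in annotation.positions:
        tpos = mapping.get(pos)
        if tpos is None:
            continue
        if matrix.score(db_tf_seq[pos], candidate_seq[tpos]) > 0:
            conserved += 1
    return 100.0 * conserved / len(annotation.positions)
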