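"""Parsing and validation of protein-RNA complex structures.

A complex is read from PDB-format text into a light-weight hierarchy
(:class:`ComplexStructure` -> :class:`Chain` -> :class:`Residue`) built on top
of Biopython's PDB parser.  Chains are typed as protein, RNA or other by
residue-alphabet majority, sequences are extracted in one-letter code, and the
dataset admission rule is enforced: every retained protein chain must have at
least 30 residues and every retained RNA chain at least 2 nucleotides, and a
valid complex must keep at least one chain of each kind.

Only the first model of a multi-model (NMR) file is used, and for alternate
locations the highest-occupancy conformer is kept.  Coordinates are carried
along but no geometric quantity is derived from them here: structural features
come from external-tool outputs (DSSP, RNAfold, RNAVIEW) parsed elsewhere.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from Bio import BiopythonWarning
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

__all__ = [
    "ChainKind",
    "Residue",
    "Chain",
    "ComplexStructure",
    "PDBParseError",
    "ComplexValidationError",
    "parse_complex",
    "classify_chain",
    "extract_sequences",
    "validate_complex",
    "to_pdb_text",
    "MIN_PROTEIN_RESIDUES",
    "MIN_RNA_NUCLEOTIDES",
]

#: Admission thresholds for a usable complex: protein chains need >= 30
#: residues, RNA chains >= 2 nucleotides.
MIN_PROTEIN_RESIDUES = 30
MIN_RNA_NUCLEOTIDES = 2

#: Fraction of polymer residues that must match an alphabet for a chain to be
#: typed as protein or RNA.  Tolerates occasional modified residues.
CHAIN_TYPE_THRESHOLD = 0.8

AMINO_ACIDS_3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in AMINO_ACIDS_3.items()}
RIBONUCLEOTIDES = {"A", "U", "G", "C"}
WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    """Raised when PDB-format text cannot be parsed into a complex."""


class ComplexValidationError(ValueError):
    """Raised when a parsed complex fails the dataset admission rules.

    ``reason`` is one of ``"no_protein"``, ``"no_rna"`` or ``"too_short"``.
    """

    def __init__(self, message: str, reason: str):
        super().__init__(message)
        self.reason = reason


class ChainKind(str, Enum):
    PROTEIN = "protein"
    RNA = "rna"
    OTHER = "other"


@dataclass
class Residue:
    """One residue: 3-letter (protein) or 1-letter (nucleotide) name, PDB
    sequence number, insertion code and its atoms as (name, x, y, z) in Å."""

    name: str
    seq_number: int
    insertion_code: str = ""
    atoms: list[tuple[str, float, float, float]] = field(default_factory=list)


@dataclass
class Chain:
    chain_id: str
    kind: ChainKind
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ComplexStructure:
    complex_id: str
    chains: list[Chain] = field(default_factory=list)
    source_path: Optional[str] = None

    def chains_of_kind(self, kind: ChainKind) -> list[Chain]:
        return [c for c in self.chains if c.kind is kind]

    @property
    def protein_chains(self) -> list[Chain]:
        return self.chains_of_kind(ChainKind.PROTEIN)

    @property
    def rna_chains(self) -> list[Chain]:
        return self.chains_of_kind(ChainKind.RNA)


def _prescan(pdb_text: str) -> None:
    """Validate fixed-column coordinate records, reporting the line number of
    the first malformed one."""
    n_atoms = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        n_atoms += 1
        if len(line) < 54:
            raise PDBParseError(
                f"line {lineno}: truncated {rec} record (< 54 columns)"
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtxt = line[lo:hi].strip()
            try:
                value = float(fieldtxt)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} coordinate {fieldtxt!r}"
                ) from None
            if not math.isfinite(value):
                raise PDBParseError(
                    f"line {lineno}: non-finite {what} coordinate {fieldtxt!r}"
                )
        try:
            int(line[22:26].strip())
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed residue sequence number "
                f"{line[22:26].strip()!r}"
            ) from None
    if n_atoms == 0:
        raise PDBParseError("no ATOM records found")


def _first_model_only(pdb_text: str) -> str:
    """Truncate multi-model text to its first model."""
    if "\nMODEL" not in pdb_text and not pdb_text.startswith("MODEL"):
        return pdb_text
    out: list[str] = []
    in_model = False
    seen_model = False
    for line in pdb_text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            if seen_model:
                break
            in_model = seen_model = True
            continue
        if rec == "ENDMDL" and in_model:
            break
        out.append(line)
    return "\n".join(out) + "\n"


def classify_chain(chain: Chain) -> ChainKind:
    """Type a chain by the alphabet of its polymer residues.

    A chain is protein (resp. RNA) when more than 80% of its non-water
    residues carry standard amino-acid (resp. A/U/G/C ribonucleotide) names;
    anything below threshold, including waters-only chains, is ``other``.
    """
    if not chain.residues:
        raise ValueError(f"chain {chain.chain_id!r} has no residues")
    polymer = [r for r in chain.residues if r.name not in WATER_NAMES]
    if not polymer:
        return ChainKind.OTHER
    n_aa = sum(1 for r in polymer if r.name in AMINO_ACIDS_3)
    n_nt = sum(1 for r in polymer if r.name in RIBONUCLEOTIDES)
    frac_aa = n_aa / len(polymer)
    frac_nt = n_nt / len(polymer)
    if frac_aa > CHAIN_TYPE_THRESHOLD and frac_aa >= frac_nt:
        return ChainKind.PROTEIN
    if frac_nt > CHAIN_TYPE_THRESHOLD:
        return ChainKind.RNA
    return ChainKind.OTHER


def parse_complex(pdb_text: str, complex_id: str,
                  source_path: Optional[str] = None) -> ComplexStructure:
    """Parse PDB-format text into a typed :class:`ComplexStructure`.

    Raises :class:`PDBParseError` when the text has no ATOM records or a
    malformed fixed-column record (the error names the offending line).
    """
    _prescan(pdb_text)
    text = _first_model_only(pdb_text)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BiopythonWarning)
        try:
            structure = parser.get_structure(complex_id, io.StringIO(text))
        except Exception as exc:  # Biopython raises several exception types
            raise PDBParseError(f"PDB parse failed: {exc}") from exc
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise PDBParseError("no model could be built from ATOM records")

    chains: list[Chain] = []
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            het, seq_number, icode = bio_res.id
            atoms = []
            for atom in bio_res:
                # disordered atoms expose their highest-occupancy conformer
                x, y, z = (float(v) for v in atom.coord)
                atoms.append((atom.get_name(), x, y, z))
            residues.append(
                Residue(
                    name=bio_res.get_resname().strip(),
                    seq_number=seq_number,
                    insertion_code=icode.strip(),
                    atoms=atoms,
                )
            )
        residues.sort(key=lambda r: (r.seq_number, r.insertion_code))
        chain = Chain(chain_id=bio_chain.id, kind=ChainKind.OTHER,
                      residues=residues)
        chain.kind = classify_chain(chain)
        chains.append(chain)
    seen = [c.chain_id for c in chains]
    if len(seen) != len(set(seen)):
        raise PDBParseError(f"duplicate chain identifiers: {sorted(seen)}")
    return ComplexStructure(complex_id=complex_id, chains=chains,
                            source_path=source_path)


def extract_sequences(
    cs: ComplexStructure,
) -> tuple[dict[str, str], dict[str, str], list[tuple[str, int, str]]]:
    """One-letter sequences per protein chain and per RNA chain.

    Returns ``(protein_seqs, rna_seqs, unknown_residues)`` where the dicts map
    chain id to sequence in chain order and ``unknown_residues`` lists
    ``(chain_id, seq_number, residue_name)`` for residues mapped to ``'X'``
    (nonstandard residues such as MSE).
    """
    protein_seqs: dict[str, str] = {}
    rna_seqs: dict[str, str] = {}
    unknown: list[tuple[str, int, str]] = []
    for chain in cs.chains:
        if chain.kind is ChainKind.PROTEIN:
            letters = []
            for r in chain.residues:
                if r.name in WATER_NAMES:
                    continue
                aa = AMINO_ACIDS_3.get(r.name)
                if aa is None:
                    aa = "X"
                    unknown.append((chain.chain_id, r.seq_number, r.name))
                letters.append(aa)
            protein_seqs[chain.chain_id] = "".join(letters)
        elif chain.kind is ChainKind.RNA:
            letters = []
            for r in chain.residues:
                if r.name in WATER_NAMES:
                    continue
                if r.name in RIBONUCLEOTIDES:
                    letters.append(r.name)
                else:
                    letters.append("X")
                    unknown.append((chain.chain_id, r.seq_number, r.name))
            rna_seqs[chain.chain_id] = "".join(letters)
    if unknown:
        logger.warning(
            "%s: %d nonstandard residues mapped to 'X'", cs.complex_id,
            len(unknown)
        )
    return protein_seqs, rna_seqs, unknown


def validate_complex(cs: ComplexStructure) -> ComplexStructure:
    """Apply the dataset admission rule and return the filtered complex.

    Protein chains shorter than 30 residues and RNA chains shorter than 2
    nucleotides are dropped with a warning; the complex is rejected
    (:class:`ComplexValidationError`) when no protein or no RNA chain
    survives.
    """
    kept: list[Chain] = []
    dropped: list[tuple[str, str]] = []
    for chain in cs.chains:
        n_polymer = sum(1 for r in chain.residues if r.name not in WATER_NAMES)
        if chain.kind is ChainKind.PROTEIN and n_polymer < MIN_PROTEIN_RESIDUES:
            dropped.append((chain.chain_id, "too_short"))
            continue
        if chain.kind is ChainKind.RNA and n_polymer < MIN_RNA_NUCLEOTIDES:
            dropped.append((chain.chain_id, "too_short"))
            continue
        kept.append(chain)
    for chain_id, why in dropped:
        logger.warning("%s: dropping chain %s (%s)", cs.complex_id, chain_id,
                       why)
    validated = ComplexStructure(complex_id=cs.complex_id, chains=kept,
                                 source_path=cs.source_path)
    if not validated.protein_chains:
        raise ComplexValidationError(
            f"{cs.complex_id}: no protein chain with >= "
            f"{MIN_PROTEIN_RESIDUES} residues", reason="no_protein")
    if not validated.rna_chains:
        raise ComplexValidationError(
            f"{cs.complex_id}: no RNA chain with >= "
            f"{MIN_RNA_NUCLEOTIDES} nucleotides", reason="no_rna")
    return validated


def to_pdb_text(cs: ComplexStructure) -> str:
    """Serialize a complex back to fixed-column PDB-format text."""
    lines: list[str] = []
    serial = 0
    for chain in cs.chains:
        for res in chain.residues:
            resname = res.name.rjust(3)
            for atom_name, x, y, z in res.atoms:
                serial += 1
                name_field = atom_name if len(atom_name) >= 4 \
                    else f" {atom_name:<3s}"
                element = atom_name.strip()[0]
                lines.append(
                    f"ATOM  {serial:5d} {name_field}{'':1s}{resname} "
                    f"{chain.chain_id}{res.seq_number:4d}"
                    f"{res.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {element:>2s}"
                )
        serial += 1
        lines.append(f"TER   {serial:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"
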