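"""Protein-derived features of a protein-RNA complex.

Sequence-based features are additive sums and class counts over the one-letter
protein sequence, driven by a versioned :class:`ResiduePropertyTable` (masses,
hydrogen-bond capacities, physicochemical class memberships) loaded from a
YAML config so alternative partitions can be swapped in.  Structure-based
features come from classic DSSP output: residue counts, masses and percentages
of alpha-helix (DSSP codes H/G/I) and beta-sheet (E/B), and the summed
solvent-accessible surface area (ACC column, Å²).

Unknown residues ('X', e.g. selenomethionine) count toward chain length but
are excluded from property sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ResiduePropertyTable",
    "DsspResidue",
    "SecondaryStructureRecord",
    "DsspParseError",
    "parse_dssp",
    "protein_molecular_mass",
    "hydrogen_bond_total",
    "residue_class_counts",
    "secondary_structure_features",
    "total_rasa",
    "compute_protein_features",
    "ProteinFeatureBlock",
    "HELIX_CODES",
    "SHEET_CODES",
]

STANDARD_AA = set("ARNDCEQGHILKMFPSTWYV")
#: DSSP 8-state codes counted as helix / sheet.
HELIX_CODES = frozenset("HGI")
SHEET_CODES = frozenset("EB")

#: The five residue-class groupings emitted as count + percentage features.
CLASS_GROUPS = (
    "hydrophilic",
    "hydrophobic",
    "aromatic_positive",
    "charged",
    "polar",
)


class DsspParseError(ValueError):
    """Raised on malformed classic DSSP output."""


@dataclass(frozen=True)
class ResiduePropertyTable:
    """Versioned per-amino-acid property table.

    ``mass`` is in Da (free amino acid, average mass); ``hbond`` is the
    hydrogen-bonding capacity per residue; ``classes`` maps each class name to
    its residue set.  The table is loadable from YAML (see
    ``data/residue_properties.yaml`` for the schema) so that alternative
    hydropathy partitions or mass conventions can be tested.
    """

    mass: dict[str, float]
    hbond: dict[str, int]
    classes: dict[str, frozenset[str]]
    version: int = 1

    def __post_init__(self):
        missing = STANDARD_AA - set(self.mass) | STANDARD_AA - set(self.hbond)
        if missing:
            raise ValueError(f"property table missing residues: {sorted(missing)}")
        overlap = self.classes["hydrophilic"] & self.classes["hydrophobic"]
        if overlap:
            raise ValueError(
                f"hydrophilic/hydrophobic sets overlap: {sorted(overlap)}")
        for name, members in self.classes.items():
            bad = set(members) - STANDARD_AA
            if bad:
                raise ValueError(f"class {name!r} has non-standard residues: "
                                 f"{sorted(bad)}")

    @classmethod
    def from_dict(cls, payload: dict) -> "ResiduePropertyTable":
        return cls(
            mass={k: float(v) for k, v in payload["mass"].items()},
            hbond={k: int(v) for k, v in payload["hbond"].items()},
            classes={k: frozenset(v) for k, v in payload["classes"].items()},
            version=int(payload.get("version", 1)),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ResiduePropertyTable":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def default(cls) -> "ResiduePropertyTable":
        text = (
            resources.files("rnaffinity")
            .joinpath("data/residue_properties.yaml")
            .read_text()
        )
        return cls.from_yaml(text)

    def in_group(self, aa: str, group: str) -> bool:
        """Membership in one of the emitted class groupings.

        ``aromatic_positive`` is the union of the aromatic and positively
        charged sets (histidine is counted once).
        """
        if group == "aromatic_positive":
            return (aa in self.classes["aromatic"]
                    or aa in self.classes["positively_charged"])
        return aa in self.classes[group]


def _require_seq(seq: str) -> None:
    if not seq:
        raise ValueError("empty protein sequence")


def protein_molecular_mass(seq: str, table: ResiduePropertyTable) -> float:
    """Total molecular mass of the protein fraction, Da.

    Sum of per-residue masses from the configured table; unknown residues
    ('X') are skipped with a warning.
    """
    _require_seq(seq)
    skipped = sum(1 for aa in seq if aa not in table.mass)
    if skipped:
        logger.warning("protein_molecular_mass: skipped %d unknown residues",
                       skipped)
    return sum(table.mass[aa] for aa in seq if aa in table.mass)


def hydrogen_bond_total(seq: str, table: ResiduePropertyTable) -> int:
    """Total hydrogen-bonding capacity over the protein sequence."""
    _require_seq(seq)
    return sum(table.hbond[aa] for aa in seq if aa in table.hbond)


def residue_class_counts(
    seq: str, table: ResiduePropertyTable
) -> dict[str, float]:
    """Counts and percentages of the five residue-class groupings.

    Percentages are over the full sequence length (unknown residues included
    in the denominator, never in a numerator).
    """
    _require_seq(seq)
    out: dict[str, float] = {}
    n = len(seq)
    for group in CLASS_GROUPS:
        count = sum(1 for aa in seq if aa in table.mass
                    and table.in_group(aa, group))
        out[f"n_{group}"] = float(count)
        out[f"pct_{group}"] = 100.0 * count / n
    return out


@dataclass(frozen=True)
class DsspResidue:
    chain_id: str
    seq_number: int
    insertion_code: str
    aa: str
    ss_code: str
    accessibility: float


@dataclass
class SecondaryStructureRecord:
    """Per-residue DSSP assignments for one complex."""

    residues: list[DsspResidue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def for_chain(self, chain_id: str) -> "SecondaryStructureRecord":
        return SecondaryStructureRecord(
            [r for r in self.residues if r.chain_id == chain_id])


def parse_dssp(dssp_text: str) -> SecondaryStructureRecord:
    """Parse classic fixed-column DSSP output.

    Expects the standard header terminated by the ``#  RESIDUE AA`` column
    ruler; chain-break lines (``!`` in the AA column) are skipped.
    """
    if not dssp_text.strip():
        raise DsspParseError("empty DSSP text")
    lines = dssp_text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#") and "RESIDUE" in line and "AA" in line:
            start = i + 1
            break
    if start is None:
        raise DsspParseError("missing '#  RESIDUE AA' header line")
    residues: list[DsspResidue] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        if len(line) < 38:
            raise DsspParseError(f"line {lineno}: residue line too short")
        aa = line[13]
        if aa == "!":  # chain break
            continue
        try:
            seq_number = int(line[5:10])
            acc = float(line[34:38])
        except ValueError as exc:
            raise DsspParseError(f"line {lineno}: {exc}") from None
        if acc < 0:
            raise DsspParseError(
                f"line {lineno}: negative accessibility {acc}")
        residues.append(
            DsspResidue(
                chain_id=line[11].strip(),
                seq_number=seq_number,
                insertion_code=line[10].strip(),
                aa=aa,
                ss_code=line[16].strip() or "-",
                accessibility=acc,
            )
        )
    return SecondaryStructureRecord(residues)


def _segment_count(flags: list[bool]) -> int:
    segments = 0
    prev = False
    for f in flags:
        if f and not prev:
            segments += 1
        prev = f
    return segments


def secondary_structure_features(
    ssr: SecondaryStructureRecord,
    seq: str,
    table: ResiduePropertyTable,
    max_mismatch_frac: float = 0.10,
) -> dict[str, float]:
    """Helix/sheet residue counts, masses, percentages and segment counts.

    The DSSP record is joined to the protein sequence positionally; the join
    fails when lengths differ or more than 10% of amino-acid letters disagree
    (unknown residues tolerated on either side).
    """
    if len(ssr) != len(seq):
        raise ValueError(
            f"cannot join DSSP record ({len(ssr)} residues) to sequence "
            f"({len(seq)} residues)")
    mismatches = sum(
        1 for r, aa in zip(ssr.residues, seq)
        if r.aa != aa and r.aa.upper() in STANDARD_AA and aa in STANDARD_AA
    )
    if seq and mismatches / len(seq) > max_mismatch_frac:
        raise ValueError(
            f"DSSP/sequence join failed: {mismatches}/{len(seq)} residues "
            "disagree")
    helix_flags = [r.ss_code in HELIX_CODES for r in ssr.residues]
    sheet_flags = [r.ss_code in SHEET_CODES for r in ssr.residues]
    n = len(seq)

    def mass_of(flags: list[bool]) -> float:
        return sum(table.mass.get(aa, 0.0)
                   for aa, f in zip(seq, flags) if f)

    helix_count = sum(helix_flags)
    sheet_count = sum(sheet_flags)
    return {
        "helix_count": float(helix_count),
        "sheet_count": float(sheet_count),
        "helix_mass": mass_of(helix_flags),
        "sheet_mass": mass_of(sheet_flags),
        "helix_pct": 100.0 * helix_count / n,
        "sheet_pct": 100.0 * sheet_count / n,
        "helix_segments": float(_segment_count(helix_flags)),
        "sheet_segments": float(_segment_count(sheet_flags)),
    }


def total_rasa(ssr: SecondaryStructureRecord) -> float:
    """Summed solvent-accessible surface area over protein residues, Å²."""
    if not ssr.residues:
        raise ValueError("empty secondary-structure record")
    for r in ssr.residues:
        if r.accessibility < 0:
            raise ValueError(
                f"negative accessibility for residue {r.seq_number}")
    return float(sum(r.accessibility for r in ssr.residues))


@dataclass
class ProteinFeatureBlock:
    """All protein-derived features for one complex, as a name->value map
    split into sequence-based and structure-based parts."""

    sequence: dict[str, float]
    structure: dict[str, float]

    def as_dict(self) -> dict[str, float]:
        return {**self.sequence, **self.structure}


def compute_protein_features(
    seq: str,
    table: Optional[ResiduePropertyTable] = None,
    ssr: Optional[SecondaryStructureRecord] = None,
) -> ProteinFeatureBlock:
    """Compute every protein feature for a (possibly concatenated) sequence.

    Multi-chain proteins are handled by passing the concatenation of all
    protein chains; every feature here is additive or a percentage, so
    concatenation order does not matter.  Structure-based features are filled
    only when a DSSP record is supplied.
    """
    table = table or ResiduePropertyTable.default()
    sequence = {
        "protein_molecular_mass": protein_molecular_mass(seq, table),
        "hbond_total": float(hydrogen_bond_total(seq, table)),
    }
    sequence.update(residue_class_counts(seq, table))
    structure: dict[str, float] = {}
    if ssr is not None and len(ssr):
        structure.update(secondary_structure_features(ssr, seq, table))
        structure["total_rasa"] = total_rasa(ssr)
    return ProteinFeatureBlock(sequence=sequence, structure=structure)
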