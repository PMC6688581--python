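"""The feature registry: every feature the pipeline can emit, with its
family and units.

The registry fixes feature order (all tie-breaking in ranking and selection
follows it) and defines the ablation masks: ``protein_only`` / ``rna_only``
split by molecule, ``sequence_only`` / ``structure_only`` split by
information source, ``all`` keeps everything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

__all__ = ["FeatureDescriptor", "FeatureRegistry", "DEFAULT_REGISTRY",
           "FAMILIES", "MASKS"]

FAMILIES = ("protein_seq", "protein_struct", "rna_seq", "rna_struct")
MASKS = ("all", "protein_only", "rna_only", "sequence_only", "structure_only")


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    family: str
    units: str
    producer: str  # operation that computes it

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


class FeatureRegistry:
    """Ordered, unique-named collection of feature descriptors."""

    def __init__(self, descriptors: Sequence[FeatureDescriptor]):
        names = [d.name for d in descriptors]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names in registry")
        self.descriptors = list(descriptors)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def family_of(self, name: str) -> str:
        for d in self.descriptors:
            if d.name == name:
                return d.family
        raise KeyError(name)

    def resolve_mask(self, mask: Union[str, Sequence[str]]) -> list[str]:
        """Feature names selected by a named mask or an explicit list."""
        if not isinstance(mask, str):
            unknown = [m for m in mask if m not in self.names]
            if unknown:
                raise ValueError(f"unknown features in mask: {unknown}")
            if not mask:
                raise ValueError("explicit feature mask is empty")
            return list(mask)
        if mask == "all":
            return self.names
        if mask == "protein_only":
            fams = {"protein_seq", "protein_struct"}
        elif mask == "rna_only":
            fams = {"rna_seq", "rna_struct"}
        elif mask == "sequence_only":
            fams = {"protein_seq", "rna_seq"}
        elif mask == "structure_only":
            fams = {"protein_struct", "rna_struct"}
        else:
            raise ValueError(f"unknown mask {mask!r}; named masks: {MASKS}")
        out = [d.name for d in self.descriptors if d.family in fams]
        if not out:
            raise ValueError(f"mask {mask!r} resolves to no features")
        return out


DEFAULT_REGISTRY = FeatureRegistry([
    # protein sequence-based
    FeatureDescriptor("protein_molecular_mass", "protein_seq", "Da",
                      "protein_molecular_mass"),
    FeatureDescriptor("hbond_total", "protein_seq", "count",
                      "hydrogen_bond_total"),
    FeatureDescriptor("n_hydrophilic", "protein_seq", "count",
                      "residue_class_counts"),
    FeatureDescriptor("pct_hydrophilic", "protein_seq", "%",
                      "residue_class_counts"),
    FeatureDescriptor("n_hydrophobic", "protein_seq", "count",
                      "residue_class_counts"),
    FeatureDescriptor("pct_hydrophobic", "protein_seq", "%",
                      "residue_class_counts"),
    FeatureDescriptor("n_aromatic_positive", "protein_seq", "count",
                      "residue_class_counts"),
    FeatureDescriptor("pct_aromatic_positive", "protein_seq", "%",
                      "residue_class_counts"),
    FeatureDescriptor("n_charged", "protein_seq", "count",
                      "residue_class_counts"),
    FeatureDescriptor("pct_charged", "protein_seq", "%",
                      "residue_class_counts"),
    FeatureDescriptor("n_polar", "protein_seq", "count",
                      "residue_class_counts"),
    FeatureDescriptor("pct_polar", "protein_seq", "%",
                      "residue_class_counts"),
    # protein structure-based
    FeatureDescriptor("helix_count", "protein_struct", "residues",
                      "secondary_structure_features"),
    FeatureDescriptor("sheet_count", "protein_struct", "residues",
                      "secondary_structure_features"),
    FeatureDescriptor("helix_mass", "protein_struct", "Da",
                      "secondary_structure_features"),
    FeatureDescriptor("sheet_mass", "protein_struct", "Da",
                      "secondary_structure_features"),
    FeatureDescriptor("helix_pct", "protein_struct", "%",
                      "secondary_structure_features"),
    FeatureDescriptor("sheet_pct", "protein_struct", "%",
                      "secondary_structure_features"),
    FeatureDescriptor("helix_segments", "protein_struct", "segments",
                      "secondary_structure_features"),
    FeatureDescriptor("sheet_segments", "protein_struct", "segments",
                      "secondary_structure_features"),
    FeatureDescriptor("total_rasa", "protein_struct", "A^2", "total_rasa"),
    # RNA sequence-based
    FeatureDescriptor("rna_molecular_mass", "rna_seq", "Da",
                      "rna_molecular_mass"),
    # RNA structure-based
    FeatureDescriptor("mfe_frequency", "rna_struct", "probability",
                      "parse_rnafold_output"),
    FeatureDescriptor("ensemble_diversity", "rna_struct", "dimensionless",
                      "parse_rnafold_output"),
    FeatureDescriptor("cww_count", "rna_struct", "count",
                      "basepair_features"),
    FeatureDescriptor("cww_relative_frequency", "rna_struct", "fraction",
                      "basepair_features"),
    FeatureDescriptor("bph0_count", "rna_struct", "count",
                      "basepair_features"),
    FeatureDescriptor("bph0_relative_frequency", "rna_struct", "fraction",
                      "basepair_features"),
])
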