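"""RNA-derived features: molecular mass, Boltzmann-ensemble quantities and
base-pair family counts.

The RNA molecular mass is the linear base-composition formula

    W = 329.2*A + 306.2*U + 305.2*C + 345.2*G + 159

with A/U/C/G the base counts and a constant 159 Da terminal correction per
molecule.  Ensemble features (probability of the minimum-free-energy
structure, ensemble diversity) are read from ViennaRNA RNAfold
partition-function output; base-pair families (cWW = cis
Watson-Crick/Watson-Crick in the Leontis-Westhof nomenclature) and
base-phosphate categories (0BPh) are read from RNAVIEW-style annotation
listings.  External tools are never executed here -- only their text output
dialects are consumed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = [
    "RNAEnsembleRecord",
    "BasePair",
    "BasePhosphate",
    "BasePairRecord",
    "RnaToolParseError",
    "rna_molecular_mass",
    "parse_rnafold_output",
    "parse_rnaview_output",
    "basepair_features",
    "BASE_MASS",
    "TERMINAL_MASS",
]

#: Per-base coefficients (Da) and per-molecule terminal term of the RNA mass
#: formula.
BASE_MASS = {"A": 329.2, "U": 306.2, "C": 305.2, "G": 345.2}
TERMINAL_MASS = 159.0


class RnaToolParseError(ValueError):
    """Raised on malformed RNAfold / RNAVIEW output text."""


def rna_molecular_mass(seq: str) -> float:
    """Molecular mass of one RNA molecule from its base composition, Da.

    Characters outside {A,U,G,C} are skipped with a warning.  The empty
    sequence evaluates to the terminal constant alone (159 Da).
    """
    skipped = sum(1 for nt in seq if nt not in BASE_MASS)
    if skipped:
        logger.warning("rna_molecular_mass: skipped %d non-AUGC characters",
                       skipped)
    return sum(BASE_MASS[nt] for nt in seq if nt in BASE_MASS) + TERMINAL_MASS


@dataclass(frozen=True)
class RNAEnsembleRecord:
    """Partition-function summary of an RNA secondary-structure ensemble."""

    mfe_frequency: float   # Boltzmann probability of the MFE structure
    ensemble_diversity: float  # expected base-pair distance, dimensionless

    def __post_init__(self):
        if not 0.0 <= self.mfe_frequency <= 1.0:
            raise RnaToolParseError(
                f"MFE frequency {self.mfe_frequency} outside [0, 1]")
        if self.ensemble_diversity < 0:
            raise RnaToolParseError(
                f"negative ensemble diversity {self.ensemble_diversity}")


_FREQ_RE = re.compile(
    r"frequency of mfe structure in ensemble\s+([0-9.eE+-]+)")
_DIV_RE = re.compile(r"ensemble diversity\s+([0-9.eE+-]+)")


def parse_rnafold_output(text: str) -> RNAEnsembleRecord:
    """Extract MFE-structure frequency and ensemble diversity from RNAfold
    partition-function (``-p``) output.

    Dot-bracket structure lines are ignored.  MFE-only output (no ensemble
    lines) is a parse error.
    """
    freq_m = _FREQ_RE.search(text)
    div_m = _DIV_RE.search(text)
    if freq_m is None or div_m is None:
        raise RnaToolParseError(
            "not partition-function output: missing 'frequency of mfe "
            "structure in ensemble' and/or 'ensemble diversity' line")
    return RNAEnsembleRecord(
        mfe_frequency=float(freq_m.group(1)),
        ensemble_diversity=float(div_m.group(1)),
    )


@dataclass(frozen=True)
class BasePair:
    i: int          # 1-based nucleotide indices
    j: int
    family: str     # Leontis-Westhof label, e.g. "cWW", "tHS"


@dataclass(frozen=True)
class BasePhosphate:
    i: int
    j: int
    category: str   # e.g. "0BPh"


@dataclass
class BasePairRecord:
    """Annotated base pairs and base-phosphate interactions of one RNA."""

    pairs: list[BasePair] = field(default_factory=list)
    base_phosphates: list[BasePhosphate] = field(default_factory=list)
    rna_length: int = 0

    def __post_init__(self):
        for p in list(self.pairs) + list(self.base_phosphates):
            if not (1 <= p.i <= self.rna_length
                    and 1 <= p.j <= self.rna_length):
                raise RnaToolParseError(
                    f"pair index ({p.i}, {p.j}) outside [1, "
                    f"{self.rna_length}]")


# RNAVIEW pair line, e.g.
#      1_19, A:     1 G-C    19 A: +/+ cis         XIX
_PAIR_RE = re.compile(
    r"^\s*\d+_\d+,\s+\S+:\s+(-?\d+)\s+\S-\S\s+(-?\d+)\s+\S+:\s+"
    r"([WHS+\-.?])/([WHS+\-.?])\s+(cis|tran)")
# Base-phosphate line in the same positional syntax with a category label.
_BPH_RE = re.compile(
    r"^\s*\d+_\d+,\s+\S+:\s+(-?\d+)\s+\S-\S\s+(-?\d+)\s+\S+:\s+(\d+BPh)")

#: RNAVIEW edge symbols: '+'/'-' denote the Watson-Crick edge of canonical
#: and wobble pairs respectively.
_EDGE_MAP = {"+": "W", "-": "W", "W": "W", "H": "H", "S": "S", ".": "?",
             "?": "?"}


def _family_label(edge_i: str, edge_j: str, orientation: str) -> str:
    prefix = "c" if orientation == "cis" else "t"
    return prefix + _EDGE_MAP[edge_i] + _EDGE_MAP[edge_j]


def parse_rnaview_output(text: str, rna_length: int) -> BasePairRecord:
    """Parse an RNAVIEW base-pair annotation listing.

    Pair lines inside the ``BEGIN_base-pair`` block are mapped to
    Leontis-Westhof family labels (canonical ``+/+`` and wobble ``-/-``
    Watson-Crick lines both map onto the W edge, so a ``cis`` line of either
    kind is cWW).  An optional ``BEGIN_base-phosphate`` block in the same
    positional syntax carries base-phosphate categories such as ``0BPh``.
    Pair indices must lie within ``[1, rna_length]``.
    """
    pairs: list[BasePair] = []
    bphs: list[BasePhosphate] = []
    section = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("BEGIN_base-pair"):
            section = "pair"
            continue
        if stripped.startswith("BEGIN_base-phosphate"):
            section = "bph"
            continue
        if stripped.startswith("END_"):
            section = None
            continue
        if section == "pair":
            m = _PAIR_RE.match(line)
            if m is None:
                if stripped and not stripped.startswith("#"):
                    logger.debug("rnaview line %d not a pair line: %r",
                                 lineno, stripped)
                continue
            i, j = int(m.group(1)), int(m.group(2))
            family = _family_label(m.group(3), m.group(4), m.group(5))
            pairs.append(BasePair(i=i, j=j, family=family))
        elif section == "bph":
            m = _BPH_RE.match(line)
            if m is None:
                continue
            bphs.append(BasePhosphate(i=int(m.group(1)), j=int(m.group(2)),
                                      category=m.group(3)))
    return BasePairRecord(pairs=pairs, base_phosphates=bphs,
                          rna_length=rna_length)


def basepair_features(bpr: BasePairRecord) -> dict[str, float]:
    """cWW and 0BPh counts with their relative frequencies.

    Relative frequencies are over total annotated base pairs (cWW) and total
    annotated base-phosphate interactions (0BPh); an empty denominator yields
    frequency 0 by convention.
    """
    n_pairs = len(bpr.pairs)
    n_bph = len(bpr.base_phosphates)
    cww = sum(1 for p in bpr.pairs if p.family == "cWW")
    bph0 = sum(1 for b in bpr.base_phosphates if b.category == "0BPh")
    return {
        "cww_count": float(cww),
        "cww_relative_frequency": cww / n_pairs if n_pairs else 0.0,
        "bph0_count": float(bph0),
        "bph0_relative_frequency": bph0 / n_bph if n_bph else 0.0,
    }
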