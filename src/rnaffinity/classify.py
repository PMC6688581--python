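"""Six-way classification of protein-RNA complexes by RNA type.

Complexes are grouped by the kind of RNA bound: (I) single-stranded RNA,
(II) duplex RNA, (III) tRNA, (IV) RNA with loop structure, (V) small RNA
fragment, (VI) miscellaneous.  The authoritative path is an explicit label
(e.g. an NDB-style category string in the input manifest), which always
dominates.  When no label is available a documented, configurable rule
cascade is applied instead -- a tool extension that makes the otherwise
manual annotation step reproducible, with fixed precedence V, II, III, IV, I
and VI as the catch-all.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .rna_features import BasePairRecord

__all__ = ["RNAClass", "ClassifyConfig", "RNAClassLabel", "assign_class"]


class RNAClass(str, Enum):
    I_SINGLE_STRANDED = "I"
    II_DUPLEX = "II"
    III_TRNA = "III"
    IV_LOOP = "IV"
    V_SMALL_FRAGMENT = "V"
    VI_MISCELLANEOUS = "VI"


_EXPLICIT_LABELS = {
    "i": RNAClass.I_SINGLE_STRANDED,
    "single-stranded rna": RNAClass.I_SINGLE_STRANDED,
    "single stranded rna": RNAClass.I_SINGLE_STRANDED,
    "ssrna": RNAClass.I_SINGLE_STRANDED,
    "ii": RNAClass.II_DUPLEX,
    "duplex rna": RNAClass.II_DUPLEX,
    "double-stranded rna": RNAClass.II_DUPLEX,
    "dsrna": RNAClass.II_DUPLEX,
    "iii": RNAClass.III_TRNA,
    "trna": RNAClass.III_TRNA,
    "iv": RNAClass.IV_LOOP,
    "rna loop": RNAClass.IV_LOOP,
    "loop": RNAClass.IV_LOOP,
    "v": RNAClass.V_SMALL_FRAGMENT,
    "small fragment": RNAClass.V_SMALL_FRAGMENT,
    "small rna fragment": RNAClass.V_SMALL_FRAGMENT,
    "vi": RNAClass.VI_MISCELLANEOUS,
    "misc": RNAClass.VI_MISCELLANEOUS,
    "miscellaneous": RNAClass.VI_MISCELLANEOUS,
}


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds of the heuristic rule cascade (all configurable)."""

    small_fragment_max_nt: int = 7       # total length < 8 nt -> class V
    duplex_min_interchain_frac: float = 0.5  # nt in inter-chain cWW -> II
    trna_min_nt: int = 60                # tRNA-like length window
    trna_max_nt: int = 100
    trna_min_hairpins: int = 3           # cloverleaf has >= 3 stem-loops
    loop_min_paired_frac: float = 0.3    # pairing needed to call a loop


@dataclass(frozen=True)
class RNAClassLabel:
    value: RNAClass
    source: str  # "explicit_label" | "rule"


def _hairpin_count(pairs: Sequence[tuple[int, int]]) -> int:
    """Number of hairpin loops: pairs enclosing no other pair."""
    norm = [(min(i, j), max(i, j)) for i, j in pairs]
    count = 0
    for i, j in norm:
        if not any(i < k and l < j for k, l in norm if (k, l) != (i, j)):
            count += 1
    return count


def assign_class(
    rna_seqs: Sequence[str],
    bpr: Optional[BasePairRecord] = None,
    explicit_label: Optional[str] = None,
    config: ClassifyConfig = ClassifyConfig(),
) -> RNAClassLabel:
    """Assign one of the six RNA-type classes to a complex.

    ``rna_seqs`` are the complex's RNA chain sequences in chain order; pair
    indices in ``bpr`` refer to their concatenation (1-based).  An explicit
    label (class numeral or NDB-style category string) short-circuits the
    cascade.
    """
    if not rna_seqs or not any(rna_seqs):
        raise ValueError("at least one non-empty RNA sequence required")
    if explicit_label is not None:
        key = explicit_label.strip().lower()
        if key not in _EXPLICIT_LABELS:
            raise ValueError(
                f"unmappable RNA class label {explicit_label!r}; accepted: "
                f"{sorted(set(_EXPLICIT_LABELS))}")
        return RNAClassLabel(value=_EXPLICIT_LABELS[key],
                             source="explicit_label")

    total_nt = sum(len(s) for s in rna_seqs)
    # V: small fragment
    if total_nt <= config.small_fragment_max_nt:
        return RNAClassLabel(RNAClass.V_SMALL_FRAGMENT, "rule")

    pairs = [(p.i, p.j) for p in bpr.pairs] if bpr is not None else []
    cww = [(p.i, p.j) for p in bpr.pairs
           if p.family == "cWW"] if bpr is not None else []

    # II: duplex -- >= 2 chains with most nucleotides in inter-chain cWW pairs
    if len(rna_seqs) >= 2 and cww:
        bounds = []
        offset = 0
        for s in rna_seqs:
            bounds.append((offset + 1, offset + len(s)))
            offset += len(s)

        def chain_of(idx: int) -> int:
            for c, (lo, hi) in enumerate(bounds):
                if lo <= idx <= hi:
                    return c
            return -1

        inter_nt = set()
        for i, j in cww:
            if chain_of(i) != chain_of(j):
                inter_nt.update((i, j))
        if len(inter_nt) / total_nt > config.duplex_min_interchain_frac:
            return RNAClassLabel(RNAClass.II_DUPLEX, "rule")

    single_chain = len(rna_seqs) == 1
    hairpins = _hairpin_count(pairs) if pairs else 0

    # III: tRNA-like -- cloverleaf-sized single chain with >= 3 stem-loops
    if (single_chain and config.trna_min_nt <= total_nt <= config.trna_max_nt
            and hairpins >= config.trna_min_hairpins):
        return RNAClassLabel(RNAClass.III_TRNA, "rule")

    # IV: loop-structured single chain
    if single_chain and pairs:
        paired_nt = {k for ij in pairs for k in ij}
        paired_frac = len(paired_nt) / total_nt
        if hairpins >= 1 and paired_frac >= config.loop_min_paired_frac:
            return RNAClassLabel(RNAClass.IV_LOOP, "rule")

    # I: no annotated pairing at all
    if not pairs:
        return RNAClassLabel(RNAClass.I_SINGLE_STRANDED, "rule")

    return RNAClassLabel(RNAClass.VI_MISCELLANEOUS, "rule")
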