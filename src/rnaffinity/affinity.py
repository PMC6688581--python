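"""Binding-affinity target variable: dissociation free energy from Kd.

The regression target is the dissociation Gibbs free energy

    dG = -R * T * ln(Kd)      [kcal/mol]

with R = 1.987e-3 kcal mol^-1 K^-1, Kd in mol/L and T in Kelvin.  Under this
sign convention a sub-molar Kd gives a positive dG, and tighter binding means
a larger dG.  Affinity tables are TSV files with columns ``complex_id``,
``kd_molar``, ``temperature_k``, ``delta_g_kcal_mol`` and optional ``ph``;
dG is derived from (Kd, T) when absent and cross-checked when both are given.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from typing import Optional, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "AffinityRecord",
    "delta_g_from_kd",
    "kd_from_delta_g",
    "read_affinity_table",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987e-3
#: Standard temperature assumed when a table row omits one.
DEFAULT_TEMPERATURE_K = 298.0
#: Allowed |dG(Kd, T) - dG| discrepancy when a row states both, kcal/mol.
CONSISTENCY_TOL = 1e-6


def delta_g_from_kd(kd: float, temperature: float) -> float:
    """dG = -R*T*ln(Kd) in kcal/mol; requires kd > 0 and temperature > 0."""
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return -GAS_CONSTANT_KCAL * temperature * math.log(kd)


def kd_from_delta_g(delta_g: float, temperature: float) -> float:
    """Inverse of :func:`delta_g_from_kd`."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return math.exp(-delta_g / (GAS_CONSTANT_KCAL * temperature))


@dataclass(frozen=True)
class AffinityRecord:
    """One measured affinity: Kd (mol/L) and/or dG (kcal/mol) at T (K)."""

    complex_id: str
    delta_g: float
    temperature: float
    kd: Optional[float] = None
    ph: Optional[float] = None

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError(
                f"{self.complex_id}: temperature must be positive")
        if self.kd is not None:
            implied = delta_g_from_kd(self.kd, self.temperature)
            if abs(implied - self.delta_g) > CONSISTENCY_TOL:
                raise ValueError(
                    f"{self.complex_id}: delta_g {self.delta_g} inconsistent "
                    f"with kd {self.kd} at T={self.temperature} "
                    f"(implies {implied:.6f})")


def read_affinity_table(
    source: Union[str, io.TextIOBase],
) -> list[AffinityRecord]:
    """Read a TSV affinity table into validated records.

    ``source`` is TSV text, a path, or an open handle.  Each row must carry
    ``delta_g_kcal_mol`` or (``kd_molar`` + ``temperature_k``); rows with
    neither raise, as do rows where the stated dG contradicts (Kd, T).
    A missing temperature falls back to 298 K with a warning.
    """
    if isinstance(source, str) and ("\t" in source or "\n" in source):
        handle: Union[str, io.TextIOBase] = io.StringIO(source)
    else:
        handle = source
    df = pd.read_csv(handle, sep="\t")
    if "complex_id" not in df.columns:
        raise ValueError("affinity table must have a 'complex_id' column")
    has_kd = "kd_molar" in df.columns
    has_dg = "delta_g_kcal_mol" in df.columns
    if not has_kd and not has_dg:
        raise ValueError(
            "affinity table needs 'kd_molar' or 'delta_g_kcal_mol'")
    records: list[AffinityRecord] = []
    for idx, row in df.iterrows():
        cid = str(row["complex_id"])
        temperature = row.get("temperature_k")
        if temperature is None or pd.isna(temperature):
            logger.warning("%s: no temperature, assuming %.0f K", cid,
                           DEFAULT_TEMPERATURE_K)
            temperature = DEFAULT_TEMPERATURE_K
        temperature = float(temperature)
        kd = row.get("kd_molar") if has_kd else None
        kd = None if kd is None or pd.isna(kd) else float(kd)
        dg = row.get("delta_g_kcal_mol") if has_dg else None
        dg = None if dg is None or pd.isna(dg) else float(dg)
        if dg is None:
            if kd is None:
                raise ValueError(
                    f"row {idx} ({cid}): neither kd_molar nor "
                    "delta_g_kcal_mol given")
            dg = delta_g_from_kd(kd, temperature)
        ph = row.get("ph")
        ph = None if ph is None or pd.isna(ph) else float(ph)
        try:
            records.append(AffinityRecord(complex_id=cid, delta_g=dg,
                                          temperature=temperature, kd=kd,
                                          ph=ph))
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
    return records
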