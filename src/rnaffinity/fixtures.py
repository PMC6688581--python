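"""Synthetic inputs for every pipeline stage.

Real runs of this tool consume PDB structures plus canned DSSP, RNAfold and
RNAVIEW output files.  This module generates mutually consistent toy versions
of all of them from a seed, so the full pipeline is exercisable with no
downloads and no external binaries: chain lengths in the PDB text match the
DSSP residue count, RNAVIEW pair indices stay within the RNA length, and
every generated artifact parses with the package's own parsers.

It also generates the regression datasets behind the learner tests and a
benchmark shaped like the study dataset: six RNA-type classes with
21/34/8/9/11/20 complexes (103 in total), dissociation free energies in the
5-15.2 kcal/mol range driven by a small number of planted informative
features among noise features, with a residual noise standard deviation of
1 kcal/mol (comparable to the ~1.1 kcal/mol LOOCV MAE regime the tool
targets).  Toy PDB coordinates lie on a simple helix-like curve; no feature
reads them, so geometric realism is not attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .affinity import kd_from_delta_g
from .structure_io import ONE_TO_THREE

__all__ = [
    "ToyComplexSpec",
    "ToyComplexFiles",
    "make_toy_complex",
    "make_regression_dataset",
    "make_affinity_benchmark",
    "AffinityBenchmark",
    "STUDY_CLASS_SIZES",
]

#: Per-class complex counts of the study dataset (classes I..VI, 103 total).
STUDY_CLASS_SIZES = {"I": 21, "II": 34, "III": 8, "IV": 9, "V": 11, "VI": 20}

#: dG range emulated by the affinity benchmark, kcal/mol.
DELTA_G_RANGE = (5.0, 15.2)

_AA20 = "ARNDCEQGHILKMFPSTWYV"
_NT4 = "AUGC"


@dataclass
class ToyComplexSpec:
    """Recipe for one synthetic complex and its canned tool outputs."""

    n_protein_residues: int = 35
    n_rna_nt: int = 12
    seed: int = 0
    protein_composition: Optional[dict[str, float]] = None
    rna_composition: Optional[dict[str, float]] = None
    ss_string: Optional[str] = None      # DSSP codes, len == n_protein_residues
    n_basepairs: int = 3
    cww_fraction: float = 0.7            # fraction of pairs labelled cWW
    n_base_phosphates: int = 1
    rna_class_label: Optional[str] = None
    delta_g: float = 9.0
    temperature: float = 298.0

    def validate(self) -> None:
        if self.n_protein_residues < 1 or self.n_rna_nt < 1:
            raise ValueError("chain lengths must be positive")
        if self.ss_string is not None \
                and len(self.ss_string) != self.n_protein_residues:
            raise ValueError(
                f"ss_string length {len(self.ss_string)} does not match "
                f"n_protein_residues {self.n_protein_residues}")
        if self.n_basepairs > self.n_rna_nt // 2:
            raise ValueError(
                f"{self.n_basepairs} base pairs do not fit in "
                f"{self.n_rna_nt} nucleotides")
        if not 0.0 <= self.cww_fraction <= 1.0:
            raise ValueError("cww_fraction must be in [0, 1]")


@dataclass
class ToyComplexFiles:
    pdb_text: str
    dssp_text: str
    rnafold_text: str
    rnaview_text: str
    manifest_row: dict
    protein_seq: str = ""
    rna_seq: str = ""


def _random_seq(rng: np.random.Generator, alphabet: str, n: int,
                composition: Optional[dict[str, float]]) -> str:
    letters = list(alphabet)
    if composition:
        probs = np.array([composition.get(a, 0.0) for a in letters])
        if probs.sum() <= 0:
            raise ValueError("composition has no mass on the alphabet")
        probs = probs / probs.sum()
    else:
        probs = np.full(len(letters), 1.0 / len(letters))
    return "".join(rng.choice(letters, size=n, p=probs))


def _helix_coords(i: int) -> tuple[float, float, float]:
    t = 0.6 * i
    return (5.0 * math.cos(t), 5.0 * math.sin(t), 1.5 * i)


def _pdb_text(protein_seq: str, rna_seq: str) -> str:
    lines = []
    serial = 0
    for i, aa in enumerate(protein_seq):
        serial += 1
        x, y, z = _helix_coords(i)
        res3 = ONE_TO_THREE[aa]
        lines.append(
            f"ATOM  {serial:5d}  CA  {res3} A{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
    serial += 1
    lines.append(f"TER   {serial:5d}")
    for i, nt in enumerate(rna_seq):
        serial += 1
        x, y, z = _helix_coords(i)
        lines.append(
            f"ATOM  {serial:5d}  P     {nt} B{i + 1:4d}    "
            f"{x + 20.0:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           P")
    serial += 1
    lines.append(f"TER   {serial:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _default_ss(n: int, rng: np.random.Generator) -> str:
    # alternating helix / strand / coil segments, DSSP-style codes
    out = []
    codes = ["H", "E", " "]
    i = 0
    while len(out) < n:
        code = codes[i % 3]
        seg = int(rng.integers(3, 7))
        out.extend(code * seg)
        i += 1
    return "".join(out[:n])


def _dssp_text(protein_seq: str, ss: str, acc: Sequence[int]) -> str:
    header = [
        "==== Secondary Structure Definition (synthetic fixture, format v1)"
        " ====",
        "REFERENCE see package documentation",
        f"  {len(protein_seq):4d}  1 ...",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
        "    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI"
        "    X-CA   Y-CA   Z-CA",
    ]
    lines = []
    for i, (aa, code, a) in enumerate(zip(protein_seq, ss, acc)):
        # fixed columns: [5:10] resnum, [10] icode, [11] chain, [13] aa,
        # [16] ss, [34:38] ACC
        lines.append(
            f"{i + 1:5d}{i + 1:5d} A {aa}  {code}{'':17s}{a:4d}")
    return "\n".join(header + lines) + "\n"


def _dotbracket(n: int, pairs: Sequence[tuple[int, int]]) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i - 1], s[j - 1] = "(", ")"
    return "".join(s)


def _rnafold_text(rna_seq: str, pairs: Sequence[tuple[int, int]],
                  mfe_freq: float, diversity: float) -> str:
    db = _dotbracket(len(rna_seq), pairs)
    return (
        ">synthetic\n"
        f"{rna_seq}\n"
        f"{db} ( -5.00)\n"
        f"{db} [ -5.20]\n"
        f"{db} {{ -5.00 d={diversity:.2f}}}\n"
        f" frequency of mfe structure in ensemble {mfe_freq:.6f};"
        f" ensemble diversity {diversity:.2f}\n"
    )


def _rnaview_text(rna_seq: str, pairs: Sequence[tuple[int, int, bool]],
                  bphs: Sequence[tuple[int, int]]) -> str:
    lines = ["PDB data file name: synthetic fixture (format v1)",
             "BEGIN_base-pair"]
    for i, j, is_cww in pairs:
        edge = "+/+ cis         XIX" if is_cww else "H/S tran        !1H(b_b)"
        lines.append(
            f"     {i}_{j}, B: {i:5d} {rna_seq[i - 1]}-{rna_seq[j - 1]} "
            f"{j:5d} B: {edge}")
    lines.append("END_base-pair")
    lines.append("BEGIN_base-phosphate")
    for i, j in bphs:
        lines.append(
            f"     {i}_{j}, B: {i:5d} {rna_seq[i - 1]}-{rna_seq[j - 1]} "
            f"{j:5d} B: 0BPh")
    lines.append("END_base-phosphate")
    lines.append(f"The total base pairs = {len(pairs)}")
    return "\n".join(lines) + "\n"


def make_toy_complex(spec: ToyComplexSpec) -> ToyComplexFiles:
    """Generate one synthetic complex with matched canned tool outputs.

    Deterministic in ``spec.seed``; the same spec yields byte-identical
    texts.  All four artifacts are mutually consistent and parseable by the
    package's parsers.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    protein_seq = _random_seq(rng, _AA20, spec.n_protein_residues,
                              spec.protein_composition)
    rna_seq = _random_seq(rng, _NT4, spec.n_rna_nt, spec.rna_composition)
    ss = spec.ss_string if spec.ss_string is not None \
        else _default_ss(spec.n_protein_residues, rng)
    acc = [int(a) for a in rng.integers(0, 200, size=spec.n_protein_residues)]

    # nested stem pairs: (1, n), (2, n-1), ...
    n = spec.n_rna_nt
    pair_idx = [(k + 1, n - k) for k in range(spec.n_basepairs)]
    n_cww = int(round(spec.cww_fraction * spec.n_basepairs))
    pairs = [(i, j, k < n_cww) for k, (i, j) in enumerate(pair_idx)]
    bphs = []
    for k in range(spec.n_base_phosphates):
        i = 1 + (2 * k) % n
        j = 1 + (2 * k + 1) % n
        bphs.append((i, j))

    mfe_freq = float(0.2 + 0.6 * rng.random())
    diversity = float(5.0 * rng.random())
    kd = kd_from_delta_g(spec.delta_g, spec.temperature)
    manifest_row = {
        "complex_id": f"toy{spec.seed:04d}",
        "rna_class": spec.rna_class_label,
        "kd_molar": kd,
        "temperature_k": spec.temperature,
        "delta_g_kcal_mol": spec.delta_g,
    }
    return ToyComplexFiles(
        pdb_text=_pdb_text(protein_seq, rna_seq),
        dssp_text=_dssp_text(protein_seq, ss, acc),
        rnafold_text=_rnafold_text(rna_seq, pair_idx, mfe_freq, diversity),
        rnaview_text=_rnaview_text(rna_seq, pairs, bphs),
        manifest_row=manifest_row,
        protein_seq=protein_seq,
        rna_seq=rna_seq,
    )


def make_regression_dataset(
    n: int,
    p: int,
    signal_spec: Optional[dict] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Synthetic regression data y = f(X) + N(0, noise_sd).

    ``signal_spec`` declares the true function: ``kind`` is ``"linear"``,
    ``"piecewise"`` (piecewise-constant steps in each informative feature) or
    ``"constant"``; ``informative`` lists the feature indices carrying
    signal; ``coefs`` optionally weights them.  Returns (X, y, f).
    """
    if n < 2 or p < 1:
        raise ValueError(f"invalid dimensions n={n}, p={p}")
    spec = dict(signal_spec or {"kind": "linear", "informative": [0]})
    kind = spec.get("kind", "linear")
    informative = list(spec.get("informative", [0]))
    if any(not 0 <= j < p for j in informative):
        raise ValueError(f"informative indices {informative} outside [0, {p})")
    coefs = list(spec.get("coefs", [1.0] * len(informative)))
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))

    def f(Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        out = np.zeros(Z.shape[0])
        if kind == "constant":
            return out + spec.get("value", 1.0)
        for j, c in zip(informative, coefs):
            if kind == "linear":
                out += c * Z[:, j]
            elif kind == "piecewise":
                out += c * np.floor(2.0 * Z[:, j])
            else:
                raise ValueError(f"unknown signal kind {kind!r}")
        return out

    y = f(X) + noise_sd * rng.standard_normal(n)
    return X, y, f


@dataclass
class AffinityBenchmark:
    """Feature table, affinity table and manifest of a synthetic benchmark."""

    features: pd.DataFrame        # index complex_id, one column per feature
    affinities: pd.DataFrame      # complex_id, delta_g_kcal_mol, temperature_k
    manifest: pd.DataFrame        # complex_id, rna_class
    informative: dict[str, list[str]] = field(default_factory=dict)

    @property
    def delta_g(self) -> np.ndarray:
        return self.affinities.set_index("complex_id").loc[
            self.features.index, "delta_g_kcal_mol"].to_numpy()

    @property
    def classes(self) -> pd.Series:
        return self.manifest.set_index("complex_id").loc[
            self.features.index, "rna_class"]


def make_affinity_benchmark(
    class_sizes: Optional[dict[str, int]] = None,
    planted_features: int = 3,
    seed: int = 0,
    n_noise_features: int = 12,
    effect_size: float = 1.4,
    noise_sd: float = 1.0,
    class_specific: bool = False,
    class_effect_size: float = 3.0,
    class_noise_sd: float = 0.5,
) -> AffinityBenchmark:
    """Affinity benchmark shaped like the study dataset.

    In the default (shared-signal) mode, dG is an equal-weight combination of
    ``planted_features`` standard-normal informative features plus
    ``n_noise_features`` pure-noise features, centred mid-range and clipped
    to 5-15.2 kcal/mol.  With ``class_specific=True`` each RNA-type class
    instead responds to its own single feature (feature k for the k-th
    class), which makes pooling across classes actively misleading -- the
    construction behind the classification-matters contrast.
    """
    sizes = dict(class_sizes or STUDY_CLASS_SIZES)
    if any(v < 3 for v in sizes.values()):
        raise ValueError("every class needs at least 3 complexes")
    rng = np.random.default_rng(seed)
    n_total = sum(sizes.values())
    n_signal = len(sizes) if class_specific else planted_features
    p = n_signal + n_noise_features
    X = rng.standard_normal((n_total, p))
    feat_names = [f"feat_{j:02d}" for j in range(p)]

    lo, hi = DELTA_G_RANGE
    mid = 0.5 * (lo + hi)
    y = np.full(n_total, mid)
    informative: dict[str, list[str]] = {}
    row = 0
    class_col = []
    for k, (label, size) in enumerate(sorted(sizes.items())):
        sl = slice(row, row + size)
        if class_specific:
            y[sl] += class_effect_size * X[sl, k]
            y[sl] += class_noise_sd * rng.standard_normal(size)
            informative[label] = [feat_names[k]]
        else:
            for j in range(planted_features):
                y[sl] += effect_size * X[sl, j]
            y[sl] += noise_sd * rng.standard_normal(size)
            informative[label] = feat_names[:planted_features]
        class_col.extend([label] * size)
        row += size
    y = np.clip(y, lo, hi)

    ids = [f"cplx{i:03d}" for i in range(n_total)]
    features = pd.DataFrame(X, index=pd.Index(ids, name="complex_id"),
                            columns=feat_names)
    affinities = pd.DataFrame({
        "complex_id": ids,
        "delta_g_kcal_mol": y,
        "temperature_k": 298.0,
    })
    manifest = pd.DataFrame({"complex_id": ids, "rna_class": class_col})
    return AffinityBenchmark(features=features, affinities=affinities,
                             manifest=manifest, informative=informative)
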