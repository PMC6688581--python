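"""End-to-end orchestration: extract features, classify, select, train,
predict, evaluate, ablate.

The single entry point is a TSV manifest with one row per complex
(``complex_id``, paths to the PDB file and the canned DSSP / RNAfold /
RNAVIEW outputs, an optional ``rna_class`` label, and Kd or dG with
temperature).  Feature extraction fills the registry columns, degrading
gracefully: a missing tool output leaves its columns null with a logged
warning.  Training is per RNA-type class (or pooled), runs single-feature
ranking then greedy forward selection, fits the final boosted-tree model on
the selected features and reports LOOCV Pearson r, MAE and R2.  Rows with
nulls among candidate features are dropped per group with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import protein_features as pf
from . import rna_features as rf
from . import structure_io as sio
from .affinity import read_affinity_table
from .classify import assign_class
from .gbrt import GBRTConfig, GBRTModel, fit_gbrt
from .registry import DEFAULT_REGISTRY, FeatureRegistry, MASKS
from .selection import (SelectionResult, evaluate_predictions, greedy_select,
                        loocv, rank_features, EvaluationReport)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "TrainingResult",
    "gbrt_trainer",
    "extract_features",
    "classify_complexes",
    "run_training",
    "run_predict",
    "run_ablation",
]


@dataclass
class RunConfig:
    """Configuration of a training / ablation run."""

    class_mode: str = "per_class"            # "per_class" | "pooled"
    feature_mask: Union[str, Sequence[str]] = "all"
    gbrt: GBRTConfig = field(default_factory=GBRTConfig)
    seed: int = 0
    min_class_size: int = 3
    top_k: int = 10
    improvement_tol: float = 1e-4
    rank_use_loocv: bool = True

    def __post_init__(self):
        if self.class_mode not in ("per_class", "pooled"):
            raise ValueError(f"unknown class_mode {self.class_mode!r}")


@dataclass
class TrainingResult:
    class_label: str
    selected_features: list[str]
    model: GBRTModel
    report: EvaluationReport
    selection: Optional[SelectionResult] = None


def gbrt_trainer(config: GBRTConfig):
    """Adapt the boosted-tree learner to the generic trainer protocol."""

    def train(X: np.ndarray, y: np.ndarray):
        model = fit_gbrt(X, y, config)
        return model.predict

    return train


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _read_text(base_dir: Optional[Path], value) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    path = Path(value)
    if base_dir is not None and not path.is_absolute():
        path = base_dir / path
    if not path.exists():
        return None
    return path.read_text()


def _row_features(cid, pdb_text, dssp_text, rnafold_text,
                  rnaview_text, table) -> dict[str, float]:
    values: dict[str, float] = {name: np.nan for name in
                                DEFAULT_REGISTRY.names}
    cs = sio.parse_complex(pdb_text, cid)
    cs = sio.validate_complex(cs)
    protein_seqs, rna_seqs, _ = sio.extract_sequences(cs)
    protein_seq = "".join(protein_seqs.values())
    rna_chain_seqs = list(rna_seqs.values())

    ssr = None
    if dssp_text is not None:
        ssr = pf.parse_dssp(dssp_text)
    else:
        logger.warning("%s: no DSSP output; protein structure features null",
                       cid)
    block = pf.compute_protein_features(protein_seq, table, ssr)
    values.update(block.as_dict())

    # one mass formula evaluation per RNA molecule, summed over chains
    values["rna_molecular_mass"] = sum(
        rf.rna_molecular_mass(s) for s in rna_chain_seqs)

    if rnafold_text is not None:
        ens = rf.parse_rnafold_output(rnafold_text)
        values["mfe_frequency"] = ens.mfe_frequency
        values["ensemble_diversity"] = ens.ensemble_diversity
    else:
        logger.warning("%s: no RNAfold output; ensemble features null", cid)
    if rnaview_text is not None:
        rna_len = sum(len(s) for s in rna_chain_seqs)
        bpr = rf.parse_rnaview_output(rnaview_text, rna_len)
        values.update(rf.basepair_features(bpr))
    else:
        logger.warning("%s: no RNAVIEW output; base-pair features null", cid)
    return values


def extract_features(
    manifest: Union[pd.DataFrame, str, Path],
    base_dir: Optional[Union[str, Path]] = None,
    table: Optional[pf.ResiduePropertyTable] = None,
) -> pd.DataFrame:
    """One feature row per manifest complex, columns in registry order.

    The manifest needs ``complex_id`` and ``pdb_path``; ``dssp_path``,
    ``rnafold_path`` and ``rnaview_path`` are optional per row (missing tool
    outputs leave their feature columns null).  An unresolvable PDB path is a
    row error.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, sep="\t")
    base = Path(base_dir) if base_dir is not None else None
    table = table or pf.ResiduePropertyTable.default()
    rows = []
    for idx, row in manifest.iterrows():
        cid = str(row["complex_id"])
        pdb_text = _read_text(base, row.get("pdb_path"))
        if pdb_text is None:
            raise FileNotFoundError(
                f"row {idx} ({cid}): PDB file "
                f"{row.get('pdb_path')!r} not found")
        values = _row_features(
            cid,
            pdb_text,
            _read_text(base, row.get("dssp_path")),
            _read_text(base, row.get("rnafold_path")),
            _read_text(base, row.get("rnaview_path")),
            table,
        )
        values["complex_id"] = cid
        rows.append(values)
    out = pd.DataFrame(rows).set_index("complex_id")
    return out[DEFAULT_REGISTRY.names]


def classify_complexes(
    manifest: pd.DataFrame,
    base_dir: Optional[Union[str, Path]] = None,
) -> pd.Series:
    """RNA-type class per complex: explicit ``rna_class`` labels dominate,
    otherwise the rule cascade runs on the parsed structure/annotation."""
    base = Path(base_dir) if base_dir is not None else None
    labels = {}
    for _, row in manifest.iterrows():
        cid = str(row["complex_id"])
        explicit = row.get("rna_class")
        if explicit is not None and not pd.isna(explicit):
            labels[cid] = assign_class(["N"], explicit_label=str(explicit)
                                       ).value.value
            continue
        pdb_text = _read_text(base, row.get("pdb_path"))
        if pdb_text is None:
            raise FileNotFoundError(f"{cid}: no rna_class label and no PDB "
                                    "file to classify from")
        cs = sio.validate_complex(sio.parse_complex(pdb_text, cid))
        _, rna_seqs, _ = sio.extract_sequences(cs)
        seqs = list(rna_seqs.values())
        bpr = None
        rnaview_text = _read_text(base, row.get("rnaview_path"))
        if rnaview_text is not None:
            bpr = rf.parse_rnaview_output(rnaview_text,
                                          sum(len(s) for s in seqs))
        labels[cid] = assign_class(seqs, bpr=bpr).value.value
    return pd.Series(labels, name="rna_class")


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------

def _candidate_columns(feature_table: pd.DataFrame,
                       mask: Union[str, Sequence[str]],
                       registry: FeatureRegistry) -> list[str]:
    if not isinstance(mask, str):
        cols = registry.resolve_mask(mask) if all(
            m in registry.names for m in mask) else list(mask)
    elif mask == "all":
        cols = [c for c in feature_table.columns
                if pd.api.types.is_numeric_dtype(feature_table[c])]
    else:
        cols = [c for c in registry.resolve_mask(mask)
                if c in feature_table.columns]
    cols = [c for c in cols if c in feature_table.columns]
    if not cols:
        raise ValueError(f"feature mask {mask!r} resolves to no columns of "
                         "the feature table")
    return cols


def _target_frame(affinity_table) -> pd.Series:
    if isinstance(affinity_table, pd.DataFrame):
        if "delta_g_kcal_mol" not in affinity_table.columns:
            records = read_affinity_table(
                affinity_table.to_csv(sep="\t", index=False))
            return pd.Series({r.complex_id: r.delta_g for r in records})
        return affinity_table.set_index("complex_id")["delta_g_kcal_mol"]
    records = affinity_table
    return pd.Series({r.complex_id: r.delta_g for r in records})


def _groups(feature_table: pd.DataFrame, classes: Optional[pd.Series],
            config: RunConfig):
    if config.class_mode == "pooled" or classes is None:
        yield "all", feature_table.index
        return
    for label in sorted(classes.unique()):
        yield str(label), classes.index[classes == label]


def run_training(
    feature_table: pd.DataFrame,
    affinity_table,
    config: Optional[RunConfig] = None,
    classes: Optional[pd.Series] = None,
) -> dict[str, TrainingResult]:
    """Rank -> greedy-select -> fit -> LOOCV-evaluate, per class or pooled.

    ``classes`` maps complex_id to class label (required for per-class
    mode); classes with fewer than ``min_class_size`` usable rows are
    skipped with a warning.
    """
    config = config or RunConfig()
    y_all = _target_frame(affinity_table)
    cols = _candidate_columns(feature_table, config.feature_mask,
                              DEFAULT_REGISTRY)
    trainer = gbrt_trainer(config.gbrt)
    results: dict[str, TrainingResult] = {}
    for label, ids in _groups(feature_table, classes, config):
        ids = [i for i in ids if i in feature_table.index and i in y_all.index]
        sub = feature_table.loc[ids, cols]
        ok = sub.notna().all(axis=1)
        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.warning("class %s: dropping %d rows with null features",
                           label, n_dropped)
        sub = sub[ok]
        if len(sub) < max(config.min_class_size, 3):
            logger.warning("class %s: only %d usable complexes, skipped",
                           label, len(sub))
            continue
        X = sub.to_numpy(dtype=float)
        y = y_all.loc[sub.index].to_numpy(dtype=float)
        ranked = rank_features(X, y, trainer, feature_names=cols,
                               top_k=config.top_k,
                               use_loocv=config.rank_use_loocv)
        sel = greedy_select(X, y, ranked, trainer,
                            tol=config.improvement_tol,
                            use_loocv=config.rank_use_loocv)
        chosen = [cols[j] for j in sel.selected]
        Xsel = X[:, sel.selected]
        model = fit_gbrt(Xsel, y, config.gbrt, feature_names=chosen)
        preds = loocv(Xsel, y, trainer)
        report = evaluate_predictions(preds, y, class_label=label,
                                      selected_features=chosen,
                                      complex_ids=list(sub.index))
        results[label] = TrainingResult(class_label=label,
                                        selected_features=chosen,
                                        model=model, report=report,
                                        selection=sel)
    if not results:
        raise ValueError("no class had enough usable complexes to train on")
    return results


def run_predict(
    models: dict[str, Union[TrainingResult, GBRTModel]],
    feature_table: pd.DataFrame,
    classes: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Batch prediction: each row is scored by its class's model.

    A row whose class has no model, or with a null among the model's selected
    features, is a row error.
    """
    out = []
    for cid in feature_table.index:
        label = "all" if classes is None else str(classes.loc[cid])
        entry = models.get(label)
        if entry is None:
            raise KeyError(f"{cid}: no model for class {label!r} "
                           f"(have {sorted(models)})")
        model = entry.model if isinstance(entry, TrainingResult) else entry
        missing = [f for f in model.feature_names
                   if f not in feature_table.columns]
        if missing:
            raise KeyError(f"{cid}: feature table lacks {missing}")
        x = feature_table.loc[cid, model.feature_names].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"{cid}: null value among selected features")
        out.append({"complex_id": cid, "rna_class": label,
                    "predicted_delta_g": float(model.predict([x])[0])})
    return pd.DataFrame(out)


def run_ablation(
    feature_table: pd.DataFrame,
    affinity_table,
    config: Optional[RunConfig] = None,
    classes: Optional[pd.Series] = None,
    masks: Sequence[str] = MASKS,
) -> pd.DataFrame:
    """Train under each feature mask and tabulate per-class metrics.

    One row per (class, mask) with LOOCV Pearson r, MAE and R2 -- the
    protein-only / RNA-only and sequence-only / structure-only contrasts.
    """
    config = config or RunConfig()
    rows = []
    for mask in masks:
        cfg = RunConfig(class_mode=config.class_mode, feature_mask=mask,
                        gbrt=config.gbrt, seed=config.seed,
                        min_class_size=config.min_class_size,
                        top_k=config.top_k,
                        improvement_tol=config.improvement_tol,
                        rank_use_loocv=config.rank_use_loocv)
        results = run_training(feature_table, affinity_table, cfg,
                               classes=classes)
        for label, res in sorted(results.items()):
            rows.append({
                "class": label,
                "mask": mask,
                "n_complexes": res.report.n_complexes,
                "pearson_r": res.report.pearson_r,
                "mae": res.report.mae,
                "r2": res.report.r2,
                "selected_features": ",".join(res.selected_features),
            })
    return pd.DataFrame(rows)
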