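"""Reading and writing interaction tables, and the evaluation metric menu.

The on-disk layout is a UTF-8 CSV with a header; recognized columns are
sample_id (optional), peptide (required), cdr3a, cdr3b, mhc_pseudo (each
optional) and label (required for training/evaluation, optional for
prediction). An empty cell means the sequence is missing for that record.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    mean_squared_error,
    r2_score,
    roc_auc_score,
)

from .encoding import AminoAcidSequence, Role
from .model import SequenceRecord

__all__ = [
    "read_dataset",
    "write_dataset",
    "records_from_dataframe",
    "records_to_dataframe",
    "classification_metrics",
    "regression_metrics",
    "train_test_split_records",
]

logger = logging.getLogger("avib")

SEQUENCE_COLUMNS = {
    "peptide": Role.PEPTIDE,
    "cdr3a": Role.CDR3A,
    "cdr3b": Role.CDR3B,
    "mhc_pseudo": Role.MHC_PSEUDO,
}


def records_from_dataframe(
    df: pd.DataFrame, require_label: bool = True, strict: bool = True
) -> list[SequenceRecord]:
    """Parse a DataFrame row-wise into records, preserving row order.

    strict=True aborts on the first bad row; strict=False logs and drops it.
    """
    if "peptide" not in df.columns:
        raise ValueError("missing required column 'peptide'")
    has_label = "label" in df.columns
    if require_label and not has_label:
        raise ValueError("missing required column 'label'")
    roles_present = [c for c in SEQUENCE_COLUMNS if c in df.columns]
    records = []
    for pos, (_, row) in enumerate(df.iterrows()):
        try:
            seqs = {}
            for col in roles_present:
                cell = row[col]
                if pd.isna(cell) or str(cell).strip() == "":
                    continue  # empty cell: sequence absent, never empty
                role = SEQUENCE_COLUMNS[col]
                seqs[role] = AminoAcidSequence(str(cell).strip().upper(), role)
            if Role.PEPTIDE not in seqs:
                raise ValueError("peptide is missing")
            label = None
            if has_label and not pd.isna(row["label"]):
                label = float(row["label"])
            if require_label and label is None:
                raise ValueError("label is missing")
            sid = str(row["sample_id"]) if "sample_id" in df.columns else f"row_{pos}"
            records.append(SequenceRecord(sequences=seqs, label=label, sample_id=sid))
        except ValueError as e:
            if strict:
                raise ValueError(f"row {pos}: {e}") from e
            logger.warning("dropping row %d: %s", pos, e)
    return records


def read_dataset(path, require_label: bool = True, strict: bool = True) -> list[SequenceRecord]:
    """Read the CSV layout above into validated records."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    return records_from_dataframe(df, require_label=require_label, strict=strict)


def records_to_dataframe(records) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {"sample_id": rec.sample_id}
        for col, role in SEQUENCE_COLUMNS.items():
            row[col] = rec.sequences[role].residues if role in rec.sequences else ""
        row["label"] = rec.label
        rows.append(row)
    df = pd.DataFrame(rows)
    # drop sequence columns that are entirely absent
    for col in list(SEQUENCE_COLUMNS):
        if (df[col] == "").all():
            df = df.drop(columns=col)
    return df


def write_dataset(records, path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def train_test_split_records(records, test_fraction: float = 0.2, seed: int = 0):
    """Seeded shuffled split into (train, test)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_test = int(round(test_fraction * len(records)))
    test_idx = set(order[:n_test].tolist())
    train = [records[i] for i in range(len(records)) if i not in test_idx]
    test = [records[i] for i in sorted(test_idx)]
    return train, test


def classification_metrics(preds, labels, threshold: float = 0.5) -> dict:
    """AUROC, AUPR, F1 and accuracy (F1/accuracy at the given threshold)."""
    preds = np.asarray(preds, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC/AUPR need both classes present")
    hard = (preds >= threshold).astype(int)
    return {
        "auroc": float(roc_auc_score(labels, preds)),
        "aupr": float(average_precision_score(labels, preds)),
        "f1": float(f1_score(labels, hard)),
        "accuracy": float(accuracy_score(labels, hard)),
    }


def regression_metrics(preds, labels) -> dict:
    """MSE, RMSE and the R² coefficient."""
    preds = np.asarray(preds, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must have equal length")
    mse = float(mean_squared_error(labels, preds))
    return {"mse": mse, "rmse": float(np.sqrt(mse)), "r2": float(r2_score(labels, preds))}
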