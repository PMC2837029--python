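"""Delimited-text I/O and the aligned in-memory dataset container.

The interchange format is plain CSV/TSV: a clinical table with a sample-ID
column (the outcome may be one of its columns or a separate file), and a
molecular matrix with feature IDs.  Expression matrices conventionally come
features x samples; an explicit orientation flag transposes them — explicit
rather than auto-detected, to avoid silent transposition bugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Outcome, encode_outcome

logger = logging.getLogger("permboost")


@dataclass
class Dataset:
    """Row-aligned clinical block Z, molecular block X, and outcome y."""

    sample_ids: list[str]
    Z: np.ndarray
    X: np.ndarray
    y: Outcome
    covariate_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if n < 4:
            raise ValueError(f"need at least 4 samples, got {n}")
        if self.Z.shape[0] != n or self.X.shape[0] != n or self.y.n != n:
            raise ValueError("Z, X and y must be row-aligned on sample_ids")
        if self.Z.shape[1] != len(self.covariate_ids):
            raise ValueError("covariate_ids length mismatch")
        if self.X.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length mismatch")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]


def _read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited table, sniffing the delimiter unless given.

    Uses the exact (round-trip) float parser so a 17-significant-digit write
    followed by a read reproduces doubles bit-for-bit.
    """
    if delimiter is None:
        import csv

        with open(path, newline="") as fh:
            sample = fh.read(8192)
        try:
            delimiter = csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
        except csv.Error:
            delimiter = ","
    return pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")


def load_dataset(
    clinical_path: str | Path,
    molecular_path: str | Path,
    outcome_spec: str | Path,
    *,
    orientation: str = "samples_by_features",
    delimiter: str | None = None,
) -> Dataset:
    """Load and align clinical, molecular and outcome tables.

    Parameters
    ----------
    clinical_path
        Table with sample IDs in the first column and one column per
        clinical covariate; non-numeric covariates are dummy-encoded
        (reference level: first sorted level).
    molecular_path
        Numeric matrix with IDs in the first column/row per ``orientation``.
    outcome_spec
        Name of a column in the clinical table, or a path to a two-column
        (ID, label) file.
    orientation
        ``samples_by_features`` (default) or ``features_by_samples``
        (molecular matrix is transposed on load).
    delimiter
        Explicit delimiter; sniffed when omitted.

    Sample IDs are intersected across all blocks; the clinical file's order
    wins.  Rows with missing values in the outcome or the clinical
    covariates are dropped with a logged count.
    """
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    clin = _read_table(clinical_path, delimiter)
    clin.index = clin.index.astype(str)
    if clin.index.duplicated().any():
        raise ValueError("duplicate sample IDs in clinical table")

    # outcome: a clinical column, or a separate ID -> label file
    outcome_spec = str(outcome_spec)
    if outcome_spec in clin.columns:
        y_series = clin[outcome_spec]
        clin = clin.drop(columns=[outcome_spec])
    else:
        ytab = _read_table(outcome_spec, delimiter)
        ytab.index = ytab.index.astype(str)
        if ytab.shape[1] != 1:
            raise ValueError("outcome file must have exactly ID + one label column")
        y_series = ytab.iloc[:, 0]

    mol = _read_table(molecular_path, delimiter)
    if orientation == "features_by_samples":
        mol = mol.T
    mol.index = mol.index.astype(str)
    if mol.index.duplicated().any():
        raise ValueError("duplicate sample IDs in molecular table")
    bad = mol.columns[~mol.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValueError(f"non-numeric molecular values in column(s) {list(bad)[:5]}")

    ids = [s for s in clin.index if s in set(mol.index) & set(y_series.index)]
    if not ids:
        raise ValueError("no sample IDs shared by clinical, molecular and outcome")

    clin = clin.loc[ids]
    y_series = y_series.loc[ids]
    missing = clin.isna().any(axis=1) | y_series.isna()
    if missing.any():
        dropped = list(clin.index[missing])
        logger.info(
            "dropping %d sample(s) with missing clinical/outcome values: %s",
            len(dropped), dropped,
        )
        ids = [s for s in ids if s not in set(dropped)]
        clin, y_series = clin.loc[ids], y_series.loc[ids]

    clin_enc = pd.get_dummies(clin, drop_first=True, dtype=float)
    mol = mol.loc[ids]
    if mol.isna().any().any():
        raise ValueError("missing values in molecular matrix")

    return Dataset(
        sample_ids=ids,
        Z=clin_enc.to_numpy(dtype=float),
        X=mol.to_numpy(dtype=float),
        y=encode_outcome(y_series.to_numpy()),
        covariate_ids=[str(c) for c in clin_enc.columns],
        feature_ids=[str(c) for c in mol.columns],
    )


def save_dataset(ds: Dataset, out_dir: str | Path, delimiter: str = ",") -> dict:
    """Write a dataset as the CSV trio ``load_dataset`` reads back.

    Values are written with 17 significant digits so the round trip is
    lossless at double precision.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if delimiter == "\t" else "csv"
    clin_path = out / f"clinical.{ext}"
    mol_path = out / f"molecular.{ext}"

    clin = pd.DataFrame(ds.Z, index=ds.sample_ids, columns=ds.covariate_ids)
    clin["outcome"] = [
        ds.y.original_levels[1] if v > 0 else ds.y.original_levels[0]
        for v in ds.y.labels
    ]
    clin.index.name = "sample_id"
    clin.to_csv(clin_path, sep=delimiter, float_format="%.17g")

    mol = pd.DataFrame(ds.X, index=ds.sample_ids, columns=ds.feature_ids)
    mol.index.name = "sample_id"
    mol.to_csv(mol_path, sep=delimiter, float_format="%.17g")
    return {"clinical": str(clin_path), "molecular": str(mol_path)}
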