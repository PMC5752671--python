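"""Readers/writers for expression, drug-response and annotation tables.

All downstream statistics assume a genes x samples expression matrix and a
drugs x samples AUC matrix whose sample columns have been aligned with
:func:`align_samples`.  Matrices are stored as thin wrappers around a pandas
DataFrame so that IDs travel with the values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mergeprior")

#: cell contents treated as missing on read
MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}


class SampleMatrix:
    """A real matrix with row identifiers (genes or drugs) and sample columns.

    Parameters
    ----------
    row_ids : sequence of str
        Unique identifiers for the rows (gene symbols or drug names).
    sample_ids : sequence of str
        Unique identifiers for the columns.
    values : ndarray, shape (n_rows, n_samples)
        Finite real values.
    """

    _row_kind = "row"

    def __init__(self, row_ids, sample_ids, values):
        row_ids = [str(r) for r in row_ids]
        sample_ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=float)
        _check_unique(row_ids, f"{self._row_kind} id")
        _check_unique(sample_ids, "sample id")
        if values.shape != (len(row_ids), len(sample_ids)):
            raise ValueError(
                f"value shape {values.shape} does not match "
                f"{len(row_ids)} rows x {len(sample_ids)} samples"
            )
        self._df = pd.DataFrame(values, index=row_ids, columns=sample_ids)

    # -- basic accessors -------------------------------------------------
    @property
    def row_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def subset_samples(self, sample_ids) -> "SampleMatrix":
        out = object.__new__(type(self))
        out._df = self._df.loc[:, list(sample_ids)]
        return out

    def subset_rows(self, row_ids) -> "SampleMatrix":
        out = object.__new__(type(self))
        out._df = self._df.loc[list(row_ids), :]
        return out

    def __repr__(self):  # pragma: no cover - cosmetic
        p, n = self.shape
        return f"<{type(self).__name__} {p} {self._row_kind}s x {n} samples>"


class ExpressionMatrix(SampleMatrix):
    """Genes x samples log-scale expression values."""

    _row_kind = "gene"

    @property
    def gene_ids(self) -> list[str]:
        return self.row_ids


class DrugResponseMatrix(SampleMatrix):
    """Drugs x samples AUC values (lower AUC = more sensitive)."""

    _row_kind = "drug"

    @property
    def drug_ids(self) -> list[str]:
        return self.row_ids


@dataclass
class DrugClassAnnotation:
    """Mapping from drug to its mechanism-of-action class label(s)."""

    classes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __getitem__(self, drug_id: str) -> frozenset[str]:
        return self.classes[drug_id]

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.classes

    @property
    def drug_ids(self) -> list[str]:
        return list(self.classes)

    @property
    def class_labels(self) -> list[str]:
        return sorted({c for s in self.classes.values() for c in s})

    def drugs_in_class(self, label: str) -> set[str]:
        return {d for d, s in self.classes.items() if label in s}

    def restrict(self, drug_ids) -> "DrugClassAnnotation":
        keep = set(drug_ids)
        return DrugClassAnnotation(
            {d: s for d, s in self.classes.items() if d in keep}
        )

    def summary(self) -> dict[str, int]:
        labels = self.class_labels
        sizes = {c: len(self.drugs_in_class(c)) for c in labels}
        return {
            "n_drugs": len(self.classes),
            "n_classes": len(labels),
            "n_classes_multi_drug": sum(1 for c in labels if sizes[c] > 1),
            "n_multiclass_drugs": sum(
                1 for s in self.classes.values() if len(s) > 1
            ),
        }


def _check_unique(ids, what):
    seen, dupes = set(), []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise ValueError(f"duplicate {what}(s): {sorted(set(dupes))}")


def _sniff_delimiter(header_line: str) -> str:
    # supplementary tables come as either TSV or CSV
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_matrix(
    path,
    orientation: str = "rows-are-genes",
    max_missing_fraction: float = 0.2,
    impute: bool = True,
):
    """Read a delimited genes-x-samples (or drugs-x-samples) matrix.

    The file must have one header row of sample IDs and one leading ID
    column.  The delimiter is auto-detected (tab vs comma).  Missing cells
    (``""``, ``NA``, ``NaN``) are mean-imputed per row; rows with more than
    ``max_missing_fraction`` missing are dropped with a log record.

    Parameters
    ----------
    orientation : {"rows-are-genes", "rows-are-drugs"}
        Determines whether an :class:`ExpressionMatrix` or a
        :class:`DrugResponseMatrix` is returned.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)

    _check_unique(list(df.index), "row id")
    _check_unique(list(df.columns), "sample id")

    num = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = num.isna() & ~df.isin(MISSING_TOKENS) & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r}"
        )

    missing_frac = num.isna().mean(axis=1)
    drop = missing_frac > max_missing_fraction
    if drop.any():
        logger.warning(
            "%s: dropped %d row(s) with >%d%% missing: %s",
            path.name,
            int(drop.sum()),
            int(100 * max_missing_fraction),
            list(num.index[drop])[:10],
        )
        num = num.loc[~drop]
    if impute and num.isna().to_numpy().any():
        row_means = num.mean(axis=1)
        num = num.apply(lambda row: row.fillna(row_means[row.name]), axis=1)

    cls = ExpressionMatrix if orientation == "rows-are-genes" else DrugResponseMatrix
    if orientation not in ("rows-are-genes", "rows-are-drugs"):
        raise ValueError(f"unknown orientation {orientation!r}")
    return cls(list(num.index), list(num.columns), num.to_numpy())


def write_matrix(matrix: SampleMatrix, path, sep: str = "\t") -> None:
    """Write a matrix as delimited text at 10 significant digits."""
    df = matrix.to_frame()
    df.index.name = matrix._row_kind + "_id"
    df.to_csv(path, sep=sep, float_format="%.10g")


def align_samples(
    X: ExpressionMatrix, Y: DrugResponseMatrix
) -> tuple[ExpressionMatrix, DrugResponseMatrix]:
    """Restrict both matrices to their shared samples, identically ordered.

    The shared samples are returned in sorted order so the result does not
    depend on the column order of either input.  At least 3 shared samples
    are required (fewer makes every correlation degenerate).
    """
    shared = sorted(set(X.sample_ids) & set(Y.sample_ids))
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared sample(s) between expression and "
            "drug response; need at least 3"
        )
    dropped_x = sorted(set(X.sample_ids) - set(shared))
    dropped_y = sorted(set(Y.sample_ids) - set(shared))
    if dropped_x:
        logger.info("align_samples: dropped from expression: %s", dropped_x)
    if dropped_y:
        logger.info("align_samples: dropped from drug response: %s", dropped_y)
    return X.subset_samples(shared), Y.subset_samples(shared)


def assert_aligned(X: SampleMatrix, Y: SampleMatrix) -> None:
    if X.sample_ids != Y.sample_ids:
        raise ValueError("matrices are not sample-aligned; call align_samples")


def read_drug_classes(path) -> DrugClassAnnotation:
    """Read a two-column drug_id / class-label table.

    Repeated drug rows encode multi-class membership.  Drugs are expected to
    carry one or two mechanism classes; more than two triggers a warning.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty drug-class file")
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment=None)
    # tolerate an optional header line
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (drug_id, class)")
    first = df.iloc[0]
    if str(first[0]).lower() in {"drug", "drug_id"}:
        df = df.iloc[1:]
    mapping: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        drug, label = str(row[0]).strip(), str(row[1]).strip()
        if label in MISSING_TOKENS:
            raise ValueError(f"{path}: empty class label for drug {drug!r}")
        mapping.setdefault(drug, set()).add(label)
    for drug, labels in mapping.items():
        if len(labels) > 2:
            warnings.warn(
                f"drug {drug!r} carries {len(labels)} classes; "
                "screens of this kind annotate at most two",
                stacklevel=2,
            )
    ann = DrugClassAnnotation({d: frozenset(s) for d, s in mapping.items()})
    logger.info("read_drug_classes: %s", ann.summary())
    return ann


def load_config(path) -> dict:
    """Load a flat YAML config (thresholds, subset size, seeds)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return dict(cfg)
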