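"""Dataset container and readers/writers.

A study is three pieces: a features x cells numeric matrix, a cell table
mapping each cell to its subject, and a subject table mapping each subject
to a condition plus optional covariates.  `read_dataset` validates the
cross-references strictly — orphan cells, unknown subjects, duplicate ids
and non-numeric entries are hard errors, never silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = ["ClusteredExpression", "read_dataset", "write_dataset", "write_results"]

RESULT_COLUMNS = [
    "feature_id",
    "pi_estimate",
    "statistic",
    "p_value",
    "q_value",
    "de_call",
    "status",
    "n_case_subjects",
    "n_control_subjects",
]


@dataclass
class ClusteredExpression:
    """Features x cells matrix with its subject/condition structure.

    cells    : DataFrame with columns ``cell_id``, ``subject_id``, aligned
               with the matrix columns.
    subjects : DataFrame with ``subject_id``, ``condition`` and any covariate
               columns; a ``cell_count`` column is (re)computed on
               construction.
    """

    matrix: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    cells: pd.DataFrame
    subjects: pd.DataFrame
    condition_col: str = "condition"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        nf, nc = self.matrix.shape
        if len(self.feature_ids) != nf:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {nf} matrix rows"
            )
        if len(self.cell_ids) != nc:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {nc} matrix columns")
        for frame, key in ((self.cells, "cell_id"), (self.subjects, "subject_id")):
            dup = frame[key][frame[key].duplicated()]
            if len(dup):
                raise ValueError(f"duplicate {key}: {sorted(set(dup))}")
        if list(self.cells["cell_id"]) != list(self.cell_ids):
            raise ValueError("cell table must list the matrix columns in order")
        known = set(self.subjects["subject_id"])
        orphans = [s for s in self.cells["subject_id"] if s not in known]
        if orphans:
            raise ValueError(f"cells reference unknown subjects: {sorted(set(orphans))}")
        if self.condition_col not in self.subjects.columns:
            raise ValueError(f"subject table lacks a {self.condition_col!r} column")
        counts = self.cells["subject_id"].value_counts()
        self.subjects = self.subjects.copy()
        self.subjects["cell_count"] = (
            self.subjects["subject_id"].map(counts).fillna(0).astype(int)
        )

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def conditions(self) -> list[str]:
        return sorted(self.subjects[self.condition_col].unique())

    def subjects_of(self, condition: str) -> list[str]:
        sel = self.subjects[self.subjects[self.condition_col] == condition]
        return list(sel["subject_id"])

    def cell_matrix(self, subject_id: str) -> np.ndarray:
        """Features x K submatrix of one subject's cells."""
        mask = (self.cells["subject_id"] == subject_id).to_numpy()
        return self.matrix[:, mask]

    def covariate_matrix(
        self, columns: list[str], subject_order: list[str]
    ) -> np.ndarray:
        tab = self.subjects.set_index("subject_id").loc[subject_order, columns]
        arr = tab.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite covariate values in columns {columns}")
        return arr


def _read_table(path, what: str) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    if tab.columns.duplicated().any():
        raise ValueError(f"{what} table {path} has duplicate column names")
    return tab


def read_dataset(
    counts_path,
    cells_path,
    subjects_path,
    fmt: str = "mtx",
    condition_col: str = "condition",
) -> ClusteredExpression:
    """Load a study from disk.

    fmt="mtx": MatrixMarket counts (features as rows) with feature / cell
    ids taken from the metadata tables; fmt="tsv": a dense table whose first
    column is the feature id and remaining columns are cells.  The cell
    table needs ``cell_id`` and ``subject_id`` columns; the subject table
    needs ``subject_id`` and the condition column.
    """
    cells = _read_table(cells_path, "cell")
    subjects = _read_table(subjects_path, "subject")
    for col in ("cell_id", "subject_id"):
        if col not in cells.columns:
            raise ValueError(f"cell table {cells_path} lacks column {col!r}")
    if "subject_id" not in subjects.columns:
        raise ValueError(f"subject table {subjects_path} lacks column 'subject_id'")
    if fmt == "mtx":
        mat = spio.mmread(str(counts_path))
        mat = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        feature_ids = [f"feature{i}" for i in range(mat.shape[0])]
        cell_ids = list(cells["cell_id"])
        if mat.shape[1] != len(cell_ids):
            raise ValueError(
                f"matrix has {mat.shape[1]} columns but cell table lists "
                f"{len(cell_ids)} cells"
            )
    elif fmt == "tsv":
        dense = pd.read_csv(counts_path, sep="\t", index_col=0)
        bad = dense.columns[dense.dtypes == object]
        if len(bad):
            raise ValueError(f"non-numeric entries in columns {list(bad)}")
        feature_ids = [str(f) for f in dense.index]
        cell_ids = [str(c) for c in dense.columns]
        mat = dense.to_numpy(dtype=float)
        if cell_ids != list(cells["cell_id"].astype(str)):
            raise ValueError("matrix columns and cell table disagree on cell ids")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not np.all(np.isfinite(mat)):
        raise ValueError("count matrix contains non-finite values")
    return ClusteredExpression(
        matrix=mat,
        feature_ids=feature_ids,
        cell_ids=list(cells["cell_id"]),
        cells=cells,
        subjects=subjects,
        condition_col=condition_col,
    )


def write_dataset(data: ClusteredExpression, counts_path, cells_path, subjects_path):
    """Write a study as MatrixMarket counts + two TSV metadata tables."""
    spio.mmwrite(str(counts_path), sparse.csr_matrix(data.matrix))
    data.cells.to_csv(cells_path, sep="\t", index=False)
    data.subjects.drop(columns=["cell_count"], errors="ignore").to_csv(
        subjects_path, sep="\t", index=False
    )


def write_results(table: pd.DataFrame, path) -> None:
    """Write a DE result table as TSV: fixed column order, 6 significant
    digits, booleans as true/false literals."""
    out = table.copy()
    cols = [c for c in RESULT_COLUMNS if c in out.columns] + [
        c for c in out.columns if c not in RESULT_COLUMNS
    ]
    out = out[cols]
    if "de_call" in out.columns:
        out["de_call"] = out["de_call"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
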