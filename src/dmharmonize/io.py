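"""Reading and writing connectivity matrices and subject metadata.

Connectivity is handled in two shapes: per-subject square symmetric matrix
files (whitespace- or comma-delimited text, auto-detected) and an in-memory
:class:`ConnectivityTable` whose rows are subjects and whose columns are the
vectorized strict upper triangle of the matrix (0-based region indices
``(i, j)`` with ``i < j``, row-major).  Diagonal entries are ignored on read
and written as zero; asymmetric inputs are symmetrized by averaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityTable",
    "SubjectMetadata",
    "pair_index",
    "vectorize_matrix",
    "devectorize_row",
    "read_connectivity_matrices",
    "write_connectivity_matrices",
    "read_metadata",
    "write_metadata",
    "read_stacked_table",
    "write_stacked_table",
]

REQUIRED_METADATA_COLUMNS = ("subject_id", "site")


def pair_index(n_regions: int) -> list[tuple[int, int]]:
    """Ordered (i, j) region pairs of the strict upper triangle, row-major."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    iu, ju = np.triu_indices(n_regions, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


@dataclass
class ConnectivityTable:
    """Subjects-by-connections matrix of non-negative connectivity values.

    Parameters
    ----------
    values
        Array of shape ``(n_subjects, n_connections)`` with
        ``n_connections = n_regions * (n_regions - 1) / 2``.
    subject_ids
        Unique subject labels, one per row.
    n_regions
        Number of brain regions R of the underlying square matrices.
    """

    values: np.ndarray
    subject_ids: list[str]
    n_regions: int
    pair_index: list[tuple[int, int]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x connections)")
        n_conn = self.n_regions * (self.n_regions - 1) // 2
        if self.values.shape[1] != n_conn:
            raise ValueError(
                f"expected {n_conn} connections for {self.n_regions} regions, "
                f"got {self.values.shape[1]}"
            )
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("one subject id per row required")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")
        if np.isnan(self.values).any():
            raise ValueError("connectivity values must not contain NaN")
        if (self.values < 0).any():
            raise ValueError("connectivity values must be non-negative")
        if self.pair_index is None:
            self.pair_index = pair_index(self.n_regions)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_connections(self) -> int:
        return self.values.shape[1]

    def matrix(self, subject: int | str) -> np.ndarray:
        """The square symmetric matrix of one subject (zero diagonal)."""
        row = subject if isinstance(subject, int) else self.subject_ids.index(subject)
        return devectorize_row(self.values[row], self.n_regions)

    def with_values(self, values: np.ndarray) -> "ConnectivityTable":
        """A copy of this table carrying new values."""
        return ConnectivityTable(
            values=values,
            subject_ids=list(self.subject_ids),
            n_regions=self.n_regions,
        )


def vectorize_matrix(mat: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a square matrix, row-major."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("matrix must be square")
    iu, ju = np.triu_indices(mat.shape[0], k=1)
    return mat[iu, ju]


def devectorize_row(row: np.ndarray, n_regions: int) -> np.ndarray:
    """Rebuild the symmetric matrix (zero diagonal) from an upper-triangle row."""
    row = np.asarray(row, dtype=float)
    mat = np.zeros((n_regions, n_regions))
    iu, ju = np.triu_indices(n_regions, k=1)
    if row.size != iu.size:
        raise ValueError("row length does not match n_regions")
    mat[iu, ju] = row
    mat[ju, iu] = row
    return mat


def _load_matrix(path: Path) -> np.ndarray:
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        mat = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric matrix content") from exc
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({mat.shape})")
    if np.isnan(mat).any():
        raise ValueError(f"{path}: matrix contains NaN")
    if (mat < 0).any():
        raise ValueError(f"{path}: matrix contains negative values")
    return mat


def read_connectivity_matrices(
    paths: list[str | Path], subject_ids: list[str] | None = None
) -> ConnectivityTable:
    """Read per-subject square matrix files into a ConnectivityTable.

    Matrices are symmetrized by averaging the (i, j) and (j, i) entries;
    diagonals are discarded.  All files must share one dimension.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no matrix files given")
    if subject_ids is None:
        subject_ids = [p.stem for p in paths]
    if len(subject_ids) != len(paths):
        raise ValueError("one subject id per file required")
    rows = []
    n_regions = None
    for path in paths:
        mat = _load_matrix(path)
        if n_regions is None:
            n_regions = mat.shape[0]
        elif mat.shape[0] != n_regions:
            raise ValueError(
                f"{path}: dimension {mat.shape[0]} differs from first file ({n_regions})"
            )
        rows.append(vectorize_matrix((mat + mat.T) / 2.0))
    return ConnectivityTable(
        values=np.vstack(rows), subject_ids=list(subject_ids), n_regions=n_regions
    )


def write_connectivity_matrices(
    table: ConnectivityTable, out_dir: str | Path, delimiter: str = ","
) -> list[Path]:
    """Write one square symmetric matrix file per subject; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for k, sid in enumerate(table.subject_ids):
        path = out_dir / f"{sid}.csv"
        # %.17g round-trips float64 exactly through text
        np.savetxt(path, table.matrix(k), fmt="%.17g", delimiter=delimiter)
        written.append(path)
    return written


def write_stacked_table(table: ConnectivityTable, path: str | Path) -> Path:
    """Write the subjects-by-connections table as TSV with a JSON sidecar.

    The sidecar (``<path>.json``) records ``n_regions`` and ``pair_index`` so
    the table can be devectorized without the original matrix files.
    """
    path = Path(path)
    cols = [f"c_{i}_{j}" for i, j in table.pair_index]
    df = pd.DataFrame(table.values, columns=cols)
    df.insert(0, "subject_id", table.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = path.with_name(path.name + ".json")
    sidecar.write_text(
        json.dumps(
            {"n_regions": table.n_regions, "pair_index": [list(p) for p in table.pair_index]}
        )
    )
    return path


def read_stacked_table(path: str | Path) -> ConnectivityTable:
    """Read a stacked subjects-by-connections TSV written by write_stacked_table."""
    path = Path(path)
    sidecar = path.with_name(path.name + ".json")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str},
                     float_precision="round_trip")
    return ConnectivityTable(
        values=df.drop(columns="subject_id").to_numpy(dtype=float),
        subject_ids=df["subject_id"].tolist(),
        n_regions=int(meta["n_regions"]),
    )


class SubjectMetadata:
    """Per-subject site, sex, and continuous covariates.

    Wraps a DataFrame indexed by ``subject_id`` with a ``site`` column, an
    optional ``sex`` column, and any further columns treated as covariates.
    Missing covariate or sex entries are preserved as NaN; downstream analyses
    drop incomplete subjects themselves.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.name != "subject_id":
            if "subject_id" not in frame.columns:
                raise ValueError("metadata requires a subject_id column")
            frame["subject_id"] = frame["subject_id"].astype(str)
            frame = frame.set_index("subject_id")
        if frame.index.duplicated().any():
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        if "site" not in frame.columns:
            raise ValueError("metadata requires a site column")
        if frame["site"].isna().any():
            raise ValueError("site must be non-missing for every subject")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sites(self) -> list[str]:
        return sorted(self.frame["site"].astype(str).unique().tolist())

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("site", "sex")]

    def site_of(self, subject_ids: list[str]) -> pd.Series:
        return self.frame.loc[list(subject_ids), "site"].astype(str)

    def sex_of(self, subject_ids: list[str]) -> pd.Series:
        if "sex" not in self.frame.columns:
            raise KeyError("metadata has no sex column")
        return self.frame.loc[list(subject_ids), "sex"]

    def covariate(self, name: str, subject_ids: list[str]) -> np.ndarray:
        """Covariate values aligned to the given subject order (NaN = missing)."""
        if name not in self.frame.columns:
            raise KeyError(f"unknown covariate: {name}")
        return self.frame.loc[list(subject_ids), name].to_numpy(dtype=float)

    def subset(self, subject_ids: list[str]) -> "SubjectMetadata":
        return SubjectMetadata(self.frame.loc[list(subject_ids)].reset_index())


def read_metadata(path: str | Path) -> SubjectMetadata:
    """Read a delimited metadata table (header row; subject_id and site required)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"subject_id": str})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    return SubjectMetadata(df)


def write_metadata(meta: SubjectMetadata, path: str | Path) -> Path:
    path = Path(path)
    meta.frame.reset_index().to_csv(path, sep="\t", index=False)
    return path
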