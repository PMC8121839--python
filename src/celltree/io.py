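"""Reading and writing expression matrices, label tables and models.

Expression matrices are accepted either as dense TSV/CSV (cells in rows,
genes in columns, with a header row of gene names and a first column of cell
ids) or as Matrix Market triplet files with ``<stem>_genes.tsv`` and
``<stem>_cells.tsv`` sidecars holding the row/column names, one per line.
Cells-by-genes is the canonical orientation everywhere; an MTX file stored
genes-by-cells is transposed based on the sidecar lengths.
"""

from __future__ import annotations

from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}_genes.tsv"), Path(f"{stem}_cells.tsv")


def _read_names(path: Path) -> np.ndarray:
    return np.array(
        [line.rstrip("\n") for line in path.read_text().splitlines() if line.strip()],
        dtype=object,
    )


def read_expression(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an expression matrix.

    Returns
    -------
    (matrix, gene_names, cell_ids) with the matrix cells-by-genes.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        genes_path, cells_path = _sidecar_paths(path)
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FileNotFoundError(f"missing sidecar file {p}")
        genes = _read_names(genes_path)
        cells = _read_names(cells_path)
        M = spio.mmread(path)
        M = M.toarray() if sparse.issparse(M) else np.asarray(M)
        if M.shape == (len(cells), len(genes)):
            pass
        elif M.shape == (len(genes), len(cells)):
            M = M.T
        else:
            raise ValueError(
                f"matrix shape {M.shape} matches neither {len(cells)} cells x "
                f"{len(genes)} genes nor its transpose"
            )
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        genes = np.array(header[1:], dtype=object)  # pandas mangles duplicates
        df = pd.read_csv(
            path, sep=sep, index_col=0, header=None, skiprows=1,
            names=["__cell__", *range(len(genes))],
        )
        cells = df.index.to_numpy(dtype=object).astype(str)
        M = df.to_numpy(dtype=float)
    dup = pd.Index(genes)[pd.Index(genes).duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate gene names: {sorted(set(dup))[:10]}")
    return np.asarray(M, dtype=float), genes, cells


def write_expression(path, matrix, gene_names, cell_ids) -> None:
    """Write a cells-by-genes matrix as dense TSV/CSV or MTX with sidecars."""
    path = Path(path)
    matrix = np.asarray(matrix)
    if path.suffix == ".mtx":
        genes_path, cells_path = _sidecar_paths(path)
        genes_path.write_text("\n".join(map(str, gene_names)) + "\n")
        cells_path.write_text("\n".join(map(str, cell_ids)) + "\n")
        spio.mmwrite(str(path), sparse.coo_matrix(matrix))
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        pd.DataFrame(matrix, index=cell_ids, columns=gene_names).to_csv(
            path, sep=sep
        )


def read_labels(path, cell_ids) -> np.ndarray:
    """Read a two-column (cell_id, label) table aligned to ``cell_ids``.

    The header row is optional; rows may come in any order.  Missing or
    extra cell ids raise an error listing up to ten offenders.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"expected two columns in {path}, got {df.shape[1]}")
    cell_ids = np.asarray(cell_ids, dtype=object).astype(str)
    id_set = set(cell_ids)
    if df.iloc[0, 0] not in id_set:  # header row
        df = df.iloc[1:]
    df.columns = ["cell_id", "label"]
    if df["label"].isna().any() or (df["label"].str.strip() == "").any():
        raise ValueError("empty label values in the label table")
    extra = sorted(set(df["cell_id"]) - id_set)
    missing = sorted(id_set - set(df["cell_id"]))
    if extra or missing:
        raise ValueError(
            f"label table does not match the matrix; "
            f"missing ids: {missing[:10]}, extra ids: {extra[:10]}"
        )
    mapping = dict(zip(df["cell_id"], df["label"]))
    return np.array([mapping[c] for c in cell_ids], dtype=object)


def write_labels(path, cell_ids, labels, header: bool = True) -> None:
    df = pd.DataFrame({"cell_id": cell_ids, "label": labels})
    df.to_csv(path, sep="\t", index=False, header=header)


def save_model(model, path) -> None:
    """Persist a fitted estimator (single binary archive)."""
    joblib.dump(model, path)


def load_model(path):
    return joblib.load(path)
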