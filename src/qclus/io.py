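"""Readers and writers for droplet count matrices and filter results.

Supported inputs: an MTX directory (``matrix.mtx`` plus barcode and feature
tables, the layout droplet preprocessors emit), an ``.h5ad`` file, a
loom-style HDF5 container with ``spliced``/``unspliced``/``ambiguous``
layers, and a two-column table of precomputed per-droplet unspliced
fractions. Outputs: a retained-barcode list, a per-droplet TSV report and a
YAML run manifest sufficient to reproduce the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import FilterResult

LAYER_KEYS = ("spliced", "unspliced", "ambiguous")


class MatrixFormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass
class DropletMatrix:
    """Sparse droplets x genes counts with optional splicing layers.

    ``layers``, when present, holds sparse matrices of the same shape as
    ``counts`` keyed ``spliced``/``unspliced``/``ambiguous``. Their per-entry
    sum need not equal ``counts``: they typically originate from a separate
    read-annotation run. ``splicing_available`` marks droplets for which the
    unspliced fraction can be computed (from layers or a precomputed table).
    """

    counts: sp.csr_matrix
    barcodes: np.ndarray
    genes: np.ndarray
    layers: dict[str, sp.csr_matrix] = field(default_factory=dict)
    splicing_available: np.ndarray | None = None
    unspliced_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.genes = np.asarray(self.genes, dtype=object)
        n, g = self.counts.shape
        if len(self.barcodes) != n:
            raise MatrixFormatError(
                f"matrix has {n} rows but {len(self.barcodes)} barcodes"
            )
        if len(self.genes) != g:
            raise MatrixFormatError(
                f"matrix has {g} columns but {len(self.genes)} gene symbols"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise MatrixFormatError("count matrix contains negative entries")
        for key, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise MatrixFormatError(
                    f"layer {key!r} shape {layer.shape} != counts shape {self.counts.shape}"
                )

    @property
    def n_droplets(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def set_unspliced_fractions(self, fractions: Mapping[str, float]) -> None:
        """Attach precomputed per-droplet unspliced fractions by barcode."""
        frac = np.full(self.n_droplets, np.nan)
        avail = np.zeros(self.n_droplets, dtype=bool)
        for i, bc in enumerate(self.barcodes):
            if bc in fractions:
                frac[i] = fractions[bc]
                avail[i] = True
        if not avail.any():
            raise MatrixFormatError(
                "no barcode overlap between matrix and unspliced-fraction table"
            )
        self.unspliced_fraction = frac
        self.splicing_available = avail


def _read_table_column(path: Path, column: int = 0) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if column >= df.shape[1]:
        raise MatrixFormatError(
            f"{path.name}: expected at least {column + 1} column(s), found {df.shape[1]}"
        )
    return df.iloc[:, column].to_numpy(dtype=object)


def _find_one(directory: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        p = directory / stem
        if p.is_file():
            return p
    raise MatrixFormatError(
        f"{directory}: none of {', '.join(stems)} found"
    )


def read_matrix(path: str | Path) -> DropletMatrix:
    """Read a droplet matrix from an MTX directory or an ``.h5ad`` file.

    MTX directories must contain ``matrix.mtx``, ``barcodes.tsv`` and
    ``features.tsv`` (or ``genes.tsv``). The MTX convention stores genes as
    rows; the returned matrix is droplets x genes. Gene symbols come from
    the feature table's symbol column (second column when present).
    """
    path = Path(path)
    if path.is_file() and path.suffix == ".h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        return DropletMatrix(
            counts=sp.csr_matrix(adata.X),
            barcodes=adata.obs_names.to_numpy(dtype=object),
            genes=adata.var_names.to_numpy(dtype=object),
            layers={
                k: sp.csr_matrix(v) for k, v in adata.layers.items() if k in LAYER_KEYS
            },
        )
    if not path.is_dir():
        raise MatrixFormatError(f"{path}: not an MTX directory or .h5ad file")
    mtx_path = _find_one(path, ("matrix.mtx",))
    try:
        mat = scipy.io.mmread(mtx_path)
    except ValueError as exc:
        raise MatrixFormatError(f"{mtx_path}: unreadable MTX file ({exc})") from exc
    mat = sp.csr_matrix(mat.T)  # stored genes x barcodes
    barcodes = _read_table_column(_find_one(path, ("barcodes.tsv",)))
    feat_path = _find_one(path, ("features.tsv", "genes.tsv"))
    feat = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    genes = feat.iloc[:, 1 if feat.shape[1] > 1 else 0].to_numpy(dtype=object)
    return DropletMatrix(counts=mat, barcodes=barcodes, genes=genes)


def attach_layers(matrix: DropletMatrix, path: str | Path) -> DropletMatrix:
    """Join spliced/unspliced/ambiguous layers from a loom-style container.

    The container is HDF5 in the loom dialect: a genes x cells ``/matrix``,
    per-layer datasets under ``/layers`` and barcodes in
    ``/col_attrs/CellID``. Layers are joined to ``matrix`` by barcode
    intersection (and by gene symbol where the container provides
    ``/row_attrs/Gene`` symbols present in the matrix); droplets absent from
    the container are flagged as lacking splicing information. Zero barcode
    overlap is an error.
    """
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as f:
        if "col_attrs" not in f or "CellID" not in f["col_attrs"]:
            raise MatrixFormatError(f"{path}: no /col_attrs/CellID barcode table")
        loom_bcs = np.array(
            [b.decode() if isinstance(b, bytes) else str(b) for b in f["col_attrs/CellID"][:]],
            dtype=object,
        )
        missing = [k for k in LAYER_KEYS if f"layers/{k}" not in f]
        if missing:
            raise MatrixFormatError(f"{path}: missing layer(s) {missing}")
        raw_layers = {k: np.asarray(f[f"layers/{k}"][:]) for k in LAYER_KEYS}
        loom_genes = None
        if "row_attrs" in f and "Gene" in f["row_attrs"]:
            loom_genes = np.array(
                [g.decode() if isinstance(g, bytes) else str(g) for g in f["row_attrs/Gene"][:]],
                dtype=object,
            )

    bc_to_row = {bc: i for i, bc in enumerate(matrix.barcodes)}
    col_idx = [(j, bc_to_row[bc]) for j, bc in enumerate(loom_bcs) if bc in bc_to_row]
    if not col_idx:
        raise MatrixFormatError(
            f"{path}: zero barcode overlap with the count matrix"
        )
    avail = np.zeros(matrix.n_droplets, dtype=bool)
    layers: dict[str, sp.csr_matrix] = {}
    gene_map: list[tuple[int, int]] | None = None
    if loom_genes is not None:
        g_to_col = {g: i for i, g in enumerate(matrix.genes)}
        gene_map = [(i, g_to_col[g]) for i, g in enumerate(loom_genes) if g in g_to_col]
    for key, arr in raw_layers.items():
        out = sp.lil_matrix(matrix.counts.shape, dtype=arr.dtype)
        for loom_col, mat_row in col_idx:
            col = arr[:, loom_col]
            if gene_map is not None:
                for loom_row, mat_col in gene_map:
                    if col[loom_row]:
                        out[mat_row, mat_col] = col[loom_row]
            else:
                if arr.shape[0] != matrix.n_genes:
                    raise MatrixFormatError(
                        f"{path}: layer gene dimension {arr.shape[0]} does not match "
                        f"matrix ({matrix.n_genes}) and no /row_attrs/Gene to join on"
                    )
                out[mat_row, :] = col
            avail[mat_row] = True
        layers[key] = sp.csr_matrix(out)
    matrix.layers.update(layers)
    matrix.splicing_available = avail
    return matrix


def read_unspliced_table(path: str | Path) -> dict[str, float]:
    """Read a two-column barcode / unspliced-fraction table (TSV).

    Accepts an optional header row. Fractions must lie in [0, 1]; an empty
    table is an error. The result can stand in for layer-derived fractions
    in the pipeline.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise MatrixFormatError(f"{path}: expected two columns")
    # tolerate a header row of non-numeric text
    try:
        float(df.iloc[0, 1])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    if df.empty:
        raise MatrixFormatError(f"{path}: table has no data rows")
    fractions = df.iloc[:, 1].astype(float)
    if ((fractions < 0) | (fractions > 1)).any():
        bad = df.loc[(fractions < 0) | (fractions > 1)].iloc[0, 0]
        raise MatrixFormatError(
            f"{path}: unspliced fraction outside [0, 1] (first offender: barcode {bad})"
        )
    return dict(zip(df.iloc[:, 0], fractions))


def write_matrix(matrix: DropletMatrix, out_dir: str | Path) -> None:
    """Write an MTX directory (plus layer MTX files when layers exist)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(matrix.counts.T))
    pd.Series(matrix.barcodes).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.DataFrame({"id": matrix.genes, "symbol": matrix.genes}).to_csv(
        out / "features.tsv", sep="\t", index=False, header=False
    )
    for key, layer in matrix.layers.items():
        scipy.io.mmwrite(out / f"{key}.mtx", sp.coo_matrix(layer.T))


def read_layer_mtx(matrix: DropletMatrix, directory: str | Path) -> DropletMatrix:
    """Attach layers stored as ``spliced.mtx``/... alongside a matrix directory."""
    directory = Path(directory)
    for key in LAYER_KEYS:
        p = directory / f"{key}.mtx"
        if not p.is_file():
            raise MatrixFormatError(f"{directory}: missing {key}.mtx")
        matrix.layers[key] = sp.csr_matrix(scipy.io.mmread(p).T)
        if matrix.layers[key].shape != matrix.counts.shape:
            raise MatrixFormatError(f"{p}: shape does not match counts")
    matrix.splicing_available = np.ones(matrix.n_droplets, dtype=bool)
    return matrix


def write_results(result: "FilterResult", out_dir: str | Path) -> dict[str, Path]:
    """Write the retained-barcode list, per-droplet report and run manifest.

    Returns the paths written, keyed ``barcodes``/``report``/``manifest``.
    Barcode order in both outputs matches the input matrix order.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "barcodes": out / "retained_barcodes.txt",
        "report": out / "droplet_report.tsv",
        "manifest": out / "manifest.yaml",
    }
    retained = result.report.loc[result.report["status"] == "retained", "barcode"]
    paths["barcodes"].write_text("\n".join(retained) + ("\n" if len(retained) else ""))
    result.report.to_csv(paths["report"], sep="\t", index=False)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(result.manifest(), fh, sort_keys=False)
    return paths


def read_manifest(path: str | Path) -> dict:
    """Load a run manifest written by :func:`write_results`."""
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
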