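"""Per-droplet quality metrics.

Six clustering features drive the filtering: the unspliced read fraction
(high in nuclear RNA, low in cytoplasmic ambient contamination), the
mitochondrial count percentage (mitochondria are cytoplasmic, so this
tracks contamination), the nuclear-enriched gene fraction computed on
log1p-transformed counts, the nuclear and cytoplasmic cardiomyocyte marker
percentages, and the maximum percentage over the non-CM cell-type marker
sets. Alongside them the table carries detected-gene and total-count base
QC quantities.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genesets import GeneSetRegistry, resolve
from .io import DropletMatrix

#: Feature-table columns, in canonical order. doublet_score is filled by the
#: pipeline's doublet step and is NaN until then.
FEATURE_COLUMNS = [
    "total_counts",
    "n_genes",
    "fraction_unspliced",
    "pct_mito",
    "nuclear_fraction",
    "pct_cm_nuclear",
    "pct_cm_cyto",
    "pct_nonCM_max",
    "doublet_score",
]

#: The clustering features for heart tissue, in the default ordering.
HEART_FEATURES = [
    "fraction_unspliced",
    "pct_mito",
    "nuclear_fraction",
    "pct_cm_nuclear",
    "pct_cm_cyto",
    "pct_nonCM_max",
]

#: Brain runs drop the two cardiomyocyte-specific features.
BRAIN_FEATURES = ["fraction_unspliced", "pct_mito", "nuclear_fraction", "pct_nonCM_max"]


def unspliced_fraction(spliced, unspliced, ambiguous):
    """Unspliced reads over all annotated reads (spliced + unspliced + ambiguous).

    Returns NaN where the denominator is zero. Scalar or array inputs;
    negative counts are an error.
    """
    s = np.asarray(spliced, dtype=float)
    u = np.asarray(unspliced, dtype=float)
    a = np.asarray(ambiguous, dtype=float)
    if (s < 0).any() or (u < 0).any() or (a < 0).any():
        raise ValueError("read counts must be non-negative")
    total = s + u + a
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, u / np.where(total > 0, total, 1), np.nan)
    return float(frac) if frac.ndim == 0 else frac


def _row_vector(row) -> np.ndarray:
    if sp.issparse(row):
        return np.asarray(row.todense()).ravel().astype(float)
    return np.asarray(row, dtype=float).ravel()


def gene_set_percentage(
    row, indices: Sequence[int], log_transform: bool = False
) -> float:
    """Percent of a droplet's counts falling in a gene set.

    With ``log_transform`` the ratio is computed on element-wise
    ``log1p(count)`` values instead of raw counts (the nuclear-fraction
    convention). A zero (transformed) total yields 0.
    """
    vec = _row_vector(row)
    if (vec < 0).any():
        raise ValueError("counts must be non-negative")
    if log_transform:
        vec = np.log1p(vec)
    total = vec.sum()
    if total == 0:
        return 0.0
    return 100.0 * vec[np.asarray(indices, dtype=int)].sum() / total


def max_celltype_percentage(row, celltype_indices: Mapping[str, Sequence[int]]) -> float:
    """Maximum raw-count gene-set percentage over the cell-type marker sets."""
    if not celltype_indices:
        raise ValueError("no cell-type marker sets provided")
    return max(gene_set_percentage(row, idx) for idx in celltype_indices.values())


def _set_percent_matrix(
    X: sp.csr_matrix, indices: Sequence[int], totals: np.ndarray
) -> np.ndarray:
    s = np.asarray(X[:, np.asarray(indices, dtype=int)].sum(axis=1)).ravel()
    return np.where(totals > 0, 100.0 * s / np.where(totals > 0, totals, 1), 0.0)


def _layer_fraction_unspliced(matrix: DropletMatrix) -> np.ndarray:
    sums = {
        k: np.asarray(matrix.layers[k].sum(axis=1)).ravel()
        for k in ("spliced", "unspliced", "ambiguous")
    }
    return unspliced_fraction(sums["spliced"], sums["unspliced"], sums["ambiguous"])


def build_feature_table(
    matrix: DropletMatrix,
    registry: GeneSetRegistry,
    resolved: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Compute the per-droplet QC feature table.

    Rows follow the matrix barcode order; the index is the barcode. The
    unspliced fraction comes from the matrix's splicing layers when all
    three are attached, otherwise from precomputed per-droplet fractions
    (see :meth:`DropletMatrix.set_unspliced_fractions`); droplets without
    either are NaN. Cardiomyocyte columns are only present when the
    registry declares the corresponding sets (heart yes, brain no).
    """
    if resolved is None:
        resolved = resolve(registry, matrix.genes)
    X = sp.csr_matrix(matrix.counts, dtype=float)
    X.eliminate_zeros()
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)

    Xlog = X.copy()
    Xlog.data = np.log1p(Xlog.data)
    log_totals = np.asarray(Xlog.sum(axis=1)).ravel()

    if all(k in matrix.layers for k in ("spliced", "unspliced", "ambiguous")):
        frac_unspliced = _layer_fraction_unspliced(matrix)
        if matrix.splicing_available is not None:
            frac_unspliced = np.where(matrix.splicing_available, frac_unspliced, np.nan)
    elif matrix.unspliced_fraction is not None:
        frac_unspliced = matrix.unspliced_fraction.astype(float)
    else:
        frac_unspliced = np.full(matrix.n_droplets, np.nan)

    table = pd.DataFrame(index=pd.Index(matrix.barcodes, name="barcode"))
    table["total_counts"] = totals
    table["n_genes"] = n_genes
    table["fraction_unspliced"] = frac_unspliced
    mito = registry.single("mitochondrial")
    table["pct_mito"] = _set_percent_matrix(X, resolved[mito.name], totals)
    nuc = registry.single("nuclear_enriched")
    nuc_sum = np.asarray(Xlog[:, np.asarray(resolved[nuc.name], dtype=int)].sum(axis=1)).ravel()
    table["nuclear_fraction"] = np.where(
        log_totals > 0, nuc_sum / np.where(log_totals > 0, log_totals, 1), 0.0
    )
    for role, col in (("cm_nuclear", "pct_cm_nuclear"), ("cm_cytoplasmic", "pct_cm_cyto")):
        hits = registry.by_role(role)
        if hits:
            table[col] = _set_percent_matrix(X, resolved[hits[0].name], totals)
    ct_sets = registry.celltype_sets
    per_set = np.column_stack(
        [_set_percent_matrix(X, resolved[s.name], totals) for s in ct_sets]
    )
    table["pct_nonCM_max"] = per_set.max(axis=1)
    table["doublet_score"] = np.nan
    return table
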