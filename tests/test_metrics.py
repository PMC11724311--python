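"""Per-droplet QC metrics against independent brute-force oracles."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import qclus
from qclus.genesets import GeneSet, GeneSetRegistry, resolve
from qclus.metrics import gene_set_percentage, max_celltype_percentage, unspliced_fraction


def dense_oracle(dense, resolved, registry):
    """Naive per-droplet loop recomputation of every feature column."""
    n = dense.shape[0]
    out = {
        "total_counts": [],
        "n_genes": [],
        "pct_mito": [],
        "nuclear_fraction": [],
        "pct_cm_nuclear": [],
        "pct_cm_cyto": [],
        "pct_nonCM_max": [],
    }
    mito = resolved[registry.single("mitochondrial").name]
    nuc = resolved[registry.single("nuclear_enriched").name]
    cmn = resolved[registry.single("cm_nuclear").name]
    cmc = resolved[registry.single("cm_cytoplasmic").name]
    ct = [resolved[s.name] for s in registry.celltype_sets]
    for i in range(n):
        row = dense[i]
        total = row.sum()
        out["total_counts"].append(total)
        out["n_genes"].append(int((row > 0).sum()))
        pct = lambda idx: 100.0 * row[idx].sum() / total if total else 0.0
        out["pct_mito"].append(pct(mito))
        logrow = np.log1p(row)
        out["nuclear_fraction"].append(
            logrow[nuc].sum() / logrow.sum() if logrow.sum() else 0.0
        )
        out["pct_cm_nuclear"].append(pct(cmn))
        out["pct_cm_cyto"].append(pct(cmc))
        out["pct_nonCM_max"].append(max(pct(idx) for idx in ct))
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}


class TestUnsplicedFraction:
    @pytest.mark.parametrize(
        "s,u,a,expected",
        [(0, 10, 0, 1.0), (5, 5, 0, 0.5), (3, 2, 5, 0.2), (7, 0, 3, 0.0)],
    )
    def test_arithmetic(self, s, u, a, expected):
        assert unspliced_fraction(s, u, a) == pytest.approx(expected)

    def test_zero_denominator_is_nan(self):
        assert np.isnan(unspliced_fraction(0, 0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            unspliced_fraction(-1, 2, 0)

    @given(st.integers(0, 10**6), st.integers(0, 10**6), st.integers(0, 10**6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, s, u, a):
        frac = unspliced_fraction(s, u, a)
        if s + u + a == 0:
            assert np.isnan(frac)
        else:
            assert 0.0 <= frac <= 1.0


class TestGeneSetPercentage:
    def test_all_counts_in_set(self):
        assert gene_set_percentage([10, 0, 0, 0], [0]) == 100.0

    def test_half_counts_in_set(self):
        assert gene_set_percentage([5, 5, 0, 0], [0]) == 50.0

    def test_log_transform_uses_log1p(self):
        e1 = np.e - 1  # log1p gives exactly 1
        assert gene_set_percentage([e1, e1, 0, 0], [0], log_transform=True) == pytest.approx(50.0)

    def test_zero_row_yields_zero(self):
        assert gene_set_percentage([0, 0, 0], [1]) == 0.0

    def test_max_over_sets_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        row = rng.integers(0, 20, size=60)
        sets = {f"s{i}": list(rng.choice(60, size=5, replace=False)) for i in range(11)}
        expected = max(gene_set_percentage(row, idx) for idx in sets.values())
        assert max_celltype_percentage(row, sets) == expected

    def test_max_with_empty_droplet(self):
        assert max_celltype_percentage([0, 0], {"a": [0], "b": [1]}) == 0.0

    def test_scale_invariance_of_raw_percentages(self):
        row = np.array([3, 0, 7, 2, 9])
        for mult in (2, 10, 1000):
            assert gene_set_percentage(row * mult, [0, 3]) == pytest.approx(
                gene_set_percentage(row, [0, 3])
            )


@pytest.fixture(scope="module")
def random_fixture():
    """200 droplets x 500 genes with a registry covering part of the universe."""
    rng = np.random.default_rng(42)
    genes, registry = qclus.make_gene_universe(11, 10, 316)  # 74 + 110 + 316 = 500
    dense = rng.poisson(0.4, size=(200, 500)) * rng.integers(0, 2, size=(200, 500))
    matrix = qclus.DropletMatrix(
        counts=sp.csr_matrix(dense),
        barcodes=np.array([f"D{i}" for i in range(200)], dtype=object),
        genes=genes,
        unspliced_fraction=rng.uniform(0, 1, size=200),
        splicing_available=np.ones(200, dtype=bool),
    )
    return dense, matrix, registry


class TestBuildFeatureTable:
    def test_every_column_matches_dense_oracle(self, random_fixture):
        dense, matrix, registry = random_fixture
        resolved = resolve(registry, matrix.genes)
        table = qclus.build_feature_table(matrix, registry, resolved)
        expected = dense_oracle(dense.astype(float), resolved, registry)
        for col, exp in expected.items():
            got = table[col].to_numpy(dtype=float)
            np.testing.assert_allclose(got, exp, rtol=1e-9, atol=1e-12, err_msg=col)

    def test_matches_scanpy_qc_metrics(self, random_fixture):
        """Cross-check raw-count percentages against scanpy's QC routine."""
        scanpy = pytest.importorskip("scanpy")
        anndata = pytest.importorskip("anndata")
        dense, matrix, registry = random_fixture
        adata = anndata.AnnData(X=sp.csr_matrix(dense.astype(np.float32)))
        adata.var_names = [str(g) for g in matrix.genes]
        adata.var["mito"] = [g in registry["mitochondrial"].genes for g in matrix.genes]
        scanpy.pp.calculate_qc_metrics(
            adata, qc_vars=["mito"], percent_top=None, log1p=False, inplace=True
        )
        table = qclus.build_feature_table(matrix, registry)
        np.testing.assert_allclose(
            table["pct_mito"].to_numpy(),
            adata.obs["pct_counts_mito"].to_numpy(),
            rtol=1e-5,
        )
        np.testing.assert_allclose(
            table["n_genes"].to_numpy(), adata.obs["n_genes_by_counts"].to_numpy()
        )

    def test_partition_property(self):
        """Cell-type sets partitioning the universe -> per-set percentages sum to 100."""
        rng = np.random.default_rng(3)
        genes = np.array([f"G{i}" for i in range(30)], dtype=object)
        sets = {
            f"part{j}": GeneSet(f"part{j}", tuple(genes[10 * j : 10 * (j + 1)]), "celltype_marker")
            for j in range(3)
        }
        registry = GeneSetRegistry(sets=sets)
        resolved = resolve(registry, genes)
        row = rng.integers(0, 9, size=30)
        assert row.sum() > 0
        total = sum(gene_set_percentage(row, idx) for idx in resolved.values())
        assert total == pytest.approx(100.0)

    def test_zero_count_droplet(self, heart_registry):
        universe = np.array(
            [g for gs in heart_registry.sets.values() for g in gs.genes], dtype=object
        )
        matrix = qclus.DropletMatrix(
            counts=sp.csr_matrix((1, len(universe)), dtype=float),
            barcodes=np.array(["empty"], dtype=object),
            genes=universe,
        )
        table = qclus.build_feature_table(matrix, heart_registry)
        row = table.iloc[0]
        assert row["n_genes"] == 0 and row["total_counts"] == 0
        for col in ("pct_mito", "nuclear_fraction", "pct_cm_nuclear", "pct_cm_cyto", "pct_nonCM_max"):
            assert row[col] == 0.0
        assert np.isnan(row["fraction_unspliced"])

    def test_brain_registry_drops_cm_columns(self):
        genes, registry = qclus.make_gene_universe(0, 10, 50)
        rng = np.random.default_rng(0)
        matrix = qclus.DropletMatrix(
            counts=sp.csr_matrix(rng.poisson(1.0, size=(5, len(genes)))),
            barcodes=np.array([f"b{i}" for i in range(5)], dtype=object),
            genes=genes,
        )
        table = qclus.build_feature_table(matrix, registry)
        assert "pct_cm_nuclear" not in table.columns
        assert "pct_cm_cyto" not in table.columns
        assert "pct_nonCM_max" in table.columns
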