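import logging

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from perfuseq.qc import (
    QCThresholds,
    annotate_clusters,
    cluster_cells,
    compute_qc_metrics,
    filter_cells,
    flag_doublets_by_depth,
    select_hvgs,
)
from perfuseq.simulate import annotation_panels

from .conftest import make_matrix


class TestComputeQCMetrics:
    def test_forced_arithmetic(self):
        matrix = make_matrix(np.array([[5], [5]]), gene_names=["geneA", "MT-CO1"])
        m = compute_qc_metrics(matrix)
        assert m.loc["c0", "n_genes_detected"] == 2
        assert m.loc["c0", "total_counts"] == 10
        assert m.loc["c0", "pct_mito"] == 50.0

    def test_all_zero_cell_convention(self):
        matrix = make_matrix(np.array([[0, 3], [0, 1]]), gene_names=["a", "MT-1"])
        m = compute_qc_metrics(matrix)
        assert tuple(m.loc["c0"]) == (0, 0, 0.0)

    def test_against_dense_loop_oracle(self, rng):
        counts = rng.integers(0, 6, size=(50, 20))
        gene_names = [f"MT-{i}" if i < 8 else f"g{i}" for i in range(50)]
        matrix = make_matrix(counts, gene_names=gene_names)
        m = compute_qc_metrics(matrix)
        for j in range(20):
            n_genes = sum(1 for i in range(50) if counts[i, j] > 0)
            total = sum(int(counts[i, j]) for i in range(50))
            mito = sum(int(counts[i, j]) for i in range(8))
            pct = 100.0 * mito / total if total else 0.0
            assert m.iloc[j]["n_genes_detected"] == n_genes
            assert m.iloc[j]["total_counts"] == total
            assert m.iloc[j]["pct_mito"] == pytest.approx(pct)


class TestFilterCells:
    def _metrics(self, rows):
        return pd.DataFrame(
            rows, columns=["n_genes_detected", "total_counts", "pct_mito"],
            index=pd.Index([f"c{i}" for i in range(len(rows))], name="cell_id"),
        )

    def test_bounds_inclusive_and_mito_strict(self):
        matrix = make_matrix(np.ones((3, 4), dtype=int))
        metrics = self._metrics(
            [[250, 1000, 0.0], [8000, 100_000, 29.99], [251, 1001, 30.0], [249, 1000, 0.0]]
        )
        kept = filter_cells(matrix, metrics, QCThresholds())
        assert list(kept.cell_ids) == ["c0", "c1"]

    def test_misaligned_metrics_rejected(self):
        matrix = make_matrix(np.ones((2, 3), dtype=int))
        metrics = self._metrics([[300, 2000, 1.0]] * 2)
        with pytest.raises(ValueError, match="aligned"):
            filter_cells(matrix, metrics, QCThresholds())

    def test_idempotent_and_counts_untouched(self, rng):
        counts = rng.integers(0, 40, size=(30, 200))
        matrix = make_matrix(counts)
        metrics = compute_qc_metrics(matrix)
        th = QCThresholds(min_genes=10, max_genes=28, min_counts=300, max_counts=700, max_pct_mito=50)
        once = filter_cells(matrix, metrics, th)
        twice = filter_cells(once, compute_qc_metrics(once), th)
        assert list(once.cell_ids) == list(twice.cell_ids)
        assert (once.counts != twice.counts).nnz == 0
        # retained columns equal the original submatrix
        orig_cols = matrix.cell_meta.index.get_indexer(once.cell_ids)
        assert (once.counts != matrix.counts[:, orig_cols]).nnz == 0

    def test_matches_brute_force_predicate(self, rng):
        counts = rng.integers(0, 30, size=(40, 500))
        gene_names = [f"MT-{i}" if i < 5 else f"g{i}" for i in range(40)]
        matrix = make_matrix(counts, gene_names=gene_names)
        metrics = compute_qc_metrics(matrix)
        th = QCThresholds(min_genes=15, max_genes=35, min_counts=300, max_counts=600, max_pct_mito=15)
        kept = set(filter_cells(matrix, metrics, th).cell_ids)
        expected = set()
        for cid, row in metrics.iterrows():
            if (
                th.min_genes <= row["n_genes_detected"] <= th.max_genes
                and th.min_counts <= row["total_counts"] <= th.max_counts
                and row["pct_mito"] < th.max_pct_mito
            ):
                expected.add(cid)
        assert kept == expected

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            QCThresholds(min_genes=100, max_genes=100)
        with pytest.raises(ValueError):
            QCThresholds(max_pct_mito=0)


def test_flag_doublets_by_depth():
    matrix = make_matrix(np.ones((2, 100), dtype=int) * np.r_[np.ones(99), 100][None, :].astype(int))
    metrics = compute_qc_metrics(matrix)
    flagged = flag_doublets_by_depth(metrics, quantile=0.99)
    assert list(flagged) == ["c99"]


class TestSelectHVGs:
    def test_constant_genes_fall_back_to_stable_order(self):
        matrix = make_matrix(np.full((10, 20), 3, dtype=int))
        hvgs = select_hvgs(matrix, n_top=4)
        assert hvgs == ["g0", "g1", "g2", "g3"]

    def test_planted_variance_gene_ranked_first(self, rng):
        n_genes, n_cells = 60, 200
        counts = rng.poisson(10, size=(n_genes, n_cells))
        # one gene with ~10x the variance at the same mean, in every batch
        counts[7, :] = rng.choice([0, 20], size=n_cells)
        patients = ["P1"] * 100 + ["P2"] * 100
        matrix = make_matrix(counts, patients=patients)
        hvgs = select_hvgs(matrix, n_top=5)
        assert hvgs[0] == "g7"

    def test_single_batch_equals_standardized_variance_order(self, rng):
        from perfuseq.qc import _standardized_variance

        counts = rng.poisson(rng.uniform(1, 20, size=(30, 1)), size=(30, 80))
        matrix = make_matrix(counts)
        hvgs = select_hvgs(matrix, n_top=10)
        sv = _standardized_variance(matrix.counts.tocsr())
        order = np.argsort(-sv, kind="stable")[:10]
        assert hvgs == [f"g{i}" for i in order]

    def test_permutation_invariance(self, rng):
        counts = rng.poisson(rng.uniform(1, 20, size=(40, 1)), size=(40, 100))
        matrix = make_matrix(counts)
        hvgs = select_hvgs(matrix, n_top=8)
        perm = rng.permutation(40)
        matrix_p = make_matrix(counts[perm])
        matrix_p.gene_meta.index = pd.Index([f"g{i}" for i in perm], name="gene")
        hvgs_p = select_hvgs(matrix_p, n_top=8)
        assert set(hvgs) == set(hvgs_p)

    def test_small_batch_excluded_with_warning(self, caplog, rng):
        counts = rng.poisson(5, size=(20, 11))
        patients = ["P1"] * 10 + ["P2"]
        matrix = make_matrix(counts, patients=patients)
        with caplog.at_level(logging.WARNING):
            select_hvgs(matrix, n_top=5)
        assert any("excluded" in r.message for r in caplog.records)

    def test_n_top_bounds(self):
        matrix = make_matrix(np.ones((5, 4), dtype=int))
        with pytest.raises(ValueError):
            select_hvgs(matrix, n_top=6)


class TestClusterCells:
    def _two_populations(self, rng, n_per=60):
        # disjoint high-expression blocks, lfc >> 4
        base = np.full((40, 2 * n_per), 1.0)
        base[:10, :n_per] = 40.0
        base[10:20, n_per:] = 40.0
        counts = rng.poisson(base)
        truth = np.array([0] * n_per + [1] * n_per)
        return make_matrix(counts), truth

    def test_planted_partition_recovered(self, rng):
        matrix, truth = self._two_populations(rng)
        hvgs = list(matrix.gene_names)
        asg = cluster_cells(matrix, hvgs, n_pcs=5, k_neighbors=10, resolution=0.2, seed=0)
        assert asg["cluster"].nunique() == 2
        assert adjusted_rand_score(truth, asg["cluster"]) == 1.0

    def test_identical_cells_single_cluster(self):
        matrix = make_matrix(np.full((20, 50), 5, dtype=int))
        asg = cluster_cells(matrix, list(matrix.gene_names), n_pcs=3, resolution=0.5, seed=0)
        assert asg["cluster"].nunique() == 1

    def test_determinism(self, rng):
        matrix, _ = self._two_populations(rng)
        hvgs = list(matrix.gene_names)
        a = cluster_cells(matrix, hvgs, n_pcs=5, resolution=1.0, seed=11)
        b = cluster_cells(matrix, hvgs, n_pcs=5, resolution=1.0, seed=11)
        assert (a["cluster"] == b["cluster"]).all()

    def test_n_pcs_reduced_with_few_cells(self, caplog, rng):
        matrix = make_matrix(rng.poisson(5, size=(30, 8)))
        with caplog.at_level(logging.WARNING):
            asg = cluster_cells(matrix, list(matrix.gene_names), n_pcs=20, seed=0)
        assert len(asg) == 8
        assert any("reducing n_pcs" in r.message for r in caplog.records)


class TestAnnotateClusters:
    def test_single_support_argmax(self, rng):
        counts = np.zeros((4, 10), dtype=int)
        counts[0, :] = 9  # only the neutrophil panel gene is expressed
        matrix = make_matrix(counts, gene_names=["FCGR3B", "CD68", "x", "y"])
        asg = pd.DataFrame({"cluster": [0] * 10}, index=matrix.cell_ids)
        out = annotate_clusters(asg, matrix, {"neutrophil": ["FCGR3B"], "mono": ["CD68"]})
        assert (out["label"] == "neutrophil").all()

    def test_tie_gives_unassigned(self):
        counts = np.array([[5] * 6, [5] * 6, [0] * 6])
        matrix = make_matrix(counts, gene_names=["a", "b", "c"])
        asg = pd.DataFrame({"cluster": [0] * 6}, index=matrix.cell_ids)
        out = annotate_clusters(asg, matrix, {"t1": ["a"], "t2": ["b"]})
        assert (out["label"] == "unassigned").all()

    def test_zero_score_gives_unassigned(self):
        counts = np.array([[1] * 4, [0] * 4])
        matrix = make_matrix(counts, gene_names=["expressed", "silent"])
        asg = pd.DataFrame({"cluster": [0] * 4}, index=matrix.cell_ids)
        out = annotate_clusters(asg, matrix, {"only": ["silent"]})
        assert (out["label"] == "unassigned").all()

    def test_no_panel_gene_present_errors(self):
        matrix = make_matrix(np.ones((2, 3), dtype=int))
        asg = pd.DataFrame({"cluster": [0, 0, 0]}, index=matrix.cell_ids)
        with pytest.raises(ValueError, match="panel"):
            annotate_clusters(asg, matrix, {"t": ["absent1"], "u": ["absent2"]})

    def test_empty_panel_rejected(self):
        matrix = make_matrix(np.ones((2, 3), dtype=int))
        asg = pd.DataFrame({"cluster": [0, 0, 0]}, index=matrix.cell_ids)
        with pytest.raises(ValueError, match="empty"):
            annotate_clusters(asg, matrix, {"t": []})


def test_cluster_annotate_recovers_truth(small_dataset):
    cfg, matrix, truth = small_dataset
    hvgs = select_hvgs(matrix, n_top=200)
    asg = cluster_cells(matrix, hvgs, n_pcs=15, k_neighbors=15, resolution=1.0, seed=0)
    out = annotate_clusters(asg, matrix, annotation_panels(truth))
    accuracy = (out["label"] == matrix.cell_meta["cell_type"]).mean()
    assert accuracy == 1.0
    assert adjusted_rand_score(matrix.cell_meta["cell_type"], out["label"]) >= 0.9
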