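import numpy as np
import pandas as pd
import pytest

from perfuseq.communication import (
    LRDatabase,
    build_edges,
    differential_ligands,
    edge_table_for_plot,
    expression_fraction,
)
from perfuseq.data import CellCountMatrix
from perfuseq.pseudobulk import DEResult

from .conftest import make_matrix


def _db(records=None):
    if records is None:
        records = pd.DataFrame(
            {
                "interaction": ["L1_R1", "L1_R2R3", "L2_R4"],
                "ligand_subunits": [("LIG1",), ("LIG1",), ("LIG2",)],
                "receptor_subunits": [("R1",), ("R2", "R3"), ("R4",)],
                "pathway": ["p", "p", "q"],
            }
        )
    return LRDatabase(records)


def _de(genes, padj, lfc):
    tab = pd.DataFrame(
        {"base_mean": 1.0, "log2fc": lfc, "se": 0.1, "wald_stat": 0.0,
         "pvalue": padj, "padj": padj},
        index=pd.Index(genes, name="gene"),
    )
    return DEResult(table=tab, cell_type="", contrast=("T1", "T0"), design="", n_samples={})


class TestExpressionFraction:
    def test_mean_of_fractions_not_pooled(self):
        # patient A: 5/10 express; patient B: 100/1000 -> (0.5 + 0.1)/2 = 0.3
        n = 1010
        counts = np.zeros((1, n), dtype=int)
        counts[0, :5] = 1       # 5 of patient A's 10
        counts[0, 10:110] = 1   # 100 of patient B's 1000
        matrix = make_matrix(
            counts, gene_names=["g"], patients=["A"] * 10 + ["B"] * 1000,
            cell_types=["T"] * n,
        )
        assert expression_fraction(matrix, "g", "T") == pytest.approx(0.3)

    def test_everywhere_expressed_is_one(self):
        matrix = make_matrix(np.ones((1, 20), dtype=int), cell_types=["T"] * 20)
        assert expression_fraction(matrix, "g0", "T") == 1.0

    def test_no_cells_gives_nan(self):
        matrix = make_matrix(np.ones((1, 5), dtype=int), cell_types=["T"] * 5)
        assert np.isnan(expression_fraction(matrix, "g0", "other"))

    def test_against_loop_oracle(self, rng):
        counts = rng.integers(0, 3, size=(10, 200))
        patients = rng.choice(["P1", "P2", "P3"], size=200)
        cell_types = rng.choice(["A", "B"], size=200)
        matrix = make_matrix(counts, patients=patients, cell_types=cell_types)
        for gi in [0, 3, 7]:
            for ct in ["A", "B"]:
                fracs = []
                for p in pd.unique(patients[cell_types == ct]):
                    member = (patients == p) & (cell_types == ct)
                    fracs.append(
                        sum(counts[gi, j] > 0 for j in np.flatnonzero(member)) / member.sum()
                    )
                got = expression_fraction(matrix, f"g{gi}", ct)
                assert got == pytest.approx(float(np.mean(fracs)))

    def test_patient_replication_invariance_exact(self, rng):
        counts = rng.integers(0, 3, size=(5, 60))
        patients = ["P1"] * 20 + ["P2"] * 40
        matrix = make_matrix(counts, patients=patients, cell_types=["T"] * 60)
        base = expression_fraction(matrix, "g0", "T")
        # triplicate all of P1's cells
        rep = np.concatenate([counts, counts[:, :20], counts[:, :20]], axis=1)
        meta_patients = patients + ["P1"] * 40
        matrix2 = make_matrix(rep, patients=meta_patients, cell_types=["T"] * 100)
        assert expression_fraction(matrix2, "g0", "T") == base


class TestDifferentialLigands:
    def test_fdr_gate(self):
        de = {"S": _de(["LIG1", "LIG2", "other"], [0.01, 0.2, 0.001], [1.2, -2.0, 3.0])}
        out = differential_ligands(de, _db(), ligand_fdr=0.05)["S"]
        assert list(out["ligand"]) == ["LIG1"]
        assert list(out["direction"]) == ["up"]

    def test_down_direction(self):
        de = {"S": _de(["LIG1"], [0.04], [-1.0])}
        out = differential_ligands(de, _db())["S"]
        assert list(out["direction"]) == ["down"]

    def test_ligand_absent_from_universe_skipped(self):
        de = {"S": _de(["other"], [0.001], [1.0])}
        out = differential_ligands(de, _db())["S"]
        assert out.empty

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            differential_ligands({}, LRDatabase(pd.DataFrame(
                columns=["interaction", "ligand_subunits", "receptor_subunits"])))


def _receiver_matrix(rng, fractions, n_per_type=100, patients=("P1", "P2")):
    """Matrix whose receptor detection fractions per cell type are exact."""
    types = sorted(fractions)
    genes = sorted({g for d in fractions.values() for g in d})
    cols, metas = [], []
    for ct in types:
        for p in patients:
            block = np.zeros((len(genes) + 1, n_per_type), dtype=int)
            block[0, :] = 5  # housekeeping so depth normalization works
            for gi, g in enumerate(genes, start=1):
                k = int(round(fractions[ct].get(g, 0.0) * n_per_type))
                block[gi, :k] = 1
            cols.append(block)
            metas.extend([(p, ct)] * n_per_type)
    counts = np.concatenate(cols, axis=1)
    return make_matrix(
        counts,
        gene_names=["HK"] + genes,
        patients=[m[0] for m in metas],
        cell_types=[m[1] for m in metas],
    )


class TestBuildEdges:
    def test_fraction_gate_at_ten_percent(self, rng):
        matrix = _receiver_matrix(rng, {"recv": {"R1": 0.09}, "other": {"R1": 0.5}})
        ligands = {"S": pd.DataFrame({"ligand": ["LIG1"], "log2fc": [1.0],
                                      "padj": [0.01], "direction": ["up"]})}
        edges = build_edges(ligands, _db(), matrix, min_fraction=0.10)
        receivers = {e.receiver for e in edges if e.interaction == "L1_R1"}
        assert receivers == {"other"}  # 0.09 < 0.10 -> no edge

    def test_multisubunit_all_must_pass_and_min_fraction(self, rng):
        matrix = _receiver_matrix(
            rng, {"both": {"R2": 0.4, "R3": 0.3}, "partial": {"R2": 0.9, "R3": 0.05}}
        )
        ligands = {"S": pd.DataFrame({"ligand": ["LIG1"], "log2fc": [1.0],
                                      "padj": [0.01], "direction": ["up"]})}
        edges = [e for e in build_edges(ligands, _db(), matrix) if e.interaction == "L1_R2R3"]
        assert {e.receiver for e in edges} == {"both"}
        assert edges[0].receiver_fraction == pytest.approx(0.3)

    def test_missing_receptor_gene_skips_pair(self, rng, caplog):
        import logging

        matrix = _receiver_matrix(rng, {"recv": {"R1": 0.5}})  # no R2/R3/R4 genes
        ligands = {"S": pd.DataFrame({"ligand": ["LIG1"], "log2fc": [1.0],
                                      "padj": [0.01], "direction": ["up"]})}
        with caplog.at_level(logging.WARNING):
            edges = build_edges(ligands, _db(), matrix)
        assert {e.interaction for e in edges} == {"L1_R1"}
        assert any("skipped" in r.message for r in caplog.records)

    def test_order_independent_of_db_and_cell_order(self, rng):
        matrix = _receiver_matrix(rng, {"a": {"R1": 0.5, "R4": 0.6}, "b": {"R1": 0.3}})
        ligands = {"S": pd.DataFrame({"ligand": ["LIG1", "LIG2"], "log2fc": [1.0, -1.0],
                                      "padj": [0.01, 0.02], "direction": ["up", "down"]})}
        e1 = build_edges(ligands, _db(), matrix)
        shuffled = _db().records.sample(frac=1.0, random_state=1).reset_index(drop=True)
        perm = rng.permutation(matrix.n_cells)
        matrix2 = CellCountMatrix(
            counts=matrix.counts[:, perm],
            cell_meta=matrix.cell_meta.iloc[perm],
            gene_meta=matrix.gene_meta,
        )
        e2 = build_edges(ligands, LRDatabase(shuffled), matrix2)
        key = lambda e: (e.sender, e.ligand, e.receiver, e.interaction)
        assert [key(e) for e in e1] == [key(e) for e in e2]
        for a, b in zip(e1, e2):
            assert a.receiver_fraction == pytest.approx(b.receiver_fraction)

    def test_gates_recheckable_from_inputs(self, rng):
        matrix = _receiver_matrix(rng, {"a": {"R1": 0.5}, "b": {"R1": 0.15}})
        ligands = {"S": pd.DataFrame({"ligand": ["LIG1"], "log2fc": [1.0],
                                      "padj": [0.04], "direction": ["up"]})}
        edges = build_edges(ligands, _db(), matrix, min_fraction=0.10)
        for e in edges:
            assert e.ligand_padj <= 0.05
            for g in e.receptor:
                assert expression_fraction(matrix, g, e.receiver) >= 0.10


class TestEdgeTable:
    def test_direction_display_flag(self, rng):
        matrix = _receiver_matrix(rng, {"a": {"R1": 0.5, "R4": 0.5}})
        ligands = {"S": pd.DataFrame({"ligand": ["LIG1", "LIG2"], "log2fc": [1.0, -1.0],
                                      "padj": [0.01, 0.02], "direction": ["up", "down"]})}
        edges = build_edges(ligands, _db(), matrix)
        tab = edge_table_for_plot(edges, direction_filter="up")
        assert set(tab["direction"]) == {"up", "down"}  # both kept in data
        assert (tab.loc[tab["display"], "direction"] == "up").all()
        assert (~tab.loc[tab["direction"] == "down", "display"]).all()

    def test_empty_edges_full_header(self):
        tab = edge_table_for_plot([])
        assert tab.empty
        assert "receiver_fraction" in tab.columns and "display" in tab.columns

    def test_round_trip(self, rng, tmp_path):
        matrix = _receiver_matrix(rng, {"a": {"R1": 0.5}})
        ligands = {"S": pd.DataFrame({"ligand": ["LIG1"], "log2fc": [1.0],
                                      "padj": [0.01], "direction": ["up"]})}
        tab = edge_table_for_plot(build_edges(ligands, _db(), matrix))
        path = tmp_path / "edges.tsv"
        tab.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(tab, back)


class TestLRDatabaseValidation:
    def test_duplicate_interaction_rejected(self):
        rec = pd.DataFrame(
            {
                "interaction": ["X", "X"],
                "ligand_subunits": [("a",), ("b",)],
                "receptor_subunits": [("c",), ("d",)],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            LRDatabase(rec)

    def test_empty_subunits_rejected(self):
        rec = pd.DataFrame(
            {"interaction": ["X"], "ligand_subunits": [()], "receptor_subunits": [("c",)]}
        )
        with pytest.raises(ValueError, match="nonempty"):
            LRDatabase(rec)
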