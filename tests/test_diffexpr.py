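import itertools

import numpy as np
import pandas as pd
import pytest

from spermseq import diffexpr, qc
from spermseq.types import ExpressionMatrix, PipelineError, ValidationError

from oracles import bh_bruteforce


def log_matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes=genes, cells=cells, values=values, scale="log")


class TestAvgLogDiff:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 1], [0, 0], 1.0),
            ([1.5, 0.3], [1.5, 0.3], 0.0),
            ([2, 0], [0, 0], np.log2(2.5)),  # mean(2^x - 1) = 1.5
        ],
    )
    def test_formula(self, x, y, expected):
        assert diffexpr.avg_log_diff(x, y) == pytest.approx(expected)

    def test_empty_group_is_error(self):
        with pytest.raises(ValidationError):
            diffexpr.avg_log_diff([], [1.0])


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_known_values(self, p, expected):
        assert np.allclose(diffexpr.bh_adjust(p), expected)

    def test_matches_bruteforce_on_exhaustive_grid(self):
        # every p-vector (with repetition) from a fixed grid, n <= 5
        grid = [0.001, 0.01, 0.04, 0.05, 0.2, 0.5, 1.0]
        for n in range(1, 6):
            for combo in itertools.combinations_with_replacement(grid, n):
                got = diffexpr.bh_adjust(list(combo))
                want = bh_bruteforce(list(combo))
                assert np.allclose(got, want), combo

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for n in (6, 7, 8):
            for _ in range(50):
                p = rng.uniform(0, 1, n)
                assert np.allclose(diffexpr.bh_adjust(p), bh_bruteforce(list(p)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            diffexpr.bh_adjust([0.5, 1.5])


class TestDegTest:
    def test_identical_groups_all_ns(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 5, size=(20, 4))
        em = log_matrix(np.hstack([vals, vals]))
        res = diffexpr.deg_test(em, em.cells[:4], em.cells[4:])
        assert (res["call"] == "ns").all()
        assert np.allclose(res["avg_diff"], 0)

    def test_zero_variance_genes_reported_ns_p1(self):
        em = log_matrix([[1, 1, 1, 1], [0, 2, 1, 3]])
        res = diffexpr.deg_test(em, em.cells[:2], em.cells[2:])
        assert res.iloc[0]["p_value"] == 1.0 and res.iloc[0]["call"] == "ns"

    def test_antisymmetry_under_group_swap(self, default_log_matrix, default_sim):
        _spec, _cm, meta, _ann, _truth = default_sim
        stages = meta.set_index("cell_id")["stage"]
        a = stages.index[stages == "L"].tolist()
        b = stages.index[stages == "Z"].tolist()
        r1 = diffexpr.deg_test(default_log_matrix, a, b)
        r2 = diffexpr.deg_test(default_log_matrix, b, a)
        assert np.allclose(r1["avg_diff"], -r2["avg_diff"])
        assert np.allclose(r1["p_value"], r2["p_value"])
        flip = {"up": "down", "down": "up", "ns": "ns"}
        assert list(r1["call"].map(flip)) == list(r2["call"])

    def test_overlapping_groups_rejected(self, default_log_matrix):
        cells = default_log_matrix.cells
        with pytest.raises(ValidationError):
            diffexpr.deg_test(default_log_matrix, cells[:4], cells[3:6])

    def test_planted_degs_recovered_at_depth(self, deep_two_stage_sim):
        """Planted log2-fold-2 effects between consecutive stages are
        recalled at >= 90% given enough cells, and the direction is right."""
        _spec, cm, meta, _ann, truth = deep_two_stage_sim
        em = qc.log_expr(qc.tpm(cm))
        stages = meta.set_index("cell_id")["stage"]
        later = stages.index[stages == "eP"].tolist()
        earlier = stages.index[stages == "Z"].tolist()
        res = diffexpr.deg_test(em, later, earlier).set_index("gene_id")
        planted = truth.deg[("Z", "eP")]
        calls = [res.at[g, "call"] == "up" for g in planted["up"]]
        calls += [res.at[g, "call"] == "down" for g in planted["down"]]
        assert np.mean(calls) >= 0.9


class TestScreens:
    def test_regulator_screen_recovers_planted_deg(self, deep_two_stage_sim):
        _spec, cm, meta, ann, truth = deep_two_stage_sim
        em = qc.log_expr(qc.tpm(cm))
        stages = meta.set_index("cell_id")["stage"]
        later = stages.index[stages == "eP"].tolist()
        earlier = stages.index[stages == "Z"].tolist()
        regulators = ann.loc[ann["is_splicing_regulator"], "gene_id"].tolist()
        res = diffexpr.splicing_regulator_screen(em, later, earlier, regulators)
        planted = truth.deg[("Z", "eP")]
        planted_regs = (set(planted["up"]) | set(planted["down"])) & set(regulators)
        assert planted_regs
        sig = set(res.loc[res["call"] != "ns", "gene_id"])
        assert len(planted_regs & sig) / len(planted_regs) >= 0.9

    def test_non_regulator_genes_excluded(self, deep_two_stage_sim):
        _spec, cm, meta, ann, _truth = deep_two_stage_sim
        em = qc.log_expr(qc.tpm(cm))
        stages = meta.set_index("cell_id")["stage"]
        regulators = ann.loc[ann["is_splicing_regulator"], "gene_id"].tolist()
        res = diffexpr.splicing_regulator_screen(
            em,
            stages.index[stages == "eP"].tolist(),
            stages.index[stages == "Z"].tolist(),
            regulators,
        )
        assert set(res["gene_id"]) <= set(regulators)

    def test_disjoint_regulator_set_gives_empty_result(self, default_log_matrix):
        cells = default_log_matrix.cells
        res = diffexpr.splicing_regulator_screen(
            default_log_matrix, cells[:5], cells[5:10], ["not_a_gene"]
        )
        assert res.empty

    def test_empty_regulator_set_is_error(self, default_log_matrix):
        cells = default_log_matrix.cells
        with pytest.raises(PipelineError):
            diffexpr.splicing_regulator_screen(default_log_matrix, cells[:5], cells[5:10], [])

    def test_marker_screen_top_ranks_planted_markers(self, default_sim, default_log_matrix):
        _spec, _cm, meta, ann, truth = default_sim
        labels = meta.set_index("cell_id")["cluster"].to_dict()
        markers = ann.loc[ann["is_surface_marker"], "gene_id"].tolist()
        res = diffexpr.surface_marker_screen(default_log_matrix, labels, markers)
        for cluster, table in res.items():
            planted_here = {g for g, c in truth.marker_cluster.items() if c == cluster}
            if planted_here:
                assert table.iloc[0]["gene_id"] in planted_here

    def test_single_cluster_is_error(self, default_log_matrix):
        labels = {c: "C1" for c in default_log_matrix.cells}
        with pytest.raises(PipelineError):
            diffexpr.surface_marker_screen(default_log_matrix, labels, ["g"])

    def test_identical_clusters_yield_no_significant_markers(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 4, size=(30, 10))
        em = log_matrix(np.hstack([vals, vals]))
        labels = {c: ("C1" if i < 10 else "C2") for i, c in enumerate(em.cells)}
        res = diffexpr.surface_marker_screen(em, labels, list(em.genes))
        for table in res.values():
            assert (table["call"] == "ns").all()
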