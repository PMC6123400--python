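import numpy as np
import pandas as pd
import pytest

from spermseq import msci, qc
from spermseq.msci import StageExpressionTable
from spermseq.simulate import SimulationSpec, simulate_dataset, true_stage_expression_table
from spermseq.types import STAGE_ORDER, StagingError, ValidationError

from oracles import msci_bruteforce


def table_from_profiles(profiles: dict[str, dict[str, bool]], n_cells=10):
    """Build a stage table where expressed stages have mean TPM 10 in all
    cells and silent stages are all-zero."""
    genes = list(profiles)
    mean = pd.DataFrame(
        {s: [10.0 if profiles[g][s] else 0.0 for g in genes] for s in STAGE_ORDER},
        index=genes,
    )
    nge1 = pd.DataFrame(
        {s: [n_cells if profiles[g][s] else 0 for g in genes] for s in STAGE_ORDER},
        index=genes,
    )
    return StageExpressionTable(mean_tpm=mean, n_ge1=nge1, n_cells={s: n_cells for s in STAGE_ORDER})


class TestExpressedAtStage:
    def make(self, tpms):
        em_vals = np.array(tpms, dtype=float)[None, :]
        mean = pd.DataFrame({"A1": [em_vals.mean()]}, index=["g"])
        nge1 = pd.DataFrame({"A1": [int((em_vals >= 1).sum())]}, index=["g"])
        return StageExpressionTable(mean_tpm=mean, n_ge1=nge1, n_cells={"A1": len(tpms)})

    @pytest.mark.parametrize(
        "tpms,expected",
        [
            ([0, 0, 2, 3, 4], True),    # mean 1.8 > 1 and 3 cells >= 1
            ([10, 0, 0, 0, 0], False),  # mean 2 but only one cell
            ([1, 1, 1, 0, 0], False),   # mean 0.6 fails the mean rule
        ],
    )
    def test_two_part_rule(self, tpms, expected):
        assert msci.expressed_at_stage("g", "A1", self.make(tpms)) is expected

    def test_understaffed_stage_is_error(self):
        table = self.make([5, 5])
        with pytest.raises(StagingError):
            msci.expressed_at_stage("g", "A1", table)


class TestClassification:
    def profile(self, on):
        return {s: s in on for s in STAGE_ORDER}

    @pytest.mark.parametrize(
        "on,category,subtype",
        [
            ({"L", "Z"}, "MSCI_PMSC", "TYPE_I"),
            ({"G1", "mP", "RS2"}, "MSCI_ESCAPE_PMSC", "TYPE_II"),
            ({"RS6"}, "RS_SPECIFIC", "NA"),
            ({"A1", "D"}, "ESCAPE_MSCI", "NA"),
            ({"MI"}, "OTHER", "NA"),
        ],
    )
    def test_known_profiles(self, on, category, subtype):
        table = table_from_profiles({"g": self.profile(on)})
        labels = msci.classify_sex_linked(["g"], table)
        assert labels.iloc[0]["category"] == category
        assert labels.iloc[0]["msci_subtype"] == subtype

    def test_methods_semantics_flag_flips_pmsc_labels(self):
        table = table_from_profiles({"g": self.profile({"L", "Z"})})
        flipped = msci.classify_sex_linked(["g"], table, pmsc_semantics="methods")
        assert flipped.iloc[0]["category"] == "MSCI_ESCAPE_PMSC"

    def test_oracle_equivalence_on_random_profiles(self):
        """Classifier output equals an independently coded brute-force rule
        evaluator on 1,000 random per-stage profiles."""
        rng = np.random.default_rng(21)
        profiles = {}
        i = 0
        while len(profiles) < 1000:
            on = {s for s in STAGE_ORDER if rng.random() < 0.3}
            if on:  # universe requires expression somewhere
                profiles[f"g{i}"] = {s: s in on for s in STAGE_ORDER}
            i += 1
        table = table_from_profiles(profiles)
        labels = msci.classify_sex_linked(list(profiles), table).set_index("gene_id")
        for g, prof in profiles.items():
            cat, sub = msci_bruteforce(prof)
            assert labels.at[g, "category"] == cat
            assert labels.at[g, "msci_subtype"] == sub

    def test_categories_partition_the_universe(self):
        rng = np.random.default_rng(22)
        profiles = {}
        for i in range(300):
            on = {s for s in STAGE_ORDER if rng.random() < 0.4}
            if on:
                profiles[f"g{i}"] = {s: s in on for s in STAGE_ORDER}
        table = table_from_profiles(profiles)
        labels = msci.classify_sex_linked(list(profiles), table)
        assert len(labels) == len(profiles)
        assert set(labels["category"]) <= {
            "MSCI_PMSC", "MSCI_ESCAPE_PMSC", "ESCAPE_MSCI", "RS_SPECIFIC", "OTHER"
        }
        is_msci = labels["category"].isin(["MSCI_PMSC", "MSCI_ESCAPE_PMSC"])
        assert ((labels["msci_subtype"] != "NA") == is_msci).all()

    def test_gene_outside_universe_rejected(self):
        table = table_from_profiles({"g": {s: False for s in STAGE_ORDER}})
        with pytest.raises(ValidationError):
            msci.classify_sex_linked(["g"], table)


class TestSimulatedRecovery:
    def test_noiseless_truth_table_recovers_all_labels(self, default_sim):
        spec, _cm, _meta, _ann, truth = default_sim
        table = true_stage_expression_table(spec, truth)
        labels = msci.classify_sex_linked(list(truth.msci["gene_id"]), table)
        merged = labels.merge(truth.msci, on="gene_id", suffixes=("", "_true"))
        assert (merged["category"] == merged["category_true"]).all()
        assert (merged["msci_subtype"] == merged["msci_subtype_true"]).all()

    def test_noisy_pipeline_recovery_at_default_conditions(self, default_sim):
        """Full pipeline (NB counts, dropout, TPM, stage table) recovers
        >= 95% of planted category labels."""
        _spec, cm, meta, ann, truth = default_sim
        em = qc.tpm(cm)
        table = msci.stage_expression_table(em, meta.set_index("cell_id")["stage"])
        _, staged = msci.sex_linked_universe(ann, em, table)
        labels = msci.classify_sex_linked(staged, table).set_index("gene_id")
        truth_idx = truth.msci.set_index("gene_id")
        common = labels.index.intersection(truth_idx.index)
        agree = (labels.loc[common, "category"] == truth_idx.loc[common, "category"]).mean()
        recovered = agree * len(common) / len(truth_idx)
        assert recovered >= 0.95

    def test_lncrna_mode_applies_same_rules(self):
        spec = SimulationSpec(seed=31, cells_per_stage=20, n_autosomal=1000,
                              n_deg_per_transition=10, n_markers=0, n_tfs=0)
        cm, meta, ann, truth = simulate_dataset(spec)
        # relabel the sex-linked genes as lncRNA and rerun via the lncRNA mode
        ann2 = ann.copy()
        sex = ann2["chromosome"].isin(["X", "Y"])
        ann2.loc[sex, "biotype"] = "lncRNA"
        em = qc.tpm(cm)
        table = msci.stage_expression_table(em, meta.set_index("cell_id")["stage"])
        labels = msci.lncrna_msci_mode(ann2, em, table).set_index("gene_id")
        truth_idx = truth.msci.set_index("gene_id")
        common = labels.index.intersection(truth_idx.index)
        assert len(common) > 0
        assert (labels.loc[common, "category"] == truth_idx.loc[common, "category"]).mean() >= 0.9
        # protein-coding genes are excluded from this mode
        pc = set(ann2.loc[ann2["biotype"] == "protein_coding", "gene_id"])
        assert not (set(labels.index) & pc)


class TestSummary:
    def test_published_style_percentages(self):
        labels = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(575)],
                "category": ["MSCI_PMSC"] * 140 + ["MSCI_ESCAPE_PMSC"] * 285 + ["ESCAPE_MSCI"] * 150,
                "msci_subtype": ["TYPE_I"] * 154 + ["TYPE_II"] * 271 + ["NA"] * 150,
            }
        )
        s = msci.msci_summary(labels)
        assert s["pct_msci"] == 73.9 and s["pct_escape_msci"] == 26.1
        assert s["pct_type_i"] == 36.2 and s["pct_type_ii"] == 63.8
        assert s["pct_pmsc_silent"] == 32.9 and s["pct_pmsc_escape"] == 67.1
        assert s["pct_msci"] + s["pct_escape_msci"] == pytest.approx(100.0, abs=0.1)

    def test_empty_labels_yield_na_percentages(self):
        empty = pd.DataFrame(columns=["gene_id", "category", "msci_subtype"])
        s = msci.msci_summary(empty)
        assert s["n_universe"] == 0 and s["pct_msci"] is None
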