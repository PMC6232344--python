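import numpy as np
import pandas as pd
import pytest

import herbnet as hn
from herbnet.errors import IncompleteDesignError, UnbalancedDesignError, ValidationError
from herbnet.factorial import CellSummary, FactorialDesign, FactorialModel

from conftest import replicates_matching


def random_balanced_model(seed, k=None, n=None):
    rng = np.random.default_rng(seed)
    k = k if k is not None else int(rng.integers(2, 4))
    n = n if n is not None else int(rng.integers(3, 9))
    design = FactorialDesign(tuple("ABCD"[:k]))
    cells = [
        CellSummary(levels, n, float(rng.normal(10, 2)), float(rng.uniform(0.1, 1.5)))
        for levels in design.cells()
    ]
    return design, cells


class TestEffectsFromMeans:
    def test_published_block_interaction_contrast(self, taurine_block):
        design, frame = taurine_block
        means = {
            tuple(-1 if row[f] == 2.5 else 1 for f in design.factors): row["mean"]
            for _, row in frame.iterrows()
        }
        eff = hn.effects_from_means(design, means).set_index("term")
        tp = eff.loc["Taurine:Paeonol"]
        assert tp["contrast"] == pytest.approx(-0.266)
        assert tp["effect"] == pytest.approx(-0.0665)

    def test_additive_means_kill_interactions(self):
        design = FactorialDesign(("A", "B", "C"))
        mains = {"A": 2.0, "B": -1.0, "C": 0.5}
        means = {
            cell: 10 + sum(lv * mains[f] / 2 for f, lv in zip(design.factors, cell))
            for cell in design.cells()
        }
        eff = hn.effects_from_means(design, means)
        inter = eff[eff["order"] >= 2]
        assert np.allclose(inter["contrast"], 0, atol=1e-12)
        mains_est = eff.set_index("term").loc[["A", "B", "C"], "effect"]
        assert np.allclose(mains_est, [2.0, -1.0, 0.5])

    def test_constant_means_zero_everywhere(self):
        design = FactorialDesign(("A", "B"))
        eff = hn.effects_from_means(design, {c: 7.7 for c in design.cells()})
        assert np.allclose(eff["contrast"], 0, atol=1e-12)

    def test_missing_cell_named_in_error(self):
        design = FactorialDesign(("A", "B"))
        means = {(-1, -1): 1.0, (1, 1): 2.0, (-1, 1): 1.5}
        with pytest.raises(IncompleteDesignError, match=r"\(1, -1\)"):
            hn.effects_from_means(design, means)


class TestAnovaFromSummary:
    def test_taurine_paeonol_interaction_significant(self, taurine_block):
        design, frame = taurine_block
        res = hn.anova_from_summary(design, frame, dispersion_is="sd")
        assert res.term("Taurine", "Paeonol")["p"] < 0.01

    def test_rg1_rb1_interaction_significant(self, ginsenoside_block):
        design, frame = ginsenoside_block
        res = hn.anova_from_summary(design, frame, dispersion_is="sd")
        assert res.term("Ginsenoside Rg1", "Ginsenoside Rb1")["p"] < 0.01

    def test_three_way_term_not_significant_in_either_block(
        self, taurine_block, ginsenoside_block
    ):
        for design, frame in (taurine_block, ginsenoside_block):
            res = hn.anova_from_summary(design, frame)
            assert res.term(*design.factors)["p"] > 0.05

    def test_residual_df_and_ss_nonnegative(self, taurine_block):
        design, frame = taurine_block
        res = hn.anova_from_summary(design, frame)
        assert res.df_within == 8 * 4
        assert (res.anova_table["ss"] >= 0).all()
        assert ((res.anova_table["p"] > 0) & (res.anova_table["p"] <= 1)).all()

    def test_sem_reading_converts_to_sd(self, taurine_block):
        design, frame = taurine_block
        sd_res = hn.anova_from_summary(design, frame, dispersion_is="sd")
        sem_frame = frame.copy()
        sem_frame["sd"] = sem_frame["sd"] / np.sqrt(sem_frame["n"])
        sem_res = hn.anova_from_summary(design, sem_frame, dispersion_is="sem")
        pd.testing.assert_frame_equal(sd_res.anova_table, sem_res.anova_table)

    def test_unbalanced_design_rejected(self):
        design, cells = random_balanced_model(0, k=2, n=4)
        cells[0] = CellSummary(cells[0].levels, 5, cells[0].mean, cells[0].sd)
        with pytest.raises(UnbalancedDesignError):
            FactorialModel(design, cells)

    def test_single_replicate_cell_rejected(self):
        with pytest.raises(ValidationError, match="n = 1"):
            CellSummary((-1, 1), 1, 1.0, 0.0)

    def test_duplicate_cell_rejected(self):
        design, cells = random_balanced_model(1, k=2, n=3)
        with pytest.raises(ValidationError, match="duplicate"):
            FactorialModel(design, cells + [cells[0]])


class TestSummaryReplicateIdentity:
    @pytest.mark.parametrize("seed", range(8))
    def test_summary_equals_replicates_exactly(self, seed):
        design, cells = random_balanced_model(seed)
        data = replicates_matching(design, cells)
        by_summary = hn.anova_from_summary(design, cells).anova_table
        by_replicates = hn.anova_from_replicates(design, data).anova_table
        pd.testing.assert_frame_equal(by_summary, by_replicates, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_statsmodels_oracle(self, seed):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        design, cells = random_balanced_model(seed, k=3)
        data = replicates_matching(design, cells).rename(
            columns=dict(zip(design.factors, ["A", "B", "C"]))
        )
        fit = ols("response ~ A * B * C", data=data).fit()
        oracle = sm.stats.anova_lm(fit, typ=2)
        res = hn.anova_from_replicates(FactorialDesign(("A", "B", "C")), data)
        ours = res.anova_table.set_index("term")
        for term in ours.index:
            oracle_row = oracle.loc[term.replace("*", ":")]
            assert ours.loc[term, "ss"] == pytest.approx(oracle_row["sum_sq"], rel=1e-9)
            assert ours.loc[term, "F"] == pytest.approx(oracle_row["F"], rel=1e-9)
            assert ours.loc[term, "p"] == pytest.approx(oracle_row["PR(>F)"], rel=1e-9, abs=1e-12)
        assert res.ss_within == pytest.approx(oracle.loc["Residual", "sum_sq"], rel=1e-9)


class TestInvariances:
    def test_total_ss_conservation(self):
        design, cells = random_balanced_model(5, k=3, n=4)
        data = replicates_matching(design, cells)
        res = hn.anova_from_replicates(design, data)
        y = data["response"].to_numpy()
        total_ss = float(((y - y.mean()) ** 2).sum())
        assert res.anova_table["ss"].sum() + res.ss_within == pytest.approx(total_ss, rel=1e-10)

    def test_factor_permutation_preserves_f_and_p(self):
        design, cells = random_balanced_model(6, k=3, n=5)
        res = hn.anova_from_summary(design, cells)
        perm = FactorialDesign(("C", "A", "B"))
        perm_cells = [
            CellSummary((c.levels[2], c.levels[0], c.levels[1]), c.n, c.mean, c.sd)
            for c in cells
        ]
        res_perm = hn.anova_from_summary(perm, perm_cells)
        def keyed(r):
            return {frozenset(t.split(":")): (f, p) for t, f, p in
                    zip(r.anova_table["term"], r.anova_table["F"], r.anova_table["p"])}
        orig, permuted = keyed(res), keyed(res_perm)
        for term, (f, p) in orig.items():
            assert permuted[term][0] == pytest.approx(f)
            assert permuted[term][1] == pytest.approx(p)

    def test_scale_equivariance(self):
        design, cells = random_balanced_model(7, k=2, n=6)
        doubled = [CellSummary(c.levels, c.n, 2 * c.mean, 2 * c.sd) for c in cells]
        res, res2 = hn.anova_from_summary(design, cells), hn.anova_from_summary(design, doubled)
        assert np.allclose(res2.anova_table["ss"], 4 * res.anova_table["ss"])
        assert np.allclose(res2.anova_table["F"], res.anova_table["F"])
        assert np.allclose(res2.anova_table["p"], res.anova_table["p"])


class TestReplicatesPath:
    def test_noiseless_planted_interaction_recovered_exactly(self):
        cfg = hn.SyntheticConfig(seed=3)
        cfg.factorial.noise_sd = 0.0
        data = hn.simulate_factorial(cfg)
        design = FactorialDesign(cfg.factorial.factors)
        res = hn.anova_from_replicates(design, data)
        assert res.term("Taurine", "Paeonol")["effect"] == pytest.approx(-0.0665, abs=1e-12)

    def test_physical_dose_levels_coded_low_to_minus_one(self, taurine_block):
        design, frame = taurine_block
        rng = np.random.default_rng(0)
        rows = []
        for _, row in frame.iterrows():
            for _ in range(3):
                rows.append({f: row[f] for f in design.factors} | {"response": rng.normal()})
        data = pd.DataFrame(rows)
        model = FactorialModel.from_replicates(design, data)
        assert set(model.cells) == set(design.cells())

    def test_empty_cell_rejected(self):
        design = FactorialDesign(("A", "B"))
        data = pd.DataFrame({"A": [-1, -1, 1], "B": [-1, -1, -1], "response": [1.0, 2.0, 3.0]})
        with pytest.raises(IncompleteDesignError):
            hn.anova_from_replicates(design, data)


class TestCalibration:
    def test_power_against_two_sd_interaction(self):
        # an interaction of 2 within-cell sd units at n = 6 is essentially
        # always detected at alpha = 0.05
        sd = 0.05
        detections = 0
        reps = 500
        for seed in range(reps):
            cfg = hn.SyntheticConfig(seed=50_000 + seed)
            cfg.factorial = hn.FactorialSpec(
                factors=("A", "B", "C"),
                n=6,
                baseline=1.0,
                main_effects=(0.0, 0.0, 0.0),
                interaction_effects={("A", "B"): 2 * sd},
                noise_sd=sd,
            )
            data = hn.simulate_factorial(cfg)
            res = hn.anova_from_replicates(FactorialDesign(("A", "B", "C")), data)
            if res.term("A", "B")["p"] < 0.05:
                detections += 1
        assert detections / reps > 0.9


class TestInteractionReport:
    def test_block_one_report_at_alpha_001(self, taurine_block):
        design, frame = taurine_block
        rep = hn.anova_from_summary(design, frame).interaction_report(alpha=0.01)
        row = rep[rep["term"] == "Taurine:Paeonol"].iloc[0]
        assert row["present"]
        assert row["direction"] == -1

    def test_all_p_one_reports_none_present(self):
        design = FactorialDesign(("A", "B"))
        cells = [CellSummary(lv, 4, 5.0, 1.0) for lv in design.cells()]
        rep = hn.anova_from_summary(design, cells).interaction_report(alpha=0.05)
        assert not rep["present"].any()

    def test_alpha_one_reports_all_present(self, taurine_block):
        design, frame = taurine_block
        rep = hn.anova_from_summary(design, frame).interaction_report(alpha=1.0)
        assert rep["present"].all()

    def test_summary_text_mentions_interactions(self, taurine_block):
        design, frame = taurine_block
        text = hn.anova_from_summary(design, frame).summary(alpha=0.01)
        assert "Taurine:Paeonol" in text
        assert "first-order interactions present" in text
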