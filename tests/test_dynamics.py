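"""Stratum blocks, event aggregation, accumulation-model fitting,
phylogenetic signal, local regression and the standard group tests."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from tedyn.config import DynamicsConfig
from tedyn.core import GeneFeature, Interval
from tedyn.dynamics import (
    aggregate_event_te_content,
    anova_tukey,
    assign_stratum_blocks,
    fit_accumulation_models,
    intact_fraction_trend,
    negexp,
    pearson_test,
    phylo_signal_test,
    plateau_summary,
    wilcoxon_paired,
)
from tedyn.simulate import generate_accumulation_table


def make_genes(spec):
    """spec: list of (start_kb, end_kb, stratum)."""
    return [
        GeneFeature(Interval("c", int(s * 1000), int(e * 1000)), f"g{i}", lab)
        for i, (s, e, lab) in enumerate(spec)
    ]


class TestStratumBlocks:
    def test_midpoint_boundary_between_strata(self):
        genes = make_genes(
            [(10, 12, "A"), (50, 52, "A"), (98, 100, "A"),
             (150, 152, "B"), (200, 202, "B"), (290, 292, "B")]
        )
        blocks, report = assign_stratum_blocks(genes, {"c": (0, 300000)})
        assert [(iv.start, iv.end, lab) for iv, lab in blocks] == [
            (0, 125000, "A"), (125000, 300000, "B")
        ]
        assert report["retained_percent"] == pytest.approx(100.0)

    def test_block_under_80kb_discarded(self):
        genes = make_genes([(10, 12, "A"), (60, 62, "A")])
        blocks, report = assign_stratum_blocks(genes, {"c": (0, 70000)})
        assert blocks == []
        assert report["retained_percent"] == 0.0
        assert report["discarded"][0][2].startswith("block <")

    def test_single_gene_run_discarded(self):
        genes = make_genes([(50, 52, "A")])
        blocks, report = assign_stratum_blocks(genes, {"c": (0, 100000)})
        assert blocks == []
        assert "fewer than 2 genes" in report["discarded"][0][2]

    def test_unlabeled_gene_is_an_error_naming_ids(self):
        genes = make_genes([(10, 12, "A"), (50, 52, None)])
        with pytest.raises(ValueError, match="g1"):
            assign_stratum_blocks(genes, {"c": (0, 100000)})

    def test_retained_blocks_never_overlap(self):
        genes = make_genes(
            [(5, 7, "A"), (80, 82, "A"), (120, 122, "B"), (240, 242, "B"),
             (300, 302, "C"), (420, 422, "C")]
        )
        blocks, report = assign_stratum_blocks(genes, {"c": (0, 500000)})
        spans = sorted((iv.start, iv.end) for iv, _ in blocks)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        assert 0 <= report["retained_percent"] <= 100


class TestAggregation:
    def base_frame(self):
        return pd.DataFrame(
            [
                {"stratum_id": "s1", "species": "sp1", "haplotype": "a1",
                 "te_percent": 10.0, "age_MY": 1.0},
                {"stratum_id": "s1", "species": "sp1", "haplotype": "a2",
                 "te_percent": 12.0, "age_MY": 1.0},
                {"stratum_id": "s1", "species": "sp2", "haplotype": "a1",
                 "te_percent": 14.0, "age_MY": 1.0},
                {"stratum_id": "s1", "species": "sp2", "haplotype": "a2",
                 "te_percent": 16.0, "age_MY": 1.0},
            ]
        )

    def test_haplotype_then_species_means(self):
        out = aggregate_event_te_content(self.base_frame(), {"s1": "E1"})
        assert out.loc[0, "te_percent"] == pytest.approx(13.0)  # mean(11, 15)
        assert out.loc[0, "n_species"] == 2

    def test_time_zero_record_appended_with_stated_age(self):
        out = aggregate_event_te_content(
            self.base_frame(), {"s1": "E1"}, time_zero_te_percent=6.57
        )
        zero = out[out.event == "time_zero"].iloc[0]
        assert zero.age_my == pytest.approx(3e-8)
        assert zero.te_percent == pytest.approx(6.57)

    def test_stratum_missing_in_one_haplotype_is_an_error(self):
        df = self.base_frame().iloc[:3]
        with pytest.raises(ValueError, match="missing in one haplotype"):
            aggregate_event_te_content(df, {"s1": "E1"})

    def test_excluded_strata_dropped(self):
        df = self.base_frame()
        cfg = DynamicsConfig(exclude_strata=["s1"])
        out = aggregate_event_te_content(df, {"s1": "E1"}, cfg=cfg)
        assert out.empty


class TestAccumulationFits:
    ages = np.linspace(0.1, 7.0, 21)

    def test_noiseless_negexp_recovered_exactly(self):
        tab = generate_accumulation_table(5, 50, 2, self.ages, 0.0, 0)
        fits, best = fit_accumulation_models(tab)
        assert best.model == "negexp"
        assert best.params["A"] == pytest.approx(50.0, abs=1e-4)
        assert best.params["r"] == pytest.approx(2.0, abs=1e-4)
        assert best.params["y0"] == pytest.approx(5.0, abs=1e-4)

    def test_linear_data_prefers_linear_over_negexp(self):
        tab = pd.DataFrame(
            {"age_my": self.ages, "te_percent": 3.0 + 2.0 * self.ages}
        )
        fits, best = fit_accumulation_models(tab)
        aic = {f.model: f.aic for f in fits}
        assert aic["linear"] <= aic["negexp"]

    def test_fit_invariant_to_record_order(self):
        tab = generate_accumulation_table(5, 50, 2, self.ages, 5.0, 11)
        shuffled = tab.sample(frac=1.0, random_state=3)
        f1, b1 = fit_accumulation_models(tab)
        f2, b2 = fit_accumulation_models(shuffled)
        assert b1.model == b2.model
        assert b1.aic == pytest.approx(b2.aic, abs=1e-8)

    def test_covariable_term_is_accepted(self):
        tab = generate_accumulation_table(5, 50, 2, self.ages, 5.0, 4)
        tab["ancestral_size_bp"] = np.linspace(1e5, 5e6, len(tab))
        fits, best = fit_accumulation_models(tab, with_covariable=True)
        ne = [f for f in fits if f.model == "negexp"][0]
        assert "beta_cov0" in ne.params

    def test_too_few_records_rejected(self):
        tab = generate_accumulation_table(5, 50, 2, [1, 2, 3, 4, 5], 0, 0)
        with pytest.raises(ValueError, match=">= 6"):
            fit_accumulation_models(tab)

    @pytest.mark.parametrize("r,expected", [(2.0, 1.4979), (0.1, 29.9573)])
    def test_plateau_time_closed_form(self, r, expected):
        tab = generate_accumulation_table(5, 50, r, self.ages, 0.0, 0)
        fits, best = fit_accumulation_models(tab)
        summary = plateau_summary(best)
        assert summary["A"] == pytest.approx(50.0, abs=1e-3)
        assert summary["t95_my"] == pytest.approx(expected, abs=1e-3)

    def test_negative_rate_flagged_no_plateau(self):
        from tedyn.dynamics import AccumulationFit

        fit = AccumulationFit("negexp", {"y0": 5, "A": 50, "r": -0.5},
                              aic=0.0, rss=0.0, n=10, k=4,
                              fitted=np.zeros(10))
        assert plateau_summary(fit)["plateau"] is False


class TestPhyloSignal:
    @staticmethod
    def balanced_tree(n_tips=16, depth=4.0):
        def rec(labels, d):
            if len(labels) == 1:
                return f"{labels[0]}:{d}"
            half = len(labels) // 2
            return f"({rec(labels[:half], d / 2)},{rec(labels[half:], d / 2)}):{d / 2}"

        labels = [f"T{i}" for i in range(n_tips)]
        nwk = f"({rec(labels[:n_tips // 2], depth / 2)},{rec(labels[n_tips // 2:], depth / 2)});"
        return labels, dendropy.Tree.get(data=nwk, schema="newick")

    def test_lambda_zero_equals_ols(self):
        labels, tree = self.balanced_tree(4, 4.0)
        rec = pd.DataFrame(
            {"event": labels, "age_my": [1, 2, 3, 4],
             "te_percent": [10.0, 20.0, 28.0, 44.0]}
        )
        res = phylo_signal_test(rec, tree)
        slope_ols = np.polyfit(rec.age_my, rec.te_percent, 1)[0]
        if res.lambda_hat == 0.0:
            assert res.slope == pytest.approx(slope_ols, abs=1e-8)

    def test_brownian_residuals_recover_high_lambda(self):
        from tedyn.dynamics import _vcv_from_tree

        labels, tree = self.balanced_tree()
        V = _vcv_from_tree(tree, labels)
        L = np.linalg.cholesky(V)
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 5, len(labels))
        lams = []
        for _ in range(100):
            y = 3 + 2 * x + L @ rng.normal(0, 2, len(labels))
            res = phylo_signal_test(
                pd.DataFrame({"event": labels, "age_my": x, "te_percent": y}),
                tree,
            )
            lams.append(res.lambda_hat)
        assert np.median(lams) >= 0.8

    def test_star_tree_flagged_unidentifiable(self):
        labels = ["A", "B", "C", "D", "E"]
        nwk = "(" + ",".join(f"{lab}:1" for lab in labels) + ");"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        rec = pd.DataFrame(
            {"event": labels, "age_my": [1, 2, 3, 4, 5],
             "te_percent": [5.0, 9.0, 16.0, 22.0, 25.0]}
        )
        res = phylo_signal_test(rec, tree)
        assert res.warning is not None and "star" in res.warning

    def test_missing_tip_is_an_error_naming_it(self):
        labels, tree = self.balanced_tree(4)
        rec = pd.DataFrame(
            {"event": ["T0", "T1", "nope", "T3"], "age_my": [1, 2, 3, 4],
             "te_percent": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(KeyError, match="nope"):
            phylo_signal_test(rec, tree)


class TestLocalRegression:
    def test_straight_line_reproduced_for_every_span(self):
        x = [1, 2, 3, 4, 5, 6, 7]
        y = [2 * v + 1 for v in x]
        for span in (0.5, 0.7, 1.0):
            res = intact_fraction_trend(x, y, spans=(span,))
            assert np.max(np.abs(res["fitted"] - np.array(y, float))) < 1e-6

    def test_step_data_prefers_adaptive_span(self):
        x = np.linspace(0, 10, 20)
        y = np.where(x < 5, 0.2, 0.02)
        res = intact_fraction_trend(x, y, spans=(0.3, 0.5, 1.0))
        full = intact_fraction_trend(x, y, spans=(1.0,))
        assert res["span"] < 1.0
        assert res["rss"] < full["rss"]

    def test_four_points_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            intact_fraction_trend([1, 2, 3, 4], [1, 2, 3, 4])


class TestGroupTests:
    def test_all_zero_differences_flagged_p_one(self):
        res = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert "zero" in res.note

    def test_wilcoxon_detects_paired_shift(self, rng):
        a = rng.normal(10, 1, 30)
        res = wilcoxon_paired(a, a + 1.5)
        assert res.p_value < 0.001

    def test_pearson_on_exact_line(self):
        res = pearson_test([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert res.statistic == pytest.approx(1.0)

    def test_tukey_type_i_error_rate_under_null(self):
        """Three equal-mean Gaussian groups: Tukey-adjusted comparisons stay
        above 0.05 in the vast majority of replicates."""
        rng = np.random.default_rng(17)
        ok = 0
        for _ in range(100):
            frame = pd.DataFrame(
                {
                    "value": rng.normal(0, 1, 150),
                    "group": np.repeat(["g1", "g2", "g3"], 50),
                }
            )
            results = anova_tukey(frame, "value", "group")
            tukeys = [r for r in results if r.test_name.startswith("tukey")]
            if all(r.adjusted_p > 0.05 for r in tukeys):
                ok += 1
        assert ok >= 93

    def test_zero_variance_group_rejected(self):
        frame = pd.DataFrame(
            {"value": [1.0, 1.0, 1.0, 1.0], "group": ["a", "a", "b", "b"]}
        )
        with pytest.raises(ValueError, match="degenerate"):
            anova_tukey(frame, "value", "group")

    def test_anova_with_blocking_factor(self, rng):
        frame = pd.DataFrame(
            {
                "value": np.concatenate(
                    [rng.normal(0, 1, 40), rng.normal(2, 1, 40)]
                ),
                "group": np.repeat(["nrr", "auto"], 40),
                "species": list(np.tile(np.repeat(["sp1", "sp2"], 20), 2)),
            }
        )
        results = anova_tukey(frame, "value", "group", block="species")
        anova_group = [r for r in results if "_g" in r.test_name][0]
        assert anova_group.p_value < 0.001
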