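"""Rc cross-tabulation and seed-trait statistics."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from pigdiv import (
    PanelConfig,
    colour_anova,
    describe_traits,
    rc_crosstab,
    simulate_indel_calls,
    simulate_panel,
    simulate_traits,
    trait_correlations,
    trait_pca,
)
from pigdiv.syndata import SyntheticTruth


def _truth(n=120, n_white=20):
    colour = {f"a{i:03d}": ("white" if i < n_white else "red") for i in range(n)}
    return SyntheticTruth(group_of={a: "g" for a in colour}, duplicate_pairs=[],
                          divergence_F={}, allele_frequencies=pd.DataFrame(),
                          colour_of=colour)


class TestRcCrosstab:
    def test_concordant_calls_no_discordance_and_exact_marginals(self):
        truth = _truth()
        calls = simulate_indel_calls(truth, concordance=1.0, rng_seed=0)
        colours = pd.Series(truth.colour_of)
        res = rc_crosstab(calls, colours)
        assert res.discordant == []
        assert res.table.to_numpy().sum() == len(calls)
        assert res.table.loc["white", 0] == 20 and res.table.loc["red", 1] == 100

    def test_planted_discordant_set_recovered(self):
        truth = _truth()
        calls = simulate_indel_calls(truth, concordance=0.9, rng_seed=5)
        res = rc_crosstab(calls, pd.Series(truth.colour_of))
        assert res.discordant == sorted(truth.discordant_indel_accessions)

    def test_unmatched_ids_listed_and_zero_class_rows(self):
        truth = _truth(n=30, n_white=5)
        calls = simulate_indel_calls(truth, concordance=1.0, rng_seed=1)
        colours = pd.Series(truth.colour_of).drop("a000")
        colours.loc["ghost"] = "purple"  # class with no matching call
        res = rc_crosstab(calls, colours)
        assert set(res.unmatched) == {"a000", "ghost"}
        assert res.table.loc["purple"].sum() == 0

    def test_ambiguous_calls_counted_separately(self):
        truth = _truth(n=10, n_white=2)
        calls = simulate_indel_calls(truth, concordance=1.0, rng_seed=2)
        calls.loc["a005", "rc_score"] = 2  # multi-band profile
        res = rc_crosstab(calls, pd.Series(truth.colour_of))
        assert res.ambiguous == ["a005"]
        assert res.table.to_numpy().sum() == 9


class TestDescribeTraits:
    def test_hand_arithmetic(self):
        tt = pd.DataFrame({"colour_class": ["red"] * 3, "x": [1.0, 2.0, 3.0]})
        d = describe_traits(tt)
        assert d.loc["x", "median"] == 2.0
        assert d.loc["x", "SD"] == pytest.approx(1.0)
        assert d.loc["x", "CV"] == pytest.approx(0.5)
        assert d.loc["x", "range"] == 2.0

    def test_constant_trait_flagged(self):
        tt = pd.DataFrame({"colour_class": ["red"] * 5, "x": [3.0] * 5,
                           "y": [1, 2, 3, 4, 5.0]})
        d = describe_traits(tt)
        assert d.loc["x", "SD"] == 0.0 and d.loc["x", "CV"] == 0.0
        assert np.isnan(d.loc["x", "shapiro_p"])

    def test_cv_ordering_matches_generating_model(self):
        truth = _truth(n=300, n_white=150)
        tt = simulate_traits(truth, rng_seed=4)
        d = describe_traits(tt)
        colour = ["lightness", "a_star", "b_star", "hue", "saturation", "intensity"]
        assert d.loc[colour, "CV"].idxmax() == "saturation"
        assert d.loc[colour, "CV"].idxmin() == "hue"


class TestCorrelations:
    def test_exact_and_degenerate_cases(self):
        tt = pd.DataFrame({"colour_class": ["red"] * 10,
                           "x": np.arange(10.0)})
        tt["same"] = tt["x"]
        tt["neg"] = -tt["x"]
        tt["flat"] = 1.0
        r, p = trait_correlations(tt)
        assert r.loc["x", "same"] == pytest.approx(1.0)
        assert r.loc["x", "neg"] == pytest.approx(-1.0)
        assert np.isnan(r.loc["x", "flat"])

    def test_generating_correlation_recovered(self):
        rng = np.random.default_rng(8)
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        xy = rng.multivariate_normal([0, 0], cov, size=200)
        tt = pd.DataFrame({"colour_class": ["red"] * 200,
                           "x": xy[:, 0], "y": xy[:, 1]})
        r, _ = trait_correlations(tt)
        assert abs(r.loc["x", "y"] - 0.9) < 0.05


class TestTraitPca:
    def test_two_perfectly_correlated_traits(self):
        x = np.arange(20.0)
        tt = pd.DataFrame({"colour_class": ["red"] * 20, "x": x, "y": 3 * x + 1})
        res = trait_pca(tt)
        assert res.pct_variance[0] == pytest.approx(100.0)

    def test_constant_trait_dropped_with_warning(self):
        tt = pd.DataFrame({"colour_class": ["red"] * 10, "x": np.arange(10.0),
                           "y": np.arange(10.0) ** 2, "flat": 5.0})
        with pytest.warns(UserWarning, match="flat"):
            res = trait_pca(tt)
        assert "flat" not in res.loadings.index

    def test_colour_classes_separate_on_pc1(self):
        cfg = PanelConfig(n_markers=50, group_spec=(("g", 200, 0.0),), rng_seed=3)
        _, truth = simulate_panel(cfg)
        tt = simulate_traits(truth, rng_seed=11)
        res = trait_pca(tt)
        sc = res.scores
        dark = sc[sc["colour_class"].isin(["purple", "variable purple"])]["PC1"]
        light = sc[sc["colour_class"].isin(["red", "white"])]["PC1"]
        # PC1 is the colour axis: the class means must sit far apart
        gap = abs(dark.mean() - light.mean())
        pooled = np.sqrt((dark.var() + light.var()) / 2)
        assert gap > pooled


class TestColourAnova:
    @pytest.fixture
    def textbook(self):
        rng = np.random.default_rng(0)
        rows = []
        for cls, mu in [("red", 10.0), ("purple", 12.0), ("white", 15.0)]:
            for v in rng.normal(mu, 1.0, size=20):
                rows.append({"colour_class": cls, "y": v})
        return pd.DataFrame(rows)

    def test_matches_independent_reference(self, textbook):
        res = colour_anova(textbook, "y")
        # independent route: statsmodels Tukey + closed-form F
        groups = [g["y"].to_numpy() for _, g in textbook.groupby("colour_class")]
        k, n = len(groups), sum(len(g) for g in groups)
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_ref = (ssb / (k - 1)) / (ssw / (n - k))
        assert res.F == pytest.approx(f_ref)
        assert res.df == (2, 57)
        sm = pairwise_tukeyhsd(textbook["y"], textbook["colour_class"])
        sm_p = dict(zip([tuple(r) for r in sm.summary().data[1:]],
                        sm.pvalues))
        for _, row in res.tukey.iterrows():
            match = [p for key, p in sm_p.items()
                     if {key[0], key[1]} == {row["class_a"], row["class_b"]}]
            assert abs(row["p_adj"] - match[0]) < 1e-4

    def test_f_invariant_to_affine_rescaling(self, textbook):
        res1 = colour_anova(textbook, "y")
        tt2 = textbook.copy()
        tt2["y"] = 100.0 * tt2["y"] + 7.0
        res2 = colour_anova(tt2, "y")
        assert res2.F == pytest.approx(res1.F)

    def test_design_df_five_classes(self):
        rng = np.random.default_rng(1)
        sizes = [96, 23, 16, 5, 57]  # five colour classes, 197 accessions
        rows = []
        for cls, sz in zip("abcde", sizes):
            for v in rng.normal(0.0, 1.0, size=sz):
                rows.append({"colour_class": cls, "y": v})
        res = colour_anova(pd.DataFrame(rows), "y")
        assert res.df == (4, 192)

    def test_heterogeneous_trait_precluded_after_transform(self):
        rng = np.random.default_rng(2)
        rows = []
        # variances wildly unequal in both raw and log scale
        for cls, mu, sd in [("a", 0.0, 0.01), ("b", 0.0, 5.0), ("c", 0.0, 0.2)]:
            for v in rng.normal(mu, sd, size=40):
                rows.append({"colour_class": cls, "y": v})
        res = colour_anova(pd.DataFrame(rows), "y")
        assert res.precluded and res.transform == "log"
        assert res.tukey is None

    def test_single_member_class_dropped(self, textbook):
        extra = pd.concat([textbook,
                           pd.DataFrame([{"colour_class": "mix", "y": 11.0}])],
                          ignore_index=True)
        with pytest.warns(UserWarning, match="mix"):
            res = colour_anova(extra, "y")
        assert res.dropped_classes == ["mix"]
        assert res.df == (2, 57)
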