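"""Agreement statistics, score audits and fragment attribution."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import molpref as mp


# -- independent brute-force oracles (direct formula re-derivations) -------

def fleiss_brute(table):
    table = np.asarray(table, dtype=float)
    n_items, _ = table.shape
    n = table[0].sum()
    p_i = ((table ** 2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = p_i.mean()
    p_j = table.sum(axis=0) / (n_items * n)
    p_e = (p_j ** 2).sum()
    return (p_bar - p_e) / (1 - p_e)


def cohen_brute(a, b):
    cats = sorted(set(a) | set(b))
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    return (p_o - p_e) / (1 - p_e)


class TestFleissKappa:
    def test_unanimous_is_one(self):
        assert mp.fleiss_kappa([[2, 0], [0, 2], [2, 0], [0, 2]]) == pytest.approx(1.0)

    def test_hand_computed_zero(self):
        # P-bar = 0.5 and chance P-e = 0.5 give kappa exactly 0
        assert mp.fleiss_kappa([[2, 0], [1, 1], [0, 2], [1, 1]]) == pytest.approx(0.0, abs=1e-12)

    def test_single_category_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(mp.fleiss_kappa([[3, 0], [3, 0]]))

    def test_ragged_raises(self):
        with pytest.raises(mp.ShapeError):
            mp.fleiss_kappa([[2, 0], [1, 1, 1]])
        with pytest.raises(mp.ShapeError):
            mp.fleiss_kappa([[2, 0], [1, 1], [3, 0]])  # unequal rater counts

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            items = rng.integers(3, 12)
            cats = rng.integers(2, 5)
            raters = rng.integers(2, 7)
            table = rng.multinomial(raters, np.ones(cats) / cats, size=items)
            expected = fleiss_brute(table)
            if abs(1 - (table.sum(0) / table.sum()).max()) < 1e-12:
                continue  # degenerate chance agreement
            assert mp.fleiss_kappa(table) == pytest.approx(expected, abs=1e-12)


class TestCohenKappa:
    def test_identical_is_one(self):
        assert mp.cohen_kappa(["A", "B", "A"], ["A", "B", "A"]) == 1.0

    def test_hand_computed_half(self):
        # p_o = 0.75, p_e = 0.5 by hand
        assert mp.cohen_kappa(list("AABB"), list("ABBB")) == pytest.approx(0.5)

    def test_length_mismatch_raises(self):
        with pytest.raises(mp.LengthError):
            mp.cohen_kappa(["A"], ["A", "B"])
        with pytest.raises(mp.LengthError):
            mp.cohen_kappa([], [])

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            a = [str(x) for x in rng.integers(0, 3, size=n)]
            b = [str(x) for x in rng.integers(0, 3, size=n)]
            if a == b:
                continue  # exact agreement handled by its own test
            assert mp.cohen_kappa(a, b) == pytest.approx(cohen_brute(a, b),
                                                         abs=1e-12)


class TestLeftRightBias:
    def test_balanced_is_p_one(self):
        pct, p = mp.left_right_bias(["left"] * 50 + ["right"] * 50)
        assert pct == 50.0 and p == pytest.approx(1.0)

    def test_all_left_closed_form(self):
        pct, p = mp.left_right_bias(["left"] * 100)
        assert pct == 100.0
        assert p == pytest.approx(2 * 0.5 ** 100, rel=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mp.left_right_bias([])


class TestDescriptorCorrelations:
    def test_perfect_and_anti_correlation(self):
        desc = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0],
                             "const": [1.0, 1.0, 1.0]})
        scores = [np.array([1.0, 2.0, 3.0])]
        out = mp.descriptor_correlations(scores, desc)
        by_name = out.set_index("descriptor")
        assert by_name.loc["a", "mean_r"] == pytest.approx(1.0)
        assert by_name.loc["b", "mean_r"] == pytest.approx(-1.0)
        assert by_name.loc["const", "constant"] and by_name.loc["const", "mean_r"] == 0.0
        # sorted by |mean r| descending
        assert out["mean_r"].abs().is_monotonic_decreasing

    def test_independent_scores_weakly_correlated(self):
        rng = np.random.default_rng(0)
        desc = pd.DataFrame({"x": rng.normal(size=2000)})
        scores = [rng.normal(size=2000) for _ in range(3)]
        out = mp.descriptor_correlations(scores, desc)
        assert out["mean_r"].abs().max() < 0.1


class TestSetDiscrimination:
    def test_identical_distributions(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=500)
        res = mp.set_discrimination({"drug": a, "control": a.copy()}, "control")
        assert res["auc_vs_control"]["drug"] == pytest.approx(0.5, abs=0.01)
        assert res["anova_F"] == pytest.approx(0.0, abs=1e-9)

    def test_fully_separated(self):
        res = mp.set_discrimination(
            {"drug": [-3.0, -2.5, -2.0], "control": [1.0, 1.5, 2.0]}, "control")
        assert res["auc_vs_control"]["drug"] == 1.0  # lower score = positive

    def test_null_anova_large_p(self):
        rng = np.random.default_rng(42)
        sets = {k: rng.normal(size=400) for k in ("a", "b", "c")}
        res = mp.set_discrimination(sets, "c")
        assert res["anova_p"] > 0.05

    def test_auc_matches_mann_whitney(self):
        rng = np.random.default_rng(3)
        drug = rng.normal(-0.5, 1.0, size=80)
        ctrl = rng.normal(0.5, 1.0, size=120)
        res = mp.set_discrimination({"drug": drug, "gdb": ctrl}, "gdb")
        # AUC == U / (n1 n2) with lower-score-positive orientation
        u = mannwhitneyu(-drug, -ctrl, alternative="two-sided").statistic
        assert res["auc_vs_control"]["drug"] == pytest.approx(
            u / (len(drug) * len(ctrl)), abs=1e-12)

    def test_degenerate_sets_raise(self):
        with pytest.raises(mp.DegenerateSetError):
            mp.set_discrimination({"a": [1.0]}, "a")
        with pytest.raises(mp.DegenerateSetError):
            mp.set_discrimination({"a": [1.0], "b": [1.0, 1.0]}, "b")


class TestFragmentScores:
    def test_single_molecule_leaves_inherit_score(self):
        out = mp.brics_fragment_scores(["CCOC(=O)c1ccccc1N"], [2.5], min_count=1)
        assert len(out) >= 2
        assert np.allclose(out["mean_score"], 2.5)
        assert (out["n_parents"] == 1).all()

    def test_min_count_omits_rare_fragments(self):
        mols = ["CCOC(=O)c1ccccc1N"] * 4  # same leaves, but 4 < 5 parents
        out = mp.brics_fragment_scores(mols, [0.0] * 4, min_count=5)
        assert len(out) == 0

    def test_shared_fragment_mean(self):
        # both esters share the ethyl and benzoate-like leaves
        mols = ["CCOC(=O)c1ccccc1N", "CCOC(=O)c1ccccc1"]
        out = mp.brics_fragment_scores(mols, [-2.0, 2.0], min_count=2)
        assert len(out) >= 1
        assert np.allclose(out["mean_score"], 0.0)  # mean of {-2, +2}
        assert out["mean_score"].is_monotonic_increasing  # best (lowest) first

    def test_unbreakable_molecule_is_its_own_leaf(self):
        out = mp.brics_fragment_scores(["c1ccccc1"], [1.0], min_count=1)
        assert len(out) == 1 and out.iloc[0]["n_parents"] == 1

    def test_attribution_conserves_evidence(self, small_pool):
        smiles = small_pool["smiles_canonical"].head(25).tolist()
        scores = np.linspace(-1, 1, len(smiles))
        out = mp.brics_fragment_scores(smiles, scores, min_count=1)
        total_leaves = sum(len(mp.brics_leaves(s)) for s in smiles)
        assert out["n_parents"].sum() == total_leaves


class TestAgreementReport:
    def test_consistent_panel(self, bench):
        pairs = bench["pairs"].head(40)
        panel = mp.simulate_rater_panel(pairs, bench["oracle"], n_raters=4,
                                        p_consistent=1.0, n_redundant=10, seed=0)
        report = mp.agreement_report(panel)
        # perfectly consistent raters: full agreement everywhere
        assert report["fleiss_kappa"] == pytest.approx(1.0)
        for entry in report["per_rater"].values():
            assert entry["cohen_kappa"] == 1.0
            assert entry["repeat_agreement_pct"] == 100.0

    def test_noisy_panel_moderate_agreement(self, rater_panel):
        report = mp.agreement_report(rater_panel)
        assert 0.1 < report["fleiss_kappa"] < 0.95
        assert np.isfinite(report["mean_cohen_kappa"])
        for entry in report["per_rater"].values():
            assert 0 <= entry["left_pct"] <= 100
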