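import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from emovox import stats


class TestHitRates:
    def test_perfect_decoding_diagonal(self):
        table = stats.ConfusionTable(np.diag([6, 6, 6, 6]), ("h", "s", "a", "n"))
        m = stats.hit_rates(table)
        np.testing.assert_allclose(m.h_biased, 1.0)
        np.testing.assert_allclose(m.h_unbiased, 1.0)

    def test_uniform_2x2_random_responding(self):
        # uniform responding: H_b = 0.5 and H_u equals chance p_c = 0.25
        table = stats.ConfusionTable(np.array([[1, 1], [1, 1]]), ("a", "b"))
        m = stats.hit_rates(table)
        np.testing.assert_allclose(m.h_biased, 0.5)
        np.testing.assert_allclose(m.h_unbiased, 0.25)
        np.testing.assert_allclose(m.p_chance, 0.25)

    def test_hand_computed_2x2(self):
        # [[3,1],[2,2]]: cat 1 has H_b=3/4, H_u=9/(4*5)=0.45, p_c=20/64
        table = stats.ConfusionTable(np.array([[3, 1], [2, 2]]), ("a", "b"))
        m = stats.hit_rates(table)
        assert m.h_biased[0] == pytest.approx(0.75)
        assert m.h_unbiased[0] == pytest.approx(0.45)
        assert m.p_chance[0] == pytest.approx(0.3125)

    def test_unused_label_gets_zero_unbiased(self):
        table = stats.ConfusionTable(np.array([[2, 0], [2, 0]]), ("a", "b"))
        m = stats.hit_rates(table)
        assert m.h_unbiased[1] == 0.0

    def test_zero_row_rejected(self):
        table = stats.ConfusionTable(np.array([[0, 0], [1, 1]]), ("a", "b"))
        with pytest.raises(ValueError):
            stats.hit_rates(table)

    @settings(max_examples=200, deadline=None)
    @given(
        counts=arrays(
            np.int64,
            (4, 4),
            elements=st.integers(min_value=0, max_value=30),
        ).filter(lambda c: np.all(c.sum(axis=1) > 0))
    )
    def test_unbiased_never_exceeds_biased(self, counts):
        m = stats.hit_rates(stats.ConfusionTable(counts, ("h", "s", "a", "n")))
        assert np.all(m.h_unbiased <= m.h_biased + 1e-12)
        assert np.all((m.p_chance >= 0) & (m.p_chance <= 1))


class TestProportionIndex:
    # printed (H_b %, pi %) pairs from a 4-alternative categorization report
    TABLE_PAIRS = [
        (39.5, 66.2), (41.2, 67.8), (32.2, 58.7), (86.0, 94.9),
        (29.2, 55.3), (20.9, 44.3), (91.0, 96.8), (33.5, 60.2),
        (64.7, 84.6), (25.2, 50.2), (87.0, 95.3), (57.1, 79.9),
        (37.7, 64.5), (38.7, 65.4), (88.2, 95.7), (27.2, 52.8),
    ]

    @pytest.mark.parametrize("hb_pct,pi_pct", TABLE_PAIRS)
    def test_reproduces_printed_pairs(self, hb_pct, pi_pct):
        # the printed pi values were computed from unrounded hit rates, so
        # recomputing from the one-decimal H_b can differ by one unit in the
        # last printed digit
        pi = stats.proportion_index(hb_pct / 100, k=4)
        assert 100 * pi == pytest.approx(pi_pct, abs=0.15)

    @pytest.mark.parametrize(
        "hb_pct,pi_pct",
        [(39.5, 66.2), (41.2, 67.8), (86.0, 94.9), (91.0, 96.8),
         (29.2, 55.3), (64.7, 84.6), (87.0, 95.3)],
    )
    def test_exact_to_printed_decimal(self, hb_pct, pi_pct):
        pi = stats.proportion_index(hb_pct / 100, k=4)
        assert round(100 * pi, 1) == pytest.approx(pi_pct, abs=1e-9)

    def test_chance_maps_to_half(self):
        for k in (2, 3, 4, 6):
            assert stats.proportion_index(1 / k, k) == pytest.approx(0.5)

    def test_perfect_maps_to_one(self):
        for k in (2, 4, 8):
            assert stats.proportion_index(1.0, k) == 1.0

    def test_group_mean_relation(self):
        # a report's group "Mean" rows compute pi from the mean H_b
        assert round(100 * stats.proportion_index(0.497, 4), 1) == 74.8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stats.proportion_index(1.2, 4)
        with pytest.raises(ValueError):
            stats.proportion_index(0.5, 1)


class TestPairedContrast:
    def test_equal_samples_zero(self):
        x = np.array([0.3, 0.4, 0.5])
        res = stats.paired_contrast(x, x.copy())
        assert res.degenerate
        assert res.t == 0.0 and res.cohens_d == 0.0

    def test_hand_computed_effect(self):
        # diff = (1,2,3): mean 2, sd 1 -> d = 2, t = mean/(sd/sqrt(3)) = 2*sqrt(3)
        x = np.array([2.0, 4.0, 6.0])
        y = np.array([1.0, 2.0, 3.0])
        res = stats.paired_contrast(x, y)
        assert res.cohens_d == pytest.approx(2.0)
        assert res.t == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=10)
        a = stats.paired_contrast(x, y)
        b = stats.paired_contrast(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.cohens_d == pytest.approx(-b.cohens_d)
        assert a.p_raw == pytest.approx(b.p_raw)

    def test_bonferroni_alpha_carried(self):
        x = np.array([1.0, 2.0, 3.0])
        res = stats.paired_contrast(x, x + 0.5, alpha_family=0.05, n_comparisons=2)
        assert res.alpha_bonferroni == 0.025

    def test_chance_test_sign_contract(self):
        rng = np.random.default_rng(1)
        p_c = np.full(20, 0.06) + rng.normal(0, 0.005, 20)
        h_u = p_c + 0.1 + rng.normal(0, 0.02, 20)
        res = stats.chance_test(h_u, p_c)
        assert res.t > 0
        assert res.alpha_bonferroni == pytest.approx(0.05 / 12)


def brute_force_mixed_ss(df):
    """Independent sums-of-squares decomposition by explicit enumeration."""
    wide = df.pivot_table(index=["subject", "group"], columns="language", values="y")
    y = wide.to_numpy()
    grp = wide.index.get_level_values("group").to_numpy()
    grand = y.mean()
    groups = sorted(set(grp))
    subj = y.mean(axis=1)
    ss_group = 2 * sum(
        (grp == g).sum() * (subj[grp == g].mean() - grand) ** 2 for g in groups
    )
    ss_subj = 2 * sum((subj - grand) ** 2) - ss_group
    ss_lang = y.shape[0] * sum((y.mean(axis=0) - grand) ** 2)
    ss_cells = sum(
        (grp == g).sum() * (y[grp == g, j].mean() - grand) ** 2
        for g in groups
        for j in range(2)
    )
    ss_inter = ss_cells - ss_group - ss_lang
    ss_total = ((y - grand) ** 2).sum()
    ss_err_w = ss_total - ss_group - ss_subj - ss_lang - ss_inter
    n = y.shape[0]
    return {
        "F_group": (ss_group / 1) / (ss_subj / (n - 2)),
        "F_lang": (ss_lang / 1) / (ss_err_w / (n - 2)),
        "F_inter": (ss_inter / 1) / (ss_err_w / (n - 2)),
        "eta_inter": ss_inter / (ss_inter + ss_err_w),
    }


def _cohort_frame(n1=8, n2=10, effect=0.08, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for group, n, sign in (("FR", n1, 1), ("JP", n2, -1)):
        for _ in range(n):
            sid += 1
            base = rng.normal(0.3, 0.08)
            for lang, is_nat in (("FR", sign > 0), ("JP", sign < 0)):
                rows.append(
                    {
                        "subject": sid,
                        "group": group,
                        "language": lang,
                        "y": base + (effect if is_nat else 0) + rng.normal(0, 0.03),
                    }
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_all_equal_cells_give_zero_f(self):
        df = _cohort_frame(effect=0.0)
        df["y"] = 0.5
        res = stats.mixed_anova_2x2(df)
        assert res.group.F == 0.0
        assert res.within.F == 0.0
        assert res.interaction.F == 0.0

    @pytest.mark.parametrize("n1,n2", [(8, 8), (8, 10), (20, 21)])
    def test_matches_brute_force_decomposition(self, n1, n2):
        df = _cohort_frame(n1, n2, seed=n1 * 100 + n2)
        res = stats.mixed_anova_2x2(df)
        ref = brute_force_mixed_ss(df)
        assert res.group.F == pytest.approx(ref["F_group"], rel=1e-10)
        assert res.within.F == pytest.approx(ref["F_lang"], rel=1e-10)
        assert res.interaction.F == pytest.approx(ref["F_inter"], rel=1e-10)
        assert res.interaction.eta_p2 == pytest.approx(ref["eta_inter"], rel=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = _cohort_frame(20, 21, seed=7)
        res = stats.mixed_anova_2x2(df)
        ref = pg.mixed_anova(
            data=df, dv="y", within="language", subject="subject", between="group"
        ).set_index("Source")
        assert res.group.F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert res.within.F == pytest.approx(ref.loc["language", "F"], rel=1e-9)
        assert res.interaction.F == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)
        assert res.interaction.eta_p2 == pytest.approx(
            ref.loc["Interaction", "np2"], rel=1e-9
        )

    def test_eta_invariant_under_affine_rescaling(self):
        df = _cohort_frame(10, 12, seed=3)
        res = stats.mixed_anova_2x2(df)
        df2 = df.assign(y=100 * df["y"] - 17)
        res2 = stats.mixed_anova_2x2(df2)
        for a, b in [(res.group, res2.group), (res.interaction, res2.interaction)]:
            assert a.eta_p2 == pytest.approx(b.eta_p2, rel=1e-9)
            assert a.F == pytest.approx(b.F, rel=1e-9)

    def test_requires_two_by_two(self):
        df = _cohort_frame()
        with pytest.raises(ValueError):
            stats.mixed_anova_2x2(df[df.group == "FR"])
        tiny = df[df.subject.isin([1, 9, 10])]
        with pytest.raises(ValueError):
            stats.mixed_anova_2x2(tiny)


class TestConfusionMatrixBuilder:
    def _responses(self):
        rows = []
        for true in ("happy", "sad"):
            for resp in ("happy", "sad"):
                n = 6 if true == resp else 2
                rows += [
                    {
                        "participant_id": 1,
                        "stimulus_language": "FR",
                        "condition": "normal",
                        "true_category": true,
                        "response_category": resp,
                    }
                ] * n
        return pd.DataFrame(rows)

    def test_counts_and_selector(self):
        table = stats.confusion_matrix(
            self._responses(), categories=("happy", "sad"), participant_id=1
        )
        np.testing.assert_array_equal(table.counts, [[6, 2], [2, 6]])

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            stats.confusion_matrix(self._responses(), participant_id=99)

    def test_single_offdiagonal_trial(self):
        df = pd.DataFrame([{"true_category": "happy", "response_category": "sad"}])
        table = stats.confusion_matrix(df, categories=("happy", "sad"))
        np.testing.assert_array_equal(table.counts, [[0, 1], [0, 0]])
        with pytest.raises(ValueError):
            stats.hit_rates(table)  # empty "sad" row: metrics undefined


class TestExp2Accuracy:
    def _table(self, correct):
        return pd.DataFrame(
            {
                "participant_id": 1,
                "group": "FR",
                "stimulus_language": ["FR", "FR", "JP", "JP"],
                "condition": "normal",
                "correct": correct,
            }
        )

    def test_all_correct(self):
        acc = stats.exp2_accuracy(self._table([True] * 4))
        assert (acc["accuracy"] == 1.0).all()

    def test_mixed(self):
        acc = stats.exp2_accuracy(self._table([True, False, True, True]))
        fr = acc[acc.stimulus_language == "FR"].accuracy.iloc[0]
        assert fr == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stats.exp2_accuracy(pd.DataFrame())
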