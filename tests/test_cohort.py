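"""Batch adjustment, cohort filtering rules, HER2 surrogate, subtypes and
subgroups."""

import math

import numpy as np
import pandas as pd
import pytest

from prognomod.containers import DataError, ExpressionMatrix
from prognomod.cohort import (
    BUILTIN_SUBGROUPS,
    apply_followup_cutpoint,
    assign_subtypes,
    complete_case_filter,
    define_subgroup,
    dwd_adjust,
    her2_surrogate,
)


def _two_batch_expr(n_per=30, g=120, shift_sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((g, 2 * n_per))
    delta = rng.normal(0, shift_sd, g)
    vals = base.copy()
    vals[:, n_per:] += delta[:, None]
    samples = [f"S{i:03d}" for i in range(2 * n_per)]
    ann = pd.DataFrame({"batch": ["a"] * n_per + ["b"] * n_per}, index=samples)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=[f"G{i}" for i in range(g)], columns=samples), ann
    )


class TestDWD:
    def test_identical_batches_pass_through_unchanged(self):
        rng = np.random.default_rng(1)
        block = rng.standard_normal((50, 20))
        vals = np.hstack([block, block])
        samples = [f"S{i}" for i in range(40)]
        ann = pd.DataFrame({"batch": ["a"] * 20 + ["b"] * 20}, index=samples)
        em = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"G{i}" for i in range(50)], columns=samples), ann
        )
        adj = dwd_adjust(em)
        assert np.allclose(adj.values.to_numpy(), em.values.to_numpy(), atol=1e-6)

    def test_constant_shift_removed_at_least_90_percent(self):
        em = _two_batch_expr()
        adj = dwd_adjust(em)
        def dist(e):
            m = e.values.T.groupby(e.sample_annotations["batch"]).mean()
            return np.linalg.norm(m.loc["a"] - m.loc["b"])
        assert dist(adj) <= 0.1 * dist(em)
        assert list(adj.values.index) == list(em.values.index)
        assert list(adj.values.columns) == list(em.values.columns)

    def test_adjustment_is_idempotent(self):
        adj = dwd_adjust(_two_batch_expr(seed=5))
        again = dwd_adjust(adj)
        assert np.abs(again.values.to_numpy() - adj.values.to_numpy()).max() < 1e-4

    def test_mean_center_fallback_equalises_per_gene_means_exactly(self):
        em = _two_batch_expr(n_per=5, g=20)
        adj = dwd_adjust(em, mode="mean_center")
        means = adj.values.T.groupby(adj.sample_annotations["batch"]).mean()
        assert np.allclose(means.loc["a"], means.loc["b"], atol=1e-12)

    def test_small_batch_raises_and_advises_fallback(self):
        em = _two_batch_expr(n_per=10, g=15)
        labels = em.sample_annotations["batch"].copy()
        labels.iloc[:18] = "a"
        labels.iloc[18:] = "b"  # 2-sample batch
        with pytest.raises(DataError, match="mean_center"):
            dwd_adjust(em, batch_labels=labels)


class TestCompleteCase:
    def test_no_missing_and_empty_requirements_are_identity(self):
        t = pd.DataFrame({"er": ["pos", "neg"], "grade": ["1", "2"]}, index=["a", "b"])
        pd.testing.assert_frame_equal(complete_case_filter(t, ["er", "grade"]), t)
        pd.testing.assert_frame_equal(complete_case_filter(t, []), t)

    def test_666_to_550_retention(self):
        n, n_complete = 666, 550
        er = ["pos"] * n_complete + ["missing"] * (n - n_complete)
        t = pd.DataFrame({"er": er, "grade": ["2"] * n},
                         index=[f"P{i}" for i in range(n)])
        out = complete_case_filter(t, ["er", "grade"])
        assert len(out) == 550
        assert round(100 * len(out) / n) == 83

    def test_all_missing_raises(self):
        t = pd.DataFrame({"er": ["missing", np.nan]}, index=["a", "b"])
        with pytest.raises(DataError):
            complete_case_filter(t, ["er"])


class TestCutpoint:
    @pytest.mark.parametrize(
        "time, event, exp_time, exp_event",
        [(5.0, 1, 5.0, 1), (8.0, 1, 7.0, 0), (9.0, 0, 7.0, 0), (7.0, 1, 7.0, 1)],
    )
    def test_rule_application(self, time, event, exp_time, exp_event):
        t = pd.DataFrame({"time": [time], "event": [event]}, index=["p"])
        out = apply_followup_cutpoint(t, 7.0)
        assert out.loc["p", "time"] == exp_time
        assert out.loc["p", "event"] == exp_event

    def test_nonpositive_time_names_sample(self):
        t = pd.DataFrame({"time": [3.0, -1.0], "event": [1, 0]}, index=["ok", "bad"])
        with pytest.raises(DataError, match="bad"):
            apply_followup_cutpoint(t)


class TestHer2Surrogate:
    def test_550_distinct_values_give_110_positive(self):
        vals = pd.Series(np.arange(550, dtype=float),
                         index=[f"P{i:03d}" for i in range(550)])
        labels = her2_surrogate(vals)
        assert (labels == "pos").sum() == 110
        # the positives are exactly the top expressers
        top = set(vals.nlargest(110).index)
        assert set(labels.index[labels == "pos"]) == top

    @pytest.mark.parametrize("n", [5, 7, 10, 11, 49, 550])
    def test_positive_count_is_ceil_of_fraction(self, n):
        vals = pd.Series(np.random.default_rng(n).permutation(n).astype(float),
                         index=[f"P{i}" for i in range(n)])
        labels = her2_surrogate(vals, top_fraction=0.20)
        assert (labels == "pos").sum() == math.ceil(0.2 * n)

    def test_all_equal_values_use_documented_tie_rule(self):
        vals = pd.Series(1.0, index=[f"P{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="tie"):
            labels = her2_surrogate(vals)
        assert (labels == "pos").sum() == 2
        # ascending sample-id tie break
        assert set(labels.index[labels == "pos"]) == {"P0", "P1"}

    def test_positive_count_property_over_random_cohorts(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @given(n=st.integers(5, 300), frac=st.floats(0.01, 0.5), seed=st.integers(0, 10**6))
        @settings(deadline=None, max_examples=30, derandomize=True)
        def check(n, frac, seed):
            vals = pd.Series(
                np.random.default_rng(seed).normal(size=n),
                index=[f"P{i:04d}" for i in range(n)],
            )
            labels = her2_surrogate(vals, top_fraction=frac)
            assert (labels == "pos").sum() == math.ceil(frac * n)
            assert ((labels == "pos") | (labels == "neg")).all()
            # positives have expression >= every negative's expression
            assert vals[labels == "pos"].min() >= vals[labels == "neg"].max()

        check()

    def test_missing_expression_labelled_missing(self):
        vals = pd.Series([5.0, 4.0, np.nan, 2.0, 1.0, 0.0],
                         index=list("abcdef"))
        labels = her2_surrogate(vals)
        assert labels["c"] == "missing"
        assert (labels == "pos").sum() == 1


class TestSubtypes:
    CENTROIDS = {
        "LumA": {"ESR1": 2.0, "ERBB2": -1.0, "MKI67": -1.5},
        "Her2": {"ESR1": -1.0, "ERBB2": 2.5, "MKI67": 0.5},
        "Basal": {"ESR1": -2.0, "ERBB2": -0.5, "MKI67": 2.0},
    }

    def _expr(self, profiles, samples):
        genes = ["ESR1", "ERBB2", "MKI67"]
        return ExpressionMatrix(pd.DataFrame(
            np.column_stack(profiles), index=genes, columns=samples))

    def test_sample_equal_to_centroid_gets_its_label(self):
        c = self.CENTROIDS
        expr = self._expr(
            [[c["LumA"][g] for g in ["ESR1", "ERBB2", "MKI67"]],
             [c["Basal"][g] for g in ["ESR1", "ERBB2", "MKI67"]]],
            ["s1", "s2"],
        )
        labels = assign_subtypes(expr, c)
        assert labels["s1"] == "LumA" and labels["s2"] == "Basal"

    def test_tie_is_deterministic_with_warning(self):
        cents = {"A": {"G1": 1.0, "G2": 0.0, "G3": -1.0},
                 "B": {"G1": 1.0, "G2": 0.0, "G3": -1.0}}
        expr = ExpressionMatrix(pd.DataFrame([[3.0], [2.0], [1.0]],
                                index=["G1", "G2", "G3"], columns=["s"]))
        with pytest.warns(UserWarning, match="tie"):
            labels = assign_subtypes(expr, cents)
        assert labels["s"] == "A"

    def test_noisy_samples_recover_generating_centroid(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(20)]
        cents = {f"C{k}": dict(zip(genes, rng.normal(0, 1, 20))) for k in range(5)}
        truth_label = "C2"
        base = np.array([cents[truth_label][g] for g in genes])
        profiles = [base + rng.normal(0, 0.1, 20) for _ in range(100)]
        expr = ExpressionMatrix(pd.DataFrame(
            np.column_stack(profiles), index=genes,
            columns=[f"s{i}" for i in range(100)]))
        labels = assign_subtypes(expr, cents)
        assert (labels == truth_label).mean() >= 0.95


class TestSubgroups:
    def _cohort(self):
        return pd.DataFrame(
            {
                "er": ["pos", "pos", "pos", "neg", "neg"],
                "her2": ["neg", "pos", "neg", "neg", "pos"],
                "subtype": ["LumA", "Her2", "LumB", "Basal", "Her2"],
            },
            index=list("abcde"),
        )

    def test_er_positive_picks_the_right_ids(self):
        assert set(define_subgroup(self._cohort(), "ER+")) == {"a", "b", "c"}

    def test_luminal_is_union_of_luma_and_lumb(self):
        t = self._cohort()
        lum = set(define_subgroup(t, "Luminal"))
        la = set(t.index[t["subtype"] == "LumA"])
        lb = set(t.index[t["subtype"] == "LumB"])
        assert lum == la | lb

    def test_er_subgroups_partition_when_nothing_missing(self):
        t = self._cohort()
        assert len(define_subgroup(t, "ER+")) + len(define_subgroup(t, "ER-")) == len(t)

    def test_unknown_subgroup_or_field_raises(self):
        with pytest.raises(KeyError, match="unknown subgroup"):
            define_subgroup(self._cohort(), "nope")
        t = self._cohort().drop(columns="subtype")
        with pytest.raises(KeyError):
            define_subgroup(t, BUILTIN_SUBGROUPS["Luminal"])

    def test_combined_er_her2_subgroup(self):
        assert set(define_subgroup(self._cohort(), "ER+/HER2-")) == {"a", "c"}
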