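"""Correlation structure and the impact decision tree."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from evip2 import (
    Comparison,
    ExpressionMatrix,
    Thresholds,
    VariantImpactModel,
    generate_experiment,
)
from evip2.core import (
    CorrelationTriplet,
    build_triplet,
    classify,
    correlation_matrix,
    direction_test,
    disting_test,
    impact_direction_score,
    impact_test,
)
from evip2.synthetic import SimSpec, scenario_spec

from conftest import make_annotation


def _zscore_matrix(rng, n_genes=40, n_samples=12, prefix="s"):
    df = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"{prefix}{i}" for i in range(n_samples)],
    )
    df = df.sub(df.mean(axis=1), axis=0).div(df.std(axis=1, ddof=1), axis=0)
    return ExpressionMatrix(df, "zscore")


class TestCorrelationMatrix:
    def test_matches_scipy_oracle(self, rng):
        z = _zscore_matrix(rng, n_genes=25, n_samples=7)
        corr = correlation_matrix(z)
        oracle = sps.spearmanr(z.data.to_numpy()).statistic
        np.testing.assert_allclose(corr.to_numpy(), oracle, atol=1e-12)

    def test_symmetric_unit_diagonal(self, rng):
        corr = correlation_matrix(_zscore_matrix(rng))
        arr = corr.to_numpy()
        np.testing.assert_allclose(arr, arr.T)
        np.testing.assert_allclose(np.diag(arr), 1.0)
        assert arr.min() >= -1.0 and arr.max() <= 1.0

    def test_duplicated_columns_correlate_perfectly(self, rng):
        z = _zscore_matrix(rng, n_genes=30, n_samples=4)
        df = z.data.copy()
        df["dup"] = df["s0"]
        corr = correlation_matrix(ExpressionMatrix(df, "zscore",
                                                   check_zscore_rows=False))
        assert corr.loc["s0", "dup"] == pytest.approx(1.0)

    def test_constant_sample_named(self):
        df = pd.DataFrame(
            {"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]},
            index=["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(ExpressionMatrix(df, "zscore",
                                                check_zscore_rows=False))


class TestTriplet:
    def test_cardinalities_4_4_4(self, rng):
        z = _zscore_matrix(rng, n_samples=12)
        z.data.columns = [f"{c}_r{i}" for c in ("control", "WT", "MUT")
                          for i in range(1, 5)]
        corr = correlation_matrix(z)
        t = build_triplet(corr, make_annotation(), Comparison("control", "WT", "MUT"))
        assert (len(t.wt_self), len(t.mut_self), len(t.wt_mut), len(t.null_dist)) == (
            6, 6, 16, 16,
        )

    def test_cardinalities_3_wt_4_mut(self, rng):
        z = _zscore_matrix(rng, n_samples=11)
        names = [f"control_r{i}" for i in range(1, 5)]
        names += [f"WT_r{i}" for i in range(1, 4)]
        names += [f"MUT_r{i}" for i in range(1, 5)]
        z.data.columns = names
        corr = correlation_matrix(z)
        annot = make_annotation(n_wt=3)
        t = build_triplet(corr, annot, Comparison("control", "WT", "MUT"))
        assert len(t.wt_self) == 3 and len(t.wt_mut) == 12

    def test_contents_match_pair_enumeration(self, rng):
        z = _zscore_matrix(rng, n_samples=12)
        z.data.columns = [f"{c}_r{i}" for c in ("control", "WT", "MUT")
                          for i in range(1, 5)]
        corr = correlation_matrix(z)
        t = build_triplet(corr, make_annotation(), Comparison("control", "WT", "MUT"))
        wt = [f"WT_r{i}" for i in range(1, 5)]
        mut = [f"MUT_r{i}" for i in range(1, 5)]
        expected_wt_self = sorted(
            corr.loc[a, b] for i, a in enumerate(wt) for b in wt[i + 1:]
        )
        assert sorted(t.wt_self) == pytest.approx(expected_wt_self)
        expected_cross = sorted(corr.loc[a, b] for a in wt for b in mut)
        assert sorted(t.wt_mut) == pytest.approx(expected_cross)

    def test_too_few_replicates_rejected(self, rng):
        z = _zscore_matrix(rng, n_samples=12)
        z.data.columns = [f"{c}_r{i}" for c in ("control", "WT", "MUT")
                          for i in range(1, 5)]
        corr = correlation_matrix(z)
        annot = make_annotation()
        annot.sample_to_condition["MUT_r2"] = "other"
        annot.sample_to_condition["MUT_r3"] = "other"
        annot.sample_to_condition["MUT_r4"] = "other"
        with pytest.raises(ValueError, match="MUT"):
            build_triplet(corr, annot, Comparison("control", "WT", "MUT"))

    def test_cardinality_invariant_enforced(self):
        with pytest.raises(ValueError, match="wt_self"):
            CorrelationTriplet(
                wt_self=np.zeros(5), mut_self=np.zeros(6),
                wt_mut=np.zeros(16), null_dist=np.zeros(16),
                n_wt=4, n_mut=4, n_ctrl=4,
            )


def _triplet(wt_self, mut_self, wt_mut, null_dist, n_wt=4, n_mut=4, n_ctrl=4):
    return CorrelationTriplet(
        wt_self=np.asarray(wt_self, float),
        mut_self=np.asarray(mut_self, float),
        wt_mut=np.asarray(wt_mut, float),
        null_dist=np.asarray(null_dist, float),
        n_wt=n_wt, n_mut=n_mut, n_ctrl=n_ctrl,
    )


class TestDecisionTreeTests:
    def test_impact_null_when_distributions_coincide(self, rng):
        vals = rng.uniform(0.5, 0.9, 6)
        t = _triplet(vals, vals, np.tile(vals, 3)[:16], np.zeros(16))
        res = impact_test(t)
        assert res.pvalue > 0.9

    def test_impact_small_p_on_separated_fixture(self, rng):
        t = _triplet(
            rng.uniform(0.85, 0.95, 6), rng.uniform(0.85, 0.95, 6),
            rng.uniform(0.05, 0.15, 16), rng.uniform(-0.1, 0.1, 16),
        )
        res = impact_test(t)
        oracle = sps.kruskal(t.wt_self, t.mut_self, t.wt_mut)
        assert res.pvalue == pytest.approx(oracle.pvalue, abs=1e-10)
        assert res.pvalue < 0.01

    def test_impact_symmetric_under_group_swap(self, rng):
        a, b = rng.uniform(0.2, 0.9, 6), rng.uniform(0.1, 0.8, 6)
        cross = rng.uniform(0.0, 0.5, 16)
        null = rng.uniform(-0.2, 0.2, 16)
        p1 = impact_test(_triplet(a, b, cross, null)).pvalue
        p2 = impact_test(_triplet(b, a, cross, null)).pvalue
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_direction_null_and_separation(self, rng):
        vals = rng.uniform(0.4, 0.8, 6)
        t = _triplet(vals, vals, rng.uniform(0, 1, 16), rng.uniform(-1, 1, 16))
        assert direction_test(t).pvalue == pytest.approx(1.0)
        mut = np.array([0.9, 0.91, 0.92, 0.93, 0.94, 0.95])
        wt = np.array([0.1, 0.11, 0.12, 0.13, 0.14, 0.15])
        t2 = _triplet(wt, mut, rng.uniform(0, 1, 16), rng.uniform(-1, 1, 16))
        res = direction_test(t2)
        oracle = sps.mannwhitneyu(mut, wt, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(oracle.pvalue, abs=1e-12)

    def test_disting_null_and_order_invariance(self, rng):
        null = rng.uniform(-0.3, 0.3, 16)
        t = _triplet(rng.uniform(0, 1, 6), rng.uniform(0, 1, 6), null.copy(), null)
        assert disting_test(t).pvalue == pytest.approx(1.0)
        shuffled = _triplet(t.wt_self, t.mut_self, t.wt_mut,
                            rng.permutation(null))
        assert disting_test(shuffled).pvalue == pytest.approx(
            disting_test(t).pvalue, abs=1e-12
        )

    def test_disting_small_p_on_separated_fixture(self, rng):
        t = _triplet(
            rng.uniform(0, 1, 6), rng.uniform(0, 1, 6),
            rng.uniform(0.85, 0.95, 16), rng.uniform(-0.05, 0.05, 16),
        )
        assert disting_test(t).pvalue < 1e-4


class TestDirectionScore:
    def test_score_values(self, rng):
        up = _triplet(np.full(6, 0.3), np.full(6, 0.8),
                      rng.uniform(0, 1, 16), rng.uniform(-1, 1, 16))
        assert impact_direction_score(up, 1.0) == 0.0
        assert impact_direction_score(up, 0.01) == pytest.approx(2.0)
        down = _triplet(np.full(6, 0.8), np.full(6, 0.3),
                        rng.uniform(0, 1, 16), rng.uniform(-1, 1, 16))
        assert impact_direction_score(down, 0.1) == pytest.approx(-1.0)

    def test_underflow_capped(self, rng):
        up = _triplet(np.full(6, 0.3), np.full(6, 0.8),
                      rng.uniform(0, 1, 16), rng.uniform(-1, 1, 16))
        assert impact_direction_score(up, 0.0, cap=20.0) == 20.0


class TestClassify:
    th = Thresholds()

    def test_gof_branch(self, rng):
        t = _triplet(rng.uniform(0.3, 0.4, 6), rng.uniform(0.8, 0.9, 6),
                     rng.uniform(0.0, 0.1, 16), rng.uniform(-0.1, 0.1, 16))
        assert classify(t, self.th, 0.001, 0.01, 0.5) == "GOF"

    def test_lof_branch(self, rng):
        t = _triplet(rng.uniform(0.8, 0.9, 6), rng.uniform(0.1, 0.2, 6),
                     rng.uniform(0.0, 0.1, 16), rng.uniform(-0.1, 0.1, 16))
        assert classify(t, self.th, 0.001, 0.01, 0.5) == "LOF"

    def test_cof_branch_direction_insignificant(self, rng):
        t = _triplet(rng.uniform(0.7, 0.8, 6), rng.uniform(0.7, 0.8, 6),
                     rng.uniform(0.0, 0.1, 16), rng.uniform(-0.1, 0.1, 16))
        assert classify(t, self.th, 0.001, 0.5, 0.5) == "COF"

    def test_neutral_requires_direction_of_similarity(self, rng):
        t = _triplet(rng.uniform(0.7, 0.8, 6), rng.uniform(0.7, 0.8, 6),
                     rng.uniform(0.7, 0.8, 16), rng.uniform(-0.1, 0.1, 16))
        assert classify(t, self.th, 0.5, 0.9, 0.001) == "Neutral"
        # same p-values but the cross-correlations sit BELOW the null:
        # the mutant is not "more similar to WT than to control"
        t2 = _triplet(t.wt_self, t.mut_self,
                      rng.uniform(-0.8, -0.7, 16), rng.uniform(-0.1, 0.1, 16))
        assert classify(t2, self.th, 0.5, 0.9, 0.001) == "NI"

    def test_ni_branch(self, rng):
        t = _triplet(rng.uniform(-0.1, 0.1, 6), rng.uniform(-0.1, 0.1, 6),
                     rng.uniform(-0.1, 0.1, 16), rng.uniform(-0.1, 0.1, 16))
        assert classify(t, self.th, 0.5, 0.9, 0.8) == "NI"

    def test_median_tie_falls_back_to_cof(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        t = _triplet(vals, vals, np.zeros(16), np.zeros(16))
        assert classify(t, self.th, 0.001, 0.01, 0.5) == "COF"

    def test_impact_gate_monotone_in_conn_thresh(self, rng):
        impactful = {"GOF", "LOF", "COF"}
        for _ in range(30):
            t = _triplet(rng.uniform(0, 1, 6), rng.uniform(0, 1, 6),
                         rng.uniform(-1, 1, 16), rng.uniform(-1, 1, 16))
            p_imp, p_dir, p_dis = rng.random(3)
            lo = classify(t, Thresholds(conn_thresh=0.05), p_imp, p_dir, p_dis)
            hi = classify(t, Thresholds(conn_thresh=0.3), p_imp, p_dir, p_dis)
            if lo in impactful:
                assert hi in impactful


class TestModel:
    @pytest.mark.parametrize("kind,expected", [
        ("neutral", "Neutral"), ("lof", "LOF"), ("gof", "GOF"), ("cof", "COF"),
    ])
    def test_scenario_recovery(self, scenario_fits, kind, expected):
        call = scenario_fits[kind].calls[0]
        assert call.call == expected
        if expected == "GOF":
            assert call.impact_direction_score > 0
        if expected == "LOF":
            assert call.impact_direction_score < 0

    def test_replicate_order_does_not_change_calls(self, scenario_fits):
        _, tpm, annot = generate_experiment(scenario_spec("gof", seed=7))
        shuffled = ExpressionMatrix(
            tpm.data[list(reversed(tpm.sample_ids))], "tpm"
        )
        res = VariantImpactModel.from_tpm(shuffled, annot).fit()
        ref = scenario_fits["gof"].calls[0]
        assert res.calls[0].call == ref.call
        assert res.calls[0].impact_pval == pytest.approx(ref.impact_pval, abs=1e-12)

    def test_exact_wt_duplicates_called_neutral(self):
        spec = scenario_spec("lof", seed=3)  # WT program, mutant empty
        _, tpm, annot = generate_experiment(spec)
        df = tpm.data.copy()
        for r in range(1, 5):
            df[f"MUT_r{r}"] = df[f"WT_r{r}"]
        res = VariantImpactModel.from_tpm(ExpressionMatrix(df, "tpm"), annot).fit()
        assert res.calls[0].call == "Neutral"

    def test_adjusted_p_geq_raw_and_bh_family_across_variants(self):
        spec = SimSpec(
            n_genes=400,
            conditions={"control": 4, "WT": 4, "m1": 4, "m2": 4, "m3": 4},
            comparisons=[Comparison("control", "WT", m) for m in ("m1", "m2", "m3")],
            replicate_noise_sd=0.5,
            seed=5,
        )
        _, tpm, annot = generate_experiment(spec)
        res = VariantImpactModel.from_tpm(tpm, annot).fit()
        frame = res.to_frame()
        assert len(frame) == 3
        for stem in ("impact", "direction", "disting"):
            raw = frame[f"{stem}_pval"].to_numpy()
            adj = frame[f"{stem}_pval_adj"].to_numpy()
            assert np.all(adj >= raw - 1e-15)
            from evip2.stats import benjamini_hochberg

            np.testing.assert_allclose(adj, benjamini_hochberg(raw), atol=1e-12)

    def test_sparkler_coordinates(self, scenario_fits):
        sp = scenario_fits["gof"].sparkler_frame()
        call = scenario_fits["gof"].calls[0]
        assert sp.loc[0, "x"] == pytest.approx(-np.log10(call.impact_pval_adj))
        assert sp.loc[0, "y"] == call.impact_direction_score

    def test_summary_mentions_call_and_thresholds(self, scenario_fits):
        text = scenario_fits["lof"].summary()
        assert "LOF" in text and "conn=0.1" in text
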