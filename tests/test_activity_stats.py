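"""Activity scores, z-score calls, variance moderation, and the allelic test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from mprakit.activity_stats import (
    ActivityError,
    ModerationParams,
    adjust_fdr,
    call_general_enhancers,
    compute_activity,
    estimate_moderation,
    fit_allelic_model,
    moderated_t,
    tier_of,
)


def _elements(rows, reps=(1, 2, 3)):
    """Build an element-count frame from {element: {col: n}} shorthand."""
    df = pd.DataFrame(rows).T
    df.index.name = "element_id"
    return df[[f"{a}_{r}" for a in ("dna", "rna") for r in reps]]


class TestComputeActivity:
    def test_symmetric_counts_give_zero(self):
        rows = {
            e: {f"{a}_{r}": 50 for a in ("dna", "rna") for r in (1, 2, 3)}
            for e in ("e1_ref", "e2_ref")
        }
        activity = compute_activity(_elements(rows))
        assert np.allclose(activity.to_numpy(), 0.0)

    def test_pseudocount_hand_example(self):
        # equal assay depths (10 each); rna 7 / dna 3 -> log2(8/4) = 1
        rows = {
            "e1_ref": dict(dna_1=3, rna_1=7, dna_2=3, rna_2=7),
            "e2_ref": dict(dna_1=7, rna_1=3, dna_2=7, rna_2=3),
        }
        activity = compute_activity(_elements(rows, reps=(1, 2)))
        assert activity.loc["e1_ref", "activity_1"] == pytest.approx(1.0)

    def test_depth_doubling_nearly_invariant(self):
        rows = {
            "e1_ref": dict(dna_1=1000, rna_1=1000, dna_2=1000, rna_2=2001),
            "e2_ref": dict(dna_1=1000, rna_1=1000, dna_2=1000, rna_2=2001),
        }
        activity = compute_activity(_elements(rows, reps=(1, 2)))
        # doubling every RNA count (and hence depth) only moves a through the +1
        assert abs(activity.loc["e1_ref", "activity_2"] - activity.loc["e1_ref", "activity_1"]) < 0.01

    def test_degenerate_replicate_rejected(self):
        rows = {"e1_ref": dict(dna_1=0, rna_1=5, dna_2=1, rna_2=5)}
        with pytest.raises(ActivityError, match="zero total"):
            compute_activity(_elements(rows, reps=(1, 2)))


class TestGeneralEnhancers:
    def _activity(self, pooled):
        return pd.DataFrame(
            {"activity": pooled},
            index=pd.Index([f"e{i}_ref" for i in range(len(pooled))], name="element_id"),
        )

    def test_all_equal_yields_no_calls(self):
        calls = call_general_enhancers(self._activity([1.5] * 10))
        assert not calls["is_enhancer"].any()
        assert np.allclose(calls["z"], 0.0)

    def test_z_just_below_threshold(self):
        calls = call_general_enhancers(self._activity([0.0] * 9 + [9.0]))
        assert calls["z"].max() == pytest.approx(2.846, abs=1e-3)
        assert not calls["is_enhancer"].any()

    def test_z_above_threshold(self):
        calls = call_general_enhancers(self._activity([0.0] * 19 + [14.0]))
        assert calls["z"].max() == pytest.approx(4.249, abs=1e-3)
        assert calls["is_enhancer"].sum() == 1

    def test_one_sided_by_default_two_sided_optional(self):
        pooled = [0.0] * 19 + [-14.0]
        assert not call_general_enhancers(self._activity(pooled))["is_enhancer"].any()
        two = call_general_enhancers(self._activity(pooled), two_sided=True)
        assert two["is_enhancer"].sum() == 1


class TestEstimateModeration:
    def test_constant_variances_give_infinite_prior(self):
        rng = np.random.default_rng(0)
        s_sq = 2.0 * rng.chisquare(50, size=100) / 50  # d_g = 50, true var 2
        params = estimate_moderation(s_sq, 50)
        assert params.d0 > 50  # little excess dispersion beyond sampling noise
        assert params.s0_sq == pytest.approx(2.0, rel=0.1)

    def test_recovers_planted_prior(self):
        rng = np.random.default_rng(42)
        n, d0, s0_sq, d_g = 2000, 4.0, 1.0, 10
        sigma_sq = d0 * s0_sq / rng.chisquare(d0, size=n)
        s_sq = sigma_sq * rng.chisquare(d_g, size=n) / d_g
        params = estimate_moderation(s_sq, d_g)
        assert 3.0 <= params.d0 <= 5.0
        assert 0.9 <= params.s0_sq <= 1.1

    def test_too_few_variants_rejected(self):
        with pytest.raises(ActivityError, match=">= 3"):
            estimate_moderation([1.0, 2.0], 2)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ActivityError, match="degenerate"):
            estimate_moderation([0.0, 0.0, 0.0], 2)


class TestModeratedT:
    def test_worked_example(self):
        prior = ModerationParams(d0=4.0, s0_sq=1.0)
        t, df, p = moderated_t([2.0], [4.0], [4.0], [1 / 3], prior)
        assert t[0] == pytest.approx(2.1909, abs=1e-4)
        assert df[0] == 8.0
        assert p[0] == pytest.approx(2 * sstats.t.sf(2.1909, 8), abs=1e-4)

    def test_zero_differences(self):
        prior = ModerationParams(d0=4.0, s0_sq=1.0)
        t, _, p = moderated_t([0.0], [0.0], [2.0], [1 / 3], prior)
        assert t[0] == 0.0 and p[0] == 1.0

    def test_d0_zero_equals_ordinary_paired_t(self):
        rng = np.random.default_rng(7)
        prior = ModerationParams(d0=0.0, s0_sq=1.0)
        for _ in range(100):
            d = rng.normal(0.3, 1.0, size=5)
            t, df, p = moderated_t(
                [d.mean()], [d.var(ddof=1)], [len(d) - 1], [1 / len(d)], prior
            )
            ref = sstats.ttest_1samp(d, 0.0)
            assert abs(t[0] - ref.statistic) < 1e-8
            assert abs(p[0] - ref.pvalue) < 1e-8
            assert df[0] == len(d) - 1


class TestAdjustFdr:
    def test_hand_example(self):
        assert np.allclose(adjust_fdr([0.01, 0.03, 0.04]), [0.03, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert np.allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)
        assert adjust_fdr([0.2]) == pytest.approx([0.2])
        assert adjust_fdr([]).size == 0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ActivityError):
            adjust_fdr([0.5, 0.0])
        with pytest.raises(ActivityError):
            adjust_fdr([0.5, 1.2])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_matches_statsmodels_and_preserves_order(self, pvals):
        from statsmodels.stats.multitest import multipletests

        adj = adjust_fdr(pvals)
        _, expected, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(adj, expected, atol=1e-12)
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestAllelicModel:
    def _activity_frame(self, ref_rows, alt_rows):
        index, data = [], []
        for vid in ref_rows:
            index += [f"{vid}_ref", f"{vid}_alt"]
            data += [ref_rows[vid], alt_rows[vid]]
        return pd.DataFrame(
            data, index=pd.Index(index, name="element_id"),
            columns=["activity_1", "activity_2", "activity_3"],
        )

    def _pairs(self, vids):
        return {v: (f"{v}_ref", f"{v}_alt") for v in vids}

    def test_scale_equivariance_in_replicates(self):
        rng = np.random.default_rng(3)
        vids = [f"v{i}" for i in range(20)]
        ref = {v: rng.normal(size=3) for v in vids}
        alt = {v: ref[v] + rng.normal(0.2, 0.3, size=3) for v in vids}
        base = fit_allelic_model(self._activity_frame(ref, alt), self._pairs(vids))
        shift = np.array([5.0, 0.0, 0.0])  # replicate-1 batch effect, both alleles
        shifted = fit_allelic_model(
            self._activity_frame(
                {v: ref[v] + shift for v in vids}, {v: alt[v] + shift for v in vids}
            ),
            self._pairs(vids),
        )
        pd.testing.assert_frame_equal(base.drop(columns="tier"), shifted.drop(columns="tier"))

    def test_incomplete_pairs_skipped(self):
        rng = np.random.default_rng(4)
        vids = [f"v{i}" for i in range(5)]
        frame = self._activity_frame(
            {v: rng.normal(size=3) for v in vids}, {v: rng.normal(size=3) for v in vids}
        ).drop(index="v0_alt")
        result = fit_allelic_model(frame, self._pairs(vids))
        assert "v0" not in result.index and len(result) == 4

    def test_tier_boundaries(self):
        assert tier_of(0.049) == "active"
        assert tier_of(0.05) == "suggestive"
        assert tier_of(0.099) == "suggestive"
        assert tier_of(0.1) == "ns"
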