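"""Tests for the immunoaffinity-purification statistics.

The moderated-t reference values were produced by an independent
implementation of the empirical-Bayes moderated t-test (limma 3.58.1,
lmFit + eBayes) on the fixture matrix generated below, and frozen here.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stereoquant.ip_stats import (
    bh_fdr,
    enrichment_ratio,
    filter_specific,
    fit_f_dist,
    moderated_t_test,
    stoichiometry,
)
from stereoquant.types import QuantMatrix, StudyDesign, ValidationError


def _design(n_specific=6, n_control=6, n_total=3):
    return StudyDesign(
        ip_conditions={
            **{f"specific_{i+1}": "specific" for i in range(n_specific)},
            **{f"control_{i+1}": "control" for i in range(n_control)},
            **{f"total_{i+1}": "total" for i in range(n_total)},
        }
    )


class TestFilterSpecific:
    def test_six_of_six_no_control_passes(self):
        d = _design()
        vals = pd.DataFrame(
            {**{f"specific_{i+1}": [1.0] for i in range(6)},
             **{f"control_{i+1}": [np.nan] for i in range(6)}},
            index=["p"],
        )
        assert filter_specific(QuantMatrix(vals), d) == ["p"]

    def test_three_of_six_fails(self):
        d = _design()
        vals = pd.DataFrame(
            {**{f"specific_{i+1}": [1.0 if i < 3 else np.nan] for i in range(6)},
             **{f"control_{i+1}": [np.nan] for i in range(6)}},
            index=["p"],
        )
        assert filter_specific(QuantMatrix(vals), d) == []

    def test_any_control_detection_fails_at_default(self):
        d = _design()
        vals = pd.DataFrame(
            {**{f"specific_{i+1}": [1.0] for i in range(6)},
             **{f"control_{i+1}": [1.0 if i == 0 else np.nan] for i in range(6)}},
            index=["p"],
        )
        assert filter_specific(QuantMatrix(vals), d) == []
        assert filter_specific(QuantMatrix(vals), d, max_control=1) == ["p"]

    def test_matches_bruteforce_on_random_detection_patterns(self):
        d = _design(n_total=0)
        cols = d.runs("specific") + d.runs("control")
        rng = np.random.default_rng(7)
        for _ in range(50):
            det = rng.random((30, 12)) < 0.5
            vals = pd.DataFrame(
                np.where(det, 1.0, np.nan),
                index=[f"p{i:02d}" for i in range(30)],
                columns=cols,
            )
            m = QuantMatrix(vals)
            expected = sorted(
                pid
                for i, pid in enumerate(vals.index)
                if det[i, :6].sum() >= 4 and det[i, 6:].sum() == 0
            )
            assert filter_specific(m, d) == expected

    def test_min_specific_larger_than_runs_rejected(self):
        d = _design(n_specific=3)
        m = QuantMatrix(pd.DataFrame({c: [1.0] for c in d.ip_conditions}, index=["p"]))
        with pytest.raises(ValidationError):
            filter_specific(m, d, min_specific=4)


class TestEnrichmentRatio:
    def test_equal_means_give_unit_ratio(self):
        d = _design(n_specific=2, n_control=0, n_total=2)
        vals = pd.DataFrame(
            {"specific_1": [2e-3], "specific_2": [2e-3], "total_1": [2e-3], "total_2": [2e-3]},
            index=["p"],
        )
        out = enrichment_ratio(QuantMatrix(vals), d)
        assert out.loc["p", "enrichment_ratio"] == pytest.approx(1.0)
        assert out.loc["p", "category"] == "both"

    def test_bait_like_case_reaches_ten_thousand_fold(self):
        d = _design(n_specific=2, n_control=0, n_total=2)
        vals = pd.DataFrame(
            {"specific_1": [2e-2], "specific_2": [2e-2], "total_1": [2e-6], "total_2": [2e-6]},
            index=["bait"],
        )
        out = enrichment_ratio(QuantMatrix(vals), d)
        assert out.loc["bait", "enrichment_ratio"] == pytest.approx(1e4)
        assert out.loc["bait", "log10_enrichment"] == pytest.approx(4.0)

    def test_random_values_match_mean_ratio_oracle(self):
        rng = np.random.default_rng(13)
        d = _design(n_specific=4, n_control=0, n_total=3)
        cols = d.runs("specific") + d.runs("total")
        vals = pd.DataFrame(
            rng.uniform(1e-6, 1e-2, size=(20, 7)),
            index=[f"p{i}" for i in range(20)],
            columns=cols,
        )
        out = enrichment_ratio(QuantMatrix(vals), d)
        for pid in vals.index:
            expected = vals.loc[pid, d.runs("specific")].mean() / vals.loc[pid, d.runs("total")].mean()
            assert out.loc[pid, "enrichment_ratio"] == pytest.approx(expected, rel=1e-12)

    def test_eluate_only_is_censored_against_smallest_total(self):
        d = _design(n_specific=2, n_control=0, n_total=2)
        vals = pd.DataFrame(
            {
                "specific_1": [1e-3, 5e-4],
                "specific_2": [1e-3, np.nan],
                "total_1": [np.nan, 1e-5],
                "total_2": [np.nan, 3e-5],
            },
            index=["only_eluate", "in_both"],
        )
        out = enrichment_ratio(QuantMatrix(vals), d)
        assert out.loc["only_eluate", "category"] == "eluate_only"
        assert out.loc["only_eluate", "censored"]
        assert out.loc["only_eluate", "enrichment_ratio"] == pytest.approx(1e-3 / 1e-5)

    def test_ratio_invariant_to_global_rescaling_of_either_side(self):
        rng = np.random.default_rng(8)
        d = _design(n_specific=3, n_control=0, n_total=3)
        cols = d.runs("specific") + d.runs("total")
        raw = pd.DataFrame(
            10.0 ** rng.normal(5, 1, size=(10, 6)),
            index=[f"p{i}" for i in range(10)],
            columns=cols,
        )
        from stereoquant.quant_core import compute_ribaq

        base = compute_ribaq(QuantMatrix(raw.copy()))
        scaled_raw = raw.copy()
        scaled_raw[d.runs("specific")] *= 37.0
        scaled = compute_ribaq(QuantMatrix(scaled_raw))
        pd.testing.assert_frame_equal(
            enrichment_ratio(base, d), enrichment_ratio(scaled, d), atol=1e-15
        )


def _modt_fixture():
    rng = np.random.default_rng(17)
    n = 20
    base = rng.normal(0, 1, size=(n, 6))
    shift = np.zeros((n, 6))
    shift[:5, :3] = rng.normal(2, 0.5, size=(5, 1))
    return QuantMatrix(
        pd.DataFrame(
            base + shift,
            index=[f"P{i:02d}" for i in range(n)],
            columns=["g1_1", "g1_2", "g1_3", "g2_1", "g2_2", "g2_3"],
        ),
        log_scale=True,
    )


# frozen reference output (limma lmFit/eBayes on the fixture above)
LIMMA_T = [3.08963763203, 2.35062325352, 1.85276881561, 3.67156075031, 1.54500176982,
           0.588485843663, 0.066464031762, 1.67658669141, -0.208818484779, 1.58865753863,
           -0.814856679008, -1.29087324179, -0.216964767025, 0.760237136641, -0.625114281531,
           0.918901127035, -0.0785044582765, 0.519311676647, -1.01906314001, 1.47402874603]
LIMMA_P = [0.00786316348899, 0.033650711069, 0.0847565781522, 0.00245169858616, 0.144278848297,
           0.565425753114, 0.947932694602, 0.115434106235, 0.837548000519, 0.134091579592,
           0.428574762096, 0.217315538787, 0.83131406251, 0.459517840411, 0.54178607222,
           0.373453096105, 0.938519462275, 0.61152174819, 0.325177943152, 0.162239117164]
LIMMA_S2_PRIOR = 1.09818163807695
LIMMA_DF_PRIOR = 10.2376518262958


class TestModeratedT:
    G1 = ["g1_1", "g1_2", "g1_3"]
    G2 = ["g2_1", "g2_2", "g2_3"]

    def test_matches_independent_reference_implementation(self):
        m = _modt_fixture()
        res = moderated_t_test(m, self.G1, self.G2)
        assert res.attrs["prior_s2"] == pytest.approx(LIMMA_S2_PRIOR, abs=1e-10)
        assert res.attrs["prior_df"] == pytest.approx(LIMMA_DF_PRIOR, abs=1e-10)
        np.testing.assert_allclose(res["moderated_t"], LIMMA_T, atol=1e-6)
        np.testing.assert_allclose(res["p_value"], LIMMA_P, atol=1e-6)

    def test_zero_prior_df_reduces_to_ordinary_pooled_t(self):
        m = _modt_fixture()
        res = moderated_t_test(m, self.G1, self.G2, prior_df=0.0, prior_s2=1.0)
        v = m.values
        for i, pid in enumerate(res.index):
            t, p = stats.ttest_ind(v.loc[pid, self.G1], v.loc[pid, self.G2], equal_var=True)
            assert res.loc[pid, "moderated_t"] == pytest.approx(t, abs=1e-10)
            assert res.loc[pid, "p_value"] == pytest.approx(p, abs=1e-10)

    def test_infinite_prior_df_uses_prior_variance_exactly(self):
        m = _modt_fixture()
        s0 = 0.7
        res = moderated_t_test(m, self.G1, self.G2, prior_df=np.inf, prior_s2=s0)
        v = m.values
        for pid in res.index:
            diff = v.loc[pid, self.G1].mean() - v.loc[pid, self.G2].mean()
            expected = diff / np.sqrt(s0 * (1 / 3 + 1 / 3))
            assert res.loc[pid, "moderated_t"] == pytest.approx(expected, abs=1e-12)

    def test_constant_rows_omitted_with_warning(self):
        vals = pd.DataFrame(
            np.vstack([np.ones(6), np.random.default_rng(1).normal(size=(5, 6))]),
            index=["flat"] + [f"p{i}" for i in range(5)],
            columns=self.G1 + self.G2,
        )
        m = QuantMatrix(vals, log_scale=True)
        with pytest.warns(UserWarning, match="constant"):
            res = moderated_t_test(m, self.G1, self.G2)
        assert "flat" not in res.index

    def test_prior_fit_recovers_known_hierarchy(self):
        # variances drawn from s0^2 * chi2_d0/d0 scaled F model
        rng = np.random.default_rng(23)
        d0, s0_sq, dg = 8.0, 2.0, 4
        num = stats.chi2.rvs(dg, size=4000, random_state=rng) / dg
        den = stats.chi2.rvs(d0, size=4000, random_state=rng) / d0
        s2 = s0_sq * num / den
        est_s0, est_d0 = fit_f_dist(s2, np.full(4000, float(dg)))
        assert est_s0 == pytest.approx(s0_sq, rel=0.1)
        assert est_d0 == pytest.approx(d0, rel=0.2)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_never_below_raw_and_permutation_invariant(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all()
        perm = rng.permutation(40)
        np.testing.assert_allclose(bh_fdr(p[perm]), adj[perm])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        p = rng.uniform(size=100)
        np.testing.assert_allclose(
            bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestStoichiometry:
    def test_prey_equal_to_bait_scores_one(self):
        el = pd.Series({"bait": 0.2, "prey": 0.2})
        tot = pd.Series({"bait": 1e-4, "prey": 1e-4})
        out = stoichiometry(el, tot, "bait")
        assert out.loc["prey", "unadjusted"] == pytest.approx(1.0)

    def test_worked_example_both_formulas(self):
        el = pd.Series({"bait": 0.2, "prey": 0.002})
        tot = pd.Series({"bait": 0.0002, "prey": 0.0004})
        out = stoichiometry(el, tot, "bait")
        assert out.loc["prey", "unadjusted"] == pytest.approx(0.01)
        assert out.loc["prey", "adjusted"] == pytest.approx(0.005)

    def test_bait_scores_exactly_one_under_both_definitions(self):
        rng = np.random.default_rng(3)
        ids = [f"p{i}" for i in range(10)] + ["bait"]
        el = pd.Series(rng.uniform(1e-4, 1e-1, 11), index=ids)
        tot = pd.Series(rng.uniform(1e-6, 1e-3, 11), index=ids)
        out = stoichiometry(el, tot, "bait")
        assert out.loc["bait", "unadjusted"] == 1.0
        assert out.loc["bait", "adjusted"] == 1.0

    def test_missing_total_leaves_adjusted_missing(self):
        el = pd.Series({"bait": 0.2, "prey": 0.02})
        tot = pd.Series({"bait": 0.0002, "prey": np.nan})
        out = stoichiometry(el, tot, "bait")
        assert out.loc["prey", "unadjusted"] == pytest.approx(0.1)
        assert np.isnan(out.loc["prey", "adjusted"])

    def test_absent_bait_rejected(self):
        with pytest.raises(ValidationError):
            stoichiometry(pd.Series({"p": 1.0}), pd.Series({"p": 1.0}), "bait")
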