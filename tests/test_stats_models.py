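import logging

import numpy as np
import pandas as pd
import pytest

from wdcpipe.errors import ComparisonError, DesignError, ValidationError
from wdcpipe.stats_models import (
    compare_models_ic,
    fdr_adjust_by_two_stage,
    fit_lmm_full,
    fit_lmm_reduced,
    fit_lmm_within,
    lmm_permutation_inference,
    permutation_test,
)
from wdcpipe.synthetic_data import simulate_long_table

logging.getLogger("wdcpipe").setLevel(logging.ERROR)


# ---------------------------------------------------------------------------
# Independent reference: literal step-by-step two-stage BY procedure
# ---------------------------------------------------------------------------

def _by_stepup_reject(p, level):
    """BY linear step-up at `level`: largest k with p_(k) <= k*level/(m*c(m))."""
    m = len(p)
    c_m = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * level / (m * c_m):
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


def two_stage_by_reference(p, alpha=0.05):
    p = np.asarray(p, float)
    m = len(p)
    a1 = alpha / (1.0 + alpha)
    stage1 = _by_stepup_reject(p, a1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    m0 = m - r1
    return _by_stepup_reject(p, a1 * m / m0)


class TestTwoStageByFdr:
    def test_large_p_no_rejections(self):
        _, rej = fdr_adjust_by_two_stage([0.9, 0.95])
        assert not rej.any()

    def test_all_zero_all_rejected(self):
        p_fdr, rej = fdr_adjust_by_two_stage([0.0] * 5)
        assert rej.all()
        assert np.all(p_fdr == 0.0)

    def test_worked_vector_matches_reference(self):
        p = [0.001, 0.01, 0.02, 0.2, 0.8]
        _, rej = fdr_adjust_by_two_stage(p)
        assert np.array_equal(rej, two_stage_by_reference(p))
        # the sharpened stage-2 level rescues the 0.01 entry
        assert np.array_equal(rej, [True, True, False, False, False])

    def test_agrees_with_reference_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for trial in range(1000):
            m = int(rng.integers(2, 21))
            # mix of null and signal p-values, occasionally with ties
            p = np.where(
                rng.random(m) < 0.4, rng.random(m) * 0.05, rng.random(m)
            ).round(int(rng.integers(1, 6)))
            p_fdr, rej = fdr_adjust_by_two_stage(p)
            assert np.array_equal(rej, two_stage_by_reference(p)), p
            assert np.array_equal(rej, p_fdr <= 0.05)

    def test_rejections_monotone_in_p(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p = rng.random(8)
            _, rej = fdr_adjust_by_two_stage(p)
            if rej.any():
                assert rej[p <= p[rej].max()].all()

    def test_validation(self):
        with pytest.raises(ValidationError):
            fdr_adjust_by_two_stage([0.5, 1.2])


# ---------------------------------------------------------------------------
# Mixed-model fitter
# ---------------------------------------------------------------------------

class TestLmmFitter:
    def test_matches_statsmodels_mixedlm(self):
        """The profiled fitter agrees with an independent REML/ML implementation."""
        import statsmodels.formula.api as smf

        tab = simulate_long_table(
            n_per_group=10,
            beta=(0.2, 0.1, 0.3, 0.2, 0.5),
            participant_sd=0.5,
            resid_sd=0.3,
            seed=1,
        )
        tab2 = tab.assign(
            g=(tab["group"] == "autistic").astype(float),
            d=(tab["drug"] == "drug").astype(float),
        )
        fit = fit_lmm_full(tab)
        sm_reml = smf.mixedlm(
            "mean_wdc ~ g*d + mfd", tab2, groups=tab2["participant_id"]
        ).fit(reml=True)
        order = ["Intercept", "g", "d", "g:d", "mfd"]
        assert np.allclose(fit.params, sm_reml.fe_params[order], atol=1e-4)
        assert np.allclose(fit.bse, sm_reml.bse_fe[order], rtol=0.05)
        assert fit.llf == pytest.approx(sm_reml.llf, abs=1e-5)
        sm_ml = smf.mixedlm(
            "mean_wdc ~ g*d + mfd", tab2, groups=tab2["participant_id"]
        ).fit(reml=False)
        assert fit_lmm_full(tab, reml=False).llf == pytest.approx(sm_ml.llf, abs=1e-5)

    def test_parameter_recovery_within_3se(self):
        beta = (0.0, 0.2, 0.1, 0.3, 0.0)
        tab = simulate_long_table(
            n_per_group=24, beta=beta, participant_sd=0.15, resid_sd=0.08, seed=2
        )
        fit = fit_lmm_full(tab)
        for b_hat, se, b_true in zip(fit.params, fit.bse, beta):
            assert abs(b_hat - b_true) < 3 * se

    def test_constant_outcome(self):
        tab = simulate_long_table(n_per_group=6, seed=3)
        tab["mean_wdc"] = 5.0
        fit = fit_lmm_full(tab)
        assert fit.params[0] == pytest.approx(5.0, abs=1e-8)
        assert np.allclose(fit.params[1:], 0.0, atol=1e-8)
        assert fit.singular

    def test_shrinkage_limit_recovers_participant_means(self):
        tab = simulate_long_table(
            n_per_group=8, participant_sd=1.0, resid_sd=1e-5, seed=4
        )
        fit = fit_lmm_full(tab)
        assert fit.var_ratio > 1e4
        # with negligible residual noise, participant means explain the data
        resid = tab["mean_wdc"].to_numpy() - fit._x @ fit.params
        shrunk = pd.Series(resid).groupby(fit._codes).transform("mean")
        assert np.max(np.abs(resid - shrunk)) < 1e-2

    def test_within_group_drug_sign_recovery(self):
        tab = simulate_long_table(
            n_per_group=10,
            beta=(0.0, 0.0, 0.0, 0.6, 0.0),
            participant_sd=0.3,
            resid_sd=0.2,
            seed=5,
        )
        aut = tab[tab["group"] == "autistic"].reset_index(drop=True)
        fit = fit_lmm_within(aut)
        assert fit.params[fit.term_names.index("drug")] > 0

    def test_constant_drug_column_is_design_error(self):
        tab = simulate_long_table(n_per_group=6, seed=6)
        aut = tab[(tab["group"] == "autistic") & (tab["drug"] == "placebo")]
        with pytest.raises(DesignError):
            fit_lmm_within(aut.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

class TestPermutationTest:
    def test_extreme_effect_hits_floor(self):
        tab = simulate_long_table(
            n_per_group=8,
            beta=(0.0, 0.0, 10.0, 0.0, 0.0),
            participant_sd=0.05,
            resid_sd=0.1,
            seed=7,
        )
        res = permutation_test(tab, "full", n_permutations=200, seed=8)
        i = res["term_names"].index("drug")
        assert res["p_perm"][i] == pytest.approx(1.0 / 201.0)

    def test_same_seed_reproducible_and_seeds_agree_within_mc_error(self):
        tab = simulate_long_table(
            n_per_group=8,
            beta=(0.0, 0.0, 0.35, 0.0, 0.0),
            participant_sd=0.3,
            resid_sd=0.3,
            seed=9,
        )
        a = permutation_test(tab, "full", n_permutations=800, seed=1)
        b = permutation_test(tab, "full", n_permutations=800, seed=1)
        c = permutation_test(tab, "full", n_permutations=800, seed=2)
        assert np.array_equal(a["p_perm"], b["p_perm"], equal_nan=True)
        i = a["term_names"].index("drug")
        p = a["p_perm"][i]
        mc = 3.0 * np.sqrt(p * (1.0 - p) / 800.0)
        assert abs(c["p_perm"][i] - p) <= mc + 1e-9

    def test_within_participant_scheme_runs(self):
        tab = simulate_long_table(n_per_group=6, participant_sd=0.3, seed=10)
        res = permutation_test(
            tab, "full", n_permutations=100, seed=11, scheme="within_participant"
        )
        assert np.all(res["p_perm"][1:] >= 1.0 / 101.0)

    def test_power_monotone_in_effect_size(self):
        """Rejection frequency is nondecreasing as the drug effect grows."""
        rates = []
        for effect in (0.0, 0.4, 1.0):
            rej = 0
            reps = 60
            for r in range(reps):
                tab = simulate_long_table(
                    n_per_group=8,
                    beta=(0.0, 0.0, effect, 0.0, 0.0),
                    participant_sd=0.3,
                    resid_sd=0.3,
                    seed=1000 * int(effect * 10 + 1) + r,
                )
                aut = tab[tab["group"] == "nonautistic"].reset_index(drop=True)
                res = permutation_test(aut, "within", n_permutations=250, seed=r)
                rej += res["p_perm"][res["term_names"].index("drug")] <= 0.05
            rates.append(rej / reps)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9


# ---------------------------------------------------------------------------
# Information criteria
# ---------------------------------------------------------------------------

class TestInformationCriteria:
    def test_identical_models_tie(self):
        tab = simulate_long_table(n_per_group=8, seed=12)
        cmp = compare_models_ic(fit_lmm_full(tab), fit_lmm_full(tab))
        assert cmp.preferred_aic == "tie" and cmp.preferred_bic == "tie"

    def test_different_rows_rejected(self):
        a = simulate_long_table(n_per_group=8, seed=13)
        b = simulate_long_table(n_per_group=8, seed=14)
        with pytest.raises(ComparisonError):
            compare_models_ic(fit_lmm_full(a), fit_lmm_full(b))

    def test_no_interaction_data_prefers_reduced_model(self):
        """Without a true interaction, BIC picks the simpler model ~96% of the
        time and AIC ~84% (the chi-square(1) < 2 rate); checked over replicates."""
        prefer_bic = prefer_aic = 0
        reps = 100
        for r in range(reps):
            tab = simulate_long_table(
                n_per_group=20,
                beta=(0.1, 0.3, 0.2, 0.0, 0.0),
                participant_sd=0.3,
                resid_sd=0.3,
                seed=100 + r,
            )
            cmp = compare_models_ic(fit_lmm_full(tab), fit_lmm_reduced(tab))
            prefer_bic += cmp.preferred_bic == "reduced"
            prefer_aic += cmp.preferred_aic == "reduced"
        assert prefer_bic / reps >= 0.90
        assert prefer_aic / reps >= 0.75

    def test_noise_covariate_aic_difference_matches_asymptotics(self):
        """AIC(reduced) - AIC(full) for a pure-noise interaction is ~ 2 - chi2(1):
        never above 2 and with mean near 1."""
        diffs = []
        for r in range(300):
            tab = simulate_long_table(
                n_per_group=16,
                beta=(0.0, 0.2, 0.2, 0.0, 0.0),
                participant_sd=0.3,
                resid_sd=0.3,
                seed=7000 + r,
            )
            cmp = compare_models_ic(fit_lmm_full(tab), fit_lmm_reduced(tab))
            diffs.append(cmp.aic[0] - cmp.aic[1])  # = 2 - LRT
        diffs = np.asarray(diffs)
        assert np.all(diffs <= 2.0 + 1e-6)
        assert 0.5 < diffs.mean() < 1.5


class TestInferenceSummary:
    def test_result_fields_consistent(self):
        tab = simulate_long_table(
            n_per_group=8,
            beta=(0.0, 0.0, 0.8, 0.0, 0.0),
            participant_sd=0.3,
            resid_sd=0.3,
            seed=15,
        )
        res = lmm_permutation_inference(tab, "full", n_permutations=300, seed=16)
        tested = [i for i, t in enumerate(res.term_names) if t != "intercept"]
        assert np.isnan(res.p_perm[0]) and not res.reject[0]
        assert np.all(res.p_perm[tested] >= 1.0 / 301.0)
        assert np.array_equal(res.reject[tested], res.p_fdr[tested] <= 0.05)
        frame = res.to_frame()
        assert list(frame["term"]) == list(res.term_names)
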