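"""Moderated differential-methylation statistics.

The empirical-Bayes machinery is checked three ways: against closed-form
limits (no shrinkage / total shrinkage), against hyperparameter recovery
on simulated variances, and against the R limma reference implementation
on a shared fixture.
"""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from episig import (
    adjust_bh,
    call_dmps,
    compute_delta_beta,
    ebayes_moderate,
    fit_probewise,
)
from episig.dmp import (
    ModerationHyperparams,
    build_design,
    estimate_hyperparams,
    probe_stats,
)
from episig.errors import ValidationError
from episig.preprocess import beta_to_m
from episig.simulate import SimulationConfig, simulate_cohort


def toy_fit(values, groups, covariates=None):
    m = pd.DataFrame(
        np.atleast_2d(values), columns=[f"s{i}" for i in range(len(groups))]
    )
    indicator = pd.Series(np.asarray(groups, dtype=float), index=m.columns)
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(
            np.atleast_2d(covariates).T, index=m.columns,
            columns=[f"c{i}" for i in range(np.atleast_2d(covariates).shape[0])],
        )
    return fit_probewise(m, build_design(indicator, cov))


class TestFitProbewise:
    def test_two_group_coefficient_is_mean_difference(self):
        fits = toy_fit([1.0, 2.0, 3.0, 10.0, 11.0], [0, 0, 0, 1, 1])
        assert fits["coef_m"].iloc[0] == pytest.approx(8.5)
        assert fits["df_residual"].iloc[0] == 3.0

    def test_constant_probe_has_zero_effect_and_variance(self):
        fits = toy_fit([2.0, 2.0, 2.0, 2.0], [0, 0, 1, 1])
        assert fits["coef_m"].iloc[0] == pytest.approx(0.0)
        assert fits["s2"].iloc[0] == pytest.approx(0.0)

    def test_zero_covariates_reduce_to_two_sample_case(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 12)
        groups = [0] * 6 + [1] * 6
        plain = toy_fit(y, groups)
        with_cov = toy_fit(y, groups, covariates=[np.zeros(12)])
        assert plain["coef_m"].iloc[0] == pytest.approx(
            np.mean(y[6:]) - np.mean(y[:6])
        )
        assert with_cov["coef_m"].iloc[0] == pytest.approx(plain["coef_m"].iloc[0])
        assert with_cov["s2"].iloc[0] == pytest.approx(plain["s2"].iloc[0])
        assert with_cov["df_residual"].iloc[0] == 10.0

    def test_rank_deficient_design_rejected(self):
        m = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        indicator = pd.Series([1.0, 1.0, 1.0, 1.0], index=m.columns)
        with pytest.raises(ValidationError):
            build_design(indicator)


class TestEbayesModerate:
    def _fits(self, seed=0, n_probes=300, heterogeneous=True):
        rng = np.random.default_rng(seed)
        n = 12
        if heterogeneous:
            sigma2 = 0.05 * 4.0 / rng.chisquare(4.0, size=n_probes)
        else:
            sigma2 = np.full(n_probes, 0.05)
        M = rng.normal(0, np.sqrt(sigma2)[:, None], size=(n_probes, n))
        m = pd.DataFrame(M, columns=[f"s{i}" for i in range(n)])
        indicator = pd.Series([1.0] * 4 + [0.0] * 8, index=m.columns)
        return fit_probewise(m, build_design(indicator))

    def test_zero_prior_df_reproduces_ordinary_t(self):
        fits = self._fits()
        mod = ebayes_moderate(fits, ModerationHyperparams(d0=0.0, s0_sq=1.0))
        v = fits.attrs["coef_variance_factor"]
        ordinary = fits["coef_m"] / np.sqrt(fits["s2"] * v)
        assert np.abs(mod["t_moderated"] - ordinary).max() < 1e-10

    def test_infinite_prior_df_replaces_every_variance(self):
        fits = self._fits()
        mod = ebayes_moderate(fits, ModerationHyperparams(d0=np.inf, s0_sq=0.07))
        v = fits.attrs["coef_variance_factor"]
        expected = fits["coef_m"] / np.sqrt(0.07 * v)
        assert np.allclose(mod["t_moderated"], expected)

    def test_hyperparameter_recovery_on_simulated_variances(self):
        # marginal model: s2 = sigma2 * chi2_df / df with sigma2 scaled
        # inverse chi-square (d0=4, s0_sq=0.05)
        rng = np.random.default_rng(1)
        d0_true, s0_true, df = 4.0, 0.05, 10.0
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(df, size=5000) / df
        hyper = estimate_hyperparams(s2, df)
        assert 3.0 <= hyper.d0 <= 5.0
        assert 0.04 <= hyper.s0_sq <= 0.06

    def test_posterior_variance_between_prior_and_observed(self):
        fits = self._fits()
        hyper = ModerationHyperparams(d0=4.0, s0_sq=0.05)
        mod = ebayes_moderate(fits, hyper)
        df = fits["df_residual"].iloc[0]
        s2_tilde = (hyper.d0 * hyper.s0_sq + df * fits["s2"]) / (hyper.d0 + df)
        low = np.minimum(fits["s2"], hyper.s0_sq)
        high = np.maximum(fits["s2"], hyper.s0_sq)
        assert ((s2_tilde >= low - 1e-12) & (s2_tilde <= high + 1e-12)).all()
        # and the reported t uses exactly that posterior variance
        v = fits.attrs["coef_variance_factor"]
        assert np.allclose(mod["t_moderated"], fits["coef_m"] / np.sqrt(s2_tilde * v))

    def test_all_zero_variances_rejected(self):
        m = pd.DataFrame(np.ones((20, 6)), columns=[f"s{i}" for i in range(6)])
        indicator = pd.Series([1.0] * 3 + [0.0] * 3, index=m.columns)
        fits = fit_probewise(m, build_design(indicator))
        with pytest.raises(ValidationError):
            ebayes_moderate(fits, "estimate")

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_agreement_with_limma_reference(self, tmp_path):
        """Moderated t and p match the R limma implementation to 1e-10."""
        rng = np.random.default_rng(11)
        n_probes, n = 400, 12
        sigma2 = 0.05 * 4.0 / rng.chisquare(4.0, size=n_probes)
        M = rng.normal(0, np.sqrt(sigma2)[:, None], size=(n_probes, n))
        groups = np.array([1] * 4 + [0] * 8)
        cov = rng.normal(0, 1, size=n)
        M[:20, groups == 1] += 0.5
        probes = [f"p{i}" for i in range(n_probes)]
        m = pd.DataFrame(M, index=probes, columns=[f"s{i}" for i in range(n)])
        m.to_csv(tmp_path / "m.tsv", sep="\t")
        pd.DataFrame({"case": groups, "cov": cov}).to_csv(
            tmp_path / "design.csv", index=False
        )
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("m.tsv", row.names=1))
            d <- read.csv("design.csv")
            design <- model.matrix(~ case + cov, data=d)
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(probe=rownames(m), t=fit$t[,"case"],
                              p=fit$p.value[,"case"])
            write.csv(out, "limma_out.csv", row.names=FALSE)
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(
            ["Rscript", "oracle.R"], cwd=tmp_path, check=True, capture_output=True
        )
        oracle = pd.read_csv(tmp_path / "limma_out.csv", index_col="probe")

        indicator = pd.Series(groups.astype(float), index=m.columns)
        covdf = pd.DataFrame({"cov": cov}, index=m.columns)
        fits = fit_probewise(m, build_design(indicator, covdf))
        mod = ebayes_moderate(fits, "estimate")
        assert np.abs(mod["t_moderated"] - oracle["t"]).max() < 1e-10
        assert np.abs(mod["p_raw"] - oracle["p"]).max() < 1e-10


class TestDeltaBeta:
    def test_identical_groups_give_zero(self):
        beta = pd.DataFrame(
            {"a": [0.4, 0.6], "b": [0.5, 0.5], "c": [0.4, 0.6], "d": [0.5, 0.5]}
        )
        delta = compute_delta_beta(beta, ["a", "b"], ["c", "d"])
        assert np.allclose(delta, 0.0)

    def test_constant_shift_recovered(self):
        beta = pd.DataFrame({"a": [0.6], "b": [0.6], "c": [0.5], "d": [0.5]})
        delta = compute_delta_beta(beta, ["a", "b"], ["c", "d"])
        assert delta.iloc[0] == pytest.approx(0.10)

    def test_noise_free_simulation_recovers_planted_effects(self):
        cfg = SimulationConfig(
            n_probes=1000, signature_size=50, n_cases=6, n_control_pool=12,
            n_discriminating_probes=50, effect_delta_beta=0.12,
            noise_sd_logit=0.0, fixed_cell_proportions=True, seed=2,
        )
        beta, samples, truth = simulate_cohort(cfg)
        cases = list(samples.index[samples["group"] == "case"])
        controls = list(samples.index[samples["group"] == "control"])
        delta = compute_delta_beta(beta, cases, controls)
        effects = truth.cohort_effects["syndrome_a"]
        assert np.allclose(delta.loc[effects.index], effects, atol=1e-12)

    def test_overlapping_groups_rejected(self):
        beta = pd.DataFrame({"a": [0.5], "b": [0.5]})
        with pytest.raises(ValidationError):
            compute_delta_beta(beta, ["a"], ["a", "b"])


def bh_stepup_oracle(p):
    """Direct step-up evaluation: q_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum(1.0, m * p[order] / np.arange(1, m + 1))
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestAdjustBh:
    def test_single_p_value_unchanged(self):
        assert adjust_bh(np.array([0.05]))[0] == pytest.approx(0.05)

    def test_three_value_example(self):
        q = adjust_bh(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_stepup_oracle_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=rng.integers(1, 200))
        assert np.allclose(adjust_bh(p), bh_stepup_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_q_at_least_p(self, p_list):
        p = np.array(p_list)
        assert (adjust_bh(p) >= p - 1e-12).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 100)
        perm = rng.permutation(100)
        assert np.allclose(adjust_bh(p)[perm], adjust_bh(p[perm]))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh(np.array([0.5, 1.2]))


class TestCallDmps:
    def _stats(self, delta, q):
        return pd.DataFrame(
            {"delta_beta": delta, "q_bh": q},
            index=[f"p{i}" for i in range(len(delta))],
        )

    def test_thresholds_are_strict(self):
        stats = self._stats([0.04, 0.05, 0.051, 0.06], [1e-6, 1e-6, 1e-6, 0.01])
        dmps = call_dmps(stats)
        # 0.04 fails the effect bound, 0.05 exactly is excluded (strict),
        # q = 0.01 exactly is excluded (strict)
        assert list(dmps) == ["p2"]

    def test_hypomethylated_probes_qualify_via_absolute_effect(self):
        stats = self._stats([-0.10], [1e-8])
        assert list(call_dmps(stats)) == ["p0"]

    def test_planted_simulation_recall_and_false_calls(self, discovery_result, discovery_sim):
        _, _, truth = discovery_sim
        stats = discovery_result.probe_stats
        dmps = set(discovery_result.dmp_ids)
        planted = truth.planted_probe_ids
        recall = len(dmps & planted) / len(planted)
        false_rate = len(dmps - planted) / (len(stats) - len(planted))
        assert recall >= 0.8
        assert false_rate <= 0.01


class TestNullBehaviour:
    def test_false_positive_rate_controlled_under_global_null(self):
        fractions = []
        for seed in range(3):
            cfg = SimulationConfig(
                n_probes=4000, signature_size=100, n_cases=10,
                n_control_pool=40, n_discriminating_probes=200,
                effect_delta_beta=0.0, seed=seed,
            )
            beta, samples, _ = simulate_cohort(cfg)
            cases = list(samples.index[samples["group"] == "case"])
            controls = list(samples.index[samples["group"] == "control"])
            stats = probe_stats(beta, beta_to_m(beta), cases, controls)
            fractions.append((stats["q_bh"] < 0.01).mean())
        assert max(fractions) <= 0.02
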