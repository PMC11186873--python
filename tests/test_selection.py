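"""Three-stage episignature probe selection and LOOCV."""

import numpy as np
import pandas as pd
import pytest

from episig import (
    SelectionConfig,
    probe_auroc,
    product_score,
    prune_correlated,
    run_loocv,
    select_episignature,
    select_stage1,
    select_stage2,
)
from episig.errors import ConfigError, ValidationError
from episig.simulate import SimulationConfig, simulate_cohort


def stats_frame(scores_and_q):
    return pd.DataFrame(
        scores_and_q, index=[f"p{i}" for i in range(len(scores_and_q))]
    )


class TestProductScore:
    def test_reference_value(self):
        stats = stats_frame([{"delta_beta": 0.1, "q_bh": 0.01}])
        assert product_score(stats).iloc[0] == pytest.approx(0.460517, abs=1e-6)

    @pytest.mark.parametrize(
        "delta,q", [(0.3, 1.0), (0.0, 1e-10), (-0.0, 0.5)]
    )
    def test_zero_score_cases(self, delta, q):
        stats = stats_frame([{"delta_beta": delta, "q_bh": q}])
        assert product_score(stats).iloc[0] == pytest.approx(0.0)

    def test_q_floor_keeps_score_finite(self):
        stats = stats_frame([{"delta_beta": 0.2, "q_bh": 0.0}])
        score = product_score(stats).iloc[0]
        assert np.isfinite(score)
        assert score == pytest.approx(0.2 * -np.log(1e-300))


class TestStage1:
    def test_caps_at_i_product(self):
        rng = np.random.default_rng(0)
        stats = stats_frame(
            [{"delta_beta": d, "q_bh": q}
             for d, q in zip(rng.uniform(0, 0.3, 2000), rng.uniform(0, 1, 2000))]
        )
        kept = select_stage1(product_score(stats), stats["q_bh"], 1000)
        assert len(kept) == 1000

    def test_undersized_input_passes_through(self):
        stats = stats_frame(
            [{"delta_beta": 0.1, "q_bh": 0.5} for _ in range(700)]
        )
        kept = select_stage1(product_score(stats), stats["q_bh"], 1000)
        assert len(kept) == 700

    def test_tie_broken_by_smaller_q(self):
        # equal products, different q: 0.2 * -ln(0.01) == 0.1 * -ln(0.0001)
        stats = pd.DataFrame(
            {
                "delta_beta": [0.2, 0.1],
                "q_bh": [0.01, 0.0001],
            },
            index=["pa", "pb"],
        )
        scores = product_score(stats)
        assert scores.iloc[0] == pytest.approx(scores.iloc[1])
        kept = select_stage1(scores, stats["q_bh"], 1)
        assert kept == ["pb"]

    def test_selects_by_descending_score(self):
        stats = stats_frame(
            [
                {"delta_beta": 0.1, "q_bh": 0.5},
                {"delta_beta": 0.3, "q_bh": 0.001},
                {"delta_beta": 0.05, "q_bh": 0.9},
            ]
        )
        kept = select_stage1(product_score(stats), stats["q_bh"], 2)
        assert kept == ["p1", "p0"]


class TestProbeAuroc:
    def test_complete_separation(self):
        assert probe_auroc([2, 3], [0, 1]) == 1.0

    def test_partial_overlap_brute_force_value(self):
        # pairs: (1,2) no, (1,4) no, (3,2) yes, (3,4) no -> 1/4
        assert probe_auroc([1, 3], [2, 4]) == pytest.approx(0.25)

    def test_all_ties_give_half(self):
        assert probe_auroc([1, 1, 1], [1, 1]) == pytest.approx(0.5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            probe_auroc([], [1, 2])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        case = rng.choice(np.arange(10) / 2.0, size=rng.integers(1, 21))
        control = rng.choice(np.arange(10) / 2.0, size=rng.integers(1, 21))
        wins = sum(
            1.0 if c > k else (0.5 if c == k else 0.0)
            for c in case
            for k in control
        )
        expected = wins / (len(case) * len(control))
        assert probe_auroc(case, control) == pytest.approx(expected, abs=1e-12)


class TestStage2:
    def _values(self, n_probes, case_ids, control_ids, seed=0):
        rng = np.random.default_rng(seed)
        cols = list(case_ids) + list(control_ids)
        return pd.DataFrame(
            rng.uniform(0, 1, size=(n_probes, len(cols))),
            index=[f"p{i}" for i in range(n_probes)],
            columns=cols,
        )

    def test_caps_at_j_auroc(self):
        cases = [f"c{i}" for i in range(5)]
        controls = [f"k{i}" for i in range(10)]
        values = self._values(1000, cases, controls)
        out = select_stage2(list(values.index), values, cases, controls, 500)
        assert len(out) == 500

    def test_undersized_input_passes_through(self):
        cases, controls = ["c0", "c1"], ["k0", "k1", "k2"]
        values = self._values(300, cases, controls)
        out = select_stage2(list(values.index), values, cases, controls, 500)
        assert len(out) == 300

    def test_hypomethylated_probe_ranks_high(self):
        cases, controls = ["c0", "c1"], ["k0", "k1"]
        values = pd.DataFrame(
            {
                "c0": [0.1, 0.5],
                "c1": [0.2, 0.6],
                "k0": [0.8, 0.55],
                "k1": [0.9, 0.45],
            },
            index=["hypo", "null"],
        )
        out = select_stage2(["hypo", "null"], values, cases, controls, 1)
        assert list(out.index) == ["hypo"]
        assert out.loc["hypo", "auroc"] == 0.0  # raw orientation
        assert out.loc["hypo", "auroc_ranking"] == 1.0


class TestPruneCorrelated:
    def test_duplicate_probe_pruned(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 1, 20)
        values = pd.DataFrame(
            {"s%d" % i: [base[i], base[i], rng.uniform()] for i in range(20)},
            index=["pa", "pa_dup", "pb"],
        )
        kept = prune_correlated(["pa", "pa_dup", "pb"], values, 0.75)
        assert kept == ["pa", "pb"]

    def test_orthogonal_probes_all_survive(self):
        # build exactly uncorrelated rows via an orthogonal basis
        q, _ = np.linalg.qr(np.random.default_rng(2).normal(size=(30, 6)))
        values = pd.DataFrame(
            q.T * 0.1 + 0.5, index=[f"p{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(30)],
        )
        kept = prune_correlated(list(values.index), values, 0.75)
        assert kept == list(values.index)

    def test_anticorrelated_probes_also_pruned(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0.2, 0.8, 20)
        values = pd.DataFrame(
            np.vstack([base, 1.0 - base]), index=["pa", "pb"],
            columns=[f"s{j}" for j in range(20)],
        )
        kept = prune_correlated(["pa", "pb"], values, 0.75)
        assert kept == ["pa"]

    def test_zero_variance_probe_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(
            np.vstack([np.full(10, 0.5), rng.uniform(0, 1, 10)]),
            index=["flat", "ok"], columns=[f"s{j}" for j in range(10)],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            kept = prune_correlated(["flat", "ok"], values, 0.75)
        assert kept == ["ok"]

    def test_kept_set_respects_pairwise_bound(self, discovery_result, discovery_sim):
        """Exhaustive |Pearson r| <= k check on the returned signature."""
        beta, _, _ = discovery_sim
        probes = discovery_result.selector.probes_
        train = discovery_result.case_ids + discovery_result.match.control_ids
        values = beta.values.loc[probes, train].to_numpy()
        corr = np.corrcoef(values)
        off_diag = corr[~np.eye(len(probes), dtype=bool)]
        assert np.abs(off_diag).max() <= 0.75 + 1e-12


class TestSelectorPipeline:
    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SelectionConfig(i_product=100, j_auroc=500)
        with pytest.raises(ConfigError):
            SelectionConfig(k_corr=0.0)

    def test_selection_is_deterministic(self, discovery_sim):
        beta, samples, truth = discovery_sim
        cases = list(samples.index[samples["cohort"] == "syndrome_a"])[:6]
        controls = list(samples.index[samples["group"] == "control"])[:24]
        cfg = SelectionConfig(i_product=200, j_auroc=100)
        a = select_episignature(beta, cases, controls, cfg)
        b = select_episignature(beta, cases, controls, cfg)
        assert a.probes_ == b.probes_
        pd.testing.assert_frame_equal(a.selection_, b.selection_)

    def test_episignature_satisfies_structural_invariants(self, discovery_result):
        selector = discovery_result.selector
        assert len(selector.stage1_probes_) == 1000
        assert len(selector.stage2_) == 500
        assert 1 <= len(selector.probes_) <= 500
        # selection table mirrors the kept probes in rank order
        assert list(selector.selection_.index) == selector.probes_
        assert (
            selector.selection_["selection_rank"]
            == np.arange(1, len(selector.probes_) + 1)
        ).all()

    def test_noise_free_selection_is_subset_of_planted(self):
        cfg = SimulationConfig(
            n_probes=2000, signature_size=100, n_cases=8, n_control_pool=32,
            n_discriminating_probes=100, effect_delta_beta=0.12,
            noise_sd_logit=0.0, fixed_cell_proportions=True, seed=5,
        )
        beta, samples, truth = simulate_cohort(cfg)
        cases = list(samples.index[samples["group"] == "case"])
        controls = list(samples.index[samples["group"] == "control"])
        selector = select_episignature(
            beta, cases, controls, SelectionConfig(i_product=200, j_auroc=100)
        )
        assert set(selector.probes_) <= truth.planted_probe_ids
        assert len(selector.probes_) >= 1

    def test_transform_restricts_to_selected_probes(self, discovery_sim):
        beta, samples, _ = discovery_sim
        cases = list(samples.index[samples["cohort"] == "syndrome_a"])[:5]
        controls = list(samples.index[samples["group"] == "control"])[:20]
        selector = select_episignature(
            beta, cases, controls, SelectionConfig(i_product=100, j_auroc=50)
        )
        X = beta.values[cases + controls].T
        restricted = selector.transform(X)
        assert list(restricted.columns) == selector.probes_


class TestLoocv:
    def test_one_iteration_per_case(self, discovery_result):
        assert len(discovery_result.loocv) == 13
        assert set(discovery_result.loocv["held_out"]) == set(
            discovery_result.case_ids
        )

    def test_held_out_cases_assigned_to_case_side(self, discovery_result):
        assert discovery_result.loocv["correct"].sum() >= 12

    def test_too_few_cases_rejected(self, discovery_sim):
        beta, samples, _ = discovery_sim
        cases = list(samples.index[samples["cohort"] == "syndrome_a"])[:2]
        controls = list(samples.index[samples["group"] == "control"])[:8]
        with pytest.raises(ValidationError):
            run_loocv(beta, cases, controls)
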