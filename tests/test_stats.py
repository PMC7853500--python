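"""Group statistics: Wilks' lambda oracle, RM-ANOVA follow-ups, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from thalcort.inversion import InversionSettings, default_priors, Posterior
from thalcort.observation import ParameterVector, design, free_quantities
from thalcort.stats import (
    ConditionParameterTable,
    build_parameter_table,
    condition_parameters,
    rm_manova,
    univariate_followups,
)


def _posterior_with(spec, dsgn, theta=None, beta=None):
    """Construct a Posterior carrying given estimates (no fitting needed)."""
    priors = default_priors(spec, dsgn, InversionSettings())
    mean = np.zeros(len(priors.names))
    names = list(priors.names)
    quantities = free_quantities(spec)
    if theta is not None:
        for q, v in theta.items():
            mean[names.index(f"t:{q}")] = v
    if beta is not None:
        for (row, q), v in beta.items():
            mean[names.index(f"b{row}:{q}")] = v
    return Posterior(names=tuple(names), mean=mean,
                     cov=np.eye(len(names)), lam=0.0, F=0.0,
                     F_trace=np.zeros(1), fitted=np.zeros((3, 4)),
                     explained_variance=1.0, accuracy=0.0, complexity=0.0,
                     design=dsgn.name)


class TestConditionParameters:
    def test_zero_beta_identical_conditions(self, default_spec):
        d = design("linear")
        post = _posterior_with(default_spec, d, theta={"g:rl->ss": 0.3})
        vals = condition_parameters(post, d, default_spec)
        np.testing.assert_allclose(vals[0], vals[1])
        np.testing.assert_allclose(vals[0], vals[2])

    def test_linear_effect_scales_conditions(self, default_spec):
        d = design("linear")
        b = 0.25
        post = _posterior_with(default_spec, d, beta={(0, "g:rl->ss"): b})
        vals = condition_parameters(post, d, default_spec, parameters=("g:rl->ss",))
        baseline = vals[1, 0]
        np.testing.assert_allclose(
            vals[:, 0], baseline * np.array([np.exp(-b), 1.0, np.exp(b)]), rtol=1e-12)

    def test_zero_everything_gives_baseline_defaults(self, default_spec):
        d = design("linear")
        post = _posterior_with(default_spec, d)
        vals = condition_parameters(post, d, default_spec,
                                    parameters=("g:rl->ss", "d:AMPA"))
        # edge coupling strength and AMPA time constant (ms) at their defaults
        i, j = default_spec.index("ss"), default_spec.index("rl")
        assert vals[0, 0] == pytest.approx(default_spec.gains[0, i, j]
                                           / default_spec.receptor_mix["AMPA"])
        assert vals[0, 1] == pytest.approx(4.0)
        np.testing.assert_allclose(vals[1], vals[0])
        np.testing.assert_allclose(vals[2], vals[0])

    def test_decay_effect_reported_as_time_constant(self, default_spec):
        d = design("linear")
        post = _posterior_with(default_spec, d, beta={(0, "d:AMPA"): 0.2})
        vals = condition_parameters(post, d, default_spec, parameters=("d:AMPA",))
        # a faster decay rate is a shorter time constant
        assert vals[2, 0] == pytest.approx(4.0 * np.exp(-0.2))

    def test_design_mismatch_rejected(self, default_spec):
        post = _posterior_with(default_spec, design("linear"))
        with pytest.raises(ValueError, match="design"):
            condition_parameters(post, design("nonlinear"), default_spec)


@pytest.fixture()
def toy_table():
    rng = np.random.default_rng(12)
    vals = rng.normal(1.0, 0.1, (12, 3, 2))
    vals[:, 1:, 0] += 0.15
    return ConditionParameterTable(values=vals, parameter_labels=("g:rl->ss", "d:AMPA"))


class TestRmManova:
    def test_null_identity(self):
        rng = np.random.default_rng(0)
        base = rng.normal(1.0, 0.1, (12, 1, 2))
        diffs = rng.normal(0, 0.05, (12, 2, 2))
        diffs -= diffs.mean(axis=0, keepdims=True)   # exact zero mean change
        vals = np.concatenate([base, base + diffs], axis=1)
        lam, f_stat, _, p = rm_manova(
            ConditionParameterTable(values=vals, parameter_labels=("a", "b")))
        assert lam == pytest.approx(1.0)
        assert f_stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_determinant_ratio_oracle(self, toy_table):
        """Brute-force det(E)/det(E+H) agrees with the eigenvalue route."""
        lam, *_ = rm_manova(toy_table)
        d = toy_table.values[:, 1:, :] - toy_table.values[:, :1, :]
        Y = d.reshape(12, -1)
        yc = Y - Y.mean(axis=0)
        E = yc.T @ yc
        H = 12 * np.outer(Y.mean(axis=0), Y.mean(axis=0))
        lam_oracle = np.linalg.det(E) / np.linalg.det(E + H)
        assert lam == pytest.approx(lam_oracle, abs=1e-10)

    def test_scale_invariance(self, toy_table):
        lam1, *_ = rm_manova(toy_table)
        scaled = ConditionParameterTable(values=toy_table.values * 10,
                                         parameter_labels=toy_table.parameter_labels)
        lam2, *_ = rm_manova(scaled)
        assert lam1 == pytest.approx(lam2, rel=1e-10)

    def test_too_few_subjects_rejected(self):
        vals = np.random.default_rng(1).normal(size=(4, 3, 2))
        with pytest.raises(ValueError, match="subset"):
            rm_manova(ConditionParameterTable(values=vals, parameter_labels=("a", "b")))

    def test_singular_names_collinear_parameters(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(12, 3, 2))
        vals[:, :, 1] = vals[:, 1, 1][:, None]      # constant across conditions
        vals[:, :, 1] = vals[:, 0, 0][:, None]      # and duplicated -> zero diffs
        with pytest.raises(ValueError, match="singular"):
            rm_manova(ConditionParameterTable(values=vals, parameter_labels=("a", "b")))

    def test_single_parameter_matches_multivariate_followup(self):
        """With one parameter the MANOVA equals the per-parameter multivariate test."""
        rng = np.random.default_rng(3)
        vals = rng.normal(1.0, 0.2, (15, 3, 1))
        vals[:, 2, 0] += 0.1
        table = ConditionParameterTable(values=vals, parameter_labels=("a",))
        _, _, _, p_manova = rm_manova(table)
        fu = univariate_followups(table)
        assert p_manova == pytest.approx(fu["p_multivariate"].iloc[0], abs=1e-8)


class TestUnivariateFollowups:
    def test_identical_conditions_no_rejections(self):
        rng = np.random.default_rng(4)
        base = rng.normal(1.0, 0.1, (10, 1, 3))
        vals = np.tile(base, (1, 3, 1))
        fu = univariate_followups(
            ConditionParameterTable(values=vals, parameter_labels=("a", "b", "c")))
        assert np.allclose(fu["F"], 0.0)
        assert not fu["significant"].any()

    def test_detects_injected_effect(self, toy_table):
        fu = univariate_followups(toy_table)
        assert fu.set_index("parameter").loc["g:rl->ss", "significant"]
        assert fu.set_index("parameter").loc["g:rl->ss", "direction"] == 1

    def test_zero_variance_parameter_flagged(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(1.0, 0.1, (10, 3, 2))
        vals[:, :, 1] = 7.0
        fu = univariate_followups(
            ConditionParameterTable(values=vals, parameter_labels=("a", "b")))
        row = fu.set_index("parameter").loc["b"]
        assert row["excluded"]
        assert not row["significant"]

    def test_matches_hand_rm_anova(self):
        """pingouin result equals the closed-form sum-of-squares computation."""
        rng = np.random.default_rng(6)
        vals = rng.normal(0.0, 1.0, (9, 3, 1))
        vals[:, 1, 0] += 0.8
        fu = univariate_followups(
            ConditionParameterTable(values=vals, parameter_labels=("a",)))
        v = vals[:, :, 0]
        n, c = v.shape
        grand = v.mean()
        ss_cond = n * np.sum((v.mean(axis=0) - grand) ** 2)
        ss_subj = c * np.sum((v.mean(axis=1) - grand) ** 2)
        ss_err = np.sum((v - grand) ** 2) - ss_cond - ss_subj
        f_oracle = (ss_cond / (c - 1)) / (ss_err / ((n - 1) * (c - 1)))
        assert fu["F"].iloc[0] == pytest.approx(f_oracle, rel=1e-10)


class TestBenjaminiHochberg:
    def test_all_rejected_toy(self):
        # largest k with p(k) <= k q / m is k = 4 -> all four rejected
        p = [0.001, 0.02, 0.03, 0.04]
        rej, _, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert rej.all()

    def test_partial_rejection_toy(self):
        # thresholds 0.025 and 0.05: only the first survives
        p = [0.01, 0.4]
        rej, _, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert rej.tolist() == [True, False]

    def test_bh_through_followups(self):
        """The follow-up table applies the same step-up rule."""
        rng = np.random.default_rng(7)
        vals = rng.normal(1.0, 0.1, (14, 3, 4))
        vals[:, 1:, 0] += 0.2
        vals[:, 1:, 1] += 0.12
        table = ConditionParameterTable(values=vals,
                                        parameter_labels=("a", "b", "c", "d"))
        fu = univariate_followups(table, q=0.05)
        rej, p_adj, _, _ = multipletests(fu["p_gg"], alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(fu["significant"], rej)
        np.testing.assert_allclose(fu["p_fdr"], p_adj)

    def test_adjusted_p_monotone_and_nested(self):
        rng = np.random.default_rng(8)
        p = np.sort(rng.uniform(0, 0.2, 12))
        _, p_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.all(np.diff(p_adj) >= -1e-15)
        rej05, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        rej01, *_ = multipletests(p, alpha=0.01, method="fdr_bh")
        assert set(np.where(rej01)[0]) <= set(np.where(rej05)[0])


class TestBuildParameterTable:
    def test_stacks_subjects(self, default_spec):
        d = design("linear")
        posts = [_posterior_with(default_spec, d, beta={(0, "g:rl->ss"): 0.1 * i})
                 for i in range(3)]
        table = build_parameter_table(posts, d, default_spec,
                                      parameters=("g:rl->ss",))
        assert table.values.shape == (3, 3, 1)
        assert table.values[0, 0, 0] == pytest.approx(table.values[0, 2, 0])
        assert table.values[2, 2, 0] > table.values[2, 0, 0]
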