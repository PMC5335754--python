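import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from subnetbench.expression import (ExpressionMatrix, GGParams,
                                    differential_test, generate_expression,
                                    gg_density)


class TestGGDensity:
    def test_exponential_limit_at_origin(self):
        # alpha=1, beta=1 is Exponential(1): density -> 1 as y -> 0+
        assert gg_density(1e-12, 1.0, 1.0) == pytest.approx(1.0, rel=1e-6)

    def test_closed_form_value(self):
        # alpha=2, beta=1, y=1 -> e^-1 / Gamma(2)
        assert gg_density(1.0, 2.0, 1.0) == pytest.approx(math.exp(-1))

    def test_integrates_to_one(self):
        total, _ = integrate.quad(lambda y: gg_density(y, 10.0, 0.5), 0,
                                  np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mean_is_alpha_beta(self):
        mean, _ = integrate.quad(lambda y: y * gg_density(y, 10.0, 0.5), 0,
                                 np.inf)
        assert mean == pytest.approx(10.0 * 0.5, rel=1e-6)

    def test_nonpositive_y_rejected(self):
        with pytest.raises(ValueError):
            gg_density(0.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            gg_density(-1.0, 2.0, 1.0)


def make_states(genes, de_genes):
    return pd.Series({g: int(g in de_genes) for g in genes})


class TestGenerateExpression:
    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            GGParams(alpha=0)
        with pytest.raises(ValueError):
            GGParams(nu=-1)

    def test_shapes_labels_and_positivity(self):
        genes = [f"g{i}" for i in range(20)]
        params = GGParams(n_case=6, n_control=4, seed=1)
        expr = generate_expression(genes, make_states(genes, genes[:5]),
                                   params)
        assert expr.values.shape == (20, 10)
        assert (expr.labels == "case").sum() == 6
        assert (expr.values.to_numpy() > 0).all()

    def test_missing_state_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            generate_expression(["a", "b"], pd.Series({"a": 0}), GGParams())

    def test_bit_identical_for_same_seed(self):
        genes = [f"g{i}" for i in range(10)]
        st = make_states(genes, genes[:2])
        a = generate_expression(genes, st, GGParams(seed=3))
        b = generate_expression(genes, st, GGParams(seed=3))
        assert a.values.equals(b.values)

    def test_changing_n_case_leaves_controls_untouched(self):
        genes = [f"g{i}" for i in range(10)]
        st = make_states(genes, genes[:2])
        a = generate_expression(genes, st, GGParams(seed=3, n_case=10))
        b = generate_expression(genes, st, GGParams(seed=3, n_case=25))
        assert np.allclose(a.control.to_numpy(), b.control.to_numpy())
        assert b.case.shape[1] == 25

    def test_ee_gene_moments_match_gamma_observation_model(self):
        # At large n an EE gene's samples are Gamma(alpha, beta_g) for one
        # shared scale: mean^2/var estimates alpha, and the case and
        # control means agree to Monte-Carlo error.
        genes = ["only"]
        params = GGParams(n_case=5000, n_control=5000, seed=8)
        expr = generate_expression(genes, make_states(genes, set()), params)
        vals = expr.values.to_numpy().ravel()
        alpha_hat = vals.mean() ** 2 / vals.var(ddof=1)
        assert alpha_hat == pytest.approx(params.alpha, rel=0.1)
        se = vals.std(ddof=1) / math.sqrt(vals.size / 2)
        cm, nm = expr.case.to_numpy().mean(), expr.control.to_numpy().mean()
        assert abs(cm - nm) < 4 * se

    def test_marginal_mean_matches_iterated_expectation(self):
        # E[y] = alpha * E[beta_g] = alpha * alpha0 * nu = 4.5
        genes = [f"g{i}" for i in range(3000)]
        params = GGParams(seed=21)
        expr = generate_expression(genes, make_states(genes, set()), params)
        grand = expr.values.to_numpy().mean()
        assert grand == pytest.approx(10 * 0.9 * 0.5, abs=0.3)

    def test_rate_convention_shrinks_means(self):
        genes = [f"g{i}" for i in range(500)]
        st = make_states(genes, set())
        scale = generate_expression(genes, st, GGParams(seed=2))
        rate = generate_expression(genes, st, GGParams(seed=2,
                                                       nu_is_rate=True))
        # nu=0.5 as a rate doubles the prior scale
        assert rate.values.to_numpy().mean() > scale.values.to_numpy().mean()

    def test_de_detection_calibration(self):
        # DE genes reject equality far above the 5% level; EE genes near it.
        genes = [f"g{i}" for i in range(1000)]
        de_set = set(genes[:300])
        expr = generate_expression(genes, make_states(genes, de_set),
                                   GGParams(seed=5))
        de = differential_test(expr)
        p = de["p_value"]
        de_reject = (p.loc[list(de_set)] < 0.05).mean()
        ee_reject = (p.loc[[g for g in genes if g not in de_set]] < 0.05
                     ).mean()
        assert de_reject > 0.5
        assert abs(ee_reject - 0.05) < 0.04

    def test_round_trip(self, tmp_path):
        genes = [f"g{i}" for i in range(5)]
        expr = generate_expression(genes, make_states(genes, {"g0"}),
                                   GGParams(seed=1, n_case=3, n_control=3))
        expr.write(tmp_path / "e.tsv", tmp_path / "l.tsv")
        back = ExpressionMatrix.read(tmp_path / "e.tsv", tmp_path / "l.tsv")
        assert np.allclose(back.values.to_numpy(), expr.values.to_numpy())
        assert (back.labels == expr.labels).all()


class TestDifferentialTest:
    def _expr(self, case_rows, ctrl_rows, genes=None):
        case = np.atleast_2d(np.asarray(case_rows, dtype=float))
        ctrl = np.atleast_2d(np.asarray(ctrl_rows, dtype=float))
        genes = genes or [f"g{i}" for i in range(case.shape[0])]
        cols = [f"case_{i}" for i in range(case.shape[1])] + \
               [f"control_{i}" for i in range(ctrl.shape[1])]
        values = pd.DataFrame(np.hstack([case, ctrl]), index=genes,
                              columns=cols)
        labels = pd.Series(["case"] * case.shape[1]
                           + ["control"] * ctrl.shape[1], index=cols)
        return ExpressionMatrix(values, labels)

    def test_symmetric_groups_give_null_result(self):
        expr = self._expr([[1, 2, 3, 4]], [[4, 3, 2, 1]])
        de = differential_test(expr)
        assert de["t_statistic"].iloc[0] == pytest.approx(0.0)
        assert de["p_value"].iloc[0] == pytest.approx(1.0)
        assert de["z_score"].iloc[0] == 0.0

    def test_welch_matches_textbook_formula(self):
        case, ctrl = [1, 2, 3, 4, 5], [6, 7, 8, 9, 10]
        de = differential_test(self._expr([case], [ctrl]))
        # independent Welch computation from first principles
        m1, m2 = np.mean(case), np.mean(ctrl)
        v1, v2 = np.var(case, ddof=1), np.var(ctrl, ddof=1)
        n1, n2 = len(case), len(ctrl)
        t = (m1 - m2) / math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert de["t_statistic"].iloc[0] == pytest.approx(t)
        assert de["p_value"].iloc[0] == pytest.approx(p)

    def test_z_is_signed_normal_quantile(self):
        rng = np.random.default_rng(0)
        expr = self._expr(rng.gamma(10, 0.5, (20, 8)),
                          rng.gamma(10, 0.7, (20, 8)))
        de = differential_test(expr)
        expected = stats.norm.isf(de["p_value"] / 2) * np.sign(
            de["t_statistic"])
        assert np.allclose(de["z_score"], expected)
        # quantile identity: p = 0.05 with positive t -> z ~ 1.96
        assert stats.norm.isf(0.05 / 2) == pytest.approx(1.959964, abs=1e-6)

    def test_zero_variance_everywhere_logged_as_null(self, caplog):
        expr = self._expr([[5, 5, 5]], [[5, 5, 5]])
        with caplog.at_level("WARNING"):
            de = differential_test(expr)
        assert de["p_value"].iloc[0] == 1.0
        assert de["z_score"].iloc[0] == 0.0
        assert "zero variance" in caplog.text

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            differential_test(self._expr([[1]], [[2, 3]]))

    @pytest.mark.parametrize("method", ["student", "wilcoxon"])
    def test_alternative_tests_run_and_agree_in_direction(self, method):
        rng = np.random.default_rng(1)
        expr = self._expr(rng.gamma(10, 1.0, (30, 15)),
                          rng.gamma(10, 0.4, (30, 15)))
        welch = differential_test(expr)
        alt = differential_test(expr, method=method)
        assert (np.sign(alt["t_statistic"]) == np.sign(
            welch["t_statistic"])).mean() > 0.9
        assert ((alt["p_value"] > 0) & (alt["p_value"] <= 1)).all()


def test_ee_pvalues_approximately_uniform():
    # KS check over a seeded batch of runs.
    genes = [f"g{i}" for i in range(400)]
    states = pd.Series({g: 0 for g in genes})
    passes = 0
    for seed in range(10):
        expr = generate_expression(genes, states, GGParams(seed=seed))
        p = differential_test(expr)["p_value"].to_numpy()
        stat = stats.kstest(p, "uniform").statistic
        crit = 1.6276 / math.sqrt(len(p))  # alpha = 0.01 asymptotic
        passes += stat < crit
    assert passes >= 9


def test_de_genes_have_inflated_absolute_z():
    genes = [f"g{i}" for i in range(2000)]
    de_set = set(genes[:400])
    states = pd.Series({g: int(g in de_set) for g in genes})
    de = differential_test(generate_expression(genes, states,
                                               GGParams(seed=17)))
    z_de = de["z_score"].loc[list(de_set)].abs()
    z_ee = de["z_score"].loc[[g for g in genes if g not in de_set]].abs()
    assert stats.mannwhitneyu(z_de, z_ee,
                              alternative="greater").pvalue < 0.01
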