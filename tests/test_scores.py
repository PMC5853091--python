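"""Gene-set scores, phase and hybrid threshold rules, PC1 correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from orgsc import scores
from orgsc.scores import (ScorePanel, gene_set_score, hybrid_state,
                          load_default_panels, phase_from_scores,
                          score_pseudotime_correlation)


class TestGeneSetScore:
    def test_arithmetic_mean_of_two_genes(self):
        expr = pd.DataFrame({"c1": [4.0, 2.0]}, index=["a", "b"])
        s = gene_set_score(expr, ScorePanel("P", ("a", "b")))
        assert s["c1"] == 3.0

    def test_all_zero_panel_scores_zero(self):
        expr = pd.DataFrame({"c1": [0.0, 0.0, 5.0]}, index=["a", "b", "c"])
        assert gene_set_score(expr, ScorePanel("P", ("a", "b")))["c1"] == 0.0

    def test_matches_independent_mean_oracle(self, rng):
        genes = [f"g{i}" for i in range(50)]
        expr = pd.DataFrame(rng.random((50, 30)), index=genes,
                            columns=[f"c{i}" for i in range(30)])
        panel_genes = list(rng.choice(genes, size=20, replace=False))
        s = gene_set_score(expr, ScorePanel("P", tuple(panel_genes)))
        for cell in expr.columns:
            assert s[cell] == pytest.approx(
                np.mean([expr.loc[g, cell] for g in panel_genes]))

    def test_panel_gene_order_and_missing_genes_ignored(self, rng, caplog):
        expr = pd.DataFrame(rng.random((4, 5)),
                            index=list("abcd"), columns=[f"c{i}" for i in range(5)])
        fwd = gene_set_score(expr, ScorePanel("P", ("a", "b", "c")))
        rev = gene_set_score(expr, ScorePanel("P", ("c", "b", "a")))
        with caplog.at_level("WARNING"):
            plus = gene_set_score(expr, ScorePanel("P", ("a", "b", "c", "ghost")))
        assert np.allclose(fwd, rev) and np.allclose(fwd, plus)
        assert "absent" in caplog.text

    def test_empty_intersection_is_an_error(self):
        expr = pd.DataFrame({"c1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="ghostpanel"):
            gene_set_score(expr, ScorePanel("ghostpanel", ("x", "y")))


class TestPhaseRule:
    @pytest.mark.parametrize("g1s, g2m, expected", [
        (1.2, 1.9, scores.PHASE_QUIESCENT),   # both below 2
        (2.5, 3.0, scores.PHASE_G2M),         # proliferative, G2M larger
        (3.0, 3.0, scores.PHASE_G1S),         # tie: strictly-greater rule
        (2.0, 1.0, scores.PHASE_G1S),         # boundary: score exactly 2
        (1.0, 2.0, scores.PHASE_G2M),         # boundary on the G2M side
        (1.999, 1.999, scores.PHASE_QUIESCENT),
    ])
    def test_threshold_truth_table(self, g1s, g2m, expected):
        phase = phase_from_scores(pd.Series({"c": g1s}), pd.Series({"c": g2m}))
        assert phase["c"] == expected

    def test_phases_exhaustive_and_exclusive(self, rng):
        g1s = pd.Series(rng.random(200) * 4)
        g2m = pd.Series(rng.random(200) * 4)
        phase = phase_from_scores(g1s, g2m)
        assert phase.isin([scores.PHASE_QUIESCENT, scores.PHASE_G1S,
                           scores.PHASE_G2M]).all()

    def test_default_cellcycle_panels_have_core_set_sizes(self):
        panels = load_default_panels()
        assert len(panels["G1S"].genes) == 43
        assert len(panels["G2M"].genes) == 54


class TestHybridState:
    @pytest.mark.parametrize("e, m, expected", [
        (3.1, 2.4, True),
        (3.1, 2.0, False),   # strict "exceed": 2.0 is not hybrid
        (2.0, 3.0, False),
        (2.001, 2.001, True),
    ])
    def test_threshold_truth_table(self, e, m, expected):
        expr = pd.DataFrame({"c": [e, m]}, index=["Epcam", "Vim"])
        assert bool(hybrid_state(expr)["c"]) is expected

    def test_missing_marker_gene_is_an_error(self):
        expr = pd.DataFrame({"c": [3.0]}, index=["Epcam"])
        with pytest.raises(ValueError, match="Vim"):
            hybrid_state(expr)

    def test_hybrid_fraction_matches_bivariate_exceedance(self, rng):
        """Empirical hybrid rate equals the closed-form P(X>2, Y>2).

        Latent Epcam/Vim log-expression drawn from a correlated bivariate
        normal; the analytic orthant probability is the oracle.
        """
        rho = 0.6
        mean = [2.2, 1.8]
        cov = [[1.0, rho], [rho, 1.0]]
        n = 40_000
        draws = rng.multivariate_normal(mean, cov, size=n)
        expr = pd.DataFrame(draws.T.clip(min=0), index=["Epcam", "Vim"],
                            columns=[f"c{i}" for i in range(n)])
        frac = hybrid_state(expr).mean()
        # P(X > 2, Y > 2) = CDF of (-X, -Y) at (-2, -2); negation keeps cov
        expected = multivariate_normal(
            mean=[-mean[0], -mean[1]], cov=cov).cdf([-2, -2])
        mc_se = np.sqrt(expected * (1 - expected) / n)
        assert frac == pytest.approx(expected, abs=4 * mc_se + 1e-3)


class TestPc1Correlation:
    def test_score_equal_to_pc1_gives_unit_correlation(self, rng):
        # one dominant axis: each gene is a loading times a latent t
        t = np.linspace(0, 1, 40)
        load = rng.random(20) + 0.5
        X = np.outer(load, t) + rng.normal(0, 0.01, (20, 40))
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(20)],
                            columns=[f"c{i}" for i in range(40)])
        pc1, corr = score_pseudotime_correlation(
            expr, [ScorePanel("P", tuple(expr.index))])
        assert abs(corr["P"]) == pytest.approx(1.0, abs=0.01)

    def test_permuting_cells_leaves_r_unchanged(self, small_expr, rng,
                                                small_truth):
        genes, slope = next(iter(
            small_truth.gradient_genes.items())) if small_truth.gradient_genes \
            else (None, None)
        panel = ScorePanel("P", tuple(small_expr.index[:15]))
        sub = small_expr.iloc[:, :40]
        _, corr = score_pseudotime_correlation(sub, [panel])
        perm = rng.permutation(sub.shape[1])
        _, corr_p = score_pseudotime_correlation(sub.iloc[:, perm], [panel])
        assert corr["P"] == pytest.approx(corr_p["P"], abs=1e-9)

    def test_constant_score_reported_as_nan(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.random((5, 10)),
                            index=[f"g{i}" for i in range(5)],
                            columns=[f"c{i}" for i in range(10)])
        expr.loc["g0"] = 2.0
        _, corr = score_pseudotime_correlation(expr, [ScorePanel("F", ("g0",))])
        assert np.isnan(corr["F"])

    def test_too_few_cells_is_an_error(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError):
            score_pseudotime_correlation(expr, [ScorePanel("P", ("g",))])
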