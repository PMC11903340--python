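"""Lasso CV, ISM, ensemble variant effects, and ASV concordance."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cresuite import (
    PWM,
    asv_concordance,
    fit_lasso_cv,
    ism,
    predict_variant_effect,
    scan_pwm,
    simulate_asv_table,
    simulate_features,
    truth_from_activities,
)
from cresuite.models import assign_folds, zscore_features
from sklearn.linear_model import Lasso


def feature_frame(rng, n, n_noise):
    idx = pd.Index([f"E{i}" for i in range(n)], name="element_id")
    x1 = rng.normal(0, 1, n)
    cols = {"x1": x1}
    for j in range(n_noise):
        cols[f"noise_{j}"] = rng.normal(0, 1, n)
    return pd.DataFrame(cols, index=idx), x1


class TestFitLassoCV:
    def test_sparse_recovery_noiseless(self):
        rng = np.random.default_rng(0)
        feats, x1 = feature_frame(rng, 500, 20)
        y = pd.Series(2.0 * zscore_features(feats)["x1"].to_numpy(), index=feats.index)
        fit = fit_lasso_cv(feats, y, seed=1)
        assert fit.coefficients["x1"] == pytest.approx(2.0, abs=0.05)
        noise_coefs = fit.coefficients.drop("x1")
        assert (noise_coefs.abs() < 0.01).all()
        assert np.nanmean(fit.per_fold_r) > 0.999

    def test_zero_response_returns_trivial_model(self):
        rng = np.random.default_rng(1)
        feats, _ = feature_frame(rng, 120, 5)
        y = pd.Series(0.0, index=feats.index)
        with pytest.warns(UserWarning):
            fit = fit_lasso_cv(feats, y)
        assert (fit.coefficients == 0).all()
        assert fit.per_fold_r.isna().all()

    def test_other_constant_response_is_an_error(self):
        rng = np.random.default_rng(2)
        feats, _ = feature_frame(rng, 120, 5)
        with pytest.raises(ValueError, match="constant"):
            fit_lasso_cv(feats, pd.Series(3.0, index=feats.index))

    def test_largest_lambda_zeroes_everything(self):
        rng = np.random.default_rng(3)
        feats, x1 = feature_frame(rng, 200, 10)
        y = pd.Series(x1 + rng.normal(0, 0.5, 200), index=feats.index)
        fit = fit_lasso_cv(feats, y, seed=0)
        lam_max = fit.cv_mse.index.max()
        x = zscore_features(feats).to_numpy()
        model = Lasso(alpha=lam_max, max_iter=50_000).fit(x, y.to_numpy())
        assert np.allclose(model.coef_, 0.0)

    def test_pure_noise_features_select_nothing(self):
        rng = np.random.default_rng(4)
        ids = [f"E{i}" for i in range(300)]
        truth = truth_from_activities(pd.Series(rng.normal(1, 1, 300), index=ids))
        feats = simulate_features(truth, n_features=30, n_informative=0, noise_sd=0.5, seed=5)
        fit = fit_lasso_cv(feats, truth.activity.iloc[:, 0], seed=6)
        assert (fit.coefficients.abs() < 0.05).all()

    def test_fold_assignment_is_stable_and_partitioning(self):
        ids = [f"E{i}" for i in range(400)]
        f1 = assign_folds(ids, 10, seed=7)
        f2 = assign_folds(list(reversed(ids)), 10, seed=7)
        assert (f1 == f2.reindex(f1.index)).all()
        assert set(f1.unique()) <= set(range(10))
        # reasonably balanced
        assert f1.value_counts().max() - f1.value_counts().min() < 40

    def test_simulated_features_in_expected_performance_band(self):
        """Mean held-out r for 5/50 informative features, noise_sd 0.5.

        Band fixed from 10 generator seeds of this configuration.
        """
        rs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            ids = [f"E{i}" for i in range(300)]
            truth = truth_from_activities(
                pd.Series(rng.uniform(-1, 3, 300), index=ids)
            )
            feats = simulate_features(truth, 50, 5, noise_sd=0.5, seed=seed)
            fit = fit_lasso_cv(feats, truth.activity.iloc[:, 0], seed=seed)
            rs.append(np.nanmean(fit.per_fold_r))
        assert 0.85 <= np.mean(rs) <= 1.0


def pwm_hit_scorer(pwms):
    def scorer(seq: str) -> float:
        return float(sum(scan_pwm(seq, p)["score"].sum() for p in pwms))

    return scorer


class TestISM:
    def test_delta_count_and_reference_omitted(self, pwms):
        seq = "ACGT" * 50  # 200 nt
        deltas = ism(lambda s: float(len(set(s))), seq)
        assert deltas.shape == (200, 5)  # ref column + one column per base
        n_deltas = deltas.drop(columns="ref").notna().to_numpy().sum()
        assert n_deltas == 600  # reference cells are absent (NaN)

    def test_antisymmetry(self, pwms):
        scorer = pwm_hit_scorer(pwms[:1])
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 40))
        deltas = ism(scorer, seq)
        pos, ref = 7, seq[7]
        alt = "A" if ref != "A" else "C"
        mutated = seq[:pos] + alt + seq[pos + 1 :]
        back = ism(scorer, mutated)
        assert back.loc[pos, ref] == pytest.approx(-deltas.loc[pos, alt], abs=1e-12)

    def test_pwm_scorer_deltas_match_analytic_log_odds(self, pwms):
        """Mutating inside a surviving hit shifts the score by the exact
        log-odds difference; positions outside any hit window give 0."""
        gata = pwms[1]
        seq = "C" * 20 + gata.consensus + "C" * 20
        scorer = pwm_hit_scorer([gata])
        deltas = ism(scorer, seq)
        lo = gata.log_odds()
        base_idx = {b: i for i, b in enumerate("ACGT")}
        pos_in_hit = 3  # third column of the motif
        ref = gata.consensus[pos_in_hit]
        for alt in "ACGT":
            if alt == ref:
                continue
            mutated = seq[: 20 + pos_in_hit] + alt + seq[20 + pos_in_hit + 1 :]
            still_hit = len(scan_pwm(mutated, gata)) == 1
            if still_hit:
                analytic = lo[pos_in_hit, base_idx[alt]] - lo[pos_in_hit, base_idx[ref]]
                # binned scoring quantizes each position to 1e-3 bits
                assert deltas.loc[20 + pos_in_hit, alt] == pytest.approx(
                    analytic, abs=1e-3
                )
        # a position far from the motif cannot change anything
        assert deltas.loc[2].drop("ref").abs().max() == 0.0


class TestPredictVariantEffect:
    def test_identical_nonzero_deltas_flagged(self):
        scorers = [lambda s: float(len(s))] * 3
        with pytest.warns(UserWarning, match="degenerate"):
            mean, p, _ = predict_variant_effect(scorers, "ACGT", "ACGTA")
        assert mean == 1.0 and p == 0.0

    def test_all_zero_deltas_give_p_one(self):
        scorers = [lambda s: 1.0, lambda s: 2.0]
        mean, p, _ = predict_variant_effect(scorers, "ACGT", "ACGA")
        assert mean == 0.0 and p == 1.0

    def test_symmetric_deltas_not_significant(self):
        vals = iter([0.0, 0.5, 0.0, -0.5])
        scorers = [lambda s, v=v: {"ACGT": 0.0, "ACGA": v}[s] for v in (0.5, -0.5)]
        mean, p, _ = predict_variant_effect(scorers, "ACGT", "ACGA")
        assert mean == 0.0 and p == pytest.approx(1.0)

    def test_strong_consistent_deltas_highly_significant(self):
        rng = np.random.default_rng(8)
        deltas = rng.normal(0.5, 0.1, 9)
        scorers = [lambda s, d=d: d if s == "alt" else 0.0 for d in deltas]
        mean, p, got = predict_variant_effect(scorers, "ref", "alt")
        # closed-form t statistic
        t = deltas.mean() / (deltas.std(ddof=1) / math.sqrt(9))
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=8), rel=1e-9)
        assert p < 0.001


def fisher_two_sided_oracle(table):
    """Exact two-sided Fisher p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestASVConcordance:
    @staticmethod
    def tables_from_counts(n_pp, n_pm, n_mp, n_mm):
        rows = (
            [(1.0, 1.0)] * n_pp + [(1.0, -1.0)] * n_pm
            + [(-1.0, 1.0)] * n_mp + [(-1.0, -1.0)] * n_mm
        )
        variants = [f"v{i}" for i in range(len(rows))]
        pred = pd.DataFrame(
            {
                "variant": variants,
                "delta": [r[0] for r in rows],
                "uncertainty_p": 0.01,
            }
        )
        obs = pd.DataFrame(
            {
                "variant": variants,
                "observed_effect": [r[1] for r in rows],
                "fdr": 0.01,
            }
        )
        return pred, obs

    def test_or_nine_for_30_10_10_30(self):
        pred, obs = self.tables_from_counts(30, 10, 10, 30)
        res = asv_concordance(pred, obs)
        assert res.odds_ratio == pytest.approx(9.0)
        assert res.concordant == 60 and res.discordant == 20 and res.excluded == 0

    def test_fisher_p_matches_enumeration_oracle(self):
        from scipy import stats

        for cells in [(30, 10, 10, 30), (5, 2, 7, 11), (1, 9, 3, 12), (8, 8, 8, 8)]:
            pred, obs = self.tables_from_counts(*cells)
            res = asv_concordance(pred, obs)
            oracle = fisher_two_sided_oracle(res.table)
            assert res.fisher_p == pytest.approx(oracle, rel=1e-6)

    def test_exclusion_rules_and_conservation(self):
        pred, obs = self.tables_from_counts(10, 5, 5, 10)
        pred.loc[:4, "uncertainty_p"] = 0.5  # too uncertain
        obs.loc[25:27, "fdr"] = 0.2  # not significant
        res = asv_concordance(pred, obs)
        assert res.excluded == 8
        assert res.concordant + res.discordant + res.excluded == 30

    def test_perfect_concordance_is_degenerate_flagged(self):
        pred_effects = pd.Series(
            np.linspace(-1, 1, 60), index=[f"v{i}" for i in range(60)]
        )
        observed = simulate_asv_table(pred_effects, error_rate=0.0, seed=1)
        pred = pd.DataFrame(
            {
                "variant": pred_effects.index,
                "delta": pred_effects.to_numpy(),
                "uncertainty_p": 0.01,
            }
        )
        res = asv_concordance(pred, observed)
        assert res.discordant == 0
        assert res.degenerate and np.isinf(res.odds_ratio)

    def test_error_rate_half_gives_or_near_one(self):
        rng = np.random.default_rng(3)
        pred_effects = pd.Series(
            rng.normal(0, 1, 2000), index=[f"v{i}" for i in range(2000)]
        )
        observed = simulate_asv_table(pred_effects, error_rate=0.5, seed=3)
        pred = pd.DataFrame(
            {
                "variant": pred_effects.index,
                "delta": pred_effects.to_numpy(),
                "uncertainty_p": 0.01,
            }
        )
        res = asv_concordance(pred, observed)
        assert 0.7 < res.odds_ratio < 1.4

    def test_error_rate_point_two_recovers_or_sixteen(self):
        """sign-flip rate e gives OR -> ((1-e)/e)^2 = 16 at e = 0.2."""
        ors = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pred_effects = pd.Series(
                rng.normal(0, 1, 400), index=[f"v{i}" for i in range(400)]
            )
            observed = simulate_asv_table(pred_effects, error_rate=0.2, seed=seed)
            pred = pd.DataFrame(
                {
                    "variant": pred_effects.index,
                    "delta": pred_effects.to_numpy(),
                    "uncertainty_p": 0.01,
                }
            )
            ors.append(asv_concordance(pred, observed).odds_ratio)
        assert 10 < np.median(ors) < 26  # Monte-Carlo CI around 16
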