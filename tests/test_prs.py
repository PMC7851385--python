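"""Polygenic scoring, Nagelkerke pseudo-R² and top-percentile odds ratios."""

import numpy as np
import pandas as pd
import pytest

from rarescreen.prs import (
    PRSWeight,
    compute_prs,
    fit_status_on_score,
    nagelkerke_r2,
    top_percentile_or,
)


def _weights(entries):
    return [PRSWeight(s, "A", b, p) for s, b, p in entries]


class TestComputePRS:
    def test_single_snp_score(self):
        dosages = pd.DataFrame({"rs1": [2.0]}, index=["s1"])
        res = compute_prs(dosages, _weights([("rs1", 0.1, 0.01)]), 0.05)
        assert res[0].score == pytest.approx(0.2)
        assert res[0].n_snps_used == 1

    def test_zero_betas_zero_scores(self):
        dosages = pd.DataFrame({"rs1": [1.0], "rs2": [2.0]}, index=["s1"])
        res = compute_prs(
            dosages, _weights([("rs1", 0.0, 0.01), ("rs2", 0.0, 0.01)]), 0.05
        )
        assert res[0].score == 0.0

    def test_training_p_threshold_excludes_snps(self):
        dosages = pd.DataFrame({"rs1": [2.0], "rs2": [2.0]}, index=["s1"])
        res = compute_prs(
            dosages, _weights([("rs1", 0.1, 0.01), ("rs2", 5.0, 0.2)]), 0.05
        )
        assert res[0].score == pytest.approx(0.2)
        assert res[0].n_snps_used == 1  # rs2 excluded by P_T

    def test_missing_dosage_contributes_zero_and_uncounted(self):
        dosages = pd.DataFrame(
            {"rs1": [2.0, np.nan], "rs2": [1.0, 1.0]}, index=["a", "b"]
        )
        res = compute_prs(
            dosages, _weights([("rs1", 0.5, 0.01), ("rs2", 0.5, 0.01)]), 0.05
        )
        by = {r.sample_id: r for r in res}
        assert by["b"].score == pytest.approx(0.5)
        assert by["b"].n_snps_used == 1

    def test_dosage_out_of_range_rejected(self):
        dosages = pd.DataFrame({"rs1": [2.5]}, index=["s1"])
        with pytest.raises(ValueError):
            compute_prs(dosages, _weights([("rs1", 0.1, 0.01)]), 0.05)

    def test_linearity_in_betas(self):
        rng = np.random.default_rng(0)
        dosages = pd.DataFrame(
            rng.integers(0, 3, size=(5, 4)).astype(float),
            index=list("abcde"), columns=[f"rs{i}" for i in range(4)],
        )
        betas = rng.normal(0, 1, 4)
        w1 = [PRSWeight(f"rs{i}", "A", betas[i], 0.01) for i in range(4)]
        w3 = [PRSWeight(f"rs{i}", "A", 3 * betas[i], 0.01) for i in range(4)]
        s1 = np.array([r.score for r in compute_prs(dosages, w1, 0.05)])
        s3 = np.array([r.score for r in compute_prs(dosages, w3, 0.05)])
        assert s3 == pytest.approx(3 * s1)


def _newton_logistic_loglik(x, y, with_slope=True):
    """Independent Newton–Raphson logistic fit; returns the log-likelihood."""
    X = np.column_stack([np.ones_like(x), x]) if with_slope else np.ones((len(x), 1))
    beta = np.zeros(X.shape[1])
    for _ in range(50):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = (X * W[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    eta = X @ beta
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


class TestNagelkerke:
    def test_null_fit_gives_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 200) == 0.0

    def test_perfect_separation_limit_gives_one(self):
        n = 100
        ll_null = n * np.log(0.5)
        assert nagelkerke_r2(ll_null, 0.0, n) == pytest.approx(1.0)

    def test_matches_independent_newton_solver_on_synthetic_data(self):
        rng = np.random.default_rng(42)
        n = 500
        x = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
        y = (rng.random(n) < p).astype(float)
        ll_null, ll_full, n_fit = fit_status_on_score(x, y)
        oracle_full = _newton_logistic_loglik(x, y, with_slope=True)
        oracle_null = _newton_logistic_loglik(x, y, with_slope=False)
        assert ll_full == pytest.approx(oracle_full, abs=1e-6)
        assert ll_null == pytest.approx(oracle_null, abs=1e-6)
        r2 = nagelkerke_r2(ll_null, ll_full, n_fit)
        r2_oracle = nagelkerke_r2(oracle_null, oracle_full, n)
        assert r2 == pytest.approx(r2_oracle, abs=1e-6)
        assert 0.0 < r2 < 1.0

    def test_monotone_in_full_likelihood(self):
        r_lo = nagelkerke_r2(-100.0, -90.0, 100)
        r_hi = nagelkerke_r2(-100.0, -50.0, 100)
        assert r_hi > r_lo


class TestTopPercentileOR:
    def test_constructed_table_cross_product(self):
        # counts (16, 8, 243, 217): OR = (16*217)/(8*243)
        rng = np.random.default_rng(1)
        scores = np.concatenate([
            rng.uniform(1, 2, 16), rng.uniform(1, 2, 8),      # top stratum
            rng.uniform(-1, 0, 243), rng.uniform(-1, 0, 217),  # remainder
        ])
        labels = np.concatenate([
            np.ones(16), np.zeros(8), np.ones(243), np.zeros(217)
        ]).astype(int)
        cut = (16 + 8) / len(scores)
        ev = top_percentile_or(scores, labels, percentile_cut=cut)
        assert ev.odds_ratio == pytest.approx((16 * 217) / (8 * 243), rel=1e-6)
        assert ev.or_ci[0] < ev.odds_ratio < ev.or_ci[1]

    def test_null_calibration_or_near_one(self):
        """Cases and controls from one score distribution: OR within
        [0.6, 1.67] in >= 95% of seeded replicates."""
        rng = np.random.default_rng(7)
        inside = 0
        reps = 200
        for _ in range(reps):
            scores = rng.normal(0, 1, 2000)
            labels = np.concatenate([np.ones(1000), np.zeros(1000)]).astype(int)
            ev = top_percentile_or(scores, labels, percentile_cut=0.20)
            inside += 0.6 <= ev.odds_ratio <= 1.67
        assert inside / reps >= 0.95

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            top_percentile_or([1.0] * 10, [0, 1] * 5, percentile_cut=0.2)

    def test_everyone_in_top_stratum_rejected(self):
        scores = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            top_percentile_or(scores, [0, 1] * 5, percentile_cut=0.999999)


class TestParameterRecovery:
    def test_case_control_score_shift_recovers_simulated_effect(self, default_cohort):
        """The simulator's PRS enrichment is recovered from the scored cohort
        within three standard errors."""
        from rarescreen.prs import PRSWeight, compute_prs

        fixtures, _ = default_cohort
        weights = [
            PRSWeight(str(r.snp_id), str(r.effect_allele), float(r.beta),
                      float(r.p_train))
            for r in fixtures.prs_weights.itertuples(index=False)
        ]
        res = compute_prs(fixtures.prs_dosages, weights, 0.05)
        scores = pd.Series({r.sample_id: r.score for r in res})
        is_case = fixtures.phenotypes.set_index("sample_id")["is_case"]
        case_scores = scores[is_case.reindex(scores.index)]
        ctrl_scores = scores[~is_case.reindex(scores.index)]
        diff = case_scores.mean() - ctrl_scores.mean()
        se = np.sqrt(
            case_scores.var() / len(case_scores)
            + ctrl_scores.var() / len(ctrl_scores)
        )
        assert abs(diff - 0.5) < 3 * se  # default simulated shift is 0.5
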