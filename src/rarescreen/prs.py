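"""Additive polygenic-score computation and case/control evaluation.

A polygenic risk score (PRS) is the sum of log-odds weights times allele
dosages over SNPs whose training-GWAS association p-value passes the
threshold P_T.  Discrimination between cases and controls is summarised
by Nagelkerke's pseudo-R² from a logistic regression of status on score,
and by the odds ratio of case status in the top score percentile versus
the remainder (Woolf log-interval CI, Haldane–Anscombe correction for
empty cells).

Weights are assumed pre-clumped (no linkage-disequilibrium handling
here) and dosages precisely genotyped, so no imputation-quality terms
appear anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, sqrt
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PRSWeight",
    "PRSResult",
    "PRSEvaluation",
    "compute_prs",
    "nagelkerke_r2",
    "fit_status_on_score",
    "top_percentile_or",
    "evaluate_prs",
]


@dataclass(frozen=True)
class PRSWeight:
    snp_id: str
    effect_allele: str
    beta: float
    p_train: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_train <= 1.0):
            raise ValueError(f"p_train must be in (0, 1], got {self.p_train}")


@dataclass(frozen=True)
class PRSResult:
    sample_id: str
    score: float
    n_snps_used: int


@dataclass(frozen=True)
class PRSEvaluation:
    p_threshold: float
    nagelkerke_r2: float
    percentile_cut: float
    odds_ratio: float
    or_ci: tuple[float, float]
    n_top_cases: int
    n_top_controls: int


def compute_prs(
    dosages: pd.DataFrame,
    weights: Sequence[PRSWeight],
    p_threshold: float = 0.05,
) -> list[PRSResult]:
    """Score every sample: sum of beta x dosage over SNPs with p_train <= P_T.

    ``dosages`` is a samples-by-SNPs frame of effect-allele dosages in
    [0, 2]; NaN marks a SNP unobserved in that sample — it contributes 0
    and is excluded from ``n_snps_used``.
    """
    vals = dosages.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ValueError("allele dosages must lie in [0, 2]")

    selected = [w for w in weights if w.p_train <= p_threshold]
    sel_ids = [w.snp_id for w in selected if w.snp_id in dosages.columns]
    betas = pd.Series(
        {w.snp_id: w.beta for w in selected if w.snp_id in dosages.columns}
    )
    sub = dosages[sel_ids]
    observed = sub.notna()
    scores = sub.fillna(0.0).to_numpy() @ betas[sel_ids].to_numpy()
    n_used = observed.sum(axis=1).to_numpy()
    return [
        PRSResult(sample_id=str(s), score=float(sc), n_snps_used=int(k))
        for s, sc, k in zip(dosages.index, scores, n_used)
    ]


def nagelkerke_r2(loglik_null: float, loglik_full: float, n: int) -> float:
    """Nagelkerke's pseudo-R²: Cox–Snell R² rescaled to a [0, 1] maximum.

    R²_CS = 1 − exp(2(ll_null − ll_full)/n), divided by its attainable
    maximum 1 − exp(2·ll_null/n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_full < loglik_null - 1e-9:
        raise ValueError("loglik_full must be >= loglik_null")
    r2_cs = 1.0 - exp(2.0 * (loglik_null - loglik_full) / n)
    max_cs = 1.0 - exp(2.0 * loglik_null / n)
    if max_cs == 0.0:
        return 0.0
    return float(min(1.0, r2_cs / max_cs))


def fit_status_on_score(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, int]:
    """Logistic fit of case status on PRS; returns (ll_null, ll_full, n).

    Any maximiser of the binomial likelihood is acceptable; the pseudo-R²
    consumes only the two log-likelihoods.
    """
    y = np.asarray(labels, dtype=float)
    x = sm.add_constant(np.asarray(scores, dtype=float))
    fit = sm.Logit(y, x).fit(disp=0)
    return float(fit.llnull), float(fit.llf), int(y.size)


def top_percentile_or(
    scores: Sequence[float],
    labels: Sequence[int],
    percentile_cut: float = 0.20,
    p_threshold: float = 0.05,
) -> PRSEvaluation:
    """Odds ratio of case status in the top score stratum vs the remainder.

    The pooled score distribution is cut at its (1 − percentile_cut)
    quantile; OR = (case_top·control_rest)/(case_rest·control_top), with
    a Haldane–Anscombe 0.5 added to every cell when any cell is zero,
    and a 95% Woolf log-scale interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if not (0.0 < percentile_cut < 1.0):
        raise ValueError("percentile_cut must lie strictly in (0, 1)")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate score distribution (all scores identical)")
    if round(percentile_cut * scores.size) >= scores.size:
        raise ValueError("percentile cut leaves no remainder stratum")
    cut = np.quantile(scores, 1.0 - percentile_cut)
    top = scores > cut
    if not top.any() or top.all():
        raise ValueError("percentile cut leaves an empty stratum")
    a = int(((labels == 1) & top).sum())  # cases, top
    b = int(((labels == 0) & top).sum())  # controls, top
    c = int(((labels == 1) & ~top).sum())  # cases, rest
    d = int(((labels == 0) & ~top).sum())  # controls, rest
    af, bf, cf, df = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if 0 in (a, b, c, d) else (a, b, c, d)
    )
    odds_ratio = (af * df) / (bf * cf)
    se = sqrt(1 / af + 1 / bf + 1 / cf + 1 / df)
    z = stats.norm.ppf(0.975)
    ci = (odds_ratio * exp(-z * se), odds_ratio * exp(z * se))
    ll_null, ll_full, n = fit_status_on_score(scores, labels)
    return PRSEvaluation(
        p_threshold=p_threshold,
        nagelkerke_r2=nagelkerke_r2(ll_null, ll_full, n),
        percentile_cut=percentile_cut,
        odds_ratio=float(odds_ratio),
        or_ci=(float(ci[0]), float(ci[1])),
        n_top_cases=a,
        n_top_controls=b,
    )


def evaluate_prs(
    dosages: pd.DataFrame,
    weights: Sequence[PRSWeight],
    labels: pd.Series,
    p_threshold: float = 0.05,
    percentile_cut: float = 0.20,
) -> tuple[pd.DataFrame, PRSEvaluation]:
    """Score a cohort and evaluate case/control discrimination end to end."""
    results = compute_prs(dosages, weights, p_threshold)
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "score": [r.score for r in results],
            "n_snps_used": [r.n_snps_used for r in results],
        }
    ).set_index("sample_id")
    aligned = labels.reindex(frame.index)
    if aligned.isna().any():
        raise ValueError("labels missing for some scored samples")
    evaluation = top_percentile_or(
        frame["score"].to_numpy(),
        aligned.to_numpy(dtype=int),
        percentile_cut=percentile_cut,
        p_threshold=p_threshold,
    )
    return frame.reset_index(), evaluation
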