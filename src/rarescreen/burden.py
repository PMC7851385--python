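"""Gene-level recurrence testing and cohort/subgroup burden statistics.

The recurrence test asks, for each LoF-intolerant gene, whether the
number of cohort members carrying a qualifying ultra-rare LoF variant
exceeds expectation: ``k`` carriers among ``n`` individuals are compared
to a Binomial(n, null_rate) upper tail.  The per-gene null carrier rate
is supplied as data (a simple coding-length-proportional estimator is
provided as a helper); multiple testing across the ``m`` screened genes
is controlled by Benjamini–Hochberg step-up FDR.

Also here: the classical two-group comparisons used for cohort
subgroup contrasts — Fisher's exact test on carrier counts, the
Wilcoxon/Mann–Whitney rank-sum test on per-individual burdens (with an
exact enumeration null for small samples), and bootstrap/permutation
summaries of clinically-relevant variant burden per phenotype subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneRecurrenceResult",
    "GroupBurdenSummary",
    "binomial_recurrence_test",
    "bh_adjust",
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "recurrence_table",
    "lengthwise_null_rates",
    "group_burden_summary",
]

EXACT_ENUMERATION_MAX_N = 12


def binomial_recurrence_test(k: int, n: int, null_rate: float) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, null_rate).

    Computed with the numerically stable binomial survival function, so
    tail probabilities far below machine-epsilon-of-1 are exact.
    """
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= null_rate <= 1.0):
        raise ValueError(f"null_rate={null_rate} outside [0, 1]")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, null_rate))


def bh_adjust(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values against ``m`` tests.

    ``m`` may exceed ``len(pvalues)`` — the usual case when only the top
    of a genome-wide screen is tabulated; it defaults to ``len(pvalues)``.
    adjusted_(i) = min_{j>=i} p_(j)·m/j, capped at 1, in the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values outside [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than number of tests ({p.size})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def fisher_exact_2x2(
    table: Sequence[Sequence[float]], sidedness: str = "two-sided"
) -> float:
    """Fisher's exact test on a 2x2 table of non-negative counts."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    return float(stats.fisher_exact(t, alternative=sidedness)[1])


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_rank_sum_p(
    x: np.ndarray, y: np.ndarray, sidedness: str
) -> float:
    """Exact rank-sum null by enumerating all assignments of pooled ranks.

    Ties handled with midranks; conditional on the observed tie pattern.
    """
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n, total = len(x), len(pooled)
    observed = ranks[:n].sum()
    sums = np.array(
        [ranks[list(idx)].sum() for idx in combinations(range(total), n)]
    )
    eps = 1e-9
    p_less = np.mean(sums <= observed + eps)  # x shifted down
    p_greater = np.mean(sums >= observed - eps)
    if sidedness == "less":
        return float(p_less)
    if sidedness == "greater":
        return float(p_greater)
    return float(min(1.0, 2.0 * min(p_less, p_greater)))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], sidedness: str = "two-sided"
) -> float:
    """Rank-sum (Mann–Whitney) test of location shift between two groups.

    Exact enumeration of the null when n_x + n_y <= 12, otherwise the
    normal approximation with tie correction.  ``sidedness='less'``
    tests the alternative that ``x`` is stochastically smaller than ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if sidedness not in {"two-sided", "less", "greater"}:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if x.size + y.size <= EXACT_ENUMERATION_MAX_N:
        return _exact_rank_sum_p(x, y, sidedness)
    return float(
        stats.mannwhitneyu(x, y, alternative=sidedness, method="asymptotic")[1]
    )


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], sidedness: str = "two-sided"
) -> float:
    """Paired signed-rank test (provided for paired designs only)."""
    return float(stats.wilcoxon(x, y, alternative=sidedness)[1])


@dataclass(frozen=True)
class GeneRecurrenceResult:
    gene_symbol: str
    k_carriers: int
    n: int
    null_rate: float
    p_binomial: float
    fdr: float
    rank: int


def lengthwise_null_rates(
    genes: pd.DataFrame,
    total_qualifying_carriers: int,
    n: int,
) -> pd.Series:
    """Helper per-gene null carrier rates, proportional to coding length.

    rate_g = total_qualifying_carriers * (len_g / total_len) / n — i.e.
    qualifying variation scattered over the screened gene set in
    proportion to coding length.  ``genes`` needs columns ``symbol`` and
    ``coding_length_kb``.  This is a convenience estimator; any
    externally derived per-gene rates can be passed instead.
    """
    lengths = genes.set_index("symbol")["coding_length_kb"].astype(float)
    rates = total_qualifying_carriers * (lengths / lengths.sum()) / n
    return rates.clip(upper=1.0)


def recurrence_table(
    carrier_counts: pd.Series | dict,
    n: int,
    null_rates: pd.Series | dict,
    m: int,
) -> pd.DataFrame:
    """Gene-level recurrence tests with BH FDR across ``m`` screened genes.

    Parameters
    ----------
    carrier_counts
        distinct qualifying-variant carriers per gene symbol.
    n
        cohort size.
    null_rates
        per-gene null carrier probability (input data; see
        :func:`lengthwise_null_rates` for a helper).
    m
        number of genes screened genome-wide (the FDR denominator may far
        exceed the number of tabulated genes).
    """
    counts = pd.Series(carrier_counts, dtype=int)
    rates = pd.Series(null_rates, dtype=float)
    missing = counts.index.difference(rates.index)
    if len(missing):
        raise ValueError(f"null rate missing for genes: {list(missing)[:5]}")
    p = np.array(
        [
            binomial_recurrence_test(int(counts[g]), n, float(rates[g]))
            for g in counts.index
        ]
    )
    fdr = bh_adjust(p, m=m)
    out = pd.DataFrame(
        {
            "gene_symbol": counts.index,
            "k_carriers": counts.values,
            "n": n,
            "null_rate": rates[counts.index].values,
            "p_binomial": p,
            "fdr": fdr,
        }
    ).sort_values("p_binomial", kind="stable", ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass(frozen=True)
class GroupBurdenSummary:
    group: str
    n: int
    mean_burden: float
    ci_low: float
    ci_high: float
    p_vs_complement: float


def _permutation_mean_diff_p(
    burdens: np.ndarray, in_group: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Two-sided permutation p for the group-vs-complement mean difference."""
    n_in = int(in_group.sum())
    if n_in == 0 or n_in == burdens.size:
        return 1.0
    observed = burdens[in_group].mean() - burdens[~in_group].mean()
    if np.ptp(burdens) == 0:
        return 1.0
    idx = np.argsort(rng.random((n_perm, burdens.size)), axis=1)[:, :n_in]
    perm_in = burdens[idx].mean(axis=1)
    total = burdens.sum()
    perm_out = (total - burdens[idx].sum(axis=1)) / (burdens.size - n_in)
    diffs = perm_in - perm_out
    extreme = np.abs(diffs) >= abs(observed) - 1e-12
    return float((extreme.sum() + 1) / (n_perm + 1))


def group_burden_summary(
    burdens: Sequence[float],
    groups: Sequence[str],
    n_boot: int = 2000,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> list[GroupBurdenSummary]:
    """Per-group mean clinically-relevant variant burden with uncertainty.

    For each group label: the mean per-individual burden, a percentile
    bootstrap 95% CI of that mean, and a two-sided permutation p-value
    for the mean difference against the complement of the group.
    """
    burdens = np.asarray(burdens, dtype=float)
    groups = np.asarray(groups)
    if burdens.size != groups.size:
        raise ValueError("burdens and groups must align")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000 for stable percentile CIs")
    rng = np.random.default_rng(seed)
    out = []
    for label in pd.unique(groups):
        mask = groups == label
        vals = burdens[mask]
        if vals.size == 0:
            raise ValueError(f"group {label!r} is empty")
        boot_idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
        boot_means = vals[boot_idx].mean(axis=1)
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
        mean = float(vals.mean())
        lo, hi = min(lo, mean), max(hi, mean)
        p = _permutation_mean_diff_p(burdens, mask, n_perm, rng)
        out.append(
            GroupBurdenSummary(
                group=str(label),
                n=int(vals.size),
                mean_burden=mean,
                ci_low=float(lo),
                ci_high=float(hi),
                p_vs_complement=p,
            )
        )
    return out
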