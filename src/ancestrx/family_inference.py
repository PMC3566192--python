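"""Family-wise summaries of model-fit p-values.

Given the p-values from a family of drug-outcome regressions, this module
quantifies systematic departure from the global null: the inflation factor
lambda (ratio of the median observed chi-square-1 test statistic to its null
median), QQ coordinates with pointwise 95% confidence bands, a one-sample
Wilcoxon signed-rank test that the median p-value sits below 0.5,
Benjamini-Hochberg and Storey q-values, and one-sample chi-square tests of
the proportion of significant results against a null proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "FamilySummary",
    "lambda_inflation",
    "qq_with_ci",
    "wilcoxon_median_test",
    "fdr_qvalues",
    "proportion_chisq",
    "summarize_family",
]

#: Median of the chi-square distribution with 1 df.
CHI2_1_MEDIAN: float = float(stats.chi2.ppf(0.5, 1))  # 0.454936...


@dataclass
class FamilySummary:
    """All family-level statistics for one set of model-fit p-values."""

    m: int
    lambda_: float
    qq: pd.DataFrame = field(repr=False)
    wilcoxon_v: float
    wilcoxon_p: float
    qvalues: pd.DataFrame = field(repr=False)
    proportion_tests: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "lambda": self.lambda_,
            "wilcoxon": {"V": self.wilcoxon_v, "p": self.wilcoxon_p},
            "proportion_tests": self.proportion_tests,
        }


def _clean_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-D array of p-values")
    if np.isnan(p).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p <= 0).any():
        tiny = np.finfo(float).tiny
        logger.warning(
            "%d non-positive p-values clamped to %g", int((p <= 0).sum()), tiny
        )
        p = np.where(p <= 0, tiny, p)
    return p


def lambda_inflation(pvalues) -> float:
    """Genomic-inflation-style lambda for a family of p-values.

    Each p is mapped back to a chi-square-1 statistic via the upper-tail
    quantile; lambda is the ratio of the median of those statistics to the
    null chi-square-1 median (~0.4549).  Under a true global null lambda is
    1; lambda > 1 means the family's tests are systematically larger than
    chance.  Working on the chi-square scale makes medians comparable across
    families whose F statistics carry heterogeneous degrees of freedom.
    """
    p = _clean_pvalues(pvalues)
    q = stats.chi2.isf(p, 1)
    return float(np.median(q) / CHI2_1_MEDIAN)


def qq_with_ci(pvalues) -> pd.DataFrame:
    """QQ-plot coordinates with pointwise 95% bands, on the -log10 scale.

    Rank-i expected p is i/(m+1); the band comes from the Beta(i, m-i+1)
    distribution of the i-th uniform order statistic (quantiles 0.025 and
    0.975).  Columns: expected, observed, lower, upper.
    """
    p = np.sort(_clean_pvalues(pvalues))
    m = p.size
    ranks = np.arange(1, m + 1)
    expected = ranks / (m + 1.0)
    lower = stats.beta.ppf(0.025, ranks, m - ranks + 1)
    upper = stats.beta.ppf(0.975, ranks, m - ranks + 1)
    return pd.DataFrame(
        {
            "rank": ranks,
            "expected": -np.log10(expected),
            "observed": -np.log10(p),
            # band on -log10 scale: small p bound is the *upper* -log10 value
            "lower": -np.log10(upper),
            "upper": -np.log10(lower),
        }
    )


def wilcoxon_median_test(
    pvalues, null_median: float = 0.5, log10_scale: bool = False
) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test of the family's median p-value.

    Tests whether observed p-values sit systematically below ``null_median``
    (one-sided).  V is the sum of ranks of positive deviations
    ``null_median - p_i``.  Exact distribution for m <= 25 without ties;
    normal approximation with tie correction otherwise.  With
    ``log10_scale`` the deviations are computed between -log10 p and
    -log10(null_median) instead; the ranks, and hence the test, differ only
    when ties interact with the monotone transform.
    """
    p = _clean_pvalues(pvalues)
    if p.size < 5:
        raise ValueError("need at least 5 p-values for the signed-rank test")
    if log10_scale:
        d = (-np.log10(p)) - (-np.log10(null_median))
    else:
        d = null_median - p
    if np.all(d == 0):
        logger.warning("all deviations from the null median are zero")
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(d[d != 0]))) < np.count_nonzero(d)
    method = "exact" if (p.size <= 25 and not has_ties and np.all(d != 0)) else "approx"
    res = stats.wilcoxon(d, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def fdr_qvalues(pvalues, method: str = "bh", storey_lambda: float = 0.5) -> np.ndarray:
    """Benjamini-Hochberg or Storey q-values, in input order.

    BH: step-up ``q_(i) = min_{j>=i} m p_(j) / j``.  Storey: the BH q-values
    scaled by the null-proportion estimate
    ``pi0 = #{p > lambda_s} / (m (1 - lambda_s))`` (capped at 1), with
    lambda_s fixed at 0.5.  Storey q-values are therefore never larger than
    BH q-values.
    """
    p = _clean_pvalues(pvalues)
    _, bh, _, _ = multipletests(p, method="fdr_bh")
    if method.lower() == "bh":
        return bh
    if method.lower() == "storey":
        pi0 = min((p > storey_lambda).sum() / (p.size * (1.0 - storey_lambda)), 1.0)
        return np.minimum(pi0 * bh, 1.0)
    raise ValueError(f"unknown FDR method {method!r}; use 'bh' or 'storey'")


def proportion_chisq(x: int, n: int, p0: float) -> tuple[float, float]:
    """One-sample chi-square test that a proportion exceeds ``p0``.

    ``z = (x/n - p0) / sqrt(p0 (1-p0) / n)`` without continuity correction;
    the statistic is z^2 and the p-value is the one-sided (greater) normal
    tail.  Used to ask whether the number of significant marginal effects in
    a family exceeds the count expected by chance.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    z = (x / n - p0) / np.sqrt(p0 * (1.0 - p0) / n)
    return float(z * z), float(stats.norm.sf(z))


def summarize_family(
    pvalues,
    null_prop: float = 0.05,
    alpha: float = 0.05,
) -> FamilySummary:
    """Bundle lambda, QQ, Wilcoxon, q-values and the proportion test."""
    p = _clean_pvalues(pvalues)
    qframe = pd.DataFrame(
        {
            "p": p,
            "q_bh": fdr_qvalues(p, "bh"),
            "q_storey": fdr_qvalues(p, "storey"),
        }
    )
    if p.size >= 5:
        v, wp = wilcoxon_median_test(p)
    else:
        logger.warning("family of %d tests: signed-rank test skipped", p.size)
        v, wp = float("nan"), float("nan")
    x = int((p < alpha).sum())
    chi2, prop_p = proportion_chisq(x, p.size, null_prop)
    return FamilySummary(
        m=int(p.size),
        lambda_=lambda_inflation(p),
        qq=qq_with_ci(p),
        wilcoxon_v=v,
        wilcoxon_p=wp,
        qvalues=qframe,
        proportion_tests=[
            {
                "x": x,
                "n": int(p.size),
                "p0": null_prop,
                "chi2": chi2,
                "p_one_sided": prop_p,
            }
        ],
    )
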