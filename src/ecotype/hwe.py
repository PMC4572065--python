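"""Exact Hardy-Weinberg heterozygote-excess test.

The conditional distribution of the heterozygote count h given the sample
size n and the allele counts (nA, nB = 2n - nA) under random union of
gametes is

    P(h | n, nA) = n! / (n_AA! h! n_BB!) * 2**h * nA! nB! / (2n)!

with n_AA = (nA - h)/2 and n_BB = (nB - h)/2, so admissible h share the
parity of nA and run up to min(nA, nB).  The one-sided excess probability
is the upper tail P(H >= h_obs).  This is the exact test used to flag
array markers whose apparent heterozygosity is too high to be credible,
a classic signature of paralogous or badly clustered probes.
"""
from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .errors import MonomorphicMarkerError

__all__ = [
    "het_count_distribution",
    "het_excess_probability",
    "fisher_combine",
]


def _admissible_h(n_a: int, n_b: int) -> np.ndarray:
    lo = n_a % 2
    hi = min(n_a, n_b)
    return np.arange(lo, hi + 1, 2)


def het_count_distribution(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of the heterozygote count given n individuals and nA alleles.

    Returns ``(h_values, probabilities)``; the probabilities sum to 1.
    """
    if n < 1:
        raise ValueError("need at least one individual")
    n_b = 2 * n - n_a
    if n_a <= 0 or n_b <= 0:
        raise MonomorphicMarkerError(
            f"both alleles must be observed (nA={n_a}, nB={n_b})"
        )
    h = _admissible_h(n_a, n_b)
    n_aa = (n_a - h) // 2
    n_bb = (n_b - h) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(h + 1)
        - gammaln(n_bb + 1)
        + h * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp)
    return h, p


def het_excess_probability(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-sided exact P of observing >= n_ab heterozygotes.

    Small values indicate heterozygote excess beyond Hardy-Weinberg
    expectation conditional on the observed allele counts.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    h, p = het_count_distribution(n, n_a)
    return float(p[h >= n_ab].sum())


def fisher_combine(pvalues: "np.ndarray | list[float]") -> float:
    """Fisher's method: X^2 = -2 sum(ln P) ~ chi-square with 2k df."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no P values to combine")
    # clip so a numerically-zero P does not give an infinite statistic
    stat = -2.0 * np.sum(np.log(np.clip(p, 1e-300, 1.0)))
    return float(chi2.sf(stat, df=2 * p.size))
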