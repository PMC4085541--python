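"""Frequentist step: four confirmatory tests, Stouffer combination, FDR.

Genes that pass the functional step are challenged with four one-sided
tests, each in the "more driver-like" direction: the higher-frequency test
(is the gene mutated above the rate of its own carrier patients?), the
non-synonymous/synonymous ratio test (is the non-silent fraction above the
gene's codon-structure expectation?), the tumor-specificity test (is the
carrier frequency above the pan-cancer background?), and the functional
impact test (are the gene's impact scores above its patients' average?).
The p-values are combined by weighted Stouffer and corrected by
Benjamini-Hochberg within each hypothesis family (TSG and OG separately).

All binomial tests are exact upper tails. Each test also exposes the
strict tail P(X > k), so a randomized probability-integral transform
``p_gt + U * (p_ge - p_gt)`` — exactly Uniform(0,1) when the null is
correct — can be used for calibration diagnostics on discrete statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "higher_frequency_test",
    "ns_ratio_test",
    "tumor_specificity_test",
    "functional_impact_test",
    "stouffer_combine",
    "bh_fdr",
    "randomized_pit",
]

P_CLIP = 1e-15


@dataclass(frozen=True)
class TestResult:
    """One-sided test outcome: inclusive tail ``p`` = P(X >= k) and strict
    tail ``p_strict`` = P(X > k) under the null."""

    p: float
    p_strict: float

    @property
    def mid(self) -> float:
        """Mid-p value (P(X > k) + P(X = k)/2): the standard correction for
        combining discrete one-sided tests, with mean ~0.5 under the null."""
        return 0.5 * (self.p + self.p_strict)

    def pit(self, u: float) -> float:
        """Randomized probability integral transform (uniform under H0)."""
        return randomized_pit(self.p, self.p_strict, u)


def randomized_pit(p_ge: float, p_gt: float, u: float) -> float:
    return float(p_gt + u * (p_ge - p_gt))


def _binom_tails(k: int, n: int, p: float) -> TestResult:
    return TestResult(
        p=float(stats.binom.sf(k - 1, n, p)),
        p_strict=float(stats.binom.sf(k, n, p)),
    )


def _carrier_truncated_null(carrier_totals: np.ndarray, p: float, need: int) -> np.ndarray:
    """Pmf of the number of *extra* in-gene mutations beyond one per carrier.

    Each carrier with m non-silent mutations contributes N ~ Binomial(m, p)
    conditioned on N >= 1; the null counts sum(N) - n_carriers. Per-carrier
    supports are truncated where the tail mass is negligible but always
    cover the observed count, then convolved.
    """
    pmf = np.array([1.0])
    for m in carrier_totals:
        m = int(m)
        if m <= 1:
            continue  # a single-mutation carrier can contribute no extras
        jmax = int(min(m - 1, max(need, stats.binom.ppf(1 - 1e-13, m, p) + 1)))
        j = np.arange(jmax + 1)
        part = stats.binom.pmf(j + 1, m, p)
        denom = 1.0 - (1.0 - p) ** m
        part = part / denom
        part[-1] += max(0.0, 1.0 - part.sum())  # park the truncated tail
        pmf = np.convolve(pmf, part)
    return pmf


def higher_frequency_test(
    k_gene: int,
    carrier_total: int,
    gene_length_bp: float,
    territory_bp: float,
    carrier_totals: np.ndarray | None = None,
) -> TestResult:
    """Is the gene's non-silent mutation rate above its carriers' exome rate?

    ``k_gene`` non-silent mutations fall in the gene out of
    ``carrier_total`` non-silent mutations carried by the patients mutated
    in the gene; under the null each lands in the gene with probability
    gene length / territory.

    With ``carrier_totals`` (per-carrier non-silent counts) the null
    conditions on the carrier definition — every carrier has at least one
    in-gene mutation — by convolving >=1-truncated binomials; this is the
    calibrated form used by the pipeline. Without it, the test is the plain
    binomial on (k_gene, carrier_total).
    """
    if gene_length_bp >= territory_bp:
        raise ValueError("gene coding length must be smaller than the territory")
    if gene_length_bp <= 0 or territory_bp <= 0:
        raise ValueError("lengths must be positive")
    p = gene_length_bp / territory_bp
    if carrier_totals is None:
        return _binom_tails(k_gene, carrier_total, p)
    carrier_totals = np.asarray(carrier_totals, dtype=int)
    c = len(carrier_totals)
    if k_gene < c:
        raise ValueError("k_gene cannot be below the number of carriers")
    extras = k_gene - c
    pmf = _carrier_truncated_null(carrier_totals, p, need=extras + 1)
    if extras >= len(pmf):
        return TestResult(p=0.0, p_strict=0.0)
    p_ge = float(pmf[extras:].sum())
    p_gt = float(pmf[extras + 1 :].sum())
    return TestResult(p=min(p_ge, 1.0), p_strict=min(p_gt, 1.0))


def ns_ratio_test(k_ns: int, n_total: int, p_ns: float) -> TestResult:
    """Is the non-silent count above the gene's codon-structure expectation?

    P(X >= k_ns) with X ~ Binomial(n_total, p_ns), where p_ns is the
    probability that a random substitution on the gene's codon composition
    is non-silent. The pipeline applies this to SNVs only (indels are
    non-silent with probability one and carry no information here).
    """
    if not 0 <= k_ns <= n_total:
        raise ValueError("need 0 <= k_ns <= n_total")
    if n_total == 0:
        return TestResult(p=1.0, p_strict=1.0)
    if not 0.0 <= p_ns <= 1.0:
        raise ValueError("p_ns must lie in [0,1]")
    return _binom_tails(k_ns, n_total, p_ns)


def tumor_specificity_test(
    n_carriers: int, cohort_size: int, background_frequency: float | None
) -> TestResult | None:
    """Is the carrier frequency above the pan-cancer background?

    Returns None (test absent) when the gene has no background entry.
    """
    if background_frequency is None:
        return None
    if not 0.0 <= background_frequency <= 1.0:
        raise ValueError("background frequency must lie in [0,1]")
    return _binom_tails(n_carriers, cohort_size, background_frequency)


def functional_impact_test(
    gene_fi: np.ndarray,
    pool_fi: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> TestResult | None:
    """Permutation test: is the gene's mean impact score above its patients'?

    The statistic is the mean FI of the gene's scored mutations; each null
    replicate redraws the same number of scores without replacement from
    the pooled scores of all mutations in the carrier patients.
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    gene_fi = np.asarray(gene_fi, dtype=float)
    pool_fi = np.asarray(pool_fi, dtype=float)
    m = len(gene_fi)
    if m == 0:
        return None
    if len(pool_fi) < m:
        logger.warning("FI pool smaller than the gene's scored mutations; test absent")
        return None
    observed = gene_fi.mean()
    rng = np.random.default_rng(seed)
    n_pool = len(pool_fi)
    ge = gt = 0
    chunk = max(1, int(2_000_000 / n_pool))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n_pool))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        null_means = pool_fi[idx].mean(axis=1)
        ge += int((null_means >= observed).sum())
        gt += int((null_means > observed).sum())
        done += b
    return TestResult(p=(1 + ge) / (1 + n_perm), p_strict=(1 + gt) / (1 + n_perm))


def stouffer_combine(
    pvalues: list[float | None],
    weights: list[float],
) -> float | None:
    """Weighted Stouffer combination of one-sided p-values.

    Absent tests (None) are dropped with their weights; with a single
    present test the combination is that test's p. Returns None when every
    test is absent (the gene cannot be called).
    Z = sum(w_i z_i) / sqrt(sum(w_i^2)), z_i = Phi^{-1}(1 - p_i).
    """
    if len(pvalues) != len(weights):
        raise ValueError("pvalues and weights must align")
    pairs = [(p, w) for p, w in zip(pvalues, weights) if p is not None and w > 0]
    if not pairs:
        return None
    p = np.clip([pv for pv, _ in pairs], P_CLIP, 1.0 - P_CLIP)
    w = np.asarray([wt for _, wt in pairs], dtype=float)
    z = stats.norm.isf(p)
    Z = (w * z).sum() / np.sqrt((w**2).sum())
    return float(stats.norm.sf(Z))


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]
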