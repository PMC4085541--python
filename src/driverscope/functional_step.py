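"""Functional step: TSG-S and OG-S scores and their thresholds.

The tumor-suppressor score (TSG-S) asks whether a gene carries an excess of
truncating mutations relative to the truncating/total ratio of the patients
in which the gene is mutated: it is the -log10 upper tail of a binomial
with a patient-environment background ratio p0. The oncogene score (OG-S)
asks whether the gene's missense mutations (and in-frame indels) cluster on
the protein: it is the standardized entropy deficit of a Gaussian-smoothed
position density against a bootstrap null of uniformly placed mutations.

Thresholds for the two scores are calibrated by maximizing the Matthews
correlation coefficient against a labeled driver-gene set (appropriate for
the extremely unbalanced driver/non-driver classes), then rescaled for the
cohort's sample size and mutation rate, with a lower floor that the ``lax``
option removes for very small cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import matthews_corrcoef

from .maf_io import PatientProfile

__all__ = [
    "Thresholds",
    "BootstrapNull",
    "tsg_score",
    "background_trunc_ratio",
    "kernel_density",
    "shannon_entropy",
    "og_score",
    "default_bandwidth",
    "calibrate_thresholds",
    "rescale_thresholds",
]

P0_CLIP = 1e-4


@dataclass(frozen=True)
class Thresholds:
    """Base and cohort-effective score thresholds.

    ``tsg_base``/``og_base`` come from calibration (or package defaults);
    the effective values are base x g(cohort), clipped below at the floors
    (25% of base by default) unless ``lax``.
    """

    tsg_base: float
    og_base: float
    tsg_eff: float
    og_eff: float
    floor_tsg: float
    floor_og: float
    lax: bool = False


@dataclass(frozen=True)
class BootstrapNull:
    """Moments of the bootstrap null for one gene's entropy statistic."""

    n_reps: int
    seed: int
    mean: float
    sd: float


def tsg_score(k_trunc: int, n_total: int, p0: float) -> float:
    """TSG-S: -log10 P(X >= k_trunc), X ~ Binomial(n_total, p0).

    Upper tail is inclusive; k=0 gives tail 1 and score 0.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0,1), got {p0}")
    if not 0 <= k_trunc <= n_total or n_total < 1:
        raise ValueError("need 0 <= k_trunc <= n_total, n_total >= 1")
    tail = stats.binom.sf(k_trunc - 1, n_total, p0)
    # sf underflow guard: fall back to log-pmf of the dominant term
    if tail <= 0.0:
        logp = stats.binom.logpmf(np.arange(k_trunc, n_total + 1), n_total, p0)
        return float(-np.max(logp) / np.log(10))
    return float(-np.log10(tail))


def background_trunc_ratio(
    profiles: Mapping[str, PatientProfile],
    carriers: set[str] | Sequence[str],
    shrinkage_k: float = 20.0,
) -> float:
    """Patient-environment background truncating/total ratio for one gene.

    Each carrier's own truncating ratio is shrunk toward the cohort mean
    with weight n_total / (n_total + shrinkage_k), so a ratio observed in a
    sparsely mutated patient (where a single truncating event carries more
    information but the ratio estimate is noisy) is stabilized; p0 is the
    mean of the shrunk ratios over carriers, clipped away from {0, 1}.
    """
    carriers = [c for c in carriers if c in profiles and profiles[c].n_total >= 1]
    if not carriers:
        raise ValueError("gene has no carriers with coding mutations")
    all_profiles = [p for p in profiles.values() if p.n_total >= 1]
    cohort_mean = float(np.mean([p.trunc_ratio for p in all_profiles]))
    vals = []
    for c in carriers:
        p = profiles[c]
        w = p.n_total / (p.n_total + shrinkage_k)
        vals.append(w * p.trunc_ratio + (1.0 - w) * cohort_mean)
    return float(np.clip(np.mean(vals), P0_CLIP, 1.0 - P0_CLIP))


def default_bandwidth(protein_length: int) -> float:
    """Default Gaussian kernel sigma: max(2, L/50) amino acids.

    Wide enough to smooth sparse patterns on long proteins, narrow enough
    to resolve a 1-2 residue hotspot on a short GTPase-like protein.
    """
    return max(2.0, protein_length / 50.0)


def _kernel_matrix(L: int, bandwidth: float) -> np.ndarray:
    """Row i-1: Gaussian kernel centred at residue i, renormalized on [1, L]
    so no mass is lost off the protein ends. Shape (L, L)."""
    grid = np.arange(1, L + 1, dtype=float)
    G = np.exp(-0.5 * ((grid[None, :] - grid[:, None]) / bandwidth) ** 2)
    return G / G.sum(axis=1, keepdims=True)


def kernel_density(
    positions: Sequence[int],
    weights: Sequence[float],
    L: int,
    bandwidth: float,
    _G: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted Gaussian mixture over residues 1..L, normalized to sum 1."""
    if L < 2:
        raise ValueError("protein length must be >= 2")
    pos = np.asarray(positions, dtype=int)
    w = np.asarray(weights, dtype=float)
    if np.any((pos < 1) | (pos > L)):
        raise ValueError("positions must lie in [1, L]")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        w = np.ones_like(w)
    G = _kernel_matrix(L, bandwidth) if _G is None else _G
    d = w @ G[pos - 1]
    return d / d.sum()


def shannon_entropy(density: np.ndarray) -> float:
    """Shannon entropy (nats) of a discrete density."""
    d = density[density > 0]
    return float(-(d * np.log(d)).sum())


def og_score(
    positions: Sequence[int],
    weights: Sequence[float] | None,
    L: int,
    bandwidth: float | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    return_null: bool = False,
):
    """OG-S: standardized entropy deficit of the missense position pattern.

    The observed entropy H of the Gaussian-smoothed, impact-weighted
    position density is compared with a bootstrap null in which the same
    number of mutations is placed uniformly on 1..L (weights resampled with
    replacement from the observed weights): og_s = (E[H_null] - H) / SD[H_null].
    Higher means more clustered. Fewer than 2 positions carry no clustering
    information and score 0.
    """
    if L < 2:
        raise ValueError("protein length must be >= 2")
    M = len(positions)
    if weights is None:
        weights = np.ones(M)
    if M < 2:
        return (0.0, None) if return_null else 0.0
    if bandwidth is None:
        bandwidth = default_bandwidth(L)
    G = _kernel_matrix(L, bandwidth)
    H_obs = shannon_entropy(kernel_density(positions, weights, L, bandwidth, _G=G))

    rng = np.random.default_rng(seed)
    w = np.asarray(weights, dtype=float)
    H_null = np.empty(n_reps)
    chunk = max(1, int(2_000_000 / (M * L)))  # bound the gather to ~2e6 floats
    for start in range(0, n_reps, chunk):
        m = min(chunk, n_reps - start)
        pos = rng.integers(1, L + 1, size=(m, M))
        ww = rng.choice(w, size=(m, M), replace=True)
        dens = np.einsum("rm,rml->rl", ww, G[pos - 1])
        sums = dens.sum(axis=1, keepdims=True)
        dens = dens / sums
        with np.errstate(divide="ignore", invalid="ignore"):
            logd = np.where(dens > 0, np.log(np.where(dens > 0, dens, 1.0)), 0.0)
        H_null[start : start + m] = -(dens * logd).sum(axis=1)
    mean, sd = float(H_null.mean()), float(H_null.std(ddof=1))
    null = BootstrapNull(n_reps=n_reps, seed=seed, mean=mean, sd=sd)
    score = 0.0 if sd == 0 else float((mean - H_obs) / sd)
    return (score, null) if return_null else score


def calibrate_thresholds(
    scores: Sequence[tuple[str, float]],
    positives: set[str],
) -> tuple[float, float]:
    """Threshold maximizing the Matthews correlation coefficient.

    Scans every observed score value as a candidate cut (predicted positive
    = score >= t); ties in MCC break toward the larger threshold (fewer
    calls). Returns (threshold, mcc at threshold).
    """
    genes = [g for g, _ in scores]
    vals = np.asarray([s for _, s in scores], dtype=float)
    y = np.asarray([g in positives for g in genes], dtype=int)
    if y.all() or not y.any():
        raise ValueError("calibration needs at least one positive and one negative gene")
    best_t, best_mcc = None, -np.inf
    for t in np.unique(vals):
        mcc = matthews_corrcoef(y, (vals >= t).astype(int))
        if mcc > best_mcc or (mcc == best_mcc and (best_t is None or t > best_t)):
            best_t, best_mcc = float(t), float(mcc)
    return best_t, best_mcc


def cohort_scale_factor(
    n_samples: int,
    median_mutations: float,
    n_ref: int = 200,
    median_ref: float = 40.0,
    h_clip: tuple[float, float] = (0.5, 2.0),
) -> float:
    """Monotone cohort rescaling g = sqrt(min(1, n/n_ref)) * clip(med/med_ref).

    Equals 1 at the reference cohort scale; small or quiet cohorts lower the
    effective thresholds (less evidence attainable), hypermutated cohorts
    raise them.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    g_n = np.sqrt(min(1.0, n_samples / n_ref))
    h = float(np.clip(median_mutations / median_ref, *h_clip))
    return float(g_n * h)


def rescale_thresholds(
    tsg_base: float,
    og_base: float,
    n_samples: int,
    median_mutations: float,
    lax: bool = False,
    floor_fraction: float = 0.25,
    n_ref: int = 200,
    median_ref: float = 40.0,
) -> Thresholds:
    """Build effective thresholds for a cohort.

    Effective = base x g(cohort), clipped below at floor_fraction x base
    unless ``lax`` (the option that lets very small cohorts pass genes
    through the functional step)."""
    g = cohort_scale_factor(n_samples, median_mutations, n_ref=n_ref, median_ref=median_ref)
    floor_tsg = floor_fraction * tsg_base
    floor_og = floor_fraction * og_base
    tsg_eff = tsg_base * g
    og_eff = og_base * g
    if not lax:
        tsg_eff = max(tsg_eff, floor_tsg)
        og_eff = max(og_eff, floor_og)
    return Thresholds(
        tsg_base=tsg_base,
        og_base=og_base,
        tsg_eff=tsg_eff,
        og_eff=og_eff,
        floor_tsg=floor_tsg,
        floor_og=floor_og,
        lax=lax,
    )
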