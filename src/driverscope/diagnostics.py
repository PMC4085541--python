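"""Calibration diagnostics for the frequentist tests.

Each confirmatory test is discrete, so its exact p-values cannot be
uniform; the correct uniformity check is the randomized probability
integral transform p_gt + U * (p_ge - p_gt), which is exactly Uniform(0,1)
when the test's null distribution is right. This module evaluates the four
tests over every sufficiently mutated gene of a cohort and returns the PIT
values, ready for a Kolmogorov-Smirnov check against uniformity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import frequentist_step as fq
from .model import DriverScan, _gene_seed

__all__ = ["frequentist_calibration_pits", "ks_uniformity"]


def frequentist_calibration_pits(
    model: DriverScan,
    min_mutations: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomized-PIT values of the four tests across the cohort's genes.

    ``min_mutations`` applies to the three tests whose statistics are
    compositions conditional on the gene's mutation count (higher
    frequency, NS/S ratio, functional impact): below a handful of
    mutations their discrete nulls are degenerate. The tumor-specificity
    test is evaluated on every modeled gene instead — its statistic is the
    carrier count, so filtering genes by their mutation tally would select
    on the statistic itself and bias the check regardless of calibration.

    Returns a DataFrame with one row per gene and columns pit_freq,
    pit_nssil, pit_spec, pit_fi (NaN where a test is absent or filtered).
    """
    from .maf_io import GeneAggregate, aggregate

    cfg = model.config
    genes, patients = aggregate(model.records, model.gene_models, cfg.territory_mb)
    cohort_size = len({r.sample for r in model.records})
    fi_by_sample: dict[str, list[float]] = {}
    for rec in model.records:
        if rec.fi_score is not None:
            fi_by_sample.setdefault(rec.sample, []).append(rec.fi_score)

    rng = np.random.default_rng(seed)
    rows = []
    for g in sorted(model.gene_models):
        agg = genes.get(g, GeneAggregate(gene=g, cohort_size=cohort_size))
        carriers = sorted(agg.carriers)
        r_freq = r_nssil = r_fi = None
        if agg.n_total >= min_mutations and carriers:
            carrier_totals = np.array([patients[c].n_nonsilent for c in carriers], dtype=int)
            r_freq = fq.higher_frequency_test(
                agg.k_nonsilent,
                int(carrier_totals.sum()),
                gene_length_bp=model.gene_models[g].cds_length_bp,
                territory_bp=cfg.territory_mb * 1e6,
                carrier_totals=carrier_totals,
            )
            n_snv = agg.n_total - agg.n_indel
            k_ns_snv = agg.k_nonsilent - agg.n_indel
            r_nssil = fq.ns_ratio_test(k_ns_snv, n_snv, model._ns_model_p(agg))
            pool = np.array([v for c in carriers for v in fi_by_sample.get(c, [])], dtype=float)
            r_fi = fq.functional_impact_test(
                np.asarray(agg.fi_scores, dtype=float),
                pool,
                n_perm=cfg.n_perm,
                seed=_gene_seed(cfg.seed, g, salt=2),
            )
        bg = model.background.get(g) if model.background else None
        r_spec = fq.tumor_specificity_test(len(carriers), cohort_size, bg)
        row = {"gene": g}
        for name, r in (("freq", r_freq), ("nssil", r_nssil), ("spec", r_spec), ("fi", r_fi)):
            row[f"pit_{name}"] = np.nan if r is None else r.pit(rng.random())
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", "pit_freq", "pit_nssil", "pit_spec", "pit_fi"])


def ks_uniformity(pits: pd.DataFrame) -> dict[str, float]:
    """KS p-value against Uniform(0,1) for each test's PIT column."""
    out = {}
    for col in ("pit_freq", "pit_nssil", "pit_spec", "pit_fi"):
        vals = pits[col].dropna().to_numpy()
        out[col.replace("pit_", "")] = (
            float(stats.kstest(vals, "uniform").pvalue) if len(vals) >= 10 else float("nan")
        )
    return out
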