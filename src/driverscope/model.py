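"""Driver-gene detection model.

:class:`DriverScan` is built from a cohort of somatic mutations plus gene
models; :meth:`DriverScan.fit` runs the three stages — aggregation,
functional scoring (TSG-S / OG-S with cohort-rescaled thresholds), and the
four-test frequentist confirmation with weighted-Stouffer combination and
Benjamini-Hochberg correction within the TSG and OG hypothesis families —
and returns a :class:`DriverScanResults` carrying the ranked candidate
tables, per-gene diagnostics and a text summary.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import frequentist_step as fq
from . import functional_step as fn
from .genetic_code import gene_ns_probability, ns_probability_from_codon_counts
from .maf_io import (
    GeneAggregate,
    GeneModel,
    MutationRecord,
    PatientProfile,
    aggregate,
    read_background_table,
    read_fi_table,
    read_gene_models,
    read_label_list,
    read_maf,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "DriverScan", "DriverScanResults"]


@dataclass
class RunConfig:
    """Tunable parameters of a run; defaults are the package's reference
    conditions (see docs/methods.md for units and rationale)."""

    territory_mb: float = 30.0  # exome territory for per-Mb rates
    qcut: float = 0.1
    lax: bool = False
    seed: int = 0
    boot_reps: int = 1000  # OG-S bootstrap null replicates
    n_perm: int = 10_000  # FI permutation replicates
    bandwidth: float | None = None  # Gaussian sigma (aa); None = max(2, L/50)
    min_mutations: int = 2  # non-silent mutations required to score a gene
    shrinkage_k: float = 20.0  # background-ratio shrinkage constant
    tsg_base: float = 2.0  # base thresholds when no label calibration
    og_base: float = 2.0
    floor_fraction: float = 0.25
    n_ref: int = 200
    median_ref: float = 40.0
    w_freq: float = 1.0  # Stouffer weights
    w_nssil: float = 1.0
    w_spec: float = 0.5
    w_fi: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.qcut < 1.0:
            raise ValueError("qcut must be in (0,1)")
        if self.territory_mb <= 0:
            raise ValueError("territory_mb must be positive")

    @property
    def stouffer_weights(self) -> list[float]:
        return [self.w_freq, self.w_nssil, self.w_spec, self.w_fi]


def _gene_seed(base_seed: int, gene: str, salt: int) -> int:
    """Deterministic, order-independent per-gene seed below 2**31."""
    return (base_seed * 1_000_003 + zlib.crc32(gene.encode()) + salt) % (2**31)


class DriverScan:
    """Driver-gene detection on one cohort.

    Parameters
    ----------
    records : sequence of MutationRecord
        The cohort's somatic mutations.
    gene_models : mapping gene -> GeneModel
        Protein lengths and codon compositions.
    config : RunConfig, optional
    background : mapping gene -> float, optional
        Pan-cancer non-silent carrier frequencies (specificity test input).
    labels : set of str, optional
        Known driver genes; when given, score thresholds are calibrated on
        them by Matthews-correlation maximization instead of the defaults.
    """

    def __init__(
        self,
        records: Sequence[MutationRecord],
        gene_models: Mapping[str, GeneModel],
        config: RunConfig | None = None,
        background: Mapping[str, float] | None = None,
        labels: set[str] | None = None,
    ):
        self.records = list(records)
        self.gene_models = dict(gene_models)
        self.config = config or RunConfig()
        self.background = dict(background) if background else None
        self.labels = set(labels) if labels else None

    @classmethod
    def from_maf(
        cls,
        maf_path,
        gene_models_path,
        fi_table_path=None,
        background_path=None,
        labels_path=None,
        config: RunConfig | None = None,
    ) -> "DriverScan":
        """Build the model from the file inputs of a command-line run."""
        fi = read_fi_table(fi_table_path) if fi_table_path else None
        records = read_maf(maf_path, fi_scores=fi)
        models = read_gene_models(gene_models_path)
        background = read_background_table(background_path) if background_path else None
        labels = read_label_list(labels_path) if labels_path else None
        return cls(records, models, config=config, background=background, labels=labels)

    # ------------------------------------------------------------------ fit
    def fit(self) -> "DriverScanResults":
        cfg = self.config
        genes, patients = aggregate(self.records, self.gene_models, cfg.territory_mb)
        cohort_size = len({r.sample for r in self.records})
        unmodeled = sorted({r.gene for r in self.records} - set(self.gene_models))
        stage_counts = {"records": len(self.records), "samples": cohort_size, "modeled_genes": len(genes)}

        median_mut = float(np.median([p.n_total for p in patients.values()])) if patients else 0.0

        # per-sample FI pools for the functional impact test
        fi_by_sample: dict[str, list[float]] = {}
        for rec in self.records:
            if rec.fi_score is not None:
                fi_by_sample.setdefault(rec.sample, []).append(rec.fi_score)

        # ---------------- functional step ----------------
        diag: dict[str, str] = {g: "unmodeled" for g in unmodeled}
        score_rows = []
        for g in sorted(genes):
            agg = genes[g]
            if agg.k_nonsilent < cfg.min_mutations:
                diag[g] = "insufficient evidence"
                continue
            p0 = fn.background_trunc_ratio(patients, agg.carriers, cfg.shrinkage_k)
            tsg_s = fn.tsg_score(agg.k_trunc, agg.n_total, p0)
            og_s = fn.og_score(
                agg.mis_positions,
                agg.mis_weights,
                agg.protein_length,
                bandwidth=cfg.bandwidth,
                n_reps=cfg.boot_reps,
                seed=_gene_seed(cfg.seed, g, salt=1),
            )
            score_rows.append({"gene": g, "tsg_s": tsg_s, "og_s": og_s, "p0": p0})
        scores = pd.DataFrame(score_rows, columns=["gene", "tsg_s", "og_s", "p0"])

        if self.labels is not None and len(scores):
            tsg_base, _ = fn.calibrate_thresholds(
                list(zip(scores["gene"], scores["tsg_s"])), self.labels
            )
            og_base, _ = fn.calibrate_thresholds(
                list(zip(scores["gene"], scores["og_s"])), self.labels
            )
        else:
            tsg_base, og_base = cfg.tsg_base, cfg.og_base
        thresholds = fn.rescale_thresholds(
            tsg_base,
            og_base,
            n_samples=cohort_size if cohort_size else 1,
            median_mutations=median_mut,
            lax=cfg.lax,
            floor_fraction=cfg.floor_fraction,
            n_ref=cfg.n_ref,
            median_ref=cfg.median_ref,
        )
        if len(scores):
            scores["tsg_pass"] = scores["tsg_s"] >= thresholds.tsg_eff
            scores["og_pass"] = scores["og_s"] >= thresholds.og_eff
        else:
            scores["tsg_pass"] = pd.Series(dtype=bool)
            scores["og_pass"] = pd.Series(dtype=bool)

        # ---------------- frequentist step ----------------
        candidates = scores[scores["tsg_pass"] | scores["og_pass"]]
        stage_counts["scored_genes"] = len(scores)
        stage_counts["functional_pass"] = len(candidates)
        if len(scores) and not len(candidates):
            logger.warning(
                "no gene passed the functional step; for small cohorts consider lax=True"
            )

        test_rows = {}
        for g in candidates["gene"]:
            test_rows[g] = self._test_gene(genes[g], patients, fi_by_sample, cohort_size)

        tsg_table = self._family_table(scores, test_rows, genes, "tsg_pass")
        og_table = self._family_table(scores, test_rows, genes, "og_pass")

        for _, row in scores.iterrows():
            g = row["gene"]
            if not (row["tsg_pass"] or row["og_pass"]):
                diag[g] = "below functional thresholds"
            else:
                fam = []
                if row["tsg_pass"]:
                    sig = bool(tsg_table.loc[tsg_table["gene"] == g, "significant"].iloc[0])
                    fam.append("TSG" if sig else "TSG candidate, not significant")
                if row["og_pass"]:
                    sig = bool(og_table.loc[og_table["gene"] == g, "significant"].iloc[0])
                    fam.append("OG" if sig else "OG candidate, not significant")
                diag[g] = "; ".join(fam)
        stage_counts["tsg_called"] = int(tsg_table["significant"].sum()) if len(tsg_table) else 0
        stage_counts["og_called"] = int(og_table["significant"].sum()) if len(og_table) else 0

        return DriverScanResults(
            model=self,
            scores=scores,
            thresholds=thresholds,
            tsg_table=tsg_table,
            og_table=og_table,
            diagnostics=pd.DataFrame(
                [{"gene": g, "status": s} for g, s in sorted(diag.items())],
                columns=["gene", "status"],
            ),
            gene_aggregates=genes,
            patient_profiles=patients,
            stage_counts=stage_counts,
        )

    # ------------------------------------------------------------ internals
    def _ns_model_p(self, agg: GeneAggregate) -> float:
        model = self.gene_models[agg.gene]
        if model.cds is not None:
            return gene_ns_probability(model.cds, gene=agg.gene).p_ns
        return ns_probability_from_codon_counts(model.codon_counts, gene=agg.gene).p_ns

    def _test_gene(
        self,
        agg: GeneAggregate,
        patients: Mapping[str, PatientProfile],
        fi_by_sample: Mapping[str, list[float]],
        cohort_size: int,
    ) -> dict:
        cfg = self.config
        carriers = sorted(agg.carriers)
        carrier_totals = np.array([patients[c].n_nonsilent for c in carriers], dtype=int)

        r_freq = fq.higher_frequency_test(
            agg.k_nonsilent,
            int(carrier_totals.sum()),
            gene_length_bp=self.gene_models[agg.gene].cds_length_bp,
            territory_bp=cfg.territory_mb * 1e6,
            carrier_totals=carrier_totals,
        )
        # SNV-only counts: indels are non-silent with probability 1
        n_snv = agg.n_total - agg.n_indel
        k_ns_snv = agg.k_nonsilent - agg.n_indel
        r_nssil = fq.ns_ratio_test(k_ns_snv, n_snv, self._ns_model_p(agg))
        bg = self.background.get(agg.gene) if self.background else None
        r_spec = fq.tumor_specificity_test(len(carriers), cohort_size, bg)
        pool = np.array([v for c in carriers for v in fi_by_sample.get(c, [])], dtype=float)
        r_fi = fq.functional_impact_test(
            np.asarray(agg.fi_scores, dtype=float),
            pool,
            n_perm=cfg.n_perm,
            seed=_gene_seed(cfg.seed, agg.gene, salt=2),
        )
        results = (r_freq, r_nssil, r_spec, r_fi)
        ps = [r.p if r is not None else None for r in results]
        # combine on mid-p: exact inclusive tails of discrete tests have a
        # conservative atom at p = 1 that would bias the z-sum downward
        mids = [r.mid if r is not None else None for r in results]
        combined = fq.stouffer_combine(mids, cfg.stouffer_weights)
        return {
            "p_freq": ps[0],
            "p_nssil": ps[1],
            "p_spec": ps[2],
            "p_fi": ps[3],
            "combined_p": combined,
        }

    def _family_table(
        self,
        scores: pd.DataFrame,
        test_rows: Mapping[str, dict],
        genes: Mapping[str, GeneAggregate],
        pass_col: str,
    ) -> pd.DataFrame:
        cols = [
            "gene",
            "ns_frequency",
            "p_freq",
            "p_nssil",
            "p_spec",
            "p_fi",
            "combined_p",
            "q_value",
            "significant",
        ]
        if not len(scores):
            return pd.DataFrame(columns=cols)
        members = [
            g
            for g in scores.loc[scores[pass_col], "gene"]
            if test_rows.get(g, {}).get("combined_p") is not None
        ]
        if not members:
            return pd.DataFrame(columns=cols)
        df = pd.DataFrame(
            [
                {
                    "gene": g,
                    "ns_frequency": genes[g].ns_frequency,
                    **test_rows[g],
                }
                for g in members
            ]
        )
        df["q_value"] = fq.bh_fdr(df["combined_p"].to_numpy())
        df["significant"] = df["q_value"] <= self.config.qcut
        df = df.sort_values(
            ["q_value", "combined_p", "ns_frequency"],
            ascending=[True, True, False],
            kind="mergesort",
        ).reset_index(drop=True)
        return df[cols]


@dataclass
class DriverScanResults:
    """Fitted results: scores, thresholds, ranked family tables, diagnostics."""

    model: DriverScan
    scores: pd.DataFrame
    thresholds: fn.Thresholds
    tsg_table: pd.DataFrame
    og_table: pd.DataFrame
    diagnostics: pd.DataFrame
    gene_aggregates: dict[str, GeneAggregate]
    patient_profiles: dict[str, PatientProfile]
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def called_tsgs(self) -> list[str]:
        t = self.tsg_table
        return list(t.loc[t["significant"], "gene"]) if len(t) else []

    @property
    def called_ogs(self) -> list[str]:
        t = self.og_table
        return list(t.loc[t["significant"], "gene"]) if len(t) else []

    def summary(self) -> str:
        cfg = self.model.config
        th = self.thresholds
        lines = [
            "DriverScan results",
            "==================",
            f"samples: {self.stage_counts.get('samples', 0)}   "
            f"records: {self.stage_counts.get('records', 0)}   "
            f"modeled genes: {self.stage_counts.get('modeled_genes', 0)}",
            f"seed: {cfg.seed}   qcut: {cfg.qcut}   lax: {cfg.lax}",
            f"thresholds: TSG-S >= {th.tsg_eff:.3f} (base {th.tsg_base:.3f}), "
            f"OG-S >= {th.og_eff:.3f} (base {th.og_base:.3f})",
            f"functional pass: {self.stage_counts.get('functional_pass', 0)} of "
            f"{self.stage_counts.get('scored_genes', 0)} scored genes",
            f"called TSGs (q <= {cfg.qcut}): {len(self.called_tsgs)}",
            f"called OGs  (q <= {cfg.qcut}): {len(self.called_ogs)}",
        ]
        for name, table in (("TSGs", self.tsg_table), ("OGs", self.og_table)):
            if len(table):
                lines.append("")
                lines.append(f"Top {name}:")
                head = table.head(10)[["gene", "ns_frequency", "combined_p", "q_value", "significant"]]
                lines.append(head.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
        return "\n".join(lines)

    def to_tsv(self, prefix) -> dict[str, str]:
        """Write the TSG table, OG table, scores and diagnostics as TSVs.

        The run seed and thresholds are recorded in a header line of each
        file so outputs are self-describing and reproducible."""
        cfg = self.model.config
        header = (
            f"# driverscope seed={cfg.seed} qcut={cfg.qcut} lax={cfg.lax} "
            f"tsg_eff={self.thresholds.tsg_eff:.6g} og_eff={self.thresholds.og_eff:.6g}\n"
        )
        paths = {}
        for name, df in (
            ("tsg", self.tsg_table),
            ("og", self.og_table),
            ("scores", self.scores),
            ("diagnostics", self.diagnostics),
        ):
            path = f"{prefix}.{name}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
            paths[name] = path
        return paths

    def plot_gene(self, gene: str, ax=None):
        """Protein-ideogram pattern plot for one gene (see plotting module)."""
        from .plotting import render_pattern

        return render_pattern(self.gene_aggregates[gene], bandwidth=self.model.config.bandwidth, ax=ax)
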