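"""Synthetic somatic-mutation cohorts with known truth.

The generator emulates the inputs of the pipeline — a MAF cohort, gene
models, a functional-impact table and a pan-cancer background table —
with planted drivers so every stage is testable without external data:

* passenger mutations land on genes in proportion to coding length; SNVs
  pick a uniform codon position and base change and are classified by the
  standard genetic code (so a neutral gene's non-silent fraction matches
  its codon-structure expectation by construction), while a small indel
  admixture (frame-shift vs in-frame) lifts the cohort truncating/total
  ratio to the target p0 (default 14%, the ratio typical of cancer exomes);
* planted tumor suppressors receive diffuse truncating mutations at a
  target fraction (default 85%, an APC-like landscape);
* planted oncogenes receive missense mutations concentrated on a hotspot
  codon (default 83% of mutations on one residue, a KRAS 12/13-like
  landscape);
* one "fishy" gene is simply a 10x-length passenger gene: long, heavily
  mutated, neutral — the canonical false positive a driver caller must
  reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import CODONS, substitution_census, translate
from .maf_io import GeneModel, MutationRecord, write_maf

__all__ = ["SimSpec", "SimulatedCohort", "simulate", "subsample_cohort"]

_SENSE_CODONS = [c for c in CODONS if translate(c) != "*"]
_STOP_CODONS = [c for c in CODONS if translate(c) == "*"]
_CENSUS = substitution_census()
# per-SNV truncating probability under a uniform substitution model
_SNV_TRUNC_RATE = (_CENSUS.n_stop_gain + _CENSUS.n_stop_loss) / _CENSUS.n_total


@dataclass
class SimSpec:
    """Study conditions of a simulated cohort."""

    n_samples: int = 100
    n_genes: int = 500
    median_protein_length: int = 400
    length_sigma: float = 0.6  # log-normal spread of protein lengths
    median_mutations: float = 40.0  # coding mutations per patient
    mutations_sigma: float = 0.5
    p0_sim: float = 0.14  # target cohort truncating/total ratio
    frameshift_fraction: float = 0.9  # of indels
    n_tsg: int = 3
    tsg_trunc_fraction: float = 0.85
    tsg_carriers: int = 30
    n_og: int = 3
    og_hotspot_mass: float = 0.83
    og_carriers: int = 20
    og_protein_length: int = 190  # KRAS-like small GTPase scale
    n_fishy: int = 1
    fishy_length_multiplier: float = 10.0
    with_fi: bool = True
    fi_beta: tuple[float, float] = (2.0, 2.0)  # FI ~ 4 * Beta(a, b)
    fi_driver_shift: float = 1.0
    with_background: bool = True
    seed: int = 0

    @property
    def indel_fraction(self) -> float:
        """Indel admixture solving f*P(trunc|indel) + (1-f)*r_snv = p0_sim."""
        r = _SNV_TRUNC_RATE
        f = (self.p0_sim - r) / (self.frameshift_fraction - r)
        if not 0.0 <= f < 1.0:
            raise ValueError("p0_sim unreachable with this frameshift fraction")
        return f


@dataclass
class SimulatedCohort:
    """A generated cohort plus its ground truth and internal tallies."""

    spec: SimSpec
    records: list[MutationRecord]
    models: dict[str, GeneModel]
    truth: dict[str, str]  # gene -> TSG / OG / PASSENGER / FISHY
    fi_table: dict[tuple, float] | None
    background: dict[str, float] | None
    territory_mb: float
    hotspots: dict[str, int] = field(default_factory=dict)
    tallies: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return [f"S{i:04d}" for i in range(1, self.spec.n_samples + 1)]

    def write(self, prefix) -> dict[str, Path]:
        """Write MAF, gene models, truth, FI and background tables as TSVs."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {"maf": Path(f"{prefix}.maf")}
        write_maf(self.records, paths["maf"])
        rows = []
        for g in sorted(self.models):
            m = self.models[g]
            row = {"gene": g, "protein_length": m.protein_length}
            row.update({f"n_{c}": int(m.codon_counts[i]) for i, c in enumerate(CODONS)})
            rows.append(row)
        paths["models"] = Path(f"{prefix}.gene_models.tsv")
        pd.DataFrame(rows).to_csv(paths["models"], sep="\t", index=False)
        paths["truth"] = Path(f"{prefix}.truth.tsv")
        pd.DataFrame(
            [{"gene": g, "label": v} for g, v in sorted(self.truth.items())]
        ).to_csv(paths["truth"], sep="\t", index=False)
        if self.fi_table is not None:
            paths["fi"] = Path(f"{prefix}.fi.tsv")
            pd.DataFrame(
                [
                    {"gene": g, "sample": s, "protein_position": p, "fi_score": v}
                    for (g, s, p), v in self.fi_table.items()
                ]
            ).to_csv(paths["fi"], sep="\t", index=False)
        if self.background is not None:
            paths["background"] = Path(f"{prefix}.background.tsv")
            pd.DataFrame(
                [{"gene": g, "frequency": f} for g, f in sorted(self.background.items())]
            ).to_csv(paths["background"], sep="\t", index=False)
        return paths


def _random_cds(rng: np.random.Generator, protein_length: int) -> str:
    body = rng.choice(len(_SENSE_CODONS), size=protein_length)
    stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
    return "".join(_SENSE_CODONS[i] for i in body) + stop


def _snv_on_gene(rng: np.random.Generator, cds: str) -> tuple[str, int | None]:
    """Place a uniform single-base substitution on the CDS; return the MAF
    classification and the protein position (None on the stop codon)."""
    n_codons = len(cds) // 3
    ci = int(rng.integers(n_codons))
    codon = cds[3 * ci : 3 * ci + 3]
    bi = int(rng.integers(3))
    ref = codon[bi]
    alt = "ACGT".replace(ref, "")[rng.integers(3)]
    new = codon[:bi] + alt + codon[bi + 1 :]
    a, b = translate(codon), translate(new)
    pos = ci + 1
    if a != "*" and b == "*":
        return "Nonsense_Mutation", pos
    if a == "*" and b != "*":
        return "Nonstop_Mutation", None  # stop codon is past the protein end
    if a == "*" and b == "*":
        return "Silent", None
    if a == b:
        return "Silent", pos
    return "Missense_Mutation", pos


def _neutral_mutation(rng: np.random.Generator, spec: SimSpec, cds: str) -> tuple[str, str, int | None]:
    """One passenger mutation: (classification, variant type, position)."""
    if rng.random() < spec.indel_fraction:
        vt = "DEL" if rng.random() < 0.5 else "INS"
        n_codons = len(cds) // 3 - 1  # indels on the protein body
        pos = int(rng.integers(1, max(2, n_codons + 1)))
        if rng.random() < spec.frameshift_fraction:
            return ("Frame_Shift_Del" if vt == "DEL" else "Frame_Shift_Ins", vt, pos)
        return ("In_Frame_Del" if vt == "DEL" else "In_Frame_Ins", vt, pos)
    vc, pos = _snv_on_gene(rng, cds)
    return vc, "SNP", pos


def simulate(spec: SimSpec | None = None, seed: int | None = None) -> SimulatedCohort:
    """Generate a cohort under ``spec`` (defaults are the study conditions)."""
    spec = spec or SimSpec()
    if seed is not None:
        spec = SimSpec(**{**spec.__dict__, "seed": seed})
    rng = np.random.default_rng(spec.seed)

    # --- gene universe -----------------------------------------------------
    n_passenger = spec.n_genes - spec.n_tsg - spec.n_og - spec.n_fishy
    if n_passenger < 0:
        raise ValueError("more planted genes than n_genes")
    names, truth = [], {}
    for i in range(n_passenger):
        g = f"GENE{i + 1:04d}"
        names.append(g)
        truth[g] = "PASSENGER"
    for i in range(spec.n_tsg):
        g = f"TSG{i + 1:02d}"
        names.append(g)
        truth[g] = "TSG"
    for i in range(spec.n_og):
        g = f"OG{i + 1:02d}"
        names.append(g)
        truth[g] = "OG"
    for i in range(spec.n_fishy):
        g = f"FISHY{i + 1:02d}"
        names.append(g)
        truth[g] = "FISHY"

    mu = np.log(spec.median_protein_length)
    models: dict[str, GeneModel] = {}
    for g in names:
        L = max(50, int(round(rng.lognormal(mu, spec.length_sigma))))
        if truth[g] == "FISHY":
            L = int(round(spec.fishy_length_multiplier * spec.median_protein_length))
        elif truth[g] == "OG":
            L = spec.og_protein_length
        cds = _random_cds(rng, L)
        counts = np.zeros(64)
        idx = {c: i for i, c in enumerate(CODONS)}
        for i in range(0, len(cds), 3):
            counts[idx[cds[i : i + 3]]] += 1
        models[g] = GeneModel(gene=g, protein_length=L, codon_counts=counts, cds=cds)
    territory_bp = sum(m.cds_length_bp for m in models.values())
    territory_mb = territory_bp / 1e6

    # passenger placement: genes in proportion to coding length, planted
    # driver genes excluded (their mutations are planted explicitly)
    passenger_pool = [g for g in names if truth[g] in ("PASSENGER", "FISHY")]
    pool_w = np.array([models[g].cds_length_bp for g in passenger_pool], dtype=float)
    pool_w /= pool_w.sum()

    samples = [f"S{i:04d}" for i in range(1, spec.n_samples + 1)]
    records: list[MutationRecord] = []
    mlog = np.log(spec.median_mutations)
    burdens: list[int] = []  # realized passenger mutation counts per patient

    for s in samples:
        m_i = max(1, int(round(rng.lognormal(mlog, spec.mutations_sigma))))
        burdens.append(m_i)
        gene_idx = rng.choice(len(passenger_pool), size=m_i, p=pool_w)
        for gi in gene_idx:
            g = passenger_pool[gi]
            vc, vt, pos = _neutral_mutation(rng, spec, models[g].cds)
            records.append(
                MutationRecord(gene=g, sample=s, variant_classification=vc, variant_type=vt, protein_position=pos)
            )

    # --- planted drivers ---------------------------------------------------
    hotspots: dict[str, int] = {}
    driver_keys: set[tuple] = set()
    for g in names:
        if truth[g] == "TSG":
            carriers = rng.choice(spec.n_samples, size=min(spec.tsg_carriers, spec.n_samples), replace=False)
            L = models[g].protein_length
            for ci in carriers:
                s = samples[ci]
                if rng.random() < spec.tsg_trunc_fraction:
                    pos = int(rng.integers(1, L + 1))
                    if rng.random() < 0.5:
                        vc, vt = "Nonsense_Mutation", "SNP"
                    else:
                        vc, vt = ("Frame_Shift_Del", "DEL") if rng.random() < 0.5 else ("Frame_Shift_Ins", "INS")
                else:
                    pos = int(rng.integers(1, L + 1))
                    vc, vt = "Missense_Mutation", "SNP"
                records.append(
                    MutationRecord(gene=g, sample=s, variant_classification=vc, variant_type=vt, protein_position=pos)
                )
                driver_keys.add((g, s, pos))
        elif truth[g] == "OG":
            carriers = rng.choice(spec.n_samples, size=min(spec.og_carriers, spec.n_samples), replace=False)
            L = models[g].protein_length
            hot = int(rng.integers(L // 4, 3 * L // 4))
            hotspots[g] = hot
            for ci in carriers:
                s = samples[ci]
                pos = hot if rng.random() < spec.og_hotspot_mass else int(rng.integers(1, L + 1))
                records.append(
                    MutationRecord(
                        gene=g, sample=s, variant_classification="Missense_Mutation", variant_type="SNP", protein_position=pos
                    )
                )
                driver_keys.add((g, s, pos))

    # --- functional impact scores (all non-silent mutations) ---------------
    fi_table: dict[tuple, float] | None = None
    if spec.with_fi:
        fi_table = {}
        a, b = spec.fi_beta
        for rec in records:
            if not rec.variant_classification.startswith("Silent"):
                fi = 4.0 * rng.beta(a, b)
                if (rec.gene, rec.sample, rec.protein_position) in driver_keys:
                    fi += spec.fi_driver_shift
                key = (rec.gene, rec.sample, rec.protein_position)
                fi_table[key] = fi
                rec.fi_score = fi

    # --- background table: neutral expected carrier frequency --------------
    # Evaluated at the cohort's realized passenger burdens, i.e. a
    # burden-matched background: the tumor-specificity test then probes a
    # gene's excess over neutrality rather than a cohort-vs-population
    # mutation-rate offset (the confounder it inherits with a fixed
    # pan-cancer table on a cohort whose rate differs from the average).
    background: dict[str, float] | None = None
    if spec.with_background:
        m_draws = np.asarray(burdens, dtype=float)
        background = {}
        from .genetic_code import ns_probability_from_codon_counts

        f = spec.indel_fraction
        for g in names:
            m = models[g]
            p_ns_snv = ns_probability_from_codon_counts(m.codon_counts, gene=g).p_ns
            p_ns_eff = f + (1.0 - f) * p_ns_snv
            w = (m.cds_length_bp / territory_bp) * p_ns_eff
            background[g] = float(np.mean(1.0 - (1.0 - w) ** m_draws))

    # internal tallies for the aggregation round-trip invariant
    from .maf_io import FunctionalCategory, classify_variant

    tallies: dict[str, dict[str, int]] = {}
    for rec in records:
        t = tallies.setdefault(rec.gene, {"truncating": 0, "missense": 0, "silent": 0})
        cat = classify_variant(rec)
        if cat is not FunctionalCategory.EXCLUDED:
            t[cat.value] += 1

    return SimulatedCohort(
        spec=spec,
        records=records,
        models=models,
        truth=truth,
        fi_table=fi_table,
        background=background,
        territory_mb=territory_mb,
        hotspots=hotspots,
        tallies=tallies,
    )


def subsample_cohort(
    records: list[MutationRecord], fraction: float, seed: int = 0
) -> list[MutationRecord]:
    """Keep a random fraction of patients (all their mutations retained)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    samples = sorted({r.sample for r in records})
    n_keep = int(round(fraction * len(samples)))
    if n_keep == 0:
        raise ValueError("fraction keeps zero patients")
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(samples, size=n_keep, replace=False))
    return [r for r in records if r.sample in keep]
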