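"""MAF input, functional classification and gene/patient aggregation.

This is the preliminary step of the pipeline: a TCGA-dialect Mutation
Annotation Format table is read, each mutation is assigned one functional
category (truncating / missense / silent / excluded), and the cohort is
aggregated into per-gene and per-patient summaries that the functional and
frequentist steps consume.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import CODONS, translate

logger = logging.getLogger(__name__)

__all__ = [
    "FunctionalCategory",
    "MutationRecord",
    "PatientProfile",
    "GeneAggregate",
    "GeneModel",
    "classify_variant",
    "read_maf",
    "read_gene_models",
    "read_fi_table",
    "read_background_table",
    "read_label_list",
    "aggregate",
    "write_maf",
    "write_gene_table",
]


class FunctionalCategory(Enum):
    """Functional effect class of a coding mutation."""

    TRUNCATING = "truncating"
    MISSENSE = "missense"
    SILENT = "silent"
    EXCLUDED = "excluded"


# Case-insensitive Variant_Classification -> category. Truncating covers
# frame shifts, stop gains, stop losses, translation-start and splice-site
# events; in-frame indels are grouped with missense for hotspot scoring.
_TRUNCATING = {
    "nonsense_mutation",
    "frame_shift_del",
    "frame_shift_ins",
    "splice_site",
    "translation_start_site",
    "nonstop_mutation",
}
_MISSENSE = {"missense_mutation", "in_frame_del", "in_frame_ins"}
_SILENT = {"silent", "synonymous"}
_EXCLUDED = {
    "3'utr",
    "5'utr",
    "3'flank",
    "5'flank",
    "intron",
    "igr",
    "rna",
    "lincrna",
    "noncoding",
    "targeted_region",
    "de_novo_start_inframe",
    "de_novo_start_outofframe",
}


@dataclass
class MutationRecord:
    """One somatic mutation from a MAF row."""

    gene: str
    sample: str
    variant_classification: str
    variant_type: str  # SNP / INS / DEL
    protein_position: int | None = None
    fi_score: float | None = None

    @property
    def category(self) -> FunctionalCategory:
        return classify_variant(self)


@dataclass
class PatientProfile:
    """Per-sample mutation profile over coding (non-excluded) mutations."""

    sample: str
    n_truncating: int = 0
    n_missense: int = 0
    n_silent: int = 0

    @property
    def n_total(self) -> int:
        return self.n_truncating + self.n_missense + self.n_silent

    @property
    def n_nonsilent(self) -> int:
        return self.n_truncating + self.n_missense

    @property
    def trunc_ratio(self) -> float:
        return self.n_truncating / self.n_total if self.n_total else 0.0

    def ns_rate_per_mb(self, territory_mb: float) -> float:
        if territory_mb <= 0:
            raise ValueError("territory_mb must be positive")
        return self.n_nonsilent / territory_mb


@dataclass
class GeneModel:
    """Gene model: protein length and codon composition (optionally the CDS)."""

    gene: str
    protein_length: int
    codon_counts: np.ndarray  # 64-vector, CODONS order
    cds: str | None = None

    @property
    def cds_length_bp(self) -> int:
        return int(np.sum(self.codon_counts)) * 3


@dataclass
class GeneAggregate:
    """Per-gene aggregate of the cohort's mutations."""

    gene: str
    k_trunc: int = 0
    k_mis: int = 0
    k_sil: int = 0
    n_indel: int = 0  # coding INS/DEL records (always non-silent)
    carriers: set[str] = field(default_factory=set)
    trunc_positions: list[int] = field(default_factory=list)
    mis_positions: list[int] = field(default_factory=list)
    mis_weights: list[float] = field(default_factory=list)
    fi_scores: list[float] = field(default_factory=list)  # all scored mutations
    protein_length: int | None = None
    codon_counts: np.ndarray | None = None
    cohort_size: int = 0

    @property
    def n_total(self) -> int:
        return self.k_trunc + self.k_mis + self.k_sil

    @property
    def k_nonsilent(self) -> int:
        return self.k_trunc + self.k_mis

    @property
    def ns_frequency(self) -> float:
        return len(self.carriers) / self.cohort_size if self.cohort_size else 0.0


def classify_variant(rec: MutationRecord | str) -> FunctionalCategory:
    """Map a MAF Variant_Classification to its functional category.

    Unknown classes are excluded with a warning rather than dropped silently.
    """
    vc = rec if isinstance(rec, str) else rec.variant_classification
    key = vc.strip().lower()
    if key in _TRUNCATING:
        return FunctionalCategory.TRUNCATING
    if key in _MISSENSE:
        return FunctionalCategory.MISSENSE
    if key in _SILENT:
        return FunctionalCategory.SILENT
    if key in _EXCLUDED:
        return FunctionalCategory.EXCLUDED
    warnings.warn(f"unknown Variant_Classification {vc!r}; excluding", stacklevel=2)
    return FunctionalCategory.EXCLUDED


_HGVSP_RE = re.compile(r"^p\.\(?[A-Za-z*]{1,3}(\d+)")
_POS_RE = re.compile(r"^(\d+)")


def parse_protein_position(value: object) -> int | None:
    """Parse a 1-based amino-acid position from HGVSp (``p.G12D``) or a
    bare/ranged position field (``12``, ``12/189``, ``12-13``)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s in {".", "-", "NA", "nan"}:
        return None
    m = _HGVSP_RE.match(s)
    if m is None:
        m = _POS_RE.match(s)
    if m is None:
        return None
    pos = int(m.group(1))
    return pos if pos >= 1 else None


_MANDATORY = [
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Variant_Type",
]
# columns searched, in order, for a protein position
_POSITION_COLUMNS = ["HGVSp_Short", "HGVSp", "Protein_position", "Protein_Change", "amino_acid_position"]


def read_maf(path, fi_scores: Mapping[tuple, float] | None = None) -> list[MutationRecord]:
    """Read a tab-separated MAF file into mutation records.

    Header spellings are matched case-insensitively (TCGA MAF versions
    drift, e.g. ``Start_position`` vs ``Start_Position``). Rows with
    non-coding classes are retained; they classify as EXCLUDED downstream.
    Unparseable protein positions yield records without a position.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    lower = {c.lower(): c for c in df.columns}
    for col in _MANDATORY:
        if col.lower() not in lower:
            raise ValueError(f"MAF is missing mandatory column {col}")
    pos_col = next((lower[c.lower()] for c in _POSITION_COLUMNS if c.lower() in lower), None)
    fi_col = next((lower[c.lower()] for c in ("fi_score", "FIS", "MA_FIS") if c.lower() in lower), None)

    records: list[MutationRecord] = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        pos = parse_protein_position(d[pos_col]) if pos_col else None
        fi = None
        if fi_col and d[fi_col] not in ("", "NA", "."):
            fi = float(d[fi_col])
        records.append(
            MutationRecord(
                gene=d[lower["hugo_symbol"]],
                sample=d[lower["tumor_sample_barcode"]],
                variant_classification=d[lower["variant_classification"]],
                variant_type=d[lower["variant_type"]].upper(),
                protein_position=pos,
                fi_score=fi,
            )
        )
    if fi_scores:
        for rec in records:
            key = (rec.gene, rec.sample, rec.protein_position)
            if rec.fi_score is None and key in fi_scores:
                rec.fi_score = fi_scores[key]
    return records


def write_maf(records: Iterable[MutationRecord], path) -> None:
    """Write records to a minimal TCGA-dialect MAF (round-trips all fields
    the pipeline uses)."""
    rows = []
    for r in records:
        rows.append(
            {
                "Hugo_Symbol": r.gene,
                "Tumor_Sample_Barcode": r.sample,
                "Variant_Classification": r.variant_classification,
                "Variant_Type": r.variant_type,
                "HGVSp_Short": f"p.X{r.protein_position}X" if r.protein_position else "",
                "fi_score": "" if r.fi_score is None else f"{r.fi_score:.6g}",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol",
            "Tumor_Sample_Barcode",
            "Variant_Classification",
            "Variant_Type",
            "HGVSp_Short",
            "fi_score",
        ],
    ).to_csv(path, sep="\t", index=False)


def _codon_counts_from_cds(cds: str) -> np.ndarray:
    counts = np.zeros(64)
    index = {c: i for i, c in enumerate(CODONS)}
    for i in range(0, len(cds), 3):
        counts[index[cds[i : i + 3].upper()]] += 1
    return counts


def read_gene_models(path) -> dict[str, GeneModel]:
    """Read gene models from either a CDS FASTA (keyed by gene symbol) or a
    TSV ``gene, protein_length, n_<codon> ...``.

    FASTA protein length excludes the trailing stop codon when present.
    """
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    models: dict[str, GeneModel] = {}
    if first.startswith(">"):
        for rec in SeqIO.parse(path, "fasta"):
            cds = str(rec.seq).upper()
            if len(cds) % 3 != 0:
                raise ValueError(f"CDS of {rec.id} has length {len(cds)}, not divisible by 3")
            counts = _codon_counts_from_cds(cds)
            n_codons = len(cds) // 3
            has_stop = translate(cds[-3:]) == "*"
            models[rec.id] = GeneModel(
                gene=rec.id,
                protein_length=n_codons - 1 if has_stop else n_codons,
                codon_counts=counts,
                cds=cds,
            )
        return models
    df = pd.read_csv(path, sep="\t")
    codon_cols = [f"n_{c}" for c in CODONS]
    for _, row in df.iterrows():
        if all(c in df.columns for c in codon_cols):
            counts = row[codon_cols].to_numpy(dtype=float)
        else:
            # length-only model: uniform sense-codon composition
            counts = np.full(64, row["protein_length"] / 61.0)
            for i, c in enumerate(CODONS):
                if c in ("TAA", "TAG", "TGA"):
                    counts[i] = 0.0
        models[row["gene"]] = GeneModel(
            gene=str(row["gene"]),
            protein_length=int(row["protein_length"]),
            codon_counts=np.asarray(counts, dtype=float),
        )
    return models


def read_fi_table(path) -> dict[tuple, float]:
    """Read a functional-impact table TSV ``gene, sample, protein_position,
    fi_score`` into a lookup keyed by (gene, sample, position)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple, float] = {}
    for row in df.itertuples(index=False):
        pos = None if pd.isna(row.protein_position) else int(row.protein_position)
        out[(row.gene, row.sample, pos)] = float(row.fi_score)
    return out


def read_background_table(path) -> dict[str, float]:
    """Read a pan-cancer background frequency TSV ``gene, frequency``."""
    df = pd.read_csv(path, sep="\t")
    bad = df[(df["frequency"] < 0) | (df["frequency"] > 1)]
    if len(bad):
        raise ValueError(f"background frequencies outside [0,1] for {list(bad['gene'])}")
    return dict(zip(df["gene"].astype(str), df["frequency"].astype(float)))


def read_label_list(path) -> set[str]:
    """Read a driver-gene label list (one symbol per line)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def aggregate(
    records: Sequence[MutationRecord],
    models: Mapping[str, GeneModel],
    territory_mb: float = 30.0,
) -> tuple[dict[str, GeneAggregate], dict[str, PatientProfile]]:
    """Aggregate mutation records by gene and by patient.

    Carrier sets and gene counts are restricted to genes with a model;
    unmodeled genes are logged once. Patient profiles count every coding
    mutation (modeled or not) so per-patient ratios reflect the whole exome.
    EXCLUDED records contribute to nothing.
    """
    if territory_mb <= 0:
        raise ValueError("territory_mb must be positive")
    genes: dict[str, GeneAggregate] = {}
    patients: dict[str, PatientProfile] = {}
    unmodeled: set[str] = set()
    samples = {r.sample for r in records}

    for rec in records:
        cat = classify_variant(rec)
        prof = patients.setdefault(rec.sample, PatientProfile(sample=rec.sample))
        if cat is FunctionalCategory.EXCLUDED:
            continue
        if cat is FunctionalCategory.TRUNCATING:
            prof.n_truncating += 1
        elif cat is FunctionalCategory.MISSENSE:
            prof.n_missense += 1
        else:
            prof.n_silent += 1

        model = models.get(rec.gene)
        if model is None:
            unmodeled.add(rec.gene)
            continue
        agg = genes.setdefault(
            rec.gene,
            GeneAggregate(
                gene=rec.gene,
                protein_length=model.protein_length,
                codon_counts=model.codon_counts,
                cohort_size=len(samples),
            ),
        )
        if cat is FunctionalCategory.TRUNCATING:
            agg.k_trunc += 1
            if rec.protein_position is not None and 1 <= rec.protein_position <= model.protein_length:
                agg.trunc_positions.append(rec.protein_position)
        elif cat is FunctionalCategory.MISSENSE:
            agg.k_mis += 1
            if rec.protein_position is not None and 1 <= rec.protein_position <= model.protein_length:
                agg.mis_positions.append(rec.protein_position)
                agg.mis_weights.append(rec.fi_score if rec.fi_score is not None else 1.0)
        else:
            agg.k_sil += 1
        if rec.variant_type in ("INS", "DEL") and cat is not FunctionalCategory.SILENT:
            agg.n_indel += 1
        if cat is not FunctionalCategory.SILENT:
            agg.carriers.add(rec.sample)
            if rec.fi_score is not None:
                agg.fi_scores.append(rec.fi_score)
    if unmodeled:
        logger.warning("no gene model for %d genes: %s ...", len(unmodeled), sorted(unmodeled)[:10])
    return genes, patients


def write_gene_table(genes: Mapping[str, GeneAggregate], path) -> None:
    """Write the aggregated per-gene table as TSV."""
    rows = [
        {
            "gene": g.gene,
            "k_trunc": g.k_trunc,
            "k_mis": g.k_mis,
            "k_sil": g.k_sil,
            "n_indel": g.n_indel,
            "n_carriers": len(g.carriers),
            "ns_frequency": g.ns_frequency,
            "protein_length": g.protein_length,
        }
        for g in sorted(genes.values(), key=lambda a: a.gene)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
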