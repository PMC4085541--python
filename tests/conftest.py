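import numpy as np
import pytest

from driverscope import MutationRecord, SimSpec, simulate
from driverscope.maf_io import GeneModel


@pytest.fixture(scope="session")
def tiny_models():
    """Two hand-built gene models with explicit CDS."""
    def make(gene, cds):
        from driverscope.maf_io import _codon_counts_from_cds

        return GeneModel(
            gene=gene,
            protein_length=len(cds) // 3 - 1,
            codon_counts=_codon_counts_from_cds(cds),
            cds=cds,
        )

    # GA: 4 codons + stop; GB: 6 codons + stop
    return {
        "GA": make("GA", "ATGAAACCCGGGTAA"),
        "GB": make("GB", "ATGTGGTGGAAAGAATTTTGA"),
    }


@pytest.fixture(scope="session")
def tiny_cohort_records():
    """Three patients, two genes, hand-countable categories."""
    R = MutationRecord
    return [
        R("GA", "P1", "Missense_Mutation", "SNP", 2, 1.5),
        R("GA", "P1", "Nonsense_Mutation", "SNP", 3, None),
        R("GA", "P2", "Silent", "SNP", 4, None),
        R("GB", "P1", "Frame_Shift_Del", "DEL", 1, None),
        R("GB", "P2", "Missense_Mutation", "SNP", 5, 2.0),
        R("GB", "P2", "In_Frame_Ins", "INS", 2, 0.5),
        R("GB", "P3", "Silent", "SNP", 6, None),
        R("GB", "P3", "3'UTR", "SNP", None, None),  # excluded everywhere
    ]


@pytest.fixture(scope="session")
def small_planted_cohort():
    """A reduced planted cohort for pipeline tests (fast to fit)."""
    spec = SimSpec(
        n_samples=60,
        n_genes=120,
        n_tsg=1,
        n_og=1,
        n_fishy=1,
        tsg_carriers=20,
        og_carriers=15,
        median_mutations=30.0,
        seed=42,
    )
    return simulate(spec)
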