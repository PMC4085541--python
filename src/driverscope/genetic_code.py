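"""Standard-genetic-code utilities.

Two things live here: the exhaustive census of the 576 single-base codon
substitutions (the combinatorial backbone of the truncating / missense /
silent accounting), and the per-gene probability that a random single-base
substitution on a coding sequence is non-silent, which feeds the
non-synonymous vs synonymous ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "BASES",
    "CODONS",
    "STOP",
    "SubstitutionCensus",
    "GeneNsModel",
    "translate",
    "substitution_census",
    "codon_nonsilent_fraction",
    "gene_ns_probability",
    "ns_probability_from_codon_counts",
]

BASES = "ACGT"
#: all 64 codons in lexicographic ACGT order; this order is the contract for
#: every 64-vector of codon counts in the package.
CODONS: tuple[str, ...] = tuple("".join(c) for c in product(BASES, repeat=3))
STOP = "*"

_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODE[_stop] = STOP

#: the 12 ordered nucleotide changes, e.g. "A>C"; the key order is the
#: contract for spectrum vectors.
CHANGES: tuple[str, ...] = tuple(
    f"{a}>{b}" for a in BASES for b in BASES if a != b
)
_CHANGE_INDEX = {c: i for i, c in enumerate(CHANGES)}


def translate(codon: str) -> str:
    """Translate one DNA codon to its amino-acid symbol ('*' for stop).

    Parameters
    ----------
    codon : str
        Three-letter DNA string over {A, C, G, T}; lowercase accepted.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"not a DNA codon: {codon!r}")
    return _CODE[codon]


@dataclass(frozen=True)
class SubstitutionCensus:
    """Exhaustive classification of all 64 x 9 single-base codon substitutions.

    The five fine-grained classes partition the 576 substitutions:

    ``n_stop_gain``       sense codon -> stop (truncating SNVs)
    ``n_stop_loss``       stop codon -> sense codon
    ``n_missense_sense``  sense -> different sense amino acid
    ``n_synonymous``      sense -> same amino acid
    ``n_stop_to_stop``    stop -> stop

    Three aggregates reproduce the classical accounting in which the 576
    changes split into 23 truncating, 415 non-synonymous and 138 silent:
    ``n_nonsense`` (= stop gains), ``n_nonsyn_sense`` (= missense + stop
    loss, i.e. every symbol-changing substitution that is not a stop gain)
    and ``n_symbol_preserving`` (= synonymous + stop-to-stop).
    """

    n_stop_gain: int
    n_stop_loss: int
    n_missense_sense: int
    n_synonymous: int
    n_stop_to_stop: int

    @property
    def n_total(self) -> int:
        return (
            self.n_stop_gain
            + self.n_stop_loss
            + self.n_missense_sense
            + self.n_synonymous
            + self.n_stop_to_stop
        )

    @property
    def n_nonsense(self) -> int:
        return self.n_stop_gain

    @property
    def n_nonsyn_sense(self) -> int:
        return self.n_missense_sense + self.n_stop_loss

    @property
    def n_symbol_preserving(self) -> int:
        return self.n_synonymous + self.n_stop_to_stop


def _classify_substitution(src: str, dst: str) -> str:
    a, b = _CODE[src], _CODE[dst]
    if a != STOP and b == STOP:
        return "stop_gain"
    if a == STOP and b != STOP:
        return "stop_loss"
    if a == STOP and b == STOP:
        return "stop_to_stop"
    return "synonymous" if a == b else "missense_sense"


def substitution_census() -> SubstitutionCensus:
    """Enumerate and classify all single-base substitutions of the 64 codons."""
    counts = {
        "stop_gain": 0,
        "stop_loss": 0,
        "missense_sense": 0,
        "synonymous": 0,
        "stop_to_stop": 0,
    }
    for codon in CODONS:
        for i in range(3):
            for b in BASES:
                if b == codon[i]:
                    continue
                counts[_classify_substitution(codon, codon[:i] + b + codon[i + 1 :])] += 1
    return SubstitutionCensus(
        n_stop_gain=counts["stop_gain"],
        n_stop_loss=counts["stop_loss"],
        n_missense_sense=counts["missense_sense"],
        n_synonymous=counts["synonymous"],
        n_stop_to_stop=counts["stop_to_stop"],
    )


@dataclass(frozen=True)
class GeneNsModel:
    """Per-gene non-silent substitution probability.

    ``p_ns`` is the probability that a single-base substitution placed on the
    gene's coding sequence (position and change drawn from the mutational
    spectrum, uniform by default) changes the translated symbol: amino-acid
    change, stop gain or stop loss.
    """

    gene: str
    p_ns: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_ns <= 1.0:
            raise ValueError(f"p_ns out of [0,1]: {self.p_ns}")


def _spectrum_weights(spectrum: Sequence[float] | Mapping[str, float] | None) -> np.ndarray:
    if spectrum is None:
        return np.ones(12)
    if isinstance(spectrum, Mapping):
        w = np.zeros(12)
        for k, v in spectrum.items():
            w[_CHANGE_INDEX[k]] = v
    else:
        w = np.asarray(spectrum, dtype=float)
        if w.shape != (12,):
            raise ValueError("spectrum must have 12 entries (ordered as CHANGES)")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("spectrum weights must be non-negative with positive sum")
    return w


def codon_nonsilent_fraction(
    codon: str, spectrum: Sequence[float] | Mapping[str, float] | None = None
) -> tuple[float, float]:
    """Return (total weight, non-silent weight) over a codon's 9 substitutions."""
    w = _spectrum_weights(spectrum)
    codon = codon.upper()
    tot = ns = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            wt = w[_CHANGE_INDEX[f"{codon[i]}>{b}"]]
            tot += wt
            klass = _classify_substitution(codon, codon[:i] + b + codon[i + 1 :])
            if klass not in ("synonymous", "stop_to_stop"):
                ns += wt
    return tot, ns


def gene_ns_probability(
    cds: str,
    gene: str = "",
    spectrum: Sequence[float] | Mapping[str, float] | None = None,
) -> GeneNsModel:
    """Non-silent probability of a random substitution on a coding sequence.

    Enumerates every single-base change at every position of ``cds``,
    weighting changes by the (12-entry) nucleotide-change spectrum; uniform
    when no spectrum is given.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if any(b not in BASES for b in cds):
        raise ValueError("CDS contains non-DNA letters")
    tot = ns = 0.0
    for i in range(0, len(cds), 3):
        t, n = codon_nonsilent_fraction(cds[i : i + 3], spectrum)
        tot += t
        ns += n
    if tot == 0:
        raise ValueError("spectrum assigns zero weight to every change on this CDS")
    return GeneNsModel(gene=gene, p_ns=ns / tot)


def ns_probability_from_codon_counts(
    codon_counts: Sequence[float],
    gene: str = "",
    spectrum: Sequence[float] | Mapping[str, float] | None = None,
) -> GeneNsModel:
    """Same as :func:`gene_ns_probability` but from a 64-vector of codon counts.

    The count vector follows the ``CODONS`` (lexicographic ACGT) order.
    """
    counts = np.asarray(codon_counts, dtype=float)
    if counts.shape != (64,):
        raise ValueError("codon_counts must be a 64-vector in CODONS order")
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("codon_counts must be non-negative with positive sum")
    tot = ns = 0.0
    for codon, c in zip(CODONS, counts):
        if c == 0:
            continue
        t, n = codon_nonsilent_fraction(codon, spectrum)
        tot += c * t
        ns += c * n
    return GeneNsModel(gene=gene, p_ns=ns / tot)
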