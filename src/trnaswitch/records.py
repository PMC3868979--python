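"""Core domain types for tRNA gene repertoires.

A :class:`TRNAGeneRecord` holds one tRNA gene as annotated by a tRNA gene
finder: its genomic sequence (DNA, sense orientation), the anticodon triplet
and its offset within the gene, the covariance-model bit score (COVE score)
used to separate genuine genes from pseudogenes, and species bookkeeping.
A :class:`SpeciesRepertoire` is the per-species collection the screen
operates on: all downstream stages (masking, alignment, tree building,
switch calling) run within a single species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

DOMAINS = ("bacteria", "archaea", "eukaryota", "unknown")

_DNA = set("ACGTN")

# codon tables are overkill here: the amino acid is cosmetic metadata, but we
# derive it from the anticodon when the input does not annotate it.
_CODON_TO_AA3 = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import standard_dna_table
    from Bio.SeqUtils import seq3

    for codon, aa1 in standard_dna_table.forward_table.items():
        _CODON_TO_AA3[codon] = seq3(aa1)
    for codon in standard_dna_table.stop_codons:
        _CODON_TO_AA3[codon] = "Und"


def anticodon_to_amino_acid(anticodon: str) -> str:
    """Three-letter amino acid decoded by a tRNA with this (DNA) anticodon.

    The codon read by the tRNA is the reverse complement of the anticodon.
    Stop-codon-reading (suppressor-like) anticodons map to ``"Und"``.
    """
    if not _CODON_TO_AA3:
        _build_codon_table()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    try:
        codon = "".join(comp[b] for b in reversed(anticodon.upper()))
    except KeyError:
        return "Und"
    return _CODON_TO_AA3.get(codon, "Und")


def rna(triplet: str) -> str:
    """Render a DNA triplet in RNA lettering (T -> U) for reports."""
    return triplet.upper().replace("T", "U")


@dataclass(frozen=True)
class TRNAGeneRecord:
    """One tRNA gene.

    Parameters
    ----------
    gene_id : str
        Unique identifier within the species.
    species_id : str
        Species the gene belongs to.
    amino_acid : str
        Three-letter code of the decoded amino acid, or ``"Und"``.
    anticodon : str
        Anticodon triplet as DNA (``T``, not ``U``).
    anticodon_start : int
        0-based offset of the anticodon within ``sequence``.
    sequence : str
        Uppercase DNA over ``{A,C,G,T,N}``, 50-250 nt.
    cove_score : float
        Covariance-model bit score; genes below 40.0 bits are treated as
        pseudogenes by the default filter.
    domain_of_life : str
        One of ``bacteria``, ``archaea``, ``eukaryota``, ``unknown``.
    """

    gene_id: str
    species_id: str
    anticodon: str
    anticodon_start: int
    sequence: str
    cove_score: float | None = None
    amino_acid: str = "Und"
    domain_of_life: str = "unknown"

    def __post_init__(self) -> None:
        seq = self.sequence
        if seq != seq.upper():
            raise ValueError(f"{self.gene_id}: sequence must be uppercase")
        if not set(seq) <= _DNA:
            bad = sorted(set(seq) - _DNA)
            raise ValueError(f"{self.gene_id}: non-DNA characters {bad!r}")
        if not 50 <= len(seq) <= 250:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(seq)} outside [50, 250]"
            )
        ac = self.anticodon
        if len(ac) != 3 or not set(ac) <= set("ACGT"):
            raise ValueError(f"{self.gene_id}: bad anticodon {ac!r}")
        if self.domain_of_life not in DOMAINS:
            raise ValueError(
                f"{self.gene_id}: domain {self.domain_of_life!r} not in {DOMAINS}"
            )
        start = self.anticodon_start
        if start is not None:
            if not 0 <= start <= len(seq) - 3:
                raise ValueError(f"{self.gene_id}: anticodon_start out of bounds")
            window = seq[start : start + 3]
            if window != ac:
                raise ValueError(
                    f"{self.gene_id}: sequence[{start}:{start + 3}]={window!r} "
                    f"does not match anticodon {ac!r}"
                )

    def with_(self, **kwargs) -> "TRNAGeneRecord":
        return replace(self, **kwargs)


@dataclass
class SpeciesRepertoire:
    """Ordered collection of tRNA genes from one species."""

    species_id: str
    records: list[TRNAGeneRecord] = field(default_factory=list)
    domain_of_life: str = "unknown"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.species_id != self.species_id:
                raise ValueError(
                    f"record {rec.gene_id} has species {rec.species_id!r}, "
                    f"repertoire is {self.species_id!r}"
                )
            if rec.gene_id in seen:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
            seen.add(rec.gene_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TRNAGeneRecord]:
        return iter(self.records)

    def gene_ids(self) -> list[str]:
        return [rec.gene_id for rec in self.records]


def locate_anticodon(sequence: str, anticodon: str) -> int | None:
    """Best-guess 0-based anticodon offset when coordinates are not given.

    Returns the offset of the occurrence of ``anticodon`` in ``sequence``
    closest to the sequence midpoint (the anticodon loop sits near the middle
    of the molecule), or ``None`` if the triplet does not occur at all.
    """
    hits = []
    start = sequence.find(anticodon)
    while start != -1:
        hits.append(start)
        start = sequence.find(anticodon, start + 1)
    if not hits:
        return None
    mid = (len(sequence) - 3) / 2.0
    return min(hits, key=lambda h: (abs(h - mid), h))
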