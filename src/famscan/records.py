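"""Core sequence and table containers shared by every pipeline stage.

Coordinate convention: every interval in memory is 0-based, half-open
``[start, end)``.  1-based inclusive coordinates appear only in rendered
reports (GFF, TSV output), never in the data model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}
NUCLEOTIDES = set("ACGT")
NUCLEOTIDE_ALPHABET = NUCLEOTIDES | {"N"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with an identifier.

    The alphabet is the 20 standard residues plus ``X`` for unknowns;
    lowercase input is accepted and uppercased.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.id:
            raise ValueError("protein record must have a non-empty id")
        if not self.sequence:
            raise ValueError(f"protein record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein record {self.id!r} contains non-amino-acid "
                f"letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NucleotideRecord:
    """A DNA sequence (ACGT plus ``N``) with an identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.id:
            raise ValueError("nucleotide record must have a non-empty id")
        if not self.sequence:
            raise ValueError(f"nucleotide record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            raise ValueError(
                f"nucleotide record {self.id!r} contains non-nucleotide "
                f"letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "NucleotideRecord":
        return NucleotideRecord(self.id, reverse_complement(self.sequence))


@dataclass
class GeneModel:
    """A CDS laid out on a genomic sequence as an ordered exon chain.

    ``exons`` are 0-based half-open intervals on ``genomic`` (always in
    ascending genomic order regardless of strand).  Splicing the exons
    together (and reverse-complementing on the minus strand) must
    reproduce the coding sequence exactly.
    """

    gene_id: str
    genomic: NucleotideRecord
    exons: list[tuple[int, int]]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene model {self.gene_id!r} has no exons")
        prev_end = None
        for start, end in self.exons:
            if not (0 <= start < end <= len(self.genomic)):
                raise ValueError(
                    f"gene model {self.gene_id!r}: exon [{start}, {end}) "
                    f"outside genomic sequence of length {len(self.genomic)}"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"gene model {self.gene_id!r}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intervals strictly between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def spliced(self) -> str:
        """The coding sequence implied by the exon chain."""
        seq = "".join(self.genomic.sequence[s:e] for s, e in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq


class FpkmMatrix:
    """A genes x tissues matrix of non-negative FPKM values."""

    def __init__(self, frame: pd.DataFrame):
        if frame.empty:
            raise ValueError("FPKM matrix is empty")
        values = frame.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("FPKM matrix contains negative values")
        if frame.index.duplicated().any():
            dupes = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids in FPKM matrix: {dupes}")
        self.frame = frame.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.frame.columns)

    def profile(self, gene: str):
        return self.frame.loc[gene].to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"FpkmMatrix({len(self.genes)} genes x {len(self.tissues)} tissues)"


@dataclass
class PlaceMotif:
    """A cis-regulatory element: PLACE-style id plus IUPAC pattern."""

    element_id: str
    iupac: str

    def __post_init__(self) -> None:
        from .promoter import IUPAC_CODES  # local import avoids a cycle

        self.iupac = self.iupac.upper()
        if not self.iupac:
            raise ValueError(f"element {self.element_id!r} has an empty pattern")
        bad = set(self.iupac) - set(IUPAC_CODES)
        if bad:
            raise ValueError(
                f"element {self.element_id!r} uses invalid IUPAC "
                f"codes: {sorted(bad)}"
            )


@dataclass
class ElementHit:
    """A match of a cis-element in a promoter.

    ``start`` is the 0-based position of the match window on the forward
    promoter sequence; for minus-strand hits ``matched`` is the reverse
    complement of that window, i.e. the sequence that satisfies the
    IUPAC pattern on the reported strand.
    """

    gene_id: str
    element_id: str
    start: int
    strand: str
    matched: str


@dataclass
class MotifHit:
    """A protein motif match, 0-based half-open on the protein."""

    protein_id: str
    start: int
    end: int
    matched: str


@dataclass
class KaKsResult:
    """NG86 substitution summary for one aligned coding-sequence pair.

    ``s_sites``/``n_sites`` are synonymous/nonsynonymous site counts
    averaged over the two sequences; ``ka``/``ks`` carry the
    Jukes-Cantor correction.  ``mya`` converts Ks to million years via
    the molecular clock ``Ks / (2 * lambda_rate) * 1e-6``.
    """

    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ka: float
    ks: float
    ratio: float | None
    lambda_rate: float
    mya: float
    selection_class: str
    n_codons: int
    saturated: bool = False
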