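"""Promoter scanning for IUPAC-coded cis-regulatory elements.

Elements come from a PLACE-style table (id + degenerate nucleotide
pattern).  Promoters are typically the 1,500 bp upstream of the
translation start.  Both strands are scanned by default: a minus-strand
hit is a forward-sequence window whose reverse complement satisfies the
pattern.  All (self-)overlapping matches are reported.
"""

from __future__ import annotations

import re
from collections import defaultdict

from .records import ElementHit, NucleotideRecord, PlaceMotif, reverse_complement

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_to_regex(iupac: str) -> re.Pattern:
    parts = []
    for code in iupac:
        bases = IUPAC_CODES.get(code)
        if bases is None:
            raise ValueError(f"invalid IUPAC code {code!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def iupac_reverse_complement(iupac: str) -> str:
    return iupac.translate(_IUPAC_COMPLEMENT)[::-1]


def iupac_matches(iupac: str, window: str) -> bool:
    """True when ``window`` satisfies the degenerate pattern exactly."""
    return len(window) == len(iupac) and all(
        base in IUPAC_CODES[code] for code, base in zip(iupac, window)
    )


def scan_promoter(
    promoter: NucleotideRecord,
    motifs: list[PlaceMotif],
    both_strands: bool = True,
) -> list[ElementHit]:
    """All element matches in a promoter, overlaps included.

    Hits are ordered by (element id, strand, start).  ``start`` is the
    0-based forward-strand coordinate of the match window; for a
    minus-strand hit ``matched`` is the reverse complement of that
    window.  Invalid IUPAC codes raise ``ValueError`` naming the
    element.
    """
    seq = promoter.sequence
    hits: list[ElementHit] = []
    for motif in motifs:
        try:
            rx_fwd = iupac_to_regex(motif.iupac)
        except ValueError as exc:
            raise ValueError(f"element {motif.element_id!r}: {exc}") from exc
        strand_rx = [("+", rx_fwd)]
        if both_strands:
            strand_rx.append(
                ("-", iupac_to_regex(iupac_reverse_complement(motif.iupac)))
            )
        for strand, rx in strand_rx:
            pos = 0
            while True:
                m = rx.search(seq, pos)
                if m is None:
                    break
                window = m.group(0)
                matched = (
                    window if strand == "+" else reverse_complement(window)
                )
                hits.append(
                    ElementHit(
                        gene_id=promoter.id,
                        element_id=motif.element_id,
                        start=m.start(),
                        strand=strand,
                        matched=matched,
                    )
                )
                pos = m.start() + 1  # overlapping matches
    hits.sort(key=lambda h: (h.element_id, h.strand, h.start))
    return hits


def summarize_elements(hits_by_gene: dict[str, list[ElementHit]]) -> dict:
    """Shared / gene-specific element summary over a promoter set.

    ``shared`` = elements with at least one hit in every gene;
    ``gene_specific`` = elements hit in exactly one gene (mapped to that
    gene); ``per_gene_counts`` = distinct elements per gene.
    """
    if not hits_by_gene:
        raise ValueError("no genes to summarize")
    genes = list(hits_by_gene)
    element_genes: dict[str, set[str]] = defaultdict(set)
    for gene, hits in hits_by_gene.items():
        for hit in hits:
            element_genes[hit.element_id].add(gene)
    shared = sorted(
        el for el, gs in element_genes.items() if len(gs) == len(genes)
    )
    specific = {
        el: next(iter(gs))
        for el, gs in sorted(element_genes.items())
        if len(gs) == 1
    }
    per_gene = {
        gene: len({h.element_id for h in hits})
        for gene, hits in hits_by_gene.items()
    }
    return {
        "shared_elements": shared,
        "gene_specific_elements": specific,
        "per_gene_counts": per_gene,
    }
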