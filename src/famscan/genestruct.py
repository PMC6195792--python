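"""Exon-intron structure inference from a CDS and its genomic sequence.

The CDS is assumed to occur *exactly* (mismatch tolerance 0) within the
genomic sequence as a chain of exons separated by introns of at least
``min_intron`` bp.  Among all exact chains the solver prefers
(1) chains whose introns all have canonical GT...AG ends, then
(2) chains with fewer introns, then (3) the leftmost placement — the
last rule resolves "sliding" introns created by repeated bases at the
splice junction.  The search is a memoized depth-first chaining over
exact-substring anchors, trying the plus strand first and falling back
to the reverse complement.
"""

from __future__ import annotations

from .records import GeneModel, NucleotideRecord, reverse_complement

MIN_INTRON = 20
_ANCHOR = 12


class SpliceError(ValueError):
    """No exact exon chain reproduces the CDS from the genomic sequence."""


def _lce(a: str, ai: int, b: str, bi: int) -> int:
    """Longest common extension of a[ai:] and b[bi:]."""
    n = 0
    la, lb = len(a), len(b)
    while ai + n < la and bi + n < lb and a[ai + n] == b[bi + n]:
        n += 1
    return n


def _occurrences(needle: str, haystack: str, start: int):
    pos = haystack.find(needle, start)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)


def _solve(cds: str, genomic: str, min_intron: int):
    """Best exon chain or None.  Score = (non-canonical introns,
    intron count, exon interval tuple); smaller is better."""
    nc = len(cds)
    memo: dict[tuple[int, int], tuple | None] = {}

    def best(ci: int, gi: int):
        key = (ci, gi)
        if key in memo:
            return memo[key]
        memo[key] = None  # cycle guard; overwritten below
        rem = nc - ci
        ext = _lce(cds, ci, genomic, gi)
        candidates = []
        if ext >= rem:
            candidates.append((0, 0, ((gi, gi + rem),)))
        for length in range(1, min(ext, rem - 1) + 1):
            ci2 = ci + length
            donor = gi + length
            anchor = cds[ci2 : ci2 + _ANCHOR]
            canonical_donor = genomic[donor : donor + 2] == "GT"
            for g2 in _occurrences(anchor, genomic, donor + min_intron):
                canonical = canonical_donor and genomic[g2 - 2 : g2] == "AG"
                sub = best(ci2, g2)
                if sub is None:
                    continue
                candidates.append(
                    (
                        sub[0] + (0 if canonical else 1),
                        sub[1] + 1,
                        ((gi, gi + length),) + sub[2],
                    )
                )
        result = min(candidates) if candidates else None
        memo[key] = result
        return result

    overall = None
    start_anchor = cds[: min(_ANCHOR, nc)]
    for g0 in _occurrences(start_anchor, genomic, 0):
        sol = best(0, g0)
        if sol is not None and (overall is None or sol < overall):
            overall = sol
    return overall


def infer_structure(
    cds: NucleotideRecord,
    genomic: NucleotideRecord,
    min_intron: int = MIN_INTRON,
    gene_id: str | None = None,
) -> GeneModel:
    """Infer the exon chain embedding ``cds`` in ``genomic``.

    Tries the plus strand first; if the CDS only embeds in the reverse
    complement, the returned model has strand ``-`` with exons in
    genomic (plus-strand) coordinates.  Raises :class:`SpliceError`
    when no exact chain exists on either strand.
    """
    if len(cds) % 3:
        raise ValueError(f"CDS {cds.id!r} length is not a multiple of 3")
    if len(genomic) < len(cds):
        raise ValueError(
            f"genomic sequence shorter than CDS for {cds.id!r}"
        )
    gid = gene_id or cds.id
    sol = _solve(cds.sequence, genomic.sequence, min_intron)
    if sol is not None:
        return GeneModel(gid, genomic, list(sol[2]), strand="+")
    rc = reverse_complement(genomic.sequence)
    sol = _solve(cds.sequence, rc, min_intron)
    if sol is not None:
        glen = len(genomic)
        exons = sorted((glen - e, glen - s) for s, e in sol[2])
        return GeneModel(gid, genomic, exons, strand="-")
    raise SpliceError(
        f"no-splice-solution: CDS {cds.id!r} cannot be spliced from the "
        f"genomic sequence on either strand"
    )


def intron_phases(model: GeneModel) -> list[int]:
    """Phase of each intron: cumulative coding length (mod 3) upstream
    of the splice junction, in transcription order."""
    lengths = [e - s for s, e in model.exons]
    if model.strand == "-":
        lengths = lengths[::-1]
    phases = []
    acc = 0
    for length in lengths[:-1]:
        acc += length
        phases.append(acc % 3)
    return phases


def canonical_flags(model: GeneModel) -> list[int]:
    """1 when the intron has GT...AG ends (plus-strand coordinates are
    complemented for minus-strand genes), else 0; transcription order."""
    seq = model.genomic.sequence
    flags = []
    introns = model.introns
    if model.strand == "-":
        introns = introns[::-1]
    for s, e in introns:
        if model.strand == "+":
            ok = seq[s : s + 2] == "GT" and seq[e - 2 : e] == "AG"
        else:
            ok = (
                reverse_complement(seq[e - 2 : e]) == "GT"
                and reverse_complement(seq[s : s + 2]) == "AG"
            )
        flags.append(int(ok))
    return flags


def write_gff3(models: list[GeneModel], path) -> None:
    """Render gene/exon/intron features as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = (m.exons[0][0] + 1, m.exons[-1][1])
            fh.write(
                f"{m.genomic.id}\tfamscan\tgene\t{span[0]}\t{span[1]}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.genomic.id}\tfamscan\texon\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\tID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )
            for i, (s, e) in enumerate(m.introns, 1):
                fh.write(
                    f"{m.genomic.id}\tfamscan\tintron\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\tID={m.gene_id}.intron{i};Parent={m.gene_id}\n"
                )
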