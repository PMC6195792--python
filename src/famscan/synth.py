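"""Seeded generators emulating the data each pipeline stage consumes.

Every generator is a pure function of ``(config, index)``: the same
config and index always produce the same records, and each generated
object carries its ground-truth annotation (planted motif position,
exon chain, applied substitution counts, planted element positions,
expression class) so downstream stages can be scored for recall.

Default parameters mirror a small plant channel-family survey: a dozen
family members among a similar number of CNBD-carrying decoys, protein
lengths of roughly 330-745 aa, genes with 0-7 canonical GT..AG introns,
1,500-bp promoters, duplicate pairs near Ks = 0.18 with Ka/Ks = 0.14,
and a 12-gene x 6-tissue FPKM matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kaks import GENETIC_CODE, SENSE_CODONS, codon_sites
from .records import (
    ElementHit,
    FpkmMatrix,
    GeneModel,
    NucleotideRecord,
    PlaceMotif,
    ProteinRecord,
    reverse_complement,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

# op tags keep per-operation random streams independent
_TAG_PROTEIN, _TAG_DECOY, _TAG_GENE, _TAG_PAIR = 1, 2, 3, 4
_TAG_PROMOTER, _TAG_FPKM, _TAG_MSA = 5, 6, 7


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_cngc: int = 12
    n_decoy: int = 11
    protein_length: tuple[int, int] = (330, 745)
    n_introns: tuple[int, int] = (0, 7)
    intron_length: tuple[int, int] = (80, 1200)
    flank_length: tuple[int, int] = (60, 300)
    n_codons: int = 900
    target_ks: float = 0.18
    omega: float = 0.14
    ts_tv: float = 2.0
    promoter_length: int = 1500
    planted_elements: list[PlaceMotif] = field(default_factory=list)
    tissues: tuple[str, ...] = (
        "ear", "embryo", "endosperm", "pollen", "root", "tassel",
    )
    n_genes_fpkm: int = 12
    n_silent: int = 1
    specific_fraction: float = 2.0 / 3.0
    expressed_threshold: float = 1.0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.protein_length, self.n_introns,
            self.intron_length, self.flank_length,
        ):
            if lo > hi:
                raise ValueError(f"invalid range ({lo}, {hi})")
        if self.intron_length[0] < 20:
            raise ValueError("intron length minimum must be >= 20 bp")
        if not 0 <= self.target_ks <= 0.7:
            raise ValueError("target_ks must be in [0, 0.7]")
        if not 0 <= self.omega <= 1:
            raise ValueError("omega must be in [0, 1]")
        if len(self.tissues) < 2:
            raise ValueError("need at least 2 tissues")


def _rng(config: SyntheticConfig, tag: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed % 2**31, tag, index])
    )


def _random_aa(rng, n: int) -> str:
    return "".join(rng.choice(list(_AA), size=n))


def _random_nt(rng, n: int) -> str:
    return "".join(rng.choice(list(_NT), size=n))


# -- motif-bearing proteins --------------------------------------------

def expand_pattern(pattern, rng) -> str:
    """One concrete string accepted by a compiled motif pattern."""
    out = []
    for pos in pattern.positions:
        reps = int(rng.integers(pos.min_repeat, pos.max_repeat + 1))
        pool = _AA if pos.residues is None else "".join(sorted(pos.residues))
        out.append("".join(rng.choice(list(pool), size=reps)))
    return "".join(out)


@dataclass
class PlantedProtein:
    record: ProteinRecord
    motif_start: int
    motif_seq: str


def gen_cngc_protein(
    config: SyntheticConfig, index: int = 0, pattern=None
) -> PlantedProtein:
    """A background protein with one motif expansion planted inside it."""
    from .motifs import stringent_pattern

    pattern = pattern or stringent_pattern()
    rng = _rng(config, _TAG_PROTEIN, index)
    lo, hi = config.protein_length
    length = int(rng.integers(lo, hi + 1))
    motif = expand_pattern(pattern, rng)
    if length < len(motif):
        raise ValueError(
            f"protein length {length} is below the motif span {len(motif)}"
        )
    start = int(rng.integers(0, length - len(motif) + 1))
    bg = _random_aa(rng, length)
    seq = bg[:start] + motif + bg[start + len(motif):]
    return PlantedProtein(
        ProteinRecord(f"CNGC_like_{index:02d}", seq), start, motif
    )


def gen_decoy_protein(
    config: SyntheticConfig, index: int = 0, pattern=None
) -> ProteinRecord:
    """A motif-free background protein (AKT/KAT-style false positive).

    Rejection-sampled so the diagnostic pattern never matches."""
    from .motifs import scan, stringent_pattern

    pattern = pattern or stringent_pattern()
    rng = _rng(config, _TAG_DECOY, index)
    lo, hi = config.protein_length
    for _ in range(100):
        length = int(rng.integers(lo, hi + 1))
        rec = ProteinRecord(f"AKT_like_{index:02d}", _random_aa(rng, length))
        if not scan(pattern, rec):
            return rec
    raise RuntimeError("could not sample a motif-free decoy")  # pragma: no cover


def gen_proteome(
    config: SyntheticConfig, pattern=None
) -> tuple[list[ProteinRecord], dict[str, bool]]:
    """Mixed proteome of planted family members and decoys, with truth."""
    records, truth = [], {}
    for i in range(config.n_cngc):
        planted = gen_cngc_protein(config, i, pattern)
        records.append(planted.record)
        truth[planted.record.id] = True
    for i in range(config.n_decoy):
        rec = gen_decoy_protein(config, i, pattern)
        records.append(rec)
        truth[rec.id] = False
    return records, truth


# -- gene models --------------------------------------------------------

def _random_cds(rng, n_codons: int) -> str:
    """An open reading frame: ATG, sense codons, trailing stop."""
    codons = ["ATG"]
    codons += list(rng.choice(SENSE_CODONS, size=n_codons - 2))
    codons.append(str(rng.choice(["TAA", "TAG", "TGA"])))
    return "".join(codons)


@dataclass
class PlantedGene:
    model: GeneModel
    cds: NucleotideRecord
    genomic: NucleotideRecord
    phases: list[int]


def gen_gene_model(
    config: SyntheticConfig, index: int = 0, n_introns: int | None = None
) -> PlantedGene:
    """A CDS embedded in a genomic sequence with planted GT..AG introns."""
    rng = _rng(config, _TAG_GENE, index)
    if n_introns is None:
        n_introns = int(
            rng.integers(config.n_introns[0], config.n_introns[1] + 1)
        )
    n_codons = int(rng.integers(150, 400))
    cds = _random_cds(rng, n_codons)
    # intron insertion points spaced so every exon is >= 30 bp; the
    # structure solver anchors on 12-bp exact matches, so micro-exons
    # are out of scope for the generator
    for _ in range(1000):
        cuts = sorted(
            int(c) for c in rng.integers(30, len(cds) - 29, size=n_introns)
        )
        if all(b - a >= 30 for a, b in zip(cuts, cuts[1:])):
            break
    else:  # pragma: no cover - ranges guarantee feasibility
        raise RuntimeError("could not place spaced introns")
    flank5 = _random_nt(rng, int(rng.integers(*_incl(config.flank_length))))
    flank3 = _random_nt(rng, int(rng.integers(*_incl(config.flank_length))))
    pieces = [flank5]
    exons = []
    cursor = len(flank5)
    prev = 0
    phases = []
    for cut in cuts:
        exon = cds[prev:cut]
        pieces.append(exon)
        exons.append((cursor, cursor + len(exon)))
        cursor += len(exon)
        ilen = int(rng.integers(*_incl(config.intron_length)))
        intron = "GT" + _random_nt(rng, ilen - 4) + "AG"
        pieces.append(intron)
        cursor += ilen
        phases.append(cut % 3)
        prev = cut
    exon = cds[prev:]
    pieces.append(exon)
    exons.append((cursor, cursor + len(exon)))
    pieces.append(flank3)
    genomic = NucleotideRecord(f"gene_{index:02d}", "".join(pieces))
    cds_rec = NucleotideRecord(f"gene_{index:02d}", cds)
    model = GeneModel(f"gene_{index:02d}", genomic, exons, "+")
    return PlantedGene(model, cds_rec, genomic, phases)


def _incl(rng_pair):
    return rng_pair[0], rng_pair[1] + 1


# -- duplicate CDS pairs for Ka/Ks -------------------------------------

def _codon_changes(codon: str):
    """All single-nt changes of a sense codon that avoid stops."""
    out = []
    for pos in range(3):
        for base in _NT:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if GENETIC_CODE[mutant] == "*":
                continue
            out.append(
                (
                    pos,
                    base,
                    mutant,
                    GENETIC_CODE[mutant] == GENETIC_CODE[codon],
                    (codon[pos], base) in _TRANSITIONS,
                )
            )
    return out


@dataclass
class PlantedPair:
    cds_a: NucleotideRecord
    cds_b: NucleotideRecord
    applied_syn: int
    applied_nonsyn: int
    s_sites: float
    n_sites: float
    true_ks: float
    true_ka: float
    target_ks: float
    target_ka: float


def _p_from_k(k: float) -> float:
    return 0.75 * (1.0 - np.exp(-4.0 / 3.0 * k))


def _k_from_p(p: float) -> float:
    return float(-0.75 * np.log1p(-4.0 / 3.0 * p))


def gen_duplicate_pair(config: SyntheticConfig, index: int = 0) -> PlantedPair:
    """A duplicate CDS pair with controlled synonymous divergence.

    One copy of a random ancestor is mutated by Poisson numbers of
    synonymous and nonsynonymous single-nucleotide codon changes
    (transition/transversion bias ``ts_tv``; stops rejected).  The
    recorded truth is the realized applied-change count converted to a
    rate over the ancestor's NG86 site totals, Jukes-Cantor corrected.
    """
    rng = _rng(config, _TAG_PAIR, index)
    cds = _random_cds(rng, config.n_codons + 2)[3:-3]  # strip ATG/stop
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    s_sites = sum(codon_sites(c)[0] for c in codons)
    n_sites = sum(codon_sites(c)[1] for c in codons)
    target_ka = config.omega * config.target_ks
    n_syn = int(rng.poisson(s_sites * config.target_ks))
    n_nonsyn = int(rng.poisson(n_sites * target_ka))
    applied = {"syn": 0, "nonsyn": 0}

    def apply_changes(count: int, synonymous: bool) -> None:
        for _ in range(count):
            for _attempt in range(10000):
                ci = int(rng.integers(len(codons)))
                options = [
                    c for c in _codon_changes(codons[ci])
                    if c[3] == synonymous
                ]
                if not options:
                    continue
                weights = np.array(
                    [config.ts_tv if o[4] else 1.0 for o in options]
                )
                choice = options[
                    int(rng.choice(len(options), p=weights / weights.sum()))
                ]
                codons[ci] = choice[2]
                applied["syn" if synonymous else "nonsyn"] += 1
                break
            else:  # pragma: no cover - infeasible target
                raise RuntimeError("no eligible positions left for changes")

    apply_changes(n_syn, True)
    apply_changes(n_nonsyn, False)
    derived = "".join(codons)
    # truth is the realized number of applied events per NG86 site; the
    # Jukes-Cantor correction is the estimator's job, not the truth's
    true_ks = applied["syn"] / s_sites
    true_ka = applied["nonsyn"] / n_sites
    return PlantedPair(
        cds_a=NucleotideRecord(f"dup_{index:02d}_a", cds),
        cds_b=NucleotideRecord(f"dup_{index:02d}_b", derived),
        applied_syn=applied["syn"],
        applied_nonsyn=applied["nonsyn"],
        s_sites=s_sites,
        n_sites=n_sites,
        true_ks=true_ks,
        true_ka=true_ka,
        target_ks=config.target_ks,
        target_ka=target_ka,
    )


# -- promoters ----------------------------------------------------------

def default_elements(n: int = 5) -> list[PlaceMotif]:
    from importlib import resources

    from .io import load_place_table

    path = resources.files("famscan.data").joinpath("place_elements.tsv")
    return load_place_table(str(path))[:n]


@dataclass
class PlantedPromoter:
    record: NucleotideRecord
    hits: list[ElementHit]


def gen_promoter(
    config: SyntheticConfig,
    index: int = 0,
    elements: list[PlaceMotif] | None = None,
) -> PlantedPromoter:
    """A promoter with each element instantiated once, strands random.

    Instances are placed without overlap; an element set too large for
    the promoter raises ``ValueError``.
    """
    rng = _rng(config, _TAG_PROMOTER, index)
    if elements is None:
        elements = config.planted_elements or default_elements()
    length = config.promoter_length
    if sum(len(e.iupac) for e in elements) > length:
        raise ValueError("planted elements do not fit in the promoter")
    seq = list(_random_nt(rng, length))
    occupied: list[tuple[int, int]] = []
    hits = []
    gene_id = f"promoter_{index:02d}"
    for element in elements:
        from .promoter import IUPAC_CODES

        instance = "".join(
            str(rng.choice(list(IUPAC_CODES[c]))) for c in element.iupac
        )
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = instance if strand == "+" else reverse_complement(instance)
        for _ in range(10000):
            start = int(rng.integers(0, length - len(inserted) + 1))
            span = (start, start + len(inserted))
            if all(span[1] <= s or span[0] >= e for s, e in occupied):
                break
        else:  # pragma: no cover
            raise ValueError("could not place elements without overlap")
        occupied.append(span)
        seq[span[0] : span[1]] = inserted
        hits.append(
            ElementHit(gene_id, element.element_id, start, strand, instance)
        )
    hits.sort(key=lambda h: (h.element_id, h.strand, h.start))
    return PlantedPromoter(NucleotideRecord(gene_id, "".join(seq)), hits)


# -- expression matrices ------------------------------------------------

def gen_fpkm(config: SyntheticConfig) -> tuple[FpkmMatrix, dict]:
    """A genes x tissues FPKM matrix with planted expression classes.

    Truth maps each gene to ``("specific", tissue)``, ``("uniform",)``
    or ``("silent",)``.  Specific genes have one dominant tissue
    (log-normal high vs low), uniform genes are near-equal everywhere,
    silent genes stay below the expressed threshold in all tissues.
    """
    rng = _rng(config, _TAG_FPKM, 0)
    import pandas as pd

    n = config.n_genes_fpkm
    tissues = list(config.tissues)
    n_specific = int(round(config.specific_fraction * n))
    n_specific = min(n_specific, n - config.n_silent)
    truth = {}
    rows = {}
    for g in range(n):
        gene = f"gene_{g:02d}"
        if g < n_specific:
            tissue = tissues[int(rng.integers(len(tissues)))]
            profile = rng.lognormal(mean=-1.5, sigma=0.4, size=len(tissues))
            profile[tissues.index(tissue)] = rng.lognormal(4.0, 0.3)
            truth[gene] = ("specific", tissue)
        elif g < n - config.n_silent:
            profile = rng.lognormal(2.3, 0.05, size=len(tissues))
            truth[gene] = ("uniform",)
        else:
            profile = rng.uniform(
                0, config.expressed_threshold * 0.5, size=len(tissues)
            )
            truth[gene] = ("silent",)
        rows[gene] = profile
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
    return FpkmMatrix(frame), truth


# -- group-structured alignments ---------------------------------------

def gen_group_alignment(
    config: SyntheticConfig,
    groups: tuple[str, ...] = ("I", "II", "III", "IVa", "IVb"),
    n_ref: int = 2,
    n_query: int = 1,
    length: int = 300,
    p_between: float = 0.45,
    p_within: float = 0.04,
) -> tuple[list[ProteinRecord], dict[str, str], dict[str, str]]:
    """A gap-free protein alignment with well-separated planted clades.

    Returns ``(msa, references, truth)``: each group has ``n_ref``
    reference leaves (in ``references``) plus ``n_query`` query leaves
    whose true group is recorded in ``truth``.
    """
    rng = _rng(config, _TAG_MSA, 0)
    root = _random_aa(rng, length)

    def mutate(seq: str, p: float) -> str:
        out = list(seq)
        for i in range(len(out)):
            if rng.random() < p:
                out[i] = _AA[int(rng.integers(len(_AA)))]
        return "".join(out)

    msa, references, truth = [], {}, {}
    for group in groups:
        ancestor = mutate(root, p_between)
        for r in range(n_ref):
            name = f"{group}_ref{r}"
            msa.append(ProteinRecord(name, mutate(ancestor, p_within)))
            references[name] = group
        for q in range(n_query):
            name = f"{group}_query{q}"
            msa.append(ProteinRecord(name, mutate(ancestor, p_within)))
            truth[name] = group
    return msa, references, truth
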