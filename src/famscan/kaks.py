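"""Nei-Gojobori (1986) Ka/Ks estimation and Ks-based divergence dating.

The NG86 method counts, for each codon, the fraction of possible
single-nucleotide changes that are synonymous (synonymous sites S) and
nonsynonymous (N), with changes to stop codons counted as
nonsynonymous.  Observed differences between an aligned codon pair are
classified by averaging over all minimal substitution paths (paths
through stop codons excluded), giving Sd and Nd.  The proportions
pS = Sd/S and pN = Nd/N are Jukes-Cantor corrected:

    K = -(3/4) * ln(1 - (4/3) * p)

Duplication/divergence dates use the molecular clock

    Mya = Ks / (2 * lambda) * 1e-6,   lambda = 6.5e-9 subst/site/year,

and Ka/Ks < 1, = 1, > 1 classify selection as purifying, neutral, or
positive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from .records import KaKsResult, NucleotideRecord

DEFAULT_LAMBDA = 6.5e-9

_BASES = "ACGT"

# standard genetic code
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOP_CODONS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}
SENSE_CODONS = sorted(set(GENETIC_CODE) - STOP_CODONS)


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (no gaps); internal stops are errors."""
    if len(cds) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = GENETIC_CODE.get(codon)
        if aa is None:
            raise ValueError(f"ambiguous codon {codon!r} at nt {i}")
        if aa == "*":
            if i == len(cds) - 3:
                break  # trailing stop is fine and dropped
            raise ValueError(f"internal stop codon {codon!r} at nt {i}")
        aas.append(aa)
    return "".join(aas)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts for one sense codon.

    Each of the three positions contributes the fraction of its three
    possible single-nucleotide changes that preserve the encoded amino
    acid; changes creating a stop codon count as nonsynonymous.
    Always satisfies S + N = 3.
    """
    aa = GENETIC_CODE.get(codon)
    if aa is None:
        raise ValueError(f"not a codon: {codon!r}")
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no NG86 sites")
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Observed synonymous/nonsynonymous differences between two codons.

    For codons differing at k positions all k! substitution orders are
    enumerated; each step is classified by whether it preserves the
    amino acid of the codon it leaves.  Paths passing through a stop
    codon are excluded and the average renormalized over the survivors
    (if every path is blocked the unrestricted average is used).
    """
    for c in (codon_a, codon_b):
        if GENETIC_CODE.get(c, "*") == "*":
            raise ValueError(f"invalid or stop codon {c!r}")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order, allow_stops):
        syn = nsyn = 0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if GENETIC_CODE[nxt] == "*" and not allow_stops:
                return None
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                syn += 1
            else:
                nsyn += 1
            current = nxt
        return syn, nsyn

    for allow_stops in (False, True):
        totals = [
            r
            for order in itertools.permutations(diff_pos)
            if (r := walk(order, allow_stops)) is not None
        ]
        if totals:
            n = len(totals)
            return (
                sum(t[0] for t in totals) / n,
                sum(t[1] for t in totals) / n,
            )
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-aligned CDS pair whose gaps respect codon boundaries."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError("aligned sequences differ in length")
        if len(a) % 3:
            raise ValueError("alignment length is not a multiple of 3")
        for seq in (a, b):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if "-" in codon and codon != "---":
                    raise ValueError(
                        f"frame-breaking gap in codon {codon!r} at nt {i}"
                    )

    def codon_pairs(self):
        """Yield ungapped (codon_a, codon_b) columns."""
        for i in range(0, len(self.seq_a), 3):
            ca = self.seq_a[i : i + 3]
            cb = self.seq_b[i : i + 3]
            if "-" not in ca and "-" not in cb:
                yield ca, cb


def build_codon_alignment(
    cds_a: NucleotideRecord | str, cds_b: NucleotideRecord | str
) -> CodonAlignment:
    """Protein-guided codon alignment of two coding sequences.

    The translated proteins are globally aligned (BLOSUM62) and the
    codons are threaded back through the protein alignment, so gaps can
    only occur in multiples of 3 and the frame is preserved.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    def _seq(x):
        return x.sequence if hasattr(x, "sequence") else x.upper()

    sa, sb = _seq(cds_a), _seq(cds_b)
    pa, pb = translate_cds(sa), translate_cds(sb)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(pa, pb)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(sa[3 * ia : 3 * ia + 3])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(sb[3 * ib : 3 * ib + 3])
            ib += 1
    return CodonAlignment("".join(out_a), "".join(out_b))


def _jukes_cantor(p: float) -> float:
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def kaks_pair(
    aln: CodonAlignment, lambda_rate: float = DEFAULT_LAMBDA
) -> KaKsResult:
    """NG86 Ka/Ks for one aligned pair; gapped codons are skipped.

    When pS or pN reaches 3/4 the Jukes-Cantor correction is undefined
    and the result is flagged ``saturated`` (the affected rate is NaN).
    """
    s_sites = n_sites = sd = nd = 0.0
    n_codons = 0
    for ca, cb in aln.codon_pairs():
        sa_, na_ = codon_sites(ca)
        sb_, nb_ = codon_sites(cb)
        s_sites += (sa_ + sb_) / 2.0
        n_sites += (na_ + nb_) / 2.0
        dsyn, dnsyn = codon_differences(ca, cb)
        sd += dsyn
        nd += dnsyn
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no ungapped codon pairs in alignment")
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    saturated = ps >= 0.75 or pn >= 0.75
    ks = float("nan") if ps >= 0.75 else _jukes_cantor(ps)
    ka = float("nan") if pn >= 0.75 else _jukes_cantor(pn)
    if saturated:
        ratio, mya, sel = None, float("nan"), "undefined"
    else:
        ratio, mya, sel = ratio_and_date(ka, ks, lambda_rate)
    return KaKsResult(
        s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd, ps=ps, pn=pn,
        ka=ka, ks=ks, ratio=ratio, lambda_rate=lambda_rate, mya=mya,
        selection_class=sel, n_codons=n_codons, saturated=saturated,
    )


def ratio_and_date(
    ka: float, ks: float, lambda_rate: float = DEFAULT_LAMBDA
) -> tuple[float | None, float, str]:
    """Ka/Ks ratio, clock date in million years, and selection class.

    ``mya = Ks / (2 * lambda_rate) * 1e-6``.  A zero Ks leaves the
    ratio undefined (``None``) and dates the event at 0 Mya.  The
    neutral class is the ratio-equals-1 band (within 1e-9); below is
    purifying, above is positive selection.
    """
    if ka < 0 or ks < 0:
        raise ValueError("Ka and Ks must be non-negative")
    mya = ks / (2.0 * lambda_rate) * 1e-6
    if ks == 0.0:
        return None, 0.0, "undefined"
    ratio = ka / ks
    if abs(ratio - 1.0) < 1e-9:
        sel = "neutral"
    elif ratio < 1.0:
        sel = "purifying"
    else:
        sel = "positive"
    return ratio, mya, sel
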