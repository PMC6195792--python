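"""Protein physicochemical properties: MW, theoretical pI, GRAVY.

Conventions follow the ExPASy Compute pI/Mw tool: average (not
monoisotopic) residue masses, the Bjellqvist pKa set for the
isoelectric point, and the Kyte-Doolittle hydropathy scale for GRAVY.
Ambiguity letters (``X``) are rejected rather than averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import ProteinRecord

# average residue (i.e. water-free) masses, Da
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Bjellqvist pKa values as used by ExPASy Compute pI/Mw
PKA_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERM_DEFAULT = 7.5
PKA_NTERM_BY_RESIDUE = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
    "T": 6.82, "V": 7.44, "E": 7.7,
}
PKA_CTERM = 3.55


@dataclass(frozen=True)
class PhysicoProps:
    length_aa: int
    mw: float
    pi: float
    gravy: float


def _check_strict(protein: ProteinRecord) -> str:
    seq = protein.sequence
    bad = [i for i, aa in enumerate(seq) if aa not in AVERAGE_RESIDUE_MASS]
    if bad:
        raise ValueError(
            f"protein {protein.id!r} has non-standard residues at "
            f"0-based positions {bad[:10]}"
        )
    return seq


def molecular_weight(protein: ProteinRecord) -> float:
    """Average-isotopic molecular weight in daltons."""
    seq = _check_strict(protein)
    return sum(AVERAGE_RESIDUE_MASS[aa] for aa in seq) + WATER_MASS


def gravy(protein: ProteinRecord) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle score."""
    seq = _check_strict(protein)
    return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)


def net_charge(sequence: str, ph: float) -> float:
    """Net charge at a given pH under the Bjellqvist model.

    Positive groups (N-terminus, K, R, H) contribute
    ``1 / (1 + 10**(pH - pKa))``; negative groups (C-terminus, D, E,
    C, Y) contribute ``-1 / (1 + 10**(pKa - pH))``.  Strictly
    decreasing in pH, so the zero crossing (the pI) is unique.
    """
    nterm_pka = PKA_NTERM_BY_RESIDUE.get(sequence[0], PKA_NTERM_DEFAULT)
    charge = 1.0 / (1.0 + 10 ** (ph - nterm_pka))
    charge -= 1.0 / (1.0 + 10 ** (PKA_CTERM - ph))
    for aa in sequence:
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(protein: ProteinRecord, tol: float = 1e-4) -> float:
    """Theoretical pI: the pH of zero net charge, by bisection on [0, 14]."""
    seq = _check_strict(protein)
    lo, hi = 0.0, 14.0
    ph = 7.0
    while hi - lo > 1e-12:
        ph = (lo + hi) / 2.0
        q = net_charge(seq, ph)
        if abs(q) < tol:
            break
        if q > 0:
            lo = ph
        else:
            hi = ph
    return ph


def physico_props(protein: ProteinRecord) -> PhysicoProps:
    return PhysicoProps(
        length_aa=len(protein),
        mw=molecular_weight(protein),
        pi=isoelectric_point(protein),
        gravy=gravy(protein),
    )
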