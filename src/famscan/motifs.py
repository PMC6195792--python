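"""PROSITE-dialect motif compilation, scanning, and family identification.

The diagnostic for plant cyclic nucleotide-gated channels (CNGCs) is a
short sequence motif spanning the phosphate-binding cassette (PBC) and
hinge inside the cyclic nucleotide-binding domain (CNBD).  Potassium
AKT/KAT (Shaker-type) channels share the CNBD + transmembrane
architecture but lack this motif, so motif presence separates the two
families.  This module compiles the motif dialect, scans proteomes, and
applies the identification filters (motif presence, minimum length,
redundancy removal).

Dialect, token by token (tokens are hyphen-separated):

* a run of residue letters (``ELL``) — one literal position per letter;
* ``[ED]`` — one position matching any residue in the set;
* ``X`` — wildcard position;
* a ``(n)`` or ``(n,m)`` suffix repeats the position n or n..m times;
* a ``0`` inside a bracket (``[LIMV0]``), or a ``(0,1)`` repeat, makes
  the position optional (match 0 or 1 residues).

Variable repeats are expanded non-greedily: at each start position the
shortest accepted match is reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .records import AMINO_ACIDS, MotifHit, ProteinRecord


@dataclass(frozen=True)
class MotifPosition:
    """One position of a compiled pattern.

    ``residues`` is ``None`` for the wildcard ``X``; ``min_repeat`` /
    ``max_repeat`` bound how many sequence residues the position
    consumes (0 lower bound encodes an optional position).
    """

    residues: frozenset | None
    min_repeat: int
    max_repeat: int

    @property
    def optional(self) -> bool:
        return self.min_repeat == 0


class PatternError(ValueError):
    """Raised on a malformed pattern, with the offending token index."""

    def __init__(self, message: str, token_index: int):
        super().__init__(f"token {token_index}: {message}")
        self.token_index = token_index


@dataclass(frozen=True)
class MotifPattern:
    source_text: str
    positions: tuple

    @property
    def min_length(self) -> int:
        return sum(p.min_repeat for p in self.positions)

    @property
    def max_length(self) -> int:
        return sum(p.max_repeat for p in self.positions)

    def to_regex(self) -> re.Pattern:
        """Equivalent regular expression, all quantifiers non-greedy."""
        parts = []
        for pos in self.positions:
            atom = "." if pos.residues is None else (
                "[" + "".join(sorted(pos.residues)) + "]"
            )
            lo, hi = pos.min_repeat, pos.max_repeat
            if lo == hi == 1:
                parts.append(atom)
            elif lo == hi:
                parts.append(f"{atom}{{{lo}}}")
            else:
                parts.append(f"{atom}{{{lo},{hi}}}?")
        return re.compile("".join(parts))


_REPEAT_RE = re.compile(r"\((\d+)(?:,(\d+))?\)$")


def _parse_repeat(token: str, idx: int) -> tuple[str, int, int]:
    """Split a trailing (n) / (n,m) repeat off a token."""
    m = _REPEAT_RE.search(token)
    if m is None:
        if "(" in token or ")" in token:
            raise PatternError(f"malformed repeat in {token!r}", idx)
        return token, 1, 1
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) is not None else lo
    if lo > hi:
        raise PatternError(f"repeat ({lo},{hi}) has n > m", idx)
    return token[: m.start()], lo, hi


def compile_pattern(source_text: str) -> MotifPattern:
    """Compile a hyphen-separated PROSITE-dialect pattern.

    Raises :class:`PatternError` (naming the token index) on unbalanced
    brackets, inverted repeat bounds, or illegal residue letters.
    """
    text = source_text.strip()
    if not text:
        raise PatternError("empty pattern", 0)
    positions: list[MotifPosition] = []
    for idx, token in enumerate(text.split("-")):
        token = token.strip()
        if not token:
            raise PatternError("empty token", idx)
        body, lo, hi = _parse_repeat(token, idx)
        if body.startswith("["):
            if not body.endswith("]"):
                raise PatternError(f"unbalanced bracket in {token!r}", idx)
            inner = body[1:-1]
            if "[" in inner or "]" in inner:
                raise PatternError(f"nested bracket in {token!r}", idx)
            optional = "0" in inner
            residues = frozenset(inner) - {"0"}
            if not residues:
                raise PatternError(f"empty residue set in {token!r}", idx)
            bad = residues - AMINO_ACIDS
            if bad:
                raise PatternError(
                    f"illegal residue letters {sorted(bad)} in {token!r}", idx
                )
            if optional:
                lo = 0
            positions.append(MotifPosition(residues, lo, hi))
        elif "]" in body:
            raise PatternError(f"unbalanced bracket in {token!r}", idx)
        elif body == "X":
            positions.append(MotifPosition(None, lo, hi))
        else:
            # a run of literal residues; a repeat may follow only a
            # single letter (e.g. "A(3)"), never a run
            bad = set(body) - AMINO_ACIDS
            if bad:
                raise PatternError(
                    f"illegal residue letters {sorted(bad)} in {token!r}", idx
                )
            if len(body) > 1 and (lo, hi) != (1, 1):
                raise PatternError(
                    f"repeat after multi-residue literal {token!r}", idx
                )
            for letter in body:
                positions.append(MotifPosition(frozenset(letter), lo, hi))
    return MotifPattern(text, tuple(positions))


def scan(pattern: MotifPattern, protein: ProteinRecord) -> list[MotifHit]:
    """All matches of ``pattern`` in ``protein``, ordered by start.

    One hit per matching start position, taking the shortest accepted
    match length there (candidate lengths are probed in ascending
    order, so variable repeats expand non-greedily).
    """
    rx = pattern.to_regex()
    seq = protein.sequence
    lo, hi = pattern.min_length, pattern.max_length
    hits = []
    for start in range(len(seq) - lo + 1):
        for length in range(lo, min(hi, len(seq) - start) + 1):
            if rx.fullmatch(seq, start, start + length):
                hits.append(
                    MotifHit(protein.id, start, start + length,
                             seq[start : start + length])
                )
                break
    return hits


# -- packaged patterns -------------------------------------------------

def _packaged(name: str) -> str:
    return (
        resources.files("famscan.data").joinpath(name).read_text().strip()
    )


def stringent_pattern() -> MotifPattern:
    """The stringent maize PBC+hinge motif (Results-grade diagnostic)."""
    return compile_pattern(_packaged("stringent.pat"))


def plant_consensus_pattern() -> MotifPattern:
    """The broader plant CNGC PBC+hinge consensus."""
    return compile_pattern(_packaged("plant_consensus.pat"))


def load_pattern(spec: str) -> MotifPattern:
    """Resolve ``stringent``, ``consensus``, or a pattern-file path."""
    if spec == "stringent":
        return stringent_pattern()
    if spec == "consensus":
        return plant_consensus_pattern()
    with open(spec) as fh:
        return compile_pattern(fh.read())


# -- identification pipeline -------------------------------------------

@dataclass
class CandidateReport:
    protein_id: str
    length: int
    motif_found: bool
    long_enough: bool
    redundant: bool
    redundant_with: str | None = None

    @property
    def accepted(self) -> bool:
        return self.motif_found and self.long_enough and not self.redundant


@dataclass
class IdentificationReport:
    candidates: list

    @property
    def accepted_ids(self) -> list[str]:
        return [c.protein_id for c in self.candidates if c.accepted]


def _pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity over the shorter sequence."""
    from Bio import Align

    if a == b:
        return 1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        matches += sum(x == y for x, y in zip(a[a0:a1], b[b0:b1]))
    return matches / min(len(a), len(b))


def identify_cngc(
    proteome: list[ProteinRecord],
    pattern: MotifPattern,
    min_length: int = 200,
    identity_threshold: float = 0.99,
) -> IdentificationReport:
    """Run the family-identification filters over a proteome.

    A candidate is accepted when it carries at least one motif hit, is
    at least ``min_length`` residues long, and is not redundant with an
    already-kept candidate (identical sequence, or identity >=
    ``identity_threshold`` over the shorter of the pair; the longer
    member of a redundant pair is kept).
    """
    reports: list[CandidateReport] = []
    for rec in proteome:
        reports.append(
            CandidateReport(
                protein_id=rec.id,
                length=len(rec),
                motif_found=bool(scan(pattern, rec)),
                long_enough=len(rec) >= min_length,
                redundant=False,
            )
        )
    # redundancy pass over candidates that survive the other filters,
    # longest first so the longer member of a near-identical pair wins
    by_id = {rec.id: rec for rec in proteome}
    survivors = [
        r for r in reports if r.motif_found and r.long_enough
    ]
    survivors.sort(key=lambda r: (-r.length, r.protein_id))
    kept: list[CandidateReport] = []
    for cand in survivors:
        seq = by_id[cand.protein_id].sequence
        for other in kept:
            if (
                _pairwise_identity(seq, by_id[other.protein_id].sequence)
                >= identity_threshold
            ):
                cand.redundant = True
                cand.redundant_with = other.protein_id
                break
        else:
            kept.append(cand)
    return IdentificationReport(reports)
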