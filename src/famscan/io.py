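"""Readers and writers: FASTA, header TSV tables, Newick trees."""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO

from .records import FpkmMatrix, NucleotideRecord, PlaceMotif, ProteinRecord


def read_fasta(path, kind: str = "protein"):
    """Read a multi-record FASTA file.

    Record ids are the header token before the first whitespace;
    sequences are uppercased.  ``kind`` selects the record type
    (``"protein"`` or ``"nucleotide"``).

    Raises ``ValueError`` on an empty file or on duplicate ids.
    """
    cls = {"protein": ProteinRecord, "nucleotide": NucleotideRecord}[kind]
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        records.append(cls(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_table(path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a header TSV, enforcing and typing the columns in ``schema``.

    Row order is preserved; extra columns are kept untyped.  A missing
    schema column raises ``ValueError`` naming it.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    for column, dtype in schema.items():
        if column not in frame.columns:
            raise ValueError(f"table {path} is missing required column {column!r}")
        frame[column] = frame[column].astype(dtype)
    return frame


def read_fpkm(path) -> FpkmMatrix:
    """Read a genes x tissues FPKM table (first column = gene id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return FpkmMatrix(frame)


def write_fpkm(matrix: FpkmMatrix, path) -> None:
    matrix.frame.to_csv(path, sep="\t", index_label="gene")


def load_place_table(path) -> list[PlaceMotif]:
    """Load a PLACE-style element table: columns ``element_id``, ``iupac``."""
    frame = read_table(path, {"element_id": str, "iupac": str})
    ids = frame["element_id"]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate element ids in PLACE table: {dupes}")
    return [PlaceMotif(r.element_id, r.iupac) for r in frame.itertuples()]


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a tree as Newick, supports serialized as internal-node labels.

    Requires at least two named leaves; an unnamed leaf is an error.
    """
    leaves = [leaf for leaf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    for leaf in leaves:
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree contains an unnamed leaf")
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
            + "\n"
        )


def read_newick(path) -> dendropy.Tree:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return dendropy.Tree.get(path=str(path), schema="newick")
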