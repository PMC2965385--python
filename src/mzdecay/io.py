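"""Readers and writers for the TSV/GMT/FASTA formats the pipeline uses."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .matrix import ExpressionMatrix


def read_expression(matrix_path, design_path) -> ExpressionMatrix:
    """Load an expression TSV (first column gene_id) plus its design TSV.

    The design must cover every sample column; validation errors name
    the offending samples or genes.
    """
    matrix_path, design_path = Path(matrix_path), Path(design_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell in {matrix_path}: {exc}") from exc
    return ExpressionMatrix(values, design)


def write_expression(matrix: ExpressionMatrix, matrix_path, design_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    matrix.design.to_csv(design_path, sep="\t", index_label="sample")


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT file: name, description, tab-separated member ids."""
    collections: dict[str, set] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, members")
        name = fields[0]
        members = {g for g in fields[2:] if g}
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
        collections[name] = members
    return collections


def write_gmt(collections: dict[str, set], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in collections.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_fasta(path) -> dict[str, str]:
    """id -> sequence; ids are headers truncated at the first whitespace."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id: {record.id}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
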