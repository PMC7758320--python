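"""Readers and writers for the pipeline's plain-text interchange formats.

Counts are featureCounts-style TSV (gene_id column plus one integer column
per sample; ``#`` comment lines skipped), designs and allele tables are
TSV, sequences are FASTA via Biopython.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .de import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_allele_table",
    "write_allele_table",
    "read_alignment_pairs",
    "write_alignment_pairs",
    "read_fasta",
    "write_fasta",
]


def read_counts(counts_path, design_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", comment="#")
    counts = counts.set_index(counts.columns[0])
    counts.index.name = "gene_id"
    design = read_design(design_path)
    return CountMatrix(counts, design)


def write_counts(cm: CountMatrix, counts_path, design_path=None) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    if design_path is not None:
        write_design(cm.design, design_path)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    if "sample" not in design.columns or "group" not in design.columns:
        raise ValueError("design table needs 'sample' and 'group' columns")
    return design.set_index("sample")


def write_design(design: pd.DataFrame, path) -> None:
    design.rename_axis("sample").to_csv(path, sep="\t")


def read_allele_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "sample", "reads_p1", "reads_p2"}
    if not required <= set(table.columns):
        raise ValueError(f"allele table needs columns {sorted(required)}")
    return table


def write_allele_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_pairs(path) -> dict[str, tuple[str, str]]:
    """Paired alignment FASTA: two records per gene, ids ``<gene>|a`` / ``<gene>|b``."""
    pairs: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"record id {rec.id!r} is not '<gene>|a' or '<gene>|b'")
        gene, which = rec.id.rsplit("|", 1)
        pairs.setdefault(gene, {})[which] = str(rec.seq).upper()
    out = {}
    for gene, d in pairs.items():
        if set(d) != {"a", "b"}:
            raise ValueError(f"gene {gene!r} does not have exactly records a and b")
        out[gene] = (d["a"], d["b"])
    return out


def write_alignment_pairs(pairs: dict[str, tuple[str, str]], path) -> None:
    records = []
    for gene, (a, b) in pairs.items():
        records.append(SeqRecord(Seq(a), id=f"{gene}|a", description=""))
        records.append(SeqRecord(Seq(b), id=f"{gene}|b", description=""))
    SeqIO.write(records, str(path), "fasta")
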