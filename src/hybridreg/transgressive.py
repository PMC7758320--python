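"""Transgressive expression calls and expression-difference metrics.

A hybrid gene is transgressive when it is in the consensus DE set against
BOTH parents with the same fold-change sign: its expression falls
significantly outside the parental range. The smaller of the two absolute
log2 fold-changes is kept as the minimum transgressive expression, the
expression-difference metric used in the hybrid correlation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TransgressiveCall",
    "expression_difference",
    "call_transgressive",
    "partition_by_parental_de",
]


@dataclass
class TransgressiveCall:
    gene_id: str
    hybrid: str
    direction: str  # "over" | "under"
    lfc_vs_p1: float
    lfc_vs_p2: float
    min_transgressive_lfc: float
    parental_de: bool | None = None


def expression_difference(mean_a: float, mean_b: float) -> float:
    """Absolute log2 difference of two (normalized) expression means."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("expression means must be positive")
    return abs(float(np.log2(mean_a) - np.log2(mean_b)))


def call_transgressive(consensus_vs_p1: pd.DataFrame, consensus_vs_p2: pd.DataFrame,
                       hybrid: str, lfc_threshold: float = 1.0,
                       require_lfc_both: bool = True) -> list[TransgressiveCall]:
    """Call transgressive genes for one hybrid.

    Inputs are the consensus DE frames for the hybrid against each parent,
    with ``lfc`` oriented hybrid-over-parent. A gene is transgressive iff
    present in both sets with agreeing lfc sign; ``require_lfc_both``
    additionally demands |lfc| >= ``lfc_threshold`` against both parents
    (the consensus step normally enforces this already).
    """
    for df, name in ((consensus_vs_p1, "vs_p1"), (consensus_vs_p2, "vs_p2")):
        if df is None or "lfc" not in df.columns:
            raise ValueError(f"missing consensus DE frame: {name}")
    merged = consensus_vs_p1[["gene_id", "lfc"]].merge(
        consensus_vs_p2[["gene_id", "lfc"]], on="gene_id",
        suffixes=("_p1", "_p2"))
    calls = []
    for row in merged.itertuples(index=False):
        l1, l2 = float(row.lfc_p1), float(row.lfc_p2)
        if np.sign(l1) != np.sign(l2) or l1 == 0.0:
            continue
        if require_lfc_both and (abs(l1) < lfc_threshold or abs(l2) < lfc_threshold):
            continue
        calls.append(TransgressiveCall(
            gene_id=row.gene_id, hybrid=hybrid,
            direction="over" if l1 > 0 else "under",
            lfc_vs_p1=l1, lfc_vs_p2=l2,
            min_transgressive_lfc=min(abs(l1), abs(l2))))
    return calls


def partition_by_parental_de(transgressive_genes, parental_de_genes
                             ) -> dict[str, set[str]]:
    """Three-way partition over parental-DE and transgressive genes.

    Returns the disjoint, exhaustive groups
    ``parental_de_not_transgressive`` (P1!=P2, not transgressive),
    ``parental_de_transgressive`` (P1!=P2 and transgressive) and
    ``transgressive_only`` (P1=P2 but transgressive).
    """
    t = set(transgressive_genes)
    d = set(parental_de_genes)
    return {
        "parental_de_not_transgressive": d - t,
        "parental_de_transgressive": d & t,
        "transgressive_only": t - d,
    }
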