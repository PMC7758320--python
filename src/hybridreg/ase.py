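"""Allele-specific expression and regulatory-divergence classification.

Diagnostic fixed SNPs (each parental line homozygous for a different base,
each with at least three supporting reads) let hybrid reads be assigned to
a parent of origin. Per gene, allele-informative reads are summed, genes
with fewer than 20 combined parental reads are discarded, counts are
adjusted for sequencing depth (zeros become 1 so the test is defined), and
a two-sided Fisher's exact test compares the parental read ratio with the
hybrid allelic ratio.

The classification follows the standard cis/trans logic: for a gene that is
differentially expressed between the parents, a significant Fisher test
means the hybrid allelic ratio departs from the parental ratio (cis-trans
divergence) while a non-significant test means the parental difference is
carried by the alleles themselves (cis-only). For a gene with no parental
difference, a significant test reveals hidden allelic imbalance
(compensatory cis and trans changes) and a non-significant test indicates
conserved regulation (non-compensatory).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .stats import bh_fdr

__all__ = [
    "FixedSNP",
    "RegulatoryCall",
    "CATEGORIES",
    "call_fixed_snps",
    "read_fixed_snps_vcf",
    "assign_allele_reads",
    "filter_min_reads",
    "depth_adjust",
    "fisher_ase_test",
    "classify_regulatory",
    "classify_all",
]

CATEGORIES = ("cis_only", "cis_trans_divergent", "compensatory",
              "non_compensatory", "uninformative")


@dataclass
class FixedSNP:
    gene_id: str
    position: int  # 0-based on the reference
    allele_p1: str
    allele_p2: str
    support_p1: int
    support_p2: int


@dataclass
class RegulatoryCall:
    gene_id: str
    hybrid: str
    category: str
    fisher_p: float | None
    parental_de: bool
    parental_p1: int = 0
    parental_p2: int = 0
    hybrid_p1: int = 0
    hybrid_p2: int = 0


def call_fixed_snps(parental_allele_counts: pd.DataFrame,
                    min_support: int = 3) -> list[FixedSNP]:
    """Identify SNPs fixed for different alleles in the two parents.

    ``parental_allele_counts`` needs columns gene_id, position, parent
    (P1/P2), base, count. A site qualifies iff each parent shows exactly
    one base, the two bases differ, and each parent's supporting count is
    at least ``min_support``.
    """
    required = {"gene_id", "position", "parent", "base", "count"}
    if not required <= set(parental_allele_counts.columns):
        raise ValueError(f"allele-count table needs columns {sorted(required)}")
    snps = []
    grouped = parental_allele_counts.groupby(["gene_id", "position"], sort=True)
    for (gene, pos), site in grouped:
        per_parent = {}
        ok = True
        for parent in ("P1", "P2"):
            obs = site[(site["parent"] == parent) & (site["count"] > 0)]
            bases = obs.groupby("base")["count"].sum()
            if len(bases) != 1:
                ok = False  # absent or polymorphic in this parent
                break
            per_parent[parent] = (bases.index[0], int(bases.iloc[0]))
        if not ok:
            continue
        (b1, c1), (b2, c2) = per_parent["P1"], per_parent["P2"]
        if b1 == b2 or c1 < min_support or c2 < min_support:
            continue
        snps.append(FixedSNP(gene_id=gene, position=int(pos), allele_p1=b1,
                             allele_p2=b2, support_p1=c1, support_p2=c2))
    return snps


def read_fixed_snps_vcf(path, sample_p1: str, sample_p2: str,
                        min_support: int = 3,
                        gene_id_tag: str = "GENE") -> list[FixedSNP]:
    """Import fixed SNPs from a VCF of the two parental lines.

    Only biallelic SNP records with FILTER PASS (or unset) are considered.
    A site qualifies when the two samples are homozygous for different
    alleles, each with depth >= ``min_support`` (per-sample DP). The gene is
    read from the INFO field named by ``gene_id_tag``. Positions are
    converted to 0-based.
    """
    import pysam

    snps: list[FixedSNP] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.filter.keys() not in ([], ["PASS"]):
                continue
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            gene = rec.info.get(gene_id_tag)
            if gene is None:
                continue
            alleles = {}
            depths = {}
            ok = True
            for label, sample in (("P1", sample_p1), ("P2", sample_p2)):
                call = rec.samples[sample]
                gt = call.get("GT")
                if gt is None or None in gt or len(set(gt)) != 1:
                    ok = False  # missing or heterozygous
                    break
                alleles[label] = rec.alleles[gt[0]]
                depths[label] = int(call.get("DP") or 0)
            if not ok or alleles["P1"] == alleles["P2"]:
                continue
            if depths["P1"] < min_support or depths["P2"] < min_support:
                continue
            snps.append(FixedSNP(
                gene_id=str(gene), position=rec.pos - 1,
                allele_p1=alleles["P1"], allele_p2=alleles["P2"],
                support_p1=depths["P1"], support_p2=depths["P2"]))
    return snps


def assign_allele_reads(hybrid_site_counts: pd.DataFrame,
                        fixed_snps: list[FixedSNP]) -> pd.DataFrame:
    """Sum hybrid reads per gene by parental allele at fixed SNP sites.

    ``hybrid_site_counts`` needs columns gene_id, position, sample, base,
    count. Reads matching neither diagnostic allele are ignored. Genes with
    fixed SNPs but no overlapping reads get zero rows for every sample seen.
    """
    required = {"gene_id", "position", "sample", "base", "count"}
    if not required <= set(hybrid_site_counts.columns):
        raise ValueError(f"site-count table needs columns {sorted(required)}")
    snp_index = {(s.gene_id, s.position): s for s in fixed_snps}
    genes_with_snps = {s.gene_id for s in fixed_snps}
    samples = sorted(hybrid_site_counts["sample"].unique())
    totals: dict[tuple[str, str], list[int]] = {
        (g, s): [0, 0] for g in genes_with_snps for s in samples}
    for row in hybrid_site_counts.itertuples(index=False):
        snp = snp_index.get((row.gene_id, row.position))
        if snp is None:
            continue  # site is not a fixed SNP
        key = (row.gene_id, row.sample)
        if row.base == snp.allele_p1:
            totals[key][0] += int(row.count)
        elif row.base == snp.allele_p2:
            totals[key][1] += int(row.count)
        # third-base observations are discarded
    rows = [{"gene_id": g, "sample": s, "reads_p1": v[0], "reads_p2": v[1]}
            for (g, s), v in sorted(totals.items())]
    return pd.DataFrame(rows, columns=["gene_id", "sample", "reads_p1", "reads_p2"])


def _parental_totals(table: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Raw combined parental SNP reads per gene (pre-adjustment)."""
    grp = design.loc[table["sample"], "group"].to_numpy()
    parental = table[(grp == "P1") | (grp == "P2")]
    return parental.groupby("gene_id")[["reads_p1", "reads_p2"]].sum().sum(axis=1)


def filter_min_reads(table: pd.DataFrame, design: pd.DataFrame,
                     min_total: int = 20) -> pd.DataFrame:
    """Drop genes whose combined parental SNP reads are below ``min_total``.

    The boundary is inclusive: exactly ``min_total`` reads are retained.
    """
    totals = _parental_totals(table, design)
    keep = set(totals.index[totals >= min_total])
    return table[table["gene_id"].isin(keep)].reset_index(drop=True)


def depth_adjust(table: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Rescale per-sample SNP counts to the mean sequencing depth.

    Each sample's counts are multiplied by mean(library sizes)/its library
    size and rounded to the nearest integer. (Zero replacement for
    testability happens on the pooled contingency table, where a zero can
    still occur after summing replicates.)
    """
    lib = pd.Series(library_sizes).astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    missing = set(table["sample"]) - set(lib.index)
    if missing:
        raise ValueError(f"samples without library size: {sorted(missing)}")
    scale = (lib.mean() / lib).reindex(table["sample"]).to_numpy()
    out = table.copy()
    for col in ("reads_p1", "reads_p2"):
        out[col] = np.rint(out[col].to_numpy() * scale).astype(np.int64)
    return out


def fisher_ase_test(parental_p1: int, parental_p2: int,
                    hybrid_allele_p1: int, hybrid_allele_p2: int) -> float:
    """Two-sided Fisher's exact test of parental vs hybrid allelic ratio."""
    cells = (parental_p1, parental_p2, hybrid_allele_p1, hybrid_allele_p2)
    for c in cells:
        if int(c) != c or c < 0:
            raise ValueError("contingency cells must be non-negative integers")
    table = [[int(parental_p1), int(parental_p2)],
             [int(hybrid_allele_p1), int(hybrid_allele_p2)]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def classify_regulatory(parental_de: bool, fisher_significant: bool) -> str:
    """Four-way regulatory category from the two boolean inputs."""
    if parental_de:
        return "cis_trans_divergent" if fisher_significant else "cis_only"
    return "compensatory" if fisher_significant else "non_compensatory"


def classify_all(ase_table: pd.DataFrame, design: pd.DataFrame,
                 genes, hybrid_group: str, parental_de_genes,
                 alpha: float = 0.05, min_reads: int = 20,
                 library_sizes: pd.Series | None = None,
                 fdr_correct: bool = False) -> list[RegulatoryCall]:
    """Classify each gene's regulatory divergence for one hybrid.

    ``ase_table`` is the long per-sample allele-read table; replicates are
    pooled by summation within the parental groups and within
    ``hybrid_group``. Genes absent from the table, with no informative
    reads, or below the combined parental read floor are ``uninformative``.
    ``fdr_correct`` optionally applies BH to the Fisher p-values before
    thresholding (off by default).
    """
    parental_de_genes = set(parental_de_genes)
    if library_sizes is not None:
        ase_table = depth_adjust(ase_table, library_sizes)
    grp = design.loc[ase_table["sample"], "group"].to_numpy()
    p1_tab = ase_table[grp == "P1"].groupby("gene_id")[["reads_p1", "reads_p2"]].sum()
    p2_tab = ase_table[grp == "P2"].groupby("gene_id")[["reads_p1", "reads_p2"]].sum()
    hyb_tab = ase_table[grp == hybrid_group].groupby("gene_id")[
        ["reads_p1", "reads_p2"]].sum()

    provisional: list[tuple] = []
    for gene in genes:
        par1 = int(p1_tab.loc[gene].sum()) if gene in p1_tab.index else 0
        par2 = int(p2_tab.loc[gene].sum()) if gene in p2_tab.index else 0
        if gene in hyb_tab.index:
            h1 = int(hyb_tab.loc[gene, "reads_p1"])
            h2 = int(hyb_tab.loc[gene, "reads_p2"])
        else:
            h1 = h2 = 0
        parental_de = gene in parental_de_genes
        if par1 + par2 < min_reads or h1 + h2 == 0:
            provisional.append((gene, None, parental_de, par1, par2, h1, h2))
            continue
        # pooled cells can still be zero after adjustment; substitute 1 so
        # the exact test is defined
        cells = [max(1, v) for v in (par1, par2, h1, h2)]
        p = fisher_ase_test(*cells)
        provisional.append((gene, p, parental_de, *cells))

    pvals = [p for _, p, *_ in provisional if p is not None]
    if fdr_correct and pvals:
        adjusted = iter(bh_fdr(np.array(pvals)))
        provisional = [
            (g, next(adjusted) if p is not None else None, de, a, b, c, d)
            for g, p, de, a, b, c, d in provisional]
    calls = []
    for gene, p, parental_de, a, b, c, d in provisional:
        if p is None:
            category = "uninformative"
        else:
            category = classify_regulatory(parental_de, p < alpha)
        calls.append(RegulatoryCall(
            gene_id=gene, hybrid=hybrid_group, category=category,
            fisher_p=p, parental_de=parental_de,
            parental_p1=a, parental_p2=b, hybrid_p1=c, hybrid_p2=d))
    return calls
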