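"""End-to-end pipeline orchestration and summary arithmetic.

Runs the synthetic experiment through every stage — simulation, consensus
differential expression at both lfc thresholds, transgressive calling,
ASE-based regulatory classification, NG86 divergence with the correlation
and rate-comparison statistics, and the co-option screen — then assembles a
summary report whose percentages always recompute from their stored
numerators and denominators. Every run writes a manifest with the config,
seed and SHA-256 of each output, so re-running the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .ase import classify_all
from .cooption import ScreenThresholds, screen_cooption
from .de import (CountMatrix, consensus_de, cpm, filter_low_expression,
                 run_de_engine, tmm_factors)
from .divergence import CodonAlignment, compare_rate_distributions, estimate_dnds, spearman
from .simulate import (SimDesign, simulate_allele_reads, simulate_architecture,
                       simulate_cds_pair, simulate_counts,
                       simulate_upstream_regions, truth_table)
from .stats import proportion_ztest
from .transgressive import call_transgressive, partition_by_parental_de

__all__ = [
    "PipelineConfig",
    "percentage",
    "summarize_classification",
    "summarize_rates",
    "proportion_ztest",
    "run_pipeline",
]

HYBRIDS = ("HybFertile", "HybSterile")


def percentage(numerator: int, denominator: int, mode: str = "percent"):
    """Percentage of ``numerator/denominator`` in one of three print styles.

    ``percent`` rounds to a whole percent, ``one_decimal`` rounds to one
    decimal, ``two_decimal`` truncates at two decimals (the style used for
    small-denominator tables). Returns None for a zero denominator.
    """
    if denominator == 0:
        return None
    frac = 100.0 * numerator / denominator
    if mode == "percent":
        return int(round(frac))
    if mode == "one_decimal":
        return round(frac, 1)
    if mode == "two_decimal":
        return math.floor(frac * 100.0 + 1e-9) / 100.0
    raise ValueError(f"unknown percentage mode {mode!r}")


def _fraction(name: str, num: int, den: int, mode: str) -> dict:
    return {"name": name, "numerator": int(num), "denominator": int(den),
            "percent": percentage(num, den, mode), "mode": mode}


def summarize_classification(n_transgressive: int, n_not_parental_de: int,
                             category_counts: dict[str, int],
                             n_coopted: int = 0,
                             n_protein_coding: int | None = None,
                             n_parental_de: int | None = None,
                             percent_mode: str = "percent") -> dict:
    """Summary fractions over a transgressive-gene classification.

    ``category_counts`` holds the per-category gene counts (including
    ``uninformative``). Reports the share of transgressive genes without
    parental differential expression, the uninformative share, the share of
    informative genes explained by trans-acting divergence (compensatory +
    cis-trans divergent), the co-opted share, and — when the protein-coding
    and parental-DE totals are given — the protein-coding share of parental
    DE genes. Raw numerators and denominators are always retained.
    """
    n_uninformative = int(category_counts.get("uninformative", 0))
    n_informative = int(n_transgressive) - n_uninformative
    n_trans_driven = int(category_counts.get("compensatory", 0)
                         + category_counts.get("cis_trans_divergent", 0))
    fractions = [
        _fraction("transgressive_not_parental_de", n_not_parental_de,
                  n_transgressive, percent_mode),
        _fraction("uninformative_of_transgressive", n_uninformative,
                  n_transgressive, "percent"),
        _fraction("trans_driven_of_informative", n_trans_driven,
                  n_informative, "percent"),
        _fraction("coopted_of_transgressive", n_coopted, n_transgressive,
                  "percent"),
    ]
    if n_protein_coding is not None and n_parental_de is not None:
        fractions.append(_fraction("protein_coding_of_parental_de",
                                   n_protein_coding, n_parental_de,
                                   "one_decimal"))
    total_cats = sum(int(v) for v in category_counts.values())
    if total_cats != int(n_transgressive):
        raise ValueError(
            f"category counts sum to {total_cats}, expected {n_transgressive}")
    return {
        "n_transgressive": int(n_transgressive),
        "category_counts": {k: int(v) for k, v in sorted(category_counts.items())},
        "fractions": {f["name"]: f for f in fractions},
    }


def summarize_rates(estimates: dict[str, "object"], partition: dict[str, set]
                    ) -> dict:
    """Per-partition mean (+/- SD) dN, dS and dN/dS with pairwise tests.

    ``estimates`` maps gene id -> DivergenceEstimate; ``partition`` maps
    group label -> gene set. Undefined rates are excluded per group with
    the usable n reported. Empty groups yield n = 0 rows and no tests.
    """
    groups: dict[str, dict[str, np.ndarray]] = {}
    for label, genes in partition.items():
        vals = {"dN": [], "dS": [], "omega": []}
        for g in genes:
            est = estimates.get(g)
            if est is None:
                continue
            for rate in vals:
                v = getattr(est, rate)
                if v is not None:
                    vals[rate].append(v)
        groups[label] = {k: np.array(v, dtype=float) for k, v in vals.items()}
    summary_rows = []
    for label, table in groups.items():
        for rate, v in table.items():
            summary_rows.append({
                "group": label, "rate": rate, "n": int(v.size),
                "mean": float(v.mean()) if v.size else None,
                "sd": float(v.std(ddof=1)) if v.size > 1 else None,
            })
    testable = {g: t for g, t in groups.items()
                if all(v.size > 0 for v in t.values())}
    tests = None
    if len(testable) >= 2:
        tests_df, _ = compare_rate_distributions(testable)
        tests = tests_df.to_dict(orient="records")
    return {"summary": summary_rows, "tests": tests}


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Declarative configuration for one synthetic pipeline run."""

    seed: int = 0
    n_genes: int = 2000
    n_replicates: int = 4
    library_size: int = 2_000_000
    snp_coverage_fraction: float = 0.25
    class_proportions: dict = field(default_factory=lambda: {
        "conserved": 0.85, "cis_only": 0.05,
        "cis_trans_divergent": 0.05, "compensatory": 0.05})
    effect_size: object = (1.0, 4.0)
    dispersion: float = 0.05
    alpha: float = 0.05
    lfc_thresholds: tuple = (0.5, 1.0)
    min_snp_support: int = 3
    min_ase_reads: int = 20
    n_codons: int = 200
    mean_syn: float = 3.0
    mean_nonsyn: float = 1.0
    region_len: int = 4000
    cooption_flank: int = 2000
    cooption_min_len: int = 173
    cooption_min_identity: float = 64.0
    cooption_max_evalue: float = 1e-14
    planted_cooption_pairs: int = 2
    planted_motif_len: int = 250

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["lfc_thresholds"] = list(self.lfc_thresholds)
        if isinstance(d["effect_size"], tuple):
            d["effect_size"] = list(d["effect_size"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "lfc_thresholds" in d:
            d["lfc_thresholds"] = tuple(d["lfc_thresholds"])
        if isinstance(d.get("effect_size"), list):
            d["effect_size"] = tuple(d["effect_size"])
        return cls(**d)

    def sim_design(self) -> SimDesign:
        return SimDesign(
            n_genes=self.n_genes, n_replicates=self.n_replicates,
            library_size=self.library_size,
            snp_coverage_fraction=self.snp_coverage_fraction,
            class_proportions=dict(self.class_proportions),
            effect_size=self.effect_size, dispersion=self.dispersion,
            seed=self.seed)


# ---------------------------------------------------------------------------
# pipeline


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _consensus_for(cm: CountMatrix, contrast, alpha, lfc_threshold, cache):
    key = contrast
    if key not in cache:
        cache[key] = {e: run_de_engine(cm, contrast, e)
                      for e in ("nb_exact", "nb_wald")}
    res = cache[key]
    return consensus_de(res["nb_exact"], res["nb_wald"], alpha=alpha,
                        lfc_threshold=lfc_threshold)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on a synthetic experiment and write all outputs.

    Returns the summary report (also written as ``summary.json``); stage
    tables land as TSV under ``out_dir`` and ``manifest.json`` records the
    config plus the SHA-256 of every file written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.sim_design()
    arch = simulate_architecture(design)
    truth = truth_table(arch)
    cm = simulate_counts(arch, design)
    ase_table = simulate_allele_reads(arch, cm, design)
    hio.write_counts(cm, out / "counts.tsv", out / "design.tsv")
    hio.write_allele_table(ase_table, out / "allele_counts.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    filtered = filter_low_expression(cm)
    # composition-corrected depths for the allele-count adjustment
    effective_sizes = cm.library_sizes() * tmm_factors(cm.counts)
    engine_cache: dict = {}
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[7])
    n_syn = rng.poisson(config.mean_syn, size=len(arch))
    n_nonsyn = rng.poisson(config.mean_nonsyn, size=len(arch))
    estimates = {}
    div_rows = []
    for i, a in enumerate(arch):
        ns = min(int(n_syn[i]), config.n_codons // 2)
        nn = min(int(n_nonsyn[i]), config.n_codons // 2)
        pair = simulate_cds_pair(config.n_codons, ns, nn,
                                 seed=int(rng.integers(0, 2 ** 31)))
        est = estimate_dnds(CodonAlignment(a.gene_id, *pair))
        estimates[a.gene_id] = est
        div_rows.append({"gene_id": a.gene_id, "dN": est.dN, "dS": est.dS,
                         "omega": est.omega, "n_codons_used": est.n_codons_used})
    pd.DataFrame(div_rows).to_csv(out / "divergence.tsv", sep="\t", index=False)

    norm_means = cpm(filtered.counts)
    group_mean = {g: norm_means[filtered.samples_in_group(g)].mean(axis=1)
                  for g in filtered.groups()}

    report: dict = {"seed": config.seed, "n_genes": config.n_genes,
                    "n_genes_after_filter": len(filtered.gene_ids),
                    "thresholds": {}}
    for lfc_threshold in config.lfc_thresholds:
        block: dict = {}
        parental = _consensus_for(filtered, ("P1", "P2"), config.alpha,
                                  lfc_threshold, engine_cache)
        parental_set = set(parental["gene_id"])
        block["n_parental_de"] = len(parental_set)

        all_trans: dict[str, list] = {}
        for hyb in HYBRIDS:
            cons_p1 = _consensus_for(filtered, ("P1", hyb), config.alpha,
                                     lfc_threshold, engine_cache)
            cons_p2 = _consensus_for(filtered, ("P2", hyb), config.alpha,
                                     lfc_threshold, engine_cache)
            all_trans[hyb] = call_transgressive(cons_p1, cons_p2, hyb,
                                                lfc_threshold=lfc_threshold)
        trans_genes = sorted({c.gene_id for calls in all_trans.values()
                              for c in calls})
        partition = partition_by_parental_de(trans_genes, parental_set)
        block["n_transgressive_total"] = len(trans_genes)
        block["n_transgressive_per_hybrid"] = {
            h: len(calls) for h, calls in all_trans.items()}

        # regulatory classification of transgressive genes, per hybrid
        calls_rows = []
        category_counts: dict[str, int] = {}
        classified_genes: dict[str, str] = {}
        for hyb in HYBRIDS:
            genes = [c.gene_id for c in all_trans[hyb]]
            calls = classify_all(ase_table, cm.design, genes, hyb,
                                 parental_set, alpha=config.alpha,
                                 min_reads=config.min_ase_reads,
                                 library_sizes=effective_sizes)
            for c in calls:
                calls_rows.append(dataclasses.asdict(c))
                classified_genes.setdefault(c.gene_id, c.category)
        for g, cat in classified_genes.items():
            category_counts[cat] = category_counts.get(cat, 0) + 1

        # co-option screen over trans-driven transgressive genes
        trans_driven = sorted(g for g, cat in classified_genes.items()
                              if cat in ("compensatory", "cis_trans_divergent"))
        coopted: set[str] = set()
        if trans_driven:
            region_names = trans_genes
            n_background = min(20, config.n_genes - len(region_names))
            planted = min(config.planted_cooption_pairs, len(trans_driven) // 2)
            regions, _ = simulate_upstream_regions(
                len(region_names) + n_background, region_len=config.region_len,
                planted_pairs=[(i, i + 1) for i in range(0, 2 * planted, 2)],
                motif_len=config.planted_motif_len, identity=1.0,
                seed=config.seed + 17)
            keys = list(regions)
            trans_regions = {region_names[i]: regions[keys[i]]
                             for i in range(len(region_names))}
            background = {f"bg{i}": regions[keys[len(region_names) + i]]
                          for i in range(n_background)}
            # planted pairs were laid over the first region names; only
            # trans-driven genes are queried, per the screen's definition
            hits = screen_cooption(
                trans_driven, trans_regions, background,
                ScreenThresholds(max_evalue=config.cooption_max_evalue,
                                 min_length=config.cooption_min_len,
                                 min_identity=config.cooption_min_identity))
            for h in hits:
                coopted.update((h.query_gene, h.subject_gene))
            pd.DataFrame([dataclasses.asdict(h) for h in hits]).drop(
                columns=["query_segment"], errors="ignore").to_csv(
                out / f"cooption_lfc{lfc_threshold}.tsv", sep="\t", index=False)

        block["classification"] = summarize_classification(
            n_transgressive=len(trans_genes),
            n_not_parental_de=len(partition["transgressive_only"]),
            category_counts=category_counts or {"uninformative": 0},
            n_coopted=len(coopted)) if trans_genes else None

        # correlations: parental expression difference vs divergence
        de_genes = [g for g in parental_set if g in group_mean["P1"].index]
        expr_diff = [abs(float(np.log2(group_mean["P1"][g] + 0.5)
                               - np.log2(group_mean["P2"][g] + 0.5)))
                     for g in de_genes]
        block["correlations"] = {}
        for rate in ("dN", "dS", "omega"):
            vals = [getattr(estimates[g], rate) if estimates[g] is not None
                    else None for g in de_genes]
            pairs = [(e, v) for e, v in zip(expr_diff, vals) if v is not None]
            if len(pairs) >= 4:
                res = spearman([p[0] for p in pairs], [p[1] for p in pairs])
                block["correlations"][rate] = {
                    "n": res.n, "rho": res.rho, "pvalue": res.pvalue}
            else:
                block["correlations"][rate] = None

        block["rate_comparison"] = summarize_rates(
            estimates, {k: v for k, v in partition.items()})

        pd.DataFrame(calls_rows).to_csv(
            out / f"regulatory_calls_lfc{lfc_threshold}.tsv", sep="\t", index=False)
        parental.to_csv(out / f"parental_de_lfc{lfc_threshold}.tsv",
                        sep="\t", index=False)
        report["thresholds"][str(lfc_threshold)] = block

    (out / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest = {
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        "seed": config.seed,
        "outputs": {p.name: _sha256(p)
                    for p in sorted(set(out.glob("*.tsv")) | {out / "summary.json"})
                    if p.exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
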