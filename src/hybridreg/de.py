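"""Differential expression on gene-level count matrices.

Implements the count preprocessing (CPM filtering, TMM and median-of-ratios
normalization) and two self-contained negative-binomial DE engines:

``nb_exact``
    TMM-normalized counts, tagwise method-of-moments dispersions shrunk
    toward the common dispersion, and a conditional NB exact test on the
    group sums (edgeR-style).

``nb_wald``
    Median-of-ratios size factors, per-group NB maximum-likelihood rates via
    Newton iteration, and a Wald test on the log-rate difference
    (DESeq-style).

A gene enters the consensus DE set for a contrast only when both engines
call it significant at the FDR cutoff, with agreeing fold-change signs and
|lfc| at or above the threshold in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .stats import bh_fdr

__all__ = [
    "CountMatrix",
    "cpm",
    "filter_low_expression",
    "tmm_factors",
    "median_of_ratios_factors",
    "run_de_engine",
    "consensus_de",
    "bh_fdr",
]

GROUPS = ("P1", "P2", "HybFertile", "HybSterile")

#: prior degrees of freedom pulling tagwise dispersions toward the common one
DISPERSION_PRIOR_DF = 20.0
DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, plus the sample design.

    ``counts`` is indexed by gene id with one column per sample; ``design``
    is indexed by sample id with columns ``group`` and ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.counts.columns) <= set(self.design.index):
            missing = set(self.counts.columns) - set(self.design.index)
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        arr = self.counts.to_numpy()
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            g = self.design.loc[s, "group"]
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.design.loc[s, "group"] == group]

    def subset_groups(self, groups) -> "CountMatrix":
        samples = [s for s in self.counts.columns if self.design.loc[s, "group"] in groups]
        return CountMatrix(self.counts[samples], self.design.loc[samples])


def cpm(counts: pd.DataFrame, library_sizes=None) -> pd.DataFrame:
    """Counts per million: ``counts / library_size * 1e6`` per sample."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes, index=counts.columns).astype(float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(library_sizes, axis=1) * 1e6


def filter_low_expression(cm: CountMatrix, min_cpm: float = 1.0,
                          mode: str = "any_group_low_excludes") -> CountMatrix:
    """Drop genes with low counts-per-million.

    ``mode="any_group_low_excludes"`` (default) removes a gene as soon as any
    group's mean CPM falls below ``min_cpm`` — the strict reading of the
    common edgeR-style filter. ``mode="all_groups_low_excludes"`` removes a
    gene only when every group is below the threshold.
    """
    if mode not in ("any_group_low_excludes", "all_groups_low_excludes"):
        raise ValueError(f"unknown filter mode: {mode}")
    if cm.counts.empty:
        return cm
    c = cpm(cm.counts)
    group_means = pd.DataFrame(
        {g: c[cm.samples_in_group(g)].mean(axis=1) for g in cm.groups()}
    )
    if mode == "any_group_low_excludes":
        keep = (group_means >= min_cpm).all(axis=1)
    else:
        keep = (group_means >= min_cpm).any(axis=1)
    return CountMatrix(cm.counts.loc[keep], cm.design)


def _choose_tmm_reference(counts: pd.DataFrame) -> str:
    # sample whose upper-quartile CPM is closest to the mean of those quantiles
    q = cpm(counts).quantile(0.75, axis=0)
    return (q - q.mean()).abs().idxmin()


def tmm_factors(counts: pd.DataFrame, reference_sample: str | None = None,
                log_ratio_trim: float = 0.3, abs_expr_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    Per-gene log2 ratios (M) against the reference sample are trimmed by
    ``log_ratio_trim`` at each tail, absolute expression values (A) by
    ``abs_expr_trim``, and the surviving M values averaged with
    inverse-asymptotic-variance weights. Factors are centred so their
    geometric mean is 1.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    if reference_sample is None:
        reference_sample = _choose_tmm_reference(counts)
    yr = counts[reference_sample].to_numpy(dtype=float)
    nr = lib[reference_sample]
    factors = {}
    for s in counts.columns:
        ys = counts[s].to_numpy(dtype=float)
        ns = lib[s]
        ok = (ys > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(f"no genes shared between {s} and reference")
        fs, fr = ys[ok] / ns, yr[ok] / nr
        m = np.log2(fs / fr)
        a = 0.5 * np.log2(fs * fr)
        # rank-based two-sided trimming on both M and A
        n = m.size
        lo_m = np.floor(n * log_ratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_expr_trim) + 1
        hi_a = n + 1 - lo_a
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            factors[s] = 1.0
            continue
        w = 1.0 / ((ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok]))
        f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
        factors[s] = 2.0 ** f
    out = pd.Series(factors, index=counts.columns, dtype=float)
    return out / np.exp(np.mean(np.log(out)))


def median_of_ratios_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style).

    Each sample's factor is the median, over genes expressed in every
    sample, of that sample's count divided by the gene's geometric mean.
    """
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logs = np.log(arr[allpos])
    log_geo = logs.mean(axis=1, keepdims=True)
    return pd.Series(np.exp(np.median(logs - log_geo, axis=0)),
                     index=counts.columns, dtype=float)


# ---------------------------------------------------------------------------
# dispersion estimation


def _tagwise_dispersions(norm_counts: np.ndarray, group_cols: list[np.ndarray],
                         prior_df: float = DISPERSION_PRIOR_DF) -> np.ndarray:
    """Method-of-moments NB dispersions shrunk toward the common value.

    ``norm_counts`` are counts on a common library scale; ``group_cols``
    gives the column indices of each group. Uses var = mu + phi*mu^2 within
    each group, pools numerators and denominators across groups, and shrinks
    the per-gene estimate toward the common dispersion with ``prior_df``
    prior degrees of freedom.
    """
    num = np.zeros(norm_counts.shape[0])
    den = np.zeros(norm_counts.shape[0])
    resid_df = 0
    for cols in group_cols:
        y = norm_counts[:, cols]
        if y.shape[1] < 2:
            continue
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        num += v - m
        den += m ** 2
        resid_df += y.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    phi = np.clip(phi, 0.0, None)
    finite = phi[np.isfinite(phi)]
    common = float(np.mean(finite)) if finite.size else 0.0
    shrunk = (prior_df * common + resid_df * phi) / (prior_df + max(resid_df, 1))
    return np.clip(shrunk, DISPERSION_FLOOR, None)


# ---------------------------------------------------------------------------
# nb_exact engine


def _exact_nb_pvalue(a: int, b: int, r_a: float, r_b: float) -> float:
    """Conditional NB exact test p-value.

    Under the null the group sums A ~ NB(r_a, p), B ~ NB(r_b, p); conditional
    on T = A + B the distribution of A is negative hypergeometric. The
    two-sided p-value sums the probabilities of all outcomes no more likely
    than the observed one.
    """
    t = a + b
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    # pmf recurrence: pmf(k)/pmf(k-1) = (k-1+rA)/k * (t-k+1)/(t-k+rB)
    with np.errstate(divide="ignore"):
        steps = np.log(k[1:] - 1.0 + r_a) - np.log(k[1:]) \
            + np.log(t - k[1:] + 1.0) - np.log(t - k[1:] + r_b)
    logpmf = np.concatenate([[0.0], np.cumsum(steps)])
    logpmf -= logsumexp(logpmf)
    obs = logpmf[a]
    sel = logpmf <= obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logpmf[sel]))))


def _engine_nb_exact(cm: CountMatrix, contrast: tuple[str, str]) -> pd.DataFrame:
    ga, gb = contrast
    sub = cm.subset_groups([ga, gb])
    counts = sub.counts
    lib = counts.sum(axis=0).astype(float)
    eff = lib * tmm_factors(counts)
    ref = float(np.exp(np.mean(np.log(eff))))
    pseudo = counts.to_numpy(dtype=float) * (ref / eff.to_numpy())

    cols_a = [counts.columns.get_loc(s) for s in sub.samples_in_group(ga)]
    cols_b = [counts.columns.get_loc(s) for s in sub.samples_in_group(gb)]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least two replicates")
    phi = _tagwise_dispersions(pseudo, [np.array(cols_a), np.array(cols_b)])

    sum_a = np.rint(pseudo[:, cols_a].sum(axis=1)).astype(np.int64)
    sum_b = np.rint(pseudo[:, cols_b].sum(axis=1)).astype(np.int64)
    n_a, n_b = len(cols_a), len(cols_b)
    pvals = np.ones(counts.shape[0])
    for i in range(counts.shape[0]):
        pvals[i] = _exact_nb_pvalue(int(sum_a[i]), int(sum_b[i]),
                                    n_a / phi[i], n_b / phi[i])
    mean_a = pseudo[:, cols_a].mean(axis=1)
    mean_b = pseudo[:, cols_b].mean(axis=1)
    lfc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    return pd.DataFrame({
        "gene_id": counts.index,
        "lfc": lfc,
        "pvalue": pvals,
        "fdr": bh_fdr(pvals),
        "engine": "nb_exact",
        "contrast": f"{ga}:{gb}",
    }).set_index("gene_id", drop=False)


# ---------------------------------------------------------------------------
# nb_wald engine


def _nb_group_mle(y: np.ndarray, sf: np.ndarray, phi: np.ndarray,
                  n_iter: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Newton solve for per-gene NB log-rates within one group.

    Model: y_ij ~ NB(mu_ij = rate_i * sf_j, phi_i). Returns (eta, info)
    where eta = log rate and info is the observed Fisher information of eta.
    """
    base = np.maximum((y / sf).mean(axis=1), 1e-8)
    eta = np.log(base)
    for _ in range(n_iter):
        mu = np.exp(eta)[:, None] * sf[None, :]
        w = 1.0 + phi[:, None] * mu
        score = ((y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        eta = eta + np.clip(step, -5.0, 5.0)
    mu = np.exp(eta)[:, None] * sf[None, :]
    info = (mu / (1.0 + phi[:, None] * mu)).sum(axis=1)
    return eta, info


def _engine_nb_wald(cm: CountMatrix, contrast: tuple[str, str]) -> pd.DataFrame:
    ga, gb = contrast
    sub = cm.subset_groups([ga, gb])
    counts = sub.counts
    sf = median_of_ratios_factors(counts)
    arr = counts.to_numpy(dtype=float)
    cols_a = [counts.columns.get_loc(s) for s in sub.samples_in_group(ga)]
    cols_b = [counts.columns.get_loc(s) for s in sub.samples_in_group(gb)]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least two replicates")
    normed = arr / sf.to_numpy()[None, :]
    phi = _tagwise_dispersions(normed, [np.array(cols_a), np.array(cols_b)])

    eta_a, info_a = _nb_group_mle(arr[:, cols_a], sf.to_numpy()[cols_a], phi)
    eta_b, info_b = _nb_group_mle(arr[:, cols_b], sf.to_numpy()[cols_b], phi)
    delta = eta_b - eta_a
    se = np.sqrt(1.0 / np.maximum(info_a, 1e-12) + 1.0 / np.maximum(info_b, 1e-12))
    z = delta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    return pd.DataFrame({
        "gene_id": counts.index,
        "lfc": delta / np.log(2.0),
        "pvalue": pvals,
        "fdr": bh_fdr(pvals),
        "engine": "nb_wald",
        "contrast": f"{ga}:{gb}",
    }).set_index("gene_id", drop=False)


ENGINES = {"nb_exact": _engine_nb_exact, "nb_wald": _engine_nb_wald}


def run_de_engine(cm: CountMatrix, contrast: tuple[str, str],
                  engine: str = "nb_exact") -> pd.DataFrame:
    """Run one NB differential-expression engine on one two-group contrast.

    ``lfc`` is log2(second group / first group). Returns a DataFrame indexed
    by gene with columns gene_id, lfc, pvalue, fdr, engine, contrast.
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {sorted(ENGINES)}")
    ga, gb = contrast
    if ga == gb:
        raise ValueError("contrast must name two distinct groups")
    for g in contrast:
        if not cm.samples_in_group(g):
            raise ValueError(f"group {g!r} has no samples")
    return ENGINES[engine](cm, contrast)


def consensus_de(results_engine1: pd.DataFrame, results_engine2: pd.DataFrame,
                 alpha: float = 0.05, lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Intersect two engines' DE calls for one contrast.

    A gene is kept iff FDR < ``alpha`` in both engines, the fold-change
    signs agree, and |lfc| >= ``lfc_threshold`` in both. The returned frame
    carries both engines' lfc plus their mean as ``lfc``.
    """
    c1 = set(results_engine1["contrast"].unique())
    c2 = set(results_engine2["contrast"].unique())
    if c1 != c2:
        raise ValueError(f"contrast mismatch: {c1} vs {c2}")
    merged = results_engine1.reset_index(drop=True).merge(
        results_engine2.reset_index(drop=True), on="gene_id",
        suffixes=("_1", "_2"))
    keep = (
        (merged["fdr_1"] < alpha)
        & (merged["fdr_2"] < alpha)
        & (np.sign(merged["lfc_1"]) == np.sign(merged["lfc_2"]))
        & (merged["lfc_1"].abs() >= lfc_threshold)
        & (merged["lfc_2"].abs() >= lfc_threshold)
    )
    out = merged.loc[keep, ["gene_id", "lfc_1", "lfc_2", "fdr_1", "fdr_2"]].copy()
    out["lfc"] = (out["lfc_1"] + out["lfc_2"]) / 2.0
    out["contrast"] = results_engine1["contrast"].iloc[0] if len(results_engine1) else ""
    return out.reset_index(drop=True)
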