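"""Coding-sequence divergence: NG86 dN/dS and the correlation statistics.

Pairwise dN and dS are estimated with the Nei-Gojobori (1986) pathway
counting method. Synonymous and non-synonymous site counts are computed per
codon as the fraction of the three possible single-base changes at each
position that are synonymous, with changes to stop codons excluded from the
denominator. Observed differences in multi-hit codons are averaged over all
minimal mutational pathways that avoid stop codons; codons whose every
pathway passes through a stop are masked. Proportions are corrected for
multiple hits with the Jukes-Cantor formula d = -3/4 ln(1 - 4p/3), which is
undefined at p >= 3/4; undefined dN, dS or dN/dS are reported explicitly as
None, never as silent zeros.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats as sps

from .stats import bh_fdr

__all__ = [
    "CodonAlignment",
    "DivergenceEstimate",
    "CorrelationResult",
    "validate_orf",
    "ng86_site_counts",
    "estimate_dnds",
    "spearman",
    "compare_rate_distributions",
    "STOP_CODONS",
    "translate_codon",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
_FORWARD = dict(_STANDARD.forward_table)
_BASES = "ACGT"


def translate_codon(codon: str) -> str | None:
    """Amino acid for a sense codon; None for a stop codon."""
    return _FORWARD.get(codon)


class OrfValidationError(ValueError):
    """Alignment violates the intact-ORF requirements."""


@dataclass
class CodonAlignment:
    """An aligned coding-sequence pair for one gene (gaps allowed)."""

    gene_id: str
    seq_a: str
    seq_b: str


@dataclass
class DivergenceEstimate:
    """Per-gene NG86 divergence. Undefined values are None, with a reason."""

    gene_id: str
    dN: float | None
    dS: float | None
    omega: float | None
    n_codons_used: int
    flags: tuple[str, ...] = ()


@dataclass
class CorrelationResult:
    n: int
    rho: float
    pvalue: float


def validate_orf(alignment: CodonAlignment) -> CodonAlignment:
    """Check frame, gap structure and internal stops.

    Requires equal lengths, a multiple-of-three alignment, gaps confined to
    whole codons, and no internal stop codon in either sequence. A terminal
    stop is allowed (it is excluded from estimation).
    """
    a, b = alignment.seq_a.upper(), alignment.seq_b.upper()
    if len(a) != len(b):
        raise OrfValidationError(f"{alignment.gene_id}: unequal lengths")
    if len(a) == 0 or len(a) % 3 != 0:
        raise OrfValidationError(
            f"{alignment.gene_id}: length {len(a)} is not a positive multiple of three")
    n_codons = len(a) // 3
    for seq, label in ((a, "seq_a"), (b, "seq_b")):
        for k in range(n_codons):
            codon = seq[3 * k: 3 * k + 3]
            if "-" in codon and codon != "---":
                raise OrfValidationError(
                    f"{alignment.gene_id}: {label} has a partial-codon gap at codon {k}")
            if codon in STOP_CODONS and k < n_codons - 1:
                raise OrfValidationError(
                    f"{alignment.gene_id}: {label} has an internal stop at codon {k}")
    return CodonAlignment(alignment.gene_id, a, b)


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """NG86 synonymous and non-synonymous site counts for one sense codon.

    Each position contributes the fraction of its non-stop single-base
    changes that are synonymous; positions whose every change is a stop
    contribute nothing (hence sites sum to at most 3).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon has no site counts: {codon}")
    aa = translate_codon(codon)
    syn = nonsyn = 0.0
    for pos in range(3):
        s = n = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            if translate_codon(mut) == aa:
                s += 1
            else:
                n += 1
        if s + n:
            syn += s / (s + n)
            nonsyn += n / (s + n)
    return syn, nonsyn


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float] | None:
    """Average (syn, nonsyn) differences over stop-free minimal pathways.

    Returns None when every pathway passes through a stop codon (codon is
    then masked from estimation).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(nxt) == translate_codon(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    arr = np.array(results, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def _jukes_cantor(p: float) -> float | None:
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return float(-0.75 * np.log(1.0 - 4.0 * p / 3.0))


def estimate_dnds(alignment: CodonAlignment) -> DivergenceEstimate:
    """NG86 dN/dS for one validated codon alignment.

    Sites are averaged over both sequences; pS = Sd/S and pN = Nd/N receive
    the Jukes-Cantor correction. dN/dS is undefined (None) when dS is 0 or
    undefined.
    """
    aln = validate_orf(alignment)
    a, b = aln.seq_a, aln.seq_b
    n_codons = len(a) // 3
    S = N = Sd = Nd = 0.0
    used = 0
    flags: list[str] = []
    for k in range(n_codons):
        ca, cb = a[3 * k: 3 * k + 3], b[3 * k: 3 * k + 3]
        if any(ch not in _BASES for ch in ca + cb):
            continue  # gap or ambiguity: codon masked
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue  # terminal stop
        path = _pathway_counts(ca, cb)
        if path is None:
            flags.append(f"codon_{k}_stop_blocked")
            continue
        sa, na = ng86_site_counts(ca)
        sb, nb = ng86_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += path[0]
        Nd += path[1]
        used += 1
    if used == 0:
        return DivergenceEstimate(aln.gene_id, None, None, None, 0,
                                  ("no_usable_codons",))
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    if dS is None:
        flags.append("dS_saturated")
    if dN is None:
        flags.append("dN_saturated")
    if dN is None or dS is None or dS == 0.0:
        omega = None
        if dS == 0.0:
            flags.append("omega_undefined_dS_zero")
    else:
        omega = dN / dS
    return DivergenceEstimate(aln.gene_id, dN, dS, omega, used, tuple(flags))


# ---------------------------------------------------------------------------
# correlation and rate-comparison statistics


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Permutation null of Spearman's rho (all n! orderings of y)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    perms = np.array(list(itertools.permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc ** 2).sum() * (pc ** 2).sum(axis=1))
    rhos = pc @ rxc / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing value are dropped. The p-value uses the exact
    permutation distribution for n <= 9 and the t approximation otherwise.
    Requires n >= 4 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    rho, p_t = sps.spearmanr(x, y)
    if n <= 9:
        p = _exact_spearman_pvalue(x, y, rho)
    else:
        p = float(p_t)
    return CorrelationResult(n=n, rho=float(rho), pvalue=p)


def compare_rate_distributions(groups: dict[str, dict[str, np.ndarray]]
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise two-sided Mann-Whitney tests on per-group rate sets.

    ``groups`` maps group label -> {rate name -> values}. Missing values are
    dropped per rate. Returns ``(tests, summary)``: ``tests`` holds one row
    per group pair per rate with U, raw p and BH FDR across the whole
    family; ``summary`` holds n, mean and sample SD (ddof=1; NaN for n < 2)
    per group and rate.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    clean: dict[str, dict[str, np.ndarray]] = {}
    rates: list[str] = []
    for g, table in groups.items():
        clean[g] = {}
        for rate, vals in table.items():
            v = np.asarray(vals, dtype=float)
            v = v[np.isfinite(v)]
            clean[g][rate] = v
            if rate not in rates:
                rates.append(rate)
    rows = []
    labels = list(clean)
    for rate in rates:
        for ga, gb in itertools.combinations(labels, 2):
            va, vb = clean[ga].get(rate), clean[gb].get(rate)
            if va is None or vb is None or va.size == 0 or vb.size == 0:
                raise ValueError(f"empty group for rate {rate!r}")
            u, p = sps.mannwhitneyu(va, vb, alternative="two-sided")
            rows.append({"rate": rate, "group_a": ga, "group_b": gb,
                         "u_statistic": float(u), "pvalue": float(p)})
    tests = pd.DataFrame(rows)
    tests["fdr"] = bh_fdr(tests["pvalue"].to_numpy())
    summary_rows = []
    for g in labels:
        for rate in rates:
            v = clean[g][rate]
            summary_rows.append({
                "group": g, "rate": rate, "n": int(v.size),
                "mean": float(v.mean()) if v.size else np.nan,
                "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
            })
    return tests, pd.DataFrame(summary_rows)
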