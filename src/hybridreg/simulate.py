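"""Synthetic data with known regulatory ground truth.

Generates everything the downstream stages consume: negative-binomial count
matrices for two parental lines and their reciprocal F1 hybrids, per-gene
allele-specific read tables at informative fixed SNPs, pairwise codon
alignments with planted synonymous/non-synonymous substitutions, and
upstream regions with planted shared motifs for the co-option screen.

The regulatory model is additive on the log2 scale. Each gene carries a
``cis_effect`` (linked to the parent-2 allele) and a ``trans_effect``
(property of the parent-2 cellular background):

* parent 1 mean          = 2^base
* parent 2 mean          = 2^(base + cis + trans)
* hybrid allele-1 mean   = 0.5 * 2^(base + trans/2)
* hybrid allele-2 mean   = 0.5 * 2^(base + cis + trans/2)

Both hybrid alleles share the mixed trans environment (trans/2), so the
hybrid allelic log2 ratio equals ``cis`` while the parental log2 ratio
equals ``cis + trans``. Compensatory genes have ``cis = -trans``: equal
parental expression but allelic imbalance in the hybrid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import CountMatrix
from .divergence import STOP_CODONS, translate_codon

__all__ = [
    "TRUE_CLASSES",
    "GeneArchitecture",
    "SimDesign",
    "simulate_architecture",
    "simulate_counts",
    "simulate_allele_reads",
    "simulate_cds_pair",
    "simulate_upstream_regions",
    "expected_category",
]

TRUE_CLASSES = ("conserved", "cis_only", "cis_trans_divergent", "compensatory")

#: map from simulated regulatory architecture to the category the
#: ASE classifier should recover for it
_EXPECTED = {
    "conserved": "non_compensatory",
    "cis_only": "cis_only",
    "cis_trans_divergent": "cis_trans_divergent",
    "compensatory": "compensatory",
}


def expected_category(true_class: str) -> str:
    """Regulatory category the classifier should assign to a true class."""
    return _EXPECTED[true_class]


class GenerationError(RuntimeError):
    """Requested synthetic construct cannot be realised."""


@dataclass
class GeneArchitecture:
    """Ground-truth regulatory architecture of one simulated gene."""

    gene_id: str
    base_log2_expr: float
    cis_effect: float
    trans_effect: float
    dispersion: float
    true_class: str

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.true_class not in TRUE_CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")
        c, t = self.cis_effect, self.trans_effect
        ok = {
            "conserved": c == 0 and t == 0,
            "cis_only": c != 0 and t == 0,
            "compensatory": c != 0 and c == -t,
            "cis_trans_divergent": c != 0 and t != 0 and c != -t,
        }[self.true_class]
        if not ok:
            raise ValueError(
                f"effects (cis={c}, trans={t}) violate class {self.true_class!r}")


@dataclass
class SimDesign:
    """Study design for the synthetic experiment.

    Defaults describe a modest whole-tissue RNA-seq experiment: four
    biological replicates per group, two-million-read libraries, a quarter
    of each gene's reads overlapping diagnostic fixed SNPs, and effect
    sizes of 1.5 log2 units for diverged genes.
    """

    n_genes: int = 2000
    n_replicates: int = 4
    library_size: int = 2_000_000
    snp_coverage_fraction: float = 0.25
    class_proportions: dict = field(default_factory=lambda: {
        "conserved": 0.85,
        "cis_only": 0.05,
        "cis_trans_divergent": 0.05,
        "compensatory": 0.05,
    })
    #: log2 effect magnitude for diverged genes: a fixed value, or a
    #: (low, high) range sampled uniformly per gene
    effect_size: float | tuple[float, float] = (1.0, 4.0)
    dispersion: float = 0.05
    base_log2_range: tuple[float, float] = (5.0, 9.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_replicates < 2 or self.library_size <= 0:
            raise ValueError("n_genes, n_replicates>=2 and library_size must be positive")
        if not 0.0 <= self.snp_coverage_fraction <= 1.0:
            raise ValueError("snp_coverage_fraction must be in [0, 1]")
        if set(self.class_proportions) - set(TRUE_CLASSES):
            raise ValueError("unknown class in class_proportions")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative and sum to 1")
        e = self.effect_size
        if isinstance(e, (tuple, list)):
            if len(e) != 2 or e[0] <= 0 or e[1] < e[0]:
                raise ValueError("effect_size range must be 0 < low <= high")
        elif e <= 0:
            raise ValueError("effect_size must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def simulate_architecture(design: SimDesign) -> list[GeneArchitecture]:
    """Draw per-gene regulatory architectures from the design's class mix."""
    design.validate()
    rng = _rng(design.seed, 0)
    classes = [c for c in TRUE_CLASSES if design.class_proportions.get(c, 0) > 0]
    probs = np.array([design.class_proportions[c] for c in classes], dtype=float)
    probs /= probs.sum()
    draws = rng.choice(len(classes), size=design.n_genes, p=probs)
    lo, hi = design.base_log2_range
    bases = rng.uniform(lo, hi, size=design.n_genes)
    signs = rng.choice([-1.0, 1.0], size=design.n_genes)
    if isinstance(design.effect_size, (tuple, list)):
        mags = rng.uniform(design.effect_size[0], design.effect_size[1],
                           size=design.n_genes)
    else:
        mags = np.full(design.n_genes, float(design.effect_size))
    arch = []
    for i in range(design.n_genes):
        cls = classes[draws[i]]
        e = float(mags[i])
        if cls == "conserved":
            cis, trans = 0.0, 0.0
        elif cls == "cis_only":
            cis, trans = signs[i] * e, 0.0
        elif cls == "compensatory":
            cis, trans = signs[i] * e, -signs[i] * e
        else:  # cis_trans_divergent: same-sign cis and trans
            cis, trans = signs[i] * e, signs[i] * e
        arch.append(GeneArchitecture(
            gene_id=f"g{i:05d}", base_log2_expr=float(bases[i]),
            cis_effect=cis, trans_effect=trans,
            dispersion=design.dispersion, true_class=cls))
    return arch


def group_means(arch: list[GeneArchitecture]) -> pd.DataFrame:
    """Expected (unnormalised) expression per group under the additive model."""
    base = np.array([a.base_log2_expr for a in arch])
    cis = np.array([a.cis_effect for a in arch])
    trans = np.array([a.trans_effect for a in arch])
    p1 = 2.0 ** base
    p2 = 2.0 ** (base + cis + trans)
    hyb = 0.5 * 2.0 ** (base + trans / 2.0) * (1.0 + 2.0 ** cis)
    return pd.DataFrame(
        {"P1": p1, "P2": p2, "HybFertile": hyb, "HybSterile": hyb},
        index=[a.gene_id for a in arch])


def truth_table(arch: list[GeneArchitecture]) -> pd.DataFrame:
    """Per-gene ground-truth labels for downstream comparison."""
    return pd.DataFrame({
        "gene_id": [a.gene_id for a in arch],
        "true_class": [a.true_class for a in arch],
        "cis_effect": [a.cis_effect for a in arch],
        "trans_effect": [a.trans_effect for a in arch],
        "expected_category": [expected_category(a.true_class) for a in arch],
    }).set_index("gene_id", drop=False)


def simulate_counts(arch: list[GeneArchitecture], design: SimDesign) -> CountMatrix:
    """Draw NB read counts for every sample; means follow ``group_means``.

    Each sample's expected counts are the group's relative expression scaled
    to the design library size; counts are NB with variance
    ``mu + dispersion * mu^2`` (Poisson when dispersion is 0).
    """
    design.validate()
    rng = _rng(design.seed, 1)
    means = group_means(arch)
    disp = np.array([a.dispersion for a in arch])
    cols, design_rows = {}, []
    for grp in means.columns:
        rel = means[grp].to_numpy()
        mu = rel / rel.sum() * design.library_size
        for rep in range(1, design.n_replicates + 1):
            sample = f"{grp}_{rep}"
            with np.errstate(divide="ignore"):
                n_param = np.where(disp > 0, 1.0 / np.maximum(disp, 1e-300), np.inf)
            counts = np.empty(len(arch), dtype=np.int64)
            pois = disp == 0
            if pois.any():
                counts[pois] = rng.poisson(mu[pois])
            if (~pois).any():
                n = n_param[~pois]
                p = n / (n + mu[~pois])
                counts[~pois] = rng.negative_binomial(n, p)
            cols[sample] = counts
            design_rows.append({"sample": sample, "group": grp, "replicate": rep})
    counts_df = pd.DataFrame(cols, index=means.index)
    design_df = pd.DataFrame(design_rows).set_index("sample")
    return CountMatrix(counts_df, design_df)


def simulate_allele_reads(arch: list[GeneArchitecture], cm: CountMatrix,
                          design: SimDesign) -> pd.DataFrame:
    """Binomially thin gene counts into allele-informative SNP reads.

    Per gene and sample, ``Binomial(total, snp_coverage_fraction)`` reads
    are informative. Parental samples carry only their own allele; hybrid
    informative reads split between alleles with parent-2 probability
    ``2^cis / (1 + 2^cis)``.
    """
    design.validate()
    rng = _rng(design.seed, 2)
    cis = np.array([a.cis_effect for a in arch])
    p2_prob = 2.0 ** cis / (1.0 + 2.0 ** cis)
    rows = []
    for s in cm.sample_ids:
        grp = cm.design.loc[s, "group"]
        total = cm.counts[s].to_numpy()
        informative = rng.binomial(total, design.snp_coverage_fraction)
        if grp == "P1":
            r1, r2 = informative, np.zeros_like(informative)
        elif grp == "P2":
            r1, r2 = np.zeros_like(informative), informative
        else:
            r2 = rng.binomial(informative, p2_prob)
            r1 = informative - r2
        rows.append(pd.DataFrame({
            "gene_id": cm.gene_ids, "sample": s,
            "reads_p1": r1, "reads_p2": r2}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# codon alignments

_BASES = "ACGT"


def _synonymous_options(codon: str) -> list[str]:
    out = []
    aa = translate_codon(codon)
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            if translate_codon(mut) == aa:
                out.append(mut)
    return out


def _nonsynonymous_options(codon: str) -> list[str]:
    out = []
    aa = translate_codon(codon)
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            if translate_codon(mut) != aa:
                out.append(mut)
    return out


_SENSE_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                 if a + b + c not in STOP_CODONS]


def simulate_cds_pair(n_codons: int, n_syn: int, n_nonsyn: int,
                      seed: int = 0) -> tuple[str, str]:
    """Gap-free in-frame codon pair with planted substitution counts.

    Each planted difference occupies its own codon and is a single-base
    change that is unambiguously synonymous or non-synonymous, so pathway
    counting recovers the planted counts exactly.
    """
    if n_syn + n_nonsyn > n_codons:
        raise GenerationError("more substitutions requested than codons")
    rng = np.random.default_rng(seed)
    codons = [(_SENSE_CODONS[i]) for i in rng.integers(0, len(_SENSE_CODONS),
                                                       size=n_codons)]
    order = rng.permutation(n_codons)
    seq_b = list(codons)
    placed_syn = placed_nonsyn = 0
    for idx in order:
        if placed_syn < n_syn:
            opts = _synonymous_options(codons[idx])
            if opts:
                seq_b[idx] = opts[rng.integers(0, len(opts))]
                placed_syn += 1
                continue
        if placed_nonsyn < n_nonsyn:
            opts = _nonsynonymous_options(codons[idx])
            if opts:
                seq_b[idx] = opts[rng.integers(0, len(opts))]
                placed_nonsyn += 1
                continue
        if placed_syn == n_syn and placed_nonsyn == n_nonsyn:
            break
    if placed_syn < n_syn or placed_nonsyn < n_nonsyn:
        raise GenerationError("could not place all requested substitutions")
    return "".join(codons), "".join(seq_b)


# ---------------------------------------------------------------------------
# upstream regions


def simulate_upstream_regions(n_genes: int, region_len: int = 4000,
                              planted_pairs: int | list[tuple[int, int]] = 0,
                              motif_len: int = 200, identity: float = 1.0,
                              seed: int = 0) -> tuple[dict[str, str], pd.DataFrame]:
    """Random extended gene regions with optional planted shared motifs.

    ``planted_pairs`` may be a count (pairs drawn over disjoint gene pairs)
    or explicit index pairs. Each planted pair shares a ``motif_len``
    subsequence copied at the stated per-base ``identity``; all other
    sequence is i.i.d. uniform. Returns the regions and a truth table of
    planted pairs.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must be in (0, 1]")
    if motif_len + 8 > region_len:
        raise GenerationError("region too short for motif plus mismatch flanks")
    rng = np.random.default_rng(seed)
    names = [f"g{i:05d}" for i in range(n_genes)]
    seqs = {n: rng.integers(0, 4, size=region_len) for n in names}
    if isinstance(planted_pairs, int):
        if 2 * planted_pairs > n_genes:
            raise GenerationError("not enough genes for requested planted pairs")
        perm = rng.permutation(n_genes)
        pairs = [(int(perm[2 * k]), int(perm[2 * k + 1])) for k in range(planted_pairs)]
    else:
        pairs = [(int(i), int(j)) for i, j in planted_pairs]
    truth = []
    for i, j in pairs:
        src = int(rng.integers(4, region_len - motif_len - 3))
        dst = int(rng.integers(4, region_len - motif_len - 3))
        sa, sb = seqs[names[i]], seqs[names[j]]
        motif = sa[src:src + motif_len].copy()
        if identity < 1.0:
            mutate = rng.random(motif_len) > identity
            shift = rng.integers(1, 4, size=motif_len)
            motif[mutate] = (motif[mutate] + shift[mutate]) % 4
        sb[dst:dst + motif_len] = motif
        # force the bases flanking each junction to mismatch so the
        # shared segment has exactly the planted length
        for off in (1, 2, 3, 4):
            sb[dst - off] = (sa[src - off] + rng.integers(1, 4)) % 4
            sb[dst + motif_len - 1 + off] = (
                sa[src + motif_len - 1 + off] + rng.integers(1, 4)) % 4
        truth.append({"gene_a": names[i], "gene_b": names[j],
                      "pos_a": src, "pos_b": dst, "motif_len": motif_len})
    lut = np.array(list("ACGT"))
    out = {n: "".join(lut[v]) for n, v in seqs.items()}
    return out, pd.DataFrame(truth, columns=["gene_a", "gene_b", "pos_a",
                                             "pos_b", "motif_len"])
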