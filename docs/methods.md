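# Methods

`hybridreg` analyses bulk RNA-seq of two diverged (sub)species and their F1
hybrids to ask how regulatory divergence produces *transgressive*
expression — hybrid expression significantly outside the parental range —
and whether that misexpression traces to cis-regulatory change, trans
change, or offsetting (compensatory) cis–trans change. Every stage can run
on synthetic data with known ground truth; this note records the models,
parameter choices, numerical conventions and limitations.

## The regulatory model behind the generator

Each simulated gene carries a log2 baseline `b`, a cis effect `c` linked to
the parent-2 allele (promoter/enhancer divergence travelling with the
allele), and a trans effect `t` belonging to the parent-2 cellular
background (a diffusible regulator acting on both alleles). Effects are
additive on the log2 scale, and an F1 hybrid is modelled as a 50:50 mix of
the two trans backgrounds, i.e. each allele experiences `t/2`:

| quantity | expectation |
| --- | --- |
| parent-1 mean | `2^b` |
| parent-2 mean | `2^(b + c + t)` |
| hybrid allele-1 mean | `½ · 2^(b + t/2)` |
| hybrid allele-2 mean | `½ · 2^(b + c + t/2)` |

Consequences used throughout: the parental log2 ratio is `c + t`, the
hybrid allelic log2 ratio is exactly `c`, and a compensatory gene
(`c = −t ≠ 0`) has identical parental means but an imbalanced hybrid. The
mid-trans (`t/2`) choice is the simplest model under which the
classification logic is exactly recoverable; dominance of one trans
background is not modelled. Under this additive model a hybrid's total
expression always lies at or above the geometric mid-parent, so only genes
with opposing cis and trans effects (compensatory-like architectures)
become transgressive, and always upward: `lfc = log2((1+2^c)/2^(1+c/2))`,
about 0.19 at `|c| = 1.5`, 0.66 at 3, 1.09 at 4. Real transgressive
expression also arises from dominance and epistasis, which the generator
deliberately omits.

Counts are negative binomial with variance `μ + φμ²` (`φ` = dispersion,
0 = Poisson), each sample scaled so the genome-wide expected total equals
the library size. Allele-informative reads are a binomial thinning of the
gene's counts at the SNP coverage fraction; hybrid informative reads split
between alleles with parent-2 probability `2^c/(1+2^c)`. Read-level
artefacts (mapping bias toward the reference allele, positional coverage,
PCR duplicates) are not simulated, so passing tests say nothing about
reference-bias robustness on real data.

### Generator defaults

| parameter | default | why |
| --- | --- | --- |
| genes | 2000 | enough for stable normalization and FDR behaviour at desk scale |
| replicates/group | 4 | a typical whole-tissue design |
| library size | 2×10⁶ | keeps per-gene depth realistic (~10³ reads) at desk-scale gene counts |
| dispersion `φ` | 0.05 | BCV ≈ 0.22, ordinary biological replicates |
| class mix | 85% conserved, 5% each diverged class | divergence is the exception between close taxa |
| effect size | per-gene magnitude ~ U(1, 4) log2 units | regulatory effects span subtle to >10-fold; fixed magnitudes are used in the recovery suites |
| SNP coverage | 0.25 | only a minority of reads overlap diagnostic SNPs between close subspecies |

## Differential expression

Genes are removed when any group's mean CPM falls below 1 (the stricter
reading of the usual filter; the lenient "all groups low" variant is a
flag). Two self-contained NB engines then test each two-group contrast:

* **nb_exact** — TMM normalization (reference = sample whose upper-quartile
  CPM is nearest the mean of those quantiles; 30%/5% M/A trims; precision
  weights; factors centred to geometric mean 1 — verified in the test suite
  against edgeR's `calcNormFactors` to ~10⁻⁷), counts rescaled to a common
  effective depth, and a conditional NB exact test on the group sums. The
  conditional pmf is evaluated by recurrence and normalised with
  log-sum-exp; the two-sided p sums all outcomes no more probable than the
  observed one.
* **nb_wald** — median-of-ratios size factors, per-gene per-group NB
  log-rate MLE by Newton iteration, Wald z on the log-rate difference.

Both use tagwise method-of-moments dispersions shrunk toward the common
dispersion with 20 prior degrees of freedom and floored at 10⁻⁸. The
consensus set for a contrast requires FDR < α in both engines, agreeing
lfc signs, and |lfc| at or above the threshold (0.5 or 1.0) in both;
Benjamini–Hochberg correction is applied per contrast. These engines are
deliberately simple (no Cox–Reid adjustment, no GLM covariates) and are
pluggable: externally computed DE tables can be substituted wherever a
consensus frame is consumed.

On 2000-gene null simulations both engines give P(p < 0.05) ≈ 0.05–0.06 and
pass a Kolmogorov–Smirnov uniformity check at the seed stated in the test.
One caveat is worth stating precisely: estimated normalization factors
carry a shared ~1–2% error per sample, which shifts every gene's null
statistic by the same ≈0.07 sd. The 2000 p-values are therefore weakly
correlated, and a KS statistic computed as if they were independent
fluctuates more than its nominal distribution allows; with other seeds the
check can reject even though per-gene error rates stay near nominal. FDR
false-positive rates on the null stay at or below 5% plus sampling error.
Planted four-fold changes are recovered essentially always at FDR < 0.05;
the mean recovered lfc is unbiased (±0.02 over ~100 planted genes), while
single-gene estimates at 4 replicates and BCV 0.22 have sd ≈ 0.23 — recovery
statements are made about the mean, not each gene.

## Transgressive calling

A gene is transgressive for a hybrid when it sits in the consensus DE set
against *both* parents with the same sign; the direction follows the sign,
and the smaller |lfc| is kept as the *minimum transgressive expression*,
the hybrid expression-difference metric used in correlations. An option
(default on) additionally requires the lfc threshold against both parents.
Transgressive status is computed per hybrid (fertile and sterile)
independently. The three-way partition — parental-DE-only, parental-DE and
transgressive, transgressive-only — is disjoint and exhaustive over the
union of the two gene sets.

## ASE classification

Fixed diagnostic SNPs require each parental line to show exactly one base,
the bases to differ, and ≥3 supporting reads per parent (a VCF import with
the same semantics — biallelic, PASS, homozygous-different, per-sample
depth — is provided). Hybrid reads at those sites accrue to the matching
parental allele; third bases are discarded; per-gene sums over SNPs are
the unit of analysis. Genes with fewer than 20 combined parental reads
(boundary inclusive) are uninformative, as are genes with no informative
hybrid reads.

Counts are depth-adjusted by *effective* library size — library size times
TMM factor — rather than raw totals: when expression divergence shifts one
group's transcriptome total, every parental SNP-count ratio acquires the
same compositional offset, and at deep coverage Fisher tests would flag
that offset in every gene. Replicates are then pooled by summation (one
test per gene, matching the single-ratio design), and any of the four
pooled 2×2 cells that is zero is set to 1 so the test is defined — the
pooled table is the only place a zero can survive pooling, which is where
the per-sample zero-substitution rule lands after summation.

The two-sided Fisher's exact test compares (parental-P1 reads,
parental-P2 reads) against (hybrid allele-1, hybrid allele-2). With the
gene's parental-DE status it yields: DE + significant → cis–trans
divergent; DE + not significant → cis-only; not DE + significant →
compensatory; not DE + not significant → non-compensatory. α = 0.05,
uncorrected, matching the single-test-per-gene design; a BH option exists.

**Limitation, by construction:** the Fisher test models sampling noise
only. Biological overdispersion between parental replicates makes the
parental ratio wobble beyond binomial error, and at high SNP coverage the
test detects that wobble — conserved genes are then systematically called
compensatory. This is the recognised tendency of ASE designs to
overestimate compensatory evolution. The recovery suites therefore run the
generator at dispersion 0 (pure sampling noise), the regime in which the
classifier's guarantees — null trans-driven calls ≤ α, accuracy
non-decreasing in depth — actually hold; on overdispersed data the
compensatory count should be read as an upper bound. At the recovery
conditions (400 genes, four balanced classes, |c| = |t| = 1.5, ≥500
informative reads/gene) ~93% of informative genes recover their true
category; residual errors are Fisher false positives (conserved →
compensatory, cis-only → cis–trans) at ≈ α each.

## Sequence divergence

Validated codon alignments (equal length, multiple of three, gaps only in
whole codons, no internal stops; gap/ambiguity codons masked) are scored
with Nei–Gojobori (1986) pathway counting. Site counts per position are
the fraction of non-stop single-base changes that are synonymous; observed
differences in multi-hit codons average over stop-free minimal pathways
(codon masked if none exists); `pS = Sd/S`, `pN = Nd/N` receive the
Jukes–Cantor correction `d = −¾ ln(1 − 4p/3)`, undefined at `p ≥ ¾`.
dN/dS is undefined when dS = 0; undefined values are explicit `None`s and
are excluded pairwise from correlations (with n reported), never silently
zeroed. NG86 was chosen over LWL-family estimators because every quantity
is hand-verifiable by enumeration; the estimator sits behind a single
function so an LWL variant can be added.

Spearman correlations use average ranks, the exact permutation null for
n ≤ 9 and the t approximation above; rate comparisons between gene groups
use two-sided Mann–Whitney U with BH correction across the whole family,
reported with per-group mean ± sample SD (ddof = 1; undefined for n < 2).

## Co-option screen

Extended gene regions (gene body ± 2 kb, minus-strand genes
reverse-complemented) of trans-driven transgressive genes (cis–trans
divergent or compensatory) are compared against all transgressive regions
with a seed-and-extend local aligner: shared 11-mers, diagonal clustering,
an ungapped X-drop gate, then affine-gap Smith–Waterman on a window around
each cluster (match +2, mismatch −3, gap open −5, extend −2; scores agree
with Biopython's `PairwiseAligner` in the test suite). Both orientations
are searched; plus/plus hits are read as upstream–upstream similarity,
plus/minus as upstream–downstream. E-values use the ungapped
Karlin–Altschul form `E = K·m·n·e^(−λS)` with K = 0.41, λ = 0.625; since
the thresholds of interest sit at extreme significance, the length
(≥173 bp) and identity (>64%) filters are the operative gates, with
E < 10⁻¹⁴ as the ceiling. A hit is discarded when its matched query
segment also aligns, at the same thresholds, to any non-transgressive
genome region (uniqueness), or when query and subject are the same gene.
One caveat: a local aligner may extend a shared segment a few bases past
its true end through chance flank matches, so segments within ~5 bp of the
length threshold can fall on either side of it; the planted-length tests
use fixtures whose flanks cannot align (homopolymers of different bases)
to pin the boundary exactly.

## Pipeline, reporting, reproducibility

The orchestrated run simulates the experiment, fits both engines on the
five pairwise contrasts, calls transgressive genes at thresholds 0.5 and
1.0, classifies them, estimates divergence on generator codon pairs
(200 codons; planted substitutions ~ Poisson(3) synonymous, Poisson(1)
non-synonymous), runs the correlation and rate-comparison statistics, and
screens upstream regions (planted shared motifs among trans-driven genes
emulate co-option). Summary percentages always store numerator and
denominator beside the rounded value; whole percents round, one-decimal
values round, and the two-decimal style truncates (matching the reporting
convention of the small-denominator table it reproduces). Every RNG
derives from the single config seed via `SeedSequence` spawning, so a
rerun with the same config is bit-identical; the manifest records the
config and the SHA-256 of every output. Problem sizes in the test and
acceptance runs (≤2000 genes, 4 replicates, 2×10⁶-read libraries, ≤12
background regions) were chosen as the smallest at which the statistical
checks are stable.

## Known limitations

* No dominance or epistasis in the hybrid model; transgressive recovery
  statements concern compensatory-type architectures only.
* The Fisher classifier ignores biological overdispersion (see above) and
  mapping bias; no beta-binomial alternative is provided.
* The DE engines are intentionally minimal; exact numerical agreement with
  DESeq2/edgeR is not a goal (the consensus-and-threshold logic is).
* Karlin–Altschul parameters are fixed ungapped defaults, so E-values are
  indicative rather than BLAST-identical.
* Reciprocal hybrids are simulated identically; sterile-specific
  misexpression is not modelled.
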