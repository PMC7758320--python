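"""Co-option ("transcriptional drive") similarity screen.

Looks for shared putative cis-regulatory sequence between extended gene
regions (gene body plus 2-kb flanks) of transgressive genes whose
misexpression implicates a diverged trans factor (cis-trans divergent or
compensatory genes). The aligner is a seed-and-extend local aligner:
shared 11-mers are clustered by diagonal and each cluster is refined with
an affine-gap Smith-Waterman over a window around it, using BLASTn-like
scores (match +2, mismatch -3, gap open -5, gap extend -2). Both
orientations are searched; plus/plus matches are read as upstream-upstream
similarity, plus/minus as upstream-downstream. Expectation values use the
Karlin-Altschul form E = K*m*n*exp(-lambda*score).

Retained hits must clear an E-value ceiling, a minimum alignment length
and a minimum identity, and must be unique: a hit whose matched segment
also aligns to a non-transgressive region of the genome at the same
thresholds is discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ExtendedRegion",
    "SimilarityHit",
    "ScreenThresholds",
    "extract_extended_region",
    "local_align",
    "evalue",
    "screen_cooption",
]

MATCH, MISMATCH = 2, -3
GAP_OPEN, GAP_EXTEND = -5, -2
KA_K, KA_LAMBDA = 0.41, 0.625

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ExtendedRegion:
    """Gene body plus flanking sequence, oriented 5'->3' on the gene."""

    gene_id: str
    sequence: str
    flank_len: int = 2000
    truncated_left: int = 0
    truncated_right: int = 0


@dataclass
class SimilarityHit:
    query_gene: str
    subject_gene: str
    alignment_length: int
    identity: float  # percent
    score: int
    evalue: float
    strand: str  # "plus/plus" | "plus/minus"
    orientation_interpretation: str = ""
    query_start: int = 0
    query_end: int = 0
    query_segment: str = field(default="", repr=False)


@dataclass
class ScreenThresholds:
    max_evalue: float = 1e-14
    min_length: int = 173
    min_identity: float = 64.0  # percent, exclusive bound


def extract_extended_region(gene_id: str, contig: str, start: int, end: int,
                            genome: dict[str, str], strand: str = "+",
                            flank: int = 2000) -> ExtendedRegion:
    """Extract [start-flank, end+flank) around a gene, truncated at contig ends.

    Coordinates are 0-based half-open. Minus-strand genes are
    reverse-complemented so the 5' flank is upstream of the gene.
    """
    if contig not in genome:
        raise KeyError(f"unknown contig {contig!r}")
    seq = genome[contig]
    if not (0 <= start < end <= len(seq)):
        raise ValueError(f"gene interval [{start},{end}) outside contig bounds")
    left = max(0, start - flank)
    right = min(len(seq), end + flank)
    region = seq[left:right]
    trunc_left = flank - (start - left)
    trunc_right = flank - (right - end)
    if strand == "-":
        region = reverse_complement(region)
        trunc_left, trunc_right = trunc_right, trunc_left
    return ExtendedRegion(gene_id=gene_id, sequence=region.upper(), flank_len=flank,
                          truncated_left=trunc_left, truncated_right=trunc_right)


def evalue(score: float, query_len: int, db_len: int,
           K: float = KA_K, lam: float = KA_LAMBDA) -> float:
    """Karlin-Altschul expectation value E = K*m*n*exp(-lambda*score)."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return K * query_len * db_len * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# seed-and-extend alignment

_SEED_K = 11


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        out.setdefault(kmer, []).append(i)
    return out


def _seed_diagonals(a: str, b: str, k: int = _SEED_K) -> dict[int, list[tuple[int, int]]]:
    """Shared k-mer positions grouped by diagonal (i - j)."""
    index = _kmer_positions(a, k)
    diags: dict[int, list[tuple[int, int]]] = {}
    for j in range(len(b) - k + 1):
        kmer = b[j:j + k]
        for i in index.get(kmer, ()):
            diags.setdefault(i - j, []).append((i, j))
    return diags


def _smith_waterman(a: str, b: str) -> tuple[int, int, int, int, int] | None:
    """Affine-gap (Gotoh) local alignment of two short windows.

    Returns ``(score, a_start, a_end, matches, length)`` for the best local
    alignment, with ``a_start:a_end`` the half-open aligned query span, or
    None when no positive-scoring alignment exists. Plain dynamic
    programming; callers keep the windows small.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("empty sequence")
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends with gap in a
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends with gap in b
    # pointers: PH 0=stop, 1=diag, 2=from E, 3=from F; PE/PF True=opened here
    PH = [[0] * (m + 1) for _ in range(n + 1)]
    PE = [[True] * (m + 1) for _ in range(n + 1)]
    PF = [[True] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        PHi, PEi, PFi = PH[i], PE[i], PF[i]
        for j in range(1, m + 1):
            e_open = Hi[j - 1] + GAP_OPEN
            e_ext = Ei[j - 1] + GAP_EXTEND
            e = e_open if e_open >= e_ext else e_ext
            PEi[j] = e_open >= e_ext
            f_open = Hi1[j] + GAP_OPEN
            f_ext = Fi1[j] + GAP_EXTEND
            f = f_open if f_open >= f_ext else f_ext
            PFi[j] = f_open >= f_ext
            d = Hi1[j - 1] + (MATCH if ai == b[j - 1] else MISMATCH)
            h, ptr = d, 1
            if e > h:
                h, ptr = e, 2
            if f > h:
                h, ptr = f, 3
            if h <= 0:
                h, ptr = 0, 0
            Ei[j], Fi[j], Hi[j], PHi[j] = e, f, h, ptr
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return None
    # traceback from the optimum along the recorded pointers
    i, j, state = bi, bj, "H"
    matches = length = 0
    a_end = bi
    while i > 0 and j > 0:
        if state == "H":
            ptr = PH[i][j]
            if ptr == 0:
                break
            if ptr == 1:
                length += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif ptr == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            length += 1
            opened = PE[i][j]
            j -= 1
            if opened:
                state = "H"
        else:
            length += 1
            opened = PF[i][j]
            i -= 1
            if opened:
                state = "H"
    a_start = i
    return best, a_start, a_end, matches, length


def _ungapped_seed_score(a: str, b: str, i: int, j: int, k: int = _SEED_K,
                         xdrop: int = 30) -> int:
    """X-drop ungapped extension score around one exact k-mer seed.

    Cheap gate: clusters whose best ungapped extension cannot reach the
    score floor are skipped before the windowed Smith-Waterman runs.
    """
    score = best = MATCH * k
    ii, jj = i + k, j + k
    while ii < len(a) and jj < len(b):
        score += MATCH if a[ii] == b[jj] else MISMATCH
        if score > best:
            best = score
        if best - score > xdrop:
            break
        ii += 1
        jj += 1
    score = best
    ii, jj = i - 1, j - 1
    cur = score
    while ii >= 0 and jj >= 0:
        cur += MATCH if a[ii] == b[jj] else MISMATCH
        if cur > score:
            score = cur
        if score - cur > xdrop:
            break
        ii -= 1
        jj -= 1
    return score


def _align_one_strand(a: str, b: str, min_score: int) -> list[dict]:
    """Seeded local alignments of a vs b on the given strands."""
    hits: list[dict] = []
    diags = _seed_diagonals(a, b)
    # merge nearby diagonals into clusters
    used: set[int] = set()
    diag_keys = sorted(diags)
    clusters: list[list[int]] = []
    for d in diag_keys:
        if clusters and d - clusters[-1][-1] <= 32:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    for cluster in clusters:
        seeds = [pos for d in cluster for pos in diags[d]]
        gate = max(_ungapped_seed_score(a, b, i, j) for i, j in seeds)
        if gate < min_score:
            continue
        i_lo = min(p[0] for p in seeds)
        i_hi = max(p[0] for p in seeds) + _SEED_K
        j_lo = min(p[1] for p in seeds)
        j_hi = max(p[1] for p in seeds) + _SEED_K
        pad = 100
        ai, aj = max(0, i_lo - pad), min(len(a), i_hi + pad)
        bi, bj = max(0, j_lo - pad), min(len(b), j_hi + pad)
        res = _smith_waterman(a[ai:aj], b[bi:bj])
        if res is None:
            continue
        score, qa, qb, matches, length = res
        if score < min_score or length == 0:
            continue
        hits.append({
            "score": score,
            "length": length,
            "identity": 100.0 * matches / length,
            "query_start": ai + qa,
            "query_end": ai + qb,
        })
    # deduplicate overlapping window hits, keep best score per query span
    hits.sort(key=lambda h: -h["score"])
    kept: list[dict] = []
    for h in hits:
        if any(not (h["query_end"] <= k["query_start"]
                    or h["query_start"] >= k["query_end"]) for k in kept):
            continue
        kept.append(h)
    return kept


def local_align(a: str, b: str, min_score: int = 40) -> list[SimilarityHit]:
    """Best non-overlapping local alignments of two nucleotide sequences.

    Searches plus/plus and plus/minus (reverse complement of ``b``)
    orientations. ``min_score`` is the raw-score floor below which
    candidate extensions are dropped.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    out: list[SimilarityHit] = []
    for strand, bb in (("plus/plus", b), ("plus/minus", reverse_complement(b))):
        for h in _align_one_strand(a, bb, min_score):
            out.append(SimilarityHit(
                query_gene="", subject_gene="",
                alignment_length=h["length"], identity=h["identity"],
                score=h["score"],
                evalue=evalue(h["score"], len(a), len(b)),
                strand=strand,
                query_start=h["query_start"], query_end=h["query_end"],
                query_segment=a[h["query_start"]:h["query_end"]]))
    out.sort(key=lambda h: -h.score)
    return out


def _passes(hit: SimilarityHit, thr: ScreenThresholds) -> bool:
    return (hit.evalue < thr.max_evalue
            and hit.alignment_length >= thr.min_length
            and hit.identity > thr.min_identity)


def screen_cooption(trans_driven_genes, transgressive_regions: dict[str, str],
                    genome_regions: dict[str, str] | None = None,
                    thresholds: ScreenThresholds | None = None
                    ) -> list[SimilarityHit]:
    """Screen trans-driven transgressive genes for shared cis-regions.

    ``trans_driven_genes`` (cis-trans divergent or compensatory genes) are
    queried against every other transgressive region. Hits must pass the
    E-value/length/identity thresholds; a hit whose matched query segment
    also aligns to any ``genome_regions`` entry (non-transgressive genes)
    at the same thresholds is discarded as non-unique. Self-hits are
    excluded. Returns one record per unordered gene pair (best hit).
    """
    thr = thresholds or ScreenThresholds()
    queries = [g for g in trans_driven_genes if g in transgressive_regions]
    genome_regions = genome_regions or {}
    results: dict[tuple[str, str], SimilarityHit] = {}
    for q in queries:
        for s, subject_seq in transgressive_regions.items():
            if s == q:
                continue
            pair = tuple(sorted((q, s)))
            if pair in results:
                continue
            for hit in local_align(transgressive_regions[q], subject_seq):
                if not _passes(hit, thr):
                    continue
                # uniqueness: matched segment must not occur elsewhere
                segment = hit.query_segment
                shared = False
                for other_id, other_seq in genome_regions.items():
                    if other_id in (q, s):
                        continue
                    for g_hit in local_align(segment, other_seq):
                        if _passes(g_hit, thr):
                            shared = True
                            break
                    if shared:
                        break
                if shared:
                    continue
                hit.query_gene = q
                hit.subject_gene = s
                hit.orientation_interpretation = (
                    "upstream-upstream" if hit.strand == "plus/plus"
                    else "upstream-downstream")
                prev = results.get(pair)
                if prev is None or hit.score > prev.score:
                    results[pair] = hit
    return sorted(results.values(), key=lambda h: (h.query_gene, h.subject_gene))
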