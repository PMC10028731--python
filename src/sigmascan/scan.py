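"""Motif occurrence scanning with exact p-values and FDR q-values.

The scanner scores every window of a query sequence with a log-odds matrix
(bits, query-composition background by default), converts scores to p-values
with an exact dynamic-programming null distribution over a discretized score
axis, and attaches Benjamini-Hochberg q-values computed over *all* scored
windows of a run. Promoters are the 100 bp immediately upstream of each
annotated CDS, strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io import encode_sequence, reverse_complement
from .motif import MotifModel, background_composition, mask_motif

DEFAULT_STEP = 1e-3  # bits; p-value score error is bounded by width * step


@dataclass
class ScoringMatrix:
    """Per-position log2-odds scores in bits:
    score[i,s] = log2((p[i,s] + smoothing) / (b[s] + smoothing))."""

    scores: np.ndarray  # (width, 4) float bits
    background: np.ndarray
    smoothing: float

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    def reverse_complement(self) -> "ScoringMatrix":
        return ScoringMatrix(self.scores[::-1, ::-1].copy(), self.background, self.smoothing)


@dataclass
class ScoreDistribution:
    """Exact null distribution of the discretized total score under the
    0-order background model. ``pmf[k]`` is P(int score == min_score + k);
    ``tail[k]`` is P(int score >= min_score + k)."""

    step: float
    min_score: int  # in step units
    pmf: np.ndarray
    tail: np.ndarray = field(init=False)

    def __post_init__(self):
        t = np.cumsum(self.pmf[::-1])[::-1]
        self.tail = np.minimum(t, 1.0)

    def pvalue_of_int(self, int_score: int) -> float:
        k = int_score - self.min_score
        if k <= 0:
            return 1.0
        if k >= self.pmf.size:
            return float(self.tail[-1])
        return float(self.tail[k])


@dataclass
class ScanHit:
    seq_id: str
    start: int  # 0-based, forward coordinates
    end: int  # half-open
    strand: str
    score: float  # bits (discretized axis)
    p_value: float
    matched_seq: str
    q_value: float | None = None


def log_odds_matrix(
    model: MotifModel, background: np.ndarray, smoothing: float = 1e-4
) -> ScoringMatrix:
    """Build the scoring matrix; smoothing is added to both the motif
    probability and the background so a masked column (p == b) scores
    exactly 0 for every letter."""
    background = np.asarray(background, dtype=np.float64)
    if background.shape != (4,) or not np.isclose(background.sum(), 1.0, atol=1e-9):
        raise ValueError("background must be 4 frequencies summing to 1")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    p = model.probabilities + smoothing
    b = background + smoothing
    if np.any(p <= 0) or np.any(b <= 0):
        raise ValueError("zero probability with smoothing=0 gives -inf scores")
    return ScoringMatrix(np.log2(p / b[None, :]), background, smoothing)


def _int_scores(matrix: ScoringMatrix, step: float) -> np.ndarray:
    # round-half-even onto the discretized axis
    return np.rint(matrix.scores / step).astype(np.int64)


def score_distribution(
    matrix: ScoringMatrix, background: np.ndarray, step: float = DEFAULT_STEP
) -> ScoreDistribution:
    """Exact DP convolution of per-position discretized score distributions
    under the 0-order background letter model."""
    if step <= 0:
        raise ValueError("step must be positive")
    background = np.asarray(background, dtype=np.float64)
    si = _int_scores(matrix, step)
    dp = np.ones(1)
    total_min = 0
    for i in range(matrix.width):
        row = si[i]
        lo, hi = int(row.min()), int(row.max())
        new = np.zeros(dp.size + hi - lo)
        for s in range(4):
            off = int(row[s]) - lo
            new[off : off + dp.size] += dp * background[s]
        dp = new
        total_min += lo
    return ScoreDistribution(step=step, min_score=total_min, pmf=dp)


def window_int_scores(
    matrix: ScoringMatrix, sequence: str, step: float = DEFAULT_STEP
) -> tuple[np.ndarray, np.ndarray]:
    """Discretized total score of every window of the sequence, plus a
    validity mask (windows containing non-ACGT letters are invalid)."""
    w = matrix.width
    enc = encode_sequence(sequence)
    if enc.size < w:
        raise ValueError("sequence shorter than the motif")
    si = _int_scores(matrix, step)
    si5 = np.column_stack([si, np.zeros(w, dtype=np.int64)])  # letter 4 = N
    wins = sliding_window_view(enc, w)
    scores = si5[np.arange(w)[None, :], wins].sum(axis=1)
    valid = ~(wins > 3).any(axis=1)
    return scores, valid


def window_pvalues(
    matrix: ScoringMatrix,
    dist: ScoreDistribution,
    sequence: str,
    both_strands: bool = True,
) -> np.ndarray:
    """p-values of all valid windows on the requested strand(s); used to
    pool the full set of tests for BH correction."""
    out = []
    mats = [matrix] + ([matrix.reverse_complement()] if both_strands else [])
    for m in mats:
        scores, valid = window_int_scores(m, sequence, dist.step)
        k = np.clip(scores[valid] - dist.min_score, 0, dist.pmf.size - 1)
        pv = np.where(scores[valid] - dist.min_score <= 0, 1.0, dist.tail[k])
        out.append(pv)
    return np.concatenate(out) if out else np.zeros(0)


def scan_sequence(
    matrix: ScoringMatrix,
    dist: ScoreDistribution,
    sequence: str,
    p_threshold: float = 1e-4,
    both_strands: bool = True,
    seq_id: str = "seq",
) -> list[ScanHit]:
    """Score every window; report those with p <= p_threshold. Minus-strand
    windows are scored against the reverse-complement matrix and reported in
    forward coordinates. Case-insensitive; windows with non-ACGT letters are
    skipped."""
    w = matrix.width
    hits: list[ScanHit] = []
    strands = [("+", matrix)] + ([("-", matrix.reverse_complement())] if both_strands else [])
    useq = sequence.upper()
    for strand, m in strands:
        scores, valid = window_int_scores(m, useq, dist.step)
        for j in np.flatnonzero(valid):
            p = dist.pvalue_of_int(int(scores[j]))
            if p <= p_threshold:
                window = useq[j : j + w]
                hits.append(
                    ScanHit(
                        seq_id=seq_id,
                        start=int(j),
                        end=int(j) + w,
                        strand=strand,
                        score=float(scores[j]) * dist.step,
                        p_value=p,
                        matched_seq=window if strand == "+" else reverse_complement(window),
                    )
                )
    hits.sort(key=lambda h: (h.p_value, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# FDR

def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input:
    q_i = min_{rank j >= rank(i)} p_(j) * n / j, capped at 1."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def qvalues_against_pool(hit_pvalues: np.ndarray, pool: np.ndarray) -> np.ndarray:
    """q-values for selected tests, with BH computed over the full pool of
    scored windows (the selected p-values must be elements of the pool)."""
    pool_sorted = np.sort(pool)
    n = pool_sorted.size
    ranked = pool_sorted * n / np.arange(1, n + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    idx = np.searchsorted(pool_sorted, hit_pvalues, side="left")
    idx = np.clip(idx, 0, n - 1)
    return q_sorted[idx]


# ---------------------------------------------------------------------------
# promoters

@dataclass
class PromoterRecord:
    gene_id: str
    chrom: str
    start: int  # genomic interval, 0-based half-open
    end: int
    strand: str
    sequence: str  # promoter-oriented (reverse-complemented for minus genes)
    truncated: bool = False

    @property
    def fasta_id(self) -> str:
        return f"{self.gene_id}|{self.chrom}:{self.start}-{self.end}({self.strand})"


def extract_promoters(
    annotations: pd.DataFrame, genome: dict[str, str], length: int = 100
) -> list[PromoterRecord]:
    """The ``length`` bp immediately upstream of each CDS: for plus-strand
    genes the interval [start-length, start); for minus-strand genes the
    interval [end, end+length) reverse-complemented. Records truncated at a
    contig edge keep a flag."""
    out = []
    for row in annotations.itertuples(index=False):
        if row.chrom not in genome:
            raise ValueError(f"chromosome {row.chrom!r} not in genome")
        seq = genome[row.chrom]
        L = len(seq)
        if not 0 <= row.start < row.end <= L:
            raise ValueError(f"CDS {row.gene_id} outside genome")
        if row.strand == "+":
            lo, hi = max(0, row.start - length), row.start
            prom = seq[lo:hi]
        else:
            lo, hi = row.end, min(L, row.end + length)
            prom = reverse_complement(seq[lo:hi])
        out.append(
            PromoterRecord(
                gene_id=row.gene_id,
                chrom=row.chrom,
                start=lo,
                end=hi,
                strand=row.strand,
                sequence=prom,
                truncated=(hi - lo) < length,
            )
        )
    return out


# ---------------------------------------------------------------------------
# query scanning with per-query background + report

def scan_queries(
    model: MotifModel,
    queries: dict[str, str],
    p_threshold: float = 1e-4,
    both_strands: bool = True,
    background: str = "query",
    mask_r_threshold: float | None = 1.0,
    smoothing: float = 1e-4,
    step: float = DEFAULT_STEP,
) -> tuple[list[ScanHit], np.ndarray]:
    """Scan a set of query sequences. With background='query' (default) the
    motif is re-masked and re-scored against each query's own composition,
    mirroring the masking rule; 'uniform' uses a flat background. Returns
    (hits with q-values, pooled window p-values)."""
    all_hits: list[ScanHit] = []
    pools = []
    uniform = np.full(4, 0.25)
    for qid, seq in queries.items():
        bg = background_composition(seq) if background == "query" else uniform
        m = mask_motif(model, bg, mask_r_threshold) if mask_r_threshold is not None else model
        matrix = log_odds_matrix(m, bg, smoothing)
        dist = score_distribution(matrix, bg, step)
        all_hits.extend(
            scan_sequence(matrix, dist, seq, p_threshold, both_strands, seq_id=qid)
        )
        pools.append(window_pvalues(matrix, dist, seq, both_strands))
    pool = np.concatenate(pools) if pools else np.zeros(0)
    if all_hits:
        qv = qvalues_against_pool(np.array([h.p_value for h in all_hits]), pool)
        for h, q in zip(all_hits, qv):
            h.q_value = float(q)
    all_hits.sort(key=lambda h: (h.p_value, h.seq_id, h.start))
    return all_hits, pool


def scan_report(
    hits: list[ScanHit], q_threshold: float = 0.6
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(filtered, full) hit tables, sorted by p ascending. The full table is
    always complete; the filtered one keeps q <= q_threshold."""
    cols = ["seq_id", "start", "end", "strand", "score", "p_value", "q_value", "matched_seq"]
    rows = [
        dict(
            seq_id=h.seq_id, start=h.start, end=h.end, strand=h.strand,
            score=h.score, p_value=h.p_value, q_value=h.q_value,
            matched_seq=h.matched_seq,
        )
        for h in hits
    ]
    full = pd.DataFrame(rows, columns=cols)
    if full.empty:
        return full.copy(), full
    filtered = full[full["q_value"] <= q_threshold].reset_index(drop=True)
    return filtered, full


def hits_to_tsv(df: pd.DataFrame) -> str:
    """GFF3-style TSV with 1-based start, as FIMO prints it."""
    out = df.copy()
    if not out.empty:
        out["start"] = out["start"] + 1
    return out.to_csv(sep="\t", index=False)
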