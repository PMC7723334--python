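"""Cis/trans lncRNA target prediction and promoter TF scanning.

Cis targets are protein-coding genes within a genomic window (default
10 kb) of a lncRNA, classified by relative position/strand and filtered
by co-expression (r >= 0.99, Holm-adjusted p < 0.5).  Trans targets are
co-expressed mRNAs whose 3'UTR shares a high-identity local alignment
with the lncRNA (Smith-Waterman, match +1 / mismatch -1 / gap -2).
Transcription-factor candidates are PWM log-odds hits in the promoter
window spanning 2000 bp upstream to 500 bp downstream of the lncRNA TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .coexpression import pearson_with_p
from .de import adjust_holm
from .io import PWM, BASES, ExpressionMatrix, GenomicFeature, revcomp

CIS_CATEGORIES = ("sense", "antisense", "intronic", "divergent", "neighbor")


# ---------------------------------------------------------------------------
# Cis relations
# ---------------------------------------------------------------------------

def _interval_gap(a: GenomicFeature, b: GenomicFeature) -> int:
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if a.end <= b.start else a.start - b.end


def classify_cis_relation(
    lnc: GenomicFeature,
    gene: GenomicFeature,
    window: int = 10_000,
    divergent_gap: int = 1_000,
) -> str | None:
    """Positional class of a lncRNA relative to a protein-coding gene.

    Precedence: intronic (lncRNA wholly inside a gene intron, either
    strand) > sense (overlap, same strand) > antisense (overlap, opposite
    strand) > divergent (no overlap, opposite strands, head-to-head, TSS
    gap <= divergent_gap) > neighbor (no overlap, gap <= window); None
    otherwise or on different chromosomes.
    """
    if lnc.chrom != gene.chrom:
        return None
    for istart, iend in gene.introns:
        if istart <= lnc.start and lnc.end <= iend:
            return "intronic"
    overlap = lnc.start < gene.end and gene.start < lnc.end
    if overlap:
        return "sense" if lnc.strand == gene.strand else "antisense"
    gap = _interval_gap(lnc, gene)
    if lnc.strand != gene.strand:
        upstream, downstream = (lnc, gene) if lnc.start < gene.start else (gene, lnc)
        head_to_head = upstream.strand == "-" and downstream.strand == "+"
        if head_to_head and abs(lnc.tss - gene.tss) <= divergent_gap and gap <= window:
            return "divergent"
    if gap <= window:
        return "neighbor"
    return None


def find_cis_pairs(
    lncs: list[GenomicFeature],
    genes: list[GenomicFeature],
    lnc_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    window: int = 10_000,
    min_r: float = 0.99,
    holm_alpha: float = 0.5,
    samples=None,
) -> pd.DataFrame:
    """Proximity candidates filtered by positive correlation.

    Candidates are classified same-chromosome pairs within ``window``;
    the Holm adjustment runs across the whole candidate family and pairs
    are kept when r >= min_r and adjusted p < holm_alpha.
    """
    if samples is None:
        samples = lnc_expr.sample_ids
    candidates = []
    for lnc in lncs:
        if lnc.id not in lnc_expr.values.index:
            continue
        x = lnc_expr.values.loc[lnc.id, list(samples)].to_numpy(dtype=float)
        for gene in genes:
            if gene.id not in gene_expr.values.index:
                continue
            category = classify_cis_relation(lnc, gene, window=window)
            if category is None:
                continue
            y = gene_expr.values.loc[gene.id, list(samples)].to_numpy(dtype=float)
            r, p = pearson_with_p(x, y)
            candidates.append(
                (lnc.id, gene.id, category, _interval_gap(lnc, gene), r, p)
            )
    if not candidates:
        return pd.DataFrame(
            columns=["lncrna_id", "gene_id", "category", "distance", "r", "p_holm"]
        )
    df = pd.DataFrame(
        candidates, columns=["lncrna_id", "gene_id", "category", "distance", "r", "p"]
    )
    df["p_holm"] = adjust_holm(df["p"].to_numpy())
    df = df[(df["r"] >= min_r) & (df["p_holm"] < holm_alpha)]
    return df.drop(columns="p").sort_values(
        ["lncrna_id", "gene_id"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# Local alignment (Smith-Waterman, linear gap)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_fill(a, b, match, mismatch, gap):  # pragma: no cover - numba kernel
    n, m = a.size, b.size
    h = np.zeros((n + 1, m + 1), dtype=np.int32)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            v = h[i - 1, j - 1] + s
            if h[i - 1, j] + gap > v:
                v = h[i - 1, j] + gap
            if h[i, j - 1] + gap > v:
                v = h[i, j - 1] + gap
            if v < 0:
                v = 0
            h[i, j] = v
            if v > best:
                best, bi, bj = v, i, j
    return h, best, bi, bj


_ENCODE = {c: i for i, c in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid alphabet character {exc.args[0]!r}") from exc


@dataclass
class LocalAlignment:
    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int
    identity: float


def local_align(
    seq_a: str, seq_b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment with linear gap penalty.

    Ties on the optimum are broken toward the smallest end cell (a, then
    b) with a diagonal-preferring traceback.  A zero score returns an
    empty alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a, b = _encode(seq_a), _encode(seq_b)
    h, best, bi, bj = _sw_fill(a, b, match, mismatch, gap)
    if best == 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0.0)
    i, j = bi, bj
    matches = 0
    length = 0
    while i > 0 and j > 0 and h[i, j] > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if h[i, j] == h[i - 1, j - 1] + s:
            matches += a[i - 1] == b[j - 1]
            length += 1
            i, j = i - 1, j - 1
        elif h[i, j] == h[i - 1, j] + gap:
            length += 1
            i -= 1
        else:
            length += 1
            j -= 1
    return LocalAlignment(
        score=int(best), a_start=i, a_end=bi, b_start=j, b_end=bj,
        length=length, identity=matches / length,
    )


def predict_trans_targets(
    lnc_seqs: dict[str, str],
    utr_seqs: dict[str, str],
    edges: pd.DataFrame,
    min_len: int = 20,
    min_identity: float = 0.9,
) -> pd.DataFrame:
    """Trans hits: co-expressed lncRNA/mRNA pairs with a long, near-exact
    shared subsequence between the lncRNA and the mRNA 3'UTR.

    Only pairs present in ``edges`` (columns node_a = lncRNA, node_b =
    mRNA) are evaluated, mirroring the restriction to co-expressed mRNAs.
    """
    rows = []
    for _, edge in edges.iterrows():
        lnc_id, mrna_id = edge["node_a"], edge["node_b"]
        if lnc_id not in lnc_seqs:
            raise KeyError(f"missing lncRNA sequence {lnc_id!r}")
        if mrna_id not in utr_seqs:
            raise KeyError(f"missing 3'UTR sequence {mrna_id!r}")
        aln = local_align(lnc_seqs[lnc_id], utr_seqs[mrna_id])
        if aln.length >= min_len and aln.identity >= min_identity:
            rows.append(
                (lnc_id, mrna_id, aln.a_start, aln.b_start, aln.length,
                 aln.identity, aln.score)
            )
    return pd.DataFrame(
        rows,
        columns=["lncrna_id", "mrna_id", "lnc_start", "utr_start", "length",
                 "identity", "score"],
    ).sort_values(["lncrna_id", "mrna_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# Promoter windows and PWM scanning
# ---------------------------------------------------------------------------

@dataclass
class PromoterWindow:
    sequence: str        # 5'->3' on the feature's strand
    genomic_start: int   # 0-based half-open genomic span
    genomic_end: int
    clipped: bool


def promoter_interval(
    feature: GenomicFeature, upstream: int = 2000, downstream: int = 500
) -> tuple[int, int]:
    """Genomic [start, end) of the promoter window around the TSS."""
    t = feature.tss
    if feature.strand == "+":
        return t - upstream, t + downstream
    return t - downstream, t + upstream


def extract_promoter_window(
    feature: GenomicFeature,
    chrom_seqs: dict[str, str],
    upstream: int = 2000,
    downstream: int = 500,
) -> PromoterWindow:
    """Strand-aware promoter sequence, clipped at chromosome ends."""
    if feature.chrom not in chrom_seqs:
        raise KeyError(f"chromosome {feature.chrom!r} absent from sequence store")
    chrom = chrom_seqs[feature.chrom]
    raw_start, raw_end = promoter_interval(feature, upstream, downstream)
    start, end = max(0, raw_start), min(len(chrom), raw_end)
    seq = chrom[start:end]
    if feature.strand == "-":
        seq = revcomp(seq)
    return PromoterWindow(seq, start, end, clipped=(start != raw_start or end != raw_end))


def scan_pwm(window_sequence: str, pwm: PWM, threshold: float = 0.8) -> pd.DataFrame:
    """Log-odds PWM hits on both strands of a window.

    Score at an offset is sum_i log2(p[base_i, i] / bg[base_i]); hits are
    offsets scoring >= threshold * max attainable score.
    """
    seq = window_sequence.upper()
    L = pwm.length
    if len(seq) < L:
        raise ValueError("window shorter than motif")
    lo = pwm.log_odds
    # N (or any non-ACGT) contributes the background-neutral score 0
    code = np.array([_ENCODE.get(c, 4) for c in seq])
    padded = np.vstack([lo, np.zeros(L)])
    windows = np.lib.stride_tricks.sliding_window_view(code, L)
    fwd = padded[windows, np.arange(L)].sum(axis=1)
    rc = np.array([_ENCODE.get(c, 4) for c in revcomp(seq)])
    rev = padded[np.lib.stride_tricks.sliding_window_view(rc, L), np.arange(L)].sum(axis=1)
    cutoff = threshold * pwm.max_score
    rows = []
    for offset in np.nonzero(fwd >= cutoff)[0]:
        rows.append((int(offset), "+", float(fwd[offset])))
    for k in np.nonzero(rev >= cutoff)[0]:
        # map back to forward-strand offset of the motif's left edge
        rows.append((len(seq) - L - int(k), "-", float(rev[k])))
    return pd.DataFrame(rows, columns=["offset", "strand", "score"]).sort_values(
        ["offset", "strand"], ignore_index=True
    )


def build_tf_network(
    lncs: list[GenomicFeature],
    pwms: list[PWM],
    chrom_seqs: dict[str, str],
    threshold: float = 0.8,
    upstream: int = 2000,
    downstream: int = 500,
) -> pd.DataFrame:
    """Bipartite lncRNA-TF edges: one edge per (lncRNA, motif) with >= 1
    promoter-window hit; returns columns lncrna_id, motif_id, n_hits,
    best_score."""
    rows = []
    for lnc in lncs:
        window = extract_promoter_window(lnc, chrom_seqs, upstream, downstream)
        for pwm in pwms:
            if len(window.sequence) < pwm.length:
                continue
            hits = scan_pwm(window.sequence, pwm, threshold)
            if len(hits):
                rows.append((lnc.id, pwm.motif_id, len(hits), float(hits["score"].max())))
    return pd.DataFrame(
        rows, columns=["lncrna_id", "motif_id", "n_hits", "best_score"]
    ).sort_values(["lncrna_id", "motif_id"], ignore_index=True)


def tf_degrees(tf_edges: pd.DataFrame) -> pd.Series:
    """Per-TF degree (number of connected lncRNAs), ties broken lexically."""
    if tf_edges.empty:
        return pd.Series(dtype=int)
    deg = tf_edges.groupby("motif_id")["lncrna_id"].nunique()
    return deg.sort_index().sort_values(ascending=False, kind="stable")
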