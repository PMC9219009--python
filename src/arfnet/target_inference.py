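"""Putative downstream-target inference for query transcription factors.

A gene is called a putative target of a query TF when it satisfies both of:

1. co-expression with the query (Pearson r above a signed threshold with a
   significant two-sided t-test p-value), and
2. at least one auxin-response-element (AuxRE) motif hit in its upstream
   promoter sequence, where hit significance is an exact log-odds score
   p-value under a 0-order background model.

The exact motif p-value is obtained from the full score distribution of the
PWM under the background, computed by dynamic programming over per-position
score contributions: identical partial sums merge, so the resulting tail
probabilities equal brute-force enumeration over all 4^w words exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .go_mining import GeneSet
from .io_formats import PWMDefinition, SequenceRecord, log, reverse_complement

__all__ = [
    "CoexpressionEntry",
    "ScoredMotifHit",
    "TargetGeneSet",
    "coexpression_filter",
    "scan_promoters",
    "filter_by_motif",
    "score_distribution",
    "log_odds_matrix",
    "correlation_pvalue",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class CoexpressionEntry:
    query_gene: str
    partner_gene: str
    r: float
    p: float

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if not (0 < self.p <= 1):
            raise ValueError(f"p must lie in (0, 1], got {self.p}")


@dataclass(frozen=True)
class ScoredMotifHit:
    sequence_id: str
    start: int  # 0-based forward-strand offset of the leftmost base
    strand: str  # '+' or '-'
    score: float  # log2 odds
    p: float  # exact tail probability of the score under the background
    motif_id: str = ""
    width: int = 0

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass
class CoexpressedGeneSet(GeneSet):
    """GeneSet annotated with the best (r, p) per member across queries."""

    stats: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class TargetGeneSet:
    """Genes passing both the co-expression and the motif criterion."""

    query_label: str
    genes: set[str] = field(default_factory=set)
    provenance: dict[str, dict] = field(default_factory=dict)
    n_no_promoter: int = 0

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


# ---------------------------------------------------------------------------
# Co-expression


def correlation_pvalue(r: float, m: int) -> float:
    """Two-sided p for Pearson r via t = r * sqrt((m-2)/(1-r^2)), df = m-2."""
    if m < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return np.finfo(float).tiny
    t = r * np.sqrt((m - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=m - 2))


def coexpression_filter(
    source: pd.DataFrame,
    query_genes: Sequence[str],
    r_min: float = 0.7,
    p_max: float = 0.05,
    top_k: int = 20000,
) -> CoexpressedGeneSet:
    """Genes co-expressed with any query above a signed r threshold.

    ``source`` is either an expression matrix (genes as index, samples as
    columns) or a precomputed table with columns (query_gene, partner_gene,
    r, p). From a matrix, Pearson r is computed per (query, candidate) pair
    with a two-sided t-test p-value; pairs with r >= r_min (signed) and
    p <= p_max are kept, capped at ``top_k`` per query by descending r, and
    unioned over queries. Self pairs and candidates whose expression vector
    is identical to the query's are excluded; constant candidates are
    skipped with a warning (r undefined).
    """
    is_table = set(source.columns) >= {"query_gene", "partner_gene", "r", "p"}
    stats_out: dict[str, tuple[float, float]] = {}
    genes: set[str] = set()

    if is_table:
        for q in query_genes:
            sub = source[source["query_gene"] == q]
            sub = sub[(sub["r"] >= r_min) & (sub["p"] <= p_max)]
            sub = sub[sub["partner_gene"] != q]
            sub = sub.sort_values("r", ascending=False).head(top_k)
            for row in sub.itertuples():
                genes.add(row.partner_gene)
                prev = stats_out.get(row.partner_gene)
                if prev is None or row.r > prev[0]:
                    stats_out[row.partner_gene] = (float(row.r), float(row.p))
    else:
        m = source.shape[1]
        if m < 3:
            raise ValueError("expression matrix needs at least 3 samples")
        X = source.to_numpy(dtype=float)
        sd = X.std(axis=1)
        centered = X - X.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        index = list(source.index)
        pos = {g: i for i, g in enumerate(index)}
        constant_logged = False
        for q in query_genes:
            if q not in pos:
                raise KeyError(f"query gene {q!r} absent from expression matrix")
            qi = pos[q]
            if sd[qi] == 0:
                log("warning", f"query {q!r} has constant expression; skipped")
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                r = centered @ centered[qi] / (norms * norms[qi])
            kept: list[tuple[float, float, str]] = []
            for gi, g in enumerate(index):
                if gi == qi or np.array_equal(X[gi], X[qi]):
                    continue
                if sd[gi] == 0:
                    if not constant_logged:
                        log("warning", f"constant expression vector for {g!r}; skipped")
                        constant_logged = True
                    continue
                ri = float(np.clip(r[gi], -1.0, 1.0))
                if ri < r_min:
                    continue
                p = correlation_pvalue(ri, m)
                if p <= p_max:
                    kept.append((ri, p, g))
            kept.sort(key=lambda t: (-t[0], t[2]))
            for ri, p, g in kept[:top_k]:
                genes.add(g)
                prev = stats_out.get(g)
                if prev is None or ri > prev[0]:
                    stats_out[g] = (ri, p)

    label = "coexpr:" + ",".join(query_genes)
    return CoexpressedGeneSet(label=label, genes=genes, stats=stats_out)


# ---------------------------------------------------------------------------
# Motif scanning


def log_odds_matrix(
    pwm: PWMDefinition, background: np.ndarray, pseudocount: float = 0.01
) -> np.ndarray:
    """Per-position log2 odds: log2((p_base + pseudocount) / background_base)."""
    return np.log2((pwm.matrix + pseudocount) / background[None, :])


def _binned_distribution(
    lom: np.ndarray, background: np.ndarray, bins_per_column: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Lattice DP fallback for wide motifs: scores rounded to a fixed grid."""
    w = lom.shape[0]
    span = float(lom.max(axis=1).sum() - lom.min(axis=1).sum())
    delta = span / (bins_per_column * w) if span > 0 else 1.0
    iscore = np.round(lom / delta).astype(np.int64)
    cur = {0: 1.0}
    for j in range(w):
        nxt: dict[int, float] = {}
        for s, p in cur.items():
            for b in range(4):
                k = s + int(iscore[j, b])
                nxt[k] = nxt.get(k, 0.0) + p * background[b]
        cur = nxt
    keys = np.array(sorted(cur), dtype=np.int64)
    probs = np.array([cur[k] for k in keys])
    scores = keys * delta
    tail = np.cumsum(probs[::-1])[::-1]
    return scores, tail


def score_distribution(
    lom: np.ndarray, background: np.ndarray, max_support: int = 200_000
) -> tuple[np.ndarray, np.ndarray]:
    """Exact score distribution of a log-odds matrix under the background.

    Returns (scores ascending, tail) with ``tail[i] = P(S >= scores[i])``
    for a random word drawn i.i.d. from ``background``. Partial sums are
    accumulated position by position exactly as window scoring does, so the
    support coincides bit-for-bit with enumeration over all 4^w words. If
    the sparse support outgrows ``max_support`` states the computation falls
    back to a 1000-bins-per-position lattice.
    """
    dist: dict[float, float] = {0.0: 1.0}
    for j, row in enumerate(lom):
        nxt: dict[float, float] = {}
        for s, p in dist.items():
            for b in range(4):
                k = s + row[b]
                nxt[k] = nxt.get(k, 0.0) + p * background[b]
        dist = nxt
        if len(dist) > max_support:
            return _binned_distribution(lom, background)
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    tail = np.minimum(np.cumsum(probs[::-1])[::-1], 1.0)
    return scores, tail


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Sequential left-to-right accumulation over positions (matches the DP)."""
    w = lom.shape[0]
    nwin = len(codes) - w + 1
    if nwin <= 0:
        return np.empty(0)
    lom_ext = np.hstack([lom, np.full((w, 1), -np.inf)])  # code 4 = N/other
    scores = np.zeros(nwin)
    for j in range(w):
        scores = scores + lom_ext[j, codes[j:j + nwin]]
    return scores


def scan_promoters(
    promoters: Iterable[SequenceRecord],
    pwm: PWMDefinition,
    background: np.ndarray | str = "from-input",
    p_max: float = 1e-4,
    strand_policy: str = "both",
    pseudocount: float = 0.01,
) -> list[ScoredMotifHit]:
    """Scan promoter sequences for PWM hits with exact score p-values.

    The background is either an explicit (A, C, G, T) probability vector or
    ``"from-input"``, the 0-order base composition of the scanned set.
    Windows containing N score minus infinity and are never reported.
    Reverse-strand hits carry the forward-strand coordinate of their
    leftmost base.
    """
    promoters = list(promoters)
    if strand_policy not in ("both", "forward"):
        raise ValueError("strand_policy must be 'both' or 'forward'")

    if isinstance(background, str):
        if background != "from-input":
            raise ValueError(f"unknown background spec {background!r}")
        counts = np.zeros(4)
        for rec in promoters:
            codes = _encode(rec.residues)
            counts += np.bincount(codes[codes < 4], minlength=4)
        if counts.sum() == 0:
            raise ValueError("cannot estimate background: no A/C/G/T bases in input")
        bg = counts / counts.sum()
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6 or (bg <= 0).any():
            raise ValueError("background must be a positive 4-vector summing to 1")

    lom = log_odds_matrix(pwm, bg, pseudocount)
    scores_tbl, tail = score_distribution(lom, bg)
    w = pwm.width

    def pvalues(scores: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(scores_tbl, scores, side="left")
        out = np.ones_like(scores)
        ok = idx < len(scores_tbl)
        out[ok] = tail[idx[ok]]
        out[~ok] = 0.0  # score above the entire support (cannot happen for real words)
        return out

    hits: list[ScoredMotifHit] = []
    strands = ("+", "-") if strand_policy == "both" else ("+",)
    for rec in promoters:
        L = len(rec.residues)
        for strand in strands:
            seq = rec.residues if strand == "+" else reverse_complement(rec.residues)
            sc = _window_scores(_encode(seq), lom)
            finite = np.isfinite(sc)
            if not finite.any():
                continue
            ps = np.ones_like(sc)
            ps[finite] = pvalues(sc[finite])
            for i in np.nonzero(finite & (ps <= p_max))[0]:
                start = int(i) if strand == "+" else L - w - int(i)
                hits.append(
                    ScoredMotifHit(
                        sequence_id=rec.id,
                        start=start,
                        strand=strand,
                        score=float(sc[i]),
                        p=float(ps[i]),
                        motif_id=pwm.motif_id,
                        width=w,
                    )
                )
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.strand))
    return hits


def filter_by_motif(
    coexpressed: GeneSet,
    hits: Iterable[ScoredMotifHit],
    min_hits: int = 1,
    promoter_ids: set[str] | None = None,
) -> TargetGeneSet:
    """Keep co-expressed genes with at least ``min_hits`` motif hits.

    ``promoter_ids``, when given, is the set of genes that had a promoter
    sequence available: co-expressed genes outside it are dropped and
    counted in a logged "no-promoter" tally. Provenance records each kept
    gene's best hit (lowest p, then highest score) and, when the input set
    carries them, its co-expression (r, p).
    """
    by_gene: dict[str, list[ScoredMotifHit]] = {}
    for h in hits:
        by_gene.setdefault(h.sequence_id, []).append(h)

    stats = getattr(coexpressed, "stats", {})
    out = TargetGeneSet(query_label=coexpressed.label)
    no_promoter = 0
    for gene in sorted(coexpressed.genes):
        if promoter_ids is not None and gene not in promoter_ids:
            no_promoter += 1
            continue
        gene_hits = by_gene.get(gene, [])
        if len(gene_hits) < min_hits:
            continue
        best = min(gene_hits, key=lambda h: (h.p, -h.score))
        prov: dict = {"best_hit": best, "n_hits": len(gene_hits)}
        if gene in stats:
            prov["r"], prov["p"] = stats[gene]
        out.genes.add(gene)
        out.provenance[gene] = prov
    out.n_no_promoter = no_promoter
    if no_promoter:
        log("warning", f"{no_promoter} co-expressed gene(s) had no promoter sequence")
    return out
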