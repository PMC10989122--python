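"""TE-SV association: overlap classes, windowed co-occurrence, context.

Overlap fractions are computed against the union of TE spans (merged, so a
fragmented annotation cannot double-count), while the intact-derived call
uses the best single intact element with reciprocal overlap > 95% by
default (both overlap/len_sv and overlap/len_te). Insertions have no
reference footprint and are excluded from overlap statistics. Windowed
co-occurrence tiles each chromosome (last partial window kept), marks a
window as occupied at >= 1 bp overlap, and tests the 2x2 occupancy matrix
with Pearson's chi-square without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .io import GeneModel, SvRecord, TeInterval
from .regions import GenomeLayout, Interval, merge_ranges, overlap_bp, \
    tile_windows

FOOTPRINT_TYPES = ("DEL", "INV", "DUP")
OVERLAP_CLASSES = ("none", "partial", "high", "intact_derived")


def sv_te_overlap(svs, tes, min_len: int = 100,
                  intact_threshold: float = 0.95,
                  reciprocal: bool = True) -> pd.DataFrame:
    """Per-SV TE-overlap statistics and class.

    Classes: partial (any overlap), high (>= 50% of the SV covered by the
    merged TE union), intact_derived (reciprocal overlap with a single
    intact element > ``intact_threshold``). Class statistics are intended
    for SVs longer than ``min_len`` (the ``eligible`` column); smaller SVs
    are still reported.
    """
    merged_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for te in tes:
        merged_by_chrom.setdefault(te.interval.chrom, []).append(
            (te.interval.start, te.interval.end))
    merged_by_chrom = {c: merge_ranges(v) for c, v in merged_by_chrom.items()}

    intact_ids = match_intact_derived(svs, tes, threshold=intact_threshold,
                                      reciprocal=reciprocal)
    rows = []
    for sv in svs:
        if sv.svtype not in FOOTPRINT_TYPES:
            continue
        iv = sv.interval
        covered = sum(overlap_bp(iv.start, iv.end, s, e)
                      for s, e in merged_by_chrom.get(iv.chrom, ()))
        frac = covered / len(iv)
        best_recip = 0.0
        for te in tes:
            o = iv.overlap_bp(te.interval)
            if o:
                best_recip = max(best_recip,
                                 o / max(len(iv), len(te.interval)))
        if sv.id in intact_ids:
            cls = "intact_derived"
        elif frac >= 0.5:
            cls = "high"
        elif covered > 0:
            cls = "partial"
        else:
            cls = "none"
        rows.append((sv.id, sv.svtype, len(iv), covered, frac, best_recip,
                     cls, len(iv) > min_len))
    return pd.DataFrame(rows, columns=["sv_id", "svtype", "length",
                                       "te_bases", "te_fraction",
                                       "best_reciprocal_overlap",
                                       "overlap_class", "eligible"])


def match_intact_derived(svs, tes, threshold: float = 0.95,
                         reciprocal: bool = True) -> set[str]:
    """SV ids matching an intact TE with overlap strictly > ``threshold``.

    Reciprocal mode (default) requires overlap/len_sv AND overlap/len_te to
    exceed the threshold; one-sided mode only overlap/len_sv.
    """
    intact = [te for te in tes if te.intact]
    out: set[str] = set()
    for sv in svs:
        if sv.svtype not in FOOTPRINT_TYPES:
            continue
        iv = sv.interval
        for te in intact:
            o = iv.overlap_bp(te.interval)
            if o == 0:
                continue
            if reciprocal:
                hit = (o / len(iv) > threshold
                       and o / len(te.interval) > threshold)
            else:
                hit = o / len(iv) > threshold
            if hit:
                out.add(sv.id)
                break
    return out


def window_occupancy(svs, tes, layout: GenomeLayout,
                     window_size: int) -> np.ndarray:
    """2x2 window occupancy counts [[TE&SV, TE only], [SV only, neither]].

    Non-overlapping tiling windows per chromosome; the last partial window
    is kept; a window holds a feature at >= 1 bp overlap (an insertion
    anchor counts as 1 bp).
    """
    counts = np.zeros((2, 2), dtype=int)
    for chrom, clen in zip(layout.names, layout.lengths):
        windows = tile_windows(clen, window_size)
        n_win = len(windows)
        has_te = np.zeros(n_win, dtype=bool)
        has_sv = np.zeros(n_win, dtype=bool)
        for te in tes:
            if te.interval.chrom == chrom:
                _mark(has_te, te.interval.start, te.interval.end,
                      window_size, n_win)
        for sv in svs:
            iv = sv.interval
            if iv.chrom == chrom:
                _mark(has_sv, iv.start, iv.end, window_size, n_win)
        counts[0, 0] += int((has_te & has_sv).sum())
        counts[0, 1] += int((has_te & ~has_sv).sum())
        counts[1, 0] += int((~has_te & has_sv).sum())
        counts[1, 1] += int((~has_te & ~has_sv).sum())
    return counts


def _mark(flags: np.ndarray, start: int, end: int, window: int,
          n_win: int) -> None:
    first = start // window
    last = min((end - 1) // window, n_win - 1)
    flags[first:last + 1] = True


@dataclass
class CooccurrenceResult:
    window_size: int
    counts: np.ndarray
    chi2: float
    p: float
    odds_ratio: float
    valid: bool


def chi_square_2x2(counts, window_size: int = 0) -> CooccurrenceResult:
    """Pearson chi-square (no Yates correction) on a 2x2 occupancy table.

    A zero margin leaves the test undefined (flagged invalid). The odds
    ratio uses a 0.5 Haldane correction when any cell is zero.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2) or counts.sum() < 1:
        raise ValueError("need a 2x2 table with total >= 1")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return CooccurrenceResult(window_size, counts.astype(int),
                                  np.nan, np.nan, np.nan, False)
    chi2, p, _, _ = chi2_contingency(counts, correction=False)
    c = counts + 0.5 if (counts == 0).any() else counts
    oddsr = (c[0, 0] * c[1, 1]) / (c[0, 1] * c[1, 0])
    return CooccurrenceResult(window_size, counts.astype(int),
                              float(chi2), float(p), float(oddsr), True)


def cooccurrence_scan(svs, tes, layout: GenomeLayout,
                      window_sizes=(2000, 5000, 10000)) -> pd.DataFrame:
    """Chi-square co-occurrence at each window size (default 2/5/10 kb)."""
    rows = []
    for w in window_sizes:
        res = chi_square_2x2(window_occupancy(svs, tes, layout, w), w)
        rows.append((w, *res.counts.ravel(), res.chi2, res.p,
                     res.odds_ratio, res.valid))
    return pd.DataFrame(rows, columns=["window_size", "n_te_sv", "n_te_only",
                                       "n_sv_only", "n_neither", "chi2", "p",
                                       "odds_ratio", "valid"])


# ---------------------------------------------------------------------------
# genomic context
# ---------------------------------------------------------------------------

def classify_context(svs, genes, upstream_bp: int = 5000) -> pd.DataFrame:
    """Assign each SV a genomic context and nearest gene.

    gene_body: the SV overlaps a gene's exon-spanning extent; upstream5k:
    within ``upstream_bp`` 5' of a gene's TSS on that gene's strand;
    otherwise intergenic. gene_body takes precedence over upstream5k.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for v in by_chrom.values():
        v.sort(key=lambda g: g.start)

    rows = []
    for sv in svs:
        iv = sv.interval
        context = "intergenic"
        for g in by_chrom.get(iv.chrom, ()):
            if overlap_bp(iv.start, iv.end, g.start, g.end) > 0:
                context = "gene_body"
                break
            if _in_upstream(iv, g, upstream_bp):
                context = "upstream5k"
        ng = nearest_gene(sv, genes)
        rows.append((sv.id, context, *(ng if ng else (None, None))))
    return pd.DataFrame(rows, columns=["sv_id", "context", "nearest_gene",
                                       "distance"])


def _in_upstream(iv: Interval, g: GeneModel, upstream_bp: int) -> bool:
    if g.strand == "+":
        lo, hi = g.start - upstream_bp, g.start
    else:
        lo, hi = g.end, g.end + upstream_bp
    return overlap_bp(iv.start, iv.end, max(0, lo), hi) > 0


def nearest_gene(sv: SvRecord, genes):
    """(gene id, signed edge distance); positive = gene downstream of SV.

    Overlap gives distance 0; ties are broken by ascending gene start.
    Returns None when the SV's chromosome carries no gene.
    """
    iv = sv.interval
    best = None
    for g in sorted((g for g in genes if g.chrom == iv.chrom),
                    key=lambda g: g.start):
        if overlap_bp(iv.start, iv.end, g.start, g.end) > 0:
            dist = 0
        elif g.start >= iv.end:
            dist = g.start - iv.end
        else:
            dist = -(iv.start - g.end)
        if best is None or abs(dist) < abs(best[1]):
            best = (g.gene_id, dist)
    return best
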