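"""SV-frequency selection scans between population groups.

An SV is called selected in a contrast (wild -> native for domestication,
native -> commercial for improvement) when its allele-count Fisher exact
test survives an FDR threshold (Benjamini-Hochberg, default 0.001) AND its
Weir-Cockerham (1984) single-locus theta-hat reaches the contrast's top
percentile (default 99th). Direction labels frequency increase/decrease of
the derived (= ALT) allele along the contrast.

The Fisher two-sided p-value is computed by exact integer hypergeometric
enumeration (probability-mass two-sidedness, the convention of mainstream
statistics packages), so it agrees exactly with brute-force enumeration on
any table. The Weir-Cockerham estimator keeps its a (among-population),
b (among individuals within populations) and c (within-individual)
components; monomorphic sites are undefined and excluded from the
percentile.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import MISSING, SvGenotypeMatrix, groups_of
from .regions import Interval


@dataclass
class GroupAlleleCounts:
    """Allele-level counts for one group at many sites (vectors)."""

    group: str
    d: np.ndarray   # derived (ALT) allele count
    m: np.ndarray   # called alleles (2 x called samples)
    h: np.ndarray   # observed heterozygote count
    n: np.ndarray   # called samples

    @property
    def af(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.m > 0, self.d / np.maximum(self.m, 1), np.nan)


def group_allele_counts(matrix: SvGenotypeMatrix, metadata,
                        groups=None) -> dict[str, GroupAlleleCounts]:
    """Per-group derived/total/heterozygote counts; missing dosages excluded."""
    by_group = groups_of(metadata)
    if groups is not None:
        missing = [g for g in groups if g not in by_group]
        if missing:
            raise ValueError(f"groups absent from metadata: {missing}")
        by_group = {g: by_group[g] for g in groups}
    out = {}
    for g, names in by_group.items():
        idx = matrix.sample_index(names)
        dos = matrix.dosages[idx, :]
        called = dos != MISSING
        d = np.where(called, dos, 0).sum(axis=0)
        n = called.sum(axis=0)
        h = ((dos == 1) & called).sum(axis=0)
        out[g] = GroupAlleleCounts(g, d.astype(int), (2 * n).astype(int),
                                   h.astype(int), n.astype(int))
    return out


def maf_filter(matrix: SvGenotypeMatrix, min_maf: float = 0.01,
               exclude_chroms=()) -> SvGenotypeMatrix:
    """Drop sites with pooled minor-allele frequency below ``min_maf``.

    Optionally drops whole chromosomes first (e.g. sex chromosomes, keeping
    the analysis autosomal).
    """
    keep_chrom = np.array([r.interval.chrom not in set(exclude_chroms)
                           for r in matrix.records])
    called = matrix.dosages != MISSING
    m = 2 * called.sum(axis=0)
    d = np.where(called, matrix.dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(m > 0, d / np.maximum(m, 1), 0.0)
    maf = np.minimum(af, 1.0 - af)
    return matrix.subset_records(keep_chrom & (maf >= min_maf))


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by exact enumeration.

    Sums the hypergeometric probability of every table with the same
    margins whose probability does not exceed the observed table's
    probability. All arithmetic is exact (integer), so the result equals
    brute-force enumeration to the last bit.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    obs = comb(r1, a) * comb(r2, c)
    total = comb(n, c1)
    kmin, kmax = max(0, c1 - r2), min(c1, r1)
    num = 0
    for k in range(kmin, kmax + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= obs:
            num += w
    return num / total


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def wc_fst_components(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham (1984) variance components for two populations.

    Arguments are per-population called sample counts (diploids), ALT
    allele frequencies, and observed heterozygote *frequencies* (het
    count / called samples). Accepts scalars or aligned arrays. Returns
    (a, b, c) where theta-hat = a / (a + b + c).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2
                             - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                 - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2.0
    return a, b, c


def wc_fst(counts: dict[str, GroupAlleleCounts]):
    """Single-locus theta-hat (with components) for exactly two groups.

    Sites where a + b + c = 0 (monomorphic across both groups) are
    undefined and returned as NaN; sites where either group has < 2 called
    samples are NaN as well.
    """
    if len(counts) != 2:
        raise ValueError("wc_fst needs exactly two groups")
    (g1, g2) = counts.values()
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = g1.d / np.maximum(g1.m, 1)
        p2 = g2.d / np.maximum(g2.m, 1)
        hf1 = g1.h / np.maximum(g1.n, 1)
        hf2 = g2.h / np.maximum(g2.n, 1)
        a, b, c = wc_fst_components(g1.n, p1, hf1, g2.n, p2, hf2)
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom == 0, 1, denom),
                         np.nan)
    bad = (np.asarray(g1.n) < 2) | (np.asarray(g2.n) < 2)
    theta = np.where(bad, np.nan, theta)
    return theta, a, b, c


def scan_selection(matrix: SvGenotypeMatrix, metadata,
                   contrast: tuple[str, str], fdr: float = 0.001,
                   fst_quantile: float = 0.99,
                   table_counts: str = "allele") -> pd.DataFrame:
    """Per-SV Fisher exact + BH q + theta-hat intersection scan.

    ``contrast = (A, B)`` orders the comparison: direction is "increased"
    when AF(B) > AF(A) (domestication: A=wild, B=native; improvement:
    A=native, B=commercial). ``table_counts`` chooses allele (default) or
    genotype-class counts for the Fisher table.
    """
    ga, gb = contrast
    counts = group_allele_counts(matrix, metadata, groups=[ga, gb])
    ca, cb = counts[ga], counts[gb]

    pvals = np.empty(matrix.n_records)
    for j in range(matrix.n_records):
        if table_counts == "allele":
            table = ((int(ca.d[j]), int(ca.m[j] - ca.d[j])),
                     (int(cb.d[j]), int(cb.m[j] - cb.d[j])))
        elif table_counts == "genotype":
            # carriers (>= 1 ALT allele) vs non-carriers
            carr_a = int(ca.h[j] + (ca.d[j] - ca.h[j]) // 2)
            carr_b = int(cb.h[j] + (cb.d[j] - cb.h[j]) // 2)
            table = ((carr_a, int(ca.n[j]) - carr_a),
                     (carr_b, int(cb.n[j]) - carr_b))
        else:
            raise ValueError(f"unknown table_counts {table_counts!r}")
        pvals[j] = fisher_exact_two_sided(table)
    q = bh_adjust(pvals)

    theta, a, b, c = wc_fst({ga: ca, gb: cb})
    ok = np.isfinite(theta)
    threshold = np.quantile(theta[ok], fst_quantile) if ok.any() else np.nan

    af_a, af_b = ca.af, cb.af
    direction = np.where(af_b > af_a, "increased",
                         np.where(af_b < af_a, "decreased", "none"))
    selected = (q <= fdr) & ok & (theta >= threshold)

    n_ok = int(ok.sum())
    ranks = np.full(matrix.n_records, np.nan)
    if n_ok:
        order = theta[ok].argsort().argsort()  # rank within non-missing
        ranks[ok] = (order + 1) / n_ok
    return pd.DataFrame({
        "sv_id": [r.id for r in matrix.records],
        "chrom": [r.interval.chrom for r in matrix.records],
        "start": [r.interval.start for r in matrix.records],
        f"af_{ga}": af_a,
        f"af_{gb}": af_b,
        "fisher_p": pvals,
        "q": q,
        "fst": theta,
        "fst_percentile_rank": ranks,
        "selected": selected,
        "direction": direction,
    })


def delta_af(matrix: SvGenotypeMatrix, metadata, group_hi: str,
             group_lo: str, region: Interval) -> pd.DataFrame:
    """|AF(hi) - AF(lo)| for variants in a region, ranked descending.

    Ties are broken by ascending genomic position so the ranking is
    deterministic. An empty region yields an empty frame (with a warning).
    """
    import warnings

    counts = group_allele_counts(matrix, metadata,
                                 groups=[group_hi, group_lo])
    rows = []
    for j, r in enumerate(matrix.records):
        iv = r.interval
        if iv.chrom != region.chrom or iv.end <= region.start \
                or iv.start >= region.end:
            continue
        daf = abs(counts[group_hi].af[j] - counts[group_lo].af[j])
        rows.append((r.id, iv.start, daf))
    if not rows:
        warnings.warn(f"no variants in region "
                      f"{region.chrom}:{region.start}-{region.end}")
        return pd.DataFrame(columns=["variant", "position", "delta_af",
                                     "rank"])
    df = pd.DataFrame(rows, columns=["variant", "position", "delta_af"])
    df = df.sort_values(["delta_af", "position"],
                        ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
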