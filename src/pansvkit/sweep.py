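"""Windowed diversity statistics and single-marker association.

Nucleotide diversity pi uses the unbiased per-site heterozygosity
2*p*(1-p)*n/(n-1) summed over sites and divided by window length. Tajima's
D follows the 1989 normalization D = (kbar - S/a1) / sqrt(e1*S +
e2*S*(S-1)). Windowed F_ST is the ratio-of-sums of Weir-Cockerham
components across sites (sum a / sum (a+b+c)), the standard windowed
estimator. Single-marker association fits an ordinary least-squares model
y ~ sex + g with the marker coded additively; the marker's p-value is an
F-test against the sex-only model and its R^2 is the marker sum of squares
after all other terms divided by the total sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING
from .regions import tile_windows
from .selection import wc_fst_components

WINDOW_PRESETS = {
    "fst": (20_000, 20_000),
    "pi": (20_000, 20_000),
    "tajima_d": (10_000, 5_000),
}


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def site_frequencies(matrix) -> tuple[np.ndarray, np.ndarray]:
    """(derived counts, called haplotype counts) per site.

    ``matrix`` is haplotypes (values 0/1) or diploid dosages (0/1/2, with
    the missing sentinel), sites in rows and individuals in columns. Diploid
    columns contribute two haplotypes each (no phasing needed for
    frequency-based statistics).
    """
    m = np.asarray(matrix)
    called = m != MISSING
    vals = np.where(called, m, 0)
    if m.size and vals.max(initial=0) > 1:
        # diploid dosages
        d = vals.sum(axis=1)
        n = 2 * called.sum(axis=1)
    else:
        d = vals.sum(axis=1)
        n = called.sum(axis=1)
    return d.astype(float), n.astype(float)


def pi_window(derived, n_haplotypes, window_length: float) -> float:
    """Per-site nucleotide diversity over a window.

    pi = sum_sites 2*p*(1-p) * n/(n-1) / L with per-site called haplotype
    counts n.
    """
    if window_length <= 0:
        raise ValueError("window length must be positive")
    d = np.asarray(derived, dtype=float)
    n = np.asarray(n_haplotypes, dtype=float)
    if d.size == 0:
        return 0.0
    if (n < 2).any():
        raise ValueError("need >= 2 called haplotypes at every site")
    p = d / n
    het = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return float(het.sum() / window_length)


def pi_per_site(hap_matrix, window_length: float) -> float:
    """pi for a window given a haplotype (or dosage) matrix, sites x ind."""
    d, n = site_frequencies(hap_matrix)
    seg = (d > 0) & (d < n)
    return pi_window(d[seg], n[seg], window_length)


@dataclass
class TajimaComponents:
    n: int
    S: int
    kbar: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float  # NaN when S == 0


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalization constants for n haplotypes."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(hap_matrix=None, derived=None,
              n_haplotypes: int | None = None) -> TajimaComponents:
    """Tajima's D from a haplotype matrix or per-site derived counts.

    D = (kbar - S/a1) / sqrt(e1*S + e2*S*(S-1)); kbar is the mean number
    of pairwise differences. Undefined (NaN) when S = 0; n < 4 is an error.
    """
    if hap_matrix is not None:
        d, n_arr = site_frequencies(hap_matrix)
        if n_arr.size and not np.all(n_arr == n_arr[0]):
            raise ValueError("per-site haplotype counts differ; pass "
                             "derived counts and a single n instead")
        n = int(n_arr[0]) if n_arr.size else int(np.asarray(
            hap_matrix).shape[1])
    else:
        d = np.asarray(derived, dtype=float)
        n = int(n_haplotypes)
    if n < 4:
        raise ValueError("Tajima's D needs >= 4 haplotypes")
    seg = (d > 0) & (d < n)
    d = d[seg]
    S = int(d.size)
    const = tajima_constants(n)
    if S == 0:
        return TajimaComponents(n, 0, 0.0, **const, D=float("nan"))
    npairs = n * (n - 1) / 2.0
    kbar = float(np.sum(d * (n - d)) / npairs)
    var = const["e1"] * S + const["e2"] * S * (S - 1)
    D = (kbar - S / const["a1"]) / np.sqrt(var)
    return TajimaComponents(n, S, kbar, **const, D=float(D))


# ---------------------------------------------------------------------------
# windowed scans
# ---------------------------------------------------------------------------

def windowed_scan(positions, matrix, chrom_length: int, statistic: str,
                  window: int | None = None, step: int | None = None,
                  group_index=None,
                  denominator: str = "window") -> pd.DataFrame:
    """Sliding-window pi / Tajima's D / F_ST along one chromosome.

    ``matrix`` is sites x individuals (haplotypes 0/1 or diploid dosages
    0/1/2 with missing sentinel), ``positions`` the site coordinates.
    Defaults follow the named presets (20 kb/20 kb for pi and F_ST,
    10 kb/5 kb for Tajima's D). F_ST needs ``group_index``: an integer
    array with 0/1 labelling each *diploid* column's group; it is computed
    as the ratio of summed Weir-Cockerham components over the window's
    sites. ``denominator`` for pi: "window" (window length) or "sites"
    (count of usable sites). Windows without usable sites report NaN.
    """
    if statistic not in ("pi", "tajima_d", "fst"):
        raise ValueError(f"unknown statistic {statistic!r}")
    preset = WINDOW_PRESETS[statistic]
    window = preset[0] if window is None else window
    step = preset[1] if step is None else step
    positions = np.asarray(positions)
    m = np.asarray(matrix)

    rows = []
    for (ws, we) in tile_windows(chrom_length, window, step):
        sel = (positions >= ws) & (positions < we)
        sub = m[sel]
        value, n_sites = np.nan, int(sel.sum())
        if statistic == "pi":
            if n_sites:
                L = (we - ws) if denominator == "window" else n_sites
                value = pi_per_site(sub, L)
        elif statistic == "tajima_d":
            if n_sites:
                comp = tajimas_d(sub)
                value = comp.D
        else:
            if group_index is None:
                raise ValueError("fst needs group_index")
            if n_sites:
                value = _window_fst(sub, np.asarray(group_index))
        rows.append((ws, we, statistic, value, n_sites, m.shape[1]))
    return pd.DataFrame(rows, columns=["start", "end", "statistic", "value",
                                       "n_sites", "n_columns"])


def _window_fst(dosages: np.ndarray, group_index: np.ndarray) -> float:
    """Ratio-of-sums Weir-Cockerham F_ST over a window of diploid sites."""
    sum_a = sum_abc = 0.0
    for row in dosages:
        comp = _site_wc(row, group_index)
        if comp is None:
            continue
        a, b, c = comp
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc if sum_abc != 0 else np.nan


def _site_wc(dosages_row: np.ndarray, group_index: np.ndarray):
    stats_ = []
    for g in (0, 1):
        dd = dosages_row[group_index == g]
        dd = dd[dd != MISSING]
        n = dd.size
        if n < 2:
            return None
        stats_.append((n, dd.sum() / (2.0 * n), np.mean(dd == 1)))
    (n1, p1, h1), (n2, p2, h2) = stats_
    if p1 in (0.0, 1.0) and p2 == p1:
        return None  # monomorphic across both groups
    return wc_fst_components(n1, p1, h1, n2, p2, h2)


# ---------------------------------------------------------------------------
# single-marker association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    marker: str
    trait: str
    effect: float
    f_stat: float
    p: float
    r2: float      # marker SS after all other terms / total SS
    n: int
    model: str


def single_marker_glm(y, marker, sex, model: str = "additive",
                      marker_id: str = "marker",
                      trait: str = "trait") -> AssociationResult:
    """OLS y ~ sex + marker with an F-test against the sex-only model.

    ``model='additive'`` codes the marker 0/1/2; ``model='genotype'`` fits
    genotype classes (2 df). Marker R^2 = (RSS_reduced - RSS_full) / TSS.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    g = np.asarray(marker, dtype=float)
    sex = np.asarray(sex, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need n >= 10")
    if np.unique(g).size < 2:
        raise ValueError("marker is constant")
    if np.unique(sex).size > 1 and abs(np.corrcoef(g, sex)[0, 1]) > 0.999:
        raise ValueError("marker collinear with sex")

    x_red = sm.add_constant(sex[:, None])
    if model == "additive":
        gx = g[:, None]
        df_marker = 1
    elif model == "genotype":
        classes = np.unique(g)
        gx = np.column_stack([(g == c).astype(float)
                              for c in classes[1:]])
        df_marker = gx.shape[1]
    else:
        raise ValueError(f"unknown model {model!r}")
    x_full = np.column_stack([x_red, gx])

    fit_red = sm.OLS(y, x_red).fit()
    fit_full = sm.OLS(y, x_full).fit()
    rss_red = float(fit_red.ssr)
    rss_full = float(fit_full.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    df_resid = n - x_full.shape[1]
    f = ((rss_red - rss_full) / df_marker) / (rss_full / df_resid)
    p = float(stats.f.sf(f, df_marker, df_resid))
    r2 = (rss_red - rss_full) / tss
    effect = float(fit_full.params[-1]) if model == "additive" else np.nan
    return AssociationResult(marker_id, trait, effect, float(f), p,
                             float(r2), n, model)
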