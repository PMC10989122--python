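"""Gene presence/absence calling, occupancy classes and pan-genome curves.

A gene is called present in a sample when the pooled fraction of its exonic
bases covered by at least ``min_depth`` reads exceeds ``min_exon_fraction``
(default 5%). Presence frequencies across samples partition genes into
core (f = 1), softcore (0.99 < f < 1), shell (0.01 <= f <= 0.99) and cloud
(f < 0.01) classes. Pan and core growth curves over random genome orderings
are fitted with power-law (pan) and exponential (core) models
y = A*x^B + C and y = A*exp(B*x) + C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

PAV_CLASSES = ("core", "softcore", "shell", "cloud")


@dataclass
class PavMatrix:
    """Boolean gene x sample presence matrix (no missing entries)."""

    genes: list[str]
    samples: list[str]
    presence: np.ndarray  # shape (n_genes, n_samples), bool

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.genes), len(self.samples)):
            raise ValueError("presence shape does not match genes x samples")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence.astype(int), index=self.genes,
                            columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PavMatrix":
        return cls(list(df.index), list(df.columns),
                   df.to_numpy(dtype=bool))


def call_gene_presence(bases_ge_min_depth, exon_lengths,
                       min_exon_fraction: float = 0.05,
                       mode: str = "pooled") -> bool:
    """Presence rule for one (gene, sample) from per-exon coverage counts.

    ``pooled`` (default): covered exonic bases summed over exons, divided by
    total exonic length, strictly greater than ``min_exon_fraction``.
    ``per_exon``: fraction of exons with any covered base, same threshold.
    """
    bases = np.asarray(bases_ge_min_depth, dtype=float)
    lengths = np.asarray(exon_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("exon lengths must be positive")
    if (bases > lengths).any():
        raise ValueError("bases_ge_min_depth exceeds exon length")
    if mode == "pooled":
        frac = bases.sum() / lengths.sum()
    elif mode == "per_exon":
        frac = (bases > 0).mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return bool(frac > min_exon_fraction)


def build_pav_matrix(coverage: pd.DataFrame,
                     min_exon_fraction: float = 0.05,
                     mode: str = "pooled",
                     exclude_genes=()) -> PavMatrix:
    """Apply the presence rule to a (sample, gene, exon) coverage table."""
    cov = coverage[~coverage["gene"].isin(set(exclude_genes))]
    genes = sorted(cov["gene"].unique())
    samples = sorted(cov["sample"].unique())
    if mode == "pooled":
        agg = cov.groupby(["gene", "sample"], sort=True)[
            ["bases_ge_min_depth", "exon_length"]].sum()
        frac = agg["bases_ge_min_depth"] / agg["exon_length"]
    else:
        covered = cov.assign(hit=(cov["bases_ge_min_depth"] > 0).astype(float))
        frac = covered.groupby(["gene", "sample"], sort=True)["hit"].mean()
    present = (frac > min_exon_fraction).unstack("sample")
    present = present.reindex(index=genes, columns=samples)
    if present.isna().any().any():
        raise ValueError("coverage table has missing (gene, sample) cells")
    return PavMatrix(genes, samples, present.to_numpy(dtype=bool))


def classify_pav(matrix: PavMatrix) -> pd.DataFrame:
    """Per-gene presence frequency and occupancy class.

    Thresholds are strict: a gene present in every sample is core; softcore
    requires f strictly between 0.99 and 1; f exactly at a boundary falls to
    the lower class.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples to classify occupancy")
    if not matrix.genes:
        raise ValueError("empty PAV matrix")
    f = matrix.presence.mean(axis=1)
    cls = np.where(f == 1.0, "core",
                   np.where(f > 0.99, "softcore",
                            np.where(f >= 0.01, "shell", "cloud")))
    return pd.DataFrame({"gene": matrix.genes, "frequency": f,
                         "pav_class": cls})


def pav_class_counts(classification: pd.DataFrame) -> dict[str, int]:
    counts = classification["pav_class"].value_counts()
    return {c: int(counts.get(c, 0)) for c in PAV_CLASSES}


def pan_core_single_order(matrix: PavMatrix, order) -> tuple[np.ndarray, np.ndarray]:
    """Pan (union) and core (intersection) gene counts along one ordering."""
    pres = matrix.presence[:, list(order)]
    union = np.logical_or.accumulate(pres, axis=1).sum(axis=0)
    inter = np.logical_and.accumulate(pres, axis=1).sum(axis=0)
    return union.astype(int), inter.astype(int)


def pan_core_trajectories(matrix: PavMatrix, n_orders: int = 100,
                          seed: int = 0) -> pd.DataFrame:
    """Mean pan/core gene counts over random genome orderings.

    Returns a tidy frame with columns (x, kind, y): for each x = 1..S, the
    mean over ``n_orders`` random orderings of the union (pan) and
    intersection (core) of the gene sets of the first x samples.
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    rng = np.random.default_rng(seed)
    s = len(matrix.samples)
    pans = np.zeros(s)
    cores = np.zeros(s)
    for _ in range(n_orders):
        order = rng.permutation(s)
        union, inter = pan_core_single_order(matrix, order)
        pans += union
        cores += inter
    pans /= n_orders
    cores /= n_orders
    x = np.arange(1, s + 1)
    return pd.concat([
        pd.DataFrame({"x": x, "kind": "pan", "y": pans}),
        pd.DataFrame({"x": x, "kind": "core", "y": cores}),
    ], ignore_index=True)


@dataclass
class PanCurveFit:
    """Least-squares fit of a pan/core growth curve."""

    model: str  # "power" or "exponential"
    A: float
    B: float
    C: float
    rss: float
    converged: bool

    @property
    def closed(self) -> bool:
        """A closed pan-genome: the curve approaches a finite asymptote."""
        return self.B < 0

    @property
    def asymptote(self) -> float | None:
        """Estimated total (pan) or floor (core) gene count, C, when B < 0."""
        return self.C if self.closed else None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "power":
            return self.A * x ** self.B + self.C
        return self.A * np.exp(self.B * x) + self.C


def _residuals(params, x, y, model):
    a, b, c = params
    if model == "power":
        pred = a * x ** b + c
    else:
        with np.errstate(over="ignore"):
            pred = a * np.exp(b * x) + c
    return pred - y


def fit_growth_curve(points: pd.DataFrame | None = None,
                     model: str = "power",
                     x=None, y=None) -> PanCurveFit:
    """Fit y = A*x^B + C (power) or y = A*exp(B*x) + C (exponential).

    Bounded multi-start least squares over a deterministic grid of starts
    (A free in sign, B in [-5, 5], C >= 0); the lowest residual sum of
    squares wins, so fits are reproducible.
    """
    if points is not None:
        x = points["x"].to_numpy(dtype=float)
        y = points["y"].to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    if model not in ("power", "exponential"):
        raise ValueError(f"unknown model {model!r}")
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct x values to fit 3 parameters")

    span = y.max() - y.min()
    scale = max(abs(y).max(), 1.0)
    starts = []
    for a0 in (span + 1.0, -(span + 1.0), scale, -scale):
        for b0 in (-2.0, -1.0, -0.5, -0.1, 0.1, 0.5, 1.0):
            for c0 in (0.0, y.min(), y.max()):
                starts.append((a0, b0, max(c0, 0.0)))

    best = None
    lower = (-np.inf, -5.0, 0.0)
    upper = (np.inf, 5.0, np.inf)
    import warnings as _warnings

    for p0 in starts:
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                sol = least_squares(_residuals, p0, args=(x, y, model),
                                    bounds=(lower, upper),
                                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                    max_nfev=2000)
        except ValueError:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("growth-curve fit failed from every start")
    rss, sol = best
    a, b, c = sol.x
    return PanCurveFit(model, float(a), float(b), float(c), rss,
                       bool(best[1].success))
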