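"""LTR retrotransposon insertion dating from terminal-repeat divergence.

The two LTRs of an element are identical at insertion time; the divergence
K accumulated between them since then dates the insertion as T = K / (2r),
with r the neutral substitution rate per site per year (default
1.91e-9). Divergence is measured on a global pairwise alignment over
ungapped, N-free columns and corrected with JC69 by default (raw p and
Kimura 2-parameter are available).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, sqrt

import numpy as np
import pandas as pd
from Bio import Align

from .io import read_fasta

DEFAULT_RATE = 1.91e-9  # substitutions per site per year
MIN_ALIGNED_COLUMNS = 50

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -2
    return al


def align_ltr_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global pairwise alignment (match +1, mismatch -1, gap -2).

    Returns the two gapped sequences of the highest-scoring alignment; the
    aligner's deterministic ordering breaks ties.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aln = _aligner().align(seq_a.upper(), seq_b.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b


@dataclass
class DivergenceEstimate:
    element: str
    aligned_length: int     # ungapped, N-free columns
    mismatches: int
    p: float                # raw proportion of mismatching columns
    model: str              # raw | jc69 | k2p
    K: float                # model-corrected divergence (NaN if undefined)
    defined: bool
    T: float | None = None  # insertion time in years
    rate: float | None = None


def ltr_divergence(aligned_a: str, aligned_b: str, model: str = "jc69",
                   element: str = "") -> DivergenceEstimate:
    """Divergence over ungapped columns of an aligned LTR pair.

    Columns containing a gap or N are excluded from both numerator and
    denominator. JC69: K = -(3/4) ln(1 - 4p/3), undefined for p >= 0.75.
    K2P uses the transition/transversion split.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    n = mism = ts = tv = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x in "-N" or y in "-N":
            continue
        n += 1
        if x != y:
            mism += 1
            if (x, y) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n < MIN_ALIGNED_COLUMNS:
        raise ValueError(f"only {n} ungapped columns "
                         f"(need >= {MIN_ALIGNED_COLUMNS})")
    p = mism / n
    defined = True
    if model == "raw":
        K = p
    elif model == "jc69":
        if p >= 0.75:
            K, defined = float("nan"), False
        else:
            K = -0.75 * log(1.0 - 4.0 * p / 3.0)
    elif model == "k2p":
        P, Q = ts / n, tv / n
        w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if w1 <= 0 or w2 <= 0:
            K, defined = float("nan"), False
        else:
            K = -0.5 * log(w1 * sqrt(w2))
    else:
        raise ValueError(f"unknown model {model!r}")
    return DivergenceEstimate(element, n, mism, p, model, K, defined)


def insertion_time(K: float, rate: float = DEFAULT_RATE) -> float:
    """T = K / (2r) in years."""
    if K < 0:
        raise ValueError("K must be >= 0")
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    return K / (2.0 * rate)


def date_ltr_pair(seq_a: str, seq_b: str, rate: float = DEFAULT_RATE,
                  model: str = "jc69",
                  element: str = "") -> DivergenceEstimate:
    """Align one LTR pair, estimate K, and date the insertion."""
    est = ltr_divergence(*align_ltr_pair(seq_a, seq_b), model=model,
                         element=element)
    est.rate = rate
    est.T = insertion_time(est.K, rate) if est.defined else float("nan")
    return est


def date_ltr_fasta(path, rate: float = DEFAULT_RATE,
                   model: str = "jc69") -> pd.DataFrame:
    """Date every ``<element>_5LTR`` / ``<element>_3LTR`` pair in a FASTA."""
    seqs = read_fasta(path)
    elements = {}
    for name in seqs:
        for suffix in ("_5LTR", "_3LTR"):
            if name.endswith(suffix):
                elements.setdefault(name[: -len(suffix)], {})[suffix] = name
    rows = []
    for elem in sorted(elements):
        pair = elements[elem]
        if set(pair) != {"_5LTR", "_3LTR"}:
            raise ValueError(f"element {elem!r} lacks a complete LTR pair")
        est = date_ltr_pair(seqs[pair["_5LTR"]], seqs[pair["_3LTR"]],
                            rate=rate, model=model, element=elem)
        rows.append((elem, est.aligned_length, est.mismatches, est.p,
                     est.model, est.K, est.T))
    return pd.DataFrame(rows, columns=["element", "aligned_length",
                                       "mismatches", "p", "model", "K",
                                       "T_years"])
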