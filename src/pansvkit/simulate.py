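"""Ground-truth-bearing synthetic cohorts for every pipeline stage.

The generator emulates the statistical structure of a three-group duck
resequencing cohort (wild / native / commercial, 20 + 70 + 41 samples):
SV sites with group-differentiated allele frequencies under within-group
Hardy-Weinberg sampling, a TE landscape with tunable SV co-localization,
SVs copied from intact TEs, LTR pairs diverged at a known K, per-exon
coverage at ~45x with gene dropout, and an F2 phenotype with a marker of
known variance fraction. Each piece returns a machine-readable truth record
so downstream statistics can be scored against what was planted.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` substreams, so outputs are byte-identical
across runs with the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (MISSING, GeneModel, SampleMetadata, SvGenotypeMatrix,
                 SvRecord, TeInterval, write_fasta, write_gene_models,
                 write_sv_vcf, write_te_bed)
from .pav import PavMatrix
from .regions import GenomeLayout, Interval, tile_windows

BASES = np.array(list("ACGT"))

# substitution rate used throughout for LTR insertion dating (per site/year)
DEFAULT_SUBSTITUTION_RATE = 1.91e-9


def default_layout() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (5_000_000, 5_000_000))


@dataclass(frozen=True)
class F2Config:
    """Design of the simulated F2 association cohort.

    The marker segregates 1/4 : 1/2 : 1/4; phenotypic variance is scaled to
    1 with the marker explaining fraction ``v`` and sex explaining
    ``sex_var`` in expectation.
    """

    n: int = 500
    v: float = 0.2761
    sex_var: float = 0.10
    mean: float = 10.0

    def __post_init__(self):
        if not (0 <= self.v < 1):
            raise ValueError("marker variance fraction v must be in [0, 1)")
        if self.v + self.sex_var >= 1:
            raise ValueError("v + sex_var must leave residual variance")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Group sizes default to 20 wild + 70 native + 41 commercial; the planted
    allele-frequency triples mirror near-fixed differences of the kind seen
    at domestication/improvement loci (e.g. native 0.89 vs commercial 0.012).
    """

    seed: int = 0
    layout: GenomeLayout = field(default_factory=default_layout)
    group_sizes: tuple[tuple[str, int], ...] = (
        ("wild", 20), ("native", 70), ("commercial", 41))
    n_sv: int = 1000
    af_beta: tuple[float, float] = (0.5, 0.5)
    planted_svs: tuple[tuple[float, float, float], ...] = (
        (0.85, 0.89, 0.012),   # improvement-decreased, IGF2BP1-like deletion
        (0.80, 0.93, 0.0),     # improvement-decreased, MITF-like deletion
        (0.05, 0.75, 0.80),    # domestication-increased
        (0.95, 0.10, 0.08),    # domestication-decreased
    )
    te_density: float = 50.0          # elements per Mb
    rho: float = 0.5                  # SV placement inside TE-occupied windows
    intact_fraction: float = 0.05     # SVs copied from intact TE spans
    placement_window: int = 2000
    K_list: tuple[float, ...] = (0.002292, 0.014823)  # ~0.6 and ~3.88 Myr
    ltr_length: int = 1000
    n_ltr_per_k: int = 3
    coverage_depth: float = 45.0
    background_cov_fraction: float = 0.03
    n_genes: int = 400
    core_fraction: float = 0.9767
    softcore_share: float = 0.26      # softcore share of dispensable genes
    f2: F2Config = field(default_factory=F2Config)

    def __post_init__(self):
        for name, size in self.group_sizes:
            if size < 2:
                raise ValueError(f"group {name!r} needs >= 2 samples")
        for p in (self.rho, self.intact_fraction, self.core_fraction,
                  self.softcore_share):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for triple in self.planted_svs:
            if any(not 0 <= a <= 1 for a in triple):
                raise ValueError(f"planted AF outside [0, 1]: {triple}")
        for k in self.K_list:
            if k < 0 or k > 0.75:
                raise ValueError("K must be in [0, 0.75]")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.group_sizes)

    def sample_names(self) -> list[str]:
        out = []
        for g, n in self.group_sizes:
            out.extend(f"{g}_{i:03d}" for i in range(1, n + 1))
        return out


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(6)
    names = ("landscape", "genotypes", "ltr", "coverage", "f2", "haplotypes")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# TE landscape + SV positions
# ---------------------------------------------------------------------------

_TE_CLASSES = ("LTR/Gypsy", "LTR/ERVL", "LINE/CR1", "SINE/MIR", "DNA/hAT")
_TE_WEIGHTS = (0.25, 0.15, 0.35, 0.15, 0.10)
_SV_TYPES = ("DEL", "INS", "INV", "DUP")
_SV_TYPE_WEIGHTS = (0.60, 0.20, 0.15, 0.05)
_LTR_ARM = 250  # bp of terminal repeat annotated on intact LTR elements


def _pick_chrom(layout: GenomeLayout, rng) -> str:
    w = np.array(layout.lengths, dtype=float)
    return layout.names[rng.choice(len(w), p=w / w.sum())]


def simulate_te_sv_landscape(config: SimulationConfig, rng=None):
    """Place TEs uniformly and SV intervals with tunable TE attraction.

    With probability ``rho`` an SV start falls inside a randomly chosen
    TE-occupied window (size ``placement_window``), otherwise uniformly.
    A fraction ``intact_fraction`` of SVs copies an intact-TE span with
    per-edge jitter of at most 1% of the element length, guaranteeing
    > 95% reciprocal overlap with the source element.

    Returns (te track, SV records, truth intact-derived SV ids).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    layout = config.layout
    n_te = int(round(config.te_density * layout.total_length / 1e6))
    if config.te_density > 0 and n_te == 0:
        raise ValueError("layout too small for the requested TE density")

    tes: list[TeInterval] = []
    for _ in range(n_te):
        chrom = _pick_chrom(layout, rng)
        clen = layout.length_of(chrom)
        length = int(np.clip(rng.lognormal(np.log(1500), 0.8), 200, 10_000))
        if length >= clen:
            raise ValueError("layout too small for the requested TE lengths")
        start = int(rng.integers(0, clen - length))
        te_class = _TE_CLASSES[rng.choice(len(_TE_CLASSES), p=_TE_WEIGHTS)]
        iv = Interval(chrom, start, start + length, ".", te_class)
        intact = (te_class.startswith("LTR") and length >= 4 * _LTR_ARM
                  and rng.random() < 0.15)
        ltr5 = ltr3 = None
        if intact:
            ltr5 = Interval(chrom, start, start + _LTR_ARM)
            ltr3 = Interval(chrom, start + length - _LTR_ARM, start + length)
        tes.append(TeInterval(iv, te_class, intact, ltr5, ltr3))

    # TE-occupied placement windows (flag-array marking keeps this O(n))
    w = config.placement_window
    occupied: list[tuple[str, int, int]] = []
    for chrom, clen in zip(layout.names, layout.lengths):
        n_win = (clen + w - 1) // w
        flags = np.zeros(n_win, dtype=bool)
        for t in tes:
            if t.interval.chrom == chrom:
                flags[t.interval.start // w:
                      (t.interval.end - 1) // w + 1] = True
        occupied.extend((chrom, int(i) * w, min(int(i) * w + w, clen))
                        for i in np.flatnonzero(flags))

    n_intact_sv = int(round(config.intact_fraction * config.n_sv))
    intact_pool = [t for t in tes if t.intact]
    if n_intact_sv > 0 and not intact_pool:
        raise ValueError("intact_fraction > 0 but no intact TEs were placed")

    records: list[SvRecord] = []
    truth_intact: list[str] = []
    for i in range(config.n_sv):
        sv_id = f"SV{i:05d}"
        if i < n_intact_sv:
            te = intact_pool[rng.integers(0, len(intact_pool))]
            length = len(te.interval)
            j = max(1, int(0.01 * length))
            ds = int(rng.integers(-j, j + 1))
            de = int(rng.integers(-j, j + 1))
            clen = layout.length_of(te.interval.chrom)
            start = max(0, te.interval.start + ds)
            end = min(clen, te.interval.end + de)
            iv = Interval(te.interval.chrom, start, end)
            records.append(SvRecord(sv_id, iv, "DEL", len(iv)))
            truth_intact.append(sv_id)
            continue
        svtype = _SV_TYPES[rng.choice(len(_SV_TYPES), p=_SV_TYPE_WEIGHTS)]
        svlen = int(np.clip(rng.lognormal(np.log(300), 1.0), 50, 20_000))
        footprint = 1 if svtype == "INS" else svlen
        if occupied and rng.random() < config.rho:
            chrom, ws, we = occupied[rng.integers(0, len(occupied))]
            clen = layout.length_of(chrom)
            start = int(rng.integers(ws, we))
            start = min(start, max(0, clen - footprint))
        else:
            chrom = _pick_chrom(layout, rng)
            clen = layout.length_of(chrom)
            start = int(rng.integers(0, max(1, clen - footprint)))
        iv = Interval(chrom, start, start + footprint)
        records.append(SvRecord(sv_id, iv, svtype, svlen))
    return tes, records, truth_intact


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_cohort_genotypes(config: SimulationConfig, rng=None,
                              records=None, planted=None):
    """Draw diploid dosages under within-group Hardy-Weinberg sampling.

    Null SVs share one Beta-distributed allele frequency across groups;
    planted SVs carry explicit per-group frequency triples (one per group in
    config order). Dosages are Binomial(2, AF) independently per sample.

    Returns (SvGenotypeMatrix, metadata list, truth dict). ``truth`` maps
    planted SV ids to their frequency triples and stores the per-group
    frequencies used for every site.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if records is None:
        _, records, _ = simulate_te_sv_landscape(config, rng)
    n_sv = len(records)
    groups = config.groups

    if planted is None:
        k = len(config.planted_svs)
        if k > n_sv:
            raise ValueError("more planted SVs than records")
        chosen = rng.choice(n_sv, size=k, replace=False)
        planted = {records[int(i)].id: tuple(t)
                   for i, t in zip(chosen, config.planted_svs)}
    for triple in planted.values():
        if len(triple) != len(groups):
            raise ValueError("planted triple length must match group count")
        if any(not 0 <= a <= 1 for a in triple):
            raise ValueError(f"planted AF outside [0, 1]: {triple}")

    a, b = config.af_beta
    base_af = rng.beta(a, b, size=n_sv)
    af = np.tile(base_af, (len(groups), 1))  # groups x sv
    id_index = {r.id: j for j, r in enumerate(records)}
    for sv_id, triple in planted.items():
        af[:, id_index[sv_id]] = triple

    blocks = []
    metadata: list[SampleMetadata] = []
    for gi, (gname, gsize) in enumerate(config.group_sizes):
        blocks.append(rng.binomial(2, af[gi][None, :],
                                   size=(gsize, n_sv)).astype(np.int8))
        metadata.extend(SampleMetadata(f"{gname}_{i:03d}", gname)
                        for i in range(1, gsize + 1))
    dosages = np.vstack(blocks)
    matrix = SvGenotypeMatrix(records, [m.sample for m in metadata],
                              dosages, config.layout)
    truth = {"planted": {k: list(v) for k, v in planted.items()},
             "group_af": {g: af[i].tolist() for i, g in enumerate(groups)}}
    return matrix, metadata, truth


# ---------------------------------------------------------------------------
# LTR pairs
# ---------------------------------------------------------------------------

def random_sequence(length: int, rng) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def simulate_ltr_pair(seed_seq: str, K: float, rng) -> tuple[str, str]:
    """Diverge two copies of one LTR by per-site substitutions.

    Each copy receives substitutions at per-site probability K/2 with a
    uniformly random target among the three other bases, so the expected
    pairwise raw divergence is ~K for small K (Jukes-Cantor-consistent).
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    if K > 0.75:
        raise ValueError("K > 0.75 is outside JC69 validity")
    if len(seed_seq) < 100:
        raise ValueError("seed sequence must be >= 100 bp")
    idx = np.array(["ACGT".index(c) for c in seed_seq.upper()])

    def mutate():
        out = idx.copy()
        hit = rng.random(len(out)) < K / 2.0
        shift = rng.integers(1, 4, size=len(out))
        out[hit] = (out[hit] + shift[hit]) % 4
        return "".join(BASES[out])

    return mutate(), mutate()


def simulate_ltr_pairs(config: SimulationConfig, rng=None):
    """FASTA-ready LTR pairs for every divergence in ``K_list``.

    Sequence names use the ``<element>_5LTR`` / ``<element>_3LTR`` suffix
    convention. Returns (seqs dict, truth element id -> true K).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    seqs: dict[str, str] = {}
    truth: dict[str, float] = {}
    idx = 0
    for K in config.K_list:
        for _ in range(config.n_ltr_per_k):
            name = f"LTRelem{idx:03d}"
            seed_seq = random_sequence(config.ltr_length, rng)
            a, b = simulate_ltr_pair(seed_seq, K, rng)
            seqs[f"{name}_5LTR"] = a
            seqs[f"{name}_3LTR"] = b
            truth[name] = K
            idx += 1
    return seqs, truth


# ---------------------------------------------------------------------------
# PAV coverage
# ---------------------------------------------------------------------------

def _p_ge2(lam: float) -> float:
    """Poisson tail P(depth >= 2) at mean lam."""
    return float(1.0 - np.exp(-lam) * (1.0 + lam))


def simulate_pav_genes(config: SimulationConfig, rng) -> list[GeneModel]:
    """Lay out three-exon genes along the genome, round-robin by chromosome."""
    genes = []
    cursors = {c: 10_000 for c in config.layout.names}
    chroms = list(config.layout.names)
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        pos = cursors[chrom]
        exons = []
        for _ in range(3):
            elen = int(rng.integers(150, 401))
            exons.append(Interval(chrom, pos, pos + elen))
            pos += elen + int(rng.integers(200, 2001))
        cursors[chrom] = pos + int(rng.integers(1000, 5001))
        if cursors[chrom] >= config.layout.length_of(chrom):
            raise ValueError("layout too small for the requested gene count")
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel.from_raw_exons(f"gene{i:04d}", chrom, strand,
                                              exons))
    return genes


def simulate_pav_coverage(config: SimulationConfig, rng=None, genes=None):
    """Per-exon coverage table plus the true presence matrix.

    Present genes are covered at the sample's depth; absent genes receive
    background mis-mapped coverage over a small fraction
    (``background_cov_fraction``) of their exonic bases, so the covered
    fraction of an absent gene sits near 3%, below the 5% presence
    threshold but not at zero. Per-exon counts of bases at depth >= 2 are
    Binomial draws at the corresponding Poisson tail probability.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if genes is None:
        genes = simulate_pav_genes(config, rng)
    samples = config.sample_names()

    # gene classes: core always present; dispensable split softcore/shell
    n_core = int(round(config.core_fraction * len(genes)))
    presence_p = np.ones(len(genes))
    for gi in range(n_core, len(genes)):
        if rng.random() < config.softcore_share:
            presence_p[gi] = 0.995
        else:
            presence_p[gi] = rng.uniform(0.05, 0.95)
    truth = rng.random((len(genes), len(samples))) < presence_p[:, None]

    depth_mult = np.exp(rng.normal(0.0, 0.1, size=len(samples)))
    rows = []
    for gi, g in enumerate(genes):
        for si, s in enumerate(samples):
            lam = config.coverage_depth * depth_mult[si]
            p_cov = _p_ge2(lam)
            if not truth[gi, si]:
                p_cov *= config.background_cov_fraction
            for ei, exon in enumerate(g.exons):
                elen = len(exon)
                rows.append((s, g.gene_id, ei,
                             int(rng.binomial(elen, p_cov)), elen))
    coverage = pd.DataFrame(rows, columns=["sample", "gene", "exon_index",
                                           "bases_ge_min_depth",
                                           "exon_length"])
    truth_matrix = PavMatrix([g.gene_id for g in genes], samples, truth)
    return coverage, truth_matrix, genes


# ---------------------------------------------------------------------------
# F2 phenotypes
# ---------------------------------------------------------------------------

def simulate_f2(config: SimulationConfig, rng=None):
    """F2 phenotypes with a marker of known variance fraction.

    y = mu + s*sex + a*g + e with g ~ (1/4, 1/2, 1/4) on {0,1,2}; the
    additive effect and residual variance are scaled so the marker explains
    fraction ``v`` and sex ``sex_var`` of Var(y) = 1 in expectation.

    Returns (phenotype frame with columns sample/sex/weight, marker dosage
    array, truth dict).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    f2 = config.f2
    sex = rng.integers(0, 2, size=f2.n)
    g = rng.choice([0, 1, 2], size=f2.n, p=[0.25, 0.5, 0.25])
    a = np.sqrt(2.0 * f2.v)          # Var(g) = 1/2 in an F2
    s = 2.0 * np.sqrt(f2.sex_var)    # Var(sex) = 1/4 with balanced sexes
    resid_sd = np.sqrt(1.0 - f2.v - f2.sex_var)
    y = f2.mean + s * sex + a * g + rng.normal(0.0, resid_sd, size=f2.n)
    pheno = pd.DataFrame({
        "sample": [f"f2_{i:04d}" for i in range(1, f2.n + 1)],
        "sex": sex.astype(int),
        "weight": y,
    })
    truth = {"v": f2.v, "additive_effect": float(a), "sex_effect": float(s)}
    return pheno, g.astype(int), truth


# ---------------------------------------------------------------------------
# neutral window haplotypes
# ---------------------------------------------------------------------------

def simulate_window_haplotypes(n_haplotypes: int, n_sites: int,
                               window_length: int, rng):
    """Segregating sites with a neutral site-frequency spectrum.

    Derived-allele counts i in 1..n-1 are drawn with probability
    proportional to 1/i; positions are uniform and distinct within the
    window. Returns (positions, matrix of shape (sites, haplotypes)).
    """
    if n_haplotypes < 4:
        raise ValueError("need >= 4 haplotypes")
    if n_sites > window_length:
        raise ValueError("more sites than positions in the window")
    if n_sites == 0:
        return np.array([], dtype=int), np.zeros((0, n_haplotypes), dtype=np.int8)
    i = np.arange(1, n_haplotypes)
    p = (1.0 / i) / np.sum(1.0 / i)
    counts = rng.choice(i, size=n_sites, p=p)
    positions = np.sort(rng.choice(window_length, size=n_sites, replace=False))
    mat = np.zeros((n_sites, n_haplotypes), dtype=np.int8)
    for row, c in enumerate(counts):
        carriers = rng.choice(n_haplotypes, size=c, replace=False)
        mat[row, carriers] = 1
    return positions, mat


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    config: SimulationConfig
    sv_matrix: SvGenotypeMatrix
    metadata: list[SampleMetadata]
    tes: list[TeInterval]
    genes: list[GeneModel]
    coverage: pd.DataFrame
    pav_truth: PavMatrix
    ltr_seqs: dict[str, str]
    phenotypes: pd.DataFrame
    marker: np.ndarray
    truth: dict


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate every synthetic input from one seed."""
    rngs = _streams(config.seed)
    tes, records, intact_ids = simulate_te_sv_landscape(config,
                                                        rngs["landscape"])
    matrix, metadata, gt_truth = simulate_cohort_genotypes(
        config, rngs["genotypes"], records=records)
    ltr_seqs, ltr_truth = simulate_ltr_pairs(config, rngs["ltr"])
    coverage, pav_truth, genes = simulate_pav_coverage(config,
                                                       rngs["coverage"])
    pheno, marker, f2_truth = simulate_f2(config, rngs["f2"])
    truth = {
        "planted_svs": gt_truth["planted"],
        "intact_derived_ids": intact_ids,
        "ltr_true_K": ltr_truth,
        "f2": f2_truth,
    }
    return SimulatedCohort(config, matrix, metadata, tes, genes, coverage,
                           pav_truth, ltr_seqs, pheno, marker, truth)


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write the cohort as standard files plus a truth sidecar."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_sv_vcf(cohort.sv_matrix, out / "svs.vcf")
    write_te_bed(cohort.tes, out / "tes.bed")
    write_gene_models(cohort.genes, out / "genes.gff3")
    cohort.coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)
    write_fasta(cohort.ltr_seqs, out / "ltr_pairs.fasta")
    pheno = cohort.phenotypes.copy()
    pheno["marker"] = cohort.marker
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False,
                 float_format="%.6f")
    pd.DataFrame({"sample": [m.sample for m in cohort.metadata],
                  "group": [m.group for m in cohort.metadata]}).to_csv(
        out / "groups.tsv", sep="\t", index=False)
    cohort.config.layout.write_tsv(out / "layout.tsv")
    cohort.pav_truth.to_frame().to_csv(out / "pav_truth.tsv", sep="\t")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
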