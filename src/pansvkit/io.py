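"""Readers and writers for the standard formats the pipeline touches.

Internally everything is 0-based half-open (:mod:`pansvkit.regions`); this
module is the only place where VCF/GFF3 1-based coordinates are converted.
Downstream modules consume the in-memory types defined here and never parse
files themselves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .regions import GenomeLayout, Interval, merge_ranges

log = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel for uncalled genotypes

SV_TYPES = ("DEL", "INS", "INV", "DUP")
MIN_SV_LEN = 50  # SVs are defined as events of more than 50 bp


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SvRecord:
    """One structural-variant locus.

    For insertions the reference footprint is a single anchor base
    (``interval`` has length 1) and ``svlen`` carries the inserted length.
    """

    id: str
    interval: Interval
    svtype: str
    svlen: int

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}")
        if self.svlen < MIN_SV_LEN:
            raise ValueError(f"{self.id}: svlen {self.svlen} < {MIN_SV_LEN}")
        if self.svtype == "INS" and len(self.interval) != 1:
            raise ValueError(f"{self.id}: INS must have a 1 bp anchor interval")


@dataclass
class SvGenotypeMatrix:
    """SV loci with per-sample diploid dosages.

    ``dosages`` has shape (n_samples, n_records) with values in {0, 1, 2}
    or :data:`MISSING`.
    """

    records: list[SvRecord]
    samples: list[str]
    dosages: np.ndarray
    layout: GenomeLayout | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.records)):
            raise ValueError("dosage matrix shape does not match samples x records")
        ok = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2} or missing")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_records(self, keep: np.ndarray) -> "SvGenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return SvGenotypeMatrix(
            records=[self.records[i] for i in idx],
            samples=list(self.samples),
            dosages=self.dosages[:, idx].copy(),
            layout=self.layout,
        )

    def sample_index(self, names) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[n] for n in names], dtype=int)


@dataclass(frozen=True)
class GeneModel:
    """A gene as a strand-aware set of merged exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: gene strand must be + or -")
        if any(e.chrom != self.chrom for e in self.exons):
            raise ValueError(f"{self.gene_id}: exons on multiple chromosomes")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")

    @staticmethod
    def from_raw_exons(gene_id, chrom, strand, exons) -> "GeneModel":
        """Build a model with exons merged into non-overlapping intervals."""
        merged = merge_ranges([(e.start, e.end) for e in exons])
        return GeneModel(
            gene_id,
            chrom,
            strand,
            tuple(Interval(chrom, s, e, strand, gene_id) for s, e in merged),
        )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """Strand-aware transcription start (0-based position)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class SampleMetadata:
    sample: str
    group: str
    sex: int | None = None
    traits: tuple = ()

    def trait(self, name):
        return dict(self.traits).get(name)


@dataclass(frozen=True)
class TeInterval:
    """A transposable-element span with class label and intact structure."""

    interval: Interval
    te_class: str
    intact: bool = False
    ltr5: Interval | None = None
    ltr3: Interval | None = None

    def __post_init__(self):
        for sub in (self.ltr5, self.ltr3):
            if sub is not None and not self.interval.contains(sub):
                raise ValueError("LTR sub-interval outside the parent element")
        if self.ltr5 is not None and self.ltr3 is not None:
            if self.ltr5.overlap_bp(self.ltr3) > 0:
                raise ValueError("5' and 3' LTR sub-intervals overlap")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_sv_vcf(path) -> SvGenotypeMatrix:
    """Read a structural-variant VCF into an :class:`SvGenotypeMatrix`.

    POS/END are converted to 0-based half-open; ``./.`` genotypes become
    missing; phased and unphased calls are treated identically by allele
    count. Records without SVTYPE and multi-allelic records are rejected
    with a warning.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    names, lengths = [], []
    for contig in vf.header.contigs.values():
        names.append(contig.name)
        lengths.append(contig.length or 1)
    layout = GenomeLayout(tuple(names), tuple(lengths)) if names else None

    records: list[SvRecord] = []
    dosage_cols: list[np.ndarray] = []
    for rec in vf:
        svtype = rec.info.get("SVTYPE")
        if svtype is None:
            log.warning("record %s at %s:%s has no SVTYPE; skipped",
                        rec.id, rec.chrom, rec.pos)
            continue
        if rec.alts is None or len(rec.alts) != 1:
            log.warning("record %s at %s:%s is not biallelic; skipped",
                        rec.id, rec.chrom, rec.pos)
            continue
        svlen = rec.info.get("SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        if svtype == "INS":
            interval = Interval(rec.chrom, rec.start, rec.start + 1)
            if svlen is None:
                raise ValueError(f"INS record {rec.id} lacks SVLEN")
            svlen = abs(int(svlen))
        else:
            # htslib recomputes the stop from SVLEN under padding-base
            # semantics; we take POS as the first affected base, so derive
            # the footprint from SVLEN directly when it is present.
            if svlen is not None:
                svlen = abs(int(svlen))
                end = rec.start + svlen
            else:
                end = rec.stop
                svlen = end - rec.start
            interval = Interval(rec.chrom, rec.start, end)
        records.append(SvRecord(rec.id or f"{rec.chrom}_{rec.pos}",
                                interval, svtype, svlen))
        col = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or all(a is None for a in gt):
                col[i] = MISSING
                continue
            if len(gt) != 2 or any(a not in (0, 1) for a in gt):
                raise ValueError(
                    f"malformed GT {gt} for sample {s} in record "
                    f"{rec.id} at {rec.chrom}:{rec.pos}"
                )
            col[i] = sum(1 for a in gt if a > 0)
        dosage_cols.append(col)
    vf.close()

    dosages = (np.column_stack(dosage_cols) if dosage_cols
               else np.zeros((len(samples), 0), dtype=np.int8))
    return SvGenotypeMatrix(records, samples, dosages, layout)


def write_sv_vcf(matrix: SvGenotypeMatrix, path) -> None:
    """Write a matrix as VCF 4.2 with SVTYPE/SVLEN/END INFO and GT."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,'
                    'Description="Type of structural variant">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,'
                    'Description="Length of structural variant">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,'
                    'Description="End position of the variant">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,'
                    'Description="Genotype">')
    if matrix.layout is not None:
        for name, length in zip(matrix.layout.names, matrix.layout.lengths):
            header.contigs.add(name, length=length)
    else:
        for chrom in dict.fromkeys(r.interval.chrom for r in matrix.records):
            header.contigs.add(chrom)
    for s in matrix.samples:
        header.add_sample(s)

    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, r in enumerate(matrix.records):
            rec = out.new_record(
                contig=r.interval.chrom,
                start=r.interval.start,
                stop=r.interval.end,
                alleles=("N", f"<{r.svtype}>"),
                id=r.id,
            )
            rec.info["SVTYPE"] = r.svtype
            if r.svtype == "INS":
                # SVLEN only where END cannot carry the length: htslib
                # forces END = POS + SVLEN on symbolic footprint records,
                # which clashes with POS-as-first-affected-base output.
                rec.info["SVLEN"] = int(r.svlen)
            for i, s in enumerate(matrix.samples):
                rec.samples[s]["GT"] = gt_of[int(matrix.dosages[i, j])]
            out.write(rec)


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------

def read_intervals(path, format: str = "BED"):
    """Read genomic features.

    BED (0-based half-open) yields ``list[Interval]``; GFF3 (1-based
    inclusive) yields ``list[GeneModel]`` with exons grouped per gene and
    merged.
    """
    fmt = format.upper()
    if fmt == "BED":
        return _read_bed(path)
    if fmt == "GFF3":
        return read_gene_models(path)
    raise ValueError(f"unsupported format {format!r}")


def _read_bed(path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            label = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            out.append(Interval(chrom, start, end, strand, label))
    return out


def read_gene_models(path) -> list[GeneModel]:
    """Parse gene/exon features from GFF3 into merged-exon gene models."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                            merge_strategy="create_unique", force=True)
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        for ex in db.children(g, featuretype="exon"):
            if ex.start > ex.end:
                raise ValueError(f"{path}: exon with start > end in {g.id}")
            exons.append(Interval(ex.seqid, ex.start - 1, ex.end))
        if not exons:
            exons = [Interval(g.seqid, g.start - 1, g.end)]
        genes.append(GeneModel.from_raw_exons(g.id, g.seqid, g.strand, exons))
    return genes


def write_gene_models(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tpansvkit\tgene\t{g.start + 1}\t{g.end}\t."
                     f"\t{g.strand}\t.\tID={g.gene_id}\n")
            for i, e in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tpansvkit\texon\t{e.start + 1}\t{e.end}\t."
                         f"\t{g.strand}\t.\tID={g.gene_id}.exon{i};"
                         f"Parent={g.gene_id}\n")


# TE track: BED6 + intact flag + optional LTR sub-spans (all 0-based half-open)
TE_BED_COLUMNS = ("chrom", "start", "end", "te_class", "score", "strand",
                  "intact", "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end")


def read_te_bed(path) -> list[TeInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: need >= 4 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            iv = Interval(chrom, start, end,
                          f[5] if len(f) > 5 and f[5] in "+-" else ".",
                          f[3])
            intact = len(f) > 6 and f[6] == "1"
            ltr5 = ltr3 = None
            if len(f) > 10 and f[7] != ".":
                ltr5 = Interval(chrom, int(f[7]), int(f[8]))
                ltr3 = Interval(chrom, int(f[9]), int(f[10]))
            out.append(TeInterval(iv, f[3], intact, ltr5, ltr3))
    return out


def write_te_bed(tes, path) -> None:
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            ltr = (f"{te.ltr5.start}\t{te.ltr5.end}\t{te.ltr3.start}\t{te.ltr3.end}"
                   if te.ltr5 is not None and te.ltr3 is not None
                   else ".\t.\t.\t.")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.te_class}\t0\t"
                     f"{iv.strand if iv.strand in '+-' else '.'}\t"
                     f"{1 if te.intact else 0}\t{ltr}\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

TABLE_SCHEMAS = {
    "coverage": ("sample", "gene", "exon_index", "bases_ge_min_depth",
                 "exon_length"),
    "phenotype": ("sample", "sex"),
    "groups": ("sample", "group"),
}

_NUMERIC = {"exon_index", "bases_ge_min_depth", "exon_length", "sex"}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a TSV with one of the declared schemas, validating columns."""
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, sep="\t")
    for col in TABLE_SCHEMAS[schema]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in df.columns:
        if col in _NUMERIC:
            df[col] = pd.to_numeric(df[col])
    if schema == "phenotype":
        # every non-key column is a numeric trait
        for col in df.columns:
            if col not in ("sample", "sex"):
                df[col] = pd.to_numeric(df[col])
    if schema == "coverage":
        bad = df["bases_ge_min_depth"] > df["exon_length"]
        if bad.any():
            raise ValueError(
                f"{path}: bases_ge_min_depth exceeds exon_length in "
                f"{int(bad.sum())} rows"
            )
    return df


def read_sample_metadata(groups_path, phenotype_path=None) -> list[SampleMetadata]:
    groups = read_table(groups_path, "groups")
    pheno = (read_table(phenotype_path, "phenotype")
             if phenotype_path is not None else None)
    out = []
    for _, row in groups.iterrows():
        sex, traits = None, ()
        if pheno is not None and (row["sample"] == pheno["sample"]).any():
            prow = pheno[pheno["sample"] == row["sample"]].iloc[0]
            sex = int(prow["sex"])
            traits = tuple((c, float(prow[c])) for c in pheno.columns
                           if c not in ("sample", "sex"))
        out.append(SampleMetadata(str(row["sample"]), str(row["group"]),
                                  sex, traits))
    return out


def groups_of(metadata) -> dict[str, list[str]]:
    """Group label -> ordered sample-id list."""
    out: dict[str, list[str]] = {}
    for m in metadata:
        out.setdefault(m.group, []).append(m.sample)
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA -> {name: upper-cased sequence}; duplicate names are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"{path}: {rec.id} has non-ACGTN characters")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
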