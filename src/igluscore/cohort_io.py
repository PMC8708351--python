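"""Cohort input/output and gene-region bookkeeping.

Reads diploid genotypes (VCF 4.x with GT fields) together with a
case/control phenotype table into a :class:`GenotypeMatrix`, writes the
matrix back to VCF, classifies variants into gene regions (promoter,
UTRs, exon, intron), tabulates per-kilobase variability, and applies
the 50-bp rule for nonsense-mediated decay.

Internal coordinates are 0-based half-open; VCF positions (1-based)
are converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

MISSING = -1  # dosage sentinel for uncalled genotypes

#: precedence when a position falls in several region classes of a gene
REGION_PRECEDENCE = ("five_prime_utr", "three_prime_utr", "exon", "intron", "promoter")

REGION_CLASSES = frozenset(REGION_PRECEDENCE)

_X_NAMES = frozenset({"X", "chrX", "x", "chrx"})


class SampleMismatchError(ValueError):
    """A VCF sample is absent from the phenotype table."""


class MalformedGenotypeError(ValueError):
    """A GT field could not be decoded."""


@dataclass
class VariantRecord:
    """One biallelic variant; multi-allelic sites must be split upstream."""

    chrom: str
    pos: int  # 1-based, as printed in VCF
    id: str | None
    ref: str
    alt: str
    dosages: np.ndarray  # per-sample alt-allele count, MISSING where uncalled

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if "," in self.alt:
            raise ValueError(f"multi-allelic record at {self.chrom}:{self.pos}; split first")

    @property
    def is_x(self) -> bool:
        return self.chrom in _X_NAMES


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with phenotype labels.

    ``dosages`` is variants x samples, int8, with :data:`MISSING` (-1)
    marking uncalled genotypes.  ``phenotype`` holds ``"case"`` or
    ``"control"`` per sample; ``sex`` (optional) holds ``"M"``/``"F"``.
    """

    samples: list[str]
    phenotype: np.ndarray
    variants: pd.DataFrame  # columns chrom, pos, id, ref, alt
    dosages: np.ndarray
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if len(self.phenotype) != len(self.samples):
            raise ValueError("phenotype length does not match sample count")
        bad = set(self.phenotype) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype == "case"

    @property
    def control_mask(self) -> np.ndarray:
        return self.phenotype == "control"

    @property
    def is_x(self) -> np.ndarray:
        """Boolean per-variant X-chromosome indicator."""
        return self.variants["chrom"].isin(_X_NAMES).to_numpy()

    def allele_frequencies(self) -> pd.DataFrame:
        """Per-variant alt-allele frequency in cases and controls.

        Missing genotypes are dropped site-wise from the denominator.
        Groups with no called genotype at a site yield NaN.
        """
        out = {}
        for label, mask in (("case", self.case_mask), ("control", self.control_mask)):
            d = self.dosages[:, mask].astype(float)
            d[d == MISSING] = np.nan
            n_called = np.sum(~np.isnan(d), axis=1)
            with np.errstate(invalid="ignore"):
                out[f"{label}_freq"] = np.nansum(d, axis=1) / (2 * n_called)
            out[f"{label}_n_called"] = n_called
        return pd.DataFrame(out, index=self.variants.index)

    def genotype_counts(self, variant_idx: int, group: str) -> tuple[int, int, int]:
        """(n_homref, n_het, n_homalt) among called genotypes of a group."""
        mask = self.case_mask if group == "case" else self.control_mask
        d = self.dosages[variant_idx, mask]
        return int(np.sum(d == 0)), int(np.sum(d == 1)), int(np.sum(d == 2))

    def record(self, i: int) -> VariantRecord:
        v = self.variants.iloc[i]
        return VariantRecord(v["chrom"], int(v["pos"]), v["id"], v["ref"], v["alt"],
                             self.dosages[i].copy())


@dataclass(frozen=True)
class RegionAnnotation:
    """One gene-region interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    gene: str
    region_class: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end}) for {self.gene}")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read the sample table: TSV with sample_id, group and optional sex."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in tab.columns or "group" not in tab.columns:
        raise ValueError(f"{path}: expected columns sample_id and group")
    bad = set(tab["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"{path}: group labels must be case/control, got {sorted(bad)}")
    return tab.set_index("sample_id")


def _decode_genotype(gt: list, alt_index: int) -> int:
    """Alt-allele dosage of one sample for alt number ``alt_index`` (1-based)."""
    alleles = gt[:-1]  # cyvcf2 appends the phased flag
    if any(a < 0 for a in alleles):
        return MISSING
    return sum(1 for a in alleles if a == alt_index)


def read_vcf_genotypes(vcf_path: str, phenotype_table_path: str) -> GenotypeMatrix:
    """Load a VCF and phenotype table into a :class:`GenotypeMatrix`.

    Multi-allelic records are split into one biallelic record per alt
    allele (alleles other than the one under consideration count
    toward neither dosage class and are treated as reference).
    ``./.`` genotypes map to missing; sites are retained.
    """
    pheno = read_phenotypes(phenotype_table_path)
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in pheno.index]
    if missing_samples:
        raise SampleMismatchError(
            f"samples in VCF but not in phenotype table: {', '.join(missing_samples)}"
        )

    rows, dosage_rows = [], []
    for line_no, var in enumerate(vcf, start=1):
        gts = var.genotypes
        if gts is None or len(gts) != len(samples):
            raise MalformedGenotypeError(f"{vcf_path}: bad GT at record {line_no}")
        for alt_index, alt in enumerate(var.ALT, start=1):
            try:
                dos = [_decode_genotype(g, alt_index) for g in gts]
            except TypeError as exc:
                raise MalformedGenotypeError(
                    f"{vcf_path}: undecodable GT at record {line_no}"
                ) from exc
            rows.append((var.CHROM, var.POS, var.ID, var.REF, alt))
            dosage_rows.append(dos)
    vcf.close()

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    dosages = (np.array(dosage_rows, dtype=np.int8)
               if dosage_rows else np.zeros((0, len(samples)), dtype=np.int8))
    phenotype = pheno.loc[samples, "group"].to_numpy()
    sex = pheno.loc[samples, "sex"].to_numpy() if "sex" in pheno.columns else None
    return GenotypeMatrix(samples, phenotype, variants, dosages, sex=sex)


_DOSAGE_TO_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with unphased GT fields."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    chrom_order = list(dict.fromkeys(matrix.variants["chrom"]))
    for chrom in chrom_order:
        header.contigs.add(chrom)
    for s in matrix.samples:
        header.add_sample(s)

    with pysam.VariantFile(path, "w", header=header) as out:
        for i in range(matrix.n_variants):
            v = matrix.variants.iloc[i]
            rec = out.new_record(
                contig=v["chrom"],
                start=int(v["pos"]) - 1,
                alleles=(v["ref"], v["alt"]),
                id=v["id"] if pd.notna(v["id"]) and v["id"] else None,
            )
            for j, s in enumerate(matrix.samples):
                d = int(matrix.dosages[i, j])
                alleles = (None, None) if d == MISSING else _DOSAGE_TO_GT[d]
                rec.samples[s]["GT"] = alleles
                rec.samples[s].phased = False
            out.write(rec)


def derive_promoter(tss: int, strand: str, length: int = 1500) -> tuple[int, int]:
    """Promoter window: ``length`` bases immediately upstream of the TSS.

    ``tss`` is 1-based; the returned interval is 0-based half-open.
    Windows running off the start of the chromosome are truncated at 0
    with a warning.
    """
    if tss < 1:
        raise ValueError("TSS position must be >= 1")
    if strand == "+":
        start, end = tss - 1 - length, tss - 1
    elif strand == "-":
        start, end = tss, tss + length
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if start < 0:
        warnings.warn(f"promoter window truncated at chromosome start (TSS {tss})",
                      stacklevel=2)
        start = 0
    return start, end


def classify_variant(record: VariantRecord, annotations: list[RegionAnnotation],
                     gene: str | None = None) -> str:
    """Region class of a variant position, or ``"intergenic"``.

    Classification is per-gene: when ``gene`` is given only that
    gene's intervals are consulted.  Overlaps resolve by precedence
    UTR > exon > intron > promoter (UTRs are tabulated separately from
    the exons that contain them).
    """
    pos0 = record.pos - 1
    hits = [a.region_class for a in annotations
            if a.chrom == record.chrom and a.start <= pos0 < a.end
            and (gene is None or a.gene == gene)]
    if not hits:
        return "intergenic"
    return min(hits, key=REGION_PRECEDENCE.index)


def variability_table(matrix: GenotypeMatrix, annotations: list[RegionAnnotation],
                      group: str) -> pd.DataFrame:
    """Per-gene, per-region variant counts and rates per 1000 bp.

    A variant counts for a group when at least one member of that
    group carries the alternate allele.  The rate is
    ``1000 * count / total region length``; genes lacking a region
    class get a null rate there.
    """
    if group not in ("case", "control"):
        raise ValueError("group must be 'case' or 'control'")
    gmask = matrix.case_mask if group == "case" else matrix.control_mask
    genes = sorted({a.gene for a in annotations})
    lengths: dict[tuple[str, str], int] = {}
    for a in annotations:
        lengths[(a.gene, a.region_class)] = lengths.get((a.gene, a.region_class), 0) + a.length

    counts = {(g, rc): 0 for g in genes for rc in REGION_PRECEDENCE}
    for i in range(matrix.n_variants):
        d = matrix.dosages[i, gmask]
        if not np.any(d > 0):
            continue
        rec = matrix.record(i)
        for g in genes:
            cls = classify_variant(rec, annotations, gene=g)
            if cls != "intergenic":
                counts[(g, cls)] += 1

    rows = []
    for g in genes:
        for rc in REGION_PRECEDENCE:
            length = lengths.get((g, rc))
            n = counts[(g, rc)]
            rate = 1000.0 * n / length if length else None
            rows.append({"gene": g, "region_class": rc, "group": group,
                         "n_variants": n, "length_bp": length, "per_kb": rate})
    return pd.DataFrame(rows)


def nmd_predict(stop_codon_end: int, exon_junction_positions: list[int]) -> str:
    """Apply the 50-bp rule for nonsense-mediated decay.

    A premature stop escapes NMD when it lies in the last exon or no
    more than 50 nt upstream of the final exon-exon junction;
    otherwise the transcript is targeted for decay.  Coordinates are
    transcript-relative; single-exon transcripts always escape.
    """
    if not exon_junction_positions:
        return "escaping"
    last_junction = exon_junction_positions[-1]
    if stop_codon_end >= last_junction:  # in the last exon
        return "escaping"
    return "escaping" if last_junction - stop_codon_end <= 50 else "targeted"


def read_bed_annotations(path: str) -> list[RegionAnnotation]:
    """Read BED6-like TSV: chrom, start, end, gene, region_class, strand."""
    tab = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene", "region_class", "strand"],
                      dtype={"chrom": str})
    return [RegionAnnotation(r.chrom, int(r.start), int(r.end), r.gene,
                             r.region_class, r.strand)
            for r in tab.itertuples()]


def write_bed_annotations(annotations: list[RegionAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.gene}\t{a.region_class}\t{a.strand}\n")
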