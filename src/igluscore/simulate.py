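"""Synthetic case/control cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
small diploid cohort (63 cases, 32 controls by default) carrying
autosomal risk-haplotype blocks at specified case/control frequencies
under Hardy-Weinberg equilibrium, a background of non-differentiated
variants, an optional X-linked block (hemizygous males), optional
within-block linkage decay and uniformly random missing genotypes.

Haplotype blocks are sampled at the block level: a latent block dosage
~ Binomial(2, p_group) per individual, copied to every member SNP when
``within_block_r2 = 1``.  With partial linkage a member keeps the
block dosage with probability sqrt(r2) and is otherwise redrawn
independently from Binomial(2, p_group), which makes the expected
dosage correlation sqrt(r2) and hence the squared correlation r2.
Blocks are mutually independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_io import (MISSING, GenotypeMatrix, RegionAnnotation,
                        write_bed_annotations, write_vcf)


@dataclass(frozen=True)
class BlockSpec:
    """Specification of one risk-haplotype block (or a single SNP)."""

    name: str
    gene: str
    chrom: str
    member_positions: tuple[int, ...]
    risk_allele_freq_case: float
    risk_allele_freq_control: float
    within_block_r2: float = 1.0
    member_ids: tuple[str, ...] | None = None
    member_alleles: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.member_positions:
            raise ValueError(f"{self.name}: block needs at least one member position")
        for p in (self.risk_allele_freq_case, self.risk_allele_freq_control):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: frequency {p} outside [0, 1]")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ValueError(f"{self.name}: within_block_r2 outside [0, 1]")


# Eight autosomal risk-haplotype blocks of the published iGluR study
# cohort (genes, hg38 member positions, rs ids, risk alleles and
# case/control risk-allele frequencies), used as the generator default.
TABLE4_BLOCKS: tuple[BlockSpec, ...] = (
    BlockSpec("Hap1", "GRIK3", "chr1",
              (37014543, 37017453, 37023779, 37028109, 37031920, 37035122),
              0.381, 0.188,
              member_ids=("rs3753776", "rs2359647", "rs6686296", "rs59729868",
                          "rs3845491", "rs2134846"),
              member_alleles=("T", "T", "G", "A", "T", "A")),
    BlockSpec("Hap2", "GRIA1", "chr5",
              (153527505, 153532297, 153534826),
              0.183, 0.047,
              member_ids=("rs566577", "rs1493395", "rs1908100"),
              member_alleles=("C", "G", "T")),
    BlockSpec("Hap3", "GRIK2", "chr6",
              (101460819, 101462357, 101467933),
              0.548, 0.344,
              member_ids=("rs2518230", "rs2245037", "rs2579937"),
              member_alleles=("T", "G", "A")),
    BlockSpec("Hap4", "GRIN3A", "chr9",
              (101711604, 101714448, 101715378, 101716352, 101717714, 101720595),
              0.079, 0.000,
              member_ids=("rs2485530", "rs2506363", "rs2210991", "rs2506364",
                          "rs2065965", "rs7849059"),
              member_alleles=("C", "C", "C", "A", "G", "A")),
    BlockSpec("Hap5", "GRIK4", "chr11",
              (120746795, 120747370),
              0.683, 0.500,
              member_ids=("rs1945010", "rs1939673"),
              member_alleles=("C", "T")),
    BlockSpec("Hap6", "GRIK4", "chr11",
              (120927187, 120927920, 120930476),
              0.222, 0.047,
              member_ids=("rs5795249", "rs1893816", "rs2186620"),
              member_alleles=("T", "T", "C")),
    BlockSpec("Hap7", "GRIN2B", "chr12",
              (13728086, 13741902, 13744486),
              0.317, 0.156,
              member_ids=("rs2284412", "rs10772710", "rs2268121"),
              member_alleles=("T", "A", "C")),
    BlockSpec("Hap8", "GRIK1", "chr21",
              (29925689, 29926886, 29927152, 29929318, 29930154, 29930365,
               29931426, 29931851, 29933351, 29933357, 29933999, 29934461,
               29934499, 29934740, 29934751, 29936109, 29937434, 29937912,
               29938441, 29938848, 29938853, 29938854),
              0.730, 0.563,
              member_ids=("rs2832486", "rs2832488", "rs2832489", "rs2832490",
                          "rs2255821", "rs767253", "rs2300333", "rs2832492",
                          "rs9982938", "rs9982699", "rs3831792", "rs2243533",
                          "rs2243535", "rs2243435", "rs2243436", "rs2832494",
                          "rs2832495", "rs2409355", "rs2832496", "rs66799775",
                          "rs75584618", "rs77191337"),
              member_alleles=("T", "T", "A", "G", "A", "C", "G", "C", "T", "C",
                              "A", "T", "T", "T", "C", "C", "C", "C", "T", "G",
                              "T", "T")),
)

#: the four standalone case-enriched SNPs accompanying the blocks
STANDALONE_SNPS: tuple[BlockSpec, ...] = (
    BlockSpec("rs2160519", "GRIN2B", "chr12", (13634912,), 0.087, 0.000,
              member_ids=("rs2160519",), member_alleles=("C",)),
    BlockSpec("rs2110984", "GRIN2B", "chr12", (13722646,), 0.825, 0.641,
              member_ids=("rs2110984",), member_alleles=("T",)),
    BlockSpec("rs10845851", "GRIN2B", "chr12", (13871835,), 0.095, 0.000,
              member_ids=("rs10845851",), member_alleles=("G",)),
    BlockSpec("rs56125279", "GRIN2D", "chr19", (48437650,), 0.190, 0.063,
              member_ids=("rs56125279",), member_alleles=("G",)),
)

# X-linked block (GRIA3 intron 12; nine sites spanning
# chrX:123,436,446-123,444,102).  Group risk frequencies are a
# modelling choice producing divergence of the observed order.
X_BLOCK = BlockSpec("HapX", "GRIA3", "chrX",
                    tuple(np.linspace(123436446, 123444102, 9, dtype=int).tolist()),
                    0.30, 0.12)

#: fraction of males per group (from the study's demographics)
MALE_FRACTION = {"case": 39 / 63, "control": 15 / 32}


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions under which a cohort is simulated."""

    n_cases: int = 63
    n_controls: int = 32
    blocks: tuple[BlockSpec, ...] = TABLE4_BLOCKS + STANDALONE_SNPS
    n_background_variants: int = 200
    background_freq_beta: tuple[float, float] = (0.8, 3.0)
    missing_rate: float = 0.0
    include_x_block: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate outside [0, 1)")
        if self.n_background_variants < 0:
            raise ValueError("negative background variant count")


@dataclass
class SyntheticCohort:
    """Generator output: the matrix plus the latent truth behind it."""

    matrix: GenotypeMatrix
    latent_block_dosage: dict[str, np.ndarray]  # block name -> per-sample dosage
    annotations: list[RegionAnnotation]
    config: SyntheticConfig


def _sample_block(rng: np.random.Generator, spec: BlockSpec,
                  group_p: np.ndarray, sex: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Latent block dosage and member dosage matrix for one block."""
    n = len(group_p)
    if spec.chrom in ("chrX", "X"):
        # hemizygous males carry 0 or 2 copies in dosage coding
        male = sex == "M"
        latent = rng.binomial(2, group_p)
        latent[male] = 2 * rng.binomial(1, group_p[male])
    else:
        latent = rng.binomial(2, group_p)
    k = len(spec.member_positions)
    members = np.tile(latent, (k, 1))
    if spec.within_block_r2 < 1.0:
        keep_p = math.sqrt(spec.within_block_r2)
        for j in range(k):
            redraw = rng.random(n) >= keep_p
            if np.any(redraw):
                members[j, redraw] = rng.binomial(2, group_p[redraw])
    return latent, members


_ALLELE_PAIR = {"A": "G", "C": "T", "G": "A", "T": "C"}


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Simulate a diploid case/control cohort under the configuration.

    Per block, each individual's latent dosage is Binomial(2, p) with p
    the group risk-allele frequency (HWE); background variants share
    one Beta-distributed frequency across both groups.  A fixed seed
    yields identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    samples = ([f"case{i + 1:03d}" for i in range(config.n_cases)]
               + [f"ctrl{i + 1:03d}" for i in range(config.n_controls)])
    phenotype = np.array(["case"] * config.n_cases + ["control"] * config.n_controls,
                         dtype=object)
    sex = np.empty(n, dtype=object)
    n_male_case = round(MALE_FRACTION["case"] * config.n_cases)
    n_male_ctrl = round(MALE_FRACTION["control"] * config.n_controls)
    sex[:config.n_cases] = ["M"] * n_male_case + ["F"] * (config.n_cases - n_male_case)
    sex[config.n_cases:] = ["M"] * n_male_ctrl + ["F"] * (config.n_controls - n_male_ctrl)

    blocks = list(config.blocks)
    if config.include_x_block:
        blocks.append(X_BLOCK)

    rows: list[tuple] = []
    dosage_rows: list[np.ndarray] = []
    latent: dict[str, np.ndarray] = {}
    for spec in blocks:
        group_p = np.where(phenotype == "case",
                           spec.risk_allele_freq_case, spec.risk_allele_freq_control)
        lat, members = _sample_block(rng, spec, group_p, sex)
        latent[spec.name] = lat
        for j, pos in enumerate(spec.member_positions):
            alt = spec.member_alleles[j] if spec.member_alleles else "T"
            ref = _ALLELE_PAIR[alt]
            vid = spec.member_ids[j] if spec.member_ids else f"{spec.name}_snp{j + 1}"
            rows.append((spec.chrom, pos, vid, ref, alt))
            dosage_rows.append(members[j])

    if config.n_background_variants:
        a, b = config.background_freq_beta
        freqs = rng.beta(a, b, size=config.n_background_variants)
        bg = rng.binomial(2, freqs[:, None], size=(config.n_background_variants, n))
        for i in range(config.n_background_variants):
            rows.append(("chr2", 1_000_000 + 100 * i, f"bg{i + 1:05d}", "A", "G"))
            dosage_rows.append(bg[i])

    dosages = np.array(dosage_rows, dtype=np.int8)
    if config.missing_rate > 0.0:
        dosages = dosages.copy()
        dosages[rng.random(dosages.shape) < config.missing_rate] = MISSING

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    order = np.lexsort((variants["pos"].to_numpy(),
                        variants["chrom"].to_numpy().astype(str)))
    variants = variants.iloc[order].reset_index(drop=True)
    dosages = dosages[order]

    matrix = GenotypeMatrix(samples, phenotype, variants, dosages, sex=sex)
    annotations = [
        RegionAnnotation(spec.chrom, min(spec.member_positions) - 1001,
                         max(spec.member_positions) + 1000, spec.gene, "intron", "+")
        for spec in blocks
    ]
    return SyntheticCohort(matrix=matrix, latent_block_dosage=latent,
                           annotations=annotations, config=config)


def estimate_block_frequencies(matrix: GenotypeMatrix,
                               blocks: list[BlockSpec]) -> pd.DataFrame:
    """Per-group risk-allele frequency of each block.

    The frequency is (sum of dosages) / (2 x called genotypes), pooled
    over the block's member variants; a block whose members are all
    missing in a group gets a null frequency.
    """
    key = {(c, p): i for i, (c, p) in
           enumerate(zip(matrix.variants["chrom"], matrix.variants["pos"]))}
    rows = []
    for spec in blocks:
        idxs = [key[(spec.chrom, p)] for p in spec.member_positions
                if (spec.chrom, p) in key]
        if not idxs:
            raise KeyError(f"block {spec.name}: no member variant found in matrix")
        row: dict[str, object] = {"block": spec.name, "gene": spec.gene}
        for label, mask in (("case", matrix.case_mask), ("control", matrix.control_mask)):
            d = matrix.dosages[np.ix_(idxs, np.flatnonzero(mask))].astype(float)
            d[d == MISSING] = np.nan
            n_called = np.sum(~np.isnan(d))
            row[f"{label}_freq"] = (float(np.nansum(d) / (2 * n_called))
                                    if n_called else None)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cohort: SyntheticCohort, out_prefix: str) -> dict[str, str]:
    """Write VCF, phenotype TSV and BED for a simulated cohort."""
    paths = {"vcf": f"{out_prefix}.vcf", "phenotypes": f"{out_prefix}.phenotypes.tsv",
             "bed": f"{out_prefix}.bed"}
    write_vcf(cohort.matrix, paths["vcf"])
    m = cohort.matrix
    pd.DataFrame({"sample_id": m.samples, "group": m.phenotype,
                  "sex": m.sex if m.sex is not None else ["."] * m.n_samples}
                 ).to_csv(paths["phenotypes"], sep="\t", index=False)
    write_bed_annotations(cohort.annotations, paths["bed"])
    return paths
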