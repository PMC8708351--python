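"""Per-unit association statistics and the cumulative haplotype score.

Association is allele-based by default: each block or SNP contributes
a 2x2 table of risk vs non-risk chromosome counts (2n per group),
tested with Fisher's exact test and summarized by the odds ratio.
Genotype likelihood ratios P(genotype | case) / P(genotype | control)
characterize the per-genotype evidence.  Cells that cannot be
estimated (a zero table cell for the OR, a zero control count for an
LR) are reported as ND (None), never as 0 or infinity.

The cumulative score penalizes each risk haplotype by one point for
heterozygous and two points for homozygous carriage: a sample's score
is the sum of its block dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import HaplotypeBlock
from .cohort_io import MISSING, GenotypeMatrix

GENOTYPE_LABELS = ("wt/wt", "wt/H", "H/H")


@dataclass
class AssociationRecord:
    """One association-table row for a block or standalone SNP."""

    unit: str
    gene: str | None
    case_freq: float | None
    control_freq: float | None
    fisher_p: float
    odds_ratio: float | None          # None = ND (a zero 2x2 cell)
    genotype_lr: dict[str, float | None]  # label -> LR, None = ND


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums hypergeometric probabilities no larger than that of the
    observed table.  A zero margin makes every table equally likely:
    p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def odds_ratio(table) -> float | None:
    """Cross-product odds ratio; ND (None) when any cell is zero."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t == 0).any():
        return None
    return float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))


def genotype_lr(case_genotype_counts, control_genotype_counts
                ) -> dict[str, float | None]:
    """Per-genotype likelihood ratios P(g | case) / P(g | control).

    ND (None) where the control count is zero.
    """
    case = np.asarray(case_genotype_counts, dtype=float)
    ctrl = np.asarray(control_genotype_counts, dtype=float)
    if case.shape != (3,) or ctrl.shape != (3,):
        raise ValueError("need (wt/wt, het, hom) counts per group")
    n_case, n_ctrl = case.sum(), ctrl.sum()
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("empty group")
    out: dict[str, float | None] = {}
    for label, nc, nk in zip(GENOTYPE_LABELS, case, ctrl):
        out[label] = None if nk == 0 else float((nc / n_case) / (nk / n_ctrl))
    return out


def allele_count_table(dosage: np.ndarray, case_mask: np.ndarray,
                       control_mask: np.ndarray) -> np.ndarray:
    """Risk vs non-risk chromosome counts per group from a dosage vector."""
    rows = []
    for mask in (case_mask, control_mask):
        d = dosage[mask]
        d = d[d != MISSING]
        risk = int(d.sum())
        rows.append([risk, int(2 * len(d) - risk)])
    return np.array(rows, dtype=np.int64)


def associate_block(block: HaplotypeBlock, matrix: GenotypeMatrix) -> AssociationRecord:
    """Full association row (frequencies, Fisher p, OR, genotype LRs)."""
    table = allele_count_table(block.dosage, matrix.case_mask, matrix.control_mask)
    case_chrom = table[0].sum()
    ctrl_chrom = table[1].sum()
    case_counts = [int(np.sum(block.dosage[matrix.case_mask] == g)) for g in (0, 1, 2)]
    ctrl_counts = [int(np.sum(block.dosage[matrix.control_mask] == g)) for g in (0, 1, 2)]
    return AssociationRecord(
        unit=block.name,
        gene=block.gene,
        case_freq=float(table[0, 0] / case_chrom) if case_chrom else None,
        control_freq=float(table[1, 0] / ctrl_chrom) if ctrl_chrom else None,
        fisher_p=fisher_exact_2x2(table),
        odds_ratio=odds_ratio(table),
        genotype_lr=genotype_lr(case_counts, ctrl_counts),
    )


@dataclass
class ScoreProfile:
    """Per-sample cumulative haplotype scores."""

    samples: list[str]
    group: np.ndarray                  # "case"/"control" per sample
    score: np.ndarray                  # non-negative integers
    n_blocks: int
    low_confidence: np.ndarray         # True where > half the block dosages were missing

    def by_group(self, label: str) -> np.ndarray:
        return self.score[self.group == label]


def compute_scores(blocks: list[HaplotypeBlock], matrix: GenotypeMatrix) -> ScoreProfile:
    """Sum of block dosages per sample (1 point per heterozygous, 2 per
    homozygous risk haplotype).

    Missing block dosages contribute 0; samples missing more than half
    of their block dosages are flagged low-confidence but still scored.
    """
    if not blocks:
        raise ValueError("need at least one block to score")
    d = np.stack([b.dosage for b in blocks]).astype(float)
    miss = d == MISSING
    d[miss] = 0.0
    score = d.sum(axis=0).astype(int)
    low_conf = miss.sum(axis=0) > len(blocks) / 2
    return ScoreProfile(samples=list(matrix.samples), group=matrix.phenotype.copy(),
                        score=score, n_blocks=len(blocks), low_confidence=low_conf)


def pearson_stdres(contingency) -> tuple[np.ndarray, float]:
    """Standardized Pearson residuals and the chi-squared p of a table.

    The residual of cell (i, j) is
    (O - E) / sqrt(E (1 - row_i/n) (1 - col_j/n)), asymptotically
    standard normal under independence.
    """
    obs = np.asarray(contingency, dtype=float)
    if (obs < 0).any():
        raise ValueError("negative counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, _, expected = stats.chi2_contingency(obs, correction=False)
    stdres = (obs - expected) / np.sqrt(expected * (1 - row / n) * (1 - col / n))
    return stdres, float(p)


def association_table(blocks: list[HaplotypeBlock],
                      singletons: list[HaplotypeBlock],
                      matrix: GenotypeMatrix) -> pd.DataFrame:
    """Association rows for all blocks and standalone SNPs as a frame."""
    rows = []
    for unit in list(blocks) + list(singletons):
        rec = associate_block(unit, matrix)
        rows.append({
            "unit": rec.unit, "gene": rec.gene, "n_members": unit.n_members,
            "case_freq": rec.case_freq, "control_freq": rec.control_freq,
            "fisher_p": rec.fisher_p, "odds_ratio": rec.odds_ratio,
            "lr_wtwt": rec.genotype_lr["wt/wt"],
            "lr_het": rec.genotype_lr["wt/H"],
            "lr_hom": rec.genotype_lr["H/H"],
        })
    return pd.DataFrame(rows)
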