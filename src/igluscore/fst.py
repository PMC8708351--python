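"""Weir-Cockerham fixation-index estimation and candidate selection.

The per-site estimator partitions allelic variance into components
a (among populations), b (among individuals within populations) and
c (within individuals); theta = a / (a + b + c).  Here the two
"populations" are the case and control groups of one cohort, so theta
measures case-control allelic divergence at each site.  Candidate
variants are those in the upper tail of the theta distribution
(theta >= 0.05 by default) whose alternate allele is more frequent in
cases than in controls; X-chromosome variants are screened out first
because sex-chromosome allele counts are not diploid-comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import MISSING, GenotypeMatrix

#: number of subpopulations compared (cases vs controls)
R_POPULATIONS = 2


@dataclass(frozen=True)
class FstComponents:
    """Per-site variance components and the quantities behind them."""

    a: float
    b: float
    c: float
    n_bar: float  # mean sample size over groups
    n_c: float    # squared-CV correction of sample sizes
    p_bar: float  # sample-size-weighted mean alt frequency
    s2: float     # weighted variance of group frequencies
    h_bar: float  # weighted mean observed heterozygote proportion

    @property
    def theta(self) -> float | None:
        """a / (a + b + c); None when the site is monomorphic overall."""
        denom = self.a + self.b + self.c
        if denom == 0.0:
            return None
        return self.a / denom


def wc_fst_site(case_counts: tuple[float, float, float],
                control_counts: tuple[float, float, float]) -> FstComponents:
    """Variance components for one biallelic site from genotype counts.

    Each argument is ``(n_homref, n_het, n_homalt)``; fractional counts
    are accepted (useful for expectation-based reconstructions).  Each
    group must contain at least one called genotype.
    """
    groups = (case_counts, control_counts)
    n = [sum(g) for g in groups]
    if any(ni <= 0 for ni in n):
        raise ValueError("each group needs at least one non-missing genotype")
    p = [(g[1] + 2 * g[2]) / (2 * ni) for g, ni in zip(groups, n)]
    h = [g[1] / ni for g, ni in zip(groups, n)]

    r = R_POPULATIONS
    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni * ni for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return FstComponents(a=a, b=b, c=c, n_bar=n_bar, n_c=n_c,
                         p_bar=p_bar, s2=s2, h_bar=h_bar)


def weighted_fst(components: list[FstComponents]) -> float:
    """Ratio-of-sums estimate over sites: sum(a) / sum(a + b + c).

    Sites with an all-zero denominator (monomorphic) are ignored;
    raises if no site is informative.
    """
    num = denom = 0.0
    for comp in components:
        d = comp.a + comp.b + comp.c
        if d == 0.0:
            continue
        num += comp.a
        denom += d
    if denom == 0.0:
        raise ValueError("all sites monomorphic; weighted Fst undefined")
    return num / denom


def fst_scan(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant theta and components for a whole matrix.

    Missing genotypes are dropped site-wise.  Sites where either group
    has no called genotype, and sites monomorphic in both groups
    combined, get ``theta = NaN``.
    """
    freqs = matrix.allele_frequencies()
    rows = []
    for i in range(matrix.n_variants):
        case = matrix.genotype_counts(i, "case")
        ctrl = matrix.genotype_counts(i, "control")
        if sum(case) == 0 or sum(ctrl) == 0:
            rows.append((np.nan, np.nan, np.nan, np.nan))
            continue
        comp = wc_fst_site(case, ctrl)
        theta = comp.theta
        rows.append((comp.a, comp.b, comp.c,
                     np.nan if theta is None else theta))
    out = pd.DataFrame(rows, columns=["a", "b", "c", "theta"], index=matrix.variants.index)
    out["case_freq"] = freqs["case_freq"]
    out["control_freq"] = freqs["control_freq"]
    return out


def hwe_exact_test(genotype_counts: tuple[int, int, int]) -> float:
    """Exact conditional Hardy-Weinberg test on one site.

    Conditions on the observed allele counts and sums the
    probabilities of all heterozygote counts whose conditional
    probability does not exceed that of the observed configuration.
    Monomorphic sites return p = 1.
    """
    n_homref, n_het, n_homalt = (int(x) for x in genotype_counts)
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("negative genotype count")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise ValueError("empty site")
    n_alt = n_het + 2 * n_homalt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0

    # log-probability of each feasible heterozygote count, conditional on
    # the allele counts (Levene's distribution)
    hets = range(n_minor % 2, n_minor + 1, 2)
    logps = {}
    for het in hets:
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        if hom_major < 0:
            continue
        logps[het] = (het * math.log(2)
                      + math.lgamma(n + 1)
                      - math.lgamma(hom_minor + 1) - math.lgamma(het + 1)
                      - math.lgamma(hom_major + 1)
                      + math.lgamma(n_minor + 1) + math.lgamma(2 * n - n_minor + 1)
                      - math.lgamma(2 * n + 1))
    norm = max(logps.values())
    probs = {het: math.exp(lp - norm) for het, lp in logps.items()}
    total = sum(probs.values())
    observed = probs[n_het] / total
    p = sum(pr / total for pr in probs.values() if pr / total <= observed * (1 + 1e-12))
    return min(p, 1.0)


@dataclass
class SelectionResult:
    """Outcome of the upper-tail Fst candidate screen."""

    flagged: pd.Index       # autosomal variants with theta >= threshold
    retained: pd.Index      # flagged and case-enriched (alt freq higher in cases)
    excluded_direction: pd.Index  # flagged but control-enriched or tied
    excluded_x: pd.Index    # X-chromosome variants removed before screening

    def __post_init__(self) -> None:
        assert len(self.flagged) == len(self.retained) + len(self.excluded_direction)


def select_candidates(matrix: GenotypeMatrix, fst_results: pd.DataFrame,
                      threshold: float = 0.05) -> SelectionResult:
    """Apply the selection rule: drop X, flag theta >= threshold, keep
    case-enriched variants.

    ``fst_results`` must align row-wise with ``matrix.variants`` and
    carry columns theta, case_freq, control_freq (as from
    :func:`fst_scan`).  The threshold is inclusive.
    """
    if len(fst_results) != matrix.n_variants:
        raise ValueError("fst_results not aligned with matrix")
    idx = fst_results.index
    x_mask = matrix.is_x
    excluded_x = idx[x_mask]
    auto = fst_results.loc[~x_mask]
    flagged = auto.index[auto["theta"] >= threshold]
    sub = auto.loc[flagged]
    case_enriched = sub["case_freq"] > sub["control_freq"]
    retained = flagged[case_enriched.to_numpy()]
    excluded_direction = flagged[~case_enriched.to_numpy()]
    return SelectionResult(flagged=flagged, retained=retained,
                           excluded_direction=excluded_direction,
                           excluded_x=excluded_x)
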