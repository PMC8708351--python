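"""Diagnostic-test evaluation of the cumulative score, and the
end-to-end pipeline.

The score is dichotomized at a cutoff (6 by default; a score at or
above the cutoff is a positive test).  From the resulting confusion
counts come sensitivity, specificity and the likelihood ratios; with
a pretest prevalence the positive likelihood ratio converts, through
Bayes' rule on the odds scale, into a post-test probability, and the
population positive rate times that probability gives the fraction of
prevalence the test can account for.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import association, blocks as blocks_mod, fst as fst_mod
from .association import ScoreProfile, association_table, compute_scores
from .blocks import group_blocks
from .cohort_io import (GenotypeMatrix, classify_variant, read_bed_annotations,
                        read_vcf_genotypes)

logger = logging.getLogger("igluscore")

#: lifetime prevalence used as the default pretest probability
DEFAULT_PREVALENCE = 4.8 / 1000


@dataclass(frozen=True)
class ConfusionCounts:
    """Case/control counts above and below the score cutoff."""

    tp: int  # cases with a positive test (score >= cutoff)
    fn: int  # cases with a negative test
    fp: int  # controls with a positive test
    tn: int  # controls with a negative test

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn


@dataclass
class DiagnosticReport:
    sensitivity: float
    specificity: float
    lr_positive: float | None    # None = ND (specificity 1)
    lr_negative: float | None    # None = ND (specificity 0)
    post_test_probability: float | None = None
    prevalence_explained: float | None = None


def classify_scores(profile: ScoreProfile, cutoff: int = 6) -> ConfusionCounts:
    """Dichotomize scores: positive test iff score >= cutoff."""
    cases = profile.by_group("case")
    controls = profile.by_group("control")
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    return ConfusionCounts(
        tp=int(np.sum(cases >= cutoff)), fn=int(np.sum(cases < cutoff)),
        fp=int(np.sum(controls >= cutoff)), tn=int(np.sum(controls < cutoff)),
    )


def diagnostic_metrics(counts: ConfusionCounts) -> DiagnosticReport:
    """Sensitivity, specificity and likelihood ratios from counts."""
    if counts.n_cases == 0 or counts.n_controls == 0:
        raise ValueError("empty group")
    sens = counts.tp / counts.n_cases
    spec = counts.tn / counts.n_controls
    lr_pos = None if spec == 1.0 else sens / (1.0 - spec)
    lr_neg = None if spec == 0.0 else (1.0 - sens) / spec
    return DiagnosticReport(sensitivity=sens, specificity=spec,
                            lr_positive=lr_pos, lr_negative=lr_neg)


def post_test_probability(pretest_prob: float, lr: float) -> float:
    """Bayes on the odds scale: posterior = LR*odds / (1 + LR*odds)."""
    if not 0.0 < pretest_prob < 1.0:
        raise ValueError("pretest probability must lie strictly inside (0, 1)")
    if lr <= 0:
        raise ValueError("likelihood ratio must be positive")
    odds = pretest_prob / (1.0 - pretest_prob)
    return lr * odds / (1.0 + lr * odds)


def prevalence_explained(population_positive_rate: float, post_test_prob: float,
                         prevalence: float) -> float:
    """Fraction of disease prevalence accounted for by test positives.

    population_positive_rate x post-test probability is the disease
    mass among test positives; dividing by the prevalence expresses it
    as a fraction of all disease.  A result above 1 signals an
    internally inconsistent model and raises a warning.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly inside (0, 1)")
    frac = population_positive_rate * post_test_prob / prevalence
    if frac > 1.0:
        warnings.warn("explained fraction exceeds 1; inputs are inconsistent",
                      stacklevel=2)
    return frac


def hwe_expected_genotypes(p: float) -> tuple[float, float, float]:
    """(hom_alt, het, hom_ref) probabilities at allele frequency p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency outside [0, 1]")
    return p * p, 2 * p * (1 - p), (1 - p) * (1 - p)


def distribution_tests(profile: ScoreProfile) -> dict[str, float]:
    """Normality and location tests on the score distributions.

    Kolmogorov-Smirnov against a normal with each group's estimated
    mean and SD (approximate: parameters are estimated from the same
    data), and a one-sided Mann-Whitney U test of cases > controls.
    Small tie-free samples use the exact U distribution; otherwise
    midranks with the normal approximation and tie correction apply.
    """
    cases = profile.by_group("case").astype(float)
    controls = profile.by_group("control").astype(float)
    if len(cases) < 3 or len(controls) < 3:
        raise ValueError("need at least 3 samples per group")
    out = {}
    for label, x in (("cases", cases), ("controls", controls)):
        sd = x.std(ddof=1)
        if sd == 0:
            out[f"ks_p_{label}"] = 0.0
        else:
            out[f"ks_p_{label}"] = float(
                stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)
    mwu = stats.mannwhitneyu(cases, controls, alternative="greater",
                             method="auto", use_continuity=True)
    out["mwu_one_sided_p"] = float(mwu.pvalue)
    return out


def covariate_by_score_summary(profile: ScoreProfile,
                               covariate_values: np.ndarray) -> pd.DataFrame:
    """Group means of a per-sample covariate at each score level.

    Returns one row per (group, score level) plus an "all" row per
    group with mean and SD; empty cells are null.
    """
    cov = np.asarray(covariate_values, dtype=float)
    if len(cov) != len(profile.samples):
        raise ValueError("covariate length does not match sample count")
    df = pd.DataFrame({"group": profile.group, "score": profile.score, "cov": cov})
    rows = []
    levels = sorted(df["score"].unique())
    for group in ("case", "control"):
        sub = df[df["group"] == group]
        for level in levels:
            vals = sub.loc[sub["score"] == level, "cov"]
            rows.append({"group": group, "score": level,
                         "n": len(vals),
                         "mean": float(vals.mean()) if len(vals) else None,
                         "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None})
        rows.append({"group": group, "score": "all", "n": len(sub),
                     "mean": float(sub["cov"].mean()) if len(sub) else None,
                     "sd": float(sub["cov"].std(ddof=1)) if len(sub) > 1 else None})
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Tunable parameters of the end-to-end analysis."""

    fst_threshold: float = 0.05
    r2_threshold: float = 0.9
    cutoff: int = 6
    prevalence: float = DEFAULT_PREVALENCE


def _round(x, nd=6):
    return None if x is None else round(float(x), nd)


def run_pipeline(vcf: str, phenotypes: str, bed: str,
                 config: PipelineConfig | None = None,
                 out_dir: str | None = None) -> dict:
    """Run the full screen: Fst scan, candidate selection, block
    construction, association, scoring and diagnostic evaluation.

    Deterministic given the inputs.  When ``out_dir`` is set, writes
    fst.tsv, blocks.tsv, association.tsv, scores.tsv and report.json.
    Returns the report as a dict.
    """
    cfg = config or PipelineConfig()
    t0 = time.time()
    matrix = read_vcf_genotypes(vcf, phenotypes)
    annotations = read_bed_annotations(bed)
    logger.info("loaded %d variants x %d samples in %.2fs",
                matrix.n_variants, matrix.n_samples, time.time() - t0)

    t0 = time.time()
    fst_results = fst_mod.fst_scan(matrix)
    comps = [fst_mod.wc_fst_site(matrix.genotype_counts(i, "case"),
                                 matrix.genotype_counts(i, "control"))
             for i in range(matrix.n_variants)
             if sum(matrix.genotype_counts(i, "case")) > 0
             and sum(matrix.genotype_counts(i, "control")) > 0]
    weighted = fst_mod.weighted_fst(comps)
    selection = fst_mod.select_candidates(matrix, fst_results, cfg.fst_threshold)
    logger.info("fst scan: %d flagged, %d retained (%.2fs)",
                len(selection.flagged), len(selection.retained), time.time() - t0)

    gene_map = {}
    for i in selection.retained:
        rec = matrix.record(i)
        gene = None
        for a in annotations:
            if a.chrom == rec.chrom and a.start <= rec.pos - 1 < a.end:
                gene = a.gene
                break
        gene_map[i] = gene

    t0 = time.time()
    blocks, singletons = group_blocks(matrix, selection.retained, gene_map,
                                      cfg.r2_threshold)
    logger.info("blocks: %d multi-variant, %d standalone (%.2fs)",
                len(blocks), len(singletons), time.time() - t0)

    assoc = association_table(blocks, singletons, matrix) if blocks or singletons \
        else pd.DataFrame()
    report: dict = {
        "fst_summary": {"weighted_theta": _round(weighted),
                        "n_sites": len(comps)},
        "selection": {"flagged": len(selection.flagged),
                      "retained": len(selection.retained),
                      "excluded_direction": len(selection.excluded_direction),
                      "excluded_x": len(selection.excluded_x)},
        "blocks": [{"name": b.name, "gene": b.gene, "n_members": b.n_members,
                    "member_ids": b.member_ids} for b in blocks],
        "singletons": [s.name for s in singletons],
        "association": [
            {k: (None if isinstance(v, float) and np.isnan(v) else v)
             for k, v in rec.items()}
            for rec in assoc.to_dict("records")
        ] if len(assoc) else [],
    }

    if blocks:
        profile = compute_scores(blocks, matrix)
        counts = classify_scores(profile, cfg.cutoff)
        metrics = diagnostic_metrics(counts)
        if metrics.lr_positive is not None:
            metrics.post_test_probability = post_test_probability(
                cfg.prevalence, metrics.lr_positive)
            pop_rate = counts.fp / counts.n_controls
            if pop_rate > 0:
                metrics.prevalence_explained = prevalence_explained(
                    pop_rate, metrics.post_test_probability, cfg.prevalence)
        dist = distribution_tests(profile) if min(counts.n_cases,
                                                  counts.n_controls) >= 3 else {}
        report["scores"] = {
            "per_sample": {s: int(v) for s, v in zip(profile.samples, profile.score)},
            "case_mean": _round(np.mean(profile.by_group("case"))),
            "control_mean": _round(np.mean(profile.by_group("control"))),
            "distribution_tests": {k: _round(v) for k, v in dist.items()},
        }
        report["diagnostics"] = {
            "cutoff": cfg.cutoff,
            "confusion": {"tp": counts.tp, "fn": counts.fn,
                          "fp": counts.fp, "tn": counts.tn},
            "sensitivity": _round(metrics.sensitivity),
            "specificity": _round(metrics.specificity),
            "lr_positive": _round(metrics.lr_positive),
            "lr_negative": _round(metrics.lr_negative),
            "post_test_probability": _round(metrics.post_test_probability),
            "prevalence_explained": _round(metrics.prevalence_explained),
        }
    else:
        report["scores"] = None
        report["diagnostics"] = None

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fst_out = fst_results.copy()
        fst_out.insert(0, "chrom", matrix.variants["chrom"])
        fst_out.insert(1, "pos", matrix.variants["pos"])
        fst_out.insert(2, "id", matrix.variants["id"])
        fst_out["flagged"] = fst_out.index.isin(selection.flagged)
        fst_out["retained"] = fst_out.index.isin(selection.retained)
        fst_out.to_csv(out / "fst.tsv", sep="\t", index=False)
        pd.DataFrame(report["blocks"]).to_csv(out / "blocks.tsv", sep="\t", index=False)
        if len(assoc):
            assoc.to_csv(out / "association.tsv", sep="\t", index=False)
        if report["scores"]:
            pd.DataFrame({
                "sample": list(report["scores"]["per_sample"]),
                "group": matrix.phenotype,
                "score": list(report["scores"]["per_sample"].values()),
            }).to_csv(out / "scores.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
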