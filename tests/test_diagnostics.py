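"""Score dichotomization, test metrics, Bayesian risk, pipeline."""

import itertools
import json

import numpy as np
import pytest

from igluscore.association import ScoreProfile
from igluscore.diagnostics import (ConfusionCounts, PipelineConfig,
                                   classify_scores, covariate_by_score_summary,
                                   diagnostic_metrics, distribution_tests,
                                   hwe_expected_genotypes,
                                   post_test_probability, prevalence_explained,
                                   run_pipeline)
from igluscore.simulate import SyntheticConfig, generate_cohort, write_cohort


def profile_from(case_scores, control_scores):
    scores = np.array(list(case_scores) + list(control_scores))
    group = np.array(["case"] * len(case_scores) + ["control"] * len(control_scores),
                     dtype=object)
    samples = [f"s{i}" for i in range(len(scores))]
    return ScoreProfile(samples=samples, group=group, score=scores,
                        n_blocks=8, low_confidence=np.zeros(len(scores), bool))


class TestClassifyScores:
    def test_cutoff_semantics(self):
        profile = profile_from([6, 5], [6, 5])
        counts = classify_scores(profile, cutoff=6)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (1, 1, 1, 1)

    def test_all_zero_scores(self):
        counts = classify_scores(profile_from([0, 0], [0, 0]), cutoff=6)
        assert counts.tp == counts.fp == 0

    def test_cutoff_zero_everyone_positive(self):
        counts = classify_scores(profile_from([0, 3], [0, 9]), cutoff=0)
        assert counts.fn == counts.tn == 0

    def test_raising_cutoff_never_adds_positives(self):
        rng = np.random.default_rng(0)
        profile = profile_from(rng.integers(0, 12, 60), rng.integers(0, 12, 30))
        positives = [classify_scores(profile, c).tp + classify_scores(profile, c).fp
                     for c in range(0, 13)]
        assert positives == sorted(positives, reverse=True)


class TestDiagnosticMetrics:
    def test_published_likelihood_ratio(self):
        """42/63 positive cases and 3/32 positive controls give LR+ 7.11."""
        m = diagnostic_metrics(ConfusionCounts(tp=42, fn=21, fp=3, tn=29))
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.specificity == pytest.approx(29 / 32)
        assert m.lr_positive == pytest.approx(7.11, abs=0.005)

    def test_perfect_test_lr_not_determined(self):
        m = diagnostic_metrics(ConfusionCounts(tp=10, fn=0, fp=0, tn=10))
        assert m.sensitivity == m.specificity == 1.0
        assert m.lr_positive is None

    def test_uninformative_test_unit_lr(self):
        m = diagnostic_metrics(ConfusionCounts(tp=5, fn=5, fp=5, tn=5))
        assert m.lr_positive == pytest.approx(1.0)

    def test_lr_identity(self):
        m = diagnostic_metrics(ConfusionCounts(tp=13, fn=7, fp=4, tn=16))
        assert m.lr_positive == pytest.approx(
            m.sensitivity / (1 - m.specificity))


class TestPostTestProbability:
    def test_published_lifetime_risk(self):
        """Prevalence 4.8/1000 and LR+ 7.11 give a 3.3% post-test risk."""
        assert post_test_probability(0.0048, 64 / 9) == pytest.approx(0.0332, abs=5e-4)

    def test_unit_lr_identity(self):
        assert post_test_probability(0.37, 1.0) == pytest.approx(0.37)

    def test_odds_arithmetic(self):
        assert post_test_probability(0.5, 3.0) == pytest.approx(0.75)

    def test_strictly_increasing_in_lr_and_pretest(self):
        lrs = [0.5, 1, 2, 4, 8]
        vals = [post_test_probability(0.01, lr) for lr in lrs]
        assert vals == sorted(vals) and len(set(vals)) == len(vals)
        ps = [0.001, 0.01, 0.1, 0.5]
        vals = [post_test_probability(p, 3.0) for p in ps]
        assert vals == sorted(vals) and len(set(vals)) == len(vals)

    def test_boundary_rejected(self):
        for p in (0.0, 1.0):
            with pytest.raises(ValueError):
                post_test_probability(p, 2.0)


class TestPrevalenceExplained:
    def test_published_arithmetic(self):
        """9% positives at 3.3% risk explain ~60% of a 0.48% prevalence."""
        assert prevalence_explained(0.09, 0.033, 0.0048) == pytest.approx(0.619, abs=5e-4)

    def test_zero_rate(self):
        assert prevalence_explained(0.0, 0.033, 0.0048) == 0.0

    def test_algebraic_identity(self):
        assert prevalence_explained(0.2, 0.01, 0.2 * 0.01) == pytest.approx(1.0)

    def test_inconsistent_inputs_warn(self):
        with pytest.warns(UserWarning):
            prevalence_explained(0.9, 0.9, 0.001)


class TestHweExpectedGenotypes:
    @pytest.mark.parametrize("p,expected", [
        (0.300, (0.09, 0.42, 0.49)),
        (0.0, (0.0, 0.0, 1.0)),
        (0.5, (0.25, 0.5, 0.25)),
    ])
    def test_genotype_probabilities(self, p, expected):
        assert hwe_expected_genotypes(p) == pytest.approx(expected)


def exact_mwu_permutation_p(cases, controls):
    """Exhaustive one-sided (cases > controls) permutation p of the U
    statistic, ties scored as half."""
    pooled = np.array(list(cases) + list(controls), dtype=float)
    n1 = len(cases)

    def u(idx):
        sel = set(idx)
        grp = pooled[list(idx)]
        rest = [x for i, x in enumerate(pooled) if i not in sel]
        return sum((a > b) + 0.5 * (a == b) for a in grp for b in rest)

    u_obs = u(range(n1))
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        hits += u(idx) >= u_obs - 1e-9
    return hits / total


class TestDistributionTests:
    def test_identical_groups_one_sided_half(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 10, 50)
        out = distribution_tests(profile_from(x, x))
        assert out["mwu_one_sided_p"] == pytest.approx(0.5, abs=0.02)

    def test_strong_shift_tiny_p(self):
        rng = np.random.default_rng(2)
        controls = rng.integers(0, 6, 30)
        cases = rng.integers(0, 6, 60) + 5
        out = distribution_tests(profile_from(cases, controls))
        assert out["mwu_one_sided_p"] < 1e-4

    def test_matches_exhaustive_permutation_small_n(self):
        rng = np.random.default_rng(6)
        for _ in range(8):
            cases = rng.normal(0.8, 1.0, 6)
            controls = rng.normal(0.0, 1.0, 5)
            out = distribution_tests(profile_from(cases, controls))
            oracle = exact_mwu_permutation_p(cases, controls)
            assert out["mwu_one_sided_p"] == pytest.approx(oracle, abs=0.005)

    def test_ks_separates_normal_from_skewed(self):
        rng = np.random.default_rng(3)
        profile = profile_from(rng.normal(6.3, 1.6, 63),
                               rng.normal(3.7, 1.4, 32))
        out = distribution_tests(profile)
        assert out["ks_p_cases"] > 0.05
        assert out["ks_p_controls"] > 0.05
        skewed = profile_from(rng.exponential(1.0, 200) ** 2,
                              rng.normal(0, 1, 32))
        assert distribution_tests(skewed)["ks_p_cases"] < 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            distribution_tests(profile_from([1, 2], [1, 2, 3]))


class TestCovariateSummary:
    def test_constant_covariate(self):
        profile = profile_from([3, 4, 5], [3, 4, 5])
        tab = covariate_by_score_summary(profile, np.full(6, 2.5))
        means = tab.loc[tab["mean"].notna(), "mean"]
        assert np.allclose(means, 2.5)

    def test_covariate_equal_to_score(self):
        profile = profile_from([3, 4, 5, 5], [2, 3, 4, 4])
        tab = covariate_by_score_summary(profile, profile.score.astype(float))
        sub = tab[(tab["score"] != "all") & tab["mean"].notna()]
        assert np.allclose(sub["mean"], sub["score"].astype(float))

    def test_group_mean_recovery(self):
        rng = np.random.default_rng(9)
        n_case, n_ctrl = 400, 400
        profile = profile_from(rng.integers(0, 10, n_case),
                               rng.integers(0, 10, n_ctrl))
        cov = np.where(profile.group == "case",
                       rng.normal(2.44, 5.54, n_case + n_ctrl),
                       rng.normal(0.14, 3.94, n_case + n_ctrl))
        tab = covariate_by_score_summary(profile, cov).set_index(["group", "score"])
        for grp, mu, sd, n in (("case", 2.44, 5.54, n_case),
                               ("control", 0.14, 3.94, n_ctrl)):
            got = tab.loc[(grp, "all"), "mean"]
            assert abs(got - mu) < 3 * sd / np.sqrt(n)


@pytest.fixture(scope="module")
def sim_paths(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("cohort")
    cohort = generate_cohort(SyntheticConfig(n_cases=630, n_controls=320, seed=0))
    return write_cohort(cohort, str(tmp / "sim"))


class TestRunPipeline:
    def test_recovers_eight_autosomal_blocks(self, sim_paths, tmp_path):
        report = run_pipeline(sim_paths["vcf"], sim_paths["phenotypes"],
                              sim_paths["bed"], out_dir=str(tmp_path))
        assert len(report["blocks"]) == 8
        assert report["scores"]["control_mean"] == pytest.approx(3.69, abs=0.2)

    def test_block_odds_ratios_within_sampling_error(self, sim_paths):
        """Every recovered block's log odds ratio lies within 3 SE of the
        value implied by its configured frequencies (Wald SE from the
        realized 2x2 allele counts)."""
        from igluscore.simulate import TABLE4_BLOCKS
        report = run_pipeline(sim_paths["vcf"], sim_paths["phenotypes"],
                              sim_paths["bed"])
        assoc = {a["unit"]: a for a in report["association"]}
        for b in report["blocks"]:
            spec = next(s for s in TABLE4_BLOCKS
                        if set(s.member_ids) == set(b["member_ids"]))
            pc, pk = spec.risk_allele_freq_case, spec.risk_allele_freq_control
            if pk in (0.0, 1.0) or pc in (0.0, 1.0):
                continue
            true_or = (pc / (1 - pc)) / (pk / (1 - pk))
            got = assoc[b["name"]]["odds_ratio"]
            assert got is not None, b["name"]
            cells = [pc * 1260, (1 - pc) * 1260, pk * 640, (1 - pk) * 640]
            se = np.sqrt(sum(1 / c for c in cells))
            assert abs(np.log(got) - np.log(true_or)) < 3 * se, b["name"]

    def test_null_cohort_rarely_yields_candidates(self):
        """With no group-differentiated variants, at least 95% of seeds
        retain zero candidates at the 0.05 threshold."""
        from igluscore.fst import fst_scan, select_candidates
        zero = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cohort = generate_cohort(SyntheticConfig(
                n_cases=63, n_controls=32, blocks=(),
                n_background_variants=10, seed=200 + seed))
            sel = select_candidates(cohort.matrix, fst_scan(cohort.matrix))
            zero += len(sel.retained) == 0
        assert zero >= 0.95 * n_seeds

    def test_deterministic_report(self, sim_paths, tmp_path):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        run_pipeline(sim_paths["vcf"], sim_paths["phenotypes"], sim_paths["bed"],
                     out_dir=str(d1))
        run_pipeline(sim_paths["vcf"], sim_paths["phenotypes"], sim_paths["bed"],
                     out_dir=str(d2))
        assert (d1 / "report.json").read_bytes() == (d2 / "report.json").read_bytes()

    def test_report_has_all_sections(self, sim_paths, tmp_path):
        report = run_pipeline(sim_paths["vcf"], sim_paths["phenotypes"],
                              sim_paths["bed"], out_dir=str(tmp_path / "out"))
        for key in ("fst_summary", "selection", "blocks", "association",
                    "scores", "diagnostics"):
            assert key in report
        written = json.loads((tmp_path / "out" / "report.json").read_text())
        assert written["selection"] == report["selection"]
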