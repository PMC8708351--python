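"""Evaluate the cumulative score as a diagnostic test.

First reproduces the published arithmetic from its confusion counts
(42 of 63 cases and 3 of 32 controls test positive at cutoff 6):
LR+ = 7.11 and a post-test schizophrenia risk of 3.3% at a lifetime
prevalence of 4.8/1000.  Then runs the same machinery on a freshly
simulated cohort.
"""

from igluscore import (ConfusionCounts, SyntheticConfig, classify_scores,
                       compute_scores, diagnostic_metrics, fst_scan,
                       generate_cohort, group_blocks, post_test_probability,
                       prevalence_explained, select_candidates)

counts = ConfusionCounts(tp=42, fn=21, fp=3, tn=29)
m = diagnostic_metrics(counts)
post = post_test_probability(0.0048, m.lr_positive)
print("published confusion counts:")
print(f"  sensitivity {m.sensitivity:.2f}, specificity {m.specificity:.2f}")
print(f"  LR+ {m.lr_positive:.2f}")
print(f"  post-test risk at prevalence 4.8/1000: {100 * post:.1f}%")
print(f"  prevalence explained at a 9% positive rate: "
      f"{100 * prevalence_explained(0.09, post, 0.0048):.0f}%\n")

cohort = generate_cohort(SyntheticConfig(n_cases=630, n_controls=320, seed=0))
matrix = cohort.matrix
selection = select_candidates(matrix, fst_scan(matrix))
gene_map = {i: next((a.gene for a in cohort.annotations
                     if a.chrom == matrix.variants["chrom"].iloc[i]
                     and a.start <= matrix.variants["pos"].iloc[i] - 1 < a.end),
                    None)
            for i in selection.retained}
blocks, _ = group_blocks(matrix, selection.retained, gene_map)
profile = compute_scores(blocks, matrix)
sim_counts = classify_scores(profile, cutoff=6)
sim = diagnostic_metrics(sim_counts)
print("simulated cohort (630 cases / 320 controls, cutoff 6):")
print(f"  sensitivity {sim.sensitivity:.2f}, specificity {sim.specificity:.2f}, "
      f"LR+ {sim.lr_positive:.2f}")
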