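"""Transcriptome-wide anchor correlation with cross-cohort mean-r ranking.

Correlates every gene with the anchor in each cohort separately, adjusts
p-values with Benjamini-Hochberg within each cohort, then ranks genes
quantified in both cohorts by the mean of the two correlation coefficients —
the statistic used to call a co-expression signal replicated.
"""

from anchorscope import (
    PreprocessConfig,
    SyntheticSpec,
    correlate_anchor,
    cross_cohort_merge,
    generate_cohort,
    preprocess,
)

spec = SyntheticSpec(
    n_samples_per_cohort=(400, 300),
    n_genes=200,
    planted_correlates=(("POS1", 0.75), ("POS2", 0.5), ("NEG1", -0.55)),
    seed=1,
)

records = []
for i in (0, 1):
    cooked = preprocess(generate_cohort(spec, i), PreprocessConfig())
    records.append(correlate_anchor(cooked, spec.anchor_id))

merged = cross_cohort_merge(records[0], records[1])
print("gene      r_mean   r_A      p_fdr_A    r_B      p_fdr_B")
for m in merged[:3] + merged[-2:]:
    print(
        f"{m.gene:<8} {m.r_mean_reported:+.2f}   {m.record_a.r:+.3f}  "
        f"{m.record_a.p_fdr:9.2e}  {m.record_b.r:+.3f}  {m.record_b.p_fdr:9.2e}"
    )
# The three planted correlates bracket the table: positive ones at the top,
# the negative one at the bottom; the ~197 noise genes fill the middle with
# r_mean near 0 and non-significant adjusted p-values.
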