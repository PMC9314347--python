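"""Allelic skew of hsa_circ_0022025 between the rs4752856 alleles.

Normalises each heterozygote's circRNA A/G peak ratio by the matched gDNA
ratio, averages replicates per subject, and tests the cohort of subject
means against the balanced value 1 with a one-sample Wilcoxon test.
"""

from circsnp import analyse_allelic, hwe_test
from circsnp.datasets import GENOTYPE_COUNTS, rs4752856_allelic_ratios

hwe = hwe_test(GENOTYPE_COUNTS["G/G"], GENOTYPE_COUNTS["G/A"], GENOTYPE_COUNTS["A/A"])
print(f"genotype counts G/G={hwe.n_major_hom} G/A={hwe.n_het} A/A={hwe.n_minor_hom}: "
      f"HWE exact P = {hwe.pvalue:.2f} -> {'fulfilled' if hwe.fulfilled else 'violated'}")

res = analyse_allelic(rs4752856_allelic_ratios())
for subject, mean in sorted(res.summary.subject_means.items()):
    print(f"  {subject:<11} mean normalised ratio = {mean:.2f}")
t = res.test
print(f"cohort (n = {t.n}): median = {t.median:.2f}, mean = {res.mean:.2f} "
      f"[{res.ci_low:.2f}, {res.ci_high:.2f}]")
print(f"Wilcoxon vs 1: W+ = {t.w_plus:.0f}, z = {t.z:.3f}, P = {t.pvalue:.3f}, "
      f"r = {t.effect_r:.2f}")
# A median above 1 with P < 0.05 means the BMI-risk A allele contributes
# more circRNA than the G allele in the same heterozygous cells; r ~ 0.63
# is a large effect for n = 8.
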