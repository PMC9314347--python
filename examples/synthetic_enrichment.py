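"""Full pipeline on a synthetic study with known true enrichment.

Generates circRNA loci and GWAS SNPs whose on-locus placement
probabilities imply a known odds ratio, then runs classification,
overlap counting and the enrichment test, under all four classification
schemes.
"""

from circsnp import ClassificationConfig, run_enrichment
from circsnp.synthetic_data import (
    SimulationConfig,
    gen_circ_loci,
    gen_ld_structure,
    gen_snps,
)

# a sparse genome so LD windows/blocks do not swallow every SNP
cfg = SimulationConfig(seed=42, n_snps=50_000, frac_significant=0.002,
                       n_chrom=10, chrom_length=50_000_000, n_circ=1000,
                       p_on_locus_sig=0.6, p_on_locus_nonsig=0.5)
loci = gen_circ_loci(cfg)
snps = gen_snps(cfg, loci)
regions, _ = gen_ld_structure(cfg, snps)
print(f"simulated {len(snps):,} SNPs over {len(loci)} circRNA loci; "
      f"true OR = {cfg.true_or:.2f}")

schemes = {
    "threshold": ClassificationConfig(),
    "sensitivity (cutoff 5e-6)": ClassificationConfig(sensitivity_alpha=5e-6),
    "LD 1 Mb window": ClassificationConfig(ld_mode="window"),
    "LD regions": ClassificationConfig(ld_mode="regions"),
}
for name, scheme in schemes.items():
    res = run_enrichment(snps, loci, scheme, ld_regions=regions)
    ct = res.contingency
    print(f"{name:<26} OR = {ct.odds_ratio:.2f} [{ct.ci_low:.2f}, {ct.ci_high:.2f}]  "
          f"P = {ct.pvalue:.2g}  (sig n = {res.n_significant:,})")
# With only ~100 significant SNPs the threshold estimate is noisy (wide
# CI); the LD schemes promote thousands of nearby non-significant SNPs
# into the significant group, tightening the interval but biasing the
# contrast towards the non-significant placement rate.
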