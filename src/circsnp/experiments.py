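"""Calibration experiments for the enrichment test on synthetic studies.

These run the full pipeline (simulation -> classification -> overlap
counting -> chi-square / Woolf interval) many times to measure its
operating characteristics: the type-I error rate under a no-enrichment
null and the coverage of the Woolf confidence interval under a known true
odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .locus_enrichment import run_enrichment, OverlapIndex
from .synthetic_data import SimulationConfig, gen_circ_loci, gen_snps


@dataclass
class CalibrationResult:
    n_replicates: int
    rate: float          # rejection rate or coverage fraction
    mean_odds_ratio: float


def null_type_i_error(
    seed: int = 0,
    n_replicates: int = 1000,
    n_snps: int = 4000,
    frac_significant: float = 0.25,
    p_on_locus: float = 0.5,
    alpha_test: float = 0.05,
) -> CalibrationResult:
    """Rejection rate of the enrichment chi-square when no enrichment exists.

    Both groups share the same on-locus placement probability, so the true
    odds ratio is 1; the two-sided chi-square should reject at close to
    ``alpha_test``.
    """
    base = SimulationConfig(
        seed=seed, n_snps=n_snps, frac_significant=frac_significant,
        p_on_locus_sig=p_on_locus, p_on_locus_nonsig=p_on_locus, n_circ=100,
    )
    loci = gen_circ_loci(base)
    index = OverlapIndex(loci)
    rejections = 0
    ors = np.empty(n_replicates)
    for i in range(n_replicates):
        cfg = replace(base, seed=seed + 1000 + i)
        snps = gen_snps(cfg, loci)
        res = run_enrichment(snps, loci, index=index)
        rejections += res.contingency.pvalue < alpha_test
        ors[i] = res.contingency.odds_ratio
    return CalibrationResult(n_replicates, rejections / n_replicates, float(ors.mean()))


def woolf_coverage(
    seed: int = 0,
    n_replicates: int = 200,
    n_snps: int = 100_000,
    frac_significant: float = 0.02,
    p_on_locus_sig: float = 0.6,
    p_on_locus_nonsig: float = 0.5,
) -> CalibrationResult:
    """Fraction of replicates whose Woolf 95% CI covers the true odds ratio."""
    base = SimulationConfig(
        seed=seed, n_snps=n_snps, frac_significant=frac_significant,
        p_on_locus_sig=p_on_locus_sig, p_on_locus_nonsig=p_on_locus_nonsig,
        n_circ=100,
    )
    true_or = base.true_or
    loci = gen_circ_loci(base)
    index = OverlapIndex(loci)
    covered = 0
    ors = np.empty(n_replicates)
    for i in range(n_replicates):
        cfg = replace(base, seed=seed + 5000 + i)
        snps = gen_snps(cfg, loci)
        res = run_enrichment(snps, loci, index=index)
        ct = res.contingency
        covered += ct.ci_low <= true_or <= ct.ci_high
        ors[i] = ct.odds_ratio
    return CalibrationResult(n_replicates, covered / n_replicates, float(ors.mean()))
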