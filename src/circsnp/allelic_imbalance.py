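"""Allelic skew of a circRNA from primer-extension peak ratios.

Each heterozygous subject contributes replicate A/G peak ratios measured
on circRNA-derived cDNA and on genomic DNA; the gDNA ratio of the same
subject normalises away assay bias:

    normalised value = (A/G on circRNA cDNA) / (A/G on gDNA)

A value of 1 means both alleles contribute equally to the circRNA.  The
cohort of per-subject means is tested against the hypothesised median 1
with a one-sample Wilcoxon signed-rank test using the asymptotic normal
approximation without continuity correction; the effect size is
r = z / sqrt(2 n).  Genotype counts are checked against Hardy-Weinberg
proportions (exact test for small samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import AllelicTriplicate, DataError


@dataclass(frozen=True, slots=True)
class NormalisedRatio:
    subject_id: str
    replicate: int
    value: float


def normalise_ratio(ag_circ: float, ag_gdna: float) -> float:
    """gDNA-normalised allelic ratio of the circRNA (1 = balanced)."""
    if ag_circ <= 0 or ag_gdna <= 0:
        raise DataError(f"ratios must be positive, got ({ag_circ}, {ag_gdna})")
    return ag_circ / ag_gdna


def normalise_triplicates(trips: Iterable[AllelicTriplicate]) -> list[NormalisedRatio]:
    return [
        NormalisedRatio(t.subject_id, t.replicate, normalise_ratio(t.ag_circ, t.ag_gdna))
        for t in trips
    ]


@dataclass
class SubjectSummary:
    subject_means: dict[str, float]
    cohort_median: float
    n_subjects: int
    dropped_subjects: list[str]


def subject_summary(
    trips: Sequence[AllelicTriplicate],
    exclusions: Iterable[str] = (),
    genotypes: tuple[str, ...] = ("G/A",),
) -> SubjectSummary:
    """Per-subject mean normalised ratio and the cohort median over means.

    Homozygous subjects are assay controls and are dropped, as are
    subjects on the exclusion list (e.g. low-signal assays).  A subject
    left with no replicates is dropped and reported.
    """
    exclusions = set(exclusions)
    values: dict[str, list[float]] = {}
    for t in trips:
        if t.genotype not in genotypes or t.subject_id in exclusions:
            continue
        values.setdefault(t.subject_id, []).append(
            normalise_ratio(t.ag_circ, t.ag_gdna)
        )
    dropped = [s for s, v in values.items() if not v]
    means = {s: float(np.mean(v)) for s, v in values.items() if v}
    if not means:
        raise DataError("no heterozygous subjects remain after exclusions")
    return SubjectSummary(
        subject_means=means,
        cohort_median=float(np.median(list(means.values()))),
        n_subjects=len(means),
        dropped_subjects=dropped,
    )


@dataclass(frozen=True)
class WilcoxonResult:
    n: int
    w_plus: float
    z: float
    pvalue: float
    effect_r: float
    median: float


def wilcoxon_one_sample(values: Sequence[float], mu: float = 1.0) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test against ``mu``.

    Values equal to ``mu`` are dropped; absolute differences are ranked
    with midranks for ties.  The asymptotic statistic is

        z = (W+ - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24)

    with no continuity and no tie correction, a two-sided normal P-value,
    and effect size r = z / sqrt(2 n).
    """
    values = np.asarray(values, dtype=np.float64)
    d = values - mu
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise DataError("Wilcoxon test undefined: all values equal the null median")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    sd_w = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (w_plus - mean_w) / sd_w
    p = float(2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(
        n=n,
        w_plus=w_plus,
        z=float(z),
        pvalue=min(p, 1.0),
        effect_r=float(z / math.sqrt(2 * n)),
        median=float(np.median(values)),
    )


def descriptive_ci(values: Sequence[float], conf: float = 0.95) -> tuple[float, float, float]:
    """Mean with a t-based confidence interval (mean, lower, upper)."""
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if n < 2:
        raise DataError("t-based confidence interval needs n >= 2")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / math.sqrt(n))
    t = float(stats.t.ppf(0.5 + conf / 2.0, df=n - 1))
    return mean, mean - t * sem, mean + t * sem


@dataclass(frozen=True)
class HweResult:
    n_major_hom: int
    n_het: int
    n_minor_hom: int
    minor_allele_freq: float
    chi2: float
    pvalue_chi2: float
    pvalue: float
    method: str  # "exact" | "chi2"
    fulfilled: bool


def _hwe_exact_pvalue(n_het: int, n_minor_hom: int, n_major_hom: int) -> float:
    """Exact Hardy-Weinberg test: sum of heterozygote-count probabilities
    no larger than the observed one, conditional on allele counts."""
    n = n_het + n_minor_hom + n_major_hom
    n_minor = 2 * n_minor_hom + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # work with the rarer allele
    # probabilities over possible heterozygote counts (same parity as n_minor)
    het_values = list(range(n_minor % 2, n_minor + 1, 2))
    logs = []
    for h in het_values:
        rare_hom = (n_minor - h) // 2
        common_hom = n - h - rare_hom
        if common_hom < 0:
            logs.append(-np.inf)
            continue
        lg = (
            h * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma(h + 1)
            - math.lgamma(rare_hom + 1)
            - math.lgamma(common_hom + 1)
        )
        logs.append(lg)
    logs = np.asarray(logs)
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = het_values.index(n_het) if n_het in het_values else None
    if obs is None:  # inconsistent counts; impossible under the conditioning
        return 0.0
    p_obs = probs[obs]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_test(
    n_major_hom: int, n_het: int, n_minor_hom: int,
    alpha: float = 0.05, exact_below: int = 50,
) -> HweResult:
    """Test genotype counts against Hardy-Weinberg proportions.

    Pearson goodness-of-fit chi-square with df = 1 is always reported; for
    cohorts smaller than ``exact_below`` the verdict uses the exact
    conditional test instead.  ``fulfilled`` is True when P >= alpha.
    """
    n = n_major_hom + n_het + n_minor_hom
    if n <= 0:
        raise DataError("HWE test needs at least one genotyped subject")
    q = (2 * n_minor_hom + n_het) / (2 * n)
    p = 1.0 - q
    expected = np.asarray([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.asarray([n_major_hom, n_het, n_minor_hom], dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    p_chi2 = float(stats.chi2.sf(chi2, df=1))
    if n < exact_below:
        p_final = _hwe_exact_pvalue(n_het, n_minor_hom, n_major_hom)
        method = "exact"
    else:
        p_final, method = p_chi2, "chi2"
    return HweResult(
        n_major_hom=n_major_hom,
        n_het=n_het,
        n_minor_hom=n_minor_hom,
        minor_allele_freq=float(min(q, 1 - q)),
        chi2=chi2,
        pvalue_chi2=p_chi2,
        pvalue=p_final,
        method=method,
        fulfilled=p_final >= alpha,
    )


@dataclass
class AllelicAnalysis:
    summary: SubjectSummary
    test: WilcoxonResult
    mean: float
    ci_low: float
    ci_high: float


def analyse_allelic(
    trips: Sequence[AllelicTriplicate],
    exclusions: Iterable[str] = (),
    mu: float = 1.0,
    conf: float = 0.95,
) -> AllelicAnalysis:
    """Full allelic-imbalance analysis: gDNA normalisation, subject
    means, cohort median, Wilcoxon inference and t-based descriptives."""
    summary = subject_summary(trips, exclusions)
    means = list(summary.subject_means.values())
    test = wilcoxon_one_sample(means, mu=mu)
    mean, lo, hi = descriptive_ci(means, conf)
    return AllelicAnalysis(summary=summary, test=test, mean=mean, ci_low=lo, ci_high=hi)
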