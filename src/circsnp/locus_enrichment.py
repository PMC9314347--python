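"""Enrichment of SNP groups on circRNA genomic loci.

The 2x2 table contrasts significant vs non-significant SNPs against
on-locus vs off-locus placement; association is tested with a two-sided
Pearson chi-square (df = 1) and summarised by the odds ratio with a Woolf
logit confidence interval.  A SNP lying exactly on a printed start or stop
position of a locus counts as on-locus (closed-interval semantics in
1-based terms, i.e. the stored half-open span).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from . import snp_classification as sc
from .data_io import CircRnaLocus, ConfigurationError, DataError, HighLdRegion, SnpRecord


class DegenerateTableError(DataError):
    """A 2x2 margin (or, for Woolf, a cell) is zero."""


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 counts with chi-square test and Woolf-interval odds ratio.

    Layout: a = significant on-locus, b = significant off-locus,
    c = non-significant on-locus, d = non-significant off-locus.
    """

    a: int
    b: int
    c: int
    d: int
    chi2: float
    pvalue: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95

    @classmethod
    def from_counts(
        cls, a: int, b: int, c: int, d: int,
        conf_level: float = 0.95, correction: bool = False,
    ) -> "ContingencyResult":
        chi2, p = pearson_chi2_2x2(a, b, c, d, correction=correction)
        orr, lo, hi = odds_ratio_woolf(a, b, c, d, conf_level)
        return cls(a, b, c, d, chi2, p, orr, lo, hi, conf_level)


class OverlapIndex:
    """Point-in-interval index over circRNA loci.

    Bulk membership queries use merged per-chromosome boundary arrays with
    binary search (vectorised over many SNPs); per-position locus lookup
    uses an interval tree so overlapping loci are all reported.
    """

    def __init__(self, loci: Iterable[CircRnaLocus]):
        self._trees: dict[str, IntervalTree] = {}
        by_chrom: dict[str, list[CircRnaLocus]] = {}
        for c in loci:
            by_chrom.setdefault(c.chrom, []).append(c)
            self._trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end, c)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, cs in by_chrom.items():
            ivals = sorted((c.start, c.end) for c in cs)
            merged: list[list[int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.asarray([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.asarray([m[1] for m in merged], dtype=np.int64)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """Is the 1-based position inside at least one locus span?"""
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        p0 = pos_1based - 1
        i = int(np.searchsorted(starts, p0, side="right")) - 1
        return i >= 0 and p0 < self._ends[chrom][i]

    def contains_many(self, chroms: Sequence[str], pos_1based: Sequence[int]) -> np.ndarray:
        """Vectorised membership for parallel chrom/pos arrays."""
        chroms = np.asarray(chroms, dtype=object)
        pos0 = np.asarray(pos_1based, dtype=np.int64) - 1
        out = np.zeros(len(pos0), dtype=bool)
        for chrom in np.unique(chroms):
            starts = self._starts.get(chrom)
            if starts is None:
                continue
            mask = chroms == chrom
            p = pos0[mask]
            i = np.searchsorted(starts, p, side="right") - 1
            ok = (i >= 0) & (p < self._ends[chrom][np.clip(i, 0, None)])
            out[mask] = ok
        return out

    def loci_at(self, chrom: str, pos_1based: int) -> list[CircRnaLocus]:
        """All loci whose span contains the 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos_1based - 1)), key=lambda c: c.circ_id)


def build_overlap_index(loci: Iterable[CircRnaLocus]) -> OverlapIndex:
    return OverlapIndex(loci)


def count_on_loci(snps: Sequence[SnpRecord], index: OverlapIndex) -> int:
    """Number of unique SNPs located on at least one locus span."""
    seen: set[str] = set()
    unique: list[SnpRecord] = []
    for s in snps:
        if s.rsid not in seen:
            seen.add(s.rsid)
            unique.append(s)
    if not unique:
        return 0
    hits = index.contains_many([s.chrom for s in unique], [s.pos for s in unique])
    return int(hits.sum())


def pearson_chi2_2x2(
    a: int, b: int, c: int, d: int, correction: bool = False
) -> tuple[float, float]:
    """Two-sided Pearson chi-square for a 2x2 table (df = 1).

    No Yates continuity correction by default; a ``correction`` flag is
    available for small tables.  Raises on zero margins.
    """
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise DegenerateTableError(
            f"degenerate 2x2 table ({a}, {b}, {c}, {d}): zero margin"
        )
    chi2, p, _, _ = stats.chi2_contingency(
        np.asarray([[a, b], [c, d]], dtype=np.float64), correction=correction
    )
    return float(chi2), float(p)


def odds_ratio_woolf(
    a: int, b: int, c: int, d: int, conf_level: float = 0.95
) -> tuple[float, float, float]:
    """Odds ratio (a*d)/(b*c) with a Woolf logit confidence interval.

    The log-odds-ratio standard error is sqrt(1/a + 1/b + 1/c + 1/d); the
    interval is exp(ln OR -/+ z * SE).  All four cells must be positive —
    no Haldane-style 0.5 correction is applied.
    """
    if min(a, b, c, d) <= 0:
        raise DegenerateTableError(
            f"Woolf interval undefined with a zero cell ({a}, {b}, {c}, {d}); "
            "no Haldane correction is applied"
        )
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    lo = float(np.exp(np.log(orr) - z * se))
    hi = float(np.exp(np.log(orr) + z * se))
    return float(orr), lo, hi


@dataclass(frozen=True)
class EnrichmentResult:
    """Full enrichment summary for one scheme x locus set."""

    contingency: ContingencyResult
    n_significant: int
    n_non_significant: int
    n_excluded: int
    prop_sig_on: float
    prop_nonsig_on: float


def run_enrichment(
    snps: Sequence[SnpRecord],
    loci: Iterable[CircRnaLocus],
    config: sc.ClassificationConfig | None = None,
    ld_regions: Iterable[HighLdRegion] | None = None,
    conf_level: float = 0.95,
    correction: bool = False,
    index: OverlapIndex | None = None,
) -> EnrichmentResult:
    """Classify SNPs, count on-locus placement per group, test enrichment."""
    assignments = sc.classify(snps, config, ld_regions)
    index = index if index is not None else OverlapIndex(loci)
    sig = [s for s, g in zip(snps, assignments) if g.group == sc.SIGNIFICANT]
    non = [s for s, g in zip(snps, assignments) if g.group == sc.NON_SIGNIFICANT]
    n_excl = len(snps) - len(sig) - len(non)
    a = count_on_loci(sig, index)
    c = count_on_loci(non, index)
    b, d = len(sig) - a, len(non) - c
    result = ContingencyResult.from_counts(a, b, c, d, conf_level, correction)
    return EnrichmentResult(
        contingency=result,
        n_significant=len(sig),
        n_non_significant=len(non),
        n_excluded=n_excl,
        prop_sig_on=a / len(sig) if sig else float("nan"),
        prop_nonsig_on=c / len(non) if non else float("nan"),
    )


def compare_strata(
    a1: int, b1: int, a2: int, b2: int,
    conf_level: float = 0.95, correction: bool = False,
) -> ContingencyResult:
    """Compare on-locus placement of significant SNPs between two strata.

    Rows are strata (e.g. females vs males), columns on/off locus; the
    odds ratio is oriented stratum-1 odds over stratum-2 odds.
    """
    return ContingencyResult.from_counts(a1, b1, a2, b2, conf_level, correction)
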