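"""Assign GWAS SNPs to significant / non-significant / excluded groups.

Four schemes are supported: the plain genome-wide threshold (P < 5e-8), a
sensitivity variant that excludes a band of borderline P-values, and two
linkage-disequilibrium approximations that promote non-significant SNPs to
the significant group — either when they lie within a 1 Mb region around a
threshold-significant SNP, or when they share a published high-LD region
with one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .data_io import ConfigurationError, HighLdRegion, SnpRecord

GENOME_WIDE_ALPHA = 5e-8

SIGNIFICANT = "significant"
NON_SIGNIFICANT = "non_significant"
EXCLUDED = "excluded"


@dataclass
class ClassificationConfig:
    """Parameters of a classification scheme.

    ``window_semantics`` controls how "within a 1 Mb region adjacent to a
    significant SNP" is read: ``"centered"`` (default) treats the region as
    1 Mb centred on the SNP (distance <= window_bp / 2 per side);
    ``"flank"`` uses the full window on each side.
    """

    alpha: float = GENOME_WIDE_ALPHA
    sensitivity_alpha: float | None = None
    ld_mode: str = "none"  # none | window | regions
    window_bp: int = 1_000_000
    window_semantics: str = "centered"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha {self.alpha} outside (0, 1)")
        if self.sensitivity_alpha is not None and not (
            self.alpha < self.sensitivity_alpha < 1.0
        ):
            raise ConfigurationError(
                f"sensitivity_alpha {self.sensitivity_alpha} must exceed alpha {self.alpha}"
            )
        if self.ld_mode not in ("none", "window", "regions"):
            raise ConfigurationError(f"unknown ld_mode {self.ld_mode!r}")
        if self.window_bp <= 0:
            raise ConfigurationError("window_bp must be positive")
        if self.window_semantics not in ("centered", "flank"):
            raise ConfigurationError(f"unknown window_semantics {self.window_semantics!r}")


@dataclass(frozen=True, slots=True)
class GroupAssignment:
    rsid: str
    group: str  # significant | non_significant | excluded
    reason: str  # threshold | sensitivity_band | ld_window | ld_region


def classify_by_threshold(
    snps: Sequence[SnpRecord], alpha: float = GENOME_WIDE_ALPHA
) -> list[GroupAssignment]:
    """Strict threshold partition: P < alpha is significant, P >= alpha is not."""
    return [
        GroupAssignment(
            s.rsid,
            SIGNIFICANT if s.pvalue < alpha else NON_SIGNIFICANT,
            "threshold",
        )
        for s in snps
    ]


def apply_sensitivity(
    snps: Sequence[SnpRecord],
    alpha: float = GENOME_WIDE_ALPHA,
    sensitivity_alpha: float = 5e-7,
) -> list[GroupAssignment]:
    """Threshold partition with a borderline band excluded.

    SNPs with ``alpha <= P < sensitivity_alpha`` are removed from the
    non-significant group so that the delineation between groups is
    sharper; the significant set is unchanged.
    """
    if sensitivity_alpha <= alpha:
        raise ConfigurationError(
            f"sensitivity_alpha {sensitivity_alpha} must exceed alpha {alpha}"
        )
    out = []
    for s in snps:
        if s.pvalue < alpha:
            out.append(GroupAssignment(s.rsid, SIGNIFICANT, "threshold"))
        elif s.pvalue < sensitivity_alpha:
            out.append(GroupAssignment(s.rsid, EXCLUDED, "sensitivity_band"))
        else:
            out.append(GroupAssignment(s.rsid, NON_SIGNIFICANT, "threshold"))
    return out


def expand_by_window(
    assignments: Sequence[GroupAssignment],
    snps: Sequence[SnpRecord],
    window_bp: int = 1_000_000,
    semantics: str = "centered",
) -> list[GroupAssignment]:
    """Promote non-significant SNPs near a threshold-significant SNP.

    A non-significant SNP becomes significant (reason ``ld_window``) iff a
    threshold-significant SNP on the same chromosome lies within the
    half-window (``window_bp // 2`` for centered semantics, ``window_bp``
    for flank semantics).
    """
    if len(assignments) != len(snps):
        raise ConfigurationError("assignments and snps must be parallel sequences")
    half = window_bp // 2 if semantics == "centered" else window_bp
    by_group = {a.rsid: a.group for a in assignments}
    sig_pos: dict[str, np.ndarray] = {}
    for s in snps:
        if by_group[s.rsid] == SIGNIFICANT:
            sig_pos.setdefault(s.chrom, []).append(s.pos)  # type: ignore[arg-type]
    sig_pos = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in sig_pos.items()}

    out: list[GroupAssignment] = []
    for a, s in zip(assignments, snps):
        if a.group != NON_SIGNIFICANT or s.chrom not in sig_pos:
            out.append(a)
            continue
        arr = sig_pos[s.chrom]
        i = int(np.searchsorted(arr, s.pos))
        near = False
        if i < len(arr) and arr[i] - s.pos <= half:
            near = True
        if not near and i > 0 and s.pos - arr[i - 1] <= half:
            near = True
        out.append(replace(a, group=SIGNIFICANT, reason="ld_window") if near else a)
    return out


def merge_regions(regions: Iterable[HighLdRegion]) -> list[HighLdRegion]:
    """Merge overlapping regions per chromosome (touching half-open spans
    are disjoint and stay separate)."""
    by_chrom: dict[str, list[HighLdRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    merged: list[HighLdRegion] = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: r.start)
        cur_start, cur_end = rs[0].start, rs[0].end
        for r in rs[1:]:
            if r.start < cur_end:
                cur_end = max(cur_end, r.end)
            else:
                merged.append(HighLdRegion(chrom, cur_start, cur_end))
                cur_start, cur_end = r.start, r.end
        merged.append(HighLdRegion(chrom, cur_start, cur_end))
    return merged


def expand_by_ld_regions(
    assignments: Sequence[GroupAssignment],
    snps: Sequence[SnpRecord],
    regions: Iterable[HighLdRegion],
) -> list[GroupAssignment]:
    """Promote non-significant SNPs sharing a high-LD region with a significant one.

    Regions are merged before use; for every region containing at least one
    threshold-significant SNP, each non-significant SNP inside it is
    reassigned as significant with reason ``ld_region``.
    """
    if len(assignments) != len(snps):
        raise ConfigurationError("assignments and snps must be parallel sequences")
    merged = merge_regions(regions)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {r.chrom for r in merged}:
        rs = [r for r in merged if r.chrom == chrom]
        starts[chrom] = np.asarray([r.start for r in rs], dtype=np.int64)
        ends[chrom] = np.asarray([r.end for r in rs], dtype=np.int64)

    def region_of(s: SnpRecord) -> tuple[str, int] | None:
        if s.chrom not in starts:
            return None
        i = int(np.searchsorted(starts[s.chrom], s.pos0, side="right")) - 1
        if i >= 0 and s.pos0 < ends[s.chrom][i]:
            return (s.chrom, i)
        return None

    hot: set[tuple[str, int]] = set()
    for a, s in zip(assignments, snps):
        if a.group == SIGNIFICANT:
            reg = region_of(s)
            if reg is not None:
                hot.add(reg)

    out: list[GroupAssignment] = []
    for a, s in zip(assignments, snps):
        if a.group == NON_SIGNIFICANT and region_of(s) in hot:
            out.append(replace(a, group=SIGNIFICANT, reason="ld_region"))
        else:
            out.append(a)
    return out


def classify(
    snps: Sequence[SnpRecord],
    config: ClassificationConfig | None = None,
    ld_regions: Iterable[HighLdRegion] | None = None,
) -> list[GroupAssignment]:
    """Dispatch to the scheme described by ``config``."""
    config = config or ClassificationConfig()
    if config.sensitivity_alpha is not None:
        return apply_sensitivity(snps, config.alpha, config.sensitivity_alpha)
    base = classify_by_threshold(snps, config.alpha)
    if config.ld_mode == "window":
        return expand_by_window(base, snps, config.window_bp, config.window_semantics)
    if config.ld_mode == "regions":
        if ld_regions is None:
            raise ConfigurationError("ld_mode='regions' requires ld_regions")
        return expand_by_ld_regions(base, snps, ld_regions)
    return base


def group_counts(assignments: Iterable[GroupAssignment]) -> dict[str, int]:
    counts = {SIGNIFICANT: 0, NON_SIGNIFICANT: 0, EXCLUDED: 0}
    for a in assignments:
        counts[a.group] += 1
    return counts
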