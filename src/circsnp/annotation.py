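"""miRNA target-site density per circRNA and candidate SNP/circRNA selection.

Density is the number of target sites linked to a circRNA divided by the
genomic span length (end - start).  Candidate selection applies, in order:
genome-wide significance on a locus, a minor-allele-frequency floor, an
evidence floor (detection in multiple cell lines/tissues), proximity to the
backsplice junction, and lead/proxy LD status.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_io import (
    CircRnaLocus,
    ConfigurationError,
    DataError,
    MirnaTargetSite,
    SnpRecord,
)
from .locus_enrichment import OverlapIndex


@dataclass(frozen=True)
class MirnaDensityRecord:
    circ_id: str
    raw_count: int
    span_length: int
    density: float


@dataclass
class MirnaLinkReport:
    """Join of significant-SNP-bearing circRNAs against a target-site table."""

    n_circ: int
    n_linked: int
    fraction_linked: float
    sites_by_circ: dict[str, list[MirnaTargetSite]]
    circs_per_mirna: dict[str, int]


def link_mirna_targets(
    circ_ids: Iterable[str], sites: Iterable[MirnaTargetSite]
) -> MirnaLinkReport:
    """Link circRNAs (those bearing >= 1 significant SNP) to miRNA sites by id."""
    circ_ids = set(circ_ids)
    sites_by_circ: dict[str, list[MirnaTargetSite]] = defaultdict(list)
    mirna_circs: dict[str, set[str]] = defaultdict(set)
    for s in sites:
        if s.circ_id in circ_ids:
            sites_by_circ[s.circ_id].append(s)
            mirna_circs[s.mirna_id].add(s.circ_id)
    n_linked = len(sites_by_circ)
    return MirnaLinkReport(
        n_circ=len(circ_ids),
        n_linked=n_linked,
        fraction_linked=n_linked / len(circ_ids) if circ_ids else 0.0,
        sites_by_circ=dict(sites_by_circ),
        circs_per_mirna={m: len(cs) for m, cs in mirna_circs.items()},
    )


def mirna_density(raw_count: int, span_length: int) -> float:
    """Target sites per base of genomic span."""
    if span_length <= 0:
        raise ConfigurationError(f"span_length must be positive, got {span_length}")
    if raw_count < 0:
        raise ConfigurationError(f"raw_count must be non-negative, got {raw_count}")
    return raw_count / span_length


def density_table(
    loci: Sequence[CircRnaLocus], sites: Iterable[MirnaTargetSite]
) -> pd.DataFrame:
    """Per-circRNA site counts, span lengths, densities and both rankings."""
    counts: dict[str, int] = defaultdict(int)
    for s in sites:
        counts[s.circ_id] += 1
    rows = [
        {
            "circ_id": c.circ_id,
            "raw_count": counts.get(c.circ_id, 0),
            "span_length": c.length,
            "density": mirna_density(counts.get(c.circ_id, 0), c.length),
        }
        for c in loci
    ]
    df = pd.DataFrame(rows, columns=["circ_id", "raw_count", "span_length", "density"])
    if len(df):
        df["rank_by_density"] = df["density"].rank(ascending=False, method="min").astype(int)
        df["rank_by_count"] = df["raw_count"].rank(ascending=False, method="min").astype(int)
    return df


def distance_to_bsj(snp_pos_1based: int, locus: CircRnaLocus) -> int:
    """Distance (bases) from a SNP inside the locus to the nearer backsplice end.

    Measured in 1-based closed terms against the printed span endpoints;
    a SNP exactly on an endpoint is at distance 0.
    """
    start1, end1 = locus.start + 1, locus.end
    if not (start1 <= snp_pos_1based <= end1):
        raise DataError(
            f"position {snp_pos_1based} outside locus {locus.circ_id} "
            f"[{start1}, {end1}]"
        )
    return min(snp_pos_1based - start1, end1 - snp_pos_1based)


@dataclass
class CandidateCriteria:
    """Thresholds of the four-stage candidate filter."""

    min_maf: float = 0.30
    min_evidence: int = 2
    max_bsj_distance: int = 2000  # strict: distance < max_bsj_distance
    require_lead_or_proxy: bool = True

    def __post_init__(self):
        if self.min_maf <= 0 or self.min_evidence <= 0 or self.max_bsj_distance <= 0:
            raise ConfigurationError("candidate criteria thresholds must be positive")


STAGES = ("on_locus", "maf", "evidence", "bsj_distance", "lead_or_proxy")


@dataclass(frozen=True)
class Candidate:
    rsid: str
    circ_id: str
    maf: float | None
    bsj_distance: int
    n_evidence: int
    stage_reached: str


def select_candidates(
    sig_snps: Sequence[SnpRecord],
    loci: Sequence[CircRnaLocus],
    ld_proxy_flags: Mapping[str, bool],
    criteria: CandidateCriteria | None = None,
    index: OverlapIndex | None = None,
) -> tuple[list[Candidate], dict[str, int]]:
    """Apply the staged candidate filter to significant SNPs.

    Returns candidates that survive every stage (ranked by ascending
    backsplice-junction distance) plus per-stage survivor counts.  A SNP
    on several loci passes a stage if any containing locus satisfies the
    cumulative constraints; its reported locus is the surviving one with
    the smallest distance.
    """
    criteria = criteria or CandidateCriteria()
    index = index if index is not None else OverlapIndex(loci)
    survivors: dict[str, int] = {s: 0 for s in STAGES}
    passed: list[Candidate] = []

    for snp in sig_snps:
        containing = index.loci_at(snp.chrom, snp.pos)
        if not containing:
            continue
        survivors["on_locus"] += 1
        if snp.maf is None or snp.maf < criteria.min_maf:
            continue
        survivors["maf"] += 1
        with_evidence = [c for c in containing if c.n_evidence >= criteria.min_evidence]
        if not with_evidence:
            continue
        survivors["evidence"] += 1
        near = [
            (distance_to_bsj(snp.pos, c), c)
            for c in with_evidence
            if distance_to_bsj(snp.pos, c) < criteria.max_bsj_distance
        ]
        if not near:
            continue
        survivors["bsj_distance"] += 1
        if criteria.require_lead_or_proxy and not ld_proxy_flags.get(snp.rsid, False):
            continue
        survivors["lead_or_proxy"] += 1
        dist, best = min(near, key=lambda t: (t[0], t[1].circ_id))
        passed.append(
            Candidate(
                rsid=snp.rsid,
                circ_id=best.circ_id,
                maf=snp.maf,
                bsj_distance=dist,
                n_evidence=best.n_evidence,
                stage_reached="lead_or_proxy",
            )
        )
    passed.sort(key=lambda c: (c.bsj_distance, c.rsid))
    return passed, survivors
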