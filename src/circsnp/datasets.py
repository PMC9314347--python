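"""Published summary numbers used as worked-example inputs.

These are the printed study inputs for the BMI SNP/circRNA analyses: the
2x2 enrichment counts per circRNA database, the sex-stratified counts, the
rs4752856 / hsa_circ_0022025 pair, the genotype counts of the assayed
cohort, and the 8-subject x 3-replicate primer-extension peak-ratio table
for the heterozygous carriers.  All analyses recompute their statistics
from these inputs at run time.
"""

from __future__ import annotations

from .data_io import AllelicTriplicate, CircRnaLocus, SnpRecord

# lead BMI SNP chosen for in-vitro follow-up (GRCh37, 1-based)
RS4752856 = SnpRecord(
    rsid="rs4752856", chrom="11", pos=47_648_402, pvalue=9.4e-46,
    beta=0.0242, maf=0.3526,
)

# MTCH2-derived circRNA carrying it; printed span chr11:47,647,226-47,648,679
# (1-based closed), detected in multiple cell lines / tissues
HSA_CIRC_0022025 = CircRnaLocus(
    circ_id="hsa_circ_0022025", chrom="11",
    start=47_647_226 - 1, end=47_648_679,
    n_evidence=5, source_db="circBase",
)

# BMI enrichment 2x2 cells (a, b, c, d) = (significant on-locus, significant
# off-locus, non-significant on-locus, non-significant off-locus).
# 40,835 significant and 2,283,734 non-significant SNPs in total; the
# circAtlas non-significant on-locus cell is 54.96% of the latter.
BMI_SIG_TOTAL = 40_835
BMI_NONSIG_TOTAL = 2_283_734

BMI_ENRICHMENT_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "circAtlas": (25_669, BMI_SIG_TOTAL - 25_669, 1_255_140, BMI_NONSIG_TOTAL - 1_255_140),
}

# Sex-stratified BMI analysis against circBase loci:
# females: 27,653 significant / 27,352,598 non-significant SNPs, 7,109 and
# 5,292,550 on-locus; males: 22,833 / 27,357,420 with 5,372 and 5,294,287.
SEX_STRATIFIED_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "female": (7_109, 27_653 - 7_109, 5_292_550, 27_352_598 - 5_292_550),
    "male": (5_372, 22_833 - 5_372, 5_294_287, 27_357_420 - 5_294_287),
}

# genotype counts of the 21 assayed participants at rs4752856
GENOTYPE_COUNTS = {"G/G": 10, "G/A": 10, "A/A": 1}

# A/G peak ratios (circRNA cDNA, gDNA) per heterozygous subject and
# replicate; two further heterozygous subjects were excluded upstream for
# low signal and are not part of this table.
_ALLELIC_ROWS: list[tuple[str, int, float, float]] = [
    ("Subject 1", 1, 0.61, 0.59), ("Subject 1", 2, 0.65, 0.55), ("Subject 1", 3, 0.76, 0.58),
    ("Subject 2", 1, 0.62, 0.59), ("Subject 2", 2, 0.66, 0.56), ("Subject 2", 3, 0.80, 0.56),
    ("Subject 3", 1, 0.70, 0.59), ("Subject 3", 2, 0.78, 0.55), ("Subject 3", 3, 0.80, 0.56),
    ("Subject 6", 1, 0.65, 0.60), ("Subject 6", 2, 0.84, 0.57), ("Subject 6", 3, 0.75, 0.56),
    ("Subject 7", 1, 0.74, 0.57), ("Subject 7", 2, 0.71, 0.57), ("Subject 7", 3, 0.79, 0.59),
    ("Subject 8", 1, 0.62, 0.57), ("Subject 8", 2, 0.70, 0.54), ("Subject 8", 3, 0.75, 0.58),
    ("Subject 9", 1, 0.69, 0.62), ("Subject 9", 2, 0.80, 0.60), ("Subject 9", 3, 0.72, 0.60),
    ("Subject 10", 1, 1.08, 0.59), ("Subject 10", 2, 1.37, 0.56), ("Subject 10", 3, 1.25, 0.57),
]


def rs4752856_allelic_ratios() -> list[AllelicTriplicate]:
    """Primer-extension replicates of the eight analysed heterozygotes."""
    return [
        AllelicTriplicate(
            subject_id=s, genotype="G/A", replicate=rep, ag_circ=circ, ag_gdna=gdna
        )
        for s, rep, circ, gdna in _ALLELIC_ROWS
    ]
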