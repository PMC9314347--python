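"""Staged selection of a SNP/circRNA pair for wet-lab follow-up.

A candidate must be a genome-wide significant SNP on a circRNA locus, be
common enough for heterozygote assays (MAF >= 0.30), lie on a circRNA
detected in multiple cell lines/tissues, sit < 2 kb from the backsplice
junction (so junction and SNP amplify on one fragment), and be a lead SNP
or a proxy of one.
"""

from circsnp import select_candidates
from circsnp.datasets import HSA_CIRC_0022025, RS4752856

cands, stages = select_candidates(
    [RS4752856], [HSA_CIRC_0022025], ld_proxy_flags={"rs4752856": True}
)
print("survivors per stage:", ", ".join(f"{k}={v}" for k, v in stages.items()))
for c in cands:
    print(f"candidate: {c.rsid} on {c.circ_id}: MAF = {c.maf}, "
          f"BSJ distance = {c.bsj_distance} bp, evidence = {c.n_evidence}")
# The published pair survives every stage: MAF 0.3526, 277 bp from the
# nearer backsplice end, multi-tissue support, lead SNP.
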