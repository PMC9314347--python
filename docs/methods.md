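# Methods

## Coordinates and overlap semantics

All intervals are stored 0-based half-open. circRNA database dumps usually
print 1-based closed spans `[s, e]`; the reader converts them to
`[s-1, e)` when the caller declares the `onebased_closed` dialect, and the
writers convert back, so the conversion is an involution. A SNP's point
interval is `[pos-1, pos)`. Consequence: a SNP exactly at a printed start
or stop position of a locus is on-locus, which matches treating the printed
span as the locus in 1-based closed terms. Loci are strandless spans; no
splice-isoform structure is modelled, so the span of a multi-exon circRNA
overstates its mature length (see Limitations).

Bulk overlap counting merges each chromosome's spans into disjoint
intervals and uses binary search over the boundary arrays (vectorised over
all SNPs); per-position lookup of the individual containing loci uses an
interval tree. Both paths are checked against an O(n·m) double loop in the
tests. A SNP in several loci counts once; duplicate rsids count once.

## SNP classification

Four schemes, all strict at the boundary:

- **threshold**: significant iff P < α (default α = 5×10⁻⁸); P = α is
  non-significant.
- **sensitivity**: additionally excludes α ≤ P < α_s for a higher cutoff
  α_s ∈ {5×10⁻⁷, 5×10⁻⁶, 5×10⁻⁵}. The band's lower edge is included in
  the exclusion so the three groups always partition the input; a SNP with
  P exactly α is excluded rather than kept.
- **ld window**: a non-significant SNP becomes significant if a
  threshold-significant SNP on the same chromosome lies within the
  half-window. "Within a 1 Mb region adjacent to a significant SNP" is
  read as a 1 Mb region centred on the SNP (≤ 500 kb per side); a
  `window_semantics="flank"` knob instead uses the full window per side.
- **ld regions**: regions are merged where they genuinely overlap
  (touching half-open regions stay separate, which matters when block
  tilings are used as region lists); every region containing ≥ 1
  threshold-significant SNP promotes all its non-significant SNPs.

Both expansions are monotone (they only add to the significant group),
conserve totals, and are idempotent.

## Enrichment test

Pearson χ² on the 2×2 table without Yates correction, with a `correction`
flag for small tables; the χ² itself is delegated to
`scipy.stats.chi2_contingency`. The odds ratio uses the Woolf logit
interval with the z quantile taken from the normal distribution for
arbitrary confidence levels. Zero cells raise rather than silently apply a
Haldane 0.5 correction, since the analyses this package targets have cell
counts in the thousands; degenerate margins raise before the χ². No
multiple-testing correction is applied across databases or strata. The
between-strata comparison reuses the same machinery with rows = strata
among significant SNPs, oriented stratum-1 odds / stratum-2 odds.

## miRNA annotation and candidate selection

Target sites are linked to circRNAs by identifier (sites need not fall
inside the span; site coordinates are carried but not used for linkage).
Density is raw site count divided by genomic span length `end − start`,
with rankings by density and by raw count.

Candidate selection applies stages in order: on-locus significance → MAF ≥
0.30 → evidence in ≥ 2 cell lines/tissues → backsplice-junction distance
strictly < 2000 bp (distance = bases to the nearer printed span endpoint,
0 at an endpoint) → lead-or-proxy LD status (an input flag; no r² is
computed). Survivor counts per stage are reported and are monotonically
non-increasing. MAF and evidence commute: reordering them changes the
intermediate counts, never the final set.

## Allelic imbalance

The normalised value is the exact quotient of the two A/G peak ratios; it
is invariant to common scaling of the two inputs. Homozygous subjects are
assay controls and never enter inference; low-signal subjects are removed
via an explicit exclusion list (no automatic QC threshold is applied, since
signal quality is an assay-level judgement). Subject means over replicates
feed a one-sample Wilcoxon signed-rank test against 1: zero differences are
dropped, absolute differences ranked with midranks,

    z = (W₊ − n(n+1)/4) / √(n(n+1)(2n+1)/24)

with no continuity and no tie correction, a two-sided normal P-value, and
effect size r = z/√(2n). This convention is stated explicitly because
statistics packages differ in the correction defaults; the package's tests
pin it against an exact enumeration oracle (all 2ⁿ sign assignments) and
against scipy's uncorrected normal approximation. The asymptotic P is
within 0.01 of the exact P from n ≈ 15 on ties-free data; at n = 8 it is a
serviceable approximation (the exact one-sided P for all-positive
differences is 1/256). Descriptive means carry t-based confidence
intervals.

Hardy–Weinberg QC: Pearson goodness-of-fit χ² (df = 1) is always reported;
for cohorts below 50 subjects the verdict uses the exact conditional test
(probability of the observed heterozygote count given the allele counts,
summing outcomes no more probable than observed).

## Synthetic data

The generators emulate the study's input formats with known truth:

- **Loci**: spans with log-uniform lengths (default 200 bp – 20 kb) placed
  uniformly on synthetic autosomes (default 4 × 10 Mb); overlap allowed,
  evidence counts 1–5.
- **SNPs**: significant fraction 0.018 (mirroring ~40.8 k of 2.32 M);
  significant P-values log-uniform below 5×10⁻⁸, others log-uniform above.
  Placement is per-SNP Bernoulli: probability 0.63 (significant) or 0.55
  (non-significant) of landing uniformly inside a uniformly chosen locus,
  otherwise length-weighted uniform in inter-locus space. These defaults
  reproduce the observed on-locus fractions of the motivating analysis, and
  the model gives the closed-form truth OR = [p_s/(1−p_s)]/[p_n/(1−p_n)]
  (≈ 1.39 at the defaults).
- **LD**: chromosomes tiled into 1 Mb blocks; a SNP is a proxy if it shares
  a block with a threshold-significant SNP. No coalescent realism.
- **Allelic assay**: per replicate, gDNA ratio = ρ_g·ε and circRNA ratio =
  ρ·ρ_g·ε′ with ε, ε′ log-normal with coefficient of variation `cv`.
  Defaults n = 8 subjects × 3 replicates, true skew ρ = 1.25, baseline
  ρ_g = 0.57 (the dye/peak bias a balanced genome shows in this assay),
  cv = 0.1, consistent with the replicate spread of the published table.

Each generator draws from its own `numpy` PCG64 stream seeded at a fixed
offset from the study seed, so stages are reproducible independently.

What the synthetic model does **not** capture: positional clustering of
association signal (placement is independent across SNPs, so there is no
genuine LD between P-values and position), realistic allele-frequency and
effect-size architecture, database-specific annotation noise. Passing the
calibration tests therefore shows the statistics behave correctly under
independent sampling — not that they are robust to correlated SNPs, which
the LD schemes only approximate.

## Calibration experiments

`circsnp.experiments` runs the full pipeline repeatedly on synthetic
studies: the null type-I error uses 1000 replicates of 4000 SNPs (25%
significant, both groups placed at 0.5) and should reject at ≈ 5%; Woolf
coverage uses 200 replicates of 100,000 SNPs (2% significant, placements
0.6/0.5, true OR 1.5) and should cover ≥ 93–95%. These replicate counts and
sizes keep each experiment around a minute on one core while leaving the
Monte-Carlo error well below the tolerances being checked (binomial SE
≈ 0.007 for the type-I rate, ≈ 0.015 for coverage).

## Numerical and degenerate-input choices

- Unparsable GWAS rows are skipped and counted, not fatal; missing optional
  fields are written as `NA` so whitespace-delimited columns stay aligned.
- Tested-allele frequencies are folded to MAF = min(f, 1−f); values outside
  (0, 1) become missing.
- Ties in Wilcoxon ranks use midranks; exact ties require exactly equal
  floating-point differences (binary representation caveat, noted in the
  tests).
- Duplicate rsids and duplicate circRNA records keep the first occurrence,
  with removals counted per rule in the preprocessing reports.
- All randomness flows from explicit integer seeds.

## Known limitations

Genomic-span overlap overestimates on-transcript overlap for multi-exon
circRNAs (flanking-intron SNPs still count); the LD window/region schemes
are coarse approximations that dilute true enrichment towards the
non-significant rate when the promoted SNPs were never truly associated;
lift-over is represented only by a per-record validity flag; no permutation
null conditioned on SNP density is provided.
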