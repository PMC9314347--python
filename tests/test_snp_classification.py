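import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circsnp.data_io import ConfigurationError, HighLdRegion, SnpRecord
from circsnp.snp_classification import (
    EXCLUDED,
    NON_SIGNIFICANT,
    SIGNIFICANT,
    ClassificationConfig,
    apply_sensitivity,
    classify,
    classify_by_threshold,
    expand_by_ld_regions,
    expand_by_window,
    group_counts,
    merge_regions,
)


def snp(rsid, pvalue, chrom="1", pos=100):
    return SnpRecord(rsid, chrom, pos, pvalue)


class TestThreshold:
    @pytest.mark.parametrize(
        "pvalue,expected",
        [(4.9e-8, SIGNIFICANT), (5e-8, NON_SIGNIFICANT), (1.0, NON_SIGNIFICANT)],
    )
    def test_strict_inequality_boundary(self, pvalue, expected):
        (a,) = classify_by_threshold([snp("rs1", pvalue)])
        assert a.group == expected

    def test_partition_counts(self):
        snps = [snp(f"rs{i}", p) for i, p in enumerate([1e-10, 5e-8, 0.3, 4e-9, 0.9])]
        counts = group_counts(classify_by_threshold(snps))
        assert counts[SIGNIFICANT] == 2 and counts[NON_SIGNIFICANT] == 3

    def test_invariant_to_input_order(self, rng):
        snps = [snp(f"rs{i}", float(p)) for i, p in enumerate(rng.uniform(1e-10, 1, 50))]
        direct = {a.rsid: a.group for a in classify_by_threshold(snps)}
        shuffled = list(snps)
        rng.shuffle(shuffled)
        assert {a.rsid: a.group for a in classify_by_threshold(shuffled)} == direct


class TestSensitivity:
    @pytest.mark.parametrize(
        "pvalue,expected",
        [
            (2e-7, EXCLUDED),          # inside the exclusion band
            (5e-7, NON_SIGNIFICANT),   # band upper bound is exclusive
            (1e-9, SIGNIFICANT),       # significant set unchanged
            (5e-8, EXCLUDED),          # band lower bound kept in the band
        ],
    )
    def test_band_boundaries(self, pvalue, expected):
        (a,) = apply_sensitivity([snp("rs1", pvalue)], sensitivity_alpha=5e-7)
        assert a.group == expected

    def test_significant_set_invariant_across_cutoffs(self):
        snps = [snp(f"rs{i}", float(p)) for i, p in enumerate(
            np.logspace(-12, -0.1, 40)
        )]
        base = {a.rsid for a in classify_by_threshold(snps) if a.group == SIGNIFICANT}
        for cutoff in (5e-7, 5e-6, 5e-5):
            sens = {a.rsid for a in apply_sensitivity(snps, sensitivity_alpha=cutoff)
                    if a.group == SIGNIFICANT}
            assert sens == base

    def test_inverted_cutoff_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            apply_sensitivity([snp("rs1", 0.5)], alpha=5e-8, sensitivity_alpha=5e-9)


def brute_force_window(snps, assignments, half):
    """All-pairs oracle for the 1 Mb-region reclassification."""
    groups = {a.rsid: a.group for a in assignments}
    sig = [s for s in snps if groups[s.rsid] == SIGNIFICANT]
    out = {}
    for s in snps:
        g = groups[s.rsid]
        if g == NON_SIGNIFICANT and any(
            t.chrom == s.chrom and abs(t.pos - s.pos) <= half for t in sig
        ):
            g = SIGNIFICANT
        out[s.rsid] = g
    return out


class TestWindowExpansion:
    def test_neighbour_within_half_window_promoted(self):
        snps = [snp("lead", 1e-9, pos=1_000_000), snp("near", 0.5, pos=1_400_000)]
        out = expand_by_window(classify_by_threshold(snps), snps, window_bp=1_000_000)
        assert out[1].group == SIGNIFICANT and out[1].reason == "ld_window"
        assert out[0].reason == "threshold"

    def test_different_chromosome_not_promoted(self):
        snps = [snp("lead", 1e-9, chrom="1", pos=1_000_000),
                snp("far", 0.5, chrom="2", pos=1_000_000)]
        out = expand_by_window(classify_by_threshold(snps), snps, window_bp=1_000_000)
        assert out[1].group == NON_SIGNIFICANT

    def test_matches_all_pairs_oracle_on_random_instance(self, rng):
        snps = [
            snp(f"rs{i}", float(rng.uniform(1e-10, 1)),
                chrom=str(int(rng.integers(1, 4))), pos=int(rng.integers(1, 5_000_000)))
            for i in range(200)
        ]
        base = classify_by_threshold(snps)
        got = {a.rsid: a.group for a in expand_by_window(base, snps, 1_000_000)}
        assert got == brute_force_window(snps, base, 500_000)

    def test_flank_semantics_uses_full_window(self):
        snps = [snp("lead", 1e-9, pos=1_000_000), snp("near", 0.5, pos=1_900_000)]
        base = classify_by_threshold(snps)
        centered = expand_by_window(base, snps, 1_000_000, semantics="centered")
        flank = expand_by_window(base, snps, 1_000_000, semantics="flank")
        assert centered[1].group == NON_SIGNIFICANT
        assert flank[1].group == SIGNIFICANT


def brute_force_regions(snps, assignments, regions):
    groups = {a.rsid: a.group for a in assignments}
    merged = merge_regions(regions)

    def inside(s, r):
        return s.chrom == r.chrom and r.start <= s.pos - 1 < r.end

    out = {}
    for s in snps:
        g = groups[s.rsid]
        if g == NON_SIGNIFICANT:
            for r in merged:
                if inside(s, r) and any(
                    groups[t.rsid] == SIGNIFICANT and inside(t, r) for t in snps
                ):
                    g = SIGNIFICANT
                    break
        out[s.rsid] = g
    return out


class TestRegionExpansion:
    def test_hot_region_promotes_all_inside(self):
        snps = [snp("lead", 1e-9, pos=150)] + [
            snp(f"n{i}", 0.5, pos=200 + i) for i in range(3)
        ]
        out = expand_by_ld_regions(
            classify_by_threshold(snps), snps, [HighLdRegion("1", 100, 1000)]
        )
        assert all(a.group == SIGNIFICANT for a in out)

    def test_cold_region_unchanged(self):
        snps = [snp("n1", 0.5, pos=150), snp("n2", 0.5, pos=160)]
        out = expand_by_ld_regions(
            classify_by_threshold(snps), snps, [HighLdRegion("1", 100, 1000)]
        )
        assert all(a.group == NON_SIGNIFICANT for a in out)

    def test_matches_region_scan_oracle(self, rng):
        snps = [
            snp(f"rs{i}", float(rng.uniform(1e-10, 1)),
                chrom=str(int(rng.integers(1, 3))), pos=int(rng.integers(1, 100_000)))
            for i in range(150)
        ]
        regions = []
        for _ in range(8):
            start = int(rng.integers(0, 90_000))
            regions.append(
                HighLdRegion(str(int(rng.integers(1, 3))), start, start + int(rng.integers(100, 20_000)))
            )
        base = classify_by_threshold(snps)
        got = {a.rsid: a.group for a in expand_by_ld_regions(base, snps, regions)}
        assert got == brute_force_regions(snps, base, regions)

    def test_idempotent(self, rng):
        snps = [
            snp(f"rs{i}", float(rng.uniform(1e-10, 1)), pos=int(rng.integers(1, 10_000)))
            for i in range(60)
        ]
        regions = [HighLdRegion("1", 0, 5_000), HighLdRegion("1", 4_000, 9_000)]
        once = expand_by_ld_regions(classify_by_threshold(snps), snps, regions)
        twice = expand_by_ld_regions(once, snps, regions)
        assert once == twice


class TestPartitionProperty:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        pvalues=st.lists(
            st.floats(min_value=1e-30, max_value=1.0, allow_nan=False), min_size=1, max_size=80
        ),
        scheme=st.sampled_from(["threshold", "sensitivity", "window", "regions"]),
    )
    def test_groups_always_partition_the_input(self, pvalues, scheme):
        snps = [snp(f"rs{i}", p, pos=i + 1) for i, p in enumerate(pvalues)]
        if scheme == "threshold":
            out = classify_by_threshold(snps)
        elif scheme == "sensitivity":
            out = apply_sensitivity(snps, sensitivity_alpha=5e-6)
        elif scheme == "window":
            out = expand_by_window(classify_by_threshold(snps), snps, 100)
        else:
            out = expand_by_ld_regions(
                classify_by_threshold(snps), snps, [HighLdRegion("1", 0, 40)]
            )
        counts = group_counts(out)
        assert sum(counts.values()) == len(snps)
        if scheme != "sensitivity":
            assert counts[EXCLUDED] == 0  # expansions never create exclusions

    def test_expansion_is_monotone(self, rng):
        snps = [
            snp(f"rs{i}", float(rng.uniform(1e-10, 1)), pos=int(rng.integers(1, 1_000_000)))
            for i in range(100)
        ]
        base = classify_by_threshold(snps)
        base_sig = {a.rsid for a in base if a.group == SIGNIFICANT}
        for out in (
            expand_by_window(base, snps, 1_000_000),
            expand_by_ld_regions(base, snps, [HighLdRegion("1", 0, 500_000)]),
        ):
            assert {a.rsid for a in out if a.group == SIGNIFICANT} >= base_sig


class TestDispatch:
    def test_classify_routes_by_config(self):
        snps = [snp("rs1", 1e-9), snp("rs2", 2e-7), snp("rs3", 0.5)]
        sens = classify(snps, ClassificationConfig(sensitivity_alpha=5e-7))
        assert group_counts(sens)[EXCLUDED] == 1
        with pytest.raises(ConfigurationError):
            classify(snps, ClassificationConfig(ld_mode="regions"))

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            ClassificationConfig(alpha=0.0)
        with pytest.raises(ConfigurationError):
            ClassificationConfig(sensitivity_alpha=5e-9)
        with pytest.raises(ConfigurationError):
            ClassificationConfig(ld_mode="clump")
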