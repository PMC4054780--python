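"""Frequency blocks, differentials, CI thresholds, and criteria ordering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sweepscan import prioritize as pri
from sweepscan.prioritize import (CandidateRegion, FrequencyBlock,
                                  block_differential, check_against_panels,
                                  enrichment_test, find_frequency_blocks,
                                  merge_windows, prioritize_regions,
                                  refine_with_external, sampling_ci_threshold,
                                  transcript_overlap)


def sig_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "sig_s_pi"])
    df["significant"] = df["sig_s_pi"]
    return df


class TestMergeWindows:
    def test_overlapping_step_windows_union(self):
        regions = merge_windows(sig_frame([("1", 1, 50_000, True),
                                           ("1", 2_001, 52_000, True)]))
        assert [(r.start, r.end) for r in regions] == [(1, 52_000)]
        assert regions[0].tests == ["s_pi"]

    def test_disjoint_windows_stay_separate(self):
        regions = merge_windows(sig_frame([("1", 1, 100, True),
                                           ("1", 500, 600, True)]))
        assert len(regions) == 2

    def test_many_windows_in_clusters(self, rng):
        """420 significant windows in 3 clusters merge to 3 regions
        (interval-union oracle: intervaltree merge_overlaps)."""
        from intervaltree import IntervalTree
        rows = []
        for base in (10**6, 3 * 10**6, 7 * 10**6):
            for i in range(140):
                s = base + 2_000 * i
                rows.append(("1", s, s + 49_999, True))
        rng.shuffle(rows)
        df = sig_frame(rows).sort_values(["chrom", "start"])
        regions = merge_windows(df)
        tree = IntervalTree()
        for _, s, e, _ in rows:
            tree.addi(s, e + 1)
        tree.merge_overlaps()
        assert len(regions) == len(tree) == 3
        got = sorted((r.start, r.end) for r in regions)
        assert got == sorted((iv.begin, iv.end - 1) for iv in tree)


class TestFrequencyBlocks:
    def test_uniform_sites_form_one_block(self):
        pos = np.arange(12)
        blocks = find_frequency_blocks(pos, np.full(12, 6 / 12), n_hap=12)
        assert len(blocks) == 1
        assert blocks[0].n_members == 12
        assert blocks[0].f == pytest.approx(0.5)

    def test_below_min_block_is_nothing(self):
        blocks = find_frequency_blocks(np.arange(9), np.full(9, 0.5), n_hap=12)
        assert blocks == []

    def test_large_block_among_scattered_low_frequency(self, rng):
        """135 SNPs near 0.48 among scattered low-frequency sites form a
        single 135-member block (the prioritized-region block structure)."""
        n = 12
        block_pos = np.arange(1_000, 1_000 + 135 * 10, 10)
        block_freq = np.round(rng.uniform(0.44, 0.52, size=135) * n) / n
        noise_pos = np.arange(0, 1_000, 37)
        noise_freq = np.full(len(noise_pos), 1 / n)
        pos = np.concatenate([noise_pos, block_pos])
        freq = np.concatenate([noise_freq, block_freq])
        blocks = find_frequency_blocks(pos, freq, n_hap=n)
        big = max(blocks, key=lambda b: b.n_members)
        assert big.n_members == 135
        assert abs(big.mean_freq - 0.48) < 0.1

    def test_genome_consecutive_mode_breaks_runs(self):
        pos = np.arange(24)
        freq = np.full(24, 0.5)
        freq[11] = 1 / 12  # an intervening low-frequency site
        loose = find_frequency_blocks(pos, freq, 12, genome_consecutive=False)
        strict = find_frequency_blocks(pos, freq, 12, genome_consecutive=True)
        assert max(b.n_members for b in loose) == 23
        assert max(b.n_members for b in strict) == 12


class TestBlockDifferential:
    def block(self, mean_freq=0.48, members=None):
        members = members if members is not None else np.arange(10)
        return FrequencyBlock(f=0.5, chrom="1", positions=members,
                              mean_freq=mean_freq, n_hap=12)

    def control(self, freq, members=None):
        members = members if members is not None else np.arange(10)
        return pd.DataFrame({"pos": members, "freq": freq})

    def test_closer_control_wins(self):
        diff, _ = block_differential(self.block(0.48),
                                     {"CTRL1": self.control(0.16),
                                      "CTRL2": self.control(0.01)})
        assert diff == pytest.approx(0.32)

    def test_second_study_population_arithmetic(self):
        diff, _ = block_differential(self.block(0.42),
                                     {"CTRL1": self.control(0.16),
                                      "CTRL2": self.control(0.01)})
        assert diff == pytest.approx(0.26)

    def test_identical_control_gives_zero(self):
        diff, _ = block_differential(self.block(0.3), {"X": self.control(0.3)})
        assert diff == pytest.approx(0.0)

    def test_missing_sites_excluded_pairwise(self):
        ctrl = self.control([0.1] * 5, members=np.arange(5))
        diff, _ = block_differential(self.block(0.5), {"X": ctrl})
        assert diff == pytest.approx(0.4)


class TestSamplingCiThreshold:
    def test_worked_values(self):
        # n=14 at f=0.5: central {4..10}/14 set -> ~0.21 half-width
        assert sampling_ci_threshold(14, 0.5) == pytest.approx(3 / 14)
        # halved haplotypes (X chromosome): threshold roughly doubles
        t7, t14 = sampling_ci_threshold(7, 0.5), sampling_ci_threshold(14, 0.5)
        assert 0.30 <= t7 <= 0.45
        assert 1.4 <= t7 / t14 <= 2.5

    def test_exact_enumeration_oracle(self):
        """Threshold equals the half-width of the central binomial set
        whose exact coverage is closest to 95%, by direct enumeration."""
        for n, f in [(12, 0.5), (14, 0.25), (20, 0.4)]:
            best = None
            for lo in range(0, n + 1):
                for hi in range(lo, n + 1):
                    cov = sum(sps.binom.pmf(k, n, f) for k in range(lo, hi + 1))
                    # restrict to central equal-tail candidates around f
                    if lo / n <= f <= hi / n:
                        width = max(f - lo / n, hi / n - f)
                        key = (abs(cov - 0.95), width)
                        if best is None or key < best[0]:
                            best = (key, width)
            assert sampling_ci_threshold(n, f) <= best[1] + 1e-9

    def test_shrinks_toward_frequency_extremes(self):
        mid = sampling_ci_threshold(14, 0.5)
        assert sampling_ci_threshold(14, 0.05) < mid
        assert sampling_ci_threshold(14, 0.95) < mid

    def test_non_increasing_in_sample_size(self):
        vals = [sampling_ci_threshold(n, 0.5) for n in (7, 12, 14, 24, 28, 100, 400)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sampling_ci_threshold(1, 0.5)
        with pytest.raises(ValueError):
            sampling_ci_threshold(14, 0.0)


class TestPanelsAndExternal:
    def block(self, mean_freq=0.48):
        return FrequencyBlock(f=0.5, chrom="1", positions=np.arange(10),
                              mean_freq=mean_freq, n_hap=12)

    def panel(self, freq, members=None):
        members = members if members is not None else np.arange(10)
        return pd.DataFrame({"pos": members, "freq": freq})

    def test_pass_requires_every_panel(self):
        ok, _ = check_against_panels(self.block(), {"A": self.panel(0.16),
                                                    "B": self.panel(0.10)}, 0.21)
        assert ok is True
        ok, _ = check_against_panels(self.block(), {"A": self.panel(0.16),
                                                    "B": self.panel(0.45)}, 0.21)
        assert ok is False

    def test_no_overlap_not_evaluable(self):
        empty = self.panel([], members=np.array([], dtype=int))
        ok, _ = check_against_panels(self.block(), {"A": empty}, 0.21)
        assert ok == "not_evaluable"

    def test_weighted_average_worked_example(self):
        assert refine_with_external(0.8, 12, 0.85, 126) == pytest.approx(
            0.846, abs=5e-4)

    def test_external_fixed_point_and_limit(self):
        assert refine_with_external(0.7, 12, 0.7, 126) == pytest.approx(0.7)
        assert refine_with_external(0.7, 12, 0.9, 10**9) == pytest.approx(0.9, abs=1e-6)
        assert refine_with_external(0.7, 12, 0.9, 0) == pytest.approx(0.7)

    @pytest.mark.parametrize("fi,fe,ni,ne", [(0.2, 0.9, 5, 50), (0.9, 0.1, 40, 3)])
    def test_convex_combination(self, fi, fe, ni, ne):
        r = refine_with_external(fi, ni, fe, ne)
        assert min(fi, fe) <= r <= max(fi, fe)


class TestTranscriptOverlap:
    def region(self, start, end):
        return CandidateRegion("chrA", start, end)

    def transcripts(self):
        return pd.DataFrame({
            "chrom": ["chrA"] * 3 + ["chrB"],
            "start": [100, 500, 900, 100],
            "end": [200, 600, 1_000, 200],
            "name": ["GENE1", "GENE2", "GENE3", "OTHER"],
        })

    def test_multi_gene_region(self):
        ok, genes = transcript_overlap(self.region(50, 950), self.transcripts())
        assert ok and genes == ["GENE1", "GENE2", "GENE3"]

    def test_intergenic_region_fails(self):
        ok, genes = transcript_overlap(self.region(250, 450), self.transcripts())
        assert not ok and genes == []

    def test_abutting_transcript_does_not_overlap(self):
        # transcript [100, 200) in BED; region starting at 1-based 201 abuts
        ok, _ = transcript_overlap(self.region(201, 300), self.transcripts())
        assert not ok
        ok, _ = transcript_overlap(self.region(200, 300), self.transcripts())
        assert ok


class TestEnrichment:
    def test_degenerate_all_hits_background(self):
        assert enrichment_test(4, 4, 2187, 2187) == pytest.approx(1.0)

    def test_no_enrichment_upper_tail_is_one(self):
        assert enrichment_test(4, 0, 2187, 44) == pytest.approx(1.0, abs=1e-6)

    def test_matches_hypergeometric_enumeration(self):
        """Upper tail equals an explicit hypergeometric sum."""
        tested, hits, bg, bg_hits = 4, 3, 2187, 44
        N, K = tested + bg, hits + bg_hits
        from math import comb
        brute = sum(comb(K, k) * comb(N - K, tested - k) for k in range(hits, tested + 1)) \
            / comb(N, tested)
        assert enrichment_test(tested, hits, bg, bg_hits) == pytest.approx(
            brute, rel=1e-9)
        assert brute < 1e-3  # strong enrichment signal


class TestCriteriaMonotonicity:
    def test_each_criterion_only_shrinks(self, rng):
        """The surviving set after criterion k+1 is a subset of the set
        after criterion k, across a batch of synthetic regions."""
        n = 12
        regions = []
        study_rows = []
        panels = {}
        external_rows = []
        transcripts = pd.DataFrame({"chrom": ["1"], "start": [0],
                                    "end": [5_000], "name": ["GENE"]})
        for i in range(12):
            start = i * 100_000 + 1
            pos = np.arange(start, start + 40 * 25, 25)
            # half the regions get a tight high-frequency block
            if i % 2 == 0:
                freq = np.round(rng.uniform(0.70, 0.78, size=40) * n) / n
            else:
                freq = rng.integers(1, n, size=40) / n
            study_rows.append(pd.DataFrame({"chrom": "1", "pos": pos, "freq": freq}))
            regions.append(CandidateRegion("1", start, start + 1_000,
                                           tests=["s_pi"]))
            # controls at low frequency; one panel close to study for some
            ctrl_freq = 0.72 if i in (4, 6) else 0.1
            external_rows.append(pd.DataFrame({
                "chrom": "1", "pos": pos,
                "freq": 0.75 if i != 8 else 0.15}))
            panels.setdefault("HAPMAP", []).append(
                pd.DataFrame({"chrom": "1", "pos": pos, "freq": ctrl_freq}))
        study = pd.concat(study_rows, ignore_index=True)
        primary = {"CTRL1": study.assign(freq=0.1), "CTRL2": study.assign(freq=0.05)}
        extra = {"HAPMAP": pd.concat(panels["HAPMAP"], ignore_index=True)}
        external = pd.concat(external_rows, ignore_index=True)
        out = prioritize_regions(regions, study, n, primary, extra_panels=extra,
                                 external=external, n_external=126,
                                 transcripts=transcripts)
        order = ["differential", "panels", "external", "transcript"]
        survivors = []
        current = set(range(len(out)))
        for crit in order:
            current = {i for i in current
                       if out[i].criteria.get(crit) in (True, "not_evaluable")}
            survivors.append(set(current))
        for a, b in zip(survivors, survivors[1:]):
            assert b <= a
        # at least one narrowing actually happened and someone survived
        assert survivors[-1] < set(range(len(out))) or len(out) == 0
        assert any(out[i].prioritized for i in survivors[-1])
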