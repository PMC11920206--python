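"""Site classes, bubble/breakpoint detection and LD behaviour."""

import numpy as np
import pandas as pd
import pytest

from fmscan.bubble_ld import (
    FIXED_CLASSES,
    UNDEFINED,
    _block_boundary,
    classify_sites,
    detect_breakpoint,
    detect_bubble,
    pairwise_r2,
    reference_consistent_segments,
)
from fmscan.regions import GenomicInterval, InvalidParameterError


def profile(freqs, n_called=100, positions=None):
    freqs = np.asarray(freqs, dtype=float)
    if positions is None:
        positions = np.arange(1, freqs.size + 1) * 10
    return pd.DataFrame({"chrom": "chr20", "pos": positions, "freq": freqs,
                         "n_called_alleles": n_called,
                         "missing_frac": 0.0})


class TestClassify:
    @pytest.mark.parametrize("f,expected", [
        (1.0, "FIXED_REF"), (0.97, "FIXED_REF"),
        (0.0, "FIXED_ALT"), (0.04, "FIXED_ALT"),
        (0.5, "FIXED_HET"), (0.47, "FIXED_HET"),
        (0.30, "POLYMORPHIC"), (0.70, "POLYMORPHIC"),
    ])
    def test_class_boundaries(self, f, expected):
        assert classify_sites(profile([f]))[0] == expected

    def test_thin_sites_undefined(self):
        assert classify_sites(profile([0.5], n_called=10))[0] == UNDEFINED

    def test_overlapping_eps_rejected(self):
        with pytest.raises(InvalidParameterError):
            classify_sites(profile([0.5]), eps=0.3)

    def test_partition_complete_and_idempotent(self):
        rng = np.random.default_rng(0)
        f = rng.random(500)
        prof = profile(f, n_called=rng.integers(0, 200, 500))
        c1 = classify_sites(prof)
        c2 = classify_sites(prof)
        assert np.array_equal(c1, c2)
        assert set(np.unique(c1)) <= {"FIXED_REF", "FIXED_ALT", "FIXED_HET",
                                      "POLYMORPHIC", "UNDEFINED"}


class TestBubble:
    def test_flags_and_insufficient(self):
        regions = {"A": GenomicInterval("c", 1, 200, "A"),
                   "B": GenomicInterval("c", 200, 400, "B"),
                   "C": GenomicInterval("c", 400, 500, "C")}
        # A: 15 fixed-ref sites (bubbled); B: 15 polymorphic; C: 3 sites
        f = [1.0] * 15 + [0.3] * 15 + [0.5] * 3
        pos = list(range(10, 160, 10)) + list(range(210, 360, 10)) + \
            [410, 420, 430]
        cls = classify_sites(profile(f, positions=pos))
        rep = detect_bubble(cls, np.array(pos), regions)
        assert rep["A"]["bubble"] and rep["A"]["fixed_fraction"] == 1.0
        assert not rep["B"]["bubble"]
        assert rep["C"]["status"] == "insufficient" and not rep["C"]["bubble"]

    def test_fm2_flags_are_1_0_0(self, fm2_run):
        assert fm2_run["result"]["bubble"].bubble_flags() == \
            (True, False, False)

    def test_wt_cohort_shows_no_bubble(self, fm2_run):
        # classify the wild-type cohort of the same dataset: no region
        # should exceed the bubble threshold
        from fmscan.scanstats import filter_variants, ref_allele_frequency
        res = fm2_run["result"]
        pop = fm2_run["pop"]
        vmf = filter_variants(fm2_run["obs"].variants)
        prof = ref_allele_frequency(vmf, res["groups"]["N/N"])
        cls = classify_sites(prof)
        rep = detect_bubble(cls, vmf.positions, pop.map.named_regions)
        assert not any(rep[r]["bubble"] for r in ("DUP1", "INT", "DUP2"))


class TestBreakpoint:
    def test_perfect_split(self):
        x = [1] * 5 + [0] * 5
        pos = np.arange(10, 110, 10)
        b = detect_breakpoint(x, pos, min_sites=10, lrt_threshold=1.0)
        assert b["index"] == 5
        assert b["position"] == (pos[4] + pos[5]) // 2
        assert (b["rate_left"], b["rate_right"]) == (1.0, 0.0)

    def test_constant_series_gives_none(self):
        pos = np.arange(10, 310, 10)
        assert detect_breakpoint([1] * 30, pos) is None
        assert detect_breakpoint([0] * 30, pos) is None

    def test_noisy_recovery_within_20_sites(self):
        # Bernoulli(0.9) then Bernoulli(0.1), change at site 300 of 1000
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(100):
            x = np.concatenate([rng.random(300) < 0.9,
                                rng.random(700) < 0.1])
            pos = np.arange(1, 1001)
            b = detect_breakpoint(x.astype(int), pos)
            if b is not None and abs(b["index"] - 300) <= 20:
                hits += 1
        assert hits >= 95

    def test_injected_suppression_break_is_recovered(self):
        from fmscan.config import RunConfig
        from fmscan.pipeline import analyze, simulate_and_observe
        cfg = RunConfig(dup1_suppression_break=0.6, seed=2)
        pop, obs = simulate_and_observe(cfg)
        res = analyze(obs.variants, obs.depth, pop.map, cfg,
                      include_trees=False)
        bp = res["bubble"].breakpoint
        truth = pop.truth["dup1_suppression_break"]
        assert bp is not None
        # within a few sites: filtered DUP1 sites are ~3 bp apart here
        assert abs(bp["position"] - truth) <= 10


class TestRefConsistentSegments:
    def test_whole_region_one_segment(self):
        region = GenomicInterval("c", 1, 200, "R")
        prof = profile([0.6] * 10)
        segs = reference_consistent_segments(prof, region)
        assert len(segs) == 1
        assert (segs[0]["start"], segs[0]["end"]) == (10, 100)

    def test_alternating_frequencies_give_no_segment(self):
        region = GenomicInterval("c", 1, 200, "R")
        prof = profile([0.9, 0.1] * 8)
        assert reference_consistent_segments(prof, region) == []

    def test_injected_span_recovered_within_one_site(self):
        from fmscan.config import RunConfig
        from fmscan.pipeline import simulate_and_observe
        from fmscan.scanstats import filter_variants, ref_allele_frequency
        cfg = RunConfig(dup2_ref_span=(0.3, 0.7), sfs_alpha=None, seed=3)
        pop, obs = simulate_and_observe(cfg)
        fm = [s for s, (_, _, g) in zip(pop.samples, pop.individuals)
              if g == "FM/FM"]
        vmf = filter_variants(obs.variants)
        prof = ref_allele_frequency(vmf, fm)
        segs = reference_consistent_segments(prof, pop.map.dup2)
        lo, hi = pop.truth["dup2_ref_span"]
        assert len(segs) == 1
        # ends within one site spacing (~2 bp at this scale and density)
        spacing = np.median(np.diff(
            prof.loc[(prof["pos"] >= pop.map.dup2.start)
                     & (prof["pos"] < pop.map.dup2.end), "pos"]))
        assert abs(segs[0]["start"] - lo) <= 2 * spacing
        assert abs(segs[0]["end"] - hi) <= 2 * spacing


class TestPairwiseR2:
    def test_hand_values(self, toy_matrix_factory):
        vm = toy_matrix_factory([[0, 0, 1, 1, 2, 2],
                                 [2, 2, 1, 1, 0, 0],
                                 [0, 1, 2, 0, 1, 2]])
        r2, _ = pairwise_r2(vm)
        assert r2[0, 1] == pytest.approx(1.0, abs=1e-12)   # perfect negative
        x = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        y = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        hand = (np.mean(x * y) - x.mean() * y.mean()) ** 2 / \
            (x.var() * y.var())
        assert r2[2, 1] == pytest.approx(hand, abs=1e-12)

    def test_invariances(self, toy_matrix_factory):
        rng = np.random.default_rng(6)
        gt = rng.integers(0, 3, size=(6, 30))
        vm = toy_matrix_factory(gt)
        r2, _ = pairwise_r2(vm)
        # sample permutation
        perm = rng.permutation(30)
        vmp = toy_matrix_factory(gt[:, perm])
        r2p, _ = pairwise_r2(vmp)
        np.testing.assert_allclose(r2, r2p, atol=1e-12)
        # allele relabeling flips dosage x -> 2 - x
        vmr = toy_matrix_factory(2 - gt)
        r2r, _ = pairwise_r2(vmr)
        np.testing.assert_allclose(r2, r2r, atol=1e-12)
        # symmetric, unit diagonal
        np.testing.assert_allclose(r2, r2.T, atol=1e-12)
        assert np.all(np.diag(r2) == 1.0)

    def test_too_few_sites_rejected(self, toy_matrix_factory):
        vm = toy_matrix_factory([[0, 1, 2]])
        with pytest.raises(InvalidParameterError):
            pairwise_r2(vm)


class TestBlockBoundary:
    def _two_block_matrix(self, n1, n2, cross=0.0, within=1.0):
        n = n1 + n2
        r2 = np.full((n, n), cross)
        r2[:n1, :n1] = within
        r2[n1:, n1:] = within
        np.fill_diagonal(r2, 1.0)
        return r2

    def test_perfect_blocks_found_at_junction(self):
        r2 = self._two_block_matrix(12, 12)
        pos = np.arange(1, 25) * 10
        b = _block_boundary(r2, pos)
        assert b["index"] == 12
        assert b["contrast"] == pytest.approx(1.0, abs=1e-9)

    def test_uniform_matrix_gives_none(self):
        n = 30
        r2 = np.full((n, n), 0.4)
        np.fill_diagonal(r2, 1.0)
        assert _block_boundary(r2, np.arange(n) * 10 + 10) is None

    def test_boundary_matches_fixed_het_breakpoint(self):
        # the concordance property: the LD block boundary falls within two
        # sites of the fixed-heterozygosity breakpoint
        from fmscan.config import RunConfig
        from fmscan.pipeline import analyze, simulate_and_observe
        hits = 0
        for seed in range(1, 6):
            cfg = RunConfig(dup1_suppression_break=0.6, seed=seed)
            pop, obs = simulate_and_observe(cfg)
            res = analyze(obs.variants, obs.depth, pop.map, cfg,
                          include_trees=False)
            bp = res["bubble"].breakpoint
            ld = res["ld"].boundary
            if bp is None or ld is None:
                continue
            k_bp = np.searchsorted(res["ld"].positions, bp["position"])
            if abs(k_bp - ld["index"]) <= 2:
                hits += 1
        assert hits >= 4
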