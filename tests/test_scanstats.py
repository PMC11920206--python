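"""Scan statistics against independent oracles and hand-computed values."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fmscan.regions import GenomicInterval, InvalidParameterError
from fmscan.scanstats import (
    build_windows,
    filter_variants,
    ref_allele_frequency,
    region_mean,
    windowed_fst,
    windowed_pi,
    zscore_fdr,
)


def one_window(lo=1, hi=10_000):
    return pd.DataFrame({"chrom": ["chr20"], "start": [lo], "end": [hi],
                         "partial": [False]})


# -- oracles ------------------------------------------------------------------

def wc_components_oracle(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) two-population a, b, c written out
    literally, scalar arithmetic only."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2.0
    return a, b, c


def pi_site_bruteforce(alleles):
    """Mean pairwise difference over all allele pairs, by enumeration."""
    pairs = list(itertools.combinations(alleles, 2))
    if not pairs:
        return 0.0
    return sum(a != b for a, b in pairs) / len(pairs)


def bh_oracle(pvals):
    """Benjamini-Hochberg step-up, written out by hand."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * pvals[i] / rank)
        q[i] = prev
    return q


# -- filtering ----------------------------------------------------------------

class TestFilter:
    def test_maf_missingness_and_counting(self, toy_matrix_factory):
        # 10 samples; site0 MAF 0.05 kept, site1 MAF 0.04 < 0.05 removed
        # via a rare alt; site2 has 2/10 missing -> call rate 0.8 removed
        gt = np.zeros((4, 10), dtype=int)
        gt[0, 0] = 1                       # alt freq 1/20 = 0.05
        gt[1, :] = 0                       # monomorphic (MAF 0) removed
        gt[2, 0] = -1
        gt[2, 1] = -1
        gt[2, 2:] = 1                      # call rate 0.8 -> removed
        gt[3, :5] = 2                      # freq 0.5 kept
        vm = toy_matrix_factory(gt)
        kept = filter_variants(vm, maf=0.05, max_missing=0.9)
        assert list(kept.positions) == [10, 40]

    def test_empty_result_allowed(self, toy_matrix_factory):
        vm = toy_matrix_factory(np.zeros((3, 6), dtype=int))
        assert filter_variants(vm).n_sites == 0


class TestRefAlleleFrequency:
    @pytest.mark.parametrize("genos,expected", [
        ([0, 0, 0], 1.0),          # all hom-ref
        ([1, 1, 1], 0.5),          # all het: the collapsed fixed difference
        ([0, 1, 2], 0.5),          # one of each: 3 ref alleles of 6
    ])
    def test_hand_values(self, toy_matrix_factory, genos, expected):
        vm = toy_matrix_factory([genos])
        prof = ref_allele_frequency(vm, vm.samples)
        assert prof["freq"].iloc[0] == expected

    def test_unknown_sample_rejected(self, toy_matrix_factory):
        vm = toy_matrix_factory([[0, 1]])
        with pytest.raises(KeyError):
            ref_allele_frequency(vm, ["NOPE"])

    def test_agrees_with_bruteforce_on_random_matrices(self,
                                                       toy_matrix_factory):
        rng = np.random.default_rng(0)
        for _ in range(20):
            gt = rng.integers(-1, 3, size=(5, 8))
            vm = toy_matrix_factory(gt)
            prof = ref_allele_frequency(vm, vm.samples)
            for i in range(5):
                alleles = []
                for g in gt[i]:
                    if g >= 0:
                        alleles += [0] * (2 - g) + [1] * g
                if alleles:
                    expect = alleles.count(0) / len(alleles)
                    assert prof["freq"].iloc[i] == pytest.approx(expect,
                                                                 abs=1e-15)
                else:
                    assert np.isnan(prof["freq"].iloc[i])


# -- windows ------------------------------------------------------------------

class TestWindows:
    def test_grid_and_partial_flag(self):
        iv = GenomicInterval("chr20", 1, 51, "X")  # 50 bp
        win = build_windows(iv, 20, 10)
        assert list(win["start"]) == [1, 11, 21, 31, 41]
        assert list(win["end"]) == [20, 30, 40, 50, 50]
        assert list(win["partial"]) == [False, False, False, False, True]

    def test_invalid_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_windows(GenomicInterval("c", 1, 10, "X"), 0, 5)


class TestWindowedPi:
    def test_monomorphic_window_is_zero(self, toy_matrix_factory):
        vm = toy_matrix_factory(np.zeros((4, 6), dtype=int))
        win = windowed_pi(vm, vm.samples, one_window(1, 1000))
        assert win["value"].iloc[0] == 0.0

    def test_single_site_hand_value(self, toy_matrix_factory):
        # 4 alleles split 2/2 over 1000 bp: (2*2/6)/1000
        vm = toy_matrix_factory([[0, 2]])
        win = windowed_pi(vm, vm.samples, one_window(1, 1000))
        assert win["value"].iloc[0] == pytest.approx(6.667e-4, rel=1e-3)

    def test_agrees_with_bruteforce(self, toy_matrix_factory):
        rng = np.random.default_rng(1)
        gt = rng.integers(-1, 3, size=(5, 6))
        vm = toy_matrix_factory(gt, positions=[5, 10, 20, 30, 40])
        win = windowed_pi(vm, vm.samples, one_window(1, 100))
        expect = 0.0
        for i in range(5):
            alleles = [al for g in gt[i] if g >= 0
                       for al in [0] * (2 - g) + [1] * g]
            expect += pi_site_bruteforce(alleles)
        assert win["value"].iloc[0] == pytest.approx(expect / 100, abs=1e-15)

    def test_fm2_pi_reduced_in_dup1_but_not_int(self, fm2_run):
        # the frozen DUP1 pair carries only the donor divergence; the
        # eroded INT tracks wild-type diversity
        res = fm2_run["result"]
        m = fm2_run["pop"].map
        pi_dup1 = region_mean(res["pi_fm"], m.dup1)
        pi_int = region_mean(res["pi_fm"], m.int_region)
        assert pi_dup1 < pi_int


class TestWindowedFst:
    def _matrix_from_counts(self, factory, counts1, counts2):
        """counts = (n_AA, n_Aa, n_aa) per population, one site."""
        row = []
        for (naa, nab, nbb) in (counts1, counts2):
            row += [0] * naa + [1] * nab + [2] * nbb
        return factory([row])

    def test_identical_groups_near_zero(self, toy_matrix_factory):
        rng = np.random.default_rng(2)
        gt = rng.integers(0, 3, size=(30, 100))
        vm = toy_matrix_factory(gt)
        a = vm.samples[:50]
        b = vm.samples[50:]
        win = windowed_fst(vm, a, b, one_window(1, 1000))
        assert abs(win["value"].iloc[0]) < 0.05

    def test_fixed_opposite_is_one(self, toy_matrix_factory):
        gt = np.array([[0] * 10 + [2] * 10] * 3)
        vm = toy_matrix_factory(gt)
        win = windowed_fst(vm, vm.samples[:10], vm.samples[10:],
                           one_window(1, 1000))
        assert win["value"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_overlapping_groups_rejected(self, toy_matrix_factory):
        vm = toy_matrix_factory([[0, 1, 2, 0]])
        with pytest.raises(InvalidParameterError):
            windowed_fst(vm, vm.samples[:3], vm.samples[2:], one_window())

    def test_matches_formula_literal_oracle_on_100_instances(
            self, toy_matrix_factory):
        rng = np.random.default_rng(3)
        for _ in range(100):
            c1 = rng.integers(0, 8, size=3) + np.array([1, 0, 0])
            c2 = rng.integers(0, 8, size=3) + np.array([0, 0, 1])
            vm = self._matrix_from_counts(toy_matrix_factory, c1, c2)
            n1, n2 = c1.sum(), c2.sum()
            if n1 < 2 or n2 < 2:
                continue
            win = windowed_fst(vm, vm.samples[:n1], vm.samples[n1:],
                               one_window(1, 100))
            p1 = (c1[1] + 2 * c1[2]) / (2 * n1)   # alt frequency
            p2 = (c2[1] + 2 * c2[2]) / (2 * n2)
            h1, h2 = c1[1] / n1, c2[1] / n2
            a, b, c = wc_components_oracle(n1, p1, h1, n2, p2, h2)
            if a + b + c == 0:
                assert np.isnan(win["value"].iloc[0])
            else:
                assert win["value"].iloc[0] == pytest.approx(
                    a / (a + b + c), abs=1e-12)

    def test_fm2_fst_elevated_in_dup1_relative_to_int(self, fm2_run):
        res = fm2_run["result"]
        m = fm2_run["pop"].map
        assert region_mean(res["fst"], m.dup1, "z") > \
            region_mean(res["fst"], m.int_region, "z")


class TestZscoreFdr:
    def _bg(self, values):
        return pd.DataFrame({"chrom": "bg", "start": 1, "end": 2,
                             "value": values})

    def test_mean_value_gives_z0_p_half(self):
        bg = self._bg([1.0, 2.0, 3.0, 4.0])
        stats = self._bg([2.5])
        out = zscore_fdr(stats, bg)
        assert out["z"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(0.5)

    def test_z_1645_gives_p_005(self):
        bg = self._bg([0.0, 2.0] * 10)   # mean 1, sd ~1.026
        mu, sd = 1.0, np.std([0.0, 2.0] * 10, ddof=1)
        out = zscore_fdr(self._bg([mu + 1.645 * sd]), bg)
        assert out["p"].iloc[0] == pytest.approx(0.05, abs=1e-3)

    def test_zero_background_sd_rejected(self):
        with pytest.raises(InvalidParameterError):
            zscore_fdr(self._bg([1.0]), self._bg([2.0, 2.0]))

    def test_q_matches_hand_bh_over_the_joint_family(self):
        rng = np.random.default_rng(4)
        bg_vals = rng.normal(0, 1, 50)
        stat_vals = rng.normal(1, 1, 20)
        out = zscore_fdr(self._bg(stat_vals), self._bg(bg_vals))
        from scipy.stats import norm
        mu = bg_vals.mean()
        sd = bg_vals.std(ddof=1)
        p_family = norm.sf((np.concatenate([stat_vals, bg_vals]) - mu) / sd)
        q_family = bh_oracle(p_family)
        np.testing.assert_allclose(out["q"].to_numpy(), q_family[:20],
                                   atol=1e-12)

    def test_bh_qualities_monotone_and_nested(self):
        rng = np.random.default_rng(5)
        bg = self._bg(rng.normal(0, 1, 30))
        out = zscore_fdr(self._bg(rng.normal(0.5, 1, 30)), bg)
        df = out.sort_values("p")
        assert (df["q"].diff().dropna() >= -1e-15).all()
        assert set(df.index[df["q"] < 0.01]) <= set(df.index[df["q"] < 0.05])
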