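"""Collapsed-reference observation model.

Short reads from every copy of a duplicated region align to the single copy
present in the reference assembly, so sequencing depth sums over copies and
per-site allele fractions pool paralogs.  This module converts a simulated
population into that observable: a per-sample depth profile and a diploid
genotype matrix with allele depths, the product an alignment + joint-calling
pipeline would hand downstream.

Per site and sample with total chromosomal copy number ``c`` and ``d``
reference-carrying copies, read count ``n ~ Poisson(depth * c / 2)`` and
reference reads ``~ Binomial(n, (d/c)(1-e) + (1-d/c)e)`` with sequencing
error ``e``.  The diploid genotype call is a symmetric allele-fraction band:
hom-alt below ``lo``, hom-ref above ``hi``, het in between, missing at zero
reads — the simplest surrogate that reproduces the heterozygote-at-0.5
behaviour of collapsed mapping without reimplementing a caller.  A
``deterministic`` mode replaces sampling with expectations for exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import GenomicInterval, InvalidParameterError, RegionMap
from .simulate import SimulatedPopulation

__all__ = [
    "VariantMatrix",
    "DepthProfile",
    "ObservedDataset",
    "GT_MISSING",
    "site_copy_state",
    "observe",
]

GT_MISSING = np.int8(-1)  # gt matrix holds alt-allele dosage; -1 = no call


@dataclass
class VariantMatrix:
    """Biallelic genotype matrix: sites x samples, with allele depths.

    ``gt`` holds the alternate-allele dosage (0 hom-ref, 1 het, 2 hom-alt,
    -1 missing); ``ad_ref``/``ad_alt`` the supporting read counts.
    """

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    samples: list[str]

    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample {e} in group") from None

    def take_sites(self, mask_or_idx) -> "VariantMatrix":
        return VariantMatrix(
            chrom=self.chrom,
            positions=self.positions[mask_or_idx],
            ref=self.ref[mask_or_idx],
            alt=self.alt[mask_or_idx],
            gt=self.gt[mask_or_idx],
            ad_ref=self.ad_ref[mask_or_idx],
            ad_alt=self.ad_alt[mask_or_idx],
            samples=list(self.samples),
        )

    def sites_in(self, interval: GenomicInterval) -> "VariantMatrix":
        return self.take_sites(
            (self.positions >= interval.start) & (self.positions < interval.end)
        )

    def equals(self, other: "VariantMatrix") -> bool:
        return (
            self.chrom == other.chrom
            and self.samples == other.samples
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.ad_ref, other.ad_ref)
            and np.array_equal(self.ad_alt, other.ad_alt)
        )


@dataclass
class DepthProfile:
    """Mean read depth per sample in tiling windows, plus each sample's
    genome-background mean depth (from the background regions only)."""

    windows: pd.DataFrame           # chrom, start, end, region, n_sites
    depth: np.ndarray               # (n_windows, n_samples), NaN if no sites
    background_mean: np.ndarray     # (n_samples,)
    samples: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = self.windows.copy()
        for j, s in enumerate(self.samples):
            df[s] = self.depth[:, j]
        return df


@dataclass
class ObservedDataset:
    variants: VariantMatrix
    depth: DepthProfile


# -- copy state ---------------------------------------------------------------

def _hap_copy_vectors(pop: SimulatedPopulation, hap):
    """(copy-count, ref-copy-count) site vectors contributed by a haplotype."""
    kind, idx = hap
    reg = pop.registry
    if kind == "WT":
        alleles = pop.wt_haplotypes[idx]
        return np.ones(reg.n_sites, dtype=np.int16), \
            (alleles == 0).astype(np.int16)
    fm = pop.fm_haplotypes[idx]
    c = np.ones(reg.n_sites, dtype=np.int16)
    d = (fm.single == 0).astype(np.int16)
    for region, copies in fm.dup_copies.items():
        ridx = reg.region_idx(region)
        c[ridx] = 2
        d[ridx] = (copies == 0).sum(axis=0)
    return c, d


def _population_copy_state(pop: SimulatedPopulation):
    """Stacked (c, d) matrices of shape (n_sites, n_individuals)."""
    n = pop.registry.n_sites
    c = np.empty((n, pop.n_individuals), dtype=np.int16)
    d = np.empty((n, pop.n_individuals), dtype=np.int16)
    cache: dict = {}
    for j, (h1, h2, _label) in enumerate(pop.individuals):
        for h in (h1, h2):
            if h not in cache:
                cache[h] = _hap_copy_vectors(pop, h)
        c[:, j] = cache[h1][0] + cache[h2][0]
        d[:, j] = cache[h1][1] + cache[h2][1]
    return c, d


def site_copy_state(pop: SimulatedPopulation, individual: int,
                    site: int) -> tuple[int, int]:
    """Total copy number ``c`` and reference dosage ``d`` of one individual
    at one registry site (2 outside duplications, 3 for FM/N inside one,
    4 for FM/FM)."""
    h1, h2, _ = pop.individuals[individual]
    c = d = 0
    for h in (h1, h2):
        cv, dv = _hap_copy_vectors(pop, h)
        c += int(cv[site])
        d += int(dv[site])
    return c, d


# -- observation --------------------------------------------------------------

def _depth_windows(region_map: RegionMap, width: int) -> pd.DataFrame:
    rows = []
    for iv in region_map.all_intervals():
        start = iv.start
        while start < iv.end:
            end = min(start + width, iv.end)
            mid = (start + end) // 2
            rows.append((iv.chrom, start, end,
                         region_map.region_of(mid) or "BG"))
            start = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region"])


def observe(
    pop: SimulatedPopulation,
    depth: float = 30.0,
    error_rate: float = 0.001,
    het_band: tuple[float, float] = (0.2, 0.8),
    seed: int | None = 0,
    deterministic: bool = False,
    depth_window_bp: int | None = None,
) -> ObservedDataset:
    """Emit the collapsed-reference genotype matrix and depth profile."""
    if pop.n_individuals == 0:
        raise InvalidParameterError("population has no individuals")
    if depth <= 0:
        raise InvalidParameterError("depth must be > 0")
    if not 0 <= error_rate < 0.5:
        raise InvalidParameterError("error_rate must be in [0, 0.5)")
    lo, hi = het_band
    if not 0 < lo < hi < 1:
        raise InvalidParameterError("het_band must satisfy 0 < lo < hi < 1")

    c, d = _population_copy_state(pop)
    expected = depth * c / 2.0
    frac_true = d / c
    p_ref = frac_true * (1 - error_rate) + (1 - frac_true) * error_rate

    if deterministic:
        n = np.rint(expected).astype(np.int64)
        r = np.rint(n * p_ref).astype(np.int64)
        frac = np.where(n > 0, p_ref, 0.0)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        n = rng.poisson(expected)
        r = rng.binomial(n, p_ref)
        with np.errstate(invalid="ignore"):
            frac = np.where(n > 0, r / np.maximum(n, 1), 0.0)

    gt = np.full(c.shape, 1, dtype=np.int8)
    gt[frac > hi] = 0
    gt[frac < lo] = 2
    gt[n == 0] = GT_MISSING
    ad_ref = np.where(n > 0, r, 0).astype(np.int32)
    ad_alt = np.where(n > 0, n - r, 0).astype(np.int32)

    reg = pop.registry
    vm = VariantMatrix(
        chrom=reg.chrom, positions=reg.positions.copy(),
        ref=reg.ref.copy(), alt=reg.alt.copy(),
        gt=gt, ad_ref=ad_ref, ad_alt=ad_alt, samples=list(pop.samples),
    )

    if depth_window_bp is None:
        depth_window_bp = max(int(round(20_000 / pop.map.scale)), 1)
    windows = _depth_windows(pop.map, depth_window_bp)
    wdepth = np.full((len(windows), pop.n_individuals), np.nan)
    n_sites_per_window = np.zeros(len(windows), dtype=int)
    for i, row in enumerate(windows.itertuples(index=False)):
        mask = (reg.positions >= row.start) & (reg.positions < row.end)
        n_sites_per_window[i] = int(mask.sum())
        if n_sites_per_window[i]:
            wdepth[i] = n[mask].mean(axis=0)
    windows = windows.assign(n_sites=n_sites_per_window)
    bg_mask = reg.region == "BG"
    background_mean = n[bg_mask].mean(axis=0)

    profile = DepthProfile(windows=windows, depth=wdepth,
                           background_mean=background_mean,
                           samples=list(pop.samples))
    return ObservedDataset(variants=vm, depth=profile)
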