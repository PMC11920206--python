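"""Synthetic population generator for the FM locus.

Builds a neutral wild-type haplotype pool over a Poisson site registry,
constructs the FM allele under a chosen candidate configuration via an
inter-chromosomal birth event (two donor haplotypes whose duplicated-region
copies carry fixed differences), erodes the FM-linked haplotype outside the
recombination-suppressed span, and assembles diploid individuals.

Model choices, in brief:

* Founder allele frequencies are Beta(alpha, alpha) (U-shaped at the default
  alpha=0.3) and haplotypes are sampled per site independently: background
  linkage disequilibrium is absent by construction, so any elevated LD is
  produced by the FM allele's identity by descent.
* Generations of recombination are collapsed into a single memoryless
  parameter ``erosion_p``: each *free* (unsuppressed) segment of each FM
  chromosome is independently replaced, with probability ``erosion_p``, by
  the corresponding segment of a random wild-type haplotype — standing in
  for 1 - exp(-r*g).  Frozen segments are never replaced.
* ``donor_divergence`` is the per-site rate of fixed differences between the
  two copies of a duplicated region on the founding FM haplotype (copy 2 is
  copy 1 with each site flipped at that rate), the signal that collapsed
  mapping later reads out as fixed heterozygosity.

Alleles are encoded as 0 = reference, 1 = alternate, one ``uint8`` row per
haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import (
    ConfigurationGeometry,
    GenomicInterval,
    InvalidParameterError,
    RegionMap,
    build_region_map,
    configuration_geometry,
)

__all__ = [
    "SimParams",
    "SiteRegistry",
    "FMHaplotype",
    "SimulatedPopulation",
    "DegenerateRegionError",
    "InsufficientDonorsError",
    "simulate_founders",
    "construct_fm_allele",
    "erode_population",
    "assemble_individuals",
    "simulate_population",
]


class DegenerateRegionError(ValueError):
    """A named region received zero sites; raise density or lower scale."""


class InsufficientDonorsError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Generator parameters.  Defaults are the standard study conditions
    used throughout the tests: a scale-100 locus, 50 wild-type and 50 FM
    homozygous birds at the paper's FM-2 arrangement."""

    n_wt: int = 50
    n_fm_het: int = 0
    n_fm_hom: int = 50
    site_density: float = 1.0 / 200.0   # expected sites per *unscaled* bp
    sfs_alpha: float | None = 0.3       # None => all founder freqs fixed at 0.5
    config: str = "FM-2"
    erosion_p: float = 0.9
    donor_divergence: float = 0.3
    lineage_mutation_rate: float = 0.0
    seed: int = 0
    #: fraction of DUP1 beyond which suppression is broken (sites distal to
    #: the break are free to erode) — injects a fixed-heterozygosity
    #: breakpoint with a matching LD block boundary
    dup1_suppression_break: float | None = None
    #: (start_frac, end_frac) of DUP2 over which the frozen copy is forced
    #: to match the reference (and to mismatch it outside) — injects
    #: reference-consistent segments with sharp ends
    dup2_ref_span: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("erosion_p", "donor_divergence", "lineage_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_wt, self.n_fm_het, self.n_fm_hom) < 0:
            raise InvalidParameterError("individual counts must be >= 0")
        if self.site_density <= 0:
            raise InvalidParameterError("site_density must be > 0")
        if self.sfs_alpha is not None and self.sfs_alpha <= 0:
            raise InvalidParameterError("sfs_alpha must be > 0 or None")


@dataclass
class SiteRegistry:
    """Sorted site positions with per-site region labels and founder
    reference-allele frequencies."""

    chrom: str
    positions: np.ndarray          # int64, strictly increasing, 1-based
    ref: np.ndarray                # base labels, e.g. "A"
    alt: np.ndarray
    region: np.ndarray             # str: DUP1/INT/DUP2/FLANK/BG
    founder_ref_freq: np.ndarray   # float64 in (0, 1)

    @property
    def n_sites(self) -> int:
        return self.positions.size

    def region_idx(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.region == name)


@dataclass
class _Segment:
    """A unit of erosion: a contiguous run of sites written either to the
    single-copy track or to one copy of a duplicated region."""

    name: str
    target: str                 # "single" or a duplicated region name
    copy: int                   # 0 for single-copy targets
    global_idx: np.ndarray      # site indices into the registry
    local_idx: np.ndarray       # indices into the region's site list
    frozen: bool


@dataclass
class FMHaplotype:
    """One FM chromosome: a single-copy allele track over all sites plus,
    for each duplicated region, a (2, n_region_sites) copy-allele array."""

    single: np.ndarray
    dup_copies: dict[str, np.ndarray]
    provenance: dict[str, str] = field(default_factory=dict)

    def clone(self) -> "FMHaplotype":
        return FMHaplotype(
            single=self.single.copy(),
            dup_copies={k: v.copy() for k, v in self.dup_copies.items()},
            provenance=dict(self.provenance),
        )


@dataclass
class SimulatedPopulation:
    map: RegionMap
    geometry: ConfigurationGeometry
    registry: SiteRegistry
    wt_haplotypes: np.ndarray                  # (n_pool, n_sites) uint8
    fm_haplotypes: list[FMHaplotype]
    individuals: list[tuple[tuple[str, int], tuple[str, int], str]]
    samples: list[str]
    truth: dict

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


# -- founders -----------------------------------------------------------------

_REF_BASE, _ALT_BASE = "A", "G"


def simulate_founders(
    region_map: RegionMap,
    params: SimParams,
    rng: np.random.Generator,
    n_haplotypes: int | None = None,
) -> tuple[SiteRegistry, np.ndarray]:
    """Place sites by a Poisson process and sample the wild-type pool.

    ``site_density`` is defined per unscaled bp; the per-bp rate on a scaled
    map is ``site_density * scale`` so expected per-region site counts are
    scale-invariant.
    """
    rate = params.site_density * region_map.scale
    pos_chunks: list[np.ndarray] = []
    for iv in region_map.all_intervals():
        n = rng.poisson(iv.length_bp * rate)
        n = min(n, iv.length_bp)
        pos = rng.choice(iv.length_bp, size=n, replace=False) + iv.start
        pos_chunks.append(np.sort(pos))
    positions = np.concatenate(pos_chunks)
    positions = np.unique(positions)

    region = np.array([region_map.region_of(int(p)) or "BG" for p in positions])
    for name in ("DUP1", "INT", "DUP2"):
        if not np.any(region == name):
            raise DegenerateRegionError(
                f"region {name} received zero sites; increase site_density "
                f"or use a smaller scale"
            )

    n_sites = positions.size
    if params.sfs_alpha is None:
        freq = np.full(n_sites, 0.5)
    else:
        freq = rng.beta(params.sfs_alpha, params.sfs_alpha, size=n_sites)
        # keep frequencies away from exact fixation so every site segregates
        freq = np.clip(freq, 1e-6, 1 - 1e-6)

    registry = SiteRegistry(
        chrom=region_map.scan_region.chrom,
        positions=positions.astype(np.int64),
        ref=np.full(n_sites, _REF_BASE),
        alt=np.full(n_sites, _ALT_BASE),
        region=region,
        founder_ref_freq=freq,
    )

    if n_haplotypes is None:
        n_haplotypes = 2 * params.n_wt + params.n_fm_het + 8
    n_haplotypes = max(n_haplotypes, 2)
    pool = (rng.random((n_haplotypes, n_sites)) >= freq).astype(np.uint8)
    return registry, pool


# -- the FM allele ------------------------------------------------------------

def _segment_plan(
    registry: SiteRegistry,
    geometry: ConfigurationGeometry,
    region_map: RegionMap,
    params: SimParams,
) -> tuple[list[_Segment], int | None]:
    """Erosion segments for one FM chromosome under a configuration.

    Returns the plan and, when a DUP1 suppression break is injected, the
    genomic position of the break.
    """
    from .regions import BOTH_FROZEN, FROZEN, ONE_FROZEN

    segs: list[_Segment] = []
    break_pos: int | None = None

    # single-copy stretches: INT, the two flanks, the background intervals
    sup = geometry.region_suppression
    scan = region_map.scan_region
    single_spans = [
        ("int", region_map.int_region, sup["INT"] == FROZEN),
        ("flank_l", GenomicInterval(scan.chrom, scan.start,
                                    region_map.dup1.start, "FLANK_L"), False),
        ("flank_r", GenomicInterval(scan.chrom, region_map.dup2.end,
                                    scan.end, "FLANK_R"), False),
    ] + [(f"bg{i}", bg, False)
         for i, bg in enumerate(region_map.background_regions)]
    pos = registry.positions
    for name, iv, frozen in single_spans:
        idx = np.flatnonzero((pos >= iv.start) & (pos < iv.end))
        if idx.size:
            segs.append(_Segment(name, "single", 0, idx, idx, frozen))

    for region in ("DUP1", "DUP2"):
        if geometry.copy_number(region) == 1:
            idx = registry.region_idx(region)
            segs.append(_Segment(region.lower(), "single", 0, idx, idx, False))
            continue
        idx = registry.region_idx(region)
        local = np.arange(idx.size)
        state = sup[region]
        frozen_copies = {BOTH_FROZEN: (True, True),
                         ONE_FROZEN: (True, False)}[state]
        if region == "DUP1" and params.dup1_suppression_break is not None:
            iv = region_map.dup1
            break_pos = iv.start + int(params.dup1_suppression_break *
                                       iv.length_bp)
            prox = registry.positions[idx] < break_pos
            for c, fz in enumerate(frozen_copies):
                segs.append(_Segment(f"dup1_c{c}_prox", region, c,
                                     idx[prox], local[prox], fz))
                segs.append(_Segment(f"dup1_c{c}_dist", region, c,
                                     idx[~prox], local[~prox], False))
        else:
            for c, fz in enumerate(frozen_copies):
                segs.append(_Segment(f"{region.lower()}_c{c}", region, c,
                                     idx, local, fz))
    return segs, break_pos


def construct_fm_allele(
    pool: np.ndarray,
    geometry: ConfigurationGeometry,
    registry: SiteRegistry,
    region_map: RegionMap,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[FMHaplotype, dict]:
    """Build the founding FM haplotype from two donor wild-type haplotypes.

    Copy 1 of each duplicated region carries donor A's alleles; copy 2 is
    donor B's, whose duplicated-region content differs from A at each site
    with probability ``donor_divergence`` (a controlled fixed-difference
    rate).  Single-copy regions carry donor A throughout.
    """
    if pool.shape[0] < 2:
        raise InsufficientDonorsError(
            f"need >= 2 wild-type haplotypes to found the FM allele, "
            f"have {pool.shape[0]}"
        )
    i_a, i_b = map(int, rng.choice(pool.shape[0], size=2, replace=False))
    a = pool[i_a]

    single = a.copy()
    dup_copies: dict[str, np.ndarray] = {}
    fixed_diff: dict[str, np.ndarray] = {}
    truth: dict = {"donors": [i_a, i_b], "fixed_diff_positions": {},
                   "dup2_ref_span": None}

    for region in ("DUP1", "DUP2"):
        if geometry.copy_number(region) != 2:
            continue
        idx = registry.region_idx(region)
        copy1 = a[idx].copy()
        if region == "DUP2" and params.dup2_ref_span is not None:
            iv = region_map.dup2
            f0, f1 = params.dup2_ref_span
            lo = iv.start + int(f0 * iv.length_bp)
            hi = iv.start + int(f1 * iv.length_bp)
            inside = (registry.positions[idx] >= lo) & \
                     (registry.positions[idx] < hi)
            copy1[inside] = 0   # matches the reference
            copy1[~inside] = 1  # mismatches it
            truth["dup2_ref_span"] = [int(lo), int(hi)]
        diff = rng.random(idx.size) < params.donor_divergence
        copy2 = copy1 ^ diff.astype(np.uint8)
        dup_copies[region] = np.stack([copy1, copy2])
        fixed_diff[region] = diff
        truth["fixed_diff_positions"][region] = \
            registry.positions[idx[diff]].astype(int).tolist()

    hap = FMHaplotype(single=single, dup_copies=dup_copies,
                      provenance={"single": f"donor_A[{i_a}]"})
    truth["fixed_diff_masks"] = fixed_diff
    return hap, truth


def erode_population(
    founder: FMHaplotype,
    pool: np.ndarray,
    segments: list[_Segment],
    params: SimParams,
    n_fm_chromosomes: int,
    rng: np.random.Generator,
) -> tuple[list[FMHaplotype], list[dict]]:
    """Replicate the founder and erode every free segment independently.

    Each free segment of each chromosome is replaced, with probability
    ``erosion_p``, by the corresponding segment of a random wild-type
    haplotype.  Frozen segments are never touched.
    """
    haps: list[FMHaplotype] = []
    events: list[dict] = []
    for i in range(n_fm_chromosomes):
        hap = founder.clone()
        for seg in segments:
            if seg.frozen or seg.global_idx.size == 0:
                continue
            replaced = bool(rng.random() < params.erosion_p)
            donor = int(rng.integers(0, pool.shape[0]))
            if replaced:
                if seg.target == "single":
                    hap.single[seg.global_idx] = pool[donor, seg.global_idx]
                else:
                    hap.dup_copies[seg.target][seg.copy, seg.local_idx] = \
                        pool[donor, seg.global_idx]
                hap.provenance[seg.name] = f"eroded<-WT[{donor}]"
            events.append({"chromosome": i, "segment": seg.name,
                           "replaced": replaced,
                           "donor": donor if replaced else None})
        if params.lineage_mutation_rate > 0:
            mut = rng.random(hap.single.size) < params.lineage_mutation_rate
            hap.single[mut] ^= 1
            for region, copies in hap.dup_copies.items():
                mut = rng.random(copies.shape) < params.lineage_mutation_rate
                copies ^= mut.astype(np.uint8)
        haps.append(hap)
    return haps, events


# -- individuals --------------------------------------------------------------

def assemble_individuals(
    registry: SiteRegistry,
    pool: np.ndarray,
    fm_haplotypes: list[FMHaplotype],
    params: SimParams,
) -> tuple[list[tuple[tuple[str, int], tuple[str, int], str]], list[str]]:
    """Pair haplotypes into diploids and record truth genotypes."""
    need_wt = 2 * params.n_wt + params.n_fm_het
    need_fm = params.n_fm_het + 2 * params.n_fm_hom
    if pool.shape[0] < need_wt:
        raise InvalidParameterError(
            f"wild-type pool of {pool.shape[0]} cannot supply {need_wt} "
            f"haplotypes"
        )
    if len(fm_haplotypes) < need_fm:
        raise InvalidParameterError(
            f"{len(fm_haplotypes)} FM haplotypes cannot supply {need_fm}"
        )
    individuals = []
    w = f = 0
    for _ in range(params.n_wt):
        individuals.append((("WT", w), ("WT", w + 1), "N/N"))
        w += 2
    for _ in range(params.n_fm_het):
        individuals.append((("FM", f), ("WT", w), "FM/N"))
        f += 1
        w += 1
    for _ in range(params.n_fm_hom):
        individuals.append((("FM", f), ("FM", f + 1), "FM/FM"))
        f += 2
    samples = [f"S{i + 1:04d}" for i in range(len(individuals))]
    return individuals, samples


def simulate_population(
    region_map: RegionMap | None = None,
    params: SimParams | None = None,
) -> SimulatedPopulation:
    """End-to-end generator: founders -> FM allele -> erosion -> diploids.

    The root seed is split into three child streams consumed in a fixed,
    documented order: (1) site placement and founder sampling, (2) FM-allele
    construction, (3) erosion.  Assembly is deterministic.
    """
    params = params or SimParams()
    region_map = region_map or build_region_map(100)
    geometry = configuration_geometry(params.config)

    ss = np.random.SeedSequence(params.seed)
    rng_found, rng_con, rng_ero = (np.random.default_rng(s)
                                   for s in ss.spawn(3))

    registry, pool = simulate_founders(region_map, params, rng_found)
    founder, con_truth = construct_fm_allele(
        pool, geometry, registry, region_map, params, rng_con)
    segments, break_pos = _segment_plan(registry, geometry, region_map, params)
    n_fm = params.n_fm_het + 2 * params.n_fm_hom
    fm_haps, erosion_events = erode_population(
        founder, pool, segments, params, n_fm, rng_ero)
    individuals, samples = assemble_individuals(registry, pool, fm_haps, params)

    truth = {
        "config": params.config,
        "seed": params.seed,
        "scale": region_map.scale,
        "samples": samples,
        "genotypes": {s: ind[2] for s, ind in zip(samples, individuals)},
        "fixed_diff_positions": con_truth["fixed_diff_positions"],
        "dup2_ref_span": con_truth["dup2_ref_span"],
        "dup1_suppression_break": break_pos,
        "donors": con_truth["donors"],
        "erosion_events": erosion_events,
    }
    return SimulatedPopulation(
        map=region_map, geometry=geometry, registry=registry,
        wt_haplotypes=pool, fm_haplotypes=fm_haps,
        individuals=individuals, samples=samples, truth=truth,
    )
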