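"""End-to-end orchestration: simulate/load -> genotype -> scan -> call.

Every stage is also runnable from files alone (see :mod:`fmscan.cli`); this
module wires the in-memory path used by the CLI, the tests and the
reproduction script.  Cohorts for the scan default to the depth-deduced CNV
genotypes (FM homozygotes vs wild type), mirroring how the depth clusters
define the analysis groups; an explicit sample->group mapping overrides.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import bubble_ld, cnv, configcall, phylo, scanstats
from .collapse import DepthProfile, VariantMatrix, observe
from .config import RunConfig
from .regions import RegionMap, build_region_map
from .simulate import SimParams, simulate_population

log = logging.getLogger("fmscan")

__all__ = ["sim_params_from_config", "simulate_and_observe", "analyze",
           "recover_configuration"]


def sim_params_from_config(cfg: RunConfig) -> SimParams:
    return SimParams(
        n_wt=cfg.n_wt, n_fm_het=cfg.n_fm_het, n_fm_hom=cfg.n_fm_hom,
        site_density=cfg.site_density, sfs_alpha=cfg.sfs_alpha,
        config=cfg.config, erosion_p=cfg.erosion_p,
        donor_divergence=cfg.donor_divergence, seed=cfg.seed,
        dup1_suppression_break=cfg.dup1_suppression_break,
        dup2_ref_span=cfg.dup2_ref_span,
    )


def simulate_and_observe(cfg: RunConfig):
    """Simulate a population under the configured conditions and emit its
    collapsed-reference observables.  The observation stream is seeded from
    the run seed (+1) so simulation and sequencing noise are independent."""
    region_map = build_region_map(cfg.scale)
    pop = simulate_population(region_map, sim_params_from_config(cfg))
    obs = observe(pop, depth=cfg.depth, error_rate=cfg.error_rate,
                  het_band=(cfg.het_lo, cfg.het_hi), seed=cfg.seed + 1)
    return pop, obs


def analyze(
    vm: VariantMatrix,
    depth_profile: DepthProfile,
    region_map: RegionMap,
    cfg: RunConfig | None = None,
    groups: dict[str, list[str]] | None = None,
    include_trees: bool = True,
) -> dict:
    """Run the full inference on an observed dataset.

    Returns a dict with the CNV table, cohorts, window statistics, bubble
    report, LD result, signature, configuration call and (optionally) the
    region trees.
    """
    cfg = (cfg or RunConfig()).validate()
    result: dict = {}

    cnv_table = cnv.genotype_samples(depth_profile, region_map,
                                     t1=cfg.t1, t2=cfg.t2)
    result["cnv"] = cnv_table
    if groups is None:
        fm = cnv_table.loc[cnv_table["call"] == "FM/FM", "sample"].tolist()
        wt = cnv_table.loc[cnv_table["call"] == "N/N", "sample"].tolist()
    else:
        fm = list(groups.get("FM/FM", []))
        wt = list(groups.get("N/N", []))
    result["groups"] = {"FM/FM": fm, "N/N": wt}

    vmf = scanstats.filter_variants(vm, maf=cfg.maf,
                                    max_missing=cfg.max_missing)
    result["n_sites_filtered"] = vmf.n_sites
    win_scan = scanstats.build_windows(
        region_map.scan_region,
        cfg.window_bp or max(int(round(20_000 / region_map.scale)), 1),
        cfg.step_bp or max(int(round(10_000 / region_map.scale)), 1))
    win_bg = pd.concat(
        [scanstats.build_windows(
            bg,
            cfg.window_bp or max(int(round(20_000 / region_map.scale)), 1),
            cfg.step_bp or max(int(round(10_000 / region_map.scale)), 1))
         for bg in region_map.background_regions],
        ignore_index=True)

    if len(fm) < 2 or len(wt) < 2:
        # no FM cohort (e.g. a wild-type population): no bubble anywhere
        log.info("cohorts too small for the scan (FM/FM=%d, N/N=%d); "
                 "calling the configuration from the absent CNV signal",
                 len(fm), len(wt))
        bubble = bubble_ld.BubbleReport(regions={
            name: {"status": "insufficient" if len(fm) < 2 else "ok",
                   "n_classified": 0, "fixed_fraction": float("nan"),
                   "fixed_het_fraction": float("nan"), "bubble": False}
            for name in ("DUP1", "INT", "DUP2")})
        sig = configcall.SignatureVector(bubble_flags=(False, False, False))
        result["bubble"] = bubble
        result["call"] = configcall.call_configuration(sig)
        return result

    # windowed scans
    fst_scan = scanstats.windowed_fst(vmf, fm, wt, win_scan)
    fst_bg = scanstats.windowed_fst(vmf, fm, wt, win_bg)
    result["fst"] = scanstats.zscore_fdr(fst_scan, fst_bg)
    result["pi_fm"] = scanstats.windowed_pi(vmf, fm, win_scan)
    result["pi_wt"] = scanstats.windowed_pi(vmf, wt, win_scan)

    # allele-frequency profile, site classes, bubble evidence
    freq_fm = scanstats.ref_allele_frequency(vmf, fm)
    classes = bubble_ld.classify_sites(freq_fm, eps=cfg.eps,
                                       min_called=cfg.min_called)
    regions = bubble_ld.detect_bubble(classes, vmf.positions,
                                      region_map.named_regions, tau=cfg.tau)
    dup1 = region_map.dup1
    in_dup1 = (vmf.positions >= dup1.start) & (vmf.positions < dup1.end) & \
        (classes != bubble_ld.UNDEFINED)
    is_fixed = np.isin(classes, list(bubble_ld.FIXED_CLASSES))
    breakpoint = bubble_ld.detect_breakpoint(
        is_fixed[in_dup1], vmf.positions[in_dup1],
        lrt_threshold=cfg.lrt_threshold)
    segments = bubble_ld.reference_consistent_segments(
        freq_fm, region_map.dup2, eps=cfg.eps, min_called=cfg.min_called)
    bubble = bubble_ld.BubbleReport(regions=regions, breakpoint=breakpoint,
                                    ref_consistent_segments=segments)
    result["bubble"] = bubble
    result["freq_fm"] = freq_fm
    result["classes"] = classes

    # LD retention and block boundary (all samples)
    ld = bubble_ld.ld_retention_and_boundary(
        vmf, win_scan, dup1, win_bg,
        contrast_threshold=cfg.contrast_threshold)
    result["ld"] = ld

    sig = configcall.observed_signature(bubble, result["pi_fm"],
                                        result["pi_wt"], ld, region_map)
    result["signature"] = sig
    result["call"] = configcall.call_configuration(sig)

    if include_trees:
        try:
            t1 = phylo.neighbor_joining(phylo.distance_matrix(vmf, dup1))
            t2 = phylo.neighbor_joining(
                phylo.distance_matrix(vmf, region_map.dup2))
            result["tree_dup1"], result["tree_dup2"] = t1, t2
            if fm:
                result["branch_contrast"] = phylo.branch_length_contrast(
                    t1, t2, fm)
        except Exception as e:  # trees are descriptive, never fatal
            log.warning("tree construction skipped: %s", e)
    return result


def recover_configuration(config: str, seed: int,
                          cfg: RunConfig | None = None):
    """One replicate of the identifiability experiment: simulate under a
    configuration, observe, analyze, and return the ConfigurationCall."""
    import dataclasses

    cfg = dataclasses.replace(cfg or RunConfig(), config=config, seed=seed)
    pop, obs = simulate_and_observe(cfg)
    result = analyze(obs.variants, obs.depth, pop.map, cfg,
                     include_trees=False)
    return result["call"]
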