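"""Shared fixtures: one default FM-2 run reused across test modules, and a
tiny hand-built genotype matrix for exact-value tests."""

import numpy as np
import pytest

from fmscan.collapse import VariantMatrix, observe
from fmscan.config import RunConfig
from fmscan.pipeline import analyze, simulate_and_observe


@pytest.fixture(scope="session")
def fm2_run():
    """Default FM-2 study conditions (scale 100, 50 WT + 50 FM/FM, 30x),
    simulated, observed and fully analyzed once per session."""
    cfg = RunConfig(seed=1)
    pop, obs = simulate_and_observe(cfg)
    result = analyze(obs.variants, obs.depth, pop.map, cfg,
                     include_trees=True)
    return {"cfg": cfg, "pop": pop, "obs": obs, "result": result}


@pytest.fixture(scope="session")
def mixed_cohort_run():
    """100 individuals with all three FM genotype classes, for depth-ratio
    genotyping checks."""
    cfg = RunConfig(n_wt=40, n_fm_het=30, n_fm_hom=30, seed=11)
    pop, obs = simulate_and_observe(cfg)
    return {"cfg": cfg, "pop": pop, "obs": obs}


def make_matrix(gt_rows, positions=None, samples=None, chrom="chr20"):
    """VariantMatrix from a list of per-site genotype lists (alt dosage,
    -1 = missing); allele depths are filled as perfect calls at depth 30."""
    gt = np.array(gt_rows, dtype=np.int8)
    n_sites, n_samples = gt.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    if samples is None:
        samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    ad_alt = np.where(gt > 0, 15 * np.maximum(gt, 0), 0).astype(np.int32)
    ad_ref = np.where(gt >= 0, 30 - ad_alt, 0).astype(np.int32)
    return VariantMatrix(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.full(n_sites, "A"),
        alt=np.full(n_sites, "G"),
        gt=gt, ad_ref=ad_ref, ad_alt=ad_alt,
        samples=list(samples),
    )


@pytest.fixture
def toy_matrix_factory():
    return make_matrix
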