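"""Depth-ratio genotyping of the FM copy-number classes.

The duplicated regions carry one extra copy per FM haplotype, so the
relative sequence depth (region mean depth over genome-background mean
depth) clusters at ~1.0 for N/N, ~1.5 for FM/N and ~2.0 for FM/FM samples.
Calls use the midpoint thresholds 1.25 and 1.75 between those expectations
and require DUP1 and DUP2 to agree; disagreement yields ``ambiguous``
rather than a forced genotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .collapse import DepthProfile
from .regions import GenomicInterval, InvalidParameterError, RegionMap

__all__ = ["relative_depth", "call_fm_genotype", "genotype_samples"]

CALL_LABELS = {0: "N/N", 1: "FM/N", 2: "FM/FM"}


class ZeroBackgroundDepthError(ValueError):
    pass


def relative_depth(profile: DepthProfile,
                   region: GenomicInterval) -> np.ndarray:
    """Per-sample ratio of mean window depth in ``region`` to the
    genome-background mean depth."""
    win = profile.windows
    mid = (win["start"] + win["end"]) // 2
    in_region = (mid >= region.start) & (mid < region.end) & \
                (win["n_sites"] > 0)
    if not in_region.any():
        raise InvalidParameterError(
            f"region {region.label!r} covers no depth windows with sites"
        )
    zero = np.flatnonzero(profile.background_mean <= 0)
    if zero.size:
        bad = ", ".join(profile.samples[i] for i in zero[:5])
        raise ZeroBackgroundDepthError(
            f"zero background depth for sample(s): {bad}"
        )
    region_mean = np.nanmean(profile.depth[np.asarray(in_region)], axis=0)
    return region_mean / profile.background_mean


def _copy_class(ratio: np.ndarray, t1: float, t2: float) -> np.ndarray:
    cls = np.ones(ratio.shape, dtype=int)
    cls[ratio < t1] = 0
    cls[ratio >= t2] = 2
    return cls


def call_fm_genotype(
    ratio_dup1: np.ndarray,
    ratio_dup2: np.ndarray,
    t1: float = 1.25,
    t2: float = 1.75,
) -> list[str]:
    """Class per region (<t1: one copy per haplotype; [t1, t2): het;
    >=t2: hom) with the overall call requiring both regions to agree."""
    ratio_dup1 = np.asarray(ratio_dup1, dtype=float)
    ratio_dup2 = np.asarray(ratio_dup2, dtype=float)
    if (ratio_dup1 < 0).any() or (ratio_dup2 < 0).any():
        raise InvalidParameterError("depth ratios must be >= 0")
    if not 0 < t1 < t2:
        raise InvalidParameterError("thresholds must satisfy 0 < t1 < t2")
    c1 = _copy_class(ratio_dup1, t1, t2)
    c2 = _copy_class(ratio_dup2, t1, t2)
    return [CALL_LABELS[a] if a == b else "ambiguous"
            for a, b in zip(c1, c2)]


def genotype_samples(
    profile: DepthProfile,
    region_map: RegionMap,
    t1: float = 1.25,
    t2: float = 1.75,
) -> pd.DataFrame:
    """CNV-call table: sample, the three region depth ratios and the call.

    The INT ratio is reported for context (it stays near 1.0 in every
    class) but plays no part in the call.
    """
    r1 = relative_depth(profile, region_map.dup1)
    r2 = relative_depth(profile, region_map.dup2)
    ri = relative_depth(profile, region_map.int_region)
    calls = call_fm_genotype(r1, r2, t1=t1, t2=t2)
    return pd.DataFrame({
        "sample": profile.samples,
        "ratio_dup1": r1,
        "ratio_dup2": r2,
        "ratio_int": ri,
        "call": calls,
    })
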