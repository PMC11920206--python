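"""Signature matching: which candidate arrangement produced the data?

The verbal logic of the source analysis, made mechanical: each candidate
configuration predicts a bubble-flag triple over (DUP1, INT, DUP2) —
WT (0,0,0), FM-1 (1,1,1), FM-2 (1,0,0), FM-3 (0,0,1) — and the observed
triple is matched by Hamming distance.  A call is ``confident`` only on an
exact, unique match; anything else is ``ambiguous-nearest`` with the tie
recorded.  Continuous evidence (fixed-het fractions, pi ratios, LD mean Z)
is reported alongside but deliberately not scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bubble_ld import BubbleReport, LDResult
from .regions import (
    CONFIGURATIONS,
    InvalidParameterError,
    RegionMap,
    REGION_NAMES,
    predicted_signature,
)
from .scanstats import region_mean

__all__ = ["SignatureVector", "ConfigurationCall",
           "observed_signature", "call_configuration"]


@dataclass
class SignatureVector:
    """Per-region observed evidence: fixed-site fractions, pi ratio
    (FM homozygotes over wild type) and mean LD-retention Z, plus the
    boolean bubble triple that drives the configuration call."""

    bubble_flags: tuple[bool, bool, bool]
    per_region: dict[str, dict] = field(default_factory=dict)


@dataclass
class ConfigurationCall:
    best: str
    status: str                      # "confident" | "ambiguous-nearest"
    distances: dict[str, int]
    tie: bool
    signature: SignatureVector

    def to_dict(self) -> dict:
        return {
            "call": self.best,
            "status": self.status,
            "tie": self.tie,
            "distances": self.distances,
            "bubble_flags": list(map(bool, self.signature.bubble_flags)),
            "evidence": self.signature.per_region,
        }


def observed_signature(
    bubble: BubbleReport,
    pi_fm: pd.DataFrame,
    pi_wt: pd.DataFrame,
    ld: LDResult | None,
    region_map: RegionMap,
) -> SignatureVector:
    """Assemble the per-region signature from the bubble report, the two
    cohorts' windowed pi and the annotated LD retention windows."""
    per_region: dict[str, dict] = {}
    for name in REGION_NAMES:
        if name not in bubble.regions:
            raise InvalidParameterError(f"region {name} missing from bubble "
                                        f"report")
        iv = region_map.named_regions[name]
        rep = bubble.regions[name]
        mean_fm = region_mean(pi_fm, iv)
        mean_wt = region_mean(pi_wt, iv)
        pi_ratio = mean_fm / mean_wt if mean_wt and mean_wt > 0 else \
            float("nan")
        ld_z = region_mean(ld.retention, iv, column="z") \
            if ld is not None else float("nan")
        per_region[name] = {
            "fixed_fraction": rep["fixed_fraction"],
            "fixed_het_fraction": rep["fixed_het_fraction"],
            "pi_fm": mean_fm,
            "pi_wt": mean_wt,
            "pi_ratio": pi_ratio,
            "ld_z": ld_z,
        }
    return SignatureVector(bubble_flags=bubble.bubble_flags(),
                           per_region=per_region)


def call_configuration(observed: SignatureVector) -> ConfigurationCall:
    """Hamming-match the observed bubble triple against the four templates."""
    flags = tuple(bool(f) for f in observed.bubble_flags)
    if len(flags) != 3:
        raise InvalidParameterError("bubble triple must have three entries")
    distances = {
        label: sum(a != b for a, b in zip(flags, predicted_signature(label)))
        for label in CONFIGURATIONS
    }
    dmin = min(distances.values())
    nearest = sorted(l for l, d in distances.items() if d == dmin)
    tie = len(nearest) > 1
    best = nearest[0]
    status = "confident" if dmin == 0 and not tie else "ambiguous-nearest"
    return ConfigurationCall(best=best, status=status, distances=distances,
                             tie=tie, signature=observed)
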