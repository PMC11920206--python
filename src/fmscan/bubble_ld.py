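"""Allele-frequency site classes, bubble and breakpoint detection, and LD.

In FM homozygotes, collapsed mapping over a recombination-suppressed
duplicated region pins per-site reference-allele frequencies to 0, 0.5 or 1
(the "bubble"): the two frozen copies are either identical (fixed hom) or
carry a fixed difference, which every individual then reports as a
heterozygote.  This module classifies sites into those states, flags
bubbled regions, locates the change-point where fixed heterozygosity breaks
down, finds runs where the frozen copy matches the reference (pooled
frequency >= 0.5), and computes composite genotype-dosage r² with
window-level LD retention and an LD block boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .collapse import VariantMatrix
from .regions import GenomicInterval, InvalidParameterError
from .scanstats import zscore_fdr

__all__ = [
    "SITE_CLASSES",
    "BubbleReport",
    "LDResult",
    "classify_sites",
    "detect_bubble",
    "detect_breakpoint",
    "reference_consistent_segments",
    "pairwise_r2",
    "ld_retention",
    "ld_retention_and_boundary",
]

FIXED_REF = "FIXED_REF"
FIXED_ALT = "FIXED_ALT"
FIXED_HET = "FIXED_HET"
POLYMORPHIC = "POLYMORPHIC"
UNDEFINED = "UNDEFINED"
SITE_CLASSES = (FIXED_REF, FIXED_ALT, FIXED_HET, POLYMORPHIC, UNDEFINED)
FIXED_CLASSES = frozenset({FIXED_REF, FIXED_ALT, FIXED_HET})


def classify_sites(profile: pd.DataFrame, eps: float = 0.05,
                   min_called: int = 20) -> np.ndarray:
    """Classify each site of a group frequency profile.

    UNDEFINED below ``min_called`` called alleles; FIXED_REF at
    f >= 1 - eps; FIXED_ALT at f <= eps; FIXED_HET at |f - 0.5| <= eps;
    POLYMORPHIC otherwise.  ``eps`` must stay below 0.25 or the classes
    would overlap.
    """
    if not 0 < eps < 0.25:
        raise InvalidParameterError("eps must be in (0, 0.25)")
    f = profile["freq"].to_numpy(dtype=float)
    n = profile["n_called_alleles"].to_numpy()
    cls = np.full(f.shape, POLYMORPHIC, dtype=object)
    cls[f >= 1 - eps] = FIXED_REF
    cls[f <= eps] = FIXED_ALT
    cls[np.abs(f - 0.5) <= eps] = FIXED_HET
    cls[(n < min_called) | ~np.isfinite(f)] = UNDEFINED
    return cls


@dataclass
class BubbleReport:
    """Per-region bubble evidence plus the DUP1 fixed-heterozygosity
    breakpoint and the DUP2 reference-consistent segments."""

    regions: dict[str, dict]
    breakpoint: dict | None = None
    ref_consistent_segments: list[dict] | None = None

    def bubble_flags(self) -> tuple[bool, bool, bool]:
        return tuple(bool(self.regions[r]["bubble"])
                     for r in ("DUP1", "INT", "DUP2"))


def detect_bubble(classes: np.ndarray, positions: np.ndarray,
                  regions: dict[str, GenomicInterval], tau: float = 0.5,
                  min_sites: int = 10) -> dict[str, dict]:
    """Flag each region whose fraction of fixed-class sites exceeds ``tau``.

    Fractions are computed over classified (non-UNDEFINED) sites only;
    regions with fewer than ``min_sites`` of them are reported as
    ``insufficient`` rather than silently flagged.
    """
    out = {}
    is_fixed = np.isin(classes, list(FIXED_CLASSES))
    is_het = classes == FIXED_HET
    classified = classes != UNDEFINED
    for name, iv in regions.items():
        in_r = (positions >= iv.start) & (positions < iv.end) & classified
        n = int(in_r.sum())
        if n < min_sites:
            out[name] = {"status": "insufficient", "n_classified": n,
                         "fixed_fraction": float("nan"),
                         "fixed_het_fraction": float("nan"), "bubble": False}
            continue
        ff = float(is_fixed[in_r].mean())
        out[name] = {"status": "ok", "n_classified": n,
                     "fixed_fraction": ff,
                     "fixed_het_fraction": float(is_het[in_r].mean()),
                     "bubble": ff > tau}
    return out


def _bernoulli_ll(k: float, n: float) -> float:
    if n == 0 or k == 0 or k == n:
        return 0.0
    p = k / n
    return k * np.log(p) + (n - k) * np.log(1 - p)


def detect_breakpoint(is_fixed: np.ndarray, positions: np.ndarray,
                      min_sites: int = 20,
                      lrt_threshold: float = 10.0) -> dict | None:
    """Single change-point in a binary site series by exhaustive scan.

    Maximizes the two-segment Bernoulli log-likelihood over every split and
    reports the change only when the likelihood-ratio statistic
    ``2 * (LL2 - LL1)`` exceeds ``lrt_threshold`` (strong support); a
    homogeneous series comes back None.  The reported position is the
    midpoint between the two sites flanking the split.
    """
    x = np.asarray(is_fixed, dtype=float)
    n = x.size
    if n < min_sites:
        return None
    csum = np.cumsum(x)
    total = csum[-1]
    ll1 = _bernoulli_ll(total, n)
    best_ll, best_k = -np.inf, None
    for k in range(1, n):
        ll = _bernoulli_ll(csum[k - 1], k) + \
            _bernoulli_ll(total - csum[k - 1], n - k)
        if ll > best_ll:
            best_ll, best_k = ll, k
    lrt = 2.0 * (best_ll - ll1)
    if best_k is None or lrt <= lrt_threshold:
        return None
    return {
        "index": int(best_k),
        "position": int((positions[best_k - 1] + positions[best_k]) // 2),
        "rate_left": float(csum[best_k - 1] / best_k),
        "rate_right": float((total - csum[best_k - 1]) / (n - best_k)),
        "lrt": float(lrt),
    }


def reference_consistent_segments(
    profile: pd.DataFrame,
    region: GenomicInterval,
    eps: float = 0.05,
    min_sites: int = 5,
    min_called: int = 20,
) -> list[dict]:
    """Maximal runs of classified sites with frequency >= 0.5 - eps inside
    a region, at least ``min_sites`` long — the stretches where a frozen,
    non-recombining duplicate copy matches the reference so the pooled
    frequency can never drop below one half."""
    pos = profile["pos"].to_numpy()
    f = profile["freq"].to_numpy(dtype=float)
    n = profile["n_called_alleles"].to_numpy()
    sel = (pos >= region.start) & (pos < region.end) & \
        np.isfinite(f) & (n >= min_called)
    pos, f = pos[sel], f[sel]
    segments = []
    run_start = None
    for i in range(pos.size + 1):
        hit = i < pos.size and f[i] >= 0.5 - eps
        if hit and run_start is None:
            run_start = i
        elif not hit and run_start is not None:
            if i - run_start >= min_sites:
                segments.append({"start": int(pos[run_start]),
                                 "end": int(pos[i - 1]),
                                 "n_sites": i - run_start})
            run_start = None
    return segments


# -- linkage disequilibrium ---------------------------------------------------

def _dosage(vm: VariantMatrix) -> np.ndarray:
    dos = vm.gt.astype(float)
    dos[vm.gt < 0] = np.nan
    return dos


def pairwise_r2(vm: VariantMatrix, interval: GenomicInterval | None = None,
                min_shared: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise composite r²: squared Pearson correlation of genotype
    dosage vectors over samples called at both sites.  Entries with fewer
    than ``min_shared`` shared calls, and sites without dosage variance,
    are NaN.  Returns (matrix, site positions)."""
    sub = vm.sites_in(interval) if interval is not None else vm
    if sub.n_sites < 2:
        raise InvalidParameterError(
            f"need >= 2 usable sites, have {sub.n_sites}")
    dos = _dosage(sub)
    if not np.isnan(dos).any():
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(dos)
        r2 = r ** 2
    else:
        df = pd.DataFrame(dos.T)
        r2 = df.corr(min_periods=min_shared).to_numpy() ** 2
    np.fill_diagonal(r2, 1.0)
    return r2, sub.positions.copy()


def ld_retention(vm: VariantMatrix, windows: pd.DataFrame,
                 min_shared: int = 4) -> pd.DataFrame:
    """Mean defined pairwise r² among site pairs within each window (the
    window length caps the pair distance by construction)."""
    out = windows.copy().reset_index(drop=True)
    pos = vm.positions
    values = np.full(len(out), np.nan)
    n_sites = np.zeros(len(out), dtype=int)
    for i, row in enumerate(out.itertuples(index=False)):
        mask = (pos >= row.start) & (pos <= row.end)
        n_sites[i] = int(mask.sum())
        if n_sites[i] < 2:
            continue
        r2, _ = pairwise_r2(vm.take_sites(mask), min_shared=min_shared)
        iu = np.triu_indices(r2.shape[0], k=1)
        vals = r2[iu]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            values[i] = float(vals.mean())
    out["n_sites"] = n_sites
    out["value"] = values
    return out


@dataclass
class LDResult:
    retention: pd.DataFrame
    boundary: dict | None
    r2: np.ndarray | None = None
    positions: np.ndarray | None = None


def _block_boundary(r2: np.ndarray, positions: np.ndarray,
                    min_side: int | None = None,
                    contrast_threshold: float = 0.1) -> dict | None:
    """Split of the site set maximizing (within-block mean r² − cross
    mean r²); reported only when that contrast clears the threshold.

    Candidate splits leave at least ``min_side`` sites (default: 5% of the
    sites, floor 5) on each side: near-edge splits ride the sampling noise
    of a handful of sites and would otherwise dominate homogeneous blocks.
    """
    n = r2.shape[0]
    if min_side is None:
        min_side = max(5, round(0.05 * n))
    if n < 2 * min_side:
        return None
    a = np.where(np.isfinite(r2), r2, 0.0)
    m = np.isfinite(r2).astype(float)
    np.fill_diagonal(a, 0.0)
    np.fill_diagonal(m, 0.0)
    pa = a.cumsum(0).cumsum(1)
    pm = m.cumsum(0).cumsum(1)

    def rect(p, r0, r1, c0, c1):  # sum over rows [r0, r1), cols [c0, c1)
        tot = p[r1 - 1, c1 - 1]
        if r0 > 0:
            tot -= p[r0 - 1, c1 - 1]
        if c0 > 0:
            tot -= p[r1 - 1, c0 - 1]
        if r0 > 0 and c0 > 0:
            tot += p[r0 - 1, c0 - 1]
        return tot

    best = None
    for k in range(min_side, n - min_side + 1):
        cross_sum = rect(pa, 0, k, k, n)
        cross_cnt = rect(pm, 0, k, k, n)
        within_sum = (rect(pa, 0, k, 0, k) + rect(pa, k, n, k, n)) / 2.0
        within_cnt = (rect(pm, 0, k, 0, k) + rect(pm, k, n, k, n)) / 2.0
        if cross_cnt == 0 or within_cnt == 0:
            continue
        contrast = within_sum / within_cnt - cross_sum / cross_cnt
        if best is None or contrast > best[0]:
            best = (contrast, k)
    if best is None or best[0] <= contrast_threshold:
        return None
    contrast, k = best
    return {
        "index": int(k),
        "position": int((positions[k - 1] + positions[k]) // 2),
        "contrast": float(contrast),
    }


def ld_retention_and_boundary(
    vm: VariantMatrix,
    windows: pd.DataFrame,
    target_interval: GenomicInterval,
    background_windows: pd.DataFrame,
    min_shared: int = 4,
    contrast_threshold: float = 0.1,
) -> LDResult:
    """Window-level LD retention with genome-background Z/FDR annotation,
    plus the LD block boundary inside ``target_interval``."""
    if background_windows is None or not len(background_windows):
        raise InvalidParameterError("background windows are required")
    ret = ld_retention(vm, windows, min_shared=min_shared)
    bg = ld_retention(vm, background_windows, min_shared=min_shared)
    annotated = zscore_fdr(ret, bg)
    r2, positions = pairwise_r2(vm, target_interval, min_shared=min_shared)
    boundary = _block_boundary(r2, positions,
                               contrast_threshold=contrast_threshold)
    return LDResult(retention=annotated, boundary=boundary,
                    r2=r2, positions=positions)
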