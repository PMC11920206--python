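"""Site filtering, group allele-frequency profiles, and windowed scans.

Implements the scan layer of the pipeline: variant filtering (biallelic
SNPs at minor-allele frequency >= 0.05 and call rate >= 0.9), per-group
reference-allele frequency profiles, sliding-window nucleotide diversity
and Weir & Cockerham (1984) F_ST between two cohorts, and the
genome-background Z-score / Benjamini-Hochberg FDR annotation used to
declare windows significantly elevated over the genome-wide distribution.

Windows are 1-based inclusive ``[start, start + W - 1]`` advancing by the
step ``S`` (defaults 20 kb / 10 kb at scale 1, divided by the map scale
otherwise); a final partial window is kept and flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .collapse import VariantMatrix
from .regions import GenomicInterval, InvalidParameterError, RegionMap

__all__ = [
    "filter_variants",
    "ref_allele_frequency",
    "build_windows",
    "scan_windows",
    "windowed_pi",
    "windowed_fst",
    "zscore_fdr",
    "region_mean",
]


def filter_variants(vm: VariantMatrix, maf: float = 0.05,
                    max_missing: float = 0.9) -> VariantMatrix:
    """Keep sites with minor-allele frequency >= ``maf`` over all called
    alleles and call rate >= ``max_missing`` (the VCFtools convention:
    ``--max-missing 0.9`` keeps sites genotyped in >= 90% of samples)."""
    called = vm.gt >= 0
    n_called = called.sum(axis=1)
    call_rate = n_called / vm.n_samples
    alt = np.where(called, vm.gt, 0).sum(axis=1)
    total = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    minor = np.minimum(p_alt, 1 - p_alt)
    keep = (call_rate >= max_missing) & (minor >= maf)
    keep &= ~np.isnan(p_alt)
    return vm.take_sites(keep)


def ref_allele_frequency(vm: VariantMatrix, group: list[str]) -> pd.DataFrame:
    """Per-site reference-allele frequency in a sample group, from called
    genotypes: (2 * hom-ref + het) / (2 * called)."""
    if not group:
        raise InvalidParameterError("group is empty")
    idx = vm.sample_indices(group)
    gt = vm.gt[:, idx]
    called = gt >= 0
    n_called = called.sum(axis=1)
    ref_alleles = np.where(called, 2 - gt, 0).sum(axis=1)
    total = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, ref_alleles / np.maximum(total, 1), np.nan)
    return pd.DataFrame({
        "chrom": vm.chrom,
        "pos": vm.positions,
        "freq": freq,
        "n_called_alleles": total,
        "missing_frac": 1 - n_called / len(idx),
    })


# -- windows ------------------------------------------------------------------

def build_windows(interval: GenomicInterval, window_bp: int,
                  step_bp: int) -> pd.DataFrame:
    """Sliding 1-based inclusive windows over an interval."""
    if window_bp <= 0 or step_bp <= 0:
        raise InvalidParameterError("window and step must be positive")
    rows = []
    start = interval.start
    last = interval.end - 1  # half-open interval -> last included position
    while start <= last:
        end = min(start + window_bp - 1, last)
        rows.append((interval.chrom, start, end, end - start + 1 < window_bp))
        start += step_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


def scan_windows(region_map: RegionMap, window_bp: int | None = None,
                 step_bp: int | None = None) -> pd.DataFrame:
    """The default window grid: the scan region plus every background
    interval, at 20 kb / 10 kb divided by the map scale."""
    if window_bp is None:
        window_bp = max(int(round(20_000 / region_map.scale)), 1)
    if step_bp is None:
        step_bp = max(int(round(10_000 / region_map.scale)), 1)
    frames = [build_windows(iv, window_bp, step_bp)
              for iv in region_map.all_intervals()]
    return pd.concat(frames, ignore_index=True)


def _per_site_counts(vm: VariantMatrix, group: list[str]):
    idx = vm.sample_indices(group)
    gt = vm.gt[:, idx]
    called = gt >= 0
    n_dip = called.sum(axis=1)
    n_alt = np.where(called, gt, 0).sum(axis=1)
    n_het = (gt == 1).sum(axis=1)
    return n_dip, n_alt, n_het


def windowed_pi(vm: VariantMatrix, group: list[str],
                windows: pd.DataFrame) -> pd.DataFrame:
    """Windowed nucleotide diversity from genotype calls.

    Per site, with ``n`` called alleles of which ``n_ref``/``n_alt`` are
    reference/alternate, the contribution is ``n_ref * n_alt / C(n, 2)``;
    the window value divides the summed contributions by the window length
    in bp (the standard VCF-based windowed-pi definition, so monomorphic
    and uncalled sites simply contribute zero).
    """
    if (windows["end"] < windows["start"]).any():
        raise InvalidParameterError("zero-length window")
    n_dip, n_alt_cnt, _ = _per_site_counts(vm, group)
    n = 2 * n_dip
    n_ref = n - n_alt_cnt
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(
            n >= 2, n_ref * n_alt_cnt / (n * (n - 1) / 2.0), 0.0)
    return _aggregate(vm, windows, num=contrib,
                      den=None, per_bp=True)


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) two-population variance components a, b, c
    per site (vectorized).  Sites with fewer than one called diploid in
    either group, or with nbar <= 1, come back NaN."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    valid = (n1 >= 1) & (n2 >= 1) & ((n1 + n2) / 2.0 > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nsum = n1 + n2
        nc = (nsum - (n1 ** 2 + n2 ** 2) / nsum) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
            / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    bad = ~valid
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def windowed_fst(vm: VariantMatrix, group_a: list[str], group_b: list[str],
                 windows: pd.DataFrame) -> pd.DataFrame:
    """Windowed Weir & Cockerham F_ST between two cohorts: the weighted
    ("ratio of sums") estimator sum(a) / sum(a + b + c) over the usable
    sites in each window.  Windows whose denominator is zero are reported
    with their site count and a NaN value."""
    if set(group_a) & set(group_b):
        raise InvalidParameterError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise InvalidParameterError("each group needs >= 2 samples")
    na, alt_a, het_a = _per_site_counts(vm, group_a)
    nb, alt_b, het_b = _per_site_counts(vm, group_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(na > 0, alt_a / np.maximum(2 * na, 1), np.nan)
        p2 = np.where(nb > 0, alt_b / np.maximum(2 * nb, 1), np.nan)
        hh1 = np.where(na > 0, het_a / np.maximum(na, 1), np.nan)
        hh2 = np.where(nb > 0, het_b / np.maximum(nb, 1), np.nan)
    a, b, c = _wc_components(na, p1, hh1, nb, p2, hh2)
    den_site = a + b + c
    # monomorphic (and otherwise degenerate) sites carry no information
    usable = np.isfinite(den_site) & (den_site != 0)
    num = np.where(usable, a, 0.0)
    den = np.where(usable, den_site, 0.0)
    return _aggregate(vm, windows, num=num, den=den, per_bp=False)


def _aggregate(vm: VariantMatrix, windows: pd.DataFrame, num: np.ndarray,
               den: np.ndarray | None, per_bp: bool) -> pd.DataFrame:
    out = windows.copy().reset_index(drop=True)
    pos = vm.positions
    values = np.full(len(out), np.nan)
    n_sites = np.zeros(len(out), dtype=int)
    for i, row in enumerate(out.itertuples(index=False)):
        mask = (pos >= row.start) & (pos <= row.end)
        n_sites[i] = int(mask.sum())
        if per_bp:
            length = row.end - row.start + 1
            values[i] = num[mask].sum() / length
        else:
            d = den[mask].sum()
            values[i] = num[mask].sum() / d if d != 0 else np.nan
    out["n_sites"] = n_sites
    out["value"] = values
    return out


def zscore_fdr(stats: pd.DataFrame, background: pd.DataFrame,
               side: str = "upper", alpha: float = 0.05) -> pd.DataFrame:
    """Z-score each window value against the genome-background window
    distribution, with one-sided upper-tail p-values by default (the
    elevation test) and BH-adjusted q over the full tested family
    (scan plus background windows)."""
    bg_vals = background["value"].dropna().to_numpy(dtype=float)
    if bg_vals.size < 2:
        raise InvalidParameterError("background needs >= 2 defined windows")
    mu = bg_vals.mean()
    sd = bg_vals.std(ddof=1)
    if sd == 0:
        raise InvalidParameterError("background standard deviation is zero")

    out = stats.copy().reset_index(drop=True)
    family = pd.concat([stats["value"], background["value"]],
                       ignore_index=True).to_numpy(dtype=float)
    z_all = (family - mu) / sd
    if side == "upper":
        p_all = sps.norm.sf(z_all)
    elif side == "two-sided":
        p_all = 2 * sps.norm.sf(np.abs(z_all))
    else:
        raise InvalidParameterError(f"unknown side {side!r}")
    defined = np.isfinite(p_all)
    q_all = np.full(family.shape, np.nan)
    if defined.any():
        q_all[defined] = multipletests(p_all[defined], method="fdr_bh")[1]
    k = len(out)
    out["z"] = z_all[:k]
    out["p"] = p_all[:k]
    out["q"] = q_all[:k]
    out["significant"] = out["q"] < alpha
    return out


def region_mean(stats: pd.DataFrame, interval: GenomicInterval,
                column: str = "value") -> float:
    """Mean of a window statistic over windows whose midpoint falls in the
    interval (the per-region summary used for signatures and region-level
    mean Z)."""
    mid = (stats["start"] + stats["end"]) // 2
    sel = stats[(mid >= interval.start) & (mid < interval.end)]
    vals = sel[column].dropna()
    return float(vals.mean()) if len(vals) else float("nan")
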