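"""Coordinates and candidate architectures of the chicken FM locus.

The fibromelanosis (*FM*) allele on chicken chromosome 20 carries two large
duplicated intervals, DUP1 and DUP2, separated by a non-duplicated
intervening region (INT), with an inversion whose extent differs between the
three candidate arrangements FM-1/FM-2/FM-3.  This module stores the locus
geometry, scales it down for desk-size simulation, and encodes, for each
candidate arrangement, which region copies are frozen by recombination
suppression and hence which regions are predicted to show an
allele-frequency "bubble" in FM homozygotes.

Intervals are 1-based with half-open extent: ``length_bp = end - start``,
so printed boundary coordinates are stored verbatim and DUP1, INT and DUP2
tile the locus sharing boundary points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

__all__ = [
    "GenomicInterval",
    "RegionMap",
    "CopySpec",
    "ConfigurationGeometry",
    "CONFIGURATIONS",
    "REGION_NAMES",
    "build_region_map",
    "configuration_geometry",
    "predicted_signature",
    "ancestral_unit_length_kb",
]

REGION_NAMES = ("DUP1", "INT", "DUP2")

#: Published locus coordinates (GRCg6a, chromosome 20), 1-based.
CHROM = "chr20"
DUP1_START, DUP1_END = 10_766_772, 10_894_151
DUP2_START, DUP2_END = 11_306_686, 11_477_501
SCAN_START, SCAN_END = 10_600_000, 11_700_000
#: Genome-background intervals used as the stand-in for the whole-genome
#: depth / diversity background; disjoint from the scan region.
BACKGROUND_SPANS = ((9_000_000, 9_550_000), (12_000_000, 12_550_000))


class InvalidParameterError(ValueError):
    """A parameter is outside its documented domain."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based, inclusive
    end: int    # half-open: first position *not* in the interval
    label: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InvalidParameterError(
                f"interval {self.label!r}: end {self.end} < start {self.start}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def length_kb(self, ndigits: int = 1) -> float:
        """Length in kb rounded half-up to ``ndigits`` decimals.

        Decimal half-up rounding matches how lengths are conventionally
        printed (e.g. 412,535 bp -> 412.54 kb), which binary-float round()
        does not reproduce.
        """
        kb = Decimal(self.length_bp) / Decimal(1000)
        q = Decimal(1).scaleb(-ndigits)
        return float(kb.quantize(q, rounding=ROUND_HALF_UP))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class RegionMap:
    """The named intervals of the FM locus at a given reduction scale."""

    dup1: GenomicInterval
    int_region: GenomicInterval
    dup2: GenomicInterval
    scan_region: GenomicInterval
    background_regions: tuple[GenomicInterval, ...]
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.dup1.end <= self.int_region.start
                <= self.int_region.end <= self.dup2.start):
            raise InvalidParameterError("DUP1/INT/DUP2 are not ordered")
        if not (self.scan_region.start <= self.dup1.start
                and self.dup2.end <= self.scan_region.end):
            raise InvalidParameterError("scan region must contain the locus")
        for bg in self.background_regions:
            if not (bg.end <= self.scan_region.start
                    or bg.start >= self.scan_region.end):
                raise InvalidParameterError(
                    f"background region {bg.label!r} overlaps the scan region"
                )

    @property
    def named_regions(self) -> dict[str, GenomicInterval]:
        return {"DUP1": self.dup1, "INT": self.int_region, "DUP2": self.dup2}

    def all_intervals(self) -> list[GenomicInterval]:
        return [self.scan_region, *self.background_regions]

    def region_of(self, pos: int) -> str | None:
        """Region label for a position: DUP1/INT/DUP2, FLANK (in the scan
        region but outside the locus), BG, or None."""
        for name, iv in self.named_regions.items():
            if iv.contains(pos):
                return name
        if self.scan_region.contains(pos):
            return "FLANK"
        for bg in self.background_regions:
            if bg.contains(pos):
                return "BG"
        return None


def _scale_pos(pos: int, scale: float) -> int:
    # deterministic half-up integer rounding; banker's rounding would make
    # scaled maps platform-stable but position-parity dependent
    return int(pos / scale + 0.5)


def build_region_map(scale: float = 1.0) -> RegionMap:
    """The FM locus map, with all coordinates divided by ``scale``.

    At ``scale=1`` the published coordinates are returned exactly; at
    ``scale=s`` every coordinate is ``round(pos / s)``, preserving relative
    order and proportional gaps to within 1 bp of rounding.
    """
    if not scale or scale < 1:
        raise InvalidParameterError(f"scale must be >= 1, got {scale!r}")

    def iv(start: int, end: int, label: str) -> GenomicInterval:
        return GenomicInterval(CHROM, _scale_pos(start, scale),
                               _scale_pos(end, scale), label)

    return RegionMap(
        dup1=iv(DUP1_START, DUP1_END, "DUP1"),
        int_region=iv(DUP1_END, DUP2_START, "INT"),
        dup2=iv(DUP2_START, DUP2_END, "DUP2"),
        scan_region=iv(SCAN_START, SCAN_END, "SCAN"),
        background_regions=tuple(
            iv(s, e, f"BG{i + 1}") for i, (s, e) in enumerate(BACKGROUND_SPANS)
        ),
        scale=float(scale),
    )


# -- candidate configurations -------------------------------------------------

#: Suppression states.  ``both_copies_frozen`` / ``frozen`` regions are inside
#: the recombination-suppressed span of the FM allele and never exchange with
#: wild-type chromosomes; ``free`` copies erode over generations.
BOTH_FROZEN = "both_copies_frozen"
ONE_FROZEN = "one_copy_frozen"
FROZEN = "frozen"
FREE = "free"


@dataclass(frozen=True)
class CopySpec:
    source_region: str
    orientation: str  # "forward" | "inverted"
    suppressed: bool


@dataclass(frozen=True)
class ConfigurationGeometry:
    """Copy layout and suppression states of one candidate arrangement."""

    label: str
    copies: tuple[CopySpec, ...]
    region_suppression: dict[str, str] = field(hash=False)

    def copy_number(self, region: str) -> int:
        return sum(1 for c in self.copies if c.source_region == region)

    def bubble_flags(self) -> tuple[bool, bool, bool]:
        """Predicted allele-frequency bubble per (DUP1, INT, DUP2)."""
        return tuple(
            self.region_suppression[r] in (BOTH_FROZEN, FROZEN)
            for r in REGION_NAMES
        )


def _cfg(label, copies, suppression) -> ConfigurationGeometry:
    return ConfigurationGeometry(
        label=label,
        copies=tuple(CopySpec(*c) for c in copies),
        region_suppression=dict(suppression),
    )


CONFIGURATIONS: dict[str, ConfigurationGeometry] = {
    # wild type: one free forward copy of everything
    "WT": _cfg(
        "WT",
        [("DUP1", "forward", False), ("INT", "forward", False),
         ("DUP2", "forward", False)],
        {"DUP1": FREE, "INT": FREE, "DUP2": FREE},
    ),
    # FM-1: inversion of an entire block (one DUP1 copy, INT, one DUP2 copy);
    # the whole locus is recombination-suppressed
    "FM-1": _cfg(
        "FM-1",
        [("DUP1", "forward", True), ("DUP2", "inverted", True),
         ("INT", "inverted", True), ("DUP1", "inverted", True),
         ("DUP2", "forward", True)],
        {"DUP1": BOTH_FROZEN, "INT": FROZEN, "DUP2": BOTH_FROZEN},
    ),
    # FM-2: inverted DUP2 copy inserted between two tandem DUP1 copies;
    # suppression covers DUP1-invDUP2-DUP1, while INT and the second DUP2
    # copy recombine freely with wild-type chromosomes
    "FM-2": _cfg(
        "FM-2",
        [("DUP1", "forward", True), ("DUP2", "inverted", True),
         ("DUP1", "forward", True), ("INT", "forward", False),
         ("DUP2", "forward", False)],
        {"DUP1": BOTH_FROZEN, "INT": FREE, "DUP2": ONE_FROZEN},
    ),
    # FM-3: mirror image — inverted DUP1 copy next to DUP2
    "FM-3": _cfg(
        "FM-3",
        [("DUP1", "forward", False), ("INT", "forward", False),
         ("DUP2", "forward", True), ("DUP1", "inverted", True),
         ("DUP2", "forward", True)],
        {"DUP1": ONE_FROZEN, "INT": FREE, "DUP2": BOTH_FROZEN},
    ),
}


def configuration_geometry(label: str) -> ConfigurationGeometry:
    try:
        return CONFIGURATIONS[label]
    except KeyError:
        raise InvalidParameterError(
            f"unknown configuration {label!r}; expected one of "
            f"{sorted(CONFIGURATIONS)}"
        ) from None


def predicted_signature(label: str) -> tuple[bool, bool, bool]:
    """Predicted bubble-flag triple (DUP1, INT, DUP2) for a configuration.

    A region shows the bubble (site frequencies pinned at 0, 0.5 and 1 in FM
    homozygotes) exactly when all of its copies on the FM haplotype are
    frozen by suppressed recombination.
    """
    return configuration_geometry(label).bubble_flags()


def ancestral_unit_length_kb(
    printed_lengths_kb: Sequence[float] | dict[str, float],
) -> float:
    """Span of the hypothesized ancestral tandem duplication unit.

    Under the birth model, the FM allele arose by an unequal cross-over
    duplicating the whole DUP1..DUP2 span, followed by an inversion that
    lost one copy of the intervening region.  The ancestral unit length is
    the sum of the three per-region lengths at their printed (one-decimal)
    precision.
    """
    if isinstance(printed_lengths_kb, dict):
        try:
            vals = [printed_lengths_kb[r] for r in REGION_NAMES]
        except KeyError as e:
            raise InvalidParameterError(f"missing region length: {e}") from None
    else:
        vals = list(printed_lengths_kb)
    if len(vals) != 3 or any(v is None for v in vals):
        raise InvalidParameterError(
            "need exactly three per-region lengths (DUP1, INT, DUP2)"
        )
    total = sum(Decimal(str(v)) for v in vals)
    return float(total.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
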