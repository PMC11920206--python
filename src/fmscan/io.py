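"""Readers and writers for the pipeline's on-disk formats.

Formats are the field's plain-text standards: VCF v4.2 with GT and AD
(read back through cyvcf2; multiallelic records are skipped with a logged
count, since only biallelic loci enter the analysis), a long-format depth
TSV, BED (0-based half-open at the file boundary only; coordinates are
1-based half-open in memory), newick trees, and JSON sidecars for truth
and reports.  Every writer round-trips losslessly through its reader.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .collapse import DepthProfile, VariantMatrix
from .phylo import TreeNode
from .regions import GenomicInterval, RegionMap

log = logging.getLogger("fmscan")

__all__ = [
    "write_vcf", "read_vcf",
    "write_depth_tsv", "read_depth_tsv",
    "write_bed", "read_bed",
    "write_newick", "read_newick",
    "write_json", "read_json",
    "write_observed", "read_groups_tsv",
]

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(vm: VariantMatrix, path: str | Path,
              contig_length: int | None = None) -> None:
    path = Path(path)
    if contig_length is None:
        contig_length = int(vm.positions.max()) + 1000 if vm.n_sites else 1000
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={vm.chrom},length={contig_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Allelic depths (ref,alt)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(vm.samples),
    ]
    gt = vm.gt
    for i in range(vm.n_sites):
        fields = [vm.chrom, str(int(vm.positions[i])), ".",
                  str(vm.ref[i]), str(vm.alt[i]), ".", "PASS", ".", "GT:AD"]
        cells = [
            f"{_GT_STR[int(gt[i, j])]}:{int(vm.ad_ref[i, j])},"
            f"{int(vm.ad_alt[i, j])}"
            for j in range(vm.n_samples)
        ]
        lines.append("\t".join(fields + cells))
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> tuple[VariantMatrix, int]:
    """Read a biallelic GT[:AD] VCF; returns the matrix and the number of
    skipped multiallelic records."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    positions, ref, alt, gt_rows, adr_rows, ada_rows = [], [], [], [], [], []
    chrom = None
    skipped = 0
    header = vcf.raw_header or ""
    if "##FORMAT=<ID=GT" not in header:
        raise ValueError(f"{path}: FORMAT/GT missing from header")
    has_ad = "##FORMAT=<ID=AD" in header
    for v in vcf:
        if len(v.ALT) != 1:
            skipped += 1
            continue
        chrom = v.CHROM
        positions.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        g = np.array(v.genotypes, dtype=object)
        row = np.empty(len(samples), dtype=np.int8)
        for j, cell in enumerate(g):
            a = [x for x in cell[:-1] if x is not None and x >= 0]
            row[j] = sum(a) if len(a) == 2 else -1
        gt_rows.append(row)
        ad = v.format("AD") if has_ad else None
        if ad is None:
            adr_rows.append(np.zeros(len(samples), dtype=np.int32))
            ada_rows.append(np.zeros(len(samples), dtype=np.int32))
        else:
            ad = np.where(ad < 0, 0, ad)
            adr_rows.append(ad[:, 0].astype(np.int32))
            ada_rows.append(ad[:, 1].astype(np.int32))
    vcf.close()
    if skipped:
        log.info("read_vcf: skipped %d multiallelic record(s)", skipped)
    n = len(positions)
    vm = VariantMatrix(
        chrom=chrom or "chr20",
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(ref), alt=np.array(alt),
        gt=(np.vstack(gt_rows) if n else
            np.empty((0, len(samples)), dtype=np.int8)),
        ad_ref=(np.vstack(adr_rows) if n else
                np.empty((0, len(samples)), dtype=np.int32)),
        ad_alt=(np.vstack(ada_rows) if n else
                np.empty((0, len(samples)), dtype=np.int32)),
        samples=samples,
    )
    return vm, skipped


def write_depth_tsv(profile: DepthProfile, path: str | Path) -> None:
    rows = []
    win = profile.windows
    for j, s in enumerate(profile.samples):
        for i in range(len(win)):
            rows.append((s, win.iloc[i]["chrom"], int(win.iloc[i]["start"]),
                         int(win.iloc[i]["end"]), win.iloc[i]["region"],
                         int(win.iloc[i]["n_sites"]), profile.depth[i, j]))
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "region",
                                "n_sites", "mean_depth"]) \
        .to_csv(path, sep="\t", index=False)


def read_depth_tsv(path: str | Path) -> DepthProfile:
    df = pd.read_csv(path, sep="\t")
    samples = list(dict.fromkeys(df["sample"]))
    win = df[df["sample"] == samples[0]][
        ["chrom", "start", "end", "region", "n_sites"]].reset_index(drop=True)
    depth = np.column_stack([
        df[df["sample"] == s]["mean_depth"].to_numpy() for s in samples])
    bg = win["region"] == "BG"
    w = win["n_sites"].to_numpy()[np.asarray(bg)]
    sub = depth[np.asarray(bg)]
    with np.errstate(invalid="ignore"):
        background_mean = np.nansum(sub * w[:, None], axis=0) / w.sum()
    return DepthProfile(windows=win, depth=depth,
                        background_mean=background_mean, samples=samples)


def write_bed(intervals: list[GenomicInterval] | RegionMap,
              path: str | Path) -> None:
    """BED is 0-based half-open; in-memory intervals are 1-based half-open,
    so the start shifts by one and the exclusive end carries over."""
    if isinstance(intervals, RegionMap):
        m = intervals
        intervals = [m.dup1, m.int_region, m.dup2, m.scan_region,
                     *m.background_regions]
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end - 1}\t{iv.label}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: malformed BED line")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-integer BED coordinates")
        name = parts[3] if len(parts) > 3 else ""
        out.append(GenomicInterval(parts[0], start + 1, end + 1, name))
    return out


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path: str | Path) -> TreeNode:
    import skbio

    sk = skbio.TreeNode.read(str(path))

    def convert(node) -> TreeNode:
        return TreeNode(
            name=node.name,
            length=float(node.length or 0.0),
            children=[convert(c) for c in node.children],
        )

    return convert(sk)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_observed(dataset, vcf_path: str | Path,
                   depth_path: str | Path) -> None:
    """Emit a collapsed-reference dataset as VCF + depth TSV."""
    write_vcf(dataset.variants, vcf_path)
    write_depth_tsv(dataset.depth, depth_path)


def read_groups_tsv(path: str | Path) -> dict[str, list[str]]:
    """sample -> group TSV (two columns, optional header)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if str(df.iloc[0, 0]).lower() == "sample":
        df = df.iloc[1:]
    groups: dict[str, list[str]] = {}
    for s, g in zip(df.iloc[:, 0], df.iloc[:, 1]):
        groups.setdefault(str(g), []).append(str(s))
    return groups
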