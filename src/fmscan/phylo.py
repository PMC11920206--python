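"""Neighbor-joining trees from SNP allele-sharing distances.

Separate trees for the DUP1 and DUP2 regions expose the asymmetry of the FM
allele: where recombination is suppressed the FM haplotypes are frozen
copies of one founder, so FM samples cluster on short terminal branches;
where erosion acts their sequences have re-randomized toward the wild-type
pool.  Distances are allele-sharing distances on unphased genotype dosages,
``d_ij = mean |dosage_i - dosage_j| / 2`` over co-called sites, and trees
are built with the Saitou-Nei neighbor-joining algorithm (deterministic
lexicographic tie-breaking, negative branch lengths clamped to zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collapse import VariantMatrix
from .regions import GenomicInterval, InvalidParameterError

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "distance_matrix",
    "neighbor_joining",
    "branch_length_contrast",
    "leaf_bipartitions",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise InvalidParameterError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InvalidParameterError("distance matrix is not symmetric")
        self.values = v


@dataclass
class TreeNode:
    """Minimal tree node; leaves carry sample names.  ``length`` is the
    branch to the parent."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def to_newick(self) -> str:
        return self._newick_part() + ";"

    def _newick_part(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_part() for c in self.children)
        name = self.name or ""
        return f"({inner}){name}:{self.length:.10g}"

    def terminal_branch_lengths(self) -> dict[str, float]:
        return {l.name: l.length for l in self.leaves()}

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path distances (for additivity checks)."""
        out: dict[tuple[str, str], float] = {}

        def below(node):
            if node.is_leaf:
                return {node.name: node.length}
            sub = [below(c) for c in node.children]
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for a, da in sub[i].items():
                        for b, db in sub[j].items():
                            key = tuple(sorted((a, b)))
                            out[key] = da + db
            merged = {}
            for s in sub:
                for a, da in s.items():
                    merged[a] = da + node.length
            return merged

        below(self)
        return out


def distance_matrix(vm: VariantMatrix,
                    region: GenomicInterval | None = None,
                    samples: list[str] | None = None) -> DistanceMatrix:
    """Allele-sharing distance in [0, 1] between every sample pair, from
    dosages at co-called sites in the region."""
    sub = vm.sites_in(region) if region is not None else vm
    if samples is not None:
        idx = sub.sample_indices(samples)
        labels = list(samples)
    else:
        idx = np.arange(sub.n_samples)
        labels = list(sub.samples)
    if len(labels) < 3:
        raise InvalidParameterError("need >= 3 samples for a tree")
    gt = sub.gt[:, idx].astype(float)
    gt[gt < 0] = np.nan
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(gt[:, i:i + 1] - gt[:, i:]) / 2.0
        shared = np.isfinite(diff)
        cnt = shared.sum(axis=0)
        for off in np.flatnonzero(cnt == 0):
            j = i + off
            if i != j:
                raise InvalidParameterError(
                    f"samples {labels[i]!r} and {labels[j]!r} share no "
                    f"called sites"
                )
        with np.errstate(invalid="ignore"):
            row = np.nansum(np.where(shared, diff, 0.0), axis=0) / cnt
        d[i, i:] = row
        d[i:, i] = row
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, values=d)


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Ties in Q are broken by the lexicographically smallest label pair so
    the topology is platform-independent; negative branch lengths are
    clamped to zero.  The returned tree is unrooted, represented with a
    trifurcating root (or the single internal node for 3 taxa).
    """
    n0 = len(dist.labels)
    if n0 < 3:
        raise InvalidParameterError("need >= 3 taxa")
    nodes = [TreeNode(name=l) for l in dist.labels]
    # sort key per active node: smallest leaf label below it
    keys = list(dist.labels)
    d = dist.values.astype(float).copy()
    active = list(range(n0))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        cand = np.argwhere(q <= qmin + tol)
        best = None
        for i, j in cand:
            if i >= j:
                continue
            pair_key = tuple(sorted((keys[active[i]], keys[active[j]])))
            if best is None or pair_key < best[0]:
                best = (pair_key, int(i), int(j))
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[ai].length = li
        nodes[aj].length = lj
        parent = TreeNode(children=sorted(
            [nodes[ai], nodes[aj]],
            key=lambda nd: min(nd.leaf_names())))
        # distances from the new node to every remaining node
        new_row = np.zeros(d.shape[0] + 1)
        for t, at in enumerate(active):
            if at in (ai, aj):
                continue
            new_row[at] = 0.5 * (sub[i, t] + sub[j, t] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[ai], keys[aj]))
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    # join the final three on a trifurcating root
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    nodes[a].length = max(0.5 * (dab + dac - dbc), 0.0)
    nodes[b].length = max(0.5 * (dab + dbc - dac), 0.0)
    nodes[c].length = max(0.5 * (dac + dbc - dab), 0.0)
    root = TreeNode(children=sorted(
        [nodes[a], nodes[b], nodes[c]],
        key=lambda nd: min(nd.leaf_names())))
    return root


def leaf_bipartitions(tree: TreeNode) -> list[frozenset]:
    """The leaf set below each internal edge (for monophyly checks)."""
    parts = []

    def walk(node, at_root):
        if not node.is_leaf and not at_root:
            parts.append(frozenset(node.leaf_names()))
        for c in node.children:
            walk(c, False)

    walk(tree, True)
    return parts


def branch_length_contrast(tree_dup1: TreeNode, tree_dup2: TreeNode,
                           fm_samples: list[str]) -> dict:
    """Mean terminal branch length of the FM samples in each region tree
    and their DUP1/DUP2 ratio — short FM branches in a region indicate a
    frozen (suppressed) haplotype there."""
    t1 = tree_dup1.terminal_branch_lengths()
    t2 = tree_dup2.terminal_branch_lengths()
    if set(t1) != set(t2):
        raise InvalidParameterError("trees have different leaf sets")
    missing = [s for s in fm_samples if s not in t1]
    if missing:
        raise InvalidParameterError(f"samples not in trees: {missing[:5]}")
    m1 = float(np.mean([t1[s] for s in fm_samples]))
    m2 = float(np.mean([t2[s] for s in fm_samples]))
    return {
        "mean_terminal_dup1": m1,
        "mean_terminal_dup2": m2,
        "ratio": m1 / m2 if m2 > 0 else float("inf") if m1 > 0 else 1.0,
    }
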