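"""Population trees from allele frequencies.

Re-implements the classic frequency-based phylogenetics pipeline for
SNP data: per-population allele frequencies, Nei's standard genetic
distance

    D = -ln( Jxy / sqrt(Jx * Jy) ),

with J-statistics averaged over biallelic loci (Jxy = mean of
x*y + (1-x)(1-y), Jx = mean of x^2 + (1-x)^2), Saitou-Nei
neighbor-joining with deterministic tie-breaking, and a bootstrap
majority-rule consensus over marker resamplings with percentage support
values, optionally displayed rooted on an outgroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeDataError, GenotypeMatrix

log = logging.getLogger(__name__)

#: Distance assigned when populations share no allele identity (Jxy = 0).
DEFAULT_MAX_DISTANCE = 10.0

_NEWICK_SPECIALS = set("()[]{}:;,'\" \t\n")


@dataclass
class AlleleFrequencyTable:
    populations: list[str]
    rs_ids: list[str]
    freq: np.ndarray  # P x L, nan where a group had no calls
    n_obs: np.ndarray  # P x L non-missing allele counts


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: int | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


# ---------------------------------------------------------------------------
# allele frequencies and Nei distance
# ---------------------------------------------------------------------------

def _as_grouping(grouping, sample_ids) -> pd.Series:
    if isinstance(grouping, pd.Series):
        s = grouping
    else:
        s = pd.Series(dict(grouping))
    missing = [sid for sid in sample_ids if sid not in s.index]
    if missing:
        raise GenotypeDataError(f"no population label for sample {missing[0]!r}")
    return s.loc[sample_ids]


def allele_frequencies(gm: GenotypeMatrix, grouping) -> AlleleFrequencyTable:
    """Per-population alt-allele frequencies over non-missing calls."""
    labels = _as_grouping(grouping, gm.sample_ids)
    populations = sorted(labels.unique())
    freq = np.empty((len(populations), gm.n_markers))
    n_obs = np.empty((len(populations), gm.n_markers), dtype=np.int64)
    for i, pop in enumerate(populations):
        rows = (labels == pop).to_numpy()
        if rows.sum() == 0:
            raise GenotypeDataError(f"population {pop!r} has no samples")
        sub = gm.calls[rows]
        obs = sub != MISSING
        alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq[i] = np.where(alleles > 0, alt / np.maximum(alleles, 1), np.nan)
        n_obs[i] = alleles
    return AlleleFrequencyTable(populations, gm.rs_ids, freq, n_obs)


def nei_distance(
    x: np.ndarray, y: np.ndarray, max_distance: float = DEFAULT_MAX_DISTANCE
) -> float:
    """Nei's standard genetic distance from two biallelic frequency vectors.

    Loci where either frequency is undefined (nan) are excluded; a zero
    probability of allele identity between the populations (possible only
    with fixed differences at every locus) is clamped to ``max_distance``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    valid = ~(np.isnan(x) | np.isnan(y))
    if valid.sum() == 0:
        raise GenotypeDataError("no shared valid markers between populations")
    x, y = x[valid], y[valid]
    jxy = float(np.mean(x * y + (1 - x) * (1 - y)))
    jx = float(np.mean(x * x + (1 - x) * (1 - x)))
    jy = float(np.mean(y * y + (1 - y) * (1 - y)))
    if jxy <= 0.0:
        log.info("Nei distance clamped to %.3g (no shared allele identity)", max_distance)
        return max_distance
    return min(max_distance, -float(np.log(jxy / np.sqrt(jx * jy))))


def nei_distance_matrix(
    aft: AlleleFrequencyTable, max_distance: float = DEFAULT_MAX_DISTANCE
) -> DistanceMatrix:
    p = len(aft.populations)
    d = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            d[i, j] = d[j, i] = nei_distance(
                aft.freq[i], aft.freq[j], max_distance
            )
    return DistanceMatrix(list(aft.populations), d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q-criterion resolve to the pair whose (lexicographically
    sorted) representative leaf labels are smallest.  Negative branch
    lengths are clamped to zero with the excess moved to the sister
    branch.  Returns an unrooted tree as a trifurcating root node.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 labels")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    reps: list[str] = list(dm.labels)  # representative = min leaf label
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        r = len(active)
        rsums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best, best_q, best_key = None, np.inf, None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - rsums[i] - rsums[j]
                key = tuple(sorted((reps[i], reps[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best_key is None or key < best_key)
                ):
                    best, best_q, best_key = (i, j), q, key
        i, j = best
        li = d[i, j] / 2.0 + (rsums[i] - rsums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        u = len(nodes)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    root = TreeNode(
        children=[
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ]
    )
    return root


# ---------------------------------------------------------------------------
# bipartitions and consensus
# ---------------------------------------------------------------------------

def bipartitions(tree: TreeNode) -> dict[frozenset, float]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge is encoded as the frozenset of leaves on the side
    *not* containing the reference leaf (the lexicographically smallest
    label), mapped to the edge's branch length.
    """
    all_leaves = sorted(tree.leaves())
    ref = all_leaves[0]
    total = set(all_leaves)
    out: dict[frozenset, float] = {}

    def walk(node: TreeNode) -> set:
        below = set()
        for child, length in node.children:
            child_set = walk(child)
            if 1 < len(child_set) < len(total) - 1:
                side = child_set if ref not in child_set else total - child_set
                out[frozenset(side)] = length
            below |= child_set
        if node.is_leaf():
            return {node.label}
        return below

    walk(tree)
    return out


def _leaf_branch_lengths(tree: TreeNode) -> dict[str, float]:
    out: dict[str, float] = {}

    def walk(node: TreeNode) -> None:
        for child, length in node.children:
            if child.is_leaf():
                out[child.label] = length
            else:
                walk(child)

    walk(tree)
    return out


def _compatible(cluster: frozenset, selected) -> bool:
    return all(
        cluster <= other or other <= cluster or not (cluster & other)
        for other in selected
    )


def consensus_tree(
    trees: list[TreeNode],
    strict_majority: bool = False,
) -> TreeNode:
    """Majority-rule (extended) consensus with percentage supports.

    Extended mode (the default) seeds the tree with all bipartitions in
    more than half the replicates and then adds remaining bipartitions in
    frequency order while they stay compatible; strict-majority mode
    keeps only the >50% set.  Branch lengths are replicate means.
    """
    if not trees:
        raise ValueError("no trees to summarise")
    n_rep = len(trees)
    leaves = sorted(trees[0].leaves())
    ref = leaves[0]

    counts: dict[frozenset, int] = {}
    length_sums: dict[frozenset, float] = {}
    leaf_len_sums = {l: 0.0 for l in leaves}
    for t in trees:
        for clade, length in bipartitions(t).items():
            counts[clade] = counts.get(clade, 0) + 1
            length_sums[clade] = length_sums.get(clade, 0.0) + length
        for l, length in _leaf_branch_lengths(t).items():
            leaf_len_sums[l] += length

    ordered = sorted(
        counts.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0])))
    )
    selected: list[frozenset] = []
    for clade, count in ordered:
        if strict_majority and count * 2 <= n_rep:
            continue
        if count * 2 > n_rep or (not strict_majority and _compatible(clade, selected)):
            if _compatible(clade, selected):
                selected.append(clade)

    # nest selected clusters (none contains the reference leaf)
    selected.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    cluster_nodes: dict[frozenset, TreeNode] = {}
    parent_of: dict[frozenset, frozenset | None] = {}
    for clade in selected:
        node = TreeNode(support=int(round(100.0 * counts[clade] / n_rep)))
        cluster_nodes[clade] = node
        parent = None
        for other in selected:
            if clade < other and (
                parent is None or other < parent
            ):
                parent = other
        parent_of[clade] = parent

    root = TreeNode()
    for clade in selected:
        parent = parent_of[clade]
        holder = root if parent is None else cluster_nodes[parent]
        holder.children.append(
            (cluster_nodes[clade], length_sums[clade] / counts[clade])
        )
    for leaf in leaves:
        host = None
        for clade in selected:
            if leaf in clade and (host is None or clade < host):
                host = clade
        holder = root if host is None else cluster_nodes[host]
        holder.children.append(
            (TreeNode(label=leaf), leaf_len_sums[leaf] / n_rep)
        )
    return root


def root_on_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Return the tree displayed rooted on the edge leading to ``outgroup``."""
    if outgroup not in tree.leaves():
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")

    def detach(node: TreeNode) -> tuple[TreeNode, float] | None:
        for idx, (child, length) in enumerate(node.children):
            if child.is_leaf() and child.label == outgroup:
                node.children.pop(idx)
                return child, length
            found = detach(child)
            if found is not None:
                return found
        return None

    out_leaf, length = detach(tree)
    if len(tree.children) == 1:
        tree = tree.children[0][0]
    return TreeNode(children=[(out_leaf, length / 2.0), (tree, length / 2.0)])


def bootstrap_consensus(
    gm: GenotypeMatrix,
    grouping,
    n_replicates: int = 100,
    seed: int = 0,
    outgroup: str | None = None,
    strict_majority: bool = False,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> TreeNode:
    """Bootstrap NJ consensus over marker resamplings.

    Each replicate resamples markers with replacement, recomputes the
    population frequencies, Nei distances and the NJ tree; supports are
    the percentage of replicates containing each bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels = _as_grouping(grouping, gm.sample_ids)
    if outgroup is not None and outgroup not in set(labels):
        raise ValueError(f"outgroup {outgroup!r} not among population labels")
    aft = allele_frequencies(gm, grouping)
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_replicates):
        idx = rng.integers(0, len(aft.rs_ids), size=len(aft.rs_ids))
        rep = AlleleFrequencyTable(
            aft.populations, [aft.rs_ids[i] for i in idx], aft.freq[:, idx],
            aft.n_obs[:, idx],
        )
        trees.append(neighbor_joining(nei_distance_matrix(rep, max_distance)))
    cons = consensus_tree(trees, strict_majority=strict_majority)
    if outgroup is not None:
        cons = root_on_outgroup(cons, outgroup)
    return cons


# ---------------------------------------------------------------------------
# Newick output
# ---------------------------------------------------------------------------

def _quote(label: str) -> str:
    if any(c in _NEWICK_SPECIALS for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: TreeNode) -> str:
    def fmt(node: TreeNode, length: float | None) -> str:
        if node.is_leaf():
            body = _quote(node.label)
        else:
            inner = ",".join(fmt(c, l) for c, l in node.children)
            sup = "" if node.support is None else str(node.support)
            body = f"({inner}){sup}"
        return body if length is None else f"{body}:{length:.6g}"

    return fmt(tree, None) + ";"


def write_newick(tree: TreeNode, sink) -> None:
    text = to_newick(tree) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)
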