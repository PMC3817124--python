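"""Iterative-pruning PCA subpopulation assignment.

Individuals are recursively bisected in principal-component space until
the eigenvalue spectrum of a node looks like that of a homogeneous
population.  The stopping statistic, EigenDev, is the root-mean-square
deviation of the top eigenvalues of the (1/L) X X^T sample covariance of
the standardized genotype matrix:

    EigenDev = sqrt( (1/p) * sum_i (lambda_i - mean(lambda))^2 ),

over the top p = min(N-1, 100) eigenvalues.  Nodes with EigenDev at or
below the threshold (default 0.21) become terminal subpopulations;
otherwise members are split in two by fuzzy c-means on the top two PC
scores.  Children smaller than ``min_subpop_size`` are set aside as
outlier terminal nodes — the individuals that "cannot be assigned" to
any subpopulation.  Region labels are never consulted: the procedure is
fully unsupervised, and labels enter only in reporting.

Because the published threshold was calibrated on a particular platform,
:func:`calibrate_threshold` provides a null-simulation quantile as a
principled alternative for other data shapes.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_EIGENDEV_THRESHOLD = 0.21
DEFAULT_MIN_SUBPOP_SIZE = 20
DEFAULT_MAX_DEPTH = 20


@dataclass
class StandardizedMatrix:
    values: np.ndarray  # N x L, mean-imputed, centred, unit-variance columns
    marker_means: np.ndarray  # 2 * p-hat per marker
    marker_scales: np.ndarray  # sqrt(2 p (1-p)); 0 marks a degenerate column


@dataclass
class ClusterNode:
    node_id: str
    member_ids: list[str]
    eigendev: float
    status: str  # "internal" | "terminal_subpop" | "terminal_outlier"
    children: list[str] = field(default_factory=list)
    subpop_label: str | None = None

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusterTree:
    nodes: dict[str, ClusterNode]
    root_id: str
    assignment: pd.Series  # sample_id -> terminal node id
    outlier_ids: list[str]

    def terminal_nodes(self, status: str | None = None) -> list[ClusterNode]:
        out = [
            n
            for n in self.nodes.values()
            if n.status in ("terminal_subpop", "terminal_outlier")
        ]
        if status is not None:
            out = [n for n in out if n.status == status]
        return sorted(out, key=lambda n: n.node_id)

    def subpopulations(self) -> dict[str, list[str]]:
        """Subpop label -> member sample ids, in discovery order."""
        return {
            n.subpop_label: list(n.member_ids)
            for n in sorted(
                self.terminal_nodes("terminal_subpop"),
                key=lambda n: int(n.subpop_label.removeprefix("SP")),
            )
        }

    def subpop_assignment(self) -> pd.Series:
        """sample_id -> subpop label, outliers excluded."""
        pairs = {}
        for node in self.terminal_nodes("terminal_subpop"):
            for sid in node.member_ids:
                pairs[sid] = node.subpop_label
        return pd.Series(pairs, name="subpop")


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------

def standardize(gm_or_calls) -> StandardizedMatrix:
    """Centre and scale genotype columns for PCA.

    Missing calls are mean-imputed; each column is centred by 2*p-hat and
    scaled by sqrt(2 p-hat (1 - p-hat)).  Monomorphic columns are zeroed.
    """
    calls = gm_or_calls.calls if isinstance(gm_or_calls, GenotypeMatrix) else gm_or_calls
    if calls.shape[0] < 2:
        raise ValueError("standardization requires at least 2 samples")
    x = calls.astype(float)
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    col_mean = np.where(
        n_obs > 0, np.where(obs, x, 0.0).sum(axis=0) / np.maximum(n_obs, 1), 0.0
    )
    x = np.where(obs, x, col_mean)
    p_hat = col_mean / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    degenerate = scale <= 0.0
    safe = np.where(degenerate, 1.0, scale)
    x = (x - col_mean) / safe
    x[:, degenerate] = 0.0
    return StandardizedMatrix(x, col_mean, np.where(degenerate, 0.0, scale))


def pca_spectrum(
    sm: StandardizedMatrix, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and top PC scores of (1/L) X X^T."""
    x = sm.values
    if not np.any(sm.marker_scales > 0):
        raise ValueError("all markers are degenerate; no spectrum")
    l = x.shape[1]
    cov = (x @ x.T) / l
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    eigvecs = eigvecs[:, order]
    k = min(n_components, len(eigvals))
    scores = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    return eigvals, scores


def eigendev(eigenvalues: np.ndarray, n_top: int | None = None) -> float:
    """RMS deviation of the top eigenvalues around their mean.

    ``n_top`` defaults to min(N-1, 100) where N is the spectrum length.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 2:
        raise ValueError("EigenDev requires at least 2 eigenvalues")
    p = min(ev.size - 1, 100) if n_top is None else min(n_top, ev.size)
    top = np.sort(ev)[::-1][:p]
    return float(np.sqrt(np.mean((top - top.mean()) ** 2)))


def calibrate_threshold(
    n: int,
    l: int,
    n_null_sims: int = 100,
    quantile: float = 0.99,
    seed: int = 0,
) -> float:
    """EigenDev quantile under homogeneous (structure-free) simulation.

    Simulates single-population genotype matrices of the given shape
    (ancestral frequencies uniform on (0.05, 0.5), HWE binomial calls)
    and returns the requested quantile of the null EigenDev sample.
    """
    if n_null_sims < 20:
        raise ValueError("need at least 20 null simulations")
    rng = np.random.default_rng(seed)
    devs = np.empty(n_null_sims)
    for i in range(n_null_sims):
        p = rng.uniform(0.05, 0.5, size=l)
        calls = rng.binomial(2, p, size=(n, l)).astype(np.int16)
        ev, _ = pca_spectrum(standardize(calls), n_components=1)
        devs[i] = eigendev(ev)
    return float(np.quantile(devs, quantile, method="higher"))


# ---------------------------------------------------------------------------
# fuzzy c-means bisection
# ---------------------------------------------------------------------------

def _kmeans_pp_init(points: np.ndarray, c: int, rng) -> np.ndarray:
    centers = [points[rng.integers(points.shape[0])]]
    for _ in range(c - 1):
        d2 = np.min(
            [np.sum((points - ctr) ** 2, axis=1) for ctr in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:
            centers.append(points[rng.integers(points.shape[0])])
            continue
        centers.append(points[rng.choice(points.shape[0], p=d2 / total)])
    return np.array(centers)


def fuzzy_cmeans_2(
    points: np.ndarray,
    seed: int,
    m: float = 2.0,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> np.ndarray:
    """Two-cluster fuzzy c-means; returns hard maximum-membership labels."""
    rng = np.random.default_rng(seed)
    centers = _kmeans_pp_init(points, 2, rng)
    u = np.full((points.shape[0], 2), 0.5)
    power = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        d2 = np.stack(
            [np.sum((points - ctr) ** 2, axis=1) for ctr in centers], axis=1
        )
        d2 = np.maximum(d2, 1e-300)
        inv = (1.0 / d2) ** (power / 2.0)
        new_u = inv / inv.sum(axis=1, keepdims=True)
        um = new_u**m
        centers = (um.T @ points) / um.sum(axis=0)[:, None]
        if np.max(np.abs(new_u - u)) < tol:
            u = new_u
            break
        u = new_u
    return np.argmax(u, axis=1)


def _kmeans_2(points: np.ndarray, seed: int, max_iter: int = 300) -> np.ndarray:
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, n_init=5, max_iter=max_iter, random_state=seed % (2**31))
    return km.fit_predict(points)


# ---------------------------------------------------------------------------
# the recursion
# ---------------------------------------------------------------------------

def _node_seed(seed: int, member_ids: list[str]) -> int:
    """Per-node RNG seed from the member-id set, not the recursion path,
    so identical member sets split identically regardless of how the
    recursion reached them."""
    digest = zlib.crc32("\x1f".join(sorted(member_ids)).encode())
    return (int(seed) ^ digest) % (2**31)


@dataclass
class IterativePruningPCA:
    """Unsupervised recursive bisection of individuals in PC space.

    Parameters
    ----------
    threshold
        EigenDev stopping criterion; nodes at or below it are declared
        homogeneous terminal subpopulations.
    min_subpop_size
        Children smaller than this become outlier terminal nodes.
    n_pcs
        Number of leading PC scores fed to the split engine.
    split_method
        "fcm" (fuzzy c-means, c=2, fuzzifier 2; the default) or "kmeans".
    """

    threshold: float = DEFAULT_EIGENDEV_THRESHOLD
    min_subpop_size: int = DEFAULT_MIN_SUBPOP_SIZE
    max_depth: int = DEFAULT_MAX_DEPTH
    n_pcs: int = 2
    split_method: str = "fcm"

    def fit(self, gm: GenotypeMatrix, seed: int = 0) -> ClusterTree:
        if gm.n_samples < 2:
            raise ValueError("need at least 2 samples")
        nodes: dict[str, ClusterNode] = {}
        assignment: dict[str, str] = {}
        outliers: list[str] = []
        subpop_counter = [0]
        row_of = {s: i for i, s in enumerate(gm.sample_ids)}

        def finish(node: ClusterNode, status: str) -> None:
            node.status = status
            if status == "terminal_subpop":
                subpop_counter[0] += 1
                node.subpop_label = f"SP{subpop_counter[0]}"
            else:
                outliers.extend(node.member_ids)
            for sid in node.member_ids:
                assignment[sid] = node.node_id

        def recurse(member_ids: list[str], node_id: str, depth: int) -> None:
            rows = np.array([row_of[s] for s in member_ids])
            calls = gm.calls[rows]
            try:
                ev, scores = pca_spectrum(
                    standardize(calls), n_components=max(self.n_pcs, 2)
                )
                dev = eigendev(ev)
            except ValueError:
                dev = 0.0
                scores = None
            node = ClusterNode(node_id, list(member_ids), dev, "internal")
            nodes[node_id] = node

            if dev <= self.threshold or scores is None:
                finish(node, "terminal_subpop")
                return
            if depth >= self.max_depth:
                log.warning(
                    "node %s reached max depth %d; forcing terminal",
                    node_id,
                    self.max_depth,
                )
                finish(node, "terminal_subpop")
                return
            if len(member_ids) < 2 * self.min_subpop_size:
                finish(node, "terminal_subpop")
                return

            pts = scores[:, : self.n_pcs]
            node_seed = _node_seed(seed, member_ids)
            if self.split_method == "kmeans":
                labels = _kmeans_2(pts, node_seed)
            else:
                labels = fuzzy_cmeans_2(pts, node_seed)
            left = [member_ids[i] for i in np.flatnonzero(labels == 0)]
            right = [member_ids[i] for i in np.flatnonzero(labels == 1)]
            if not left or not right:
                finish(node, "terminal_subpop")
                return

            small = [c for c in (left, right) if len(c) < self.min_subpop_size]
            if len(small) == 2:
                # a split yielding two sub-minimum children is no split
                finish(node, "terminal_subpop")
                return

            for child_ids, tag in ((left, "0"), (right, "1")):
                child_id = f"{node_id}.{tag}"
                node.children.append(child_id)
                if len(child_ids) < self.min_subpop_size:
                    child = ClusterNode(
                        child_id, list(child_ids), float("nan"), "terminal_outlier"
                    )
                    nodes[child_id] = child
                    finish(child, "terminal_outlier")
                else:
                    recurse(child_ids, child_id, depth + 1)

        recurse(list(gm.sample_ids), "N0", 0)
        return ClusterTree(
            nodes=nodes,
            root_id="N0",
            assignment=pd.Series(assignment, name="node_id").loc[gm.sample_ids],
            outlier_ids=outliers,
        )


def ippca(
    gm: GenotypeMatrix,
    threshold: float = DEFAULT_EIGENDEV_THRESHOLD,
    min_subpop_size: int = DEFAULT_MIN_SUBPOP_SIZE,
    max_depth: int = DEFAULT_MAX_DEPTH,
    seed: int = 0,
    n_pcs: int = 2,
    split_method: str = "fcm",
) -> ClusterTree:
    """Functional front-end to :class:`IterativePruningPCA`."""
    model = IterativePruningPCA(
        threshold=threshold,
        min_subpop_size=min_subpop_size,
        max_depth=max_depth,
        n_pcs=n_pcs,
        split_method=split_method,
    )
    return model.fit(gm, seed=seed)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def serialize_cluster_tree(tree: ClusterTree, sink, labels=None) -> None:
    """Dump the clustering decision tree as TSV.

    Optional ``labels`` (sample_id -> region label) add per-label member
    counts to each node row; labels are reporting-only and never affect
    the clustering itself.
    """
    label_series = pd.Series(dict(labels)) if labels is not None else None
    rows = []
    for node_id in sorted(tree.nodes):
        node = tree.nodes[node_id]
        counts = {}
        if label_series is not None:
            counts = (
                label_series.reindex(node.member_ids)
                .fillna("unlabelled")
                .value_counts()
                .to_dict()
            )
        rows.append(
            {
                "node_id": node.node_id,
                "eigendev": node.eigendev,
                "status": node.status,
                "n_members": node.size,
                "subpop_label": node.subpop_label or "",
                "children": ";".join(node.children),
                "label_counts": json.dumps(counts, sort_keys=True),
                "member_ids": ";".join(node.member_ids),
            }
        )
    df = pd.DataFrame(rows)
    if hasattr(sink, "write"):
        df.to_csv(sink, sep="\t", index=False, lineterminator="\n")
    else:
        df.to_csv(sink, sep="\t", index=False, lineterminator="\n")


def load_cluster_tree(source) -> ClusterTree:
    """Rebuild a :class:`ClusterTree` from :func:`serialize_cluster_tree` output."""
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    nodes: dict[str, ClusterNode] = {}
    assignment: dict[str, str] = {}
    outliers: list[str] = []
    for row in df.itertuples(index=False):
        members = row.member_ids.split(";") if row.member_ids else []
        node = ClusterNode(
            node_id=row.node_id,
            member_ids=members,
            eigendev=float(row.eigendev) if row.eigendev != "" else float("nan"),
            status=row.status,
            children=row.children.split(";") if row.children else [],
            subpop_label=row.subpop_label or None,
        )
        nodes[node.node_id] = node
        if node.status in ("terminal_subpop", "terminal_outlier"):
            for sid in members:
                assignment[sid] = node.node_id
            if node.status == "terminal_outlier":
                outliers.extend(members)
    root_id = min(nodes, key=len)
    return ClusterTree(
        nodes=nodes,
        root_id=root_id,
        assignment=pd.Series(assignment, name="node_id"),
        outlier_ids=outliers,
    )
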