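"""Weir-Cockerham Fst between assigned subpopulations.

Per locus, the diploid variance components of Weir & Cockerham's theta
estimator are computed from per-population sample sizes n_i, alt-allele
frequencies p_i and observed heterozygote frequencies h_i:

    a  — among-population variance,
    b  — among-individual-within-population variance,
    c  — within-individual variance (h-bar / 2),

and theta = a / (a + b + c).  Genome-wide theta aggregates ratio-of-sums
(sum of a over sum of a+b+c across defined loci), which is robust to
near-monomorphic loci; the estimator admits small negative values under
no differentiation.  Significance comes from permuting individuals
between the two groups and recomputing theta (one-sided: permuted theta
at least the observed), with the add-one estimator
p = (#{theta_perm >= theta_obs} + 1) / (B + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeDataError, GenotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 1023
STAR_P = 0.01
_PERM_CHUNK = 64


@dataclass
class FstPairResult:
    pop_pair: tuple[str, str]
    theta_genomewide: float
    p_value: float | None = None
    n_permutations: int = 0
    per_locus_theta: np.ndarray | None = None


@dataclass
class FstReport:
    labels: list[str]
    matrix: pd.DataFrame
    pairs: list[FstPairResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

def _wc_components_stats(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized WC84 components from stacked per-population statistics.

    Parameters are (r x L) arrays of sample sizes (individuals), alt
    frequencies and heterozygote frequencies.  Loci where any population
    has no data, or that are monomorphic pooled, yield nan components.
    """
    r = n.shape[0]
    valid = (n > 0).all(axis=0)
    n = n.astype(float)
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)

        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0

    poly = (pbar > 0) & (pbar < 1)
    defined = valid & poly & (nbar > 1) & (nc > 0)
    a = np.where(defined, a, np.nan)
    b = np.where(defined, b, np.nan)
    c = np.where(defined, c, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    theta = np.where(defined & (np.abs(a + b + c) > 0), theta, np.nan)
    return a, b, c, theta


def _group_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n, p, h) for one group's call matrix."""
    obs = calls != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / np.maximum(2.0 * n, 1.0)
    h = (calls == 1).sum(axis=0) / np.maximum(n, 1.0)
    return n, p, h


def wc_components_locus(calls_by_pop: list[np.ndarray]) -> tuple[float, float, float, float]:
    """WC84 components for a single marker given per-population call vectors.

    Returns (a, b, c, theta); theta is nan when the locus is undefined
    (monomorphic across the pooled populations or a population without
    data).
    """
    if len(calls_by_pop) < 2:
        raise ValueError("need at least two populations")
    stats = [
        _group_stats(np.asarray(c, dtype=np.int16).reshape(-1, 1))
        for c in calls_by_pop
    ]
    n = np.vstack([s[0] for s in stats])
    p = np.vstack([s[1] for s in stats])
    h = np.vstack([s[2] for s in stats])
    a, b, c, theta = _wc_components_stats(n, p, h)
    return float(a[0]), float(b[0]), float(c[0]), float(theta[0])


def per_locus_theta(
    gm: GenotypeMatrix, members_x: list[str], members_y: list[str]
) -> np.ndarray:
    """Per-marker theta between two member sets (nan where undefined)."""
    gx = gm.select_samples(members_x).calls
    gy = gm.select_samples(members_y).calls
    nx, px, hx = _group_stats(gx)
    ny, py, hy = _group_stats(gy)
    _, _, _, theta = _wc_components_stats(
        np.vstack([nx, ny]), np.vstack([px, py]), np.vstack([hx, hy])
    )
    return theta


def _genomewide_from_stats(n, p, h) -> float:
    a, b, c, _ = _wc_components_stats(n, p, h)
    defined = ~np.isnan(a)
    if not defined.any():
        raise GenotypeDataError("no defined loci for genome-wide theta")
    return float(a[defined].sum() / (a + b + c)[defined].sum())


def genomewide_fst(
    gm: GenotypeMatrix, members_x: list[str], members_y: list[str]
) -> float:
    """Ratio-of-sums genome-wide theta between two member sets."""
    if len(members_x) < 2 or len(members_y) < 2:
        raise GenotypeDataError("each member set needs at least 2 individuals")
    gx = gm.select_samples(members_x).calls
    gy = gm.select_samples(members_y).calls
    nx, px, hx = _group_stats(gx)
    ny, py, hy = _group_stats(gy)
    return _genomewide_from_stats(
        np.vstack([nx, ny]), np.vstack([px, py]), np.vstack([hx, hy])
    )


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    gm: GenotypeMatrix,
    members_x: list[str],
    members_y: list[str],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    return_null: bool = False,
):
    """One-sided permutation p-value for genome-wide theta.

    Individuals are pooled and re-split at random into groups of the
    original sizes; the smallest attainable p is 1/(B+1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if len(members_x) < 2 or len(members_y) < 2:
        raise GenotypeDataError("each member set needs at least 2 individuals")
    pooled = list(members_x) + list(members_y)
    sub = gm.select_samples(pooled)
    calls = sub.calls
    nx = len(members_x)
    n_all = len(pooled)

    # stack dosage, heterozygosity and observation indicators so that all
    # per-group counts of one permutation batch come from a single matmul
    obs = (calls != MISSING).astype(np.float64)
    dose = np.where(calls != MISSING, calls, 0).astype(np.float64)
    het = (calls == 1).astype(np.float64)
    data = np.hstack([dose, het, obs])  # n_all x 3L
    l = calls.shape[1]

    tot = data.sum(axis=0)

    def theta_for(rows_matrix: np.ndarray) -> np.ndarray:
        """rows_matrix: B x n_all 0/1 indicator of group-x membership."""
        gx = rows_matrix @ data  # B x 3L
        gy = tot[None, :] - gx
        out = np.empty(rows_matrix.shape[0])
        for bidx in range(rows_matrix.shape[0]):
            nxv = gx[bidx, 2 * l :]
            nyv = gy[bidx, 2 * l :]
            with np.errstate(invalid="ignore", divide="ignore"):
                pxv = gx[bidx, :l] / np.maximum(2 * nxv, 1.0)
                pyv = gy[bidx, :l] / np.maximum(2 * nyv, 1.0)
                hxv = gx[bidx, l : 2 * l] / np.maximum(nxv, 1.0)
                hyv = gy[bidx, l : 2 * l] / np.maximum(nyv, 1.0)
            out[bidx] = _genomewide_from_stats(
                np.vstack([nxv, nyv]), np.vstack([pxv, pyv]), np.vstack([hxv, hyv])
            )
        return out

    ind_obs = np.zeros((1, n_all))
    ind_obs[0, :nx] = 1.0
    theta_obs = theta_for(ind_obs)[0]

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        batch = min(_PERM_CHUNK, n_permutations - done)
        ind = np.zeros((batch, n_all))
        for bidx in range(batch):
            ind[bidx, rng.permutation(n_all)[:nx]] = 1.0
        null[done : done + batch] = theta_for(ind)
        done += batch

    p = (np.sum(null >= theta_obs) + 1.0) / (n_permutations + 1.0)
    if return_null:
        return float(p), theta_obs, null
    return float(p)


# ---------------------------------------------------------------------------
# pairwise matrix and ranking
# ---------------------------------------------------------------------------

def _members_by_subpop(assignment: pd.Series) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for sid, label in assignment.items():
        groups.setdefault(label, []).append(sid)
    return dict(sorted(groups.items()))


def pairwise_fst_matrix(
    gm: GenotypeMatrix,
    assignment: pd.Series,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> FstReport:
    """Genome-wide theta and permutation p for every subpopulation pair.

    Subpopulations with fewer than 2 members are excluded with a notice.
    Set ``n_permutations=0`` to skip significance testing.
    """
    groups = _members_by_subpop(assignment)
    for label in [l for l, mem in groups.items() if len(mem) < 2]:
        log.info("subpopulation %r has <2 members; excluded from Fst", label)
        del groups[label]
    labels = list(groups)
    if len(labels) < 2:
        raise GenotypeDataError("need at least two subpopulations of size >= 2")
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    pairs: list[FstPairResult] = []
    for idx, (x, y) in enumerate(combinations(labels, 2)):
        theta = genomewide_fst(gm, groups[x], groups[y])
        p = None
        if n_permutations > 0:
            p = permutation_test(
                gm,
                groups[x],
                groups[y],
                n_permutations=n_permutations,
                seed=(seed + 31 * idx) % (2**31),
            )
        mat.loc[x, y] = mat.loc[y, x] = theta
        pairs.append(
            FstPairResult(
                pop_pair=(x, y),
                theta_genomewide=theta,
                p_value=p,
                n_permutations=n_permutations,
                per_locus_theta=per_locus_theta(gm, groups[x], groups[y]),
            )
        )
    return FstReport(labels=labels, matrix=mat, pairs=pairs)


def render_pairwise_table(report: FstReport, star_p: float = STAR_P) -> pd.DataFrame:
    """Upper-triangle rendering with significance stars at p < star_p."""
    labels = report.labels
    cells = {(p.pop_pair[0], p.pop_pair[1]): p for p in report.pairs}
    out = pd.DataFrame("", index=labels, columns=labels, dtype=object)
    for x in labels:
        out.loc[x, x] = "0"
    for (x, y), pair in cells.items():
        star = (
            "*"
            if pair.p_value is not None and pair.p_value < star_p
            else ""
        )
        out.loc[x, y] = f"{pair.theta_genomewide:.4f}{star}"
    return out.reset_index(names="")


def rank_snps_by_fst(
    gm: GenotypeMatrix,
    assignment: pd.Series,
    top_n: int = 200,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-pair descending per-locus theta rankings with subpop MAFs.

    Dense ranks, ties broken by (chromosome, position); each table also
    reports minor-allele frequencies in every subpopulation.
    """
    groups = _members_by_subpop(assignment)
    groups = {l: m for l, m in groups.items() if len(m) >= 2}
    labels = list(groups)
    if len(labels) < 2:
        raise GenotypeDataError("need at least two subpopulations of size >= 2")

    mafs = {}
    for label, members in groups.items():
        sub = gm.select_samples(members)
        mafs[label] = sub.minor_allele_frequency()
    pos_of = {rs: j for j, rs in enumerate(gm.rs_ids)}

    out: dict[tuple[str, str], pd.DataFrame] = {}
    for x, y in combinations(labels, 2):
        theta = per_locus_theta(gm, groups[x], groups[y])
        defined = ~np.isnan(theta)
        if top_n > defined.sum():
            log.info(
                "top_n=%d exceeds %d defined loci for pair (%s,%s); truncating",
                top_n,
                defined.sum(),
                x,
                y,
            )
        df = pd.DataFrame(
            {
                "rs_id": gm.rs_ids,
                "chrom": gm.markers["chrom"],
                "pos": gm.markers["pos"],
                "theta": theta,
            }
        )[defined]
        df = df.sort_values(
            by=["theta", "chrom", "pos"], ascending=[False, True, True]
        ).reset_index(drop=True)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        df = df.head(top_n).reset_index(drop=True)
        cols = np.array([pos_of[r] for r in df["rs_id"]], dtype=np.intp)
        for label in labels:
            df[f"maf_{label}"] = mafs[label][cols]
        out[(x, y)] = df
    return out
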