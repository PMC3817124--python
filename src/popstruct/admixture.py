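"""Maximum-likelihood ancestry estimation under the unlinked admixture model.

Each individual i carries ancestry proportions q_i on the K-simplex and
each ancestral population k has allele frequencies f_kl; a genotype at
locus l is Binomial(2, pi_il) with pi_il = sum_k q_ik f_kl, independent
across loci.  The log-likelihood is maximized by plain EM on the expected
allele-origin counts, which yields closed-form Q and F updates and a
monotone likelihood trace.  Missing calls are excluded from the
likelihood, not imputed.

The label of an ancestral component is arbitrary (the likelihood is
invariant to permuting components); :func:`align_components` matches a
result against a reference for plotting or truth comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

_EPS = 1e-6


@dataclass
class AdmixtureResults:
    """Fitted ancestry proportions and ancestral frequencies."""

    K: int
    Q: np.ndarray  # N x K, rows on the simplex
    F: np.ndarray  # K x L, clamped to [eps, 1-eps]
    loglik_trace: list[float]
    converged: bool
    seed: int
    sample_ids: list[str] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Q,
            index=self.sample_ids or range(self.Q.shape[0]),
            columns=[f"K{k + 1}" for k in range(self.K)],
        )

    def summary(self) -> str:
        lines = [
            f"Admixture model (K={self.K})",
            f"  individuals:     {self.Q.shape[0]}",
            f"  loci:            {self.F.shape[1]}",
            f"  log-likelihood:  {self.loglik:.4f}",
            f"  EM iterations:   {len(self.loglik_trace)}",
            f"  converged:       {self.converged}",
            "  mean ancestry proportions:",
        ]
        for k, v in enumerate(self.Q.mean(axis=0)):
            lines.append(f"    K{k + 1}: {v:.4f}")
        return "\n".join(lines)


def _masked_calls(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    g = gm.calls.astype(float)
    mask = gm.calls != MISSING
    g[~mask] = 0.0
    return g, mask.astype(float)


def loglikelihood(gm: GenotypeMatrix, Q: np.ndarray, F: np.ndarray) -> float:
    """Binomial admixture log-likelihood; missing calls contribute zero."""
    g, mask = _masked_calls(gm)
    pi = np.clip(Q @ F, _EPS, 1.0 - _EPS)
    ll = mask * (g * np.log(pi) + (2.0 - g) * np.log(1.0 - pi))
    return float(ll.sum())


class AdmixtureModel:
    """EM estimator of Q and F for a fixed number of ancestral populations.

    Parameters
    ----------
    gm
        Genotype matrix; missing calls are allowed.
    K
        Number of assumed ancestral populations (>= 1).
    """

    def __init__(self, gm: GenotypeMatrix, K: int):
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > gm.n_samples:
            raise ValueError("K cannot exceed the number of individuals")
        if K > gm.n_markers:
            raise ValueError("K cannot exceed the number of markers")
        self.gm = gm
        self.K = K

    # -- single EM run ----------------------------------------------------
    def _run_em(
        self, rng, max_iter: int, tol: float
    ) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
        g, mask = _masked_calls(self.gm)
        n, l = g.shape
        k = self.K
        n_calls = mask.sum(axis=1, keepdims=True)  # non-missing per individual

        if k == 1:
            f = (g * mask).sum(axis=0) / np.maximum(2.0 * mask.sum(axis=0), 1.0)
            F = np.clip(f[None, :], _EPS, 1.0 - _EPS)
            Q = np.ones((n, 1))
            ll = loglikelihood(self.gm, Q, F)
            return Q, F, [ll], True

        Q = rng.dirichlet(np.ones(k), size=n)
        global_f = (g * mask).sum(axis=0) / np.maximum(2.0 * mask.sum(axis=0), 1.0)
        F = np.clip(
            global_f[None, :] + rng.normal(0.0, 0.05, size=(k, l)), _EPS, 1.0 - _EPS
        )

        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            pi = np.clip(Q @ F, _EPS, 1.0 - _EPS)
            ll = float(
                (mask * (g * np.log(pi) + (2.0 - g) * np.log(1.0 - pi))).sum()
            )
            if trace and ll - trace[-1] < tol * (1.0 + abs(trace[-1])):
                trace.append(ll)
                converged = True
                break
            trace.append(ll)

            ratio_alt = mask * g / pi
            ratio_ref = mask * (2.0 - g) / (1.0 - pi)
            new_Q = np.empty_like(Q)
            new_F = np.empty_like(F)
            for kk in range(k):
                a_k = ratio_alt * (Q[:, kk : kk + 1] * F[kk][None, :])
                b_k = ratio_ref * (Q[:, kk : kk + 1] * (1.0 - F[kk])[None, :])
                new_Q[:, kk] = (a_k + b_k).sum(axis=1)
                denom = (a_k + b_k).sum(axis=0)
                new_F[kk] = np.where(denom > 0, a_k.sum(axis=0) / np.maximum(denom, 1e-300), F[kk])
            Q = new_Q / np.maximum(2.0 * n_calls, 1e-300)
            Q = Q / Q.sum(axis=1, keepdims=True)
            F = np.clip(new_F, _EPS, 1.0 - _EPS)
        return Q, F, trace, converged

    def fit(
        self,
        seed: int = 0,
        n_restarts: int = 3,
        max_iter: int = 2000,
        tol: float = 1e-6,
    ) -> AdmixtureResults:
        """Best-of-restarts EM fit."""
        best: AdmixtureResults | None = None
        for restart in range(max(n_restarts, 1)):
            rng = np.random.default_rng((seed + 7919 * restart) % (2**31))
            Q, F, trace, converged = self._run_em(rng, max_iter, tol)
            res = AdmixtureResults(
                K=self.K,
                Q=Q,
                F=F,
                loglik_trace=trace,
                converged=converged,
                seed=seed,
                sample_ids=self.gm.sample_ids,
            )
            if best is None or res.loglik > best.loglik:
                best = res
        log.info(
            "admixture K=%d: loglik %.2f after %d iterations (converged=%s)",
            self.K,
            best.loglik,
            len(best.loglik_trace),
            best.converged,
        )
        return best


def fit_admixture(
    gm: GenotypeMatrix,
    K: int,
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 3,
    seed: int = 0,
) -> AdmixtureResults:
    return AdmixtureModel(gm, K).fit(
        seed=seed, n_restarts=n_restarts, max_iter=max_iter, tol=tol
    )


def sweep_k(
    gm: GenotypeMatrix,
    k_min: int = 2,
    k_max: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 3,
    seed: int = 0,
) -> list[AdmixtureResults]:
    """Independent fits for K = k_min..k_max with derived per-K seeds."""
    if k_min > k_max:
        raise ValueError("k_min must not exceed k_max")
    results = []
    for k in range(k_min, k_max + 1):
        results.append(
            fit_admixture(
                gm,
                k,
                max_iter=max_iter,
                tol=tol,
                n_restarts=n_restarts,
                seed=(seed + 104729 * k) % (2**31),
            )
        )
    return results


def align_components(
    result: AdmixtureResults, reference_q: np.ndarray
) -> AdmixtureResults:
    """Permute components to best match a reference Q (label switching).

    Greedy one-to-one matching maximizing the correlation between the
    result's and the reference's ancestry columns; the permutation is
    applied consistently to Q and F and cannot change the likelihood.
    """
    reference_q = np.asarray(reference_q, dtype=float)
    if reference_q.shape[1] != result.K:
        raise ValueError("reference has a different number of components")
    k = result.K
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            a, b = result.Q[:, i], reference_q[:, j]
            sa, sb = a.std(), b.std()
            corr[i, j] = (
                ((a - a.mean()) * (b - b.mean())).mean() / (sa * sb)
                if sa > 0 and sb > 0
                else -np.inf
            )
    perm = [-1] * k
    used_rows, used_cols = set(), set()
    for _ in range(k):
        best = None
        for i in range(k):
            if i in used_rows:
                continue
            for j in range(k):
                if j in used_cols:
                    continue
                if best is None or corr[i, j] > corr[best]:
                    best = (i, j)
        i, j = best
        perm[j] = i
        used_rows.add(i)
        used_cols.add(j)
    return AdmixtureResults(
        K=k,
        Q=result.Q[:, perm],
        F=result.F[perm, :],
        loglik_trace=list(result.loglik_trace),
        converged=result.converged,
        seed=result.seed,
        sample_ids=list(result.sample_ids),
    )


def summarize_by_group(result: AdmixtureResults, grouping) -> pd.DataFrame:
    """Five-number summary of ancestry proportions per group and component."""
    labels = pd.Series(dict(grouping)) if not isinstance(grouping, pd.Series) else grouping
    qf = result.q_frame()
    rows = []
    for group in sorted(labels.dropna().unique()):
        members = labels.index[labels == group]
        members = [m for m in members if m in qf.index]
        if not members:
            log.info("group %r empty after matching samples; skipped", group)
            continue
        sub = qf.loc[members]
        for comp in qf.columns:
            v = sub[comp].to_numpy()
            rows.append(
                {
                    "group": group,
                    "component": comp,
                    "min": float(np.min(v)),
                    "q1": float(np.percentile(v, 25)),
                    "median": float(np.median(v)),
                    "q3": float(np.percentile(v, 75)),
                    "max": float(np.max(v)),
                }
            )
    return pd.DataFrame(rows)
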