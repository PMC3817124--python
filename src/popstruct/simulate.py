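"""Synthetic genotype datasets with known population structure.

Subpopulation allele frequencies follow the Balding-Nichols model: around
an ancestral frequency ``p`` each subpopulation drifts independently,

    p_k ~ Beta(p (1-F)/F, (1-p)(1-F)/F),

so that E[p_k] = p and Var[p_k] = F p (1-p).  Genotypes are then binomial
draws, Binomial(2, p_k), independent across individuals and loci (no LD).
The generator also produces admixed individuals (Dirichlet ancestry
vectors), a small set of strongly divergent "planted" loci, unassignable
outlier individuals drawn from private heavily-drifted frequency vectors,
two-platform marker splits with strand flips and strand-ambiguous SNPs,
and missing calls — everything a downstream structure analysis has to
cope with, with the ground truth recorded for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (
    MISSING,
    GenotypeMatrix,
    complement_pair,
    concat_samples,
    make_marker_table,
    make_sample_table,
)

#: Non-ambiguous allele pairs assigned to simulated markers.
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]

#: Post-draw clamp keeping Binomial loci non-degenerate.
_FREQ_CLAMP = (0.001, 0.999)


class ConfigError(ValueError):
    """A SimulationConfig field is invalid; the message names the field."""


@dataclass
class SimulationConfig:
    """Parameters of a synthetic structured-population dataset.

    Defaults describe a four-subpopulation cohort of 1000 individuals at
    20,000 unlinked loci with drift strong enough (F = 0.05) for the
    structure to be recoverable at this marker count; real SNP-array
    studies resolve far weaker differentiation by using an order of
    magnitude more markers.
    """

    n_subpops: int = 4
    n_per_subpop: list[int] | int = 250
    n_loci: int = 20_000
    drift_f: list[float] | float = 0.05
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    admixture_alpha: tuple[float, ...] | None = None
    n_outliers: int = 0
    outlier_drift: float = 0.3
    n_planted_loci: int = 0
    planted_delta: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def sizes(self) -> list[int]:
        if isinstance(self.n_per_subpop, int):
            return [self.n_per_subpop] * self.n_subpops
        return list(self.n_per_subpop)

    def drifts(self) -> list[float]:
        if isinstance(self.drift_f, (int, float)):
            return [float(self.drift_f)] * self.n_subpops
        return [float(f) for f in self.drift_f]

    def validate(self) -> None:
        if self.n_subpops < 1:
            raise ConfigError("n_subpops: must be >= 1")
        if self.n_loci < 1:
            raise ConfigError("n_loci: must be >= 1")
        sizes = self.sizes()
        if len(sizes) != self.n_subpops or any(s < 0 for s in sizes):
            raise ConfigError("n_per_subpop: need n_subpops non-negative counts")
        drifts = self.drifts()
        if len(drifts) != self.n_subpops or any(
            not (0.0 <= f < 1.0) for f in drifts
        ):
            raise ConfigError("drift_f: need values in [0, 1) per subpopulation")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("ancestral_maf_range: must lie within (0, 0.5]")
        if self.admixture_alpha is not None:
            if len(self.admixture_alpha) != self.n_subpops:
                raise ConfigError("admixture_alpha: length must equal n_subpops")
            if any(a <= 0 for a in self.admixture_alpha):
                raise ConfigError("admixture_alpha: entries must be positive")
        if self.n_outliers < 0:
            raise ConfigError("n_outliers: must be >= 0")
        if not (0.0 <= self.outlier_drift < 1.0):
            raise ConfigError("outlier_drift: must lie in [0, 1)")
        if self.n_planted_loci < 0:
            raise ConfigError("n_planted_loci: must be >= 0")
        if self.n_planted_loci > self.n_loci:
            raise ConfigError("n_planted_loci: cannot exceed n_loci")
        if not (0.0 < self.planted_delta < 1.0) and self.n_planted_loci > 0:
            raise ConfigError("planted_delta: must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate: must lie in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset.

    ``membership`` and ``true_q`` cover assigned (non-outlier) samples
    only; ``outlier_ids`` is disjoint from the membership keys.
    """

    membership: pd.Series  # sample_id -> subpop label
    true_q: pd.DataFrame  # assigned samples x K, rows sum to 1
    true_freqs: np.ndarray  # K x L subpopulation alt-allele frequencies
    ancestral_freqs: np.ndarray  # L ancestral frequencies
    planted_loci: list[str] = field(default_factory=list)
    outlier_ids: list[str] = field(default_factory=list)
    parametric_fst: pd.DataFrame | None = None

    @property
    def n_subpops(self) -> int:
        return self.true_freqs.shape[0]

    def subpop_labels(self) -> list[str]:
        return [f"SP{k + 1}" for k in range(self.n_subpops)]


def parametric_fst(true_freqs: np.ndarray, labels=None) -> pd.DataFrame:
    """Pairwise Fst implied by known subpopulation allele frequencies.

    For a pair with per-locus frequencies p1, p2 the locus contributes
    numerator (p1-p2)^2/2 and denominator pbar(1-pbar) + (p1-p2)^2/4,
    the large-sample limit of the Weir-Cockerham variance components
    under within-population Hardy-Weinberg proportions; loci are combined
    ratio-of-sums.
    """
    k = true_freqs.shape[0]
    labels = labels or [f"SP{i + 1}" for i in range(k)]
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p1, p2 = true_freqs[i], true_freqs[j]
            pbar = (p1 + p2) / 2.0
            num = (p1 - p2) ** 2 / 2.0
            den = pbar * (1.0 - pbar) + (p1 - p2) ** 2 / 4.0
            valid = den > 0
            theta = num[valid].sum() / den[valid].sum() if valid.any() else 0.0
            out[i, j] = out[j, i] = theta
    return pd.DataFrame(out, index=labels, columns=labels)


def _draw_subpop_freqs(p_anc: np.ndarray, drifts, rng) -> np.ndarray:
    freqs = np.empty((len(drifts), p_anc.size))
    for k, f in enumerate(drifts):
        if f == 0.0:
            freqs[k] = p_anc
        else:
            a = p_anc * (1.0 - f) / f
            b = (1.0 - p_anc) * (1.0 - f) / f
            freqs[k] = np.clip(rng.beta(a, b), *_FREQ_CLAMP)
    return freqs


def _marker_table(n_loci: int, rng) -> pd.DataFrame:
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_loci)
    swap = rng.integers(0, 2, size=n_loci).astype(bool)
    refs, alts = [], []
    for i in range(n_loci):
        ref, alt = _ALLELE_PAIRS[pair_idx[i]]
        if swap[i]:
            ref, alt = alt, ref
        refs.append(ref)
        alts.append(alt)
    return make_marker_table(
        [f"rs{i + 1:06d}" for i in range(n_loci)],
        chrom=["1"] * n_loci,
        pos=np.arange(1, n_loci + 1) * 1000,
        allele_ref=refs,
        allele_alt=alts,
    )


def _apply_missing(calls: np.ndarray, rate: float, rng) -> None:
    if rate > 0.0:
        calls[rng.random(calls.shape) < rate] = MISSING


def simulate_subpopulations(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate K discrete subpopulations under Balding-Nichols drift."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes, drifts = config.sizes(), config.drifts()
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=config.n_loci)
    freqs = _draw_subpop_freqs(p_anc, drifts, rng)

    n_total = sum(sizes)
    calls = np.empty((n_total, config.n_loci), dtype=np.int16)
    membership, row = [], 0
    for k, size in enumerate(sizes):
        calls[row : row + size] = rng.binomial(
            2, freqs[k], size=(size, config.n_loci)
        )
        membership += [f"SP{k + 1}"] * size
        row += size
    _apply_missing(calls, config.missing_rate, rng)

    sample_ids = [f"S{i + 1:05d}" for i in range(n_total)]
    gm = GenotypeMatrix(
        calls, _marker_table(config.n_loci, rng), make_sample_table(sample_ids)
    )
    q = np.zeros((n_total, config.n_subpops))
    codes = pd.Series(membership).str.removeprefix("SP").astype(int) - 1
    q[np.arange(n_total), codes] = 1.0
    truth = TruthRecord(
        membership=pd.Series(membership, index=sample_ids, name="subpop"),
        true_q=pd.DataFrame(
            q, index=sample_ids, columns=[f"SP{k + 1}" for k in range(config.n_subpops)]
        ),
        true_freqs=freqs,
        ancestral_freqs=p_anc,
        parametric_fst=parametric_fst(freqs),
    )
    return gm, truth


def simulate_admixed(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate individuals with Dirichlet-distributed ancestry mixtures.

    Each individual draws q ~ Dirichlet(alpha) over the K drifted
    subpopulations and genotypes Binomial(2, q . p_l) per locus.  The
    ``membership`` label records the majority ancestry component.
    """
    config.validate()
    if config.admixture_alpha is None:
        raise ConfigError("admixture_alpha: required for admixed simulation")
    rng = np.random.default_rng(config.seed)
    sizes, drifts = config.sizes(), config.drifts()
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=config.n_loci)
    freqs = _draw_subpop_freqs(p_anc, drifts, rng)

    n_total = sum(sizes)
    if config.n_subpops == 1:
        q = np.ones((n_total, 1))
    else:
        q = rng.dirichlet(config.admixture_alpha, size=n_total)
    pi = q @ freqs
    calls = rng.binomial(2, pi).astype(np.int16)
    _apply_missing(calls, config.missing_rate, rng)

    sample_ids = [f"S{i + 1:05d}" for i in range(n_total)]
    gm = GenotypeMatrix(
        calls, _marker_table(config.n_loci, rng), make_sample_table(sample_ids)
    )
    labels = [f"SP{k + 1}" for k in np.argmax(q, axis=1)]
    truth = TruthRecord(
        membership=pd.Series(labels, index=sample_ids, name="subpop"),
        true_q=pd.DataFrame(
            q, index=sample_ids, columns=[f"SP{k + 1}" for k in range(config.n_subpops)]
        ),
        true_freqs=freqs,
        ancestral_freqs=p_anc,
        parametric_fst=parametric_fst(freqs),
    )
    return gm, truth


def plant_divergent_loci(
    gm: GenotypeMatrix,
    truth: TruthRecord,
    n_loci: int,
    delta: float,
    seed: int,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Shift one subpopulation's frequency by +delta at ``n_loci`` markers.

    Emulates strongly divergent SNPs (one subpopulation carrying a much
    higher minor-allele frequency than the rest); the affected genotype
    columns are re-drawn and the marker ids recorded as planted.
    """
    if n_loci == 0:
        return gm, truth
    if delta <= 0:
        raise ConfigError("planted_delta: must be > 0")
    if n_loci > gm.n_markers:
        raise ConfigError("n_planted_loci: cannot exceed n_loci")
    rng = np.random.default_rng(seed)
    gm = gm.copy()
    freqs = truth.true_freqs.copy()
    k_total = freqs.shape[0]

    loci = np.sort(rng.choice(gm.n_markers, size=n_loci, replace=False))
    targets = rng.integers(0, k_total, size=n_loci)
    assigned = truth.true_q.index
    row_of = {s: i for i, s in enumerate(gm.sample_ids)}
    rows = np.array([row_of[s] for s in assigned])
    qmat = truth.true_q.to_numpy()

    for locus, k in zip(loci, targets):
        freqs[k, locus] = np.clip(freqs[k, locus] + delta, 0.01, 0.99)
        pi = qmat @ freqs[:, locus]
        col = gm.calls[:, locus]
        new = rng.binomial(2, pi).astype(np.int16)
        keep_missing = col[rows] == MISSING
        new[keep_missing] = MISSING
        col[rows] = new

    planted = [gm.rs_ids[int(l)] for l in loci]
    truth = replace(
        truth,
        true_freqs=freqs,
        planted_loci=sorted(set(truth.planted_loci) | set(planted)),
        parametric_fst=parametric_fst(freqs),
    )
    return gm, truth


def inject_outliers(
    gm: GenotypeMatrix,
    truth: TruthRecord,
    n_outliers: int,
    outlier_drift: float,
    seed: int,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Append individuals drawn from a private, strongly drifted population.

    All outliers share one Balding-Nichols frequency vector drawn around
    the ancestral frequencies at drift ``outlier_drift`` — a small,
    genetically distinct group (e.g. recent ancestry from elsewhere)
    that belongs to none of the K subpopulations and is far too small to
    count as a subpopulation itself.
    """
    if n_outliers == 0:
        return gm, truth
    if not (0.0 <= outlier_drift < 1.0):
        raise ConfigError("outlier_drift: must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    p_priv = _draw_subpop_freqs(truth.ancestral_freqs, [outlier_drift], rng)[0]
    calls = rng.binomial(
        2, p_priv, size=(n_outliers, gm.n_markers)
    ).astype(np.int16)
    ids = [f"OUT{i + 1:03d}" for i in range(n_outliers)]
    extra = GenotypeMatrix(calls, gm.markers.copy(), make_sample_table(ids))
    merged = concat_samples(gm, extra)
    truth = replace(truth, outlier_ids=list(truth.outlier_ids) + ids)
    return merged, truth


def split_platforms(
    gm: GenotypeMatrix,
    overlap_fraction: float,
    flip_fraction: float,
    ambiguous_fraction: float,
    per_cohort_missing: float,
    seed: int,
) -> tuple[GenotypeMatrix, GenotypeMatrix, GenotypeMatrix]:
    """Split one dataset into two platform cohorts plus the expected merge.

    Samples are split at random into cohorts A and B; the cohorts share
    ``overlap_fraction`` of the markers by rs-id and receive the remaining
    markers as platform-private.  A ``flip_fraction`` of shared markers
    has cohort A's allele pair strand-complemented (dosages are allele
    counts and survive the relabeling); an ``ambiguous_fraction`` is
    rewritten to A/T or C/G pairs, which a harmonizer must drop.  The
    returned ``expected_merged`` is the ground-truth harmonized
    intersection (cohort B's allele frame, ambiguous markers excluded).
    """
    for name, val in (
        ("overlap_fraction", overlap_fraction),
        ("flip_fraction", flip_fraction),
        ("ambiguous_fraction", ambiguous_fraction),
        ("per_cohort_missing", per_cohort_missing),
    ):
        if not (0.0 <= val <= 1.0):
            raise ConfigError(f"{name}: must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n, l = gm.n_samples, gm.n_markers

    sample_perm = rng.permutation(n)
    a_rows = np.sort(sample_perm[: n // 2])
    b_rows = np.sort(sample_perm[n // 2 :])

    marker_perm = rng.permutation(l)
    n_shared = int(round(overlap_fraction * l))
    shared = np.sort(marker_perm[:n_shared])
    leftovers = marker_perm[n_shared:]
    priv_a = np.sort(leftovers[: len(leftovers) // 2])
    priv_b = np.sort(leftovers[len(leftovers) // 2 :])

    n_amb = int(round(ambiguous_fraction * n_shared))
    amb_set = set(rng.choice(shared, size=n_amb, replace=False)) if n_amb else set()
    flippable = np.array([m for m in shared if m not in amb_set], dtype=np.intp)
    n_flip = min(int(round(flip_fraction * n_shared)), flippable.size)
    flip_set = (
        set(rng.choice(flippable, size=n_flip, replace=False)) if n_flip else set()
    )

    def build(rows, own_markers, flip: bool, cohort: str) -> GenotypeMatrix:
        idx = np.sort(np.concatenate([shared, own_markers]).astype(np.intp))
        sub = gm.take_samples(rows).take_markers(idx)
        sub.samples["cohort"] = cohort
        markers = sub.markers
        for j, m in enumerate(idx):
            if m in amb_set:
                ref, alt = markers.at[j, "allele_ref"], markers.at[j, "allele_alt"]
                # rewrite to a self-complementary pair, keeping orientation
                pair = ("A", "T") if {ref, alt} & {"A", "G"} else ("C", "G")
                markers.loc[j, ["allele_ref", "allele_alt"]] = pair
            elif flip and m in flip_set:
                ref, alt = markers.at[j, "allele_ref"], markers.at[j, "allele_alt"]
                markers.loc[j, ["allele_ref", "allele_alt"]] = complement_pair(
                    ref, alt
                )
        _apply_missing(sub.calls, per_cohort_missing, rng)
        return sub

    cohort_a = build(a_rows, priv_a, flip=True, cohort="A")
    cohort_b = build(b_rows, priv_b, flip=False, cohort="B")

    kept_shared = np.array([m for m in shared if m not in amb_set], dtype=np.intp)
    b_pos = {m: j for j, m in enumerate(
        np.sort(np.concatenate([shared, priv_b]).astype(np.intp))
    )}
    a_pos = {m: j for j, m in enumerate(
        np.sort(np.concatenate([shared, priv_a]).astype(np.intp))
    )}
    exp_calls = np.vstack(
        [
            cohort_a.calls[:, [a_pos[m] for m in kept_shared]],
            cohort_b.calls[:, [b_pos[m] for m in kept_shared]],
        ]
    )
    exp_markers = cohort_b.markers.iloc[[b_pos[m] for m in kept_shared]].reset_index(
        drop=True
    )
    exp_samples = pd.concat(
        [cohort_a.samples, cohort_b.samples], ignore_index=True
    )
    expected = GenotypeMatrix(exp_calls, exp_markers, exp_samples)
    return cohort_a, cohort_b, expected


def write_truth_tsv(truth: TruthRecord, sink) -> None:
    """Write per-sample ground truth (subpopulation, q-vector, outlier flag)."""
    rows = []
    qcols = list(truth.true_q.columns)
    for sid in truth.membership.index:
        rows.append(
            {
                "sample_id": sid,
                "subpop": truth.membership[sid],
                **{f"q_{c}": truth.true_q.at[sid, c] for c in qcols},
                "outlier": 0,
            }
        )
    for sid in truth.outlier_ids:
        rows.append(
            {
                "sample_id": sid,
                "subpop": "NA",
                **{f"q_{c}": np.nan for c in qcols},
                "outlier": 1,
            }
        )
    from .io import write_table_tsv

    write_table_tsv(pd.DataFrame(rows), sink)


def write_planted_tsv(truth: TruthRecord, sink) -> None:
    from .io import write_table_tsv

    write_table_tsv(pd.DataFrame({"rs_id": truth.planted_loci}), sink)
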