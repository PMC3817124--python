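"""Cross-platform cohort merging and marker quality control.

Merging two SNP-array cohorts keyed on rs-id must reconcile strand: when
one platform reports the complementary strand (A/G versus T/C) the allele
pair is complemented into the other cohort's frame — dosages are allele
counts and survive the relabeling.  Strand-ambiguous SNPs (A/T, C/G) are
excluded outright because complementing maps their pair onto itself.
Marker QC applies a Hardy-Weinberg exact test, a per-marker missingness
cap and sliding-window LD pruning; a per-marker chi-squared test on
allele counts screens for systematic frequency bias between cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .data import (
    MISSING,
    GenotypeDataError,
    GenotypeMatrix,
    complement_pair,
    is_ambiguous_pair,
)

log = logging.getLogger(__name__)


@dataclass
class HarmonizationReport:
    n_shared: int = 0
    n_complemented: int = 0
    n_ambiguous_excluded: int = 0
    n_allele_mismatch_excluded: int = 0
    n_merged: int = 0
    maf_correlation: float | None = None
    maf_table: pd.DataFrame | None = None


@dataclass
class QCReport:
    n_input: int = 0
    n_fail_hwe: int = 0
    n_fail_missing: int = 0
    n_pruned_ld: int = 0
    n_pass: int = 0
    thresholds: dict = field(default_factory=dict)


def intersect_and_harmonize(
    cohort_a: GenotypeMatrix, cohort_b: GenotypeMatrix
) -> tuple[GenotypeMatrix, HarmonizationReport]:
    """Merge two cohorts over their shared rs-ids in cohort B's allele frame.

    Cohort A is the one complemented/recoded into cohort B's frame.  A
    shared marker survives when its allele pair equals cohort B's, either
    directly or after strand complement; if the surviving orientation has
    reference and alternate swapped relative to cohort B, cohort A's
    dosages are recoded ``g -> 2 - g``.  A/T and C/G markers in either
    cohort are excluded as strand-ambiguous; remaining disagreements are
    excluded as allele mismatches.
    """
    if cohort_a.n_samples == 0 or cohort_b.n_samples == 0:
        raise GenotypeDataError("both cohorts must contain samples")
    a_idx = {r: i for i, r in enumerate(cohort_a.rs_ids)}
    report = HarmonizationReport()
    keep_b_pos: list[int] = []
    keep_a_pos: list[int] = []
    recode_a: list[bool] = []

    b_mark = cohort_b.markers
    a_mark = cohort_a.markers
    for jb, rs in enumerate(cohort_b.rs_ids):
        ja = a_idx.get(rs)
        if ja is None:
            continue
        report.n_shared += 1
        aref, aalt = a_mark.at[ja, "allele_ref"], a_mark.at[ja, "allele_alt"]
        bref, balt = b_mark.at[jb, "allele_ref"], b_mark.at[jb, "allele_alt"]
        if is_ambiguous_pair(aref, aalt) or is_ambiguous_pair(bref, balt):
            report.n_ambiguous_excluded += 1
            continue
        if {aref, aalt} == {bref, balt}:
            flip = False
        else:
            caref, caalt = complement_pair(aref, aalt)
            if {caref, caalt} == {bref, balt}:
                flip = True
                aref, aalt = caref, caalt
            else:
                report.n_allele_mismatch_excluded += 1
                continue
        if flip:
            report.n_complemented += 1
        keep_b_pos.append(jb)
        keep_a_pos.append(ja)
        # same unordered pair; recode dosages if A's alternate is B's reference
        recode_a.append(aalt != balt)

    if not keep_b_pos:
        raise GenotypeDataError("no markers shared between the cohorts")
    report.n_merged = len(keep_b_pos)

    a_calls = cohort_a.calls[:, keep_a_pos].copy()
    recode = np.asarray(recode_a)
    if recode.any():
        cols = a_calls[:, recode]
        obs = cols != MISSING
        cols[obs] = 2 - cols[obs]
        a_calls[:, recode] = cols
    b_calls = cohort_b.calls[:, keep_b_pos]

    samples_a = cohort_a.samples.copy()
    samples_b = cohort_b.samples.copy()
    if samples_a["cohort"].isna().all():
        samples_a["cohort"] = "A"
    if samples_b["cohort"].isna().all():
        samples_b["cohort"] = "B"

    merged = GenotypeMatrix(
        np.vstack([a_calls, b_calls]),
        cohort_b.markers.iloc[keep_b_pos].reset_index(drop=True),
        pd.concat([samples_a, samples_b], ignore_index=True),
    )
    log.info(
        "harmonized: %d shared, %d merged, %d complemented, %d ambiguous, "
        "%d mismatched",
        report.n_shared,
        report.n_merged,
        report.n_complemented,
        report.n_ambiguous_excluded,
        report.n_allele_mismatch_excluded,
    )
    return merged, report


def maf_concordance(
    merged: GenotypeMatrix, cohort_labels: tuple[str, str] | None = None
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of per-cohort minor-allele frequencies.

    A high correlation indicates the platforms call the shared markers
    consistently; strand errors surface as a cloud around MAF = 0.5.
    """
    cohorts = merged.samples["cohort"]
    if cohort_labels is None:
        uniq = sorted(c for c in cohorts.dropna().unique())
        if len(uniq) != 2:
            raise GenotypeDataError(
                f"expected exactly two cohort labels, found {uniq}"
            )
        cohort_labels = (uniq[0], uniq[1])
    if merged.n_markers < 2:
        raise GenotypeDataError("MAF concordance undefined for fewer than 2 markers")
    mafs = []
    for label in cohort_labels:
        rows = (cohorts == label).to_numpy()
        if rows.sum() == 0:
            raise GenotypeDataError(f"cohort {label!r} has no samples")
        mafs.append(merged.take_samples(rows).minor_allele_frequency())
    maf_a, maf_b = mafs
    valid = ~(np.isnan(maf_a) | np.isnan(maf_b))
    if valid.sum() < 2:
        raise GenotypeDataError("fewer than 2 markers with defined MAF in both cohorts")
    r = float(np.corrcoef(maf_a[valid], maf_b[valid])[0, 1])
    table = pd.DataFrame(
        {
            "rs_id": merged.rs_ids,
            f"maf_{cohort_labels[0]}": maf_a,
            f"maf_{cohort_labels[1]}": maf_b,
        }
    )
    return r, table


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact p-value (Levene's conditional
    distribution of the heterozygote count given the allele counts).

    The p-value sums the probabilities of all heterozygote counts whose
    conditional probability does not exceed the observed configuration's.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotyped individual required")
    n_alt = n_het + 2 * n_hom_alt
    n_rare = min(n_alt, 2 * n - n_alt)
    # attainable het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logw = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((n_rare - hets) / 2 + 1)
        - gammaln((2 * n - n_rare - hets) / 2 + 1)
    )
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    p_obs = probs[hets == n_het]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count is unattainable")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


def _genotype_counts(gm: GenotypeMatrix) -> np.ndarray:
    """L x 3 genotype counts (hom-ref, het, hom-alt) over non-missing calls."""
    return np.stack(
        [(gm.calls == g).sum(axis=0) for g in (0, 1, 2)], axis=1
    )


def hwe_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    counts = _genotype_counts(gm)
    out = np.ones(gm.n_markers)
    for j in range(gm.n_markers):
        a, h, b = counts[j]
        if a + h + b > 0:
            out[j] = hwe_exact_test(int(a), int(h), int(b))
    return out


def filter_markers(
    gm: GenotypeMatrix, hwe_p: float = 1e-3, missing_max: float = 0.05
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop markers deviating from HWE (p < hwe_p) or with missingness
    above ``missing_max``; each failing marker is counted once, HWE first.
    """
    for name, val in (("hwe_p", hwe_p), ("missing_max", missing_max)):
        if not (0.0 < val < 1.0):
            raise ValueError(f"{name} must lie in (0, 1)")
    pvals = hwe_pvalues(gm)
    missing = gm.missing_fraction()
    fail_hwe = pvals < hwe_p
    fail_missing = (missing > missing_max) & ~fail_hwe
    keep = ~(fail_hwe | (missing > missing_max))
    report = QCReport(
        n_input=gm.n_markers,
        n_fail_hwe=int(fail_hwe.sum()),
        n_fail_missing=int(fail_missing.sum()),
        n_pass=int(keep.sum()),
        thresholds={"hwe_p": hwe_p, "missing_max": missing_max},
    )
    log.info(
        "marker QC: %d in, %d fail HWE, %d fail missingness, %d pass",
        report.n_input,
        report.n_fail_hwe,
        report.n_fail_missing,
        report.n_pass,
    )
    return gm.take_markers(keep), report


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    both = (x != MISSING) & (y != MISSING)
    if both.sum() < 2:
        return 0.0
    xv, yv = x[both].astype(float), y[both].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix,
    r2_max: float = 0.5,
    window: int = 50,
    step: int = 5,
) -> tuple[GenotypeMatrix, QCReport]:
    """Sliding-window LD pruning on squared dosage correlation.

    Within each window (markers ordered by chromosome and position) any
    pair exceeding ``r2_max`` loses the member with the higher missing
    fraction (ties: the later position).  Deterministic.
    """
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 and step >= 1")
    order = np.lexsort(
        (gm.markers["pos"].to_numpy(), gm.markers["chrom"].to_numpy())
    )
    if not np.array_equal(order, np.arange(gm.n_markers)):
        log.info("ld_prune: markers were not position-sorted; sorting internally")
    sorted_gm = gm.take_markers(order)
    missing = sorted_gm.missing_fraction()
    keep = np.ones(sorted_gm.n_markers, dtype=bool)
    chroms = sorted_gm.markers["chrom"].to_numpy()

    start = 0
    while start < sorted_gm.n_markers:
        idx = [
            j
            for j in range(start, min(start + window, sorted_gm.n_markers))
            if chroms[j] == chroms[start]
        ]
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                a, b = idx[ii], idx[jj]
                if not (keep[a] and keep[b]):
                    continue
                if _pairwise_r2(sorted_gm.calls[:, a], sorted_gm.calls[:, b]) > r2_max:
                    drop = a if missing[a] > missing[b] else b
                    keep[drop] = False
        start += step

    report = QCReport(
        n_input=gm.n_markers,
        n_pruned_ld=int((~keep).sum()),
        n_pass=int(keep.sum()),
        thresholds={"r2_max": r2_max, "window": window, "step": step},
    )
    log.info("LD pruning: %d in, %d pruned", report.n_input, report.n_pruned_ld)
    return sorted_gm.take_markers(keep), report


def batch_bias_test(
    cohort_a: GenotypeMatrix,
    cohort_b: GenotypeMatrix,
    bonferroni_alpha: float = 1e-7,
) -> pd.DataFrame:
    """Per-marker 2x2 allele-count chi-squared test between two cohorts.

    One degree of freedom, no continuity correction; ``flagged`` marks
    markers with p below the Bonferroni-corrected threshold.  Markers
    monomorphic in both cohorts score chi2 = 0, p = 1.
    """
    b_ids = set(cohort_b.rs_ids)
    shared = [rs for rs in cohort_a.rs_ids if rs in b_ids]
    if not shared:
        raise GenotypeDataError("no shared markers between cohorts")
    a_pos = {r: i for i, r in enumerate(cohort_a.rs_ids)}
    b_pos = {r: i for i, r in enumerate(cohort_b.rs_ids)}
    ja = [a_pos[r] for r in shared]
    jb = [b_pos[r] for r in shared]

    def allele_counts(gm: GenotypeMatrix, cols) -> tuple[np.ndarray, np.ndarray]:
        calls = gm.calls[:, cols]
        obs = calls != MISSING
        alt = np.where(obs, calls, 0).sum(axis=0).astype(float)
        total = 2.0 * obs.sum(axis=0)
        return alt, total - alt

    alt_a, ref_a = allele_counts(cohort_a, ja)
    alt_b, ref_b = allele_counts(cohort_b, jb)
    n = alt_a + ref_a + alt_b + ref_b
    row_a = alt_a + ref_a
    row_b = alt_b + ref_b
    col_alt = alt_a + alt_b
    col_ref = ref_a + ref_b
    denom = row_a * row_b * col_alt * col_ref
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(
            denom > 0, n * (alt_a * ref_b - ref_a * alt_b) ** 2 / np.maximum(denom, 1), 0.0
        )
    pvals = chi2_dist.sf(stat, df=1)
    pvals = np.where(denom > 0, pvals, 1.0)
    return pd.DataFrame(
        {
            "rs_id": shared,
            "chi2": stat,
            "p": pvals,
            "flagged": pvals < bonferroni_alpha,
        }
    )
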