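"""Core in-memory containers shared by every analysis stage.

A :class:`GenotypeMatrix` holds diploid biallelic SNP calls for N samples
by L markers as alt-allele dosages (0 = homozygous reference, 1 =
heterozygous, 2 = homozygous alternate), with ``-1`` marking a missing
call.  Marker and sample metadata travel with the calls as pandas
DataFrames so that filtering stages can subset both consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING: int = -1

VALID_BASES = frozenset("ACGT")

#: Watson-Crick complement used for cross-platform strand reconciliation.
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

MARKER_COLUMNS = ["rs_id", "chrom", "pos", "allele_ref", "allele_alt"]
SAMPLE_COLUMNS = ["sample_id", "region", "cohort"]


class GenotypeDataError(ValueError):
    """Raised when genotype data violates the container contract."""


def complement_pair(ref: str, alt: str) -> tuple[str, str]:
    """Complement an allele pair (strand flip); an involution."""
    return COMPLEMENT[ref], COMPLEMENT[alt]


def is_ambiguous_pair(ref: str, alt: str) -> bool:
    """True for A/T and C/G SNPs, whose strand cannot be reconciled."""
    return {ref, alt} in ({"A", "T"}, {"C", "G"})


def make_marker_table(
    rs_ids,
    chrom=None,
    pos=None,
    allele_ref=None,
    allele_alt=None,
) -> pd.DataFrame:
    """Build a marker metadata table with defaulted columns."""
    rs_ids = list(rs_ids)
    n = len(rs_ids)
    return pd.DataFrame(
        {
            "rs_id": rs_ids,
            "chrom": list(chrom) if chrom is not None else ["1"] * n,
            "pos": np.asarray(pos, dtype=np.int64)
            if pos is not None
            else np.arange(1, n + 1, dtype=np.int64),
            "allele_ref": list(allele_ref) if allele_ref is not None else ["A"] * n,
            "allele_alt": list(allele_alt) if allele_alt is not None else ["G"] * n,
        }
    )


def make_sample_table(sample_ids, region=None, cohort=None) -> pd.DataFrame:
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "region": list(region) if region is not None else [None] * n,
            "cohort": list(cohort) if cohort is not None else [None] * n,
        }
    )


@dataclass
class GenotypeMatrix:
    """N x L diploid genotype matrix with marker and sample metadata.

    Parameters
    ----------
    calls
        Integer array of shape (n_samples, n_markers) with values in
        {0, 1, 2, MISSING}.  ``calls[i, l]`` counts copies of
        ``allele_alt`` of marker ``l`` carried by sample ``i``.
    markers
        DataFrame with columns rs_id, chrom, pos, allele_ref, allele_alt.
    samples
        DataFrame with columns sample_id, region, cohort.
    """

    calls: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.ndim != 2:
            raise GenotypeDataError("calls must be a 2-D array")
        self.markers = self.markers.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        n, l = self.calls.shape
        if len(self.samples) != n:
            raise GenotypeDataError(
                f"sample table has {len(self.samples)} rows for {n} call rows"
            )
        if len(self.markers) != l:
            raise GenotypeDataError(
                f"marker table has {len(self.markers)} rows for {l} call columns"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeDataError(
                f"invalid call {self.calls[i, j]} at sample {i}, marker {j}"
            )
        if self.markers["rs_id"].duplicated().any():
            dup = self.markers["rs_id"][self.markers["rs_id"].duplicated()].iloc[0]
            raise GenotypeDataError(f"duplicate rs_id {dup!r}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][
                self.samples["sample_id"].duplicated()
            ].iloc[0]
            raise GenotypeDataError(f"duplicate sample_id {dup!r}")
        same = self.markers["allele_ref"] == self.markers["allele_alt"]
        if same.any():
            raise GenotypeDataError(
                f"marker {self.markers['rs_id'][same].iloc[0]!r} has identical alleles"
            )

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def rs_ids(self) -> list[str]:
        return self.markers["rs_id"].tolist()

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def alt_frequency(self) -> np.ndarray:
        """Per-marker alt-allele frequency over non-missing calls (nan if none)."""
        obs = self.observed()
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    # -- subsetting -------------------------------------------------------
    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[index, :],
            self.markers.copy(),
            self.samples.iloc[index].reset_index(drop=True),
        )

    def take_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[:, index],
            self.markers.iloc[index].reset_index(drop=True),
            self.samples.copy(),
        )

    def select_samples(self, sample_ids) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [order[s] for s in sample_ids]
        return self.take_samples(np.asarray(idx, dtype=np.intp))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.copy(), self.markers.copy(), self.samples.copy()
        )


def concat_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two cohorts sharing an identical marker frame."""
    if a.rs_ids != b.rs_ids:
        raise GenotypeDataError("marker frames differ; harmonize before stacking")
    return GenotypeMatrix(
        np.vstack([a.calls, b.calls]),
        a.markers.copy(),
        pd.concat([a.samples, b.samples], ignore_index=True),
    )
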