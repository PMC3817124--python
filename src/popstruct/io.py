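"""Readers and writers for PLINK-style text PED/MAP and plain TSV matrices.

Conventions
-----------
* Dosages count copies of ``allele_alt``; the alternate allele is the
  cohort minor allele at load time (ties broken lexicographically, the
  smaller base becoming the reference).
* PLINK missing genotype is ``0 0``; TSV missing is ``NA``.
* Positions are 1-based, as in MAP files.
* All writers emit UTF-8, tab-delimited, newline-terminated text.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    MISSING,
    VALID_BASES,
    GenotypeDataError,
    GenotypeMatrix,
    make_marker_table,
    make_sample_table,
)

log = logging.getLogger(__name__)

#: Family-id values recognised as self-reported regional labels.
KNOWN_REGION_LABELS = frozenset({"North", "Northeast", "Central", "South"})


class ParseError(GenotypeDataError):
    """Malformed input file."""


def _open(source, mode="r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(Path(source), mode, encoding="utf-8"), True


def read_plink_text(ped_source, map_source) -> GenotypeMatrix:
    """Read a text PED/MAP pair into a :class:`GenotypeMatrix`.

    The PED family-id column is interpreted as a regional label when it
    matches the known label set (North/Northeast/Central/South).
    """
    fh, close = _open(map_source)
    try:
        map_rows = []
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(
                    f"MAP line {lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, rs_id, _cm, pos = parts
            map_rows.append((chrom, rs_id, int(pos)))
    finally:
        if close:
            fh.close()
    n_markers = len(map_rows)

    fh, close = _open(ped_source)
    try:
        sample_ids, regions = [], []
        allele_rows = []
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_markers:
                raise ParseError(
                    f"PED line {lineno}: expected {6 + 2 * n_markers} columns, "
                    f"got {len(parts)}"
                )
            fam, iid = parts[0], parts[1]
            sample_ids.append(iid)
            regions.append(fam if fam in KNOWN_REGION_LABELS else None)
            allele_rows.append(parts[6:])
    finally:
        if close:
            fh.close()

    n = len(sample_ids)
    alleles = np.array(allele_rows, dtype="U1").reshape(n, n_markers, 2) if n else (
        np.empty((0, n_markers, 2), dtype="U1")
    )

    calls = np.full((n, n_markers), MISSING, dtype=np.int16)
    refs, alts = [], []
    for j, (_chrom, rs_id, _pos) in enumerate(map_rows):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        bases, counts = np.unique(observed, return_counts=True)
        bad = [b for b in bases if b not in VALID_BASES]
        if bad:
            raise ParseError(f"marker {rs_id!r}: invalid allele {bad[0]!r}")
        if len(bases) > 2:
            raise ParseError(f"marker {rs_id!r}: more than two alleles observed")
        if len(bases) == 2:
            # minor allele is alt; on a tie the lexicographically smaller
            # base is the reference
            order = np.lexsort((bases, -counts))
            ref, alt = bases[order[0]], bases[order[1]]
            if counts[order[0]] == counts[order[1]] and alt < ref:
                ref, alt = alt, ref
        elif len(bases) == 1:
            ref = str(bases[0])
            alt = next(b for b in "ACGT" if b != ref)
        else:  # all missing
            ref, alt = "A", "G"
        refs.append(ref)
        alts.append(alt)
        obs_mask = (col != "0").all(axis=1)
        calls[obs_mask, j] = (col[obs_mask] == alt).sum(axis=1)

    markers = make_marker_table(
        [r[1] for r in map_rows],
        chrom=[r[0] for r in map_rows],
        pos=[r[2] for r in map_rows],
        allele_ref=refs,
        allele_alt=alts,
    )
    samples = make_sample_table(sample_ids, region=regions)
    gm = GenotypeMatrix(calls, markers, samples)
    log.info("read PED/MAP: %d samples, %d markers", n, n_markers)
    return gm


def write_plink_text(gm: GenotypeMatrix, ped_sink, map_sink) -> None:
    """Write PED/MAP text; heterozygotes are written ref-then-alt."""
    fh, close = _open(map_sink, "w")
    try:
        for row in gm.markers.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.rs_id}\t0\t{row.pos}\n")
    finally:
        if close:
            fh.close()

    refs = gm.markers["allele_ref"].to_numpy()
    alts = gm.markers["allele_alt"].to_numpy()
    fh, close = _open(ped_sink, "w")
    try:
        for i, srow in enumerate(gm.samples.itertuples(index=False)):
            fam = srow.region if srow.region in KNOWN_REGION_LABELS else "FAM"
            fields = [fam, srow.sample_id, "0", "0", "0", "-9"]
            row = gm.calls[i]
            for j in range(gm.n_markers):
                g = row[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [refs[j], refs[j]]
                elif g == 1:
                    fields += [refs[j], alts[j]]
                else:
                    fields += [alts[j], alts[j]]
            fh.write("\t".join(fields) + "\n")
    finally:
        if close:
            fh.close()


def read_matrix_tsv(source) -> GenotypeMatrix:
    """Read a TSV genotype matrix (header = rs-ids, first column = sample id)."""
    fh, close = _open(source)
    try:
        df = pd.read_csv(fh, sep="\t", dtype=str, index_col=0)
    finally:
        if close:
            fh.close()
    rs_ids = df.columns.tolist()
    values = df.to_numpy()
    calls = np.full(values.shape, MISSING, dtype=np.int16)
    for (i, j), cell in np.ndenumerate(values):
        if isinstance(cell, float) and np.isnan(cell):
            cell = "NA"
        cell = str(cell)
        if cell in ("NA", "nan"):
            continue
        if cell not in ("0", "1", "2"):
            raise ParseError(
                f"row {df.index[i]!r}, column {rs_ids[j]!r}: "
                f"invalid cell {cell!r} (expected 0/1/2/NA)"
            )
        calls[i, j] = int(cell)
    gm = GenotypeMatrix(
        calls,
        make_marker_table(rs_ids),
        make_sample_table(df.index.astype(str).tolist()),
    )
    log.info("read TSV matrix: %d samples, %d markers", *calls.shape)
    return gm


def write_matrix_tsv(gm: GenotypeMatrix, sink) -> None:
    fh, close = _open(sink, "w")
    try:
        fh.write("sample_id\t" + "\t".join(gm.rs_ids) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            cells = [
                "NA" if g == MISSING else str(int(g)) for g in gm.calls[i]
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")
    finally:
        if close:
            fh.close()


def write_table_tsv(df: pd.DataFrame, sink) -> None:
    """Write an arbitrary report table as TSV."""
    fh, close = _open(sink, "w")
    try:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    finally:
        if close:
            fh.close()
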