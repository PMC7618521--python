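"""Readers and writers for the pipeline's plain-text formats.

Counts travel as TSV (genes x samples, optional ``<sample>.labeled`` columns
for conversion counts) or MatrixMarket triplets with ``<path>.rows`` /
``<path>.cols`` sidecar files carrying gene and sample ids, one per line.
Regions are BED3/BED4 (0-based half-open).  Dose matrices are TSV with the
first row and column holding the doses.  All output tables may carry
'#'-prefixed metadata header lines, which readers skip.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio

from .quantify import ConversionCounts
from .synergy import DoseMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_regions",
    "write_regions",
    "read_tss_table",
    "read_dose_matrix",
    "write_dose_matrix",
    "write_table",
]

LABELED_SUFFIX = ".labeled"


def _validate_counts(df: pd.DataFrame, path) -> None:
    values = df.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: counts must be integers")
    if (values < 0).any():
        raise ValueError(f"{path}: counts must be nonnegative")


def read_counts(path, fmt: str | None = None, sample_sheet: pd.DataFrame | None = None):
    """Load a count matrix from TSV or MatrixMarket.

    Returns a :class:`ConversionCounts` when paired ``<sample>.labeled``
    columns are present (TSV only), otherwise a plain integer DataFrame.
    For MTX, gene and sample ids come from ``<path>.rows`` and ``<path>.cols``.
    """
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "mtx":
        m = sio.mmread(path)
        mat = m.toarray() if hasattr(m, "toarray") else np.asarray(m)
        rows = Path(f"{path}.rows").read_text().split()
        cols = Path(f"{path}.cols").read_text().split()
        df = pd.DataFrame(mat, index=pd.Index(rows, name="gene_id"), columns=cols)
        _validate_counts(df, path)
        return df.astype(int)
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")

    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "gene_id"
    labeled_cols = [c for c in df.columns if c.endswith(LABELED_SUFFIX)]
    _validate_counts(df, path)
    df = df.astype(int)
    if not labeled_cols:
        return df
    total = df[[c for c in df.columns if not c.endswith(LABELED_SUFFIX)]]
    labeled = df[labeled_cols].rename(columns=lambda c: c[: -len(LABELED_SUFFIX)])
    if set(labeled.columns) != set(total.columns):
        raise ValueError(f"{path}: labeled columns do not pair with total columns")
    labeled = labeled[total.columns]
    bad = labeled.to_numpy() > total.to_numpy()
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: labeled exceeds total at gene {total.index[g]!r}, "
            f"sample {total.columns[s]!r}"
        )
    if sample_sheet is None:
        sample_sheet = _default_sample_sheet(total.columns)
    return ConversionCounts(total_counts=total, labeled_counts=labeled, samples=sample_sheet)


def _default_sample_sheet(sample_ids) -> pd.DataFrame:
    """Recover metadata from 't<h>_r<rep>'-style sample ids."""
    rows = []
    for sid in sample_ids:
        t, r = np.nan, np.nan
        if sid.startswith("t") and "_r" in sid:
            try:
                tp, rep = sid[1:].split("_r")
                t, r = float(tp), int(rep)
            except ValueError:
                pass
        rows.append(
            {
                "sample_id": sid,
                "condition": "DMSO" if t == 0 else "BETi",
                "timepoint_h": t,
                "replicate": r,
            }
        )
    return pd.DataFrame(rows)


def write_counts(counts, path, header_lines: list[str] | None = None) -> None:
    """Write a count matrix (or ConversionCounts with .labeled columns) as TSV."""
    path = Path(path)
    if isinstance(counts, ConversionCounts):
        df = counts.total_counts.copy()
        for c in counts.labeled_counts.columns:
            df[c + LABELED_SUFFIX] = counts.labeled_counts[c]
    else:
        df = counts
    write_table(df, path, header_lines, index_label="gene_id")


def write_table(df: pd.DataFrame, path, header_lines: list[str] | None = None,
                index_label: str | None = None, index: bool = True) -> None:
    """TSV writer with optional '#'-prefixed metadata header lines."""
    buf = _io.StringIO()
    for line in header_lines or []:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=index, index_label=index_label)
    Path(path).write_text(buf.getvalue())


def read_regions(path) -> pd.DataFrame:
    """Read BED3/BED4 regions (0-based half-open), sorted and deduplicated.

    A missing 4th column auto-generates region ids as ``chrom:start-end``.
    Duplicate intervals collapse to one with a warning; ``start >= end`` is an
    error reported with its line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            rid = parts[3] if len(parts) >= 4 and parts[3] else f"{chrom}:{start}-{end}"
            rows.append({"region_id": rid, "chrom": chrom, "start": start, "end": end})
    df = pd.DataFrame(rows)
    if len(df) == 0:
        raise ValueError(f"{path}: no regions")
    n_dup = int(df.duplicated(subset=["chrom", "start", "end"]).sum())
    if n_dup:
        warnings.warn(f"{path}: collapsed {n_dup} duplicate region(s)", stacklevel=2)
        df = df.drop_duplicates(subset=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_regions(regions: pd.DataFrame, path) -> None:
    """Write regions as BED4 (byte-stable for round-trips)."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['region_id']}\n")


def read_tss_table(path) -> pd.DataFrame:
    """TSS annotation TSV: gene_id, chrom, strand, tss_position (0-based)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "strand", "tss_position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TSS columns {sorted(missing)}")
    return df


def read_dose_matrix(path, mode: str = "concomitant") -> DoseMatrix:
    """Dose-matrix TSV: first row = doses of drug B, first column = doses of A."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return DoseMatrix(
        doses_a=df.index.to_numpy(float),
        doses_b=df.columns.to_numpy(float),
        inhibition=df.to_numpy(float),
        mode=mode,
    )


def write_dose_matrix(matrix: DoseMatrix, path, header_lines: list[str] | None = None) -> None:
    df = pd.DataFrame(
        matrix.inhibition,
        index=pd.Index(matrix.doses_a, name="dose_a"),
        columns=matrix.doses_b,
    )
    write_table(df, path, header_lines)
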