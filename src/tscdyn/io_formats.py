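"""Readers and writers for the flat-file formats the pipeline touches.

Coordinate conventions: every file is read as its standard dictates (BED is
0-based half-open; CpG reports are 1-based as emitted by methylation
callers) and normalized internally to 0-based. Calls on the minus strand of
a symmetric CpG are shifted onto the plus-strand C and pooled with the plus
call by summing counts; pooling raises coverage and matches the common
convention for CpG-level (rather than strand-resolved) analyses.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import (
    ExpressionMatrix,
    GenomicInterval,
    MethylationCallSet,
    SampleMeta,
    TSSRecord,
    check_unique_samples,
)


class FormatError(ValueError):
    """A file violated its declared format."""


# ---------------------------------------------------------------------------
# CpG reports


def read_cpg_report(path: str | Path, sample_id: str) -> MethylationCallSet:
    """Read a per-CpG bisulfite call report.

    Expected columns (tab-separated, no header): chrom, pos (1-based),
    strand (+/-), methylated count, total coverage. Minus-strand calls are
    anchored to the plus-strand C of the symmetric CpG (position - 1 after
    0-basing) and merged with any plus-strand call there by summing counts.
    An empty file yields an empty call set.
    """
    rows = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
            chrom, pos_s, strand, meth_s, total_s = row[:5]
            try:
                pos1, meth, total = int(pos_s), int(meth_s), int(total_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            if total <= 0:
                raise FormatError(f"{path}:{lineno}: total coverage must be positive")
            if meth < 0 or meth > total:
                raise FormatError(f"{path}:{lineno}: meth count {meth} outside [0, {total}]")
            pos0 = pos1 - 1 - (1 if strand == "-" else 0)
            rows.append((chrom, pos0, meth, total))

    if not rows:
        calls = pd.DataFrame(columns=list(MethylationCallSet.COLUMNS)).astype(
            {"pos": int, "meth": int, "total": int}
        )
        return MethylationCallSet(sample_id, calls)

    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    merged = df.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "total"]].sum()
    return MethylationCallSet(sample_id, merged)


def write_cpg_report(callset: MethylationCallSet, path: str | Path) -> None:
    """Write a call set as a plus-strand, 1-based CpG report (round-trips)."""
    out = callset.calls.copy()
    out["pos"] = out["pos"] + 1
    out.insert(2, "strand", "+")
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Expression counts and sample metadata


def read_counts(path: str | Path, samples: Sequence[SampleMeta] | None = None) -> ExpressionMatrix | pd.DataFrame:
    """Read a gene x sample count TSV (first column gene_id, header row).

    With ``samples`` given, the column set must equal the metadata sample set
    and an :class:`ExpressionMatrix` is returned; otherwise the raw frame.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"{path}: duplicate gene ids {dup[:5]}")
    for col in df.columns:
        vals = df[col]
        if not pd.api.types.is_integer_dtype(vals):
            as_float = pd.to_numeric(vals, errors="coerce")
            if as_float.isna().any() or (as_float % 1 != 0).any():
                raise FormatError(f"{path}: non-integer count in column {col!r}")
            df[col] = as_float.astype(int)
    if samples is None:
        return df
    meta_ids = {s.sample_id for s in samples}
    if set(df.columns) != meta_ids:
        extra = sorted(set(df.columns) - meta_ids)
        missing = sorted(meta_ids - set(df.columns))
        raise FormatError(
            f"{path}: sample columns do not match metadata "
            f"(unknown: {extra[:5]}, missing: {missing[:5]})"
        )
    return ExpressionMatrix(df, list(samples))


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_table(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata (TSV: sample_id, condition, stage, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str, "stage": str})
    samples = [
        SampleMeta(r.sample_id, r.condition, r.stage, int(r.replicate))
        for r in df.itertuples()
    ]
    check_unique_samples(samples)
    return samples


def write_sample_table(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "condition": [s.condition for s in samples],
            "stage": [s.stage for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED intervals and TSS tables


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open), sorted by (chrom, start).

    Names are taken from column 4 when present, else auto-generated.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start_s, end_s = parts[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 and parts[3] else ""
            intervals.append((chrom, start, end, name))
    intervals.sort(key=lambda t: (t[0], t[1], t[2]))
    out = []
    for i, (chrom, start, end, name) in enumerate(intervals, start=1):
        out.append(GenomicInterval(chrom, start, end, name or f"interval_{i:05d}"))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a flat TSS table (TSV: gene_id, chrom, tss, strand).

    One record per gene: the first-listed transcript wins when a gene_id
    appears more than once.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    seen: set[str] = set()
    records = []
    for r in df.itertuples():
        if r.gene_id in seen:
            continue
        seen.add(r.gene_id)
        records.append(TSSRecord(r.gene_id, r.chrom, int(r.tss), r.strand))
    return records


def write_tss_table(records: Sequence[TSSRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "chrom": [r.chrom for r in records],
            "tss": [r.tss for r in records],
            "strand": [r.strand for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CGI methylation matrix


def write_cgi_matrix(matrix, path: str | Path) -> None:
    """Serialize a CGI x sample methylation matrix as one wide TSV.

    Columns: chrom, start, end, then per sample ratio:<id>, meth:<id>,
    total:<id>, ncpg:<id>. Round-trips through :func:`read_cgi_matrix`.
    """
    ivs = {iv.name: iv for iv in matrix.cgis}
    out = pd.DataFrame(index=matrix.ratio.index)
    out["chrom"] = [ivs[c].chrom for c in out.index]
    out["start"] = [ivs[c].start for c in out.index]
    out["end"] = [ivs[c].end for c in out.index]
    for sid in matrix.sample_ids:
        out[f"ratio:{sid}"] = matrix.ratio[sid]
        out[f"meth:{sid}"] = matrix.pooled_meth[sid]
        out[f"total:{sid}"] = matrix.pooled_total[sid]
        out[f"ncpg:{sid}"] = matrix.detected[sid]
    out.to_csv(path, sep="\t", index_label="cgi", float_format="%.10g")


def read_cgi_matrix(path: str | Path):
    from .methylation import CGIMethylationMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    sample_ids = [c.split(":", 1)[1] for c in df.columns if c.startswith("ratio:")]
    cgis = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), name)
        for name, r in zip(df.index, df.itertuples())
    ]
    def block(prefix: str, dtype=float) -> pd.DataFrame:
        sub = df[[f"{prefix}:{s}" for s in sample_ids]].astype(dtype)
        sub.columns = sample_ids
        return sub

    return CGIMethylationMatrix(
        cgis,
        block("ratio"),
        block("meth", int),
        block("total", int),
        block("ncpg", int),
    )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain one-gene-per-line list (blank lines and # comments skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
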