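"""Core domain types shared across the pipeline.

The unit of study is a trophoblast stem cell (TSC) derivation time course:
five stages (E3.5 trophectoderm through established TSC lines) sampled under
up to three derivation conditions — natural fertilization (NF), somatic cell
nuclear transfer (NT) and NT with the HDAC inhibitor Scriptaid (SNT) — plus
the donor cumulus cell (CC) and MII oocyte used as methylome references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical stage order of the derivation time course (earliest first).
STAGE_ORDER: tuple[str, ...] = ("TE3.5", "TE4.5", "outgrowth", "TSC_P1", "TSC_Pn")

#: Index of each stage in the canonical order.
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGE_ORDER)}

CONDITIONS: tuple[str, ...] = ("NF", "NT", "SNT", "CC", "MII", "other")

STAGES: tuple[str, ...] = STAGE_ORDER + ("none",)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced replicate."""

    sample_id: str
    condition: str
    stage: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def stage_index(self) -> int:
        """Position of this sample's stage in the canonical order (-1 if none)."""
        return STAGE_INDEX.get(self.stage, -1)


def check_unique_samples(samples: Sequence[SampleMeta]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dup}")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based [start, end)."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def distance_to(self, pos: int) -> int:
        """Distance from a point to this interval; 0 if the point lies inside."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


@dataclass(frozen=True)
class TSSRecord:
    """Transcription start site of a gene (0-based position)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class MethylationCallSet:
    """Per-CpG methylation calls for one sample or replicate.

    ``calls`` has columns chrom, pos (0-based, plus-strand anchored C of the
    CpG), meth, total. Opposite-strand calls of one symmetric CpG are pooled
    at read time, so one row per CpG. A CpG absent from ``calls`` is "not
    detected" — distinct from a detected CpG with ratio 0.
    """

    sample_id: str
    calls: pd.DataFrame

    COLUMNS = ("chrom", "pos", "meth", "total")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.calls.columns]
        if missing:
            raise ValueError(f"call table missing columns {missing}")
        self.calls = (
            self.calls.loc[:, list(self.COLUMNS)]
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        if len(self.calls):
            if (self.calls["total"] <= 0).any():
                raise ValueError("total coverage must be positive")
            if (self.calls["meth"] > self.calls["total"]).any():
                raise ValueError("meth count exceeds total coverage")
            if (self.calls["meth"] < 0).any():
                raise ValueError("meth count must be non-negative")

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def ratios(self) -> pd.Series:
        return self.calls["meth"] / self.calls["total"]


@dataclass
class ExpressionMatrix:
    """Gene x sample count matrix with stage/condition/replicate metadata.

    ``counts`` is indexed by gene_id with one column per sample_id, in the
    order of ``samples``. ``norm`` is log2(RPM + 1), computed lazily.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        check_unique_samples(self.samples)
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            if set(self.counts.columns) != set(ids):
                raise ValueError("count columns do not match sample metadata")
            self.counts = self.counts.loc[:, ids]
        if self.counts.index.duplicated().any():
            dup = sorted(self.counts.index[self.counts.index.duplicated()])
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @cached_property
    def norm(self) -> pd.DataFrame:
        from .expression import normalize_rpm

        return normalize_rpm(self.counts)

    def subset_samples(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = list(keep)
        meta = [s for s in self.samples if s.sample_id in set(keep)]
        return ExpressionMatrix(self.counts.loc[:, [s.sample_id for s in meta]], meta)

    def samples_where(self, condition: str | None = None, stage: str | None = None) -> list[SampleMeta]:
        out = []
        for s in self.samples:
            if condition is not None and s.condition != condition:
                continue
            if stage is not None and s.stage != stage:
                continue
            out.append(s)
        return out

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


def stage_mean_matrix(
    norm: pd.DataFrame, samples: Sequence[SampleMeta], condition: str | None = None
) -> pd.DataFrame:
    """Collapse replicates to per-stage means (columns ordered by stage).

    Replicates of each (condition, stage) group are merged using the mean of
    the normalized values. With ``condition`` given, only that condition's
    samples contribute and columns are the stage names; otherwise columns are
    "<condition>:<stage>" blocks ordered by condition then stage.
    """
    groups: dict[str, list[str]] = {}
    for s in samples:
        if s.stage not in STAGE_INDEX:
            continue
        if condition is not None:
            if s.condition != condition:
                continue
            key = s.stage
        else:
            key = f"{s.condition}:{s.stage}"
        groups.setdefault(key, []).append(s.sample_id)

    def sort_key(key: str):
        if condition is not None:
            return (STAGE_INDEX[key],)
        cond, stage = key.split(":")
        return (cond, STAGE_INDEX[stage])

    ordered = sorted(groups, key=sort_key)
    data = {k: norm.loc[:, groups[k]].mean(axis=1) for k in ordered}
    return pd.DataFrame(data, index=norm.index)
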