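"""Readers, writers and coordinate arithmetic for the pipeline's external formats.

All genomic intervals are held internally in the BED-native 0-based half-open
convention; conversion from 1-based closed coordinates (the convention of most
printed genome-browser ranges) happens only at the boundary, through
:func:`closed1_to_halfopen0`.

Supported dialects:

* BED3/BED6 and ENCODE narrowPeak (10 columns) peak sets,
* TSV count matrices (row id + one column per sample),
* triplet Hi-C contact text (``bin_i<TAB>bin_j<TAB>count``),
* variant tables (``variant_id, chrom, pos1, pval``; positions 1-based),
* pairwise-LD tables (``variant_a, variant_b, r2``),
* sample design tables (``sample_id, donor, treatment, timepoint``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneAnnot",
    "ContactMap",
    "closed1_to_halfopen0",
    "strip_chr",
    "read_peaks",
    "write_bed",
    "read_contacts",
    "read_counts",
    "write_counts",
    "read_genes",
    "write_genes",
    "read_variants",
    "write_variants",
    "read_ld_table",
    "write_ld_table",
    "read_design",
    "write_design",
]


class FormatError(ValueError):
    """A file did not conform to its declared dialect."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or reversed interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        """True if a 0-based position falls inside the half-open interval."""
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """An (unstranded) accessible-chromatin element."""

    interval: GenomicInterval
    peak_id: str
    summit_offset: int | None = None


@dataclass(frozen=True)
class GeneAnnot:
    """A gene reduced to its transcription start site."""

    gene_id: str
    chrom: str
    tss: int  # 0-based
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("negative TSS position")


def closed1_to_halfopen0(chrom: str, start1: int, end1: int) -> GenomicInterval:
    """Convert a 1-based closed range (the genome-browser printing
    convention) to the internal 0-based half-open convention.

    The length of the returned interval equals ``end1 - start1 + 1``, the
    number of bases the closed range spans.
    """
    if start1 < 1:
        raise ValueError(f"1-based start must be >= 1, got {start1}")
    if end1 < start1:
        raise ValueError(
            f"reversed 1-based coordinates ({chrom}:{start1}-{end1}): end < start"
        )
    return GenomicInterval(chrom, start1 - 1, end1)


def strip_chr(name: str) -> str:
    """Normalizer for the optional strip-chr config flag ('chr9'/'Chr9' -> '9')."""
    low = name.lower()
    return name[3:] if low.startswith("chr") else name


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path: str | Path, dialect: str = "bed") -> list[Peak]:
    """Read a BED3/BED6 or narrowPeak file into a list of :class:`Peak`.

    Coordinates are stored exactly as in the file (BED is already 0-based
    half-open).  Row order is preserved.  Peaks lacking a name column get a
    positional id ``peak_<n>``.
    """
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else f"peak_{lineno}"
            summit: int | None = None
            if dialect == "narrowPeak":
                if len(parts) < 10:
                    raise FormatError(
                        f"{path}:{lineno}: narrowPeak requires 10 columns"
                    )
                summit = int(parts[9])
                if summit == -1:
                    summit = None
            peaks.append(Peak(GenomicInterval(chrom, start, end), name, summit))
    ids = [p.peak_id for p in peaks]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate peak ids")
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\n")


# ---------------------------------------------------------------------------
# Hi-C contacts


class ContactMap:
    """Symmetric lookup of binned contact counts.

    Stored upper-triangular (``bin_i <= bin_j``); queries are symmetric and
    absent pairs return 0.  Duplicate triplets in the input are summed — the
    lossless choice given that matrix dumpers disagree on whether mirrored
    records may appear.
    """

    def __init__(self, bin_size: int, counts: Mapping[tuple[int, int], float] | None = None):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.bin_size = int(bin_size)
        self._counts: dict[tuple[int, int], float] = {}
        if counts:
            for (i, j), c in counts.items():
                self.add(i, j, c)

    @staticmethod
    def _key(b1: int, b2: int) -> tuple[int, int]:
        return (b1, b2) if b1 <= b2 else (b2, b1)

    def add(self, b1: int, b2: int, count: float) -> None:
        if b1 < 0 or b2 < 0:
            raise ValueError("negative bin index")
        if count < 0:
            raise ValueError("negative contact count")
        key = self._key(b1, b2)
        self._counts[key] = self._counts.get(key, 0.0) + float(count)

    def query(self, b1: int, b2: int) -> float:
        return self._counts.get(self._key(b1, b2), 0.0)

    def items(self):
        return self._counts.items()

    def __len__(self) -> int:
        return len(self._counts)

    def bin_of(self, pos: int) -> int:
        return pos // self.bin_size


def read_contacts(path: str | Path, bin_size: int) -> ContactMap:
    """Read triplet Hi-C text (``bin_i<TAB>bin_j<TAB>count``)."""
    cm = ContactMap(bin_size)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                b1, b2, count = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed triplet") from exc
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            if b1 < 0 or b2 < 0:
                raise FormatError(f"{path}:{lineno}: negative bin index")
            cm.add(b1, b2, count)
    return cm


def write_contacts(cm: ContactMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (b1, b2), c in sorted(cm.items()):
            fh.write(f"{b1}\t{b2}\t{c:.6g}\n")


# ---------------------------------------------------------------------------
# count matrices, genes, variants, LD, design — thin pandas wrappers


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV count matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate feature ids")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_genes(path: str | Path) -> list[GeneAnnot]:
    """Read a gene annotation TSV: gene_id, chrom, tss (0-based), strand."""
    df = pd.read_csv(path, sep="\t")
    genes = [
        GeneAnnot(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples(index=False)
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate gene ids")
    return genes


def write_genes(genes: Iterable[GeneAnnot], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand) for g in genes],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read a variant TSV (variant_id, chrom, pos1, pval); adds 0-based `pos`."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    missing = {"variant_id", "chrom", "pos1", "pval"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if (df["pos1"] < 1).any():
        raise FormatError(f"{path}: 1-based positions must be >= 1")
    df = df.copy()
    df["pos"] = df["pos1"].astype(int) - 1
    return df


def write_variants(df: pd.DataFrame, path: str | Path) -> None:
    df[["variant_id", "chrom", "pos1", "pval"]].to_csv(path, sep="\t", index=False)


def read_ld_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_a": str, "variant_b": str})
    missing = {"variant_a", "variant_b", "r2"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if ((df["r2"] < 0) | (df["r2"] > 1)).any():
        raise FormatError(f"{path}: r2 outside [0, 1]")
    return df


def write_ld_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["variant_a", "variant_b", "r2"]].to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "donor", "treatment", "timepoint"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return df


def write_design(df: pd.DataFrame, path: str | Path) -> None:
    df[["sample_id", "donor", "treatment", "timepoint"]].to_csv(
        path, sep="\t", index=False
    )
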