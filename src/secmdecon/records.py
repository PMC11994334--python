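"""Per-read methylation records: the atomic data unit of the package.

One record is one aligned, deduplicated bisulfite read: its genomic interval
(0-based, half-open) plus the number of informative CpG sites it covers and
how many of them were methylated.  This is the information content of a
per-read methylation extractor (e.g. MethylDackel perRead) run on PBAT
alignments; alignment, trimming and duplicate marking happen upstream.

Bulk storage is a pandas DataFrame (one row per read) wrapped in
:class:`SampleReadSet`; :class:`PerReadRecord` is the single-record view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    ParameterError,
    RecordValidationError,
    UndefinedLevelError,
)
from .genome import Genome

logger = logging.getLogger(__name__)

#: canonical column order of the per-read table
COLUMNS = ["read_id", "chrom", "start", "end", "n_cpg", "n_meth", "n_unmeth_ch"]
#: columns that must be present in an input table (n_unmeth_ch may be absent)
REQUIRED_COLUMNS = COLUMNS[:6]


@dataclass(frozen=True)
class PerReadRecord:
    """A single read's genomic interval and CpG methylation counts.

    ``n_unmeth_ch`` counts unmethylated CH cytosines on the read (used by the
    bisulfite-conversion filter); it defaults to 0 so pre-filtered data flow
    through unchanged.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    n_cpg: int
    n_meth: int
    n_unmeth_ch: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise RecordValidationError(
                f"read {self.read_id}: start {self.start} >= end {self.end}"
            )
        if self.n_cpg < 0 or self.n_meth < 0 or self.n_unmeth_ch < 0:
            raise RecordValidationError(f"read {self.read_id}: negative count")
        if self.n_meth > self.n_cpg:
            raise RecordValidationError(
                f"read {self.read_id}: n_meth {self.n_meth} > n_cpg {self.n_cpg}"
            )


@dataclass
class SampleReadSet:
    """An ordered collection of per-read records for one sample.

    ``records`` is a DataFrame with at least the columns in :data:`COLUMNS`;
    simulated data additionally carry an ``origin`` column (source sample of
    each read in a mixture) that is kept in memory for test oracles but never
    written to disk.
    """

    sample_id: str
    records: pd.DataFrame
    genome: Genome
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"read set missing column(s): {', '.join(missing)}")
        if "n_unmeth_ch" not in self.records.columns:
            self.records = self.records.assign(n_unmeth_ch=0)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_reads(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        """Enforce record invariants over the whole table (vectorized)."""
        df = self.records
        bad = df.index[df["n_meth"].to_numpy() > df["n_cpg"].to_numpy()]
        if len(bad):
            rid = df.loc[bad[0], "read_id"]
            raise RecordValidationError(
                f"read {rid}: n_meth > n_cpg ({len(bad)} offending record(s))"
            )
        if (df["start"].to_numpy() >= df["end"].to_numpy()).any():
            i = int(np.argmax(df["start"].to_numpy() >= df["end"].to_numpy()))
            raise RecordValidationError(f"read {df.iloc[i]['read_id']}: start >= end")
        for col in ("n_cpg", "n_meth", "n_unmeth_ch", "start"):
            if (df[col].to_numpy() < 0).any():
                raise RecordValidationError(f"negative values in column {col}")
        unknown = set(map(str, df["chrom"].unique())) - set(self.genome.chromosomes)
        if unknown:
            raise RecordValidationError(
                f"chromosome(s) {sorted(unknown)} not in genome {self.genome.name!r}"
            )

    def with_records(self, records: pd.DataFrame, **kw) -> "SampleReadSet":
        return replace(self, records=records, **kw)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_per_read_table(path, genome: Optional[Genome] = None,
                        sample_id: Optional[str] = None) -> SampleReadSet:
    """Load a per-read methylation table (TSV, ``#`` comments, gzip ok).

    The header must declare ``read_id chrom start end n_cpg n_meth``;
    ``n_unmeth_ch`` is optional and defaults to 0.  Coordinates are 0-based
    half-open.  When ``genome`` is omitted, one is inferred from the observed
    maximal end coordinate per chromosome.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"read_id": str, "chrom": str})
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse per-read table: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "n_unmeth_ch" not in df.columns:
        df["n_unmeth_ch"] = 0
    for col in ("start", "end", "n_cpg", "n_meth", "n_unmeth_ch"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(f"{path}: non-integer value in column {col} at line {line}") from exc
    if genome is None:
        genome = Genome.from_intervals(df["chrom"], df["end"], name=f"inferred:{path.name}")
    rs = SampleReadSet(sample_id=sample_id or path.stem, records=df[COLUMNS].copy(),
                       genome=genome)
    rs.validate()
    return rs


def write_per_read_table(reads: SampleReadSet, path) -> None:
    """Write the canonical TSV (lossless round-trip with read_per_read_table)."""
    reads.records[COLUMNS].to_csv(path, sep="\t", index=False)


def write_bed(reads: SampleReadSet, path) -> None:
    """Write BED4 (chrom, start, end, read_id), sorted by chrom then start.

    Chromosomes sort in genome order so the output matches the bin scheme.
    """
    order = {c: i for i, c in enumerate(reads.genome.chromosomes)}
    df = reads.records[["chrom", "start", "end", "read_id"]].copy()
    df["_c"] = df["chrom"].map(order)
    df = df.sort_values(["_c", "start"], kind="stable").drop(columns="_c")
    df.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, genome: Optional[Genome] = None,
             sample_id: Optional[str] = None) -> SampleReadSet:
    """Load a BED4 file as a read set with no methylation information.

    ``n_cpg``/``n_meth`` are set to 0; such a set can be binned and CNV-called
    but not profiled or decontaminated.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "read_id"],
                     dtype={"chrom": str, "read_id": str})
    df["n_cpg"] = 0
    df["n_meth"] = 0
    df["n_unmeth_ch"] = 0
    if genome is None:
        genome = Genome.from_intervals(df["chrom"], df["end"], name=f"inferred:{path.name}")
    rs = SampleReadSet(sample_id=sample_id or path.stem, records=df[COLUMNS].copy(),
                       genome=genome)
    rs.validate()
    return rs


# ---------------------------------------------------------------------------
# QC rules
# ---------------------------------------------------------------------------

def conversion_filter(reads: SampleReadSet, max_unmeth_ch: int = 3) -> SampleReadSet:
    """Discard reads with more than ``max_unmeth_ch`` unmethylated CH cytosines.

    Incomplete bisulfite conversion leaves unconverted (apparently methylated)
    cytosines in non-CpG context; reads exceeding the ceiling are untrustworthy
    and removed.  The boundary is strict: exactly ``max_unmeth_ch`` is kept.
    """
    if max_unmeth_ch < 0:
        raise ParameterError("max_unmeth_ch must be >= 0")
    keep = reads.records["n_unmeth_ch"].to_numpy() <= max_unmeth_ch
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("conversion_filter: removed %d/%d reads (> %d unmethylated CH)",
                    n_drop, len(reads), max_unmeth_ch)
    return reads.with_records(reads.records.loc[keep].copy())


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    n_reads: int
    min_unique_reads: int
    passed: bool


def sample_qc(reads: SampleReadSet, min_unique_reads: int = 1_000_000) -> QCReport:
    """Sample-level QC: pass iff the read count strictly exceeds the floor.

    The rule is "more than" the floor, so exactly ``min_unique_reads`` fails.
    """
    n = len(reads)
    return QCReport(sample_id=reads.sample_id, n_reads=n,
                    min_unique_reads=min_unique_reads, passed=n > min_unique_reads)


def site_methylation_level(site_table: pd.DataFrame, min_cov: int = 4) -> float:
    """Genome-wide methylation level from a per-CpG-site count table.

    ``site_table`` needs columns ``coverage`` and ``methylated`` (reads per
    site).  Sites covered by fewer than ``min_cov`` reads are excluded
    ("covered by more than three reads" -> default 4); the level is the pooled
    ratio sum(methylated)/sum(coverage) over retained sites.
    """
    for col in ("coverage", "methylated"):
        if col not in site_table.columns:
            raise FormatError(f"site table missing column {col!r}")
    cov = site_table["coverage"].to_numpy()
    meth = site_table["methylated"].to_numpy()
    if (cov < 0).any() or (meth < 0).any() or (meth > cov).any():
        raise RecordValidationError("site table: counts must satisfy 0 <= methylated <= coverage")
    keep = cov >= min_cov
    total = int(cov[keep].sum())
    if total == 0:
        raise UndefinedLevelError(
            f"no CpG site with coverage >= {min_cov}; methylation level undefined"
        )
    return float(meth[keep].sum() / total)
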