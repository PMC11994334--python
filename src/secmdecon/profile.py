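"""Read-level methylation profiling.

The discriminating signal between blastocyst and contaminant DNA is the
*per-read* methylation fraction (methylated CpGs / CpGs on the read).
Because the blastocyst sits at the bottom of the preimplantation global
demethylation wave, roughly half of its CpG-containing reads are fully
unmethylated, versus ~12% for maternal cumulus cells — an ~4-fold ratio that
the decontamination filter exploits.

This module computes per-read fractions, a sample's methylation trichotomy
(fraction of CpG-containing reads at 0, strictly between 0 and 1, and at 1),
the CpG-count histogram, and enrichment factors between cell types.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedLevelError
from .records import PerReadRecord, SampleReadSet

#: CpG-count histogram buckets: reads with 0, 1, 2, 3 and >3 CpGs
CPG_BUCKETS = ("0", "1", "2", "3", ">3")


@dataclass(frozen=True)
class MethylationDistribution:
    """A sample's read-level methylation summary.

    The trichotomy (``f_zero``, ``f_partial``, ``f_full``) is over
    CpG-containing reads only; ``cpg_histogram`` is over all reads.
    """

    n_total_reads: int
    n_cpg_containing: int
    cpg_histogram: tuple  # fractions for CPG_BUCKETS
    f_zero: float
    f_partial: float
    f_full: float

    def __post_init__(self) -> None:
        assert abs(self.f_zero + self.f_partial + self.f_full - 1.0) < 1e-9
        assert abs(sum(self.cpg_histogram) - 1.0) < 1e-9
        assert self.n_cpg_containing <= self.n_total_reads

    def as_dict(self) -> dict:
        return {
            "n_total_reads": self.n_total_reads,
            "n_cpg_containing": self.n_cpg_containing,
            "cpg_histogram": dict(zip(CPG_BUCKETS, self.cpg_histogram)),
            "f_zero": self.f_zero,
            "f_partial": self.f_partial,
            "f_full": self.f_full,
        }


def per_read_fraction(record: PerReadRecord) -> float | None:
    """Methylation fraction mC/C of one read; None when the read has no CpG.

    A CpG-free read carries no methylation information: its fraction is
    undefined, never 0.0.
    """
    if record.n_cpg == 0:
        return None
    return record.n_meth / record.n_cpg


def per_read_fractions(reads: SampleReadSet) -> np.ndarray:
    """Vectorized mC/C for every record; NaN where n_cpg == 0."""
    n_cpg = reads.records["n_cpg"].to_numpy(dtype=float)
    n_meth = reads.records["n_meth"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_cpg > 0, n_meth / np.where(n_cpg > 0, n_cpg, 1), np.nan)
    return frac


def profile_sample(reads: SampleReadSet) -> MethylationDistribution:
    """Compute the methylation trichotomy and CpG-count histogram of a sample."""
    n_total = len(reads)
    if n_total == 0:
        raise UndefinedLevelError("empty read set: distribution undefined")
    n_cpg = reads.records["n_cpg"].to_numpy()
    n_meth = reads.records["n_meth"].to_numpy()

    hist_counts = [
        int((n_cpg == 0).sum()),
        int((n_cpg == 1).sum()),
        int((n_cpg == 2).sum()),
        int((n_cpg == 3).sum()),
        int((n_cpg > 3).sum()),
    ]
    cpg_histogram = tuple(c / n_total for c in hist_counts)

    has_cpg = n_cpg > 0
    n_info = int(has_cpg.sum())
    if n_info == 0:
        raise UndefinedLevelError("no CpG-containing reads: trichotomy undefined")
    zero = int(((n_meth == 0) & has_cpg).sum())
    full = int(((n_meth == n_cpg) & has_cpg).sum())
    partial = n_info - zero - full
    return MethylationDistribution(
        n_total_reads=n_total,
        n_cpg_containing=n_info,
        cpg_histogram=cpg_histogram,
        f_zero=zero / n_info,
        f_partial=partial / n_info,
        f_full=full / n_info,
    )


def enrichment_factor(f_zero_target: float, f_zero_contaminant: float) -> float:
    """Fold-enrichment of target over contaminant DNA under unmethylated-read
    selection: the ratio of their unmethylated-read fractions.

    E.g. blastocyst 0.47 vs cumulus 0.12 -> ~3.9, reported as ~4.
    """
    if f_zero_contaminant == 0:
        raise ParameterError("contaminant unmethylated fraction is 0: enrichment undefined")
    if not (0 < f_zero_target <= 1) or not (0 < f_zero_contaminant <= 1):
        raise ParameterError("unmethylated fractions must lie in (0, 1]")
    return f_zero_target / f_zero_contaminant


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed summary values are rounded.

    Python's builtin round() is banker's rounding; reported percentages and
    fold-changes use half-up.
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))
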