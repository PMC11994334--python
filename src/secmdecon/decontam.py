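"""The decontamination filter: keep multi-CpG, fully unmethylated reads.

Blastocyst DNA is globally hypomethylated, contaminating maternal (cumulus)
and paternal (sperm) DNA is hypermethylated.  Retaining only reads with at
least two CpGs and a per-read methylation level of exactly zero therefore
enriches embryonic DNA roughly 4-fold over cumulus DNA before copy-number
calling.

Note on CpG floors: sample *profiling* counts every read with >= 1 CpG,
while the default *filter* requires >= 2 CpGs ("CpG numbers greater than 1")
— a single-CpG read at 0 is weak evidence of hypomethylation.  Both floors
are exposed through :class:`FilterPolicy`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import ParameterError
from .records import SampleReadSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterPolicy:
    """Read-retention rule.

    min_cpg
        Minimum CpG count per read (default 2).
    max_fraction
        Per-read methylation ceiling, inclusive (default 0.0: strictly
        unmethylated reads only).  Setting e.g. 0.99 admits partially
        methylated reads, which raises read counts but weakens enrichment
        (~2-fold instead of ~4-fold versus cumulus DNA).
    """

    min_cpg: int = 2
    max_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.min_cpg < 1:
            raise ParameterError("min_cpg must be >= 1")
        if not (0.0 <= self.max_fraction < 1.0):
            raise ParameterError("max_fraction must lie in [0, 1)")


DEFAULT_POLICY = FilterPolicy()


def decontaminate(reads: SampleReadSet, policy: FilterPolicy = DEFAULT_POLICY) -> SampleReadSet:
    """Apply the unmethylated-read selection; order-preserving, idempotent.

    The fraction test uses exact integer arithmetic
    (``n_meth <= max_fraction * n_cpg``, which for the default ceiling of 0
    reduces to ``n_meth == 0``), avoiding float-equality pitfalls.

    An empty result is not an error: it is returned with an
    ``"empty_after_decontamination"`` entry in ``warnings`` and downstream
    CNV calling must handle it.
    """
    df = reads.records
    n_cpg = df["n_cpg"].to_numpy()
    n_meth = df["n_meth"].to_numpy()
    keep = (n_cpg >= policy.min_cpg) & (n_meth <= policy.max_fraction * n_cpg)
    out = reads.with_records(df.loc[keep].copy(), warnings=list(reads.warnings))
    retention = keep.mean() if len(df) else 0.0
    logger.info("decontaminate(%s): retained %d/%d reads (%.1f%%)",
                reads.sample_id, len(out), len(df), 100 * retention)
    if len(out) == 0:
        out.warnings.append("empty_after_decontamination")
    return out


def retention_fraction(before: SampleReadSet, after: SampleReadSet) -> float:
    if len(before) == 0:
        return 0.0
    return len(after) / len(before)
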