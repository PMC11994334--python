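"""Two-stage aneuploidy decision engine and the expected-signal model.

Decontamination raises aneuploidy sensitivity but, by discarding most reads,
also raises the false-positive rate.  The integrated rule exploits that a
genuine whole-chromosome CNV diluted by diploid contamination must already be
visible as a *mosaic-level* signal before decontamination: a chromosome is
called non-neutral only when its summary copy number crosses a permissive
pre-decontamination threshold pair (default 1.8&2.2) AND the full-CNV
post-decontamination threshold pair (1.5&2.5) in the same direction.

The closed-form expected-signal model quantifies the dilution arithmetic:
with contamination fraction c and per-read selection probabilities s_e
(embryo) and s_c (diploid contaminant), the expected summary of a
chromosome at embryonic copy number n is

    ((1-c) s_e n + 2 c s_c) / ((1-c) s_e + c s_c)

Raw data (s_e = s_c = 1) at c = 0.5 turns a 1&3 aneuploidy into 1.5&2.5 —
exactly at the regular detection limit; unmethylated-read selection
(s_e = 0.47, s_c = 0.12 against cumulus DNA) pushes it back out to 1.2&2.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnv import (
    BinScheme,
    CNVProfile,
    KaryotypeCall,
    ThresholdPair,
    bin_counts,
    call_karyotype,
    gc_correct,
    normalize_to_reference,
)
from .decontam import DEFAULT_POLICY, FilterPolicy, decontaminate
from .errors import LowQualityError, ParameterError
from .records import SampleReadSet, sample_qc

MODES = ("integrated", "decon_only", "pre_only")


@dataclass(frozen=True)
class DecisionConfig:
    """Configuration of the two-stage caller."""

    pre_thresholds: ThresholdPair = ThresholdPair(1.8, 2.2)
    post_thresholds: ThresholdPair = ThresholdPair(1.5, 2.5)
    filter_policy: FilterPolicy = DEFAULT_POLICY
    mode: str = "integrated"
    min_post_reads: int = 10_000

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")


def expected_mixture_cn(cn_embryo: float, c: float, s_embryo: float = 1.0,
                        s_contaminant: float = 1.0) -> float:
    """Expected summary copy number of an embryonic-CN ``cn_embryo`` chromosome
    in a mixture with a diploid contaminant.

    c is the contaminant read fraction; s_embryo / s_contaminant are the
    probabilities that a read of each source survives the selection step
    (1.0 for raw data; the cell types' unmethylated-read fractions after
    decontamination).
    """
    if not (0.0 <= c <= 1.0):
        raise ParameterError("c must lie in [0, 1]")
    if not (0.0 < s_embryo <= 1.0) or not (0.0 < s_contaminant <= 1.0):
        raise ParameterError("selection probabilities must lie in (0, 1]")
    denom = (1.0 - c) * s_embryo + c * s_contaminant
    if denom == 0:
        raise ParameterError("degenerate mixture: zero selected mass")
    return ((1.0 - c) * s_embryo * cn_embryo + c * s_contaminant * 2.0) / denom


def cnv_pipeline(reads: SampleReadSet, bins: BinScheme,
                 reference_counts: np.ndarray, flags=None) -> CNVProfile:
    """Counting -> GC lowess correction -> reference normalization."""
    counts = bin_counts(reads, bins)
    corrected, usable = gc_correct(counts, bins)
    return normalize_to_reference(corrected, reference_counts, bins,
                                  n_reads_used=len(reads), usable=usable,
                                  flags=flags)


def combine_states(pre_state: str, post_state: str, mode: str) -> str:
    """Merge per-chromosome stage states according to the decision mode.

    Integrated mode requires both stages to cross *in the same direction*;
    a pre-gain/post-loss (or vice versa) chromosome is never called.
    Undetermined at a required stage propagates.
    """
    if mode == "pre_only":
        return pre_state
    if mode == "decon_only":
        return post_state
    if "undetermined" in (pre_state, post_state):
        return "undetermined"
    if pre_state == post_state and pre_state in ("loss", "gain"):
        return pre_state
    return "neutral"


@dataclass
class AuditRecord:
    """Everything needed to reconstruct a call: both stage profiles, the
    read-retention bookkeeping and a per-chromosome rationale."""

    pre_profile: CNVProfile
    post_profile: CNVProfile | None
    pre_call: KaryotypeCall
    post_call: KaryotypeCall | None
    n_raw_reads: int
    n_post_reads: int
    retention: float
    rationale: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_raw_reads": self.n_raw_reads,
            "n_post_reads": self.n_post_reads,
            "retention": round(self.retention, 6),
            "pre_call": self.pre_call.as_dict(),
            "post_call": self.post_call.as_dict() if self.post_call else None,
            "rationale": self.rationale,
        }


def integrated_call(raw_reads: SampleReadSet, bins: BinScheme,
                    reference_counts: np.ndarray,
                    config: DecisionConfig = DecisionConfig(),
                    enforce_qc: bool = False) -> tuple[KaryotypeCall, AuditRecord]:
    """Run the two-stage caller on raw per-read data.

    Returns the final karyotype call plus an audit record holding both stage
    profiles — the before/after comparison is the clinically interpretable
    output, so it is always produced.

    ``enforce_qc=True`` additionally requires the raw sample to pass the
    1-million-unique-reads floor.
    """
    if enforce_qc:
        report = sample_qc(raw_reads)
        if not report.passed:
            raise LowQualityError(
                f"sample {raw_reads.sample_id} fails QC: "
                f"{report.n_reads} <= {report.min_unique_reads} unique reads")

    pre_profile = cnv_pipeline(raw_reads, bins, reference_counts)
    pre_call = call_karyotype(pre_profile, config.pre_thresholds)

    post_reads = decontaminate(raw_reads, config.filter_policy)
    retention = len(post_reads) / len(raw_reads) if len(raw_reads) else 0.0
    flags: list = []
    post_profile = None
    post_call = None
    if config.mode != "pre_only":
        if len(post_reads) == 0:
            raise LowQualityError("no reads survive decontamination; cannot run post stage")
        if len(post_reads) < config.min_post_reads:
            flags.append("low_confidence_post_stage")
        post_profile = cnv_pipeline(post_reads, bins, reference_counts,
                                    flags=["post_decontamination"])
        post_call = call_karyotype(post_profile, config.post_thresholds)

    genome = raw_reads.genome
    states = {}
    rationale = {}
    for chrom in genome.autosomes:
        ps = pre_call.states[chrom]
        qs = post_call.states[chrom] if post_call else "undetermined"
        final = combine_states(ps, qs, config.mode)
        states[chrom] = final
        if final != "neutral" or ps != "neutral" or (post_call and qs != "neutral"):
            rationale[chrom] = {
                "pre_cn": _r(pre_call.summaries.get(chrom)),
                "pre_state": ps,
                "post_cn": _r(post_call.summaries.get(chrom)) if post_call else None,
                "post_state": qs if post_call else None,
                "final": final,
            }

    # sex and sex-dosage verdict come from the stage the mode trusts
    sex_call = post_call if config.mode != "pre_only" else pre_call
    summaries = sex_call.summaries
    sex = sex_call.sex
    sex_anomaly = "sex_chromosome_dosage_anomaly" in sex_call.flags
    autosomal_hit = any(s in ("loss", "gain") for s in states.values())
    ploidy = "aneuploid" if (autosomal_hit or sex_anomaly) else "euploid"
    flags = flags + [f for f in sex_call.flags if f != "post_decontamination"]

    final_call = KaryotypeCall(states=states, summaries=summaries, sex=sex,
                               ploidy=ploidy, flags=flags)
    audit = AuditRecord(pre_profile=pre_profile, post_profile=post_profile,
                        pre_call=pre_call, post_call=post_call,
                        n_raw_reads=len(raw_reads), n_post_reads=len(post_reads),
                        retention=retention, rationale=rationale)
    return final_call, audit


def _r(v):
    return None if v is None or not np.isfinite(v) else round(float(v), 4)
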