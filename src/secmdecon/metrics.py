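"""Concordance statistics between medium-based calls and biopsy truth.

The four clinical rates compare the ploidy/sex classification obtained from
spent-medium cfDNA (SECM) against the trophectoderm (TE) biopsy taken as
the gold standard:

    GCR = (both euploid + both aneuploid) / all samples
    FNR = (SECM euploid, TE aneuploid) / all TE-aneuploid
    FPR = (SECM aneuploid, TE euploid) / all TE-euploid
    SDR = (SECM female, TE male) / all TE-male

plus per-chromosome sensitivity/specificity for simulation benchmarks and a
Wald binomial confidence interval (clipped to [0, 1]) matching the printed
intervals of the clinical rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .errors import UndefinedLevelError

#: two-sided 95% normal quantile
_Z95 = 1.959964


@dataclass(frozen=True)
class ConcordanceTable:
    """Joint SECM-vs-TE classification counts.

    Ploidy 2x2: n_ee (both euploid), n_ea (SECM euploid / TE aneuploid,
    the false negatives), n_ae (SECM aneuploid / TE euploid, the false
    positives), n_aa (both aneuploid).  Sex 2x2 analogously with f=female,
    m=male (n_fm are the contamination-driven sex discordances).
    """

    n_ee: int = 0
    n_ea: int = 0
    n_ae: int = 0
    n_aa: int = 0
    n_ff: int = 0
    n_fm: int = 0
    n_mf: int = 0
    n_mm: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ee", "n_ea", "n_ae", "n_aa", "n_ff", "n_fm", "n_mf", "n_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_ploidy(self) -> int:
        return self.n_ee + self.n_ea + self.n_ae + self.n_aa


def gcr(t: ConcordanceTable) -> float:
    """General concordance rate: fraction of samples classified identically."""
    if t.total_ploidy == 0:
        raise UndefinedLevelError("GCR undefined: no classified samples")
    return (t.n_ee + t.n_aa) / t.total_ploidy


def fnr(t: ConcordanceTable) -> float:
    """False-negative rate among biopsy-aneuploid samples."""
    denom = t.n_ea + t.n_aa
    if denom == 0:
        raise UndefinedLevelError("FNR undefined: no TE-aneuploid samples")
    return t.n_ea / denom


def fpr(t: ConcordanceTable) -> float:
    """False-positive rate among biopsy-euploid samples."""
    denom = t.n_ae + t.n_ee
    if denom == 0:
        raise UndefinedLevelError("FPR undefined: no TE-euploid samples")
    return t.n_ae / denom


def sdr(t: ConcordanceTable) -> float:
    """Sex-discordance rate: female-by-SECM among biopsy-male samples."""
    denom = t.n_fm + t.n_mm
    if denom == 0:
        raise UndefinedLevelError("SDR undefined: no TE-male samples")
    return t.n_fm / denom


def sens_spec(calls: Iterable[tuple]) -> tuple[Optional[float], Optional[float]]:
    """Sensitivity and specificity over (truth, prediction) karyotype pairs.

    ``truth`` and ``prediction`` each expose per-chromosome states via a
    ``states`` mapping plus a ``ploidy`` field (KaryotypeCall works; for
    truth, a simulated Karyotype can be adapted with
    :func:`karyotype_truth_states`).  An aneuploid prediction counts as a
    true positive only when every truly non-neutral chromosome is called
    with the matching direction — a gain called on the wrong chromosome is
    not a detection.

    Returns None for a metric whose class is empty.
    """
    tp = fn = tn = fp = 0
    for truth, pred in calls:
        true_hits = {c: s for c, s in truth.states.items() if s in ("loss", "gain")}
        if true_hits:
            correct = all(pred.states.get(c) == s for c, s in true_hits.items())
            if correct:
                tp += 1
            else:
                fn += 1
        else:
            pred_hit = any(s in ("loss", "gain") for s in pred.states.values())
            if pred_hit:
                fp += 1
            else:
                tn += 1
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return sens, spec


@dataclass(frozen=True)
class TruthStates:
    """Adapter giving a simulated Karyotype the states/ploidy surface."""

    states: dict
    ploidy: str


def karyotype_truth_states(karyotype, genome) -> TruthStates:
    """Expand a simulated karyotype into per-autosome truth states."""
    states = {}
    for chrom in genome.autosomes:
        cn = karyotype.copy_number(chrom)
        states[chrom] = "neutral" if cn == 2 else ("gain" if cn > 2 else "loss")
    hit = any(s != "neutral" for s in states.values())
    return TruthStates(states=states, ploidy="aneuploid" if hit else "euploid")


def binomial_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wald binomial confidence interval, clipped to [0, 1].

    p_hat +/- z * sqrt(p_hat (1 - p_hat) / n).  Simple and matches how the
    clinical rate intervals are reported; degenerate at p_hat in {0, 1}
    (interval collapses to the point), where Wilson or Clopper-Pearson would
    be wider.  Only conf=0.95 is supported.
    """
    if n < 1:
        raise UndefinedLevelError("binomial CI undefined for n = 0")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if abs(conf - 0.95) > 1e-12:
        raise ValueError("only 95% intervals are supported")
    p = k / n
    half = _Z95 * (p * (1 - p) / n) ** 0.5
    return (max(0.0, p - half), min(1.0, p + half))
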