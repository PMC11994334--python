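"""Read-count copy-number calling (Ginkgo-style, whole-chromosome endpoint).

Pipeline: assign read starts to genomic bins, remove GC bias with a lowess
fit of count against bin GC fraction, normalize against a diploid reference
count profile (diploid baseline CN = 2), summarize each chromosome by the
median of its bin values, and call loss/neutral/gain states against a
threshold pair such as 1.5&2.5 (loss when CN <= 1.5, gain when CN >= 2.5).

The per-chromosome median replaces segmentation: whole-chromosome aneuploidy
is the clinical endpoint here, and the median is robust to the bin-level
noise that dominates shallow post-decontamination read sets.  Segmental and
mosaic sub-chromosomal events are out of scope; a segmentation hook can be
layered on the per-bin profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .errors import FormatError, LowQualityError, ParameterError
from .genome import Genome
from .records import SampleReadSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Bin scheme
# ---------------------------------------------------------------------------

@dataclass
class BinScheme:
    """Ordered, non-overlapping genomic bins with GC fractions.

    ``table`` columns: chrom, start, end, gc, blacklist (bool).  Bins are
    sorted by genome chromosome order then start; blacklisted bins never
    receive counts and are excluded from normalization.
    """

    table: pd.DataFrame
    genome: Genome

    def __post_init__(self) -> None:
        t = self.table
        for col in ("chrom", "start", "end", "gc"):
            if col not in t.columns:
                raise FormatError(f"bin table missing column {col!r}")
        if "blacklist" not in t.columns:
            t = t.assign(blacklist=False)
        bad_gc = (t["gc"] < 0) | (t["gc"] > 1)
        if bad_gc.any():
            raise ParameterError("gc fractions must lie in [0, 1]")
        for chrom, sub in t.groupby("chrom", observed=True, sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if (s >= e).any():
                raise ParameterError(f"{chrom}: bin with start >= end")
            if (s[1:] < e[:-1]).any():
                raise ParameterError(f"{chrom}: bins overlap or are unsorted")
            if str(chrom) not in self.genome:
                raise ParameterError(f"bin chromosome {chrom} not in genome")
            if e[-1] > self.genome.length(str(chrom)):
                raise ParameterError(f"{chrom}: bin exceeds chromosome length")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def lengths(self) -> np.ndarray:
        return (self.table["end"] - self.table["start"]).to_numpy()

    @property
    def usable(self) -> np.ndarray:
        return ~self.table["blacklist"].to_numpy()

    def autosomal_mask(self) -> np.ndarray:
        autos = set(self.genome.autosomes)
        return np.array([str(c) in autos for c in self.chroms])

    def to_bed(self, path) -> None:
        self.table[["chrom", "start", "end", "gc"]].to_csv(
            path, sep="\t", index=False, header=False)

    @classmethod
    def from_bed(cls, path, genome: Genome) -> "BinScheme":
        """Load variable-length bins from BED (4th column = GC fraction,
        optional 5th column = blacklist flag 0/1)."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
        if df.shape[1] < 4:
            raise FormatError(f"{path}: bin BED needs >= 4 columns (chrom,start,end,gc)")
        df = df.iloc[:, :5] if df.shape[1] >= 5 else df.iloc[:, :4]
        df.columns = ["chrom", "start", "end", "gc"][: df.shape[1] if df.shape[1] < 5 else 4] + (
            ["blacklist"] if df.shape[1] == 5 else [])
        if "blacklist" in df.columns:
            df["blacklist"] = df["blacklist"].astype(bool)
        df["chrom"] = df["chrom"].astype(str)
        return cls(table=df, genome=genome)


def make_bins(genome: Genome, bin_size: int = 20_000, gc_seed: int = 0) -> BinScheme:
    """Tile the genome with fixed-size bins carrying synthetic GC fractions.

    20 kb bins on the 50x-scaled genome correspond to the ~1 Mb variable
    bins used on the full genome (~3100 bins in total).  GC is a smooth
    gradient along the genome plus Gaussian noise, giving the GC-correction
    step realistic covariate structure.
    """
    if bin_size < 1:
        raise ParameterError("bin_size must be >= 1")
    rows = []
    for chrom in genome.chromosomes:
        L = genome.length(chrom)
        starts = np.arange(0, L, bin_size)
        ends = np.minimum(starts + bin_size, L)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    table = pd.concat(rows, ignore_index=True)
    rng = np.random.default_rng(gc_seed)
    t = np.linspace(0.0, 1.0, len(table))
    gc = 0.35 + 0.10 * t + rng.normal(0.0, 0.02, size=len(table))
    table["gc"] = np.clip(gc, 0.25, 0.65)
    table["blacklist"] = False
    return BinScheme(table=table, genome=genome)


def inject_gc_bias(counts: np.ndarray, bins: BinScheme, slope: float = 1.0) -> np.ndarray:
    """Multiply counts by a linear function of bin GC (simulator hook).

    Gives gc_correct a known bias to remove; the factor is clipped at 0.05
    to stay positive.
    """
    gc = bins.table["gc"].to_numpy()
    factor = np.clip(1.0 + slope * (gc - gc.mean()), 0.05, None)
    return counts * factor


# ---------------------------------------------------------------------------
# Counting and correction
# ---------------------------------------------------------------------------

def bin_counts(reads: Union[SampleReadSet, pd.DataFrame], bins: BinScheme) -> np.ndarray:
    """Per-bin read counts: a read belongs to the bin containing its start.

    Intervals are half-open, so a read starting exactly on a boundary goes
    to the bin beginning there.  Reads on chromosomes absent from the bin
    scheme raise; reads falling in gaps between bins (variable schemes) are
    dropped.  Blacklisted bins receive no counts.
    """
    df = reads.records if isinstance(reads, SampleReadSet) else reads
    counts = np.zeros(len(bins), dtype=np.int64)
    bt = bins.table
    bin_chrom_set = set(map(str, pd.unique(bt["chrom"])))
    offsets = {}
    pos = {}
    for chrom, sub in bt.groupby("chrom", observed=True, sort=False):
        offsets[str(chrom)] = sub.index.to_numpy()
        pos[str(chrom)] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    for chrom, sub in df.groupby("chrom", observed=True, sort=False):
        chrom = str(chrom)
        if len(sub) == 0:
            continue
        if chrom not in bin_chrom_set:
            raise ParameterError(f"reads on {chrom} but bin scheme has no such chromosome")
        starts, ends = pos[chrom]
        rs = sub["start"].to_numpy()
        idx = np.searchsorted(starts, rs, side="right") - 1
        ok = (idx >= 0) & (rs < ends[np.clip(idx, 0, None)])
        local = np.bincount(idx[ok], minlength=len(starts))
        counts[offsets[chrom]] += local
    counts[~bins.usable] = 0
    return counts


def gc_correct(counts: np.ndarray, bins: BinScheme, frac: float = 0.3,
               it: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Remove GC-content bias with a lowess fit of count vs GC.

    Returns ``(corrected, usable)``.  The fit uses span ``frac`` with ``it``
    robustifying iterations over usable bins; each count is divided by its
    fitted value and the result rescaled so the mean count over usable bins
    is preserved exactly.  Bins with a non-positive fitted value are flagged
    unusable rather than divided.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) != len(bins):
        raise ParameterError("counts length does not match bin scheme")
    usable = bins.usable.copy()
    if usable.sum() < 20:
        raise LowQualityError(f"gc_correct needs >= 20 usable bins, have {int(usable.sum())}")
    gc = bins.table["gc"].to_numpy()
    fit = _lowess(counts[usable], gc[usable], frac=frac, it=it, return_sorted=False)
    corrected = np.full_like(counts, np.nan)
    good = fit > 0
    if not good.all():
        logger.warning("gc_correct: %d bin(s) with non-positive lowess fit flagged unusable",
                       int((~good).sum()))
    u_idx = np.flatnonzero(usable)
    ratio = counts[u_idx[good]] / fit[good]
    scale = counts[u_idx[good]].mean() / ratio.mean() if ratio.mean() > 0 else 1.0
    corrected[u_idx[good]] = ratio * scale
    usable[u_idx[~good]] = False
    return corrected, usable


# ---------------------------------------------------------------------------
# Normalization and calling
# ---------------------------------------------------------------------------

@dataclass
class CNVProfile:
    """Per-bin copy-number values (diploid baseline 2; NaN = unusable bin)."""

    bins: BinScheme
    cn: np.ndarray
    n_reads_used: int
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.cn) != len(self.bins):
            raise ParameterError("cn length does not match bin scheme")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.cn) < 0 if np.isfinite(self.cn).any() else False:
                raise ParameterError("copy-number values must be >= 0")

    def as_frame(self) -> pd.DataFrame:
        out = self.bins.table[["chrom", "start", "end"]].copy()
        out["cn"] = self.cn
        return out


def normalize_to_reference(sample_counts: np.ndarray, reference_counts: np.ndarray,
                           bins: BinScheme, n_reads_used: Optional[int] = None,
                           usable: Optional[np.ndarray] = None,
                           flags: Optional[list] = None,
                           min_expected_reads: float = 1.0) -> CNVProfile:
    """Turn GC-corrected counts into copy numbers against a diploid reference.

    cn_i = 2 * (sample_i / S) / (reference_i / R), where S and R sum sample
    and reference counts over usable *autosomal* bins (normalization mass
    excludes sex chromosomes so sample sex does not shift the baseline);
    sex-chromosome bins are scaled with the same factor and their dosage is
    read off the result.  Bins with zero reference count are flagged
    unusable (NaN), as are low-coverage bins whose expected sample count is
    below ``min_expected_reads``.
    """
    s = np.asarray(sample_counts, dtype=float)
    r = np.asarray(reference_counts, dtype=float)
    if len(s) != len(bins) or len(r) != len(bins):
        raise ParameterError("count vectors must match the bin scheme")
    usable = (bins.usable if usable is None else usable.copy()) & np.isfinite(s) & np.isfinite(r)
    zero_ref = usable & (r <= 0)
    if zero_ref.any():
        logger.warning("normalize: %d bin(s) with zero reference count flagged unusable",
                       int(zero_ref.sum()))
        usable &= r > 0
    auto = bins.autosomal_mask() & usable
    S = s[auto].sum()
    R = r[auto].sum()
    if S <= 0 or R <= 0:
        raise LowQualityError("no usable autosomal counts to normalize on")
    cn = np.full(len(bins), np.nan)
    cn[usable] = 2.0 * (s[usable] / S) / (r[usable] / R)
    flags = list(flags or [])
    expected = S * (r / R)
    low = usable & (expected < min_expected_reads)
    if low.any():
        flags.append("low_coverage_bins")
    n_used = int(n_reads_used if n_reads_used is not None else s[usable].sum())
    if n_used < 10_000 and "low_coverage" not in flags:
        flags.append("low_coverage")
    return CNVProfile(bins=bins, cn=cn, n_reads_used=n_used, flags=flags)


def chromosome_summary(profile: CNVProfile, min_bins: int = 5) -> pd.Series:
    """Median bin copy number per chromosome; NaN below ``min_bins`` usable bins."""
    chroms = profile.bins.genome.chromosomes
    out = {}
    bc = profile.bins.chroms
    for chrom in chroms:
        vals = profile.cn[np.asarray([str(c) == chrom for c in bc])]
        vals = vals[np.isfinite(vals)]
        out[chrom] = float(np.median(vals)) if len(vals) >= min_bins else np.nan
    return pd.Series(out, name="cn")


@dataclass(frozen=True)
class ThresholdPair:
    """Loss/gain calling thresholds, written L&G in the clinical shorthand.

    Inclusive on both sides: CN <= loss is a loss, CN >= gain is a gain, so
    the printed boundary values act as detection limits (a 50%-diluted full
    aneuploidy sitting exactly at 1.5 or 2.5 is still callable).
    """

    loss: float
    gain: float

    def __post_init__(self) -> None:
        if not (0 < self.loss < 2 < self.gain):
            raise ParameterError(f"need 0 < loss < 2 < gain, got {self.loss}&{self.gain}")

    def state(self, cn: float) -> str:
        if not np.isfinite(cn):
            return "undetermined"
        if cn <= self.loss:
            return "loss"
        if cn >= self.gain:
            return "gain"
        return "neutral"

    def __str__(self) -> str:
        return f"{self.loss:g}&{self.gain:g}"


@dataclass
class KaryotypeCall:
    """Final per-chromosome states, sex call and ploidy verdict."""

    states: dict          # chrom -> loss/neutral/gain/undetermined (autosomes)
    summaries: dict       # chrom -> summary CN (may be NaN)
    sex: str              # XX / XY / undetermined
    ploidy: str           # euploid / aneuploid
    flags: list = field(default_factory=list)

    @property
    def aneuploid_chromosomes(self) -> list:
        return [c for c, s in self.states.items() if s in ("loss", "gain")]

    def as_dict(self) -> dict:
        return {
            "states": dict(self.states),
            "summaries": {c: (None if not np.isfinite(v) else round(float(v), 4))
                          for c, v in self.summaries.items()},
            "sex": self.sex,
            "ploidy": self.ploidy,
            "aneuploid_chromosomes": self.aneuploid_chromosomes,
            "flags": list(self.flags),
        }


def call_karyotype(profile: CNVProfile, thresholds: ThresholdPair,
                   min_bins: int = 5, min_autosomes: int = 20) -> KaryotypeCall:
    """Threshold the per-chromosome summaries into a karyotype call.

    Sex rule: XY when the chrY summary is >= 0.5 and chrX lies in [0.5, 1.5];
    XX when chrY < 0.5 and chrX >= 1.5; otherwise undetermined (treated as a
    sex-chromosome dosage anomaly when both summaries are defined).
    """
    summ = chromosome_summary(profile, min_bins=min_bins)
    genome = profile.bins.genome
    states = {}
    callable_autosomes = 0
    for chrom in genome.autosomes:
        cn = summ.get(chrom, np.nan)
        states[chrom] = thresholds.state(cn)
        if np.isfinite(cn):
            callable_autosomes += 1
    if callable_autosomes < min_autosomes:
        raise LowQualityError(
            f"only {callable_autosomes} callable autosomes (< {min_autosomes})")
    x = summ.get("chrX", np.nan)
    y = summ.get("chrY", np.nan)
    sex = "undetermined"
    sex_anomaly = False
    if np.isfinite(x) and np.isfinite(y):
        if y >= 0.5 and 0.5 <= x <= 1.5:
            sex = "XY"
        elif y < 0.5 and x >= 1.5:
            sex = "XX"
        else:
            sex_anomaly = True
    autosomal_hit = any(s in ("loss", "gain") for s in states.values())
    ploidy = "aneuploid" if (autosomal_hit or sex_anomaly) else "euploid"
    flags = list(profile.flags)
    if sex_anomaly:
        flags.append("sex_chromosome_dosage_anomaly")
    return KaryotypeCall(states=states, summaries=summ.to_dict(), sex=sex,
                         ploidy=ploidy, flags=flags)


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

def plot_profile(profile: CNVProfile, path, title: str = "",
                 thresholds: Optional[ThresholdPair] = None) -> None:
    """CNV line plot: per-bin copy number along the genome with chromosome
    boundaries, plus optional threshold guides."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(14, 3.5))
    x = np.arange(len(profile.bins))
    ax.plot(x, profile.cn, ".", ms=2, color="steelblue")
    bc = [str(c) for c in profile.bins.chroms]
    bounds = [i for i in range(1, len(bc)) if bc[i] != bc[i - 1]]
    for b in bounds:
        ax.axvline(b, color="0.85", lw=0.5)
    summ = chromosome_summary(profile)
    starts = [0] + bounds + [len(bc)]
    for i, chrom in enumerate(dict.fromkeys(bc)):
        lo, hi = starts[i], starts[i + 1]
        v = summ.get(chrom, np.nan)
        if np.isfinite(v):
            ax.hlines(v, lo, hi, color="crimson", lw=1.5)
        ax.text((lo + hi) / 2, 4.6, chrom.replace("chr", ""),
                ha="center", fontsize=6)
    ax.axhline(2, color="0.4", lw=0.8, ls="--")
    if thresholds is not None:
        ax.axhline(thresholds.loss, color="orange", lw=0.8, ls=":")
        ax.axhline(thresholds.gain, color="orange", lw=0.8, ls=":")
    ax.set_ylim(0, 5)
    ax.set_ylabel("copy number")
    ax.set_xlabel("bin")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
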