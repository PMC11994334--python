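"""Contamination simulator: synthetic per-read methylation data.

Generates read sets whose read-level methylation trichotomy, CpG-count
histogram and chromosomal read density emulate the measured cell types of
the niPGT-A setting (blastocyst/SECM, cumulus cells, sperm, MII oocytes as a
polar-body proxy), and mixes two samples at a stated contamination fraction
by subsampling reads without replacement — the same in-silico protocol used
to benchmark decontamination on samples with known truth.

What is emulated: the per-read trichotomy (0 / partial / fully methylated),
the CpG-per-read histogram, uniform read placement with density proportional
to chromosome length x copy number, and an optional multiplicative GC bias
on bin counts.  What is not: sequence content, sequencing error, alignment
artifacts, and any regional (locus-specific) methylation structure — reads
are exchangeable within a cell type, so results on synthetic data bound what
positional methylation heterogeneity in real data can add, not replace it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import InsufficientReadsError, ParameterError
from .genome import Genome
from .records import COLUMNS, SampleReadSet

# ---------------------------------------------------------------------------
# Cell-type signatures
# ---------------------------------------------------------------------------

#: CpG-count histogram shared by blastocyst-representative samples and
#: cumulus cells (fractions of reads with 0/1/2/3/>3 CpGs); ~70% of reads
#: carry at least one CpG.
_DEFAULT_CPG_HIST = (0.30, 0.24, 0.15, 0.09, 0.19)
#: sperm reads carry slightly fewer CpGs (~65% with >= 1).
_SPERM_CPG_HIST = (0.35, 0.23, 0.14, 0.08, 0.20)


def _norm(v) -> tuple:
    a = np.asarray(v, dtype=float)
    if (a < 0).any() or a.sum() <= 0:
        raise ParameterError("distribution entries must be nonnegative with positive sum")
    return tuple(a / a.sum())


@dataclass(frozen=True)
class CellTypeSignature:
    """Generative parameters for one cell type.

    f_zero/f_partial/f_full: target trichotomy over CpG-containing reads.
    partial_alpha/partial_beta: Beta parameters of the within-(0,1) per-read
    methylation level (default Beta(0.5, 0.5), reflecting the bimodal
    per-read landscape).
    cpg_histogram: fractions of reads with 0/1/2/3/>3 CpGs (renormalized).
    tail_p: success parameter of the truncated geometric on 4..12 used for
    the ">3 CpGs" bucket.
    genome_level: expected genome-wide methylation level (for reporting).
    """

    name: str
    f_zero: float
    f_partial: float
    f_full: float
    cpg_histogram: tuple = _DEFAULT_CPG_HIST
    partial_alpha: float = 0.5
    partial_beta: float = 0.5
    tail_p: float = 0.45
    genome_level: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpg_histogram", _norm(self.cpg_histogram))
        tri = _norm((self.f_zero, self.f_partial, self.f_full))
        object.__setattr__(self, "f_zero", tri[0])
        object.__setattr__(self, "f_partial", tri[1])
        object.__setattr__(self, "f_full", tri[2])
        if not (0.0 <= self.genome_level <= 1.0):
            raise ParameterError("genome_level must lie in [0, 1]")


def builtin_signatures() -> dict[str, CellTypeSignature]:
    """Registry of the measured cell-type signatures.

    Trichotomies (0% / 1-99% / 100% of CpG-containing reads):
    blastocyst 47/11/42 (the SECM column; ICM and TE are within 1-3 points
    and available as presets), cumulus 12/14/74, sperm 20/8/72, MII oocyte
    38/14/48 (only the unmethylated fraction is measured for oocytes; the
    remainder is split so the genome level sits between blastocyst and
    cumulus — a documented assumption).
    """
    sig = {
        "blastocyst": CellTypeSignature("blastocyst", 0.47, 0.11, 0.42, genome_level=0.29),
        "icm": CellTypeSignature("icm", 0.50, 0.12, 0.39, genome_level=0.24),
        "te": CellTypeSignature("te", 0.50, 0.11, 0.38, genome_level=0.24),
        "cumulus": CellTypeSignature("cumulus", 0.12, 0.14, 0.74, genome_level=0.71),
        "sperm": CellTypeSignature("sperm", 0.20, 0.08, 0.72,
                                   cpg_histogram=_SPERM_CPG_HIST, genome_level=0.82),
        "mii_oocyte": CellTypeSignature("mii_oocyte", 0.38, 0.14, 0.48, genome_level=0.50),
    }
    return sig


# ---------------------------------------------------------------------------
# Karyotypes
# ---------------------------------------------------------------------------

_KARYO_TOKEN = re.compile(r"^([+-])(chr)?(\d{1,2}|X|Y)$")


@dataclass(frozen=True)
class Karyotype:
    """Per-chromosome copy numbers; autosomes default to 2, sex chromosomes
    follow ``sex`` (XX: X=2 Y=0; XY: X=1 Y=1) unless overridden in ``cn``."""

    sex: str = "XX"
    cn: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("XX", "XY"):
            raise ParameterError(f"sex must be 'XX' or 'XY', got {self.sex!r}")
        for chrom, n in self.cn.items():
            if n < 0:
                raise ParameterError(f"copy number of {chrom} must be >= 0")

    def copy_number(self, chrom: str) -> int:
        if chrom in self.cn:
            return int(self.cn[chrom])
        if chrom == "chrX":
            return 2 if self.sex == "XX" else 1
        if chrom == "chrY":
            return 1 if self.sex == "XY" else 0
        return 2

    @classmethod
    def from_string(cls, spec: str) -> "Karyotype":
        """Parse strings like ``"+22,XX"`` or ``"-16,+18,XY"`` (``+`` = trisomy,
        ``-`` = monosomy); an empty alteration list means euploid."""
        sex = "XX"
        cn: dict[str, int] = {}
        for token in filter(None, (t.strip() for t in spec.split(","))):
            if token in ("XX", "XY"):
                sex = token
                continue
            m = _KARYO_TOKEN.match(token)
            if not m:
                raise ParameterError(f"cannot parse karyotype token {token!r}")
            sign, _, name = m.groups()
            chrom = f"chr{name}"
            base = 2  # alteration applies to the autosomal baseline
            cn[chrom] = base + (1 if sign == "+" else -1)
        return cls(sex=sex, cn=cn)

    @classmethod
    def euploid(cls, sex: str = "XX") -> "Karyotype":
        return cls(sex=sex)

    @classmethod
    def reference_diploid(cls) -> "Karyotype":
        """Computational reference baseline: CN 2 on *every* chromosome,
        including X and Y, so normalized profiles read sex-chromosome dosage
        on an absolute scale (XY sample -> X~1, Y~1; XX -> X~2, Y~0)."""
        return cls(sex="XX", cn={"chrX": 2, "chrY": 2})


@dataclass(frozen=True)
class MixtureSpec:
    """A planned contamination mixture (for record-keeping / CLI)."""

    contaminant_name: str
    contamination_fraction: float
    n_total: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.contamination_fraction <= 1.0):
            raise ParameterError("contamination fraction must lie in [0, 1]")
        if self.n_total < 1:
            raise ParameterError("n_total must be >= 1")


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def generate_reads(signature: CellTypeSignature, karyotype: Karyotype, n: int,
                   genome: Genome, seed: Optional[int] = None,
                   read_length: int = 100,
                   sample_id: Optional[str] = None) -> SampleReadSet:
    """Draw ``n`` synthetic reads for one cell type and karyotype.

    Chromosome of each read is drawn with probability proportional to
    chromosome length x copy number; position is uniform within the
    chromosome.  Whether a read carries CpGs follows the signature's
    histogram; for CpG-containing reads the methylation state is drawn from
    the trichotomy and then the CpG count from the histogram conditional on
    the state (partially methylated reads need >= 2 CpGs), so the realized
    trichotomy is exactly multinomial at the target fractions while the
    marginal CpG histogram is only approximately preserved.  Partial reads
    place their methylated-CpG count via a Beta(alpha, beta) level.
    Deterministic under a fixed seed.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    for chrom in karyotype.cn:
        if chrom not in genome:
            raise ParameterError(f"karyotype names {chrom}, absent from genome {genome.name!r}")
    rng = np.random.default_rng(seed)
    chroms = genome.chromosomes
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    copy = np.array([karyotype.copy_number(c) for c in chroms], dtype=float)
    weights = lengths * copy
    if weights.sum() <= 0:
        raise ParameterError("karyotype has zero total copy-weighted length")
    p = weights / weights.sum()

    ci = rng.choice(len(chroms), size=n, p=p)
    pos = np.floor(rng.random(n) * lengths[ci]).astype(np.int64)
    end = np.minimum(pos + read_length, lengths[ci].astype(np.int64))
    # a read touching the chromosome end still needs start < end
    pos = np.minimum(pos, end - 1)

    h = np.asarray(signature.cpg_histogram)
    has_cpg = rng.random(n) < (1.0 - h[0])
    n_info = int(has_cpg.sum())

    n_cpg = np.zeros(n, dtype=np.int16)
    n_meth = np.zeros(n, dtype=np.int16)
    if n_info:
        state = rng.choice(3, size=n_info,
                           p=[signature.f_zero, signature.f_partial, signature.f_full])
        # CpG count conditional on >= 1 (>= 2 for partial reads)
        p_ge1 = _norm(h[1:])
        cat = rng.choice(4, size=n_info, p=p_ge1)  # 0..3 -> 1,2,3,>3 CpGs
        redraw = (state == 1) & (cat == 0)
        if redraw.any():
            p_ge2 = _norm(h[2:])
            cat[redraw] = 1 + rng.choice(3, size=int(redraw.sum()), p=p_ge2)
        cpg = np.where(cat < 3, cat + 1, 0).astype(np.int16)
        tail = cat == 3
        if tail.any():
            cpg[tail] = _truncated_geometric(rng, int(tail.sum()), signature.tail_p)
        meth = np.zeros(n_info, dtype=np.int16)
        full = state == 2
        meth[full] = cpg[full]
        part = state == 1
        if part.any():
            level = rng.beta(signature.partial_alpha, signature.partial_beta,
                             size=int(part.sum()))
            m = 1 + np.floor(level * (cpg[part] - 1)).astype(np.int16)
            meth[part] = np.clip(m, 1, cpg[part] - 1)
        n_cpg[has_cpg] = cpg
        n_meth[has_cpg] = meth

    df = pd.DataFrame({
        "read_id": np.arange(n, dtype=np.int64),
        "chrom": pd.Categorical.from_codes(ci, categories=chroms),
        "start": pos,
        "end": end,
        "n_cpg": n_cpg,
        "n_meth": n_meth,
        "n_unmeth_ch": np.zeros(n, dtype=np.int16),
    })
    sid = sample_id or f"{signature.name}-sim"
    return SampleReadSet(sample_id=sid, records=df, genome=genome)


def _truncated_geometric(rng: np.random.Generator, size: int, p: float,
                         low: int = 4, high: int = 12) -> np.ndarray:
    """Geometric(p) support truncated to [low, high] — the ">3 CpGs" tail."""
    k = np.arange(low, high + 1)
    pmf = p * (1 - p) ** (k - low)
    pmf = pmf / pmf.sum()
    return k[rng.choice(len(k), size=size, p=pmf)].astype(np.int16)


# ---------------------------------------------------------------------------
# Mixing
# ---------------------------------------------------------------------------

def mix_samples(a: SampleReadSet, b: SampleReadSet, c: float, n_total: int,
                seed: Optional[int] = None,
                sample_id: Optional[str] = None) -> SampleReadSet:
    """Mix two read sets at contamination fraction ``c``.

    Takes a simple random sample without replacement of round((1-c)*n_total)
    reads from ``a`` (the embryonic source) and round(c*n_total) from ``b``
    (the contaminant) and concatenates them.  Each output read keeps an
    ``origin`` column naming its source sample — an in-memory provenance
    label for oracles, never written to disk.
    """
    if not (0.0 <= c <= 1.0):
        raise ParameterError("contamination fraction c must lie in [0, 1]")
    if n_total < 1:
        raise ParameterError("n_total must be >= 1")
    n_b = int(round(c * n_total))
    n_a = int(round((1.0 - c) * n_total))
    if len(a) < n_a:
        raise InsufficientReadsError(f"need {n_a} reads from {a.sample_id}, have {len(a)}")
    if len(b) < n_b:
        raise InsufficientReadsError(f"need {n_b} reads from {b.sample_id}, have {len(b)}")
    rng = np.random.default_rng(seed)
    parts = []
    for src, k in ((a, n_a), (b, n_b)):
        if k == 0:
            continue
        idx = rng.permutation(len(src))[:k]
        part = src.records.iloc[np.sort(idx)].copy()
        part["origin"] = src.sample_id
        parts.append(part)
    df = pd.concat(parts, ignore_index=True)
    sid = sample_id or f"{a.sample_id}+{b.sample_id}@{c:g}"
    return SampleReadSet(sample_id=sid, records=df, genome=a.genome)


# ---------------------------------------------------------------------------
# Reference profile
# ---------------------------------------------------------------------------

def make_reference(genome: Genome, bins, n: int, seed: Optional[int] = None,
                   signature: Optional[CellTypeSignature] = None) -> np.ndarray:
    """Per-bin read counts of a synthetic normal-diploid reference.

    Generates ``n`` euploid reads (CN 2 on every chromosome including X and
    Y; see :meth:`Karyotype.reference_diploid`) and aggregates them over the
    bin scheme.  Serves as the denominator of copy-number normalization.
    """
    from .cnv import bin_counts

    if n < 1:
        raise ParameterError("n must be >= 1")
    if len(bins) == 0:
        raise ParameterError("empty bin scheme")
    signature = signature or builtin_signatures()["blastocyst"]
    ref = generate_reads(signature, Karyotype.reference_diploid(), n, genome,
                         seed=seed, sample_id="reference-diploid")
    return bin_counts(ref, bins)
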