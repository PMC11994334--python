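# Methods

## Problem and approach

Noninvasive preimplantation genetic testing for aneuploidies (niPGT-A) reads
the cell-free DNA an embryo sheds into its spent culture medium (SECM)
instead of biopsying the trophectoderm. The medium, however, is routinely
contaminated with maternal cumulus-cell DNA (and, under conventional IVF,
sperm DNA), which dilutes the embryonic copy-number signal and produces
false-negative aneuploidy calls and sex discordances.

`secmdecon` implements a computational decontamination of bisulfite
(PBAT) SECM data that needs no extra wet-lab work. It exploits the global
demethylation wave of preimplantation development: blastocyst DNA is at its
methylation minimum (~24–29% genome-wide), whereas cumulus-cell DNA is
hypermethylated (~71%) and sperm DNA more so (~82%). At single-read
resolution the difference is dramatic. Writing the per-read methylation
level as mC/C over the CpGs a read covers, the fractions of CpG-containing
reads at level 0 / in (0,1) / at level 1 are approximately

| cell type   | 0% | 1–99% | 100% |
|-------------|----|-------|------|
| blastocyst (SECM column) | 47% | 11% | 42% |
| cumulus     | 12% | 14% | 74% |
| sperm       | 20% |  8% | 72% |
| MII oocyte  | 38% |  —  |  —  |

Selecting reads that have **at least two CpGs and a methylation level of
exactly 0** therefore enriches embryonic over cumulus DNA by a factor of
about 0.47/0.12 ≈ 4 (sperm ≈ 2.5; polar-body/oocyte only ≈ 1.2). Copy
numbers are then re-estimated from the retained reads.

## Expected-signal model

For a chromosome at embryonic copy number `n`, contaminant read fraction
`c` (contaminant assumed diploid), and per-read selection probabilities
`s_e` (embryo) and `s_c` (contaminant), the expected post-selection summary
copy number is

    CN(n, c, s_e, s_c) = ((1-c) s_e n + 2 c s_c) / ((1-c) s_e + c s_c)

Raw data are the special case `s_e = s_c = 1`. This reproduces the standard
dilution arithmetic: a 1&3 aneuploidy at 50% contamination collapses to
1.5&2.5 — exactly at the conventional calling cutoffs — and the
unmethylated-read selection (`s_e = 0.47`, `s_c = 0.12`) restores it to
1.2&2.8. At 75% contamination the raw signal is 1.75&2.25 and recovers only
to 1.43&2.57, which remains hard to call; this is the method's expected
performance boundary.

A second-order effect the closed form ignores, but the simulator and
pipeline reproduce, is normalization-mass dilution: an embryo carrying a
trisomy has slightly more total genome than the diploid reference, so all
its chromosomes scale by `2A/(2A + L_extra)` (`A` = haploid autosomal
length). For a trisomy of chromosome 13 this puts the raw 50%-contamination
expectation at 2.47, strictly below the 2.5 cutoff rather than exactly on
it.

## Two-stage decision rule

Decontamination discards ~85% of reads, and shallow counts raise the
false-positive rate. The integrated rule requires that a genuine
whole-chromosome CNV, being merely *diluted* before decontamination, must
already show a mosaic-level signal in the raw data: a chromosome is called
only when its summary crosses the permissive pre-decontamination pair
(default 1.8&2.2) **and** the full pair (1.5&2.5) after decontamination,
**in the same direction**. The same-direction requirement is a design
choice: a pre-gain/post-loss chromosome is contradictory evidence and is
never called. Modes `pre_only` and `decon_only` expose each stage alone;
the integrated call set is provably a subset of both. Sex is read from the
post-decontamination profile (the decontaminated data are the corrected
signal); an audit record with both stage profiles, retention and a
per-chromosome rationale is always produced.

## CNV pipeline

1. **Binning** — a read belongs to the bin containing its start coordinate
   (0-based, half-open everywhere). The default scheme tiles the scaled
   genome with fixed 20 kb bins (~3100 bins); variable-length bin BEDs with
   per-bin GC and blacklist flags are accepted.
2. **GC correction** — lowess of count vs bin GC fraction (span 0.3,
   3 robustifying iterations, via statsmodels); each count is divided by
   its fitted value and rescaled so the mean over usable bins is preserved
   exactly. Bins with a non-positive fit are flagged unusable, not divided.
3. **Reference normalization** — `cn_i = 2 (s_i/S)/(r_i/R)` against a
   synthetic diploid reference count profile, with `S`, `R` summed over
   usable *autosomal* bins only, so sample sex does not shift the baseline.
   The reference is generated at copy number 2 on **every** chromosome,
   including X and Y — a purely computational baseline that makes
   sex-chromosome dosage absolute (XY sample → X≈1, Y≈1; XX → X≈2, Y≈0).
   Zero-reference bins are flagged unusable.
4. **Summary and calling** — per-chromosome summary is the **median** of
   bin values (≥5 usable bins required, else undetermined). The median
   stands in for segmentation: whole-chromosome aneuploidy is the endpoint,
   and the median is robust at post-decontamination depths. Thresholds are
   inclusive (CN ≤ loss, CN ≥ gain), so printed boundary pairs act as
   detection limits. Sex: XY iff chrY ≥ 0.5 and chrX ∈ [0.5, 1.5]; XX iff
   chrY < 0.5 and chrX ≥ 1.5; anything else is a dosage anomaly and counts
   as aneuploid. Fewer than 20 callable autosomes aborts with a
   low-quality error; a post-filter read count under 10,000 flags the call
   low-confidence rather than suppressing it.

## Simulator

The simulator generates per-read records directly (post-extraction counts;
no sequence, sequencing error or alignment artifacts). Per read: the
chromosome is drawn with probability ∝ length × copy number and the
position uniformly within it (read length 100 bp); whether the read carries
CpGs follows the cell type's CpG histogram (default 0.30/0.24/0.15/0.09/0.19
for 0/1/2/3/>3 CpGs, renormalized; sperm has its own 0.35/0.23/0.14/0.08/0.20);
the methylation state of CpG-containing reads is drawn from the trichotomy
and the CpG count *conditional on the state* (partially methylated reads
need ≥2 CpGs). Drawing in this order makes the realized trichotomy exactly
multinomial at the target fractions — the property everything downstream
depends on — at the cost of shifting ~2 points of histogram mass out of the
1-CpG bucket; the alternative order would bias the unmethylated fraction
upward by the same amount. Partial reads place their methylated-CpG count
through a Beta(0.5, 0.5) level (bimodal per-read landscape); the >3-CpG
bucket is a truncated geometric on 4..12 (p = 0.45). The MII-oocyte
signature is only partially measured (38% unmethylated); the remainder is
split 0.14/0.48 so its genome level sits between blastocyst and cumulus — a
documented assumption.

Mixtures take `round((1−c)·n)` reads from the embryonic source and
`round(c·n)` from the contaminant, without replacement, and keep an
in-memory `origin` label per read for oracles (never written to disk).
Everything is deterministic under a fixed seed.

Because reads are exchangeable within a cell type, the simulator contains
no regional methylation structure, no coverage waviness beyond GC, and no
read-level quality variation. Passing tests on synthetic data therefore
validate the *arithmetic* of enrichment and dilution, not robustness to the
positional heterogeneity of real SECM libraries.

## Scale of the desk simulations

The default genome is hg19 with every chromosome scaled 1:50 (22 autosomes
+ X + Y, ~62 Mb total), so 20 kb bins correspond to the ~1 Mb variable bins
used at full scale and a 1-million-read sample has the same per-bin depth
as a 1-million-read full-genome library. The detection-pattern experiment
(trisomy 13 vs cumulus contamination at 20/50/75/90%) uses 8×10⁶ reads per
mixture and a 8×10⁶-read reference, sized by a power analysis of the three
binding margins (raw@50% below 2.5 by 0.029; pre@75% above 2.2 by 0.035;
post@75% above 2.5 by 0.033 — the last with only ~9% of chromosome-13 reads
surviving both dilution and filtering) so each margin is ≥1.5 standard
errors of the chromosome-median estimator. Chromosome 13 itself is the
choice that jointly maximizes those margins: the normalization-mass
dilution factor `2A/(2A+L)` pushes raw@50% safely under 2.5 only for
sufficiently long chromosomes, while post@75% stays above 2.5 only for
sufficiently short ones.

## QC defaults

- Conversion filter: discard reads with more than 3 unmethylated CH
  cytosines (incomplete bisulfite conversion). Paired-end data discard the
  mate as well upstream; on single-end records the rule applies per record.
- Sample floor: more than 1,000,000 unique reads (strict).
- Site-level methylation: only CpG sites covered by ≥4 reads enter the
  pooled genome-wide level; no covered site is an undefined level, not 0.

## Concordance statistics

GCR, FNR, FPR and SDR are ratios of joint SECM-vs-biopsy classification
counts (FNR = SECM-euploid among biopsy-aneuploid, etc.). Confidence
intervals are Wald, `p ± 1.959964·√(p(1−p)/n)`, clipped to [0, 1] — the
method that matches how the clinical rates are conventionally reported; it
degenerates to a point at p ∈ {0, 1}, where Wilson or Clopper–Pearson would
be wider. Sensitivity/specificity for simulation benchmarks count a
detection only when every truly aberrant chromosome is called with the
matching direction.

## Known limitations

- Whole-chromosome calls only; segmental/mosaic sub-chromosomal CNVs are
  out of scope (the per-bin profile is exposed as a segmentation hook).
- The hard filter has no probabilistic read-origin model; enrichment
  against polar-body DNA is weak (~1.2×) by the biology itself.
- The simulator's exchangeable-read assumption understates the bin-level
  variance of real libraries; thresholds tuned on synthetic data should be
  revalidated on real cohorts.
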