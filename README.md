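# secmdecon

Methylation-based decontamination of spent-embryo-culture-medium (SECM)
cfDNA and whole-chromosome aneuploidy calling for noninvasive
preimplantation genetic testing (niPGT-A).

SECM contains embryo-derived cell-free DNA but is routinely contaminated
with maternal cumulus-cell DNA (and sperm DNA under conventional IVF),
which dilutes copy-number signals and causes false-negative aneuploidy
calls and sex discordances. Because the blastocyst sits at the minimum of
the preimplantation global demethylation wave, its DNA is distinguishable
*per sequencing read*: ~47% of blastocyst CpG-containing reads are fully
unmethylated versus ~12% for cumulus cells and ~20% for sperm. Retaining
only reads with ≥2 CpGs and a per-read methylation level (mC/C) of exactly
0 enriches embryonic DNA ~4-fold over cumulus DNA before copy-number
calling.

The expected summary copy number of a chromosome at embryonic copy number
*n* under contaminant read fraction *c* and per-read selection
probabilities *s_e*, *s_c* is

```
CN = ((1−c)·s_e·n + 2·c·s_c) / ((1−c)·s_e + c·s_c)
```

so a 1&3 aneuploidy at 50% contamination collapses to 1.5&2.5 in raw data
(exactly at the usual cutoffs) and recovers to 1.2&2.8 after
unmethylated-read selection with s_e = 0.47, s_c = 0.12. Because shallow
post-filter counts inflate false positives, the default caller is a
two-stage rule: a chromosome is reported only if it crosses a permissive
*mosaic* threshold pair (1.8&2.2) before decontamination **and** the full
pair (1.5&2.5) after, in the same direction.

The package provides, for bisulfite (PBAT) per-read methylation tables:

- per-read record I/O, QC (conversion filter, read floor) and BED export —
  `secmdecon.records`
- read-level methylation profiling (trichotomy, CpG histogram, enrichment
  factors) — `secmdecon.profile`
- the decontamination filter — `secmdecon.decontam`
- a contamination simulator with measured cell-type signatures and
  karyotype strings like `"+22,XX"` — `secmdecon.simulate`
- a read-count CNV caller (binning, GC lowess correction, diploid-reference
  normalization, per-chromosome median, threshold calls including sex) —
  `secmdecon.cnv`
- the two-stage decision engine with audit records — `secmdecon.decision`
- concordance statistics (GCR/FNR/FPR/SDR, sensitivity/specificity, Wald
  CIs) — `secmdecon.metrics`

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a +22,XX embryo whose medium is 50% contaminated with cumulus
DNA, then call it (the built-in genome is hg19 scaled 1:50, so one million
reads has the per-bin depth of a one-million-read full-genome library):

```sh
nipgt simulate --signature blastocyst --karyotype "+22,XX" --n 1000000 \
      --mix cumulus:0.5 --seed 7 --out mix50.tsv
nipgt profile mix50.tsv
```

```json
{
  "n_total_reads": 1000000,
  "n_cpg_containing": 691256,
  "f_zero": 0.2952,
  "f_partial": 0.1248,
  "f_full": 0.5800
}
```

The unmethylated-read fraction 0.295 is the 50/50 blend of blastocyst
(0.47) and cumulus (0.12) — raw data this contaminated hide the trisomy
(expected chr22 ≈ 2.49, under the 2.5 cutoff). The two-stage caller
recovers it:

```sh
nipgt integrated-call mix50.tsv --ref-reads 1000000 --seed 9
```

```json
{
  "states": {"...": "neutral", "chr22": "gain"},
  "summaries": {"...": "~2.0", "chr22": 2.7095, "chrX": 1.9446, "chrY": 0.0},
  "sex": "XX",
  "ploidy": "aneuploid",
  "aneuploid_chromosomes": ["chr22"]
}
```

chr22 sits at ~2.47 pre-decontamination (crossing the 2.2 mosaic
threshold) and ~2.71 after (crossing 2.5), so the gain is called; every
other chromosome stays neutral and the sex call is XX. `--out-audit`
writes both stage profiles and the per-chromosome rationale;
`--plot-prefix` draws before/after CNV line plots.

Other subcommands: `nipgt decontaminate` (filter a table to its
unmethylated multi-CpG reads), `nipgt call` (single-stage CNV call),
`nipgt metrics` (GCR/FNR/FPR/SDR with 95% CIs from a SECM-vs-biopsy call
table).

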