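# hrdgis

Genomic-instability scoring for homologous-repair-deficiency (HRD)
classification from tumor-only allele-specific copy-number segmentation.

HRD tumors — most prominently high-grade serous ovarian carcinomas with
defective BRCA1/2-mediated double-strand-break repair — accumulate
characteristic genome-wide copy-number scars and respond to PARP
inhibition. `hrdgis` quantifies that scarring from the integer
allele-specific copy-number profile (total copies *C* and minor-allele
copies *M* per segment) that a purity/ploidy-aware caller produces from a
targeted panel, and turns it into a clinical-style HRD call. It is aimed at
molecular-pathology bioinformaticians who have segmentation in hand and
need a transparent, testable scoring layer.

## The score

Three components, each a percentage, are summed into a single
genomic-instability score:

* **PLOH** — percent of the *observed genome* lying in
  loss-of-heterozygosity regions (M = 0), counting only regions larger
  than 10 Mb and smaller than a complete chromosome arm.
* **PCNA** — percent of the observed genome whose state (C, M) deviates
  from the chromosome's *expected* state — the state covering the largest
  part of that chromosome — again counting only regions larger than 10 Mb
  that are not whole-arm events.
* **PTCNA** — percent of evaluable telomeres whose terminal segment
  (boundary within 5 Mb of the chromosome end, span above 1 Mb) deviates
  from the expected state; whole-arm events and telomeres unassembled in
  the reference (acrocentric p arms such as chr21p in hg19) are excluded.

```
GIS = PLOH + PCNA + PTCNA          GI-positive  iff  GIS >= cutoff (83)
HRD-positive  iff  GI-positive and/or pathogenic BRCA1/2 mutation
```

The observed genome — the arm territory actually covered by segments —
is the denominator throughout, so the score adapts to the variable amount
of sequenceable territory typical of FFPE material. Samples with less than
40% of the assembled reference observed, or with no evaluable telomere,
are reported *unevaluable* rather than scored.

The package also ships the cutoff-calibration machinery (Cohen's-kappa
maximization of concordance against a reference HRD assay over an integer
cutoff grid), an exact-binomial depth-for-detection helper, and a
synthetic-profile simulator that generates hg19-scale cohorts with
controlled numbers of LOH, interstitial and telomeric events, so every
stage is testable without external data.

## Worked example

A toy genome with two chromosomes (chrA 100 Mb, centromere 40–41 Mb;
chrB 60 Mb, centromere 30–31 Mb) and one 15 Mb copy-neutral LOH segment at
the start of chrA:

`segments.tsv` (1-based inclusive coordinates):

```
sample	chromosome	start	end	total_cn	minor_cn
S1	chrA	1	15000000	2	0
S1	chrA	15000001	100000000	2	1
S1	chrB	1	60000000	2	1
```

```sh
hrdgis score --segments segments.tsv --build arms.tsv --brca brca.tsv --out out
cat out/results.tsv
```

```
sample	ploh_pct	pcna_pct	ptcna_pct	gis	evaluable	gi_status	brca_status	hrd_status	observed_genome_bp	observed_fraction
S1	9.4937	9.4937	25.0000	43.9873	true	negative	wildtype	negative	158000000	1.0000
```

Reading the numbers: 158 Mb of arm territory is observed (two 1 Mb
centromeres excluded). The 15 Mb LOH region passes the >10 Mb filter and
covers well under a whole arm, so PLOH = 100·15/158 = 9.4937; the same
region deviates from chrA's expected state (2,1), so PCNA is identical
here; one of the four evaluable telomeres (chrA-p) carries the deviant
terminal segment, so PTCNA = 25. The sum, 43.99, is below the cutoff 83:
GI-negative, and with wildtype BRCA the sample is HRD-negative.

The same workflow runs end-to-end on simulated data:

```sh
hrdgis simulate --seed 7 --hrd-like --cohort 35 96 --out sim
hrdgis calibrate --scores sim/cohort.tsv --out cal
# selected cutoff: 81 (max kappa 0.8023 on [81, 85])
```

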