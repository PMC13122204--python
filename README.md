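# zdose — qPCR chromosome-dosage sex genotyping for ZZ/Z0 systems

Many coleoid cephalopods (cuttlefish, octopus, squid) determine sex
chromosomally: males are ZZ and females Z0, so a Z-linked locus is present
at twice the dose in male genomic DNA. Juveniles show no anatomical sex
marker (the male hectocotylus appears only at maturity), but the 2-fold
dosage difference is measurable by quantitative PCR from as little DNA as
a skin swab yields. `zdose` is a toolkit for building and running such
assays: it turns raw Cq replicate tables into male/female/repeat calls,
simulates realistic plates from known genotypes, provides the validation
statistics, and implements the primer-screening pipeline used to design
dosage-grade assays.

## The model

For each animal, an autosomal control assay and a Z-linked ("sex") assay
are run as technical quadruplicates. With amplification efficiency $E$
(fold-increase per cycle minus one), a template at relative copy number
$c$ crosses the threshold at

$$C_q = C_q^{\mathrm{ref}} - \frac{\ln c}{\ln(1+E)}$$

so at $E = 1$ a 2-fold template difference is exactly one cycle. The
within-sample difference

$$\Delta C_q = C_q(\text{autosome}) - C_q(\text{sex})$$

cancels input DNA amount. Plate values of $\Delta C_q$ split into two
clusters; subtracting the median of the greater-$\Delta C_q$ (male)
cluster gives $\Delta\Delta C_q$, which sits at 0 for ZZ males and $-1$
for Z0 females. Classification uses the midpoint threshold $-0.5$; a
sample whose $\Delta\Delta C_q$ lies within one summed SEM (autosome SEM
+ sex SEM) of the threshold is flagged for repeat. Replicate outliers
(>1 cycle from the group mean) are discarded before any of this.

Validation statistics: a one-sided exact binomial test of the correct-call
count against chance (0.5), Student's t tests between the sex groups, and
dilution-series efficiency estimation via the standard-curve slope,
$E = 10^{-1/\text{slope}} - 1$, accepted in the 90–110 % window.

## Worked example

Simulate an 81-animal cohort (40 ZZ, 41 Z0, quadruplicates, 0.12-cycle
replicate noise), genotype it, and validate against the simulated truth:

```sh
zdose simulate --males 40 --females 41 --noise-sd 0.12 --seed 1 \
    --out plate.tsv --truth truth.tsv
zdose genotype plate.tsv --out results.tsv
zdose stats --results results.tsv --truth truth.tsv --out stats.json
```

prints

```
wrote 648 wells for 81 samples to plate.tsv
81 samples called (0 flagged repeat); results in results.tsv
81/81 correct (binomial p = 4.14e-25); report in stats.json
```

`results.tsv` holds one row per animal:

```
sample_id   delta_cq   ddcq      sem_total  call  reference_used  flags
animal_001  -1.021925  0.005100  0.079206   male  cluster_median
animal_002  -1.029854  -0.002828 0.134741   male  cluster_median
...
```

`ddcq` near 0 is a ZZ male, near −1 a Z0 female; `sem_total` is the
per-animal precision figure the repeat rule uses. All 81 calls match the
simulated genotypes, and the exact binomial test of 81/81 against chance
gives $p = 4.14 \times 10^{-25}$.

Assay design runs off a genome FASTA plus GFF3/BED annotation:

```sh
zdose extract-targets --genome genome.fa --annotation genes.gff3 \
    --chrom chrZ --feature exon --out targets.fa
zdose design --genome genome.fa --annotation genes.gff3 --feature exon \
    --preset geneious2025 --out pairs.tsv
zdose check-primers panel.fa --preset geneious2025 --out metrics.tsv
zdose insilico-pcr --fwd GGCCGTCC... --rev AGTAGCTG... \
    --templates genome.fa --out amplicons.fa
```

The validated 24-primer panel for seven cephalopod species ships in
`zdose.published_primers`. Everything is also available as a library —
see `zdose.genotyping`, `zdose.simulate`, `zdose.stats`, `zdose.primers`,
`zdose.insilico`, and `zdose.targets`.

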