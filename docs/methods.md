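# Methods

## Dosage model and genotyping procedure

A qPCR assay at amplification efficiency `E` (fractional gain per cycle)
amplifies a template of relative copy number `c` to threshold at
`Cq = cq_ref − ln(c)/ln(1+E)`. Autosomal loci are diploid in both sexes;
a Z-linked locus has 2 copies in ZZ males and 1 in Z0 females, so at
`E = 1` the sex assay of a female runs exactly one cycle behind her
autosome assay relative to a male.

The pipeline in `zdose.genotyping` is deterministic and proceeds as:

1. **Replicate QC.** Wells reported "Undetermined" are treated as missing
   (never imputed to the cycle ceiling of 45). Each sample/target group is
   screened in a single pass: values deviating from the mean of all raw
   values by strictly more than 1 cycle are discarded; mean and SEM
   (sample SD / √n) are recomputed on survivors. The screen is
   deliberately non-iterative — one pass against the all-replicate mean —
   because that is the simplest deterministic reading of the discard rule;
   an iterative screen could cascade on pathological groups. Groups with
   fewer than two survivors have no estimable SEM; they are treated as
   infinitely imprecise, which forces a repeat call.
2. **ΔCq.** `delta_cq = mean Cq(autosome) − mean Cq(sex)`. The per-animal
   precision figure is the *arithmetic sum* of the two group SEMs, not the
   quadrature sum — a conservative (larger) figure that feeds the repeat
   rule.
3. **Clustering.** Plate ΔCq values are split by exact 1-D two-means: the
   optimal two-cluster partition in one dimension is contiguous in sorted
   order, so an exhaustive scan over the n−1 sorted split points finds the
   global within-cluster-SS minimum. Ties are broken toward the larger
   inter-cluster gap, then toward the smaller split index. The cluster
   with the greater median is male (two Z copies → relatively earlier
   autosome-vs-sex crossing → greater ΔCq). When the inter-cluster gap
   falls below `min_cluster_gap` (default 0.3 cycles) the split is flagged
   unimodal — the batch may be single-sex — and the pipeline refuses to
   normalise against it, asking for a male standard instead.
4. **ΔΔCq.** Normalisation subtracts the male-cluster median (or an
   explicit known-male standard ΔCq), mapping the male cluster to 0 and
   Z0 females to −ln2/ln(1+E_sex) ≈ −1.
5. **Call.** Threshold −0.5, the midpoint between the cluster centres.
   Values strictly above are male, strictly below female; a value exactly
   on the threshold, or within one summed SEM of it, is insufficiently
   precise and flagged repeat. Classification is by threshold, after
   cluster-median normalisation; when cluster membership and threshold
   disagree for a sample, the sample is flagged
   `cluster-threshold-disagreement` in the output rather than silently
   resolved either way.

## Simulator

`zdose.simulate` generates plates from known genotypes under the same
closed-form model. Defaults describe the study conditions the package is
validated under: 40 ZZ + 41 Z0 animals, quadruplicate replicates, both
assays at 100 % efficiency (`cq_ref` 21 autosome / 22 sex), Gaussian
replicate noise of 0.12 cycles SD, and a per-sample input-amount offset of
0.5 cycles SD added to both targets of an animal (swab DNA yields vary
widely; the offset cancels in ΔCq by construction). Replicate noise of
0.12 cycles was chosen so the simulated cohort's cluster separation sits
in the same regime as real swab data (the seed-1 81-animal plate gives an
inter-cluster nearest-point gap ≈ 0.55 and cluster-median distance
≈ 0.99 cycles, bracketing reported real-cohort figures of 0.44 and 0.97).
Aberrant wells can be injected (`outlier_prob`, ±`outlier_shift` cycles)
to exercise the outlier screen; they are off by default. All draws come
from one `numpy` generator in a documented order, so a seed fully
determines a plate.

What the simulator does *not* model: fluorescence curves and Cq calling,
efficiency drift or inhibition, plate-position effects, cross-species
primer mismatch, and heavy-tailed replicate noise. Passing tests
therefore demonstrate the correctness of the analysis pipeline under the
stated noise model, not the wet-lab performance of any assay.

## Statistics

- **Exact binomial** (`exact_binomial_one_sided`): upper tail
  P(X ≥ k | n, p₀) summed exactly — in rational arithmetic for n ≤ 64,
  otherwise by log-space accumulation of log-pmf terms — so p-values of
  order 1e-25 (81/81 correct vs chance) carry full precision. No normal
  approximation anywhere.
- **t tests**: pooled-variance Student's two-sample test (Welch available
  via `equal_var=False`) and the one-sample test against a reference
  value; both two-sided. Zero-variance degenerate inputs return the
  documented limits (equal means → p = 1; unequal → p = 0).
- **Efficiency** (`estimate_efficiency`): least-squares slope of Cq on
  log10 input; `E = 10^(−1/slope) − 1`, flagged against the accepted
  90–110 % window; non-negative slopes yield undefined efficiency and an
  automatic fail.
- **Box summaries**: quartiles by linear interpolation between order
  statistics (stated explicitly because plotting conventions differ);
  whiskers at the most extreme points within 1.5×IQR of the quartiles.

## Primer screening

Two constraint presets are shipped. `geneious2025`: 18–24 nt (optimum
20), Tm optimum 59 °C (window 54–64 °C at our conditions), GC optimum
50 % (window 30–70 %), product 100–200 bp, 3'-terminal G/C clamp of 1,
max homopolymer 3, max dimer Tm 30 °C. `ceph_pipeline`: Tm optimum 60 °C,
product 150–300 bp, max homopolymer 5, no clamp or dimer requirement.
The GC clamp is interpreted as *N consecutive* G/C bases at the 3'
terminus, and poly-X as the longest single-base run; dinucleotide repeats
are not counted.

Melting temperatures are unified-parameter nearest-neighbor values
(50 nM oligo, 50 mM monovalent salt, entropy-based salt correction).
Dimer risk is scored as the nearest-neighbor Tm of the strongest
contiguous complementary segment over all ungapped antiparallel registers
of the two oligos, a deliberately simple and fully documented metric; the
30 °C ceiling applies to it. Pairs with no complementary register of ≥2 nt
score −∞.

`design_candidates` enumerates every primer window on both strands of a
target, hard-filters (GC window, poly-X, clamp cheaply first, then Tm),
ranks feasible pairs by summed soft penalty (1.0/°C Tm deviation, 0.5/%
GC deviation, 1.0/nt size deviation; product size is a hard range only),
breaks ties deterministically (leftmost forward, then shortest product),
and returns the first ranked pair passing the dimer screen — exactly one
pair per target entry, or a reported failure. The dimer screen is capped
at the top 200 ranked pairs per target to bound effort; ranking below the
cap is unaffected.

In-silico PCR replaces both genome-scale BLAST off-target screening and
melt-curve single-product confirmation at desk scale: a primer binds where
its 3'-terminal 5-base seed matches exactly and total mismatches ≤ 2
(configurable); amplicons pair opposite-strand sites of any primer
combination within 5 kb; specificity requires exactly one amplicon of
in-range length. Consensus refinement maps a primer designed on a related
reference onto the target species' consensus, substitutes concrete
variants (counting them, and warning when one falls in the 3' seed),
keeps the primer base under compatible IUPAC ambiguity or N, and refuses
gapped or incompatible footprints.

## Numerical notes and limitations

- The noiseless dosage identity (ZZ → 0, Z0 → −1) is exact in exact
  arithmetic and bitwise exact in floating point when per-sample offsets
  are zero; with arbitrary float offsets the add-then-subtract
  cancellation leaves ≤1e-12-cycle rounding residue, which is the
  tolerance the tests assert.
- The male-cluster ΔΔCq median is identically 0 for odd male clusters;
  for even clusters it is 0 to within one ulp (the median averages two
  normalised values).
- Quartile convention, dimer metric, and in-silico PCR policy are
  package-defined where tool vendors leave them unspecified; all are
  configurable.
- Real-cohort t-test p-values depend on per-animal measurements that are
  not public; the package computes t statistics for its own simulated and
  user-supplied data only.
- Multi-plate batch correction beyond per-run normalisation, melt-curve
  analysis, probe (TaqMan) design, and thermodynamic hairpin ΔG are out
  of scope.
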