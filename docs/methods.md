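# Methods

This note documents the models, estimators and numerical choices behind
`prdscan`, and what the synthetic-data experiments do and do not
establish about real data.

## Growth model and toxicity units

Selection is modelled as exponential competition: a variant with
toxicity `t` (growth-rate deficit per generation, natural-log units)
changes frequency by a factor `exp(-t·G)` relative to wild type over `G`
generations. With this parameterization the enrichment-score contrast
`ES_WT − ES_x` equals `t·G` exactly, and dividing by the
replicate-specific number of doublings recovers `t` — the estimator
inverts the generative model with no unit constant left over. (A base-2
growth formulation differs only by a global `ln 2` factor in the units of
`t`; natural-log units keep Eq. and inversion aligned.)

The wild-type sequences are the two 42-residue windows of the human
TDP-43 prion-like domain (positions 290–331 and 332–373), back-translated
with one fixed codon per residue. The real oligonucleotide's codon usage
is not public at this level; since all analyses operate on amino-acid
variants after aggregation, the codon choice only affects which silent
variants exist, not any downstream statistic.

## Synthetic-data generator

The generator's defaults mirror the experimental layout: 126-nt windows
doped at 1.59% per base (giving 13.3% WT, 27.0% single-, 27.3%
double-nucleotide molecules by the binomial closed form), three
biological replicates with one input and two output cultures each,
generations (5.0, 5.5, 6.0) spanning the experiment's 5–6 range,
sequencing depth defaulting to 5×10⁶ reads per sample, and per-base
misread rates of 10⁻⁴ within the doped window.

The planted single-mutant landscape is
`amp(pos) · (β·(KD_wt − KD_mut) + mode + noise)`: a hydrophobicity term
(Kyte–Doolittle, β = 0.03 per KD unit, so mutations that increase
hydrophobicity lower toxicity), a three-component mode mixture
(−0.15 / 0 / +0.2 with weights 0.3 / 0.4 / 0.3) producing a tri-modal
marginal toxicity distribution, Gaussian effect noise (SD 0.05), and a
2× amplification inside the hotspot interval (default 312–342).
STOP-containing variants share one class-level toxicity (−0.3: truncation
relieves growth inhibition in this assay). Double mutants are additive
plus an optional planted coupling per position pair.

Replicate-to-replicate biological noise is a Gaussian per-generation
growth offset (SD 0.01) drawn once per protein variant per replicate,
shared by synonymous codon variants and by the two output cultures of a
replicate. Because toxicity is a contrast against wild type, the noise is
expressed directly in that contrast (WT has offset 0): a common-mode
shift of the reference is unidentifiable from relative frequencies, and
with only three replicates its realized variance would dominate any
calibration check without adding information. The generator therefore
omits common-mode reference noise; this is the one replicate-noise
feature of real data it deliberately does not emulate.

Misreads corrupt each read at `Binomial(126, rate)` positions and
re-assign it to the sequence it appears to be, conserving totals. What
the generator does **not** model: PCR amplification bias, chimeras,
position-dependent doping efficiency, codon-usage effects on growth, and
demographic drift in the cultures. Tests passing on these simulations
show the estimators are correct under the stated noise model, not that
real libraries contain no further artefacts.

## Variant aggregation and filters

Nucleotide variants are translated (standard code) and aggregated to
amino-acid classes; variants that carry a synonymous change in a codon
other than the mutated ones are aggregated separately and removed by the
filter, as are variants with more than two amino-acid changes and
variants with a mean input coverage below ten reads (boundary
inclusive). Silent variants are kept at nucleotide resolution — they are
distinct library members, and the centring step needs their
distribution, not one pooled record. Read totals are conserved exactly
through aggregation, and filtering is idempotent.

Before aggregation the expected misread inflow from the wild-type
sequence into each of its single-nucleotide neighbours
(`n_WT · rate / 3` per sample) is subtracted. WT is the largest class by
an order of magnitude, so this is the dominant contamination term;
mutant-to-mutant inflow is smaller by the class-frequency ratio and is
left uncorrected. Without this correction the estimates of strongly
depleted variants are biased toward neutrality, because the contaminating
WT reads do not deplete.

## Error model

Enrichment scores use a half-count continuity correction
(`ln((n + 1/2)/T)`), which tracks `ln(λ)` to O(λ⁻²) for Poisson counts
and removes the small-count log bias that otherwise shifts depleted
variants.

The inter-replicate error `eps_r` is the excess of the observed
across-replicate variance of (per-generation-normalized) toxicity over
its Poisson expectation, among variants in the top decile of minimum
*input* count (with an absolute floor of 200 reads — "Poisson error
approaches zero" is an absolute statement, and at desk-scale depth a pure
quantile can land in the Poisson-dominated range). Two details matter for
unbiasedness, both verified against injected noise: the threshold must
not involve output counts (selecting on outputs conditions on the very
noise being estimated and truncates it), and the per-variant excess terms
are combined with inverse-variance weights `1/(exp_var + eps²)²`,
iterated to convergence. The WT record is excluded (its toxicity is
identically zero by construction). On simulations the estimator recovers
an injected SD of 0.05 to within 1% and the pipeline-scale 0.01 to within
a few percent.

## Bayesian double-mutant correction

Per replicate, each double's posterior combines a Poisson likelihood on
its output count (given its input frequency, the sample totals, the WT
enrichment and the replicate's generations) with a normal prior fitted to
well-measured doubles (mean input ≥ 50) in the same 2D equal-occupancy
bin of constituent-single toxicity space; bins with fewer than five such
doubles fall back to an additive prior (mean `t1 + t2`, SD of the
additive residuals). The posterior is integrated on a per-double grid
spanning prior ± 6 SD and raw estimate ± 8 SE (241 points) — a shared
global grid cannot resolve the posterior SD of deep doubles. Posterior
mean/SD replace the per-replicate estimate/error; zero-output doubles
thereby receive finite estimates near their conditional prior, and the
correction's RMSE against planted truth beats the raw estimator roughly
two-fold for doubles under 20 input reads. Doubles missing a constituent
single are flagged and excluded. Singles are never imputed: a zero-output
single is dropped for that replicate and logged.

## Merging and normalization

In order: per-library replicate toxicity distributions are scaled to a
common SD (the mean of the replicate SDs); replicates are merged by
inverse-variance weighting (merged SE = `1/sqrt(Σ w)`); each library is
centred on the error-weighted mean of its *single-codon* silent variants
(multi-codon silents are excluded from the centring set — their low
counts make the zero-output drop rule censor them asymmetrically, which
would shift the zero point); libraries are scaled multiplicatively so
their single-STOP error-weighted means coincide at the cross-library
mean. Classification against wild type is a per-variant one-sample
two-sided t-test on the centred per-replicate values with
Benjamini–Hochberg control at FDR 0.05; variants with fewer than two
finite replicate values are labelled indistinguishable.

## Hotspot and property models

Per-position profiles aggregate single-mutant |toxicity| and smooth it
with loess (span 0.3 — wide enough to be stable per position, narrow
enough to resolve a 31-residue feature over the 84-residue region;
config-exposed). The hotspot is the longest contiguous run of positions
whose smoothed mean |toxicity| exceeds the global mean |toxicity| of all
singles; ties go to the run with the greater mean, and a landscape where
no position exceeds the mean has no hotspot. Detection is invariant to
affine rescaling. On censored data (strongly toxic variants dropping
out) the detected interval is a few positions narrower than the planted
one — a property of the data, not the detector.

Amino-acid property features come from a PCA of a property matrix
(indices × 20 residues, each index z-scored across residues; indices with
missing values dropped; PC1 oriented so Ile/Leu/Val score positive). The
package bundles a curated 22-scale subset of published indices
(hydrophobicity scales, charge, volume, polarity, secondary-structure
propensities, ...) so no download is needed; a full AAindex-style table
can be supplied. A variant's feature value is the WT-minus-mutant score
difference, summed over constituent singles for doubles; the
change-in-absolute-charge feature takes the absolute value. Toxicity
models are OLS fits on all variants, inside/outside-hotspot strata
(doubles must have both mutations in the stratum), or with a 0/1/2
hotspot-location code and location×feature interaction.

## Epistasis and structure inference

The expected-toxicity surface is K-nearest-neighbour local percentiles
(default K = 1000, Euclidean in the symmetrized `(t1, t2)` plane); a
double below its local 5th percentile is negative, above the 95th
positive epistasis for growth. Doubles whose local median lies within
10% of the observed toxicity range's ends are excluded (assay
saturation). The calibration caveat: the nominal 5%/5% flag rates hold
only when the neighbourhood diameter is small against the noise scale;
the null-calibration experiment uses 50,000 doubles with K = 250 for that
reason, and coarser surfaces under-flag.

Pair enrichment is the Haldane–Anscombe-corrected log odds of epistatic
classification at a position pair versus all classified doubles, with
positive and negative flags pooled into one matrix. Diagonal entries are
imputed as column means (missing pairs first as the mean of their two
column means, preserving symmetry).

The correlation score matrix is the partial correlation of enrichment
columns controlling for all other positions via the precision matrix.
An n-position matrix yields n profiles of length n, so the sample
correlation matrix is singular *by construction*; a near-zero ridge
saturates the partial correlations at ±1 and destroys the signal. The
precision matrix is therefore taken from the Ledoit–Wolf shrinkage
covariance estimator (a fixed shrinkage intensity or exact inversion
remain available). The exact three-variable closed form is preserved by
the direct `partial_correlation_from_corr` path.

The secondary-structure kernels are matched filters in correlation
space. Couplings with spacing set S (helix {3,4}, i.e. period 3.6;
strand {2}, period 2) imprint on a correlation-of-profiles matrix not at
the spacings themselves but at the offsets where two positions share
coupling partners — the autocorrelation of the spacing pattern (helix:
offsets 1, 6, 7, 8; strand: offset 4). The kernel weights `K(a, b)` are
that autocorrelation at `a − b`, Gaussian-tapered (SD 10, i.e. nearly
flat over the ±4-offset window) and centred to zero mean, which makes
propensities invariant to adding a constant to the matrix. A plain
cosine kernel at the element's own period, applied to the correlation
matrix, has almost no overlap with this signature and cannot recover
short planted elements; the matched form is this package's concrete
realization of "testing for agreement with the stereotypical
periodicity". Positions within half a window of the matrix edge are
reported unavailable.

Significance comes from jointly permuting row/column position labels
(preserving symmetry): `p(i) = (1 + #{randomized ≥ observed at i}) /
(N + 1)`, with N = 10⁴ as the analysis default and 10³ in the packaged
experiments. Null p-values are uniform by exchangeability, and the
planted-structure experiments confirm kernel specificity (each element
detected only by its own kernel).

LARKS scoring standardizes the correlation submatrix over a reference
six-residue window (off-diagonal mean 0, variance 1), multiplies it
elementwise with a zero-sum side-chain contact map (minimal side-chain
heavy-atom distance ≤ 4.5 Å; glycine falls back to Cα) and sums;
randomization is restricted to within-window label permutations.

### The structure-recovery experiment

The planted elements sit at the study's reference locations — strand
311–316 (spacing-2 couplings) and helix 324–331 (spacing-3/4 couplings)
— on a *benign* background landscape: no hotspot amplification, and
couplings of −0.4 (toward lower toxicity). Rationale: the correlation
geometry is indifferent to the epistasis sign, but couplings toward
higher toxicity on an amplified background push doubles past the
measurable range (zero output), where the Bayesian prior rightly shrinks
them to expectation and the epistatic signal is erased. A scientist
designing a recovery experiment places the signal where the assay can
see it. Simulation size: 250,000 molecules at 3×10⁶ reads per sample,
giving ≈20,000 usable doubles over 861 position pairs.

## Problem sizes and determinism

The packaged experiments run the two-library calibration at 150,000
molecules and 2×10⁶ reads per sample (≈620 well-covered records for the
coverage check, ≈18,000 sparse doubles for the shrinkage check) and the
structure recovery as above; together with the calibration nulls the
whole validation suite completes in a few minutes on one CPU. Every
source of randomness flows through one seeded generator per run
(per-stage seeds spawned via SeedSequence), outputs record their seed,
and identical seeds reproduce all outputs byte for byte.

## Known limitations

- Interval coverage of `±1.96·sigma` is validated in the Gaussian
  counting regime (mean input ≥ 100, every replicate's output ≥ 25
  reads). Outside it — strongly depleted variants — the log-count
  distribution is skewed and censored, and nominal coverage is not
  claimed (observed coverage there can drop by several points).
- The misread-inflow correction handles only WT-to-neighbour
  contamination; at depths far beyond those simulated, mutant-to-mutant
  inflow (the "extra counts per double" effect) would also need
  treatment.
- The hotspot detector reports what survives measurement; under heavy
  censoring its interval is conservative.
- Partial-correlation shrinkage intensities trade variance against bias;
  the Ledoit–Wolf default is well-behaved across the sizes tested here
  but has not been tuned for matrices much larger than ~100 positions.
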