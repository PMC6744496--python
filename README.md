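# prdscan

Analysis pipeline for deep mutational scanning (DMS) of the TDP-43
prion-like domain (PRD), built around doped-oligonucleotide libraries: it
simulates complete experiments with a known ground truth, estimates
per-variant toxicity with an explicit error model, regresses toxicity on
amino-acid physicochemical properties, and infers in vivo secondary
structure (alpha-helix, beta-strand, LARKS-like geometry) from the
epistasis patterns of double mutants.

## The problem

In a pooled selection, yeast cells expressing >50,000 PRD variants
compete; sequencing the population before and after induction quantifies
each variant's effect on growth. For a variant *x* with input and output
frequencies `F_in` and `F_out`, the enrichment score is

```
ES_x = ln(F_out / F_in),          toxicity_x = ES_WT − ES_x
```

so positive toxicity means slower growth than wild type. The uncertainty
combines Poisson counting error with an inter-replicate component
estimated from well-covered variants:

```
eps_x = sqrt(1/n_in + 1/n_out + 1/n_WT_in + 1/n_WT_out + eps_r²)
```

Toxicities and errors are normalized by the replicate's cell doublings to
growth-rate units per generation. Because doped libraries cover double
mutants sparsely (toxic doubles drop out of the output entirely), double
mutants are re-estimated by a Bayesian posterior that combines a Poisson
read-count likelihood with an empirical prior conditioned on the
toxicities of the constituent singles. Replicates are variance-equalized
and merged by error-weighted averaging; the scale is centred on
single-codon synonymous (silent) variants and aligned across sub-libraries
on the STOP-variant class.

Double-mutant epistasis (toxicity beyond the local expectation given the
two singles) is classified against non-parametric 5th/95th percentile
surfaces, aggregated into a position-pair enrichment matrix, and turned
into an epistasis correlation score matrix via regularized partial
correlations of interaction profiles. Periodicity kernels slid along the
diagonal score helix (3.6-residue period, coupling spacings 3/4) and
strand (period 2) propensity per position, with significance from
label-permuted matrices; a reference-structure side-chain contact map
(4.5 Å) scores LARKS-like non-canonical geometry the same way.

Everything runs against synthetic data with planted truth — no downloads
required: the generator emulates per-nucleotide doping at 1.59% over the
two 126-nt sub-libraries (amino acids 290–331 and 332–373 of TDP-43),
three replicate selections with two output cultures each, 5–6 generations
of exponential competition driven by a hydrophobicity-dependent,
hotspot-localized, tri-modal toxicity landscape, Poisson sequencing
sampling and per-base misreads.

## Worked example

```python
import numpy as np
from prdscan.design import tdp43_library
from prdscan import synthetic_data as sd, variant_table as vt, toxicity as tx
from prdscan import landscape_features as lf

ests = []
for i, which in enumerate(("290-331", "332-373")):
    design = tdp43_library(which)
    landscape = sd.make_landscape(design, seed=11 + i)  # planted truth
    counts = sd.simulate_experiment(design, landscape, n_molecules=150_000,
                                    depth=2_000_000, seed=1 + i)
    counts = vt.correct_misread_inflow(counts, design)
    records, log = vt.filter_variants(vt.translate_and_aggregate(counts, design))
    est, tox_log = tx.estimate_toxicity(records, design)
    ests.append(est)
    print(f"library {which}: {log['n_retained']} records, "
          f"eps_r = {tox_log['error_model'].eps_r:.4f}")

merged = tx.merge_and_normalize(ests)
merged["class_vs_wt"] = tx.classify_vs_wt(merged, fdr=0.05)
print(merged["class_vs_wt"].value_counts().to_string())

singles = merged[(merged.n_aa_mut == 1) & ~merged.is_stop].reset_index(drop=True)
print("detected hotspot:", lf.detect_hotspot(lf.per_position_profile(singles)))
```

prints

```
library 290-331: 18934 records, eps_r = 0.0100
library 332-373: 19647 records, eps_r = 0.0103
class_vs_wt
less_toxic           16337
more_toxic           12901
indistinguishable     9343
detected hotspot: (316, 339)
```

The inter-replicate error recovers the 0.01 biological noise injected by
the generator; the t-test/Benjamini–Hochberg classification splits
variants into more toxic, less toxic and indistinguishable from wild
type; and the detected mutant-effect hotspot matches the planted
amplified region 312–342, with its edges eroded because the most toxic
variants drop out of the output samples (their estimates are censored,
which lowers the surviving per-position mean).

The same stages are available from the shell:

```
prdscan run --seed 1 --outdir run1        # simulate + full analysis
prdscan validate --config my.yaml
```

`run` writes per-stage TSVs (counts, merged toxicity with per-replicate
values, position profile, enrichment and correlation matrices, structure
propensity tracks with empirical p-values) plus `report.md`/`report.json`;
every output records the seed, and re-running with the same seed
reproduces the numbers byte for byte.

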