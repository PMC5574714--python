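# tufkit

Quantitative analysis of **EF-Tu gene-replacement experiments** in *Escherichia
coli*. When the native `tufA` gene (encoding elongation factor Tu, the protein
that delivers aminoacyl-tRNA to the ribosomal A site) is replaced by a foreign
or reconstructed-ancestral homolog, the strain's fitness changes with the
evolutionary distance, expression level and catalytic quality of the
replacement. `tufkit` implements the full measurement-to-inference pipeline
for such experiments, for microbiologists and molecular-evolution researchers
working with plate-reader growth assays, β-galactosidase induction assays,
homolog alignments and protein-interaction networks.

## What it computes

**Growth kinetics.** From blank-corrected OD₆₀₀ time series, the exponential
phase is located as a 10-point (50 min at 5-min sampling) log-linear window
and fitted by ordinary least squares:

    DT  = ln 2 / slope                       (doubling time)
    lag = (initial log OD − y-intercept) / slope
    max OD = maximum blank-corrected OD over the run

Relative fitness of a strain is mean(reference DTs) / DT, averaged over
replicates, so the reference strain scores 1 and slower strains score < 1.

**Translation step time.** After lacZ induction, each sampled time point's
A₄₂₀/A₅₄₀ pair is corrected for reagent background and the time-zero sample
and linearized as √(A₄₂₀ − 1.75·A₅₄₀). The x-axis intercept of the rising
line is the *step time* — the time to complete the first β-galactosidase
chain — and the synthesis (elongation) rate is 1024 aa / step time.

**Sequence evolution.** Needleman–Wunsch global percent identity
(BLOSUM62, gap open 10 / extend 0.5, full-alignment-length denominator);
Poisson-corrected amino acid distance d = −ln(1 − p) with complete deletion
of gapped columns; patristic distances on newick trees; the
viability-discriminating column filter (columns identical in every
viability-supporting homolog but variant in ≥ 1 non-supporting homolog),
with positions mapped to reference coordinates and partitioned across the
three EF-Tu structural domains; the codon adaptation index as the geometric
mean of relative-adaptiveness weights.

**Interactome connectivity.** Degree centrality, first-neighbor subnetworks
and a one-sided hypergeometric test for essential-protein enrichment of a
protein's interaction partners.

**Correlation layer.** OLS regressions (R², slope p-value) among per-strain
fitness, divergence, EF-Tu abundance and synthesis rate, plus the unpaired
two-tailed t-test; reconstructed-ancestor records can be excluded from
extant-only fits.

**Synthetic data.** Every input kind can be generated with known ground
truth (growth curves, induction assays, Poisson-diverged homolog families
with planted discriminating columns, scale-free interactomes), which is how
the whole pipeline is validated end to end.

## Worked example

```python
import numpy as np
from tufkit import *

# simulate one Bioscreen run at the native strain's parameters and re-estimate
p = GrowthSimParams(doubling_time=25.0, lag_time=6.8, max_od=1.39,
                    noise_sd=0.005, seed=42)
(sample, blank), = simulate_growth_curve(p, strain_id="E_coli")
g = analyze_curve(sample, blank)
print(f"DT={g.doubling_time:.2f} min  lag={g.lag_time:.2f} min  max OD={g.max_od:.3f}")

# relative fitness of a slow strain (DT 41.5) against the reference (DT 25.0)
ref = [analyze_curve(*pair) for pair in simulate_growth_curve(
    GrowthSimParams(doubling_time=25.0, lag_time=6.8, max_od=1.39,
                    noise_sd=0.005, replicates=3, seed=1))]
slow = [analyze_curve(*pair) for pair in simulate_growth_curve(
    GrowthSimParams(doubling_time=41.5, lag_time=300.2, max_od=1.38,
                    noise_sd=0.005, replicates=3, seed=2))]
print(f"relative fitness = {relative_fitness(slow, ref).fitness:.3f}")

# step time from simulated induction assays (truth 60 s)
ests = []
for seed in range(100):
    s = simulate_induction_assay(InductionSimParams(
        step_time=60.0, accumulation_slope=0.002, noise_sd=0.005, seed=seed))
    ests.append(estimate_step_time(schleif_transform(s)).step_time)
print(f"mean step time over 100 assays = {np.mean(ests):.2f} s")

# Poisson-corrected distance at 10% observed difference
print(f"d = {poisson_distance('A'*10, 'C' + 'A'*9).poisson_d:.6f}")
```

Output:

```
DT=24.89 min  lag=6.77 min  max OD=1.411
relative fitness = 0.605
mean step time over 100 assays = 59.49 s
d = 0.105361
```

The doubling time and lag are recovered within the read-noise floor of a
single well; a strain growing at DT 41.5 min scores ~0.60 relative fitness
against a 25-min reference; the step-time estimator is unbiased at 20-s
sampling resolution; and −ln(1 − 0.1) = 0.105361 substitutions/site.

A command-line interface mirrors the library
(`tufkit simulate|growth|steptime|identity|distance|discriminate|cai|centrality|enrich|correlate|run`);
`tufkit run --seed 7 --out demo/` executes the whole synthetic pipeline and
writes per-stage TSV reports plus a reproducibility manifest.

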