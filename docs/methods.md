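# Methods

This note documents the models, estimators and design choices behind
`tufkit`, and what the synthetic-data validation does and does not
demonstrate about real assay data.

## Growth-curve model and estimator

**Generator.** A well's blank-corrected OD₆₀₀ is piecewise: a flat inoculum
plateau at `initial_od` until `lag_time`, exponential doubling every
`doubling_time` minutes, and a hard cap at `max_od`. Read noise is additive
Gaussian (`noise_sd`, default 0.005 OD for validation runs) on both the
sample and its medium-only blank well, truncated to keep readings positive.
This deliberately simple flat→exponential→cap shape (rather than a Baranyi
or logistic model) makes the exponential phase exactly log-linear, so the
downstream estimator has an exact inverse and every recovery test has an
unambiguous truth. Defaults: 5-min sampling over 24 h, `blank_od` 0.09
(medium plus plate background), `initial_od` 0.2. The inoculum density
matters for identifiability: the lag estimate hinges on the few pre-growth
points, whose *relative* noise is `noise_sd/initial_od`; at a
dilute-to-OD-0.2 inoculum the lag of even slowly growing strains
(DT ≈ 67 min, lag ≈ 7 min) is resolvable at 5-min sampling, whereas at
100-fold-dilution densities (≈ 0.01–0.05) it is not. We therefore model the
standardized-inoculum protocol.

**Estimator.** Sample wells are corrected by per-time-point blank
subtraction and log-transformed; points at or below a floor (default 1e-4)
are masked, not clamped, to avoid log singularities. The exponential phase
is the contiguous window of exactly 10 usable points (50 min) selected as
follows: all windows are ranked on a 9-point centered moving average of the
log curve, and the *earliest* window whose smoothed slope lies within two
standard errors of the argmax window's slope is chosen. Two details are
deliberate:

* ranking on the raw curve would make the selection an argmax over ~300
  correlated noisy slopes, which is biased upward (we measured 6–19%
  doubling-time underestimation at 0.005 OD noise); the smoothed ranking
  plus the consistency band removes that selection bias while reducing to
  the plain max-slope rule (ties → earlier start) on noiseless data, since
  the standard error is then zero;
* the reported slope, intercept and R² always come from a raw OLS refit of
  the chosen window, so `DT = ln2/slope` and the lag formula keep their
  plain least-squares meaning.

The "initial OD" entering the lag formula is a plateau estimate rather than
the single first reading: points before the window whose fitted-line value
lies below the current level estimate are averaged on the OD scale
(fixed-point iteration, ≤ 8 rounds). Because membership is decided by the
precise fitted line rather than the noisy readings, the estimate is stable;
for a curve with no lag it degenerates to the first reading, so lag 0 is
recovered exactly. A completely flat series returns slope 0 with an
undefined (NaN) R² and a `degenerate` flag; a non-positive slope yields NaN
doubling time and lag but still reports max OD.

**Relative fitness** is mean(reference DTs)/DT per replicate, then averaged —
slower growth < 1, and it is invariant under rescaling all DTs. Technical
replicates are fitted per well and enter fitness at per-measurement
granularity.

**Validation scope.** Recovery tests (median of 20 simulated wells: DT
within 5%, lag within 15%, max OD within 2% at 0.005 OD noise) quantify the
estimator under the generator's assumptions: white Gaussian read noise and
a truly log-linear phase. Real plate-reader data add condensation drift,
diauxic shoulders and well-to-well gain differences that the generator does
not emulate; passing these tests shows the inference chain is correct and
noise-calibrated, not that those artifacts are handled. The slowest-growth
parameterization (DT 66.9, lag 7.3 min) sits near the information floor of
the assay — the spread of the median lag across seed batches is comparable
to the 15% band — so occasional excursions beyond that band reflect the
assay's resolution, not estimator bias (measured bias < 0.2 min over 120
seeds).

## Induction assay and step time

The transformed signal √(A₄₂₀ − 1.75·A₅₄₀), after subtracting reagent
background and the background-corrected time-zero sample per channel, is
zero until the first complete β-galactosidase molecule appears and rises
linearly afterwards. The generator writes raw A₄₂₀/A₅₄₀ pairs that invert
exactly through that correction: A₅₄₀ carries a slow linear scattering
drift, A₄₂₀ carries the matching 1.75× term plus z·|z| where
z = truth + noise, so the corrected transform returns max(0, z). Negative
square-root operands are clamped to zero and flagged — they occur
legitimately before induction.

The estimator separates the zero plateau from the rising limb with a noise
threshold of 3× the standard deviation of the pre-induction (up to the last
non-positive) transformed values, then fits OLS over trailing suffix
windows of at least `min_fit_points` (default 4) points, keeping the
highest-R² suffix (ties → longer). The suffix convention reflects that the
transform is provably linear only after the first complete chain. Step time
is the x-intercept −intercept/slope; `synthesis_rate · step_time = 1024`
holds identically by construction. A non-positive slope or non-negative
intercept raises a no-induction error rather than returning a nonsense
intercept. At 20-s sampling and 0.005 noise on the transformed scale the
estimator is unbiased to within Monte-Carlo error (mean over 100 assays
within 5% of truth); single assays carry ~5 s spread, which is the
sampling-resolution floor, not a defect.

## Homolog families, distances and the discriminating-column filter

**Substitution process.** Each homolog draws a Poisson(d·L) number of
substitution events; each event targets a uniform position (outside planted
columns) and writes a uniformly chosen non-ancestral residue, independent of
previous hits. A site therefore differs from the ancestor iff hit at least
once, giving E[proportion differing] = 1 − e^(−d) exactly (no back-mutation
to the ancestral state), which is the precise inverse of the Poisson
correction d = −ln(1 − p). This makes the distance estimator's
unbiasedness testable without approximation; the cost is that the process
is not a full 20-state Markov chain (no reversions), which matters only at
distances where real sequences saturate.

**Distances.** p is computed after complete deletion of gapped columns;
d = −ln(1 − p), with p = 1 flagged as infinite rather than an error.
Pairwise identity uses biopython's global (Needleman–Wunsch) aligner with
BLOSUM62 and gap open 10 / extend 0.5 — the EMBOSS-needle-style defaults —
and reports identical pairs over the full alignment length. The aligner's
canonical first traceback is used; it is deterministic across runs.
Patristic distances are path sums on newick trees via dendropy.

**Discriminating columns.** A column qualifies iff all
viability-supporting rows (reference included) carry one identical non-gap
residue and ≥ 1 non-supporting row differs, a gap counting as a difference
(a conservation statement cannot hold across a gap). Planted columns are
excluded from background substitution so they are never destroyed in viable
rows (no false negatives). A background column can still qualify by chance
— whenever no viable row happens to be mutated there but a nonviable row is
— so with `ensure_exact_recovery` (default) the generator reverts such
nonviable-only differences, making the planted set and the filter's output
identical by construction. Recovery tests therefore check the filter's
correctness, not its behavior on columns that are only statistically
conserved; on real alignments the filter reports every column meeting the
definition, with no significance calibration. Domain partitioning uses the
conventional *E. coli* EF-Tu boundaries (G domain 1–200, domain 2 201–299,
domain 3 300–393), configurable because structural assignments vary by a
few residues between studies.

**CAI** is the geometric mean of relative-adaptiveness weights over codons
with a synonymous choice (ATG, TGG and stops excluded), computed in log
space; weights must be positive and are supplied as a table, so any
reference weight set can be used.

## Interactome analyses

Interactions form a simple undirected graph; duplicate records and
self-loops are dropped with a count. Degree centrality, mean degree and a
deterministic ranking (degree desc, then node id) come straight from the
graph; the first-neighbor subnetwork is the induced subgraph on a node and
its neighbors. Essential-protein enrichment is the one-sided hypergeometric
upper tail P(X ≥ overlap) with the whole loaded interactome as the
universe, evaluated through scipy's log-space survival function so P-values
at the 10⁻²⁰ scale are representable; it matches exact rational enumeration
on every universe ≤ 20 in the test suite. The toy generator grows
Barabási–Albert preferential-attachment graphs — scale-free degree
structure with a guaranteed hub — with Bernoulli essentiality flags and an
optional enriched hub neighborhood; it does not emulate interaction-score
noise or database redundancy.

## Regression layer

OLS via scipy with R² = squared Pearson correlation and the two-sided slope
t-test p-value; a constant response is defined as slope 0 / R² 0 / p 1 so
batch pipelines stay total, and a constant predictor raises. Group
comparisons default to the pooled-variance (Student) unpaired two-tailed
t-test with exact degrees of freedom; Welch is available by flag. Records
with missing fields are dropped per analysis (pairwise deletion), and
reconstructed-ancestor records can be excluded to reproduce extant-only
fits, where ancestral variants are known outliers on the
abundance–fitness axis.

## Reproducibility and problem sizes

Every generator takes one explicit seed; no global random state is used,
and identical seeds give bit-identical outputs, including through file
round-trips and the `run` pipeline (whose manifest records config, seed and
version). Validation sizes — 20 wells per growth parameterization, 100
induction assays per step time, 200 families per distance, 50 families for
filter recovery, 400-node interactomes — were chosen so the full suite runs
in a few seconds while keeping Monte-Carlo standard errors well inside the
stated tolerances.

## Known limitations

* The growth model has no death phase, no diauxie and homoscedastic noise;
  estimates on rich real curves should be inspected via the reported window
  and R².
* The induction generator encodes noise on the transformed scale; real
  absorbance noise is per-channel and approximately proportional to signal.
* The substitution process has no indels, no rate heterogeneity across
  sites and no codon structure; alignment inputs are taken as given.
* Identity percentages depend on the alignment-length denominator
  convention; comparisons with tools using ungapped denominators will
  differ by a few tenths of a percent.
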