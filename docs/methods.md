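# Methods

This note records the models, defaults and design choices behind
`kinscreen`, in the spirit of a statistical-methods appendix.  It states no
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Melt-curve model and fitting

A DSF well is modelled as a two-state thermal unfolding reported by an
environment-sensitive dye.  The fitted model is the four-parameter Boltzmann
sigmoid

    F(T) = f_pre + (f_post − f_pre) / (1 + exp((T_m − T)/a)),

with `f_pre`/`f_post` the folded/unfolded fluorescence baselines (AU), `T_m`
the unfolding midpoint (°C) and `a > 0` the transition width (°C).  Sloped
baselines and two-transition fits are deliberately out of scope: the
screen's readout is a shift of `T_m`, for which the flat-baseline sigmoid is
the field's standard choice.

Real SYPRO-Orange traces fall after the unfolding peak as the dye leaves
aggregating protein.  That regime is outside the model, so each curve is by
default truncated at its global fluorescence maximum before fitting
(`FitOptions.truncate_at_peak`).  Truncation is idempotent and never touches
a monotone trace.

Numerical choices:

* optimisation by bounded least squares (scipy `least_squares`, trust-region
  reflective), `T_m` constrained to the observed temperature range and `a`
  to (0.1, 20) °C; baselines unconstrained, preserving exact shift
  equivariance of the fit under additive fluorescence offsets;
* initial values: `T_m` from the steepest rise of a 3-point moving-average
  smoothed trace (robust to single-point spikes without biasing the
  midpoint), baselines from the first/last five points, width 2.0 °C; a
  flat trace falls back to the range midpoint and is then caught by QC;
* the logistic is evaluated through `expit`, so extreme arguments cannot
  overflow;
* convergence tolerances 1e-10 (relative), at most 2000 function
  evaluations.

QC rejects a fit that failed to converge, has `T_m` pinned at a range
boundary, explains less than `r_squared_floor = 0.9` of the variance, or has
non-positive amplitude (`f_post ≤ f_pre`, "no transition").  These
thresholds are package conventions, configurable in `FitOptions`; how
non-sigmoidal wells were excluded in comparable published screens is
generally unstated, so the rules here are the package's own and every
rejection carries machine-readable reason codes.

Accuracy, as measured by the suite: noiseless curves over the 25–95 °C ramp
are recovered to 0.01 °C across a grid of (T_m, width) values, and on noisy
curves the optimizer agrees with an exhaustive two-stage grid-search oracle
to 0.05 °C.  For generator curves with post-peak decay (below) the
truncation point sits ~2 transition-widths above `T_m`, so the upper plateau
is weakly constrained; single-curve errors at 2% amplitude noise are then
unbiased with mean ≤ 0.2 °C but individual curves can deviate by several
tenths of a degree — the reason screens use replicates.

## Thermal shifts and hit calling

For each kinase the DMSO vehicle wells define a reference: `tm_mean` and the
sample SD (n−1) of per-well control T_m values (`dtm_sd`).  At least two
QC-passing control wells are required; fewer is an error naming the kinase.
The shift of a (kinase, compound) pair is the mean of its QC-passing
replicate T_m values minus `tm_mean`.  Negative means are reported as 0 °C
— destabilisation is not the screen's readout — with the raw mean retained
and a `clamped` flag recorded.  Clamping is applied to the replicate mean
(mean-then-clamp), the less aggressive of the two possible orders.

A pair is a hit when its reported shift is **at or above**
`multiplier × dtm_sd` of its kinase (default multiplier 2.0, configurable).
QC-failed wells simply reduce the replicate count; a pair with no passing
well is reported absent and is never a hit.  A kinase with zero control SD
has a degenerate threshold: there any strictly positive shift counts, and a
warning is logged.  The DMSO SD is pooled per kinase across its plate set;
nothing in the data model prevents supplying per-plate references instead.

Percentages (hit rates, accounting ratios) are rounded half-up at one
decimal (or to whole percent where a coarser figure is conventional).  Note
that 43/627 = 6.858…% prints as 6.9% under this rule; published figures
occasionally truncate instead, which is the one known formatting divergence.

## Panel selection

The selection workflow assembles a representative kinase panel from a
kinome-wide annotation in six audited stages: expression filter (aggregated
expression ≥ 2.0 FPKM, inclusive), network prioritisation (top-k by
propagated score), family-coverage completion (one gene per still-uncovered
family), curated additions, domain filter, synthesis-failure removal.

* **Aggregation** over the expression libraries is max-over-libraries
  (a gene counts as expressed if any tissue/condition expresses it);
  mean aggregation is available.  Published panel-selection texts rarely say
  which was used — max is the permissive reading.
* **Network scoring**: the probabilistic gene networks used for trait
  enrichment in the literature do not publish a reproducible scoring rule,
  so the package uses seeded label propagation as a deterministic stand-in:
  `score' = α·score + (1−α)·(weight-normalised neighbour mean)`, α = 0.5,
  2 rounds, seeds = trait-associated genes at 1.0.  It is pluggable: any
  mapping of gene → score can be passed to `select_representatives`.
* **Determinism**: all ties break by aggregated expression (descending) then
  locus id (ascending), so identical inputs give byte-identical ledgers.

The ledger stores, per stage, in/out counts and the exact ids added or
removed, and `run_accounting` re-verifies the additive consistency of the
chain before computing any summary percentage, failing loudly on a
mismatch.

## Construct design

Boundary variants are the Cartesian product of N- and C-terminal offsets
applied to the annotated kinase domain, clipped to the protein, de-duplicated,
in deterministic (N, C) order.  Structure-guided boundary choice is out of
scope; the offsets are explicit inputs.  Each variant is expressed behind
the 23-residue N-terminal tag `MHHHHHHSSGVDLGTENLYFQSM` (His6 + TEV site);
TEV cleavage after the Q leaves an `SM-` scar.  Masses are average-isotopic
(Biopython's standard residue table plus one water), matching SDS-PAGE and
deconvoluted intact-mass usage; monoisotopic mode is a flag.  Masses are
printed to 2 decimals in tables but kept at full precision internally so
water-loss additivity holds to numerical precision.

## Synthetic data

The generators define the conditions under which the pipeline is validated.

**Curves** — Boltzmann sigmoid (defaults: baselines 100/1000 AU, T_m 55 °C,
width 2.5 °C) times an exponential post-peak decay starting
`decay_onset = 5 °C` above T_m with scale `decay_tau = 15 °C` (shapes chosen
to resemble typical SYPRO traces), plus additive Gaussian noise, sampled
25–95 °C at 0.5 °C.

**Screens** — defaults mirror the target experiment: 40 kinases × 627
compounds, triplicate wells, 16 DMSO wells per kinase (two control columns),
kinase base T_m uniform on 45–60 °C.  Promiscuity is heavy-tailed: 3.2% of
compounds draw a per-kinase binding probability uniform on (0.3, 0.8)
(the promiscuous tail), the rest uniform on (0, 0.025); binder shifts are
uniform on 1–8 °C.  This yields ~3% binder pairs overall and a ≥10-kinase
tail of roughly a dozen-to-two-dozen compounds, the qualitative shape such
panels show.

Tm noise is decomposed into a **condition-level** component
(`tm_noise_sd = 0.3 °C`, shared by the replicate wells of one
kinase–compound condition) and a small per-well jitter
(`replicate_jitter_sd = 0.05 °C`).  Same-plate replicates of the same
mixture drift together — protein batch and compound aliquot are shared — so
the dominant variance sits at the condition level; each DMSO well is its own
condition.  Under this model the replicate-mean shift of an inert compound
has essentially the SD of a single control well, so the 2×SD rule behaves
like a one-sided 2-σ test with an expected false-positive rate near the
normal tail value of ~2.3%; estimating the SD from 16 control wells (SD
estimator CV ≈ 18%) pushes the expectation modestly above that, which is why
the calibration band is stated as 1–4%.  Under a fully independent per-well
noise model the same rule would instead be a ~3.5-σ test on the triplicate
mean and the null rate would collapse to ≪ 1%.

**Kinomes** — 1467 genes in 63 families (Dirichlet-sized, minimum two genes
each) across the six kinase groups, 21 expression libraries.  Ground truth
is planted exactly: 975 genes exceed the 2.0 threshold (every family keeps
at least two); 141 of them, spread over the 45 families richest in expressed
genes, carry seed scores and form their own network component, so
propagation ranks exactly those genes on top; 3 curated genes, 15
domain-lacking flags and 18 synthesis failures are planted on the resulting
162-gene initial panel.  Non-expressed genes are capped strictly below
threshold, making the expression filter's planted recovery exact rather
than probabilistic.

**What the simulations do not capture**: instrument artifacts (edge-well
effects, dye depletion, drift within a ramp), compound autofluorescence,
concentration–response structure, correlated binding across related kinases,
and any real biology in the kinome tables.  Passing the calibration tests
therefore demonstrates the correctness and statistical behaviour of the
analysis, not the error rates to expect on a particular instrument.

## Problem sizes and reproducibility

The suite and the acceptance script size their simulations to what the
checks need: null calibration uses 40 kinases × 250 compounds (10,000
pairs), sensitivity 2,000 planted +3 °C pairs, curve-level end-to-end runs a
few hundred wells, and the kinome runs at full size (1467 genes — table
generation is cheap).  Every generator is a pure function of (parameters,
seed) with keyed substreams, so any subset of wells or genes regenerates
identically, pipeline runs are byte-reproducible, and every written artifact
is stamped with the configuration hash and seed.

## Known limitations

* The Boltzmann fit reports no parameter uncertainties; replicate spread is
  the intended error estimate at the shift level.
* Label propagation is a stand-in for whatever scoring a real gene network
  provides; panel compositions other than the planted scenario will differ.
* ΔT_m is not converted to binding affinity; ranking compounds by shift
  magnitude across kinases with different stabilities is not supported by
  the model.
* Re-analysis of an external ΔT_m matrix requires per-kinase DMSO SDs from a
  companion source, since published matrices typically omit them.
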