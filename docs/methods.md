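# Methods

This note documents the model, the numerical choices, the synthetic-data
generator and the known limitations of `cyclefit`. It states nothing the
test suite or `scripts/acceptance.py` does not itself compute.

## The cell-cycle Markov model

The population state is a vector of cell counts over four phases
(G1, S/G2, M, Multinucleated). One timestep is one hour. Permitted
transitions are: remain in the current phase; progress G1 → S/G2,
S/G2 → M; exit M either by division into two G1 daughters or by mitotic
failure into a permanent multinucleated state. The multinucleated row is
fixed at identity (absorbing), there is no death process, and every
other entry of the 4×4 transition matrix `P` is structurally zero. Each
row lies on the probability simplex over its free entries.

The update is an element-wise (Hadamard) weighting of per-flux terms,

    S_{n+1}[j] = Σ_i S_n[i] · P[i,j] · RM[i,j],

with the replication matrix `RM` equal to 1 on every permitted flux
except `RM[M,G1] = 2`. The element-wise reading — rather than a chained
matrix product `S·P·RM` — is deliberate: only the division flux doubles
cells. A true matrix product would leak the replication weight onto
fluxes that do not divide, which contradicts the biology the model
encodes. Two invariants follow and are tested: total count grows by
exactly `S[M]·P[M,G1]` each step, and the multinucleated count is
non-decreasing.

Dwell times are geometric: the expected duration of phase *i* is
`1/(1 − P[i,i])` hours, with a 1-hour floor (one timestep). Total cycle
duration sums the three cycling phases; the absorbing multinucleated
state is excluded. The mitotic success rate
`MSR = P[M,G1] / (P[M,G1] + P[M,Multi])` is the fraction of M-exit flux
that completes division.

## Loss and fitting

The loss is the arithmetic mean over the four phases of the per-phase
RMSRE, `sqrt(mean_t((pred − obs)²/obs²))`, computed over all supplied
timepoints (the seeded initial timepoint contributes zero in a fit).
Relative errors are undefined on zero observed counts; this is a hard
error by default, with an optional stabilizer `eps` added to the
denominators. Counts are normalized to the total at the earliest
timepoint before fitting (the propagation is linear, so only the scale
changes); the basis is recorded in the fit result.

Fitting is by random search with the following schedule: 15 epochs;
3000 candidates per epoch; the first epoch seeded with the identity
matrix; candidates drawn as `(1−lr)·seed + lr·R` with `R` a fresh
uniform-per-row-simplex matrix (two-entry rows by a uniform split, the
three-entry M row by a flat Dirichlet); learning rate
`lr = 0.1 · 0.5^floor((epoch−1)/2)`; the 5 lowest-error matrices kept as
the next epoch's seeds. Choices the schedule leaves open were fixed as
follows:

- **Candidate allocation.** Candidates are divided equally among the
  current seeds; any remainder goes to the best seed.
- **Elitism.** Seeds compete with their offspring for the top 5, so the
  best-so-far always survives and the per-epoch best-error trace is
  non-increasing (tested).
- **Tie-breaking.** Ties in top-5 selection resolve by generation order
  (stable sort), making fits bit-reproducible for a fixed RNG seed
  (tested).

All candidate trajectories in an epoch are propagated as one vectorized
batch, so a default fit of a 72-h series takes ~0.4 s on one CPU.

### Convergence properties and the noise floor

On noiseless 72-h series from matrices in the realistic cycling regime,
the default schedule recovers homotypic rates with median absolute error
well below 0.02 (tested over 10 random matrices). The residual RMSRE,
however, has an intrinsic floor set by the search kernel: starting from
the identity, a homotypic rate can fall at most to `Π(1−lr_e) ≈ 0.67`
over 15 epochs, and in slow-dynamics regimes the best error plateaus
around 1e-2..1e-1 even though the rates themselves are accurate. This is
exactly why the method carries a noise-floor estimator for fit errors: a
second-order loess (local quadratic, tricube weights, span 0.75),
implemented here directly because available Python smoothers are
degree-1 only, and verified against an independent reference local
regression to 1e-8. A related consequence is a small (few percent)
downward bias in the longest inferred durations, visible in the
acceptance output for the slowest conditions.

## Phase calling

Cells are classified from two ratios — perinuclear:nuclear mean
intensity and nuclear:cytoplasmic total intensity — plus the nucleus
count, with fixed thresholds 0.8 and 0.5: mononuclear cells with
peri:nuc > 0.8 and nuc:cyto < 0.5 are S/G2; cells (mono- or
multinucleated) with nuc:cyto > 0.8 and peri:nuc < 0.8 are M; remaining
mononuclear cells are G1 and remaining multinucleated cells are
Multinucleated. The thresholds are treated as fixed constants (they were
originally derived from manual annotation upstream of this package).
Boundary ties at exactly 0.8/0.5 fall through to the remainder rules — a
literal reading of the strict inequalities, documented so it is
auditable. The S/G2 and M predicates are mutually exclusive by
construction (peri:nuc cannot be both > 0.8 and < 0.8); a property test
asserts totality and single-valuedness over random feature grids.

Labeled cells are tallied per frame, smoothed with a centered 5-frame
moving average, downsampled to the frame nearest each integer hour, and
normalized to the total count at the earliest timepoint. Edge handling
and ties were open choices: windows shrink at the series edges (partial
windows averaged over available frames) so early timepoints needed for
normalization are not discarded, and hour-selection ties break toward
the earlier frame.

## Synthetic data

The generator defines study-like acquisition conditions: hourly-scale
dynamics over 72 h sampled at 15-min frames (4 frames/hour), initial
populations dominated by G1 and S/G2 (default 120/60/15/5 cells), no
death.

- **Population mode** propagates continuous expected counts with the
  replication-weighted matrix and is bit-identical to the deterministic
  trajectory when noise is off. Observed-count noise is optional
  (Poisson or multiplicative lognormal) and off by default, because the
  relationship between observed and expected counts is not part of the
  model; the noise models are stand-ins.
- **Agent mode** simulates integer cells: geometric dwell via per-hour
  Bernoulli transitions, division of M cells into two G1 daughters
  (fresh agent ids), permanent multinucleation on failure. Each agent
  emits reporter features per frame: the two calling ratios are drawn
  uniformly from the interior of the true phase's threshold region
  (margins keep noiseless draws strictly inside the decision regions,
  so the phase caller recovers the true phase for 100% of noiseless
  agent-frames — tested), then optional Gaussian ratio noise is added
  and the ratios are realized as arbitrary-unit intensities. A single
  global seed fans out to named substreams (agents, noise).

What agent mode does *not* emulate about real data: segmentation errors,
phototoxicity and focus drift, intensity distributions near the
thresholds (real cells straddle them; synthetic noiseless cells do not),
cell death, and frame-to-frame feature autocorrelation beyond the phase
itself. Passing round-trip tests therefore demonstrates the internal
consistency of calling → aggregation → smoothing → fitting, not
robustness to imaging artifacts.

Two details matter when comparing agent tallies to the population model.
First, agent phases are piecewise-constant between hourly transitions,
while the 5-frame moving average spans 1.25 h, so smoothing mixes two
adjacent hourly states (2 of the 5 frames in a centered window belong to
the previous hour). This deterministic smearing does not vanish with
more agents; law-of-large-numbers comparisons therefore push the
expected counts through the identical smoothing pipeline, which isolates
agent sampling noise (~0.006 maximum absolute deviation in hourly
fractions at 10⁴ agents, against a 2% tolerance). Second, parameter-
recovery experiments draw true matrices from the realistic dwell-time
regime (G1 4–40 h, S/G2 10–80 h, M 3.5–20 h, MSR 0.3–1, log-uniform)
rather than uniformly from the simplex: the identity-seeded schedule can
only reach homotypic rates ≥ ~0.67, so arbitrary simplex points are
structurally outside the estimator's reach — and outside the biological
regime the method targets.

The six named study conditions are parameterized by (G1, S/G2, M,
MSR) dwell-time tuples. Control and ELF3-knockdown durations follow the
reported fits for those conditions; the per-phase splits of the
paclitaxel-alone and combination conditions are not individually
reported, so they were chosen once to respect the reported total cycle
durations and per-phase HSA ratios (e.g. paclitaxel alone:
11 + 54 + 19.4 = 84.4 h with a long M phase, as expected for a
microtubule poison; the combination conditions then realize the reported
G1-synergy ratios against the larger single agent).

## Screen scoring

Percent inhibition is `100·(1 − count/control)` against the matched
vehicle + non-targeting control. The multinucleation test is the
two-sample proportions test implemented as a chi-square test with Yates
continuity correction (the common default of the named test; verified
against an independent reference implementation to 6 decimals), with
Bonferroni correction applied by the caller over an explicitly chosen
family (the original family definitions are not fixed; the CLI corrects
per cell line × treatment). Z′ uses sample standard deviations.
Phenotype distances z-score each feature across the screened population
(population SD, ddof 0) and drop zero-variance features with a warning
rather than producing infinities. EdU gating gives EdU-positivity
precedence over the DNA-content split; gate thresholds are user-supplied
config, since they are derived per-plate upstream. The apoptosis-marker
cutoff is the empirical 99th percentile of vehicle-control intensities.
The normalized growth-rate metric
`2^(log2(c_t/c_0)/log2(ctrl_t/ctrl_0)) − 1` is undefined for
non-growing controls and errors in that case.

The prediction-agreement score,
`100·(1 − mean(|pred − obs|/obs))`, is this package's own
operationalization of "percent agreement with observed counts"; no
standard definition exists, so it is labeled artifact-defined.

## Problem sizes and acceptance output

`scripts/acceptance.py` fits the six study conditions on noiseless 72-h
series (best of 5 random-search restarts each, the restart protocol
appropriate for a stochastic fit), runs the 10-matrix recovery
experiment, and measures the round trip at 10⁴ agents over 24 h — sizes
chosen so a full run completes in well under a minute on one CPU while
keeping sampling error far below the tolerances tested.

## Known limitations

- Transition rates are constant in time; weakening drug or knockdown
  effects over the 72-h window are not modeled.
- Population-level fits cannot distinguish homogeneous from
  heterogeneous dwell-time distributions; lineage tracking would be
  required.
- The RMSRE noise floor and the associated downward bias on very long
  durations (above) are properties of the fixed search budget.
- No apoptosis state: cell loss would be absorbed into biased transition
  rates rather than modeled explicitly.
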