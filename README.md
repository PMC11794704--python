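# cyclefit

Cell-cycle phase calling and constrained Markov modeling for live-cell
imaging time series.

Many anti-cancer drugs (and gene knockdowns) act by slowing or blocking
specific cell-cycle phases. Given live-cell imaging of a
translocation-based cell-cycle reporter, `cyclefit` answers three
questions quantitatively:

1. **Which phase is each cell in?** A rule-based classifier assigns
   G1, S/G2, M or a permanent multinucleated state from two reporter
   intensity ratios and the nucleus count.
2. **How fast do cells move between phases?** A discrete-time Markov
   model with division is fitted to the phase-count time series, yielding
   per-phase transition rates, mean phase durations and the mitotic
   success rate.
3. **Do a drug and a knockdown synergize?** Inferred phase durations are
   compared under a highest-single-agent (HSA) model.

It also scores fixed-cell siRNA × drug screens (percent inhibition,
multinucleation proportions tests, Z′-factor, z-scored phenotype
distances, EdU/DNA-content gating) and ships a synthetic-data generator
so the entire pipeline is testable without any imaging data.

## The model

Cells occupy one of four states ordered (G1, S/G2, M, Multinucleated).
Over one timestep (1 h) a cell may stay put, progress G1 → S/G2 → M, or
leave M either by dividing into two G1 daughters or by failing mitosis
into the absorbing multinucleated state. With phase counts `S_n`, a
row-stochastic transition matrix `P` constrained to that pattern and the
constant replication matrix `RM` (all permitted fluxes weight 1 except
`RM[M, G1] = 2`), the update weights each flux element-wise:

```
S_{n+1}[j] = Σ_i  S_n[i] · P[i, j] · RM[i, j]
```

so total cell count grows by `S[M] · P[M, G1]` per hour and never
shrinks. The model is fitted to observed counts by random search: 15
epochs, 3000 candidate matrices per epoch drawn as convex steps of size
`lr` (0.1, halving every 2 epochs) from the current seeds toward fresh
uniform random matrices, keeping the 5 lowest-error matrices as seeds,
starting from the identity matrix. The loss is the arithmetic mean over
phases of the per-phase root-mean-squared relative error (RMSRE):

```
RMSRE = √( 1/n · Σ_t (c_pred − c_obs)² / c_obs² )
```

Dwell times are geometric, so the expected duration of phase *i* is
`1 / (1 − P[i,i])` hours, and the mitotic success rate is
`MSR = P[M,G1] / (P[M,G1] + P[M,Multi])`.

## Worked example

Generate a noiseless 72-h series from a known matrix (G1 7.9 h, S/G2
37.7 h, M 3.4 h, 95% mitotic success), then recover the rates:

```python
from cyclefit import (MarkovCellCycleModel, TransitionMatrix, trajectory,
                      expected_duration, mitotic_success_rate)

truth = TransitionMatrix.from_dwell_times(7.9, 37.7, 3.4, mitotic_success_rate=0.95)
obs = trajectory([120, 60, 15, 5], truth, n_hours=72)

model = MarkovCellCycleModel(random_state=0).fit(obs)
dur = expected_duration(model.transition_matrix_)
print(f"RMSRE            {model.rmsre_:.4f}")
print(f"G1 duration      {dur.g1_hours:.1f} h")
print(f"S/G2 duration    {dur.sg2_hours:.1f} h")
print(f"M duration       {dur.m_hours:.1f} h")
print(f"total cycle      {dur.total_hours:.1f} h")
print(f"mitotic success  {mitotic_success_rate(model.transition_matrix_):.3f}")
```

prints

```
RMSRE            0.0150
G1 duration      7.9 h
S/G2 duration    37.6 h
M duration       3.4 h
total cycle      48.9 h
mitotic success  0.946
```

i.e. the search recovers the generating dwell times to within ~1% and
the mitotic success rate to within half a percentage point. The same
pipeline is available from the shell (`cyclefit simulate`,
`cyclefit call-phases`, `cyclefit fit`, `cyclefit metrics`,
`cyclefit screen`); see `cyclefit --help`.

`MarkovCellCycleModel` and `ThresholdPhaseClassifier` follow scikit-learn
conventions (`get_params`/`set_params`, fitted attributes with trailing
underscores), so they compose with sklearn model-selection tooling.

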