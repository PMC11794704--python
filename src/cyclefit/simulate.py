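"""Synthetic live-cell data with the statistical structure the analysis assumes.

Two generators share one true transition matrix:

* :func:`simulate_population` propagates expected phase counts with the
  replication-weighted matrix — the deterministic forward model — and can
  add observation noise (Poisson or multiplicative lognormal) on top.
* :func:`simulate_agents` runs individual cells: geometric dwell times
  from the homotypic rates, division of M cells into two G1 daughters or
  permanent multinucleation on mitotic failure, no death.  Each agent
  emits reporter-intensity features at the frame rate (default 15-min
  frames, i.e. 4 per hour) drawn from the interior of its true phase's
  threshold region, so the phase caller recovers the true phase exactly
  in the noiseless case.

The generators define study-like acquisition conditions: hourly-scale
dynamics observed over up to 72 h at 15-min frames, with initial
populations dominated by G1 and S/G2 cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import FEATURE_COLUMNS
from .matrices import TransitionMatrix
from .model import trajectory
from .phases import G1, M, MULTI, PHASES, SG2
from .series import PhaseCountSeries

#: Interior of each phase's threshold region in ratio space
#: (peri:nuc mean ratio, nuc:cyto total ratio).  Margins keep noiseless
#: draws strictly inside the decision regions.
_RATIO_REGIONS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "G1": ((0.20, 0.75), (0.55, 0.75)),
    "S/G2": ((0.85, 1.30), (0.10, 0.45)),
    "M": ((0.20, 0.75), (0.85, 1.30)),
    "Multinucleated": ((0.20, 0.75), (0.20, 0.75)),
}


@dataclass
class SimulationConfig:
    """Conditions for a synthetic acquisition.

    Parameters
    ----------
    true_matrix:
        The generating transition matrix.
    initial_counts:
        Cells per phase at t=0 (continuous allowed in population mode;
        rounded to integers in agent mode).  Default is a cycling
        population of 200 cells dominated by G1 and S/G2.
    n_hours:
        Observation span (>= 2); default 72 h.
    frames_per_hour:
        Imaging rate for agent-level feature emission; default 4
        (15-min frames).
    intensity_noise_sd:
        SD of Gaussian noise added to the emitted intensity ratios.
    count_noise_model:
        Observation noise on population counts: "none", "poisson", or
        "lognormal" (multiplicative, with ``lognormal_sigma``).
    seed:
        Global seed; fans out to named substreams for agents and noise.
    """

    true_matrix: TransitionMatrix
    initial_counts: np.ndarray = field(
        default_factory=lambda: np.array([120.0, 60.0, 15.0, 5.0])
    )
    n_hours: int = 72
    frames_per_hour: int = 4
    intensity_noise_sd: float = 0.0
    count_noise_model: str = "none"
    lognormal_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.initial_counts = np.asarray(self.initial_counts, dtype=float)
        if self.initial_counts.shape != (4,):
            raise ValueError("initial_counts must have one entry per phase")
        if np.any(self.initial_counts < 0) or self.initial_counts.sum() <= 0:
            raise ValueError("initial counts must be >= 0 with a positive total")
        if self.n_hours < 2:
            raise ValueError("n_hours must be >= 2")
        if self.frames_per_hour < 1:
            raise ValueError("frames_per_hour must be >= 1")
        if self.intensity_noise_sd < 0:
            raise ValueError("intensity_noise_sd must be >= 0")
        if self.count_noise_model not in ("none", "poisson", "lognormal"):
            raise ValueError(
                f"unknown count_noise_model {self.count_noise_model!r}; "
                "expected 'none', 'poisson' or 'lognormal'"
            )
        if not isinstance(self.true_matrix, TransitionMatrix):
            self.true_matrix = TransitionMatrix(np.asarray(self.true_matrix))

    def _streams(self) -> dict[str, np.random.Generator]:
        root = np.random.SeedSequence(self.seed)
        agents, noise = root.spawn(2)
        return {
            "agents": np.random.default_rng(agents),
            "noise": np.random.default_rng(noise),
        }


def simulate_population(config: SimulationConfig) -> PhaseCountSeries:
    """Hourly expected phase counts under the true matrix.

    With ``count_noise_model='none'`` the output equals the deterministic
    trajectory exactly; otherwise observation noise is applied per count.
    """
    series = trajectory(config.initial_counts, config.true_matrix, config.n_hours)
    if config.count_noise_model == "none":
        return series
    rng = config._streams()["noise"]
    counts = series.counts
    if config.count_noise_model == "poisson":
        noisy = rng.poisson(counts).astype(float)
    else:  # lognormal
        noisy = counts * rng.lognormal(0.0, config.lognormal_sigma, size=counts.shape)
    return PhaseCountSeries.from_counts(series.times, noisy)


# ---------------------------------------------------------------------------
# agent-level simulation
# ---------------------------------------------------------------------------

def _emit_features(
    phases: np.ndarray, rng: np.random.Generator, noise_sd: float
) -> pd.DataFrame:
    """Reporter-intensity features consistent with each agent's true phase.

    The two phase-calling ratios are drawn uniformly from the interior of
    the phase's threshold region, optionally jittered with Gaussian noise,
    then realized as intensity values (nuclear mean and total drawn at
    plausible arbitrary-unit scales, perinuclear mean and cytoplasmic
    total back-computed from the ratios).
    """
    n = len(phases)
    peri_nuc = np.empty(n)
    nuc_cyto = np.empty(n)
    nucleus_count = np.ones(n, dtype=int)
    for phase, ((r1_lo, r1_hi), (r2_lo, r2_hi)) in _RATIO_REGIONS.items():
        mask = phases == PHASES.index(phase)
        k = int(mask.sum())
        if k == 0:
            continue
        peri_nuc[mask] = rng.uniform(r1_lo, r1_hi, size=k)
        nuc_cyto[mask] = rng.uniform(r2_lo, r2_hi, size=k)
        if phase == "Multinucleated":
            nucleus_count[mask] = rng.integers(2, 5, size=k)
    if noise_sd > 0:
        peri_nuc = np.clip(peri_nuc + rng.normal(0, noise_sd, n), 1e-6, None)
        nuc_cyto = np.clip(nuc_cyto + rng.normal(0, noise_sd, n), 1e-6, None)
    nuclear_mean = rng.uniform(800.0, 1200.0, size=n)
    nuclear_total = nuclear_mean * rng.uniform(150.0, 300.0, size=n)
    return pd.DataFrame(
        {
            "nucleus_count": nucleus_count,
            "nuclear_total_intensity": nuclear_total,
            "cytoplasmic_total_intensity": nuclear_total / nuc_cyto,
            "nuclear_mean_intensity": nuclear_mean,
            "perinuclear_mean_intensity": peri_nuc * nuclear_mean,
        }
    )


def simulate_agents(
    config: SimulationConfig, emit_features: bool = True
) -> pd.DataFrame:
    """Individual-cell simulation emitting one record per agent per frame.

    Hourly dynamics: each cell stays in its phase with the homotypic rate
    (geometric dwell), progresses G1 -> S/G2 -> M, and at M-exit either
    divides into two G1 daughters (a fresh agent id joins the population)
    or becomes permanently multinucleated.  The phase is piecewise
    constant between hourly transitions; frames sample it every
    ``1/frames_per_hour`` hours.

    Returns a table with :data:`~cyclefit.calling.FEATURE_COLUMNS` plus a
    ``true_phase`` column (feature columns omitted when
    ``emit_features=False``).
    """
    rng = config._streams()["agents"]
    P = config.true_matrix.values

    n0 = np.round(config.initial_counts).astype(int)
    phase = np.repeat(np.arange(4), n0)
    rng.shuffle(phase)
    ids = np.arange(len(phase))
    next_id = len(phase)

    frames_per_hour = config.frames_per_hour
    chunks: list[pd.DataFrame] = []

    def _record_block(hour: int, last: bool) -> None:
        nonlocal chunks
        # frames covering [hour, hour+1), plus the final frame at n_hours
        k = 1 if last else frames_per_hour
        offsets = np.arange(k) / frames_per_hour
        n = len(ids)
        block = pd.DataFrame(
            {
                "cell_id": np.tile(ids, k),
                "time_h": np.repeat(hour + offsets, n),
                "true_phase": np.tile(np.asarray(PHASES, dtype=object)[phase], k),
            }
        )
        chunks.append(block)

    for hour in range(config.n_hours):
        _record_block(hour, last=False)
        u = rng.random(len(phase))
        new_phase = phase.copy()
        g1 = phase == G1
        new_phase[g1 & (u >= P[G1, G1])] = SG2
        sg2 = phase == SG2
        new_phase[sg2 & (u >= P[SG2, SG2])] = M
        m = phase == M
        divide = m & (u < P[M, G1])
        fail = m & (u >= P[M, G1] + P[M, M])
        new_phase[divide] = G1
        new_phase[fail] = MULTI
        n_new = int(divide.sum())
        phase = np.concatenate([new_phase, np.full(n_new, G1, dtype=phase.dtype)])
        ids = np.concatenate([ids, np.arange(next_id, next_id + n_new)])
        next_id += n_new
    _record_block(config.n_hours, last=True)

    records = pd.concat(chunks, ignore_index=True)
    records = records.sort_values(["time_h", "cell_id"], ignore_index=True)
    if emit_features:
        feat_rng = config._streams()["noise"]
        phases_idx = np.array(
            [PHASES.index(p) for p in records["true_phase"]], dtype=int
        )
        feats = _emit_features(phases_idx, feat_rng, config.intensity_noise_sd)
        records = pd.concat([records, feats], axis=1)
        records = records[FEATURE_COLUMNS + ["true_phase"]]
    return records


def random_study_matrix(rng: np.random.Generator) -> TransitionMatrix:
    """A random transition matrix from the realistic dwell-time regime.

    Dwell times are drawn log-uniformly within ranges spanning the
    conditions observed in paclitaxel/knockdown experiments (G1 4-40 h,
    S/G2 10-80 h, M 3.5-20 h) with a mitotic success rate in [0.3, 1].
    Used for parameter-recovery experiments, where the regime of interest
    is cycling populations rather than arbitrary points of the simplex.
    """
    def loguni(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return TransitionMatrix.from_dwell_times(
        g1_hours=loguni(4.0, 40.0),
        sg2_hours=loguni(10.0, 80.0),
        m_hours=loguni(3.5, 20.0),
        mitotic_success_rate=float(rng.uniform(0.3, 1.0)),
    )


#: Generating matrices for the six live-cell study conditions, expressed as
#: (G1 h, S/G2 h, M h, mitotic success rate) dwell-time parameterizations.
#: Control and ELF3-knockdown phase durations follow the reported fits; the
#: per-phase split of the paclitaxel and combination conditions is chosen to
#: respect their reported total cycle durations and G1-synergy behaviour.
STUDY_CONDITIONS: dict[str, tuple[float, float, float, float]] = {
    "DMSO_siNonTarget": (7.9, 37.7, 3.4, 0.95),
    "DMSO_siELF3": (33.5, 72.1, 9.4, 0.75),
    "PTX_siNonTarget": (11.0, 54.0, 19.4, 0.40),
    "PTX_siELF3": (85.4, 60.6, 14.0, 0.30),
    "DMSO_siIRF9": (12.0, 45.0, 5.0, 0.90),
    "PTX_siIRF9": (23.16, 100.98, 34.92, 0.35),
}


def study_condition_matrix(name: str) -> TransitionMatrix:
    """True matrix for one named study condition."""
    g1, sg2, m, msr = STUDY_CONDITIONS[name]
    return TransitionMatrix.from_dwell_times(g1, sg2, m, msr)
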