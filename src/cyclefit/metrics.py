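"""Quantities derived from fitted transition matrices.

Phase dwell times are geometric under the model, so the expected duration
of phase i is ``1 / (1 - P_ii)`` hours; total cycle duration sums the
three cycling phases (the multinucleated state is absorbing and not part
of the cycle).  The mitotic success rate is the fraction of M-exit flux
that completes division rather than failing into multinucleation.  Drug x
knockdown synergy is scored with the highest-single-agent (HSA) model on
inferred durations: per phase, combination duration divided by the larger
single-agent duration, with ratio > 1 indicating synergy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import TransitionMatrix
from .phases import G1, M, MULTI, SG2
from .series import PhaseCountSeries


@dataclass(frozen=True)
class PhaseDurations:
    """Inferred mean dwell times (hours) for the three cycling phases."""

    g1_hours: float
    sg2_hours: float
    m_hours: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not np.isfinite(v) or v < 1.0:
                raise ValueError(
                    f"{name} duration must be finite and >= 1 h (one timestep), got {v}"
                )

    @property
    def total_hours(self) -> float:
        """Total cell-cycle duration: G1 + S/G2 + M."""
        return self.g1_hours + self.sg2_hours + self.m_hours

    def as_dict(self) -> dict[str, float]:
        return {"G1": self.g1_hours, "S/G2": self.sg2_hours, "M": self.m_hours}


class InfiniteDurationError(ValueError):
    """Raised when a homotypic rate of 1 makes a phase duration infinite."""


def expected_duration(matrix: TransitionMatrix) -> PhaseDurations:
    """Expected phase durations 1/(1-P_ii) from the homotypic rates."""
    p = np.asarray(matrix)
    out = {}
    for name, idx in (("G1", G1), ("S/G2", SG2), ("M", M)):
        rate = p[idx, idx]
        if rate >= 1.0:
            raise InfiniteDurationError(
                f"homotypic rate for {name} is {rate}; duration 1/(1-p) is infinite"
            )
        out[name] = 1.0 / (1.0 - rate)
    return PhaseDurations(out["G1"], out["S/G2"], out["M"])


def mitotic_success_rate(matrix: TransitionMatrix) -> float:
    """MSR = P[M,G1] / (P[M,G1] + P[M,Multi])."""
    p = np.asarray(matrix)
    to_g1, to_multi = p[M, G1], p[M, MULTI]
    denom = to_g1 + to_multi
    if denom <= 0:
        raise ValueError(
            "mitotic success rate undefined: no M-exit flux (P[M,G1] + P[M,Multi] = 0)"
        )
    return float(to_g1 / denom)


@dataclass(frozen=True)
class SynergyReport:
    """Per-phase HSA duration ratios with qualitative interpretation."""

    g1_ratio: float
    sg2_ratio: float
    m_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {"G1": self.g1_ratio, "S/G2": self.sg2_ratio, "M": self.m_ratio}

    def interpretation(self) -> dict[str, str]:
        """'synergy' (>1), 'none' (=1) or 'antagonism' (<1) per phase."""
        return {
            phase: ("synergy" if r > 1 else "none" if r == 1 else "antagonism")
            for phase, r in self.as_dict().items()
        }


def hsa_ratio(
    combo: PhaseDurations, agent_a: PhaseDurations, agent_b: PhaseDurations
) -> SynergyReport:
    """Highest-single-agent ratios: combo duration / max single-agent duration.

    Symmetric in the two single agents.
    """
    ratios = {
        phase: combo.as_dict()[phase]
        / max(agent_a.as_dict()[phase], agent_b.as_dict()[phase])
        for phase in ("G1", "S/G2", "M")
    }
    return SynergyReport(ratios["G1"], ratios["S/G2"], ratios["M"])


def prediction_agreement(
    pred: PhaseCountSeries | np.ndarray, obs: PhaseCountSeries | np.ndarray
) -> float:
    """Percent agreement between predicted and observed counts.

    Defined here as ``100 * (1 - mean(|pred - obs| / obs))`` over all
    phases and timepoints — this package's operationalization of an
    agreement score (the quantity has no single standard definition).
    """
    p = pred.counts if isinstance(pred, PhaseCountSeries) else np.atleast_2d(np.asarray(pred, float))
    o = obs.counts if isinstance(obs, PhaseCountSeries) else np.atleast_2d(np.asarray(obs, float))
    if p.shape != o.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {o.shape}")
    if np.any(o == 0):
        raise ValueError("observed counts must be positive for relative agreement")
    return float(100.0 * (1.0 - np.mean(np.abs(p - o) / o)))
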