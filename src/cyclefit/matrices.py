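"""Constrained transition matrices for the cell-cycle Markov model.

The model permits a cell to remain in its current phase, to progress
G1 -> S/G2 -> M -> G1 (the M -> G1 transition producing two daughters),
or to fail mitosis into a permanent multinucleated state.  Every other
transition is forbidden, which gives the transition matrix a fixed
sparsity pattern over the phase ordering (G1, S/G2, M, Multinucleated)::

    G1    | p  p  0  0
    S/G2  | 0  p  p  0
    M     | p  0  p  p
    Multi | 0  0  0  1

Each row lies on the probability simplex over its free entries; the
multinucleated row is fixed (absorbing state).  The companion replication
matrix carries the division weight: every flux is weighted 1 except
M -> G1 which is weighted 2 (one mother yields two G1 daughters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .phases import G1, M, MULTI, N_PHASES, PHASES, SG2

#: Boolean mask of the free (fittable) entries of the transition matrix.
FREE_MASK = np.zeros((N_PHASES, N_PHASES), dtype=bool)
for _i, _j in [
    (G1, G1), (G1, SG2),
    (SG2, SG2), (SG2, M),
    (M, G1), (M, M), (M, MULTI),
    (MULTI, MULTI),
]:
    FREE_MASK[_i, _j] = True

#: Replication weights applied element-wise to transition fluxes.
REPLICATION_MATRIX = np.array(
    [
        [1.0, 1.0, 0.0, 0.0],
        [0.0, 1.0, 1.0, 0.0],
        [2.0, 0.0, 1.0, 1.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
REPLICATION_MATRIX.setflags(write=False)


class MatrixPatternError(ValueError):
    """Raised when a matrix violates the permitted-transition structure."""


def validate_matrix(values: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Validate a 4x4 array against the model's structural constraints.

    Checks the sparsity pattern, entry bounds, row-stochasticity and the
    fixed absorbing row.  Returns the array as float64.
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_PHASES, N_PHASES):
        raise MatrixPatternError(f"expected a 4x4 matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise MatrixPatternError("matrix entries must be finite")
    if np.any(np.abs(arr[~FREE_MASK]) > atol):
        raise MatrixPatternError(
            "non-zero entry on a forbidden transition; permitted transitions are "
            "homotypic, G1->S/G2, S/G2->M, M->G1 and M->Multinucleated"
        )
    if np.any(arr < -atol) or np.any(arr > 1 + atol):
        raise MatrixPatternError("transition probabilities must lie in [0, 1]")
    row_sums = arr.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise MatrixPatternError(f"rows must sum to 1, got {row_sums}")
    if abs(arr[MULTI, MULTI] - 1.0) > atol:
        raise MatrixPatternError("the multinucleated row is fixed at P[Multi,Multi]=1")
    return arr


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic cell-cycle transition matrix with the fixed pattern.

    One model timestep is 1 hour.  ``P[i, j]`` is the fraction of phase-i
    cells that are in phase j one hour later (before replication
    weighting).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = validate_matrix(self.values)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    # -- constructors ----------------------------------------------------
    @classmethod
    def identity(cls) -> "TransitionMatrix":
        """All homotypic rates 1: every phase absorbing (the fit's seed)."""
        return cls(np.eye(N_PHASES))

    @classmethod
    def from_rates(
        cls,
        g1_to_sg2: float,
        sg2_to_m: float,
        m_to_g1: float,
        m_to_multi: float,
    ) -> "TransitionMatrix":
        """Build a matrix from the four off-diagonal transition rates."""
        arr = np.zeros((N_PHASES, N_PHASES))
        arr[G1, SG2] = g1_to_sg2
        arr[G1, G1] = 1.0 - g1_to_sg2
        arr[SG2, M] = sg2_to_m
        arr[SG2, SG2] = 1.0 - sg2_to_m
        arr[M, G1] = m_to_g1
        arr[M, MULTI] = m_to_multi
        arr[M, M] = 1.0 - m_to_g1 - m_to_multi
        arr[MULTI, MULTI] = 1.0
        return cls(arr)

    @classmethod
    def from_dwell_times(
        cls,
        g1_hours: float,
        sg2_hours: float,
        m_hours: float,
        mitotic_success_rate: float = 1.0,
    ) -> "TransitionMatrix":
        """Build a matrix whose expected phase durations are the given hours.

        Dwell times are geometric with mean 1/(1-P_ii), so each homotypic
        rate is 1 - 1/duration; the M-exit flux is split between division
        (M->G1) and mitotic failure (M->Multinucleated) according to
        ``mitotic_success_rate``.  Durations must be >= 1 h (one timestep).
        """
        for name, d in (("G1", g1_hours), ("S/G2", sg2_hours), ("M", m_hours)):
            if d < 1.0:
                raise ValueError(f"{name} duration must be >= 1 h, got {d}")
        if not 0.0 <= mitotic_success_rate <= 1.0:
            raise ValueError("mitotic_success_rate must lie in [0, 1]")
        m_exit = 1.0 / m_hours
        return cls.from_rates(
            g1_to_sg2=1.0 / g1_hours,
            sg2_to_m=1.0 / sg2_hours,
            m_to_g1=m_exit * mitotic_success_rate,
            m_to_multi=m_exit * (1.0 - mitotic_success_rate),
        )

    # -- accessors -------------------------------------------------------
    @property
    def homotypic_rates(self) -> np.ndarray:
        """Diagonal (stay-in-phase) rates ordered (G1, S/G2, M, Multi)."""
        return np.diag(self.values)

    def __getitem__(self, key) -> float:
        i, j = key
        if isinstance(i, str):
            i = PHASES.index(i)
        if isinstance(j, str):
            j = PHASES.index(j)
        return float(self.values[i, j])

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.values, dtype=dtype)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {"phases": list(PHASES), "entries": self.values.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionMatrix":
        return cls(np.asarray(d["entries"], dtype=float))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TransitionMatrix":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def random_free_rows(rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` random valid matrices as an (n, 4, 4) array.

    The free entries of each multi-entry row are drawn jointly uniform on
    the probability simplex: the two-entry G1 and S/G2 rows via a single
    uniform split, the three-entry M row via a flat Dirichlet.
    """
    out = np.zeros((n, N_PHASES, N_PHASES))
    u_g1 = rng.random(n)
    out[:, G1, G1] = u_g1
    out[:, G1, SG2] = 1.0 - u_g1
    u_s = rng.random(n)
    out[:, SG2, SG2] = u_s
    out[:, SG2, M] = 1.0 - u_s
    m_row = rng.dirichlet(np.ones(3), size=n)
    out[:, M, G1] = m_row[:, 0]
    out[:, M, M] = m_row[:, 1]
    out[:, M, MULTI] = m_row[:, 2]
    out[:, MULTI, MULTI] = 1.0
    return out


def random_matrix(rng: np.random.Generator) -> TransitionMatrix:
    """Draw one random valid transition matrix (uniform per-row simplex)."""
    return TransitionMatrix(random_free_rows(rng, 1)[0])


def perturb(
    seed_matrix: TransitionMatrix | np.ndarray,
    lr: float,
    rng: np.random.Generator,
    n: int = 1,
) -> np.ndarray:
    """Move a seed matrix toward fresh random matrices at rate ``lr``.

    Returns ``(1 - lr) * seed + lr * random`` entrywise as an (n, 4, 4)
    array; each row stays on the simplex because it is a convex
    combination of simplex points, and fixed zeros stay zero.
    """
    if not 0.0 < lr <= 1.0:
        raise ValueError(f"learning rate must lie in (0, 1], got {lr}")
    seed = np.asarray(seed_matrix, dtype=float)
    return (1.0 - lr) * seed[None, :, :] + lr * random_free_rows(rng, n)
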