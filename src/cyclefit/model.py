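"""Discrete-time Markov model of cell-cycle progression with division.

The population state is a vector ``S`` of cell counts per phase
(G1, S/G2, M, Multinucleated).  One timestep is 1 hour and the update is

    S_{n+1}[j] = sum_i S_n[i] * P[i, j] * RM[i, j]

i.e. each transition flux ``S_n[i] * P[i, j]`` is weighted element-wise by
the replication matrix, so the M -> G1 flux is doubled (each successful
mitosis yields two G1 daughters) and every other permitted flux conserves
cells.  Total cell count therefore grows by ``S[M] * P[M, G1]`` per step
and never shrinks (the model has no death process); the multinucleated
state is absorbing.

The transition matrix is fitted to an observed phase-count series by
random search: each epoch draws a batch of candidate matrices around the
current seed matrices (a convex step of size ``lr`` toward fresh uniform
random matrices), scores every candidate by the RMSRE between its
trajectory from the first observed state and the observations, and keeps
the best few as seeds for the next epoch.  The first epoch is seeded with
the identity matrix and the learning rate halves on a fixed schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .matrices import (
    REPLICATION_MATRIX,
    TransitionMatrix,
    perturb,
    random_free_rows,
    validate_matrix,
)
from .phases import N_PHASES, PHASES
from .series import PhaseCountSeries


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def step(state: np.ndarray, matrix: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Advance a phase-count state vector by one hour.

    ``S'[j] = sum_i S[i] * P[i, j] * RM[i, j]``
    """
    s = np.asarray(state, dtype=float)
    if s.shape != (N_PHASES,):
        raise ValueError(f"state must have shape (4,), got {s.shape}")
    if np.any(s < 0) or not np.all(np.isfinite(s)):
        raise ValueError("state counts must be finite and non-negative")
    p = np.asarray(matrix, dtype=float)
    return s @ (p * REPLICATION_MATRIX)


def trajectory(
    initial_state: np.ndarray,
    matrix: TransitionMatrix | np.ndarray,
    n_hours: int,
) -> PhaseCountSeries:
    """Iterate :func:`step` for ``n_hours`` hours, returning the full series.

    The result has ``n_hours + 1`` timepoints including the initial state
    at t=0.
    """
    if n_hours < 0:
        raise ValueError("n_hours must be >= 0")
    s = np.asarray(initial_state, dtype=float)
    eff = np.asarray(matrix, dtype=float) * REPLICATION_MATRIX
    out = np.empty((n_hours + 1, N_PHASES))
    out[0] = s
    for t in range(1, n_hours + 1):
        s = s @ eff
        out[t] = s
    return PhaseCountSeries.from_counts(np.arange(n_hours + 1, dtype=float), out)


def _batch_trajectories(
    initial_state: np.ndarray, matrices: np.ndarray, n_hours: int
) -> np.ndarray:
    """Trajectories for a (k, 4, 4) stack of matrices: (n_hours+1, k, 4)."""
    k = matrices.shape[0]
    eff = matrices * REPLICATION_MATRIX[None, :, :]
    out = np.empty((n_hours + 1, k, N_PHASES))
    s = np.broadcast_to(np.asarray(initial_state, float), (k, N_PHASES)).copy()
    out[0] = s
    for t in range(1, n_hours + 1):
        s = np.einsum("ki,kij->kj", s, eff)
        out[t] = s
    return out


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

class ZeroObservedCountError(ValueError):
    """Raised when a relative error denominator is zero."""


def rmsre(
    pred: PhaseCountSeries | np.ndarray,
    obs: PhaseCountSeries | np.ndarray,
    eps: float = 0.0,
) -> float:
    """Mean over phases of the per-phase root-mean-squared relative error.

    Per phase, ``RMSRE = sqrt(mean_t ((pred - obs)^2 / obs^2))`` over all
    timepoints, then the four per-phase values are averaged arithmetically.
    Observed counts of zero make the relative error undefined; by default
    that is a hard error, or a small stabilizer ``eps`` may be added to the
    denominators.
    """
    p = pred.counts if isinstance(pred, PhaseCountSeries) else np.atleast_2d(np.asarray(pred, float))
    o = obs.counts if isinstance(obs, PhaseCountSeries) else np.atleast_2d(np.asarray(obs, float))
    if p.shape != o.shape:
        raise ValueError(f"prediction and observation shapes differ: {p.shape} vs {o.shape}")
    if (
        isinstance(pred, PhaseCountSeries)
        and isinstance(obs, PhaseCountSeries)
        and not np.allclose(pred.times, obs.times)
    ):
        raise ValueError("prediction and observation time grids differ")
    if eps == 0.0 and np.any(o == 0):
        t_idx, ph_idx = np.argwhere(o == 0)[0]
        raise ZeroObservedCountError(
            f"observed count is zero for phase {PHASES[ph_idx]} at timepoint index "
            f"{t_idx}; relative error undefined (pass eps > 0 to stabilize)"
        )
    rel_sq = (p - o) ** 2 / (o + eps) ** 2
    return float(np.mean(np.sqrt(rel_sq.mean(axis=0))))


def _batch_rmsre(preds: np.ndarray, obs: np.ndarray, eps: float) -> np.ndarray:
    """RMSRE per candidate for preds (T, k, 4) against obs (T, 4)."""
    rel_sq = (preds - obs[:, None, :]) ** 2 / (obs[:, None, :] + eps) ** 2
    return np.sqrt(rel_sq.mean(axis=0)).mean(axis=1)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Random-search schedule for fitting the transition matrix.

    Defaults follow the published training schedule: 15 epochs, 3000
    candidate matrices per epoch, the 5 lowest-error matrices kept as next
    epoch's seeds, learning rate 0.1 for the first epoch halving every 2
    epochs, first epoch seeded with the identity matrix.
    """

    epochs: int = 15
    candidates_per_epoch: int = 3000
    keep_top: int = 5
    initial_lr: float = 0.1
    lr_halving_period_epochs: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("epochs", "candidates_per_epoch", "keep_top", "lr_halving_period_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 < self.initial_lr <= 1.0:
            raise ValueError("initial_lr must lie in (0, 1]")
        if self.keep_top > self.candidates_per_epoch:
            raise ValueError("keep_top cannot exceed candidates_per_epoch")

    def learning_rate(self, epoch: int) -> float:
        """lr for a 1-indexed epoch: initial_lr * 0.5^floor((epoch-1)/period)."""
        return self.initial_lr * 0.5 ** ((epoch - 1) // self.lr_halving_period_epochs)

    def to_dict(self) -> dict:
        return {
            "epochs": self.epochs,
            "candidates_per_epoch": self.candidates_per_epoch,
            "keep_top": self.keep_top,
            "initial_lr": self.initial_lr,
            "lr_halving_period_epochs": self.lr_halving_period_epochs,
            "seed": self.seed,
        }


@dataclass
class FitResult:
    """Outcome of a random-search fit."""

    best_matrix: TransitionMatrix
    top_matrices: list[TransitionMatrix]
    top_errors: np.ndarray
    error_trace: np.ndarray  # best RMSRE after each epoch, non-increasing
    seed: int | None
    config: FitConfig
    normalization_basis: float | None = field(default=None)

    @property
    def rmsre(self) -> float:
        return float(self.top_errors[0])

    def to_dict(self) -> dict:
        return {
            "best_matrix": self.best_matrix.to_dict(),
            "top_matrices": [m.to_dict() for m in self.top_matrices],
            "top_errors": np.asarray(self.top_errors).tolist(),
            "error_trace": np.asarray(self.error_trace).tolist(),
            "seed": self.seed,
            "config": self.config.to_dict(),
            "normalization_basis": self.normalization_basis,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            best_matrix=TransitionMatrix.from_dict(d["best_matrix"]),
            top_matrices=[TransitionMatrix.from_dict(m) for m in d["top_matrices"]],
            top_errors=np.asarray(d["top_errors"], dtype=float),
            error_trace=np.asarray(d["error_trace"], dtype=float),
            seed=d["seed"],
            config=FitConfig(**d["config"]),
            normalization_basis=d.get("normalization_basis"),
        )


def fit_transition_matrix(
    obs: PhaseCountSeries,
    config: FitConfig | None = None,
    normalize: bool = True,
    eps: float = 0.0,
) -> FitResult:
    """Fit the constrained transition matrix to an observed series.

    The observed series must be on an hourly grid.  By default it is
    normalized to the total at the earliest timepoint before fitting
    (the propagation is linear, so this changes nothing but the scale);
    the original basis is recorded in the result.

    Each epoch, candidates are allocated evenly across the current seed
    matrices (remainder to the best seed), scored by the RMSRE of their
    trajectory from the first observed state, and pooled with the seeds
    themselves so the best-so-far always survives (elitism); the best-epoch
    error trace is therefore non-increasing.  Ties are broken by
    generation order, making the fit bit-reproducible for a given seed.
    """
    if config is None:
        config = FitConfig()
    if len(obs) < 2:
        raise ValueError("observed series needs at least 2 timepoints to fit")
    dt = np.diff(obs.times)
    if not np.allclose(dt, 1.0):
        raise ValueError("observed series must be sampled on a 1-hour grid")
    if np.all(obs.counts == 0):
        raise ValueError("observed series is identically zero")

    basis = None
    if normalize and not obs.normalized:
        obs = obs.normalize()
        basis = obs.normalization_basis

    obs_counts = obs.counts
    if eps == 0.0 and np.any(obs_counts == 0):
        t_idx, ph_idx = np.argwhere(obs_counts == 0)[0]
        raise ZeroObservedCountError(
            f"observed count is zero for phase {PHASES[ph_idx]} at timepoint index "
            f"{t_idx}; fit with eps > 0 or drop the offending rows"
        )
    s0 = obs_counts[0]
    n_hours = len(obs) - 1
    rng = np.random.default_rng(config.seed)

    seeds = np.eye(N_PHASES)[None, :, :]  # epoch 1: identity matrix
    seed_errors = _batch_rmsre(
        _batch_trajectories(s0, seeds, n_hours), obs_counts, eps
    )
    trace = np.empty(config.epochs)

    for epoch in range(1, config.epochs + 1):
        lr = config.learning_rate(epoch)
        n_seeds = seeds.shape[0]
        per_seed = config.candidates_per_epoch // n_seeds
        remainder = config.candidates_per_epoch - per_seed * n_seeds
        cands = np.concatenate(
            [
                perturb(seeds[i], lr, rng, n=per_seed + (remainder if i == 0 else 0))
                for i in range(n_seeds)
            ]
        )
        cand_errors = _batch_rmsre(
            _batch_trajectories(s0, cands, n_hours), obs_counts, eps
        )
        pool = np.concatenate([seeds, cands])
        pool_errors = np.concatenate([seed_errors, cand_errors])
        order = np.argsort(pool_errors, kind="stable")[: config.keep_top]
        seeds = pool[order]
        seed_errors = pool_errors[order]
        trace[epoch - 1] = seed_errors[0]

    top = [TransitionMatrix(validate_matrix(m)) for m in seeds]
    return FitResult(
        best_matrix=top[0],
        top_matrices=top,
        top_errors=seed_errors.copy(),
        error_trace=trace,
        seed=config.seed,
        config=config,
        normalization_basis=basis,
    )


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class MarkovCellCycleModel(BaseEstimator):
    """Constrained cell-cycle Markov model fitted by random search.

    A scikit-learn style estimator around :func:`fit_transition_matrix`.

    Parameters
    ----------
    epochs, candidates_per_epoch, keep_top, initial_lr, lr_halving_period_epochs:
        Random-search schedule (defaults are the published training
        schedule; see :class:`FitConfig`).
    normalize:
        Normalize observed counts to the total at the earliest timepoint
        before fitting.
    eps:
        Optional stabilizer added to RMSRE denominators (0 disables it;
        observed zeros then raise).
    random_state:
        Seed for the candidate-generation RNG; fits are bit-reproducible
        for a fixed seed.

    Attributes
    ----------
    transition_matrix_ : TransitionMatrix
        Best matrix found.
    fit_result_ : FitResult
        Full search outcome (top matrices, error trace, config).
    error_trace_ : ndarray
        Best RMSRE after each epoch (non-increasing).
    rmsre_ : float
        Final best RMSRE.
    initial_state_ : ndarray
        First observed state (after normalization if enabled), the anchor
        for :meth:`predict`.
    n_hours_ : int
        Span of the training series in hours.

    Examples
    --------
    >>> from cyclefit import MarkovCellCycleModel, TransitionMatrix, trajectory
    >>> truth = TransitionMatrix.from_dwell_times(8.0, 38.0, 3.5, 0.9)
    >>> obs = trajectory([60, 30, 8, 2], truth, 72)
    >>> model = MarkovCellCycleModel(random_state=0).fit(obs)
    >>> model.rmsre_ < 1e-2
    True
    """

    def __init__(
        self,
        epochs: int = 15,
        candidates_per_epoch: int = 3000,
        keep_top: int = 5,
        initial_lr: float = 0.1,
        lr_halving_period_epochs: int = 2,
        normalize: bool = True,
        eps: float = 0.0,
        random_state: int | None = None,
    ):
        self.epochs = epochs
        self.candidates_per_epoch = candidates_per_epoch
        self.keep_top = keep_top
        self.initial_lr = initial_lr
        self.lr_halving_period_epochs = lr_halving_period_epochs
        self.normalize = normalize
        self.eps = eps
        self.random_state = random_state

    def _as_series(self, X) -> PhaseCountSeries:
        if isinstance(X, PhaseCountSeries):
            return X
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        return PhaseCountSeries.from_counts(np.arange(arr.shape[0], dtype=float), arr)

    def fit(self, X, y=None) -> "MarkovCellCycleModel":
        """Fit to an observed phase-count series.

        ``X`` may be a :class:`PhaseCountSeries`, a DataFrame with phase
        columns, or an (n_hours+1, 4) array of hourly counts.  ``y`` is
        ignored (present for API compatibility).
        """
        obs = self._as_series(X)
        config = FitConfig(
            epochs=self.epochs,
            candidates_per_epoch=self.candidates_per_epoch,
            keep_top=self.keep_top,
            initial_lr=self.initial_lr,
            lr_halving_period_epochs=self.lr_halving_period_epochs,
            seed=self.random_state,
        )
        result = fit_transition_matrix(
            obs, config, normalize=self.normalize, eps=self.eps
        )
        self.fit_result_ = result
        self.transition_matrix_ = result.best_matrix
        self.error_trace_ = result.error_trace
        self.rmsre_ = result.rmsre
        fitted_obs = obs.normalize() if (self.normalize and not obs.normalized) else obs
        self.initial_state_ = fitted_obs.counts[0].copy()
        self.n_hours_ = len(obs) - 1
        return self

    def predict(self, n_hours: int | None = None, initial_state=None) -> PhaseCountSeries:
        """Reconstruct the phase-count series from the fitted rates.

        By default propagates the first observed state over the training
        span; pass ``n_hours`` and/or ``initial_state`` to extrapolate.
        """
        check_is_fitted(self, "transition_matrix_")
        if n_hours is None:
            n_hours = self.n_hours_
        if initial_state is None:
            initial_state = self.initial_state_
        return trajectory(initial_state, self.transition_matrix_, n_hours)

    def score(self, X, y=None) -> float:
        """Negative RMSRE of the model's reconstruction of ``X`` (higher is better)."""
        check_is_fitted(self, "transition_matrix_")
        obs = self._as_series(X)
        if self.normalize and not obs.normalized:
            obs = obs.normalize()
        pred = trajectory(obs.counts[0], self.transition_matrix_, len(obs) - 1)
        return -rmsre(pred.counts, obs.counts, eps=self.eps)
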