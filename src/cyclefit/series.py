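"""Phase-count time series container.

A :class:`PhaseCountSeries` holds counts of cells per cell-cycle phase on a
strictly increasing time grid (hours).  Counts may be continuous expected
values (population model) or integers (agent tallies).  Series may be
normalized to the total cell count at the earliest timepoint, matching how
live-cell counts are plotted and fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phases import PHASES

TIME_COLUMN = "time_h"


@dataclass
class PhaseCountSeries:
    """Counts per phase over time.

    Parameters
    ----------
    frame:
        DataFrame indexed by time in hours (strictly increasing) with one
        column per phase in the canonical order (G1, S/G2, M,
        Multinucleated).
    normalized:
        Whether counts have been divided by the total at the earliest
        timepoint.
    normalization_basis:
        The total used for normalization (None if not normalized).
    """

    frame: pd.DataFrame
    normalized: bool = False
    normalization_basis: float | None = field(default=None)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [p for p in PHASES if p not in df.columns]
        if missing:
            raise ValueError(f"missing phase columns: {missing}")
        df = df.loc[:, list(PHASES)].astype(float)
        times = np.asarray(df.index, dtype=float)
        if len(times) == 0:
            raise ValueError("series must contain at least one timepoint")
        if np.any(np.diff(times) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(df.to_numpy() < 0):
            raise ValueError("phase counts must be non-negative")
        df.index = pd.Index(times, name=TIME_COLUMN)
        self.frame = df

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_counts(
        cls,
        times: np.ndarray,
        counts: np.ndarray,
        normalized: bool = False,
        normalization_basis: float | None = None,
    ) -> "PhaseCountSeries":
        """Build from a time vector and an (n_times, 4) count array."""
        counts = np.atleast_2d(np.asarray(counts, dtype=float))
        df = pd.DataFrame(counts, index=np.asarray(times, dtype=float), columns=list(PHASES))
        return cls(df, normalized=normalized, normalization_basis=normalization_basis)

    # -- accessors -------------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.frame.index, dtype=float)

    @property
    def counts(self) -> np.ndarray:
        """(n_times, 4) array of counts in canonical phase order."""
        return self.frame.to_numpy()

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def fractions(self) -> np.ndarray:
        """Per-timepoint phase fractions (rows sum to 1)."""
        totals = self.totals
        if np.any(totals <= 0):
            raise ValueError("cannot compute fractions with a zero total count")
        return self.counts / totals[:, None]

    def __len__(self) -> int:
        return len(self.frame)

    # -- transforms ------------------------------------------------------
    def normalize(self) -> "PhaseCountSeries":
        """Divide all counts by the total cell count at the earliest timepoint.

        Idempotent on an already-normalized series (its basis is 1 by
        construction, so re-normalizing divides by 1).
        """
        basis = float(self.counts[0].sum())
        if basis <= 0:
            raise ValueError("total count at the earliest timepoint must be positive")
        return PhaseCountSeries(
            self.frame / basis, normalized=True, normalization_basis=basis
        )

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label=TIME_COLUMN)

    @classmethod
    def from_csv(cls, path, sort: bool = False) -> "PhaseCountSeries":
        """Read a series from CSV with columns (time_h, G1, S/G2, M, Multinucleated).

        With ``sort=True`` rows are sorted by time first; otherwise a
        non-monotone time column is an error.
        """
        df = pd.read_csv(path)
        if TIME_COLUMN not in df.columns:
            raise ValueError(f"missing required column '{TIME_COLUMN}'")
        missing = [p for p in PHASES if p not in df.columns]
        if missing:
            raise ValueError(f"missing phase columns: {missing}")
        df = df.set_index(TIME_COLUMN)
        if sort:
            df = df.sort_index()
        return cls(df)
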