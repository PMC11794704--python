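"""Phase calling from reporter-localization features and count aggregation.

The live-cell reporter translocates between nucleus and cytoplasm across
the cell cycle while a second marker stays nuclear, so two intensity
ratios encode phase: the perinuclear:nuclear mean-intensity ratio and the
nuclear:cytoplasmic total-intensity ratio.  Cells are classified by fixed
thresholds:

1. mononuclear cells with peri:nuc mean ratio > 0.8 and nuc:cyto total
   ratio < 0.5 are S/G2 (reporter excluded from the nucleus);
2. cells (mono- or multinucleated) with nuc:cyto total ratio > 0.8 and
   peri:nuc mean ratio < 0.8 are M (reporter concentrated in the
   nucleus);
3. remaining mononuclear cells are G1;
4. remaining multinucleated cells are Multinucleated.

Ties at exactly 0.8 / 0.5 fall through to the remainder rules.  Labeled
cells are then tallied per frame, smoothed with a centered 5-frame moving
average, downsampled to one value per hour, and normalized to the total
cell count at the earliest timepoint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .phases import PHASES
from .series import PhaseCountSeries

#: Required columns of a per-cell feature table.
FEATURE_COLUMNS = [
    "cell_id",
    "time_h",
    "nucleus_count",
    "nuclear_total_intensity",
    "cytoplasmic_total_intensity",
    "nuclear_mean_intensity",
    "perinuclear_mean_intensity",
]


class FeatureError(ValueError):
    """Raised for feature rows on which the ratios are not computable."""


def _ratios(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    nuc_mean = features["nuclear_mean_intensity"].to_numpy(float)
    peri_mean = features["perinuclear_mean_intensity"].to_numpy(float)
    nuc_total = features["nuclear_total_intensity"].to_numpy(float)
    cyto_total = features["cytoplasmic_total_intensity"].to_numpy(float)
    bad = (nuc_mean <= 0) | (cyto_total <= 0)
    if np.any(bad):
        idx = features.index[bad][0]
        raise FeatureError(
            f"zero denominator for cell row {idx!r}: nuclear mean and cytoplasmic "
            "total intensities must be positive to form the phase-calling ratios"
        )
    return peri_mean / nuc_mean, nuc_total / cyto_total


class ThresholdPhaseClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based cell-cycle phase caller.

    A scikit-learn style classifier applying the fixed intensity-ratio
    thresholds above.  It has no trainable state: ``fit`` only records the
    class labels, and ``predict`` applies the rules.

    Parameters
    ----------
    sg2_peri_nuc_min : float, default 0.8
        Peri:nuc mean ratio a mononuclear cell must exceed for S/G2.
    sg2_nuc_cyto_max : float, default 0.5
        Nuc:cyto total ratio a mononuclear cell must stay under for S/G2.
    m_nuc_cyto_min : float, default 0.8
        Nuc:cyto total ratio a cell must exceed for M.
    m_peri_nuc_max : float, default 0.8
        Peri:nuc mean ratio a cell must stay under for M.
    """

    def __init__(
        self,
        sg2_peri_nuc_min: float = 0.8,
        sg2_nuc_cyto_max: float = 0.5,
        m_nuc_cyto_min: float = 0.8,
        m_peri_nuc_max: float = 0.8,
    ):
        self.sg2_peri_nuc_min = sg2_peri_nuc_min
        self.sg2_nuc_cyto_max = sg2_nuc_cyto_max
        self.m_nuc_cyto_min = m_nuc_cyto_min
        self.m_peri_nuc_max = m_peri_nuc_max

    def fit(self, X=None, y=None) -> "ThresholdPhaseClassifier":
        self.classes_ = np.asarray(PHASES, dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Assign one phase label per feature row.

        ``X`` must contain the nucleus_count and four intensity columns of
        :data:`FEATURE_COLUMNS` (cell_id/time_h are not needed here).
        """
        if not hasattr(self, "classes_"):
            self.fit()
        peri_nuc, nuc_cyto = _ratios(X)
        mono = X["nucleus_count"].to_numpy() == 1

        labels = np.empty(len(X), dtype=object)
        is_sg2 = mono & (peri_nuc > self.sg2_peri_nuc_min) & (nuc_cyto < self.sg2_nuc_cyto_max)
        is_m = (~is_sg2) & (nuc_cyto > self.m_nuc_cyto_min) & (peri_nuc < self.m_peri_nuc_max)
        labels[is_sg2] = "S/G2"
        labels[is_m] = "M"
        rest = ~(is_sg2 | is_m)
        labels[rest & mono] = "G1"
        labels[rest & ~mono] = "Multinucleated"
        return labels


def call_phases(features: pd.DataFrame, classifier: ThresholdPhaseClassifier | None = None) -> pd.Series:
    """Phase labels for a per-cell feature table (index preserved)."""
    clf = (classifier or ThresholdPhaseClassifier()).fit()
    return pd.Series(clf.predict(features), index=features.index, name="phase")


def call_phase(
    nucleus_count: int,
    nuclear_total_intensity: float,
    cytoplasmic_total_intensity: float,
    nuclear_mean_intensity: float,
    perinuclear_mean_intensity: float,
) -> str:
    """Classify a single cell; scalar convenience over the classifier."""
    df = pd.DataFrame(
        {
            "nucleus_count": [nucleus_count],
            "nuclear_total_intensity": [nuclear_total_intensity],
            "cytoplasmic_total_intensity": [cytoplasmic_total_intensity],
            "nuclear_mean_intensity": [nuclear_mean_intensity],
            "perinuclear_mean_intensity": [perinuclear_mean_intensity],
        }
    )
    return str(call_phases(df).iloc[0])


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_counts(
    times: np.ndarray, labels: np.ndarray, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Tally labeled cells into per-frame phase counts.

    Parameters
    ----------
    times:
        Frame time (hours) of each labeled cell observation.
    labels:
        Phase label per observation.
    grid:
        Optional full frame grid; frames with no cells appear as all-zero
        rows.  Defaults to the distinct observed times.

    Returns
    -------
    DataFrame indexed by frame time with one column per phase; each row
    sums to the number of cells observed at that frame.
    """
    times = np.asarray(times, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if times.shape != labels.shape:
        raise ValueError("times and labels must have equal length")
    df = pd.DataFrame({"time": times, "phase": labels})
    table = (
        df.groupby(["time", "phase"], sort=True).size().unstack(fill_value=0)
    )
    table = table.reindex(columns=list(PHASES), fill_value=0)
    if grid is not None:
        table = table.reindex(np.asarray(grid, dtype=float), fill_value=0)
    table.index.name = "time_h"
    return table.astype(float)


def smooth_and_downsample(per_frame: pd.DataFrame, window: int = 5) -> PhaseCountSeries:
    """Smooth per-frame counts and downsample to one value per hour.

    A centered ``window``-frame moving average is applied per phase
    (windows shrink at the series edges rather than discarding frames),
    then the frame nearest each integer hour is selected, ties broken
    toward the earlier frame.
    """
    if len(per_frame) < window:
        raise ValueError(
            f"need at least {window} frames to smooth, got {len(per_frame)}"
        )
    frame_times = np.asarray(per_frame.index, dtype=float)
    smoothed = per_frame.rolling(window=window, center=True, min_periods=1).mean()

    hours = np.arange(np.floor(frame_times[0]), np.floor(frame_times[-1]) + 1)
    hours = hours[(hours >= frame_times[0]) & (hours <= frame_times[-1])]
    # nearest frame per integer hour; ties toward the earlier frame
    picks = []
    for h in hours:
        dist = np.abs(frame_times - h)
        picks.append(int(np.argmin(dist)))  # argmin takes the first (earlier) tie
    sel = smoothed.iloc[picks]
    sel.index = pd.Index(hours, name="time_h")
    return PhaseCountSeries(sel)


def normalize_counts(series: PhaseCountSeries) -> PhaseCountSeries:
    """Normalize counts to the total cell count at the earliest timepoint."""
    return series.normalize()
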