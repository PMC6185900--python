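"""Water-compartment fractions over drying time and rupture detection.

A two-component T2 fit separates tissue water into the long-T2
intracellular water (ICW, vacuole + cytoplasm) and the short-T2 free water
(FW, intercellular spaces).  Total instantaneous water is taken as 100%, so
the two fractions always sum to 100 exactly.

During hot-air drying, membrane rupture releases intracellular water into
the intercellular space: the ICW fraction drops abruptly, then partially
rebounds as the freed water evaporates.  Rupture events are therefore read
off the ICW-vs-drying-time series as large single-step drops; consecutive
above-threshold drops are merged into one event timestamped at the first
measurement where the drop is observable (sampling is discrete, typically
every 30 min).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import InsufficientDataError, UnsupportedModelError
from .model import FitResult

__all__ = [
    "CompartmentSeries",
    "RuptureEvent",
    "RuptureDetector",
    "assign_compartments",
    "build_series",
    "detect_rupture_events",
    "compare_series",
]

logger = logging.getLogger(__name__)

#: default minimum one-step ICW drop (percentage points) that counts as a
#: rupture; separates genuine membrane-collapse drops (>= ~22 pp in drying
#: data at 60-70 C) from low-temperature fluctuations (<= ~6 pp)
DEFAULT_MIN_DROP_PP = 15.0


@dataclass(frozen=True)
class CompartmentSeries:
    """ICW%/FW% against drying time at one drying temperature."""

    times: np.ndarray
    icw_pct: np.ndarray
    fw_pct: np.ndarray
    temperature_c: Optional[float] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        icw = np.asarray(self.icw_pct, dtype=float)
        fw = np.asarray(self.fw_pct, dtype=float)
        if not (len(times) == len(icw) == len(fw)):
            raise ValueError("times, icw_pct and fw_pct must have equal length")
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("drying times must be strictly increasing")
        for name, arr in (("icw_pct", icw), ("fw_pct", fw)):
            if np.any((arr < 0) | (arr > 100)):
                raise ValueError(f"{name} must lie in [0, 100]")
        if np.any(np.abs(icw + fw - 100.0) > 0.1):
            raise ValueError("icw_pct + fw_pct must equal 100 (+/- 0.1)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "icw_pct", icw)
        object.__setattr__(self, "fw_pct", fw)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "icw_pct": self.icw_pct, "fw_pct": self.fw_pct}
        )


@dataclass(frozen=True)
class RuptureEvent:
    """One membrane-rupture event: the time at which an abrupt ICW drop is
    first observable, and the size of the drop in percentage points."""

    time: float
    drop_pp: float


def assign_compartments(fit: FitResult) -> tuple[float, float]:
    """ICW%/FW% from an accepted bi-exponential fit.

    The long-T2 (index 0) amplitude fraction is ICW, the short-T2 fraction
    FW; they are normalised so the pair sums to 100 exactly.

    Raises
    ------
    UnsupportedModelError
        For 1- or 3-component models: a mono-exponential decay does not
        resolve compartments, and no compartment assignment is defined for a
        third (bound-water) component here.
    ValueError
        If the fit was rejected by the SNR gate.
    """
    if fit.model.n_components != 2:
        raise UnsupportedModelError(
            f"compartment assignment requires a 2-component model, got "
            f"{fit.model.n_components}"
        )
    if not fit.accepted:
        raise ValueError("cannot assign compartments from a rejected (low-SNR) fit")
    m_long, m_short = fit.model.amplitudes
    total = m_long + m_short
    if total <= 0:
        raise UnsupportedModelError("model has zero total amplitude")
    icw = 100.0 * m_long / total
    return icw, 100.0 - icw


def build_series(
    fits: Iterable[tuple[float, FitResult]],
    temperature_c: Optional[float] = None,
) -> CompartmentSeries:
    """Assemble a compartment series from (drying time, fit) pairs.

    Rejected (low-SNR) fits are excluded and logged, never interpolated
    over.  Requires at least two accepted fits.
    """
    rows = []
    n_rejected = 0
    for time_min, fit in fits:
        if not fit.accepted:
            n_rejected += 1
            logger.info(
                "excluding rejected fit at t=%.0f min (SNR=%s)", time_min, fit.snr
            )
            continue
        icw, fw = assign_compartments(fit)
        rows.append((float(time_min), icw, fw))
    if n_rejected:
        logger.info("excluded %d low-SNR fits from series", n_rejected)
    if len(rows) < 2:
        raise InsufficientDataError(
            f"need >= 2 accepted fits to build a series, got {len(rows)}"
        )
    rows.sort(key=lambda r: r[0])
    t, icw, fw = (np.array(col) for col in zip(*rows))
    return CompartmentSeries(times=t, icw_pct=icw, fw_pct=fw, temperature_c=temperature_c)


class RuptureDetector(BaseEstimator):
    """Detect abrupt ICW drops (membrane-rupture events) in a drying series.

    An event fires at measurement i when the one-step drop
    ``icw[i-1] - icw[i]`` is strictly positive and reaches ``min_drop_pp``.
    Events are timestamped at the post-drop measurement — the first time
    the drop is observable on the discrete sampling grid.

    Parameters
    ----------
    min_drop_pp : float, default 15.0
        Minimum drop size in ICW percentage points.

    Attributes
    ----------
    events_ : list of RuptureEvent
        Detected events, time-ordered.
    """

    def __init__(self, min_drop_pp: float = DEFAULT_MIN_DROP_PP):
        self.min_drop_pp = min_drop_pp

    @staticmethod
    def _coerce(X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, CompartmentSeries):
            return X.times, X.icw_pct
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(
                "X must be a CompartmentSeries or an (n, 2) array of "
                "(time_min, icw_pct)"
            )
        return X[:, 0], X[:, 1]

    def fit(self, X, y=None):
        """Scan the series; ``X`` is a CompartmentSeries or (n, 2) array of
        (time, icw_pct) rows."""
        times, icw = self._coerce(X)
        if len(times) < 3:
            raise ValueError("series must have >= 3 points")
        if self.min_drop_pp < 0:
            raise ValueError("min_drop_pp must be >= 0")
        drops = icw[:-1] - icw[1:]
        events = [
            RuptureEvent(time=float(times[i]), drop_pp=float(drop))
            for i, drop in enumerate(drops, start=1)
            if drop > 0 and drop >= self.min_drop_pp
        ]
        self.events_ = events
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Boolean mask over the series marking event measurements."""
        times, _ = self._coerce(X)
        self.fit(X)
        event_times = {e.time for e in self.events_}
        return np.array([t in event_times for t in times])


def detect_rupture_events(
    series: CompartmentSeries, min_drop_pp: float = DEFAULT_MIN_DROP_PP
) -> list[RuptureEvent]:
    """Thin wrapper over :class:`RuptureDetector` (see its docstring for the
    detection rule)."""
    return RuptureDetector(min_drop_pp=min_drop_pp).fit(series).events_


def compare_series(
    series_list: Sequence[CompartmentSeries],
    min_drop_pp: float = DEFAULT_MIN_DROP_PP,
) -> pd.DataFrame:
    """Per-temperature rupture summary across drying protocols.

    Returns a DataFrame with one row per series: temperature, number of
    rupture events, time of the first event (NaN if none), and final ICW%.
    Higher drying temperatures typically show earlier first events; gentle
    protocols may show none.
    """
    if len(series_list) < 2:
        raise ValueError("need >= 2 series to compare")
    rows = []
    for s in series_list:
        events = detect_rupture_events(s, min_drop_pp=min_drop_pp)
        rows.append(
            {
                "temperature_c": s.temperature_c,
                "n_events": len(events),
                "first_event_min": events[0].time if events else np.nan,
                "final_icw_pct": float(s.icw_pct[-1]),
            }
        )
    return pd.DataFrame(rows)
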