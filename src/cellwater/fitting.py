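"""Nonlinear least-squares decomposition of T2 relaxation decays.

The decay is fit with a discrete sum of 1-3 exponentials by variable
projection: the nonlinear search runs over the log-T2 values only, and for
each candidate T2 set the amplitudes are solved exactly by non-negative
linear least squares.  This keeps the search space tiny (k parameters
instead of 2k), guarantees non-negative amplitudes, and is far less
sensitive to starting values than a joint search.  Multi-start over
log-spaced T2 guesses makes the result deterministic and robust to local
minima.

Model order (how many exponentials the data support) is estimated from the
log-signal plot: a k-exponential decay shows k roughly linear regimes in
ln Z vs t, so the ln-signal is segmented into k contiguous straight lines
(exact dynamic programming) and the order with the best BIC-penalised score
wins.  See :func:`estimate_component_count` for the scoring details.

Fits are quality-gated, never deleted: a fit from a low-SNR acquisition is
flagged ``accepted=False`` and excluded from downstream series, mirroring
the practice of eliminating noisy echo trains before compartment analysis.
The default gate of 5.17 is the empirical minimum SNR at which the four
parameters of a bi-exponential fit remain stable.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Union

import numpy as np
from scipy.optimize import least_squares, nnls
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitError
from .model import (
    T2_MERGE_RTOL,
    DecayCurve,
    FitResult,
    MultiExpModel,
    log_signal,
)

__all__ = [
    "FitConfig",
    "MultiExponentialFitter",
    "fit_multiexponential",
    "estimate_component_count",
    "compute_snr",
    "gate_by_snr",
]

#: default SNR below which a multi-exponential fit is considered unreliable
DEFAULT_SNR_GATE = 5.17


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the decay decomposition.

    Attributes
    ----------
    max_components
        Upper bound on model order considered by auto-selection (1-3).
    n_starts
        Number of multi-start initialisations for the nonlinear search.
    snr_gate
        Acceptance threshold for :func:`gate_by_snr`; ties accept.
    t2_bounds
        Admissible T2 range in ms.
    tol
        Convergence tolerance (ftol/xtol) passed to the least-squares solver.
    """

    max_components: int = 3
    n_starts: int = 8
    snr_gate: float = DEFAULT_SNR_GATE
    t2_bounds: tuple[float, float] = (0.1, 10000.0)
    tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.max_components not in (1, 2, 3):
            raise ValueError("max_components must be 1, 2 or 3")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.snr_gate <= 0:
            raise ValueError("snr_gate must be > 0")
        lo, hi = self.t2_bounds
        if not 0 < lo < hi:
            raise ValueError("t2_bounds must satisfy 0 < lo < hi")


# ---------------------------------------------------------------------------
# SNR


def compute_snr(signal_roi, noise_roi) -> float:
    """Signal-to-noise ratio: mean of the sample ROI over the standard
    deviation of a noise-only ROI (the common MR convention).

    Returns ``inf`` when the noise ROI has zero variance.
    """
    signal_roi = np.asarray(signal_roi, dtype=float)
    noise_roi = np.asarray(noise_roi, dtype=float)
    if signal_roi.size == 0 or noise_roi.size == 0:
        raise ValueError("signal_roi and noise_roi must be non-empty")
    if noise_roi.size < 2:
        raise ValueError("noise_roi needs >= 2 samples to estimate a spread")
    sd = float(np.std(noise_roi, ddof=1))
    if sd == 0.0:
        return math.inf
    return float(np.mean(signal_roi)) / sd


def gate_by_snr(fit: FitResult, snr: float, config: Optional[FitConfig] = None) -> FitResult:
    """Apply the SNR acceptance gate to a fit.

    The fit is retained either way; only ``accepted`` and ``snr`` change.
    Acceptance is ``snr >= gate`` (ties accept).
    """
    config = config or FitConfig()
    return dataclasses.replace(fit, snr=float(snr), accepted=bool(snr >= config.snr_gate))


# ---------------------------------------------------------------------------
# Variable-projection NLLS


def _amplitudes_for(t: np.ndarray, y: np.ndarray, t2s: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative LS amplitudes for fixed T2s; returns (amplitudes, rnorm)."""
    basis = np.exp(-t[:, None] / t2s[None, :])
    amps, rnorm = nnls(basis, y)
    return amps, rnorm

def _t2_starts(t: np.ndarray, k: int, config: FitConfig) -> list[np.ndarray]:
    """Deterministic multi-start T2 guesses: k-subsets of a log-spaced grid
    spanning the sampled time window (clipped to the bounds)."""
    lo = max(config.t2_bounds[0], float(t[0]) / 3.0)
    hi = min(config.t2_bounds[1], float(t[-1]) * 3.0)
    if hi <= lo:
        hi = lo * 10.0
    m = k + 1
    while math.comb(m, k) < config.n_starts and m < 40:
        m += 1
    grid = np.geomspace(lo, hi, m)
    combos = list(combinations(range(m), k))
    idx = np.linspace(0, len(combos) - 1, min(config.n_starts, len(combos)))
    return [grid[list(combos[int(i)])] for i in idx]


def _fit_fixed_order(
    t: np.ndarray, y: np.ndarray, k: int, config: FitConfig
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-n-starts varpro fit; returns (amplitudes, t2s, ss_res).

    The effective lower T2 bound is raised to half the first echo time: a
    component decaying faster than the sampling grid only touches the first
    echo, so its amplitude extrapolates without constraint and poisons the
    t=0 amplitude fractions.  Such components are not resolvable by the
    acquisition and are excluded rather than reported.
    """
    lo_eff = max(config.t2_bounds[0], float(t[t > 0][0]) / 2.0 if np.any(t > 0) else config.t2_bounds[0])
    log_lo, log_hi = math.log(lo_eff), math.log(config.t2_bounds[1])

    def residual(log_t2):
        amps, _ = _amplitudes_for(t, y, np.exp(log_t2))
        basis = np.exp(-t[:, None] / np.exp(log_t2)[None, :])
        return basis @ amps - y

    best = None
    for start in _t2_starts(t, k, config):
        x0 = np.clip(np.log(start), log_lo, log_hi)
        try:
            sol = least_squares(
                residual,
                x0,
                bounds=(log_lo, log_hi),
                method="trf",
                ftol=config.tol,
                xtol=config.tol,
                gtol=None,
            )
        except Exception:  # singular Jacobian on a pathological start
            continue
        cost = 2.0 * sol.cost
        if best is None or cost < best[0]:
            best = (cost, sol.x)
    if best is None:
        raise FitError(f"all {config.n_starts} starts failed for k={k}")
    t2s = np.exp(best[1])
    amps, _ = _amplitudes_for(t, y, t2s)
    ss_res = float(best[0])
    return amps, t2s, ss_res


def _canonicalise(
    amps: np.ndarray, t2s: np.ndarray, config: FitConfig
) -> tuple[MultiExpModel, tuple[str, ...]]:
    """Sort descending by T2, merge coincident T2s, flag degeneracies."""
    flags: list[str] = []
    order = np.argsort(t2s)[::-1]
    amps, t2s = amps[order], t2s[order]
    # merge components whose T2 collided during optimisation
    merged_a, merged_t = [float(amps[0])], [float(t2s[0])]
    for a, tt in zip(amps[1:], t2s[1:]):
        if abs(merged_t[-1] - tt) <= T2_MERGE_RTOL * max(merged_t[-1], tt):
            merged_a[-1] += float(a)
            flags.append("components-merged")
        else:
            merged_a.append(float(a))
            merged_t.append(float(tt))
    if any(a == 0.0 for a in merged_a) and len(merged_a) > 1:
        flags.append("component-collapsed")
    lo, hi = config.t2_bounds
    if any(tt <= lo * 1.01 or tt >= hi * 0.99 for tt in merged_t):
        flags.append("t2-at-bound")
    # zero-amplitude components are kept (flagged) unless a merge removed them
    model = MultiExpModel.from_arrays(merged_a, merged_t)
    return model, tuple(flags)


# ---------------------------------------------------------------------------
# Model-order selection from the ln-signal


def _segment_costs(x: np.ndarray, y: np.ndarray, min_len: int) -> np.ndarray:
    """SSE of a straight-line fit on every contiguous window [i, j).

    O(1) per window via prefix sums; windows shorter than ``min_len`` get
    infinite cost.
    """
    n = len(x)
    z = np.zeros(1)
    cx = np.concatenate([z, np.cumsum(x)])
    cy = np.concatenate([z, np.cumsum(y)])
    cxx = np.concatenate([z, np.cumsum(x * x)])
    cyy = np.concatenate([z, np.cumsum(y * y)])
    cxy = np.concatenate([z, np.cumsum(x * y)])
    cost = np.full((n + 1, n + 1), np.inf)
    for i in range(n):
        js = np.arange(i + min_len, n + 1)
        if len(js) == 0:
            continue
        m = js - i
        sx = cx[js] - cx[i]
        sy = cy[js] - cy[i]
        sxx = cxx[js] - cxx[i]
        syy = cyy[js] - cyy[i]
        sxy = cxy[js] - cxy[i]
        vxx = sxx - sx * sx / m
        vyy = syy - sy * sy / m
        vxy = sxy - sx * sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            sse = vyy - np.where(vxx > 0, vxy * vxy / np.maximum(vxx, 1e-300), 0.0)
        cost[i, js] = np.maximum(sse, 0.0)
    return cost


def _piecewise_linear_sse(x: np.ndarray, y: np.ndarray, k_max: int, min_len: int = 3) -> list[float]:
    """Optimal k-segment piecewise-linear SSE for k = 1..k_max (exact DP)."""
    n = len(x)
    seg = _segment_costs(x, y, min_len)
    best = [seg[0, 1:].copy()]  # best[k-1][j-1] = cost of [0, j) with k segments
    for _ in range(1, k_max):
        prev = best[-1]
        cur = np.full(n, np.inf)
        for j in range(1, n + 1):
            cand = prev[: j - 1] + seg[1 : j, j]
            if len(cand):
                cur[j - 1] = min(cur[j - 1], float(np.min(cand)))
        best.append(cur)
    return [float(b[n - 1]) for b in best]


def estimate_component_count(
    curve: DecayCurve,
    config: Optional[FitConfig] = None,
    *,
    signal_floor_frac: float = 1e-2,
    noise_rtol: float = 1e-2,
    max_points: int = 200,
) -> int:
    """Estimate how many exponential components the decay supports.

    The ln-signal of a k-exponential decay consists of k near-linear
    regimes, so the (time, ln signal) data are segmented into k contiguous
    straight lines for k = 1..max and scored with a BIC-style criterion:

        score(k) = m * ln((SSE_k + m*s0^2)/m) + (3k - 1) * ln(m)

    where ``s0 = noise_rtol * (ln-signal range)`` is a resolution floor
    below which residual structure is not considered evidence for another
    regime (without it, any smooth curve rewards ever-finer segmentation).
    Only samples with signal above ``signal_floor_frac`` of the initial
    signal enter, restricting the analysis to the informative early window
    rather than the flat noise-floor tail.

    Returns the order in ``{1, ..., max_components}``; ties prefer the
    smaller order.
    """
    config = config or FitConfig()
    t, ln_y = log_signal(curve, on_nonpositive="drop")
    y0 = np.exp(ln_y[0])
    keep = np.exp(ln_y) >= signal_floor_frac * y0
    t, ln_y = t[keep], ln_y[keep]
    if len(t) > max_points:
        idx = np.unique(np.linspace(0, len(t) - 1, max_points).astype(int))
        t, ln_y = t[idx], ln_y[idx]
    m = len(t)
    k_max = config.max_components
    if m < 3 * k_max:
        k_max = max(1, m // 3)
        if k_max < config.max_components:
            warnings.warn(
                f"only {m} usable samples; limiting model order to {k_max}",
                stacklevel=2,
            )
    sses = _piecewise_linear_sse(t, ln_y, k_max)
    span = float(ln_y.max() - ln_y.min())
    # absolute lower limit keeps degenerate (flat) curves away from the
    # float-rounding regime where segment SSEs differ only by noise
    floor = m * (noise_rtol * max(span, 1e-3)) ** 2
    scores = [
        m * math.log((sse + floor) / m) + (3 * (k + 1) - 1) * math.log(m)
        for k, sse in enumerate(sses)
    ]
    # ties (and near-ties at solver precision) go to the simpler model
    best = min(range(len(scores)), key=lambda i: (round(scores[i], 9), i))
    return best + 1


# ---------------------------------------------------------------------------
# Estimator


class MultiExponentialFitter(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for multi-exponential decay curves.

    Fits ``Z(t) = sum_i M_i exp(-t / T2_i)`` to (time, signal) data by
    variable-projection nonlinear least squares with deterministic
    multi-start initialisation.

    Parameters
    ----------
    n_components : int or "auto", default "auto"
        Model order; "auto" selects it from the ln-signal segmentation
        score (see :func:`estimate_component_count`).
    max_components : int, default 3
        Cap for automatic order selection.
    n_starts : int, default 8
        Multi-start count for the nonlinear search.
    t2_bounds : pair of float, default (0.1, 10000.0)
        Admissible T2 range in ms.
    tol : float, default 1e-12
        Solver convergence tolerance.

    Attributes
    ----------
    model_ : MultiExpModel
        Fitted components in canonical (descending-T2) order.
    n_components_ : int
        Order actually fitted.
    r_squared_ : float
        Coefficient of determination on the training curve, clipped to [0, 1].
    residual_norm_ : float
        Sum of squared residuals.
    flags_ : tuple of str
        Degeneracy diagnostics (merged components, bounds hit, ...).

    Examples
    --------
    >>> import numpy as np
    >>> from cellwater import MultiExponentialFitter
    >>> t = 10.0 * np.arange(1, 101)
    >>> y = 88.1 * np.exp(-t / 90.67) + 11.97 * np.exp(-t / 32.76)
    >>> fitter = MultiExponentialFitter(n_components=2).fit(t.reshape(-1, 1), y)
    >>> np.round(fitter.model_.t2s, 2)
    array([90.67, 32.76])
    """

    def __init__(
        self,
        n_components: Union[int, str] = "auto",
        max_components: int = 3,
        n_starts: int = 8,
        t2_bounds: tuple[float, float] = (0.1, 10000.0),
        tol: float = 1e-12,
    ):
        self.n_components = n_components
        self.max_components = max_components
        self.n_starts = n_starts
        self.t2_bounds = t2_bounds
        self.tol = tol

    def _config(self) -> FitConfig:
        return FitConfig(
            max_components=self.max_components,
            n_starts=self.n_starts,
            t2_bounds=tuple(self.t2_bounds),
            tol=self.tol,
        )

    @staticmethod
    def _validate_times(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single column of echo times")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-D times or a (n, 1) column")
        if len(X) < 4:
            raise ValueError("need >= 4 echoes to fit a decay")
        if not np.all(np.isfinite(X)) or np.any(X < 0):
            raise ValueError("echo times must be finite and >= 0")
        return X

    def fit(self, X, y):
        """Fit the decay model.

        Parameters
        ----------
        X : array-like of shape (n_echoes,) or (n_echoes, 1)
            Echo times in ms.
        y : array-like of shape (n_echoes,)
            Magnitude signal.
        """
        t = self._validate_times(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValueError("X and y lengths differ")
        if not np.all(np.isfinite(y)):
            raise ValueError("signal must be finite")
        order = np.argsort(t)
        t, y = t[order], y[order]
        config = self._config()

        if self.n_components == "auto":
            curve = DecayCurve(times=np.maximum(t, np.finfo(float).tiny), signal=y)
            k = estimate_component_count(curve, config)
        else:
            k = int(self.n_components)
            if not 1 <= k <= 3:
                raise ValueError("n_components must be in {1, 2, 3} or 'auto'")

        amps, t2s, ss_res = _fit_fixed_order(t, y, k, config)
        self.model_, self.flags_ = _canonicalise(amps, t2s, config)
        self.n_components_ = self.model_.n_components
        if self.n_components_ < k:
            # requested order exceeded what the data identify
            self.flags_ = self.flags_ + ("order-reduced",)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            self.r_squared_ = 1.0 if ss_res == 0.0 else 0.0
        else:
            self.r_squared_ = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
        self.residual_norm_ = ss_res
        return self

    def predict(self, X) -> np.ndarray:
        """Evaluate the fitted model at the given echo times."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        return self.model_(np.atleast_1d(t))

    def to_fit_result(self) -> FitResult:
        """Package the fitted state as an immutable :class:`FitResult`."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        return FitResult(
            model=self.model_,
            r_squared=self.r_squared_,
            residual_norm=self.residual_norm_,
            flags=self.flags_,
        )


def fit_multiexponential(
    curve: DecayCurve,
    k: Union[int, str] = "auto",
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Fit a k-component decay model to a curve (thin wrapper around
    :class:`MultiExponentialFitter`).

    Parameters
    ----------
    curve
        Input decay.
    k
        Model order, or "auto" for ln-signal-based selection.
    config
        Fit tunables; defaults to :class:`FitConfig()`.
    """
    config = config or FitConfig()
    est = MultiExponentialFitter(
        n_components=k,
        max_components=config.max_components,
        n_starts=config.n_starts,
        t2_bounds=config.t2_bounds,
        tol=config.tol,
    )
    est.fit(curve.times, curve.signal)
    return est.to_fit_result()
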