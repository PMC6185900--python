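"""Domain types and the forward multi-exponential transverse-relaxation model.

A CPMG/MSME echo train from tissue with several non-exchanging water
compartments decays as a sum of exponentials,

    Z(t) = sum_i  M_i * exp(-t / T2_i),

where ``M_i`` is the relative contribution of compartment *i* (arbitrary
units; a percentage view is computed downstream) and ``T2_i`` its spin-spin
relaxation time constant in milliseconds.  Components are kept in canonical
order, sorted by *descending* T2, so that index 0 is always the "long"
(slow-relaxing, intracellular-water) component and index 1 the "short"
(free-water) component.

Times are milliseconds everywhere inside the package; unit conversion, if
any, happens at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import EmptyCurveError, InvalidModelError

__all__ = [
    "CurveMeta",
    "DecayCurve",
    "ExponentialComponent",
    "MultiExpModel",
    "FitResult",
    "evaluate_model",
    "log_signal",
]

#: relative tolerance under which two T2 values are considered identical
T2_MERGE_RTOL = 1e-6


@dataclass(frozen=True)
class CurveMeta:
    """Acquisition context of a decay curve.

    Parameters
    ----------
    temperature_c
        Drying-air temperature in degrees Celsius, if known.
    drying_time_min
        Cumulative drying time of the sample in minutes, if known.
    sample_id
        Free-form sample identifier.
    """

    temperature_c: Optional[float] = None
    drying_time_min: Optional[float] = None
    sample_id: Optional[str] = None


@dataclass(frozen=True)
class ExponentialComponent:
    """One proton environment: relative contribution and T2 in ms."""

    amplitude: float
    t2: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise InvalidModelError(
                f"component amplitude must be finite and >= 0, got {self.amplitude}"
            )
        if not np.isfinite(self.t2) or self.t2 <= 0:
            raise InvalidModelError(
                f"component T2 must be finite and > 0 ms, got {self.t2}"
            )


@dataclass(frozen=True)
class MultiExpModel:
    """A 1- to 3-component multi-exponential decay model.

    Components are stored sorted by descending T2 (canonical order); the
    constructor sorts whatever order it is given.  Two components with
    identical T2 are rejected — merge their amplitudes instead.
    """

    components: tuple[ExponentialComponent, ...]

    def __init__(self, components: Sequence[ExponentialComponent]):
        components = tuple(
            sorted(components, key=lambda c: c.t2, reverse=True)
        )
        if not 1 <= len(components) <= 3:
            raise InvalidModelError(
                f"model must have 1-3 components, got {len(components)}"
            )
        t2s = [c.t2 for c in components]
        for a, b in zip(t2s, t2s[1:]):
            if abs(a - b) <= T2_MERGE_RTOL * max(a, b):
                raise InvalidModelError(
                    f"components share T2 ({a} ms vs {b} ms); merge amplitudes"
                )
        object.__setattr__(self, "components", components)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c.amplitude for c in self.components])

    @property
    def t2s(self) -> np.ndarray:
        """T2 values in ms, descending (index 0 = long component)."""
        return np.array([c.t2 for c in self.components])

    @property
    def total_amplitude(self) -> float:
        return float(self.amplitudes.sum())

    def __call__(self, times) -> np.ndarray:
        return evaluate_model(self, times)

    @classmethod
    def from_arrays(cls, amplitudes, t2s) -> "MultiExpModel":
        return cls(
            [ExponentialComponent(float(a), float(t)) for a, t in zip(amplitudes, t2s)]
        )


@dataclass(frozen=True)
class DecayCurve:
    """Sampled magnitude decay: echo times (ms) and signal intensities (a.u.).

    Echo times must be strictly increasing and positive, with at least four
    samples.  Magnitude signals are normally non-negative, but samples at the
    noise floor of a Gaussian-noise acquisition may dip below zero; they are
    kept here and handled by the operations that cannot tolerate them
    (see :func:`log_signal`).
    """

    times: np.ndarray
    signal: np.ndarray
    meta: CurveMeta = field(default_factory=CurveMeta)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        if times.ndim != 1 or signal.ndim != 1:
            raise ValueError("times and signal must be 1-D")
        if len(times) != len(signal):
            raise ValueError(
                f"times ({len(times)}) and signal ({len(signal)}) differ in length"
            )
        if len(times) < 4:
            raise ValueError(f"need >= 4 samples, got {len(times)}")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(signal)):
            raise ValueError("times and signal must be finite")
        if times[0] <= 0:
            raise ValueError("echo times must be positive")
        if np.any(np.diff(times) <= 0):
            raise ValueError("echo times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "signal", signal)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FitResult:
    """A fitted model plus goodness-of-fit and quality-gate diagnostics.

    Attributes
    ----------
    model
        The fitted :class:`MultiExpModel`, canonical (descending-T2) order.
    r_squared
        Coefficient of determination of the fit, clipped to [0, 1].
    snr
        Signal-to-noise ratio attached by the gating step; ``None`` until
        gated.
    accepted
        Outcome of the SNR gate.  ``True`` by default (no gate applied yet);
        gating never deletes a fit, it only flips this flag.
    residual_norm
        Sum of squared residuals of the fit.
    flags
        Diagnostic markers, e.g. ``"components-merged"`` when two fitted T2
        values coincided, or ``"t2-at-bound"``.
    """

    model: MultiExpModel
    r_squared: float
    residual_norm: float
    snr: Optional[float] = None
    accepted: bool = True
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")


def evaluate_model(model: MultiExpModel, times) -> np.ndarray:
    """Evaluate the forward decay model Z(t) = sum_i M_i exp(-t/T2_i).

    Parameters
    ----------
    model
        Model to evaluate; must have at least one component.
    times
        Times in ms, all >= 0 (scalar or array-like).

    Returns
    -------
    numpy.ndarray
        Model signal at each time.  At ``t = 0`` this equals the sum of the
        amplitudes exactly; for positive amplitudes the curve is strictly
        decreasing.
    """
    if not isinstance(model, MultiExpModel):
        raise InvalidModelError(f"expected MultiExpModel, got {type(model).__name__}")
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    # (n_times, n_components) decay basis; rows sum against amplitudes
    basis = np.exp(-t[:, None] / model.t2s[None, :])
    return basis @ model.amplitudes


def log_signal(
    curve: DecayCurve, on_nonpositive: str = "drop"
) -> tuple[np.ndarray, np.ndarray]:
    """Natural log of the signal against time, for visual/piecewise-linear
    model-order inspection.

    A mono-exponential decay is exactly linear here with slope ``-1/T2``;
    extra components show up as distinct linear regimes.

    Parameters
    ----------
    curve
        Input decay.
    on_nonpositive
        ``"drop"`` (default) silently removes samples with signal <= 0
        (noise-floor samples have no defined log); ``"error"`` raises on any.

    Returns
    -------
    (times, log_values)
        Arrays over the retained samples.
    """
    if on_nonpositive not in ("drop", "error"):
        raise ValueError("on_nonpositive must be 'drop' or 'error'")
    keep = curve.signal > 0
    if on_nonpositive == "error" and not keep.all():
        raise EmptyCurveError("curve contains non-positive signal samples")
    if not keep.any():
        raise EmptyCurveError("no positive signal samples to take log of")
    return curve.times[keep], np.log(curve.signal[keep])
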