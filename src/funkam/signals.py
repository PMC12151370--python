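"""Filtering and differentiation utilities.

Two filtering paths exist in the pipeline: the offline path uses a zero-lag
low-pass Butterworth filter (net 4th order: a 2nd-order design applied forward
and backward, the dominant biomechanics convention), and the streaming path
uses a causal exponential moving average with smoothing factor 0.1525.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .errors import ValidationError

__all__ = [
    "FilterSpec",
    "butterworth_zero_lag",
    "ema_filter",
    "EmaState",
    "differentiate",
]

DEFAULT_CUTOFF_HZ = 6.0
DEFAULT_EMA_ALPHA = 0.1525


@dataclass(frozen=True)
class FilterSpec:
    """Filter configuration carried in pipeline configs.

    ``kind`` is ``butterworth_zero_lag`` or ``ema``.  ``order`` is the *net*
    order of the zero-lag filter; ``order_per_pass`` switches to interpreting
    it as the per-pass order instead.
    """

    kind: str = "butterworth_zero_lag"
    order: int = 4
    cutoff_hz: float = DEFAULT_CUTOFF_HZ
    alpha: float = DEFAULT_EMA_ALPHA
    order_per_pass: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("butterworth_zero_lag", "ema", "none"):
            raise ValidationError(f"unknown filter kind {self.kind!r}")
        if self.kind == "butterworth_zero_lag" and self.order % 2:
            raise ValidationError("net Butterworth order must be even")
        if not 0.0 < self.alpha <= 1.0:
            raise ValidationError("EMA alpha must be in (0, 1]")

    def apply(self, x: np.ndarray, rate: float) -> np.ndarray:
        if self.kind == "none":
            return np.asarray(x, dtype=float)
        if self.kind == "ema":
            return ema_filter(x, self.alpha)
        order = self.order * 2 if self.order_per_pass else self.order
        return butterworth_zero_lag(x, rate, cutoff_hz=self.cutoff_hz, order=order)


def butterworth_zero_lag(
    x: np.ndarray, rate: float, cutoff_hz: float = DEFAULT_CUTOFF_HZ, order: int = 4
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    ``order`` is the net order; each pass uses ``order // 2``.  Works along
    axis 0 so multi-channel series (frames x channels) filter in one call.
    Edges are handled by odd reflection padding of length ``3 * (order + 1)``
    samples (scipy's filtfilt default).
    """
    x = np.asarray(x, dtype=float)
    if cutoff_hz <= 0 or rate <= 2 * cutoff_hz:
        raise ValidationError("need rate > 2 * cutoff for a low-pass design")
    if order % 2 or order < 2:
        raise ValidationError("net order must be a positive even number")
    b, a = _sig.butter(order // 2, cutoff_hz / (rate / 2.0))
    padlen = 3 * (max(len(a), len(b)) - 1) * (order // 2)
    padlen = max(padlen, 3 * (order + 1))
    if x.shape[0] <= padlen:
        raise ValidationError(
            f"series of length {x.shape[0]} too short for padding length {padlen}"
        )
    return _sig.filtfilt(b, a, x, axis=0, padlen=padlen)


def ema_filter(x: np.ndarray, alpha: float = DEFAULT_EMA_ALPHA) -> np.ndarray:
    """Causal exponential moving average.

    ``y[0] = x[0]``, then ``y[t] = alpha * x[t] + (1 - alpha) * y[t-1]``.
    Streamable: :class:`EmaState` provides the one-sample-at-a-time form.
    """
    x = np.asarray(x, dtype=float)
    if not 0.0 < alpha <= 1.0:
        raise ValidationError("alpha must be in (0, 1]")
    # lfilter with initial condition chosen so that y[0] == x[0]
    zi_unit = np.ones(1) * (1.0 - alpha)
    if x.ndim == 1:
        y, _ = _sig.lfilter([alpha], [1.0, -(1.0 - alpha)], x, zi=zi_unit * x[0])
        return y
    y = np.empty_like(x)
    for j in range(x.shape[1]):
        y[:, j], _ = _sig.lfilter(
            [alpha], [1.0, -(1.0 - alpha)], x[:, j], zi=zi_unit * x[0, j]
        )
    return y


class EmaState:
    """Streaming EMA filter state (one vector sample per step)."""

    def __init__(self, alpha: float = DEFAULT_EMA_ALPHA):
        if not 0.0 < alpha <= 1.0:
            raise ValidationError("alpha must be in (0, 1]")
        self.alpha = alpha
        self.y: np.ndarray | None = None

    def step(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.y is None:
            self.y = x.copy()
        else:
            self.y = self.alpha * x + (1.0 - self.alpha) * self.y
        return self.y.copy()


def differentiate(
    x: np.ndarray, rate: float, scheme: str = "central", order: int = 1
) -> np.ndarray:
    """Numerical derivative along axis 0.

    ``central`` uses second-order central differences with one-sided endpoints
    (offline use); ``backward`` uses first-order backward differences and is
    causal (streaming use; first sample(s) copy the earliest computable value).
    ``order=2`` differentiates twice.
    """
    x = np.asarray(x, dtype=float)
    if scheme not in ("central", "backward"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    dt = 1.0 / rate
    for _ in range(order):
        if scheme == "central":
            x = np.gradient(x, dt, axis=0, edge_order=2)
        else:
            d = np.diff(x, axis=0) / dt
            x = np.concatenate([d[:1], d], axis=0)
    return x
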