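"""Axis transforms and zero-lux treatment strategies.

Light exposure spans six orders of magnitude within a day, so logarithmic
axes are standard — but exact zeros (light below the sensor's detection
floor) have no logarithm.  This module provides the transforms used to
display and to premodel such data:

* **symlog** — logarithmic beyond a threshold ``T`` (default 1 lux),
  linear through zero inside ``[-T, T]``; odd, and in the default
  ``continuous`` mode also continuous and strictly increasing.  A
  ``literal`` mode keeps the textbook piecewise definition
  ``sign(x)·log_b|x|`` for ``|x| > T``, which is discontinuous at ``±T``.
* **pseudo-log** — the smooth inverse-hyperbolic-sine alternative, for
  comparison.
* **zero treatments** — the four strategies for making zero-inflated lux
  series model-ready: drop zeros to missing, add machine epsilon, add a
  fixed constant (default 0.1 lux, one decade below a 1-lux detection
  floor), or leave the data untouched (for families with a point mass at
  zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import LightTimeSeries

__all__ = [
    "SymlogScale",
    "ZeroTreatment",
    "HybridParts",
    "symlog_forward",
    "symlog_inverse",
    "symlog_ticks",
    "pseudo_log",
    "machine_epsilon",
    "apply_zero_treatment",
    "back_adjust_predictions",
    "hybrid_split",
]


@dataclass(frozen=True)
class SymlogScale:
    """Parameters of the symmetric-log axis transform.

    threshold
        ``T > 0``: half-width of the linear band, in lux.
    base
        Logarithm base ``b > 1``.
    linear_span
        ``L > 0``: width, in transformed units, that the linear band
        ``[0, T]`` occupies in ``continuous`` mode.
    mode
        ``"continuous"`` (default): linear segment rescaled to ``L/T`` so
        the map is continuous and strictly increasing on all reals —
        the convention of established symlog axes.  ``"literal"``: plain
        ``sign(x)·log_b|x|`` outside the band and identity inside, which
        is discontinuous at ``±T`` and not injective; kept for fidelity
        checks only.
    """

    threshold: float = 1.0
    base: float = 10.0
    linear_span: float = 1.0
    mode: Literal["continuous", "literal"] = "continuous"

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if not self.base > 1:
            raise ValueError(f"base must be > 1, got {self.base}")
        if not self.linear_span > 0:
            raise ValueError(f"linear_span must be > 0, got {self.linear_span}")
        if self.mode not in ("continuous", "literal"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class ZeroTreatment:
    """A strategy for zero-lux observations ahead of log-scale modeling.

    kind
        ``drop_zeros``: zeros become missing (NaN); ``add_epsilon``: add
        the double-precision machine epsilon to every value;
        ``add_constant``: add ``constant`` lux to every value; ``none``:
        identity (for the compound Poisson–Gamma family, which carries
        its own point mass at zero).
    constant
        Offset in lux used by ``add_constant`` (default 0.1, one decade
        below a 1-lux detection floor).
    """

    kind: Literal["drop_zeros", "add_epsilon", "add_constant", "none"]
    constant: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("drop_zeros", "add_epsilon", "add_constant", "none"):
            raise ValueError(f"unknown treatment kind {self.kind!r}")
        if self.kind == "add_constant" and not self.constant > 0:
            raise ValueError(f"add_constant requires constant > 0, got {self.constant}")

    @property
    def offset(self) -> float:
        """The additive offset this treatment applies (0 for drop/none)."""
        if self.kind == "add_epsilon":
            return machine_epsilon()
        if self.kind == "add_constant":
            return self.constant
        return 0.0


def machine_epsilon() -> float:
    """Machine epsilon of IEEE-754 binary64: smallest eps with 1 + eps != 1.

    Defined operationally from the runtime's floating-point format rather
    than as a hard-coded constant; equals ``2**-52`` on any IEEE-754
    double implementation.
    """
    return float(np.finfo(np.float64).eps)


def symlog_forward(x, scale: SymlogScale = SymlogScale()):
    """Symmetric-log transform of lux values or lux differences.

    Odd by construction: ``f(-x) = -f(x)``.  In ``continuous`` mode
    ``f(x) = L·x/T`` for ``|x| <= T`` and ``sign(x)·(L + log_b(|x|/T))``
    beyond, continuous and strictly increasing.  In ``literal`` mode the
    linear branch is the identity and the log branch is
    ``sign(x)·log_b|x|``.  Values exactly at ``±T`` take the linear
    branch.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("symlog_forward requires finite input")
    T, b, L = scale.threshold, scale.base, scale.linear_span
    absx = np.abs(x)
    lin = absx <= T
    out = np.empty_like(x)
    if scale.mode == "literal":
        out[lin] = x[lin]
        with np.errstate(divide="ignore"):
            out[~lin] = np.sign(x[~lin]) * (np.log(absx[~lin]) / np.log(b))
    else:
        out[lin] = L * x[lin] / T
        out[~lin] = np.sign(x[~lin]) * (L + np.log(absx[~lin] / T) / np.log(b))
    return out if out.ndim else float(out)


def symlog_inverse(y, scale: SymlogScale = SymlogScale()):
    """Inverse of :func:`symlog_forward`.

    Defined for ``continuous`` mode everywhere.  ``literal`` mode is not
    injective: the log branch also maps values just above the threshold
    into the band the linear branch occupies, so literal-mode inversion
    is refused inside the ambiguous band ``|y| <= max(T, log_b T)``
    rather than guessed.
    """
    y = np.asarray(y, dtype=float)
    T, b, L = scale.threshold, scale.base, scale.linear_span
    if scale.mode == "literal":
        ambiguous = max(T, abs(np.log(T) / np.log(b)))
        if np.any(np.abs(y) <= ambiguous):
            raise ValueError(
                "literal-mode symlog is not invertible inside the ambiguous band "
                f"|y| <= {ambiguous:g}; use continuous mode"
            )
        out = np.sign(y) * np.power(b, np.abs(y))
        return out if out.ndim else float(out)
    lin = np.abs(y) <= L
    out = np.empty_like(y)
    out[lin] = y[lin] * T / L
    out[~lin] = np.sign(y[~lin]) * T * np.power(b, np.abs(y[~lin]) - L)
    return out if out.ndim else float(out)


def symlog_ticks(lo: float, hi: float, scale: SymlogScale = SymlogScale()
                 ) -> list[tuple[float, str]]:
    """Tick positions (transformed units) and lux labels for a symlog axis.

    Major ticks sit at 0 (when the range spans or touches it) and at the
    signed decades ``±b^k`` with ``b^k >= T`` inside the range.  A
    degenerate or sub-decade positive range falls back to a few linearly
    spaced ticks so an axis is never unlabeled.
    """
    if hi < lo:
        lo, hi = hi, lo
    T, b = scale.threshold, scale.base
    ticks: list[tuple[float, str]] = []

    def label(v: float) -> str:
        if v == 0:
            return "0"
        k = np.log(abs(v)) / np.log(b)
        if abs(v) >= 1 and np.isclose(k, round(k)) and abs(round(k)) >= 3:
            return f"{'-' if v < 0 else ''}{b:g}^{int(round(k))}"
        return f"{v:g}"

    def decades(limit: float) -> list[float]:
        if limit < T:
            return []
        kmax = int(np.floor(np.log(limit) / np.log(b) + 1e-9))
        kmin = int(np.ceil(np.log(T) / np.log(b) - 1e-9))
        return [b ** k for k in range(kmin, kmax + 1)]

    if lo < 0:
        ticks += [(-v, label(-v)) for v in sorted(decades(-lo), reverse=True)]
    if lo <= 0 <= hi:
        ticks.append((0.0, "0"))
    if hi > 0:
        ticks += [(v, label(v)) for v in decades(hi)]
    if len(ticks) < 2:
        for v in np.linspace(lo, hi, 5):
            ticks.append((float(v), label(float(v))))
        ticks = sorted(set(ticks))
    return [(float(symlog_forward(v, scale)), lab) for v, lab in ticks]


def pseudo_log(x, sigma: float = 1.0, base: float = 10.0):
    """Smooth signed log-like transform ``asinh(x / 2σ) / ln(base)``.

    Odd, strictly increasing and infinitely smooth; approaches
    ``log_base(x)`` plus a constant for large ``|x|``.  Provided for
    comparison with the sharp-threshold symlog transform.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    x = np.asarray(x, dtype=float)
    out = np.arcsinh(x / (2.0 * sigma)) / np.log(base)
    return out if out.ndim else float(out)


def apply_zero_treatment(series: LightTimeSeries,
                         treatment: ZeroTreatment) -> LightTimeSeries:
    """Apply a zero-lux treatment strategy to a series.

    ``drop_zeros`` turns exact zeros into missing values; the additive
    treatments shift every value (zeros included); ``none`` is the
    identity.  The count of non-zero observations is never changed except
    by the documented drop rule.
    """
    v = series.medi.copy()
    if treatment.kind == "drop_zeros":
        v[v == 0] = np.nan
    elif treatment.kind in ("add_epsilon", "add_constant"):
        v = v + treatment.offset
    return series.with_values(v)


def back_adjust_predictions(predicted, treatment: ZeroTreatment):
    """Map log10-scale model predictions back to lux.

    Inverts the fit-time preprocessing: ``10**pred - offset`` for the
    additive treatments (offset = machine epsilon or the constant),
    clamped below at 0; plain ``10**pred`` for ``drop_zeros`` / ``none``.
    """
    predicted = np.asarray(predicted, dtype=float)
    lux = np.power(10.0, predicted) - treatment.offset
    out = np.maximum(lux, 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HybridParts:
    """Decomposition of values for the hybrid (log + zero-band) plot."""

    positives: np.ndarray      # strictly positive magnitudes, for the log axis
    zero_mask: np.ndarray      # True where the original value was exactly 0
    sign: np.ndarray           # +1 / -1 / 0 per sample (for differences)
    magnitude: np.ndarray      # |value| per sample


def hybrid_split(values) -> HybridParts:
    """Split values into log-axis positives and a zero-band indicator.

    Nonnegative series plot positives on the log axis and flag exact
    zeros for a dedicated band at the bottom of the plot.  Difference
    series may be negative: those are carried as (sign, |d|) pairs so the
    magnitude can be log-scaled and mirrored below zero after a sign
    flip.
    """
    v = np.asarray(values, dtype=float)
    zero_mask = v == 0
    sign = np.sign(v)
    magnitude = np.abs(v)
    return HybridParts(
        positives=v[v > 0],
        zero_mask=zero_mask,
        sign=sign,
        magnitude=magnitude,
    )
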