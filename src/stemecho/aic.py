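"""Classical AIC arrival-time curve and global-minimum onset picker.

The trace is modelled as two locally stationary segments (noise vs. signal)
joined at a merge point ``k``. For a trace ``s(1..N)`` the criterion is

    AIC(k) = k * ln var(s[1..k]) + (N - k + 1) * ln var(s[k+1..N])

with the segment variance using denominator ``j - i`` over ``s(i..j)``
(i.e. the usual unbiased estimator). The global minimum of ``AIC(k)`` marks
the strongest two-segment change point; on homogeneous media that is the
signal onset, while on strongly attenuating stems it falls at the junction
between the transmitted pulse and the noise floor (see
:mod:`stemecho.hybrid` for the picker that recovers the echo proper).

``k`` ranges over ``[2, N-2]`` so both segments hold at least two samples.
A relative variance floor keeps the logarithm finite on near-silent spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import UltrasonicTrace

__all__ = ["AicCurve", "segment_variance", "aic_curve", "classic_min_pick"]

#: Variances below ``VARIANCE_FLOOR_SCALE * max|s|^2`` are floored before the log.
VARIANCE_FLOOR_SCALE = 1e-12


@dataclass(frozen=True)
class AicCurve:
    """AIC(k) over the admissible merge-point range ``[k_min, k_max]``."""

    values: np.ndarray
    k_min: int
    k_max: int
    trace_id: str = "trace"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.k_max < self.k_min:
            raise ValueError("empty admissible range")
        if values.size != self.k_max - self.k_min + 1:
            raise ValueError("values length does not match [k_min, k_max]")
        if not np.all(np.isfinite(values)):
            raise ValueError("AIC curve contains non-finite values")

    @property
    def ks(self) -> np.ndarray:
        """The 1-based merge points the curve is evaluated at."""
        return np.arange(self.k_min, self.k_max + 1)


def segment_variance(s: np.ndarray, i: int, j: int) -> float:
    """Variance of ``s(i..j)`` (1-based, inclusive) with denominator ``j - i``.

    This is the unbiased estimator: mean-centred sum of squares over the
    ``j - i + 1`` samples, divided by ``j - i``.
    """
    s = np.asarray(s, dtype=float)
    if not 1 <= i < j <= s.size:
        raise ValueError(f"need 1 <= i < j <= len(s), got i={i}, j={j}, len={s.size}")
    seg = s[i - 1 : j]
    return float(np.sum((seg - seg.mean()) ** 2) / (j - i))


def _aic_values(s: np.ndarray, variant: str) -> np.ndarray:
    """Vectorised AIC(k) for k in [2, N-2] via centred cumulative sums."""
    n = s.size
    x = s - s.mean()  # variance is shift-invariant; centring conditions the sums
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    k = np.arange(2, n - 1)
    n1 = k
    n2 = n - k
    ss1 = c2[k - 1] - c1[k - 1] ** 2 / n1
    ss2 = (c2[-1] - c2[k - 1]) - (c1[-1] - c1[k - 1]) ** 2 / n2
    v1 = np.maximum(ss1, 0.0) / (n1 - 1)
    v2 = np.maximum(ss2, 0.0) / (n2 - 1)
    floor = VARIANCE_FLOOR_SCALE * float(np.max(np.abs(s))) ** 2
    v1 = np.maximum(v1, floor)
    v2 = np.maximum(v2, floor)
    if variant == "plus1":
        w2 = n - k + 1
    elif variant == "maeda":
        w2 = n - k - 1
    else:
        raise ValueError(f"unknown aic variant {variant!r}")
    return k * np.log(v1) + w2 * np.log(v2)


def aic_curve(trace: UltrasonicTrace, variant: str = "plus1") -> AicCurve:
    """Evaluate the AIC criterion at every admissible merge point.

    Parameters
    ----------
    trace:
        The A-scan; at least 16 samples and not constant.
    variant:
        ``"plus1"`` uses the second-segment weight ``N - k + 1``; ``"maeda"``
        uses the common picker form ``N - k - 1``. The argmin is nearly
        insensitive to the choice.
    """
    s = trace.samples
    if np.ptp(s) == 0:
        raise ValueError("degenerate trace (zero variance everywhere)")
    return AicCurve(
        values=_aic_values(s, variant),
        k_min=2,
        k_max=s.size - 2,
        trace_id=trace.trace_id,
    )


def classic_min_pick(curve: AicCurve) -> int:
    """Merge point attaining the global AIC minimum (earliest on ties)."""
    return curve.k_min + int(np.argmin(curve.values))
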