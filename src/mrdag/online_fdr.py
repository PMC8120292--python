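"""Online false-discovery-rate control for the sequential independence tests.

The skeleton search performs an unknown, data-dependent number of tests; a
fixed per-test level controls only the individual type-I error.  The LOND
rule ("significance Levels based On the Number of Discoveries") instead
assigns test t the threshold

    alpha_t = beta_t * (D(t-1) + 1),

where D(t-1) counts rejections among the first t-1 tests and {beta_t} is a
nonnegative sequence summing to the target overall FDR level alpha.
Thresholds are generous early on and shrink as the test count grows, while
each discovery relaxes subsequent thresholds.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

_BETA_TMAX = 10**6
_norm_cache: dict[int, float] = {}


def _beta_norm(t_max: int = _BETA_TMAX) -> float:
    """Normalizing constant C with sum_{t<=t_max} C / (t ln^2 max(t,2)) = 1."""
    if t_max not in _norm_cache:
        t = np.arange(1, t_max + 1, dtype=float)
        denom = t * np.log(np.maximum(t, 2.0)) ** 2
        _norm_cache[t_max] = float(1.0 / np.sum(1.0 / denom))
    return _norm_cache[t_max]


def default_beta(alpha: float) -> Callable[[int], float]:
    """Summable spending sequence beta_t = alpha * C / (t ln^2 max(t, 2))."""
    c = _beta_norm()

    def beta(t: int) -> float:
        return alpha * c / (t * np.log(max(t, 2.0)) ** 2)

    return beta


@dataclasses.dataclass
class LondState:
    """Running state of the LOND procedure.

    ``alpha`` is the target overall FDR; ``beta`` maps the 1-based test index
    to the spending sequence value (defaulting to a normalized 1/(t ln^2 t)
    sequence); ``t`` and ``num_discoveries`` track progress.
    """

    alpha: float = 0.05
    beta: Callable[[int], float] | None = None
    t: int = 0
    num_discoveries: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.beta is None:
            self.beta = default_beta(self.alpha)

    def next_threshold(self) -> float:
        """Threshold for the next test; consumes one position in the sequence."""
        self.t += 1
        return self.beta(self.t) * (self.num_discoveries + 1)

    def record_result(self, p: float, threshold: float) -> bool:
        """Record a p-value against its threshold; returns True on rejection."""
        if not 0 <= p <= 1:
            raise ValueError("p-value must lie in [0, 1]")
        rejected = p <= threshold
        if rejected:
            self.num_discoveries += 1
        return rejected

    def test(self, p: float) -> tuple[bool, float]:
        """Convenience: draw the next threshold and record the result."""
        thr = self.next_threshold()
        return self.record_result(p, thr), thr


@dataclasses.dataclass
class FixedThreshold:
    """Fixed per-test significance level (no multiplicity adjustment).

    Drop-in alternative to :class:`LondState` mirroring classical PC-style
    testing, where each individual test is run at the same type-I level.
    """

    alpha: float = 0.05
    t: int = 0
    num_discoveries: int = 0

    def next_threshold(self) -> float:
        self.t += 1
        return self.alpha

    def record_result(self, p: float, threshold: float) -> bool:
        rejected = p <= threshold
        if rejected:
            self.num_discoveries += 1
        return rejected

    def test(self, p: float) -> tuple[bool, float]:
        thr = self.next_threshold()
        return self.record_result(p, thr), thr
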