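"""Kernel weights for time-localized estimation.

All smoothing in the package goes through a single weight rule: observations
at times ``t_j`` receive weights proportional to ``K((t_j - t)/h)`` and are
normalized to sum to one at the evaluation time ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelSpec", "kernel_weights"]


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    out = 0.75 * (1.0 - u**2)
    out[np.abs(u) >= 1.0] = 0.0
    return out


def _gaussian(u: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * u**2)


_FAMILIES = {"epanechnikov": _epanechnikov, "gaussian": _gaussian}


@dataclass(frozen=True)
class KernelSpec:
    """A symmetric non-negative kernel with bandwidth ``h > 0``.

    The Epanechnikov kernel (default) has compact support ``|u| < 1``, so
    only observations within ``h`` of the evaluation time contribute; the
    Gaussian kernel weights all observations.
    """

    family: str = "epanechnikov"
    h: float = 0.2

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown kernel family {self.family!r}; choose from {sorted(_FAMILIES)}"
            )
        if not self.h > 0:
            raise ValueError(f"bandwidth must be positive, got {self.h}")

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        return _FAMILIES[self.family](np.asarray(u, dtype=float))


def kernel_weights(times: np.ndarray, t: float, spec: KernelSpec) -> np.ndarray:
    """Normalized kernel weights of each observation at evaluation time ``t``.

    Returns ``w_j = K_h(t_j - t) / sum_j K_h(t_j - t)``; non-negative and
    summing to one.

    Raises
    ------
    ValueError
        If all observations fall outside the kernel support at ``t``
        (zero total mass); a larger bandwidth is needed.
    """
    times = np.asarray(times, dtype=float)
    raw = spec.evaluate((times - t) / spec.h)
    total = raw.sum()
    if total <= 0.0:
        raise ValueError(
            f"no kernel mass at t={t} with bandwidth h={spec.h}; "
            "increase the bandwidth"
        )
    return raw / total
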