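"""Mura-Knowles radial quadrature.

The MK "Log3" rule maps a uniform grid x in (0,1) through
r = -alpha * ln(1 - x^3).  Weights fold in both the map Jacobian and the
r^2 volume element, so sum_i w_i f(r_i) approximates the radial integral
int_0^inf f(r) r^2 dr.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GROUP_12_Z

#: Default MK scaling (Bohr); group-1/2 elements use the larger value.
DEFAULT_ALPHA = 5.0
GROUP12_ALPHA = 7.0


def mk_alpha(Z: int, overrides: dict[int, float] | None = None) -> float:
    """Per-element MK radial scale; overridable via ``overrides``."""
    if overrides and Z in overrides:
        return overrides[Z]
    return GROUP12_ALPHA if Z in GROUP_12_Z else DEFAULT_ALPHA


@dataclass(frozen=True)
class RadialGrid:
    radii: np.ndarray    # strictly increasing, Bohr
    weights: np.ndarray  # include the r^2 Jacobian
    alpha: float


def mk_radial(n: int, alpha: float) -> RadialGrid:
    """Mura-Knowles radial grid with ``n`` nodes and scale ``alpha``."""
    if n < 1:
        raise ValueError(f"node count must be >= 1, got {n}")
    if alpha <= 0:
        raise ValueError(f"scale must be positive, got {alpha}")
    i = np.arange(1, n + 1)
    x = i / (n + 1)
    r = -alpha * np.log1p(-x ** 3)
    w = 3.0 * alpha * x ** 2 / ((1.0 - x ** 3) * (n + 1)) * r ** 2
    return RadialGrid(radii=r, weights=w, alpha=alpha)
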