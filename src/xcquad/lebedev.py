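"""Lebedev-Laikov angular quadrature on the unit sphere.

Grids are reconstructed at run time from embedded octahedral-symmetry
generator parameters (one geometric parameter set and one weight per
symmetry class).  Stored weights are normalized to 1 over the grid and
multiplied by 4*pi at construction.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._lebedev_data import LEBEDEV_CLASSES

#: Point counts with embedded tables.
SUPPORTED_ORDERS = tuple(sorted(LEBEDEV_CLASSES))


@dataclass(frozen=True)
class AngularGrid:
    directions: np.ndarray  # (n, 3) unit vectors
    weights: np.ndarray     # sum to 4*pi
    degree: int             # algebraic order of polynomial exactness


def _orbit(cls: tuple) -> np.ndarray:
    """All distinct images of a generator point under the octahedral group
    (coordinate permutations and sign flips)."""
    t = cls[0]
    if t == 1:
        gen = np.array([1.0, 0.0, 0.0])
    elif t == 2:
        s = 1.0 / np.sqrt(2.0)
        gen = np.array([s, s, 0.0])
    elif t == 3:
        s = 1.0 / np.sqrt(3.0)
        gen = np.array([s, s, s])
    elif t == 4:
        a = cls[1]
        gen = np.array([a, a, np.sqrt(max(0.0, 1.0 - 2.0 * a * a))])
    elif t == 5:
        a = cls[1]
        gen = np.array([a, np.sqrt(max(0.0, 1.0 - a * a)), 0.0])
    elif t == 6:
        a, b = cls[1], cls[2]
        gen = np.array([a, b, np.sqrt(max(0.0, 1.0 - a * a - b * b))])
    else:  # pragma: no cover - data file is fixed
        raise ValueError(f"unknown symmetry class type {t}")
    pts = set()
    for perm in itertools.permutations(range(3)):
        p = gen[list(perm)]
        for signs in itertools.product((1.0, -1.0), repeat=3):
            pts.add(tuple(0.0 if p[k] == 0.0 else signs[k] * p[k]
                          for k in range(3)))
    return np.array(sorted(pts))


@lru_cache(maxsize=None)
def _build(n_pts: int) -> tuple[np.ndarray, np.ndarray, int]:
    degree, classes = LEBEDEV_CLASSES[n_pts]
    dirs, wts = [], []
    for cls in classes:
        orb = _orbit(cls)
        dirs.append(orb)
        wts.append(np.full(len(orb), cls[-1]))
    directions = np.vstack(dirs)
    weights = np.concatenate(wts)
    if len(directions) != n_pts:  # pragma: no cover - table sanity
        raise RuntimeError(f"table for {n_pts} produced {len(directions)}")
    weights = weights * (4.0 * np.pi)
    directions.setflags(write=False)
    weights.setflags(write=False)
    return directions, weights, degree


def lebedev_angular(n_pts: int) -> AngularGrid:
    """Lebedev-Laikov grid with exactly ``n_pts`` directions."""
    if n_pts not in LEBEDEV_CLASSES:
        raise ValueError(
            f"unsupported Lebedev point count {n_pts}; available: "
            f"{SUPPORTED_ORDERS}")
    directions, weights, degree = _build(n_pts)
    return AngularGrid(directions=directions, weights=weights, degree=degree)
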