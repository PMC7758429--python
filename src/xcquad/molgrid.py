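"""Molecular quadrature grids.

Atom-centered spherical product grids (Mura-Knowles radial x Lebedev
angular) combined into a molecular grid through the Stratmann-Scuseria-
Frisch (SSF) atomic partition of unity.  No angular pruning is applied.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Atom
from .lebedev import lebedev_angular
from .radial import mk_alpha, mk_radial

#: Grid presets: name -> (n_rad, n_ang).
PRESETS = {"FG": (75, 302), "UFG": (99, 590), "SFG": (175, 974)}

#: SSF switching-function half-width.
SSF_A = 0.64

_SSF_SHORTCUT_FACTOR = 0.5 * (1.0 - SSF_A)


def grid_preset(name: str) -> tuple[int, int]:
    """Resolve a grid preset name to (n_rad, n_ang).

    Accepts FG, UFG, SFG or ``custom:n_rad,n_ang``.
    """
    key = name.strip()
    if key.upper() in PRESETS:
        return PRESETS[key.upper()]
    if key.lower().startswith("custom:"):
        try:
            n_rad, n_ang = (int(t) for t in key.split(":", 1)[1].split(","))
        except ValueError as exc:
            raise ValueError(f"bad custom grid spec {name!r}; expected "
                             f"'custom:n_rad,n_ang'") from exc
        return n_rad, n_ang
    raise ValueError(f"unknown grid preset {name!r}; "
                     f"choose from {sorted(PRESETS)} or 'custom:n_rad,n_ang'")


@dataclass
class MolGrid:
    """Quadrature points with unscaled weights, parent atoms, and
    SSF-scaled weights."""

    points: np.ndarray            # (N_g, 3) Bohr
    weights_unscaled: np.ndarray  # (N_g,) product-rule weights, > 0
    parent: np.ndarray            # (N_g,) generating atom index
    weights: np.ndarray           # (N_g,) SSF-scaled weights

    def __len__(self) -> int:
        return len(self.points)


def build_atom_grid(atom: Atom, n_rad: int, n_ang: int,
                    alpha: float | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Spherical product grid around one atom.

    Returns (points, unscaled weights); N_g^A = n_rad * n_ang.  The weight
    of point (i, k) is w_i^rad * w_k^ang, which integrates smooth
    three-dimensional integrands directly (the r^2 Jacobian lives in the
    radial weights and the 4*pi solid-angle normalization in the angular
    ones).
    """
    if alpha is None:
        alpha = mk_alpha(atom.Z)
    rad = mk_radial(n_rad, alpha)
    ang = lebedev_angular(n_ang)
    points = (atom.position[None, None, :]
              + rad.radii[:, None, None] * ang.directions[None, :, :])
    weights = rad.weights[:, None] * ang.weights[None, :]
    return points.reshape(-1, 3), weights.reshape(-1)


def ssf_switch(mu: np.ndarray) -> np.ndarray:
    """SSF switching function g(mu): 1 below -a, 0 above +a, and a C^3
    seventh-order polynomial step in between (a = 0.64)."""
    t = np.clip(mu / SSF_A, -1.0, 1.0)
    t2 = t * t
    z = t * (35.0 + t2 * (-35.0 + t2 * (21.0 - 5.0 * t2))) / 16.0
    g = 0.5 * (1.0 - z)
    g[mu <= -SSF_A] = 1.0
    g[mu >= SSF_A] = 0.0
    return g


def ssf_partition_weights(points: np.ndarray, parent: np.ndarray,
                          atoms: list[Atom],
                          weights_unscaled: np.ndarray,
                          use_shortcut: bool = True,
                          chunk: int = 8192) -> np.ndarray:
    """Scale product-rule weights by the SSF atomic partition function.

    p_A(r) = s_A(r) / sum_B s_B(r) with s_A = prod_{B != A} g(mu_AB) and
    mu_AB = (|r - R_A| - |r - R_B|) / |R_A - R_B|.  The near-nucleus
    shortcut sets p_A = 1 without forming the product when the point lies
    within (1-a)/2 of the parent's nearest-neighbor distance; it is exactly
    equivalent to the full evaluation because g saturates to exact 0/1.
    """
    natom = len(atoms)
    if natom == 1:
        return weights_unscaled.copy()
    centers = np.array([a.position for a in atoms])
    diff = centers[:, None, :] - centers[None, :, :]
    rab = np.linalg.norm(diff, axis=-1)
    off = ~np.eye(natom, dtype=bool)
    if np.any(rab[off] == 0.0):
        raise ValueError("coincident atomic centers in SSF partitioning")
    inv_rab = np.zeros_like(rab)
    inv_rab[off] = 1.0 / rab[off]
    nearest = np.where(off, rab, np.inf).min(axis=1)

    scaled = np.empty_like(weights_unscaled)
    for lo in range(0, len(points), chunk):
        sl = slice(lo, min(lo + chunk, len(points)))
        pts = points[sl]
        par = parent[sl]
        d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=-1)
        mu = (d[:, :, None] - d[:, None, :]) * inv_rab[None, :, :]
        g = ssf_switch(mu)
        g[:, np.arange(natom), np.arange(natom)] = 1.0
        s = g.prod(axis=2)
        denom = s.sum(axis=1)
        p = s[np.arange(len(pts)), par] / denom
        if use_shortcut:
            dpar = d[np.arange(len(pts)), par]
            p = np.where(dpar < _SSF_SHORTCUT_FACTOR * nearest[par], 1.0, p)
        scaled[sl] = p * weights_unscaled[sl]
    return scaled


def build_molgrid(atoms: list[Atom], n_rad: int, n_ang: int,
                  alpha_overrides: dict[int, float] | None = None,
                  use_shortcut: bool = True) -> MolGrid:
    """Assemble the full molecular grid with SSF-scaled weights."""
    pts, wts, par = [], [], []
    for ia, atom in enumerate(atoms):
        p, w = build_atom_grid(atom, n_rad, n_ang,
                               alpha=mk_alpha(atom.Z, alpha_overrides))
        pts.append(p)
        wts.append(w)
        par.append(np.full(len(w), ia, dtype=int))
    points = np.vstack(pts)
    weights_unscaled = np.concatenate(wts)
    parent = np.concatenate(par)
    weights = ssf_partition_weights(points, parent, atoms, weights_unscaled,
                                    use_shortcut=use_shortcut)
    return MolGrid(points=points, weights_unscaled=weights_unscaled,
                   parent=parent, weights=weights)


def dump_grid(grid: MolGrid) -> str:
    """Whitespace-separated 'x y z w parent' text dump."""
    lines = [f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} {w:.17g} {a:d}"
             for p, w, a in zip(grid.points, grid.weights, grid.parent)]
    return "\n".join(lines) + "\n"
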