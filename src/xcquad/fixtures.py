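"""Self-contained toy inputs: tiny molecules, hand-written bases, and
seeded random density matrices that integrate to a prescribed electron
count on the quadrature grid.
"""
from __future__ import annotations

import numpy as np

from .basis import BasisSet, ShellTemplate, build_basis
from .geometry import Atom
from .integrator import eval_collocation
from .molgrid import build_molgrid, grid_preset

#: Fixed toy geometries (Bohr).
_MOLECULES = {
    "H1": [("H", (0.0, 0.0, 0.0))],
    "H2": [("H", (0.0, 0.0, -0.7)), ("H", (0.0, 0.0, 0.7))],
    "HeH": [("He", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 1.5))],
    "triatomic": [("O", (0.0, 0.0, 0.0)),
                  ("H", (0.0, 1.43, 1.11)),
                  ("H", (0.0, -1.43, 1.11))],
}

_Z = {"H": 1, "He": 2, "O": 8}

# Hand-written shell sets (exponents in Bohr^-2).  's+d' includes an L=2
# shell to exercise the spherical transformation.
_BASES = {
    "sto-min": {
        "H": [ShellTemplate(0, np.array([3.42525091, 0.62391373,
                                         0.16885540]),
                            np.array([0.15432897, 0.53532814,
                                      0.44463454]))],
        "He": [ShellTemplate(0, np.array([6.36242139, 1.15892300,
                                          0.31364979]),
                             np.array([0.15432897, 0.53532814,
                                       0.44463454]))],
        "O": [ShellTemplate(0, np.array([130.70932, 23.808861, 6.4436083]),
                            np.array([0.15432897, 0.53532814, 0.44463454])),
              ShellTemplate(0, np.array([5.0331513, 1.1695961, 0.3803890]),
                            np.array([-0.09996723, 0.39951283,
                                      0.70011547])),
              ShellTemplate(1, np.array([5.0331513, 1.1695961, 0.3803890]),
                            np.array([0.15591627, 0.60768372,
                                      0.39195739]))],
    },
    "s+p": {
        "H": [ShellTemplate(0, np.array([1.3, 0.25]),
                            np.array([0.6, 0.5])),
              ShellTemplate(1, np.array([0.8]), np.array([1.0]))],
        "He": [ShellTemplate(0, np.array([2.4, 0.5]),
                             np.array([0.6, 0.5])),
               ShellTemplate(1, np.array([1.1]), np.array([1.0]))],
        "O": [ShellTemplate(0, np.array([7.6, 1.3]),
                            np.array([0.5, 0.6])),
              ShellTemplate(1, np.array([1.2]), np.array([1.0]))],
    },
    "s+d": {
        "H": [ShellTemplate(0, np.array([1.0]), np.array([1.0])),
              ShellTemplate(2, np.array([0.9]), np.array([1.0]))],
        "He": [ShellTemplate(0, np.array([1.8]), np.array([1.0])),
               ShellTemplate(2, np.array([1.2]), np.array([1.0]))],
        "O": [ShellTemplate(0, np.array([2.0]), np.array([1.0])),
              ShellTemplate(2, np.array([1.5]), np.array([1.0]))],
    },
}


def toy_molecule(name: str) -> list[Atom]:
    """A fixed documented toy geometry: H1, H2, HeH, or triatomic (water
    at near-equilibrium geometry)."""
    if name not in _MOLECULES:
        raise ValueError(f"unknown toy molecule {name!r}; "
                         f"choose from {sorted(_MOLECULES)}")
    return [Atom(sym, _Z[sym], np.array(pos))
            for sym, pos in _MOLECULES[name]]


def toy_basis(name: str) -> dict[str, list[ShellTemplate]]:
    """A hand-written small basis: sto-min, s+p, or s+d."""
    if name not in _BASES:
        raise ValueError(f"unknown toy basis {name!r}; "
                         f"choose from {sorted(_BASES)}")
    return _BASES[name]


def quadrature_overlap(atoms: list[Atom], basis: BasisSet,
                       grid_spec: str = "UFG") -> np.ndarray:
    """Basis overlap matrix computed on the molecular quadrature grid."""
    n_rad, n_ang = grid_preset(grid_spec)
    grid = build_molgrid(atoms, n_rad, n_ang)
    S = np.zeros((basis.nbf, basis.nbf))
    all_shells = np.arange(len(basis))
    for lo in range(0, len(grid), 8192):
        sl = slice(lo, lo + 8192)
        phi, _ = eval_collocation(grid.points[sl], basis, all_shells)
        S += (phi * grid.weights[sl][None, :]) @ phi.T
    return 0.5 * (S + S.T)


def random_density(atoms: list[Atom], basis: BasisSet, n_electrons: int,
                   seed: int, grid_spec: str = "UFG") -> np.ndarray:
    """Seeded random closed-shell density matrix P = 2 C C^T.

    The occupied block C is orthonormalized against the quadrature-grid
    overlap, so the quadrature electron count sum_i w_i rho(r_i) equals
    ``n_electrons`` up to grid error only.
    """
    if n_electrons % 2 or n_electrons <= 0:
        raise ValueError("electron count must be positive and even")
    nocc = n_electrons // 2
    if nocc > basis.nbf:
        raise ValueError(
            f"{n_electrons} electrons need {nocc} occupied orbitals but "
            f"the basis has only {basis.nbf} functions")
    rng = np.random.default_rng(seed)
    C = rng.standard_normal((basis.nbf, nocc))
    S = quadrature_overlap(atoms, basis, grid_spec)
    # S-orthonormalize: C <- C (C^T S C)^(-1/2)
    M = C.T @ S @ C
    evals, evecs = np.linalg.eigh(M)
    C = C @ evecs @ np.diag(evals ** -0.5) @ evecs.T
    return 2.0 * C @ C.T


def fixture_system(molecule: str = "H2", basis_name: str = "sto-min",
                   pure: bool = False):
    """Convenience: (atoms, basis) for a named toy system."""
    atoms = toy_molecule(molecule)
    basis = build_basis(atoms, toy_basis(basis_name), pure=pure)
    return atoms, basis
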