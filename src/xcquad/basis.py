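"""Contracted Gaussian basis sets: Gaussian94 input, shell construction,
cutoff radii, and the Cartesian-to-spherical transformation.

A *shell* groups contracted functions sharing exponents, contraction
coefficients, center, and total angular momentum L.  Cartesian shells carry
(L+1)(L+2)/2 components, spherical (pure) shells 2L+1.  Each contracted
Cartesian component is normalized to unit self-overlap; spherical functions
are produced by an orthonormal transformation of the normalized Cartesian
components, so they are unit-normalized by construction.
"""
from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Atom

DEFAULT_ETA = 1e-10  # screening tolerance |phi| < eta outside the cutoff

MAX_L = 3
_SHELL_LETTERS = {"S": 0, "P": 1, "D": 2, "F": 3}
_L_LETTERS = {v: k for k, v in _SHELL_LETTERS.items()}


def cart_components(L: int) -> list[tuple[int, int, int]]:
    """Cartesian power triples (l, m, n) with l+m+n = L.

    Ordering is lexicographic with the x power descending first, then the
    y power: for d shells xx, xy, xz, yy, yz, zz.
    """
    return [(l, m, L - l - m)
            for l in range(L, -1, -1)
            for m in range(L - l, -1, -1)]


def n_cart(L: int) -> int:
    return (L + 1) * (L + 2) // 2


def n_sph(L: int) -> int:
    return 2 * L + 1


def _df(n: int) -> float:
    """Double factorial with (-1)!! = 1."""
    return float(math.prod(range(n, 0, -2))) if n > 0 else 1.0


def primitive_norm(alpha: float, L: int) -> float:
    """Normalization of an (L,0,0) Cartesian primitive Gaussian."""
    return ((2 * alpha / math.pi) ** 0.75
            * (4 * alpha) ** (L / 2) / math.sqrt(_df(2 * L - 1)))


def shell_cutoff_radius(exps: np.ndarray, eta: float = DEFAULT_ETA) -> float:
    """Radius beyond which every primitive of the shell is below ``eta``.

    For each primitive the radius solves exp(-a r^2) sqrt(a)... the
    shell-level criterion r = sqrt((ln(a)/2 - ln eta)/a), maximized over
    primitives.  A non-positive bracket (pathologically diffuse primitives
    with loose eta) falls back to the conservative sqrt(-ln(eta)/a), which
    keeps the guarantee |phi| < eta outside the sphere.
    """
    if not 0.0 < eta < 1.0:
        raise ValueError(f"eta must be in (0, 1), got {eta}")
    exps = np.asarray(exps, dtype=float)
    if np.any(exps <= 0):
        raise ValueError("all exponents must be positive")
    bracket = 0.5 * np.log(exps) - math.log(eta)
    val = bracket / exps
    fallback = -math.log(eta) / exps
    val = np.where(bracket <= 0, fallback, val)
    return float(np.sqrt(val).max())


@dataclass(frozen=True)
class ShellTemplate:
    """Element-level shell definition prior to placement on an atom."""

    L: int
    exps: np.ndarray
    coefs: np.ndarray

    def __post_init__(self):
        e = np.atleast_1d(np.asarray(self.exps, dtype=float))
        c = np.atleast_1d(np.asarray(self.coefs, dtype=float))
        if e.shape != c.shape or e.size < 1:
            raise ValueError("exponents and coefficients must be congruent")
        if np.any(e <= 0):
            raise ValueError("exponents must be positive")
        if not 0 <= self.L <= MAX_L:
            raise ValueError(f"unsupported angular momentum L={self.L}")
        object.__setattr__(self, "exps", e)
        object.__setattr__(self, "coefs", c)


@dataclass(frozen=True)
class Shell:
    """A placed, normalized shell.

    ``coefs`` include primitive normalization and the contraction-level
    normalization of the (L,0,0) component; per-component double-factorial
    corrections are applied at evaluation time.
    """

    center_index: int
    center: np.ndarray
    L: int
    pure: bool
    exps: np.ndarray
    coefs: np.ndarray
    r_cut: float

    @property
    def nfunc(self) -> int:
        return n_sph(self.L) if self.pure else n_cart(self.L)

    def __post_init__(self):
        if self.r_cut <= 0:
            raise ValueError("cutoff radius must be positive")


@dataclass
class BasisSet:
    """Ordered shell list with per-shell function offsets."""

    shells: list[Shell]
    offsets: np.ndarray = field(init=False)
    nbf: int = field(init=False)

    def __post_init__(self):
        counts = [sh.nfunc for sh in self.shells]
        self.offsets = np.concatenate([[0], np.cumsum(counts)]).astype(int)
        self.nbf = int(self.offsets[-1])

    def __len__(self) -> int:
        return len(self.shells)

    def shell_slice(self, i: int) -> slice:
        return slice(int(self.offsets[i]), int(self.offsets[i + 1]))

    def centers(self) -> np.ndarray:
        return np.array([sh.center for sh in self.shells])

    def cutoffs(self) -> np.ndarray:
        return np.array([sh.r_cut for sh in self.shells])


class BasisParseError(ValueError):
    pass


def read_basis_g94(text: str) -> dict[str, list[ShellTemplate]]:
    """Parse Gaussian94-format basis text into per-element shell templates.

    SP blocks are expanded into an S and a P template sharing exponents.
    """
    templates: dict[str, list[ShellTemplate]] = {}
    lines = [ln.split("!")[0].rstrip() for ln in text.splitlines()]
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        i += 1
        if not line or line == "****":
            continue
        parts = line.split()
        element = parts[0].capitalize()
        shells = templates.setdefault(element, [])
        while i < n:
            header = lines[i].strip()
            i += 1
            if not header:
                continue
            if header == "****":
                break
            hp = header.split()
            stype = hp[0].upper()
            try:
                nprim = int(hp[1])
            except (IndexError, ValueError) as exc:
                raise BasisParseError(
                    f"bad shell header {header!r}") from exc
            ncols = 3 if stype == "SP" else 2
            rows = []
            for _ in range(nprim):
                if i >= n or lines[i].strip() in ("", "****"):
                    raise BasisParseError(
                        f"shell {stype} declares {nprim} primitives but "
                        f"fewer rows follow")
                row = lines[i].replace("D", "E").replace("d", "e").split()
                i += 1
                if len(row) < ncols:
                    raise BasisParseError(
                        f"primitive row {row!r} has fewer than {ncols} "
                        f"columns for shell type {stype}")
                rows.append([float(x) for x in row[:ncols]])
            data = np.array(rows)
            if stype == "SP":
                shells.append(ShellTemplate(0, data[:, 0], data[:, 1]))
                shells.append(ShellTemplate(1, data[:, 0], data[:, 2]))
            elif stype in _SHELL_LETTERS:
                shells.append(ShellTemplate(_SHELL_LETTERS[stype],
                                            data[:, 0], data[:, 1]))
            else:
                raise BasisParseError(f"unknown shell type {stype!r}")
    return templates


def load_builtin_basis(name: str) -> dict[str, list[ShellTemplate]]:
    """Load a bundled Gaussian94 basis file by name (e.g. 'sto-3g')."""
    fname = name.lower() + ".g94"
    ref = importlib.resources.files("xcquad") / "data" / fname
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise ValueError(f"no bundled basis named {name!r}") from exc
    return read_basis_g94(text)


def _contracted_norm(exps: np.ndarray, coefs: np.ndarray, L: int) -> float:
    """Self-overlap normalization of the contracted (L,0,0) component,
    assuming ``coefs`` already include primitive normalization."""
    asum = exps[:, None] + exps[None, :]
    s = (coefs[:, None] * coefs[None, :]
         * (math.pi / asum) ** 1.5 / (2 * asum) ** L).sum()
    return 1.0 / math.sqrt(s * _df(2 * L - 1))


def build_basis(atoms: list[Atom],
                templates: dict[str, list[ShellTemplate]],
                pure: bool = False,
                eta: float = DEFAULT_ETA) -> BasisSet:
    """Instantiate shells on every atom, normalize, and assign cutoffs.

    ``pure`` selects spherical (2L+1) counting for shells with L >= 2;
    s and p shells are identical in both conventions.
    """
    shells = []
    for ia, atom in enumerate(atoms):
        if atom.symbol not in templates:
            raise KeyError(f"no basis template for element {atom.symbol}")
        for tpl in templates[atom.symbol]:
            coefs = tpl.coefs * np.array(
                [primitive_norm(a, tpl.L) for a in tpl.exps])
            coefs = coefs * _contracted_norm(tpl.exps, coefs, tpl.L)
            shells.append(Shell(
                center_index=ia,
                center=atom.position,
                L=tpl.L,
                pure=pure and tpl.L >= 2,
                exps=tpl.exps,
                coefs=coefs,
                r_cut=shell_cutoff_radius(tpl.exps, eta),
            ))
    return BasisSet(shells)


def cart_metric(L: int) -> np.ndarray:
    """Self-overlap metric among the unit-normalized Cartesian components
    of one shell; depends only on L."""
    comps = cart_components(L)
    nc = len(comps)
    S = np.zeros((nc, nc))
    for i, (l1, m1, n1) in enumerate(comps):
        for j, (l2, m2, n2) in enumerate(comps):
            if (l1 + l2) % 2 or (m1 + m2) % 2 or (n1 + n2) % 2:
                continue
            num = _df(l1 + l2 - 1) * _df(m1 + m2 - 1) * _df(n1 + n2 - 1)
            den = math.sqrt(_df(2 * l1 - 1) * _df(2 * m1 - 1)
                            * _df(2 * n1 - 1) * _df(2 * l2 - 1)
                            * _df(2 * m2 - 1) * _df(2 * n2 - 1))
            S[i, j] = num / den
    return S


# Real solid harmonics in the Cartesian *monomial* basis, as relative
# coefficients {(l, m, n): c}; rows ordered m = -L..+L.  Row scale is fixed
# afterwards by normalization under the Cartesian metric.
_SOLID_HARMONICS = {
    0: [{(0, 0, 0): 1.0}],
    1: [{(0, 1, 0): 1.0}, {(0, 0, 1): 1.0}, {(1, 0, 0): 1.0}],
    2: [
        {(1, 1, 0): 1.0},                                    # xy
        {(0, 1, 1): 1.0},                                    # yz
        {(2, 0, 0): -1.0, (0, 2, 0): -1.0, (0, 0, 2): 2.0},  # 3z^2 - r^2
        {(1, 0, 1): 1.0},                                    # xz
        {(2, 0, 0): 1.0, (0, 2, 0): -1.0},                   # x^2 - y^2
    ],
    3: [
        {(2, 1, 0): 3.0, (0, 3, 0): -1.0},                   # y(3x^2 - y^2)
        {(1, 1, 1): 1.0},                                    # xyz
        {(0, 1, 2): 4.0, (2, 1, 0): -1.0, (0, 3, 0): -1.0},  # y(5z^2 - r^2)
        {(0, 0, 3): 2.0, (2, 0, 1): -3.0, (0, 2, 1): -3.0},  # z(5z^2 - 3r^2)
        {(1, 0, 2): 4.0, (3, 0, 0): -1.0, (1, 2, 0): -1.0},  # x(5z^2 - r^2)
        {(2, 0, 1): 1.0, (0, 2, 1): -1.0},                   # z(x^2 - y^2)
        {(3, 0, 0): 1.0, (1, 2, 0): -3.0},                   # x(x^2 - 3y^2)
    ],
}


def cart_to_sph(L: int) -> np.ndarray:
    """(2L+1) x (L+1)(L+2)/2 transformation from unit-normalized Cartesian
    components to unit-normalized real spherical functions, rows m = -L..+L.

    Rows are orthonormal under the Cartesian self-overlap metric.
    """
    if not 0 <= L <= MAX_L:
        raise ValueError(f"cart_to_sph supports 0 <= L <= {MAX_L}, "
                         f"got {L}")
    comps = cart_components(L)
    S = cart_metric(L)
    T = np.zeros((n_sph(L), n_cart(L)))
    for row, terms in enumerate(_SOLID_HARMONICS[L]):
        for (l, m, n), c in terms.items():
            # monomial coefficient -> normalized-component coefficient
            T[row, comps.index((l, m, n))] = c * math.sqrt(
                _df(2 * l - 1) * _df(2 * m - 1) * _df(2 * n - 1))
    for row in range(T.shape[0]):
        T[row] /= math.sqrt(T[row] @ S @ T[row])
    return T
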