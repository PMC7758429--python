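"""Spatial batching of quadrature points and per-batch basis screening.

The grid's bounding box is subdivided recursively: cuboids holding at most
``max_pts`` points become batches; cuboids containing an atomic center split
into 27 equal-thirds children (atoms sit at grid-point accumulation centers,
so an octant cut through the nucleus would produce badly unbalanced children)
while all others split into 8 midpoint octants.  Per batch, shells survive
screening when the shell's cutoff sphere intersects the cuboid, decided via
the closest point on the cuboid to the shell center.

Compression/scatter maps extract the screened sub-blocks of symmetric
N_b x N_b matrices contiguously and add per-batch results back.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSet

DEFAULT_MAX_PTS = 512


@dataclass(frozen=True)
class Cuboid:
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        if np.any(lo > hi):
            raise ValueError("cuboid lower corner must not exceed upper")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    def closest_point(self, center: np.ndarray) -> np.ndarray:
        return np.clip(center, self.lo, self.hi)

    def contains_center(self, center: np.ndarray) -> bool:
        """Half-open membership: lo <= c < hi componentwise."""
        return bool(np.all(center >= self.lo) and np.all(center < self.hi))


@dataclass
class QuadratureBatch:
    """A cuboid of quadrature points plus its surviving shell list."""

    point_idx: np.ndarray           # indices into the molecular grid
    cuboid: Cuboid
    shells: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    nbf: int = 0                    # function count of the shell list

    @property
    def npts(self) -> int:
        return len(self.point_idx)


def _subdivide(points: np.ndarray, idx: np.ndarray, cuboid: Cuboid,
               centers: np.ndarray, max_pts: int,
               out: list[QuadratureBatch]) -> None:
    if len(idx) == 0:
        return
    if len(idx) <= max_pts:
        out.append(QuadratureBatch(point_idx=idx, cuboid=cuboid))
        return
    lo, hi = cuboid.lo, cuboid.hi
    has_atom = any(cuboid.contains_center(c) for c in centers)
    nsplit = 3 if has_atom else 2
    edges = [np.linspace(lo[d], hi[d], nsplit + 1) for d in range(3)]
    pts = points[idx]
    # half-open bin assignment per axis; the last bin is closed above so
    # points on the outer boundary stay inside
    bins = []
    for d in range(3):
        b = np.searchsorted(edges[d][1:-1], pts[:, d], side="right")
        bins.append(b)
    code = (bins[0] * nsplit + bins[1]) * nsplit + bins[2]
    if np.all(pts == pts[0]) or np.max(hi - lo) < 1e-12:
        # coincident points (or a cuboid below float resolution) cannot be
        # split further; emit as a single batch even above max_pts
        out.append(QuadratureBatch(point_idx=idx, cuboid=cuboid))
        return
    for c in np.unique(code):
        sub = idx[code == c]
        i, rem = divmod(int(c), nsplit * nsplit)
        j, k = divmod(rem, nsplit)
        child = Cuboid(
            lo=np.array([edges[0][i], edges[1][j], edges[2][k]]),
            hi=np.array([edges[0][i + 1], edges[1][j + 1], edges[2][k + 1]]),
        )
        _subdivide(points, sub, child, centers, max_pts, out)


def partition_grid(points: np.ndarray, centers: np.ndarray,
                   max_pts: int = DEFAULT_MAX_PTS) -> list[QuadratureBatch]:
    """Partition grid points into spatially local batches.

    Every point lands in exactly one batch; batch order is deterministic
    (depth-first in child-code order).
    """
    if max_pts < 1:
        raise ValueError(f"max_pts must be >= 1, got {max_pts}")
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return []
    root = Cuboid(lo=points.min(axis=0), hi=points.max(axis=0))
    out: list[QuadratureBatch] = []
    _subdivide(points, np.arange(len(points)), root,
               np.asarray(centers, dtype=float), max_pts, out)
    return out


def screen_shells(cuboid: Cuboid, basis: BasisSet) -> np.ndarray:
    """Indices of shells whose cutoff sphere touches the cuboid.

    Uses the closest point c = clamp(R, lo, hi); a shell survives iff
    |c - R| <= r_cut (inclusive, favoring soundness at the boundary).
    """
    centers = basis.centers()
    closest = np.clip(centers, cuboid.lo[None, :], cuboid.hi[None, :])
    dist = np.linalg.norm(closest - centers, axis=1)
    return np.nonzero(dist <= basis.cutoffs())[0]


def screen_batches(batches: list[QuadratureBatch],
                   basis: BasisSet) -> None:
    """Attach the surviving shell list and its function count to each
    batch in place."""
    counts = np.array([sh.nfunc for sh in basis.shells])
    for b in batches:
        b.shells = screen_shells(b.cuboid, basis)
        b.nbf = int(counts[b.shells].sum())


def merge_batches(batches: list[QuadratureBatch]) -> list[QuadratureBatch]:
    """Concatenate batches sharing an identical shell list.

    Point lists are unioned, the cuboid becomes the members' bounding box,
    and output order follows the smallest original batch index per group.
    """
    groups: dict[tuple, list[int]] = {}
    for i, b in enumerate(batches):
        groups.setdefault(tuple(b.shells.tolist()), []).append(i)
    merged = []
    for key, members in sorted(groups.items(), key=lambda kv: kv[1][0]):
        first = batches[members[0]]
        if len(members) == 1:
            merged.append(first)
            continue
        idx = np.concatenate([batches[i].point_idx for i in members])
        lo = np.min([batches[i].cuboid.lo for i in members], axis=0)
        hi = np.max([batches[i].cuboid.hi for i in members], axis=0)
        merged.append(QuadratureBatch(
            point_idx=idx, cuboid=Cuboid(lo=lo, hi=hi),
            shells=first.shells.copy(), nbf=first.nbf))
    return merged


def _batch_function_indices(basis: BasisSet,
                            shells: np.ndarray) -> np.ndarray:
    if len(shells) == 0:
        return np.empty(0, dtype=int)
    return np.concatenate([np.arange(basis.offsets[s], basis.offsets[s + 1])
                           for s in shells])


def compress_matrix(M: np.ndarray, shells: np.ndarray,
                    basis: BasisSet) -> np.ndarray:
    """Extract the rows/columns of the given shells contiguously,
    preserving shell order."""
    if len(shells) and (shells.min() < 0 or shells.max() >= len(basis)):
        raise IndexError("shell index out of range")
    idx = _batch_function_indices(basis, shells)
    return M[np.ix_(idx, idx)]


def scatter_add(V_full: np.ndarray, V_batch: np.ndarray,
                shells: np.ndarray, basis: BasisSet) -> None:
    """Add a compressed batch matrix into the corresponding blocks of the
    full matrix in place."""
    idx = _batch_function_indices(basis, shells)
    if V_batch.shape != (len(idx), len(idx)):
        raise ValueError(
            f"batch matrix shape {V_batch.shape} inconsistent with shell "
            f"list ({len(idx)} functions)")
    V_full[np.ix_(idx, idx)] += V_batch
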