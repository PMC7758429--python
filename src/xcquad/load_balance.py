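"""Cost-model load balancing of quadrature batches across ranks.

Each batch gets a FLOP-count surrogate

    W_j = N_g^j (N_A^2 + 9 N_b^j + 2 (N_b^j)^2 + 3) + (N_b^j)^2

covering, in order, the atomic weight partitioning, the collocation /
density / Z-matrix work, the level-3 BLAS, the energy dot products, and the
pack/increment of the compressed matrices.  Batches are assigned to ranks
by deterministic greedy longest-processing-time (LPT) scheduling, which is
replicable: every rank running the same code on the same batch list derives
the identical assignment, so no communication is needed.  After assignment,
batches on the same rank sharing a shell list are merged.  The final result
is combined through a single associative reduction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .batching import QuadratureBatch, merge_batches
from .integrator import XCResult


@dataclass(frozen=True)
class CostedBatch:
    batch_id: int
    npts: int
    nbf: int
    cost: int


@dataclass
class RankAssignment:
    n_ranks: int
    rank_of: dict[int, int]       # batch id -> rank
    loads: np.ndarray             # per-rank total cost

    def batches_for(self, rank: int) -> list[int]:
        return sorted(b for b, r in self.rank_of.items() if r == rank)


def batch_cost(npts: int, natoms: int, nbf: int) -> int:
    """Operation-count cost model W_j; exact in integer arithmetic."""
    if min(npts, natoms, nbf) < 0:
        raise ValueError("cost model inputs must be non-negative")
    return npts * (natoms ** 2 + 9 * nbf + 2 * nbf ** 2 + 3) + nbf ** 2


def cost_batches(batches: list[QuadratureBatch],
                 natoms: int) -> list[CostedBatch]:
    return [CostedBatch(batch_id=i, npts=b.npts, nbf=b.nbf,
                        cost=batch_cost(b.npts, natoms, b.nbf))
            for i, b in enumerate(batches)]


def assign_batches(costed: list[CostedBatch], n_ranks: int
                   ) -> RankAssignment:
    """Greedy LPT: batches by descending cost (ties: lower id first), each
    to the least-loaded rank (ties: lowest rank id)."""
    if n_ranks < 1:
        raise ValueError(f"rank count must be >= 1, got {n_ranks}")
    order = sorted(costed, key=lambda b: (-b.cost, b.batch_id))
    loads = np.zeros(n_ranks, dtype=np.int64)
    rank_of = {}
    for b in order:
        r = int(np.argmin(loads))  # argmin takes the lowest index on ties
        rank_of[b.batch_id] = r
        loads[r] += b.cost
    return RankAssignment(n_ranks=n_ranks, rank_of=rank_of, loads=loads)


def local_batches(batches: list[QuadratureBatch],
                  assignment: RankAssignment,
                  rank: int) -> list[QuadratureBatch]:
    """This rank's batch list with same-shell-list batches merged."""
    mine = [batches[i] for i in assignment.batches_for(rank)]
    return merge_batches(mine)


def reduce_results(partials: list[XCResult]) -> XCResult:
    """Single associative reduction over per-rank partial results."""
    if not partials:
        raise ValueError("nothing to reduce")
    total = partials[0]
    for part in partials[1:]:
        total = total + part
    return total


def distributed_integrate(atoms, basis, P, grid_spec: str = "UFG",
                          functional: str = "PBE", n_ranks: int = 1,
                          max_pts: int = 512,
                          return_assignment: bool = False):
    """Simulated multi-rank XC integration in one process.

    The grid and batch list are built once (they are replicated state in a
    real run); each simulated rank independently re-derives the identical
    LPT assignment, merges its local same-shell-list batches, integrates
    them, and the per-rank partials meet in a single reduction.
    """
    from .batching import partition_grid, screen_batches
    from .integrator import integrate_batches
    from .molgrid import build_molgrid, grid_preset

    n_rad, n_ang = grid_preset(grid_spec)
    grid = build_molgrid(atoms, n_rad, n_ang)
    centers = np.array([a.position for a in atoms])
    batches = partition_grid(grid.points, centers, max_pts=max_pts)
    screen_batches(batches, basis)
    costed = cost_batches(batches, len(atoms))

    partials = []
    assignment = None
    for rank in range(n_ranks):
        # replicated: every rank re-runs the identical assignment
        assignment = assign_batches(costed, n_ranks)
        mine = local_batches(batches, assignment, rank)
        partials.append(integrate_batches(mine, grid, basis, P, functional))
    result = reduce_results(partials)
    if return_assignment:
        return result, assignment
    return result


def balance_report(assignment: RankAssignment) -> str:
    loads = assignment.loads.astype(float)
    mean = loads.mean() if loads.size else 0.0
    lines = [f"rank {r}: load {int(assignment.loads[r])} "
             f"({len(assignment.batches_for(r))} batches)"
             for r in range(assignment.n_ranks)]
    ratio = loads.max() / mean if mean > 0 else float("nan")
    lines.append(f"max/mean load ratio: {ratio:.4f}")
    return "\n".join(lines)
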