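"""The DAMOKLE subnetwork search and a brute-force reference solver.

The algorithm finds connected subnetworks S of an interaction network G with
at most ``k`` genes whose differential coverage dc_S(C, D) between two
cohorts reaches a threshold ``theta``.  It works in two stages:

1. *Seeding*: every edge {u, v} of G with pairwise differential coverage
   dc_{u,v} >= theta / (k - 1) is a seed.  (If a set S with dc_S >= theta
   exists, some edge of S passes this bound with high probability in the
   generative model, so seeding discards no detectable signal.)
2. *Expansion*: from each seed, the current set S is grown one boundary
   edge at a time, branching over every vertex addition that *strictly*
   increases dc, and stopping at size k or when no addition improves dc.
   A set is reported when it is maximal in this sense and dc_S >= theta.

Reported solutions are deduplicated across seeds and branches by gene-set
identity and ranked by dc (descending; ties: smaller size, then
lexicographic genes).

Implementation notes
--------------------
Sample coverage profiles are packed into Python integers used as bitmasks,
so evaluating a candidate vertex addition costs two bitwise ORs and two
popcounts.  All dc comparisons inside the search are done on the integer
cross product ``|covered_C| * n_D - |covered_D| * n_C`` and are therefore
exact; the threshold comparison against the float ``theta`` uses a 1e-9
absolute slack to absorb decimal representation error.

A memo of expanded gene sets is shared across branches and seeds.  Because
both the emission rule and the branch set of a state depend only on the
gene set, skipping an already-expanded set never changes the output (this
equivalence is asserted in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx

from .core_model import (
    CohortPair,
    ContractError,
    EmptyCohortError,
    InteractionNetwork,
    ParameterError,
    Solution,
)
from .io_formats import SolutionReport

__all__ = [
    "DamokleParams",
    "seed_edges",
    "get_solutions",
    "damokle",
    "best_solution",
    "brute_force_discovery",
    "enumerate_connected_subgraphs",
]

_SLACK = 1e-9


@dataclass(frozen=True)
class DamokleParams:
    """Search parameters: maximum subnetwork size ``k`` and threshold ``theta``.

    ``k`` must be at least 2 (the search seeds on edges) and ``theta`` lies
    in [0, 1].

    ``expansion`` selects the growth strategy:

    * ``"branch"`` (default) — branch over *every* improving boundary edge
      and report all maximal sets reached.  Complete, but the number of
      maximal sets can explode combinatorially on large networks with a
      permissive ``theta`` (many individually-improving noise vertices).
    * ``"greedy"`` — at each step add only the boundary vertex with the
      maximum dc increase (ties: lexicographically smallest vertex), one
      maximal set per seed edge.  Scales to large instances; used by the
      planted-recovery experiments.

    Both strategies report only sets that are connected, of size <= k,
    algorithmically maximal, and meet the threshold; greedy output is always
    a subset of branch output.
    """

    k: int
    theta: float
    expansion: str = "branch"

    def __post_init__(self) -> None:
        if int(self.k) != self.k or self.k < 2:
            raise ParameterError(f"k must be an integer >= 2, got {self.k!r}")
        if not 0.0 <= self.theta <= 1.0:
            raise ParameterError(f"theta must lie in [0, 1], got {self.theta!r}")
        if self.expansion not in ("branch", "greedy"):
            raise ParameterError(f"unknown expansion strategy: {self.expansion!r}")


class _SearchContext:
    """Bitmask-packed view of a cohort pair restricted to network genes."""

    def __init__(self, pair: CohortPair, G: InteractionNetwork, params: DamokleParams):
        self.params = params
        self.n_C = pair.C.n_samples
        self.n_D = pair.D.n_samples
        if self.n_C == 0 or self.n_D == 0:
            raise EmptyCohortError("discovery requires at least one sample per cohort")
        self.mask_C: dict[str, int] = {}
        self.mask_D: dict[str, int] = {}
        for g in G.nodes:
            self.mask_C[g] = self._pack(pair.C.row(g))
            self.mask_D[g] = self._pack(pair.D.row(g))
        self.adj: dict[str, list[str]] = {g: sorted(G[g]) for g in G.nodes}
        # dc >= x  <=>  |cov_C| * n_D - |cov_D| * n_C >= x * n_C * n_D
        self.theta_num = params.theta * self.n_C * self.n_D - _SLACK
        self.seed_num = (
            params.theta / (params.k - 1) * self.n_C * self.n_D - _SLACK
        )

    @staticmethod
    def _pack(row) -> int:
        mask = 0
        for j in row.nonzero()[0]:
            mask |= 1 << int(j)
        return mask

    def dc_num(self, mC: int, mD: int) -> int:
        return mC.bit_count() * self.n_D - mD.bit_count() * self.n_C

    def dc(self, mC: int, mD: int) -> float:
        return mC.bit_count() / self.n_C - mD.bit_count() / self.n_D

    def masks(self, genes: Iterable[str]) -> tuple[int, int]:
        mC = mD = 0
        for g in genes:
            mC |= self.mask_C[g]
            mD |= self.mask_D[g]
        return mC, mD


def seed_edges(
    pair: CohortPair, G: InteractionNetwork, params: DamokleParams
) -> list[tuple[str, str]]:
    """Edges {u, v} of G with dc_{u,v} >= theta/(k-1), lexicographically sorted."""
    ctx = _SearchContext(pair, G, params)
    return _seed_edges(ctx)


def _seed_edges(ctx: _SearchContext) -> list[tuple[str, str]]:
    out = []
    for u, v in (tuple(sorted(e)) for e in _sorted_edges(ctx)):
        mC = ctx.mask_C[u] | ctx.mask_C[v]
        mD = ctx.mask_D[u] | ctx.mask_D[v]
        if ctx.dc_num(mC, mD) >= ctx.seed_num:
            out.append((u, v))
    return out


def _sorted_edges(ctx: _SearchContext) -> Iterator[tuple[str, str]]:
    for u in sorted(ctx.adj):
        for v in ctx.adj[u]:
            if u < v:
                yield (u, v)


def _expand(
    ctx: _SearchContext,
    S: frozenset[str],
    mC: int,
    mD: int,
    seed_edge: tuple[str, str] | None,
    visited: set[frozenset[str]] | None,
    out: dict[frozenset[str], Solution],
) -> None:
    if visited is not None:
        if S in visited:
            return
        visited.add(S)
    cur = ctx.dc_num(mC, mD)
    children: list[tuple[str, int, int]] = []
    if len(S) < ctx.params.k:
        candidates = set()
        for g in S:
            candidates.update(ctx.adj[g])
        candidates -= S
        for v in sorted(candidates):
            nC = mC | ctx.mask_C[v]
            nD = mD | ctx.mask_D[v]
            if ctx.dc_num(nC, nD) > cur:
                children.append((v, nC, nD))
    if not children:
        if cur >= ctx.theta_num:
            sol = Solution(genes=S, dc=ctx.dc(mC, mD), seed_edge=seed_edge)
            out.setdefault(S, sol)
        return
    for v, nC, nD in children:
        _expand(ctx, S | {v}, nC, nD, seed_edge, visited, out)


def _expand_greedy(
    ctx: _SearchContext,
    S: frozenset[str],
    mC: int,
    mD: int,
    seed_edge: tuple[str, str] | None,
    visited: set[frozenset[str]] | None,
    out: dict[frozenset[str], Solution],
) -> None:
    """Grow S by the single best improving boundary vertex until maximal.

    Deterministic: the added vertex maximizes the dc increase, ties broken
    by the lexicographically smallest vertex.  The continuation from any set
    is unique, so an already-visited set can be skipped outright.
    """
    while True:
        if visited is not None:
            if S in visited:
                return
            visited.add(S)
        cur = ctx.dc_num(mC, mD)
        best: tuple[int, str, int, int] | None = None
        if len(S) < ctx.params.k:
            candidates = set()
            for g in S:
                candidates.update(ctx.adj[g])
            candidates -= S
            for v in sorted(candidates):
                nC = mC | ctx.mask_C[v]
                nD = mD | ctx.mask_D[v]
                num = ctx.dc_num(nC, nD)
                if num > cur and (best is None or num > best[0]):
                    best = (num, v, nC, nD)
        if best is None:
            if cur >= ctx.theta_num:
                sol = Solution(genes=S, dc=ctx.dc(mC, mD), seed_edge=seed_edge)
                out.setdefault(S, sol)
            return
        _, v, mC, mD = best
        S = S | {v}


def get_solutions(
    S: Iterable[str],
    pair: CohortPair,
    G: InteractionNetwork,
    params: DamokleParams,
    *,
    memoize: bool = True,
) -> set[Solution]:
    """All maximal extensions of the connected set *S* meeting the threshold.

    Recursively grows *S* by boundary vertices that strictly increase dc,
    branching over every improving addition; emits each reachable set that
    has no improving extension (or has size k) and dc >= theta.  ``memoize``
    disables the shared visited-set (for equivalence testing only).
    """
    S = frozenset(S)
    if not S:
        raise ContractError("the starting set must be non-empty")
    missing = S - set(G.nodes)
    if missing:
        raise ContractError(f"genes not in the network: {sorted(missing)!r}")
    if not nx.is_connected(G.subgraph(S)):
        raise ContractError("the starting set must induce a connected subgraph")
    if len(S) > params.k:
        raise ContractError(f"starting set larger than k={params.k}")
    ctx = _SearchContext(pair, G, params)
    mC, mD = ctx.masks(S)
    out: dict[frozenset[str], Solution] = {}
    visited: set[frozenset[str]] | None = set() if memoize else None
    expand = _expand if params.expansion == "branch" else _expand_greedy
    expand(ctx, S, mC, mD, None, visited, out)
    return set(out.values())


def damokle(
    pair: CohortPair, G: InteractionNetwork, params: DamokleParams
) -> SolutionReport:
    """Run the full search: seed on qualifying edges, expand, rank, report.

    Every reported solution is connected in G, has 2 <= |S| <= k and
    dc_S(C, D) >= theta; solutions reached from several seeds or branches
    appear once.
    """
    ctx = _SearchContext(pair, G, params)
    visited: set[frozenset[str]] = set()
    out: dict[frozenset[str], Solution] = {}
    expand = _expand if params.expansion == "branch" else _expand_greedy
    for u, v in _seed_edges(ctx):
        S = frozenset((u, v))
        mC = ctx.mask_C[u] | ctx.mask_C[v]
        mD = ctx.mask_D[u] | ctx.mask_D[v]
        expand(ctx, S, mC, mD, (u, v), visited, out)
    return SolutionReport.from_solutions(
        out.values(), k=params.k, theta=params.theta, n_C=ctx.n_C, n_D=ctx.n_D
    )


def best_solution(report: SolutionReport) -> Solution | None:
    """The top-ranked (highest differential coverage) solution, if any."""
    return report.best


# ---------------------------------------------------------------------------
# Exhaustive reference solver
# ---------------------------------------------------------------------------

def enumerate_connected_subgraphs(
    G: InteractionNetwork, k: int
) -> Iterator[frozenset[str]]:
    """Yield every vertex set of size 1..k inducing a connected subgraph of G.

    Each set is produced exactly once (enumeration with a growing forbidden
    set, polynomial delay).  Exponential in k — callers must guard sizes.
    """
    if k < 1:
        return
    adj = {v: set(G[v]) for v in G.nodes}
    forbidden_roots: set[str] = set()

    def extend(
        S: frozenset[str], ext: set[str], forbidden: set[str]
    ) -> Iterator[frozenset[str]]:
        yield S
        if len(S) == k:
            return
        local_forbidden = set(forbidden)
        for w in sorted(ext):
            new_ext = (ext | adj[w]) - S - local_forbidden - {w}
            yield from extend(S | {w}, new_ext, local_forbidden)
            local_forbidden.add(w)

    for v in sorted(G.nodes):
        yield from extend(
            frozenset((v,)), adj[v] - forbidden_roots, set(forbidden_roots)
        )
        forbidden_roots.add(v)


def brute_force_discovery(
    pair: CohortPair,
    G: InteractionNetwork,
    params: DamokleParams,
    *,
    max_vertices: int = 20,
) -> set[frozenset[str]]:
    """All connected gene sets of size <= k with dc >= theta, by enumeration.

    Exact reference solver for validation on small graphs; refuses graphs
    with more than *max_vertices* vertices.
    """
    if G.number_of_nodes() > max_vertices:
        raise ContractError(
            f"brute force refused: {G.number_of_nodes()} vertices exceeds the "
            f"guard of {max_vertices}"
        )
    ctx = _SearchContext(pair, G, params)
    out: set[frozenset[str]] = set()
    for S in enumerate_connected_subgraphs(G, params.k):
        mC, mD = ctx.masks(S)
        if ctx.dc_num(mC, mD) >= ctx.theta_num:
            out.add(S)
    return out
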