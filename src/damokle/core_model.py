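"""Core data model: mutation matrices, cohort pairs, and coverage statistics.

The central statistic of the package is the *differential coverage* of a gene
set S between two cohorts C and D of tumour samples,

    dc_S(C, D) = c_S(C) - c_S(D),

where the coverage c_S(C) is the fraction of samples of C carrying at least
one mutation in a gene of S.  Everything downstream (the subnetwork search,
the significance machinery, the simulator) is built on the two functions
:func:`coverage` and :func:`differential_coverage` defined here.

Mutation data is held in :class:`MutationMatrix`, a binary genes x samples
incidence matrix; the interaction network is a plain undirected
:class:`networkx.Graph` whose nodes are gene identifiers (the alias
:data:`InteractionNetwork` documents this convention).

Genes referenced by a query set but absent from a matrix contribute no
mutations: they behave as implicit all-zero rows.  This supports "connector"
genes that appear in the network, are needed for connectivity of a
subnetwork, but were never mutated in either cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "DamokleError",
    "EmptyCohortError",
    "FormatError",
    "ParameterError",
    "ContractError",
    "MutationMatrix",
    "CohortPair",
    "InteractionNetwork",
    "Solution",
    "coverage",
    "differential_coverage",
    "mutation_count",
    "boundary_edges",
]


class DamokleError(Exception):
    """Base class for all errors raised by this package."""


class EmptyCohortError(DamokleError):
    """A coverage statistic was requested on a cohort with zero samples."""


class FormatError(DamokleError):
    """An input file violates its documented dialect."""


class ParameterError(DamokleError):
    """A parameter is outside its documented domain."""


class ContractError(DamokleError):
    """A precondition of an operation was violated."""


#: Undirected simple graph on gene identifiers (no self-loops, no parallel
#: edges).  We use :class:`networkx.Graph` directly as the container; readers
#: in :mod:`damokle.io_formats` enforce simplicity on construction.
InteractionNetwork = nx.Graph


@dataclass(frozen=True)
class MutationMatrix:
    """Binary genes x samples mutation incidence for one cohort.

    Parameters
    ----------
    gene_ids:
        Ordered unique gene identifiers (matrix rows).
    sample_ids:
        Ordered unique sample identifiers (matrix columns).
    values:
        Boolean array of shape ``(len(gene_ids), len(sample_ids))``;
        ``values[i, j]`` is True iff gene ``i`` is mutated in sample ``j``.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        genes = tuple(self.gene_ids)
        samples = tuple(self.sample_ids)
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        if len(set(genes)) != len(genes):
            raise FormatError("duplicate gene identifiers")
        if len(set(samples)) != len(samples):
            raise FormatError("duplicate sample identifiers")
        values = np.asarray(self.values)
        if values.dtype != bool:
            if not np.isin(values, (0, 1)).all():
                raise FormatError("mutation matrix entries must be 0 or 1")
            values = values.astype(bool)
        if values.shape != (len(genes), len(samples)):
            raise FormatError(
                f"matrix shape {values.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "_gene_index", {g: i for i, g in enumerate(genes)})
        object.__setattr__(self, "_sample_index", {s: j for j, s in enumerate(samples)})

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene: str) -> int | None:
        """Row index of *gene*, or None if the gene is unknown."""
        return self._gene_index.get(gene)

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise ContractError(f"unknown sample identifier: {sample!r}") from None

    def row(self, gene: str) -> np.ndarray:
        """Mutation indicator over samples for *gene* (all-zero if unknown)."""
        i = self.gene_index(gene)
        if i is None:
            return np.zeros(self.n_samples, dtype=bool)
        return self.values[i]

    # -- derived summaries ----------------------------------------------
    def gene_mutation_counts(self) -> np.ndarray:
        """Number of mutated samples per gene (aligned with ``gene_ids``)."""
        return self.values.sum(axis=1)

    def sample_burdens(self) -> np.ndarray:
        """Number of mutated genes per sample (aligned with ``sample_ids``)."""
        return self.values.sum(axis=0)

    # -- reshaping -------------------------------------------------------
    def subset_genes(self, genes: Iterable[str]) -> "MutationMatrix":
        """Matrix restricted to *genes* (kept in the given order)."""
        genes = list(genes)
        rows = []
        for g in genes:
            i = self.gene_index(g)
            if i is None:
                raise ContractError(f"unknown gene identifier: {g!r}")
            rows.append(i)
        return MutationMatrix(tuple(genes), self.sample_ids, self.values[rows])

    def with_gene_universe(self, genes: Iterable[str]) -> "MutationMatrix":
        """Re-index onto *genes*; genes unknown to this matrix get zero rows."""
        genes = tuple(genes)
        values = np.zeros((len(genes), self.n_samples), dtype=bool)
        for r, g in enumerate(genes):
            i = self.gene_index(g)
            if i is not None:
                values[r] = self.values[i]
        return MutationMatrix(genes, self.sample_ids, values)


@dataclass(frozen=True)
class CohortPair:
    """The two cohorts C and D under comparison, on a shared gene universe.

    ``C`` and ``D`` must carry an identical ordered gene universe and
    disjoint sample identifiers; :meth:`harmonize` aligns two arbitrary
    matrices onto the union of their genes.
    """

    C: MutationMatrix
    D: MutationMatrix

    def __post_init__(self) -> None:
        if self.C.gene_ids != self.D.gene_ids:
            raise ContractError("cohorts must share an identical ordered gene universe")
        if set(self.C.sample_ids) & set(self.D.sample_ids):
            raise ContractError("cohort sample identifiers must be disjoint")

    @classmethod
    def harmonize(
        cls,
        C: MutationMatrix,
        D: MutationMatrix,
        extra_genes: Iterable[str] = (),
    ) -> "CohortPair":
        """Build a pair on the union of gene universes (plus *extra_genes*).

        Gene order: C's genes, then D-only genes, then new extra genes, each
        block in first-seen order.  Extra genes (typically network vertices
        not mutated in either cohort) get all-zero rows.
        """
        seen = dict.fromkeys(C.gene_ids)
        for g in D.gene_ids:
            seen.setdefault(g)
        for g in extra_genes:
            seen.setdefault(g)
        universe = tuple(seen)
        return cls(C.with_gene_universe(universe), D.with_gene_universe(universe))

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self.C.gene_ids

    def swapped(self) -> "CohortPair":
        """The pair with the roles of C and D exchanged."""
        return CohortPair(C=self.D, D=self.C)


@dataclass(frozen=True)
class Solution:
    """A connected gene set with its differential coverage.

    ``seed_edge`` records the edge the search was seeded from (provenance
    only; it does not participate in equality).
    """

    genes: frozenset[str]
    dc: float
    seed_edge: tuple[str, str] | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Solution):
            return NotImplemented
        return self.genes == other.genes

    def __hash__(self) -> int:
        return hash(self.genes)

    @property
    def size(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.genes))


# ---------------------------------------------------------------------------
# Coverage statistics
# ---------------------------------------------------------------------------

def _covered(S: Iterable[str], M: MutationMatrix) -> np.ndarray:
    mask = np.zeros(M.n_samples, dtype=bool)
    for g in S:
        i = M.gene_index(g)
        if i is not None:
            mask |= M.values[i]
    return mask


def coverage(S: Iterable[str], M: MutationMatrix) -> float:
    """Fraction of samples of *M* with at least one mutated gene of *S*.

    Genes of *S* unknown to the matrix contribute nothing.  Raises
    :class:`EmptyCohortError` for a cohort with zero samples.
    """
    if M.n_samples == 0:
        raise EmptyCohortError("coverage is undefined on a cohort with no samples")
    return float(_covered(S, M).sum()) / M.n_samples


def differential_coverage(S: Iterable[str], pair: CohortPair) -> float:
    """dc_S(C, D) = c_S(C) - c_S(D); antisymmetric under swapping cohorts."""
    S = list(S)
    return coverage(S, pair.C) - coverage(S, pair.D)


def mutation_count(S: Iterable[str], sample: str, M: MutationMatrix) -> int:
    """Number of genes of *S* mutated in *sample* (errors on unknown sample)."""
    j = M.sample_index(sample)
    count = 0
    for g in set(S):
        i = M.gene_index(g)
        if i is not None and M.values[i, j]:
            count += 1
    return count


def boundary_edges(S: Iterable[str], G: InteractionNetwork) -> set[tuple[str, str]]:
    """Edges of *G* with exactly one endpoint in *S*, as sorted tuples.

    This is the edge neighbourhood N(S) used by the expansion step of the
    subnetwork search.
    """
    S = set(S)
    missing = S - set(G.nodes)
    if missing:
        raise ContractError(f"genes not in the network: {sorted(missing)!r}")
    out: set[tuple[str, str]] = set()
    for u in S:
        for v in G[u]:
            if v not in S:
                out.add((u, v) if u <= v else (v, u))
    return out


def singleton_dc(pair: CohortPair) -> Mapping[str, float]:
    """Differential coverage of every single gene of the pair's universe."""
    nC, nD = pair.C.n_samples, pair.D.n_samples
    if nC == 0 or nD == 0:
        raise EmptyCohortError("singleton dc is undefined on an empty cohort")
    covC = pair.C.values.sum(axis=1) / nC
    covD = pair.D.values.sum(axis=1) / nD
    return dict(zip(pair.gene_ids, (covC - covD).tolist()))
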