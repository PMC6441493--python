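"""Readers and writers for mutation data, interaction networks and reports.

All interchange formats are plain tab-separated text:

* mutation matrix: header ``gene<TAB>sample1<TAB>...``, one row per gene,
  cells in ``{0, 1}``;
* mutation pair list: ``sample_id<TAB>gene_id``, one mutation event per line
  (duplicates collapse);
* network: ``geneA<TAB>geneB`` edge list (the dialect of the HINT / HI-2012
  protein-interaction distributions), ``#`` comment lines skipped;
* solution report: ranked TSV plus a JSON document with full provenance.

Gene and sample identifiers are opaque case-sensitive strings; no symbol
harmonization is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .core_model import (
    FormatError,
    InteractionNetwork,
    MutationMatrix,
    Solution,
)

__all__ = [
    "SolutionReport",
    "read_mutation_matrix",
    "write_mutation_matrix",
    "read_mutation_pairs",
    "read_network",
    "write_network",
    "write_solutions",
]

logger = logging.getLogger(__name__)


def _ranking_key(item: tuple[Solution, float | None]):
    sol, _ = item
    return (-sol.dc, len(sol.genes), sol.sorted_genes())


@dataclass(frozen=True)
class SolutionReport:
    """Ranked list of discovered subnetworks plus the run's parameters.

    Solutions are ranked by differential coverage (descending); ties broken
    by smaller size, then lexicographic gene list.  ``p_values`` optionally
    maps a solution's gene set to a permutation p-value.
    """

    solutions: tuple[Solution, ...]
    k: int
    theta: float
    n_C: int
    n_D: int
    p_values: dict[frozenset[str], float] = field(default_factory=dict)

    @classmethod
    def from_solutions(
        cls,
        solutions: Iterable[Solution],
        k: int,
        theta: float,
        n_C: int,
        n_D: int,
        p_values: dict[frozenset[str], float] | None = None,
    ) -> "SolutionReport":
        p_values = dict(p_values or {})
        ranked = sorted(
            ((s, p_values.get(s.genes)) for s in solutions), key=_ranking_key
        )
        return cls(
            solutions=tuple(s for s, _ in ranked),
            k=k,
            theta=theta,
            n_C=n_C,
            n_D=n_D,
            p_values=p_values,
        )

    def __len__(self) -> int:
        return len(self.solutions)

    @property
    def best(self) -> Solution | None:
        return self.solutions[0] if self.solutions else None


# ---------------------------------------------------------------------------
# Mutation matrices
# ---------------------------------------------------------------------------

def read_mutation_matrix(path: str | Path) -> MutationMatrix:
    """Read a binary genes x samples TSV matrix.

    The header row names the samples (first cell is a label for the gene
    column and is ignored).  Any cell other than ``0`` or ``1`` is a
    :class:`FormatError` naming the offending row and column.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if header == "":
            raise FormatError(f"{path}: empty file, expected a header row")
        fields = header.rstrip("\n").split("\t")
        sample_ids = tuple(fields[1:])
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError(f"{path}: duplicate sample identifiers in header")
        gene_ids: list[str] = []
        rows: list[list[bool]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if parts == [""]:
                continue
            gene = parts[0]
            cells = parts[1:]
            if gene in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene {gene!r}")
            seen.add(gene)
            if len(cells) != len(sample_ids):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(sample_ids)} cells, "
                    f"got {len(cells)}"
                )
            row = []
            for col, cell in enumerate(cells):
                if cell == "0":
                    row.append(False)
                elif cell == "1":
                    row.append(True)
                else:
                    raise FormatError(
                        f"{path}:{lineno}: non-binary cell {cell!r} for gene "
                        f"{gene!r}, sample {sample_ids[col]!r}"
                    )
            gene_ids.append(gene)
            rows.append(row)
    values = np.array(rows, dtype=bool).reshape(len(gene_ids), len(sample_ids))
    return MutationMatrix(tuple(gene_ids), sample_ids, values)


def write_mutation_matrix(M: MutationMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\t" + "\t".join(M.sample_ids) + "\n")
        for i, g in enumerate(M.gene_ids):
            cells = "\t".join("1" if v else "0" for v in M.values[i])
            fh.write(g + ("\t" + cells if M.n_samples else "") + "\n")


def read_mutation_pairs(
    path: str | Path,
    samples: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> MutationMatrix:
    """Read a two-column ``sample<TAB>gene`` event list into a binary matrix.

    Duplicate events collapse to a single 1.  If *samples* (resp. *genes*)
    is given it fixes the column (row) universe and order — required for an
    empty file to yield a meaningful all-zero matrix; otherwise identifiers
    are taken in order of first appearance.
    """
    path = Path(path)
    events: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(
                    f"{path}:{lineno}: expected 'sample<TAB>gene', got {stripped!r}"
                )
            events.append((parts[0], parts[1]))
    if samples is None:
        samples = list(dict.fromkeys(s for s, _ in events))
    if genes is None:
        genes = list(dict.fromkeys(g for _, g in events))
    sample_index = {s: j for j, s in enumerate(samples)}
    gene_index = {g: i for i, g in enumerate(genes)}
    values = np.zeros((len(genes), len(samples)), dtype=bool)
    for s, g in events:
        if s not in sample_index:
            raise FormatError(f"{path}: sample {s!r} not in the declared sample list")
        if g not in gene_index:
            raise FormatError(f"{path}: gene {g!r} not in the declared gene list")
        values[gene_index[g], sample_index[s]] = True
    return MutationMatrix(tuple(genes), tuple(samples), values)


# ---------------------------------------------------------------------------
# Interaction networks
# ---------------------------------------------------------------------------

def read_network(path: str | Path) -> InteractionNetwork:
    """Read a two-column edge list into an undirected simple graph.

    Self-loops are dropped (the vertex is retained) and duplicate or
    reversed-duplicate edges collapse; counts of dropped records are logged.
    """
    path = Path(path)
    G = nx.Graph()
    self_loops = duplicates = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise FormatError(
                    f"{path}:{lineno}: expected 'geneA<TAB>geneB', got {stripped!r}"
                )
            u, v = parts[0], parts[1]
            if u == v:
                self_loops += 1
                G.add_node(u)
                continue
            if G.has_edge(u, v):
                duplicates += 1
                continue
            G.add_edge(u, v)
    if self_loops or duplicates:
        logger.info(
            "read_network(%s): dropped %d self-loop(s) and %d duplicate edge(s)",
            path, self_loops, duplicates,
        )
    return G


def write_network(G: InteractionNetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in G.edges):
            fh.write(f"{u}\t{v}\n")
        for v in sorted(n for n in G.nodes if G.degree(n) == 0):
            fh.write(f"# isolated\t{v}\n")


# ---------------------------------------------------------------------------
# Solution reports
# ---------------------------------------------------------------------------

def write_solutions(
    report: SolutionReport, path: str | Path, format: str = "tsv"
) -> None:
    """Write a ranked solution report as TSV or JSON.

    The TSV carries one solution per row (rank, dc, size, comma-joined
    sorted genes, p-value when known); the JSON additionally carries the run
    parameters and seed-edge provenance.  Output bytes are deterministic for
    a fixed report.
    """
    path = Path(path)
    if format == "tsv":
        with path.open("w") as fh:
            fh.write("rank\tdc\tsize\tgenes\tp_value\n")
            for rank, sol in enumerate(report.solutions, start=1):
                p = report.p_values.get(sol.genes)
                fh.write(
                    f"{rank}\t{sol.dc:.10g}\t{sol.size}\t"
                    f"{','.join(sol.sorted_genes())}\t"
                    f"{'' if p is None else format_float(p)}\n"
                )
    elif format == "json":
        doc = {
            "parameters": {
                "k": report.k,
                "theta": report.theta,
                "n_C": report.n_C,
                "n_D": report.n_D,
            },
            "solutions": [
                {
                    "rank": rank,
                    "genes": list(sol.sorted_genes()),
                    "dc": sol.dc,
                    "size": sol.size,
                    "seed_edge": list(sol.seed_edge) if sol.seed_edge else None,
                    "p_value": report.p_values.get(sol.genes),
                }
                for rank, sol in enumerate(report.solutions, start=1)
            ],
        }
        with path.open("w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format: {format!r}")


def format_float(x: float) -> str:
    return f"{x:.10g}"
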