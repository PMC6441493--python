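"""Statistical guarantees, permutation tests and cohort preprocessing.

Under the null hypothesis that a gene set S has identical mutation
distribution in both cohorts, the differential coverage is a sum of n_C
variables in [0, 1/n_C] and n_D variables in [-1/n_D, 0] with zero mean, so
Hoeffding's inequality gives the tail bound

    P(dc_S > eps) <= 2 exp(-2 eps^2 n_C n_D / (n_C + n_D)).

Multiplying by the number N_k of connected subnetworks of size <= k under
consideration yields family-wise (FWER) and false-discovery (FDR) corrected
thresholds on dc: a reported subnetwork whose dc reaches the threshold is
significant at level alpha.  The bound decreases in eps, so the operative
threshold is the *smallest* eps satisfying the corrected inequality (the
boundary of the satisfying half-line).

For realistic sample sizes the bound is loose; two permutation tests give
more power.  The gene-independence null redraws, per gene, the set of
mutated samples uniformly over the pooled cohorts while preserving the
gene's total mutation count.  The label-shuffle null reassigns whole sample
profiles to cohorts, preserving the cohort sizes and every per-sample
profile.  Both estimate the p-value of the observed best solution as
(x + 1) / (N + 1), where x counts permuted datasets on which a fresh run of
the search finds a solution at least as extreme.

The module also houses the small preprocessing operators used before
running the search on real cohorts: a per-sample mutation-burden t-test, a
single-gene differential-coverage screen, removal of named genes, and a
low-frequency gene filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_model import (
    CohortPair,
    ContractError,
    InteractionNetwork,
    MutationMatrix,
    ParameterError,
    Solution,
    singleton_dc,
)
from .discovery import (
    DamokleParams,
    best_solution,
    damokle,
    enumerate_connected_subgraphs,
)

__all__ = [
    "SignificanceConfig",
    "PermutationConfig",
    "PermutationResult",
    "hoeffding_bound",
    "count_connected_subgraphs",
    "fwer_epsilon",
    "fdr_epsilon",
    "permute_gene_null",
    "permute_label_null",
    "permutation_pvalue",
    "single_gene_screen",
    "low_frequency_filter",
    "remove_gene",
    "mutation_burden_test",
]


@dataclass(frozen=True)
class SignificanceConfig:
    """Error budget and source of the subnetwork count N_k."""

    alpha: float
    nk_mode: str = "exact"  # "exact" enumeration or "user" supplied count
    nk_value: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.nk_mode not in ("exact", "user"):
            raise ParameterError(f"unknown nk_mode: {self.nk_mode!r}")
        if self.nk_mode == "user" and (self.nk_value is None or self.nk_value < 1):
            raise ParameterError("nk_value must be a positive integer in user mode")


@dataclass(frozen=True)
class PermutationConfig:
    """Null model, permutation count and seed for a permutation test."""

    null_type: str  # "gene" (gene-independence) or "label" (label-shuffle)
    num_permutations: int
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.null_type not in ("gene", "label"):
            raise ParameterError(f"unknown null_type: {self.null_type!r}")
        if self.num_permutations < 1:
            raise ParameterError("num_permutations must be >= 1")


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a permutation test on the best observed solution."""

    p_value: float
    observed: Solution
    exceedances: int
    num_permutations: int
    null_type: str


# ---------------------------------------------------------------------------
# Analytic bounds
# ---------------------------------------------------------------------------

def hoeffding_bound(epsilon: float, n_C: int, n_D: int) -> float:
    """Null tail bound 2 exp(-2 eps^2 n_C n_D / (n_C + n_D)) on dc_S.

    Symmetric in the cohort sizes and non-increasing in epsilon; epsilon = 0
    gives the vacuous bound 2.
    """
    if epsilon < 0:
        raise ParameterError(f"epsilon must be >= 0, got {epsilon}")
    if n_C < 1 or n_D < 1:
        raise ParameterError("cohort sizes must be positive")
    return 2.0 * math.exp(-2.0 * epsilon**2 * n_C * n_D / (n_C + n_D))


def count_connected_subgraphs(
    G: InteractionNetwork, k: int, *, max_vertices: int = 30
) -> int:
    """Exact N_k: number of connected vertex sets of size 1..k.

    Exhaustive enumeration, guarded to small graphs; for larger networks
    supply a user count through :class:`SignificanceConfig`.
    """
    if G.number_of_nodes() > max_vertices:
        raise ContractError(
            f"exact N_k enumeration refused on {G.number_of_nodes()} vertices "
            f"(guard {max_vertices}); supply nk_value instead"
        )
    return sum(1 for _ in enumerate_connected_subgraphs(G, k))


def fwer_epsilon(N_k: int, n_C: int, n_D: int, alpha: float) -> float:
    """Smallest eps with N_k * hoeffding_bound(eps) <= alpha.

    Closed form: eps* = sqrt(ln(2 N_k / alpha) (n_C + n_D) / (2 n_C n_D)).
    A reported dc >= eps* is FWER-significant at level alpha.
    """
    if N_k < 1:
        raise ParameterError("N_k must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    return math.sqrt(
        math.log(2.0 * N_k / alpha) * (n_C + n_D) / (2.0 * n_C * n_D)
    )


def fdr_epsilon(
    observed_dcs: Sequence[float], N_k: int, n_C: int, n_D: int, alpha: float
) -> float | None:
    """Smallest candidate eps with N_k * bound(eps) / n(eps) <= alpha.

    n(eps) is the number of observed solution dc values >= eps — a step
    function that only changes at the observed values, so scanning the
    sorted observed dcs as candidate thresholds is exact.  Returns None
    when no candidate satisfies the inequality.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if len(observed_dcs) == 0:
        raise ParameterError("observed_dcs must be non-empty")
    dcs = sorted(observed_dcs)
    for eps in dcs:
        if eps < 0:
            continue
        n_eps = sum(1 for d in dcs if d >= eps)
        if N_k * hoeffding_bound(eps, n_C, n_D) / n_eps <= alpha:
            return float(eps)
    return None


# ---------------------------------------------------------------------------
# Permutation nulls
# ---------------------------------------------------------------------------

def _split(pair: CohortPair, pooled: np.ndarray) -> CohortPair:
    nC = pair.C.n_samples
    return CohortPair(
        C=MutationMatrix(pair.gene_ids, pair.C.sample_ids, pooled[:, :nC]),
        D=MutationMatrix(pair.gene_ids, pair.D.sample_ids, pooled[:, nC:]),
    )


def permute_gene_null(pair: CohortPair, seed: int = 0) -> CohortPair:
    """Gene-independence null: redraw each gene's mutated samples uniformly.

    Each gene's total mutation count over the pooled samples C u D is
    preserved exactly; the mutated samples are re-chosen uniformly without
    replacement from the pool, independently across genes.  Cohort
    membership of samples is unchanged.
    """
    rng = np.random.default_rng(seed)
    pooled = np.hstack([pair.C.values, pair.D.values])
    n = pooled.shape[1]
    out = np.zeros_like(pooled)
    totals = pooled.sum(axis=1)
    for i, t in enumerate(totals):
        if t == 0:
            continue
        if t == n:
            out[i] = True
            continue
        out[i, rng.choice(n, size=int(t), replace=False)] = True
    return _split(pair, out)


def permute_label_null(pair: CohortPair, seed: int = 0) -> CohortPair:
    """Label-shuffle null: reassign whole sample profiles to cohorts.

    Cohort sizes n_C and n_D are preserved; every per-sample mutation
    profile survives unchanged, only its cohort label moves.
    """
    rng = np.random.default_rng(seed)
    pooled = np.hstack([pair.C.values, pair.D.values])
    perm = rng.permutation(pooled.shape[1])
    return _split(pair, pooled[:, perm])


def permutation_pvalue(
    pair: CohortPair,
    G: InteractionNetwork,
    params: DamokleParams,
    perm_config: PermutationConfig,
) -> PermutationResult:
    """Permutation p-value of the best observed solution.

    Runs the search on the observed pair, then on ``N`` permuted datasets
    drawn from the configured null (a fresh, fully recomputed run per
    dataset, including re-seeding).  With x the number of permuted datasets
    whose best dc reaches the observed best dc, the p-value is
    (x + 1) / (N + 1); permuted datasets yielding no solution at all count
    as non-exceedances (their best dc is necessarily below theta <= the
    observed dc).  Per-permutation RNG streams derive from
    (seed, permutation index), so the result is reproducible and
    independent of evaluation order.
    """
    observed = best_solution(damokle(pair, G, params))
    if observed is None:
        raise ContractError("no observed solution: nothing to test")
    permute = permute_gene_null if perm_config.null_type == "gene" else permute_label_null
    N = perm_config.num_permutations
    x = 0
    for i in range(N):
        child = np.random.SeedSequence(
            perm_config.rng_seed, spawn_key=(i,)
        ).generate_state(1)[0]
        null_pair = permute(pair, seed=int(child) % (2**31))
        null_best = best_solution(damokle(null_pair, G, params))
        if null_best is not None and null_best.dc >= observed.dc:
            x += 1
    return PermutationResult(
        p_value=(x + 1) / (N + 1),
        observed=observed,
        exceedances=x,
        num_permutations=N,
        null_type=perm_config.null_type,
    )


# ---------------------------------------------------------------------------
# Preprocessing screens
# ---------------------------------------------------------------------------

def single_gene_screen(
    pair: CohortPair, dc_cutoff: float
) -> list[tuple[str, float]]:
    """Genes whose singleton |dc| exceeds *dc_cutoff*, with the signed dc.

    Two-sided: a gene much more mutated in either cohort is reported.
    Sorted by |dc| descending (ties: lexicographic gene).  Typically used to
    spot and remove single dominating genes before the subnetwork search.
    """
    if not 0.0 <= dc_cutoff <= 1.0:
        raise ParameterError(f"dc_cutoff must lie in [0, 1], got {dc_cutoff}")
    dcs = singleton_dc(pair)
    hits = [(g, d) for g, d in dcs.items() if abs(d) > dc_cutoff]
    return sorted(hits, key=lambda gd: (-abs(gd[1]), gd[0]))


def low_frequency_filter(pair: CohortPair, min_mutations: int) -> CohortPair:
    """Drop genes with fewer than *min_mutations* mutations in both cohorts.

    A gene is kept if it reaches the count in at least one cohort; dropped
    rows are removed from both matrices (the network is untouched).
    """
    if min_mutations < 0:
        raise ParameterError("min_mutations must be >= 0")
    countC = pair.C.gene_mutation_counts()
    countD = pair.D.gene_mutation_counts()
    keep = [
        g
        for i, g in enumerate(pair.gene_ids)
        if countC[i] >= min_mutations or countD[i] >= min_mutations
    ]
    return CohortPair(
        C=pair.C.subset_genes(keep), D=pair.D.subset_genes(keep)
    )


def remove_gene(pair: CohortPair, gene: str) -> CohortPair:
    """Remove one gene's alterations from both cohorts (row dropped)."""
    if gene not in pair.gene_ids:
        raise ContractError(f"unknown gene: {gene!r}")
    keep = [g for g in pair.gene_ids if g != gene]
    return CohortPair(C=pair.C.subset_genes(keep), D=pair.D.subset_genes(keep))


def mutation_burden_test(pair: CohortPair) -> float:
    """Two-sided Welch t-test p-value on per-sample total mutation counts.

    Used as a pre-flight check that the two cohorts do not differ grossly in
    overall mutation rate (which would confound differential coverage).
    """
    a = pair.C.sample_burdens().astype(float)
    b = pair.D.sample_burdens().astype(float)
    if a.size < 2 or b.size < 2:
        raise ContractError("burden test requires >= 2 samples per cohort")
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
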