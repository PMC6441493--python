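# Methods

## Problem and data model

Two cohorts of tumour samples, $\mathcal{C}$ ($n_C$ samples) and
$\mathcal{D}$ ($n_D$ samples), are represented as binary genes × samples
matrices; an undirected simple graph $G$ on gene identifiers supplies the
interaction structure.  For a gene set $S$, the coverage
$c_S(\mathcal{C})$ is the fraction of samples of $\mathcal{C}$ with at
least one mutation in $S$, and the differential coverage is
$dc_S(\mathcal{C},\mathcal{D}) = c_S(\mathcal{C}) - c_S(\mathcal{D})$.
The target objects are connected subgraphs $S$ of $G$ with $|S| \le k$ and
$dc_S \ge \theta$.

Genes present in the network but absent from a mutation matrix are treated
as all-zero rows rather than errors.  This admits "connector" genes that
carry no mutations but are needed for the connectivity of a subnetwork.
Sample identifiers of the two cohorts must be disjoint; whether one
physical sample may appear in both cohorts is not constrained by the
statistic itself, and we chose to forbid it.

## Search

Seeding considers every edge $\{u,v\}$ with
$dc_{\{u,v\}} \ge \theta/(k-1)$.  The bound comes from an averaging
argument: if each sample carries at most one mutation in a detectable set
$S$ ($dc_S \ge \theta$), some vertex of $S$ achieves per-gene differential
coverage $\ge \theta/k$ and one of its incident edges inside $S$ reaches
$\theta/(k-1)$; a concentration argument extends this to the general case
with high probability in $n_C, n_D$.  The comparison is non-strict and is
evaluated on exact integers (see Numerical conventions).

Expansion grows a seed set one boundary edge at a time.  Only additions
that **strictly** increase $dc$ are taken: an addition that leaves the
score flat contributes no signal, and a vertex whose addition lowers the
score below the background-overlap margin would, with high probability, be
better removed.  A set is reported when it has reached size $k$ or no
single boundary vertex improves it, and its $dc$ meets $\theta$.  Reported
sets are therefore connected, within the size bound, above threshold and
*algorithmically maximal*; note this is weaker than "no addition keeps
$dc \ge \theta$" — an addition may keep a set above threshold without
improving it, and such non-improving extensions are deliberately not taken.

Two expansion strategies are provided:

* **branch** (default): recurse over *every* improving boundary edge and
  report all maximal sets reached, deduplicated across branches and seeds
  by gene-set identity.  A shared memo of expanded states makes the cost
  proportional to the number of distinct reachable sets; skipping an
  already-expanded state cannot change the output because both the
  emission rule and the branch set depend only on the gene set (asserted
  against the memo-free recursion in the tests).
* **greedy**: take only the boundary vertex with the maximum $dc$ increase
  (ties: lexicographically smallest vertex), yielding one maximal set per
  seed.  This exists because branch enumeration is intrinsically
  exponential in adverse regimes: with a permissive $\theta$ on a large
  network, a hub vertex with $m$ individually-improving neighbours alone
  generates $\binom{m}{k-2}$ maximal sets, and at $k \ge 9$,
  $\theta = 0.01$ on the 1000-gene simulation fixture the state space
  exceeds memory.  Greedy output is always a subset of branch output and
  satisfies the same per-solution guarantees (connected, $\le k$,
  $\ge \theta$, maximal); what it gives up is completeness of the reported
  *collection*.  The planted-recovery experiments use greedy; on small
  instances both modes are validated against a brute-force enumeration of
  all connected subsets.

The direction of the comparison is fixed: the search finds sets enriched
in $\mathcal{C}$.  Enrichment in $\mathcal{D}$ is obtained by swapping the
cohorts (`--direction D-over-C` on the command line).

A consequence of the strict-improvement rule is that zero-coverage
connector genes can never be *added* by the search, although the problem
definition permits them inside solutions; the implementation inherits this
limitation from the algorithm itself.

## Statistical guarantees

If $S$ has the same mutation distribution in both cohorts, $dc_S$ is a
zero-mean sum of $n_C$ variables in $[0, 1/n_C]$ and $n_D$ variables in
$[-1/n_D, 0]$, and Hoeffding's inequality gives

$$P(dc_S > \epsilon) \le 2\,e^{-2\epsilon^2 n_C n_D/(n_C+n_D)}.$$

With $N_k$ the number of connected subnetworks of size $\le k$ under
consideration (exact enumeration on small graphs, user-supplied count
otherwise; "components" would make the count trivial, so the intended
reading is connected subgraphs), the FWER-corrected threshold is the
smallest $\epsilon$ with $N_k \cdot \mathrm{bound}(\epsilon) \le \alpha$,
available in closed form as
$\epsilon^* = \sqrt{\ln(2N_k/\alpha)\,(n_C+n_D)/(2 n_C n_D)}$.  The bound
is decreasing in $\epsilon$, so the satisfying set is a half-line and the
boundary point is the least conservative valid cutoff.  The FDR variant
divides the corrected bound by $n(\epsilon)$, the number of reported
solutions with $dc \ge \epsilon$; $n(\epsilon)$ is a step function that
changes only at observed values, so scanning the sorted observed $dc$
values as candidates is exact, and the smallest satisfying candidate is
returned (or none).

## Permutation tests

Two nulls target different hypotheses:

* **gene-independence**: each gene's mutated samples are re-drawn
  uniformly without replacement over the pooled samples
  $\mathcal{C}\cup\mathcal{D}$, independently per gene, preserving each
  gene's total mutation count.  Pooling (rather than permuting within
  cohorts) is essential: the test asks whether mutations are independent
  of cohort labels given marginal gene frequencies.
* **label-shuffle**: whole sample profiles are reassigned to cohorts with
  $n_C, n_D$ preserved, testing association between mutation profiles and
  cohort membership under the observed joint mutation structure.

For the best observed solution, the search is fully re-run (including
re-seeding) on each of $N$ permuted datasets with identical parameters;
with $x$ the number of permuted datasets whose best solution reaches the
observed $dc$, the p-value is $(x+1)/(N+1)$.  A permuted dataset with no
solution at all counts as a non-exceedance — its best $dc$ is undefined
but necessarily below $\theta \le$ the observed value.  Per-permutation
RNG streams are derived from (seed, permutation index), so results do not
depend on evaluation order.  Calibration is verified empirically: on data
generated under the null, $P(p \le 0.05)$ stays within Monte-Carlo error
of 0.05 for both nulls.

## Preprocessing operators

Mirroring the practical workflow on real cohorts: a Welch two-sample
t-test on per-sample total mutation counts (a gross mutation-rate
difference between cohorts would confound differential coverage; Welch
because equal variances cannot be assumed), a two-sided single-gene screen
reporting genes whose singleton $|dc|$ exceeds a cutoff (dominating single
genes such as pan-cancer drivers are typically removed before the
subnetwork search), removal of named genes, and a low-frequency filter
dropping genes with fewer than a minimum number of mutations in *both*
cohorts (a gene frequent in either cohort alone is informative and kept).
The command-line `run` subcommand applies them in that order and logs the
effect of each step.

## Simulation

`simulate_cohorts` implements the planted-signal protocol: every gene of
the network mutates independently with its background rate $p_g$ in both
cohorts; each case sample with no background mutation in the planted
connected set $S$ then receives, with probability $c$, exactly one extra
mutation in a uniformly chosen gene of $S$.  Writing $p_S$ for the
probability that background alone covers $S$, the expected differential
coverage is $c\,(1-p_S)$ — the protocol is implemented verbatim, and the
gap to the nominal $c$ (a few percent at the default rates) is accepted
rather than re-normalized.

`sample_from_model` draws from the explicit generative model used in the
search's analysis: controls follow the product-Bernoulli background $F$;
cases follow $F_H$ — $F$ conditioned on at least one mutation in the
planted set $H$ — with probability $1-q$ and $F$ otherwise, where $q$ is
the signal-loss rate.  $F_H$ is realized by rejection sampling restricted
to the $H$ coordinates (genes outside $H$ are unconditioned); an empty $H$
or a zero-probability conditioning event is rejected, and an iteration
guard protects against numerically tiny $p$.

The fixture network is a preferential-attachment graph (complete seed
graph on $m+1$ vertices, each new vertex attaching to $m$ distinct
degree-biased targets; $m(m+1)/2 + (n-m-1)m$ edges), giving the connected,
heavy-tailed-degree topology of protein-interaction networks at a
reduced scale.  Background rates are drawn from an exponential
distribution with mean 0.01 capped at 0.2: most genes mutate in ~1% of
samples, with a driver-like tail that cannot saturate a cohort.  Planted
sets are grown by seeded random boundary expansion — connected and of
exact size $k$, with no claim of uniformity over all connected $k$-sets —
and are re-drawn for every simulation replicate.

**What the simulation does not emulate.**  Real interaction networks are
an order of magnitude larger (~10⁴ genes, hubs with hundreds of partners)
and real per-gene rates include frequently mutated drivers estimated from
sequencing data.  Both features enlarge the pool of connected "noise" sets
competing with the planted one, which suppresses exact recovery at
intermediate sample sizes.  On the scaled-down fixture the recovery
transition for a planted 10-gene set at expected $dc = 0.46$ happens
between $n = 100$ (never exact) and $n = 250$ (usually exact), whereas on
full-size networks with realistic rates it is reported to happen between
$n = 250$ and $n = 500$.  Passing recovery tests here therefore validates
the machinery, not the quantitative difficulty of full-scale data.
Covariate structure (mutation-rate heterogeneity across samples, CNA/SNV
distinctions, mutual exclusivity) is also not modelled.

## Numerical conventions

Coverage profiles are packed into integer bitmasks (one bit per sample),
so a candidate evaluation is two ORs and two popcounts.  All score
comparisons inside the search use the exact integer cross-product
$|{\rm cov}_C|\,n_D - |{\rm cov}_D|\,n_C$; strict-improvement decisions
are therefore exact, and only the comparison against the user's float
$\theta$ carries a $10^{-9}$ absolute slack to absorb decimal
representation error.  Ranking of reported solutions is $dc$ descending,
ties by smaller size, then lexicographic gene list — a fixed convention
making reports byte-deterministic.  All generators and permutation tests
are reproducible from a single integer seed, with per-replicate streams
spawned from (seed, replicate index).

## Experiment sizes

The bundled studies run on one CPU in well under an hour in total: the
recovery experiments use the 1000-gene fixture with 10 replicates per
grid point (100 replicates where a binary exact-recovery rate needs
tighter Monte-Carlo error); oracle comparisons use 200 random instances
with ≤ 12 vertices; bound-domination uses 1000 null replicates at
$n_C = n_D = 100$; permutation calibration uses 200 outer replicates with
$N = 99$ permutations on a 30-gene fixture.
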