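# damokle

Discovery of **differentially mutated subnetworks** in two cohorts of
cancer samples.

Large cancer sequencing studies routinely compare two groups of tumours —
two cancer (sub)types, responders vs non-responders, metastatic vs
non-metastatic.  Methods that look for significantly mutated subnetworks in
one cohort at a time miss gene modules whose mutation frequency is modest
in both groups but clearly *different* between them.  This package searches
a gene–gene interaction network directly for such modules.

## The statistic and the algorithm

For a gene set $S$, the *coverage* $c_S(\mathcal{C})$ is the fraction of
samples of cohort $\mathcal{C}$ with at least one mutated gene of $S$, and
the *differential coverage* is

$$dc_S(\mathcal{C},\mathcal{D}) = c_S(\mathcal{C}) - c_S(\mathcal{D}).$$

Given an undirected interaction network $G$, a size bound $k$ and a
threshold $\theta \in [0,1]$, the problem is to find connected subgraphs
$S$ of $G$ with $|S| \le k$ and $dc_S(\mathcal{C},\mathcal{D}) \ge \theta$
(the problem is NP-hard in general).  The search

1. **seeds** on every edge $\{u,v\}$ with
   $dc_{\{u,v\}} \ge \theta/(k-1)$ — under a natural generative model, any
   detectable subnetwork contains such an edge with high probability — and
2. **expands** each seed one boundary edge at a time, keeping only
   additions that strictly increase $dc$, and reports the sets that cannot
   be improved further (or have reached size $k$) and meet the threshold.

Significance is assessed two ways: analytically, via the null tail bound
$P(dc_S > \epsilon) \le 2 e^{-2\epsilon^2 n_C n_D/(n_C+n_D)}$ turned into
FWER/FDR-corrected thresholds over the $N_k$ candidate subnetworks; and
empirically, by permutation tests (a gene-independence null preserving
per-gene mutation counts, and a label-shuffle null preserving per-sample
profiles) with p-value $(x+1)/(N+1)$ over $N$ permuted datasets.

A simulation module generates two-cohort datasets with a planted
differentially mutated subnetwork on a synthetic interaction network, so
the whole pipeline is testable without any external downloads.

## Worked example

Simulate a 200-gene network with a planted 4-gene module whose expected
differential coverage is 0.7, then recover it and test its significance:

```sh
damokle simulate --genes 200 -n 120 -c 0.7 -k 4 --seed 42 --out data
damokle run --mut-c data/cohort_C.tsv --mut-d data/cohort_D.tsv \
    --network data/network.tsv -k 4 --theta 0.3 --out run
damokle permute --mut-c data/cohort_C.tsv --mut-d data/cohort_D.tsv \
    --network data/network.tsv -k 4 --theta 0.3 --permutations 99 \
    --seed 7 --out perm
```

which prints

```
INFO damokle: per-sample mutation burden t-test: p = 0.01827
209 subnetworks; best: g0008,g0027,g0133,g0142 (dc = 0.7250)
gene null: p = 0.01 (x = 0, N = 99; observed dc = 0.7250)
label null: p = 0.01 (x = 0, N = 99; observed dc = 0.7250)
```

The top-ranked solution is exactly the planted module (see
`data/manifest.json`): its mutation coverage is 72.5 percentage points
higher in cohort C than in cohort D, and none of the 99 permuted datasets
reached that value under either null, giving the smallest attainable
p-value $1/100$.  The burden t-test warns that the two cohorts differ
somewhat in overall mutation rate — on real data this would call for
caution, here it simply reflects the planted signal.  `run/solutions.tsv`
holds the full ranked report; every run also writes a `manifest.json`
recording parameters, input hashes and seeds for exact reproduction.

The same functionality is available as a library:

```python
from damokle import (read_network, read_mutation_matrix, CohortPair,
                     DamokleParams, damokle, best_solution)
G = read_network("data/network.tsv")
pair = CohortPair.harmonize(read_mutation_matrix("data/cohort_C.tsv"),
                            read_mutation_matrix("data/cohort_D.tsv"),
                            extra_genes=G.nodes)
report = damokle(pair, G, DamokleParams(k=4, theta=0.3))
print(best_solution(report))
```

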