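# pathproxy

Optimization-driven *pathway proxies* from gene-expression data.

Given a two-group (e.g. control vs. cancer) expression matrix, `pathproxy`
runs a fully deterministic pipeline with no tunable significance thresholds:

1. **Pareto preselection** — every gene is scored by two conflicting
   criteria, the absolute difference of group means and of group medians
   (|Δmean|, |Δmedian|). The candidate biomarkers are the genes not
   dominated on both criteria (the Pareto front, optionally "peeled" for
   several layers).
2. **Difference-correlation network** — for every selected gene a vector
   of case-minus-control expression differences is built over one common
   pair ordering (by default every control sample against every case
   sample); edge weights are the absolute Pearson correlations |ρ| between
   these per-gene difference vectors.
3. **Exact network optimization** — two globally optimal structures over
   the selected genes:
   * the **maximum-correlation Hamiltonian cycle** (a TSP with gains
     instead of costs, solved exactly by Held–Karp dynamic programming) —
     a cyclic pathway proxy that can represent feedback;
   * the **maximum-correlation spanning tree** (MST under cost 1 − |ρ|) —
     an open proxy for coordinated groups without feedback.
4. **Meta-analysis** — with more than two conditions, every pairwise
   comparison is run and gene–gene relations recurring across the
   resulting tours/trees are reported as conserved *blocks*.

Because both solvers are exact, the central claim is a mathematical one: no
other cycle (of the `(n−1)!/2` possible) or tree (of the `n^(n−2)`
possible, Cayley's count) is better correlated on the given data. The
structures are observational proxies — they carry no causal or directional
claim.

Intended users: computational biologists prototyping biomarker-network
hypotheses from microarray/RNA expression tables, and method developers who
want small exact solvers with enumeration oracles and a planted-truth
simulator.

## Worked example

The package ships an 11-gene absolute-correlation matrix over candidate
lung adenocarcinoma biomarkers (AGER, SFTPC, TMEM100, FABP4, SPP1, WIF1,
COL11A1, CYP4B1, FCN3, ADH1B, CLDN18). As printed in its source, the
matrix has a few asymmetric mirror cells, so a triangle policy must be
chosen explicitly (`upper` is the package convention):

```sh
$ pathproxy tsp --matrix src/pathproxy/data/lung11_correlations.tsv \
      --policy upper --out tour.tsv
ADH1B -> CYP4B1 -> SFTPC -> WIF1 -> CLDN18 -> FABP4 -> AGER -> SPP1 -> COL11A1 -> FCN3 -> TMEM100 -> ADH1B
total |rho| = 5.250000
```

That cycle is the global maximum over all 10!/2 = 1,814,400 undirected
Hamiltonian cycles: the sum of the 11 edge correlations is 5.250 and no
other cycle exceeds it (the test suite re-verifies this against exhaustive
enumeration). The tree counterpart:

```sh
$ pathproxy mst --matrix src/pathproxy/data/lung11_correlations.tsv \
      --policy upper --out tree.tsv
10 edges, total |rho| = 5.497000
```

`tree.tsv` lists the 10 edges of the maximum-correlation spanning tree,
e.g. `AGER-SFTPC 0.643` and `FCN3-TMEM100 0.600`; SFTPC and AGER act as
hubs. The tree's total 5.497 exceeds the tour's 5.250 because a tree may
reuse high-correlation hubs instead of closing a cycle.

A full synthetic run (simulate → select → correlate → solve):

```sh
pathproxy simulate --seed 9 --out expr.tsv --design design.tsv --truth truth.json
pathproxy select --expr expr.tsv --groups design.tsv --a control --b cancer \
    --layers 8 --out genes.txt
pathproxy correlate --expr expr.tsv --groups design.tsv --control control \
    --case cancer --genes genes.txt --out corr.tsv
pathproxy tsp --matrix corr.tsv --out tour.tsv
pathproxy mst --matrix corr.tsv --out tree.tsv
```

With four condition groups, `pathproxy meta --expr ... --groups ... --out
report/` runs all six pairwise comparisons and writes per-comparison
tour/tree edge lists plus `shared_relations.tsv` (per-edge recurrence
counts) and `shared_blocks.json` (maximal chains of edges recurring in the
same comparisons). Every subcommand writes a JSON manifest of resolved
parameters and input digests.

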