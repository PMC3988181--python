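# coexmod

Non-targeted discovery of functionally coherent gene modules in genome-wide
co-expression networks, with the plant cell-wall use case in mind: given an
expression compendium (e.g., hundreds of public microarray hybridizations),
`coexmod` builds a weighted gene co-expression network, detects modules
from network topology alone, annotates them by GO enrichment, and searches
module promoters for overrepresented cis-regulatory elements. A
synthetic-data generator with planted modules, annotations and motifs makes
every stage testable offline.

## The method

1. **Redundancy-aware correlation.** Public compendia contain near-duplicate
   hybridizations. Each sample gets a weight
   `w_s = 1 / Σ_t [r_st]₊²` (sum over all samples, `r_ss = 1`), so `d`
   duplicates each count `1/d`; gene similarity is the weighted Pearson
   correlation `r(g,h)` under these weights.
2. **Density-guided threshold.** An edge is kept when `r ≥ c`. Network
   density `2E/(N(N−1))` over the retained genes falls, reaches an interior
   minimum, then rises as only dense modules survive; `c` is chosen as the
   density argmin plus 0.05.
3. **Module detection.** Modules maximize Newman modularity
   `Q = (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j)` by recursive spectral
   bisection of the modularity matrix with Kernighan–Lin refinement and a
   global single-node-move pass.
4. **GO enrichment.** Each module's terms are tested with the hypergeometric
   upper tail `P(X ≥ k)` for `k` of `n` annotated members against `K` of
   `N` background genes, with per-module Bonferroni and Benjamini–Hochberg
   FDR; modules are selected by significant terms matching keywords such as
   "cell wall".
5. **Promoter motifs.** For a selected module, all 4^k candidate k-mers
   (k = 6, 8) are counted mismatch-tolerantly (radius 1 and 2) in the
   2,000-bp strand-corrected promoters of module genes versus all other
   promoters; candidates with binomial enrichment p < 0.05 are ranked by
   log-odds and matched against an IUPAC consensus catalog of known
   cis-regulatory elements.

Network topology diagnostics (degree distribution with a log–log power-law
fit, clustering coefficients, C(k) curve, Erdős–Rényi baseline) are
reported alongside. See `docs/methods.md` for models, defaults and design
decisions.

## Worked example

Run the whole pipeline on the default synthetic compendium (2,000 genes,
120 samples, three planted 50-gene modules, one planted promoter motif):

```sh
coexmod --out-dir demo --seed 1 run-all
```

which logs each stage and prints

```
done: 612 nodes, 3963 edges, 196 modules (Q=0.7084), ARI vs planted 0.898
```

The network keeps the 612 genes with at least one correlation above the
density-guided cutoff (0.35 for this seed); the three largest detected
modules (53 genes each) recover the three planted modules, and the
remaining tiny modules are chance correlations among background genes — the
adjusted Rand index of 0.898 against the planted labels reflects essentially
exact module recovery. `demo/enrichment.tsv` shows each planted GO term as
the top term of its module (e.g., "plant-type secondary cell wall
biogenesis" at raw p ≈ 1.5e-56 in module 1), and `demo/motifs.tsv` ranks
the planted motif's one-mismatch neighborhood first for module 1, with its
catalog matches. All intermediates (edge list, density scan, topology
report, module tables, tissue profiles) are tab-separated files in `demo/`.

The same stages are importable as a library:

```python
from coexmod import (SynConfig, simulate_expression, sample_weights,
                     density_scan, select_cutoff, build_network,
                     detect_modules)

x = simulate_expression(SynConfig(seed=1))
w = sample_weights(x)
scan = density_scan(x, w)
net = build_network(x, w, select_cutoff(scan))
modules = detect_modules(net, seed=1)
print(modules.q, len(modules.module_ids()))
```

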