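# rmtnet

Gene co-expression network construction with random-matrix-theory (RMT)
thresholding, plus the machinery to ask how robust such a network is when
the input data are degraded.

## The problem

A co-expression network is built by correlating every pair of gene
expression profiles across a set of samples (microarrays or similar),
giving an *n* × *n* similarity matrix `S` of Pearson correlations, and then
keeping only pairs whose correlation exceeds a threshold. Everything hinges
on that threshold, and picking it by hand is arbitrary. RMT offers a
knowledge-independent criterion: the nearest-neighbor spacing distribution
(NNSD) of the eigenvalues of a matrix containing only genuine structure
follows the Poisson law P(s) = e^−s (independent blocks superpose their
spectra), whereas a noise-dominated matrix behaves like a Gaussian
orthogonal ensemble (GOE), whose spacings repel according to the Wigner
surmise P(s) = (π/2)s·e^(−πs²/4). Descending through candidate thresholds
*t* and pruning `S` at each level (|r| < t → 0, empty rows dropped), the
spacing statistics of the unfolded spectrum flip from Poisson to GOE
exactly where the threshold dips into the noise floor. `rmtnet` detects
that transition with a χ² test against the exponential law (60 bins on
[0, 3], df = 59; significance at χ² = 100 ≈ p 0.001, confirmed by a
sustained rise to χ² = 200) and reports the last threshold on the Poisson
side as the network cutoff.

Downstream, the package measures what a network inference practitioner
would ask of the result: topology (node/edge counts, average degree ⟨k⟩,
clustering coefficient C, scale-free exponent γ in P(k) = ck^−γ),
overlapping modules by link-community detection (edges clustered under a
Jaccard similarity and cut at maximum partition density D), annotation-term
enrichment of modules (hypergeometric, p ≤ 0.001), and chance-corrected
functional similarity between two networks' module sets via Cohen's κ.
A perturbation harness removes random fractions of samples and/or probe
sets, rebuilds the network from scratch each time, and reports shared
nodes/edges, lost and new edges, module counts and average best-match κ
against the unperturbed ("global") network. A synthetic generator plants
co-expression modules with known membership so the entire pipeline can be
validated against ground truth.

## Worked example

```python
from rmtnet import (
    build_similarity_matrix, detect_link_communities, extract_network,
    find_threshold, generate_modular_expression, planted_edge_precision_recall,
    topology_summary,
)

em, truth = generate_modular_expression(
    n_genes=600, n_samples=100, n_modules=5, module_size=20,
    loading=0.92, seed=1,
)
sm = build_similarity_matrix(em)                  # all-pairs Pearson (ccm)
res = find_threshold(sm, t_min=0.2)              # RMT threshold scan (rmm)
net = extract_network(sm, res.final_threshold)   # edge list
summary = topology_summary(net)
lcs = detect_link_communities(net)
precision, recall = planted_edge_precision_recall(net, truth)

print(f"RMT threshold : {res.final_threshold}")
print(f"network       : {summary.n_nodes} nodes, {summary.n_edges} edges, "
      f"<k>={summary.avg_degree:.1f}, C={summary.clustering_coefficient:.2f}")
print(f"modules       : {len(lcs.communities)} link communities, "
      f"partition density D={lcs.partition_density:.2f}")
print(f"planted truth : precision={precision:.3f}, recall={recall:.3f}")
```

prints

```
RMT threshold : 0.379
network       : 133 nodes, 968 edges, <k>=14.6, C=0.75
modules       : 23 link communities, partition density D=0.98
planted truth : precision=0.981, recall=1.000
```

The generator planted 5 modules of 20 genes (factor loading 0.92, expected
within-module r = 0.92² ≈ 0.85) among 600 genes; the scan confirmed the
Poisson-to-GOE transition at r = 0.378 and cut the network one step above
it. 981 of every 1000 reported edges are genuinely within a planted module
and every planted pair was recovered; the 23 link communities include the
5 planted near-cliques plus small fragments of noise edges.

The same pipeline is available from a shell:

```bash
rmtnet synth --genes 600 --samples 100 --modules 5 --seed 1 --out demo
rmtnet ccm --ematrix demo.tsv --out demo
rmtnet rmm --similarity demo.rmtb --tmin 0.2 --out demo.scan.tsv
rmtnet extract --similarity demo.rmtb --threshold 0.379 --out demo.edges.tsv
rmtnet robustness --ematrix demo.tsv --annotations demo.ann.tsv \
    --fractions 0.5,1.0 --replicates 10 --seed 1 --tmin 0.2 --out demo_rob/
```

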