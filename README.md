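# hiermap

Hierarchical protein-community mapping and clinical-hotspot scoring.

The package implements a two-stage pipeline:

1. **Supervised hierarchical graph clustering.** Protein sequences are
   embedded into fixed-width feature vectors and combined with a 5-channel
   protein-association edge table (physical evidence, mRNA co-expression,
   protein co-expression, sequence similarity, co-dependence) into an
   affinity graph. A message-passing encoder, trained against flattened
   GO-style labels, scores each edge with a linkage probability and each
   node with a density; per level, each node keeps at most one edge toward a
   higher-density neighbor, connected components of the kept edges become
   clusters, and clusters aggregate (mean + density-peak features,
   mutual-kNN cosine edges) into the next-level graph. Iterating yields a
   multi-level tree of protein systems over gene leaves.
2. **Selective-pressure scoring.** Gene-level signals (mutation counts,
   combined platform z-scores, perturbation or dependency scores) are fit
   with a nonnegative lasso `y = I·w + H·v` along a 500-value λ path, where
   `H` is the binary gene×system membership matrix of the hierarchy. Each
   system's score `S(c)` is the maximum weight fraction it captures along
   the path; significance comes from permuting the rows of `H`
   (empirical p, Benjamini–Hochberg FDR, default cutoff 0.25). Significant
   systems survive a bottom-up pruning pass and export to Cytoscape
   (SIF + node attributes).

The model is implemented in numpy with hand-written backprop; the lasso
path solver is a numba coordinate-descent kernel with KKT certification.
A fully seeded synthetic-data module (planted hierarchies, channelized
graphs, GO-like labels, burden tracks) makes every stage testable offline.

## Layout

| module | contents |
| --- | --- |
| `hiermap.graphio` | FASTA/edge-table/feature-matrix I/O, `LevelGraph`, connected components |
| `hiermap.embedder` | pluggable sequence embedders (hashed offline backend; optional pretrained model) |
| `hiermap.hilander` | label flattening, node splits, the linkage/density model, decode/aggregate, hierarchy inference |
| `hiermap.clustereval` | pairwise F, BCubed F, NMI, hierarchy-level evaluation |
| `hiermap.hisig` | meta-z, membership matrix, nonnegative lasso path, S(c), permutation p, BH, intersections |
| `hiermap.treeops` | `Hierarchy`, ontology TSV I/O, significance-guided pruning, Cytoscape export |
| `hiermap.simulate` | seeded synthetic datasets and burden signal tracks |
| `hiermap.cli` | `hiermap` command-line entry point |

## CLI

All stages chain through one executable; every run takes `--seed` and
writes a `<out>.provenance.json` (config, seed, library versions):

```sh
hiermap simulate --config spec.yaml --seed 1 --out data/
hiermap embed --fasta proteins.fasta --backend hashed --dim 1280 --out features.tsv
hiermap build-graph --edges data/edges.tsv --features data/features.tsv --out graph/
hiermap train --graph graph/ --labels data/labels.tsv --config model.yaml --seed 1 --out model.npz
hiermap infer --graph graph/ --model model.npz --out hierarchy.ont
hiermap eval --hierarchy hierarchy.ont --labels data/labels.tsv --level 1 --out metrics.json
hiermap hisig --hierarchy hierarchy.ont --signal signals.tsv --transform abs \
       --n-lambda 500 --n-perm 10000 --seed 1 --fdr 0.25 --out results.tsv
hiermap intersect --results a.tsv b.tsv --out overlap.tsv
hiermap prune --hierarchy hierarchy.ont --results results.tsv --out pruned.ont
hiermap export --hierarchy pruned.ont --results results.tsv --sif tree.sif --attrs tree_attrs.tsv
```

File formats: edge tables are TSV with columns
`u, v, physical, mrna_coexp, prot_coexp, seq_sim, codep`; feature tables are
`node_id` + float columns; hierarchies are 3-column
`parent, child, relation∈{system,gene}` TSV; signal tracks are
`gene_id, value` TSV.

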