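# phenoarc

Temporal arc mapping of phenotype-to-phenotype connections in a genetic
context.

Large time-resolved perturbation screens — siRNA knockdown studies scoring
cell-division defect morphologies frame by frame, or drug time courses
measuring transcription at fixed intervals — produce, for every gene, one
score per phenotype per time point. The hard question is rarely a single
value; it is *which phenotypes are linked, through which genes, and when*.
`phenoarc` answers it by deriving timed, weighted phenotype connections and
drawing them as arcs between phenotype lanes, alongside the gene networks
that explain them.

It is a library-first reimplementation of an arc-diagram visualization
approach for phenotypic landscapes, aimed at computational biologists who
want the analysis scriptable and its outputs deterministic and testable.

## The model

A dataset is a tensor `v[g, p, t]` of gene-associated scores over genes
*g*, phenotypes *p* and time points *t = 1..n* (0-based in all APIs).

- **Gating.** An event mask keeps `(g, p, t)` iff `lo_p <= v[g,p,t] <= hi_p`
  for per-phenotype inclusive intervals. With no thresholds every observed
  value passes — all phenotypes appear interconnected — so gating for
  outstanding behavior is the first analytic step. Quartile gating sets
  `hi_p = Q1` ("relatively lowly expressed", interval `(-inf, Q1]`) or
  `lo_p = Q3` (`[Q3, +inf)`), with quartiles pooled per phenotype over all
  genes and times using linear interpolation between order statistics.
- **Connections (arcs).** For a lag *x*, phenotypes *p* at *t* and *q* at
  *t + x* are connected by every gene with events at both endpoints; the
  weight is the gene count. Lag-0 connections are undirected; lagged ones
  directed.
- **Transitions.** Per gene, the *prominent* phenotype at each time is the
  arg-max of its (optionally gated) scores. A change of prominence between
  consecutive time points is a directed arc colored by the phenotype
  transitioned *into*; a gap (no passing value) breaks the chain.
- **Lane ordering.** Lanes are permuted to maximize the total connection
  weight between adjacent lanes, via agglomerative chain merging (greedy
  heaviest-junction concatenation, never worse than the input order).
- **Gene networks.** Per time point, genes sharing >= 1 passing phenotype
  are linked with weight = number of shared phenotypes (refused at >= 500
  nodes); genes with *identical* full prominence profiles form synchronous
  cliques; nodes present at every time point are *core*, the rest
  *variable*.
- **Profile analytics.** Succession profiles are one-hot encoded (squared
  Euclidean distance = 2 x Hamming), clustered by k-means (default 4
  classes), projected by 2-component PCA; heat maps are ordered by
  agglomerative clustering (single/average/complete, Euclidean/Manhattan).

All renderings (linear, circular and 3D-perspective arc views, heat maps,
line plots) are built as primitive scenes and serialized to SVG with fixed
formatting: identical inputs give byte-identical files.

## Worked example

Generate a synthetic knockdown screen with two planted transition motifs
(5 genes switching mitotic delay -> polylobed after time 4, 3 genes
switching binuclear -> apoptosis after time 7), then derive and render the
transitions:

```sh
phenoarc fixtures --motif mitotic_delay:polylobed:3:5 \
                  --motif binuclear:apoptosis:6:3 \
                  --genes 24 --seed 1 \
                  --out-dataset screen.txt --out-manifest truth.tsv
phenoarc transitions --dataset screen.txt --out transitions.tsv
cat transitions.tsv
```

```
source	target	t_source	t_target	weight	genes
mitotic_delay	polylobed	3	4	5	g000|g001|g002|g003|g004
binuclear	apoptosis	6	7	3	g005|g006|g007
```

Exactly the two planted arcs come back: a weight-5 arc (five genes whose
prominent phenotype switches from mitotic delay to polylobed between time
points 4 and 5, printed 0-based as 3 -> 4) and a weight-3 arc into
apoptosis. Rendering draws one arc per record — widths 5x and 3x the unit
stroke, colored by the target phenotype:

```sh
phenoarc render --dataset screen.txt --view linear --mode transitions \
                --out arcs.svg --log-level INFO
# INFO:phenoarc:2 arcs drawn
```

The same dataset object is available programmatically:

```python
import phenoarc as pa

ds = pa.parse_dataset(open("screen.txt").read())
profile = pa.derive_prominence(ds)
arcs = pa.derive_transitions(profile)
assert [(r.source, r.target, r.weight) for r in arcs] == [
    ("mitotic_delay", "polylobed", 5),
    ("binuclear", "apoptosis", 3),
]
```

Other subcommands: `gate`, `connect` (lagged co-occurrence with
`--quartile lower|upper`), `order`, `network`, `sync-network`, `cluster`,
`kmeans`, `render --view linear|circular|3d|heatmap|lines`. Any option can
come from a flat `key = value` file via `--config`.

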