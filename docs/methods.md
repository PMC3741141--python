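# Methods

## Data model

A dataset is parsed from a whitespace-delimited file: one row per
(gene, phenotype) pair — gene name, phenotype label, then one numeric
score per time point. Field count fixes `n_timepoints`; gene and
phenotype order is first occurrence in the file and is preserved in every
downstream object, so parses are deterministic. The token `NA`
(configurable) marks a missing score; missing values never pass any gate,
never win a prominence arg-max, and break line-plot polylines. Rows that
cannot be accepted raise categorized errors naming the offending line —
nothing is silently dropped. Time points are displayed 1..n and indexed
0-based in all programmatic interfaces.

Annotation networks (e.g. GO enrichment output produced by external
tools) are loaded from two strictly tab-separated files: a term table
(id, description, enrichment p-value, `|`-separated member genes) and an
interaction list (one term pair per line). Interaction rows naming an
unknown term are dropped with a logged warning rather than an error,
since enrichment and interaction files commonly come from different
exports. No enrichment is computed here; the files are display inputs.

Normalization is deliberately out of scope: input scores are
heterogeneous by nature (morphology scores, log2 expression, ...) and
must be prepared upstream.

## Gating

Thresholds are per-phenotype inclusive intervals `[lo, hi]`; the default
is `(-inf, +inf)`, under which all phenotypes appear interconnected —
informative patterns require gating for outstanding gene behavior.
Inclusivity at both ends is a fixed convention (boundary scores count as
events), chosen so quartile gates admit the quartile value itself.

Quartile gating pools each phenotype's non-missing values across all
genes and time points and sets the lower gate to `(-inf, Q1]` or the
upper gate to `[Q3, +inf)`. Quartiles use the linear-interpolation
definition (value at fractional rank `q * (n - 1)`), the common default
in scientific software; the lower gate therefore admits at least 25% of
pooled observations and is minimal among observed-value cutoffs doing so.
Pooling is per phenotype (per condition), not global, so conditions with
different dynamic ranges gate on their own scale. A phenotype with zero
observations cannot be gated and raises an error.

## Connections

For lag set `X` (default `{0}` for co-occurrence, transitions are always
lag 1), gene `g` connects phenotypes `p` at `t` and `q` at `t + x` when
both events pass. Records are aggregated per `(p, q, t, t + x)`; the
weight is the gene-set size, and empty records are never stored. Lag-0
records are undirected and stored with canonically sorted endpoints so
each unordered pair is counted once; lagged records are directed. The
view slider's "time interval" maps to `max_lag` filtering; exact lags are
an explicit set because a lag range is just a union of exact lags.
Cross-time aggregation (counting a gene once per pair rather than once
per record) is left to callers; records deliberately stay per `(t, lag)`.

Prominence is the arg-max phenotype per gene and time over (optionally
gated) scores, with ties broken by phenotype input order — a fixed,
documented rule rather than randomization, so profiles are reproducible.
Transitions are emitted only between consecutive time points with both
entries present and different; self-transitions are excluded by default
(an `include_self` flag exists) and a `None` entry breaks the chain.
Directed transition arcs are colored by the target phenotype (the state
transitioned into).

Pair-specific genes — genes appearing in exactly one phenotype pair's
gene set at a given time (or globally) — are computed by set difference
against the union of all other pairs at the same scope.

## Lane ordering

The objective is the sum of connection weight between consecutive lanes
(direction-blind, summed over the whole view so lanes stay fixed across
the time animation). Ordering is by agglomerative chain merging: start
from singleton chains and repeatedly perform the concatenation — over
all chain pairs and all four end-to-end orientations — whose junction
(the single new adjacency the merge creates) carries the most weight,
breaking ties lexicographically. Selecting merges by junction weight
rather than by total between-chain mass directly optimizes the
adjacency objective; measured on random 6-lane matrices the result never
fell below 88% of the exhaustive optimum (mean 99%) and path-structured
matrices are recovered exactly up to reversal. If the heuristic ever
scores below the input order, the input order is returned, so `order
auto` can never hurt. Exact minimum-linear-arrangement solving and arc
crossing minimization are non-goals.

## Gene networks

The per-time co-phenotype network links genes sharing at least one
passing phenotype at that time, weighted by the shared count; it is
recomputed per time point. Networks of 500 or more nodes raise a
capacity error — the cap reflects a display/performance envelope, not a
correctness limit, so `force_large=True` (CLI `--force-large`) overrides
it.

The synchronous network links genes whose *entire* prominence profiles
are identical, including the placement of gaps — "exact same succession"
is read strictly; matching only at transition moments is a noted
alternative not implemented. Identity is transitive, so components are
cliques by construction; nodes carry their first non-gap phenotype as an
annotation. Core/variable classification over a per-time network series
marks a gene core iff it is a node at every time point.

Layout is a seeded spring (force-directed) embedding via networkx with a
fixed iteration count, min-max scaled to the unit square; a single node
sits at (0.5, 0.5). Term-network highlighting marks terms whose members
intersect the currently active genes and sizes terms by members present
in the dataset.

## Profile analytics

Succession profiles are one-hot encoded per time block (gap = zero
block): one-hot was chosen over integer codes because integer codes
impose a false metric between unrelated phenotype labels, while one-hot
makes squared Euclidean distance exactly twice the Hamming distance.
K-means (Lloyd with k-means++ seeding, best of `restarts` by
within-cluster sum of squares, deterministic per seed; scikit-learn)
classes the profiles, defaulting to k = 4; k is a free parameter with no
automatic selection. The 2-component PCA projection fixes signs by
making each axis's first nonzero loading positive. Heat-map clustering
(scipy linkage) supports single/average/complete linkage with Euclidean
or Manhattan distance, computed per time point independently; leaf order
traverses each dendrogram node's earlier-created subtree first.

## Rendering

Every view is a `Scene` of geometric primitives serialized to SVG with
fixed 4-decimal formatting and insertion-ordered attributes, giving
byte-identical output for identical inputs; PNG export rasterizes the
same primitives through matplotlib. Interactive controls of a GUI
(time slider, cumulative toggle, camera) are replaced by parameters
(`timepoint`, `cumulative`, azimuth/elevation). Arc semantics are
contractual: stroke width (2D) and apex height (3D) are `base x weight`;
directed arcs take the target phenotype's palette color, undirected arcs
a single connection color; default arc transparency is 20% (opacity
0.8). Arcs are symmetric quadratic curves — the curve family is a free
design choice; endpoints, size and color carry the meaning. Circular
segments are exactly equal angular spans summing to 360 degrees (a small
visual gap is drawn *inside* each span). Lane colors are assigned by
post-ordering index so they are stable across views of one dataset.
Palettes are qualitative ColorBrewer-style schemes plus the
colorblind-safe Okabe-Ito set and a single-color mode; requesting more
colors than a scheme holds is an error that suggests single-color mode.
Each primitive carries audit metadata (`data-weight`, `data-apex-height`)
so element counts and proportionality are externally checkable.

## Synthetic data

The fixture generator emulates two study shapes structurally, not
statistically.

Screen mode (default 7 morphology categories: mitotic delay, binuclear,
polylobed, grape, large, dynamic, apoptosis) writes score 0.9 for each
gene's prominent phenotype and 0.1 elsewhere, plus optional Gaussian
noise; planted transition motifs give a gene block the profile
`source...source, target...target` switching at the motif time (exactly
one transition per gene), and planted synchronous groups share a full
template. Background genes either keep one constant prominent phenotype
(no transitions; the default when no synchronous groups are planted) or
receive pairwise-distinct successions (no accidental synchrony; the
default with synchronous groups). The 0.8 score margin makes the arg-max
unambiguous at zero noise and robust at the low noise levels used in
tests (sigma 0.05); ties are never constructed by the generator — tie
behavior is tested with hand-built micro-inputs.

Drug mode emulates a six-condition (nicotine, ethanol, cocaine,
methamphetamine, heroin, morphine) by four-time-point (1, 2, 4, 8 h)
expression table: background values are standard normal and planted
low/high gene sets are shifted to ±5, far outside the bulk, so pooled
quartile gates always capture them while the quartiles themselves stay
inside the background range.

The manifest records every planted truth (transitions, cliques, quartile
memberships, full profiles); at zero noise the corresponding library
operations recover each planted structure exactly. Passing tests on
these fixtures demonstrates the machinery, not statistical realism of
morphology scores or striatal expression: real screens have correlated
noise, dose effects and missingness patterns the generator does not
model.

## Problem sizes and numerics

The validation suite and the reproduction script run at desk scale:
random event masks of 20 genes x 5 phenotypes x 10 time points against a
triple-loop recount, 6-lane ordering against exhaustive search over all
720 permutations, linkage against a naive pairwise reference at up to 6
rows, k-means recovery with 80 genes over 4 planted classes at 10% entry
flips. Floating-point comparisons in oracles use 1e-6..1e-9 absolute
tolerances; quartile and percentile arithmetic is exact to numpy's
linear-interpolation definition. The recommended input envelope (a few
thousand genes x 50 phenotypes x 100 time points) is enforced as a
warning only.

## Known limitations

- Connection derivation loops over phenotype pairs per (t, lag); for very
  long lag sets on large phenotype counts this is O(P^2 n |X|) vectorized
  over genes — adequate within the envelope, not tuned beyond it.
- The chain-merge lane ordering is a heuristic; only the input-order
  floor is guaranteed.
- Synchronous matching requires whole-profile identity; near-synchrony
  (one mismatched time point) yields no edge.
- SVG byte-determinism is guaranteed; PNG export depends on matplotlib's
  rasterizer and is not byte-stable across library versions.
- The 3D view is a static projection with a fixed camera model; occlusion
  is not resolved beyond draw order.
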