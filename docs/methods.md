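# Methods

## The model

The object of study is an undirected, unweighted bipartite graph: plant
species on one side, bioactive metabolites on the other, an edge wherever a
database records that the species contains the compound. No edge weights are
used — the prioritization is purely topological. The working hypothesis is
that plants carrying many validated metabolites, in central network
positions, are strong candidates for the corresponding bioactivity even
without direct experimental evidence.

Node identity is namespaced by partition (`plant:<name>`, `met:<ID>`), so a
token appearing in both columns can never merge the partitions. Plant names
are normalized for identity (whitespace collapsed, case-folded) with the
first-seen display form retained; how a real database merges taxonomic
synonyms is outside our control, so this normalization is a stated
convention of the package, not a property of any source database. Metabolite
IDs must match `C` + 8 digits; malformed rows fail the run in strict mode
and are dropped with a logged warning in the default lenient mode (exports
commonly carry footnote rows).

## The eight measures

All measures are computed on the full bipartite graph; restriction to plant
nodes happens only when the top-k lists are cut. Definitions, for unweighted
hop distance $d$, shortest-path counts $\sigma$, component $C$ with size
$n_C$ and diameter $\Delta_C$:

- **degree** — incident edge count;
- **betweenness** — $\sum_{\{s,t\},\, s \ne v \ne t} \sigma_{st}(v)/\sigma_{st}$,
  unnormalized over unordered pairs (normalization is rank-invariant and
  only ranks are consumed downstream);
- **stress** — $\sum_{\{s,t\}} \sigma_{st}(v)$, the raw path count;
- **closeness** — harmonic form $\sum_{w \ne v} 1/d(v,w)$ by default, since
  the real network is fragmented and classical closeness is undefined
  across components; a config flag selects the classical within-component
  form $(n_C - 1)/\sum_w d(v,w)$;
- **eccentricity** — $\max_w d(v,w)$ within the component, 0 for isolated
  nodes. Whether small eccentricity should rank as *more* central is
  genuinely ambiguous in the field's tooling; the default treats smaller as
  more central and a flag flips it;
- **radiality** — $\sum_{w \in C, w \ne v} (\Delta_C + 1 - d(v,w))/(n_C-1)$,
  computed per component (singletons score 0);
- **bottleneck** — for every root $s$, build a deterministic BFS
  shortest-path tree (each node's parent is its lexicographically smallest
  neighbor one hop closer to the root — the underlying definition depends
  on an arbitrary tree, so we pin it); $v$ earns one point per root whose
  tree routes more than $n_C/4$ of its nodes' root-paths through $v$;
- **EPC** — over $K$ seeded Monte-Carlo realizations, retain each edge
  independently with probability $p$ and average the number of nodes still
  connected to $v$. Defaults $K = 1000$, $p = 0.5$; the seed is mandatory
  (no silent default). Per-edge independent removal is pinned by config;
  each realization draws one uniform per edge regardless of $p$, so equal
  seeds give common random numbers and the score is monotone in $p$.

Pairs in different components contribute nothing to betweenness, stress or
closeness; all scores are finite on any input.

### Numerical implementation

Distances, path counts and Brandes-style dependency accumulations are
computed level-synchronously for all sources at once, as sparse-by-dense
matrix products per BFS level. Graphs up to 2048 nodes run in float64;
larger graphs switch to float32, where only ranks are consumed and the
products are several-fold faster. Exactness guarantees (integer measures
exact; betweenness/closeness/radiality to 1e−9 against a brute-force
path-enumeration oracle) are asserted on graphs of up to a dozen nodes,
squarely in the float64 regime. Stress totals are rounded to the nearest
integer to remove accumulation noise. A full eight-measure pass on the
study-scale network (~3.9k nodes, ~5.4k edges) takes roughly 15–20 s on one
CPU.

## Ranking and selection

Each measure yields a ranked list of the top $k$ plant nodes (default
$k = 100$); metabolite nodes are excluded *before* truncation, the only
reading under which eight lists of 100 plants arise. Ties at the boundary
are broken lexicographically by node id by default (fixed list length); an
`include_ties` policy may exceed $k$. A plant's replication count is the
number of lists containing it; plants with replication ≥ cutoff (default 5)
become candidates, ordered by count then id. Candidates missing from the
annotation table default to `novel` — absence of literature evidence is
precisely what makes a candidate new — with a logged notice. Validation
percentages are rounded half-up to two decimals.

## The synthetic generator

The generator emulates the documented features of the real database export:
a bipartite network of about 3250 plants and 650 metabolites with ~5392
associations, metabolite degrees heavy-tailed up to 244, and the bulk of
nodes below degree ten. Metabolite degrees are drawn from a discrete power
law on $[1, 244]$ with exponent 1.7 — chosen analytically so the truncated
mean (~8.5) matches the target mean degree (5392/650 ≈ 8.3) — then nudged
under the run seed so the degree total hits the edge budget exactly. Plant
endpoints are dealt from a shuffled slot pool that covers every plant at
least once (every species in the real table carries at least one
metabolite); duplicates within a metabolite are resolved by rejection
sampling with a bounded retry budget, and infeasible configurations are
rejected before sampling. Plants therefore acquire degree passively
(roughly 1 + thinned-Poisson), consistent with hubs being metabolites on
the compound side while even the best-endowed plants carry tens, not
hundreds, of compounds.

Planted hubs: 5 plants are each wired to the 50 most common metabolites.
The count sits within the 6–61 metabolite range observed for real top-ranked
species and is several times the 95th percentile of the background plant
degree; tying the hubs to the *highest-frequency* compounds mirrors the
empirical pattern that top-ranked plants share the common bioactive
metabolites rather than rare ones (wiring to a random metabolite subset
instead leaves "hubs" that are locally busy but globally peripheral, since
most metabolites in the heavy tail occur in only one or two species). Annotations are independent Bernoulli draws
(default known fraction 0.85, mirroring the literature-validated share in
real rankings), with planted hubs' statuses optionally forced.

What passing tests on these inputs shows — and does not. The generator
reproduces scale, degree shape and partition structure, so planted-hub
recovery demonstrates that the scoring and aggregation stages surface
metabolite-rich plants as intended. It does not reproduce taxonomic
correlation between related species, curation biases, or the identity of
real compounds; agreement with any real ranking must be established on real
exports.

## Reproducibility

Every stochastic step (generation, annotation sampling, EPC) takes an
explicit seed; the pipeline writes a manifest with the configuration,
package version and SHA-256 of every input and output, and a rerun with
identical inputs and seed reproduces each artifact byte for byte.
Serialization order is canonical throughout (plants then metabolites, each
lexicographic).

## Assay arithmetic

`cell_viability` and `geac` are exact formula evaluations with guarded
denominators. `ic50_linear` fits response on concentration by ordinary
least squares — a straight line, not a four-parameter logistic, matching
how such IC50s are commonly read off — and returns the 50% crossing only if
it falls inside the observed concentration range; flat fits and
extrapolation are refused as non-estimable. The DPPH absorbance-to-RSA
conversion and peroxidase unit chemistry are out of scope: only the
downstream closed-form arithmetic is implemented.

## Known limitations

- Three further hub-detection measures that the field's desktop tooling
  offers are deliberately not implemented; the eight above are the
  prioritization surface.
- The replication aggregate treats the eight measures as equally credible
  votes; no weighting or rank-fusion alternative is provided.
- Eccentricity's orientation rewards nodes in small fragments (a two-node
  component has eccentricity 1); with the default smaller-is-central
  orientation its top list is dominated by fragment nodes, which is one
  reason even strongly planted hubs typically replicate 7 of 8.
- Annotation is user-supplied; no literature mining is attempted.
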