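# Methods

This note documents the models and procedures implemented in `obnet`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Random walk with restart

The reference interactome is undirected and unweighted for propagation
purposes: edge confidences (e.g. STRING combined scores) act only as an
inclusive ingestion cut (`read_edge_list(min_confidence=...)`), after
which every interaction counts 1.  The adjacency matrix is normalized
column-wise, so each non-isolated column is a probability distribution
over neighbours, and the walk

    P_{t+1} = (1 − r) A' P_t + r P_0

is iterated to its fixed point.  Parameters:

* `r = 0.5` (restart probability) — the walk stays local, about half the
  stationary mass within one hop of the seeds;
* convergence: L1 norm of successive iterates < `tol = 1e-6` (the L1
  metric is a choice; any p-norm gives the same fixed point);
* `max_iter = 10000` is a safety valve — with `r = 0.5` the iteration
  contracts by factor 0.5 per step and converges in ~20 iterations;
* isolated nodes have all-zero columns that leak probability mass; the
  converged vector is renormalized to sum 1 (rank order unaffected) and
  the leak logged.
* seeds absent from the network are dropped with a warning; it is an
  error only if none remain.

Ties in probability (symmetric positions, disconnected components) are
broken lexicographically everywhere a ranking is produced, which makes
every downstream output reproducible to the byte.  The permutation null
runs its hundred walks as one block power iteration (`rwr_batch`) on the
shared transition matrix; the scalar solver is retained and tested
against a direct linear solve of `(I − (1−r)A')p = rP_0`.

## Functional modules

Gene sets with 500 or more genes are skipped (strict bound): very large
processes blur into the whole network and carry no modular information.
A module's *core* is the set's intersection with the network; expansion
seeds an RWR at the core **on the whole reference network** — expansion
must reach genes outside the core — and admits non-core genes in walk
order until `min(5·|core|, 500)` genes.  The 5x target counts mapped
core genes, not raw set size, since off-network genes cannot
participate.  Expansion is monotone and idempotent by construction.
"Whole-network" scoring treats the entire interactome as a single,
never-expanded module.

## The reachability statistic

Both directions of the score rank a module's genes by walk probability
(one direction seeded at the disease genes, scoring the trait genes as
targets; the mirror direction swaps the roles) and take the peak of a
running enrichment sum over the ranked list.  `ES_β = β·ES₁ + (1−β)·ES₂`
with `β = 0.1`, weighting the trait-seeded direction 9:1.

Two increment conventions are implemented:

* **balanced (default)**: `+1/G` per target hit, `−1/(N−G)` per miss —
  the classic zero-sum running statistic of gene-set enrichment
  analysis.  Its peak measures how strongly targets concentrate at the
  top of the ranking.
* **per-step-rescaled** (`classic_increments=False`,
  `running_sum_es`): `+(N−G)/G` per hit, `−G/(N−G)` per miss.  This
  variant is not zero-sum — a full traversal ends at `(N−G) − G` — so
  for `G < N/2` the running sum drifts upward and its maximum reduces to
  the endpoint plus the miss decrement times the distance of the *last*
  target from the end of the list.  A statistic of the worst-ranked
  target is insensitive to top-of-list enrichment and has a strongly
  skewed null; benchmarks in this package showed it ranks planted
  diseases substantially worse (expanded-module AUC 0.69–0.96 across
  generator seeds versus 0.95–1.0 for the balanced form).  It is kept as
  an explicit option because the two forms differ only by per-direction
  rescaling and some published descriptions print this variant.

**Seed handling.** Seed genes stay in the traversal
(`include_seeds=True` default).  This is deliberate: the permutation
null below redraws the trait set, and if seeds were removed from the
ranked list, the observed statistic would remove the trait's
well-connected genes from the top of the list while every permutation
removed random ones — a degree artifact that swamps the signal (in
benchmarks it inverted rankings outright).  With seeds kept, the list's
composition is identical for the observed score and every permutation,
and only seeding and target placement vary.  `include_seeds=False` is
available for comparison; when seed-exclusion would empty a direction's
target set (seed set = target set), that direction falls back to keeping
the seeds so the score stays defined.

## Permutation significance

The null redraws the trait's in-module gene set uniformly without
replacement, `n_perm = 100` times by default.  The draw is stratified to
preserve the observed overlap with the disease seeds: shared genes sit
at the top of both ranked lists, so a null that redraws the overlap
freely is not exchangeable with the observed configuration (unstratified
draws produced systematic anti-conservative scores for disjoint gene
pairs).

The observed score is standardised to `z = (ES_β − mean_null)/sd_null`.
Two p-values are offered:

* `p_method="empirical"` (default): the add-one empirical upper tail
  `(r+1)/(n_perm+1)`.  This is calibrated for any null shape — the null
  of a running-sum *peak* is right-skewed, being a maximum — at the cost
  of a resolution floor of `1/(n_perm+1)`.
* `p_method="normal"`: the one-sided upper-tail normal probability of
  `z`.  This extrapolates far below the empirical floor (useful when
  rankings must distinguish p = 1e-30 from 1e-6) but is measurably
  anti-conservative in the tail: on a no-signal fixture about 4% of null
  p-values fall below 0.01.  Use it for ranking resolution, not for
  error-rate control.

If the null is degenerate (sd = 0), p is 1 when the observed score does
not exceed the null mean and the smallest positive float otherwise, with
a log record.

Per disease, module p-values are BH-adjusted (within-disease by default;
`adjust="bh_global"` pools all disease x module tests) and the disease's
score is the minimum adjusted p, with ties broken by module and disease
identifiers.

## Baselines

The shortest-path method averages unweighted BFS hop counts over all
(disease gene, trait gene) pairs inside the module, excluding
cross-component pairs from the mean (an infinite-contaminated mean would
make every module with one disconnected gene worst); the number of
finite pairs is recorded for audit.  Genes in both sets contribute
distance-0 self-pairs (a switch drops them).  Diseases are ranked by the
minimum mean distance across modules.  The overlap method is the plain
Jaccard coefficient on the raw gene sets.  The gold-list builder applies
the same Jaccard to pre-counted literature abstract identifiers with an
inclusive 0.004 threshold plus curated additions; live literature
querying is out of scope, counts arrive as a file.

## Key connector analysis

Dynamic neighbourhood search on the subnetwork within `L = 2` hops of
the target set: for each gene `g` and layer `h = 1, 2` the genes within
`h` hops of `g` (excluding `g`) are tested for enrichment in the target
set by a one-sided hypergeometric upper tail, with the subnetwork minus
`g` as population; `g` never counts as its own success (self-membership
is not connecting).  The per-gene p is the minimum over layers —
monotone in `H` — then Bonferroni-corrected over genes tested; corrected
p ≤ 0.05 marks a key connector.

## Evaluation

ROC/AUC against a gold trait list uses the ranking score as decision
statistic (ascending for p-values and distances, descending for
similarities).  Ties earn 0.5 per tied positive-negative pair (rank-sum
convention, pinned against a Mann-Whitney oracle).  Gold diseases
missing from a ranking enter at the worst score by default (dropping
them is a switch — the choice moves the AUC, so it is explicit), and an
optional disease `universe` pads *all* unranked diseases at the worst
score so that methods with different eligibility coverage are compared
on the same denominator.  A blocklist can exclude self-referential
traits of the query itself.

## Expression validation

MDC for a module is the ratio of mean pairwise connectivity — |Pearson
r|, optionally soft-thresholded as |r|^power with power 1 by default —
between two sample conditions; swapping conditions inverts it exactly.
Significance shuffles the condition labels over samples; the empirical
two-sided p works on |log MDC| (the scale on which the swap symmetry is
a sign flip) with add-one correction, BH across modules.  Pairwise
module overlaps use one-sided Fisher exact tests on the shared-gene
2x2 table over a configurable gene universe (default: the union of both
collections), BH across all pairs.  The permutation study shuffles the
second collection's gene labels preserving every module's size (a
partition shuffle when the collection is disjoint, independent
per-module redraws otherwise), reapplies the caller's top-k selector,
counts first-collection modules with any significant overlap, and
converts the observed count to an upper-tail normal p against the
permutation mean and standard deviation (ddof = 1).

## Synthetic benchmarks

The generator emulates the study's data shapes: a 1000-gene
stochastic-block network (5 blocks, within-block edge probability 0.04,
between 0.004 — modular topology keeps "functional modules"
non-vacuous), 8 gene sets of 80–120 genes anchored 80/20 to blocks, a
40-gene query trait drawn from two "home" sets, and 18 diseases of 60
genes each, 6 of them planted.  Gene-set sizes are small relative to
the network so that five-fold expansion stays well below the network
size, as pathway sets do against a real interactome.  Each planted
disease draws a `proximity_effect` fraction of its genes through 1–2
step walks from random trait genes, restricted to the 2-hop
neighbourhood intersected with the home sets; sampling through short
walks concentrates planted genes on direct interaction partners, which
is the locality the restart walk detects (a uniform draw over the whole
2-hop set is nearly uniform over a dense community and carries no
signal).  Background diseases draw uniformly.  Expression fixtures use
a per-module equicorrelated factor model: `x = sqrt(ρ)·f +
sqrt(1−ρ)·ε` gives every in-module pair correlation ρ per condition.

What the benchmarks do **not** emulate: real interactome degree
distributions (no hubs beyond what the block model produces), gene-set
overlap structure (GO term nesting), literal shared risk genes between
trait and planted diseases — planted genes are interaction partners,
never the trait genes themselves, so the overlap baseline is blind to
the planted signal by construction — and realistic network scale.  On
1000 genes the whole-network variant performs as well as the expanded
one because the planted neighbourhood is a large fraction of the graph;
on a full-size interactome modular restriction matters more.  Passing
tests therefore establish correctness and internal statistical
behaviour of the implementations, not field performance on real
catalogues.

## Problem sizes

The test suite runs the full pipeline on 20 generator seeds (18 diseases
by 8 modules, 100 permutations each), the calibration study on 500
replicates of the permutation test, the key-connector recovery on 100
fixture draws, and the oracle equivalences on dozens of random graphs up
to 200 nodes; the acceptance script uses one benchmark seed with the
same per-run sizes.  These sizes give stable Monte-Carlo estimates for
every property asserted while keeping a complete run in the order of a
minute or two on one CPU.
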