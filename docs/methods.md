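# Methods

`biogeodiv` reimplements, as one tested pipeline, the four analyses that
together characterize the historical biogeography and diversification of a
small temperate plant clade: ancestral-range estimation under the
Dispersal-Extinction-Cladogenesis (DEC) model averaged over a posterior
tree sample, rate-shift diversification model selection, Faith's
phylogenetic diversity (PD) with a randomization null, and
statistical-parsimony haplotype networks with coalescent-rule loop
resolution. This note records the models, the defaults that matter, the
numerical choices, and what the synthetic data do and do not establish.

## Time trees

Every stage consumes rooted ultrametric chronograms with branch lengths in
Myr. Ultrametricity is checked to a tolerance of `1e-6 × root age`;
violations warn on input and only become errors where the downstream
mathematics requires an ultrametric tree (branching times). Branch lengths
are treated as absolute time throughout; no rate rescaling is applied.
Polytomies are accepted on input, but DEC and the diversification
likelihoods need binary trees, so a seeded random resolution with
zero-length branches is available as an explicit opt-in
(`treeio.resolve_polytomies`); the default is a clear error. Clades are
identified across trees by their member-taxon set (MRCA), never by node
index, and the fraction of trees in which a clade is absent or
non-monophyletic is always reported.

## DEC ancestral ranges

**State space.** Ranges are subsets of an ordered area alphabet,
constrained to at most `max_range_size` areas (default 2) and to sets that
are connected under a user-supplied adjacency relation. The empty range
(global extinction) is part of the state space and is absorbing. Adjacency
is mandatory configuration: the study system this emulates names only two
adjacent pairs explicitly, and a complete matrix cannot be inferred, so
the shipped 8-area example (`examples/adjacency_8area.tsv`) encodes
exactly the stated pairs (D–F, E–G) plus D–E, without which the
two-area Mediterranean range reported for several nodes would not be
representable.

**Anagenesis.** Along a branch of length `t` the range evolves by a
continuous-time Markov chain: expansion `R → R ∪ {a}` at rate `d·|R|`
whenever the target is an allowed state, and local extinction
`R → R ∖ {a}` at rate `e` per occupied area. Transition matrices are
`exp(Qt)` via SciPy's scaling-and-squaring Padé implementation.

**Cladogenesis.** A singleton ancestor passes its range to both daughters
(sympatry). A two-or-more-area ancestor splits by subset sympatry
(`{a}|R`, `R|{a}`) or vicariance (`{a}|R∖{a}` and mirror, when the
complement is allowed), all scenarios weighted equally — the canonical
DEC scenario set. The empty ancestor splits `∅|∅` with probability one,
which lets extinct lineages enter the likelihood as empty-range tip
observations (used by the simulation-based validation below; real data
normally contain only survivors). Root states are weighted uniformly over
allowed non-empty ranges; the weighting is recorded in every output
because other conventions exist.

**Likelihood, fitting, node scenarios.** Conditional likelihoods are
computed by postorder pruning with per-node rescaling. `(d, e)` are
maximized by bounded L-BFGS-B on log-parameters in `[1e-9, 10]` per Myr
with three seeded restarts; non-convergence and active bounds are flagged
on the results object, not raised. Scenario probabilities at a node are
exact clamped-likelihood ratios: an outside (preorder) pass gives the
probability of the rest of the tree for each ancestral state, and each
scenario's share of the total likelihood is reported, summing to one.

**Multi-tree summarization.** The DEC analysis runs over a posterior tree
sample; per clade, scenario probabilities are averaged over the trees
where the clade exists (absent trees contribute nothing — the analysis is
deliberately conditional on the clade, mirroring the practice of
reporting only well-supported nodes). Descendant-specific ranges are
reported only when the same top split pattern recurs in at least a
configurable fraction of trees (default 0.95; the source analysis states
no number). Otherwise split patterns are grouped by their ancestral range
— the union of the two descendant ranges — and grouped mean
probabilities are reported for the node alone. Grouping is linear, so it
commutes with averaging and conserves probability mass; both properties
are asserted in tests. Rate handling is per-tree ML by default, with a
fixed-rates mode (fit once on a summary tree) for large posteriors; the
mode is recorded in the output metadata.

## Diversification

**Likelihood family.** All diversification models share one unconditioned
branching-time likelihood so their AICs are comparable. For a
piecewise-constant speciation rate λ(·),

    logL = Σ_events log λ(t_i) − ∫ N(t) λ(t) dt,

with ages `t` measured before present, every internal node (crown
included) an event, and `N(t)` the lineage count. A retained stem branch
adds exposure with `N = 1` and no event; stems are included by default
because ignoring the branch subtending the crown distorts early-rate
estimates. No survival conditioning is applied; this shifts all logL by a
data-dependent constant family-wise and is recorded in the fit metadata.

Models: `yule1` (one rate, closed-form λ̂ = events / lineage-time),
`yule2`/`yule3` (two/three rates; shift times searched over the observed
branching times, rates closed-form per segment — discrete search chosen
for determinism; an event exactly at a shift belongs to the younger
segment), and `bd` (constant-rate birth-death in (net rate r, extinction
fraction a) with a ∈ [0, 1)). The birth-death density uses the
reconstructed-process term p₁(t) = (1−a)² e^(−rt) / (1 − a e^(−rt))²,
the probability that a lineage of age t leaves exactly one extant
descendant; at a = 0 the bd likelihood equals `yule1` exactly, which the
tests assert, and p₁ is validated against a forward birth-death
Monte-Carlo oracle.

**Model selection.** Per tree, the best model has the lowest AIC, but a
model may only beat every model with fewer parameters if each of them
trails by more than ΔAIC (default 4); ties go to the simpler model.
Selections are tallied per model and per category (constant: yule1, bd;
variable: yule2, yule3), and one-dimensional two-level chi-square
goodness-of-fit tests (equal expectations by default) are run on the
tallies. Note: the source analysis prints "U" statistics for these tests
that do not match the equal-expectation chi-square closed form for its
printed counts (e.g. 4003 vs 2497 gives χ² ≈ 348.9, not 359.5); the
statistic actually used there is unrecoverable, so this package computes
and documents the stated chi-square GOF without attempting to match U.

**False-shift behavior.** With ~n discrete shift candidates, each needing
a log-likelihood gain above 4 to clear the ΔAIC rule, the probability
that a constant-rate tree of 50 tips is assigned a shift model is about
1 − (1 − P(χ²₁ > 8))⁴⁸ ≈ 0.2, and measured rates across seed blocks are
0.18–0.25. This is a property of the discrete-candidate ΔAIC procedure
itself, not an implementation artifact; the control test asserts the
20% bound under its fixed seeds.

**LTT.** Lineage-through-time curves are step functions from (crown age,
2) to (0, n), exported long-form (natural-log counts) and plottable as an
ensemble.

## Faith's PD

PD of a tip set is the branch-length sum of the minimal spanning subtree,
including the MRCA-to-root path by default (the common convention; the
flag is stored on every result because the source does not state it).
Significance per region is two-tailed at α = 0.05 against a null of
uniformly random tip sets of the region's size, drawn across the
posterior sample (replicate i uses posterior tree i mod m); the observed
value is computed on the summary tree. Verdicts compare the observation
with the empirical 2.5%/97.5% null quantiles, and the empirical
two-tailed p-value (add-one smoothed) is reported alongside. Because the
PD null is discrete, quantile verdicts are mildly conservative for small
fixed set sizes (~3% rejection at size 5 on an 18-tip tree); across
mixed region sizes 3–12 the type-I rate is 4–5%.

## Haplotype networks

**Collapsing.** Gaps and Ns are missing data; two samples share a
haplotype iff they agree wherever both are resolved. That relation is not
transitive, so samples are assigned in input order to the earliest class
whose accumulated consensus they match; multi-class compatibilities are
counted and logged. Multi-locus data are concatenated only for samples
sequenced at every locus.

**Connection limit.** The 95% statistical-parsimony limit is the largest
step count j whose no-homoplasy probability exceeds 0.95, estimated as
P_j = Π_{i=1..j} (1 − 3(i−1)/(4m)) over m sites: the i-th change lands on
a previously hit site with probability (i−1)/m, and under equal-rate
substitution three quarters of such collisions break parsimony. P₁ = 1,
so the limit is at least one step and non-decreasing in alignment length;
it yields the familiar limits of statistical-parsimony software (≈9 steps
at 600 bp, ≈17 at 2.2 kb). A fixed integer override is available.

**Construction and loop resolution.** Haplotype pairs are linked in
ascending step distance; a pair is skipped when an equally short path
already exists, links longer than one step insert unsampled intermediate
nodes (frequency 0), and nothing beyond the limit is connected.
Equal-length alternatives close cycles, which are resolved by removing
one edge per cycle under ranked coalescent predictions: keep edges
incident to higher-frequency haplotypes, then to interior (degree ≥ 2)
haplotypes, then to same-region pairs; residual ties remove the edge
latest in id order and are flagged. Surviving cycle edges are marked
"dashed". Removing a cycle edge never disconnects a component.

**Classification and statistics.** Sampled haplotypes with degree ≥ 2
(edges to intermediates count) are interior, degree ≤ 1 are tips. A
haplotype is "ambiguous" when its class flips under any alternative
single-edge resolution of a recorded cycle — an operational criterion,
configurable in effect because it derives from the resolution log. Class
statistics include mean samples per haplotype, and both the singleton
fraction and the singleton/non-singleton ratio (the source text is
ambiguous between the two, so both are emitted, neither privileged), plus
a chi-square test of interior vs tip sample totals and per-region
haplotype counts with exclusivity. The outgroup connector reports the
nearest ingroup haplotype(s) and steps − 1 needed intermediates, listing
all ties.

## Synthetic data

The generators are pure functions of a frozen `SimConfig` (seed
included); identical configs give bit-identical files. Defaults mirror
the emulated study: 18 tips, crown age 14 Myr, stem 4 Myr, a
diversification-rate increase 0.04 → 0.29 /lineage/Myr at 7.82 Mya, five
areas in a chain adjacency with DEC rates d = 0.2, e = 0.05 /Myr from a
single-area ancestor, 1000 posterior replicates, and three loci of
800/950/1100 sites collapsing to ~20–25 haplotypes in two star-like
groups plus a relict chain, with an outgroup 17 steps away.

Trees: piecewise pure-birth forward simulation over a fixed crown age,
rejected until exactly `n_tips` survive (absolute shift ages require the
fixed span); constant-rate configs may instead set `crown_age=None` to
stop at the n-th birth (plus one unexecuted waiting time), making the
crown age random with mean (1/λ) Σ_{k=2..n} 1/k — the oracle used in
tests. Posterior variation is emulated by multiplicative lognormal
node-age jitter (sd 0.05), clamped to preserve parent–child order and
ultrametricity; this reproduces tree-to-tree variability but not real
posterior correlation structure or topological uncertainty, so multi-tree
summaries over jittered replicates exercise the bookkeeping, not
topology-driven incongruence. Ranges evolve by exact Gillespie simulation
of the DEC chain with uniform scenario draws at nodes; extinct lineages
are reported with empty ranges. Haplotype truth is constructed (each
mutational step consumes a fresh site — no homoplasy), so network
recovery tests demonstrate correctness of the algorithms, not robustness
to homoplasy; gap injection (2% default) adds the missing-data ambiguity
seen in real alignments.

What passing tests therefore show: the likelihoods match independent
discretized-propagator and Monte-Carlo oracles; estimators recover known
simulated parameters at realistic scales; the pipeline's bookkeeping
(grouping, classification, calibration) is exact. What they do not show:
robustness to model misspecification (relaxed clocks, founder events,
homoplasy, recombination), which no synthetic default here generates.

## Numerical choices and limitations

- Matrix exponentials: SciPy Padé scaling-and-squaring; likelihood
  vectors rescaled per node to avoid underflow (50-tip trees validated).
- Optimizers: L-BFGS-B on log rates (DEC) and on (r, a) (bd), multiple
  deterministic-seeded starts; flat likelihoods near zero dispersal can
  stop short of the bound (estimates below ~1e-4 should be read as zero).
- Ties are broken deterministically everywhere (lexicographic ranges,
  id-sorted edges, simpler models) and flagged where scientifically
  meaningful.
- The DEC implementation is plain DEC: no founder-event (+J) speciation,
  no time-stratified dispersal, no Bayesian range estimation.
- Real-data quantities that depend on the original sequence data (e.g.
  observed regional PD values, the exact 24-haplotype table) are outside
  what synthetic runs can reproduce; the pipeline reproduces the
  procedures and their printed worked examples.
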