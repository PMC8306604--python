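# Methods

This note documents the models and procedures implemented in
`phylogeo_gec`, the assumptions they make, the defaults they ship with,
and the choices taken where the design was genuinely open.

## Problem setting

The package post-processes a posterior sample of rooted, time-calibrated
trees (for example BEAST output) whose tips are samples assigned to
discrete geographic regions — by default Australia (AUS), New Guinea (PAP),
and Wallacea (WLC).  It answers three questions: *when* did regionally
endemic maternal lineages arise (TMRCA clustering of geographically
exclusive clades), *which* migration structures are supported (Bayes-factor
comparison of constrained rate matrices), and *when* did migration events
happen on the tree (stochastic mapping with a branch-length correction).

All times are years before present (yBP), measured up from the youngest
tip; dated (ancient) tips are offset by their own age.  Branch lengths are
in years and migration rates in transitions per lineage per year.

## Tree handling and the MCC consensus

Parsing and serialisation are delegated to dendropy, which resolves NEXUS
translate blocks and tolerates bracketed `[&...]` metadata comments; trees
are converted to an array-backed `TimedTree`.  Ultrametricity is checked at
a relative tolerance of 1e-6 of the root age: violations warn on general
trees and raise only when an operation requires a clock tree.  Reading a
tree set accepts an optional burn-in (count or fraction) and defaults to 0,
assuming the input is already post burn-in.

The maximum clade credibility (MCC) tree is the posterior sample
maximising the sum of log clade frequencies (ties broken by file order,
earliest first, and logged).  Node heights follow the common-ancestor
rule: each internal node's age is replaced by the mean, over all posterior
trees, of the age of the MRCA of that node's tip set.  Mean MRCA heights
can be non-monotone along a path, exactly as in other common-ancestor
implementations; the resulting negative branch lengths are clamped to zero
(the child is pulled up to its parent's age) and a warning is emitted.

## Geographically exclusive clades (GECs)

A GEC is a monophyletic group of at least two tips all mapped to one
region.  Per posterior tree, the maximal region-pure clades are the pure
internal nodes whose parent subtree is no longer pure; maximal clades are
pairwise disjoint by construction.  Clade identity across trees is
tip-label-set equality — the only tree-independent definition available —
and a tree "contains" a clade when that exact set is monophyletic there,
whether or not it is maximal in that tree.  Candidates pooled across trees
are retained when their support (fraction of trees containing them)
exceeds the threshold, default 0.5; their TMRCA samples are the MRCA ages
in exactly the trees containing them, so sample count = support x tree
count identically.

Strict majority support almost guarantees retained clades are disjoint,
but disjointness is enforced rather than assumed: overlapping survivors
(possible with nested candidates at generalised thresholds) are resolved
by higher support, then larger size, then older median TMRCA, then
lexicographic key — a deterministic rule favouring better-supported,
larger matrilines.

## Equal-mass TMRCA densities

Clades carry unequal numbers of TMRCA samples, so raw pooling would weight
well-supported clades more.  Instead each clade gets its own Gaussian KDE,
with bandwidth from the `nrd0` rule of thumb,
0.9 min(SD, IQR/1.34) n^(-1/5); clades with fewer than three samples or
zero spread fall back to a floor bandwidth of 100 years so no clade
degenerates to a point mass.  Curves are evaluated on a shared grid of 512
points from 0 to 1.1x the oldest sample, truncated at age 0 (ages cannot
be negative), renormalised to unit mass, and averaged with equal weight —
each clade contributes exactly 1/(number of clades) of the aggregate.
Per-clade normalisation (rather than one global rescaling) is the reading
under which equal contribution actually holds.  Percentiles invert the
equal-weight CDF by linear interpolation on the grid.  Clade-size versus
median-TMRCA relationships are summarised by ordinary least squares,
linear and quadratic.

## Migration models and model comparison

Regions evolve as a continuous-time Markov chain with generator Q.  A
model is a constraint pattern over the six ordered region pairs — each
rate free, zero, or tied to a named group — so the parameter count is
(number of free pairs) + (number of tie groups).  Five models ship
bundled: the saturated six-rate model, the one-rate null, and three
restricted structures: `m4` (WLC>AUS, WLC>PAP, PAP>WLC free, all else
zero), `m9` (as m4 with the two New Guinea-Wallacea rates tied, two
parameters), and `m12` (WLC<->PAP and AUS<->PAP moves, no
Wallacea-Australia exchange).  Whether m12's AUS<->PAP rates should be
tied was not determinable from its verbal description; the
less-constrained reading (free, four parameters) was adopted.  A small
constraint mapping (`{"AUS>PAP": "free" | "zero" | "tie:g"}`, YAML/JSON
in the CLI) lets users define any other pattern.

Likelihoods use Felsenstein pruning with per-branch transition matrices
exp(Qt), computed by eigendecomposition vectorised over branches (with a
scaling-and-squaring fallback when the eigenbasis is ill-conditioned) and
per-level scaling against underflow.  Root priors: `equal` (uniform),
`fixed(state)`, or `empirical` — the normalised root conditional
likelihoods, i.e. the marginal reconstruction at the root, used as prior
weights.  The reported ancestral state is always this marginal root
posterior.  Fits default to a single tree (typically the MCC consensus);
averaging over a posterior subsample is a caller-side loop over trees.

Rate priors are independent exponentials with mean 1/(root age) — proper,
as stepping-stone sampling requires, and scale-aware: one expected
transition per root-depth of branch.  The sampler is an adaptive
per-parameter random-walk Metropolis on log rates, targeting 0.44
acceptance during burn-in; default settings mirror a production-scale run
(10M iterations, 1M burn-in, thinning 10,000) and are scaled down for
interactive use.  Low effective sample size (initial-positive-sequence
estimator) produces a warning, not an error.

Marginal likelihoods use stepping-stone sampling along a power-posterior
path with temperatures at quantiles of Beta(0.4, 1), concentrating stones
near the prior.  Each stone runs an independent chain from a fresh prior
draw with its own burn-in (default half a stone's length) and within-stone
thinning of 2; the stone at beta = 0 samples the prior directly.
Independence across stones makes the summed per-stone variances a valid
variance for the estimator; each stone's variance is the larger of a
batch-means estimate and an ESS-inflated iid estimate, since either alone
can understate the variance of these skewed means.  Models are compared by
BF = 2 (log10 L_j - log10 L_k) with j the better model, banded as weak
(BF <= 2), strong (2 < BF < 5), and very strong (BF >= 5).

## Stochastic mapping and the branch-length correction

Histories conditional on tip regions are drawn in two passes: node states
from their joint conditional distribution (upward pruning, downward
sampling), then each branch's path conditioned on its endpoints by
uniformization — the jump count from its exact conditional distribution,
the jump chain bridge-sampled via powers of R = I + Q/Omega, virtual jumps
dropped, and times placed as uniform order statistics.  Rejection sampling
is retained in the tests as the independent oracle.  A tip configuration
impossible under Q (a zero-constrained rate the data require) raises an
error naming the first impossible branch.

Because a constant-rate process accrues events wherever the tree has
branch length, per-interval event counts are corrected: the tree is cut
into successive intervals (default 1000 years) anchored at age 0, half-open
in age with boundary events assigned to the older interval; the expected
count per interval is each pair's total mean count multiplied by the
interval's share of total tree length; corrected = observed - expected,
summing to zero per pair exactly (floating-point residue is absorbed into
the oldest interval).  The correction interval (1000 yr) and the finer
reporting histogram (500 yr) are independent parameters, since the two
widths serve different purposes (correction vs display) and nothing forces
them equal.  Three standard mapping parameterisations per model are
provided: fitted Q with the empirical root, an internally re-estimated
maximum-likelihood Q with an equal root prior, and fitted Q with the root
fixed to a chosen region.

## Synthetic data: what it emulates and what it does not

The generator supplies ground truth for every stage: a dated tree
(haploid coalescent via msprime, or a forward birth-death process retried
on extinction with pendant branches extended by one waiting-time draw), a
region history evolved forward under a known Q from a known root state
with every transition recorded, and an emulated posterior — copies of the
true tree with multiplicative lognormal branch jitter, internal nodes
re-dated tip-upward (averaging over children, clamped so parents are not
younger than children), and one age-respecting nearest-neighbour
interchange per tree with configured probability.

Defaults emulate the study system at desk scale, chosen once: N_e = 1000
with 25-year generations (root ages near 50 kyr, matching mitogenome-scale
depths), 200 tips, 100 posterior trees, 5% branch jitter, 10% NNI
probability, a Wallacean root, and a model-9-style truth with the
New Guinea-Wallacea exchange at 2e-4/yr and WLC>AUS at 5e-5/yr.

The emulation reproduces the *features the pipeline consumes* — clade
support below 1, TMRCA spread per clade, occasional topology changes — but
it is not a Bayesian posterior: jitter is independent across branches
(no correlated rate uncertainty), NNI moves are local and rare, and there
is no sequence-level information.  Passing tests therefore demonstrate
correctness of the post-processing given posterior-like input, not the
behaviour of tree inference itself.

For the rate-recovery study the conditions are different by design: a
single discrete character on a coalescent tree carries too little
information for tight rate recovery (total length only ~ln n times the
depth, and an absorbing Australia soaks up deep lineages).  Recovery runs
instead use a Yule tree (birth rate 1e-4/yr, 500 tips; total length ~80x
the depth) with well-separated rates 3e-5/yr (tied PAP<->WLC) and 6e-6/yr
(WLC>AUS), giving on the order of 100 recorded events per replicate —
enough for the likelihood to dominate the prior.

## Problem sizes and numerical choices

Tests and the acceptance script run everything at reduced scale, chosen as
the smallest sizes at which the statistical checks remain sharp: oracle
comparisons on 12-tip trees with 50-tree posteriors, enumeration
likelihood checks on trees of at most 6 tips, stepping-stone calibration
with 50 stones x 150 iterations against 1-D quadrature, stochastic-mapping
frequency checks at 10,000 realisations, and recovery at 500 tips with
1200 MCMC iterations and 12-stone marginal likelihoods.  Monte-Carlo
checks use 3-standard-error bands throughout.

Other numerical details: transition matrices are clipped to [0, 1] and
row-renormalised after the eigendecomposition; pruning partials are
rescaled per level; the MCMC works on log rates with the Jacobian included;
KDE grids are truncated at age 0 and renormalised; degenerate inputs
(single-state data, zero generators, zero-length branches) are handled
explicitly and tested.

## Known limitations

- Clade identity by tip-set equality cannot track "the same" clade through
  tip-set changes; that is inherent to posterior-set summaries.
- The MCC clamp slightly biases ages at nodes where mean MRCA heights are
  non-monotone.
- The stepping-stone SE is an estimate; calibration was verified against
  quadrature for one-parameter models, and multi-parameter SEs inherit the
  same construction but were not separately validated.
- Posterior emulation does not model correlated rate or topology
  uncertainty, so absolute support values should not be read as Bayesian
  posteriors.
- Migration models assume a single Q across the whole tree (no rate
  shifts in time or across clades); the correction diagnoses, but does not
  model, departures from rate constancy.
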