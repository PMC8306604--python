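# phylogeo-gec

Phylogeographic post-processing of posterior sets of time-calibrated
trees: extraction of **geographically exclusive clades** (GECs), equal-mass
aggregation of their **TMRCA** distributions, Bayesian comparison of
constrained **migration models**, and **stochastic mapping** of migration
events with a branch-length-expectation correction.

The package is written for studies of maternally inherited markers
(mitogenomes) sampled across discrete regions — the bundled defaults use
Australia (AUS), New Guinea (PAP), and Wallacea (WLC) — where the questions
are *when* regionally endemic matrilines arose and *which* inter-regional
movements the genealogy supports.  It consumes trees (it does not infer
them): BEAST-dialect NEXUS or Newick posterior samples, a consensus tree,
and a tip-to-region TSV.

## The core quantities

**GECs.** A GEC is a monophyletic clade of >= 2 samples whose tips all come
from one region; its TMRCA bounds the occupation time of that region by the
matriline.  For each posterior tree the largest region-pure clade containing
each sample is found; candidates are pooled across trees, retained when
monophyletic in a majority (> 50%) of the posterior, and kept pairwise
tip-disjoint.  Each retained clade's TMRCA sample set is its MRCA age in
every tree containing it.

**Equal-mass densities.** Per region, each clade's TMRCA samples get a
Gaussian KDE normalised to unit mass, and clade curves are averaged with
equal weight 1/(number of clades), so support differences do not reweight
the aggregate.  Percentiles invert the equal-weight CDF.

**Migration models.**  Regions evolve as a 3-state continuous-time Markov
chain with generator Q (rates per lineage per year).  A model constrains
each of the six ordered rates to be free, zero, or tied; likelihoods come
from Felsenstein pruning, posteriors from MCMC, and marginal likelihoods
from stepping-stone sampling.  Models are compared with

&nbsp;&nbsp;&nbsp;&nbsp;BF = 2 (log10 L_j − log10 L_k),

with BF <= 2 weak, 2 < BF < 5 strong, and BF >= 5 very strong evidence for
the better model.

**Corrected migration timings.** Stochastic mapping draws full transition
histories conditional on the tip regions (uniformization on each branch).
Counts per time interval are corrected for tree shape: expected counts
distribute each pair's total in proportion to the branch length per
interval, and corrected = observed − expected (summing to zero per pair).
Positive corrected values flag periods with more migration than a
constant-rate process explains.

A first-class synthetic-data module (coalescent/birth-death trees, forward
trait evolution under a known Q, jitter+NNI posterior emulation) provides
ground truth for every stage.

## Worked example

```python
import numpy as np
import phylogeo_gec as pg

# ground-truth dataset: 200 tips, 100 emulated posterior trees
ds = pg.make_dataset(pg.SimulationConfig(seed=1))

gecs = pg.extract_gecs(ds.posterior, ds.regions)
wlc = [g for g in gecs if g.region == "WLC"]
curve = pg.aggregate_density(wlc, "WLC")
q50, q90 = pg.percentile(curve, [0.5, 0.9])

models = pg.bundled_models()          # all, null, m4, m9, m12
mcc = pg.mcc_consensus(ds.posterior)
ss9 = pg.marginal_likelihood_stepping_stone(
    mcc, ds.regions, models["m9"], stones=20, iterations_per_stone=200, seed=2)
ss0 = pg.marginal_likelihood_stepping_stone(
    mcc, ds.regions, models["null"], stones=20, iterations_per_stone=200, seed=2)
report = pg.bayes_factor(ss9.log10_marginal, ss0.log10_marginal, "m9", "null")

fit = pg.fit_mcmc(mcc, ds.regions, models["m9"],
                  settings=pg.MCMCSettings(iterations=2000, burnin=500,
                                           thin=5, seed=3))
q = models["m9"].q_matrix(fit.medians)
reals = pg.simulate_mappings(mcc, ds.regions, q, pg.RootPrior("empirical"),
                             n=1000, seed=4)
profile = pg.branch_length_profile(mcc, 1000.0)
corr, hist = pg.corrected_rates(reals, profile)
```

Output for this seed:

```
29 GECs retained (AUS: 3, PAP: 13, WLC: 13)
  AUS  n=37  support=1.00 median TMRCA=3,692 yBP
  AUS  n=24  support=1.00 median TMRCA=2,719 yBP
  AUS  n=12  support=1.00 median TMRCA=1,860 yBP
WLC TMRCA percentiles: 50% = 367 yBP, 90% = 1,720 yBP
log10 marginal (m9) = -25.37 +- 0.07
log10 marginal (null) = -30.10 +- 0.04
BF = 9.47 favouring m9: very strong evidence
PAP>WLC migration: corrected peak in interval 0k-1k yBP (+1.46 events vs expectation)
```

Reading it: 29 tip-disjoint majority-supported clades were recovered from
the emulated posterior; half the Wallacean clade mass postdates ~0.4 kyr on
this synthetic genealogy; the two-parameter model under which the data were
generated decisively beats the one-rate null (BF 9.5 >= 5); and the
corrected stochastic-mapping curve places the excess of New Guinea to
Wallacea movements in the most recent interval, where this simulation
concentrates them.

## Command line

Every step is also a subcommand of `phylogeo-gec`:

```sh
phylogeo-gec simulate --seed 3 --outdir data/
phylogeo-gec mcc      --trees data/posterior.nex --out data/mcc.nex
phylogeo-gec extract  --trees data/posterior.nex --regions data/regions.tsv \
                      --min-support 0.5 --out gecs.tsv --tmrca-samples gecs_tmrca.tsv
phylogeo-gec density  --gecs gecs_tmrca.tsv --regions-of gecs.tsv --out density.tsv
phylogeo-gec fit      --tree data/mcc.nex --regions data/regions.tsv \
                      --model m9 --stones 50 --iters 2000 --seed 1 --out m9.json
phylogeo-gec compare  m9.json null.json
phylogeo-gec simmap   --tree data/mcc.nex --regions data/regions.tsv \
                      --fit m9.json --root empirical --n 1000 --seed 2 --out rates.tsv
```

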