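# Methods

## The substitution process

The simulator realizes a continuous-time Markov process whose state is an
entire protein-coding DNA sequence of N sense codons under the universal
genetic code (61 states per site; TAA/TAG/TGA are excluded, and any event
that would create one has rate zero). Rates follow the six-way product form
described in the README: target-nucleotide frequency φ, transition
multiplier κ, nonsynonymous multiplier ω, and a CpG multiplier λ applied to
transitions in CpG context. Context is read from the current sequence at
the moment of the event and may cross a codon boundary, which is what makes
sites interdependent and the whole-sequence state space (61^N) necessary.

Conventions and choices:

* **CpG context, strand handling.** By default both deamination channels
  are hypermutable: C→T with a 3′ G, and G→A with a 5′ C (the same CpG seen
  on the opposite strand). Methylated CpG deaminates on both strands in
  double-stranded DNA, so this is the biologically natural default; a
  `c_to_t_only` mode restricts λ to the literal C→T channel for
  sensitivity analyses.
* **Termini.** The first nucleotide has no 5′ context and the last no 3′
  context; there is no wraparound.
* **Normalization.** By default (`m0_reference`) all rates are multiplied
  by one constant chosen so that the λ=1 site-independent model has mean
  rate 1 per codon site at its stationary distribution (for ω mixtures, the
  mixture-averaged mean rate, one common constant for all components).
  Branch lengths are therefore expected substitutions per codon site under
  the λ=1 reference; λ>1 inflates the realized rate above the nominal
  branch length, which is part of the violation being studied. A `none`
  mode disables scaling.
* **ω mixtures.** For mixture simulations each codon site draws its ω
  independently from the mixture (equal weights by default) once, and keeps
  it for the whole tree.

## Jump-chain simulation

Along a branch the engine repeats: draw `t = −ln(1−U)/R` with R the total
rate away from the current sequence (the sum over at most 9N accessible
single-nucleotide events, maintained incrementally — an event at site s can
only change the rate rows of sites s−1, s, s+1); if the accumulated time
exceeds the branch length, stop (the overshooting draw is discarded, which
is exact because the exponential is memoryless and sibling branches must be
independent); otherwise pick the event with probability proportional to its
rate, in a fixed site-major / position / target-A<C<G<T order, apply it and
record it. The recursion visits branches in preorder, each child starting
from its parent's end state.

The dwell-time inverse-transform formula is written out rather than calling
a library exponential sampler so that the documented formula is itself the
tested code path. The inner loop is JIT-compiled (numba); a pure-Python
reference engine built from the documented single-step operations consumes
the same MT19937 stream and is asserted to produce identical realizations,
event for event, on the same seed.

**Root states.** Three modes: `stationary_m0` draws sites independently
from the closed-form λ=1 stationary distribution (π_j ∝ φ_{j1}φ_{j2}φ_{j3});
`burn_in` (the default) first applies 50·N jump-chain events along an
artificial branch starting from that draw, which converges to the
intractable stationary distribution of the interacting model — starting
near-stationary makes 50 events per site a comfortable margin (tests verify
insensitivity and the λ=1 closed form is recovered from a deliberately
degenerate start); `fixed` uses a user sequence. Each replicate of an
experiment draws a fresh root.

**Reproducibility.** One master seed governs a simulation; per-branch RNG
substreams are spawned deterministically in preorder, so identical seeds
give byte-identical alignments and histories, and changing one branch's
length does not perturb the draws of any other branch. Experiment grids
derive per-replicate seeds from (master seed, condition index, replicate
index), so any cell can be rerun in isolation.

## Likelihoods and fits (site-independent models)

With λ=1 the process factorizes and ordinary machinery applies: transition
probabilities P(t) = exp(Qt) via eigendecomposition of the π-symmetrized
generator (the λ=1 model is reversible; asserted numerically), and
alignment log-likelihoods by the pruning recursion with per-node scaling
against underflow, site patterns compressed once per dataset.

* **M0** maximizes over (ω, κ, global tree scale), in log space, by bounded
  L-BFGS-B from the best of four deterministic starts (ω ∈ {0.2, 1}, κ ∈
  {2, 5}). Bounds: ω ∈ [1e−4, 20], κ ∈ [1e−2, 50], scale ∈ [1e−3, 1e3].
  Branch lengths are not re-optimized individually: a single global scale
  multiplies the (true, fixture) tree. This captures the rate-inflation
  pathway of the ω bias at a fraction of the cost of per-branch
  optimization.
* **M7** uses K = 10 equal-weight beta categories at quantile midpoints
  (k−0.5)/K; **M8** adds an eleventh class at ω_s ≥ 1 with weight 1−p0
  (p0 on a logit scale, ω_s − 1 on a log scale). Shape bounds p, q ∈
  [5e−3, 100]. In the experiment pipelines κ and the tree scale are
  profiled from a preceding M0 fit and shared by M7 and M8 (they can also
  be optimized jointly); the M7 optimum embedded at p0 → 1 is always a
  candidate M8 solution, so the fitted M8 log-likelihood never falls below
  M7's — the nesting the LRT needs. The LRT statistic 2(ℓ₈−ℓ₇) is clamped
  at 0 and referred to chi-square with 2 df, exactly the conventional test
  whose error behaviour is under study (no boundary correction, since the
  plain test is the object of interest).
* **Frequencies** default to the known generating φ, isolating the ω bias
  from frequency-model misspecification; an empirical F1X4 option counts
  nucleotides from the data.

Likelihood under λ≠1 is deliberately not provided — its intractability is
the premise of the whole package.

## Rejection ABC for λ

Candidate λ values are drawn from a uniform prior (default U(1, 16)); each
drives one jump-chain simulation on the observed data's tree and length,
with nuisance parameters (φ, κ, ω, tree scale) fixed — to the generating
truth in recovery experiments, or to M0 estimates in a two-stage scheme on
real data. Eight summaries are computed per alignment: mean CpG
dinucleotide frequency, the four nucleotide frequencies, the proportion of
variable codon columns, and mean pairwise transition and CpG-context
transition fractions among differing positions (all taxon-order invariant;
taxa are sorted internally so the vector is bit-reproducible). Distances
are Euclidean after standardizing each summary by its standard deviation
across the simulation pool (zero-variance coordinates are dropped with a
warning); the closest `accept_fraction` of draws forms the posterior
sample, summarized by its mean and central 95% interval. This is the
plainest likelihood-free scheme that exercises the simulator-as-kernel
idea; sequential or regression-adjusted ABC would sharpen the posteriors
but is out of scope.

## Synthetic fixtures and problem sizes

No real alignments ship with the package. Experiments run on a synthetic
"mammalian-like" fixture: a Yule-topology tree rescaled to a chosen total
length, with φ = (0.3, 0.2, 0.2, 0.3) and κ = 4 (typical mammalian
transition bias and AT-leaning composition), λ ∈ {1, 4, 8} (8 being a
typical mammalian CpG value), and ω or ω-mixtures below 1. Default sizes,
chosen to keep a full study on one CPU in minutes while leaving the
qualitative contrasts clearly resolved:

* ω-bias grid: 20 tips, total length 2.0, 300 codons, 50 replicates/cell;
* LRT trend grid: 10 tips, 200 codons, 25 replicates/cell, mixture
  (0.1, 0.2, 0.3), α = 0.05;
* ABC recovery: 12 tips, 150 codons, ω = 0.2, n_sims = 1000, accept 5%.

What the generator emulates — and does not. It produces data from exactly
the process under study, so tests isolate the CpG violation with everything
else correctly specified. Real alignments add everything the fixture lacks:
among-site rate variation beyond ω, non-stationary and non-homogeneous
composition, alignment error, selection on codon usage, recombination.
Passing tests therefore demonstrate properties of the method under its own
assumptions, not performance guarantees on real genes.

At these scaled-down sizes the *direction* and λ-ordering of every effect
reproduce cleanly, but tail fractions do not: with 300 codons and 20 tips
the replicate-to-replicate spread of ω̂ (SD ≈ 0.02 at ω₀ = 0.2) is of the
same order as the λ=8 bias (≈ +0.015 at equilibrium), so the fraction of
replicates overestimating ω at λ=8 is high but not literally 100% — that
extreme requires gene-scale data (several hundred more codons and taxa)
where the estimator SD is several-fold smaller. Likewise the M7/M8
false-positive inflation at 10 tips and 200 codons is a trend, not a large
absolute rate.

## Numerical notes

* Rates and likelihoods in double precision; generator validity, row sums
  and reversibility asserted at 1e−8…1e−12 as appropriate.
* Conditional likelihoods are rescaled per node by their per-pattern
  maximum; per-class log-scale factors are recombined by log-sum-exp.
* Eigendecomposition is performed on the symmetrized generator
  (D^{1/2} Q D^{−1/2}); transition matrices are clipped at 0 to remove
  −1e−16-level noise.
* The event-buffer for a branch is sized from the expected event count and
  deterministically re-run with a doubled buffer on overflow (the kernel
  reseeds, so results are unchanged).
* L-BFGS-B convergence: relative function tolerance 1e−9; non-convergence
  is reported in the fit objects, never raised.

## Known limitations

* Only the CpG dinucleotide context is modelled; no general
  context-dependent multipliers, amino-acid fitness terms, or indels.
* Non-reversible simulation works in principle (the jump chain does not
  care) but root placement then matters and no tooling is provided for it.
* ML fits report no standard errors or profile intervals.
* The M8 fit, like all mixture fits, can hit local optima; the embedded-M7
  safeguard bounds the damage for the LRT but does not guarantee the global
  optimum.
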