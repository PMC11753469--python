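# Methods

## The fluctuation model

Each culture is founded by a single non-mutant cell and grows to `Nt` cells.
With a per-division mutation rate `mu`, the number of mutational events in a
culture is Poisson with mean `m = mu * (Nt - 1)`: a culture of `Nt` cells is
the product of exactly `Nt - 1` divisions, whatever the growth schedule. Key
assumptions, shared by the estimator and the simulator:

* mutants and non-mutants grow at the same rate in the absence of selection;
* mutations are neither induced by, nor reverted under, the selective plating;
* a mutational event occurring when the population has size `n` founds a
  clone of roughly `Nt/n` final cells. Marginalising over the growth-weighted
  event time gives the clone-size law `P(K = k) = 1/(k(k+1))`, and the total
  mutant count per culture is then compound Poisson with the Lea–Coulson pgf
  `G(z) = exp(m (1-z) ln(1-z) / z)`.

Partial plating (a fraction `epsilon` of the culture spread on the plate)
thins every mutant cell independently, so the observed pgf is
`H(z) = G(1 - epsilon + epsilon z)` and
`P(0) = exp(m epsilon ln(epsilon) / (1 - epsilon))`.

### Numerical evaluation of the pmf

`H` is evaluated in compound-Poisson form, `log H(z) = m (psi(z) - 1)`, where
`psi_k` is the exact per-clone observed-colony pmf
`sum_j binom(k; j, epsilon) / (j (j+1))` (truncated where the binomial mass is
below ~1e-15; at `epsilon = 1` it is exactly `1/(k(k+1))`). The pmf follows
from the standard power-series exponentiation recursion
`p_k = (1/k) sum_j j q_j p_{k-j}` with `q_k = m psi_k`. All terms are
non-negative, so the recursion is stable, and entries are exact up to the
requested index — no truncation parameter is involved. Direct series division
of `H` by `(1 - epsilon + epsilon z)` was rejected: the divisor's root at
`-(1-epsilon)/epsilon` lies inside the unit disk for `epsilon > 1/2` and
breeds a parasitic solution growing like `(epsilon/(1-epsilon))^k`.

### Estimation, intervals, comparisons

`m` is estimated by 1-D maximum likelihood (coarse log-grid scan, then
bounded Brent refinement to `1e-10` on `log m`); `mu = m / Nt`. Confidence
limits are profile-likelihood bounds at `2 * dlnL = 3.84` (95%, 1 df); the
all-zero-count boundary yields `m_hat = 0` with lower limit 0. Rates are
compared between plating environments by a likelihood-ratio test whose null
shares a single per-division rate `mu` (each environment keeping its own `Nt`
and `epsilon`); the statistic is referred to chi-square with 1 df, and the
rate ratio gets a profile-likelihood 95% CI.

Uncountable ("burst") plates are excluded by default, matching how such
plates were handled in the assay design the package targets; an optional
right-censoring mode instead assigns them the upper-tail probability beyond a
stated ceiling. The same mechanism (`count_ceiling`) is used in large
simulation studies, where the heavy clone-size tail occasionally produces
jackpot counts in the tens of thousands: counts above the ceiling enter the
likelihood as right-censored observations, which keeps the pmf recursion
short without discarding information. Differential mutant fitness, the P0
estimator, and multi-dilution plating are deliberately out of scope.

## Target-size models

The default catalogue lists the printed LPS-pathway genes with their coding
lengths (11,736 bp in total) and LPS classes; the regulatory gene *rfaH* is
always reported as its own category because its mutations can produce either
phenotype. Two further inner-core genes, *hldD* (933 bp) and *gmhA* (579 bp),
observed only in combination environments, extend the catalogue for the
"added genes" model variant; their lengths are standard *E. coli* annotation
values, and their survival profiles default to the pathway-adjacent genes
(*hldD* → *hldE*, *gmhA* → *gmhB*), overridable in every API that consumes a
survival table.

Weights are computed in full precision; integer display uses round-half-up
and relative rates are reported at two decimals. One printed weight (hldE in
the phage + 2 µg/ml gentamicin column, 244) differs from the computed
`(1/6) * 1434 = 239`; the package reports the computed value — the relative
rate still rounds to 0.80 either way — and the pipeline logs a warning rather
than an error when validating against the printed table.

Model 2 applies the survival fraction to the augmented count,
`(x/n) * (count + pseudo)`, with the pseudo-count applied to every gene in
the configured candidate catalogue and the reference fixed to the phage-only
environment. Model 3 shares that contract; only the survival matrix changes
(growth threshold 12).

## Susceptibility scoring

Growth is the median across 1–5 replicates of (mean lawn greyscale − blank
greyscale); the blank's background mode is ~37 in the data this emulates, but
it is a per-record field, not a constant. Growth requires the median to
*strictly* exceed the threshold; equality counts as no growth, so the
growth/no-growth and MIC rules stay complementary. The MIC is the lowest
tested concentration, scanning upward, at which the median fails the
threshold (first-crossing rule for non-monotone profiles); strains growing at
every tested concentration are reported as above-range rather than given a
numeric MIC. Negative blank-subtracted values are clamped to zero for calls
but preserved in exports.

## Spectra, bootstrap and goodness of fit

Isolates with several mutations are classified by the most LPS-truncating
mutation (deep rough > regulatory > rough > non-LPS; ties broken by catalogue
order, which follows the biosynthetic pathway). Bootstrap SDs resample, with
replacement, a pool consisting of the observed isolates plus one
pseudo-isolate per candidate gene — the pseudo-isolates are part of the pool,
not just of the denominator, because they are added *before* sampling; each
replicate draws pool-size isolates, and the SD of per-gene (and per-class)
proportions across 100 replicates is reported. Goodness of fit is a Pearson
chi-square of observed counts against `n * predicted proportions`, with no
continuity correction and asymptotic p-values; categories with zero
expectation raise an error directing the caller to the added-genes variant.
Isolates with no identified mutation are excluded from denominators.

## The synthetic-data generator

The simulator draws Poisson(`m`) mutational events per culture, samples clone
sizes as `floor(1/U)` (exactly the `1/(k(k+1))` law, capped at `Nt`), thins
each cell binomially at `epsilon`, assigns each clone a causal gene
categorically in proportion to the model weights, and retains each plated
cell with its gene's survival fraction — the generative statement of the
target-size models. An optional per-environment establishment probability
(default 1) lets users emulate phage–antibiotic interactions that suppress
colony establishment uniformly across genes; it is deliberately not used in
any default, because such interactions are outside the target-size mechanism
the models encode.

A synchronous doubling model was considered and rejected: synchronous
divisions produce only power-of-two clone sizes (no singleton clones), so its
colony-count distribution cannot match the Lea–Coulson pmf that the estimator
assumes; the continuous-growth clone-size law above is both simpler and
exactly consistent. Greyscale plate tables use a lawn level of 70 above blank
below a strain's true MIC (uniform lawns correspond to ~30–80) and 2 above
blank at or above it, with Gaussian replicate noise (default sd 3) clipped to
[0, 255]. Default fluctuation settings — 50 cultures, `Nt = 1e8`,
`mu = 1e-8`, full plating — put most plates in the 1–100-colony regime the
assay was designed for.

What the simulator does *not* emulate: phage population dynamics and
co-evolution, gene-specific mutation bias (clone gene assignment is exactly
proportional to the configured weights), mutation-class structure
(SNP/indel/IS), plate-image artefacts, or interactions between phage and
antibiotic beyond the optional establishment knob. Passing tests therefore
show that the inference machinery is correct under the stated model, not
that real data satisfy the model.

## Problem sizes and numerical choices in the test suite

Distributional checks (pmf vs Monte-Carlo cultures) use 1e5 replicates with
tail bins pooled below an expected count of 5; CI-calibration uses 500
experiments of 50 cultures; bias checks use 1e4 cultures for
`m ∈ {0.5, 1, 3}`; the LRT type-I-error study uses 1000 paired 30-culture
experiments. The gene-share recovery test uses `Nt = 64` with a matched
`mu`: the clone-size law's diverging second moment makes colony-weighted
gene shares converge extremely slowly at realistic `Nt`, so a capped clone
distribution is the appropriate design for a convergence check. All
stochastic tests run under fixed seeds.

## Known limitations

* The estimator assumes a homogeneous plating fraction; when per-gene
  survival varies (the combination environments), fitted `m` ratios carry a
  small model-misspecification offset (~+0.03 on the 0.47 prediction at
  `m = 1`), visible in the end-to-end recovery test's tolerance.
* Model-2/3 predictions require observed mutation-count tables, which users
  must supply; the package ships only the printed gene-length inputs.
* Profile-likelihood intervals rely on the chi-square approximation, which
  degrades for experiments with very few cultures or `m` near zero.
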