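# Methods

`syntrophevo` implements the statistical machinery used to analyze
long-term evolution experiments on an obligate syntrophic coculture: a
sulfate reducer (*Desulfovibrio vulgaris*, "Dv") cross-feeding hydrogen
and formate to a methanogen (*Methanococcus maripaludis*, "Mm"), evolved
as replicate lines sampled roughly every 250 generations.  The package
is validated entirely on synthetic data with planted ground truth; this
note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Parallel-evolution G-scores

For gene *i* with observed nonsynonymous mutation count `O_i` and
length-proportional expectation `E_i = N · L_i / Σ_j L_j` (N = total
genic mutations scored, L_i = gene length in bp), the per-gene score is
the goodness-of-fit statistic

    G_i = 2 · O_i · ln(O_i / E_i),    G_i = 0 when O_i = 0.

The genome-wide parallelism statistic is the total `G = Σ_i G_i`.  Genes
with `0 < O_i < E_i` contribute *negative* terms — the formula is applied
as written and this is intentional; only top-ranked positive scores are
usually interpreted.  The null distribution of the total comes from
re-placing the N observed mutations uniformly along the genome (gene hit
probability `L_i / genome length`, implemented as a multinomial over
genes plus an intergenic bin that scores zero), with the same `E_i`
vector as the observed data; departure is summarized as
`Z = (G_obs − μ_G) / σ_G` over 1000 simulations by default.

Two counting modes are exposed because the field uses both: `pooled`
counts every mutation event (default), `per_line_unique` counts a gene at
most once per evolution line.  Synonymous and intergenic calls are
excluded from scoring (intergenic exclusions are reported).

## Temporal trajectory statistics

Trajectories are per-line, per-generation locus→frequency maps on the
sampled grid (default 100, 300, 500, 780, 1000 generations); no
interpolation is done between samples, since anything inside a ~250
generation gap is unobservable.  Operational definitions:

- **Fixation**: earliest sampled generation with frequency ≥ 0.95 that
  stays above threshold at all later samples (transient excursions do
  not count).  The 0.95 threshold and the 0.05 detection limit are
  configurable; the source experiments describe "fixed" and "below
  detection" qualitatively, so these numbers are this package's choice.
- **Co-occurrence**: number of lines where two loci are both detected at
  ≥ k common sampled time points (default k = 2).
- **Simultaneous fixation**: both loci first fix at the same sampled
  generation.
- **Nested fixation**: locus B rises above detection after locus A yet
  fixes no later than A does.
- **Cross-species sweep**: earliest interval (g1, g2] over which, in
  *both* partner organisms, a nonempty locus set drops from dominance
  (≥ 0.5) to below detection while a disjoint nonempty set rises from
  below detection to dominance.

### Permutation null

Empirical support uses `P = (s + 1)/(n + 1)`, with `s` the number of null
replicates showing an equal-or-stronger (≥) association.  The null
preserves both margins of the line × gene presence matrix — mutations per
line and lines per gene — via a serial curveball-trade chain: each trade
redistributes the symmetric difference of two random rows, which provably
preserves both margins and has the uniform distribution over matrices
with those margins as its stationary law (verified in-tree against
exhaustive enumeration on a small instance).  Burn-in is 10 chain sweeps
(one sweep = one trade per row) and one sweep of thinning separates
replicates.  Within each line, observed trajectories are reassigned
uniformly over the genes present in that line; because a pairwise
statistic only sees the two loci of interest, the bijection is sampled
marginally (an ordered pair of distinct events), which is
distribution-identical and much cheaper.

When the matrix admits no checkerboard swap, both margins pin the matrix
down and the chain cannot move; the implementation falls back to exact
enumeration over independent column-margin placements of the two loci and
reports `P = s/n` over all placements (`method="exact"`).  The exact
fallback is exact for presence-determined statistics; fixation-based
statistics in the fallback still randomize within-line labels with the
seeded generator.

Calibration caveat: margin-conditioned P values are honest when the
data's conditional law given margins is uniform — exactly true for
presence models that are logit-additive in line and gene effects.  The
uniformity test uses 60 lines so the counting statistic has enough
support; at the 13-line scale of the real design, pairwise counts take
few values and P values are visibly discrete (conservative near 1), which
is a property of any permutation test at that scale, not of this
implementation.

## Multi-caller consensus filtering

Variants from independent callers are merged on the identity key
(replicon, line, position, alt allele); multiallelic records are split
before matching.  A variant is retained when reported by ≥ 2 callers and
its consensus frequency — the median across reporting callers, robust to
one outlier — is ≥ 0.20.  The frequency filter is applied post-consensus
(the stricter of the two possible orders; the source protocol is
ambiguous on this point).  Impact classes follow the standard lookup:
start/stop gain or loss and frameshifts are HIGH; codon indels/changes
and nonsynonymous coding changes MODERATE; synonymous and
nonsynonymous-start changes LOW.  Unknown terms raise an error rather
than defaulting.

## Single-cell lineage inference

Single-cell states are coded 0 (absent), 1 (present), 3 (insufficient
reads).  Matrix construction applies the stringent single-cell filters:
state 3 when coverage < 8, else 1 when within-cell frequency ≥ 0.80
(the boundary is inclusive; sources vary between ">" and "≥"), and
mutation columns are kept only when ≥ 2 cells carry state 1.

The mutation tree is SCITE-style: a rooted tree with one mutation per
non-root node; a cell attached at a node carries the mutations on its
root path.  Observation error: `P(1|0) = fd`, `P(0|1) = ad`, missing
states contribute a factor 1.  Defaults `fd = 6.04e-5`,
`ad = 0.21545` are the whole-genome-amplification error rates of the
emulated experiment.  The homozygous second dropout parameter of the
original model is collapsed into the single `ad`, since states here are
binary presence/absence.  Cell likelihood uses the MAP attachment
(`max`; a `sum` mode averages over attachments with a uniform prior
including the root).

Search: exhaustive enumeration of parent vectors for m ≤ 7 (the
likelihood is evaluated vectorized over cells × attachments), otherwise
Metropolis MCMC with prune-and-reattach and label-swap moves (default
chain length 1e5, single repetition).  Likelihood ties — e.g. two
mutations with identical cell sets — are broken deterministically by the
lexicographically smallest parent vector, recorded as swappable label
pairs, and flagged.  `order_trunk_by_generations` resolves tied trunk
orderings against bulk longitudinal data: the mutation detected earlier
goes first; mutations never detected in bulk keep tree order and are
flagged `rare/below-detection` (rare sub-lineages below the bulk
detection limit are expected in this system).

## Growth kinetics

OD600 curves are fit with the reparameterized logistic and Gompertz
models whose parameters are directly the maximum growth rate μ (OD/h),
lag λ (h), and capacity A (OD):

    logistic:  y(t) = A / (1 + exp(4μ(λ − t)/A + 2))
    gompertz:  y(t) = A · exp(−exp(μe(λ − t)/A + 1))

plus a free baseline offset, by bounded least squares initialized from
data heuristics (A ← max rise, μ ← max finite-difference slope, λ ← the
max-slope tangent's baseline intercept).  Model choice uses
small-sample-corrected AIC with ties going to the logistic.  A well
"grew" when the fitted capacity exceeds 0.05 OD above baseline *and* at
least three consecutive raw readings sit above baseline + 0.05 — the
numeric growth call is this package's choice, as the source protocol
gives none.  Non-convergence yields `grew=False` with a diagnostic, never
an exception.

Dilution plates use a 1.5-fold density series with blank wells; blanks
exceeding the growth threshold abort the analysis as contamination.  The
minimal permissive density is the lowest seeding density with at least
one growing replicate, reported with the full per-density growth-count
profile.

## Bliss synergy

Fractional effects default to `(v_pair − v_AcAc)/v_AcAc` clamped to
[0, 1] (a `relative_to_full` mode normalizes by the EvEv − AcAc span).
The Bliss expectation is `f_DvMm = f_Dv + f_Mm − f_Dv·f_Mm` and
`EOB = (f_z − f_DvMm) × 100`.  Because fractions are estimated from
replicate means, propagated errors use standard errors of the means,
first-order and under independence (pairings are grown in separate
tubes), including the shared baseline's error:
`sd(f_DvMm)² = (1−f_Mm)²sd(f_Dv)² + (1−f_Dv)²sd(f_Mm)²`.
Classification: additive when |EOB| ≤ 2·sd(EOB) (collapsing to EOB = 0
at zero error), else synergistic/antagonistic by sign.  The ±2 sd band
operationalizes "EOB ≈ 0"; it is configurable.

## Synthetic data

The generator reproduces the study design, not its sequences: 13 lines ×
5 sampled generations, per-line mutation events Poisson(rate 10–12),
gene assignment proportional to length × enrichment (enrichment 1
everywhere is exactly length-proportional multinomial — the G-score
null), logistic frequency rises toward fixation for selected events and
low-frequency persistence for neutral ones, caller call sets as truth
minus binomial dropouts plus binomial decoy false positives with
frequency jitter, single-cell matrices drawn from a known tree with the
fd/ad/missing error model and uniform cell attachment (root included: a
root cell carries no mutations), logistic plates over the 1.5-fold
series (lag lengthening by one doubling-time per dilution step, Gaussian
OD noise truncated at zero), and 2×2 clone pairings whose EvEv effect
equals the Bliss expectation ± a planted effect size.

What it does *not* emulate: read-level sequencing noise, linkage between
loci within a line (events are independent given their gene), clonal
interference, plasmid loss, or media chemistry.  Passing tests therefore
demonstrate the *statistics* are correct and calibrated, not that any
biological conclusion transfers to real data.

## Problem sizes used in validation

Chosen to exercise each method at the scale where its guarantees are
measurable: G-score calibration uses 50 datasets × 1000 null simulations
(50 genes, ~100 mutations); power uses a 12-gene catalog with a planted
1650-bp gene at enrichment 5 (~20 hits across 13 lines), where the
planted excess is large relative to the null sd of the total G;
permutation uniformity uses 60 lines × 12 genes × 200 seeds × 499
replicates; tree recovery uses 5 mutations × 90 cells × 50 seeds at the
study's fd/ad (exhaustive search); growth recovery uses 100 curves at
noise sd 0.01.  The pipeline demo (`syntroph-evo run`) runs the full
stage chain on one synthetic dataset in well under a minute.

## Known limitations

- Exhaustive tree search is limited to m ≤ 7 mutations; larger matrices
  use MCMC with no optimality certificate.
- The exact permutation fallback conditions on column margins only (the
  double-margin chain has no moves in that regime).
- The consensus filter identity key includes the evolution line, so the
  same allele observed in two lines is two variants — the right behavior
  for longitudinal tables, but different from a plain site-keyed merge.
- Growth fitting assumes a single growth phase; diauxie or death phases
  are not modelled.
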