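# Methods

This note documents the models, estimators and numerical choices behind
`claderates`, the assumptions they rest on, and what the synthetic-data
generator does and does not emulate.

## Sister-pair design

Two clades that are each other's closest relatives have, by definition, had
the same amount of time since their most recent common ancestor to accumulate
species and substitutions. Differences between them in extant species number
measure differences in net diversification; differences in molecular branch
length measure differences in substitution rate; and each pair is
statistically independent of every other pair. All analyses therefore operate
on within-pair differences, never on raw tip values.

One sequence represents each clade, to avoid the node density effect (branch
lengths inflated by passing through many reconstructed nodes). Among tips
with data, the representative of the more speciose clade is the tip separated
from the clade's basal node by the *most* intervening internal nodes, and of
the less speciose clade by the *fewest* — maximizing the difference in
cladogenetic events spanned by the two terminal branches without
reconstructing those nodes. Node counts exclude both endpoints; ties break to
the lexicographically smallest label (the rule is otherwise
relabeling-invariant).

## Codon model

Substitution follows MG94×REV: only single-nucleotide codon changes have
nonzero rate; a change at codon position *p* from nucleotide *x* to *y* has
rate `rev(x, y) · π_p(y)`, multiplied by ω when non-synonymous. The six REV
exchangeabilities are symmetric with GT fixed at 1; π is a 3×4 matrix of
positional nucleotide frequencies taken from the data (the standard F3x4
convention), and the implied stationary codon distribution is the normalized
positional product over sense codons. Stop codons are excluded from the state
space and data containing in-frame stops are rejected at parse time with the
offending coordinate — this surfaces frame errors early. The standard
(61 sense codons) and vertebrate mitochondrial (60) codes are supported.

Each branch carries two free components: a synonymous length `s` and a
non-synonymous length `n`, in expected substitutions per codon of each class
(the two generator parts are normalized to unit stationary flux, so the
components *are* the expected counts). Reported quantities: dS = s and
dN = n per codon, T = (dN + dS)/3 per nucleotide site, ω = dN/dS (undefined
when dS = 0). Keeping dN/dS per codon and T per site lets the saturation
thresholds ("> 1 per site" for T, "> 1 per codon" for dN and dS) apply
without unit conversion.

Across-site rate variation is dual: two independent discrete-gamma
distributions (equal-probability categories whose conditional means average
exactly to 1), one multiplying `s` and one multiplying `n`; site likelihoods
average over the product set of categories. Defaults are 4 × 4 categories
with estimated shapes. The category counts and the independence of the two
distributions are configurable, since "dual rate variation" admits more than
one concrete reading.

Because every branch generator `s·A_syn + n·A_nonsyn` is reversible with
respect to the stationary distribution, transition matrices are computed
exactly by symmetrization and eigendecomposition (`Φ M Φ⁻¹` with
`Φ = diag(√π*)` is symmetric); scaling-and-squaring is the fallback for
non-reversible inputs. Reversibility also makes the pruning likelihood
independent of root placement, which the tests verify. Missing codons are
fully ambiguous (partial likelihood 1 over all states); a column missing in
every taxon is an error.

## Estimation

Per pair, the fixed topology covers {representative A, representative B,
outgroup(s)}. The likelihood is maximized by bounded L-BFGS-B over all branch
(s, n) components, optionally the five free exchangeabilities (log scale) and
the two gamma shapes (log scale). Gradients with respect to branch components
are analytic (eigenframe Fréchet derivative of the matrix exponential);
the few global parameters use forward differences. Site patterns are
compressed once per fit. Starting values come from the mean pairwise codon
mismatch fraction (a moment-style initialization); further optimizer starts
jitter multiplicatively, with the number of restarts configurable (default 3,
deterministic given the config seed). The relative log-likelihood tolerance
is 1e-9 with at most 300 iterations.

Rate variation between a pair's terminal branches is tested by comparing the
free-rate fit against an equal-rate fit in which the relevant components of
the two terminal branches are constrained equal — for T the totals s + n
(with free synonymous fractions), for dN the n components, for dS the s
components — using ΔAIC = AIC_equal − AIC_free with a significance threshold
of 10. AIC = 2k − 2lnL with k the count of free parameters. Partitioned
data are handled by comparing a pooled fit on the concatenation against
independent per-gene fits, again by AIC.

Exclusion rules for contrasts: a measure is dropped when *strictly* greater
than 1 in its own unit ("saturated"; ties are retained); ω is dropped
whenever dS is (an unreliable denominator); all measures are dropped when the
pair's total divergence T_A + T_B falls below a configurable floor
("shallow", default 0.01 substitutions/site — the literature gives no number
for "too shallow or too slow", so the floor is exposed in the configuration).
Each excluded contrast carries exactly one primary reason, with precedence
shallow → saturated → missing.

## Contrasts and trait contrasts

For every variable V the raw contrast is ln(V_A) − ln(V_B), standardized by
√(T_A + T_B) so that deeper pairs (which accumulate larger differences) do
not dominate the regression; standardization never changes a contrast's
sign. Adequacy is checked by regressing |standardized contrast| on the
standardization weight (pass iff the slope's two-tailed P > 0.05; equal
weights pass trivially), and the log-transformation check applies the same
absolute-value regression to the unstandardized log-scale contrasts.

Body-mass contrasts are differences of *time-averaged* clade values under
Brownian motion of log mass: GLS ancestral expectations are computed at every
node of the clade's crown subtree from the observed tips (the BM rate
cancels; unmeasured tips contribute branches but no observations), each
branch contributes its midpoint expectation — exact under BM, since a
midpoint's tip covariances are the average of its endpoints' — and the clade
value is the branch-duration-weighted average. Stem branches are excluded
(divergence "since the most recent common ancestor" accrues along crown
lineages); this is configurable in principle and recorded here as the
package's own operationalization of a time-averaged estimator, chosen
because it reduces to the forced cases (a single-tip clade returns its tip
value; a fully observed star clade returns the mean log mass, i.e. the log
geometric mean) and is unbiased under BM by construction of the GLS
expectations. Whether the published time-averaged estimator uses path or
node weighting is not decidable from the secondary sources; the midpoint
definition is fixed here and isolated behind one function so it can be
swapped. A geometric-mean alternative, a paired t comparison of the two
methods, and a two-sided F test of equal log-mass variances (the
homogeneity assumption) are provided; an inapplicable F test (< 2 values in
a clade) passes with a note.

## Inference

Standardized contrasts have expectation zero under the null, so regressions
are forced through the origin: slope Σxy/Σx², residual df = n − 1, slope SE
from RSS on that df, two-tailed P from the t distribution, and uncentered
R² = 1 − RSS/Σy² truncated at zero.

Families of the same hypothesis across datasets are combined by a df-weighted
Stouffer Z: each regression's two-tailed P is converted to one-tailed under
the family's assumed direction (P/2 when the observed slope matches the
direction, 1 − P/2 otherwise, 0.5 for a zero slope), Z_i = Φ⁻¹(1 − P_one),
and Z_w = Σ df_i Z_i / √(Σ df_i²), with combined one-tailed
P = 1 − Φ(Z_w). Positive combined Z denotes support for the assumed
direction. Default directions: positive for substitution rate ~ clade size,
negative for rate ~ body mass and clade size ~ body mass; ω families have no
default and are combined only when a direction is given explicitly, because
no principled default exists for them. One-tailed P values of exactly 0 or 1
are clamped to 1e-12 with a warning. The dN ~ body-mass family is reported
three ways — all datasets, nuclear only, mitochondrial only — since the two
genomes are known to behave differently for this association.

## Synthetic studies

The generator emulates family-level mammalian sister pairs. Defaults (one
time unit = the clade age): speciation λ = 4 and extinction μ = 2 per lineage
per unit time, giving surviving clades of roughly 3–20 species, the typical
range for mammalian family-level comparisons; lineage rate multipliers
r ~ lognormal(0, σ_r = 0.3), about the magnitude of among-lineage rate
variation seen in mammals; terminal substitution rate 0.1 substitutions per
site per unit time (sub-saturation divergences); ω = 0.2, typical of
protein-coding genes under purifying selection; transition/transversion
exchangeability ratio 4 with uniform positional frequencies; alignments of
1000 codons; Brownian log-mass variance 0.3 per unit time from a 1 kg root;
28 pairs per study.

Each pair draws independent r_A, r_B; the multiplier scales both branch
components (a mutation-rate-like link; a mode scaling only the
non-synonymous component, mimicking an effective-population-size link that
shifts ω, is a config switch) and, through the coupling exponent β, the
clade's speciation rate λ_eff = λ·r^β. β = 0 is the exact null; β > 0
induces a positive rate–diversification association of tunable strength.
Clades are conditioned on survival by redraw (redraw counts are recorded so
the conditioning bias is auditable), and reconstructed trees contain extant
lineages only, mirroring what real data offer. As a numerical guard,
diversification freezes if a clade reaches 3000 simultaneous lineages
(the remaining time extends the surviving branches); under the default
parameters this is unreachable, and under strong coupling it bounds the
runtime of tail draws without affecting the clade-size ranks that the
analyses use. Representatives are chosen by the same node-count rule the
pipeline applies to real subtrees; alignments are evolved on the
representative pair tree (outgroup at 1.5× the clade age) by sampling from
the model's own transition matrices; everything is reproducible bit-for-bit
from (config, seed).

What the generator does *not* emulate: taxon sampling error in clade sizes,
chimeric representatives, gene-specific model heterogeneity within a pair,
non-BM body-mass evolution, correlated body mass and substitution rate, and
topological uncertainty. Passing tests therefore demonstrate internal
consistency and statistical calibration of the pipeline under its own model
class, not robustness to those real-data complications.

## Problem sizes used by the test suite

Tests scale simulations to what one CPU handles comfortably while keeping
each check statistically meaningful: parameter recovery uses 50 replicates of
10,000-codon three-taxon alignments fitted with a single rate category and
free exchangeabilities; regression calibration uses 200 null studies of 30
pairs at 100 codons with exchangeabilities fixed at their generating values
(isolating branch-length estimation and regression calibration under a
correctly specified substitution process), plus a smaller strong-coupling
batch for power; the birth–death expectation check uses 5000 pure-birth
replicates, where the Monte-Carlo error of the mean is known exactly.
Weighted-Z null uniformity uses 10,000 simulated families.

## Known limitations

- Likelihood partials are not rescaled per node; for the small fixed
  topologies used here (a handful of taxa) double precision is ample, but
  trees of hundreds of taxa would need scaling factors.
- The equal-rate model comparison treats each pair separately (the shared
  "between-pair variation" of a joint multi-pair fit is implicit in fitting
  pairs independently).
- The GLS trait estimator inverts the tip covariance matrix directly;
  clades of thousands of measured tips would want a pruning-based
  implementation.
- ω enters the meta-analysis only with an explicit direction; the package
  deliberately refuses to guess one.
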