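# Methods

## The model of a screening contest

A screening contest has G groups, each proposing a ranked list of
compounds from a shared library; the top n_g of each list are assayed.
After the cascade, group g holds k_g hits.  The evaluation model treats
every assayed compound as an independent Bernoulli trial at the pooled
hit rate p₀ = K/N, where N counts *distinct* assayed compounds and K
distinct hits: a compound proposed by several groups is assayed once,
counted once in N and K, but credited to each proposer's k_g, because
each proposer independently chose it.  Group g's p-value is the exact
upper binomial tail P(X ≥ k_g | n_g, p₀), evaluated through the
regularized incomplete beta function; the familywise error over the G
simultaneous tests is controlled by Bonferroni multiplication (capped
at 1).  The test is one-sided because the contest question is "better
than average", never "worse".

Treating p₀ as fixed ignores that it is estimated from the same data;
with ~2000 assayed compounds the extra variance is negligible relative
to the binomial variance of a single group's count, and the pooled-rate
plug-in keeps the statistic identical to standard practice for contest
scoring.

The assay-budget design quantities are closed forms of the same model:
P(no hits) = (1 − r)^n for a method with true rate r, and
`min_assays(r, q)` inverts 1 − (1 − r)^n ≥ q as ⌈log(1−q)/log(1−r)⌉
with an exact floating-point verification step.

### Power of the corrected test

Under the default synthetic geometry (one group at rate 0.04, ten at
0.005, n = 181 each), the Bonferroni-corrected α = 0.05 test needs
k ≥ 6 hits from the enriched group.  Marginalizing over
k ~ Binomial(181, 0.04) and the pooled null hits, the exact power is
≈ 0.72.  The detection property in the test suite therefore asserts
(a) detection in the majority of simulated contests and (b) agreement
of the observed detection rate with this exactly computed power within
Monte-Carlo error — a sharper check than any fixed cutoff, since an
implementation error would shift the rate away from the analytic value
in either direction.

## Plate triage

First-screen rule: a compound passes iff its replicate mean x̄
satisfies x̄ > 25 (absolute floor, % inhibition) and
x̄ > μ_plate + 3·σ_plate.  Both inequalities are strict.  Plate
statistics are computed over the **per-compound means** of that plate
(80 values on a full plate), not over the 320 raw wells, and control
wells contribute to neither; the per-compound-mean convention keeps the
threshold on the same scale as the quantity it gates.  A config switch
is not provided for the raw-well variant because the two differ only
through the replicate-noise term σ²/4, which the mean+3SD rule absorbs.
σ is the sample (n−1) standard deviation throughout; a single-replicate
compound records SD = 0 with a logged warning rather than NaN.

The second screen applies only the fixed threshold (default 50%,
strict) to re-assayed means; it deliberately does not reapply the
plate-statistic criterion, since its input is a single plate of
pre-selected strong responders whose plate mean is itself elevated.

Under pure noise the pass rate of the mean+3SD rule is bounded by the
one-sided 3σ normal tail (≈0.13%); the bound is verified by simulation
on 250 all-inactive plates.

## Dose–response

The four-parameter logistic response is

    R(c) = B + (T − B) / (1 + (c / IC50)^h)

with R(IC50) = (B+T)/2 exactly.  With this parameterization h > 0
gives a curve falling from T to B as c grows; inhibition data that
rise with concentration fit with h < 0 (or equivalently swapped
asymptotes) — the fitter is agnostic.  Fitting is unweighted nonlinear
least squares on the log₁₀-concentration axis with the midpoint
parameterized as log₁₀ IC50.  Initializer: T = mean response at the
lowest concentration, B = at the highest, h = 1, log IC50 = the
concentration whose mean response is nearest (B+T)/2; objective
tolerance 1e−8.  The 95% CI is log IC50 ± t₀.₉₇₅,df · SE from the fit
covariance, exponentiated (delta method); a residual-bootstrap
alternative is selectable.  The t critical value (df = n − 4) rather
than 1.96 keeps coverage near nominal at the small per-curve sample
sizes typical here (15 points); the coverage simulation in the test
suite measures ≈95% at 5% noise.  On an exactly-fitting curve the
covariance is numerically singular; the CI then degenerates to the
point estimate, its correct zero-noise limit.

DRR (dose–response relationship) assessment operationalizes the
qualitative exclusion of flat curves: a fit is acceptable iff the
fitted span |T − B| ≥ 30 points **and** a two-sided Spearman rank
trend test of response against concentration rejects flatness at
α = 0.05.  Both knobs are config fields.  A hit is a compound with
acceptable DRR and IC50 point estimate strictly below 10 µM — the
point estimate, not the CI bound, so a 7.0 µM compound with CI upper
limit 9.3 is a hit while a 20 µM compound is not.

## Curation

All activity comparisons are strict as printed: IC50/K_i/K_d < 10 µM,
inhibition > 30%; promiscuity means qualifying activity on ≥ 5
distinct targets ("more than four"), gated by drug-likeness.  Potency
units are normalized to µM (nM/µM/mM accepted).  Experimental
conditions attached to annotations are ignored for flagging.  With
structureless (abstract) compounds, drug-likeness is an honored boolean
field; with SMILES available, a rule-of-five evaluator (MW ≤ 500,
logP ≤ 5, HBD ≤ 5, HBA ≤ 10) is provided.  The ledger records per-rule
in-library counts before deduplication and removes the union, so
final = initial − |union ∩ library| always.

## Fingerprint analyses

Tanimoto similarity |a∧b|/|a∨b| on equal-length bit vectors, defined 0
for two empty vectors.  Novelty of a compound is its maximum Tanimoto
to the known-inhibitor set, ties broken lexicographically on id.  PCA
runs on the raw mean-centered binary matrix (no standardization, the
usual choice for MACCS keys); component signs are fixed by making each
component's largest-magnitude loading positive, so coordinates are
deterministic.  Selectivity: k-means (k-means++ init, 10 restarts,
fixed seed, best inertia kept) on fingerprints, clusters relabeled in
decreasing-size order; each (cluster, kinase group) cell is
hits/measured with the inclusive hit criterion inhibition ≥ 50%.  The
kinase grouping constant is Group 1 {Src, Fyn, Yes, Fgr}, Group 2
{Blk, Hck, Lck, Lyn}, Group 3 {Frk, Srm, Brk}.  PAINS screening
matches the A/B/C substructure catalogs shipped with RDKit; MACCS and
PAINS need the structure backend (SMILES), everything else runs on
abstract bit vectors.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical geometry* of a contest, not
its chemistry.  Defaults: a 20,000-compound library (the real campaign
screened a 2.4-million-compound vendor library; 20,000 keeps the
end-to-end run in seconds while leaving every rate estimable), 10
fingerprint clusters from random 166-bit prototypes with 5% per-bit
flip noise, 1% latent actives with true IC50 log-uniform on 0.1–5 µM
(comfortably under the 10 µM criterion, so configured proposal hit
rates survive the cascade) and true inhibition uniform on 50–100% at
the screening concentration; 11 groups proposing 400 compounds each
with 181 selected; group hit rates 0.04 for one group and 0.005 for
the rest (the detection-property geometry); additive per-plate effects
N(0, 2²)% shared by all wells of a plate and replicate noise N(0, 5²)%
— magnitudes typical of well-behaved biochemical HTS.  Control wells:
32 positive + 32 negative per full plate (an even split of the 64
non-compound wells; real layouts vary and nothing downstream depends
on the split).  Plate assignment round-robins over proposing groups so
no plate is dominated by one group, then positions are shuffled within
the plate.

Actives appear in a group's list via a Binomial(n_selected, rate) draw
placed at ranks within the selected window with geometrically decaying
probability (decay 0.03/rank), mirroring the observed front-loading of
hits in ranked proposals; ranks beyond the selection cutoff are filled
with inactives.  The realized hit fraction is therefore unbiased for
the configured rate by construction — a property the tests verify by
sample-mean over 200 seeds.

Not emulated: real structure–activity landscapes (fingerprints are
abstract bits, not chemistry), assay drift within a plate, edge
effects, compound degradation between screens, or correlated errors
between replicates.  Passing tests demonstrate that the *analysis* is
correct under the stated noise model, not that the noise model captures
every pathology of real plates.

Determinism: every generator draws from `default_rng([seed, stream])`
with a fixed stream id per stage, so outputs are byte-identical under a
fixed seed and independent of call order; the re-assay stage offsets
the seed by a fixed constant so first- and second-screen plates get
independent noise.

## Pipeline and formats

The pipeline chains simulate → curate → propose → select → first screen
→ re-assay → dose–response → hit calling → evaluation → novelty/PCA,
logging record counts at each stage and asserting the cascade nesting
(assayed ⊇ first-pass ⊇ second-pass ⊇ hits).  Selection walks each
ranked list, skips unavailable compounds and extends down the ranks to
the quota.  All tables are UTF-8 CSV with a header; reals are written
at 12 significant digits so write∘read is an identity for every
downstream verdict.  The resolved configuration (every threshold of
every stage) is written next to the outputs of each run; unknown config
keys are rejected.

## Numerical choices and degenerate inputs

- Binomial tails via `scipy.stats.binom.sf` (incomplete beta), tested
  against exact rational enumeration for n ≤ 20.
- A contest with zero hits has a degenerate null rate; evaluation
  returns p = 1 everywhere with a warning rather than failing.
- Plates with < 2 compounds cannot define a plate SD: error naming the
  plate.  Fewer than 4 distinct concentrations cannot identify a 4PL:
  error.  Non-convergent fits are flagged (drr_ok false), not raised.
- k-means with k > n compounds: error; empty clusters are handled by
  scikit-learn's re-seeding.
- Tanimoto of two all-zero vectors is 0 by convention (documented in
  the function).

## Problem sizes

Test-suite and acceptance-script simulations use 200 replicates for
Monte-Carlo properties (4PL bias/coverage, detection power, proposal
calibration), 250 plates for the null-specificity bound, a 20,000-
compound library for the end-to-end contest and a 2,382,017-id
stand-in for the full-scale curation ledger — sizes chosen so each
property's Monte-Carlo error is small against the margin it checks
while the whole suite runs in well under a minute.

## Known limitations

- The evaluation conditions on the realized pooled rate; no
  uncertainty is propagated into p₀.
- The 4PL CI is a linearized (delta-method) interval; strongly
  asymmetric likelihoods (very weak compounds, IC50 near the top
  concentration) are better served by the bootstrap option.
- The truncation analysis holds p₀ at the full-contest value, so its
  p-values answer "same hits, smaller budget", not "what would the
  pooled rate have been".
- PAINS and MACCS require parseable SMILES; abstract-fingerprint
  compounds are not evaluable there by design.
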