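# Methods

This note records the statistical models implemented in `epilogic`, the
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical decisions a maintainer would want
written down.

## Data model and coding conventions

Genotypes are biallelic dosages counting copies of the **minor allele**,
defined by allele frequency among *controls* (frequency < 0.5; ties break to
the lexicographically smaller allele). Controls approximate the source
population, so this convention keeps odds-ratio directions stable whatever
the case:control mix. Missing calls are a distinct sentinel (−1), never a
dosage, so they cannot silently enter arithmetic. Phenotypes follow the
PLINK text convention on input (1 = control, 2 = case; 0/−9 dropped with a
warning) and are stored as 0/1.

The complete-case filter removes subjects with any missing genotype among a
SNP subset. The pairwise scan uses *pairwise*-complete subjects (each pair
keeps everyone typed at both loci); logic regression requires fully typed
subjects because a Boolean tree has no natural missing-data semantics.

## Quality control and single-locus tests

- **Hardy–Weinberg**: 1-df asymptotic chi-square goodness of fit against
  expected proportions at the sample allele frequency, computed in controls.
  The gate is a loose screen (default p > 10⁻⁶), for which the asymptotic
  test is adequate; an exact test is a possible extension. Monomorphic
  samples return p = 1 by convention (no information against equilibrium).
- **Call rate** gate: non-missing fraction > 0.99 by default.
- **Allelic test**: 2×2 allele-count chi-square (two alleles per subject),
  cross-product OR, Woolf CI; Haldane–Anscombe 0.5 correction on zero cells,
  flagged. Note the allelic and trend statistics coincide exactly only when
  the *pooled* sample is in Hardy–Weinberg proportions; with per-group
  equilibrium at different allele frequencies they differ by a small
  Wahlund-type term (~0.3% at control/case frequencies 0.25 vs 0.30).
- **Trend test**: Cochran–Armitage with scores (0, 1, 2), equivalent to the
  logistic score test with null-variance p̄(1−p̄).
- **Covariate-adjusted test**: logistic regression (statsmodels) of case
  status on dosage plus covariates; BMI enters as a single linear term —
  no functional form beyond linearity is assumed. All tests are two-sided.

## Pairwise interaction scan

Model per unordered pair: logit P(case) = b0 + b1·dA + b2·dB + b3·dA·dB with
additive dosage coding; exp(b3) is the interaction OR. Inference is Wald
(CI = exp(b3 ± 1.96·SE), two-sided p); covariates are off by default in the
scan (a flag exists). FDR control is Benjamini–Hochberg step-up over all
C(k, 2) pairs; `bh_fdr` accepts a family-size override `m` so q-values can
be computed when only the smallest p-values of a larger family are in hand.

The logistic fitter is an in-house IRLS with step-halving: convergence when
max |score| < 1e-8 or relative deviance change < 1e-10, standard errors from
the observed information. Coefficients are capped at |b| = 30; a fit hitting
the cap (separation) or a singular information matrix is returned flagged
with a finite deviance, and callers decide. The fitter is cross-checked
against statsmodels `Logit` in the test suite.

## Logic regression

Each SNP yields two binary covariates against the minor allele: dominant
(dosage ≥ 1) and recessive (dosage = 2); recessive ⇒ dominant for every
subject. A model is an intercept plus coefficients on t logic trees
(AND/OR internal nodes, optionally complemented leaves). The score of a
candidate is the binomial deviance of the model with coefficients *refit*
for that candidate — correctness over speed at panel scale; speed is
recovered by noting that with t trees the likelihood depends on the data
only through the 2ᵗ cells of the tree-output cross-classification, so each
refit is a weighted IRLS on at most 2ᵗ aggregated rows (closed-form for one
tree), and revisited candidates are served from a cache keyed on the cell
counts.

**Search.** Simulated annealing over the move set alternate-leaf,
alternate-operator, toggle-complement, split-leaf, delete-leaf, grow-branch,
prune-branch, chosen uniformly among admissible (move, site) pairs; the tree
count is fixed and a total leaf budget is enforced. Metropolis acceptance:
accept if Δdeviance ≤ 0, else with probability exp(−Δ/T) under geometric
cooling; the returned model is the best ever visited. Two choices matter and
were set after instrumenting the chain:

- **End temperature 1.0** (deviance units), not a near-zero quench. Typical
  move deltas are 2–60 deviance units; below T ≈ 1 the chain freezes in its
  current basin, so a colder finish only wastes iterations. Because the
  best-ever model is returned, a warm finish strictly improves exploration.
- **Greedy polish** (`polish=True`): the best-ever model is refined by
  deterministic steepest descent over the *full* one-move neighborhood
  (every replacement leaf and sign, both operators, every prune). This
  cheaply repairs near-misses of the stochastic search; with it, best-of-5
  restarts match the exhaustive oracle on all tested 6-covariate instances.

The start temperature auto-tunes to ~90% acceptance of score-worsening moves
probed from the initial state. Default schedule length is 50,000 iterations;
the test suite uses shorter schedules with restarts on its smaller
instances. Multi-restart (taking the best of several seeded chains) is the
recommended pattern for final fits.

**Exhaustive oracle.** `exhaustive_fit` enumerates every single tree up to
3 leaves (left-nested shapes with ordered operands cover the space up to
commutativity, deduplicated by output pattern) and returns the global
minimum-deviance model. It exists to validate the annealer and is
restricted to spaces below 10⁶ candidates.

**Size selection.** Stratified k-fold cross-validation (round-robin within
class, so k = n degenerates gracefully to leave-one-out) over a grid of
(trees, total leaves); each cell's score is the mean held-out deviance under
training-fitted coefficients. Selection uses a **one-standard-error rule**:
the most parsimonious cell within one SE of the best cell wins (exact
minimization via `one_se_rule=False`). Rationale: adjacent grid cells under
weak signal differ by less than fold noise, so exact minimization picks an
arbitrary cell about half the time; treating statistically indistinguishable
cells as ties and breaking toward the smaller model gives reproducible,
parsimonious selections while leaving strong-signal selections unchanged.

**Inference.** Permutation test: shuffle case-control labels, re-run the
full search at the selected size, and compare deviances; p = (1 + #{permuted
≤ observed}) / (n_perm + 1), so p ≥ 1/(n_perm + 1). The model *size* is held
fixed at the CV-selected value and the structure is re-searched each
permutation — an honest null for the search itself; re-running CV inside
each permutation is available (`selected_size` from a nested CV call) but
costly. Deviance is one-sided by construction, so no two-sided framing is
needed.

## Risk groups

Subjects are cross-classified by the tuple of tree outputs (2ᵗ groups,
empty groups kept). Odds ratios are raw cross-tabulation odds against a
configurable reference group (default: first tree positive, others
negative); this unadjusted arithmetic is what reproduces published
count-table odds ratios exactly. Zero cells in non-reference groups get the
Haldane–Anscombe correction, flagged. Display rounding is decimal half-up to
2 places; machine outputs keep full precision. A covariate-adjusted variant
(logistic on group dummies) and Woolf CIs are provided.

## Synthetic cohorts

`simulate_cohort` draws genotypes independently per SNP in Hardy–Weinberg
proportions, BMI from a normal (mean 26, SD 4.5) truncated to [15, 62], and
disease from a prospective logistic model: baseline prevalence 0.10 at the
reference covariate pattern, per-allele main-effect ORs, dosage-product
interaction ORs, an optional Boolean risk rule with a group OR, and a
per-unit BMI OR (default 1.02). Cases and controls are accrued by rejection
sampling until the requested counts are met exactly (default 2,718 / 4,496),
then genotype calls are masked completely at random (default per-call rate
0.00125 ⇒ ~2.1% of subjects incomplete over 17 SNPs). Rejection sampling
from a prospective model keeps planted ORs interpretable as population ORs;
logistic ORs are invariant under outcome-dependent sampling, so the planted
coefficients are recovered without attenuation when the fitted model matches
the generating model. Two caveats follow and are visible in the tests: a
marginal (cross-tab) group OR is confounded when main effects act on the
same SNPs as the planted rule, and omitting a generating covariate (e.g.
BMI) attenuates interaction coefficients slightly through logistic
non-collapsibility.

Defaults emulate a 17-SNP breast-cancer candidate panel: the panel's rs
identifiers and gene labels, two planted pairwise interactions (ORs 1.16 and
1.33), and a planted 4-leaf Boolean risk rule (group OR 1.18) over common
genotype indicators. Per-SNP minor-allele frequencies are plausible
placeholders in [0.06, 0.45] — the study's true panel frequencies are not
published in the text this package draws on — chosen so the four rule SNPs
imply the reported carrier-frequency pattern. What the generator does *not*
emulate: linkage disequilibrium between loci (the panel spans many
chromosomes), population stratification, differential or informative
missingness, haplotype structure, and age structure. Passing tests therefore
demonstrate correctness of the estimators under independence and MCAR
missingness, not robustness to those real-data features.

## Problem sizes used in the validation suite

Chosen to exercise each claim at meaningful scale: type-I error of the
interaction test from 1,000 null cohorts at the pooled size n = 7,214;
CI coverage of planted interaction ORs from 500 replicates per target at
the full 2,718/4,496 split; annealer-vs-oracle equality on twenty
200-subject, 6-covariate instances; Boolean-rule recovery on one hundred
2,000-subject cohorts with 12 annealing restarts each; permutation-p
calibration on fifty 240-subject null datasets with 99 permutations; and a
full 17-SNP cross-validation + 199-permutation run at 1,000 subjects and
5 folds.

## Known limitations

- The annealer offers no convergence guarantee; deceptive landscapes exist
  (documented in the tests) where single chains settle in a wide suboptimal
  basin. Multi-restart plus polish is the mitigation, not a proof.
- The exhaustive oracle covers single trees to 3 leaves only.
- Wald inference on b3 is first-order; with sparse dosage-product cells
  (rare alleles) a likelihood-ratio or exact approach would be preferable.
- HWE uses the asymptotic chi-square; at very low minor-allele counts an
  exact test would be more faithful.
- The PED/MAP reader supports biallelic autosomal A/C/G/T sites only.
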