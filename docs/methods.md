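# Methods

## Problem setting

Case-control genotype data: S individuals typed at L biallelic SNPs.
Genotypes are coded by minor-allele copy number (0 = homozygous major,
1 = heterozygous, 2 = homozygous minor); disease status is 1 for cases and
2 for controls. The target of inference is a K-locus set (K = 2 by
default) whose *joint* genotype distribution differs between cases and
controls — an epistatic interaction, possibly with little or no
single-locus marginal effect.

## Penetrance models and the simulator

A two-locus model is a 3x3 penetrance table f(g_A, g_B) = P(disease |
genotypes) together with the minor-allele frequencies of the two loci.
Eight classic models ship as JSON fixtures (`ieaco/data/models/`): two
multiplicative and two threshold models with marginal effects, and four
models without marginal effects (two literature tables, a ZZ model and an
XOR model).

Sampling protocol (`simulate_dataset`):

- **Embedded pair.** Under Hardy-Weinberg equilibrium (HWE) and linkage
  equilibrium the population joint-genotype distribution is the product
  f_A x f_B of per-locus HWE frequencies. Conditioning on status by
  Bayes' rule gives
  `P(g, h | case) = f_A(g) f_B(h) f(g, h) / prevalence` and the
  complementary expression for controls. Cases and controls are drawn
  directly from these conditionals, which fixes the group sizes exactly
  (no rejection step) and makes every distributional property analytic.
- **Background loci** are independent HWE noise, identical in cases and
  controls, with per-locus MAFs drawn uniformly from [0.05, 0.5] by
  default (configurable). No linkage disequilibrium is simulated.
- **Prevalence** is always the HWE-weighted mean of the table
  (`model_prevalence`). For the marginal-effect models and XOR this
  reproduces the declared prevalence to three decimals (0.100 / 0.010);
  for the ZZ model and one of the literature tables the declared value is
  *not* the HWE-weighted mean (0.025 computed vs 0.038 declared for ZZ;
  0.640 vs 0.064 for model 5, which looks like a misplaced decimal in the
  original source). The tables are taken literally; the declared value is
  stored as metadata only.
- **Multiple interactions** (`simulate_multi_dataset`): each embedded
  pair is drawn independently from its own model's conditional given the
  individual's status; pairs may not share loci. This composes signals
  additively and ignores any cross-pair dependence a joint K > 2 model
  would encode — adequate for top-N retrieval experiments, not a
  substitute for higher-order penetrance tables.

The generator is deterministic given a seed (single `numpy` Generator;
draw order: background MAFs, background genotypes, pair positions if
unspecified, case cells, control cells).

What the simulator does *not* emulate: LD structure, genotyping error and
missingness, covariates/population stratification, and quantitative
traits. Tests passing on these data show correctness of the machinery
and its statistical calibration, not robustness to those real-data
complications.

## Association scoring

Fitness of a K-set is Pearson's chi-square on the 2 x 3^K table of status
against joint genotype. Columns (joint genotypes) with zero total are
dropped before computing degrees of freedom, so dof = observed
combinations - 1 (8 for a fully occupied pair). No continuity correction
and no minimum-expected-count rule: the statistic is the raw sum over
cells with positive expectation, because it doubles as the pheromone
deposit and must be comparable across sets. p-values use the upper tail
of the chi-square distribution; a table with proportional rows (or a
single occupied column) gets statistic 0 and p = 1. Reporting uses the
Bonferroni-corrected level `significance / C(L, K)`.

Calibration caveat: with rare background alleles (MAF near 0.05) some
joint-genotype cells have expected counts far below 1 and the asymptotic
null is only approximate. The test suite therefore checks exact
uniformity of null p-values on dense tables (all expected counts > 5,
Cochran's condition) and checks the dataset-level background rejection
rate at the nominal 5% level rather than distributional uniformity of
correlated pair statistics.

## The search engines

Both engines share the loop: sample M K-sets (one per ant), score all,
record the iteration's best set, update pheromones
`tau <- (1 - rho) tau + deposits`. Every ant deposits its set's
chi-square on each locus of its set, and deposits add across ants;
unvisited loci only evaporate. Candidates from all iterations are merged
(duplicates keep their highest chi-square), filtered at the Bonferroni
threshold and ranked by chi-square.

Parameters (defaults in parentheses; dimensionless unless noted):

| parameter | meaning | default |
|---|---|---|
| M `n_ants` | ants per iteration | 500 if L <= 500 else 200 |
| N `n_iterations` | iterations | 0.2 L |
| K `set_size` | loci per set | 2 |
| alpha | pheromone exponent | 1 |
| beta | heuristic exponent | 1 |
| rho | evaporation rate per iteration | 0.05 |
| tau0 | initial pheromone | 100 |
| eta | heuristic factor (scalar or per-locus) | 1 |
| gamma | negative-feedback exponent (ieaco) | 1 |
| mu | negative-feedback upper bound (ieaco) | 300 |
| theta | entropy switch threshold, bits (ieaco) | 0.001 |
| significance | level before Bonferroni correction | 0.05 |

The entropy controller records H(0), the entropy of the initial uniform
pheromones, and after each iteration the entropy of the updated vector.
Iteration 1 always uses positive feedback; iteration i >= 2 compares
|H(i-1) - H(i-2)| to theta, switching to the negative-feedback rule when
the change is *not greater than* theta. The rule is stateless — it is
re-evaluated every iteration, with no hysteresis.

Numerical and tie-break choices:

- `w_k = mu - tau_k` can reach zero or below once a locus accumulates
  pheromone beyond mu; w is floored at 1e-6 so the selection rule stays
  defined. Saturated loci thus get essentially (not exactly) zero
  selection probability under negative feedback.
- Within-set sampling is sequential without replacement with
  renormalisation, realised by rejection (redraw on collision), which is
  distributionally identical; `theta = -1` is accepted so the switch can
  be disabled for ACO-equivalence diagnostics, and `gamma = 0` collapses
  the negative rule onto the positive one exactly.
- Equal-chi-square ties for the iteration best go to the
  lexicographically smallest locus set, for determinism.
- One seeded generator drives the whole run; ants consume draws in ant
  order, so a fixed seed reproduces the run bit-identically.
- The iteration best is recorded *before* the pheromone update.

## Evaluation

- **Detection power**: fraction of datasets whose *top-ranked reported*
  interaction equals the single embedded pair (set equality; partial
  overlap is a miss). Datasets reporting nothing count as failures.
- **Recall / precision**: over per-dataset report lists, TP = truths
  recovered at any rank, FN = truths missed, FP = reports matching no
  truth; precision is 0 by convention when nothing is reported.
- **Top-N breakdown** for multi-interaction datasets: matched-truth and
  unmatched-report fractions of N, plus the fraction of truths absent
  from the top N.
- `run_power_experiment` derives independent sub-seeds (below 2^31) from
  a master seed for every simulation and search, so batch experiments are
  reproducible end to end.

## The power ceiling of the literal-table protocol

`analytic_pair_power` computes, from the noncentral chi-square
approximation, the probability that the embedded pair itself clears the
Bonferroni threshold — an upper bound on top-hit power for *any* search,
exhaustive included, since an unreported pair cannot be a top hit. At
1000 cases / 1000 controls and L = 500 the ceilings are about 0.65 for
model 1, 0.10 for model 2 and 0.53 for model 3, while the four
no-marginal-effect models and model 4 sit at 1.0 (noncentrality
lambda > 100). A test cross-checks this calculator against direct Monte
Carlo on multinomial count tables.

Two consequences. First, measured IEACO power on models 1 and 2 (about
67% and 10-17% over 30 datasets in the acceptance run) sits *at* the
ceiling: the colony essentially always finds the embedded pair, and the
loss is entirely the significance filter, not the search. Second,
published power figures above these ceilings for identically printed
tables at this sample size cannot be reproduced by any method under this
generation protocol; they imply a generator whose embedded effects are
stronger than the literal tables (e.g. heritability-rescaled
penetrances). This package keeps the literal-table protocol because it
is fully specified by the fixtures and analytically checkable; the
ceiling calculator quantifies exactly what is attainable under it.

## Problem sizes used in the shipped experiments

The acceptance script runs 30 datasets per model (500 SNPs, 1000/1000,
about one minute total); the test suite's end-to-end checks use the same
30-dataset protocol for the two multiplicative models, a 100-SNP
threshold-model recovery experiment (exhaustive C(100,2) scan plus 20
seeded colony runs), and smaller seeded fixtures for unit-level
properties. These sizes were chosen to keep a full desk run in minutes
while leaving the per-dataset protocol (sample size, search parameters)
at the study's operating point.

## Known limitations

- K-locus *search* is supported for K >= 1, but the simulator only embeds
  two-locus models.
- No LD, covariates or quantitative traits; background loci are
  exchangeable by construction.
- The chi-square fitness is the only objective (no logistic-regression,
  MDR or permutation-null alternatives).
- With default parameters and weak models, everything hinges on the
  Bonferroni filter as discussed above; at L = 5000 (200 ants, 1000
  iterations) runs are longer and power drops further as the threshold
  tightens.
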