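# Methods

This note records the statistical models, conventions and design choices
behind castekit, at the level of detail a maintainer or reviewer needs to
trust (or challenge) each stage.

## Study design being modelled

The pipeline targets comparative designs with ~nine related social-insect
species, each contributing exactly two bulk brain RNA-seq samples: one pool of
queens and one pool of workers. There is no within-caste replication, which
shapes three decisions elsewhere: the exact test fixes its dispersion, the
species scaling reduces to a single queen/worker contrast, and all
cross-validation operates on species, not samples.

## Synthetic data generator

For orthogroup *g* and species *s*:

* baseline abundance `a_g ~ LogNormal(meanlog 3, sdlog 1.2)` on the TPM scale.
  This spans roughly 1–1000 TPM with a median near 20 — a realistic bulk
  dynamic range;
* species offset `o_gs ~ Normal(0, species_sd)` on the log2 scale
  (default 0.5). This is what makes species identity the leading axis of raw
  expression variation. Offsets are independent across species — no
  phylogenetic covariance;
* a signed caste effect `e_gs` with |e| = `effect_log2fc` (default 1.0, i.e.
  2-fold): queens express `a_g·2^{o_gs + e/2}`, workers `a_g·2^{o_gs − e/2}`.
  Toolkit genes (default 150 of 3000) carry the same direction in every
  species; a `private_caste_frac` (default 5%) of the remaining genes is
  biased in exactly one random species;
* expected reads are proportional to abundance × effective length (lengths
  uniform in 500–3000 bp), scaled so each sample totals `lib_size` (default
  10^6) in expectation; counts are NB with `var = μ + φμ²`, φ = 0.1, matching
  the dispersion the exact test assumes;
* realism defects: a `dup_rate` (5%) of cells gets 2–3 isoforms whose
  expression shares are Dirichlet(1,…,1) splits; a `missing_rate` (2%) of
  cells is deleted from both the counts and the orthogroup table.

One `numpy` Generator seeded from the config drives everything; the draw
order is fixed (effects, baselines, offsets, lengths, missing mask,
duplication structure, then counts species by species, queen before worker),
so identical configs reproduce datasets exactly.

`generate_group_asymmetry` plants a shared toolkit in all species plus extra
caste genes in group 2 only, the configuration used to probe directional
transfer.

What the generator does **not** emulate: read-level artifacts, isoform
sequence structure, phylogenetic correlation of expression, caste differences
in dispersion, library-preparation batch effects, and whatever real-data
mechanism makes whole species behave as outliers. Tests passing on this
generator therefore certify the pipeline's statistical machinery, not its
robustness to every pathology of real transcriptomes.

## Harmonisation

Three regimes produce the orthogroup × (species, caste) matrix:
`strict_single_copy` (exactly one gene per species), `isoforms3` (≤3 isoforms
per cell, represented by the most highly expressed member), and
`isoforms3_na2` (additionally ≤2 species missing, imputed). Retained rows are
nested across the regimes by construction.

* "Most highly expressed" means the largest queen+worker summed **raw count**;
  the unit is a convention (TPM would change little since isoforms of one cell
  share a library), and ties break lexicographically by gene ID for
  determinism.
* Imputed cells receive a raw count of 10 in each caste and the median
  effective length of the orthogroup's present members — a neutral pseudo-gene
  with no caste contrast.
* Dropped orthogroups are recorded with reasons in the map's audit, so row
  counts remain traceable.

## Normalisation chain

Order: TPM → log2(x+1) → quantile normalisation → CPM filter → species
scaling. Conventions and the reasons for them:

* log pseudocount 1 keeps zeros finite and order intact;
* quantile normalisation is computed **globally** across all samples (not per
  species): the subsequent species scaling removes species location anyway,
  and a global reference keeps the two castes of one species on one scale.
  Ties are assigned the average of the reference values they span;
* the CPM filter drops an orthogroup when **any** species has both castes
  below 10 CPM (the conservative reading of "low in both samples"); the
  threshold is a parameter. Imputed cells are exempt from *triggering* the
  filter: an imputed count of 10 is below 10 CPM for any library over one
  million reads, so without the exemption the imputation regime would delete
  every row it rescued. Imputed values still flow into the matrix; only their
  evidential role in the filter is removed;
* species scaling `(x − m)/m` runs last, after filtering, so a zero species
  mean cannot occur on retained rows (if it does, the row is set to 0 and the
  event logged);
* with two samples per species the output is exactly antisymmetric:
  queen = −worker per (gene, species). Several downstream choices (species-
  grouped cross-validation folds, the margin tie-break) exist because of this.

## Differential expression

`nb_exact_test(q, w, lib_q, lib_w, φ=0.1)`: both counts are first rescaled to
the geometric-mean library size and rounded to the nearest integer, which
keeps the conditional support an integer grid; the test then conditions on
the total *n = q + w*. Under H0 the queen count follows the Pólya law

    P(a | n) ∝ C(a + r − 1, a) · C(n − a + r − 1, n − a),   r = 1/φ,

which is free of the unknown mean. The two-sided p-value is the sum of
conditional probabilities of all outcomes no more probable than the observed
one ("small-p sum", which guarantees p ≤ 1); a relative tolerance of 1e−12
protects the tie at the observed outcome from round-off. Both counts zero
returns p = 1. Computation uses log-gamma weights and log-sum-exp, exact over
the finite support.

The fixed dispersion is the price of n = 1 per caste: with pooled samples and
no replication there is nothing to estimate dispersion from, and φ = 0.1 is a
standard magnitude for pooled bulk libraries. When the data's true dispersion
matches, the test is exactly calibrated up to discreteness (the acceptance
suite measures type-I ≈ 0.045 at nominal 0.05 over 10,000 null genes).

Fold changes are `log2((q* + 0.5)/(w* + 0.5))` on library-equalised counts —
antisymmetric under caste swap, shrunk at low counts. FDR is Benjamini–
Hochberg within species (via statsmodels). Gene calls support two rules:
`fdr_0.05` for within-species analyses and `raw_p_0.05` for cross-species
overlap work, where per-species FDR thresholds would make set sizes
incomparable.

## Overlap statistics

A gene biased in several species counts at level *k* = the size of its larger
direction-consistent subset (so queen-in-3 + worker-in-1 counts as k = 3)
when `same_direction` is requested, else at the number of biased species.
Both "exactly k" and "at least k" histograms are reported.

The permutation null redraws, per species, a uniform random subset of the
observed set size (directions assigned by fair coin when directions matter)
and rebuilds the histogram; 1000 permutations by default from a seeded
generator. Observed-vs-expected is tested per k with a two-sided Fisher exact
test on `[observed, N − observed; round(expected), N − round(expected)]` —
the table layout is isolated in one function because other layouts are
defensible.

Hypergeometric set comparisons are one-tailed with the tail chosen by the
sign of observed − expected (expected = ab/N exactly); the fold is reported
as expected/observed for depletion and observed/expected for enrichment, and
an overlap exactly at expectation reports fold 1 with the smaller tail.

## Classifier

**Feature ranking.** Per gene, ordinary least squares of the binary caste
label (queen = 1) on expression; the slope, its t-test p-value (df = n − 2)
and a rank are recorded. The default ordering is by **p-value**, with |slope|
available behind a flag: the raw slope of caste-on-expression is Sxy/Sxx and
explodes for near-constant genes, so |slope| ordering floods the top of the
list with low-variance noise (on the planted benchmark it captured 22/150
toolkit genes in the top 20% where p-ordering captures 130/150). The
t-statistic normalises the scale away and reduces to ranking by caste
correlation. Note the p-values inherit optimism from the antisymmetric
queen/worker pairs (10 samples carry ~5 independent contrasts but df = 8 is
used, the convention of a caste-on-expression `lm` fit); they are treated as
ranking scores and a toolkit-membership heuristic, not calibrated inference.

**SVM.** Radial kernel by default (linear, polynomial, sigmoid available),
grid-searched over γ ∈ 10^{−8..−3} × C ∈ 2^{1..10} by cross-validated
accuracy. Three conventions matter:

* every fit standardises features to zero mean and unit variance inside the
  fit (a sklearn Pipeline), the default behaviour of standard SVM front-ends;
  without it the [−1, 1] species-free values sit at a scale where the entire
  γ grid degenerates to a flat kernel;
* tuning folds hold out whole **species**, not samples: a held-out sample's
  antisymmetric twin would otherwise remain in training and make every grid
  point look perfect;
* accuracy ties are broken by the mean cross-validated functional margin
  (then by grid order). On an exactly antisymmetric matrix many grid points
  reach identical CV accuracy with vanishing margins, and a vanishing-margin
  model carries no calibratable confidence. Everything is deterministic given
  the config seed.

**Calibration.** The 0–1 classification estimate is P(queen) from a Platt
sigmoid `1/(1 + exp(a·d + b))` fitted by maximum likelihood (with the
standard regularised targets) to held-out decision values. For transfer
experiments with ≥4 training species, the calibration folds re-run the
*entire* selection chain — feature re-ranking on the fold's training species,
retention cut, SVM refit — so the held-out decision values carry neither
twin-sample leakage nor feature-selection optimism and the sigmoid reflects
genuine unseen-species transfer. With 3 training species the fold-training
blocks (4 samples) are too small to re-rank informatively, so the sigmoid is
fitted on species-fold decisions of the fixed feature set instead. A fitted
slope of the wrong sign (possible on pure noise) falls back to the
uninformative sigmoid, i.e. estimates of 0.5.

**Designs.** Leave-one-species-out ranks features on the training block only
(a leakage-guard test pins this), sweeps retention fractions 0.99…0.01 (the
top ⌈f·n⌉ ranked genes), and classifies the held-out queen/worker pair.
Group transfer fixes disjoint training/test species groups. The toolkit is
the intersection of regression-significant genes (p < 0.05) over all training
rankings of a design.

**Learning curves.** The reported cross-fold validation error is fully
nested: inside each species-fold the ranking, retention cut and tuning are
redone from scratch before scoring the held-out pair. Without the nesting the
error is identically zero even on pure noise (the selection and tuning have
already seen the held-out species). On planted-signal data the nested error
falls as uninformative genes are filtered out; on nulls it stays near 0.5.

## Problem sizes and experiment settings

The packaged experiments run at desk scale: 6–9 species, 2,000–3,000
orthogroups, 10^6-read libraries, toolkit sizes of 25–150 genes, chosen so a
full suite plus the reproduction script completes in minutes while keeping
per-gene signal-to-noise at the level the dispersion implies. The transfer-
asymmetry experiment is measured at 5% feature retention: the asymmetry is a
crowding-out phenomenon — group 2's private caste genes displace shared genes
from the feature budget only when that budget is scarce — and at generous
retention both directions dilute equally with noise genes and the effect
vanishes. The no-toolkit control is summarised by the mean estimate across
species: individual null estimates scatter widely (a sigmoid fitted to ten
noisy decision values can be steep by chance), but their mean sits at 0.5.

## Known limitations

* The exact-test library equalisation rounds rescaled counts to integers;
  at very low counts with very unequal libraries this loses sub-integer
  information. The equal-library case — the only one the enumeration oracle
  pins — is unaffected.
* Regression p-values are optimistic (see above); toolkit sets are therefore
  enriched-but-contaminated candidate lists (~50% precision at the benchmark
  settings, against a 7.5% base rate), not significance statements.
* With one queen/worker pair per held-out species, per-species estimates are
  high-variance; conclusions should rest on patterns across species, as in
  the packaged experiments.
* The generator's species effects are independent draws; real phylogenetic
  structure (closely related species sharing expression quirks) would make
  leave-one-species-out easier for species with close relatives in training
  and is deliberately out of scope.
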