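# Methods

## Model

`microimpact` treats drug–microbe growth inhibition as supervised binary
classification over concatenated feature vectors. A pair (d, m) is
represented as

    x(d, m) = [ s(m) ; z(d) ]  ∈ R^(148 + 92)

where z(d) are molecular descriptors computed with RDKit from the drug's
SMILES and s(m) are KO-partitioned pathway scores of the microbe's
genome. A random forest f is fit on screened pairs with labels
y ∈ {0, 1} (1 = growth inhibition), and the **impact score** of an
unscreened pair is the forest's predicted probability
f(x) = P(y = 1 | x), i.e. the average of per-tree leaf class
frequencies. No feature scaling or class re-weighting is applied; class
imbalance is reported through the precision–recall AUC rather than
corrected for.

Assumptions worth keeping in mind: one genome stands in for each taxon
(strain-level variation in e.g. xenobiotic-metabolizing enzymes is
invisible); screens are run at a single concentration, so the label is a
threshold on inhibition rather than a dose–response; and community
context (cross-feeding, host factors) is outside the model.

### Drug featurization (`chemspace`)

- SMILES are canonicalized and salts stripped to the largest organic
  fragment before featurization, because drug-library SMILES frequently
  carry counter-ions that would distort descriptors.
- The descriptor registry is an ordered list of 92 RDKit descriptor
  names shipped with the package, covering lipophilicity (MolLogP),
  partial-charge surface areas (PEOE_VSA1–14), polarity (TPSA),
  hydrogen bonding (donor/acceptor/NHOH/NO counts), shape (Kappa1–3),
  connectivity (Chi indices), size (MolWt and relatives), and
  electrotopological surface terms. The registry is a package choice —
  any list of valid RDKit descriptor names can be substituted — but its
  order is fixed within a run so models, catalogs and importance reports
  line up column-for-column.
- Descriptors that evaluate to NaN/inf (typically partial-charge terms
  on unusual atoms) are imputed with the library median by default
  (`zero` and `none` policies available); affected drugs are flagged.
- Molecular similarity is the Tanimoto (Jaccard) coefficient on hashed
  topological path fingerprints (2048 bits, path lengths 1–7, RDKit
  defaults). Two empty fingerprints get similarity 0 with a warning —
  empty fingerprints cannot meaningfully be "similar". Nearest-neighbour
  queries exclude the query id and break ties lexicographically so
  results are deterministic.

### Microbe featurization (`genomefeat`)

The score of pathway p for a genome with KO copy counts c(k) is

    score(p) = Σ_{k ∈ p} c(k) / m(k)

where m(k) is the number of pathways containing k. This equal 1/m
partitioning is the simplest defensible reading of "counts partitioned
among pathways"; iterative support-weighted partitioning schemes exist
but are deliberately out of scope (the equal split keeps the key
conservation property Σ_p score(p) = Σ mapped c(k) exact, which the test
suite asserts to 1e-9). Fractional counts are accepted so that predicted
per-ASV KO profiles (PICRUSt2-style output) run through the same code.
The packaged 148-pathway registry fixes column identity and order;
pathways absent from a supplied map score 0 rather than being dropped.

### Training defaults (`model`)

500 trees, Gini impurity, sqrt-p feature subsampling, out-of-bag
estimate stored, single-threaded for determinism; all randomness flows
from an explicit seed, and a trained model records seed, hyperparameters
and a dataset content hash so catalogs are auditable. The impact score
is the forest probability rather than a hard vote; with
`min_samples_leaf=1` the two coincide up to leaf purity. Evaluation
batteries and tests typically run 100–150 trees — AUCs change by well
under 0.01 relative to 500 trees at these problem sizes, and the battery
refits hundreds of forests.

## Evaluation (`evaluation`)

ROC AUC is the Mann–Whitney probability P(score₊ > score₋) + ½P(tie);
PR AUC is average precision (step-wise, no linear interpolation — the
trapezoidal PR interpolation is optimistic). Both require both classes.

Four hold-out schemes of increasing difficulty:

1. **Pair-level k-fold CV** (default k=10): folds partition *pairs*, so
   both the drug and the microbe of a test pair are usually seen in
   training with other partners — the "new interaction" setting. Splits
   are unstratified and seed-controlled; pooled (micro) AUC over all
   held-out predictions is the headline number and is invariant to fold
   order by construction. Repeats rerun the whole CV on fresh shuffles
   and report mean ± sd.
2. **Leave-one-drug-out**: all pairs of one drug held out; optionally
   all training drugs with Tanimoto similarity ≥ cutoff to the held-out
   drug are excluded too (retention is strictly < cutoff; the drug
   itself is always excluded). Per-drug diagnostics report the
   nearest-neighbour Tanimoto distance within the retained compounds and
   the training-compound count. Pooled and per-drug (macro) AUCs are
   both emitted, since either convention is defensible. A drug whose
   cutoff empties its training set is reported unevaluable rather than
   silently skipped.
3. **Leave-one-microbe-out**: per-strain held-out AUCs; when a
   precomputed phylogenetic distance matrix is supplied, the Pearson
   correlation between per-strain AUC and distance to the nearest
   training strain is reported (undefined — and reported as such — when
   distances are constant). Tree construction itself is out of scope;
   distances are consumed as a matrix.
4. **Leave-phylum-out**: per strain, every same-phylum strain is removed
   from training. Strains alone in their phylum are skipped, because for
   them the scheme degenerates to leave-one-microbe-out.

All schemes share one training path, which the test suite instruments to
assert structurally that no held-out unit ever appears in its own
training split.

## Permutation importance (`importance`)

Observed importance is the forest's mean decrease in impurity (an
impurity-corrected variant would be preferable but is not available in
the underlying library; the choice is recorded in the report metadata by
construction of the module). Significance follows the
response-permutation scheme: refit the forest on label-permuted data
n_perm times and set

    p_j = (1 + #{null_j ≥ observed_j}) / (1 + n_perm)

with BH-FDR across all model features. p-values therefore have a floor
of 1/(n_perm+1) and are never 0; constant features get importance 0 and
p = 1.

The importance forests default to `max_features="log2"` rather than
sqrt. With impurity importance, generous feature subsampling lets the
strongest feature of a correlated block win most splits, depressing the
observed importance of its correlates below their permuted-label null
and making their p-values conservative; low subsampling spreads splits
across the block so genuinely informative features each clear their
null. This matters because BH across 240 features with a 1/101 floor can
only reach q < 0.05 when ≥ 48 features sit at the floor — a breadth that
real screens show (dozens of significant pathways and descriptor
families) and that the low-subsampling forest recovers on synthetic
screens.

Per-strain profiles fit one forest per strain on that strain's pairs;
microbe features are constant within a strain, so only drug features
enter. Profiles are ordinated by PCA, and group separation (phylum, gram
stain) is tested by PERMANOVA on Euclidean distances (scikit-bio;
cross-checked in tests against a direct sum-of-squares pseudo-F).
A generic `compare_reports` utility (Pearson + paired Wilcoxon) serves
comparisons such as full-library vs human-targeted-only models.

## Landscape analytics (`landscape`)

Impact index = mean impact score of a drug over all taxa; sensitivity
index = mean score of a taxon over all drugs; both demand a complete
catalog cross product and satisfy exact bookkeeping
(Σ_d index(d) × |taxa| = Σ scores). Group comparisons use
Kruskal–Wallis with ε² = H/(n−1) (the common small-sample form; other ε²
variants exist) plus pairwise two-sided Wilcoxon rank-sum with BH-FDR;
groups under 2 members are dropped with a warning.

Phylum specificity: Δ(d) = mean impact on Firmicutes − mean impact on
Bacteroidetes. Drugs in the top Δ quartile are `firmicutes-specific`,
bottom quartile `bacteroidetes-specific`, middle half `non-specific`
(type-7 quantiles; ties resolve to the lower class, so the 25/50/25
partition is exact in the absence of ties). The sign convention is
chosen so that a drug harming only Firmicutes lands in the top quartile
and is called firmicutes-specific. Per-drug significance is a two-sided
Wilcoxon across the two phyla's taxon score sets, BH-FDR corrected.
Classes are invariant to monotone rescaling of scores since only the Δ
order matters.

The drug-target screen compares impact scores of taxa carrying a KO
homolog of a known target vs those without (two-sided Wilcoxon, ≥ 3 taxa
per side, BH-FDR across tested (drug, KO) pairs, direction = sign of the
median difference). It measures functional association, not structural
identity.

## In-vivo dysbiosis pipeline (`invivo`)

Preprocessing of a longitudinal before/after study: drop samples under
1000 reads; keep ASVs whose relative abundance exceeds 0.5% in at least
0.5% of retained samples (rounded up to ≥ 1 sample, so the rule is
meaningful in small studies); renormalize rows to sum 1; average
multiple samples of the same subject and phase; exclude subjects with
only one phase. The operation is idempotent.

Abundance change per ASV is a Welch two-sample t (after vs before;
negative = depleted). Pairing the test on subject ids is available but
not the default, since pooling pre/post samples is the more conservative
reading when the design is unclear. ASVs with zero variance in both
phases and equal means get t = 0 (and are excluded from the dysbiosis
groups, counted in the result); unequal means with zero variance are
undefined and excluded with a note.

The dysbiosis test is a two-sided Wilcoxon rank-sum of predicted impact
scores between depleted (t < 0) and enriched (t > 0) ASVs, with
rank-biserial effect size r = 2U/(n₁n₂) − 1 (U taken for the depleted
group, so r > 0 means depleted taxa scored higher — the direction
expected under true drug impact). The p-value is invariant to monotone
transformations of the scores. The shuffled-feature control permutes the
ASV-to-feature-vector assignment before prediction and repeats the test;
with any real signal the resulting p-values are uniform.

Cohort agreement consumes a summary-association table (taxon, drug
group, signed effect size): observed drug impact = mean effect size over
its associated taxa, observed taxon sensitivity = mean over its drugs;
predicted values are averaged over group members when groups map to
several catalog ids; Pearson and Spearman correlations are reported
(negative under agreement), and drug groups with strictly more than 30
associations get a two-sided Wilcoxon of predicted scores between
negatively and positively associated taxa.

## Side-effect association (`adverse`)

Adjusted frequency per (drug, term) = mean over non-placebo sources −
mean over placebo arms, floored at 0; terms reported for fewer than 50
drugs are dropped. Category frequencies average over the full member
list with absent terms contributing 0 (the alternative reported-only
mean is available via a flag); the gastrointestinal (11 terms) and
infection (5 terms) lists ship with the package. High-vs-low impact
comparison is a two-sided Wilcoxon at a 1% frequency threshold;
specificity-class analysis is a one-way ANOVA across the three
specificity classes with the percent difference between the two specific
classes reported. Terms are matched as literal preferred-term strings;
no ontology resolution is attempted. The analysis is intended for
non-antibiotic drugs (filter on `drug_class`).

## Synthetic data (`synthetic_data`)

The generator produces every input with planted ground truth:

- **Drugs**: `descriptor-space` mode samples descriptor vectors from
  configured marginals (a handful of realistic lognormal/normal
  defaults, standard normal otherwise) — fast and exactly controllable;
  `smiles-fixture` mode enumerates substituted variants of ten simple
  scaffolds (benzene, pyridine, indole, piperidine, ...) × twenty
  substituents, so the real RDKit descriptor and fingerprint code paths
  run and descriptors carry realistic collinearity. Each fixture drug
  records its scaffold family.
- **Genomes**: a birth–death tree (birth 1, death 0) with n extant
  tips; per KO a Brownian trait is evolved along the tree and mixed
  with an independent normal component, trait = √s·z_BM + √(1−s)·z_iid,
  s = `phylo_signal` ∈ [0, 1]; presence is the trait exceeding a per-KO
  threshold drawn for 25–75% marginal carriage. The two basal clades are
  labelled Firmicutes and Bacteroidetes so phylum-level analytics run
  unmodified, and each phylum's first internal split provides gram-stain
  labels. Patristic distances are returned as the distance matrix.
- **Labels**: Bernoulli(σ(β₀ + β_drug·z(x_d) + β_microbe·z(x_m) +
  β_int·z_d1·z_m1 + family effect + ε)) over the full cross product,
  with z the library z-score of each causal feature and an optional
  per-scaffold-family random intercept (structurally similar drugs share
  activity). The default β₀ = −1.81 gives ≈ 1/(1+e^1.81) ≈ 0.14
  prevalence under a null rule, about a 1:6 class imbalance; the default
  causal pair is MolLogP (lipophilicity) and ko02010 (ABC transporters),
  echoing the membrane-permeation/efflux story of real screens. A
  degenerate all-0/all-1 realization is resampled once, then raises.
- **Longitudinal studies**: subject baselines are Dirichlet draws around
  a shared community profile (concentration 50); treatment multiplies
  each taxon by exp(−effect_strength × impact) and renormalizes
  (compositional depletion); reads are multinomial at depth 10,000,
  with optional shallow samples to exercise the read-depth filter.

What the generator does *not* emulate: real chemistry beyond small
scaffolds (no ring fusion diversity, no stereochemistry), genome-scale
KO counts (hundreds rather than thousands of KOs), ecological
interactions between taxa, sequencing biases beyond multinomial
sampling, and confounding between treatment and other covariates.
Passing tests therefore demonstrate that the pipeline recovers planted
structure under its own model assumptions — not that those assumptions
hold for any particular real dataset.

## Problem sizes and numerical choices

The test and acceptance batteries choose simulation scales that balance
statistical resolution against refit counts: CV recovery uses a
150-drug × 40-taxon screen (6000 pairs, prevalence ≈ 0.33 under the
default rule at strength 2.5); the similarity-hardness battery uses 60
SMILES-fixture drugs × 20 taxa with a strong scaffold-family effect
(family_sd = 2), where the Tanimoto-exclusion sweep (cutoffs 0.9 → 0.3)
removes progressively more of the informative same-family compounds;
importance recovery uses 120 drugs × 35 taxa with phylo_signal 0.9 and
rule strength 3 (4200 pairs), the scale at which enough correlated
features clear the permutation floor for BH to resolve q < 0.05; the
dysbiosis battery runs 50 replicate studies of 20 subjects × 40 taxa.
Forests in the batteries use 100–150 trees (see above).

Other numerics: exact Mann–Whitney p-values are used automatically at
small n without ties; quantiles are type-7 (linear interpolation);
PERMANOVA p-values come from 999 label permutations by default; BH is
the standard step-up procedure; the Welch t is undefined (and the ASV
excluded) only when both phases have zero variance and different means;
all generators, fits and permutation tests are driven by explicit seeds
and single-threaded, so identical configurations reproduce identical
outputs byte-for-byte.

## Known limitations

- Equal 1/m KO partitioning ignores pathway support; pathway scores for
  heavily shared KOs are correspondingly diffuse.
- Mean-decrease-impurity importance is biased toward high-cardinality
  features; the permutation null corrects the significance calls but
  the raw importance values retain the bias.
- The impact score is an uncalibrated forest probability; treat it as a
  ranking score, not a calibrated inhibition probability.
- The per-drug Wilcoxon in phylum specificity tests *location* shift
  between phyla score sets; a drug can be called specific by quartile
  yet non-significant with few taxa per phylum.
- The cohort-agreement analysis inherits whatever confounder adjustment
  the upstream association table applied; none is added here.
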