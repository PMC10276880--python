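# microimpact

Predicting the impact of small-molecule drugs on gut-microbiome members
from chemistry and genome content.

Many common medications inhibit the growth of commensal gut bacteria, but
pairwise drug × microbe screens cover only a tiny corner of the space of
approved drugs and resident taxa. `microimpact` implements a data-driven
framework for extrapolating from such screens: each drug is featurized
from its SMILES string (92 physicochemical and topological descriptors —
lipophilicity, partial-charge surface terms, TPSA, hydrogen-bonding
counts, kappa/chi indices, molecular weight, ...), each microbe from its
KEGG Orthology (KO) annotation (148 pathway scores, with multi-pathway
KOs partitioned equally among their pathways), and a random forest is
trained on binary growth-inhibition labels over (drug, microbe) pairs.
The forest's predicted probability of inhibition for an unscreened pair
is its **impact score** in [0, 1].

Around that core the package provides:

- **Similarity- and phylogeny-aware evaluation** — pair-level k-fold CV,
  leave-one-drug-out with Tanimoto-similarity exclusion of related
  training compounds, leave-one-microbe-out with phylogenetic-distance
  diagnostics, and leave-phylum-out (ROC AUC and average-precision PR AUC).
- **Permutation feature importance** with per-feature significance
  (response-permutation null, BH-FDR), per-strain importance profiles,
  their PCA ordination, and PERMANOVA tests of phylum / gram-stain grouping.
- **Interaction-landscape analytics** over an impact-score catalog:
  per-drug impact indices, per-microbe sensitivity indices, Kruskal–Wallis
  comparisons across ATC / target-class groupings (with ε² effect size),
  Firmicutes-vs-Bacteroidetes specificity calls, and a Wilcoxon screen for
  drug-target homologs (KO presence vs impact score).
- **An in-vivo dysbiosis pipeline** on processed 16S ASV tables:
  read-depth / prevalence / abundance filtering, per-ASV abundance-change
  t-statistics before vs after treatment, and a Wilcoxon rank-sum test of
  predicted impact between depleted and enriched ASVs, plus a
  shuffled-feature negative control and a cohort-summary agreement analysis.
- **Side-effect association** — placebo-adjusted adverse-event frequencies,
  gastrointestinal / infection category means, and tests linking predicted
  anti-commensal activity to side-effect incidence.
- **A synthetic-data module** that generates every input with planted
  ground truth (descriptor-space or real-SMILES drug libraries, KO-annotated
  genomes evolved on a random phylogeny, logistic planted interaction rules,
  longitudinal before/after studies), so the whole pipeline is testable
  offline.

Featurizers and the classifier follow scikit-learn conventions
(`fit`/`transform`/`predict_proba`, `get_params`), so they compose with
sklearn pipelines and model selection.

## Worked example

```python
from microimpact import synthetic_data as sd
from microimpact.genomefeat import build_feature_matrix
from microimpact import evaluation, model

# a synthetic screen: 60 real-SMILES drugs x 20 KO-annotated genomes,
# labelled by a planted logistic rule on lipophilicity (MolLogP) and an
# ABC-transporter-like pathway (ko02010)
drugs = sd.gen_drugs(60, seed=7, mode="smiles-fixture")
pmap = sd.gen_pathway_map(seed=7)
panel = sd.gen_genomes(20, pmap, seed=7)
microbes = build_feature_matrix(panel.records, pmap)
rule = sd.default_rule(2.0)
screen = sd.plant_labels(drugs.features, microbes, rule,
                         seed=8, families=drugs.families)

cv = evaluation.kfold_cv(screen, k=10, seed=9,
                         hyperparams={"n_estimators": 100})
print(f"10-fold CV: ROC AUC {cv.roc_auc:.3f}, PR AUC {cv.pr_auc:.3f}")

trained = model.train(screen, hyperparams={"n_estimators": 100}, seed=9)
catalog = model.predict_impact(trained, drugs.features, microbes)
print(catalog.head(3))
```

Output:

```
10-fold CV: ROC AUC 0.914, PR AUC 0.837
  drug_id microbe_id  impact_score
0   d0000      m0000          0.00
1   d0000      m0001          0.01
2   d0000      m0002          0.04
```

The CV AUCs say the forest recovers the planted interaction rule well
above chance (label prevalence here is ~0.31); each catalog row is the
predicted probability that the drug inhibits growth of that microbe.

A command-line interface mirrors the library
(`microimpact simulate|featurize-drugs|featurize-genomes|train|evaluate|predict|importance|landscape|invivo|adverse|run`).

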