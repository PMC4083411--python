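# easemm

Sequence-based classification of mutation-induced protein stability changes
with **feature-based multiple SVM models** (EASE-MM-style consensus).

## The problem

A single amino-acid substitution changes a protein's unfolding free energy
by ΔΔG<sub>u</sub> = ΔG<sub>u</sub>(mutant) − ΔG<sub>u</sub>(wild-type)
(kcal/mol). Predicting whether a variant is *stabilising*
(ΔΔG<sub>u</sub> ≥ 0) or *destabilising* (ΔΔG<sub>u</sub> < 0) from sequence
alone matters for protein design and for interpreting disease-associated
variants, where no structure is available. The difficulty is that different
interactions govern stability in exposed vs buried residues and in helix,
sheet and coil — a single pooled model averages over regimes with different
relevant features.

## The method

Five RBF-kernel SVMs are trained on partitions of the data:

* by predicted solvent exposure — *exposed* / *buried* at a 25% relative-ASA
  threshold (strictly >25% is exposed), and
* by predicted secondary structure — *helix* / *sheet* / *coil* (argmax of
  the predicted probabilities, ties resolved H > E > C).

Each model gets its own feature set, chosen by sequential forward floating
selection (SFFS, budget 10 additions, best visited combination kept,
CV-AUC objective), and its own SVM parameters from a grid search over
C ∈ {2⁻⁵, 2⁻³, …, 2⁷}, γ ∈ {2⁻⁷, 2⁻⁵, …, 2¹}, w ∈ {1, 1.5, 2, 2.5, 3}
(175 combinations; w weights errors on the minority stabilising class).
A mutation is routed to one exposure model (method *EASE-ASA*) and one SS
model (*EASE-SS*); the consensus probability is exactly

P<sub>MM</sub> = ½ (P<sub>ASA</sub> + P<sub>SS</sub>)

Features per mutation (27 selectable groups, 51 values): SIFT substitution
tolerance; ΔM, the PSSM log-odds difference (introduced − deleted)/10; for
each of 11 amino-acid scales normalised into [−0.9, 0.9], the Δ value
(mut − wt) and mean/min/max over six neighbouring residues (three per side,
site excluded); predicted SS probabilities, relative ASA, and disorder.

Evaluation is *unseen-protein* cross-validation: homology clusters
(>25% identity) never straddle folds, folds are balanced in size and class
ratio, experiments are replicated with fresh folds, and methods are compared
with paired t-tests. Metrics: MCC, Q2, Se, Sp, PPV, NPV, and ROC AUC, with
decision thresholds optimised for maximum MCC.

Feature significance is additionally estimated by *stability selection*:
k = 100 repetitions of plain forward selection on random half-subsamples;
a feature's significance is its selection probability.

## Worked example

```bash
easemm simulate --out bundle --seed 3 --n-proteins 15 \
    --mutations-per-protein 24 --effect-size 1.5
easemm curate bundle --out curated.txt          # 360 curated records
easemm train bundle --out bank.joblib --budget 4 --grid fixed --seed 1
easemm predict bundle --bank bank.joblib --out predictions.tsv
easemm evaluate bundle --out-dir eval --method ease-mm --method single \
    --folds 5 --reps 2 --seed 2 --select-budget 10
```

The evaluate step prints, for this seed:

```
ease-mm: AUC 0.862 MCC 0.548 (2 replicates)
single: AUC 0.738 MCC 0.400 (2 replicates)
```

i.e. on data where exposed, buried, helix, sheet and coil mutations carry
*different* informative features, the routed multiple-model consensus
separates stabilising from destabilising variants clearly better than one
pooled model — the central claim this package exists to express.
`predictions.tsv` holds one row per mutation: the two routes, the two
method probabilities, their exact mean, and the thresholded label.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch at the given seed: generates a
heterogeneous synthetic bundle with injected duplicate measurements,
round-trips it through the file formats, curates it (averaging
same-condition replicates, keeping the measurement closest to pH 7,
cluster-level de-duplication), runs per-category SFFS, and evaluates the
consensus against a pooled single model with replicated unseen-protein CV,
logging curation counts, selected features, and per-method metrics to
stderr before writing the JSON results file.
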