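# Methods

## Model

The package classifies single amino-acid substitutions as stabilising
(ΔΔG<sub>u</sub> ≥ 0 kcal/mol; the positive class — zero counts as
stabilising) or destabilising, from sequence-derived inputs only. Rather
than one pooled classifier, five RBF-kernel SVMs specialise on partitions
of the training data:

* **exposure axis** — exposed vs buried at a relative-ASA threshold of 25%,
  strictly greater than 25% meaning exposed (a site at exactly 25% is
  buried); when an explicit exposed/buried provider category is present it
  takes precedence over the rASA-derived one;
* **secondary-structure axis** — helix/sheet/coil by argmax of the
  predicted 3-state probabilities, ties broken by the fixed priority
  helix > sheet > coil.

At prediction time the mutation is routed to exactly one model per axis;
the exposure-routed probability (EASE-ASA), the SS-routed probability
(EASE-SS), and their exact arithmetic mean (EASE-MM) are all reported. The
equal ½/½ weighting is fixed; class probabilities come from a Platt-style
sigmoid fitted on the SVM decision value by cross-fitting within the
training partition (scikit-learn `CalibratedClassifierCV(..., ensemble=False)`).
An uncalibrated mode substitutes a plain logistic link on the decision
value; it changes nothing that depends only on score ranking (AUC).

The SVM error weight `w` applies to the stabilising class, which is the
minority (~28%) in experimental data. Parameters come from a 10-fold
inner-CV grid search over the 7 × 5 × 5 grid
C ∈ {2⁻⁵…2⁷}, γ ∈ {2⁻⁷…2¹}, w ∈ {1…3}, objective mean AUC, ties resolved to
the smaller C, then γ, then w. The grid objective is not stated anywhere
authoritative; AUC was chosen for consistency with the feature-selection
objective.

## Features

27 selectable groups, 51 values total, in a fixed canonical order:

| group | arity | definition |
|---|---|---|
| SIFT score | 1 | substitution tolerance in [0,1], ingested from a provider table |
| ΔM | 1 | (PSSM log-odds of introduced − deleted residue)/10; log-odds block of the PSI-BLAST ASCII PSSM; values are not clipped to [−1,1] |
| Δ scale (×11) | 1 each | normalised scale value(mut) − value(wt) |
| window scale (×11) | 3 each | mean/min/max of the scale over ≤3 residues each side of the site, site excluded, truncated at termini |
| SS probabilities | 3 | (H,E,C), renormalised to sum 1 at load, no argmax collapse |
| rASA | 1 | predicted relative accessible surface area |
| disorder | 1 | predicted disorder probability |

The "window of six neighbouring residues" is read as three per side
excluding the mutated position; the half-width is a parameter
(`half_width`, default 3). Multi-valued groups (a window trio, the SS
triple) are selected or dropped as one unit in feature selection.

The 11 amino-acid scales (hydrophobicity, volume, polarisability,
isoelectric point, helix tendency, sheet tendency, steric parameter,
flexibility, compressibility, bulkiness, COOH ionisation constant) ship as
raw literature values (Kyte–Doolittle, Zamyatnin, Charton–Charton,
Zimmerman, Chou–Fasman, and standard physico-chemical compilations) and
are min-max normalised into [−0.9, 0.9] per scale; the normalisation
contract (both endpoints attained, all values in range) is what tests
enforce, not the raw values themselves.

## Data curation

Input measurements (protein id, wt, position, mut, ΔΔG<sub>u</sub>, pH,
temperature) are curated in a fixed order: (1) drop non-finite ΔΔG, logged;
(2) within each substitution, average measurements whose conditions agree —
pH and temperature both within 0.05 absolute, missing matching missing
(temperature is carried and used in this equality key but in no other
rule); (3) across conditions keep the measurement closest to pH 7, ties to
the lower pH; (4) label; (5) within each homology cluster (>25% identity,
cluster map is an input) keep one record per (wt, position, mut) key, same
pH rule. The pipeline is idempotent and insensitive to input row order;
each step's drop count is logged. Substitution identity across homologs
uses each protein's own numbering — no alignment is attempted.

## Feature selection

SFFS adds the best-scoring feature each iteration and then removes
features while a removal *strictly* improves the score (no tolerance —
prevents oscillation), until 10 cumulative additions; every visited
combination is registered and the registry best is returned. During
selection the SVM parameters stay fixed; the grid is re-run only for the
final chosen set (full per-candidate nesting would multiply cost by 175 and
the evidence it changes outcomes is absent). Stability selection runs plain
SFS (early stop when no addition improves, hard cap 10 for symmetry) on
k = 100 random half-subsamples (size ⌊n/2⌋, without replacement,
single-class draws redrawn with a retry cap) and reports per-feature
selection probabilities. Both searches are generic over an
`evaluate(set) → score` callback; two factories are provided — a
sklearn-estimator CV-AUC evaluator, and a fast least-squares linear
discriminant CV-AUC evaluator (an OLS fit of the ±1 class indicator is a
monotone proxy for Fisher's discriminant) used where thousands of
evaluations are needed.

## Evaluation

Unseen-protein k-fold CV: clusters are assigned whole to folds by a greedy
largest-first rule minimising (fold load fraction + |fold positive rate −
global rate|), equal-cost choices broken by a seeded shuffle. The load term
is a fraction of the ideal fold size rather than a distance to it — a
distance term prefers topping up an almost-full fold over starting an empty
one and degenerates badly. The achievable class-ratio deviation is bounded
by fold granularity; with realistic density (tens of clusters, folds of
≥50 mutations) the generator stays within the configured tolerance of 0.15.

Per replicate: fresh seeded folds; per fold, the method is trained on
out-of-fold data, the decision threshold is optimised for maximum MCC on
the *training* scores (candidates are midpoints of consecutive sorted
unique scores plus sentinels; ties keep the lower threshold), and the
held-out fold is scored. Pooled held-out scores give the replicate's AUC;
pooled thresholded labels give MCC/Q2/Se/Sp/PPV/NPV. Optimising the
threshold on training rather than held-out scores keeps null-data MCC
unbiased (a max-over-thresholds on the evaluation data is positively
biased). Metric conventions: MCC with a zero marginal is 0; a rate with a
zero denominator is NaN (undefined-marked), never an exception. Replicates
are summarised as mean ± sd and compared with two-sided paired t-tests
(zero-variance differences reported as the exact limit with a warning;
p-values unadjusted). Breakdown bins for per-category analysis use supplied
true-structure tables, never the routing predictions: SS ∈ {helix, sheet,
coil}; ASA ≤25%/>25% and [0,20)/[20,40)/[40,60)/[60,100]; |ΔΔG| small
(closed interval [−1,1]) vs large.

## Synthetic data

The generator emulates the development data's composition: 28% stabilising,
~24 mutations per protein, homology clusters of 1–3 proteins, roughly
balanced exposure (47% exposed), SS composition 35/25/40 H/E/C. Labels are
Bernoulli; ΔΔG magnitudes are folded Gaussians with the sign forced by the
label. Each category can plant one informative descriptor: the
class-conditional mean of its underlying input (SIFT, disorder, the PSSM
score difference, or the Δ of a scale via nearest-letter choice of the
mutant residue) is shifted by `effect_size` × the input's noise sd; all
other inputs are exchangeable noise. Provider tables are consistent by
construction (exposure ↔ rASA threshold, SS argmax ↔ true category), and
cluster members mutate disjoint strided positions so homologs never collide
on a substitution key by accident. Injected duplicates are engineered to be
removed by exactly one curation step each, so drop counts are exactly
checkable.

What a green simulation test does establish: the pipeline's machinery —
routing, per-category selection, consensus, homology-aware CV — extracts
planted heterogeneous structure and refuses to find structure in pure
noise. What it does not establish: real-data performance. The generator has
no protein energetics, no PSSM biology, no sequence homology beyond cluster
labels; Gaussian class-conditional features were chosen because they admit
analytic AUC expectations, not because stability data looks Gaussian.

## Numerical and scale choices

* Simulation-backed acceptance checks run 5-fold CV on datasets of 240–420
  mutations with fixed mid-grid SVM parameters (C=2, γ=2⁻³, w=2) instead of
  10-fold at n=1676 with the 175-point grid per fold — a single-CPU budget
  decision; replicate counts, effect sizes and statistical thresholds of the
  checks themselves are unchanged (30/20 replicates, 1.5 sd, k=100).
* Planted effect size 1.5 sd across the simulation checks matches the
  stability-selection power setting and is used consistently rather than
  per-test.
* ΔΔG is written to 2 decimal places (kcal/mol); typical database precision.
* Model bundles are joblib archives with a format version; loading a
  mismatched version or an incomplete bank is an explicit error.

## Known limitations

* The ">230" sign corrections applied to the original database extraction
  are not reproducible (sources unlisted); curation assumes input signs are
  correct.
* Reproducing the published real-data numbers (CV MCC 0.44 / AUC 0.82;
  independent-test MCC 0.47 / AUC 0.85) requires SIFT against
  Swiss-Prot/TrEMBL, PSI-BLAST against NCBI nr, SPINE-X/SPINE-D/ACCpro and
  BLASTCLUST runs plus the curated experimental datasets; this package
  provides the provider-file interfaces but does not execute those tools.
* Binary classification only: no ΔΔG regression, no three-state mode.
* The confidence-weighted consensus discussed as a possible refinement is
  not implemented; the weighting is fixed at ½/½.
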