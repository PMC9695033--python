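# Methods

This document records the modeling choices, default parameters and numerical
conventions of the package, including places where a common textbook
definition was deliberately not used and why.

## Fingerprints

`fingerprints.ecfp` computes ECFP_n circular fingerprints as sparse sets of
hashed environment identifiers (RDKit Morgan generator, sparse count
fingerprints, default atomic invariants). `n` is the environment
*diameter*: ECFP_6 hashes out to radius 3. All radii from 0 up are
retained, so the identifier set at a larger diameter is a superset of the
smaller-diameter set. Identifiers stay unfolded (no fixed-length bit
vector), so every identifier maps back to a depictable substructure for
fragment analysis.

Tanimoto similarity is `|A∩B| / |A∪B|` over identifier sets; two empty
fingerprints are defined as identical (Tc = 1). `dataset_diversity`
averages all unordered pairs exactly up to a 2,000,000-pair budget, then
switches to seeded uniform pair sampling and marks the report as sampled.

## Chemical-space diagnostics

`chemspace` provides ~22 registered descriptors. Three conventions deviate
from the most common definitions:

- **Fractional polar surface area** is the share of Labute approximate
  accessible surface area contributed by N and O atoms (per-atom ASA
  contributions including bonded hydrogens, from RDKit). The alternative —
  topological PSA divided by total ASA — exceeds 1 for small polar
  molecules (e.g. ethanol: TPSA 20.2 Å² vs total Labute ASA 19.9 Å²)
  because the two quantities come from different parameterizations, which
  breaks the invariant that a fraction lies in (0, 1). The chosen
  definition is a true fraction by construction.
- **Electrotopological atom-type counts** (`ES_Count_aasN`, `ES_Count_aaO`,
  `ES_Count_dCH2`) are implemented as SMARTS-defined atom-type counts
  (`[nD3]`, `[oD2]`, `[CX3;H2]=[*]`), i.e. the count component of the
  E-state types, not the summed E-state indices.
- **H-bond donors/acceptors** in the druglikeness check are the classic
  counts: donors = N–H plus O–H bonds, acceptors = N plus O atoms.

`correlation_filter` keeps descriptors whose point-biserial |Pearson r|
against the 0/1 activity flag reaches 0.1 (default); zero-variance
descriptors are dropped with a warning since their correlation is
undefined. PCA standardizes each retained descriptor to zero mean / unit
variance (ddof = 1), uses a full SVD, and fixes component signs so the
largest-magnitude loading in each component is positive (deterministic up
to that convention). `choose_n_components` keeps the smallest number of
components reaching 90 % cumulative explained variance, capped at 5.

## Naive Bayes classifier

With prior `p = n_active / n_total` and Laplacian stabilizer `K = 1/p`,
the weight of feature `F` (seen in `T_F` training compounds, `A_F` active)
is

```
w(F) = log( (A_F + p·K) / (T_F·p + p·K) ) = log( (A_F + 1) / (T_F·p + 1) )
```

and a compound scores the sum of `w` over its present features. Properties
relied on by the tests: a feature occurring at exactly the background
active rate has weight → 0 as counts grow; a feature in 5 of 5 actives
and no inactives at prior ½ has weight log(6/3.5) ≈ 0.539; under k-fold
duplication of the training set the weights equal
`log((kA+1)/(kT·p+1))` and converge monotonically to `log(A/(T·p))`
(exact invariance under duplication is impossible with a fixed additive
stabilizer).

**Unseen features score 0 by default** (`penalize_unseen=False`). The
alternative — assigning the minimum-evidence weight `log(1/(p+1))` — makes
out-of-fold compounds pay a penalty proportional to how many novel
identifiers they carry, which systematically drags cross-validation recall
down for structurally novel actives. Treating absence of evidence as
neutral is the behavior that makes the additive score an estimate of the
log likelihood ratio restricted to known features. The penalty is still
available as an option.

**Cutoff**: chosen on the training score distribution by maximizing
Youden's J (sensitivity + specificity − 1), then placed at the midpoint
between the J-optimal score and the next distinct score below it
(mid-margin). Placing the cutoff exactly at an observed score makes
`score ≥ cutoff` classification brittle for out-of-fold compounds whose
scores land just under the boundary value.

Featurization can append equal-frequency-binned descriptor features
(`desc:<name>:bin<i>`, only when a descriptor table is supplied; bins ≥ 2)
alongside the `ecfp:<id>` features; binary descriptors
pass through as presence features.

## Evaluation

Per-class recall, specificity, precision and F-measure
(`F = (1+α²)·P·R / (α²·P + R)`, α = 1 by default), MCC, and weighted
averages using true class sizes as weights. Zero-denominator metrics are
reported as NaN, never silently 0. ROC curves sweep thresholds with tied
scores moving together (diagonal segments), and AUC is the trapezoidal
area — numerically identical to the normalized Mann–Whitney U statistic
with half-credit for ties, which the tests verify. Cross-validation uses
stratified k-fold (shuffled, seeded), pools the out-of-fold confusion
matrix across folds, and computes AUC on the pooled out-of-fold scores.

## Fragment enrichment

For each environment identifier, `fragment_table` records how many
compounds of a set contain it, its frequency, an exemplar substructure
(SMILES of the central atom's environment out to its radius, from the first
occurrence) and, when a model is supplied, its Bayes weight.
`top_fragments` ranks by weight (frequency when no model), descending for
"good", ascending for "bad", with deterministic tie-breaks (higher count,
then smaller identifier). Note that an exemplar shows one environment, not
necessarily a complete ring system — identifier membership, not exemplar
substructure matching, is the reliable way to test whether a known motif
was recovered.

## Screening funnel

`select_top` ranks compounds by their best docking pose score, keeps the
top `ceil(fraction · n)` (ties broken by score descending then compound id
ascending), then drops compounds with fewer than `min_poses` docked
conformations. Druglikeness applies the five rules MW < 500, HBD < 5,
HBA < 10, LogP < 5 and ≤ 10 rotatable bonds; LogP is never predicted
internally — if not supplied the rule is skipped and flagged in the report.
`mw_from_formula` parses molecular formulas with IUPAC conventional atomic
weights (5 significant figures), e.g. C23H27N3O3S2 → 457.607 g/mol.

## Synthetic libraries

`synthdata.generate_library` emulates a two-class screening library:
compounds are assembled from two-slot aromatic/aliphatic scaffold templates
decorated with neutral substituents, and actives (at `implant_rate_active`,
default 1.0) receive one of three implanted activity motifs (an NH-pyrrole,
an ethyl ester, a glycol diether) in one slot. A redraw guard ensures
non-implanted compounds never contain an implant motif by accident, so the
structure–activity signal is exactly the implant rates. Potencies are drawn
from truncated normals (actives N(6.5, 0.7), inactives N(4.0, 0.7),
resampled to stay consistent with the activity flag at full signal).
Everything is deterministic per seed.

What the generator emulates: class imbalance, scaffold redundancy,
motif-driven activity, per-pose docking-score noise (normal around a
per-compound base score), and Poisson residue-contact counts dominated by
hydrophobic contacts. What it does not emulate: activity cliffs,
assay noise correlated with structure, tautomers/stereochemistry effects,
or realistic docking physics — it is a test harness for the pipeline's
statistics, not a source of chemical insight.

The default study condition in `analysis/` (500 compounds, 1:2
active:inactive, seed 7) and the null condition used in the acceptance
suite (equal implant rates 0.5/0.5, where cross-validated AUC must stay
near 0.5) are this package's own choices of problem size, selected to keep
the full suite under a minute while giving stable statistics over 20 seeds.
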