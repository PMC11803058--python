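# Methods

## Problem setting

Reversed-phase liquid chromatography elutes compounds at retention times
(RTs) governed mainly by hydrophobicity and size. QSRR models regress RT on
molecular descriptors. A single global model is dominated by the structural
diversity of a screening library; `classrt` instead partitions the library
into functional-group classes, trains one expert regressor per class, and
routes queries to the expert that fits them. Classification makes each
class's training set small, so two augmentation strategies and a guard
against over-augmentation are part of the training procedure. All RTs are
seconds.

## Compound taxonomy

A class is assigned by a rule engine over SMARTS functional-group patterns.
Each rule carries a weight (priority); the highest-weight matching rule
determines the (superclass, subclass) pair, ties break on lexicographic rule
id, and molecules matching nothing receive a configurable fallback class, so
assignment is total and deterministic. The shipped rule file
(`classrt/data/default_rules.tsv`, editable TSV) covers 13 superclasses of
small-molecule contaminant chemistry — organic acids, nitrogen/oxygen/sulfur
compounds, organohalogens, organoheterocyclics, benzenoids,
phenylpropanoids, alkaloids, lipids, lignan-type methoxyphenols, 1,3-dipolar
compounds, organophosphorus — with specificity encoded in the weights (e.g.
sulfonamide 9.0 > primary amine 4.0, so the sulfonamide nitrogen does not
land in the amine class). The number of subclasses realized on a dataset is
data-dependent, not fixed. Classes below `min_size` (default 15; per-class
training and validation below that is statistically meaningless) merge into
a residual pool that trains a single fallback submodel.

## Splitting and identity

Datasets are split train/validation/test at 8:1:1 (floors of the ratios,
remainder to train — training is where the data are needed, and augmentation
targets it anyway). Canonical SMILES (RDKit canonical form) is the identity
key: records sharing a canonical form travel together through the split, and
every leakage check compares canonical forms. Stereochemistry is preserved
in the strings but not used to separate identities, since C18 columns do not
resolve most optical isomers.

## Augmentation

**SMILES enumeration (SE).** Up to *k* (default 5) random-atom-order
renderings per training molecule (RDKit `MolToRandomSmilesVect`, retry
budget 10·k for small graphs that admit few distinct strings). Every variant
is verified to canonicalize back to its parent and enters the table with the
parent's RT and canonical form, tagged `se_augmented`. For descriptor-based
regressors the molecular graph — hence the descriptor row — is unchanged, so
SE acts as sample re-weighting, not new information. Two consequences are
built in:

* no enumerated twin may ever appear in validation/test (asserted after
  every augmentation; near-perfect metrics obtained by letting twins
  straddle the split are a failure mode, not a result);
* the feature-selection budget counts *unique molecules*, not rows
  (`effective_rows`), because counting duplicated rows as samples inflates
  the feature budget exactly when augmentation is heaviest and demonstrably
  overfits the SE arms of the ablation.

**Topology-guided active learning (Topo-AL).** Labeled compounds from a
pool (everything outside the current training subset, minus validation and
test material by canonical SMILES) join the training set when their maximum
ECFP Tanimoto similarity to any training molecule is ≥ τ (default 0.5,
inclusive reading of "50% or higher"; exposed as config). Recruits keep
their own measured RTs, tagged `topo_al_added`. Similarity is Tanimoto
|A∩B|/|A∪B| on 2048-bit radius-2 Morgan fingerprints; binary cosine is
available behind `similarity_metric="cosine"`.

**Over-augmentation guard.** The enumeration multiple m runs 1..k (Topo-AL
applied once, before the first step). After each step a cheap deterministic
probe (ridge regression on a fixed 10-descriptor panel) is refit and scored
on the class validation split; the loop stops once validation MAE exceeds
the best seen by more than `guard_tolerance` (default 1%, relative) and the
best-scoring set is kept. The probe is intentionally not the full
seven-algorithm sweep: the guard must cost O(iterations · cheap fit).

## Features

Descriptors are the RDKit 2D block (~210 columns: constitutional,
topological, autocorrelation, VSA families, logP/MR), computed once per
unique canonical SMILES, so enumeration duplicates are bit-identical to
their parents. Columns non-finite anywhere are masked `nonfinite`; constant
columns `zero-variance`. Selection is a deterministic cascade: drop
zero-variance → collapse pairs with |Pearson r| > 0.95 keeping the member
better correlated with RT (ties: lexicographic name) → rank by univariate
|corr to RT| and keep the top max(10, n_unique/5). All three thresholds are
config (`SelectionConfig`); the default 0.95 collapse can swap an exactly
generative descriptor for a 0.96-proxy, which matters only in noiseless
synthetic checks — those pass `corr_threshold=0.999, min_keep=30`.
Standardization statistics come from the training table only and are stored
with the submodel.

## Expert selection and routing

Seven candidate algorithms (RBF-SVR, random forest, XGBoost
gradient-boosted trees, extra trees, k-NN, ridge, one-hidden-layer MLP — a
pluggable registry) each get a seeded random search of `budget`
configurations (draw 0 is a fixed default per algorithm), scored by MAE on
the class validation split. The global argmin is the class's expert; ties
break on registry order. The full search log is retained, so the argmin
property is auditable after the fact. Ridge's near-zero default penalty uses
the SVD solver: the Cholesky path leaves ~1e-4-s residuals on noiseless
linear targets.

Routing is two-stage. Taxonomy first: the query's assigned subclass, when a
submodel exists for it and the query's max similarity to that submodel's
training fingerprints clears `min_route_sim` (default 0.0, i.e. taxonomy is
always trusted). Otherwise similarity fallback: the submodel maximizing the
mean of the top-`m` (default 5) Tanimoto similarities between the query and
its training fingerprints; ties prefer the larger training class, then
lexicographic class id. Routing is total and deterministic, and predictions
are invariant to the SMILES rendering of the query.

## Metrics

MAE = mean|Δ|, MedAE = median|Δ| (both seconds), MAPE = mean(|Δ|/y) as a
fraction (the CLI formats percent), R² = 1 − SS_res/SS_tot. MAPE requires
strictly positive true RTs; R² is refused on zero-variance truth.

## Synthetic library

`synthkit` generates the study conditions used throughout the tests: 6
classes × 200 molecules, noise σ = 10 s, RT clipped to [60, 1700] s (a
~30-minute gradient), class offsets drawn uniformly in ±300 s. Each class is
one scaffold family with one defining functional group — benzoic acids,
cyclohexyl primary amines, phenols, benzenesulfonamides, aliphatic esters,
benzonitriles — decorated with sampled alkyl chains and halogens only, so no
decoration introduces another class's defining group and the default rules
recover the class labels exactly. Decoration is sparse (30% per ring slot)
so family members stay structurally close (typical within-family Tanimoto
≥ 0.5), which is what gives similarity-guided recruitment true signal. The
noiseless RT is base + 110·logP + 9·heavy_atoms + offset, with logP and the
heavy-atom count computed from the generated molecule — the model must
recover the signal from descriptors, not memorize the grammar. Everything is
reproducible from the seed, and the generator returns the exact
decomposition of every RT.

What the generator does *not* emulate: nonlinear retention physics, isomer
resolution, pH/temperature effects, inter-laboratory gradient differences,
heteroatom-rich real pharmacophores, or class-overlapping chemistry.
Passing tests on this library demonstrate that the pipeline's machinery is
correct and that it recovers a recoverable signal near the noise floor; they
say nothing about accuracy on any particular real chromatographic dataset.
Clipping at the gradient bounds caps achievable R² when σ is large.

The data-sparse regime (`make_sparse_regime`) subsamples the training split
to 15 molecules per class after an 8:1:1 split; the spilled remainder
becomes the Topo-AL pool, so train ∩ pool is empty and the pool shares
scaffolds with the training set.

## Ablation harness

Four arms — none (k=0, no Topo-AL), SE only, Topo-AL only, both — run on
identical splits within each seed (the split is a pure function of the
seed), with the guard disabled so the arms differ only by strategy. On the
sparse regime over 5 seeds, Topo-AL lowers mean test MAE (it injects true
labeled data) and the combined arm beats no augmentation; SE alone is
approximately neutral, as expected for pure re-weighting under strict
leakage hygiene.

## Problem sizes and defaults in the harnesses

The test and acceptance harnesses use desk-scale sizes chosen once: the
end-to-end recovery check runs 3 seeds of 6×200 molecules with search budget
3 per algorithm over the full registry; the ablation uses 6×60 molecules,
15/class training, 5 seeds, budget 2 over a ridge/SVR/random-forest registry
(the arms compare augmentation, not algorithm breadth). The library default
budget is 20 configurations per algorithm.

## Persistence

A model directory holds `manifest.json` (schema version, taxonomy rule
hash, routing config, per-class feature lists, scaler statistics, training
fingerprints, validation metrics), the rule file itself, and one serialized
estimator per class. The manifest is the compatibility contract: a schema or
rule-hash mismatch raises, never silently reinterprets, and a reloaded model
predicts bit-identically.

## Known limitations

* The taxonomy is a compact stand-in for a full chemical ontology; rule
  coverage of exotic chemistry is limited, and the fallback class absorbs
  what the rules miss.
* SE cannot add information for descriptor-based regressors; it is
  implemented faithfully (and guarded) rather than for expected gains.
* The similarity-fallback router is a simple nearest-class discriminant; it
  has no confidence estimate and will route arbitrarily dissimilar queries
  somewhere.
* Hyperparameter search is a flat random search against one fixed validation
  split, not nested cross-validation; with small classes the selected expert
  is noisy.
* MAPE is undefined for non-positive RTs, and R² for constant truth; both
  raise rather than guess.
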