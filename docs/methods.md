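# Methods

This note documents the modelling choices behind `fpgnn`: the model and
its assumptions, the conventions adopted where the method family leaves
freedom, what the synthetic generator does and does not emulate, and the
numerical details that matter for reproducibility.

## Model

Each molecule is represented twice. The **fingerprint branch** consumes
the fixed concatenation `[MACCS | PubChem | ErG]` (166 + 881 + 315 =
1362 entries) through a feed-forward network with ReLU activations and
inverted dropout between hidden layers. The **graph branch** runs
graph-attention message passing on the heavy-atom graph: per layer and
head, transformed source, destination and bond features are scored by an
additive attention with LeakyReLU(0.2), normalised by softmax over each
atom's incoming edges, and the attention-weighted messages (transformed
neighbour plus bond term) are summed and passed through ELU. Every atom
carries a self-loop with zero bond features, so a neighbourhood is never
empty and a single-atom molecule reduces to a readout of its own
transformed features; the coefficients over a neighbourhood (bonded
neighbours plus self) sum to one by construction. The molecule embedding
is an attention-weighted sum over atoms (a tanh-gated scoring network
followed by a per-molecule softmax). Fusion concatenates both
embeddings, applies one ReLU layer with dropout, and a final linear map
produces one sigmoid output per task; each column of that map belongs to
exactly one task while all other parameters are shared. Because all
aggregations are sums or softmax-normalised sums, the whole forward pass
is invariant to atom renumbering of the input SMILES.

The loss is per-task masked binary cross-entropy averaged over tasks:
within a batch, each task averages over its labelled molecules only, and
tasks with no labelled molecule in the batch are excluded from the task
average rather than imputed — the only treatment consistent with
per-subtask averaging when assay panels overlap partially. Predicted
probabilities are clamped to [1e-7, 1 − 1e-7] before the logarithm,
since the cross-entropy is undefined at exactly 0 or 1.

The network and its gradients are implemented on a small reverse-mode
automatic differentiation engine over NumPy float64 arrays
(`fpgnn.autodiff`: dense algebra, the nonlinearities, row gather,
segment sum/softmax). The test suite validates every operation and the
whole model's loss gradient against central finite differences (1e-4
relative tolerance on a two-molecule, two-task configuration).

### Default hyperparameters

| parameter | default | rationale |
|---|---|---|
| FPN hidden sizes | (256, 64) | compress the 1362-entry fingerprint in two steps |
| GNN layers / heads / units | 2 / 2 / 48 | two message rounds reach most pharmacophore-scale contexts |
| fusion hidden | 64 | matches the combined embedding scale |
| dropout | 0.1 | mild regularisation; disabled in evaluation mode |
| optimizer | Adam, lr 1e-3, gradient-norm clip 5 | robust default for small networks |
| batch size / epochs / patience | 32 / 30 / 10 | desk-scale datasets converge within tens of epochs |
| call threshold | 0.5, ties called positive | probability ≥ 0.5 is an inhibitor call |

All sizes are configuration, not code: `ModelConfig` fully determines
every parameter shape, checkpoints embed the config plus a hash of the
featurization schema, and loading into a mismatched schema or task count
fails with an explicit error. Weight initialization is Glorot-uniform
seeded from `ModelConfig.seed`; the output head starts at zero so an
untrained model predicts probability 0.5 everywhere.

## Featurization conventions

Atom features: element one-hot over {B, C, N, O, F, Si, P, S, Cl, Br, I,
other}, degree (0–5, clipped), formal charge {−1, 0, +1, other},
aromaticity flag, total hydrogen count (0–4, clipped), hybridisation
{SP, SP2, SP3, SP3D, SP3D2, other} — 36 entries. Bond features: bond
type one-hot (single/double/triple/aromatic), conjugation, ring
membership — 6 entries. Hydrogens are implicit.

MACCS keys come from RDKit (the 167-position variant with unused
position 0 dropped, giving the standard 166 keys); the test suite checks
them bit-for-bit against reference values computed with OpenBabel's
independent MACCS implementation on a 20-molecule panel.

No installed library computes the 881-key PubChem/CACTVS substructure
fingerprint, so `fpgnn.pubchem_fp` implements an 881-slot vector that
follows the public section layout (hierarchic element counts, ring
counts, bonded atom pairs, atom-neighbourhood and substructure SMARTS
keys). Slots whose exact public definition is not reproduced here are
reserved and always zero; every populated slot resolves to a
human-readable meaning, and this shipped table — not any external
dialect — is the package's ground truth. The ErG block is RDKit's
315-entry fuzzy pharmacophore vector (21 unordered property pairs over
{Donor, Acceptor, Positive, Negative, Hydrophobic, Aromatic} ×
topological distances 1–15); `erg_bit_meaning` exposes the index →
(property, property, distance) mapping so importance tables remain
interpretable under any bit-numbering convention.

## Dataset curation and splitting

Cleaning order: (1) drop molecules with no carbon atom; (2) for
multi-fragment SMILES keep the largest carbon-containing fragment by
heavy-atom count (a deterministic salt/mixture rule), dropping records
with no such fragment; (3) re-canonicalize; (4) deduplicate by canonical
SMILES, merging label vectors — a task on which duplicates disagree is
marked missing (conservative), complementary masks are united. The
procedure is idempotent and reports per-step removal counts. Acyclic
molecules share the empty Bemis–Murcko scaffold, making the scaffold
fraction well defined.

The structure-based split clusters mixed-fingerprint vectors with
k-means (Euclidean metric on the raw real-valued concatenation, 10
restarts, best WSS kept) and draws validation and test sets
proportionally from every cluster with largest-remainder quotas and a
seeded generator. Whole-cluster holdout is a stricter alternative; the
proportional variant was chosen because it keeps validation/test label
composition usable at small n while still grouping near-duplicates on
the same side of the split.

## Applicability domain

The threshold is D_T = d̄ + Z·θ with d̄ and θ the mean and **population**
standard deviation (divisor n) of each training compound's mean distance
to its k nearest other training compounds; a query is OD when its
distance to the **single** nearest training compound exceeds D_T. The
k-NN/1-NN asymmetry between the training and query sides is deliberate
and follows the method as published. Neighbour ties break by training
index. Distances are unscaled Euclidean on the mixed fingerprint. At
fixed k, the OD count is nonincreasing in Z since D_T grows linearly in
Z. Defaults k = 3, Z = 0.2.

## Y-scrambling protocol

Each round permutes labels within every task among the labelled entries
(masks and class balance preserved) and retrains from scratch with a
fresh seed. Two protocol details matter and were fixed after observing
their failure modes:

* **Validation labels are scrambled together with training labels.**
  Epoch selection is part of the fitting pipeline; selecting a scrambled
  model by its true-label validation AUC leaks the true response into
  the null run (a scrambled round can then post AUC ≈ 0.9 purely through
  select-the-lucky-epoch).
* **The fully trained model is evaluated, with no best-epoch
  selection.** Even against scrambled validation labels, taking the
  maximum of a noisy per-epoch statistic preferentially picks transient
  models aligned (in either direction) with the dominant feature axis,
  producing extreme null AUCs. The unscrambled reference keeps the
  normal AUC-selection protocol.

Under this protocol the scrambled test AUCs concentrate near 0.5 while
the reference stays high.

## Metrics

F1 = 2TP/(2TP+FN+FP); MCC with the 0-convention when any marginal is
zero; BA = (SE+SP)/2 with SE = TP/(TP+FN), SP = TN/(TN+FP); AUC as the
Mann–Whitney pair statistic (ties 1/2), computed from midranks. Macro
averages over tasks are unweighted; a task that fails a metric's
precondition (e.g. a single-class test set for AUC) is reported as NaN
and excluded from that metric's average with a warning. F1 with
2TP+FN+FP = 0 is undefined (excluded) rather than 0.

## Interpretation

Attention maps are captured during a forward pass; the symmetric bond
score is the mean of the two directed coefficients (heads averaged by
default), per-atom aggregates are sums of incident bond scores, and the
min–max normalisation to [0, 1] is applied for rendering only, with raw
values retained. Fingerprint-bit importance defaults to occlusion — the
dataset-mean absolute change in a task's probability when one bit is
zeroed, with the graph embedding held fixed — because it is
deterministic and model-agnostic; a gradient×input variant is available.
A bit that is zero across the dataset has exactly zero occlusion
importance.

## Synthetic data

The generator assembles molecules from scaffold × substituent templates
(benzene, pyridine, furan, thiophene, cyclohexane, alkane chains ×
nitro, sulfonamide, carboxyl, halogen, nitrile, amine, ether fragments),
always emitting valid, canonical, dataset-unique SMILES. Labels are
SMARTS matches on the assembled molecule, optionally XOR-ed with seeded
Bernoulli noise and masked at a per-task missing rate; a shared latent
inclusion decision, copied by each task with probability
`task_correlation`, emulates correlated assay panels. Assembly failures
and duplicates are retried under the same label plan so they do not bias
the class balance. The out-of-domain probe family (perfluorinated
organophosphorus/organosilicon and perfluoroaryl templates) is disjoint
from the base grammar — the base grammar emits no fluorine or
phosphorus — guaranteeing structurally distant fingerprints for
applicability-domain experiments.

What the generator emulates: multiple correlated binary tasks,
substructure-determined labels with controllable noise, partial label
masks, class imbalance, and a structurally shifted query family. What it
does not: the chemical diversity of screening libraries (its scaffold
fraction is far below that of real collections), realistic property
distributions (MW/LogP ranges), tautomerism/charge states, or
activity-cliff-like label structure. Green tests therefore demonstrate
that the implementation learns and validates what it is specified to
learn, not that the architecture attains any particular accuracy on real
assay data.

The multi-task-benefit fixture deserves a note: a label defined by a
single SMARTS fragment is equivalent to one fingerprint key, and fifty
labelled molecules already suffice to learn it — both the single-task
and the multi-task model then sit at the AUC ceiling and the comparison
degenerates to ties. The fixture therefore uses a relational rule (an
amine *para* to a nitro group on a benzene ring) that no single key
encodes, which makes the low-data regime genuinely data-limited and the
shared-representation benefit measurable.

## Desk-scale study conditions

The acceptance run (`scripts/acceptance.py`) uses 1,200 molecules over
the five default tasks with 10% label noise, 30% missing labels and
correlation 0.3 — qualitatively mirroring noisy, partially overlapping
assay panels — split 800/150/250 by k-means (k = 6), a (128, 64)/2×2×24
network trained 25 epochs, an applicability-domain evaluation at
(k = 3, Z = 0.2) over the test set plus a 150-molecule alien probe, and
3 scrambling rounds. These sizes are the package's chosen desk-scale
conditions; the test suite uses smaller configurations of the same code
paths.

## Known limitations

* The PubChem-layout fingerprint is a documented dialect, not a
  bit-exact CACTVS reimplementation; cross-dialect bit numbers should be
  compared through the exposed meaning functions, not by index.
* Training is CPU-bound NumPy; it is sized for datasets of order 10³–10⁴
  molecules, not the 10⁵-scale benchmark corpora.
* The attention formulation is one standard choice (additive scoring,
  softmax per neighbourhood); other published variants would change
  coefficients, and attention weights are a visualisation aid, not a
  causal attribution.
* Occlusion importance is computed bit-by-bit and ignores bit
  correlations; strongly collinear keys (e.g. the several nitro-related
  keys) share credit.
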