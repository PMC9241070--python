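# Methods

## Problem and model

Roughly a third of deposited protein structures contain at least one metal
ion, but a metal observed in a crystal is not necessarily biologically
meaningful: cations from the purification or crystallization buffer bind
opportunistically, usually at the protein surface. `metalsites` classifies a
metal-binding site (MBS) in a 3D structure as **physiological** or
**adventitious** from a per-residue encoding of the chain that harbours it.

### Site definition (geometric extraction)

Extraction follows the MetalPDB convention. For each metal atom, every
non-hydrogen atom strictly within 3.0 Å is a *donor atom*; the residues or
small molecules contributing at least one donor atom are the *metal ligands*
(first coordination sphere); the full site additionally contains every
species with at least one heavy atom strictly within 5.0 Å of any atom of a
ligand (the *environment*, or second sphere). Metals whose ligand-residue
sets intersect are merged into one polynuclear site. Sites with no protein
donor atom are discarded, as are heme sites (het codes HEM/HEA/HEB/HEC by
default, configurable). Both cutoffs use strict inequalities; only the first
model of the asymmetric unit is used, with the highest-occupancy alternate
conformer per atom (ties broken by the lower altloc letter) and no symmetry
expansion. Atoms of other metals in the queried element set are never counted
as donors.

### Feature encoding

Each residue *t* of the chain of record (the protein chain providing the most
donor atoms; ties broken alphabetically) gets 29 features, giving an L × 29
matrix S per site:

| columns | content |
|---|---|
| 0–19 | conservation profile: the residue's row of the position-specific frequency matrix (PSFM) from an MSA, amino acids ordered A,C,D,…,Y |
| 20–21 | absolute (Å²) and relative (%) solvent accessibility |
| 22–24 | binding-role one-hot: metal ligand / second sphere / other |
| 25–28 | secondary-structure one-hot: helix / sheet / turn / other |

PSFM columns are projected onto the query (query-gap columns dropped);
columns where strictly more than half the sequences are gapped are masked and
carry the query one-hot so every residue keeps a conservation row.
Nonstandard residues are ignored in the counts. Absolute accessibility is
computed with an in-package Shrake–Rupley implementation (probe 1.4 Å, 960
quasi-uniform mesh points per atom, element vdW radii) on the isolated chain,
i.e. without the metal, waters or other chains; an independent implementation
(biotite) serves as a cross-check oracle in the tests. NACCESS `.rsa` input
overrides the internal computation when supplied. Relative accessibility is
absolute / per-type theoretical maximum (Tien et al. 2013 table, bundled and
configurable); values above 100 % are not clamped. Relative accessibility is
interpreted as NACCESS "all-atom". Secondary structure comes from DSSP output
when available (H,G,I → helix; E,B → sheet; T → turn; else other) or from a
Cα-distance fallback otherwise; this group of features has negligible
influence on classification, so dialect differences between assigners are
acceptable. The binding role given by the extraction (2 = ligand,
1 = environment, 0 = other) is one-hot encoded; the 20 + 2 + 3 + 4 accounting
is what makes the count 29.

### Classifier

A 1-D convolution of width w = 7 (odd, zero-padded so the length is
preserved) with ReLU builds a local representation S′; a unidirectional GRU
reads S′ and its final hidden state h_L summarises the whole chain; a linear
layer with two output neurons and softmax yields
y = [P(physiological | S), P(adventitious | S)]. Only h_L is read — no
bidirectionality, no pooling over time. The *confidence* of a prediction is
|P(physiological) − P(adventitious)|; the positive (physiological) call
requires P(physiological) strictly above the threshold β (default 0.5), so a
tie classifies conservatively as adventitious.

The network is implemented directly on numpy with hand-written
backpropagation (including BPTT). Variable-length sites are batched by
padding with zero feature rows; since the convolution zero-pads its ends and
the readout (hence every gradient) comes from each sequence's own step L,
batched processing is exactly equivalent to per-sequence processing (verified
by test).

Training minimises class-weighted cross-entropy — physiological sites are
up-weighted by 1.7 to counter the class imbalance of curated site datasets —
with Adam, decoupled weight decay, gradient-norm clipping at 5, inverted
dropout on the convolution activations and on h_L (one mask per sequence,
shared across timesteps), domain-scaled input-noise augmentation (per-element
Gaussian noise with sd = 0.3 × the feature's training-data range), and early
stopping on the validation loss with best-parameter restore. On plateaus (patience/3 stalled epochs) training
restarts from the best parameters at a third of the learning rate. The GRU
update-gate bias is initialised at +1 so the state carries accumulated
evidence across long chains from the first epoch — without it the network is
slow to learn count-like signals (number of ligand/site residues).
Features are standardised to zero mean/unit variance using training-set
statistics stored on the estimator.

Defaults (all exposed as estimator parameters): 64 conv channels, hidden
size 128, learning rate 5e-3, weight decay 1.5, dropout 0.3, input noise 0.3,
batch size 32, up to 250 epochs with patience 40, seed 0. These are package conventions, not
values inherited from any reference: the layer widths matter much less than
the regularisation (dropout + decay) and the carry-bias initialisation in the
regimes we test (10²–10³ training sites). The tests and the acceptance script
use 24 channels / hidden 48, which train in minutes on one CPU at ~10³ sites
with no measurable accuracy loss versus the wider net.

### Cross-validation protocol

k = 10 stratified folds (grouped folds supported: sites from the same
cluster never split). The roles rotate: fold f is the test set, fold
(f+1) mod k the validation set driving early stopping, the remaining eight
train the network. Every site is therefore predicted exactly once as a test
point; accuracies are reported as mean ± sd over folds and pooled test
predictions feed the confusion matrix, ROC/AUC and confidence-binned error
rates (0.1-wide bins, last bin closed at 1.0, plus an aggregate at
confidence ≥ 0.85).

### Feature importance

The importance of feature (group) i is the test-set accuracy drop after
degrading it: each column in the group receives additive per-residue N(0,1)
noise scaled by α_i, the empirical domain magnitude (max − min) of that
column over the rotation's training data; I_i = Acc(baseline) −
Acc(perturbed), evaluated per CV rotation and averaged over the 10 folds.
Values are not clipped to valid feature ranges — the perturbation is additive
as defined.

The importance statistic only ranks features sensibly if the network is not
generically brittle: noise whose magnitude equals a feature's whole domain is
an extreme input, and an unregularised network's predictions degrade under it
no matter which column is hit, drowning the signal-specific effect. The
input-noise augmentation used during training (same scaling, smaller
magnitude) makes the network insensitive to perturbations of columns it does
not need, so the measured accuracy drops concentrate on the feature groups
that genuinely drive the decision. Without augmentation the ranking is
dominated by this generic fragility; with it, the binding-role group leads
and the planted conservation columns follow, with near-zero importance for
uninformative columns.

By default the 20 amino-acid columns are perturbed individually
while the role one-hots (3 columns) and secondary-structure one-hots (4
columns) are perturbed jointly as groups, giving 24 groups; joint
perturbation of a group redraws noise independently per column. (Whether
grouping belongs to the computation or only to the reporting is a judgement
call; we perturb jointly and report jointly.)

### Rule baseline

An interpretable reference classifier: a site is physiological if it has
≥ 20 site residues OR ≥ 4 protein metal ligands (both inclusive), or — only
when a cutoff is explicitly configured — mean ligand accessibility below the
cutoff. No accessibility clause is active by default because the two classes'
accessibility distributions overlap too widely for a reliable threshold.
Clauses combine with OR (each alone is strong evidence), thresholds are never
fitted, and >2 His ligands within 12 residues of a chain terminus raise a
poly-His-tag warning without changing the call.

## Synthetic data: what it emulates and what it does not

Real curated site datasets are not redistributable with the package, so a
generator produces labelled L × 29 matrices with the class-conditional
structure that separates the two classes in curated zinc data:

| property | physiological | adventitious | family |
|---|---|---|---|
| site residues | mean 22.3 | mean 12.5 | negative binomial (r = 40) |
| protein ligands | mass on 3–4 | mass on 1–2 | categorical |
| ligand abs. SASA | median 12 Å² | median 40 Å² | log-normal (σ = 0.8) |
| Cys/His-conserved ligand rows | P = 0.9 | P = 0.25 | Bernoulli + Dirichlet boost |
| second-sphere SASA | shared across classes (median 35 Å², log-normal) | | |

Chain length is the site size plus a negative-binomial surplus (mean 22), so
chains average ≈ 35–45 residues — deliberately shorter than real chains to
keep CPU runtimes in minutes; nothing in the pipeline depends on this scale.
Conserved rows put ~0.8 of the frequency mass on one residue; background rows
are Dirichlet draws with occasional random conservation. Secondary structure
is sampled iid from (helix 0.35, sheet 0.25, turn 0.15, other 0.25).
Distribution families are package choices (the real data are summarised only
by box plots); every parameter is exposed on `SyntheticSpec`, and
`SyntheticSpec.equalized()` gives a null variant with all class differences
removed, under which held-out accuracy collapses to chance.

What passing tests on these data show: the extraction geometry is exact (it
is checked against a brute-force oracle, independent of the generator); the
classifier can recover multi-residue count, accessibility and conservation
signals from the L × 29 encoding; the importance machinery attributes the
decision to the planted signal groups. What they do not show: performance on
real structures, where conservation comes from real MSAs, accessibility from
real packing, and class boundaries are far less clean. The generator also
ignores residue identity/role coherence (a "conserved Cys" row is not forced
to be a cysteine in any sequence sense) and places site residues at random
sequence positions with no 3D consistency.

Toy *structure* generation is separate and exact: atoms are placed at
requested distances from a metal at the origin and written as fixed-width
PDB text (round-trip error ≤ 1e-3 Å), which is how the 3.0/5.0 Å boundary
behaviour and the merge rule are tested.

## Numerical and design choices

* Strict `<` at both distance cutoffs; environment membership uses heavy
  atoms only, consistent with the donor rule.
* Undefined metrics (zero denominators) are reported as missing, never 0.
* ROC/AUC via threshold sweep (sklearn curve) + trapezoid; built pooled and
  per fold.
* Residue-to-position mapping uses coordinate-file order of observed
  residues; author-numbering gaps do not create positional gaps, and
  SEQRES-only residues are ignored.
* Checkpoints are single-file archives (JSON config + tensors) with a schema
  version; loading verifies the version.
* Degenerate inputs fail loudly: empty structures, single-class training
  sets, ragged alignments, 28-column matrices, non-finite losses.
* The α magnitude of a constant feature is 0 (with a warning), making its
  perturbation a no-op rather than an error.
* Reduced-feature experiments (e.g. role-only or conservation-only training)
  are run by passing column-sliced matrices to the same estimator; no
  separate code path exists.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 1000 synthetic sites for the
10-fold CV (24 conv channels, hidden 48), 300 sites for the label-shuffled
control with a smaller net (the null has nothing to learn; less training
cannot manufacture signal), 1000 sites (800 train / 200 test) for the
noise-column importance control — the statistic needs a well-trained model
and a test set fine-grained enough that one flipped site does not dominate —
4000 draws for generator calibration, and 100 random toy structures
(≤ 500 atoms) for the extraction oracle. These sizes were chosen once as
the package's test conditions.

## Known limitations

* Iron sites are handled by plain inference through a zinc-trained model; no
  transfer learning or fine-tuning machinery exists (by design).
* MSAs are consumed, never computed; no HHblits/DeepMSA orchestration, and
  the MSA-depth statistic N_f is not computed.
* No clustering of equivalent sites across structures; cluster/group ids are
  accepted as optional input to keep homologous sites in one fold.
* The Cα-distance secondary-structure fallback is a coarse heuristic; use
  DSSP files when fidelity matters (the feature group barely matters for
  classification).
* The optimizer/schedule is deliberately simple (Adam + plateau restarts);
  no architecture search is performed for reduced feature sets, so those
  accuracies are lower bounds.
* Training complexity is O(total residues × hidden²) per epoch on one CPU;
  chains of many hundreds of residues and datasets of ≥10⁴ sites will be
  slow in this pure-numpy implementation.
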