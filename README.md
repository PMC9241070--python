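# metalsites

Classify metal-binding sites (MBSs) in protein 3D structures as
**physiological** (biologically functional) or **adventitious** (artifacts of
purification or crystallization buffers).

About a third of deposited protein structures contain a metal ion, but a
zinc or iron seen in a crystal is not necessarily there in vivo: buffer
cations bind opportunistically, typically at the protein surface, with few
protein donor atoms. Distinguishing the two cases matters for anyone
annotating metalloproteins, validating new structures, or mining structural
databases. `metalsites` is aimed at structural bioinformaticians and
bioinorganic chemists who need that call made automatically, with a
confidence value and an interpretable fallback rule.

## What it does

1. **Extract sites** from PDB/mmCIF files by geometric rules: donor atoms
   are non-hydrogen atoms at distance < 3.0 Å from the metal; residues with
   a donor atom are the metal ligands (first coordination sphere); the full
   site adds every species with a heavy atom < 5.0 Å from a ligand. Metals
   sharing a ligand merge into polynuclear sites; sites with no protein
   donor, and heme sites, are discarded.
2. **Encode** each site as an L × 29 matrix over the residues of its chain:
   20 amino-acid frequencies from the MSA (PSFM row), absolute and relative
   solvent accessibility, a 3-way binding-role one-hot (ligand / second
   sphere / other), and a 4-way secondary-structure one-hot.
3. **Classify** with a convolutional–recurrent network: a width-7 Conv1D
   builds local context S′, a unidirectional GRU reads S′ and its final
   hidden state h_L summarises the chain, and a 2-neuron linear+softmax head
   outputs y = [P(physiological|S), P(adventitious|S)]. The *confidence* of
   a call is |P(phys) − P(adv)|. Training weights physiological sites by
   1.7 and follows a 10-fold cross-validation with rotating
   train/validation/test roles.
4. **Explain**: feature importance I_i = Acc(clean) − Acc(after adding
   N(0,1) noise scaled by the feature's domain magnitude α_i to feature i),
   averaged over CV test folds.
5. **Fall back to rules**: sites with ≥ 20 residues or ≥ 4 protein ligands
   are called physiological by an interpretable baseline.

A synthetic-data generator reproduces the class-conditional structure of
curated zinc sites (site size 22.3 vs 12.5 residues, ligand counts 3–4 vs
1–2, buried vs exposed ligands, Cys/His conservation) so the entire pipeline
is testable offline. See `docs/methods.md` for the full model description.

## Worked example

```bash
metalsites simulate --n-physiological 300 --n-adventitious 300 --seed 42 --out data
metalsites crossval --data data --out run --k 5 --conv-channels 24 --hidden 48 --seed 42
```

prints (about a minute on one CPU):

```
wrote 600 sites to data
mean test accuracy 0.803 ± 0.047; AUC 0.919
```

meaning: over 5 rotations, each site was predicted once as a held-out test
point; 80.3% of the 600 sites were correctly classified and the pooled ROC
has area 0.919. (The architecture is data-hungry: the 1000-site, k = 10 run
performed by the acceptance script reaches ≈ 0.93 accuracy with AUC ≈ 0.98.)
`run/metrics.json` holds the pooled confusion matrix and the derived metric
suite:

```
confusion: {'tp': 273, 'fn': 27, 'fp': 91, 'tn': 209}
{'ppv': 0.75, 'tpr': 0.91, 'npv': 0.886, 'tnr': 0.697, 'fdr': 0.25,
 'acc': 0.803, 'mcc': 0.621}
```

so e.g. 91.0% of the physiological sites were recovered (TPR) and 25% of
positive calls were wrong (FDR); of the 50 predictions with confidence
≥ 0.85, only 4% were errors (`confidence_bins` in the same file). Site
extraction from a structure file works the same way:

```bash
metalsites extract my_structure.pdb --out sites/
```

writing one JSON per retained site (metals, donors, ligand and environment
residues, counts) plus a summary TSV. Other subcommands: `featurize`,
`train`, `predict` (including iron sites through a zinc-trained model),
`importance`, `rules`, `evaluate`, `report` — see `metalsites --help`.

The library surface mirrors scikit-learn:

```python
from metalsites import ConvGRUSiteClassifier, generate_dataset

ds = generate_dataset(100, 100, seed=0)
clf = ConvGRUSiteClassifier(conv_channels=24, hidden_size=48, random_state=0)
clf.fit(ds.sites[:160], ds.labels[:160])
clf.predict_proba(ds.sites[160:])       # columns: [adventitious, physiological]
```

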