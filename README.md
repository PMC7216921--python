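# nitromet

Metal-dependence inference for nitrogenase protein families.

Nitrogenases, the metalloenzymes that fix atmospheric N₂, occur in three
forms that differ in the metal content of their active-site cofactor:
Mo-dependent (Nif), V-dependent (Vnf), and Fe-only (Anf). Which cofactor a
sequence binds is written into the ~30 residues lining the cofactor pocket of
the catalytic D-subunit. `nitromet` implements, as a tested pipeline, the
sequence- and structure-based machinery needed to read that signal from
extant, uncharacterized, and *reconstructed ancestral* nitrogenases:

* **Active-site extraction** — parse a PDB structure, find every residue with
  an atom within 5 Å of the cofactor, and map positions onto the
  *A. vinelandii* NifD reference numbering by pairwise global alignment.
* **Ancestral sequence reconstruction** — exact marginal site posteriors on a
  fixed rooted tree under the JTT model (Felsenstein pruning), per-site
  argmax ancestors with parsimony-inferred gaps, and Bayesian-sampled
  ancestor variants drawn from the posteriors.
* **Metal-dependence classification** — each active-site residue is encoded
  as a probability vector over the 20 amino acids, the average of (a) a point
  mass on the observed residue, (b) the JTT transition row at 0.01
  substitutions/site, and (c) a diffuse regularizer. A one-vs-rest RBF
  support-vector classifier is trained on labeled sequences with kernel
  coefficient γ = 1/(n_features · Var(features)), class weights
  w(c) = n/(3 · count(c)), C chosen by five-fold cross-validation, and
  accuracy measured over ten replicated 60/40 train/test splits. Ancestors
  are classified either from their ML sequences or directly from their
  posterior distributions; support is the signed distance to each class
  hyperplane.
* **Pocket volumes** — grid-based cavity volume (0.5 Å lattice inside a
  user-given inclusion region, carved at van der Waals radius + 1.09 Å,
  convex-hull and 26-neighbourhood contiguity filters), with rank-sum tests
  for group comparisons.
* **Synthetic family generator** — a seeded simulator of a five-clade
  nitrogenase-like family (Nif-I, Nif-II, Mb-Mc, Vnf, Anf, plus unlabeled
  basal clades) evolving under JTT on a fixed tree, with the field's known
  conserved and clade-signature active-site residues planted as ground
  truth, so every stage of the pipeline is testable end to end without
  downloads.

## Worked example

Simulate the default family, train the classifier, and classify ancestors:

```bash
nitromet simulate --seed 3 --out out/
nitromet train --alignment out/alignment.fasta --labels out/labels.tsv --seed 1
```

```
Metal-dependence support-vector classifier (one-vs-rest, RBF)
  classes: Nif, Vnf, Anf
  replicates: 10  train fraction: 0.60  CV folds: 5
  out-of-sample accuracy: mean 1.0000  min 1.0000  max 1.0000
  deployed model: gamma 0.00473561, C 0.1, class weights Nif=0.520, Vnf=1.857, Anf=1.857
```

Every replicate classifies all held-out sequences correctly; the class
weights are the inverse-frequency weights for 50 Nif / 14 Vnf / 14 Anf
labeled training rows. The full pipeline — simulation, active-site slicing,
ancestral reconstruction, training, classification of uncharacterized leaves
and backbone ancestors, identity matrices, unique-residue tabulation, and
fixture pocket volumes — runs as one command with a checksummed manifest:

```bash
nitromet run-all --seed 2 --out run/
# replicate accuracies: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
nitromet verify run/
# all checksums match
```

In `run/report.json` the V/Fe common ancestor (`anc_vnf_anf`) is classified
**Vnf** under both the ML-sequence and the posterior-distribution encodings —
it carries the V-form T-355/P-358 and the V+Fe L-360 carbonate-loop residues —
while every deeper backbone ancestor and all uncharacterized Mo-like clades
classify **Nif**. The unique-residue table recovers exactly the planted
signature sets (3 Mo-, 6 V-, 5 Fe-, 6 V∪Fe-specific residues).

As a library, the same analysis is three objects:

```python
from nitromet import (AncestralReconstruction, MetalDependenceModel,
                      TrainConfig, encode_extant, jtt)
from nitromet.simulate import FamilySpec, generate_family

alignment, truth, newick = generate_family(FamilySpec(seed=1))
asr = AncestralReconstruction(newick, alignment, jtt()).fit()
features = encode_extant(alignment.take_columns(truth.site_columns), jtt())
labeled = [i for i, l in enumerate(alignment.labels) if l != "unknown"]
results = MetalDependenceModel(
    features.data[labeled],
    [alignment.labels[i] for i in labeled]).fit(TrainConfig(seed=1))
print(results.summary())
```

## Scope notes

Tree topology search, branch-length optimization, homology modeling, and
database curation are deliberately out of scope: trees, alignments, and
structures are inputs. Real-structure workflows (e.g. the NifD/VnfD cofactor
shells of PDB entries 3U7Q and 5N6Y) use the same `active-site` and
`pocketvol` commands on locally downloaded files.
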