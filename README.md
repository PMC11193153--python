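# peptox

Structure-aware prediction of peptide toxicity.

Antimicrobial peptides (AMPs) are a leading alternative to conventional
antibiotics, but candidates must be screened for toxicity against host
cells — classically hemolysis, the lysis of red blood cells. `peptox` is a
multimodal classifier for this screen: it fuses **what a peptide is made
of** (per-residue sequence embeddings processed by a bidirectional GRU)
with **how it folds** (predicted 3D backbones encoded as residue contact
graphs and processed by geometric vector perceptron message passing).
An 8-head self-attention layer integrates the two per-residue feature
streams; mean pooling plus a C-terminal-amidation flag feed the toxicity
head, and an auxiliary per-residue secondary-structure head regularizes
training through the combined loss

```
L = (1 − λ)·L_tox + λ·L_ss,         λ ∈ [0, 1]   (default 0.2)
```

The structural branch is exactly invariant under rotations and
translations of the input coordinates, and can be pre-trained on reverse
folding (predicting residue identity from geometry alone). At test time
the probabilities over a peptide's ensemble of predicted structures
(typically five) are averaged; a peptide is called toxic iff the averaged
probability exceeds 0.5 strictly.

The package also implements the surrounding study machinery: hemolysis
activity/concentration labeling ladders, the HC50-replicate rule (toxic
iff ≤128 µg/mL in at least two replicate assays), sequence filtering,
identity-constrained 4:1 train/validation splitting, confusion-matrix and
ranking metrics, and a synthetic-data generator that builds peptide
backbones from internal coordinates so the entire pipeline runs and is
tested without any downloads. The network runs on a small NumPy autodiff
engine bundled with the package; no GPU or deep-learning framework is
required. See `docs/methods.md` for the full model description.

## Worked example

Train on a synthetic corpus whose toxicity labels follow a planted
logistic signal in helix fraction and cationic-residue fraction — so the
model must use both its sequence and structure branches:

```python
from peptox import (SyntheticDatasetSpec, generate_labeled_dataset,
                    ModelConfig, TrainConfig, compute_metrics)
from peptox.train import train_model, prepare_samples, ensemble_validation_f1

spec = SyntheticDatasetSpec(n_peptides=120, length_range=(6, 20),
                            signal_scale=10.0, seed=42)
peptides = generate_labeled_dataset(spec)
train, val = peptides[24:], peptides[:24]

mc = ModelConfig(d_h=32, n_vector_channels=8, lambda_ss=0.2, seed=0)
tc = TrainConfig(max_epochs=15, seed=0, lambda_ss=0.2)
model, history = train_model(train, val, mc, tc)

f1, y, p = ensemble_validation_f1(model, prepare_samples(val, mc))
report = compute_metrics(y, p)
print(f"validation F1: {100 * report.f1:.1f}%  MCC: {100 * report.mcc:.1f}%")
print(report.as_markdown())
```

Output (a couple of minutes on one CPU core):

```
validation F1: 100.0%  MCC: 100.0%
| Method | Sensitivity | Specificity | F1-score | MCC | auROC | auPRC |
|---|---|---|---|---|---|---|
| peptox | 100.0 | 100.0 | 100.0 | 100.0 | 100.0 | 100.0 |
```

Each of the 24 held-out peptides is scored by averaging the model's
probability over its five jittered structures; at this corpus size the
planted signal is cleanly separable and the fused model recovers it
perfectly. Real hemolysis data is far noisier — benchmark-scale accuracy
additionally requires protein-language-model embeddings (the `esm`
adapter) and ColabFold-predicted structures.

The same pipeline is scriptable from the shell:

```bash
peptox simulate data/ --n-peptides 200 --signal-scale 10 --seed 1
peptox train data/ run/ --epochs 15 --lambda-ss 0.2
peptox predict run/model data/peptides.fasta data/structures preds.csv
peptox evaluate preds.csv metrics.json
```

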