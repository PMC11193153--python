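# Methods

## The model

`peptox` predicts whether a short peptide (5–50 residues, typically an
antimicrobial-peptide candidate) is hemolytically toxic, from two views of
the molecule:

1. **Sequence branch.** Per-residue embeddings X ∈ ℝ^{L_max×d_input}
   (right zero-padded, L_max = 50 by default) are processed by a
   bidirectional GRU; the forward and backward half-states (d_h/2 each)
   are concatenated into h_seq ∈ ℝ^{L×d_h}.
2. **Structure branch.** A predicted backbone becomes a residue graph:
   nodes carry rotation-invariant scalars (sin/cos of ω, ψ, φ) and three
   equivariant unit vectors (forward Cα direction rᵢ = Cαᵢ₊₁ − Cαᵢ,
   backward bᵢ = Cαᵢ₋₁ − Cαᵢ, side-chain dᵢ = Cβᵢ − Cαᵢ, with r_L and b₁
   zero sentinels and a virtual tetrahedral Cβ where none is recorded);
   an edge joins residues whose Cα–Cα distance is strictly below d_max
   (default 12 Å), carrying 16 Gaussian RBF distance features (centers
   evenly spaced on [0, d_max], σ = spacing), a 16-wide sinusoidal code of
   the signed backbone offset j−i, and the unit inter-Cα vector
   (v_ij = −v_ji). Message passing uses geometric vector perceptrons
   (GVPs): m_i = LayerNorm(h_i + mean_j f(h_j ‖ h_ij)) followed by
   h_i ← LayerNorm(h_i + g(m_i)), with f a two-GVP and g a three-GVP
   stack; a final scalar-only GVP reads out h_strct ∈ ℝ^{L×d_h}, which is
   exactly invariant under rigid motions of the input coordinates.
3. **Fusion and heads.** During training, channel dropout (p = 0.5) is
   applied to each modality independently before concatenation to
   h_pep ∈ ℝ^{L×2d_h}; an 8-head self-attention layer (padded positions
   masked out of the softmax) yields h′_pep; mean pooling over the true
   length, the binary C-terminal-amidation flag (AMD), a fully connected
   layer and a 2-way softmax give p_toxic, with "toxic" iff p > 0.5
   strictly. A parallel linear head maps h′_pep to per-residue 8-state
   secondary-structure scores.
4. **Objective.** L = (1−λ)·BCE(p_toxic, y) + λ·CE(ss), probabilities
   clipped to [1e-7, 1−1e-7]; padded residues are excluded from the CE.
   The secondary-structure term forces the model to keep using structural
   information. Default λ = 0.2.

The structural branch can be pre-trained on reverse folding: predicting
the residue identity (20 classes) at each node from geometry alone. The
pre-trained weights are fine-tuned, not frozen, during supervised training
(a `finetune_pretrained` switch freezes them instead).

## Training protocol

Adam, learning rate 4e-4, weight decay 1e-7, batch size 32. Every
predicted structure of a peptide (up to five) is a separate training
sample with the peptide's label; at validation/test time the per-structure
probabilities of a peptide are arithmetically averaged before
thresholding. Early stopping monitors validation F1 (toxic = positive, at
the strict 0.5 threshold) and halts after 20 epochs without improvement,
restoring the best-epoch weights. Validation F1 is computed on
ensemble-averaged probabilities by default (consistent with the test-time
procedure); a flag scores per-structure instead.

Model presets: *peptide* (d_h = 64, one GNN layer, one Bi-GRU layer) and
*protein* (d_h = 128, three GNN layers, L_max set to the corpus maximum).

## Dataset-construction rules

* **Hemolysis ladders.** A measurement (activity %, concentration µg/mL)
  marks a peptide hemolytic if it satisfies any of
  (≥40, ≤200), (≥50, ≤250), (≥60, ≤300), (≥70, ≤350), (≥80, ≤400),
  (≥90, ≤450), (=100, ≤500); nonhemolytic if it satisfies any of
  (≤50, >250), (≤40, >200), (≤30, >150), (≤20, >100), (≤10, >50).
  Peptides matching neither ladder are excluded. When different
  measurements of one peptide hit both ladders, toxic wins — the
  conservative choice for a safety screen. Labeling is order-independent.
* **HC50 replicates.** A peptide assayed in replicate (N = 3 in the
  emulated protocol) is toxic iff at least two replicates are ≤128 µg/mL.
* **Filters.** 5–50 residues, the 20 natural amino acids only, exact
  duplicates dropped (first kept).
* **Split.** Greedy identity clustering (global pairwise alignment,
  identity = identical columns / alignment length — a CD-HIT stand-in) at
  the 80% threshold; whole clusters go to one side, targeting a 4:1
  train:validation ratio per class; an audit pass moves any validation
  cluster with ≥80% identity to a training sequence back to the training
  side.

## Evaluation

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
F1 = TP/(TP + (FP+FN)/2), MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
with toxic as the positive class and strict thresholding (score > 0.5).
auROC uses the trapezoid rule (scikit-learn), auPRC is average precision —
step-wise rather than trapezoidal, which is biased for PR curves.
Zero-denominator ratios are reported as 0 with a warning flag rather than
raised.

## Synthetic data

The generator builds backbones atom by atom from internal coordinates
(NeRF-style placement; bond lengths N–Cα 1.458 Å, Cα–C 1.525 Å, C–N
1.329 Å; bond angles N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°), so
`compute_dihedrals` is an exact inverse of the builder — the basis of the
geometric round-trip tests. Presets: α-helix (φ = −57°, ψ = −47°), strand
(φ = −119°, ψ = 113°), and a "coil" sampled from the positive-φ region so
it never satisfies the helix/strand assignment rules. β-carbons are
placed on the ideal tetrahedral direction (arccos(−1/3) to both Cα→N and
Cα→C, L-chirality side, 1.522 Å) except for glycine. Synthetic pLDDT is
Uniform(70, 95).

Labeled corpora plant a logistic signal coupling a structural cue with a
compositional cue: P(toxic) = σ(s·(−8 + 8·hf + 16·cf)) where hf is the
helix fraction (a helical run at the N-terminal side of an otherwise coil
backbone), cf the K/R fraction (∈ [0, 0.6]), and s a steepness factor.
Neither cue alone determines the class, so a model must fuse both
branches to reach ceiling. Labels are drawn first (Bernoulli at the
requested class balance) and traits rejection-sampled conditionally, so
the empirical balance is exactly binomial; `signal_scale=inf` degenerates
to exact thresholding of the linear score (used by the oracle tests).
Each peptide receives five structures with 0.15 Å Gaussian coordinate
jitter, emulating an ensemble of predictor outputs. The study-scale
corpus used by the smoke runs is 200 peptides, lengths 5–50, balanced
classes; "cleanly separable" is realized by exact thresholding of the
linear score (steepness → ∞) together with a `min_margin` of 0.5 score
units around the decision boundary, so no generated peptide is
arbitrarily close to the class boundary.

What the generator does **not** emulate: physically packed side chains,
realistic coil ensembles, membrane context, or the error structure of
real structure predictors. Passing tests therefore demonstrate the
correctness and learnability of the pipeline, not benchmark-level
accuracy on experimental hemolysis data, which additionally requires the
external language-model embeddings and predicted structures.

## The embedding backends

The external adapter loads ESM2 (t12 for peptides, t33 for proteins) when
the `esm` package is installed; nothing in the pipeline depends on which
backend produced X. The built-in synthetic embedder is a deterministic
function of (residue identity, position, seed): a fixed random vector per
residue identity (Uniform(−0.8, 0.8), seeded) plus a 0.2-scaled
sinusoidal positional code, bounded in [−1, 1]. It preserves exactly the
information a linear pool needs to read compositional signals, which is
what the planted-signal tests exercise.

## Numerical and design choices

* The network runs on a compact reverse-mode autodiff engine over NumPy
  arrays written for this package (`peptox.autodiff`); gradients are
  verified against central differences in the test suite. Training is
  single-threaded and fully deterministic given the seed.
* Attention operates on the fused 2d_h width with per-head width 2d_h/8;
  scaled dot-product (÷√d_head) is the default, with an `attn_scale`
  switch for the unscaled variant. Padded keys receive −1e9 logits before
  the softmax (exactly zero weight after it).
* Mean pooling divides by the true length by default; `paper_pooling`
  divides by L_max instead (literal 1/L with L the padded length).
* LayerNorm on (scalar, vector) pairs: standard affine normalization on
  scalars, norm-rescaling without affine parameters on vector channels.
  The GNN readout to a concatenable h_strct is a single scalar-output GVP.
* ω_i is assigned to residue i for the i→i+1 peptide bond; undefined
  terminal angles contribute sin = cos = 0. Degenerate (collinear)
  dihedral geometry raises rather than returning NaN. Zero-length
  direction vectors become exact zero vectors, mirroring the r_L/b₁ rule.
* The built-in 8-state assigner is a dihedral-region approximation of
  DSSP (H for helical runs ≥4, E for strand runs ≥3, else C); externally
  computed 8-state labels can be supplied per record, since real
  pipelines would run DSSP on the predicted structures.
* Edge threshold is strict (<d_max). RBF span defaults to [0, d_max] and
  the positional code uses the transformer frequency ladder — the
  GVP-GNN conventions from the lineage this architecture derives from.
* Desk-scale problem sizes: the smoke runs train a d_h = 32 model (8
  vector channels) for ≤15 epochs on the 200-peptide corpus, which
  reaches validation F1 ≥ 0.9 in a few epochs; the tests and
  `scripts/acceptance.py` use these sizes.

## Known limitations

* The identity measure is alignment-based, not CD-HIT's word-filtered
  heuristic; on small sets it is exact, on large sets it is O(n²).
* The simplified secondary-structure assigner emits only H/E/C of the
  8-state alphabet; G/I/B/T/S require external labels.
* Benchmark-scale training (thousands of peptides, ESM2 embeddings,
  ColabFold structures) is out of scope for the bundled backends; the
  adapters define the interface for it.
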