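# Methods

`nmrmatch` decides whether a candidate molecular structure corresponds to a
paired set of ¹H and ¹³C NMR spectral images. This note records the model,
the synthetic benchmark it is validated on, and the numerical and design
choices a maintainer would want to know about.

## The matching model

A pair (molecule, ¹H image, ¹³C image) is mapped to a probability
ŷ ∈ (0,1) that the spectra belong to the molecule.

**Molecular branch.** The molecule is a heavy-atom graph G = (V, E) with a
d = 24 atom feature matrix X (element / degree / attached-H / aromaticity /
charge / hybridization one-hots plus three molecule-context features, see
below). Four stages produce a 128-d embedding f_final:

1. *Neighborhood attention.* 8-head scaled dot-product attention in which
   node i attends only over N(i) (bonded neighbors plus a self loop):
   per head, Q = XW_Q, K = XW_K, V = XW_V; scores ⟨Q_i,K_j⟩/√d_k are
   softmax-normalized over N(i) and aggregate the V rows. Head outputs are
   concatenated into H⁽⁰⁾ (width 64).
2. *Multi-scale aggregation.* Three branches with growing receptive
   fields: one GCN layer (short range), two stacked GCN layers (mid), and
   three GraphSAGE layers with mean aggregation (long). GCN uses the
   standard symmetric degree normalization D^{-1/2}(A+I)D^{-1/2}; SAGE
   concatenates self and mean-neighbor features before its linear map.
   Together with the attention hop the branches see at most 2/3/4 hops, a
   bound the tests verify on random trees.
3. *Scale fusion.* A linear layer over the concatenated branches,
   H_out = W·[H_short ‖ H_mid ‖ H_long] + b (width 384).
4. *Readout.* Per-dimension global max pooling and global average pooling
   over nodes are concatenated (f_mol, width 768), widened to 1500 with
   ReLU and dropout, then compressed to 128.

**Spectral branch.** Both 256×256 images pass through one *frozen*
convolutional trunk ending in 2048 channels. Each nucleus then owns a
trainable path: a 1×1 convolution reducing 2048 → 16 channels (spatial
size unchanged), parallel 3×3/5×5 convolutions (summed; the "multi-scale"
element, switchable), and a CBAM block — channel attention
M_c = σ(MLP(GAP(F)) + MLP(GMP(F))) with a shared 16→4→16 bottleneck MLP,
followed by spatial attention M_s = σ(conv_{7×7}[avg_c ‖ max_c]), each
applied multiplicatively. A joint gate σ(MLP([g_H ‖ g_C])) computed from
the two pooled descriptors rescales the channels of both branches, and
global average pooling of the recalibrated maps yields f_spec (32-d).

**Fusion and head.** u = [f_final ; f_spec] (160-d) is fused residually,
F_fused = FC₂(BN(ReLU(FC₁(u)))) + FC_skip(u) (width 128), and classified by
ŷ = σ(FC_out(BN(ReLU(FC_pred(F_fused))))) with threshold 0.5.

**Ablation variants.** A registry toggles three components — graph
attention, multi-scale graph aggregation (off = a single GCN stage into
the fused width), multi-scale spectral convolutions (off = plain CBAM):
A = (off, off, off), B = (off, on, on), C = (on, on, off),
D = (on, off, on), all = (on, on, on).

## Parameter budget

The frozen ResNet-101 trunk (classification head removed) contributes
exactly 42,500,160 parameters. The free hidden widths (scale-fusion width
384, joint-gate hidden width 64) were fixed with a small integer search
(`harness.search_budget`) so that the full default model totals
44,116,235 ≈ 44.12 M, i.e. ~1.62 M trainable parameters on top of the
trunk. Counting is exact (every weight, bias and BN affine parameter).

## Compute core

The network stack — reverse-mode autodiff over numpy arrays, Linear /
Conv2d / BatchNorm / Dropout layers, and Adam — lives in
`nmrmatch.autodiff` and `nmrmatch.nn`. Convolution uses im2col with an
explicit col2im backward; every op is covered by central-difference
gradient checks. Arrays are float32 in the model, float64 in oracle tests.

## Conditioning choices

Training starts from a *random* frozen trunk and runs for only a few
hundred Adam steps in the desk-scale benchmark, which makes conditioning
decisive. Three choices address it; all are part of the shipped defaults:

* **Embedding calibration.** A BatchNorm layer at the output of each
  encoder (128-d and 32-d). Without it the molecule-dependent variance of
  f_spec is ~1% of its magnitude and the fusion head cannot recover the
  cross-modal signal within the step budget.
* **Frozen-feature standardization.** Per-channel z-scoring of the trunk's
  2048-channel maps, fitted once on the training split
  (`SpectralEncoder.fit_feature_scaler`, called by `train_model`) and
  stored as buffers so checkpoints carry it.
* **Small initialization.** Trainable weight matrices start at 0.25× the
  He fan-in scale (`ModelConfig.init_scale`). Adam moves each weight by
  roughly lr × steps regardless of scale, so a smaller start lets the same
  step budget reorganize the functions rather than only perturb them.

Dropout after the 1500-wide projection defaults to 0.1. Rates near 0.5
inject enough gradient noise at this scale that even a single repeated
batch cannot be fit; 0.1 regularizes without stalling optimization.

## Atom features and molecule context

Feature blocks: element one-hot over {C,N,O} (3), degree 0–4 (5),
attached-H 0–4 (5), aromatic flag (1), formal charge {−1,0,+1} (3),
hybridization {sp,sp2,sp3,other} (4), and three molecule-context values
broadcast to every atom: heavy atoms/16, total H/34, aromatic fraction.
The context block exists because max/mean node pooling is size-invariant
for purely atomic features — without it the readout is nearly blind to
molecule size, which is the single strongest matching cue.

## Synthetic benchmark

The generator emulates the statistical structure of a real corpus of
small C/N/O/H molecules (≤ 16 heavy atoms) with paired spectra:

* **Molecules** are random connected heavy-atom graphs grown as trees with
  occasional ring closures and double bonds, respecting valence caps
  (C ≤ 4, N ≤ 3, O ≤ 2), deduplicated by canonical SMILES.
* **Chemical shifts** come from a deterministic additive-increment
  surrogate: base values per (element, hybridization) — sp3-C 30 ppm,
  sp2-C 130, aromatic-C 128, sp-C 75 for ¹³C; 2.2 / 5.8 / 7.3 ppm for
  protons on sp3/sp2/aromatic carbons, 2.8 on N, 4.5 on O — plus
  per-neighbor increments (O +25 ¹³C / +1.2 ¹H; N +12 / +0.6; C +9.5 /
  +0.25), clamped to ¹H ∈ [2, 12.05] ppm and ¹³C ∈ [2, 230] ppm. The
  surrogate is structure-sensitive and deterministic, which is the
  property the matching task needs; its values are **not** physical
  predictions.
* **Images** are 256×256 renders of Lorentzian peak profiles (half-widths
  0.02 ppm ¹H / 0.5 ppm ¹³C, multiplicity-weighted, max-normalized) with
  seeded Gaussian noise (σ = 0.01) and a smooth cubic baseline drift
  (amplitude 0.05), ppm decreasing left-to-right. Profiles are evaluated
  on an 8× supersampled grid and box-averaged, because ¹H lines are
  narrower than one pixel column; the area under the trace is filled so
  that peak positions and intensities occupy enough pixels to survive
  aggressive spatial pooling.
* **Pairs and splits**: one positive and one mismatched pair per molecule
  (1:1); molecule-level 8:1:1 train/val/test splits; the test molecules
  are halved into Test_rand (random mismatch partners) and Test_diff
  (partners with Tanimoto similarity < 0.2, with a flagged least-similar
  fallback). Mismatch partners are drawn inside the molecule's own split,
  every spectrum pair serves in exactly one positive and at most one
  mismatched pair, and the whole manifest is byte-reproducible per seed.

What passing tests on this benchmark do *not* show: robustness to real
acquisition artifacts (phasing and solvent peaks, J-coupling multiplets,
referencing errors), to shift-prediction error, or to the diversity of a
real 50k-molecule corpus.

## Desk-scale backbone

Full-scale runs and all parameter accounting use the real ResNet-101
trunk definition. Tests and the shipped benchmark use a 4-block residual
trunk ending in 2048 channels (`spectral.backbone = "tiny"`), built so a
*random frozen* trunk still exposes usable features: two fixed coordinate
channels are appended to the input (pooled features stay sensitive to
position along the chemical-shift axis) and each block carries an
average-pool skip connection into its leading channels (multi-resolution
ink statistics of the raw trace remain linearly decodable at the output
instead of being scrambled by stacked random filters). Pretrained weights
are not bundled; `spectral.pretrained` is accepted for config
compatibility but only seeded random frozen weights are available.

## Training protocol

Adam with initial learning rate 1e-4, batch size 32, binary cross-entropy
on probabilities, 100 epochs by default; after each epoch the validation
accuracy is computed and the checkpoint with the highest value is kept
(earliest epoch wins ties). The frozen trunk's feature maps are computed
once per image and cached (`PairBatcher`), so training cost is dominated
by the ~1.62 M trainable parameters. The desk-scale benchmark used by the
acceptance script trains the full variant for 20 epochs on 400 training
pairs (250 molecules) per seed and reports 3-seed medians; one seed takes
under a minute on one CPU.

## Numerical details

* AUC is the Mann–Whitney rank statistic with midrank tie correction;
  single-class splits report AUC as missing with a warning.
* Edge lists are directed-symmetric; self loops are added for attention
  and message passing (configurable; isolated nodes without self loops
  raise an instructive error).
* Max pooling routes gradients to the attaining entries, split evenly on
  ties; segment softmax subtracts per-segment maxima before
  exponentiation.
* BCE clamps probabilities at 1e-7 from both ends.
* Checkpoint files are `.npz` state dicts with an embedded JSON config
  and seed.

## Known limitations

* The shift surrogate ignores ring current effects beyond the aromatic
  base value, J-coupling, and solvent; two distinct structures can render
  near-identical spectra (the nearest-neighbor separability floor on 200
  molecules is checked in the tests).
* The desk-scale AUC is measured on small test splits (26 pairs), so
  single-seed values are noisy; medians across seeds are the stable
  quantity.
* `structural_similarity` hashes substructures into 1024 bits; collisions
  can overstate similarity for large, densely functionalized molecules.
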