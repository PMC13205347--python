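# nmrmatch

Multimodal matching between molecular structures and NMR spectra: given a
candidate molecule (as a SMILES-derived graph) and a paired set of ¹H and
¹³C spectral images, the model outputs the probability that the spectra
belong to that molecule. This is the core decision in automated structure
verification — confirming that a synthesized or isolated compound is what
it is claimed to be — and in candidate ranking for mixture analysis and
reaction monitoring.

The package is aimed at cheminformatics researchers who want a fully
self-contained, CPU-trainable reference implementation: it ships its own
numpy compute core (reverse-mode autodiff, conv/graph layers, Adam), a
synthetic molecule–spectrum benchmark generator, an ablation-variant
registry and exact parameter accounting.

## Model

* **Molecular encoder** — 8-head neighborhood-restricted scaled
  dot-product attention over the atom graph, three message-passing
  branches with 2/3/4-hop receptive fields (GCN ×1, GCN ×2, GraphSAGE ×3),
  linear scale fusion, global max+mean readout and a 1500 → 128
  projection: f_final ∈ R¹²⁸.
* **Spectral encoder** — one frozen convolutional trunk shared by both
  nuclei (ResNet-101 for accounting/full scale, a tiny residual trunk for
  CPU runs); per-branch 1×1 reduction 2048 → 16, parallel 3×3/5×5
  convolutions, channel–spatial attention (CBAM), cross-branch joint
  gating, global average pooling: f_spec ∈ R³².
* **Fusion head** — residual fusion
  F_fused = FC₂(BN(ReLU(FC₁(u)))) + FC_skip(u) of u = [f_final; f_spec],
  then ŷ = σ(FC_out(BN(ReLU(FC_pred(F_fused))))).

The frozen trunk carries 42,500,160 parameters; the default widths put
the full model at 44,116,235 ≈ 44.12 M (~1.62 M trainable). Five ablation
variants (A/B/C/D/all) toggle the graph attention, the multi-scale graph
branches and the multi-scale spectral convolutions.

See `docs/methods.md` for the full model description, the synthetic
benchmark's assumptions, and every numerical/design choice.

## Worked example

`examples/04_train_and_evaluate.py` generates a 250-molecule synthetic
benchmark (400 training pairs), trains the full variant for 20 epochs with
the benchmark protocol (Adam, lr 1e-4, batch 32, BCE, best-validation
checkpointing) and evaluates both test conditions:

```
best checkpoint: epoch 18 (validation accuracy 0.82)
test_rand  AUC 0.917  accuracy 0.808  precision 0.750  recall 0.923  F1 0.828  (n=26)
test_diff  AUC 0.799  accuracy 0.750  precision 0.667  recall 1.000  F1 0.800  (n=24)
```

`test_rand` pairs each test molecule's graph with spectra of a random
other molecule as the mismatch; `test_diff` uses structurally dissimilar
molecules (Tanimoto < 0.2). AUC is the probability that a matched pair
scores above a mismatched one; n is the number of evaluated pairs.

The other examples cover graph construction and validation (`01`),
spectrum simulation (`02`), dataset generation with manifests (`03`) and
parameter accounting across ablation variants (`05`). The same
functionality is scriptable through the thin CLI:

```bash
nmrmatch generate --n 250 --seed 0 --out dataset/
nmrmatch train --variant all --n 250 --seed 0 --epochs 20
nmrmatch count-params --variant all --backbone resnet101
nmrmatch ablate --n 250 --seed 0
```

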