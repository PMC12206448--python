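# lnpfusion

Predicting the transfection efficiency of ionizable-lipid LNPs (lipid
nanoparticles) from molecular structure, with atom-level interpretability.

Ionizable lipids dominate how well an LNP delivers mRNA, but screening them in
the wet lab is slow and expensive. `lnpfusion` implements a multimodal
structure–activity model for this problem, together with the analytics that
make its predictions auditable:

* **Molecule 3D transformer** — per-atom features from atom types, 3D
  coordinates, pairwise Euclidean distances and bond codes.  Geometry enters
  self-attention as an additive pair bias: distances expanded on Gaussian
  radial kernels, bond types embedded, the two terms blended by a trainable
  gate `g`, and attention computed as `softmax(QKᵀ/√d + bias)·V`.  A
  masked-atom pretraining interface (atom-type cross-entropy ·1, coordinate
  smooth-L1 ·5, pairwise-distance smooth-L1 ·10 on corrupted atoms) is
  included.
* **Molecule Mamba** — a selective state-space sequence encoder over SMILES
  tokens.  The continuous system `x' = Ax + Bu, y = Cx` is discretized per
  step with `Ā = exp(ΔA)`, `B̄ = Δ·B`, where Δ, B, C depend on the input
  (Δ through softplus) and the scan is the causal recurrence
  `x_k = Ā_k x_{k−1} + B̄_k u_k`, `y_k = C_k x_k + D u_k`.
* **Mol-attention fusion block** — sequence features are gathered at the atom
  token positions so both branches describe the same heavy atoms, then each
  atom gets a score `σ(W₂ ReLU(W₁ concat(z₁, z₂′)))` in (0,1).  Scores scale
  the fused features before pooling and a bounded regression head
  `tanh(W₂′ tanh(W₁′ ·))` predicts transfection efficiency in log2 units via an
  affine label scaler.  The scores are the interpretability surface: on
  transfection-cliff pairs they highlight the substituted atoms.
* **Hybrid loss** — `MSE + β · triplet`, where the cross-modal triplet term
  `max(d(a,p) − d(a,n) + margin, 0)` (summed over valid triplets, divided by
  the number of active ones) pulls the two branches' pooled embeddings of
  similar-label molecules together (β = 6 for scaffold splits, 3 for cliff
  splits).
* **Transfection-cliff analytics** — structure similarity is the mean of ECFP
  Tanimoto, MACCS Tanimoto and normalized Levenshtein SMILES similarity; the
  transfection difference of a pair labelled `m₁, m₂` (log2) is
  `TD = |log₁₀(2^(m₂−m₁))|`.  Pairs with similarity > 0.9 and TD > 1 are
  cliffs; key atoms come from a maximum-common-substructure diff.
* **Scaffold and cliff splitting** — Bemis–Murcko groups assigned greedily, or
  spectral clustering on an ECFP Tanimoto affinity matrix with per-cluster
  10% test stratification and an 8:2 train:val remainder.
* **Synthetic library generator** — combinatorial head × ester-tail lipids
  with log2-scale labels that are a linear function of interpretable
  descriptors, plus injected single-atom (C→N) cliff twins that provably pass
  the screening thresholds.

The neural stack is pure NumPy on a small reverse-mode autograd core
(`lnpfusion.minigrad`), which keeps the package dependency-light and every
numerical path testable against naive oracles.

## Worked example

```python
from lnpfusion import synthgen, splits, runtime
from lnpfusion.cliffs import screen_cliffs

# 200-molecule combinatorial library + 20 injected cliff twins
lib = synthgen.generate_library(n_heads=20, n_tails=10, seed=1)
lib = synthgen.assign_labels(lib, seed=2)
lib, injected = synthgen.inject_cliffs(lib, n_pairs=20, seed=3)

res = screen_cliffs(lib.records)
print(len(res.pairs), res.n_pairs_evaluated)   # 462 24090

split = splits.scaffold_split(lib.records, seed=0)
config = runtime.RunConfig.desk(epochs=30, seed=0).with_beta_for("scaffold")
result = runtime.train(config, lib.records, split)
print(result.test_metrics)
# {'mse': 0.887, 'mae': 0.675, 'r2': 0.881, 'pcc': 0.947}
```

Screening evaluates all 24 090 unordered pairs of the 220 molecules and finds
462 cliffs (structure similarity > 0.9 and TD > 1), including all 20 injected
twins.  The desk-profile model (width 128) trained for 30 epochs on the
scaffold split explains most of the held-out variance (R² ≈ 0.88) and ranks
molecules almost perfectly (PCC ≈ 0.95); the exact decimals depend on seeds.
`model.explain(...)` then yields per-atom scores; on the injected cliff pairs
the substituted atoms average higher scores (≈ 0.30) than the shared atoms
(≈ 0.21), i.e. the model points at the atoms that cause the cliff.

The same pipeline is available from the shell:

```bash
lnpfusion simulate --n-heads 20 --n-tails 10 --cliff-pairs 20 --seed 1 --out lib.csv
lnpfusion split lib.csv --method scaffold --out split.csv
lnpfusion cliffs lib.csv --out cliffs.json
lnpfusion train lib.csv --split-csv split.csv --desk --out model.npz
lnpfusion predict lib.csv --checkpoint model.npz --out preds.csv
lnpfusion explain lib.csv --checkpoint model.npz --out scores.csv
```

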