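# celldeconv

Cell-type deconvolution of bulk and spatial transcriptomes: given the mixed
RNA expression profile of a bulk sample or a spatial capture spot, estimate
what fraction of it came from each cell type.

The package is aimed at computational biologists who want a fully testable,
fixture-scale implementation of a neural deconvolution stack:

* **Pseudobulk mixture simulation** — synthetic training mixtures with known
  fractions built from a labeled single-cell dataset: T total cells, N unique
  types and Dirichlet fractions F are drawn at random, T·F is apportioned to
  integer cell counts by largest remainder, and the selected cells'
  depth-log-normalized profiles are averaged. The label is the realized
  composition of the averaged cells.
* **A dense deconvolution network** — an ELU stack with a softmax head, so
  every prediction row p satisfies pᵢ ≥ 0, Σᵢ pᵢ = 1. Inputs are normalized
  per sample (counts → CPM-10k → log2(1+x) → z-score → min-max) and corrupted
  during training (Gaussian noise σ = 0.05, then 20% random zeroing). The
  loss is a masked MSE computed only over cell types truly present in each
  mixture. Training uses Adam with plateau LR-halving and early stopping.
* **Ontology propagation** — predicted mass is summed upwards along a
  user-supplied cell-type ontology (a child→parent DAG), so mass assigned to
  "cd4 t cell" is also captured by "t cell": value(v) = Σ raw mass over v and
  its distinct descendants.
* **Reference-guided transfer deconvolution** — average a labeled reference
  into per-type signatures, extract the network's two middle hidden layers as
  cell-state embeddings for signatures and mixtures, reduce each feature
  block by NMF, batch-align the components, and regress fractions with a
  bagging ensemble of 48 linear nu-SVRs (CIBERSORT-style orientation:
  components are observations, cell types are predictors).
* **Integrated-gradients attribution** — per-gene attributions for any target
  cell type, accumulated by trapezoidal summation along a zero-to-input path
  (optionally with a descending random gene-dropout schedule), scaled by the
  input so unexpressed genes get exactly zero.
* **Evaluation** — Lin's concordance correlation coefficient
  CCC = 2·cov(x,y)/(var x + var y + (x̄ − ȳ)²), per-type benchmark tables,
  sensitivity sweeps over mixture size / type count / gene dropout, and
  spatial downsampling of high-resolution data into pseudo-spots with known
  truth.
* **A synthetic corpus generator** — negative-binomial counts with planted
  marker blocks and type-independent depth variation (plus Voronoi-niche
  spatial fixtures), so every stage above is testable with no downloads.

See `docs/methods.md` for the models, assumptions and design decisions.

## Worked example

Train the tiny preset on simulated mixtures and score held-out recovery:

```python
import celldeconv as cd

corpus = cd.make_corpus(cd.CorpusConfig(seed=0))          # 1,600 cells x 200 genes, 8 types
norm = cd.normalize_dataset(cd.qc_filter(corpus))
train_mix = cd.build_training_set(
    norm, 5000, cd.MixerParams(T_range=(1, 1000), N_range=(1, 8), seed=0))

cfg = cd.ModelConfig(n_genes=norm.n_genes, hidden=(256, 128, 64, 32),
                     n_outputs=8, seed=0)
model = cd.build_model(cfg, train_mix.catalog, norm.gene_symbols)
model, history = cd.train(model, train_mix, cd.TrainParams(seed=0))
print(f"trained {history.stopped_epoch} epochs ({history.stop_reason}), "
      f"final masked MSE {history.train_loss[-1]:.2e}")

test_mix = cd.build_training_set(
    norm, 300, cd.MixerParams(T_range=(1, 1000), N_range=(1, 8), seed=123))
pred = cd.predict_fractions(model, test_mix.X, already_log=True)
table = cd.benchmark(pred, test_mix.Y, truth_catalog=test_mix.catalog)
print(table.table.to_string(index=False))
print(f"mean CCC: {table.mean_ccc:.3f}")
```

Output:

```
trained 50 epochs (max_epochs), final masked MSE 1.09e-02
cell_type      ccc  degenerate
   type_0 0.941620       False
   type_1 0.973625       False
   type_2 0.969164       False
   type_3 0.950544       False
   type_4 0.957409       False
   type_5 0.970633       False
   type_6 0.963598       False
   type_7 0.972009       False
mean CCC: 0.962
```

Each row is one cell type's concordance between predicted and true fractions
across the 300 held-out mixtures; a mean CCC of 0.96 means the network
recovers the planted compositions almost exactly at this fixture scale.

The same pipeline is available from the shell:

```bash
celldeconv fixtures --out corpus.h5ad --seed 0
celldeconv train --corpus corpus.h5ad --n-mixtures 5000 --out ckpt --seed 0
celldeconv deconvolve --model ckpt --input corpus.h5ad --out fractions.csv
celldeconv bp --fractions fractions.csv --ontology edges.tsv --out propagated.csv
celldeconv explain --model ckpt --input corpus.h5ad --target type_0 --out attr.csv
```

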