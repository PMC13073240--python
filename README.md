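# scposition

Inferring the anatomical compartment of tissue-resident immune cells from
their single-cell RNA-seq transcriptomes.

## The problem

When cells are dissociated for scRNA-seq, their position in the tissue is
lost. In organs with compartmentalized anatomy — the kidney's cortex,
outer medulla (OM) and inner medulla (IM), or the brain's macro-dissected
regions — each compartment has a distinct microenvironment (osmolarity,
oxygen, nutrients) that imprints a *positional fingerprint* on the
transcriptomes of long-resident immune cells such as kidney macrophages
and microglia. Motile cells (lymphocytes, freshly infiltrated monocytes)
do not stay long enough to acquire one.

`scposition` learns that fingerprint from compartment-labeled training
datasets and uses it to assign compartments to cells from new, unlabeled
datasets. It is aimed at computational biologists who have (or can obtain)
scRNA-seq data from macro-dissected compartments and want to spatially
resolve other datasets from the same organ.

## The method

1. **Feature selection.** Within each training dataset, genes are ranked
   by highly-variable-gene (HVG) dispersion: for gene $g$ with
   log-normalized mean $\mu_g$ and variance $\sigma_g^2$, the dispersion
   $d_g = \sigma_g^2/\mu_g$ is z-scored within equal-frequency bins of
   $\mu_g$ (20 bins), and the top 100 genes per dataset are merged across
   datasets by order-preserving union. Comparison selectors —
   one-vs-rest marker genes (Wilcoxon rank-sum + Benjamini–Hochberg),
   recursive feature elimination, mutual-information ranking, and a seeded
   random control — are provided under the same interface.
2. **Classifier.** A gated-attention multilayer perceptron on z-scored
   log-normalized expression $x$ of the selected genes:
   $g = \sigma(W_g x + b_g)$, input $x \odot g$, ReLU trunk (128, 64),
   dropout 0.2, softmax over compartments, Adam with early stopping.
   All randomness flows from one seed; training is bit-reproducible.
3. **Evaluation.** Overall accuracy, per-compartment one-vs-rest ROC AUC,
   confusion matrices, repeated stratified holdout (median ± SEM), a
   seven-model classical baseline suite, and Student's *t* comparisons
   with BH correction across batches.
4. **Transfer.** Trained models apply to any matrix by gene symbol
   (missing genes zero-filled, training statistics reused) and across
   species through an explicit homology table; downstream readouts give
   compartment-resolved cell-count kinetics, per-cell gene-set module
   scores and compartment-wise differential expression.
5. **Simulation.** A negative-binomial generator (variance
   $\mu + \phi\mu^2$) with planted compartment signatures, per-dataset
   batch shifts, sex effects, library-size variation and a
   motility/residence-time attenuation makes every stage testable without
   external data.

## Worked example

Train on one simulated compartment-labeled dataset, validate externally on
a second one that carries independent batch effects:

```python
import scposition as sp

cfg = sp.SimConfig(seed=7)                      # 2 datasets, 3 compartments
datasets, truth = sp.simulate(cfg)
(mA, annA), (mB, annB) = datasets

lA = sp.log_normalize(sp.qc_filter(mA)[0])
lB = sp.log_normalize(sp.qc_filter(mB)[0])

hvg, _ = sp.hvg_rank(lA, n_top=100)
model = sp.train_position_model(lA, annA.aligned_to(lA.cell_ids), hvg,
                                sp.TrainingConfig(seed=7))
report = sp.evaluate(sp.predict(model, lB), annB.aligned_to(lB.cell_ids))
print(report.overall_accuracy, report.per_class_auc)
```

Output:

```
HVG top-100 contains 80 of the 90 planted signature genes
external-validation accuracy: 1.000
  one-vs-rest AUC IM: 1.000
  one-vs-rest AUC OM: 1.000
  one-vs-rest AUC cortex: 1.000
```

The HVG ranking recovers most of the planted signature genes, and the
classifier transfers perfectly to the batch-shifted second dataset — at
the simulator's default effect size (δ = 1.5 natural-log units on 30
genes per compartment) the compartments are strongly separable. Erasing
the positional signal (`motility_attenuation=1.0`) drops accuracy to
chance (~33%), the behavior expected for motile cells.

The same workflow runs from the shell:

```bash
scposition --seed 7 simulate --out sim/
scposition select --counts sim/ds1 --method hvg --out hvg.gmt
scposition --seed 7 train --counts sim/ds1 --annotations sim/ds1_annotations.tsv \
    --geneset hvg.gmt --out model.scpos
scposition evaluate --model model.scpos --counts sim/ds2 \
    --annotations sim/ds2_annotations.tsv --out eval.json
scposition run --quickstart --out quickstart_out/   # full pipeline + manifest
```

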