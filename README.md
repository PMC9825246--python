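# avib

Attention-based variational information bottleneck for multi-sequence
molecular interaction prediction, with unsupervised out-of-distribution
(OOD) detection in the learned latent space.

## The problem

Whether a T cell recognizes a peptide is decided jointly by the peptide and
the CDR3 loops of the receptor's α- and β-chains: no single sequence is
predictive on its own, so the task cannot be treated as ordinary multimodal
fusion of individually-informative inputs. `avib` is for computational
immunologists who need (i) a binding classifier that accepts any subset of
(peptide, CDR3α, CDR3β) or (peptide, MHC pseudo-sequence) per record —
including subsets never complete at test time — and (ii) a calibrated way to
flag test sequences that come from a different distribution than the
training data, without ever seeing OOD examples.

## The model

Each sequence role has a stochastic encoder (1-D CNN over a standardized
BLOSUM50 20×N matrix) emitting a diagonal-Gaussian posterior
q̃(Z|x_i) = N(μ_i, diag(σ_i²)) over a shared latent Z. The per-sequence
parameters, stacked with the N(0, I) prior row, are fused by multi-head
self-attention followed by column-wise max pooling ("attention of experts"):

    μ = MaxPool(MultiHead_μ(M, M, M)),   σ = exp(MaxPool(MultiHead_lnσ(ln Σ, ln Σ, ln Σ)))

which is permutation invariant and indifferent to the number of expert rows
— the property that makes missing-sequence inference work. Product/mixture
of experts and pooling ablations are available behind the same interface.
A decoder maps a reparameterized sample z = μ + σ⊙ε to the prediction, and
training minimizes the bottleneck objective

    J = (1/N) Σₙ E_ε[−log q(yₙ|zₙ)] + β · KL(p(Z|xₙ) ‖ N(0, I)),

(MSE replaces the log-likelihood for binding-affinity regression). For OOD
detection, class-conditional Gaussians with a shared covariance are fitted
to the training latent means and a test record is scored by
−min_c ½ d²_Maha(E[Z|x], μ_c) — hyperparameter-free, higher = more
in-distribution. Rate (−KL to the prior), MSP and ODIN baselines are
included, with AUROC/AUPR/FPR@95%TPR/detection-error reporting.

See `docs/methods.md` for assumptions, defaults, numerical choices and known
limitations.

## Worked example

```python
import numpy as np
from avib import AVIB, TrainingConfig
from avib.io import classification_metrics, train_test_split_records
from avib.synthetic import GeneratorConfig, generate_interaction_dataset

records = generate_interaction_dataset(
    GeneratorConfig(n_records=5000, label_noise=0.05, seed=0)
)
train, test = train_test_split_records(records, test_fraction=0.2, seed=0)

model = AVIB(train, TrainingConfig(d_z=16, heads=2, epochs=30, seed=0))
results = model.fit()
print(results.summary())

preds, posteriors = results.predict(test)
labels = np.array([r.label for r in test])
print(classification_metrics(preds, labels))
```

This trains on 5 000 synthetic (peptide, CDR3α, CDR3β) records whose label
depends only on whether the peptide's latent binding class matches the
CDR3s' class, with 5% label noise. Output (one CPU, ≈2 minutes):

```
Attentive Variational Information Bottleneck — fit summary
============================================================
task            classification
aggregator      aoe
roles           cdr3a, cdr3b, peptide
latent width    d_Z = 16   heads = 2
beta            0.001
records         4000
parameters      33345
epochs run      30
restarts        0
final objective 0.056709
final NLL term  0.036098
final KL term   20.610527
============================================================
{'auroc': 0.9200386958296174, 'aupr': 0.8784273053822367, 'f1': 0.847457627118644, 'accuracy': 0.919}
```

Held-out AUROC 0.92 sits close to the ceiling implied by the 5% label noise
(≈0.95 for a perfect classifier), while the same architecture given only
peptides stays near chance (AUROC ≈ 0.5) — the signal really is the
interaction. The same fitted model predicts from (peptide, CDR3β) pairs
alone (`results.predict` on records with CDR3α absent) with held-out AUROC
0.92: training averages the objective over peptide-preserving subsets, so
missing sequences at test time degrade the model gracefully.

The command line mirrors the library:

```bash
avib generate interaction --n 5000 --seed 0 --out train.csv
avib train --data train.csv --dz 16 --heads 2 --epochs 30 --seed 0 --out model.ckpt
avib predict --model model.ckpt --data train.csv --out preds.csv
avib eval    --model model.ckpt --data train.csv --out metrics.json
avib ood     --model model.ckpt --id-train train.csv --test-id id.csv \
             --test-ood ood.csv --method maha --out report.csv
```

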