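# Methods

## The model

`avib` predicts whether a set of amino-acid sequences interact — the driving
case is T-cell receptor (TCR) recognition, where a peptide and the CDR3 loops
of the receptor's α- and β-chains jointly determine binding, and no single
sequence is informative on its own. The same machinery handles peptide–MHC
binding-affinity regression with (peptide, MHC pseudo-sequence) pairs.

Each input role (peptide, `cdr3a`, `cdr3b`, `mhc_pseudo`) has its own
stochastic encoder producing a diagonal-Gaussian posterior over a shared
latent variable Z of width d_Z:

    q̃(Z | x_i) = N(μ_i, diag(σ_i²)),   i = 1 … M.

The per-sequence parameters are stacked together with the standard-normal
prior row (μ₀ = 0, σ₀ = 1) into matrices **M**, **Σ** ∈ R^{(M+1)×d_Z} and
aggregated into one joint posterior p(Z | x_1:M) = N(μ, diag(σ²)). The
default aggregator is attention of experts (AoE):

    μ = MaxPool( MultiHead_μ(**M**, **M**, **M**) )
    σ = exp( MaxPool( MultiHead_ln σ(ln **Σ**, ln **Σ**, ln **Σ**) ) )

with two independent multi-head self-attention blocks (no biases, no
positional encoding — the rows are an unordered set, so the output is
invariant to row permutation and indifferent to the number of rows, which is
what makes prediction with missing sequences possible). Alternatives behind
the same interface: product of experts (precisions add, prior included),
uniform mixture of experts (prior excluded; no closed-form KL, see below),
and the attention-free max-/average-pooling ablations.

A feed-forward decoder maps a reparameterized sample z = μ + σ⊙ε,
ε ~ N(0, I) to a logit (classification) or a sigmoid output (regression).
Training minimizes the information-bottleneck objective

    J = (1/N) Σ_n E_ε[ −log q(y_n | z_n) ] + β · KL( p(Z|x_n) ‖ N(0, I) )

with a single-sample Monte-Carlo estimate of the expectation and the
closed-form KL ½ Σ_d (μ_d² + σ_d² − 1 − 2 ln σ_d). For regression the
log-likelihood term is replaced by squared error.

### Multi-sequence subset terms

For records carrying three or more sequences the objective is averaged over
the full role set and every peptide-preserving subset with one non-peptide
sequence dropped (e.g. for a (peptide, CDR3α, CDR3β) triple: the triple,
(peptide, CDR3β) and (peptide, CDR3α)). This is the natural multi-sequence
extension of the bi-sequence objective for set-valued inputs, in the lineage
of multimodal variational methods that sum subset bounds. It matters
empirically: without it, a triple-trained model collapses to chance when a
CDR3 chain is missing at test time (held-out AUROC 0.49 on the synthetic
task), because nothing in pure full-set training constrains the aggregator's
behaviour on smaller stacks; with it, the same evaluation holds at ≈0.89.
`TrainingConfig(subset_terms=False)` restores the single-term objective.

### Architecture and encoding

Sequences are validated against the 20 canonical residues (non-canonical
letters are rejected, never imputed) and featurized as 20×N matrices whose
column j is the full BLOSUM50 substitution row of residue j (taken from
biopython's published table; an NCBI-format file loader is provided).
Features are standardized by a scaler fitted on training columns only —
shared across roles by default (`scaler_scope="per_role"` to change) — and
right-padded with zero columns to the longest training sequence per role
(overridable), so pads coincide with the post-standardization feature mean.
Encoding order is encode → standardize → pad, which keeps pad columns
exactly zero.

Each encoder is a 1-D CNN over the 20×N_max matrix: two convolutions
(kernel 3, channels 32→64, same-padding, ReLU), global max-pooling over
positions, then two linear heads for μ and ln σ, with ln σ clipped to
[ln 1e−4, ln 1e4] so σ is positive and bounded by construction. The decoder
is d_Z → 32 → 1 with ReLU. All parameters use scaled-uniform initialization
(±1/√fan_in), biases included — zero biases would place pre-ReLU activations
of all-pad windows exactly on the kink, which is both numerically awkward
and makes finite-difference gradient checks ill-posed.

Everything differentiable runs on a small reverse-mode automatic
differentiation core written on numpy (`avib._autodiff`): broadcastable
arithmetic, batched matmul, the usual nonlinearities with numerically stable
sigmoid/softplus/softmax, axis reductions with first-index tie-breaking for
max, shape ops, and 1-D convolution via im2col. Gradients are verified
against central finite differences op-by-op and end-to-end through the full
objective.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| β | 1e−3 | validated on the synthetic task: ≈0.003 is equivalent, ≥0.01 prevents the interaction structure from being learned at all before compressing |
| d_Z | 128 | matches the latent width customary for this model family; the synthetic study uses 16, which is sufficient for a 4-class joint pattern |
| heads | 2 | smallest multi-head configuration; must divide d_Z |
| learning rate | 1e−3 (Adam) | 2e−3 already destabilizes training at batch 64 |
| batch size | 64 | chosen by validation: 256 leaves too few gradient steps in 30 epochs for a single-CPU run (held-out AUROC 0.87 vs 0.90) |
| epochs | 30 | the synthetic task plateaus by ≈25 |
| σ aggregation | log-space | attention and pooling act on ln σ and the result is exponentiated: positivity by a smooth bijection; `sigma_mode="literal"` applies the blocks to σ directly with a softplus safeguard |
| covariance ridge λ | 1e−6·tr(Σ)/d | keeps the pooled covariance invertible when N < d or classes are degenerate |

### Multi-start optimization

The interaction objective is not benign: a fraction of initializations
either never leave the predict-the-base-rate plateau or drive the training
loss to zero by memorization without learning the joint pattern (train NLL
≈ 0.02 with held-out AUROC ≈ 0.5). `fit()` therefore holds out
`val_fraction` (5%) of the training records, runs up to `max_restarts` (4)
independently seeded attempts on the remainder, and keeps the first whose
internal validation AUROC reaches `restart_min_auroc` (0.8) — for
regression, whose validation MSE falls below 0.8× the label variance —
otherwise the attempt with the best validation score. This is the `n_init`
convention of mixture-model fitting, with selection on a leak-free internal
split. Validation AUROC rather than validation NLL is the selector because
a well-generalizing model still pays a large NLL on label-noise-flipped
validation records it confidently (and correctly, pre-flip) classifies.
With `max_restarts=1`, or too few records for a validation split, a single
attempt trains on all records.

Training is bitwise deterministic given the seed on one thread: one
`default_rng` stream per attempt (derived from the seed) drives
initialization, shuffling and the reparameterization noise, restart
selection is itself deterministic, and prediction in mean mode (z = μ)
involves no randomness at all. Mixture-of-experts models train with the per-expert
averaged objective (mean over experts of NLL + β·KL), since a Gaussian
mixture has no closed-form KL to the prior; prediction decodes the mixture
mean.

## Out-of-distribution detection

After training on in-distribution data only, the latent means E[Z|x_1:M] of
the training records are summarized by K class-conditional Gaussians
(K = 2: binders / non-binders) with a shared pooled covariance normalized by
N plus the λ ridge. The score of a test record is

    score(x) = − min_c ½ (E[Z|x] − μ_c)ᵀ Σ⁻¹ (E[Z|x] − μ_c),

hyperparameter-free, oriented so that higher means more in-distribution.
Baselines with the same orientation: the rate score −KL(p(Z|x) ‖ N(0,I));
maximum softmax probability (MSP) max(p, 1−p) from the mean-mode prediction;
and ODIN — temperature-scaled confidence after an ε-sized gradient-sign
perturbation of the standardized input encodings (defaults ε = 0.001,
T = 1000; ε = 0, T = 1 reduces exactly to MSP). Detection quality is
reported as AUROC, AUPR, FPR at 95% TPR (smallest threshold whose TPR ≥
0.95, no interpolation) and the detection error ½(1−TPR) + ½FPR at that
threshold, with ID as the positive class and seeded subsampling to balance
ID/OOD test counts.

## The synthetic data generator

The generator emulates the one property that defines this problem class:
the label depends only on the joint pattern. Each of C = 4 latent binding
classes owns a peptide motif and a cognate CDR3 motif (length 3, drawn
distinct); a record binds iff its peptide's class matches its CDR3s' class.
Class assignments are arranged so each single sequence's class marginal is
identical among binders and non-binders — audited by a chi-square test —
hence any single-sequence classifier is reduced to chance. Defaults: 5 000
records, peptide length 8–15, CDR3 10–20, positive fraction 0.25, label
noise η = 0.05, uniform residue background. OOD sequences come from a
background re-weighted 15× toward the residues W, Y, F, H, M and/or a
disjoint length range, with no implanted ID motifs. The regression generator
labels (peptide, MHC) pairs with a logistic function of the implanted
motif-match fraction plus Gaussian noise, clipped to [0, 1], and can return
the latent match fraction for oracle audits.

What the generator does **not** emulate: V(D)J recombination statistics,
germline-biased CDR3 prefixes/suffixes, peptide anchor-position structure,
class imbalance across peptides, or assay noise correlated with sequence
content. Passing the synthetic study therefore shows that the architecture,
objective and inference machinery work as specified — not that the method
reaches any particular accuracy on real TCR data.

### A structural caveat for the latent Mahalanobis score

On this generator the latent OOD detector behaves qualitatively differently
from what is reported on real TCR data, and the mechanism is instructive.
Because single sequences are uninformative by construction, the decoder must
receive both the peptide class and the CDR3 class, so the latent means of ID
records necessarily form ≈C² sub-clusters, many of them far from the two
class means; the within-class covariance is correspondingly broad. Motif-free
OOD sequences, meanwhile, collapse toward the latent origin — the bottleneck
prunes directions that carry no label-relevant signal, and the class means
themselves sit near that origin. The result is that central OOD points score
as *closer* to the class means than typical ID points: with d_Z = 16 at the
study conditions the Mahalanobis AUROC lands between 0.2 and 0.74 across
seeds (a linear probe on the same latents separates ID from OOD at 0.99, so
the information is present — the K = 2 unimodal-cluster summary is what
fails). The effect is robust to β in the learnable range, to latent width,
and to giving the OOD sequences their own foreign motif repertoire. We report
the score as specified and flag this as a known limitation: the
class-conditional Gaussian assumption behind the score requires latent class
clusters to be unimodal, which combinatorial interaction tasks violate.

## Numerical choices

- KL, PoE and the attention blocks are float64 throughout; oracle agreement
  is verified to 1e−6–1e−8 (quadrature, explicit solves, per-head loops).
- Max-pooling ties route gradients to the first index (conventional).
- Zero-variance features in the scaler are floored at 1e−8.
- Softmax subtracts the row max; softmax's shift invariance makes the
  detached shift exactly gradient-correct.
- The NaN guard aborts training with the offending epoch/batch rather than
  continuing with poisoned parameters.

## Problem sizes used by tests and the acceptance script

The synthetic study runs at n = 5 000 records (80/20 split), d_Z = 16,
2 heads, 30 epochs, batch 64 — about one minute of training on one CPU —
and 1 000 + 1 000 balanced ID/OOD test records for detection. Oracle checks
use d_Z = 4 stacks, 10⁶-sample Monte-Carlo KL estimates, 300 001-point
quadrature grids, and 50 finite-difference coordinates on a d_Z = 8 model.
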