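"""Out-of-distribution detection from the learned latent posterior.

After training on in-distribution (ID) data only, the latent means
E[Z|x_1:M] of the training records are summarized by K class-conditional
Gaussians with per-class means and a single shared covariance (pooled over
class-centred encodings, normalized by N, with a small diagonal
regularization against singularity). A test record is scored by the negative
of half its smallest squared Mahalanobis distance to any class mean — a
hyperparameter-free score needing no OOD samples at any point. Baselines with
the same "higher = more in-distribution" orientation:

- rate score: −KL(joint posterior ‖ N(0, I));
- MSP: the maximum of (p, 1−p) from the mean-mode predicted probability;
- ODIN: temperature-scaled confidence after a small gradient-sign input
  perturbation (defaults ε = 0.001, T = 1000).

Detection quality is reported as AUROC, AUPR, FPR@95%TPR and the detection
error ½(1−TPR) + ½FPR at the FPR@95%TPR operating point, with ID as the
positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

from ._autodiff import Tensor
from .model import AVIB, SequenceRecord
from .posteriors import GaussianMixture, kl_to_standard_normal

__all__ = [
    "ClassConditionalGaussian",
    "OodScoreReport",
    "fit_class_gaussians",
    "maha_score",
    "rate_score",
    "msp_score",
    "odin_score",
    "ood_metrics",
    "roc_pr_points",
    "balanced_subsample",
]


@dataclass
class ClassConditionalGaussian:
    """Per-class latent means with one shared covariance."""

    class_means: np.ndarray       # (K, d)
    shared_covariance: np.ndarray  # (d, d), symmetric positive definite
    class_counts: np.ndarray      # (K,)
    classes: np.ndarray           # (K,) original labels
    _chol: np.ndarray = None      # cached Cholesky factor

    @property
    def n(self) -> int:
        return int(self.class_counts.sum())

    def cholesky(self) -> np.ndarray:
        if self._chol is None:
            try:
                self._chol = np.linalg.cholesky(self.shared_covariance)
            except np.linalg.LinAlgError as e:
                raise np.linalg.LinAlgError(
                    "shared covariance is singular; raise the regularization lambda"
                ) from e
        return self._chol


def fit_class_gaussians(
    latents: np.ndarray, labels: np.ndarray, reg_lambda: float | None = None
) -> ClassConditionalGaussian:
    """Fit per-class means and the pooled shared covariance.

    latents: (N, d) latent means of ID training records; labels: (N,).
    The covariance is (1/N) Σ_c Σ_{i∈c} (z_i−μ_c)(z_i−μ_c)ᵀ + λI with
    λ = 1e−6 · trace(Σ)/d by default (guards the N < d singular case).
    """
    latents = np.asarray(latents, dtype=np.float64)
    labels = np.asarray(labels)
    if latents.ndim != 2 or len(labels) != len(latents):
        raise ValueError("latents must be (N, d) with one label per row")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        bad = classes[counts < 2]
        raise ValueError(f"classes {bad.tolist()} have fewer than 2 records")
    d = latents.shape[1]
    means = np.stack([latents[labels == c].mean(axis=0) for c in classes])
    cov = np.zeros((d, d))
    for c, mu in zip(classes, means):
        centered = latents[labels == c] - mu
        cov += centered.T @ centered
    cov /= len(latents)
    lam = reg_lambda if reg_lambda is not None else 1e-6 * np.trace(cov) / d
    lam = max(lam, 1e-12)
    cov = cov + lam * np.eye(d)
    return ClassConditionalGaussian(
        class_means=means, shared_covariance=cov, class_counts=counts, classes=classes
    )


def maha_score(cg: ClassConditionalGaussian, latent: np.ndarray) -> float:
    """−min_c ½ (z−μ_c)ᵀ Σ⁻¹ (z−μ_c): ≤ 0, zero exactly at a class mean.

    Hyperparameter free — no input perturbation, no layer weighting.
    """
    z = np.asarray(latent, dtype=np.float64)
    L = cg.cholesky()
    diffs = cg.class_means - z[None, :]           # (K, d)
    # squared Mahalanobis via triangular solve
    sol = np.linalg.solve(L, diffs.T)             # (d, K)
    d2 = np.sum(sol**2, axis=0)
    return float(-0.5 * d2.min())


def rate_score(model: AVIB, rec: SequenceRecord) -> float:
    """−KL(joint posterior ‖ N(0, I)); higher means more in-distribution."""
    post = model.joint_posterior(rec)
    if isinstance(post, GaussianMixture):
        raise ValueError("rate score requires a single-Gaussian joint posterior")
    return -kl_to_standard_normal(post)


def msp_score(model: AVIB, rec: SequenceRecord) -> float:
    """Maximum softmax probability for the binary head: max(p, 1−p) ∈ [½, 1]."""
    if model.config.task != "classification":
        raise ValueError("MSP requires a classification model")
    p, _ = model.predict([rec], mode="mean")
    return float(max(p[0], 1.0 - p[0]))


def _record_max_prob_graph(model: AVIB, arrays: dict, temperature: float) -> Tensor:
    """max(p, 1−p) at temperature T as a differentiable scalar."""
    mu_rows, ls_rows = model._group_posterior_graph(arrays)
    mu, _sigma = model._aggregate_rows(mu_rows, ls_rows)
    logit = model._decoder(mu) * (1.0 / temperature)   # (1,)
    p = logit.sigmoid()
    both = (p - 0.5) ** 2.0                            # monotone in max(p, 1-p)
    return p, both


def odin_score(
    model: AVIB,
    rec: SequenceRecord,
    epsilon: float = 0.001,
    temperature: float = 1000.0,
) -> float:
    """Temperature scaling + gradient-sign input perturbation.

    The standardized input encodings are nudged by ε in the direction that
    increases the temperature-scaled confidence, then the perturbed
    confidence max(p, 1−p) is returned. ε = 0, T = 1 reduces to MSP.
    """
    if model.config.task != "classification":
        raise ValueError("ODIN requires a classification model")
    if epsilon < 0 or temperature <= 0:
        raise ValueError("require epsilon >= 0 and temperature > 0")
    if model.config.aggregator == "moe":
        raise ValueError("ODIN needs a differentiable single-Gaussian posterior")
    feats = model.encode_record(rec)
    arrays = {role: Tensor(f[None], requires_grad=True) for role, f in feats.items()}
    _p, conf = _record_max_prob_graph(model, arrays, temperature)
    conf.sum().backward()
    perturbed = {}
    for role, t in arrays.items():
        grad = t.grad if t.grad is not None else np.zeros_like(t.value)
        perturbed[role] = Tensor(t.value + epsilon * np.sign(grad))
    p2, _ = _record_max_prob_graph(model, perturbed, temperature)
    p_val = float(p2.value[0])
    return max(p_val, 1.0 - p_val)


@dataclass
class OodScoreReport:
    """Threshold-free OOD detection metrics (ID = positive class)."""

    method: str
    scores: np.ndarray
    is_id: np.ndarray
    auroc: float
    aupr: float
    fpr_at_95tpr: float
    detection_error: float

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "auroc": self.auroc,
            "aupr": self.aupr,
            "fpr_at_95tpr": self.fpr_at_95tpr,
            "detection_error": self.detection_error,
        }


def ood_metrics(scores, is_id, method: str = "") -> OodScoreReport:
    """AUROC/AUPR plus FPR@95%TPR and detection error.

    scores: higher = more in-distribution; is_id: 1 for ID (positive class).
    FPR@95TPR uses the smallest threshold whose TPR >= 0.95 (no
    interpolation); detection error is ½(1−TPR) + ½FPR at that threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    is_id = np.asarray(is_id).astype(int)
    if len(np.unique(is_id)) < 2:
        raise ValueError("need both ID and OOD samples to compute metrics")
    auroc = float(roc_auc_score(is_id, scores))
    aupr = float(average_precision_score(is_id, scores))
    fpr, tpr, _ = roc_curve(is_id, scores, drop_intermediate=False)
    ok = tpr >= 0.95
    i = np.argmax(ok)  # first threshold (highest) reaching TPR >= 0.95
    fpr95 = float(fpr[i])
    det_err = float(0.5 * (1.0 - tpr[i]) + 0.5 * fpr[i])
    return OodScoreReport(
        method=method,
        scores=scores,
        is_id=is_id,
        auroc=auroc,
        aupr=aupr,
        fpr_at_95tpr=fpr95,
        detection_error=det_err,
    )


def roc_pr_points(scores, is_id):
    """ROC and precision-recall curve points for plotting.

    Returns a dict of two pandas DataFrames: {"roc": (fpr, tpr, threshold),
    "pr": (recall, precision, threshold)}; ID is the positive class.
    """
    import pandas as pd
    from sklearn.metrics import precision_recall_curve

    scores = np.asarray(scores, dtype=np.float64)
    is_id = np.asarray(is_id).astype(int)
    fpr, tpr, thr = roc_curve(is_id, scores, drop_intermediate=False)
    precision, recall, thr_pr = precision_recall_curve(is_id, scores)
    return {
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        "pr": pd.DataFrame(
            {
                "recall": recall[:-1],
                "precision": precision[:-1],
                "threshold": thr_pr,
            }
        ),
    }


def balanced_subsample(id_idx, ood_idx, rng: np.random.Generator):
    """Equalize ID/OOD test counts by subsampling the larger side, seeded."""
    id_idx = np.asarray(id_idx)
    ood_idx = np.asarray(ood_idx)
    n = min(len(id_idx), len(ood_idx))
    if len(id_idx) > n:
        id_idx = rng.choice(id_idx, size=n, replace=False)
    if len(ood_idx) > n:
        ood_idx = rng.choice(ood_idx, size=n, replace=False)
    return id_idx, ood_idx
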