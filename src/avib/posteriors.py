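"""Diagonal-Gaussian latent posteriors and expert aggregation.

Each available input sequence i contributes an "expert": a diagonal-Gaussian
approximate posterior q̃(Z|x_i) = N(μ_i, diag(σ_i²)) over the shared latent
variable Z. The standard-normal prior N(0, I) is stacked as row 0 alongside
the expert rows, and a joint posterior is produced by one of:

- AoE (attention of experts): multi-head self-attention over the stacked
  parameter rows followed by column-wise 1-D max pooling — one attention
  block for the means, an independent one for the (log) sigmas;
- PoE: the precision-weighted product of the prior and expert Gaussians;
- MoE: the uniform mixture of the expert Gaussians (prior excluded);
- max/avg pooling ablations: column-wise max or mean over the stacked rows.

Rows form an unordered set — no positional encoding, no masking — so every
aggregator is permutation invariant and accepts any number of experts, which
is what makes inference with missing sequences possible.

The attention computations are written on autodiff tensors so the training
loop can differentiate through them; the public functions accept and return
plain numpy-backed dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import multivariate_normal

from ._autodiff import Tensor, as_tensor, concat

__all__ = [
    "DiagonalGaussian",
    "ExpertStack",
    "AoeParameters",
    "GaussianMixture",
    "kl_to_standard_normal",
    "reparameterized_sample",
    "stack_experts",
    "aoe_aggregate",
    "poe_aggregate",
    "moe_aggregate",
    "pool_aggregate",
    "attention_weights",
    "aggregate",
    "AGGREGATORS",
]

PRIOR_ROLE = "prior"


@dataclass(frozen=True)
class DiagonalGaussian:
    """N(mu, diag(sigma²)) over the d_Z-dimensional latent space."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=np.float64)
        sigma = np.asarray(self.sigma, dtype=np.float64)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        if mu.shape != sigma.shape or mu.ndim != 1:
            raise ValueError("mu and sigma must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))):
            raise ValueError("mu and sigma must be finite")
        if np.any(sigma <= 0):
            raise ValueError("sigma must be strictly positive")

    @property
    def dim(self) -> int:
        return self.mu.shape[0]

    @classmethod
    def standard(cls, dim: int) -> "DiagonalGaussian":
        return cls(np.zeros(dim), np.ones(dim))


@dataclass(frozen=True)
class ExpertStack:
    """Stacked posterior parameters: row 0 the prior, rows 1..M the experts."""

    M: np.ndarray           # (M+1, d_Z) means
    S: np.ndarray           # (M+1, d_Z) sigmas, strictly positive
    row_roles: tuple        # length M+1; row_roles[0] == "prior"

    def __post_init__(self):
        M = np.asarray(self.M, dtype=np.float64)
        S = np.asarray(self.S, dtype=np.float64)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "row_roles", tuple(self.row_roles))
        if M.shape != S.shape or M.ndim != 2:
            raise ValueError("M and S must be 2-D with equal shape")
        if M.shape[0] < 2:
            raise ValueError("stack needs the prior plus at least one expert")
        if len(self.row_roles) != M.shape[0]:
            raise ValueError("row_roles length must match the row count")
        if np.any(S <= 0):
            raise ValueError("all sigmas must be strictly positive")

    @property
    def n_experts(self) -> int:
        return self.M.shape[0] - 1

    @property
    def dim(self) -> int:
        return self.M.shape[1]

    def experts(self) -> list[DiagonalGaussian]:
        """Recover the expert Gaussians (prior row excluded)."""
        return [DiagonalGaussian(self.M[i], self.S[i]) for i in range(1, self.M.shape[0])]


def kl_to_standard_normal(g: DiagonalGaussian) -> float:
    """Closed-form KL( N(mu, diag(sigma²)) ‖ N(0, I) ).

    ½ Σ_d (μ_d² + σ_d² − 1 − 2 ln σ_d); non-negative, zero iff standard normal.
    """
    return float(
        0.5 * np.sum(g.mu**2 + g.sigma**2 - 1.0 - 2.0 * np.log(g.sigma))
    )


def reparameterized_sample(g: DiagonalGaussian, eps: np.ndarray) -> np.ndarray:
    """z = mu + sigma ⊙ eps, the reparameterization that makes sampling
    differentiable; eps = 0 returns mu exactly."""
    eps = np.asarray(eps, dtype=np.float64)
    if eps.shape != g.mu.shape:
        raise ValueError(f"eps shape {eps.shape} does not match d_Z {g.mu.shape}")
    return g.mu + g.sigma * eps


def stack_experts(
    experts: Sequence[DiagonalGaussian], roles: Sequence[str] | None = None
) -> ExpertStack:
    """Stack the prior row N(0, I) on top of the expert rows, in input order."""
    if not experts:
        raise ValueError("at least one expert is required")
    d = experts[0].dim
    if any(e.dim != d for e in experts):
        raise ValueError("experts have mixed latent dimensions")
    M = np.vstack([np.zeros(d)] + [e.mu for e in experts])
    S = np.vstack([np.ones(d)] + [e.sigma for e in experts])
    if roles is None:
        roles = [f"expert_{i}" for i in range(len(experts))]
    return ExpertStack(M=M, S=S, row_roles=(PRIOR_ROLE, *roles))


# ---------------------------------------------------------------------------
# Attention of Experts
# ---------------------------------------------------------------------------


@dataclass
class AoeParameters:
    """Two independent multi-head self-attention blocks (mean branch, sigma
    branch), each with per-head query/key/value projections and an output
    projection. No biases, no positional encoding: the expert rows are a set.

    sigma_mode:
      - "log" (default): the sigma branch attends over ln σ rows and the
        pooled result is exponentiated — positivity is guaranteed by a smooth
        bijection;
      - "literal": the branch attends over σ directly and a softplus
        safeguards positivity of the pooled output.
    """

    d_z: int
    heads: int
    wq_mu: np.ndarray  # (h, d_z, d_k)
    wk_mu: np.ndarray
    wv_mu: np.ndarray
    wo_mu: np.ndarray  # (d_z, d_z)
    wq_sigma: np.ndarray
    wk_sigma: np.ndarray
    wv_sigma: np.ndarray
    wo_sigma: np.ndarray
    sigma_mode: str = "log"

    def __post_init__(self):
        if self.d_z % self.heads != 0:
            raise ValueError(f"d_z={self.d_z} not divisible by heads={self.heads}")
        if self.sigma_mode not in ("log", "literal"):
            raise ValueError("sigma_mode must be 'log' or 'literal'")

    @property
    def d_k(self) -> int:
        return self.d_z // self.heads

    @classmethod
    def initialize(
        cls, d_z: int, heads: int, rng: np.random.Generator, sigma_mode: str = "log"
    ) -> "AoeParameters":
        """Scaled-uniform initialization of all projections."""
        if d_z % heads != 0:
            raise ValueError(f"d_z={d_z} not divisible by heads={heads}")
        d_k = d_z // heads

        def u(*shape, fan_in):
            lim = np.sqrt(1.0 / fan_in)
            return rng.uniform(-lim, lim, size=shape)

        kw = dict(
            wq_mu=u(heads, d_z, d_k, fan_in=d_z),
            wk_mu=u(heads, d_z, d_k, fan_in=d_z),
            wv_mu=u(heads, d_z, d_k, fan_in=d_z),
            wo_mu=u(d_z, d_z, fan_in=d_z),
            wq_sigma=u(heads, d_z, d_k, fan_in=d_z),
            wk_sigma=u(heads, d_z, d_k, fan_in=d_z),
            wv_sigma=u(heads, d_z, d_k, fan_in=d_z),
            wo_sigma=u(d_z, d_z, fan_in=d_z),
        )
        return cls(d_z=d_z, heads=heads, sigma_mode=sigma_mode, **kw)

    def tensors(self, requires_grad: bool = False) -> dict:
        out = {}
        for name in (
            "wq_mu", "wk_mu", "wv_mu", "wo_mu",
            "wq_sigma", "wk_sigma", "wv_sigma", "wo_sigma",
        ):
            arr = getattr(self, name)
            t = arr if isinstance(arr, Tensor) else Tensor(arr, requires_grad=requires_grad)
            out[name] = t
        return out


def _attention_scores(X: Tensor, wq: Tensor, wk: Tensor, d_k: int) -> Tensor:
    """Per-head row-stochastic attention matrices softmax(QKᵀ/√d_k).

    X: (B, R, d_z); wq/wk: (h, d_z, d_k) -> (B, h, R, R)
    """
    B, R, _ = X.shape
    h = wq.shape[0]
    Xh = X.reshape(B, 1, R, X.shape[-1])        # (B, 1, R, d_z)
    Q = Xh @ wq                                  # (B, h, R, d_k)
    K = Xh @ wk
    scores = (Q @ K.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d_k))
    return scores.softmax(axis=-1)               # (B, h, R, R)


def multihead_self_attention(X, wq, wk, wv, wo, d_k: int) -> Tensor:
    """Standard multi-head self-attention, queries = keys = values = X.

    X: (B, R, d_z) -> (B, R, d_z): per-head softmax(QKᵀ/√d_k)V, heads
    concatenated then linearly projected by wo.
    """
    X = as_tensor(X)
    B, R, d_z = X.shape
    h = wq.shape[0]
    A = _attention_scores(X, wq, wk, d_k)        # (B, h, R, R)
    V = X.reshape(B, 1, R, d_z) @ wv             # (B, h, R, d_k)
    heads = A @ V                                # (B, h, R, d_k)
    merged = heads.transpose(0, 2, 1, 3).reshape(B, R, h * d_k)
    return merged @ wo                           # (B, R, d_z)


def aoe_forward(
    mu_rows: Tensor, sigma_rows_raw: Tensor, params: AoeParameters, tensors: dict | None = None
) -> tuple[Tensor, Tensor]:
    """Differentiable AoE over a batch of stacks.

    mu_rows: (B, R, d_z); sigma_rows_raw: (B, R, d_z) holding ln σ in "log"
    mode or σ in "literal" mode. Returns (mu_aoe, sigma_aoe), each (B, d_z),
    sigma strictly positive.
    """
    t = tensors if tensors is not None else params.tensors()
    d_k = params.d_k
    mu_att = multihead_self_attention(
        mu_rows, t["wq_mu"], t["wk_mu"], t["wv_mu"], t["wo_mu"], d_k
    )
    mu_aoe = mu_att.max(axis=1)                  # 1-D max pool over rows
    sg_att = multihead_self_attention(
        sigma_rows_raw, t["wq_sigma"], t["wk_sigma"], t["wv_sigma"], t["wo_sigma"], d_k
    )
    pooled = sg_att.max(axis=1)
    if params.sigma_mode == "log":
        sigma_aoe = pooled.clip(-20.0, 20.0).exp()
    else:
        sigma_aoe = pooled.softplus() + 1e-8
    return mu_aoe, sigma_aoe


def _stack_sigma_rows(stack: ExpertStack, params: AoeParameters) -> np.ndarray:
    return np.log(stack.S) if params.sigma_mode == "log" else stack.S


def aoe_aggregate(stack: ExpertStack, params: AoeParameters) -> DiagonalGaussian:
    """Attention-of-experts joint posterior from a stacked prior + experts."""
    if stack.dim != params.d_z:
        raise ValueError(f"stack d_Z {stack.dim} != params d_Z {params.d_z}")
    mu_rows = Tensor(stack.M[None, :, :])
    sg_rows = Tensor(_stack_sigma_rows(stack, params)[None, :, :])
    mu, sigma = aoe_forward(mu_rows, sg_rows, params)
    return DiagonalGaussian(mu.value[0], sigma.value[0])


def attention_weights(
    stack: ExpertStack, params: AoeParameters, branch: Literal["mu", "sigma"] = "mu"
) -> dict:
    """Per-head row-stochastic attention matrices for one stack.

    Returns {"weights": (h, R, R) array, "row_roles": tuple} where entry
    [head, i, j] is how much row i attends to row j; each row sums to 1.
    """
    if branch not in ("mu", "sigma"):
        raise ValueError("branch must be 'mu' or 'sigma'")
    if stack.dim != params.d_z:
        raise ValueError(f"stack d_Z {stack.dim} != params d_Z {params.d_z}")
    t = params.tensors()
    if branch == "mu":
        X, wq, wk = Tensor(stack.M[None]), t["wq_mu"], t["wk_mu"]
    else:
        X = Tensor(_stack_sigma_rows(stack, params)[None])
        wq, wk = t["wq_sigma"], t["wk_sigma"]
    A = _attention_scores(X, wq, wk, params.d_k)
    return {"weights": A.value[0], "row_roles": stack.row_roles}


# ---------------------------------------------------------------------------
# Product / mixture / pooling aggregation
# ---------------------------------------------------------------------------


def poe_aggregate(stack: ExpertStack) -> DiagonalGaussian:
    """Product of experts: precisions add over all rows (prior included).

    Per dimension: τ = Σ_r 1/σ_r², σ² = 1/τ, μ = (Σ_r μ_r/σ_r²)/τ.
    """
    prec = 1.0 / stack.S**2                  # (R, d)
    tau = prec.sum(axis=0)
    var = 1.0 / tau
    mu = (stack.M * prec).sum(axis=0) * var
    return DiagonalGaussian(mu, np.sqrt(var))


def poe_forward(mu_rows: Tensor, log_sigma_rows: Tensor) -> tuple[Tensor, Tensor]:
    """Differentiable PoE over a batch of stacks: (B, R, d) -> (B, d) each."""
    prec = (log_sigma_rows * (-2.0)).exp()
    tau = prec.sum(axis=1)
    var = tau ** -1.0
    mu = (mu_rows * prec).sum(axis=1) * var
    return mu, var**0.5


@dataclass(frozen=True)
class GaussianMixture:
    """Uniform mixture of diagonal Gaussians, supporting sampling and density."""

    components: tuple

    def __post_init__(self):
        if not self.components:
            raise ValueError("mixture needs at least one component")
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def dim(self) -> int:
        return self.components[0].dim

    @property
    def mean(self) -> np.ndarray:
        return np.mean([c.mu for c in self.components], axis=0)

    def pdf(self, z: np.ndarray) -> float:
        z = np.asarray(z, dtype=np.float64)
        vals = [
            multivariate_normal.pdf(z, mean=c.mu, cov=np.diag(c.sigma**2))
            for c in self.components
        ]
        return float(np.mean(vals, axis=0))

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        ks = rng.integers(0, len(self.components), size=size)
        eps = rng.standard_normal((size, self.dim))
        out = np.empty((size, self.dim))
        for i, k in enumerate(ks):
            c = self.components[k]
            out[i] = c.mu + c.sigma * eps[i]
        return out


def moe_aggregate(stack: ExpertStack) -> GaussianMixture:
    """Mixture of experts: uniform mixture over expert rows, prior excluded."""
    return GaussianMixture(components=tuple(stack.experts()))


def pool_aggregate(stack: ExpertStack, mode: Literal["max", "avg"]) -> DiagonalGaussian:
    """Column-wise max or mean over all rows (prior included) of the mean and
    sigma stacks independently — the attention-free ablations."""
    if mode == "max":
        return DiagonalGaussian(stack.M.max(axis=0), stack.S.max(axis=0))
    if mode == "avg":
        return DiagonalGaussian(stack.M.mean(axis=0), stack.S.mean(axis=0))
    raise ValueError(f"unknown pooling mode {mode!r}")


AGGREGATORS = ("aoe", "poe", "moe", "maxpool", "avgpool")


def aggregate(stack: ExpertStack, kind: str, params: AoeParameters | None = None):
    """Dispatch by aggregator name ('aoe' requires AoeParameters)."""
    if kind == "aoe":
        if params is None:
            raise ValueError("aoe aggregation requires AoeParameters")
        return aoe_aggregate(stack, params)
    if kind == "poe":
        return poe_aggregate(stack)
    if kind == "moe":
        return moe_aggregate(stack)
    if kind == "maxpool":
        return pool_aggregate(stack, "max")
    if kind == "avgpool":
        return pool_aggregate(stack, "avg")
    raise ValueError(f"unknown aggregator {kind!r}; choose from {AGGREGATORS}")
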