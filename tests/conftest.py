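import numpy as np
import pytest

from avib.encoding import Role
from avib.model import AVIB, SequenceRecord, TrainingConfig
from avib.posteriors import AoeParameters, DiagonalGaussian, ExpertStack, stack_experts
from avib.synthetic import GeneratorConfig, generate_interaction_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_gaussian(rng, d):
    return DiagonalGaussian(rng.normal(size=d), np.exp(rng.normal(scale=0.5, size=d)))


@pytest.fixture
def make_gaussian():
    return random_gaussian


def random_stack(rng, n_experts, d) -> ExpertStack:
    experts = [random_gaussian(rng, d) for _ in range(n_experts)]
    return stack_experts(experts)


@pytest.fixture
def make_stack():
    return random_stack


# ---------------------------------------------------------------------------
# Independent brute-force multi-head attention oracle (explicit loops).
# Kept free of any avib internals on purpose: per-head Q/K/V projections,
# softmax(QK^T/sqrt(d_k))V, concatenation, output projection, column-wise max.
# ---------------------------------------------------------------------------


def attention_oracle_weights(X, wq, wk):
    h = wq.shape[0]
    R = X.shape[0]
    d_k = wq.shape[2]
    out = np.zeros((h, R, R))
    for head in range(h):
        Q = X @ wq[head]
        K = X @ wk[head]
        for i in range(R):
            s = np.array([Q[i] @ K[j] / np.sqrt(d_k) for j in range(R)])
            e = np.exp(s - s.max())
            out[head, i] = e / e.sum()
    return out


def multihead_oracle(X, wq, wk, wv, wo):
    h, _, d_k = wq.shape
    R = X.shape[0]
    A = attention_oracle_weights(X, wq, wk)
    heads = []
    for head in range(h):
        V = X @ wv[head]
        out = np.zeros((R, d_k))
        for i in range(R):
            for j in range(R):
                out[i] += A[head, i, j] * V[j]
        heads.append(out)
    return np.concatenate(heads, axis=1) @ wo


def aoe_oracle(stack: ExpertStack, params: AoeParameters):
    """Full AoE by explicit loops: attend over means and (log) sigmas, max-pool
    columns, exponentiate the sigma branch in log mode."""
    mu_att = multihead_oracle(stack.M, params.wq_mu, params.wk_mu, params.wv_mu, params.wo_mu)
    mu = mu_att.max(axis=0)
    raw = np.log(stack.S) if params.sigma_mode == "log" else stack.S
    sg_att = multihead_oracle(
        raw, params.wq_sigma, params.wk_sigma, params.wv_sigma, params.wo_sigma
    )
    pooled = sg_att.max(axis=0)
    if params.sigma_mode == "log":
        sigma = np.exp(np.clip(pooled, -20, 20))
    else:
        sigma = np.log1p(np.exp(pooled)) + 1e-8
    return mu, sigma


@pytest.fixture
def oracle():
    class Oracle:
        weights = staticmethod(attention_oracle_weights)
        multihead = staticmethod(multihead_oracle)
        aoe = staticmethod(aoe_oracle)

    return Oracle


# ---------------------------------------------------------------------------
# Small shared datasets / models
# ---------------------------------------------------------------------------


def subset_roles(records, roles):
    """Copies of records keeping only the given roles."""
    return [
        SequenceRecord(
            sequences={r: s for r, s in rec.sequences.items() if r in roles},
            label=rec.label,
            sample_id=rec.sample_id,
        )
        for rec in records
    ]


@pytest.fixture
def keep_roles():
    return subset_roles


@pytest.fixture(scope="session")
def small_dataset():
    return generate_interaction_dataset(GeneratorConfig(n_records=240, seed=11))


@pytest.fixture(scope="session")
def tiny_model(small_dataset):
    """A quickly trained triple-input model for contract tests."""
    cfg = TrainingConfig(d_z=8, heads=2, epochs=4, batch_size=64, seed=5)
    return AVIB(small_dataset, cfg).fit()
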