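"""The attentive variational information bottleneck model.

A record carries several amino-acid sequences (peptide, CDR3α, CDR3β, or an
MHC pseudo-sequence) and a label: binary interaction or a continuous binding
affinity in [0, 1]. Each role has its own stochastic encoder — a small 1-D
CNN over the 20×N_max BLOSUM feature matrix with two linear heads emitting
the mean and log-sigma of a diagonal-Gaussian posterior over the shared
latent Z. The per-sequence posteriors are stacked with the N(0, I) prior and
aggregated (attention of experts by default; product, mixture, or pooling as
alternatives) into a joint posterior N(μ, diag(σ²)). A feed-forward decoder
maps a reparameterized latent sample to the prediction.

Training minimizes the variational information-bottleneck objective

    J = (1/N) Σ_n E_ε[ −log q(y_n | f(x_n, ε)) ] + β · KL( p(Z|x_n) ‖ N(0,I) )

with a single-sample Monte-Carlo estimate of the expectation (MSE replaces
the log-likelihood for regression). Because the aggregators place no order or
count restriction on the expert rows, a model trained on triples predicts
from any non-empty subset of its roles.

Organisation follows the Model/Results convention: ``AVIB`` holds data,
configuration and parameters; ``AVIB.fit()`` returns an ``AVIBResults``
carrying the loss history, prediction, diagnostics and (de)serialization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import encoding as enc
from ._autodiff import Tensor, concat, conv1d
from .posteriors import (
    AoeParameters,
    DiagonalGaussian,
    GaussianMixture,
    aoe_forward,
    poe_forward,
    stack_experts,
    moe_aggregate,
    attention_weights,
)

__all__ = [
    "SequenceRecord",
    "TrainingConfig",
    "AVIB",
    "AVIBResults",
    "avib_loss",
    "avib_mse_loss",
]

_LOG_SIGMA_MIN = math.log(1e-4)
_LOG_SIGMA_MAX = math.log(1e4)


@dataclass(frozen=True)
class SequenceRecord:
    """One interaction sample: role-tagged sequences plus a label.

    ``label`` is 0/1 for classification or a real in [0, 1] for regression;
    ``None`` for unlabeled prediction inputs. At least the peptide must be
    present; a missing sequence is an absent key, never an empty string.
    """

    sequences: Mapping[enc.Role, enc.AminoAcidSequence]
    label: float | None = None
    sample_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequences", dict(self.sequences))
        if not self.sequences:
            raise ValueError("record has no sequences")

    @property
    def roles(self) -> tuple:
        return tuple(sorted(self.sequences, key=lambda r: r.value))


@dataclass
class TrainingConfig:
    """Hyperparameters of the model and its training loop.

    beta is the Lagrange multiplier trading prediction against compression;
    d_z the latent width; heads the attention head count (must divide d_z).
    """

    beta: float = 1e-3
    d_z: int = 128
    heads: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0
    aggregator: str = "aoe"
    task: str = "classification"
    subset_terms: bool = True  # average the objective over peptide-preserving
                               # drop-one-sequence subsets of each record
    sigma_mode: str = "log"
    conv_channels: tuple = (32, 64)
    kernel_size: int = 3
    decoder_hidden: int = 32
    pos_weight: float | None = None
    scaler_scope: str = "shared"   # or "per_role"
    n_max: dict = field(default_factory=dict)  # role value -> width override
    patience: int | None = None    # early stopping on training loss, off by default
    max_restarts: int = 4          # multi-start attempts when training stalls
    restart_min_auroc: float = 0.8     # classification: attempt accepted when its
                                       # internal validation AUROC reaches this
    restart_mse_fraction: float = 0.8  # regression: attempt accepted when its
                                       # validation MSE falls below this fraction
                                       # of the label variance
    val_fraction: float = 0.05     # held-out share of the training records used
                                   # to select among multi-start attempts

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.d_z % self.heads != 0:
            raise ValueError("d_z must be divisible by heads")
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        if self.aggregator not in ("aoe", "poe", "moe", "maxpool", "avgpool"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")


def _uniform(rng, *shape, fan_in):
    lim = np.sqrt(1.0 / fan_in)
    return rng.uniform(-lim, lim, size=shape)


class AVIB:
    """Attentive variational information bottleneck model.

    Parameters
    ----------
    records : sequence of SequenceRecord
        Training data. Preprocessing (BLOSUM50 encoding, scaler fit, per-role
        N_max) happens at construction, on these records only.
    config : TrainingConfig
    """

    def __init__(self, records: Sequence[SequenceRecord], config: TrainingConfig | None = None):
        self.config = config or TrainingConfig()
        self.records = list(records)
        if not self.records:
            raise ValueError("no training records")
        self.roles = sorted(
            {r for rec in self.records for r in rec.sequences}, key=lambda r: r.value
        )
        self._fit_preprocessing()
        self.params: dict[str, Tensor] = {}
        self.fitted = False
        self._init_params(np.random.default_rng(self.config.seed))

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df, config: TrainingConfig | None = None) -> "AVIB":
        """Build from a pandas DataFrame with columns peptide, cdr3a, cdr3b,
        mhc_pseudo (any subset beyond peptide), label, optional sample_id."""
        from .io import records_from_dataframe

        return cls(records_from_dataframe(df), config)

    def _fit_preprocessing(self) -> None:
        cfg = self.config
        raw = {role: [] for role in self.roles}
        for rec in self.records:
            for role, seq in rec.sequences.items():
                raw[role].append(enc.blosum50_encode(seq))
        self.n_max = {}
        for role in self.roles:
            observed = max(m.shape[1] for m in raw[role])
            self.n_max[role] = int(cfg.n_max.get(role.value, observed))
        if cfg.scaler_scope == "shared":
            scaler = enc.fit_scaler([m for role in self.roles for m in raw[role]])
            self.scalers = {role: scaler for role in self.roles}
        else:
            self.scalers = {role: enc.fit_scaler(raw[role]) for role in self.roles}

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        c1, c2 = cfg.conv_channels
        k = cfg.kernel_size
        p: dict[str, np.ndarray] = {}
        for role in self.roles:
            pre = f"enc.{role.value}"
            p[f"{pre}.w1"] = _uniform(rng, c1, enc.N_FEATURES, k, fan_in=enc.N_FEATURES * k)
            p[f"{pre}.b1"] = _uniform(rng, c1, fan_in=enc.N_FEATURES * k)
            p[f"{pre}.w2"] = _uniform(rng, c2, c1, k, fan_in=c1 * k)
            p[f"{pre}.b2"] = _uniform(rng, c2, fan_in=c1 * k)
            p[f"{pre}.w_mu"] = _uniform(rng, c2, cfg.d_z, fan_in=c2)
            p[f"{pre}.b_mu"] = _uniform(rng, cfg.d_z, fan_in=c2)
            p[f"{pre}.w_ls"] = _uniform(rng, c2, cfg.d_z, fan_in=c2)
            p[f"{pre}.b_ls"] = _uniform(rng, cfg.d_z, fan_in=c2)
        if cfg.aggregator == "aoe":
            aoe = AoeParameters.initialize(cfg.d_z, cfg.heads, rng, sigma_mode=cfg.sigma_mode)
            for name, arr in vars(aoe).items():
                if isinstance(arr, np.ndarray):
                    p[f"aoe.{name}"] = arr
        p["dec.w1"] = _uniform(rng, cfg.d_z, cfg.decoder_hidden, fan_in=cfg.d_z)
        p["dec.b1"] = _uniform(rng, cfg.decoder_hidden, fan_in=cfg.d_z)
        p["dec.w2"] = _uniform(rng, cfg.decoder_hidden, 1, fan_in=cfg.decoder_hidden)
        p["dec.b2"] = _uniform(rng, 1, fan_in=cfg.decoder_hidden)
        self.params = {k_: Tensor(v, requires_grad=True) for k_, v in p.items()}

    def _aoe_params(self) -> AoeParameters:
        cfg = self.config
        return AoeParameters(
            d_z=cfg.d_z,
            heads=cfg.heads,
            sigma_mode=cfg.sigma_mode,
            **{n: self.params[f"aoe.{n}"].value for n in (
                "wq_mu", "wk_mu", "wv_mu", "wo_mu",
                "wq_sigma", "wk_sigma", "wv_sigma", "wo_sigma",
            )},
        )

    def _aoe_tensors(self) -> dict:
        return {n: self.params[f"aoe.{n}"] for n in (
            "wq_mu", "wk_mu", "wv_mu", "wo_mu",
            "wq_sigma", "wk_sigma", "wv_sigma", "wo_sigma",
        )}

    # ------------------------------------------------------------------
    # encoding
    # ------------------------------------------------------------------

    def encode_record(self, rec: SequenceRecord) -> dict:
        """Role -> standardized, padded (20, N_max) array for one record."""
        out = {}
        for role, seq in rec.sequences.items():
            if role not in self.n_max:
                raise ValueError(f"no encoder for role {role.value!r}")
            raw = enc.blosum50_encode(seq)
            out[role] = enc.standardize_and_pad(
                raw, self.scalers[role], self.n_max[role], role
            ).features
        return out

    def _encoder_forward(self, role: enc.Role, x: Tensor) -> tuple:
        """(B, 20, N) -> (mu, log_sigma), each (B, d_z)."""
        p, pre = self.params, f"enc.{role.value}"
        pad = self.config.kernel_size // 2
        h = conv1d(x, p[f"{pre}.w1"], p[f"{pre}.b1"], pad=pad).relu()
        h = conv1d(h, p[f"{pre}.w2"], p[f"{pre}.b2"], pad=pad).relu()
        pooled = h.max(axis=2)                                 # global max pool
        mu = pooled @ p[f"{pre}.w_mu"] + p[f"{pre}.b_mu"]
        ls = (pooled @ p[f"{pre}.w_ls"] + p[f"{pre}.b_ls"]).clip(
            _LOG_SIGMA_MIN, _LOG_SIGMA_MAX
        )
        return mu, ls

    def encode_single(self, encoded: enc.EncodedSequence) -> DiagonalGaussian:
        """Single-sequence posterior q̃(Z|x_i) for one encoded sequence."""
        role = encoded.role
        if role not in self.n_max:
            raise ValueError(f"no encoder for role {role.value!r}")
        if encoded.features.shape[1] != self.n_max[role]:
            raise ValueError(
                f"encoded width {encoded.features.shape[1]} != "
                f"N_max[{role.value}]={self.n_max[role]}"
            )
        mu, ls = self._encoder_forward(role, Tensor(encoded.features[None]))
        return DiagonalGaussian(mu.value[0], np.exp(ls.value[0]))

    # ------------------------------------------------------------------
    # joint posterior + decoding graph
    # ------------------------------------------------------------------

    def _stack_rows(self, mu_list, ls_list) -> tuple:
        """Stack prior + expert rows: lists of (B, d_z) -> (B, R, d_z) pair of
        (means, log-sigmas); prior row is μ=0, ln σ=0."""
        B = mu_list[0].shape[0]
        d = self.config.d_z
        prior = Tensor(np.zeros((B, 1, d)))
        mus = concat([prior] + [m.reshape(B, 1, d) for m in mu_list], axis=1)
        lss = concat([prior] + [s.reshape(B, 1, d) for s in ls_list], axis=1)
        return mus, lss

    def _aggregate_rows(self, mu_rows: Tensor, ls_rows: Tensor) -> tuple:
        """(B, R, d) stacks -> joint (mu, sigma), each (B, d). Not for moe."""
        kind = self.config.aggregator
        if kind == "aoe":
            raw = ls_rows if self.config.sigma_mode == "log" else ls_rows.exp()
            return aoe_forward(mu_rows, raw, self._aoe_params(), tensors=self._aoe_tensors())
        if kind == "poe":
            return poe_forward(mu_rows, ls_rows)
        if kind == "maxpool":
            return mu_rows.max(axis=1), ls_rows.exp().max(axis=1)
        if kind == "avgpool":
            return mu_rows.mean(axis=1), ls_rows.exp().mean(axis=1)
        raise ValueError(f"aggregator {kind!r} has no single-Gaussian form")

    def _group_records(self, records: Sequence[SequenceRecord]):
        """Group record indices by their present-role signature."""
        groups: dict[tuple, list] = {}
        for i, rec in enumerate(records):
            groups.setdefault(rec.roles, []).append(i)
        return groups

    def _batch_arrays(self, records, idxs, roles) -> dict:
        out = {}
        for role in roles:
            mats = []
            for i in idxs:
                feats = self.encode_record(records[i])
                mats.append(feats[role])
            out[role] = np.stack(mats)
        return out

    def _group_posterior_graph(self, arrays: dict) -> tuple:
        """arrays: role -> Tensor or ndarray (B, 20, N_max). Returns
        (mu_rows, ls_rows) stacks (B, R, d_z), expert order = sorted roles."""
        roles = sorted(arrays, key=lambda r: r.value)
        mu_list, ls_list = [], []
        for role in roles:
            x = arrays[role] if isinstance(arrays[role], Tensor) else Tensor(arrays[role])
            mu, ls = self._encoder_forward(role, x)
            mu_list.append(mu)
            ls_list.append(ls)
        return self._stack_rows(mu_list, ls_list)

    def joint_posterior(self, rec: SequenceRecord):
        """Joint posterior over Z given the record's present sequences.

        Returns a DiagonalGaussian (or a GaussianMixture when the aggregator
        is 'moe'). Works for any non-empty subset of the trained roles.
        """
        unknown = [r for r in rec.sequences if r not in self.n_max]
        if unknown:
            raise ValueError(f"roles {[r.value for r in unknown]} were not trained")
        arrays = {role: feats[None] for role, feats in self.encode_record(rec).items()}
        mu_rows, ls_rows = self._group_posterior_graph(arrays)
        if self.config.aggregator == "moe":
            experts = [
                DiagonalGaussian(mu_rows.value[0, i], np.exp(ls_rows.value[0, i]))
                for i in range(1, mu_rows.shape[1])
            ]
            return moe_aggregate(stack_experts(experts, [r.value for r in rec.roles]))
        mu, sigma = self._aggregate_rows(mu_rows, ls_rows)
        return DiagonalGaussian(mu.value[0], sigma.value[0])

    def _decoder(self, z: Tensor) -> Tensor:
        """Latent (B, d_z) -> raw logit (B,)."""
        p = self.params
        h = (z @ p["dec.w1"] + p["dec.b1"]).relu()
        B = z.shape[0]
        return (h @ p["dec.w2"] + p["dec.b2"]).reshape(B)

    @staticmethod
    def _kl_rows(mu: Tensor, sigma: Tensor) -> Tensor:
        """Per-record KL to N(0, I): (B, d) -> (B,)."""
        return ((mu**2.0 + sigma**2.0 - 1.0 - 2.0 * sigma.log()) * 0.5).sum(axis=1)

    def _nll(self, logit: Tensor, y: np.ndarray) -> Tensor:
        """Per-record negative log-likelihood / squared error, shape (B,)."""
        if self.config.task == "classification":
            per = logit.softplus() - logit * y
            if self.config.pos_weight is not None:
                per = per * (1.0 + (self.config.pos_weight - 1.0) * y)
            return per
        return (logit.sigmoid() - y) ** 2.0

    def _subsets_for(self, roles: tuple) -> list:
        """Loss terms per record group: the full role set, plus — for records
        with three or more sequences — every peptide-preserving subset with
        one non-peptide sequence dropped. Averaging the objective over these
        terms is the multi-sequence extension that teaches the aggregator to
        cope with sequences missing at test time."""
        subs = [tuple(roles)]
        if (
            self.config.subset_terms
            and self.config.aggregator != "moe"
            and len(roles) >= 3
            and enc.Role.PEPTIDE in roles
        ):
            for drop in roles:
                if drop is not enc.Role.PEPTIDE:
                    subs.append(tuple(r for r in roles if r is not drop))
        return subs

    def _group_loss(self, arrays: dict, y: np.ndarray, rng) -> tuple:
        """Summed (over records) NLL and KL contributions for one group of
        records sharing a role signature. arrays: role -> Tensor (B, 20, N)."""
        roles = tuple(sorted(arrays, key=lambda r: r.value))
        mu_e, ls_e = {}, {}
        for role in roles:
            mu_e[role], ls_e[role] = self._encoder_forward(role, arrays[role])
        B = y.shape[0]
        nll_g, kl_g = Tensor(0.0), Tensor(0.0)
        if self.config.aggregator == "moe":
            # mixture has no closed-form KL to the prior: use the
            # per-expert averaged objective (uniform weights)
            eps = rng.standard_normal((B, self.config.d_z))
            for role in roles:
                sg_i = ls_e[role].exp()
                z = mu_e[role] + sg_i * eps
                nll_g = nll_g + self._nll(self._decoder(z), y).sum()
                kl_g = kl_g + self._kl_rows(mu_e[role], sg_i).sum()
            inv = 1.0 / len(roles)
            return nll_g * inv, kl_g * inv
        subsets = self._subsets_for(roles)
        for sub in subsets:
            mu_rows, ls_rows = self._stack_rows(
                [mu_e[r] for r in sub], [ls_e[r] for r in sub]
            )
            mu, sigma = self._aggregate_rows(mu_rows, ls_rows)
            eps = rng.standard_normal((B, self.config.d_z))
            z = mu + sigma * eps
            nll_g = nll_g + self._nll(self._decoder(z), y).sum()
            kl_g = kl_g + self._kl_rows(mu, sigma).sum()
        inv = 1.0 / len(subsets)
        return nll_g * inv, kl_g * inv

    def loss_graph(self, records: Sequence[SequenceRecord], beta: float,
                   rng: np.random.Generator):
        """Differentiable objective on a batch.

        Returns (total, nll_term, kl_term) Tensors: mean NLL (single-sample
        Monte-Carlo) + beta * mean KL of the joint posterior to the prior,
        each averaged over the record's subset terms (see _subsets_for).
        """
        if not records:
            raise ValueError("empty batch")
        ys = self._check_labels(records)
        n = len(records)
        nll_sum, kl_sum = Tensor(0.0), Tensor(0.0)
        for roles, idxs in self._group_records(records).items():
            arrays = {
                role: Tensor(a)
                for role, a in self._batch_arrays(records, idxs, roles).items()
            }
            nll_g, kl_g = self._group_loss(arrays, ys[idxs], rng)
            nll_sum = nll_sum + nll_g
            kl_sum = kl_sum + kl_g
        nll_term = nll_sum * (1.0 / n)
        kl_term = kl_sum * (1.0 / n)
        return nll_term + beta * kl_term, nll_term, kl_term

    def _check_labels(self, records) -> np.ndarray:
        ys = []
        for rec in records:
            if rec.label is None:
                raise ValueError(f"record {rec.sample_id!r} has no label")
            y = float(rec.label)
            if self.config.task == "classification":
                if y not in (0.0, 1.0):
                    raise ValueError(
                        f"classification labels must be 0/1, got {y} "
                        f"(record {rec.sample_id!r})"
                    )
            elif not 0.0 <= y <= 1.0:
                raise ValueError(f"regression labels must lie in [0,1], got {y}")
            ys.append(y)
        return np.asarray(ys)

    def loss(self, records, beta: float | None = None, rng=None) -> dict:
        """Objective value on a batch; returns {'total', 'nll', 'kl'} floats."""
        beta = self.config.beta if beta is None else beta
        rng = rng or np.random.default_rng(self.config.seed)
        total, nll, kl = self.loss_graph(records, beta, rng)
        return {"total": total.item(), "nll": nll.item(), "kl": kl.item()}

    # ------------------------------------------------------------------
    # training
    # ------------------------------------------------------------------

    def _baseline_risk(self, ys: np.ndarray) -> float:
        """Risk of the best constant predictor on the training labels:
        Bernoulli entropy of the base rate (classification) or label
        variance (regression). A run whose final NLL is well below this has
        escaped the predict-the-base-rate plateau."""
        if self.config.task == "classification":
            p = float(np.clip(ys.mean(), 1e-6, 1 - 1e-6))
            return float(-p * np.log(p) - (1 - p) * np.log(1 - p))
        return float(max(ys.var(), 1e-12))

    def _mean_mode_outputs(self, idx, arrays_by_sig, index_by_sig, ys):
        """Deterministic mean-mode predictions (z = mu, no sampling) on a
        record subset; returns (probabilities, labels) in group order."""
        idx_set = np.zeros(len(self.records), dtype=bool)
        idx_set[idx] = True
        preds, labels = [], []
        for roles, g_idx in index_by_sig.items():
            take = idx_set[g_idx]
            if not take.any():
                continue
            sel = np.flatnonzero(take)
            arrays = {
                role: Tensor(arrays_by_sig[roles][role][sel]) for role in roles
            }
            mu_rows, ls_rows = self._group_posterior_graph(arrays)
            if self.config.aggregator == "moe":
                mu = mu_rows[:, 1:, :].mean(axis=1)
            else:
                mu, _ = self._aggregate_rows(mu_rows, ls_rows)
            logit = self._decoder(mu).value
            preds.append(1.0 / (1.0 + np.exp(-logit)))
            labels.append(ys[g_idx[sel]])
        return np.concatenate(preds), np.concatenate(labels)

    def _validation_score(self, idx, arrays_by_sig, index_by_sig, ys):
        """Model-selection score on the internal validation split.

        Classification: AUROC of the mean-mode prediction (robust to the
        overconfident-on-flipped-labels blowup that distorts NLL); falls back
        to accuracy against the base rate when only one class is present.
        Regression: mean squared error. Returns (score, higher_is_better).
        """
        preds, labels = self._mean_mode_outputs(idx, arrays_by_sig, index_by_sig, ys)
        if self.config.task == "regression":
            return float(np.mean((preds - labels) ** 2)), False
        if len(np.unique(labels)) < 2:
            return float(np.mean((preds >= 0.5) == labels)), True
        from sklearn.metrics import roc_auc_score

        return float(roc_auc_score(labels, preds)), True

    def fit(self, verbose: bool = False) -> "AVIBResults":
        """Train with Adam on the bottleneck objective; fully seeded.

        Optimization is multi-start: some initializations either never leave
        the predict-the-base-rate plateau or memorize without generalizing,
        so a small validation split (``val_fraction``) is held out of the
        training records and up to ``max_restarts`` seeded attempts are
        trained on the remainder. The first attempt whose validation risk
        falls below ``restart_nll_fraction`` times the constant-predictor
        risk is kept; otherwise the attempt with the lowest validation risk.
        With ``max_restarts=1`` or too few records for a validation split,
        a single attempt trains on everything. Deterministic given the seed.
        """
        cfg = self.config
        # cache encodings once (records are immutable), shared by attempts
        cache = [self.encode_record(rec) for rec in self.records]
        groups_all = self._group_records(self.records)
        arrays_by_sig = {
            roles: {role: np.stack([cache[i][role] for i in idxs]) for role in roles}
            for roles, idxs in groups_all.items()
        }
        index_by_sig = {roles: np.asarray(idxs) for roles, idxs in groups_all.items()}
        ys = self._check_labels(self.records)

        n = len(self.records)
        n_val = int(round(cfg.val_fraction * n))
        use_validation = cfg.max_restarts > 1 and n_val >= 8
        if use_validation:
            perm = np.random.default_rng(cfg.seed + 13).permutation(n)
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            if cfg.task == "regression":
                accept = cfg.restart_mse_fraction * self._baseline_risk(ys[val_idx])
            else:
                accept = cfg.restart_min_auroc
        else:
            val_idx, train_idx = None, np.arange(n)

        best = None  # (score, params, history, attempt)
        attempts = max(1, cfg.max_restarts) if use_validation else 1
        for k in range(attempts):
            if k > 0:  # attempt 0 trains from the parameters as constructed
                self._init_params(np.random.default_rng(cfg.seed + 7919 * k))
            rng = np.random.default_rng(cfg.seed + 1 + 7919 * k)
            history = self._run_training(
                rng, train_idx, arrays_by_sig, index_by_sig, ys, verbose
            )
            if not use_validation:
                self.fitted = True
                return AVIBResults(self, history, n_restarts=0)
            score, higher_better = self._validation_score(
                val_idx, arrays_by_sig, index_by_sig, ys
            )
            better = best is None or (score > best[0] if higher_better else score < best[0])
            if better:
                best = (
                    score,
                    {name: t.value.copy() for name, t in self.params.items()},
                    history,
                    k,
                )
            accepted = score >= accept if higher_better else score <= accept
            if accepted:
                break
            if verbose and k + 1 < attempts:
                print(f"restart {k + 1}: validation score {score:.4f} "
                      f"did not reach {accept:.4f}")
        score, params, history, attempt = best
        for name, t in self.params.items():
            t.value[...] = params[name]
        self.fitted = True
        return AVIBResults(
            self, history, n_restarts=attempt, validation_risk=score
        )

    def _run_training(self, rng, train_idx, arrays_by_sig, index_by_sig, ys, verbose) -> list:
        cfg = self.config
        names = sorted(self.params)
        m = {k: np.zeros_like(self.params[k].value) for k in names}
        v = {k: np.zeros_like(self.params[k].value) for k in names}
        b1, b2, eps_adam = 0.9, 0.999, 1e-8
        step = 0
        train_idx = np.asarray(train_idx)
        n = len(train_idx)
        history = []
        best, stall = np.inf, 0
        for epoch in range(cfg.epochs):
            order = train_idx[rng.permutation(n)]
            ep_total = ep_nll = ep_kl = 0.0
            for start in range(0, n, cfg.batch_size):
                batch_idx = order[start : start + cfg.batch_size]
                total, nll, kl = self._batch_loss_cached(
                    batch_idx, arrays_by_sig, index_by_sig, ys, cfg.beta, rng
                )
                if not np.isfinite(total.value):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                    )
                for t in self.params.values():
                    t.zero_grad()
                total.backward()
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
                for k in names:
                    g = self.params[k].grad
                    if g is None:
                        continue
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v[k] = b2 * v[k] + (1 - b2) * g**2
                    self.params[k].value -= lr_t * m[k] / (np.sqrt(v[k]) + eps_adam)
                w = len(batch_idx) / n
                ep_total += total.item() * w
                ep_nll += nll.item() * w
                ep_kl += kl.item() * w
            history.append({"epoch": epoch, "total": ep_total, "nll": ep_nll, "kl": ep_kl})
            if verbose:
                print(f"epoch {epoch:3d}  total {ep_total:.4f}  nll {ep_nll:.4f}  kl {ep_kl:.4f}")
            if cfg.patience is not None:
                if ep_total < best - 1e-6:
                    best, stall = ep_total, 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        break
        return history

    def _batch_loss_cached(self, batch_idx, arrays_by_sig, index_by_sig, ys, beta, rng):
        """Loss over a batch using the precomputed encoding cache."""
        n = len(batch_idx)
        batch_set = np.zeros(len(self.records), dtype=bool)
        batch_set[batch_idx] = True
        nll_sum, kl_sum = Tensor(0.0), Tensor(0.0)
        for roles, idxs in index_by_sig.items():
            take = batch_set[idxs]
            if not take.any():
                continue
            sel = np.flatnonzero(take)
            arrays = {role: Tensor(arrays_by_sig[roles][role][sel]) for role in roles}
            nll_g, kl_g = self._group_loss(arrays, ys[idxs[sel]], rng)
            nll_sum = nll_sum + nll_g
            kl_sum = kl_sum + kl_g
        nll_term = nll_sum * (1.0 / n)
        kl_term = kl_sum * (1.0 / n)
        return nll_term + beta * kl_term, nll_term, kl_term

    # ------------------------------------------------------------------
    # prediction
    # ------------------------------------------------------------------

    def predict(self, records: Sequence[SequenceRecord], mode: str = "mean"):
        """Predicted probability (or regression value) per record.

        mode='mean' decodes z = μ (ε = 0), fully deterministic;
        mode='sample:S' averages decoder outputs over S seeded draws.
        Missing sequences per record are allowed (any non-empty subset of the
        trained roles). Returns (values, posteriors).
        """
        if not self.fitted:
            raise ValueError("model is not fitted; call fit() first")
        if mode == "mean":
            n_samples = 0
        elif mode.startswith("sample:"):
            n_samples = int(mode.split(":", 1)[1])
            if n_samples < 1:
                raise ValueError("sample count must be >= 1")
        else:
            raise ValueError(f"unknown prediction mode {mode!r}")
        rng = np.random.default_rng(self.config.seed + 2)
        out = np.empty(len(records))
        posteriors = []
        for i, rec in enumerate(records):
            post = self.joint_posterior(rec)
            posteriors.append(post)
            if isinstance(post, GaussianMixture):
                zs = (
                    post.mean[None]
                    if n_samples == 0
                    else post.sample(rng, n_samples)
                )
            else:
                if n_samples == 0:
                    zs = post.mu[None]
                else:
                    eps = rng.standard_normal((n_samples, post.dim))
                    zs = post.mu[None] + post.sigma[None] * eps
            logit = self._decoder(Tensor(zs)).value
            vals = 1.0 / (1.0 + np.exp(-logit))
            out[i] = vals.mean()
        return out, posteriors

    def latent_means(self, records: Sequence[SequenceRecord]) -> np.ndarray:
        """E[Z | x_1:M] per record — the statistic the OOD detector consumes."""
        means = []
        for rec in records:
            post = self.joint_posterior(rec)
            means.append(post.mean if isinstance(post, GaussianMixture) else post.mu)
        return np.stack(means)

    def attention_maps(self, rec: SequenceRecord, branch: str = "mu") -> dict:
        """Attention weights of the AoE block for one record (aoe models only)."""
        if self.config.aggregator != "aoe":
            raise ValueError("attention maps exist only for the aoe aggregator")
        feats = self.encode_record(rec)
        roles = sorted(feats, key=lambda r: r.value)
        experts = []
        for role in roles:
            g = self.encode_single(
                enc.EncodedSequence(feats[role], len(rec.sequences[role]), role)
            )
            experts.append(g)
        stack = stack_experts(experts, [r.value for r in roles])
        return attention_weights(stack, self._aoe_params(), branch)

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------

    def state_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["conv_channels"] = list(cfg["conv_channels"])
        return {
            "config": cfg,
            "roles": [r.value for r in self.roles],
            "n_max": {r.value: int(v) for r, v in self.n_max.items()},
            "scaler_scope": self.config.scaler_scope,
            "scalers": {r.value: self.scalers[r].to_dict() for r in self.roles},
            "params": {k: v.value.tolist() for k, v in self.params.items()},
            "fitted": self.fitted,
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.state_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "AVIB":
        with open(path) as fh:
            state = json.load(fh)
        return cls.from_state_dict(state)

    @classmethod
    def from_state_dict(cls, state: dict) -> "AVIB":
        obj = cls.__new__(cls)
        cfg = dict(state["config"])
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        obj.config = TrainingConfig(**cfg)
        obj.records = []
        obj.roles = [enc.Role(r) for r in state["roles"]]
        obj.n_max = {enc.Role(r): int(v) for r, v in state["n_max"].items()}
        if state["scaler_scope"] == "shared":
            shared = enc.FeatureScaler.from_dict(state["scalers"][obj.roles[0].value])
            obj.scalers = {r: shared for r in obj.roles}
        else:
            obj.scalers = {
                r: enc.FeatureScaler.from_dict(state["scalers"][r.value]) for r in obj.roles
            }
        obj.params = {
            k: Tensor(np.asarray(v), requires_grad=True) for k, v in state["params"].items()
        }
        obj.fitted = bool(state["fitted"])
        return obj


def avib_loss(model: AVIB, records, beta: float, rng) -> dict:
    """Bottleneck objective for a classification model: mean Bernoulli NLL on
    one reparameterized sample + beta * mean KL to the prior."""
    if model.config.task != "classification":
        raise ValueError("avib_loss applies to classification models")
    total, nll, kl = model.loss_graph(records, beta, rng)
    return {"total": total.item(), "nll": nll.item(), "kl": kl.item()}


def avib_mse_loss(model: AVIB, records, beta: float, rng) -> dict:
    """Regression variant: the log-likelihood term is replaced by MSE."""
    if model.config.task != "regression":
        raise ValueError("avib_mse_loss applies to regression models")
    total, mse, kl = model.loss_graph(records, beta, rng)
    return {"total": total.item(), "mse": mse.item(), "kl": kl.item()}


class AVIBResults:
    """Fit results: the trained model, the loss history, and diagnostics."""

    def __init__(self, model: AVIB, loss_history: list[dict], n_restarts: int = 0,
                 validation_risk: float | None = None):
        self.model = model
        self.loss_history = loss_history
        self.n_restarts = n_restarts
        self.validation_risk = validation_risk

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]["total"]

    @property
    def final_kl(self) -> float:
        return self.loss_history[-1]["kl"]

    def predict(self, records, mode: str = "mean"):
        return self.model.predict(records, mode=mode)

    def latent_means(self, records) -> np.ndarray:
        return self.model.latent_means(records)

    def summary(self) -> str:
        cfg = self.model.config
        n_params = sum(t.value.size for t in self.model.params.values())
        lines = [
            "Attentive Variational Information Bottleneck — fit summary",
            "=" * 60,
            f"task            {cfg.task}",
            f"aggregator      {cfg.aggregator}",
            f"roles           {', '.join(r.value for r in self.model.roles)}",
            f"latent width    d_Z = {cfg.d_z}   heads = {cfg.heads}",
            f"beta            {cfg.beta}",
            f"records         {len(self.model.records)}",
            f"parameters      {n_params}",
            f"epochs run      {len(self.loss_history)}",
            f"restarts        {self.n_restarts}",
            f"final objective {self.final_loss:.6f}",
            f"final NLL term  {self.loss_history[-1]['nll']:.6f}",
            f"final KL term   {self.final_kl:.6f}",
            "=" * 60,
        ]
        return "\n".join(lines)

    def save(self, path: str) -> None:
        state = self.model.state_dict()
        state["loss_history"] = self.loss_history
        state["n_restarts"] = self.n_restarts
        with open(path, "w") as fh:
            json.dump(state, fh)

    @classmethod
    def load(cls, path: str) -> "AVIBResults":
        with open(path) as fh:
            state = json.load(fh)
        history = state.pop("loss_history", [])
        n_restarts = state.pop("n_restarts", 0)
        return cls(AVIB.from_state_dict(state), history, n_restarts=n_restarts)
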