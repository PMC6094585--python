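"""Denoising autoencoder for outlier detection over phrase embeddings.

After retrofitting, a DAE is trained layer-wise on the retrofitted phrase
embeddings of paraphrase pairs.  For a pair ``(x, y)`` the corrupted input
``x~`` (a fixed number ``round(v*d)`` of components forced to zero) is
encoded ``h = relu(W x~ + b)`` and decoded ``z = sigmoid(W' h + b')``; the
reconstruction loss is the sum of the binary cross-entropies of ``z``
against *both* the clean input and its paraphrase:

    L(x, z) + L(y, z)
      = -sum_k [x_k log z_k + (1-x_k) log(1-z_k)]
        -sum_k [y_k log z_k + (1-y_k) log(1-z_k)]

so the hidden code is pushed toward what paraphrases share.  At matching
time the cosine distance between two terms' (uncorrupted) hidden codes is
the outlier score.

The cross-entropy needs targets in [0, 1]; raw embeddings are mapped
there with an invertible per-dimension min-max scaler fitted on the
training embeddings.  The encoder consumes the *standardized* image of
the embedding (zero mean, unit variance per dimension, fitted on the
training corpus) while the [0,1]-scaled embedding is the reconstruction
target: [0,1] inputs share a large positive common component that
dominates every hidden code and collapses the code cosine toward zero
for all pairs, hiding exactly the local distinctions the outlier score
needs.  Zeroing a standardized component resets it to the corpus mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .embeddings import cosine_distance

log = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# scaling

@dataclass
class ScalingRecord:
    """Per-dimension (min, max, mean, sd) of the fitting corpus; constant
    dimensions (max == min) map to 0.5 scaled / 0.0 standardized."""

    lo: np.ndarray
    hi: np.ndarray
    mu: np.ndarray | None = None
    sd: np.ndarray | None = None


def fit_scaler(embeddings: Sequence[np.ndarray]) -> ScalingRecord:
    if len(embeddings) == 0:
        raise ValueError("cannot fit a scaler on an empty set")
    X = np.asarray(embeddings, dtype=np.float64)
    rec = ScalingRecord(X.min(axis=0), X.max(axis=0), X.mean(axis=0), X.std(axis=0))
    n_const = int(np.sum(rec.hi == rec.lo))
    if n_const:
        log.info("scaler: %d constant dimension(s) mapped to 0.5", n_const)
    return rec


def apply_scaler(embedding: np.ndarray, record: ScalingRecord) -> np.ndarray:
    """Min-max map onto [0,1]; out-of-range values are clipped."""
    span = record.hi - record.lo
    out = np.full_like(np.asarray(embedding, dtype=np.float64), 0.5)
    ok = span > 0
    out[ok] = np.clip((embedding[ok] - record.lo[ok]) / span[ok], 0.0, 1.0)
    return out


def standardize(embedding: np.ndarray, record: ScalingRecord) -> np.ndarray:
    """Zero-mean unit-variance encoder input; constant dimensions map to 0."""
    if record.mu is None or record.sd is None:
        raise ValueError("scaling record lacks standardization moments")
    out = np.zeros_like(np.asarray(embedding, dtype=np.float64))
    ok = record.sd > 0
    out[ok] = (embedding[ok] - record.mu[ok]) / record.sd[ok]
    return out


def invert_scaler(scaled: np.ndarray, record: ScalingRecord) -> np.ndarray:
    span = record.hi - record.lo
    out = np.where(span > 0, record.lo + scaled * span, record.lo)
    return out


# ---------------------------------------------------------------------------
# model

@dataclass
class DAEConfig:
    hidden_dim: int = 32
    corruption: float = 0.4  # fraction v of components forced to zero
    epochs: int = 15
    rho: float = 0.95        # Adadelta decay
    eps: float = 1e-8        # Adadelta epsilon
    seed: int = 0
    #: also train on each pair reversed (paraphrase as input, term as target)
    both_orientations: bool = True


@dataclass
class DAEParams:
    W: np.ndarray        # hidden_dim x d
    b: np.ndarray        # hidden_dim
    W_prime: np.ndarray  # d x hidden_dim
    b_prime: np.ndarray  # d
    scaler: ScalingRecord | None = None
    config: DAEConfig = field(default_factory=DAEConfig)

    @property
    def hidden_dim(self) -> int:
        return self.W.shape[0]

    @property
    def dim(self) -> int:
        return self.W.shape[1]

    def save(self, path: str | Path) -> None:
        np.savez(
            path, W=self.W, b=self.b, W_prime=self.W_prime, b_prime=self.b_prime,
            scaler_lo=self.scaler.lo if self.scaler else np.array([]),
            scaler_hi=self.scaler.hi if self.scaler else np.array([]),
            scaler_mu=self.scaler.mu if self.scaler is not None and self.scaler.mu is not None else np.array([]),
            scaler_sd=self.scaler.sd if self.scaler is not None and self.scaler.sd is not None else np.array([]),
            corruption=self.config.corruption,
        )

    @classmethod
    def load(cls, path: str | Path) -> "DAEParams":
        d = np.load(path)
        scaler = None
        if d["scaler_lo"].size:
            mu = d["scaler_mu"] if "scaler_mu" in d and d["scaler_mu"].size else None
            sd = d["scaler_sd"] if "scaler_sd" in d and d["scaler_sd"].size else None
            scaler = ScalingRecord(d["scaler_lo"], d["scaler_hi"], mu, sd)
        cfg = DAEConfig(hidden_dim=int(d["W"].shape[0]), corruption=float(d["corruption"]))
        return cls(d["W"], d["b"], d["W_prime"], d["b_prime"], scaler, cfg)


def init_params(dim: int, config: DAEConfig, rng: np.random.Generator) -> DAEParams:
    """Glorot-style uniform weights; a small positive encoder bias keeps
    rectifier units initially alive without dominating the signal."""
    dh = config.hidden_dim
    lim1 = np.sqrt(6.0 / (dim + dh))
    W = rng.uniform(-lim1, lim1, size=(dh, dim))
    W_prime = rng.uniform(-lim1, lim1, size=(dim, dh))
    return DAEParams(W, np.full(dh, 0.5), W_prime, np.zeros(dim), None, config)


def corrupt(x: np.ndarray, v: float, rng: np.random.Generator) -> np.ndarray:
    """Force exactly ``round(v*d)`` randomly chosen components to zero,
    leaving the rest untouched."""
    if not 0.0 < v < 1.0:
        raise ValueError(f"corruption fraction must be in (0,1), got {v}")
    d = x.shape[-1]
    k = int(round(v * d))
    out = np.array(x, dtype=np.float64, copy=True)
    if k:
        idx = rng.choice(d, size=k, replace=False)
        out[idx] = 0.0
    return out


def encode(x_tilde: np.ndarray, params: DAEParams) -> np.ndarray:
    """``h = relu(W x~ + b)``."""
    if x_tilde.shape[-1] != params.dim:
        raise ValueError(f"input dim {x_tilde.shape[-1]} != model dim {params.dim}")
    return np.maximum(params.W @ x_tilde + params.b, 0.0)


def decode(h: np.ndarray, params: DAEParams) -> np.ndarray:
    """``z = sigmoid(W' h + b')``."""
    if h.shape[-1] != params.hidden_dim:
        raise ValueError(f"code dim {h.shape[-1]} != hidden dim {params.hidden_dim}")
    a = params.W_prime @ h + params.b_prime
    return 1.0 / (1.0 + np.exp(-a))


def reconstruction_loss(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """``L(x,z) + L(y,z)``: binary cross-entropy of the reconstruction
    against both the input and its paraphrase; z is epsilon-clamped."""
    zc = np.clip(z, _EPS, 1.0 - _EPS)
    lx = -float(np.sum(x * np.log(zc) + (1.0 - x) * np.log(1.0 - zc)))
    ly = -float(np.sum(y * np.log(zc) + (1.0 - y) * np.log(1.0 - zc)))
    return lx + ly


def train_dae(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    config: DAEConfig | None = None,
    dim: int | None = None,
) -> tuple[DAEParams, list[float]]:
    """Fit the DAE on (embedding, paraphrase-embedding) pairs with Adadelta.

    Pairs must come from the *retrofitted* table (layer-wise scheme: the
    DAE is trained only after retrofitting has finished).  The scaler is
    fitted on all vectors appearing in the pairs.  Returns the parameters
    and the per-epoch mean loss (entry 0 is the pre-training loss).
    """
    cfg = config or DAEConfig()
    if not pairs:
        raise ValueError("no training pairs")
    vecs = [v for pair in pairs for v in pair]
    d = dim or len(vecs[0])
    scaler = fit_scaler(vecs)

    samples: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for x, y in pairs:
        x, y = np.asarray(x, float), np.asarray(y, float)
        xs, ys = apply_scaler(x, scaler), apply_scaler(y, scaler)
        samples.append((standardize(x, scaler), xs, ys))
        if cfg.both_orientations and not np.array_equal(xs, ys):
            samples.append((standardize(y, scaler), ys, xs))

    rng = np.random.default_rng(cfg.seed)
    params = init_params(d, cfg, rng)
    params.scaler = scaler

    # Adadelta accumulators per parameter tensor
    acc_g = {n: np.zeros_like(getattr(params, n)) for n in ("W", "b", "W_prime", "b_prime")}
    acc_dx = {n: np.zeros_like(getattr(params, n)) for n in ("W", "b", "W_prime", "b_prime")}

    def epoch_mean_loss(with_corruption_rng: np.random.Generator) -> float:
        tot = 0.0
        for xin, xs, ys in samples:
            xt = corrupt(xin, cfg.corruption, with_corruption_rng)
            z = decode(encode(xt, params), params)
            tot += reconstruction_loss(xs, ys, z)
        return tot / len(samples)

    history = [epoch_mean_loss(np.random.default_rng(cfg.seed + 1))]
    order = np.arange(len(samples))
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        tot = 0.0
        for k in order:
            xin, xs, ys = samples[k]
            xt = corrupt(xin, cfg.corruption, rng)
            pre_h = params.W @ xt + params.b
            h = np.maximum(pre_h, 0.0)
            z = decode(h, params)
            tot += reconstruction_loss(xs, ys, z)

            # backprop: dL/d(pre-sigmoid) = (z - x) + (z - y)
            dz = 2.0 * z - xs - ys
            grads = {
                "W_prime": np.outer(dz, h),
                "b_prime": dz,
            }
            dh = params.W_prime.T @ dz
            dpre = dh * (pre_h > 0.0)
            grads["W"] = np.outer(dpre, xt)
            grads["b"] = dpre

            for n, g in grads.items():
                if not np.all(np.isfinite(g)):
                    raise FloatingPointError("NaN/inf gradient in DAE training")
                acc_g[n] = cfg.rho * acc_g[n] + (1 - cfg.rho) * g * g
                dx = -np.sqrt(acc_dx[n] + cfg.eps) / np.sqrt(acc_g[n] + cfg.eps) * g
                acc_dx[n] = cfg.rho * acc_dx[n] + (1 - cfg.rho) * dx * dx
                setattr(params, n, getattr(params, n) + dx)
        history.append(tot / len(samples))
        log.info("dae epoch %d/%d: mean loss %.6g", epoch + 1, cfg.epochs, history[-1])
    return params, history


def dae_distance(
    s_i: np.ndarray,
    s_j: np.ndarray,
    params: DAEParams,
    scaler: ScalingRecord | None = None,
) -> float:
    """Outlier score: cosine distance of the two hidden codes.

    Inputs are scaled but *not* corrupted (corruption is a training-only
    regulariser).  An all-zero hidden code has no direction; the pair is
    scored 2 (maximal outlier).
    """
    rec = scaler or params.scaler
    if rec is None:
        raise ValueError("no scaling record available")
    hi = encode(standardize(np.asarray(s_i, float), rec), params)
    hj = encode(standardize(np.asarray(s_j, float), rec), params)
    if not hi.any() or not hj.any():
        log.warning("all-zero DAE hidden code; scoring pair as maximal outlier")
        return 2.0
    return cosine_distance(hi, hj)
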