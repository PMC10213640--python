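"""Imbalance-aware splitting and outcome classifiers.

The 90-day outcome is heavily imbalanced (about one unfavorable outcome per
five favorable), so the dataset is built by under-sampling: the unfavorable
group is split 2:1 into training and validation, the favorable training
arm is capped at 1.5x the unfavorable training count (sampled without
replacement), and every remaining patient goes to validation.  Both counts
use floor rounding.

Two classifier families share one interface:

* ``recurrent`` — a single-layer GRU implemented in numpy (hidden size 32 by
  default) that consumes the standardized feature vector as an ordered
  sequence of fixed-length chunks, trained by Adam on class-weighted
  cross-entropy with hand-derived backpropagation-through-time gradients;
* ``logistic`` — a deterministic class-weighted logistic regression
  baseline (scikit-learn) used whenever reproducibility at the bit level
  matters more than model capacity.

Class weights default to inverse class frequency in the training set, so a
prior-only prediction is not a loss minimum on separable imbalanced data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError, InputError

__all__ = [
    "SplitSpec",
    "ModelConfig",
    "TrainedModel",
    "undersample_split",
    "train_classifier",
    "predict_proba",
]


@dataclass
class SplitSpec:
    """Under-sampling split: 2:1 unfavorable train:val, 1.5x favorable cap."""

    unfav_train_fraction: float = 2.0 / 3.0
    fav_to_unfav_train_ratio: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.unfav_train_fraction < 1.0:
            raise ConfigurationError("unfav_train_fraction must be in (0, 1)")
        if self.fav_to_unfav_train_ratio <= 0:
            raise ConfigurationError("fav_to_unfav_train_ratio must be > 0")


def undersample_split(cohort: pd.DataFrame, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Partition patient ids into (train, validation).

    ``floor(unfav_train_fraction * n_unfav)`` unfavorable patients and
    ``floor(ratio * that)`` favorable patients are sampled without
    replacement into training; all remaining patients form the validation
    set.  Train and validation are disjoint and their union is the cohort.
    """
    rng = np.random.default_rng(spec.seed)
    ids = cohort["id"].to_numpy()
    unfav = cohort["mrs_90d"].to_numpy() > 2
    unfav_ids = ids[unfav]
    fav_ids = ids[~unfav]
    if unfav_ids.size == 0 or fav_ids.size == 0:
        raise ConfigurationError("both outcome classes must be present")
    n_unfav_train = int(np.floor(spec.unfav_train_fraction * unfav_ids.size))
    n_fav_train = int(np.floor(spec.fav_to_unfav_train_ratio * n_unfav_train))
    if n_unfav_train < 1 or n_fav_train < 1:
        raise ConfigurationError("cohort too small for the requested split ratios")
    if n_fav_train > fav_ids.size:
        raise ConfigurationError(
            f"need {n_fav_train} favorable training patients but only {fav_ids.size} available"
        )
    unfav_train = rng.choice(unfav_ids, size=n_unfav_train, replace=False)
    fav_train = rng.choice(fav_ids, size=n_fav_train, replace=False)
    train = np.concatenate([unfav_train, fav_train])
    train_set = set(train.tolist())
    val = np.array([i for i in ids if i not in train_set], dtype=ids.dtype)
    return train, val


@dataclass
class ModelConfig:
    """Classifier hyperparameters (defaults: Adam lr 1e-4, batch 10)."""

    model_kind: str = "logistic"
    hidden_size: int = 32
    chunk_len: int = 3  # how the feature vector is cut into sequence steps
    learning_rate: float = 1e-4
    batch_size: int = 10
    class_weights: tuple[float, float] | None = None  # None -> inverse frequency
    epochs: int = 300
    patience: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("logistic", "recurrent"):
            raise ConfigurationError(f"unknown model_kind {self.model_kind!r}")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.hidden_size < 1 or self.chunk_len < 1:
            raise ConfigurationError("hidden_size and chunk_len must be >= 1")


def _class_weights(y: np.ndarray, config: ModelConfig) -> np.ndarray:
    if config.class_weights is not None:
        return np.asarray(config.class_weights, dtype=float)
    n = y.size
    n1 = int(y.sum())
    n0 = n - n1
    return np.array([n / (2.0 * n0), n / (2.0 * n1)])


class _GRUParams:
    """GRU weights: update (z), reset (r) and candidate (n) gates plus a
    linear read-out on the final hidden state."""

    KEYS = ("Wz", "Uz", "bz", "Wr", "Ur", "br", "Wn", "Un", "bn", "wo", "bo")

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator):
        s_in = 1.0 / np.sqrt(d_in)
        s_h = 1.0 / np.sqrt(d_h)
        for g in ("z", "r", "n"):
            setattr(self, f"W{g}", rng.uniform(-s_in, s_in, (d_in, d_h)))
            setattr(self, f"U{g}", rng.uniform(-s_h, s_h, (d_h, d_h)))
            setattr(self, f"b{g}", np.zeros(d_h))
        self.wo = rng.uniform(-s_h, s_h, d_h)
        self.bo = 0.0

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(getattr(self, k), dtype=float) for k in self.KEYS}

    @classmethod
    def from_dict(cls, d: dict) -> "_GRUParams":
        obj = cls.__new__(cls)
        for k in cls.KEYS:
            v = np.asarray(d[k], dtype=float)
            setattr(obj, k, float(v) if k == "bo" else v)
        return obj


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, None, 60))),
                    np.exp(np.clip(x, -60, None)) / (1.0 + np.exp(np.clip(x, -60, None))))


def _to_sequence(X: np.ndarray, chunk_len: int) -> np.ndarray:
    """(B, p) -> (T, B, chunk_len), zero-padding the last chunk."""
    b, p = X.shape
    t = -(-p // chunk_len)
    pad = np.zeros((b, t * chunk_len - p))
    return np.concatenate([X, pad], axis=1).reshape(b, t, chunk_len).transpose(1, 0, 2)


def _gru_forward(params: _GRUParams, seq: np.ndarray, cache: bool = False):
    t_len, b, _ = seq.shape
    h = np.zeros((b, params.bz.size))
    steps = []
    for t in range(t_len):
        x = seq[t]
        z = _sigmoid(x @ params.Wz + h @ params.Uz + params.bz)
        r = _sigmoid(x @ params.Wr + h @ params.Ur + params.br)
        hU = h @ params.Un
        n = np.tanh(x @ params.Wn + r * hU + params.bn)
        h_new = (1.0 - z) * n + z * h
        if cache:
            steps.append((x, h, z, r, n, hU))
        h = h_new
    logit = h @ params.wo + params.bo
    return (logit, h, steps) if cache else (logit, h)


def _gru_backward(params: _GRUParams, steps, h_last, dlogit) -> dict[str, np.ndarray]:
    g = {k: np.zeros_like(np.asarray(getattr(params, k), dtype=float)) for k in _GRUParams.KEYS}
    g["wo"] = h_last.T @ dlogit
    g["bo"] = np.array(dlogit.sum())
    dh = np.outer(dlogit, params.wo)
    for x, h_prev, z, r, n, hU in reversed(steps):
        dn = dh * (1.0 - z)
        dz = dh * (h_prev - n)
        dh_prev = dh * z
        da_n = dn * (1.0 - n**2)
        g["Wn"] += x.T @ da_n
        g["bn"] += da_n.sum(axis=0)
        dr = da_n * hU
        g["Un"] += h_prev.T @ (da_n * r)
        dh_prev += (da_n * r) @ params.Un.T
        da_r = dr * r * (1.0 - r)
        g["Wr"] += x.T @ da_r
        g["Ur"] += h_prev.T @ da_r
        g["br"] += da_r.sum(axis=0)
        dh_prev += da_r @ params.Ur.T
        da_z = dz * z * (1.0 - z)
        g["Wz"] += x.T @ da_z
        g["Uz"] += h_prev.T @ da_z
        g["bz"] += da_z.sum(axis=0)
        dh_prev += da_z @ params.Uz.T
        dh = dh_prev
    return g


def _weighted_ce(logit: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean class-weighted sigmoid cross-entropy and its logit gradient."""
    p = _sigmoid(logit)
    eps = 1e-12
    wi = w[y.astype(int)]
    loss = float(np.mean(-wi * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))))
    dlogit = wi * (p - y) / y.size
    return loss, dlogit


@dataclass
class TrainedModel:
    """A fitted classifier with its feature ordering and scaling frozen in."""

    kind: str
    feature_names: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray
    config: ModelConfig
    coef: np.ndarray | None = None  # logistic
    intercept: float = 0.0
    gru: _GRUParams | None = field(default=None, repr=False)
    loss_trace: tuple[float, ...] = ()

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise InputError(
                f"expected {len(self.feature_names)} features, got shape {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise InputError("non-finite feature values")
        return (X - self.mean) / self.scale

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(unfavorable outcome) per row, in [0, 1]."""
        Z = self._standardize(X)
        if self.kind == "logistic":
            return _sigmoid(Z @ self.coef + self.intercept)
        logit, _ = _gru_forward(self.gru, _to_sequence(Z, self.config.chunk_len))
        return _sigmoid(logit)

    def save(self, path: str | Path) -> None:
        arrays = {"mean": self.mean, "scale": self.scale, "loss_trace": np.asarray(self.loss_trace)}
        if self.coef is not None:
            arrays["coef"] = self.coef
        if self.gru is not None:
            arrays.update({f"gru_{k}": v for k, v in self.gru.as_dict().items()})
        meta = {
            "kind": self.kind,
            "feature_names": list(self.feature_names),
            "intercept": self.intercept,
            "config": {
                k: getattr(self.config, k)
                for k in (
                    "model_kind", "hidden_size", "chunk_len", "learning_rate",
                    "batch_size", "epochs", "patience", "seed",
                )
            },
        }
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["_meta"]).decode())
            cfg = ModelConfig(**meta["config"])
            gru = None
            if any(k.startswith("gru_") for k in z.files):
                gru = _GRUParams.from_dict({k[4:]: z[k] for k in z.files if k.startswith("gru_")})
            return cls(
                kind=meta["kind"],
                feature_names=tuple(meta["feature_names"]),
                mean=z["mean"],
                scale=z["scale"],
                config=cfg,
                coef=z["coef"] if "coef" in z.files else None,
                intercept=float(meta["intercept"]),
                gru=gru,
                loss_trace=tuple(float(v) for v in z["loss_trace"]),
            )


def _adam_step(params, grads, m, v, t, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    for k in _GRUParams.KEYS:
        gk = grads[k]
        m[k] = beta1 * m[k] + (1 - beta1) * gk
        v[k] = beta2 * v[k] + (1 - beta2) * gk**2
        mh = m[k] / (1 - beta1**t)
        vh = v[k] / (1 - beta2**t)
        cur = np.asarray(getattr(params, k), dtype=float)
        upd = cur - lr * mh / (np.sqrt(vh) + eps)
        setattr(params, k, float(upd) if k == "bo" else upd)


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig | None = None,
    feature_names: tuple[str, ...] | None = None,
) -> TrainedModel:
    """Fit a classifier on a (samples x features) block with binary labels.

    Features are standardized internally (the scaling is stored with the
    model).  With ``model_kind="recurrent"``, the GRU is trained by Adam on
    class-weighted cross-entropy with early stopping on a training-loss
    plateau; with ``"logistic"``, a deterministic class-weighted logistic
    regression is fit.
    """
    config = config or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise InputError("X must be 2D with one row per label")
    if not np.all(np.isfinite(X)):
        raise InputError("non-finite feature values")
    if int(y.sum()) < 2 or int((1 - y).sum()) < 2:
        raise ConfigurationError("need at least 2 samples per class")
    if feature_names is None:
        feature_names = tuple(f"x{j}" for j in range(X.shape[1]))

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Z = (X - mu) / sd
    w = _class_weights(y, config)

    if config.model_kind == "logistic":
        clf = LogisticRegression(
            class_weight={0: w[0], 1: w[1]}, max_iter=5000, solver="lbfgs"
        )
        clf.fit(Z, y)
        p = clf.predict_proba(Z)[:, 1]
        eps = 1e-12
        wi = w[y]
        loss = float(np.mean(-wi * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))))
        return TrainedModel(
            kind="logistic",
            feature_names=tuple(feature_names),
            mean=mu,
            scale=sd,
            config=config,
            coef=clf.coef_.ravel(),
            intercept=float(clf.intercept_[0]),
            loss_trace=(loss,),
        )

    rng = np.random.default_rng(config.seed)
    seq_all = _to_sequence(Z, config.chunk_len)
    params = _GRUParams(config.chunk_len, config.hidden_size, rng)
    m = {k: np.zeros_like(np.asarray(getattr(params, k), dtype=float)) for k in _GRUParams.KEYS}
    v = {k: np.zeros_like(np.asarray(getattr(params, k), dtype=float)) for k in _GRUParams.KEYS}
    t_adam = 0
    n = y.size
    trace = []
    best = np.inf
    since_best = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            seq = seq_all[:, idx, :]
            logit, h_last, steps = _gru_forward(params, seq, cache=True)
            _, dlogit = _weighted_ce(logit, y[idx], w)
            grads = _gru_backward(params, steps, h_last, dlogit)
            t_adam += 1
            _adam_step(params, grads, m, v, t_adam, config.learning_rate)
        logit, _ = _gru_forward(params, seq_all)
        loss, _ = _weighted_ce(logit, y, w)
        trace.append(loss)
        if loss < best - 1e-5:
            best = loss
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    return TrainedModel(
        kind="recurrent",
        feature_names=tuple(feature_names),
        mean=mu,
        scale=sd,
        config=config,
        gru=params,
        loss_trace=tuple(trace),
    )


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`TrainedModel.predict_proba`."""
    return model.predict_proba(X)
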