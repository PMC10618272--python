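"""Latent-score preference model: a shared-weight two-legged network.

Each molecule m gets a latent desirability score s(m) from a feed-forward
network (one parameter set used by both legs).  Pairwise choices are modeled
Bradley-Terry style: the probability that m_i is preferred over m_j is

    p(m_i > m_j) = sigmoid(s_j - s_i),

so LOWER scores mean MORE preferred — the user-facing convention throughout
this package.  Training minimizes binary cross-entropy between p and the
observed choices plus a small score regularizer lambda * ||s||^2 that pins
the score scale to the origin (the BCE term alone is translation-invariant).
Optimization uses Adam at learning rate 3e-4.

Implemented directly in NumPy: the architecture (forward, backprop, Adam,
inverted dropout) is small and self-contained, and owning it lets Monte
Carlo dropout at inference share one mask across both legs (see the
acquisition module).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .curation import FilterConfig, ParseError, make_record
from .errors import ConvergenceWarning, DimensionError, LabelError
from .featurize import Featurizer, FeaturizerSpec

logger = logging.getLogger(__name__)

SCORE_BOUND_DEFAULT = 9.0  # empirical |s| boundary under the default regularizer


@dataclass
class TrainConfig:
    """Optimization hyperparameters for the score model."""

    learning_rate: float = 3e-4
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    n_folds: int = 5
    patience: int = 10          # early stop after this many non-improving epochs
    min_delta: float = 1e-5     # improvement below this counts as plateau
    hidden_sizes: tuple[int, ...] = (256, 128)
    dropout_rate: float = 0.2
    reg_lambda: float = 1e-6

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return np.where(np.asarray(x) >= 0,
                    1.0 / (1.0 + np.exp(-np.asarray(x))),
                    np.exp(np.asarray(x)) / (1.0 + np.exp(np.asarray(x))))


class ScoreModel:
    """Feed-forward scorer s: features -> R with shared weights for both legs.

    Hidden layers use ReLU with (inverted) dropout after each; the linear
    head is zero-initialized so an untrained model scores every molecule 0,
    making the pre-training pairwise loss exactly ln 2 on balanced labels.
    """

    def __init__(self, input_dim: int,
                 hidden_sizes: Sequence[int] = (256, 128),
                 dropout_rate: float = 0.2,
                 reg_lambda: float = 1e-6,
                 seed: int = 0):
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.input_dim = int(input_dim)
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.dropout_rate = float(dropout_rate)
        self.reg_lambda = float(reg_lambda)
        rng = np.random.default_rng(seed)
        dims = [self.input_dim, *self.hidden_sizes, 1]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for i in range(len(dims) - 1):
            fan_in = dims[i]
            if i == len(dims) - 2:  # zero-init head: untrained model is uninformed
                w = np.zeros((dims[i], dims[i + 1]))
            else:
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(dims[i], dims[i + 1]))
            self.W.append(w)
            self.b.append(np.zeros(dims[i + 1]))

    # -- forward ----------------------------------------------------------
    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.input_dim:
            raise DimensionError(
                f"feature dim {X.shape[1]} != model input {self.input_dim}")
        return X

    def sample_masks(self, rng: np.random.Generator,
                     n_rows: int | None = None,
                     rate: float | None = None) -> list[np.ndarray]:
        """Inverted-dropout masks for each hidden layer.

        With ``n_rows=None`` a single mask per layer is produced, to be
        broadcast over every row of the batch (the shared-mask mode used for
        Monte Carlo dropout over both legs); otherwise per-row masks.
        """
        rate = self.dropout_rate if rate is None else float(rate)
        keep = 1.0 - rate
        masks = []
        for h in self.hidden_sizes:
            shape = (h,) if n_rows is None else (n_rows, h)
            if rate == 0.0:
                masks.append(np.ones(shape))
            else:
                masks.append((rng.random(shape) < keep) / keep)
        return masks

    def forward(self, X: np.ndarray,
                masks: Sequence[np.ndarray] | None = None,
                cache: dict | None = None) -> np.ndarray:
        """Scores for a feature matrix; optional dropout masks per hidden layer."""
        a = self._check(X)
        if cache is not None:
            cache["a"] = [a]
            cache["z"] = []
        for layer, (W, b) in enumerate(zip(self.W[:-1], self.b[:-1])):
            z = a @ W + b
            h = np.maximum(z, 0.0)
            a = h * masks[layer] if masks is not None else h
            if cache is not None:
                cache["z"].append(z)
                cache["a"].append(a)
        s = (a @ self.W[-1] + self.b[-1]).ravel()
        return s

    def score(self, X: np.ndarray) -> np.ndarray:
        """Deterministic scores (dropout off)."""
        return self.forward(X)

    # -- backward ---------------------------------------------------------
    def _backward(self, cache: dict, masks: Sequence[np.ndarray] | None,
                  ds: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        ds = ds.reshape(-1, 1)
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        gW[-1] = cache["a"][-1].T @ ds
        gb[-1] = ds.sum(axis=0)
        da = ds @ self.W[-1].T
        for layer in range(len(self.hidden_sizes) - 1, -1, -1):
            if masks is not None:
                da = da * masks[layer]
            dz = da * (cache["z"][layer] > 0)
            gW[layer] = cache["a"][layer].T @ dz
            gb[layer] = dz.sum(axis=0)
            if layer > 0:
                da = dz @ self.W[layer].T
        return gW, gb


def latent_score(model: ScoreModel, features: np.ndarray,
                 dropout_active: bool = False,
                 seed: int | None = None) -> np.ndarray:
    """Score one or more feature vectors; optionally one stochastic MC pass."""
    if not dropout_active:
        return model.score(features)
    rng = np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    masks = model.sample_masks(rng, n_rows=X.shape[0])
    return model.forward(X, masks=masks)


def pair_probability(model: ScoreModel, feats_i: np.ndarray,
                     feats_j: np.ndarray) -> np.ndarray:
    """p(m_i preferred over m_j) = sigmoid(s_j - s_i); lower score wins."""
    s_i = model.score(feats_i)
    s_j = model.score(feats_j)
    return sigmoid(s_j - s_i)


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=np.float64).ravel()
    if y.size == 0:
        raise LabelError("empty label vector")
    if not np.isin(y, (0.0, 1.0)).all():
        raise LabelError("labels must be in {0, 1}")
    return y


def pair_loss(model: ScoreModel, Xi: np.ndarray, Xj: np.ndarray,
              labels, reg_lambda: float | None = None) -> float:
    """Mean BCE over the batch plus lambda * squared norm of the batch scores."""
    y = _check_labels(labels)
    lam = model.reg_lambda if reg_lambda is None else float(reg_lambda)
    s_i = model.score(Xi)
    s_j = model.score(Xj)
    delta = s_j - s_i
    # numerically stable BCE in terms of the logit delta
    bce = np.mean(np.logaddexp(0.0, -delta) + (1.0 - y) * delta)
    reg = lam * (np.sum(s_i ** 2) + np.sum(s_j ** 2))
    return float(bce + reg)


def train(Xi: np.ndarray, Xj: np.ndarray, labels,
          cfg: TrainConfig | None = None,
          model: ScoreModel | None = None) -> ScoreModel:
    """Fit the score model on labelled pairs with minibatch Adam.

    ``Xi``/``Xj`` are the normalized feature matrices of the first/second
    member of each pair and ``labels[t] = 1`` means the first member was
    chosen.  Reproducible for a fixed config seed.  Emits a
    ConvergenceWarning (non-fatal) if the final epoch loss exceeds the first.
    """
    cfg = cfg or TrainConfig()
    y = _check_labels(labels)
    Xi = np.atleast_2d(np.asarray(Xi, dtype=np.float64))
    Xj = np.atleast_2d(np.asarray(Xj, dtype=np.float64))
    if Xi.shape != Xj.shape or Xi.shape[0] != y.size:
        raise DimensionError("Xi, Xj and labels must agree in length")
    n = y.size
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = ScoreModel(Xi.shape[1], cfg.hidden_sizes, cfg.dropout_rate,
                           cfg.reg_lambda, seed=cfg.seed)

    # Adam state
    mW = [np.zeros_like(w) for w in model.W]
    vW = [np.zeros_like(w) for w in model.W]
    mb = [np.zeros_like(b) for b in model.b]
    vb = [np.zeros_like(b) for b in model.b]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    first_loss = best_loss = None
    stall = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            B = idx.size
            X = np.vstack([Xi[idx], Xj[idx]])
            masks = (model.sample_masks(rng, n_rows=2 * B)
                     if model.dropout_rate > 0 else None)
            cache: dict = {}
            s = model.forward(X, masks=masks, cache=cache)
            s_i, s_j = s[:B], s[B:]
            delta = s_j - s_i
            p = sigmoid(delta)
            yb = y[idx]
            bce = np.mean(np.logaddexp(0.0, -delta) + (1.0 - yb) * delta)
            reg = model.reg_lambda * np.sum(s ** 2)
            epoch_loss += (bce + reg) * B
            g = (p - yb) / B           # dL/d delta
            ds = np.concatenate([-g, g]) + 2.0 * model.reg_lambda * s
            gW, gb = model._backward(cache, masks, ds)
            step += 1
            for k in range(len(model.W)):
                for grad, param, m_s, v_s in ((gW[k], model.W[k], mW, vW),
                                              (gb[k], model.b[k], mb, vb)):
                    m_s[k] = beta1 * m_s[k] + (1 - beta1) * grad
                    v_s[k] = beta2 * v_s[k] + (1 - beta2) * grad ** 2
                    mhat = m_s[k] / (1 - beta1 ** step)
                    vhat = v_s[k] / (1 - beta2 ** step)
                    param -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        epoch_loss /= n
        if first_loss is None:
            first_loss = epoch_loss
        if best_loss is None or epoch_loss < best_loss - cfg.min_delta:
            best_loss = epoch_loss
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                logger.info("early stop at epoch %d (loss %.5f)", epoch, epoch_loss)
                break
    if first_loss is not None and epoch_loss > first_loss:
        warnings.warn(f"final loss {epoch_loss:.4f} > initial {first_loss:.4f}",
                      ConvergenceWarning)
    return model


def cross_validate(Xi: np.ndarray, Xj: np.ndarray, labels,
                   cfg: TrainConfig | None = None) -> dict:
    """Randomized k-fold cross-validation over pairs (not molecules).

    Returns per-fold held-out AUROC plus mean and standard deviation.  A
    fold whose held-out labels are single-class raises ValueError.
    """
    cfg = cfg or TrainConfig()
    y = _check_labels(labels)
    if y.size < cfg.n_folds:
        raise ValueError("fewer pairs than folds")
    Xi = np.atleast_2d(np.asarray(Xi, dtype=np.float64))
    Xj = np.atleast_2d(np.asarray(Xj, dtype=np.float64))
    kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    aurocs = []
    for tr, te in kf.split(Xi):
        if len(np.unique(y[te])) < 2:
            raise ValueError("held-out fold has a single class")
        model = train(Xi[tr], Xj[tr], y[tr], cfg)
        p = pair_probability(model, Xi[te], Xj[te])
        aurocs.append(float(roc_auc_score(y[te], p)))
    return {"fold_auroc": aurocs,
            "mean": float(np.mean(aurocs)),
            "sd": float(np.std(aurocs, ddof=1))}


def clamp_score(s, bound: float = SCORE_BOUND_DEFAULT):
    """Clamp scores to [-bound, +bound].

    Under the default regularizer the empirical score distribution stays
    within |s| of about 9; downstream consumers (e.g. generative-model
    scoring callbacks) should clamp to that boundary to avoid rewarding
    extrapolation far outside the training distribution.
    """
    return np.clip(s, -bound, bound)


def score_library(model: ScoreModel, featurizer: Featurizer,
                  smiles_list: Sequence[str],
                  filter_cfg: FilterConfig | None = None,
                  apply_filters: bool = True,
                  clamp: float | None = None,
                  ids: Sequence[str] | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a molecule library, enforcing the training applicability domain.

    By default the same pool filters used for training are applied and
    failing molecules are reported in the dropped table with their reasons
    (pass ``apply_filters=False`` to score everything).  Returns
    ``(scores, dropped)`` DataFrames.
    """
    filter_cfg = filter_cfg or FilterConfig()
    if ids is None:
        ids = [f"lib{i:06d}" for i in range(len(smiles_list))]
    kept_rows, dropped_rows, kept_smiles = [], [], []
    for mol_id, smi in zip(ids, smiles_list):
        try:
            rec = make_record(mol_id, smi, filter_cfg)
        except ParseError as exc:
            dropped_rows.append({"id": mol_id, "smiles": smi,
                                 "reasons": f"parse_error:{exc}"})
            continue
        if apply_filters and not rec.pool_pass:
            dropped_rows.append({"id": mol_id, "smiles": smi,
                                 "reasons": ";".join(rec.reasons)})
            continue
        kept_rows.append({"id": mol_id, "smiles": rec.smiles_canonical})
        kept_smiles.append(rec.smiles_canonical)
    scores_df = pd.DataFrame(kept_rows, columns=["id", "smiles"])
    if kept_smiles:
        s = model.score(featurizer.transform(kept_smiles))
        if clamp is not None:
            s = clamp_score(s, clamp)
        scores_df["score"] = s
    else:
        scores_df["score"] = pd.Series(dtype=float)
    dropped_df = pd.DataFrame(dropped_rows, columns=["id", "smiles", "reasons"])
    return scores_df, dropped_df


# -- checkpoints ----------------------------------------------------------

def save_checkpoint(path: str | Path, model: ScoreModel,
                    featurizer: Featurizer | FeaturizerSpec | None = None,
                    extra: dict | None = None) -> None:
    """Bundle model parameters and featurizer spec into one .npz file."""
    spec = featurizer.spec if isinstance(featurizer, Featurizer) else featurizer
    meta = {
        "input_dim": model.input_dim,
        "hidden_sizes": list(model.hidden_sizes),
        "dropout_rate": model.dropout_rate,
        "reg_lambda": model.reg_lambda,
        "featurizer": None if spec is None else spec.to_json(),
        "extra": extra or {},
    }
    arrays = {f"W{k}": w for k, w in enumerate(model.W)}
    arrays.update({f"b{k}": b for k, b in enumerate(model.b)})
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str | Path) -> tuple[ScoreModel, Featurizer | None]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        model = ScoreModel(meta["input_dim"], meta["hidden_sizes"],
                           meta["dropout_rate"], meta["reg_lambda"])
        model.W = [data[f"W{k}"] for k in range(len(model.W))]
        model.b = [data[f"b{k}"] for k in range(len(model.b))]
    featurizer = None
    if meta["featurizer"] is not None:
        featurizer = Featurizer(FeaturizerSpec.from_json(meta["featurizer"]))
    return model, featurizer
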