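"""Uncertainty-driven batch acquisition with Monte Carlo dropout.

Candidate pairs are ranked by the variance of their predicted score
difference delta = s_j - s_i over T stochastic forward passes with dropout
active (default rate 0.2, T = 100).  Within each acquisition batch at most
one comparison is allowed between any two clusters, keeping the batch
spread over chemical space.

Per forward pass ONE dropout mask is sampled and applied identically to
both legs (the legs share weights, so they share the mask): the predicted
difference of an identical pair is then exactly zero on every pass and the
variance isolates disagreement about the *difference* rather than leg
noise.  An independent-mask mode is available for comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .curation import FilterConfig
from .pairgen import pair_hardness_flag
from .ranker import ScoreModel

logger = logging.getLogger(__name__)


@dataclass
class UncertaintyEstimate:
    """MC-dropout variance of the predicted score difference for one pair."""

    pair_id: str
    variance: float
    n_samples: int = 100
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


def mc_dropout_delta_variance(model: ScoreModel,
                              feats_i: np.ndarray,
                              feats_j: np.ndarray,
                              T: int = 100,
                              rate: float = 0.2,
                              seed: int = 0,
                              shared_mask: bool = True) -> np.ndarray:
    """Sample variance of delta = s_j - s_i over T dropout forward passes.

    Vectorized over pairs: ``feats_i``/``feats_j`` may be matrices with one
    row per pair; returns one variance per pair.  With ``rate=0`` the network
    is deterministic and the variance is exactly zero.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    Xi = np.atleast_2d(np.asarray(feats_i, dtype=np.float64))
    Xj = np.atleast_2d(np.asarray(feats_j, dtype=np.float64))
    n = Xi.shape[0]
    rng = np.random.default_rng(seed)
    deltas = np.empty((T, n))
    for t in range(T):
        if shared_mask:
            masks = model.sample_masks(rng, n_rows=None, rate=rate)
            s_i = model.forward(Xi, masks=masks)
            s_j = model.forward(Xj, masks=masks)
        else:
            s_i = model.forward(Xi, masks=model.sample_masks(rng, n, rate=rate))
            s_j = model.forward(Xj, masks=model.sample_masks(rng, n, rate=rate))
        deltas[t] = s_j - s_i
    # center on the first pass before the variance: mathematically a no-op,
    # but it makes degenerate cases (rate 0, identical pairs) exactly zero
    deltas -= deltas[0]
    return deltas.var(axis=0, ddof=1)


def sample_candidate_pairs(pool: pd.DataFrame,
                           clusters: np.ndarray | Sequence[int],
                           n_candidates: int,
                           seed: int = 0,
                           cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Uniformly sample unlabelled candidate pairs from the pool.

    Pairs are distinct molecules, deduplicated as unordered pairs, and
    hardness-filtered with the same both-flagged rule as initial pair
    generation.
    """
    cfg = cfg or FilterConfig()
    rng = np.random.default_rng(seed)
    pool = pool.reset_index(drop=True)
    labels = np.asarray(clusters)
    hard = pool.apply(lambda row: pair_hardness_flag(row, cfg), axis=1).to_numpy()
    n = len(pool)
    seen: set[tuple[int, int]] = set()
    rows = []
    attempts = 0
    while len(rows) < n_candidates and attempts < 50 * n_candidates:
        attempts += 1
        a, b_ = rng.integers(0, n, size=2)
        if a == b_:
            continue
        key = (min(a, b_), max(a, b_))
        if key in seen or (hard[a] and hard[b_]):
            continue
        seen.add(key)
        rows.append({
            "id_i": pool.at[int(a), "id"], "id_j": pool.at[int(b_), "id"],
            "smiles_i": pool.at[int(a), "smiles_canonical"],
            "smiles_j": pool.at[int(b_), "smiles_canonical"],
            "cluster_i": int(labels[a]), "cluster_j": int(labels[b_]),
        })
    return pd.DataFrame(rows)


def select_batch(candidates: pd.DataFrame,
                 batch_size: int = 1000) -> pd.DataFrame:
    """Greedy descending-variance selection under the cluster-pair rule.

    Admits candidates in order of decreasing variance (ties broken by the
    lexicographically smallest ``(id_i, id_j)``, making selection a total
    order independent of input row order); a candidate is skipped when its
    unordered cluster-label pair was already used in this batch.  Warns,
    rather than errors, when fewer than ``batch_size`` candidates are
    admissible.
    """
    required = {"variance", "cluster_i", "cluster_j", "id_i", "id_j"}
    missing = required - set(candidates.columns)
    if missing:
        raise ValueError(f"candidates missing columns: {sorted(missing)}")
    df = candidates.copy()
    df["_key"] = [tuple(sorted((str(a), str(b))))
                  for a, b in zip(df["id_i"], df["id_j"])]
    df = df.sort_values(["variance", "_key"],
                        ascending=[False, True], kind="mergesort")
    used: set[frozenset] = set()
    take = []
    for idx, row in df.iterrows():
        cpair = frozenset((int(row["cluster_i"]), int(row["cluster_j"])))
        if cpair in used:
            continue
        used.add(cpair)
        take.append(idx)
        if len(take) == batch_size:
            break
    if len(take) < batch_size:
        warnings.warn(f"only {len(take)} admissible candidates "
                      f"for batch_size {batch_size}")
    return df.loc[take].drop(columns="_key").reset_index(drop=True)
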