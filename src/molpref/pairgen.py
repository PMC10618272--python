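"""Clustering of the curated pool and constrained comparison-pair generation.

The pool is grouped into k clusters (default 1000) by k-means over binary
fingerprints.  Initial-round batches draw clusters without replacement so no
cluster label appears in more than one pair of a batch, keeping batches
chemically diverse; pairs whose BOTH members are "hard" (more than 10
rotatable bonds, or a fused system of 3+ rings) are rejected, since such
comparisons give annotators no clear preference handle.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .curation import FilterConfig, MoleculeRecord
from .errors import InfeasibleBatchError
from .featurize import FeaturizerSpec, fingerprint_counts

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["id_i", "id_j", "smiles_i", "smiles_j",
                "cluster_i", "cluster_j", "side_i"]


def binary_fingerprints(smiles_list: Sequence[str],
                        spec: FeaturizerSpec | None = None) -> np.ndarray:
    """Binary (presence/absence) fingerprints: counts thresholded at >= 1."""
    spec = spec or FeaturizerSpec()
    return np.vstack([(fingerprint_counts(s, spec) >= 1).astype(np.float64)
                      for s in smiles_list])


def cluster_pool(binary_fps: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means cluster labels over binary fingerprint space.

    Deterministic given the seed.  Raises ValueError when k exceeds the pool
    size.
    """
    binary_fps = np.asarray(binary_fps, dtype=np.float64)
    n = binary_fps.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds pool size {n}")
    km = KMeans(n_clusters=k, n_init=1, random_state=int(seed))
    labels = km.fit_predict(binary_fps)
    # k-means can leave clusters empty (e.g. duplicate fingerprints); re-seed
    # each empty label with the farthest point of the largest cluster so every
    # label is populated.  Deterministic: ties break toward the lowest index.
    counts = np.bincount(labels, minlength=k)
    for empty in np.flatnonzero(counts == 0):
        donor = int(np.argmax(counts))
        members = np.flatnonzero(labels == donor)
        dists = np.linalg.norm(
            binary_fps[members] - km.cluster_centers_[donor], axis=1)
        mover = members[int(np.argmax(dists))]
        labels[mover] = empty
        counts[donor] -= 1
        counts[empty] += 1
    return labels


def pair_hardness_flag(record: MoleculeRecord | pd.Series,
                       cfg: FilterConfig | None = None) -> bool:
    """True when a molecule is too floppy or too fused for an easy comparison."""
    cfg = cfg or FilterConfig()
    if isinstance(record, pd.Series):
        n_rot, fused = int(record["n_rotatable"]), int(record["max_fused_system"])
    else:
        n_rot, fused = record.n_rotatable, record.max_fused_system
    return n_rot > cfg.rotatable_threshold or fused >= cfg.fused_ring_threshold


def generate_pairs(pool: pd.DataFrame,
                   clusters: np.ndarray | Sequence[int],
                   n_pairs: int,
                   seed: int = 0,
                   cfg: FilterConfig | None = None,
                   max_retries: int | None = None) -> pd.DataFrame:
    """Emit an unlabelled batch of comparison pairs under the study constraints.

    Clusters are drawn without replacement (two per pair, so no cluster label
    repeats within the batch) and one molecule is drawn uniformly from each;
    a draw where both molecules carry the hardness flag is rejected and its
    clusters returned to the urn, up to a retry budget.  Presentation side is
    randomized with the seed and recorded in ``side_i``.

    Raises
    ------
    InfeasibleBatchError
        If ``2 * n_pairs`` exceeds the number of clusters (pigeonhole) or the
        retry budget is exhausted.
    """
    cfg = cfg or FilterConfig()
    rng = np.random.default_rng(seed)
    pool = pool.reset_index(drop=True)
    labels = np.asarray(clusters)
    if len(labels) != len(pool):
        raise ValueError("clusters and pool length mismatch")
    if max_retries is None:
        max_retries = max(1000, 100 * n_pairs)

    by_cluster: dict[int, np.ndarray] = {
        int(c): np.flatnonzero(labels == c) for c in np.unique(labels)}
    if 2 * n_pairs > len(by_cluster):
        raise InfeasibleBatchError(
            f"{n_pairs} pairs need {2 * n_pairs} distinct clusters, "
            f"only {len(by_cluster)} available")

    hard = pool.apply(lambda row: pair_hardness_flag(row, cfg), axis=1).to_numpy()
    available = list(by_cluster)
    rows: list[dict] = []
    retries = 0
    while len(rows) < n_pairs:
        if retries > max_retries:
            raise InfeasibleBatchError(
                f"retry budget exhausted after {len(rows)} pairs")
        pick = rng.choice(len(available), size=2, replace=False)
        c_i, c_j = available[pick[0]], available[pick[1]]
        m_i = int(rng.choice(by_cluster[c_i]))
        m_j = int(rng.choice(by_cluster[c_j]))
        if hard[m_i] and hard[m_j]:
            retries += 1
            continue
        side_i = "left" if rng.random() < 0.5 else "right"
        rows.append({
            "id_i": pool.at[m_i, "id"], "id_j": pool.at[m_j, "id"],
            "smiles_i": pool.at[m_i, "smiles_canonical"],
            "smiles_j": pool.at[m_j, "smiles_canonical"],
            "cluster_i": c_i, "cluster_j": c_j, "side_i": side_i,
        })
        available = [c for c in available if c not in (c_i, c_j)]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)
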