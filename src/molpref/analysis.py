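"""Evaluation battery for the preference study and the learned scores.

Covers: chance-corrected rater agreement (Fleiss kappa across raters,
Cohen kappa within a rater on repeated pairs), screen-side positional-bias
testing, correlation of learned scores with 2D descriptors across training
seeds, discrimination between named chemical sets (ROC AUC and one-way
ANOVA), and BRICS fragment preference attribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import BRICS
from scipy import stats
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from statsmodels.stats import inter_rater

from .errors import DegenerateSetError, LengthError, ShapeError

logger = logging.getLogger(__name__)


@dataclass
class FragmentScore:
    """A BRICS leaf fragment and the mean score of its parent molecules."""

    fragment: str
    n_parents: int
    mean_parent_score: float
    sd_parent_score: float


# -- agreement statistics -------------------------------------------------

def fleiss_kappa(counts) -> float:
    """Fleiss' kappa from an items x categories count table.

    Every item must have the same number of ratings n >= 2 (subset the
    responses to the common rater set first).  Returns NaN with a warning
    when chance agreement is 1 (all ratings in a single category), where
    kappa is undefined.
    """
    try:
        table = np.asarray(counts, dtype=np.float64)
    except ValueError as exc:
        raise ShapeError(f"ragged counts table: {exc}") from None
    if table.ndim != 2 or table.shape[1] < 2:
        raise ShapeError("counts must be 2-D with >= 2 categories")
    n_per_item = table.sum(axis=1)
    if not (n_per_item == n_per_item[0]).all():
        raise ShapeError("unequal number of ratings per item")
    if n_per_item[0] < 2:
        raise ShapeError("need >= 2 ratings per item")
    p_cat = table.sum(axis=0) / table.sum()
    if np.max(p_cat) >= 1.0:
        warnings.warn("chance agreement is 1; kappa undefined")
        return float("nan")
    return float(inter_rater.fleiss_kappa(table, method="fleiss"))


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa between two equal-length categorical sequences."""
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise LengthError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise LengthError("empty sequences")
    if a == b:
        return 1.0
    return float(cohen_kappa_score(a, b))


def left_right_bias(side_choices: Sequence[str]) -> tuple[float, float]:
    """Percent of 'left' choices and the exact two-sided binomial p vs 0.5."""
    sides = list(side_choices)
    if not sides:
        raise ValueError("no side choices given")
    bad = set(sides) - {"left", "right"}
    if bad:
        raise ValueError(f"invalid side values: {bad}")
    n_left = sum(s == "left" for s in sides)
    test = stats.binomtest(n_left, len(sides), 0.5)
    return 100.0 * n_left / len(sides), float(test.pvalue)


def ratings_to_counts(responses: pd.DataFrame,
                      item_col: str = "pair_uid",
                      rater_col: str = "rater_id",
                      choice_col: str = "choice") -> np.ndarray:
    """Pivot long-form responses into an items x categories count table.

    Choices must be coded by molecule identity within the pair (e.g. "i" /
    "j"), never by screen side, so side randomization cannot corrupt the
    agreement statistics.  Only raters who rated every item are kept (the
    common rater set), giving the equal-ratings table Fleiss' kappa needs.
    """
    wide = responses.pivot_table(index=item_col, columns=rater_col,
                                 values=choice_col, aggfunc="first")
    complete = wide.dropna(axis=1)
    if complete.shape[1] < 2:
        raise ShapeError("fewer than 2 raters rated every item")
    categories = sorted(set(np.asarray(complete).ravel()))
    counts = np.zeros((complete.shape[0], len(categories)))
    for c_idx, cat in enumerate(categories):
        counts[:, c_idx] = (complete == cat).sum(axis=1)
    return counts


def agreement_report(responses: pd.DataFrame) -> dict:
    """Full agreement summary for one annotation round.

    Expects long-form responses with columns ``pair_uid``, ``rater_id``,
    ``choice`` ("i"/"j"), ``side_chosen`` ("left"/"right") and a boolean
    ``is_redundant`` marking the repeated pairs.  Fleiss' kappa is computed
    on the non-redundant shared pairs; per-rater Cohen's kappa and repeat
    agreement on first-vs-repeat answers to redundant pairs; left/right bias
    per rater over all of their responses.
    """
    red_uids = set(responses.loc[responses["is_redundant"], "pair_uid"])
    non_red = responses[~responses["pair_uid"].isin(red_uids)]
    kappa_f = fleiss_kappa(ratings_to_counts(non_red))

    per_rater = {}
    red = responses[responses["pair_uid"].isin(red_uids)]
    for rater, grp in responses.groupby("rater_id"):
        entry = {}
        g = red[red["rater_id"] == rater].sort_values(["pair_uid", "presentation"])
        firsts = g.groupby("pair_uid")["choice"].first()
        seconds = g.groupby("pair_uid")["choice"].last()
        both = firsts.index[g.groupby("pair_uid").size() >= 2]
        if len(both) > 0:
            a, b = firsts[both].tolist(), seconds[both].tolist()
            entry["repeat_agreement_pct"] = 100.0 * np.mean(
                [x == y for x, y in zip(a, b)])
            entry["cohen_kappa"] = cohen_kappa(a, b)
        pct_left, pval = left_right_bias(grp["side_chosen"].tolist())
        entry["left_pct"] = pct_left
        entry["left_bias_pvalue"] = pval
        per_rater[rater] = entry

    kappas = [e["cohen_kappa"] for e in per_rater.values() if "cohen_kappa" in e]
    return {
        "fleiss_kappa": kappa_f,
        "per_rater": per_rater,
        "mean_cohen_kappa": float(np.mean(kappas)) if kappas else float("nan"),
    }


# -- score audits ---------------------------------------------------------

def descriptor_correlations(score_sets: Sequence[np.ndarray],
                            descriptors: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between learned scores and each descriptor, across seeds.

    ``score_sets`` holds one score vector per independently trained model
    (different seeds) over the same molecules as the ``descriptors`` rows.
    Returns a table (descriptor, mean_r, sd_r, constant) sorted by |mean_r|
    descending; constant descriptors get r = 0 and a flag.
    """
    if len(score_sets) == 0:
        raise ValueError("need at least one score set")
    rows = []
    for name in descriptors.columns:
        vals = descriptors[name].to_numpy(dtype=np.float64)
        if np.std(vals) == 0 or not np.all(np.isfinite(vals)):
            rows.append({"descriptor": name, "mean_r": 0.0, "sd_r": 0.0,
                         "constant": True})
            continue
        rs = [float(stats.pearsonr(np.asarray(s, dtype=np.float64), vals)[0])
              for s in score_sets]
        rows.append({"descriptor": name, "mean_r": float(np.mean(rs)),
                     "sd_r": float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0,
                     "constant": False})
    out = pd.DataFrame(rows)
    return out.reindex(out["mean_r"].abs().sort_values(ascending=False).index
                       ).reset_index(drop=True)


def set_discrimination(score_sets: Mapping[str, Sequence[float]],
                       control: str) -> dict:
    """Discriminate drug-like sets from a control set by learned score.

    For every non-control set, the ROC AUC of separating it (positive class)
    from the control, treating LOWER score as more positive; plus a one-way
    ANOVA F-test across all sets.
    """
    if len(score_sets) < 2:
        raise DegenerateSetError("need at least 2 score sets")
    if control not in score_sets:
        raise KeyError(f"control set {control!r} not among score sets")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in score_sets.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise DegenerateSetError(f"set {name!r} has < 2 scores")
    if all(np.std(a) == 0 for a in arrays.values()):
        raise DegenerateSetError("all score sets are constant")
    aucs = {}
    ctrl = arrays[control]
    for name, arr in arrays.items():
        if name == control:
            continue
        y = np.concatenate([np.ones(arr.size), np.zeros(ctrl.size)])
        scores = -np.concatenate([arr, ctrl])  # lower score = positive class
        aucs[name] = float(roc_auc_score(y, scores))
    f_stat, p_val = stats.f_oneway(*arrays.values())
    return {"auc_vs_control": aucs, "anova_F": float(f_stat),
            "anova_p": float(p_val)}


# -- fragment attribution -------------------------------------------------

def _wildcard_fragment(frag_smiles: str) -> str:
    """Canonicalize a BRICS leaf with attachment-point labels wildcarded."""
    mol = Chem.MolFromSmiles(frag_smiles)
    if mol is None:
        return frag_smiles
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
    return Chem.MolToSmiles(mol)


def brics_leaves(smiles: str) -> set[str]:
    """Distinct BRICS leaf fragments of one molecule (wildcarded, canonical).

    A molecule with no breakable bonds contributes itself as its single leaf.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    frags = BRICS.BRICSDecompose(mol)
    if not frags:
        return {Chem.MolToSmiles(mol)}
    return {_wildcard_fragment(f) for f in frags}


def brics_fragment_scores(smiles_list: Sequence[str],
                          scores: Sequence[float],
                          min_count: int = 5) -> pd.DataFrame:
    """Score BRICS leaf fragments by the mean score of their parent molecules.

    Fragments carry attachment atoms never seen by the model, so they are
    attributed the average learned score of the training molecules they come
    from; each parent counts once per fragment even if the fragment occurs
    several times in it.  Fragments seen in fewer than ``min_count`` parents
    are omitted.  Output sorted ascending by mean score (best first under
    the lower-is-better convention).
    """
    if len(smiles_list) != len(scores):
        raise LengthError("smiles and scores length mismatch")
    parents: dict[str, list[float]] = {}
    for smi, sc in zip(smiles_list, scores):
        for frag in brics_leaves(smi):
            parents.setdefault(frag, []).append(float(sc))
    rows = []
    for frag, vals in parents.items():
        if len(vals) < min_count:
            continue
        rows.append({
            "fragment": frag, "n_parents": len(vals),
            "mean_score": float(np.mean(vals)),
            "sd_score": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        })
    out = pd.DataFrame(rows, columns=["fragment", "n_parents",
                                      "mean_score", "sd_score"])
    return out.sort_values("mean_score", kind="mergesort").reset_index(drop=True)
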