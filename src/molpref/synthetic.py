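"""Synthetic study data: molecule pools, a score oracle, and rater panels.

Everything the rest of the stack consumes can be generated here without
external databases: a compound pool assembled from a small fragment grammar
(ring cores x linkers x terminal rings) spanning the pool-filter space in
known proportions, a linear descriptor-based oracle defining a ground-truth
desirability s*, Bradley-Terry labels drawn from a sigmoid of oracle score
differences, and simulated rater panels (with redundant repeats and
randomized sides) for the agreement statistics.

Every emitted molecule is verified against the curation module at
generation time, so subset tags are guaranteed: e.g. every "mw_fail"
molecule fails exactly the molecular-weight predicate and nothing else.
The oracle is linear in named descriptors (not fingerprints) so that model
recovery can be checked against an interpretable ground truth.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .curation import FilterConfig, curate_pool, make_record
from .featurize import _DESC_FUNCS
from .pairgen import pair_hardness_flag
from .ranker import sigmoid

logger = logging.getLogger(__name__)

# -- fragment grammar -----------------------------------------------------
# Cores use ring-closure digits 1-2, terminal rings digits 8-9, so nesting
# never collides.  "{}" marks the substitution slot.

_CORES = [
    "Cc1ccc({})cc1", "COc1ccc({})cc1", "Fc1ccc({})cc1", "Clc1ccc({})cc1",
    "Cc1cccc({})n1", "COc1ncc({})cn1", "Cc1noc(C)c1{}", "Cn1ccnc1{}",
    "COc1ccc2nc({})sc2c1", "Cc1ccc2[nH]c({})nc2c1", "Cn1ncc({})c1C",
    "Cc1csc({})n1", "COc1cccc({})c1O", "Cc1ccc({})s1", "Cn1nccc1{}",
    "O=c1[nH]c2ccccc2n1{}", "Cc1cc(C)nc({})n1",
]

_LINKERS = [
    "C(=O)N{}", "CC(=O)N{}", "S(=O)(=O)N{}", "NC(=O){}", "C(=O)N(C){}",
    "CN{}", "OC{}", "CO{}", "C{}", "CC{}",
]

_TERMINALS = [
    "C8CCOCC8", "C8CCN(C)CC8", "C8CCCCC8", "C8CCNC8", "c8ccncc8",
    "c8ccc(F)cc8", "c8ccc(C)cc8", "c8cnc(C)nc8", "c8ccc(O)cc8",
    "c8csc(C)n8", "C8COC8", "c8cn(C)cn8", "C8CC8", "c8ccc(Cl)cc8",
    "c8ccc(C#N)cc8",
]

# Pre-verified violator grammars: each emitted molecule is still checked at
# generation time before receiving its subset tag.
_MW_FAIL = [  # drug-like but under 200 g/mol
    "CC(=O)Nc1ccc(O)cc1", "Cc1ccccc1S(N)(=O)=O", "OCc1ccc(F)cc1O",
    "Cc1ccc(C(=O)NC)cc1", "COc1ccccc1C(N)=O", "Cc1ncc(CO)c(C)n1",
    "CC(O)c1ccc(F)cc1C", "Cn1ccnc1CC(N)=O", "CCc1ccc(S(N)(=O)=O)cc1",
    "Cc1cc(C)nc(NC)n1",
]
_QED_FAIL = [  # greasy chains: QED below 0.2, everything else inside bounds
    "CCCCCCCCCCCCCCCCCCCCCCCC", "CCCCCCCCCCCCCCCCCCCCCCCCCC",
    "CCCCCCCCCCCCOCCCCCCCCCCCC", "CCCCCCCCCCCCSCCCCCCCCCCCC",
    "CCCCCCCCCCCCCCOCCCCCCCCCCC", "CCCCCCCCCCCCCCCCCCCCCCCCCCCC",
]
_RO5_FAIL = [  # permethoxylated terphenyls: MW>500, logP>5, acceptors>10
    "COc1c(OC)c(OC)c(-c2cc(OC)c(OC)c(OC)c2OC)c(OC)c1-c1cc(OC)c(OC)c(OC)c1OC",
    "COc1c(OC)c(OC)c(-c2c(OC)c(OC)c(OC)c(OC)c2OC)c(OC)c1-c1cc(OC)c(OC)c(OC)c1OC",
    "COc1c(OC)c(OC)c(-c2cc(OC)c(OC)c(OC)c2OC)c(OC)c1-c1ccc(OC)c(OC)c1OC",
    "COc1c(OC)c(OC)c(-c2cc(OC)c(OC)c(OC)c2OC)c(OC)c1-c1cc(OC)c(OC)c(OC)c1Cl",
]
_ALERT_CORES = [  # nitro-decorated cores: hit the alert set, pass all else
    "O=[N+]([O-])c1ccc({})cc1", "Cc1ccc({})cc1[N+](=O)[O-]",
    "COc1cc([N+](=O)[O-])ccc1{}",
]
_HARD_ROTOR = [  # pool-passing but > 10 rotatable bonds
    "c1ccc(OCCCCCCCCCCOc2ccccc2)cc1",
    "COc1ccc(OCCCCCCCCCCOc2ccc(C)cc2)cc1",
    "c1ccc(CNCCCCCCCCCCNCc2ccccc2)cc1",
    "Cc1ccc(OCCCCCCCCCOc2ccccc2C)cc1",
]
_HARD_FUSED = [  # pool-passing with a 3+ fused ring system
    "Cc1ccc2c(c1)[nH]c1ccc(CC(N)=O)cc12", "COc1ccc2oc3ccc(C(C)=O)cc3c2c1",
    "Cc1ccc2c(c1)sc1ccc(CO)cc12", "CCn1c2ccccc2c2cc(C(N)=O)ccc21",
    "COc1ccc2[nH]c3ccc(C)cc3c2c1",
]

DEFAULT_FRACTIONS: dict[str, float] = {
    "pass": 0.80, "mw_fail": 0.05, "qed_fail": 0.04, "ro5_fail": 0.03,
    "alert_fail": 0.04, "hard_rotor": 0.02, "hard_fused": 0.02,
}

_EXPECTED_REASON = {"mw_fail": ["mw_min"], "qed_fail": ["qed_min"],
                    "ro5_fail": ["ro5"], "alert_fail": ["alert"]}


def _grammar_smiles(rng: np.random.Generator, cores: Sequence[str]) -> "itertools.chain":
    """Shuffled stream of core x linker x terminal assemblies."""
    combos = list(itertools.product(range(len(cores)), range(len(_LINKERS)),
                                    range(len(_TERMINALS))))
    rng.shuffle(combos)
    for ci, li, ti in combos:
        yield cores[ci].format(_LINKERS[li].format(_TERMINALS[ti]))


def _verified(smiles: str, subset: str, cfg: FilterConfig) -> str | None:
    """Standardized SMILES if the molecule lands in its intended subset."""
    try:
        rec = make_record("x", smiles, cfg)
    except Exception:
        return None
    if subset == "pass":
        ok = rec.pool_pass and not pair_hardness_flag(rec, cfg)
    elif subset == "hard_rotor":
        ok = rec.pool_pass and rec.n_rotatable > cfg.rotatable_threshold
    elif subset == "hard_fused":
        ok = rec.pool_pass and rec.max_fused_system >= cfg.fused_ring_threshold
    else:
        ok = rec.reasons == _EXPECTED_REASON[subset]
    return rec.smiles_canonical if ok else None


def generate_pool(n: int, seed: int = 0,
                  fractions: Mapping[str, float] | None = None,
                  cfg: FilterConfig | None = None,
                  with_tags: bool = False):
    """Generate n molecules spanning the pool-filter space.

    Roughly 84% pass the default pool filters (the "pass" molecules plus
    the pool-passing hardness-flagged subsets) and each violator subset
    fails exactly one predicate, verified at generation time.  Deterministic
    under the seed; every output is already standardized and canonical.

    Returns a list of SMILES, or a DataFrame with a ``subset`` tag column
    when ``with_tags`` is set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or FilterConfig()
    fractions = dict(fractions or DEFAULT_FRACTIONS)
    rng = np.random.default_rng(seed)
    quotas = {k: int(round(v * n)) for k, v in fractions.items()}
    quotas["pass"] += n - sum(quotas.values())  # absorb rounding drift

    fixed_lists = {"mw_fail": _MW_FAIL, "qed_fail": _QED_FAIL,
                   "ro5_fail": _RO5_FAIL, "hard_rotor": _HARD_ROTOR,
                   "hard_fused": _HARD_FUSED}
    rows: list[tuple[str, str]] = []
    for subset, quota in quotas.items():
        if quota <= 0:
            continue
        if subset == "pass":
            stream = _grammar_smiles(rng, _CORES)
        elif subset == "alert_fail":
            stream = _grammar_smiles(rng, _ALERT_CORES)
        else:
            base = fixed_lists[subset]
            stream = iter([base[int(i)] for i in rng.integers(0, len(base),
                                                              size=50 * quota)])
        got = 0
        seen: set[str] = set()
        for smi in stream:
            canon = _verified(smi, subset, cfg)
            if canon is None:
                continue
            if subset in ("pass", "alert_fail") and canon in seen:
                continue
            seen.add(canon)
            rows.append((canon, subset))
            got += 1
            if got == quota:
                break
        if got < quota:
            raise RuntimeError(f"grammar exhausted for subset {subset!r} "
                               f"({got}/{quota})")
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    if with_tags:
        return pd.DataFrame(rows, columns=["smiles", "subset"])
    return [smi for smi, _ in rows]


# -- oracle ---------------------------------------------------------------

@dataclass
class OracleConfig:
    """Ground-truth desirability: a linear function of named descriptors.

    Lower s* means more desirable, mirroring the learned-score convention;
    the default weights reward drug-likeness and punish lipophilicity and
    flexibility.  After :func:`fit_oracle`, s* has zero mean and unit
    variance over the fitted pool; ``beta`` is the Bradley-Terry inverse
    temperature of the label noise (large beta = near-deterministic labels).
    """

    weights: Mapping[str, float] = field(default_factory=lambda: {
        "qed": -1.0, "MolLogP": 0.4, "NumRotatableBonds": 0.3})
    beta: float = 5.0
    seed: int = 0
    center: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        unknown = [k for k in self.weights if k not in _DESC_FUNCS]
        if unknown:
            raise ValueError(f"unknown oracle descriptors: {unknown}")


def _raw_oracle(smiles: str, cfg: OracleConfig) -> float:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return float(sum(w * float(_DESC_FUNCS[name](mol))
                     for name, w in cfg.weights.items()))


def fit_oracle(cfg: OracleConfig, smiles_list: Sequence[str]) -> OracleConfig:
    """Set center/scale so s* has zero mean, unit variance over the pool."""
    raw = np.array([_raw_oracle(s, cfg) for s in smiles_list])
    cfg.center = float(raw.mean())
    cfg.scale = float(raw.std()) or 1.0
    return cfg


def oracle_score(smiles: str | Sequence[str], cfg: OracleConfig):
    """Ground-truth score s* for one molecule or a sequence."""
    if isinstance(smiles, str):
        return (_raw_oracle(smiles, cfg) - cfg.center) / cfg.scale
    return np.array([(_raw_oracle(s, cfg) - cfg.center) / cfg.scale
                     for s in smiles])


def uniform_pairs(pool: pd.DataFrame, n_pairs: int, seed: int = 0) -> pd.DataFrame:
    """Uniform distinct unordered molecule pairs from a curated pool."""
    rng = np.random.default_rng(seed)
    pool = pool.reset_index(drop=True)
    n = len(pool)
    seen: set[tuple[int, int]] = set()
    rows = []
    while len(rows) < n_pairs:
        a, b = rng.integers(0, n, size=2)
        if a == b or (min(a, b), max(a, b)) in seen:
            continue
        seen.add((min(a, b), max(a, b)))
        rows.append({"id_i": pool.at[int(a), "id"],
                     "id_j": pool.at[int(b), "id"],
                     "smiles_i": pool.at[int(a), "smiles_canonical"],
                     "smiles_j": pool.at[int(b), "smiles_canonical"]})
    return pd.DataFrame(rows)


def simulate_labels(pairs: pd.DataFrame, cfg: OracleConfig,
                    seed: int | None = None) -> pd.DataFrame:
    """Draw Bradley-Terry labels: label=1 (m_i chosen) ~ sigmoid(beta (s*_j - s*_i)).

    Lower-is-better: the molecule with the lower oracle score is the more
    likely winner.  Returns a copy of ``pairs`` with ``label`` added.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    s_i = oracle_score(pairs["smiles_i"].tolist(), cfg)
    s_j = oracle_score(pairs["smiles_j"].tolist(), cfg)
    p_i = sigmoid(cfg.beta * (s_j - s_i))
    out = pairs.copy()
    out["label"] = (rng.random(len(out)) < p_i).astype(int)
    return out


def simulate_rater_panel(pairs: pd.DataFrame, cfg: OracleConfig,
                         n_raters: int = 9, p_consistent: float = 0.85,
                         n_redundant: int = 20, seed: int = 0) -> pd.DataFrame:
    """Simulate a shared annotation round with redundant repeats.

    Every rater answers every pair; each answer follows the oracle's
    deterministic preference with probability ``p_consistent`` and flips
    otherwise.  The first ``n_redundant`` pairs are re-presented at the end
    in fresh random screen positions, mimicking the intra-rater consistency
    probes.  Output is long-form with the columns the agreement report
    expects (choice coded by molecule identity, side coded separately).
    """
    if not 0.5 <= p_consistent <= 1.0:
        raise ValueError("p_consistent must be in [0.5, 1]")
    rng = np.random.default_rng(seed)
    pairs = pairs.reset_index(drop=True)
    s_i = oracle_score(pairs["smiles_i"].tolist(), cfg)
    s_j = oracle_score(pairs["smiles_j"].tolist(), cfg)
    oracle_choice = np.where(s_i <= s_j, "i", "j")
    n_redundant = min(n_redundant, len(pairs))

    rows = []
    schedule = [(k, 0, False) for k in range(len(pairs))] + \
               [(k, 1, True) for k in range(n_redundant)]
    for rater in range(n_raters):
        rater_id = f"rater{rater:02d}"
        for item, presentation, redundant in schedule:
            side_i = "left" if rng.random() < 0.5 else "right"
            follow = rng.random() < p_consistent
            choice = oracle_choice[item] if follow else (
                "j" if oracle_choice[item] == "i" else "i")
            side_chosen = side_i if choice == "i" else (
                "right" if side_i == "left" else "left")
            rows.append({
                "pair_uid": f"pair{item:05d}",
                "id_i": pairs.at[item, "id_i"], "id_j": pairs.at[item, "id_j"],
                "smiles_i": pairs.at[item, "smiles_i"],
                "smiles_j": pairs.at[item, "smiles_j"],
                "rater_id": rater_id, "choice": choice,
                "label": int(choice == "i"),
                "side_i": side_i, "side_chosen": side_chosen,
                "presentation": presentation, "is_redundant": redundant,
                "round": "preliminary",
            })
    return pd.DataFrame(rows)


def make_benchmark(n: int = 600, n_pairs: int = 2000, beta: float = 20.0,
                   seed: int = 0, heldout_fraction: float = 0.2,
                   cfg: FilterConfig | None = None) -> dict:
    """End-to-end synthetic study: pool, oracle, labelled pairs, held-out split.

    Generates a pool, curates it, fits the oracle on the filter-passing
    molecules, splits molecules into train/held-out, and draws labelled
    Bradley-Terry pairs among the training molecules only, so the held-out
    molecules are unseen for score-recovery checks.
    """
    cfg = cfg or FilterConfig()
    smiles = generate_pool(n, seed=seed, cfg=cfg)
    pool = curate_pool(smiles, cfg)
    passing = pool[pool["pool_pass"]].reset_index(drop=True)
    oracle = OracleConfig(beta=beta, seed=seed)
    fit_oracle(oracle, passing["smiles_canonical"].tolist())

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(passing))
    n_held = int(round(heldout_fraction * len(passing)))
    held = passing.iloc[idx[:n_held]].reset_index(drop=True)
    trainp = passing.iloc[idx[n_held:]].reset_index(drop=True)

    pairs = uniform_pairs(trainp, n_pairs, seed=seed + 1)
    pairs = simulate_labels(pairs, oracle, seed=seed + 2)
    return {"pool": pool, "train_pool": trainp, "heldout_pool": held,
            "pairs": pairs, "oracle": oracle}
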