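"""Shared fixtures: hand-built filter fixture molecules, small synthetic
feature problems, and the session-scoped end-to-end benchmark."""

import numpy as np
import pandas as pd
import pytest

import molpref as mp

# Hand-constructed filter fixture: 10 molecules designed to pass the default
# pool filters and 10 designed to each violate exactly one predicate
# (diagnostics verified with the chemistry toolkit when the fixture was built).
FIXTURE_PASS = [
    "CC(=O)Nc1ccc(O)cc1C(=O)NC1CCN(C)CC1",
    "COc1ccc2nc(N3CCN(C)CC3)sc2c1",
    "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
    "CN1CCN(c2ccc3nc(-c4ccco4)cc(=O)n3c2)CC1",
    "O=C(O)c1ccccc1Nc1cccc(C(F)(F)F)c1",
    "CCOC(=O)c1cncn1C(C)c1ccccc1",
    "CC(C)Cc1ccc(C(C)C(=O)NCc2ccccn2)cc1",
    "COc1cc2c(cc1OC)CCN(C(=O)c1ccc(F)cc1)C2",
    "Cn1cnc2c1c(=O)n(Cc1ccccc1)c(=O)n2CC(O)CO",
    "COc1ccc(CNC(=O)c2ccc(S(C)(=O)=O)cc2)cc1OC",
]
FIXTURE_FAIL = {  # smiles -> the single predicate it violates
    "CC(=O)Nc1ccc(O)cc1": "mw_min",
    "Cc1ccccc1S(N)(=O)=O": "mw_min",
    "OCc1ccc(F)cc1O": "mw_min",
    "CCCCCCCCCCCCCCCCCCCCCCCC": "qed_min",
    "CCCCCCCCCCCCOCCCCCCCCCCCC": "qed_min",
    "COc1c(OC)c(OC)c(-c2cc(OC)c(OC)c(OC)c2OC)c(OC)c1-c1cc(OC)c(OC)c(OC)c1OC": "ro5",
    "COc1c(OC)c(OC)c(-c2cc(OC)c(OC)c(OC)c2OC)c(OC)c1-c1ccc(OC)c(OC)c1OC": "ro5",
    "O=[N+]([O-])c1ccc(C(=O)N2CCN(C)CC2)cc1C": "alert",
    "CC(C)Cc1ccc(C=O)cc1OCc1ccccc1": "alert",
    "NC(=S)Nc1ccc(-c2ccccc2)cc1OC": "alert",
}

BENCH_SEED = 11


def make_linear_problem(seed=0, n_mol=60, dim=12, n_pairs=300, beta=8.0):
    """Small abstract preference problem: linear ground truth over random
    feature vectors, Bradley-Terry labels.  Returns (X, s_star, ai, bj, y)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_mol, dim))
    w = rng.normal(size=dim)
    s_star = X @ w
    s_star = (s_star - s_star.mean()) / s_star.std()
    ai = np.empty(n_pairs, dtype=int)
    bj = np.empty(n_pairs, dtype=int)
    for t in range(n_pairs):
        ai[t], bj[t] = rng.choice(n_mol, 2, replace=False)
    p = 1.0 / (1.0 + np.exp(-beta * (s_star[bj] - s_star[ai])))
    y = (rng.random(n_pairs) < p).astype(float)
    return X, s_star, ai, bj, y


@pytest.fixture(scope="session")
def linear_problem():
    return make_linear_problem(seed=0)


@pytest.fixture(scope="session")
def small_pool():
    """Tagged synthetic pool of 120 molecules, curated."""
    tagged = mp.generate_pool(120, seed=3, with_tags=True)
    pool = mp.curate_pool(tagged["smiles"].tolist())
    pool["subset"] = tagged["subset"].values
    return pool


@pytest.fixture(scope="session")
def bench():
    """End-to-end benchmark: 600 molecules, 2000 near-deterministic pairs."""
    return mp.make_benchmark(n=600, n_pairs=2000, beta=20.0, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def bench_features(bench):
    feat = mp.Featurizer().fit(bench["train_pool"]["smiles_canonical"].tolist())
    pairs = bench["pairs"]
    Xi = feat.transform(pairs["smiles_i"].tolist())
    Xj = feat.transform(pairs["smiles_j"].tolist())
    y = pairs["label"].to_numpy()
    return feat, Xi, Xj, y


@pytest.fixture(scope="session")
def bench_train_cfg():
    # 40-epoch budget: the synthetic benchmark converges well before the
    # 100-epoch default and the cross-validation loop trains six models.
    return mp.TrainConfig(seed=BENCH_SEED, epochs=40)


@pytest.fixture(scope="session")
def bench_model(bench_features, bench_train_cfg):
    _, Xi, Xj, y = bench_features
    return mp.train(Xi, Xj, y, bench_train_cfg)


@pytest.fixture(scope="session")
def rater_panel(bench):
    pairs = bench["pairs"].head(100)
    return mp.simulate_rater_panel(pairs, bench["oracle"], n_raters=6,
                                   p_consistent=0.85, n_redundant=15, seed=5)
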