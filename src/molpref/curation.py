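"""Compound curation: standardization, property diagnostics and pool filters.

Raw SMILES are standardized (salt stripping, neutralization, optional
tautomer canonicalization) and annotated with the physicochemical
diagnostics that define the study pool: molecular weight between 200 and
1000 g/mol, QED drug-likeness between 0.2 and 0.9, at most 2 rule-of-five
violations, and no structural-alert hits.  Rotatable-bond and fused-ring
counts are recorded as well; they do not gate pool membership but mark
molecules as "hard" for pair generation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import BadPatternError, EmptyAfterStripError, ParseError

logger = logging.getLogger(__name__)

# Columns of a curated-pool CSV, in write order.
RECORD_COLUMNS = [
    "id", "smiles_raw", "smiles_canonical", "mw", "qed", "ro5_violations",
    "n_rotatable", "max_fused_system", "alert_hits", "pool_pass", "reasons",
]

#: Default structural-alert collection: a compact set of common reactive /
#: toxicophore motifs.  The engine accepts any (name -> SMARTS) mapping, so a
#: full corporate filter catalogue can be loaded from CSV instead.
DEFAULT_ALERT_SMARTS: dict[str, str] = {
    "nitro": "[N+](=O)[O-]",
    "aldehyde": "[CX3H1](=O)[#6]",
    "acyl_halide": "[CX3](=O)[F,Cl,Br,I]",
    "alkyl_halide": "[CX4;!$(C(F)(F)F)][Br,I]",
    "epoxide_aziridine": "[OX2r3,NX3r3]1[CX4r3][CX4r3]1",
    "azide": "[N-]=[N+]=N",
    "isocyanate": "N=C=[O,S]",
    "peroxide": "[OX2][OX2]",
    "hydrazine": "[NX3;!$(N=*)][NX3;!$(N=*);!$(NC=O)]",
    "thiourea": "[NX3][CX3](=[SX1])[NX3]",
    "michael_acceptor": "[CX3]=[CX3][CX3](=O)[OX2,NX3]",
    "quaternary_nitrogen": "[N+X4]",
}


class AlertSet:
    """A named collection of compiled structural-alert SMARTS patterns."""

    def __init__(self, patterns: Mapping[str, str]):
        self.smarts = dict(patterns)
        self._compiled: dict[str, Chem.Mol] = {}
        for name, smarts in self.smarts.items():
            pat = Chem.MolFromSmarts(smarts)
            if pat is None:
                raise BadPatternError(f"alert {name!r}: bad SMARTS {smarts!r}")
            self._compiled[name] = pat

    @classmethod
    def default(cls) -> "AlertSet":
        return cls(DEFAULT_ALERT_SMARTS)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AlertSet":
        """Load (name, smarts) rows; header optional."""
        patterns: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() in ("name", ""):
                    continue
                patterns[row[0].strip()] = row[1].strip()
        return cls(patterns)

    def match(self, mol: Chem.Mol) -> list[str]:
        """Names of all patterns with at least one match, each reported once."""
        return [n for n, p in self._compiled.items() if mol.HasSubstructMatch(p)]

    def __len__(self) -> int:
        return len(self._compiled)


@dataclass
class FilterConfig:
    """Pool-filter thresholds and hardness flags.

    ``mw_*`` in g/mol; QED is dimensionless in [0, 1].  ``rotatable_threshold``
    and ``fused_ring_threshold`` define the pair-hardness flag, not pool
    membership: a molecule is "hard" when n_rotatable > rotatable_threshold or
    max_fused_system >= fused_ring_threshold.
    """

    mw_min: float = 200.0
    mw_max: float = 1000.0
    qed_min: float = 0.2
    qed_max: float = 0.9
    max_ro5_violations: int = 2
    rotatable_threshold: int = 10
    fused_ring_threshold: int = 3
    canonicalize_tautomer: bool = False
    alert_set: AlertSet = field(default_factory=AlertSet.default)

    def __post_init__(self) -> None:
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")
        if not self.qed_min < self.qed_max:
            raise ValueError("qed_min must be < qed_max")


@dataclass
class MoleculeRecord:
    """A curated compound with its filter diagnostics."""

    id: str
    smiles_raw: str
    smiles_canonical: str = ""
    mw: float = float("nan")
    qed: float = float("nan")
    ro5_violations: int = 0
    n_rotatable: int = 0
    max_fused_system: int = 0
    alert_hits: list[str] = field(default_factory=list)
    pool_pass: bool = False
    reasons: list[str] = field(default_factory=list)


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER = None  # built lazily; the enumerator is expensive to construct


def standardize_molecule(smiles_raw: str, canonicalize_tautomer: bool = False) -> str:
    """Standardize a raw SMILES and return the canonical SMILES.

    Keeps the largest organic fragment (salt stripping), neutralizes simple
    protonation states, and optionally canonicalizes the tautomer.  The
    result is canonical, hence idempotent under re-application.

    Raises
    ------
    ParseError
        If the SMILES cannot be parsed.
    EmptyAfterStripError
        If no organic fragment remains after stripping.
    """
    global _TAUTOMER
    if not isinstance(smiles_raw, str) or not smiles_raw.strip():
        raise ParseError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles_raw!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = _LARGEST_FRAGMENT.choose(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        raise EmptyAfterStripError(f"no organic fragment in {smiles_raw!r}")
    mol = _UNCHARGER.uncharge(mol)
    if canonicalize_tautomer:
        if _TAUTOMER is None:
            _TAUTOMER = rdMolStandardize.TautomerEnumerator()
        mol = _TAUTOMER.Canonicalize(mol)
    return Chem.MolToSmiles(mol)


def ro5_violations(mol: Chem.Mol) -> int:
    """Count of classic rule-of-five bounds exceeded (0-4).

    Bounds: MW > 500, computed logP > 5, H-bond donors > 5, acceptors > 10.
    """
    return int(
        (Descriptors.MolWt(mol) > 500)
        + (Crippen.MolLogP(mol) > 5)
        + (Lipinski.NumHDonors(mol) > 5)
        + (Lipinski.NumHAcceptors(mol) > 10)
    )


def n_rotatable_bonds(mol: Chem.Mol) -> int:
    """Strict rotatable-bond count (amides and terminal bonds excluded)."""
    return int(rdMolDescriptors.CalcNumRotatableBonds(
        mol, rdMolDescriptors.NumRotatableBondsOptions.Strict))


def max_fused_ring_system(mol: Chem.Mol) -> int:
    """Size of the largest fused ring system.

    SSSR rings are nodes; two rings are connected when they share at least one
    bond.  Returns the largest connected-component size (0 for acyclic
    molecules), so an anthracene scores 3 and a spiro junction does not fuse.
    """
    rings = mol.GetRingInfo().BondRings()
    n = len(rings)
    if n == 0:
        return 0
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    ring_sets = [set(r) for r in rings]
    for i in range(n):
        for j in range(i + 1, n):
            if ring_sets[i] & ring_sets[j]:
                parent[find(i)] = find(j)
    sizes: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values())


def apply_structural_alerts(smiles: str, alert_set: AlertSet) -> list[str]:
    """Names of all alert patterns matching the molecule (deduplicated)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return alert_set.match(mol)


def apply_pool_filters(record: MoleculeRecord,
                       cfg: FilterConfig) -> tuple[bool, list[str]]:
    """Evaluate the pool-filter conjunction on a diagnosed record.

    Returns ``(pool_pass, reasons)`` and updates the record in place.  The
    reasons list names every violated predicate (``mw_min``, ``mw_max``,
    ``qed_min``, ``qed_max``, ``ro5``, ``alert``); predicates are independent,
    so evaluation order cannot change the outcome.
    """
    reasons = []
    if record.mw < cfg.mw_min:
        reasons.append("mw_min")
    if record.mw > cfg.mw_max:
        reasons.append("mw_max")
    if record.qed < cfg.qed_min:
        reasons.append("qed_min")
    if record.qed > cfg.qed_max:
        reasons.append("qed_max")
    if record.ro5_violations > cfg.max_ro5_violations:
        reasons.append("ro5")
    if record.alert_hits:
        reasons.append("alert")
    record.pool_pass = not reasons
    record.reasons = reasons
    return record.pool_pass, reasons


def make_record(mol_id: str, smiles_raw: str, cfg: FilterConfig) -> MoleculeRecord:
    """Standardize one SMILES and compute all diagnostics and filter status."""
    record = MoleculeRecord(id=str(mol_id), smiles_raw=smiles_raw)
    record.smiles_canonical = standardize_molecule(
        smiles_raw, canonicalize_tautomer=cfg.canonicalize_tautomer)
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    record.mw = float(Descriptors.MolWt(mol))
    record.qed = float(QED.qed(mol))
    record.ro5_violations = ro5_violations(mol)
    record.n_rotatable = n_rotatable_bonds(mol)
    record.max_fused_system = max_fused_ring_system(mol)
    record.alert_hits = cfg.alert_set.match(mol)
    apply_pool_filters(record, cfg)
    return record


def curate_pool(smiles: Iterable[str] | Sequence[tuple[str, str]],
                cfg: FilterConfig | None = None,
                ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Curate an iterable of SMILES into a diagnostics table.

    Unparseable entries are dropped with a logged warning rather than
    aborting the batch.  Returns a DataFrame with one row per surviving
    molecule and the columns in :data:`RECORD_COLUMNS`.
    """
    cfg = cfg or FilterConfig()
    smiles = list(smiles)
    if ids is None:
        ids = [f"mol{i:06d}" for i in range(len(smiles))]
    rows = []
    for mol_id, smi in zip(ids, smiles):
        try:
            rec = make_record(mol_id, smi, cfg)
        except ParseError as exc:
            logger.warning("dropping %s: %s", mol_id, exc)
            continue
        rows.append({
            "id": rec.id, "smiles_raw": rec.smiles_raw,
            "smiles_canonical": rec.smiles_canonical, "mw": rec.mw,
            "qed": rec.qed, "ro5_violations": rec.ro5_violations,
            "n_rotatable": rec.n_rotatable,
            "max_fused_system": rec.max_fused_system,
            "alert_hits": ";".join(rec.alert_hits),
            "pool_pass": rec.pool_pass, "reasons": ";".join(rec.reasons),
        })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def read_smiles_file(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a .smi (one SMILES per line, optional id) or CSV with a smiles column.

    Returns ``(smiles, ids)``.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if "smiles" not in df.columns:
            raise ValueError(f"{path} has no 'smiles' column")
        ids = df["id"].astype(str).tolist() if "id" in df.columns else [
            f"mol{i:06d}" for i in range(len(df))]
        return df["smiles"].astype(str).tolist(), ids
    smiles, ids = [], []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            smiles.append(parts[0])
            ids.append(parts[1] if len(parts) > 1 else f"mol{i:06d}")
    return smiles, ids
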