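"""Screening-funnel utilities: docking-score triage, residue-interaction
aggregation, rule-based druglikeness checks and formula molecular weights.

The triage stage mirrors a structure-based pre-screen: compounds are ranked
by their best docking pose, the top fraction is kept, and compounds with too
few docked conformations are discarded (multiple poses indicate a robust
binding mode).  Druglikeness is the classic five-rule check: MW < 500,
H-bond donors < 5, H-bond acceptors < 10 (N+O counts), LogP < 5 (LogP must
be supplied — it is never predicted here), and at most 10 rotatable bonds.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Lipinski, rdMolDescriptors, Descriptors

from .chemio import Compound, DockingPoseTable, InteractionRecord, INTERACTION_TYPES

logger = logging.getLogger(__name__)


@dataclass
class TriageResult:
    selected_ids: list[str]  # sorted by best_score descending
    fraction: float
    min_poses: int
    best_score: dict[str, float]
    pose_count: dict[str, int]
    n_before_pose_filter: int = 0


def select_top(
    table: DockingPoseTable, fraction: float = 0.01, min_poses: int = 2
) -> TriageResult:
    """Keep the top ``ceil(fraction * n_compounds)`` by best pose score, then
    drop compounds with fewer than *min_poses* docked poses.

    Ties at the cut break by (score descending, compound_id ascending).
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(table) == 0:
        raise ValueError("empty docking table")
    grouped = table.frame.groupby("compound_id")["score"]
    best = grouped.max()
    n_poses = grouped.size()
    n_compounds = len(best)
    n_keep = math.ceil(fraction * n_compounds)
    ranked = sorted(best.index, key=lambda cid: (-best[cid], cid))
    cut = ranked[:n_keep]
    selected = [cid for cid in cut if n_poses[cid] >= min_poses]
    logger.info(
        "triage: %d compounds, top %d by score, %d after >=%d-pose filter",
        n_compounds, n_keep, len(selected), min_poses,
    )
    return TriageResult(
        selected_ids=selected,
        fraction=fraction,
        min_poses=min_poses,
        best_score={cid: float(best[cid]) for cid in cut},
        pose_count={cid: int(n_poses[cid]) for cid in cut},
        n_before_pose_filter=n_keep,
    )


def aggregate_interactions(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    """Residue x interaction-type count matrix with a per-residue total.

    Rows are ordered by total count descending, then residue number
    ascending; returns an empty frame for an empty record list.
    """
    cols = list(INTERACTION_TYPES) + ["total"]
    if not records:
        return pd.DataFrame(columns=cols)
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        row = counts.setdefault(r.residue, {t: 0 for t in INTERACTION_TYPES})
        row[r.interaction_type] += 1
    frame = pd.DataFrame.from_dict(counts, orient="index")[list(INTERACTION_TYPES)]
    frame["total"] = frame.sum(axis=1)

    def resnum(residue: str) -> int:
        return int(re.search(r"\d+", residue).group())

    order = sorted(frame.index, key=lambda r: (-frame.loc[r, "total"], resnum(r)))
    return frame.loc[order]


@dataclass(frozen=True)
class DruglikenessReport:
    mw: float
    hbd: int
    hba: int
    rotatable_bonds: int
    logp_input: Optional[float]
    violations: tuple[str, ...]
    logp_skipped: bool = False

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def count_rotatable_bonds(mol: Chem.Mol) -> int:
    """Non-ring single bonds between heavy atoms, excluding terminal bonds
    and amide C-N bonds."""
    return rdMolDescriptors.CalcNumRotatableBonds(mol)


def lipinski(compound: Compound | str, logp: Optional[float] = None) -> DruglikenessReport:
    """Five-rule druglikeness check.

    HBD is the N-H/O-H count and HBA the N+O count (the classic definitions).
    The LogP rule needs an externally supplied value; when absent it is
    skipped and flagged in the report rather than silently passed.
    """
    if isinstance(compound, Compound):
        mol = compound.mol()
    else:
        mol = Chem.MolFromSmiles(compound)
        if mol is None:
            raise ValueError(f"unparseable structure {compound!r}")
    mw = Descriptors.MolWt(mol)
    hbd = Lipinski.NHOHCount(mol)  # N-H and O-H bonds
    hba = Lipinski.NOCount(mol)  # N + O atoms
    rot = count_rotatable_bonds(mol)
    violations = []
    if not mw < 500:
        violations.append("MW<500")
    if not hbd < 5:
        violations.append("HBD<5")
    if not hba < 10:
        violations.append("HBA<10")
    logp_skipped = logp is None
    if logp is not None and not logp < 5:
        violations.append("LogP<5")
    if logp_skipped:
        logger.warning("LogP not supplied; LogP<5 rule skipped")
    if not rot <= 10:
        violations.append("RotB<=10")
    return DruglikenessReport(
        mw=mw, hbd=hbd, hba=hba, rotatable_bonds=rot,
        logp_input=logp, violations=tuple(violations), logp_skipped=logp_skipped,
    )


#: IUPAC conventional atomic weights (5 significant figures).
ATOMIC_WEIGHTS = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Fe": 55.845, "Cu": 63.546, "Zn": 65.38, "Se": 78.971, "Br": 79.904,
    "I": 126.90, "Sn": 118.71, "Mn": 54.938, "Co": 58.933, "Ni": 58.693,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def mw_from_formula(formula: str) -> float:
    """Molecular weight (g/mol) from a molecular formula like ``C26H30N2O2``.

    Hill order is not required; unknown element symbols raise.
    """
    pos = 0
    total = 0.0
    matched = False
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        symbol, count = m.group(1), m.group(2)
        if not symbol:
            continue
        if symbol not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element symbol {symbol!r} in {formula!r}")
        total += ATOMIC_WEIGHTS[symbol] * (int(count) if count else 1)
        matched = True
        pos = m.end()
        if pos == len(formula):
            break
    if not matched or pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return total
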