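"""Synthetic compound libraries and docking tables for pipeline validation.

Libraries are built by decorating drug-like scaffold templates with small
substituent fragments, which guarantees valid molecules without rejection
storms.  "Active" compounds carry an implanted marker substructure (by
default an NH-pyrrole ring, an ethyl ester, or a glycol-diether motif) with
a controllable probability, so the structural signal separating the classes
can be dialed from perfect (implant rate 1 vs 0) down to none (equal rates,
the null condition).  Potencies (pXC50) are drawn from two overlapping
normals — actives N(6.5, 0.7), inactives N(4.0, 0.7), truncated at 0 — so
the >5 activity rule reproduces the labels exactly at full signal and
introduces natural label noise at partial signal.  The default class ratio
is 1:2 active:inactive, the imbalance typical of curated bioactivity sets.

Everything is deterministic per seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemio import Compound, CompoundSet, DockingPoseTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImplantMotif:
    """A substituent fragment and the SMARTS that detects it.

    Fragment SMILES use ring-closure digits 8/9 so they can be spliced into
    scaffold templates (which use 1/2) without clashes.
    """

    fragment: str
    smarts: str

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS {self.smarts!r}")
        return patt


#: Default implant pool: N-containing five-membered ring, ester, diether.
DEFAULT_IMPLANTS = (
    ImplantMotif(fragment="c8cc[nH]c8", smarts="c1cc[nH]c1"),
    ImplantMotif(fragment="C(=O)OCC", smarts="C(=O)OCC"),
    ImplantMotif(fragment="OCCOC", smarts="OCCOC"),
)

# Scaffold templates with two substituent slots ({A}, {B}).
SCAFFOLDS = (
    "c1ccc({A})cc1{B}",
    "c1ccnc({A})c1{B}",
    "C1CCN({A})CC1{B}",
    "c1ccc2ccc({A})cc2c1{B}",
    "C1CCC({A})CC1{B}",
    "c1csc({A})c1{B}",
    "c1ccc({A})nc1{B}",
    "C1CN({A})CCN1{B}",
)

# Plain substituents; none matches a default implant SMARTS.
SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "O", "OC", "N", "NC", "N(C)C",
    "Cl", "F", "Br", "C#N", "C(=O)NC", "S(=O)(=O)C", "C(F)(F)F",
    "c8ccccc8", "c8ccncc8", "C(=O)O", "CO",
)


@dataclass
class LibrarySpec:
    """Parameters of one synthetic screening library."""

    n_active: int
    n_inactive: int
    seed: int
    implant_rate_active: float = 1.0
    implant_rate_inactive: float = 0.0
    implant_pool: Sequence[ImplantMotif] = DEFAULT_IMPLANTS
    scaffold_pool_size: int = len(SCAFFOLDS)
    pxc50_active: tuple[float, float] = (6.5, 0.7)
    pxc50_inactive: tuple[float, float] = (4.0, 0.7)

    def __post_init__(self) -> None:
        for r in (self.implant_rate_active, self.implant_rate_inactive):
            if not (0.0 <= r <= 1.0):
                raise ValueError("implant rates must lie in [0, 1]")
        if self.n_active < 0 or self.n_inactive < 0:
            raise ValueError("class sizes must be non-negative")
        if not (1 <= self.scaffold_pool_size <= len(SCAFFOLDS)):
            raise ValueError(f"scaffold_pool_size must be in [1, {len(SCAFFOLDS)}]")

    @property
    def full_signal(self) -> bool:
        return self.implant_rate_active == 1.0 and self.implant_rate_inactive == 0.0


class GenerationError(RuntimeError):
    pass


def _assemble(rng: np.random.Generator, scaffolds: Sequence[str],
              implant: Optional[str]) -> Optional[str]:
    template = scaffolds[rng.integers(len(scaffolds))]
    a = implant if implant is not None else SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
    b = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
    smi = template.format(A=a, B=b)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float = 0.0, high: Optional[float] = None,
                      max_tries: int = 1000) -> float:
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if x > low and (high is None or x <= high):
            return float(x)
    raise GenerationError(f"could not draw truncated normal({mean}, {sd})")


def generate_library(spec: LibrarySpec) -> CompoundSet:
    """Build a labeled compound library per *spec*.

    Each compound is a decorated scaffold; actives carry an implant motif
    with probability ``implant_rate_active`` (inactives with
    ``implant_rate_inactive``).  A compound generated *without* an implant is
    redrawn if it accidentally matches an implant SMARTS, so the zero-rate
    guarantee is exact.  pXC50 values are flag-consistent under the >5 rule
    at full signal; at partial signal the class overlap is left in place.
    """
    rng = np.random.default_rng(spec.seed)
    scaffolds = SCAFFOLDS[: spec.scaffold_pool_size]
    patterns = [(m, m.pattern()) for m in spec.implant_pool]
    compounds: list[Compound] = []
    for label, n, rate, (mu, sd) in (
        ("active", spec.n_active, spec.implant_rate_active, spec.pxc50_active),
        ("inactive", spec.n_inactive, spec.implant_rate_inactive, spec.pxc50_inactive),
    ):
        for i in range(n):
            implant = None
            if rng.random() < rate:
                implant = spec.implant_pool[rng.integers(len(spec.implant_pool))].fragment
            smiles = None
            for _ in range(50):
                cand = _assemble(rng, scaffolds, implant)
                if cand is None:
                    continue
                if implant is None:
                    mol = Chem.MolFromSmiles(cand)
                    if any(mol.HasSubstructMatch(p) for _, p in patterns):
                        continue  # accidental implant; redraw
                smiles = cand
                break
            if smiles is None:
                raise GenerationError(
                    f"failed to assemble a valid {label} compound after 50 tries"
                )
            if spec.full_signal:
                low, high = (5.0, None) if label == "active" else (0.0, 5.0)
                pxc50 = _truncated_normal(rng, mu, sd, low=low, high=high)
            else:
                pxc50 = _truncated_normal(rng, mu, sd, low=0.0)
            compounds.append(
                Compound(id=f"{label[:3]}{i + 1:05d}", smiles=smiles,
                         pxc50=pxc50, activity_flag=label)
            )
    prov = (
        f"synthetic library seed={spec.seed} n_active={spec.n_active} "
        f"n_inactive={spec.n_inactive} implant_rates="
        f"({spec.implant_rate_active},{spec.implant_rate_inactive})"
    )
    return CompoundSet(compounds=compounds, provenance=prov)


def generate_docking_table(
    cset: CompoundSet,
    poses_per_compound: tuple[int, int] = (1, 10),
    score_bias_for_pattern: Optional[tuple[str, float]] = None,
    seed: int = 0,
    base_score_mean: float = 90.0,
    base_score_sd: float = 15.0,
    pose_sd: float = 5.0,
) -> DockingPoseTable:
    """Synthetic per-pose docking scores for a compound set.

    Pose counts are uniform over ``poses_per_compound`` (inclusive); each
    pose score is normal around a per-compound base score, which is shifted
    by the given amount for compounds matching the optional SMARTS pattern.
    Larger scores mean better poses.  Deterministic per seed.
    """
    if len(cset) == 0:
        raise ValueError("empty compound set")
    lo, hi = poses_per_compound
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid pose range {poses_per_compound}")
    patt = None
    shift = 0.0
    if score_bias_for_pattern is not None:
        smarts, shift = score_bias_for_pattern
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS {smarts!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for c in cset:
        base = rng.normal(base_score_mean, base_score_sd)
        if patt is not None and c.mol().HasSubstructMatch(patt):
            base += shift
        n_poses = int(rng.integers(lo, hi + 1))
        for p in range(n_poses):
            rows.append((c.id, f"pose{p + 1}", float(rng.normal(base, pose_sd))))
    frame = pd.DataFrame(rows, columns=["compound_id", "pose_id", "score"])
    return DockingPoseTable(frame=frame)


def generate_interaction_records(
    cset: CompoundSet,
    residues: Sequence[str] = ("Leu178", "Ile399", "Arg402", "Ala403", "Leu407", "Ile592"),
    mean_contacts: float = 3.0,
    seed: int = 0,
):
    """Synthetic ligand-residue contact records, Poisson counts per residue.

    Hydrophobic contacts dominate, echoing the contact statistics of a
    lipoxygenase binding pocket.
    """
    from .chemio import InteractionRecord

    rng = np.random.default_rng(seed)
    types = ("hydrophobic", "hydrogen_bond", "electrostatic", "other")
    probs = (0.7, 0.2, 0.05, 0.05)
    records = []
    for c in cset:
        for res in residues:
            for _ in range(rng.poisson(mean_contacts)):
                t = types[rng.choice(len(types), p=probs)]
                records.append(InteractionRecord(compound_id=c.id, residue=res, interaction_type=t))
    return records
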