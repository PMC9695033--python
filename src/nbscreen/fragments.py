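"""Good/bad fragment (GF/BF) enrichment analysis over ECFP identifiers.

Each distinct circular-fingerprint identifier occurring in a classified
compound set is tabulated with its occurrence count, frequency, an exemplar
substructure (the atom environment that produced it, exported as SMILES),
and — when a fitted Bayes model is supplied — the model's weight for that
identifier.  Ranking by weight (or frequency when no model is given) yields
the "good fragments" driving active calls and the "bad fragments" driving
inactive calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from rdkit import Chem

from .chemio import CompoundSet
from .fingerprints import ecfp_with_environments
from .nbayes import BayesModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentScore:
    identifier: int
    exemplar: str  # SMILES of the atom environment, central atom first
    n_in_set: int
    frequency: float
    bayes_weight: Optional[float] = None


def environment_smiles(mol: Chem.Mol, atom_idx: int, radius: int) -> str:
    """SMILES of the circular environment around *atom_idx* out to *radius*."""
    if radius == 0:
        return Chem.MolFragmentToSmiles(mol, atomsToUse=[atom_idx], rootedAtAtom=atom_idx, canonical=True)
    bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx)
    if not bonds:
        return Chem.MolFragmentToSmiles(mol, atomsToUse=[atom_idx], rootedAtAtom=atom_idx, canonical=True)
    atoms = set()
    for b in bonds:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return Chem.MolFragmentToSmiles(
        mol, atomsToUse=sorted(atoms), bondsToUse=list(bonds), rootedAtAtom=atom_idx, canonical=True
    )


def fragment_table(
    cset: CompoundSet,
    diameter: int = 6,
    model: Optional[BayesModel] = None,
) -> list[FragmentScore]:
    """One entry per distinct ECFP identifier occurring in *cset*.

    The exemplar substructure is extracted from the identifier's first
    occurrence; if a later occurrence yields a different environment SMILES
    for the same identifier, the hash collision is logged.
    """
    if len(cset) == 0:
        raise ValueError("empty compound set")
    counts: dict[int, int] = {}
    exemplar: dict[int, str] = {}
    for c in cset:
        mol = c.mol()
        fp, envs = ecfp_with_environments(mol, diameter)
        for ident in fp.identifiers:
            counts[ident] = counts.get(ident, 0) + 1
            atom_idx, radius = envs[ident][0]
            smi = environment_smiles(mol, atom_idx, radius)
            if ident not in exemplar:
                exemplar[ident] = smi
            elif exemplar[ident] != smi:
                logger.info(
                    "identifier %d collision: %r vs %r", ident, exemplar[ident], smi
                )
    n = len(cset)
    table = []
    for ident, cnt in counts.items():
        w = model.weights.get(f"ecfp:{ident}") if model is not None else None
        table.append(
            FragmentScore(
                identifier=ident,
                exemplar=exemplar[ident],
                n_in_set=cnt,
                frequency=cnt / n,
                bayes_weight=w,
            )
        )
    return table


def top_fragments(
    table: Sequence[FragmentScore], n: int = 10, direction: str = "good"
) -> list[FragmentScore]:
    """Top-*n* fragments by Bayes weight (or frequency when unavailable).

    ``direction="good"`` ranks descending, ``"bad"`` ascending.  Ties break
    deterministically by (occurrence count descending, identifier ascending).
    """
    if direction not in {"good", "bad"}:
        raise ValueError(f"direction must be 'good' or 'bad', got {direction!r}")
    sign = -1.0 if direction == "good" else 1.0

    def sort_key(f: FragmentScore):
        primary = f.bayes_weight if f.bayes_weight is not None else f.frequency
        return (sign * primary, -f.n_in_set, f.identifier)

    return sorted(table, key=sort_key)[:n]


def export_fragment_table(table: Sequence[FragmentScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("identifier\texemplar\tcount\tfrequency\tbayes_weight\n")
        for f in table:
            w = "" if f.bayes_weight is None else repr(f.bayes_weight)
            fh.write(f"{f.identifier}\t{f.exemplar}\t{f.n_in_set}\t{f.frequency!r}\t{w}\n")
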