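"""Circular fingerprints and Tanimoto similarity/diversity.

ECFP_n fingerprints are sparse sets of hashed atom-environment identifiers
produced by Morgan-style iterative neighborhood hashing seeded with
Daylight-style atomic invariants (element, heavy-atom degree, attached
hydrogens, formal charge, ring membership).  The ``n`` in ECFP_n is the
environment *diameter*: ECFP_2 hashes to radius 1, ECFP_6 to radius 3.
Identifiers are kept sparse and unfolded so that each one maps back to a
unique depictable substructure for fragment analysis.

The mean pairwise Tanimoto coefficient over a library quantifies its
structural diversity: low values (the training sets typical of ligand-based
screening sit near 0.1) indicate broad chemical-space coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chemio import Compound, CompoundSet

logger = logging.getLogger(__name__)

#: Above this many pairs, dataset_diversity switches to seeded pair sampling.
DEFAULT_PAIR_BUDGET = 2_000_000


@dataclass(frozen=True)
class Fingerprint:
    """Sparse binary circular fingerprint of one compound."""

    identifiers: frozenset[int]
    radius: int

    def __len__(self) -> int:
        return len(self.identifiers)


@dataclass(frozen=True)
class DiversityReport:
    mean_pairwise_tc: float
    n_compounds: int
    n_pairs: int
    sampled: bool = False

    def __post_init__(self) -> None:
        if not self.sampled and self.n_pairs != self.n_compounds * (self.n_compounds - 1) // 2:
            raise ValueError("n_pairs inconsistent with n_compounds for exact mode")


def _radius_for(diameter: int) -> int:
    if diameter < 0 or diameter % 2 != 0:
        raise ValueError(f"ECFP diameter must be even and >= 0, got {diameter}")
    return diameter // 2


def ecfp(compound: Compound | Chem.Mol | str, diameter: int) -> Fingerprint:
    """ECFP fingerprint of *compound* at the given even *diameter*.

    Returns the set of distinct environment identifiers over all radii from
    0 to diameter/2, so the identifier set at a larger diameter is a superset
    of the smaller-diameter set (monotone accumulation).
    """
    radius = _radius_for(diameter)
    mol = _as_mol(compound)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    sparse = gen.GetSparseCountFingerprint(mol)
    return Fingerprint(identifiers=frozenset(sparse.GetNonzeroElements()), radius=radius)


def ecfp_with_environments(
    compound: Compound | Chem.Mol | str, diameter: int
) -> tuple[Fingerprint, dict[int, tuple[tuple[int, int], ...]]]:
    """Fingerprint plus identifier -> ((atom_index, radius), ...) map.

    The environment map lets fragment analysis extract, for any identifier,
    the substructure (central atom out to its radius) that produced it.
    """
    radius = _radius_for(diameter)
    mol = _as_mol(compound)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    extra = rdFingerprintGenerator.AdditionalOutput()
    extra.AllocateBitInfoMap()
    sparse = gen.GetSparseCountFingerprint(mol, additionalOutput=extra)
    fp = Fingerprint(identifiers=frozenset(sparse.GetNonzeroElements()), radius=radius)
    return fp, dict(extra.GetBitInfoMap())


def _as_mol(compound: Compound | Chem.Mol | str) -> Chem.Mol:
    if isinstance(compound, Chem.Mol):
        return compound
    if isinstance(compound, Compound):
        return compound.mol()
    mol = Chem.MolFromSmiles(compound)
    if mol is None:
        raise ValueError(f"unparseable SMILES {compound!r}")
    return mol


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over identifier sets.

    Two empty fingerprints are identical objects and score 1.0.
    """
    if a.radius != b.radius:
        raise ValueError(f"radius mismatch: {a.radius} vs {b.radius}")
    union = len(a.identifiers | b.identifiers)
    if union == 0:
        logger.debug("tanimoto of two empty fingerprints; defined as 1.0")
        return 1.0
    return len(a.identifiers & b.identifiers) / union


def dataset_diversity(
    cset: CompoundSet,
    diameter: int = 2,
    pair_budget: int = DEFAULT_PAIR_BUDGET,
    seed: Optional[int] = None,
) -> DiversityReport:
    """Mean pairwise Tanimoto coefficient over all unordered compound pairs.

    Exact up to *pair_budget* pairs; beyond that a seeded uniform sample of
    pairs is averaged and the report is marked as sampled.
    """
    n = len(cset)
    if n < 2:
        raise ValueError("diversity needs at least 2 compounds")
    fps = [ecfp(c, diameter) for c in cset]
    total_pairs = n * (n - 1) // 2
    if total_pairs <= pair_budget:
        acc = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                acc += tanimoto(fps[i], fps[j])
        return DiversityReport(acc / total_pairs, n, total_pairs, sampled=False)

    rng = np.random.default_rng(seed)
    acc = 0.0
    for _ in range(pair_budget):
        i, j = rng.choice(n, size=2, replace=False)
        acc += tanimoto(fps[i], fps[j])
    logger.info("diversity sampled %d of %d pairs", pair_budget, total_pairs)
    return DiversityReport(acc / pair_budget, n, pair_budget, sampled=True)


def duplicate_structures(train: CompoundSet, screen: CompoundSet) -> list[tuple[str, str]]:
    """Exact canonical-SMILES duplicates between a training and screening set.

    Returns (train_id, screen_id) pairs; used to guard against information
    leakage between the model's training data and the library it scores.
    """
    from .chemio import canonicalize

    by_smiles: dict[str, list[str]] = {}
    for c in train:
        by_smiles.setdefault(canonicalize(c.smiles), []).append(c.id)
    hits = []
    for c in screen:
        for tid in by_smiles.get(canonicalize(c.smiles), []):
            hits.append((tid, c.id))
    return hits


def export_fingerprints(cset: CompoundSet, diameter: int, path) -> None:
    """Audit export: one line per compound, tab-separated sorted identifiers."""
    with open(path, "w") as fh:
        fh.write("compound_id\tidentifiers\n")
        for c in cset:
            fp = ecfp(c, diameter)
            fh.write(f"{c.id}\t{','.join(map(str, sorted(fp.identifiers)))}\n")
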