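"""Molecular descriptors, activity-correlation filtering and PCA coordinates.

The descriptor registry covers the eight key descriptors the screening model
uses — three Kier–Hall electrotopological atom-type counts (aromatic N with a
substituent, aromatic O, terminal =CH2), aromatic-ring and ring counts,
fractional polar surface area (TPSA / total Labute surface area), a chirality
indicator and the QED druglikeness score — plus a panel of standard
physicochemical descriptors.  Descriptors weakly correlated with the activity
flag are dropped (|Pearson r| threshold), and the survivors are standardized
and projected by PCA for chemical-space inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, QED, rdMolDescriptors
from sklearn.decomposition import PCA

from .chemio import CompoundSet

logger = logging.getLogger(__name__)

KEY_DESCRIPTORS = (
    "ES_Count_aasN",
    "ES_Count_aaO",
    "ES_Count_dCH2",
    "Num_AromaticRings",
    "Molecular_FractionalPolarSurfaceArea",
    "IsChiral",
    "Num_Rings",
    "QED",
)

# Kier-Hall E-state atom types, as SMARTS over the hydrogen-suppressed graph:
#   aasN: aromatic N bonded to two aromatic neighbors plus one substituent
#   aaO : aromatic O (two aromatic bonds)
#   dCH2: terminal methylene, =CH2
_AASN = Chem.MolFromSmarts("[nD3]")
_AAO = Chem.MolFromSmarts("[oD2]")
_DCH2 = Chem.MolFromSmarts("[CX3;H2]=[*]")


def _count(mol: Chem.Mol, patt: Chem.Mol) -> int:
    return len({m[0] for m in mol.GetSubstructMatches(patt, uniquify=False)})


def _is_chiral(mol: Chem.Mol) -> int:
    centers = Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
    return int(len(centers) > 0)


def _fractional_psa(mol: Chem.Mol) -> float:
    """Polar fraction of the Labute approximate surface area.

    The share of the molecule's total (2D-approximated) surface contributed
    by nitrogen and oxygen atoms; in [0, 1] by construction.  TPSA itself is
    not used as the numerator because it is parameterized on a different
    scale than any total-surface estimate (for small polar molecules TPSA
    can exceed the whole Labute ASA).
    """
    contribs, h_contrib = rdMolDescriptors._CalcLabuteASAContribs(mol)
    total = sum(contribs) + h_contrib
    if total <= 0:
        return 0.0
    polar = sum(
        c for atom, c in zip(mol.GetAtoms(), contribs) if atom.GetAtomicNum() in (7, 8)
    )
    return polar / total


#: name -> function(mol) -> float.  Extensible via register_descriptor().
DESCRIPTOR_REGISTRY: dict[str, Callable[[Chem.Mol], float]] = {
    "ES_Count_aasN": lambda m: _count(m, _AASN),
    "ES_Count_aaO": lambda m: _count(m, _AAO),
    "ES_Count_dCH2": lambda m: _count(m, _DCH2),
    "Num_AromaticRings": rdMolDescriptors.CalcNumAromaticRings,
    "Molecular_FractionalPolarSurfaceArea": _fractional_psa,
    "IsChiral": _is_chiral,
    "Num_Rings": rdMolDescriptors.CalcNumRings,
    "QED": QED.qed,
    # standard physicochemical panel
    "Molecular_Weight": Descriptors.MolWt,
    "ALogP": Crippen.MolLogP,
    "Molecular_PolarSurfaceArea": rdMolDescriptors.CalcTPSA,
    "Molecular_SurfaceArea": rdMolDescriptors.CalcLabuteASA,
    "Num_H_Donors": rdMolDescriptors.CalcNumHBD,
    "Num_H_Acceptors": rdMolDescriptors.CalcNumHBA,
    "Num_RotatableBonds": rdMolDescriptors.CalcNumRotatableBonds,
    "Num_HeavyAtoms": lambda m: m.GetNumHeavyAtoms(),
    "Num_AromaticAtoms": lambda m: sum(a.GetIsAromatic() for a in m.GetAtoms()),
    "Num_Nitrogens": lambda m: sum(a.GetAtomicNum() == 7 for a in m.GetAtoms()),
    "Num_Oxygens": lambda m: sum(a.GetAtomicNum() == 8 for a in m.GetAtoms()),
    "Num_Halogens": lambda m: sum(a.GetAtomicNum() in (9, 17, 35, 53) for a in m.GetAtoms()),
    "Fraction_Csp3": rdMolDescriptors.CalcFractionCSP3,
    "Num_SaturatedRings": rdMolDescriptors.CalcNumSaturatedRings,
}


def register_descriptor(name: str, fn: Callable[[Chem.Mol], float]) -> None:
    DESCRIPTOR_REGISTRY[name] = fn


@dataclass
class DescriptorTable:
    """compound_id-indexed table of named real-valued descriptors."""

    frame: pd.DataFrame  # index: compound_id; columns: descriptor names

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="compound_id")

    @classmethod
    def from_csv(cls, path) -> "DescriptorTable":
        return cls(pd.read_csv(path, sep="\t", index_col="compound_id"))


def compute_descriptors(
    cset: CompoundSet, names: Sequence[str] = KEY_DESCRIPTORS
) -> DescriptorTable:
    """One descriptor row per compound.

    Unknown descriptor names raise a registry error listing what is
    supported; compounds whose computation fails are dropped with a warning.
    """
    unknown = [n for n in names if n not in DESCRIPTOR_REGISTRY]
    if unknown:
        raise KeyError(
            f"unknown descriptors {unknown}; supported: {sorted(DESCRIPTOR_REGISTRY)}"
        )
    rows, index = [], []
    for c in cset:
        mol = c.mol()
        try:
            rows.append([float(DESCRIPTOR_REGISTRY[n](mol)) for n in names])
            index.append(c.id)
        except Exception as exc:  # descriptor failure drops the row, not the run
            logger.warning("descriptor computation failed for %s: %s", c.id, exc)
    frame = pd.DataFrame(rows, index=index, columns=list(names))
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)].tolist()
        logger.warning("dropping rows with missing descriptor values: %s", bad)
        frame = frame.dropna()
    return DescriptorTable(frame)


def correlation_filter(
    table: DescriptorTable,
    activity: Sequence[int] | Sequence[bool],
    min_abs_r: float = 0.1,
) -> list[str]:
    """Descriptor names whose |Pearson r| against the 0/1 activity flag
    reaches *min_abs_r*.  Zero-variance descriptors are dropped with a
    warning (their correlation is undefined)."""
    y = np.asarray(activity, dtype=float)
    if len(y) != len(table.frame):
        raise ValueError("activity flags do not align with descriptor rows")
    if len(y) < 3:
        raise ValueError("need at least 3 compounds for a correlation filter")
    retained = []
    y_c = y - y.mean()
    sy = float(np.sqrt((y_c**2).sum()))
    if sy == 0:
        raise ValueError("activity flag has zero variance")
    for name in table.descriptor_names:
        x = table.frame[name].to_numpy(dtype=float)
        x_c = x - x.mean()
        sx = float(np.sqrt((x_c**2).sum()))
        if sx == 0:
            logger.warning("descriptor %s has zero variance; dropped (r undefined)", name)
            continue
        r = float((x_c @ y_c) / (sx * sy))
        if abs(r) >= min_abs_r:
            retained.append(name)
    return retained


@dataclass
class PCAModel:
    """Standardize-then-PCA model with a deterministic sign convention."""

    component_loadings: np.ndarray  # (n_descriptors, n_components)
    explained_variance_fraction: np.ndarray
    explained_variance: np.ndarray  # eigenvalues of the standardized covariance
    centering_means: np.ndarray
    scaling_factors: np.ndarray
    descriptor_names: list[str]

    @property
    def n_components(self) -> int:
        return self.component_loadings.shape[1]

    def to_dict(self) -> dict:
        return {
            "component_loadings": self.component_loadings.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "centering_means": self.centering_means.tolist(),
            "scaling_factors": self.scaling_factors.tolist(),
            "descriptor_names": self.descriptor_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            component_loadings=np.asarray(d["component_loadings"], dtype=float),
            explained_variance_fraction=np.asarray(d["explained_variance_fraction"], dtype=float),
            explained_variance=np.asarray(d["explained_variance"], dtype=float),
            centering_means=np.asarray(d["centering_means"], dtype=float),
            scaling_factors=np.asarray(d["scaling_factors"], dtype=float),
            descriptor_names=list(d["descriptor_names"]),
        )


def _standardize(X: np.ndarray, means: np.ndarray, scales: np.ndarray) -> np.ndarray:
    return (X - means) / scales


def fit_pca(table: DescriptorTable, n_components: int = 5) -> PCAModel:
    """Fit PCA on the z-scored descriptor table.

    Descriptor units are incommensurate, so columns are centered and scaled
    to unit variance first.  *n_components* beyond the matrix rank is
    reduced automatically with a warning.  Each loading column's
    largest-magnitude element is made positive for reproducibility.
    """
    X = table.frame.to_numpy(dtype=float)
    n, p = X.shape
    if n_components > p:
        raise ValueError(f"n_components={n_components} exceeds {p} descriptors")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    if (scales == 0).any():
        zero = [table.descriptor_names[i] for i in np.flatnonzero(scales == 0)]
        raise ValueError(f"zero-variance descriptors must be filtered first: {zero}")
    Z = _standardize(X, means, scales)
    rank = int(np.linalg.matrix_rank(Z - Z.mean(axis=0)))
    k = n_components
    if k > rank:
        logger.warning("n_components=%d exceeds rank %d; reduced", k, rank)
        k = rank
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T.copy()  # (p, k)
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAModel(
        component_loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        explained_variance=pca.explained_variance_.copy(),
        centering_means=means,
        scaling_factors=scales,
        descriptor_names=table.descriptor_names,
    )


def choose_n_components(
    model: PCAModel, min_cumulative_fraction: float = 0.9, cap: int = 5
) -> int:
    """Smallest k with cumulative explained variance >= the target, capped."""
    cum = np.cumsum(model.explained_variance_fraction)
    k = int(np.searchsorted(cum, min_cumulative_fraction) + 1)
    return min(k, cap, model.n_components)


def project(model: PCAModel, table: DescriptorTable) -> pd.DataFrame:
    """Chemical-space coordinates (PC1..PCk) of *table* under *model*."""
    if list(table.descriptor_names) != model.descriptor_names:
        raise ValueError("descriptor columns do not match the fitted model")
    Z = _standardize(table.frame.to_numpy(dtype=float), model.centering_means, model.scaling_factors)
    scores = Z @ model.component_loadings
    cols = [f"PC{i + 1}" for i in range(model.n_components)]
    return pd.DataFrame(scores, index=table.frame.index, columns=cols)


def inverse_transform(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Map PC scores back to the original descriptor units."""
    Z = np.asarray(scores, dtype=float) @ model.component_loadings.T
    return Z * model.scaling_factors + model.centering_means
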