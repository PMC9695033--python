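"""Compound, table and model I/O.

Reads SMILES (.smi) and SDF compound libraries into :class:`CompoundSet`,
assigns active/inactive flags from pXC50 potencies, and round-trips trained
models through a versioned JSON document.  Structures are sanitized and
canonicalized on load so that downstream fingerprints and duplicate checks
are representation-independent.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

#: pXC50 above which a compound is called active (pXC50 > 5 <=> XC50 <= 10 uM).
DEFAULT_ACTIVITY_THRESHOLD = 5.0

MODEL_SCHEMA = "nbscreen-model/1"

_RESIDUE_RE = re.compile(r"^[A-Za-z]{1,3}\d+$")

INTERACTION_TYPES = ("hydrophobic", "hydrogen_bond", "electrostatic", "other")


class EmptyInputError(ValueError):
    """No valid records in an input file."""


class ModelFormatError(ValueError):
    """Model file is malformed or has an unexpected schema version."""


@dataclass
class Compound:
    """A single library member.

    Attributes
    ----------
    id:
        Unique identifier within a :class:`CompoundSet`.
    smiles:
        Canonical SMILES (canonicalized by :func:`canonicalize`).
    pxc50:
        Optional potency, -log10 of the XC50 in mol/L.
    activity_flag:
        Optional ``"active"`` / ``"inactive"`` label.
    """

    id: str
    smiles: str
    pxc50: Optional[float] = None
    activity_flag: Optional[Literal["active", "inactive"]] = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - canonical SMILES always reparses
            raise ValueError(f"stored SMILES failed to parse for {self.id!r}")
        return m


@dataclass
class CompoundSet:
    """Ordered collection of compounds with unique ids."""

    compounds: list[Compound] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compounds]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self.compounds)

    def __getitem__(self, i: int) -> Compound:
        return self.compounds[i]

    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    def labels(self) -> list[str]:
        """Activity flags in set order; raises if any compound is unflagged."""
        out = []
        for c in self.compounds:
            if c.activity_flag is None:
                raise ValueError(f"compound {c.id!r} has no activity flag")
            out.append(c.activity_flag)
        return out


@dataclass
class DockingPoseTable:
    """Per-pose docking scores; larger score = better pose."""

    frame: pd.DataFrame  # columns: compound_id, pose_id, score

    def __post_init__(self) -> None:
        required = {"compound_id", "pose_id", "score"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"docking table missing columns: {sorted(missing)}")
        if self.frame.duplicated(["compound_id", "pose_id"]).any():
            raise ValueError("duplicate (compound_id, pose_id) pairs")
        import numpy as np

        if not np.isfinite(self.frame["score"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite docking scores")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class InteractionRecord:
    """One ligand-residue contact observation."""

    compound_id: str
    residue: str  # e.g. "Arg402"
    interaction_type: str

    def __post_init__(self) -> None:
        if not _RESIDUE_RE.match(self.residue):
            raise ValueError(f"malformed residue {self.residue!r}")
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")


def canonicalize(smiles: str) -> Optional[str]:
    """Sanitize and canonicalize a SMILES string; None if unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def read_compounds(path: str | Path, format: Optional[str] = None) -> CompoundSet:
    """Read a compound library from a ``.smi`` or SDF file.

    Unparseable records are skipped with a warning; the skip count is recorded
    in the returned set's provenance string.  Raises :class:`EmptyInputError`
    if no record parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.suffix.lower() in {".sdf", ".mol", ".sd"} else "smi"
    if format not in {"smi", "sdf"}:
        raise ValueError(f"unsupported format {format!r}")

    compounds: list[Compound] = []
    skipped = 0
    if format == "smi":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                smi = parts[0]
                cid = parts[1] if len(parts) > 1 else f"mol{lineno}"
                can = canonicalize(smi)
                if can is None:
                    skipped += 1
                    logger.warning("skipping unparseable SMILES at line %d: %s", lineno, smi)
                    continue
                compounds.append(Compound(id=cid, smiles=can))
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                logger.warning("skipping unparseable SDF record %d", i)
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i + 1}"
            pxc50 = None
            if mol.HasProp("pXC50"):
                try:
                    pxc50 = float(mol.GetProp("pXC50"))
                except ValueError:
                    pass
            compounds.append(Compound(id=cid, smiles=Chem.MolToSmiles(mol), pxc50=pxc50))

    if not compounds:
        raise EmptyInputError(f"no valid records in {path}")
    prov = f"{path.name} ({len(compounds)} read, {skipped} skipped)"
    if skipped:
        logger.info("read %d compounds from %s, skipped %d", len(compounds), path, skipped)
    return CompoundSet(compounds=compounds, provenance=prov)


def write_compounds(cset: CompoundSet, path: str | Path) -> None:
    """Write a set as whitespace-separated ``SMILES id`` lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in cset:
            fh.write(f"{c.smiles} {c.id}\n")


def flag_activity(cset: CompoundSet, threshold: float = DEFAULT_ACTIVITY_THRESHOLD) -> CompoundSet:
    """Assign activity flags: active iff pXC50 strictly exceeds *threshold*.

    A pXC50 equal to the threshold is inactive.  Returns a new set; the input
    is unmodified.  Raises if any compound lacks a pXC50 value.
    """
    flagged = []
    for c in cset:
        if c.pxc50 is None:
            raise ValueError(f"compound {c.id!r} lacks pxc50; cannot flag activity")
        new = Compound(
            id=c.id,
            smiles=c.smiles,
            pxc50=c.pxc50,
            activity_flag="active" if c.pxc50 > threshold else "inactive",
        )
        flagged.append(new)
    return CompoundSet(compounds=flagged, provenance=cset.provenance)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Comma- or tab-delimited text with a header row."""
    return pd.read_csv(path, sep=None, engine="python")


def read_docking_table(path: str | Path) -> DockingPoseTable:
    df = _read_delimited(path)
    df["compound_id"] = df["compound_id"].astype(str)
    df["pose_id"] = df["pose_id"].astype(str)
    df["score"] = df["score"].astype(float)
    return DockingPoseTable(frame=df[["compound_id", "pose_id", "score"]])


def write_docking_table(table: DockingPoseTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    df = _read_delimited(path)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                InteractionRecord(
                    compound_id=str(row["compound_id"]),
                    residue=str(row["residue"]),
                    interaction_type=str(row["interaction_type"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return records


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted model to a versioned JSON document.

    Floats are written with Python's shortest-round-trip repr, so a load
    reproduces every weight bit-exactly.
    """
    doc = {"schema": MODEL_SCHEMA, "class": type(model).__name__, "state": model.to_dict()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path, cls=None):
    """Load a model written by :func:`save_model`."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"not a valid model document: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema") != MODEL_SCHEMA:
        raise ModelFormatError(
            f"unexpected schema {doc.get('schema') if isinstance(doc, dict) else None!r}, "
            f"expected {MODEL_SCHEMA!r}"
        )
    if cls is None:
        from . import nbayes

        registry = {"BayesModel": nbayes.BayesModel}
        try:
            cls = registry[doc["class"]]
        except KeyError as exc:
            raise ModelFormatError(f"unknown model class {doc.get('class')!r}") from exc
    return cls.from_dict(doc["state"])
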