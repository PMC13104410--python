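"""Molecular pose and score-table I/O.

Uniform in-memory model for docked ligand poses and for the labelled
(active/decoy) score tables consumed by the enrichment analysis:

* :class:`Atom`, :class:`Conformer` — element symbols, Cartesian coordinates
  in Å (receptor frame, never recentred on read) and an explicit bond list.
* :class:`PoseSet` — a reference conformer plus an ordered ensemble of docked
  poses of the same ligand, with one score vector per scoring function.
  Pose order is file order throughout; "pose rank N" means the 1-based
  position of a pose in that order.
* :class:`LabeledScoreTable` — one row per compound with an active/decoy
  label and one (possibly missing) score per docking/scoring combination.

SDF/MOL (V2000) parsing and writing is delegated to RDKit; ligand extraction
from PDB files (HETATM records by residue name) to Biopython's Bio.PDB.
Hydrogens are retained on read and only excluded by :func:`heavy_atom_view`
at RMSD time.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Conformer",
    "PoseSet",
    "LabeledScoreTable",
    "PoseFormatError",
    "PoseValidationError",
    "ScoreTableError",
    "read_pose_file",
    "write_sdf",
    "heavy_atom_view",
    "read_score_table",
    "write_score_table",
]

HYDROGEN_ELEMENTS = frozenset({"H", "D", "T"})


class PoseFormatError(ValueError):
    """A pose file could not be parsed under the named standard."""


class PoseValidationError(ValueError):
    """Pose data violate a structural invariant (e.g. element mismatch)."""


class ScoreTableError(ValueError):
    """A score table violates its contract (labels, duplicate ids, ...)."""


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, Å coordinates, 0-based index in its conformer."""

    element: str
    coords: tuple[float, float, float]
    index: int

    def __post_init__(self) -> None:
        if not self.element:
            raise PoseValidationError("atom element symbol must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise PoseValidationError(
                f"atom {self.index} ({self.element}) has non-finite coordinates"
            )

    @property
    def is_hydrogen(self) -> bool:
        return self.element.capitalize() in HYDROGEN_ELEMENTS


@dataclass
class Conformer:
    """An ordered set of atoms with bonds; one 3-D conformation of a ligand."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise PoseValidationError(
                    f"bond ({i}, {j}) out of range for {n} atoms in '{self.name}'"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    def heavy_indices(self) -> list[int]:
        return [a.index for a in self.atoms if not a.is_hydrogen]

    def element_multiset(self, heavy_only: bool = True) -> Counter:
        return Counter(
            a.element for a in self.atoms if not (heavy_only and a.is_hydrogen)
        )


def heavy_atom_view(conf: Conformer) -> Conformer:
    """Restrict a conformer to its non-hydrogen atoms, order preserved.

    Bonds between retained atoms are kept (indices remapped).  Idempotent.
    Raises :class:`PoseValidationError` on an all-hydrogen input.
    """
    keep = [a for a in conf.atoms if not a.is_hydrogen]
    if not keep:
        raise PoseValidationError(f"conformer '{conf.name}' has no heavy atoms")
    remap = {a.index: k for k, a in enumerate(keep)}
    atoms = [Atom(a.element, a.coords, remap[a.index]) for a in keep]
    bonds = [
        (remap[i], remap[j], order)
        for i, j, order in conf.bonds
        if i in remap and j in remap
    ]
    return Conformer(atoms=atoms, bonds=bonds, name=conf.name)


@dataclass
class PoseSet:
    """A docked-pose ensemble for one ligand, with per-function score vectors.

    Every pose must share the reference's heavy-atom count and element
    multiset; every score vector must have one entry per pose.
    """

    reference: Conformer
    poses: list[Conformer]
    scores: dict[str, list[float]] = field(default_factory=dict)
    ligand_id: str = ""

    def __post_init__(self) -> None:
        ref_ms = self.reference.element_multiset()
        for k, pose in enumerate(self.poses):
            if pose.element_multiset() != ref_ms:
                raise PoseValidationError(
                    f"pose {k} of '{self.ligand_id}' does not match the "
                    f"reference heavy-atom element multiset"
                )
        for fn, vec in self.scores.items():
            if len(vec) != len(self.poses):
                raise PoseValidationError(
                    f"score vector '{fn}' has length {len(vec)} "
                    f"for {len(self.poses)} poses"
                )

    @property
    def n_poses(self) -> int:
        return len(self.poses)


# ---------------------------------------------------------------------------
# RDKit bridge (SDF / MOL V2000)
# ---------------------------------------------------------------------------

def _conformer_from_rdkit(mol, record: int, default_name: str) -> Conformer:
    from rdkit import Chem  # local import keeps module import cheap

    if mol is None:
        raise PoseFormatError(f"record {record} could not be parsed")
    if mol.GetNumConformers() == 0:
        raise PoseFormatError(f"record {record} has no coordinates")
    conf = mol.GetConformer()
    atoms = []
    for i, atom in enumerate(mol.GetAtoms()):
        p = conf.GetAtomPosition(i)
        atoms.append(Atom(atom.GetSymbol(), (p.x, p.y, p.z), i))
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    ]
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    return Conformer(atoms=atoms, bonds=bonds, name=name or default_name)


def conformer_to_rdkit(conf: Conformer):
    """Build an (unsanitised) RDKit Mol carrying the conformer's geometry."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    em = Chem.RWMol()
    for atom in conf.atoms:
        em.AddAtom(Chem.Atom(atom.element))
    order_map = {
        1.0: Chem.BondType.SINGLE,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
        1.5: Chem.BondType.AROMATIC,
    }
    for i, j, order in conf.bonds:
        em.AddBond(int(i), int(j), order_map.get(order, Chem.BondType.SINGLE))
    mol = em.GetMol()
    rdconf = Chem.Conformer(len(conf))
    for k, atom in enumerate(conf.atoms):
        rdconf.SetAtomPosition(k, Point3D(*atom.coords))
    mol.AddConformer(rdconf)
    mol.SetProp("_Name", conf.name)
    mol.UpdatePropertyCache(strict=False)
    return mol


def read_pose_file(
    path: str | Path,
    format: str = "sdf",
    resname: str | None = None,
) -> PoseSet | Conformer:
    """Read poses from SDF/MOL, or a ligand from a PDB file.

    * ``sdf`` — a single-record file returns a :class:`Conformer`; a
      multi-record file returns a :class:`PoseSet` whose reference is the
      first record and whose poses are all records, in file order.
    * ``mol`` — one V2000 record, returned as a :class:`Conformer`.
    * ``pdb-ligand`` — HETATM records of residue ``resname`` (required);
      the highest-occupancy altloc is kept (tie → first).  No bonds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "sdf":
        from rdkit import Chem

        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        confs = [
            _conformer_from_rdkit(mol, k, f"{path.stem}_{k}")
            for k, mol in enumerate(supplier)
        ]
        if not confs:
            raise PoseFormatError(f"{path}: empty SDF")
        if len(confs) == 1:
            return confs[0]
        return PoseSet(reference=confs[0], poses=confs, ligand_id=path.stem)
    if fmt == "mol":
        from rdkit import Chem

        mol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=False)
        return _conformer_from_rdkit(mol, 0, path.stem)
    if fmt == "pdb-ligand":
        if resname is None:
            raise ValueError("pdb-ligand format requires a residue name")
        return _read_pdb_ligand(path, resname)
    raise ValueError(f"unknown pose format: {format!r}")


def _read_pdb_ligand(path: Path, resname: str) -> Conformer:
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    for model in structure:
        for chain in model:
            for residue in chain:
                hetflag = residue.id[0]
                if hetflag.startswith("H_") and residue.resname.strip() == resname:
                    atoms = []
                    for i, atom in enumerate(residue.get_atoms()):
                        # Bio.PDB's DisorderedAtom already resolves altlocs to
                        # the highest-occupancy child (first on ties).
                        element = atom.element.strip().capitalize() or atom.get_name()[0]
                        x, y, z = (float(v) for v in atom.coord)
                        atoms.append(Atom(element, (x, y, z), i))
                    if not atoms:
                        break
                    return Conformer(atoms=atoms, bonds=[], name=resname)
    raise PoseFormatError(f"{path}: no HETATM residue named {resname!r}")


def write_sdf(path: str | Path, conformers: Conformer | PoseSet | Sequence[Conformer]) -> None:
    """Write one or more conformers (or a PoseSet's poses) to a V2000 SDF."""
    from rdkit import Chem

    if isinstance(conformers, Conformer):
        confs: Sequence[Conformer] = [conformers]
    elif isinstance(conformers, PoseSet):
        confs = conformers.poses
    else:
        confs = list(conformers)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for conf in confs:
            writer.write(conformer_to_rdkit(conf))
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Labelled score tables
# ---------------------------------------------------------------------------

VALID_LABELS = ("active", "decoy")


@dataclass
class LabeledScoreTable:
    """Compound ids, active/decoy labels and one score column per combination.

    ``data`` is indexed by compound id with a ``label`` column plus one float
    column per docking/scoring combination; missing scores stay NaN so that a
    compound not retrieved by a docking run is distinguishable from score 0.
    ``orientations`` maps each score column to 'higher' or 'lower'
    (better-score direction; default 'higher').
    """

    data: pd.DataFrame
    orientations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.empty:
            raise ScoreTableError("score table is empty")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ScoreTableError(f"duplicate compound ids: {dups}")
        if "label" not in self.data.columns:
            raise ScoreTableError("score table needs a 'label' column")
        bad = set(self.data["label"].unique()) - set(VALID_LABELS)
        if bad:
            raise ScoreTableError(f"unknown labels: {sorted(bad)}")
        for col in self.score_columns:
            self.orientations.setdefault(col, "higher")

    @classmethod
    def from_scores(
        cls,
        ids: Sequence[str],
        labels: Sequence[str],
        scores: Mapping[str, Iterable[float]],
        orientations: Mapping[str, str] | None = None,
    ) -> "LabeledScoreTable":
        frame = pd.DataFrame({"label": list(labels)}, index=pd.Index(ids, name="compound_id"))
        for col, vec in scores.items():
            frame[col] = np.asarray(list(vec), dtype=float)
        return cls(frame, dict(orientations or {}))

    @property
    def score_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != "label"]

    @property
    def labels(self) -> pd.Series:
        return self.data["label"]

    @property
    def n_actives(self) -> int:
        return int((self.data["label"] == "active").sum())

    @property
    def n_decoys(self) -> int:
        return int((self.data["label"] == "decoy").sum())

    def require_both_classes(self) -> None:
        if self.n_actives == 0 or self.n_decoys == 0:
            raise ScoreTableError(
                "enrichment operations need at least one active and one decoy"
            )


def read_score_table(
    path: str | Path,
    id_col: str = "compound_id",
    label_col: str = "label",
    orientations: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> LabeledScoreTable:
    """Read a delimited (comma or tab) score table with a header row."""
    frame = pd.read_csv(path, sep=sep, engine="python")
    if frame.empty:
        raise ScoreTableError(f"{path}: empty score table")
    for col in (id_col, label_col):
        if col not in frame.columns:
            raise ScoreTableError(f"{path}: missing column {col!r}")
    frame = frame.rename(columns={id_col: "compound_id", label_col: "label"})
    frame = frame.set_index("compound_id")
    for col in frame.columns:
        if col != "label":
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return LabeledScoreTable(frame, dict(orientations or {}))


def write_score_table(table: LabeledScoreTable, path: str | Path, sep: str = ",") -> None:
    table.data.to_csv(path, sep=sep, index_label="compound_id")
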