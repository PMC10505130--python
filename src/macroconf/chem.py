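"""Chemical graphs, conformers, geometry utilities and standard-format I/O.

Molecules are thin wrappers around RDKit molecules with explicit hydrogens;
conformers carry their own coordinate array so that a molecule can own many
geometries with independent energies and provenance tags.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

__all__ = [
    "Molecule",
    "Conformer",
    "AtomMap",
    "load_molecule",
    "measure_dihedral",
    "wrap_angle",
    "kabsch_superpose",
    "rmsd",
    "identity_heavy_map",
    "write_sdf",
    "read_sdf",
]

ENERGY_TAG = "E_kcal"
PROVENANCE_TAG = "provenance"


class InputError(ValueError):
    """Raised for unparsable or chemically invalid user input."""


class DegenerateGeometryError(ValueError):
    """Raised when a geometric operation is ill-posed (e.g. collinear points)."""


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into the interval (-180, 180]."""
    w = float(deg) % 360.0
    if w > 180.0:
        w -= 360.0
    if w <= -180.0:
        w += 360.0
    return w


class Molecule:
    """A chemical graph with explicit hydrogens.

    Parameters
    ----------
    rdmol : rdkit.Chem.Mol
        Sanitized molecule; hydrogens are made explicit on construction.
    name : str
        Optional display name.
    """

    def __init__(self, rdmol: Chem.Mol, name: str = ""):
        if rdmol is None:
            raise InputError("cannot build Molecule from None")
        if any(a.GetNumImplicitHs() or a.GetNumExplicitHs() for a in rdmol.GetAtoms()):
            rdmol = Chem.AddHs(rdmol, addCoords=rdmol.GetNumConformers() > 0)
        frags = Chem.GetMolFrags(rdmol)
        if len(frags) != 1:
            raise InputError(f"molecule has {len(frags)} disconnected components; expected 1")
        self.rdmol = rdmol
        self.name = name or (rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else "")
        self._automorphisms: list[tuple[int, ...]] | None = None
        self._mmff_props = None

    # -- basic queries -------------------------------------------------
    @property
    def num_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    def is_hydrogen(self, idx: int) -> bool:
        return self.rdmol.GetAtomWithIdx(idx).GetAtomicNum() == 1

    @property
    def heavy_indices(self) -> tuple[int, ...]:
        return tuple(
            a.GetIdx() for a in self.rdmol.GetAtoms() if a.GetAtomicNum() > 1
        )

    def element(self, idx: int) -> str:
        return self.rdmol.GetAtomWithIdx(idx).GetSymbol()

    def has_bond(self, i: int, j: int) -> bool:
        return self.rdmol.GetBondBetweenAtoms(int(i), int(j)) is not None

    # -- symmetry ------------------------------------------------------
    def heavy_automorphisms(self, max_matches: int = 64) -> list[dict[int, int]]:
        """Graph automorphisms of the heavy-atom skeleton.

        Returned as dicts mapping heavy-atom index -> image index (indices
        refer to this molecule, hydrogens excluded from the domain). Used to
        symmetry-correct RMSD (phenyl flips and the like).
        """
        if self._automorphisms is None:
            heavy = Chem.RemoveHs(self.rdmol, sanitize=False)
            order = [a.GetIdx() for a in self.rdmol.GetAtoms() if a.GetAtomicNum() > 1]
            matches = heavy.GetSubstructMatches(
                heavy, uniquify=False, useChirality=False, maxMatches=max_matches
            )
            self._automorphisms = [
                {order[q]: order[t] for q, t in enumerate(m)} for m in matches
            ] or [{i: i for i in order}]
        return self._automorphisms

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Molecule({self.name or Chem.MolToSmiles(Chem.RemoveHs(self.rdmol))!r}, {self.num_atoms} atoms)"


@dataclass
class Conformer:
    """One 3D coordinate set of a molecule.

    coords are in Angstrom, one row per atom; energy in kcal/mol when known.
    provenance is one of 'restrained', 'unrestrained', 'pose', 'reference'.
    """

    molecule: Molecule
    coords: np.ndarray
    energy: float | None = None
    provenance: str = "unrestrained"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] != self.molecule.num_atoms:
            raise InputError(
                f"coordinate count {self.coords.shape[0]} != atom count "
                f"{self.molecule.num_atoms}"
            )

    def copy(self, **overrides) -> "Conformer":
        kw = dict(
            molecule=self.molecule,
            coords=self.coords.copy(),
            energy=self.energy,
            provenance=self.provenance,
            metadata=dict(self.metadata),
        )
        kw.update(overrides)
        return Conformer(**kw)

    def to_rdkit(self) -> Chem.Conformer:
        conf = Chem.Conformer(self.molecule.num_atoms)
        for i, (x, y, z) in enumerate(self.coords):
            conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
        return conf


@dataclass(frozen=True)
class AtomMap:
    """An injective correspondence between atoms of two molecules."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        pairs = tuple((int(a), int(b)) for a, b in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        a_side = [p[0] for p in pairs]
        b_side = [p[1] for p in pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise InputError("AtomMap must be injective on both sides")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def b_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


def identity_heavy_map(mol: Molecule) -> AtomMap:
    """Identity map over the heavy atoms of one molecule."""
    return AtomMap(tuple((i, i) for i in mol.heavy_indices))


# ---------------------------------------------------------------------------
# loading


def _looks_like_path(source: str) -> bool:
    return os.path.sep in source or source.lower().endswith((".sdf", ".mol", ".pdb"))


def load_molecule(
    source: str,
    index: int = 0,
    residue_name: str | None = None,
    name: str = "",
) -> Molecule:
    """Load a molecule from a SMILES string or an SDF/PDB file.

    For SDF files ``index`` selects the record (0-based). For PDB files the
    ligand is extracted as the HETATM residue named ``residue_name`` (or the
    single non-water hetero residue when omitted).
    """
    if not isinstance(source, str) or not source.strip():
        raise InputError("empty molecule source")
    if os.path.exists(source) or _looks_like_path(source):
        if not os.path.exists(source):
            raise InputError(f"no such file: {source}")
        lower = source.lower()
        if lower.endswith(".pdb"):
            return _load_pdb_ligand(source, residue_name, name)
        supplier = Chem.SDMolSupplier(source, removeHs=False, sanitize=True)
        mols = [m for m in supplier]
        if index >= len(mols):
            raise InputError(f"{source}: record {index} requested but file has {len(mols)}")
        m = mols[index]
        if m is None:
            raise InputError(f"{source}: record {index} failed to parse")
        return Molecule(m, name=name)
    m = Chem.MolFromSmiles(source)
    if m is None:
        raise InputError(f"unparsable SMILES: {source!r}")
    return Molecule(Chem.AddHs(m), name=name)


def _load_pdb_ligand(path: str, residue_name: str | None, name: str) -> Molecule:
    m = Chem.MolFromPDBFile(path, removeHs=False, sanitize=False)
    if m is None:
        raise InputError(f"unparsable PDB file: {path}")
    keep = []
    for atom in m.GetAtoms():
        info = atom.GetPDBResidueInfo()
        if info is None:
            continue
        res = info.GetResidueName().strip()
        if residue_name is not None:
            if res == residue_name:
                keep.append(atom.GetIdx())
        elif info.GetIsHeteroAtom() and res != "HOH":
            keep.append(atom.GetIdx())
    if not keep:
        raise InputError(f"{path}: no ligand atoms found (residue {residue_name!r})")
    emol = Chem.RWMol(m)
    for idx in sorted(set(range(m.GetNumAtoms())) - set(keep), reverse=True):
        emol.RemoveAtom(idx)
    sub = emol.GetMol()
    Chem.SanitizeMol(sub)
    return Molecule(sub, name=name or (residue_name or "ligand"))


# ---------------------------------------------------------------------------
# geometry


def measure_dihedral(conf: Conformer, quad: Sequence[int]) -> float:
    """Dihedral angle (degrees) for an atom quadruple, IUPAC sign, (-180, 180]."""
    i, j, k, l = (int(q) for q in quad)
    if len({i, j, k, l}) != 4:
        raise InputError(f"dihedral atoms must be distinct, got {quad}")
    p = conf.coords
    b1 = p[j] - p[i]
    b2 = p[k] - p[j]
    b3 = p[l] - p[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    return wrap_angle(math.degrees(math.atan2(y, x)))


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray, amap: AtomMap
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of B onto A over mapped atoms.

    Returns ``(R, t, rmsd)`` such that ``coords_b @ R.T + t`` best fits A on
    the mapped pairs; R is a proper rotation (det = +1).
    """
    if len(amap) < 3:
        raise DegenerateGeometryError("need >= 3 mapped atoms for superposition")
    A = np.asarray(coords_a, float)[amap.a_indices]
    B = np.asarray(coords_b, float)[amap.b_indices]
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    # collinearity check: centered coords must span a plane
    if np.linalg.matrix_rank(A0, tol=1e-8) < 2 or np.linalg.matrix_rank(B0, tol=1e-8) < 2:
        raise DegenerateGeometryError("mapped atoms are collinear")
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - cb @ R.T
    diff = B @ R.T + t - A
    res = float(np.sqrt((diff**2).sum() / len(amap)))
    return R, t, res


def _plain_rmsd(ca: np.ndarray, cb: np.ndarray, amap: AtomMap, superimpose: bool) -> float:
    if superimpose:
        return kabsch_superpose(ca, cb, amap)[2]
    diff = ca[amap.a_indices] - cb[amap.b_indices]
    return float(np.sqrt((diff**2).sum() / len(amap)))


def rmsd(
    conf_a: Conformer,
    conf_b: Conformer,
    amap: AtomMap | None = None,
    superimpose: bool = True,
    symmetry: bool = False,
) -> float:
    """RMSD between two conformers over a caller-supplied atom map.

    With ``symmetry=True`` the minimum over heavy-atom graph automorphisms of
    molecule A that permute the mapped atoms among themselves is returned, so
    that e.g. a phenyl-ring flip does not inflate the value.
    """
    if amap is None:
        amap = identity_heavy_map(conf_a.molecule)
    if len(amap) == 0:
        raise InputError("empty atom map")
    base = _plain_rmsd(conf_a.coords, conf_b.coords, amap, superimpose)
    if not symmetry:
        return base
    mapped_a = set(int(i) for i in amap.a_indices)
    best = base
    for auto in conf_a.molecule.heavy_automorphisms():
        if not mapped_a.issubset(auto.keys()):
            continue
        if {auto[i] for i in mapped_a} != mapped_a:
            continue
        permuted = AtomMap(tuple((auto[a], b) for a, b in amap.pairs))
        best = min(best, _plain_rmsd(conf_a.coords, conf_b.coords, permuted, superimpose))
    return best


# ---------------------------------------------------------------------------
# SDF I/O


def write_sdf(conformers: Iterable[Conformer], path: str) -> None:
    """Write conformers as V2000 SDF records with energies in the E_kcal tag.

    Deterministic: fixed atom order, coordinates at 1e-4 Angstrom precision.
    """
    conformers = list(conformers)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for i, conf in enumerate(conformers):
            m = Chem.Mol(conf.molecule.rdmol)
            m.RemoveAllConformers()
            m.AddConformer(conf.to_rdkit(), assignId=True)
            m.SetProp("_Name", conf.molecule.name or f"conformer_{i}")
            if conf.energy is not None:
                m.SetProp(ENERGY_TAG, f"{conf.energy:.4f}")
            m.SetProp(PROVENANCE_TAG, conf.provenance)
            for key, val in sorted(conf.metadata.items()):
                if isinstance(val, float):
                    m.SetProp(str(key), f"{val:.4f}")
                else:
                    m.SetProp(str(key), str(val))
            writer.write(m)
    finally:
        writer.close()


def read_sdf(path: str) -> list[Conformer]:
    """Read an SDF written by :func:`write_sdf` back into Conformers.

    All records are assumed to share one chemical graph (taken from the first
    record); each record contributes one coordinate set.
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    out: list[Conformer] = []
    mol: Molecule | None = None
    for rec in supplier:
        if rec is None:
            raise InputError(f"{path}: unreadable SDF record")
        if mol is None:
            mol = Molecule(rec)
        coords = rec.GetConformer().GetPositions()
        energy = float(rec.GetProp(ENERGY_TAG)) if rec.HasProp(ENERGY_TAG) else None
        prov = rec.GetProp(PROVENANCE_TAG) if rec.HasProp(PROVENANCE_TAG) else "unrestrained"
        meta = {
            k: rec.GetProp(k)
            for k in rec.GetPropNames()
            if k not in (ENERGY_TAG, PROVENANCE_TAG)
        }
        out.append(Conformer(mol, coords, energy=energy, provenance=prov, metadata=meta))
    return out
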