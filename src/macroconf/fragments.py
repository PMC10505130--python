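"""Conformational preferences: 3D subfragments of a lead conformer that are
matched into analogs to transfer torsion restraints and anchor bound poses.

A preference is an ordered list of fragments (most-restrained first); for a
new analog the fragments are tried in order and the first subgraph match is
used. The matched fragment's reference dihedrals become square-well torsion
restraints on the analog, and the shared atoms anchor a rigid superposition
that turns restrained conformers into bound-pose candidates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem

from .chem import (
    AtomMap,
    Conformer,
    InputError,
    Molecule,
    kabsch_superpose,
    measure_dihedral,
)
from .restraints import DEFAULT_TORSION_K, DEFAULT_TORSION_TOL, TorsionRestraint
from .search import ConformerPool

__all__ = [
    "PreferenceFragment",
    "ConformationalPreference",
    "FragmentMatch",
    "extract_fragment",
    "match_fragment",
    "instantiate_torsion_restraints",
    "predict_pose",
]

log = logging.getLogger(__name__)


@dataclass
class PreferenceFragment:
    """A substructure of the lead with its reference 3D geometry.

    ``parent_indices[i]`` is the lead-molecule atom behind fragment atom i;
    ``torsions`` are the restrainable atom quadruples (fragment indexing).
    """

    molecule: Molecule
    reference: Conformer
    torsions: list[tuple[int, int, int, int]]
    parent_indices: tuple[int, ...] = ()
    label: str = ""

    def __post_init__(self):
        if self.molecule.num_atoms < 4:
            raise InputError("preference fragment needs at least 4 atoms")
        n = self.molecule.num_atoms
        for quad in self.torsions:
            if any(a >= n or a < 0 for a in quad):
                raise InputError(f"torsion {quad} outside fragment")

    def heavy_query(self) -> Chem.Mol:
        q = Chem.RemoveHs(Chem.Mol(self.molecule.rdmol), sanitize=False)
        q.UpdatePropertyCache(strict=False)
        return q


@dataclass
class ConformationalPreference:
    """Ordered fragments, most restrained first; order decides matching."""

    fragments: list[PreferenceFragment]

    def __post_init__(self):
        if not self.fragments:
            raise InputError("a conformational preference needs >= 1 fragment")

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class FragmentMatch:
    fragment_index: int
    atom_map: AtomMap  # fragment atom -> analog atom (heavy atoms)
    torsion_targets: list[tuple[tuple[int, int, int, int], float]] = field(
        default_factory=list
    )  # (analog quadruple, target angle deg)


def extract_fragment(
    mol: Molecule,
    conf: Conformer,
    atom_selection,
    label: str = "",
) -> PreferenceFragment:
    """Cut a connected atom selection out of ``mol`` with its geometry in ``conf``.

    Restrainable torsions are enumerated as all single bonds of the fragment
    whose two atoms are both non-terminal within the fragment (ring bonds
    included: macrocycle backbone torsions are the point of the exercise).
    """
    sel = sorted(set(int(a) for a in atom_selection))
    if len(sel) < 4:
        raise InputError(f"fragment selection has {len(sel)} atoms; need >= 4")
    # connectivity of the induced subgraph
    emol = Chem.RWMol(mol.rdmol)
    for idx in sorted(set(range(mol.num_atoms)) - set(sel), reverse=True):
        emol.RemoveAtom(idx)
    sub = emol.GetMol()
    if len(Chem.GetMolFrags(sub)) != 1:
        raise InputError("fragment selection induces a disconnected subgraph")
    Chem.SanitizeMol(
        sub,
        Chem.SanitizeFlags.SANITIZE_ALL
        ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
        ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
        catchErrors=True,
    )
    for a in sub.GetAtoms():
        # open valences from the cut are intended; they must not become
        # radical/H-count constraints during substructure matching
        a.SetNumRadicalElectrons(0)
        a.SetNoImplicit(True)
        a.SetNumExplicitHs(0)
    sub.UpdatePropertyCache(strict=False)
    frag_mol = Molecule.__new__(Molecule)  # bypass valence/H normalization: open valences are intended
    frag_mol.rdmol = sub
    frag_mol.name = label or f"{mol.name}-fragment"
    frag_mol._automorphisms = None
    frag_mol._mmff_props = None
    coords = conf.coords[sel]
    reference = Conformer(frag_mol, coords, provenance="reference")
    torsions = []
    for b in sub.GetBonds():
        if b.GetBondType() != Chem.BondType.SINGLE:
            continue
        a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
        n1 = [n for n in a1.GetNeighbors() if n.GetIdx() != a2.GetIdx() and n.GetAtomicNum() > 1]
        n2 = [n for n in a2.GetNeighbors() if n.GetIdx() != a1.GetIdx() and n.GetAtomicNum() > 1]
        if not n1 or not n2:
            continue
        torsions.append(
            (min(x.GetIdx() for x in n1), a1.GetIdx(), a2.GetIdx(), min(x.GetIdx() for x in n2))
        )
    return PreferenceFragment(
        molecule=frag_mol,
        reference=reference,
        torsions=torsions,
        parent_indices=tuple(sel),
        label=label,
    )


def match_fragment(
    pref: ConformationalPreference, analog: Molecule
) -> FragmentMatch | None:
    """First-match rule: fragments are tried in their stated order and the
    first with a subgraph embedding (element + bond order, hydrogens ignored)
    wins; among embeddings of that fragment the lowest-lexicographic analog
    index tuple is chosen."""
    for f_idx, frag in enumerate(pref.fragments):
        query = frag.heavy_query()
        heavy_frag = [a.GetIdx() for a in frag.molecule.rdmol.GetAtoms() if a.GetAtomicNum() > 1]
        matches = analog.rdmol.GetSubstructMatches(
            query, uniquify=True, useChirality=False, maxMatches=512
        )
        if not matches:
            continue
        best = min(matches)
        amap = AtomMap(tuple(zip(heavy_frag, best)))
        frag_to_analog = dict(amap.pairs)
        targets = []
        for quad in frag.torsions:
            if not all(q in frag_to_analog for q in quad):
                continue
            analog_quad = tuple(frag_to_analog[q] for q in quad)
            target = measure_dihedral(frag.reference, quad)
            targets.append((analog_quad, target))
        return FragmentMatch(fragment_index=f_idx, atom_map=amap, torsion_targets=targets)
    log.info("no preference fragment matches analog %s", analog.name)
    return None


def instantiate_torsion_restraints(
    match: FragmentMatch,
    analog: Molecule,
    tolerance: float = DEFAULT_TORSION_TOL,
    k: float = DEFAULT_TORSION_K,
) -> list[TorsionRestraint]:
    """Turn a fragment match into square-well torsion restraints on the analog.

    Torsions whose mapped bond path no longer exists in the analog (e.g. a
    ring contraction inside the fragment) are skipped with a warning.
    """
    out = []
    for analog_quad, target in match.torsion_targets:
        i, j, k_, l = analog_quad
        if not (analog.has_bond(i, j) and analog.has_bond(j, k_) and analog.has_bond(k_, l)):
            log.warning("torsion %s broken in analog %s; skipped", analog_quad, analog.name)
            continue
        out.append(
            TorsionRestraint(atoms=analog_quad, target=target, tolerance=tolerance, k=k)
        )
    return out


def predict_pose(
    pool: ConformerPool,
    reference: Conformer,
    fragment: PreferenceFragment,
    match: FragmentMatch,
    lam: float = 0.05,
) -> tuple[Conformer, float]:
    """Fragment-anchored bound-pose prediction.

    Every pool conformer is rigidly superposed onto the lead reference over
    the matched fragment atoms; the pose minimizing
    ``matched-atom RMSD + lam * (E - E_min)`` (lam in A per kcal/mol) is
    returned, aligned into the reference frame, together with its
    matched-atom RMSD.
    """
    if len(pool) == 0:
        raise InputError("empty conformer pool")
    frag_to_analog = dict(match.atom_map.pairs)
    frag_to_lead = {i: p for i, p in enumerate(fragment.parent_indices)}
    pairs = []
    for f_atom, analog_atom in frag_to_analog.items():
        lead_atom = frag_to_lead[f_atom]
        pairs.append((lead_atom, analog_atom))  # reference (A side) <- analog (B side)
    anchor = AtomMap(tuple(sorted(pairs)))
    if len(anchor) < 3:
        raise InputError("need >= 3 anchored atoms for pose prediction")
    pool.sort()
    emin = pool.min_energy
    best = None
    for conf in pool:
        rot, trans, res = kabsch_superpose(reference.coords, conf.coords, anchor)
        score = res + lam * (conf.energy - emin)
        if best is None or score < best[0] - 1e-12:
            best = (score, conf, rot, trans, res)
    _, conf, rot, trans, res = best
    aligned = conf.coords @ rot.T + trans
    pose = conf.copy(coords=aligned, provenance="pose")
    pose.metadata["anchor_rmsd"] = res
    return pose, res
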