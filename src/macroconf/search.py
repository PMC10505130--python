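"""Penalty-augmented stochastic torsional conformational search.

The engine is a seeded multi-start procedure: each start perturbs a random
subset of rotatable torsions (macrocycle ring torsions are sampled by
transiently snipping a ring bond, rotating in the resulting open chain, and
re-closing during minimization), then locally minimizes under an MMFF94
force field augmented with square-well restraint terms. Pools are
consolidated by symmetry-corrected heavy-atom RMSD, and the deep protocol
iterates rounds of search seeded from newly discovered low-energy cluster
representatives until none appear.

Stored conformer energies are force-field-only; restraint penalties are kept
as metadata so that strain arithmetic compares like with like.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms

from .chem import AtomMap, Conformer, InputError, Molecule, rmsd
from .restraints import RestraintSet, qmin_pair, total_restraint_energy

__all__ = [
    "SearchSettings",
    "ConformerPool",
    "ClusterAssignment",
    "embed_conformer",
    "load_settings",
    "minimize",
    "search_round",
    "cluster_pool",
    "deep_search",
    "low_energy_pool",
    "torsion_scan",
]

log = logging.getLogger(__name__)

DEG2RAD_SQ = (math.pi / 180.0) ** 2
# flag threshold for "restraints satisfied" on returned conformers, kcal/mol
RESTRAINT_OK_THRESHOLD = 1.0


@dataclass(frozen=True)
class SearchSettings:
    """Knobs of the stochastic search; a fixed seed makes runs reproducible."""

    starts_per_round: int = 12
    perturb_deg: float = 150.0        # max torsion kick per perturbed bond
    perturb_prob: float = 0.6         # chance each rotatable torsion is kicked
    max_minimize_steps: int = 2000
    force_tol: float = 1e-4           # minimizer convergence (kcal/mol/A)
    energy_window: float = 5.0        # low-energy pool width, kcal/mol
    consolidation_window: float = 10.0
    cluster_rmsd: float = 0.5         # A, heavy atoms, symmetry corrected
    n_restart_clusters: int = 10
    max_rounds: int = 20
    seed: int = 0
    perturb_multiplier: float = 10.0  # restraint weight boost during first pass

    def __post_init__(self):
        for name in (
            "starts_per_round", "perturb_deg", "max_minimize_steps",
            "force_tol", "energy_window", "consolidation_window",
            "cluster_rmsd", "n_restart_clusters", "max_rounds",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"SearchSettings.{name} must be positive")


def load_settings(path: str) -> SearchSettings:
    """Read SearchSettings from a flat YAML mapping (unknown keys rejected)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InputError(f"{path}: expected a flat mapping of settings")
    valid = {f.name for f in SearchSettings.__dataclass_fields__.values()}
    unknown = set(data) - valid
    if unknown:
        raise InputError(f"{path}: unknown settings {sorted(unknown)}")
    return SearchSettings(**data)


@dataclass
class ConformerPool:
    """Energy-sorted collection of non-redundant conformers of one molecule."""

    molecule: Molecule
    conformers: list[Conformer] = field(default_factory=list)
    provenance: str = "unrestrained"
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i) -> Conformer:
        return self.conformers[i]

    @property
    def min_energy(self) -> float:
        if not self.conformers:
            raise InputError("empty pool has no minimum energy")
        return self.conformers[0].energy

    def sort(self) -> None:
        # stable: ties resolved by insertion order
        self.conformers.sort(key=lambda c: c.energy)


@dataclass
class ClusterAssignment:
    """Greedy-leader RMSD clusters of a pool (representative = lowest energy)."""

    representatives: list[int]
    members: list[list[int]]

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


# ---------------------------------------------------------------------------
# force-field plumbing


def _mmff_properties(mol: Molecule):
    if mol._mmff_props is None:
        mol._mmff_props = AllChem.MMFFGetMoleculeProperties(mol.rdmol)
        if mol._mmff_props is None:
            raise InputError("MMFF94 parameters unavailable for this molecule")
    return mol._mmff_props


def _rdkit_with_coords(mol: Molecule, coords: np.ndarray) -> Chem.Mol:
    m = Chem.Mol(mol.rdmol)
    m.RemoveAllConformers()
    m.AddConformer(Conformer(mol, coords).to_rdkit(), assignId=True)
    return m


def _forcefield(mol: Molecule, rdmol: Chem.Mol):
    return AllChem.MMFFGetMoleculeForceField(rdmol, _mmff_properties(mol))


def forcefield_energy(conf: Conformer) -> float:
    """Plain MMFF94 energy (kcal/mol) of a conformer, no restraint terms."""
    m = _rdkit_with_coords(conf.molecule, conf.coords)
    return float(_forcefield(conf.molecule, m).CalcEnergy())


def embed_conformer(mol: Molecule, seed: int = 1) -> Conformer:
    """Distance-geometry (ETKDG) starting conformer; deterministic per seed."""
    m = Chem.Mol(mol.rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    params.useRandomCoords = False
    cid = AllChem.EmbedMolecule(m, params)
    if cid < 0:
        params.useRandomCoords = True
        cid = AllChem.EmbedMolecule(m, params)
    if cid < 0:
        raise InputError("3D embedding failed for this molecular graph")
    return Conformer(mol, m.GetConformer().GetPositions(), provenance="unrestrained")


def _add_restraint_terms(ff, conf: Conformer, rs: RestraintSet, multiplier: float):
    """Attach flat-bottom constraint terms for the current geometry.

    Group distance restraints are enforced through the minimum-distance proton
    pair (the qmin treatment, whose derivative involves only that pair); the
    pair is re-selected between minimization passes by the caller.
    """
    scale = rs.multiplier * multiplier
    for r in rs.distance:
        i, j = qmin_pair(conf, r)
        lo = r.lower if r.lower > 0 else 0.0
        ff.MMFFAddDistanceConstraint(int(i), int(j), False, float(lo), float(r.upper), r.weight * scale)
    for t in rs.torsion:
        lo, hi = t.well
        width = (hi - lo) % 360.0  # wells crossing +-180 are unwrapped to lo <= hi
        # RDKit's torsion constraint is quadratic in degrees; convert k from rad^-2
        k_deg = t.k * scale * DEG2RAD_SQ
        ff.MMFFAddTorsionConstraint(
            int(t.atoms[0]), int(t.atoms[1]), int(t.atoms[2]), int(t.atoms[3]),
            False, float(lo), float(lo + width), float(k_deg),
        )


def minimize(
    conf: Conformer,
    rs: RestraintSet | None = None,
    settings: SearchSettings | None = None,
    multiplier: float = 1.0,
) -> Conformer:
    """Local minimization of force-field energy plus restraint penalties.

    The returned conformer's ``energy`` is force-field-only; the restraint
    penalty at the final geometry is reported in ``metadata['penalty']``.
    Non-convergence within the step budget is flagged, not fatal.
    """
    settings = settings or SearchSettings()
    mol = conf.molecule
    m = _rdkit_with_coords(mol, conf.coords)
    converged = True
    passes = 3 if (rs is not None and rs.distance) else 1
    current = conf
    for _ in range(passes):
        ff = _forcefield(mol, m)
        if rs is not None:
            _add_restraint_terms(ff, current, rs, multiplier)
        ret = ff.Minimize(maxIts=settings.max_minimize_steps, forceTol=settings.force_tol)
        converged = ret == 0
        coords = m.GetConformer().GetPositions()
        new = Conformer(mol, coords, provenance=current.provenance)
        if rs is None or not rs.distance:
            current = new
            break
        # re-select qmin pairs; if unchanged, the geometry is self-consistent
        same = all(qmin_pair(new, r) == qmin_pair(current, r) for r in rs.distance)
        current = new
        if same:
            break
    out = current.copy(energy=forcefield_energy(current))
    out.metadata["converged"] = converged
    if not converged:
        log.warning("minimizer did not converge within %d steps", settings.max_minimize_steps)
    if rs is not None:
        penalty, _ = total_restraint_energy(out, rs)
        out.metadata["penalty"] = penalty
        out.metadata["restraints_ok"] = penalty <= RESTRAINT_OK_THRESHOLD
    return out


# ---------------------------------------------------------------------------
# torsion enumeration and perturbation


def rotatable_torsions(rdmol: Chem.Mol) -> list[tuple[int, int, int, int]]:
    """Heavy-atom quadruples around non-ring single bonds between non-terminal atoms."""
    quads = []
    for b in rdmol.GetBonds():
        if b.IsInRing() or b.GetBondType() != Chem.BondType.SINGLE:
            continue
        a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
        if a1.GetAtomicNum() == 1 or a2.GetAtomicNum() == 1:
            continue
        n1 = [n for n in a1.GetNeighbors() if n.GetIdx() != a2.GetIdx() and n.GetAtomicNum() > 1]
        n2 = [n for n in a2.GetNeighbors() if n.GetIdx() != a1.GetIdx() and n.GetAtomicNum() > 1]
        if not n1 or not n2:
            continue
        quads.append(
            (min(n1, key=lambda a: a.GetIdx()).GetIdx(), a1.GetIdx(),
             a2.GetIdx(), min(n2, key=lambda a: a.GetIdx()).GetIdx())
        )
    return quads


def _snippable_ring_bonds(mol: Molecule) -> list[tuple[int, int]]:
    """Single bonds exclusive to the largest ring (candidates for break-and-reclose)."""
    ri = mol.rdmol.GetRingInfo()
    if not ri.BondRings():
        return []
    big = max(ri.BondRings(), key=len)
    out = []
    for bidx in big:
        bond = mol.rdmol.GetBondWithIdx(bidx)
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        if ri.NumBondRings(bidx) != 1:
            continue  # shared with a fused small ring: snipping would not open the macrocycle
        out.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    return sorted(out)


def _perturb(conf: Conformer, rng: np.random.Generator, settings: SearchSettings) -> Conformer:
    """Random torsional kick; ring torsions sampled via break-and-reclose.

    The kick magnitude is itself randomized per start (20%..100% of
    perturb_deg) so one round mixes coarse basin-hopping moves with fine
    local exploration.
    """
    mol = conf.molecule
    snippable = _snippable_ring_bonds(mol)
    work = Chem.RWMol(mol.rdmol)
    snipped = None
    if snippable and rng.random() < 0.8:
        snipped = snippable[int(rng.integers(len(snippable)))]
        work.RemoveBond(*snipped)
    open_m = work.GetMol()
    open_m.RemoveAllConformers()
    open_m.AddConformer(conf.to_rdkit(), assignId=True)
    quads = rotatable_torsions(open_m)
    if not quads:
        return conf.copy()
    scale = float(rng.uniform(0.2, 1.0)) * settings.perturb_deg
    rdconf = open_m.GetConformer()
    for quad in quads:
        if rng.random() >= settings.perturb_prob:
            continue
        delta = float(rng.uniform(-scale, scale))
        try:
            cur = rdMolTransforms.GetDihedralDeg(rdconf, *quad)
            rdMolTransforms.SetDihedralDeg(rdconf, *quad, cur + delta)
        except (ValueError, RuntimeError):
            continue  # bond still in a (small) ring: not rotatable here
    return Conformer(mol, rdconf.GetPositions(), provenance=conf.provenance)


def _stereo_intact(conf: Conformer) -> bool:
    """True when the 3D geometry still realizes the graph's chiral tags.

    Aggressive ring perturbation plus re-closure can push a stereocenter
    through planarity; the force field alone will not restore it.
    """
    mol = conf.molecule
    ref_tags = {
        a.GetIdx(): a.GetChiralTag()
        for a in mol.rdmol.GetAtoms()
        if a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED
    }
    if not ref_tags:
        return True
    probe = _rdkit_with_coords(mol, conf.coords)
    Chem.AssignStereochemistryFrom3D(probe)
    return all(
        probe.GetAtomWithIdx(i).GetChiralTag() == tag for i, tag in ref_tags.items()
    )


def _bond_lengths_sane(conf: Conformer) -> bool:
    for b in conf.molecule.rdmol.GetBonds():
        d = float(np.linalg.norm(conf.coords[b.GetBeginAtomIdx()] - conf.coords[b.GetEndAtomIdx()]))
        if not (0.7 <= d <= 2.6):
            return False
    return True


# ---------------------------------------------------------------------------
# pools, consolidation and clustering


def _pair_rmsd(a: Conformer, b: Conformer) -> float:
    return rmsd(a, b, superimpose=True, symmetry=True)


def consolidate(
    pool: ConformerPool, rmsd_threshold: float, window: float | None = None
) -> ConformerPool:
    """Drop near-duplicates (keep lowest energy) and apply an energy window."""
    pool.sort()
    kept: list[Conformer] = []
    emin = pool.conformers[0].energy if pool.conformers else 0.0
    for conf in pool.conformers:
        if window is not None and conf.energy > emin + window:
            continue
        if any(_pair_rmsd(conf, k) < rmsd_threshold for k in kept):
            continue
        kept.append(conf)
    return ConformerPool(pool.molecule, kept, pool.provenance, dict(pool.metadata))


def search_round(
    mol: Molecule,
    settings: SearchSettings,
    rs: RestraintSet | None = None,
    seeds: list[Conformer] | None = None,
) -> ConformerPool:
    """One multi-start perturb-and-minimize round; deterministic per seed."""
    rng = np.random.default_rng(settings.seed)
    if not seeds:
        seeds = [minimize(embed_conformer(mol, seed=settings.seed + 1), rs, settings)]
    provenance = "restrained" if rs is not None else "unrestrained"
    out: list[Conformer] = []
    # a fraction of starts begin from fresh distance-geometry embeddings,
    # which sample ring conformations more broadly than torsion kicks alone
    n_embed = max(1, settings.starts_per_round // 4) if mol.num_atoms > 5 else 0
    for start in range(settings.starts_per_round):
        if start and n_embed and start % max(1, settings.starts_per_round // n_embed) == 0:
            try:
                base = embed_conformer(mol, seed=settings.seed + 7000 + start)
            except InputError:
                base = seeds[start % len(seeds)]
        else:
            base = seeds[start % len(seeds)]
        cand = _perturb(base, rng, settings)
        if rs is not None:
            cand = minimize(cand, rs, settings, multiplier=settings.perturb_multiplier)
        cand = minimize(cand, rs, settings, multiplier=1.0)
        if not _bond_lengths_sane(cand) or not _stereo_intact(cand):
            continue  # re-closure failed or flipped a stereocenter; discard
        cand.provenance = provenance
        out.append(cand)
    # the (minimized) seeds themselves are members: the round can only improve on them
    for base in seeds:
        member = base if base.energy is not None else minimize(base, rs, settings)
        member = member.copy(provenance=provenance)
        out.append(member)
    pool = ConformerPool(mol, out, provenance)
    return consolidate(pool, settings.cluster_rmsd)


def cluster_pool(
    pool: ConformerPool, rmsd_threshold: float, energy_window: float
) -> ClusterAssignment:
    """Greedy leader clustering in ascending-energy order within the window."""
    if len(pool) == 0:
        raise InputError("cannot cluster an empty pool")
    pool.sort()
    emin = pool.min_energy
    eligible = [i for i, c in enumerate(pool) if c.energy <= emin + energy_window]
    reps: list[int] = []
    members: list[list[int]] = []
    for i in eligible:
        for ci, r in enumerate(reps):
            if _pair_rmsd(pool[i], pool[r]) < rmsd_threshold:
                members[ci].append(i)
                break
        else:
            reps.append(i)
            members.append([i])
    return ClusterAssignment(representatives=reps, members=members)


def deep_search(
    mol: Molecule,
    settings: SearchSettings,
    rs: RestraintSet | None = None,
    seeds: list[Conformer] | None = None,
) -> ConformerPool:
    """Iterated clustered-restart search.

    Each round runs a standard search, the accumulated pool is consolidated
    into a non-redundant set within the consolidation window and clustered by
    RMSD; if any of the N lowest-energy clusters is new relative to all prior
    rounds' representatives, the next round restarts from the new clusters'
    lowest-energy conformers. Stops when no new low-energy cluster appears.
    """
    provenance = "restrained" if rs is not None else "unrestrained"
    accumulated = ConformerPool(mol, [], provenance)
    prior_reps: list[Conformer] = []
    round_seeds = list(seeds) if seeds else None
    rounds_run = 0
    converged = False
    for rnd in range(settings.max_rounds):
        rnd_settings = replace(settings, seed=settings.seed + 7919 * rnd)
        pool = search_round(mol, rnd_settings, rs, round_seeds)
        rounds_run += 1
        accumulated.conformers.extend(pool.conformers)
        accumulated = consolidate(
            accumulated, settings.cluster_rmsd, settings.consolidation_window
        )
        clusters = cluster_pool(accumulated, settings.cluster_rmsd, settings.consolidation_window)
        top = clusters.representatives[: settings.n_restart_clusters]
        new_reps = [
            accumulated[i]
            for i in top
            if all(_pair_rmsd(accumulated[i], p) >= settings.cluster_rmsd for p in prior_reps)
        ]
        prior_reps.extend(accumulated[i] for i in top)
        if not new_reps:
            converged = True
            break
        round_seeds = new_reps
    if not converged:
        log.warning("deep search hit the %d-round cap without converging", settings.max_rounds)
    accumulated.metadata.update(
        {"rounds": rounds_run, "converged": converged, "seed": settings.seed}
    )
    return accumulated


def low_energy_pool(pool: ConformerPool, window: float) -> ConformerPool:
    """Non-redundant members within ``window`` kcal/mol of the pool minimum."""
    if len(pool) == 0:
        raise InputError("empty pool")
    pool.sort()
    emin = pool.min_energy
    kept = [c for c in pool if c.energy <= emin + window]
    return ConformerPool(pool.molecule, kept, pool.provenance, dict(pool.metadata))


# ---------------------------------------------------------------------------
# relaxed torsion scan (grid oracle for small open-chain molecules)


def torsion_scan(
    mol: Molecule,
    quad: tuple[int, int, int, int],
    step_deg: float = 1.0,
    seed: int = 1,
    k_hold: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Relaxed 1D torsion scan: at each grid angle the torsion is held by a
    stiff narrow well while the rest of the molecule relaxes; returns
    (angles_deg, force-field-only energies)."""
    base = minimize(embed_conformer(mol, seed=seed))
    angles = np.arange(-180.0, 180.0, step_deg)
    energies = np.empty_like(angles)
    m = _rdkit_with_coords(mol, base.coords)
    rdconf = m.GetConformer()
    for idx, ang in enumerate(angles):
        rdMolTransforms.SetDihedralDeg(rdconf, *quad, float(ang))
        ff = _forcefield(mol, m)
        ff.MMFFAddTorsionConstraint(
            int(quad[0]), int(quad[1]), int(quad[2]), int(quad[3]),
            False, float(ang) - 0.25, float(ang) + 0.25, k_hold,
        )
        ff.Minimize(maxIts=500, forceTol=1e-4)
        energies[idx] = forcefield_energy(Conformer(mol, rdconf.GetPositions()))
    return angles, energies
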