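"""Deterministic synthetic fixtures: small cyclic peptides, reference
conformers, NMR-style restraint sets, and analog series with ground truth.

Every stage of the toolkit is testable without external downloads: the
generator builds head-to-tail or thioether-closed cyclic peptides at desk
scale (3-8 residues), derives a target conformer from a seeded deep search,
synthesizes inter-residue proton-proton upper-bound restraints from that
target (qmin treatment over chemically equivalent spin groups, NOE-like
distance cutoff and bound padding), and assembles analog series whose strain
ordering is established by a high-effort reference search.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

from .chem import Conformer, InputError, Molecule, measure_dihedral
from .fragments import ConformationalPreference, extract_fragment
from .pipeline import predict_analog
from .restraints import DistanceRestraint, RestraintSet, TorsionRestraint, spin_group
from .search import SearchSettings, deep_search, embed_conformer

__all__ = [
    "FixtureSpec",
    "CyclicPeptide",
    "GroundTruth",
    "EFFORT",
    "make_cyclic_peptide",
    "synthesize_restraints",
    "make_analog_series",
    "default_preference",
    "default_preference_from_conformer",
    "proton_name_map",
]

# side-chain SMILES fragments attached to the alpha carbon; ring residues
# (proline P, azetidine Z) are written as whole N+CA units. Uppercase codes
# are L-residues, lowercase their D-counterparts (alpha-carbon inversion).
SIDE_CHAINS = {
    "G": "",
    "A": "C",
    "V": "C(C)C",
    "L": "CC(C)C",
    "F": "Cc9ccccc9",
    "S": "CO",
    "T": "C(C)O",
    "C": "CS",
    "M": "CCSC",
}
RING_RESIDUES = {"P": "CCC", "Z": "CC"}  # N-(chain)-CA ring: pyrrolidine, azetidine


def _residue_parts(code: str) -> tuple[str, str, bool]:
    """(kind, payload, is_d) for a residue code; kind is 'side' or 'ring'."""
    is_d = code.islower()
    upper = code.upper()
    if upper in RING_RESIDUES:
        return "ring", RING_RESIDUES[upper], is_d
    return "side", SIDE_CHAINS[upper], is_d

# search-effort presets; seeds are substituted per call. "target" is used to
# pin fixture target conformers at the practical global minimum so that
# downstream strain estimates are measured against a stable reference.
EFFORT = {
    "quick": SearchSettings(starts_per_round=8, max_rounds=3, n_restart_clusters=3),
    "standard": SearchSettings(starts_per_round=16, max_rounds=6, n_restart_clusters=6),
    "reference": SearchSettings(starts_per_round=40, max_rounds=12, n_restart_clusters=10),
    "target": SearchSettings(starts_per_round=56, max_rounds=14, n_restart_clusters=10),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one fixture peptide; a fixed seed regenerates it bit-identically."""

    sequence: str = "FAGPSV"
    closure: str = "head-to-tail"
    seed: int = 11
    noe_cutoff: float = 4.5   # A, NOE-like upper-bound distance cutoff
    padding: float = 0.5      # A, slack added to observed distances
    phi_half_width: float = 30.0  # deg, half-width of synthesized phi intervals

    def __post_init__(self):
        if not (3 <= len(self.sequence) <= 8):
            raise InputError("fixture sequences are 3-8 residues")
        if self.closure not in ("head-to-tail", "thioether"):
            raise InputError(f"unknown closure {self.closure!r}")
        for code in self.sequence:
            if code.upper() not in SIDE_CHAINS and code.upper() not in RING_RESIDUES:
                raise InputError(f"unsupported residue code {code!r}")
        if self.closure == "thioether" and self.sequence[-1] != "C":
            raise InputError("thioether closure requires a C-terminal Cys (code 'C')")


@dataclass
class Residue:
    code: str
    index: int                    # 1-based position
    ring_atoms: tuple[int, ...]   # backbone segment N..C along the macro ring
    atoms: tuple[int, ...] = ()   # all atoms (incl. H) assigned to this residue
    phi: tuple[int, int, int, int] | None = None


@dataclass
class CyclicPeptide:
    spec: FixtureSpec
    molecule: Molecule
    target: Conformer             # lowest-energy conformer from the seeded search
    residues: list[Residue]
    backbone: tuple[int, ...]     # macro-ring atom indices


@dataclass
class GroundTruth:
    """Reference-search results for an analog series; never hand-edited."""

    strains: dict[str, float]
    order: list[str]              # compound names, ascending true strain
    poses: dict[str, Conformer]
    target: Conformer


# ---------------------------------------------------------------------------
# peptide construction


def _sequence_smiles(sequence: str, closure: str) -> str:
    units = []
    n = len(sequence)
    thio = closure == "thioether"
    for i, code in enumerate(sequence):
        first = i == 0 and not thio
        last_ht = (i == n - 1) and not thio
        macro = "1" if first else ""
        kind, payload, is_d = _residue_parts(code)
        ca = "[C@H]" if is_d else "[C@@H]"
        ca_ring = "[C@@H]" if is_d else "[C@H]"
        if kind == "ring":
            unit = f"N{macro}8{payload}{ca_ring}8"
        elif not payload:  # glycine
            unit = f"N{macro}C"
        else:
            unit = f"N{macro}{ca}({payload})"
        if thio and i == n - 1:
            # C-terminal Cys closes through its thioether side chain
            unit = f"N{ca}(C(=O)O)CS1"
            units.append(unit)
            continue
        unit += "C1=O" if last_ht else "C(=O)"
        units.append(unit)
    body = "".join(units)
    if thio:
        return "C1C(=O)" + body
    return body


def _macro_ring(rdmol: Chem.Mol) -> tuple[int, ...]:
    rings = rdmol.GetRingInfo().AtomRings()
    if not rings:
        raise InputError("molecule has no ring; not a macrocycle")
    return max(rings, key=len)


def _perceive_residues(mol: Molecule) -> tuple[list[Residue], tuple[int, ...]]:
    rd = mol.rdmol
    ring = list(_macro_ring(rd))
    n_ring = len(ring)

    def is_carbonyl(idx):
        a = rd.GetAtomWithIdx(idx)
        return a.GetAtomicNum() == 6 and any(
            b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetOtherAtom(a).GetAtomicNum() == 8
            for b in a.GetBonds()
        )

    n_positions = [p for p, idx in enumerate(ring) if rd.GetAtomWithIdx(idx).GetAtomicNum() == 7]
    if not n_positions:
        raise InputError("macro ring contains no nitrogen")
    # orient the ring so that from each backbone N we walk N -> CA -> ... -> C
    p0 = n_positions[0]
    fwd = is_carbonyl(ring[(p0 - 1) % n_ring])  # carbonyl precedes N in peptide order
    if not fwd:
        ring = ring[::-1]
        n_positions = [n_ring - 1 - p for p in n_positions]
    # residue 1's nitrogen has the lowest atom index (SMILES construction order)
    first_n = min(ring[p] for p in n_positions)
    start = next(p for p in n_positions if ring[p] == first_n)
    ring = ring[start:] + ring[:start]
    n_positions = sorted((p - start) % n_ring for p in n_positions)

    residues = []
    for r_i, p in enumerate(n_positions):
        nxt = n_positions[(r_i + 1) % len(n_positions)]
        seg_len = (nxt - p) % n_ring or n_ring
        seg = tuple(ring[(p + o) % n_ring] for o in range(seg_len))
        residues.append(Residue(code="?", index=r_i + 1, ring_atoms=seg))
    # assign non-ring atoms (side chains, carbonyl O, H) by BFS from ring atoms
    owner = {}
    for res in residues:
        for a in res.ring_atoms:
            owner[a] = res.index
    frontier = list(owner.keys())
    while frontier:
        nxt_frontier = []
        for a in frontier:
            for nb in rd.GetAtomWithIdx(a).GetNeighbors():
                i = nb.GetIdx()
                if i not in owner:
                    owner[i] = owner[a]
                    nxt_frontier.append(i)
        frontier = nxt_frontier
    for res in residues:
        res.atoms = tuple(sorted(i for i, o in owner.items() if o == res.index))
    # phi quadruples: preceding carbonyl C - N - CA - C (standard 3-atom segments)
    for r_i, res in enumerate(residues):
        prev = residues[(r_i - 1) % len(residues)]
        if len(res.ring_atoms) == 3 and is_carbonyl(prev.ring_atoms[-1]):
            res.phi = (prev.ring_atoms[-1], res.ring_atoms[0], res.ring_atoms[1], res.ring_atoms[2])
    return residues, tuple(ring)


_PEPTIDE_CACHE: dict = {}


def make_cyclic_peptide(spec: FixtureSpec, effort: str = "reference") -> CyclicPeptide:
    """Build the fixture macrocycle and its target conformer (cached per spec).

    The target conformer is the lowest-energy member of a seeded unrestrained
    deep search at the stated effort; same spec and effort always give
    identical coordinates.
    """
    key = (spec.sequence, spec.closure, spec.seed, effort)
    if key in _PEPTIDE_CACHE:
        return _PEPTIDE_CACHE[key]
    smi = _sequence_smiles(spec.sequence, spec.closure)
    rd = Chem.MolFromSmiles(smi)
    if rd is None:
        raise InputError(f"could not construct closure for sequence {spec.sequence!r}")
    name = f"cyclo-{spec.sequence}" + ("-S" if spec.closure == "thioether" else "")
    mol = Molecule(Chem.AddHs(rd), name=name)
    residues, backbone = _perceive_residues(mol)
    for res, code in zip(residues, spec.sequence):
        res.code = code
    settings = replace(EFFORT[effort], seed=spec.seed)
    pool = deep_search(mol, settings)
    target = pool[0].copy(provenance="reference")
    pep = CyclicPeptide(spec=spec, molecule=mol, target=target, residues=residues, backbone=backbone)
    _PEPTIDE_CACHE[key] = pep
    return pep


# ---------------------------------------------------------------------------
# spin groups and synthetic restraints


def equivalent_proton_groups(mol: Molecule) -> list[tuple[int, ...]]:
    """Partition protons into chemically equivalent groups (methyls, flipping
    aromatic pairs) using graph symmetry classes; everything else is a singleton."""
    ranks = list(Chem.CanonicalRankAtoms(mol.rdmol, breakTies=False))
    by_rank: dict[int, list[int]] = {}
    for a in mol.rdmol.GetAtoms():
        if a.GetAtomicNum() == 1:
            by_rank.setdefault(ranks[a.GetIdx()], []).append(a.GetIdx())
    return sorted(tuple(sorted(v)) for v in by_rank.values())


def synthesize_restraints(
    pep: CyclicPeptide,
    cutoff: float | None = None,
    padding: float | None = None,
    phi_residues: tuple[int, ...] | None = None,
    method: str = "qmin",
) -> RestraintSet:
    """NOE-emulating restraints read off the target conformer.

    Every inter-residue pair of equivalent-proton groups whose effective
    distance in the target is below the cutoff contributes an upper bound of
    (distance + padding); a phi interval restraint of +/- phi_half_width
    around the target value is added for the chosen residues (default: all
    residues with a defined phi). The target satisfies the set exactly.
    """
    spec = pep.spec
    cutoff = spec.noe_cutoff if cutoff is None else cutoff
    padding = spec.padding if padding is None else padding
    mol = pep.molecule
    residue_of = {}
    for res in pep.residues:
        for a in res.atoms:
            residue_of[a] = res.index
    groups = [spin_group(mol, g) for g in equivalent_proton_groups(mol)]
    rs = RestraintSet()
    from .restraints import effective_distance  # local import to avoid cycle at module load

    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ga, gb = groups[i], groups[j]
            if residue_of[ga.atoms[0]] == residue_of[gb.atoms[0]]:
                continue
            probe = DistanceRestraint(group_a=ga, group_b=gb, upper=1e9, method=method)
            d = effective_distance(pep.target, probe)
            if d < cutoff:
                rs.distance.append(
                    DistanceRestraint(
                        group_a=ga, group_b=gb, upper=d + padding, method=method
                    )
                )
    for res in pep.residues:
        if res.phi is None:
            continue
        if phi_residues is not None and res.index not in phi_residues:
            continue
        phi = measure_dihedral(pep.target, res.phi)
        rs.torsion.append(
            TorsionRestraint(
                atoms=res.phi,
                interval=(phi - spec.phi_half_width, phi + spec.phi_half_width),
            )
        )
    return rs


def proton_name_map(pep: CyclicPeptide) -> dict[tuple[int, str], tuple[int, ...]]:
    """CYANA-style (residue number, atom name) -> proton indices.

    Backbone amide H is HN, alpha H is HA; side-chain groups get pseudo-atom
    names (QB, QG, ...) by distance from the alpha carbon, singletons HB/HG...
    with a numeric suffix when needed.
    """
    rd = pep.molecule.rdmol
    greek = "ABGDEZH"
    out: dict[tuple[int, str], tuple[int, ...]] = {}
    for res in pep.residues:
        n_atom, ca = res.ring_atoms[0], res.ring_atoms[1] if len(res.ring_atoms) > 1 else None
        # graph distance from CA within the residue
        dist = {ca: 0} if ca is not None else {}
        frontier = [ca] if ca is not None else []
        while frontier:
            new = []
            for a in frontier:
                for nb in rd.GetAtomWithIdx(a).GetNeighbors():
                    i = nb.GetIdx()
                    if i in res.atoms and i not in dist and nb.GetAtomicNum() > 1:
                        dist[i] = dist[a] + 1
                        new.append(i)
            frontier = new
        groups = [
            g for g in equivalent_proton_groups(pep.molecule) if g[0] in res.atoms
        ]
        counters: dict[str, int] = {}
        n_ca_singletons = sum(
            1
            for g in groups
            if len(g) == 1 and rd.GetAtomWithIdx(g[0]).GetNeighbors()[0].GetIdx() == ca
        )
        for g in groups:
            parent = rd.GetAtomWithIdx(g[0]).GetNeighbors()[0].GetIdx()
            if parent == n_atom:
                name = "HN"
            elif parent == ca and len(g) == 1:
                if n_ca_singletons > 1:  # diastereotopic glycine alpha protons
                    counters["A"] = counters.get("A", 0) + 1
                    name = f"HA{counters['A']}"
                else:
                    name = "HA"
            else:
                d = dist.get(parent, 1)
                letter = greek[min(d, len(greek) - 1)]
                if len(g) > 1:
                    name = f"Q{letter}"
                else:
                    counters[letter] = counters.get(letter, 0) + 1
                    name = f"H{letter}{counters[letter]}"
            # two topologically distinct groups can land on one name (e.g.
            # proline CD reached through the ring nitrogen); disambiguate
            suffix = 2
            base = name
            while (res.index, name) in out:
                name = f"{base}{suffix}"
                suffix += 1
            out[(res.index, name)] = tuple(g)
    return out


# ---------------------------------------------------------------------------
# analog series


def apply_edit(spec: FixtureSpec, position: int, code: str) -> FixtureSpec:
    seq = spec.sequence
    if not (1 <= position <= len(seq)):
        raise InputError(f"edit position {position} outside sequence of length {len(seq)}")
    if code.upper() not in SIDE_CHAINS and code.upper() not in RING_RESIDUES:
        raise InputError(f"edit at position {position}: unknown residue code {code!r}")
    if spec.closure == "thioether" and position == len(seq) and code.upper() != "C":
        raise InputError(f"edit at position {position}: thioether closure needs the terminal Cys")
    new_seq = seq[:position - 1] + code + seq[position:]
    return replace(spec, sequence=new_seq)


def default_preference(pep: CyclicPeptide) -> ConformationalPreference:
    """Lead conformational preference: (1) backbone ring with carbonyl O and
    beta carbons, then (2) the bare backbone ring -- most restrained first."""
    return default_preference_from_conformer(pep.target)


def default_preference_from_conformer(conf: Conformer) -> ConformationalPreference:
    """Backbone-anchored preference derived from any macrocycle conformer."""
    mol = conf.molecule
    rd = mol.rdmol
    ring = set(_macro_ring(rd))
    extended = set(ring)
    for a in ring:
        atom = rd.GetAtomWithIdx(a)
        for nb in atom.GetNeighbors():
            if nb.GetAtomicNum() == 8:  # carbonyl O
                extended.add(nb.GetIdx())
            elif nb.GetAtomicNum() in (6, 16) and nb.GetIdx() not in ring and atom.GetAtomicNum() == 6:
                extended.add(nb.GetIdx())  # CB / thioether sulfur neighbors
    frag_full = extract_fragment(mol, conf, sorted(extended), label="backbone+CB")
    frag_ring = extract_fragment(mol, conf, sorted(ring), label="backbone")
    return ConformationalPreference(fragments=[frag_full, frag_ring])


_SERIES_CACHE: dict = {}


def make_analog_series(
    spec: FixtureSpec,
    edits: list,
    effort: str = "standard",
    oracle_seed: int | None = None,
) -> tuple[list[tuple[str, Molecule]], GroundTruth]:
    """Lead plus edited analogs, with ground-truth strain from a reference run.

    Each entry in ``edits`` describes one analog: either a single
    (1-based position, replacement code) pair or a tuple of such pairs for
    multi-site analogs. Ground truth is established by running the full
    restrained-search/pose/strain workflow at the stated effort with its own
    seed; it is cached and regenerated, never hand-edited.
    """
    oracle_seed = spec.seed + 1000 if oracle_seed is None else oracle_seed
    norm_edits = tuple(
        (e,) if e and isinstance(e[0], int) else tuple(e) for e in edits
    )
    key = (spec.sequence, spec.closure, spec.seed, norm_edits, effort, oracle_seed)
    if key in _SERIES_CACHE:
        return _SERIES_CACHE[key]
    # the lead target is pinned at the practical global minimum ("target"
    # effort) so the lead's own strain is exactly zero up to search noise
    lead = make_cyclic_peptide(spec, effort="target")
    pref = default_preference(lead)
    series: list[tuple[str, Molecule]] = [(lead.molecule.name, lead.molecule)]
    for analog_edits in norm_edits:
        espec = spec
        for pos, code in analog_edits:
            espec = apply_edit(espec, pos, code)
        emol_name = f"cyclo-{espec.sequence}"
        rd = Chem.MolFromSmiles(_sequence_smiles(espec.sequence, espec.closure))
        if rd is None:
            raise InputError(f"edits {analog_edits}: cannot build {espec.sequence!r}")
        series.append((emol_name, Molecule(Chem.AddHs(rd), name=emol_name)))
    strains: dict[str, float] = {}
    poses: dict[str, Conformer] = {}
    settings = replace(EFFORT[effort], seed=oracle_seed)
    for name, mol in series:
        result = predict_analog(mol, pref, lead.target, settings)
        if result.strain is None:
            raise InputError(f"analog {name} did not match the lead preference")
        # strains below the minimizer's energy resolution are not meaningful;
        # snap them to zero so tie ordering is well defined
        strain = result.strain if result.strain >= 0.01 else 0.0
        strains[name] = strain
        poses[name] = result.pose
    order = sorted(strains, key=lambda n: strains[n])
    gt = GroundTruth(strains=strains, order=order, poses=poses, target=lead.target)
    out = (series, gt)
    _SERIES_CACHE[key] = out
    return out


# analog-series lead: a rigid cyclic tetrapeptide whose global minimum the
# reference search reproduces reliably. L->L side-chain deletions leave the
# analog free to keep the lead backbone (strain ~ 0), while L->D inversions
# robustly shift the analog's own preferred ring geometry away from the
# transferred backbone preference, producing large bound-strain estimates --
# the desk-scale counterpart of removing a conformational lock.
SERIES_SPEC = FixtureSpec(sequence="FAPS", seed=23)

DEFAULT_EDITS: list = [
    (1, "A"),   # Phe -> Ala: smaller, unfrustrated (strain ~ 0)
    (4, "A"),   # Ser -> Ala: polar contact removed, backbone unchanged
    (1, "v"),   # Phe -> D-Val: alpha inversion at position 1
    (4, "a"),   # Ser -> D-Ala: inversion next to the ring closure
    (2, "v"),   # Ala -> D-Val: inversion + beta branching, worst frustration
]

# close analogs that genuinely share the lead's conformational preference
# (side-chain edits only): the set on which transferred torsion restraints
# are expected to hold after restrained search. The alpha-inverted analogs
# above intentionally violate the preference - that is the strain mechanism -
# so they are not part of this fidelity set.
TRANSFER_EDITS: list = [
    (1, "A"),
    (1, "L"),
    (4, "A"),
    (2, "V"),
]
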