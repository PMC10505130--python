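"""Distance restraints over equivalent spin groups and square-well torsion restraints.

Chemically equivalent protons (methyl rotors, flipping aromatic pairs) share
one NMR signal and must be restrained as a group. Three group-distance
treatments are provided:

* ``r6``     — the r^-6 averaged distance over all proton pairs,
* ``center`` — centroid-to-centroid distance plus a pseudo-atom correction,
* ``qmin``   — the minimum pairwise proton-proton distance, a cheap lower
  approximation to the r^-6 average whose gradient involves only the two
  atoms realizing the minimum.

All restraint penalties are square-well quadratics: zero inside the allowed
band, quadratic in the violation outside it, C1-continuous at the edges.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import Conformer, InputError, measure_dihedral, wrap_angle

__all__ = [
    "SpinGroup",
    "DistanceRestraint",
    "TorsionRestraint",
    "RestraintSet",
    "spin_group",
    "effective_distance",
    "distance_penalty",
    "torsion_penalty",
    "total_restraint_energy",
    "karplus_j",
    "phi_restraint_from_j",
    "parse_restraints",
    "write_restraints",
    "write_violation_report",
]

log = logging.getLogger(__name__)

DEFAULT_DISTANCE_WEIGHT = 50.0  # kcal/mol/A^2
DEFAULT_TORSION_K = 20.0  # kcal/mol/rad^2
DEFAULT_TORSION_TOL = 20.0  # degrees
KARPLUS_COEFFS = (6.51, -1.76, 1.60)  # A, B, C with theta = phi - 60 deg


@dataclass(frozen=True)
class SpinGroup:
    """A set of chemically equivalent protons restrained as one signal.

    ``delta`` is the pseudo-atom correction in Angstrom, used only by the
    center-averaging treatment to compensate for group extent.
    """

    atoms: tuple[int, ...]
    delta: float = 0.0
    label: str = ""

    def __post_init__(self):
        atoms = tuple(int(a) for a in self.atoms)
        object.__setattr__(self, "atoms", atoms)
        if len(atoms) < 1:
            raise InputError("spin group needs at least one proton")
        if len(set(atoms)) != len(atoms):
            raise InputError("duplicate atoms in spin group")
        if self.delta < 0:
            raise InputError("pseudo-atom correction must be >= 0")

    def __len__(self) -> int:
        return len(self.atoms)


def spin_group(mol, atoms: Sequence[int], label: str = "") -> SpinGroup:
    """Build a SpinGroup with a conventional pseudo-atom correction.

    Defaults: methyl (3 H on one carbon) 1.0 A; geminal methylene pair 0.9 A;
    equivalent protons on different (aromatic) carbons 2.0 A; singleton 0.0 A.
    All member atoms must be hydrogens.
    """
    atoms = tuple(int(a) for a in atoms)
    for a in atoms:
        if not mol.is_hydrogen(a):
            raise InputError(f"atom {a} in spin group is not a hydrogen")
    delta = 0.0
    if len(atoms) > 1:
        parents = {
            mol.rdmol.GetAtomWithIdx(a).GetNeighbors()[0].GetIdx() for a in atoms
        }
        if len(parents) == 1:
            delta = 1.0 if len(atoms) >= 3 else 0.9
        else:
            delta = 2.0
    return SpinGroup(atoms=atoms, delta=delta, label=label)


@dataclass(frozen=True)
class DistanceRestraint:
    group_a: SpinGroup
    group_b: SpinGroup
    upper: float
    lower: float = 0.0
    method: str = "qmin"
    weight: float = DEFAULT_DISTANCE_WEIGHT

    def __post_init__(self):
        if self.method not in ("qmin", "r6", "center"):
            raise InputError(f"unknown distance method {self.method!r}")
        if not (0.0 <= self.lower <= self.upper):
            raise InputError(f"require 0 <= lower <= upper, got {self.lower}, {self.upper}")
        if set(self.group_a.atoms) & set(self.group_b.atoms):
            raise InputError("spin groups of a restraint must be disjoint")
        if self.weight <= 0:
            raise InputError("restraint weight must be positive")


@dataclass(frozen=True)
class TorsionRestraint:
    """Square-well quadratic restraint on a dihedral angle.

    Either ``target`` with symmetric ``tolerance`` (zero penalty within
    target +/- tolerance) or an allowed ``interval`` (lo, hi) on the circle.
    ``k`` is in kcal/mol/rad^2.
    """

    atoms: tuple[int, int, int, int]
    target: float | None = None
    tolerance: float = DEFAULT_TORSION_TOL
    interval: tuple[float, float] | None = None
    k: float = DEFAULT_TORSION_K

    def __post_init__(self):
        atoms = tuple(int(a) for a in self.atoms)
        object.__setattr__(self, "atoms", atoms)
        if len(atoms) != 4 or len(set(atoms)) != 4:
            raise InputError(f"torsion restraint needs 4 distinct atoms, got {atoms}")
        if (self.target is None) == (self.interval is None):
            raise InputError("specify exactly one of target or interval")
        if self.target is not None:
            object.__setattr__(self, "target", wrap_angle(self.target))
            if self.tolerance < 0:
                raise InputError("tolerance must be >= 0")
        else:
            lo, hi = (wrap_angle(self.interval[0]), wrap_angle(self.interval[1]))
            object.__setattr__(self, "interval", (lo, hi))
        if self.k <= 0:
            raise InputError("force constant must be positive")

    @property
    def well(self) -> tuple[float, float]:
        """Allowed band as (lo, hi) on the circle (hi reached going ccw from lo)."""
        if self.interval is not None:
            return self.interval
        return (wrap_angle(self.target - self.tolerance), wrap_angle(self.target + self.tolerance))


@dataclass
class RestraintSet:
    distance: list[DistanceRestraint] = field(default_factory=list)
    torsion: list[TorsionRestraint] = field(default_factory=list)
    multiplier: float = 1.0

    def __len__(self) -> int:
        return len(self.distance) + len(self.torsion)

    def max_atom_index(self) -> int:
        idx = [-1]
        for r in self.distance:
            idx.extend(r.group_a.atoms)
            idx.extend(r.group_b.atoms)
        for t in self.torsion:
            idx.extend(t.atoms)
        return max(idx)


# ---------------------------------------------------------------------------
# distances and penalties


def _pair_distances(coords: np.ndarray, r: DistanceRestraint) -> np.ndarray:
    a = coords[list(r.group_a.atoms)]
    b = coords[list(r.group_b.atoms)]
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)


def effective_distance(conf: Conformer, r: DistanceRestraint) -> float:
    """Group-group distance under the restraint's configured treatment."""
    coords = conf.coords
    if r.method == "center":
        ca = coords[list(r.group_a.atoms)].mean(axis=0)
        cb = coords[list(r.group_b.atoms)].mean(axis=0)
        return float(np.linalg.norm(ca - cb)) + r.group_a.delta + r.group_b.delta
    d = _pair_distances(coords, r)
    if r.method == "qmin":
        return float(d.min())
    # r6: ((1/(na*nb)) * sum r^-6)^(-1/6)
    return float(np.mean(d**-6.0) ** (-1.0 / 6.0))


def qmin_pair(conf: Conformer, r: DistanceRestraint) -> tuple[int, int]:
    """The proton pair realizing the minimum distance (ties: lowest indices)."""
    d = _pair_distances(conf.coords, r)
    flat = np.round(d, 12)
    i, j = np.unravel_index(int(np.argmin(flat)), d.shape)
    return r.group_a.atoms[i], r.group_b.atoms[j]


def distance_penalty(conf: Conformer, r: DistanceRestraint) -> float:
    """Square-well quadratic penalty on the effective distance (kcal/mol)."""
    d = effective_distance(conf, r)
    v = max(0.0, d - r.upper, r.lower - d)
    return r.weight * v * v


def _circular_violation_deg(angle: float, well: tuple[float, float]) -> float:
    """Shortest angular distance (deg, >= 0) from ``angle`` to the arc [lo, hi]."""
    lo, hi = well
    width = (hi - lo) % 360.0
    pos = (angle - lo) % 360.0
    if pos <= width:
        return 0.0
    # outside: distance to the nearer edge going either way round
    return min(pos - width, 360.0 - pos)


def torsion_penalty(conf: Conformer, t: TorsionRestraint) -> float:
    """Square-well quadratic penalty on a dihedral (kcal/mol), periodic in 360."""
    measured = measure_dihedral(conf, t.atoms)
    v_deg = _circular_violation_deg(measured, t.well)
    v = math.radians(v_deg)
    return t.k * v * v


def total_restraint_energy(
    conf: Conformer, rs: RestraintSet
) -> tuple[float, list[dict]]:
    """Total penalty (kcal/mol, including the global multiplier) plus a report.

    The report lists, per restraint, the measured distance/angle, the
    violation and the (unmultiplied) penalty.
    """
    n = conf.molecule.num_atoms
    if rs.max_atom_index() >= n:
        raise InputError("restraint references atoms beyond this molecule")
    total = 0.0
    report: list[dict] = []
    for r in rs.distance:
        d = effective_distance(conf, r)
        v = max(0.0, d - r.upper, r.lower - d)
        pen = r.weight * v * v
        total += pen
        report.append(
            {
                "kind": "distance",
                "method": r.method,
                "value": d,
                "lower": r.lower,
                "upper": r.upper,
                "violation": v,
                "penalty": pen,
            }
        )
    for t in rs.torsion:
        measured = measure_dihedral(conf, t.atoms)
        v_deg = _circular_violation_deg(measured, t.well)
        pen = t.k * math.radians(v_deg) ** 2
        total += pen
        report.append(
            {
                "kind": "torsion",
                "atoms": t.atoms,
                "value": measured,
                "well": t.well,
                "violation": v_deg,
                "penalty": pen,
            }
        )
    return total * rs.multiplier, report


# ---------------------------------------------------------------------------
# J-coupling derived phi restraints


def karplus_j(phi: float, coeffs: tuple[float, float, float] = KARPLUS_COEFFS) -> float:
    """Three-bond J(HN-Halpha) coupling (Hz) from a backbone phi angle.

    Modified Karplus relation J = A cos^2(theta) + B cos(theta) + C with
    theta = phi - 60 degrees.
    """
    a, b, c = coeffs
    ct = math.cos(math.radians(phi - 60.0))
    return a * ct * ct + b * ct + c


def phi_restraint_from_j(
    j_hz: float,
    phi_quad: Sequence[int],
    threshold: float = 8.0,
    interval: tuple[float, float] = (-155.0, -95.0),
    k: float = DEFAULT_TORSION_K,
) -> TorsionRestraint | None:
    """Phi interval restraint from an amide J(HN-Halpha) coupling.

    Couplings strictly above the threshold (8.0 Hz) indicate an extended
    backbone and yield the interval restraint; smaller couplings give none.
    """
    if j_hz < 0:
        raise InputError(f"negative J coupling: {j_hz}")
    if j_hz > threshold:
        return TorsionRestraint(atoms=tuple(phi_quad), interval=interval, k=k)
    return None


# ---------------------------------------------------------------------------
# file I/O
#
# Native TSV: columns  group_a | group_b | lower | upper | method | weight
# with protons written as comma-separated H<index> labels (0-based indices).
# Torsion lines:       TOR | i,j,k,l | lo | hi | k      (interval form)
# CYANA-like dialect: separate .upl/.lol files of
# "resnum resname atomname resnum resname atomname bound"; pseudo-atom names
# (QB, QD, ...) expand through the caller-supplied name map.


def _parse_group(tok: str, line_no: int) -> tuple[int, ...]:
    atoms = []
    for part in tok.split(","):
        part = part.strip()
        if not part.startswith("H") or not part[1:].isdigit():
            raise InputError(f"line {line_no}: bad proton label {part!r}")
        atoms.append(int(part[1:]))
    return tuple(atoms)


def _format_group(g: SpinGroup) -> str:
    return ",".join(f"H{a}" for a in g.atoms)


def parse_restraints(
    path: str,
    dialect: str = "native",
    atom_name_map: dict[tuple[int, str], tuple[int, ...]] | None = None,
    lol_path: str | None = None,
    deltas: dict[tuple[int, ...], float] | None = None,
) -> RestraintSet:
    """Parse a restraint file into a RestraintSet.

    ``dialect='native'`` reads the package's TSV format. ``dialect='upl-lol'``
    reads a CYANA-like upper-bound file (plus an optional lower-bound file via
    ``lol_path``); ``atom_name_map`` maps (residue number, atom name) to proton
    indices, with pseudo-atom names expanding to several protons. 1-based
    residue numbers in the files are the caller's convention; atom indices in
    the returned set are 0-based.
    """
    if dialect == "native":
        return _parse_native(path)
    if dialect == "upl-lol":
        if atom_name_map is None:
            raise InputError("upl-lol dialect requires an atom_name_map")
        return _parse_upl_lol(path, lol_path, atom_name_map, deltas or {})
    raise InputError(f"unknown restraint dialect {dialect!r}")


def _parse_native(path: str) -> RestraintSet:
    rs = RestraintSet()
    n_lines = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            cols = [c.strip() for c in line.split("|")]
            if cols[0] == "TOR":
                if len(cols) != 5:
                    raise InputError(f"line {line_no}: torsion line needs 5 columns")
                quad = tuple(int(x) for x in cols[1].split(","))
                rs.torsion.append(
                    TorsionRestraint(
                        atoms=quad,
                        interval=(float(cols[2]), float(cols[3])),
                        k=float(cols[4]),
                    )
                )
                continue
            if len(cols) not in (5, 6, 7, 8):
                raise InputError(f"line {line_no}: expected 5-8 columns, got {len(cols)}")
            ga = _parse_group(cols[0], line_no)
            gb = _parse_group(cols[1], line_no)
            lower, upper = float(cols[2]), float(cols[3])
            method = cols[4] if len(cols) > 4 else "qmin"
            weight = float(cols[5]) if len(cols) > 5 else DEFAULT_DISTANCE_WEIGHT
            da = float(cols[6]) if len(cols) > 6 else 0.0
            db = float(cols[7]) if len(cols) > 7 else 0.0
            rs.distance.append(
                DistanceRestraint(
                    group_a=SpinGroup(ga, delta=da),
                    group_b=SpinGroup(gb, delta=db),
                    lower=lower,
                    upper=upper,
                    method=method,
                    weight=weight,
                )
            )
    if n_lines == 0:
        log.warning("restraint file %s is empty", path)
    return rs


def _parse_bound_file(path, atom_name_map, deltas):
    entries = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) != 7:
                raise InputError(f"{path} line {line_no}: expected 7 fields")
            res_a, _, name_a, res_b, _, name_b = toks[0], toks[1], toks[2], toks[3], toks[4], toks[5]
            bound = float(toks[6])
            key_a, key_b = (int(res_a), name_a), (int(res_b), name_b)
            for key in (key_a, key_b):
                if key not in atom_name_map:
                    raise InputError(
                        f"{path} line {line_no}: unknown atom {key[1]!r} in residue {key[0]}"
                    )
            ga, gb = tuple(atom_name_map[key_a]), tuple(atom_name_map[key_b])
            entries.append(((ga, gb), bound, line_no))
    return entries


def _parse_upl_lol(upl_path, lol_path, atom_name_map, deltas):
    uppers = _parse_bound_file(upl_path, atom_name_map, deltas)
    lowers = _parse_bound_file(lol_path, atom_name_map, deltas) if lol_path else []
    lower_by_pair: dict = {}
    for (ga, gb), bound, _ in lowers:
        lower_by_pair[frozenset((ga, gb))] = bound
    rs = RestraintSet()
    for (ga, gb), upper, line_no in uppers:
        lower = lower_by_pair.get(frozenset((ga, gb)), 0.0)
        if upper < lower:
            raise InputError(
                f"upl line {line_no}: upper {upper} < merged lower {lower}"
            )
        rs.distance.append(
            DistanceRestraint(
                group_a=SpinGroup(ga, delta=deltas.get(ga, 0.0)),
                group_b=SpinGroup(gb, delta=deltas.get(gb, 0.0)),
                lower=lower,
                upper=upper,
                method="qmin",
            )
        )
    return rs


def write_violation_report(report: list[dict], path: str) -> None:
    """Write a per-restraint violation report as TSV or JSON (by extension)."""
    import json

    if str(path).endswith(".json"):
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, default=list)
        return
    cols = ["kind", "value", "violation", "penalty"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in report:
            fh.write(
                "\t".join(
                    f"{row[c]:.4f}" if isinstance(row[c], float) else str(row[c])
                    for c in cols
                )
                + "\n"
            )


def write_restraints(rs: RestraintSet, path: str) -> None:
    """Write a RestraintSet in the native TSV dialect (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write("# group_a | group_b | lower | upper | method | weight | delta_a | delta_b\n")
        for r in rs.distance:
            fh.write(
                f"{_format_group(r.group_a)} | {_format_group(r.group_b)} | "
                f"{r.lower:.4f} | {r.upper:.4f} | {r.method} | {r.weight:.4f} | "
                f"{r.group_a.delta:.4f} | {r.group_b.delta:.4f}\n"
            )
        for t in rs.torsion:
            lo, hi = t.well
            fh.write(
                f"TOR | {','.join(str(a) for a in t.atoms)} | {lo:.4f} | {hi:.4f} | {t.k:.4f}\n"
            )
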