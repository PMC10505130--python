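"""End-to-end analog workflow: restraint transfer -> restrained search ->
fragment-anchored pose -> unrestrained search -> strain.

This is the glue the scoring stage relies on: the unrestrained (global)
search is seeded with the predicted pose, which guarantees that the global
pool contains a relaxation of the bound conformer and therefore that strain
is non-negative.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from .chem import Conformer, Molecule
from .fragments import (
    ConformationalPreference,
    FragmentMatch,
    instantiate_torsion_restraints,
    match_fragment,
    predict_pose,
)
from .restraints import RestraintSet
from .scoring import StrainEstimate, estimate_strain
from .search import (
    ConformerPool,
    SearchSettings,
    deep_search,
    embed_conformer,
    low_energy_pool,
    minimize,
)

__all__ = ["AnalogResult", "predict_analog"]


@dataclass
class AnalogResult:
    analog: Molecule
    match: FragmentMatch | None
    pose: Conformer | None
    anchor_rmsd: float | None
    restrained_pool: ConformerPool
    global_pool: ConformerPool
    strain_estimate: StrainEstimate | None

    @property
    def strain(self) -> float | None:
        return None if self.strain_estimate is None else self.strain_estimate.strain


def predict_analog(
    analog: Molecule,
    preference: ConformationalPreference,
    reference: Conformer,
    settings: SearchSettings,
    tolerance: float = 20.0,
    k: float = 20.0,
    lam: float = 0.05,
    extra_restraints: RestraintSet | None = None,
    global_settings: SearchSettings | None = None,
) -> AnalogResult:
    """Run the full restrained-search / pose / strain workflow for one analog.

    ``reference`` is the lead conformer the preference was extracted from
    (the pose frame). When no preference fragment matches, the restrained
    stage degenerates to an unrestrained search and no pose or strain is
    produced.
    """
    match = match_fragment(preference, analog)
    rs = RestraintSet()
    if extra_restraints is not None:
        rs.distance.extend(extra_restraints.distance)
        rs.torsion.extend(extra_restraints.torsion)
    if match is not None:
        rs.torsion.extend(
            instantiate_torsion_restraints(match, analog, tolerance=tolerance, k=k)
        )
    restrained = deep_search(analog, settings, rs if len(rs) else None)
    pose = anchor = strain = None
    gsettings = replace(
        global_settings or settings,
        seed=(global_settings or settings).seed + 104729,
    )
    if match is not None:
        frag = preference.fragments[match.fragment_index]
        candidates = low_energy_pool(restrained, settings.consolidation_window)
        pose, anchor = predict_pose(candidates, reference, frag, match, lam=lam)
        # global search seeded from a relaxation of the pose (guarantees
        # strain >= 0) plus an independent embedding (so it is not trapped
        # in the pose basin)
        pose_relaxed = minimize(pose, None, settings)
        independent = minimize(embed_conformer(analog, seed=gsettings.seed + 1), None, settings)
        global_pool = deep_search(
            analog, gsettings, None, seeds=[pose_relaxed, independent]
        )
        bound = pose.copy(energy=pose.energy)
        strain = estimate_strain(bound, global_pool)
    else:
        global_pool = deep_search(analog, gsettings, None)
    return AnalogResult(
        analog=analog,
        match=match,
        pose=pose,
        anchor_rmsd=anchor,
        restrained_pool=restrained,
        global_pool=global_pool,
        strain_estimate=strain,
    )
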