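"""Shared fixtures. Expensive search products are session-scoped and cached
inside macroconf.fixtures, so every test file sees the same objects."""
from __future__ import annotations

import numpy as np
import pytest

from macroconf import fixtures as fx
from macroconf.chem import AtomMap, load_molecule


@pytest.fixture(scope="session")
def hexapeptide():
    """The cyclic-hexapeptide fixture with its reference-effort target."""
    return fx.make_cyclic_peptide(fx.FixtureSpec())


@pytest.fixture(scope="session")
def hexapeptide_restraints(hexapeptide):
    return fx.synthesize_restraints(hexapeptide)


@pytest.fixture(scope="session")
def backbone_map(hexapeptide):
    return AtomMap(tuple((i, i) for i in hexapeptide.backbone))


@pytest.fixture(scope="session")
def series_ground_truth():
    """Reference-effort ground truth for the analog series (cached)."""
    return fx.make_analog_series(fx.SERIES_SPEC, fx.DEFAULT_EDITS, effort="reference")


@pytest.fixture(scope="session")
def series_predictions():
    """Standard-effort pipeline predictions for the same series."""
    return fx.make_analog_series(
        fx.SERIES_SPEC, fx.DEFAULT_EDITS, effort="standard", oracle_seed=5
    )


@pytest.fixture(scope="session")
def transfer_poses():
    """Restrained-search poses for the close-analog (preference-sharing) set."""
    from dataclasses import replace

    from rdkit import Chem

    from macroconf.chem import Molecule
    from macroconf.fragments import instantiate_torsion_restraints, match_fragment, predict_pose
    from macroconf.restraints import RestraintSet
    from macroconf.search import deep_search, low_energy_pool

    lead = fx.make_cyclic_peptide(fx.SERIES_SPEC, effort="target")
    pref = fx.default_preference(lead)
    out = []
    mols = [(lead.molecule.name, lead.molecule)]
    for pos, code in fx.TRANSFER_EDITS:
        espec = fx.apply_edit(fx.SERIES_SPEC, pos, code)
        rd = Chem.MolFromSmiles(fx._sequence_smiles(espec.sequence, espec.closure))
        mols.append((f"cyclo-{espec.sequence}", Molecule(Chem.AddHs(rd), name=f"cyclo-{espec.sequence}")))
    settings = replace(fx.EFFORT["standard"], seed=17)
    for name, mol in mols:
        match = match_fragment(pref, mol)
        restraints = instantiate_torsion_restraints(match, mol)
        pool = deep_search(mol, settings, RestraintSet(torsion=list(restraints)))
        frag = pref.fragments[match.fragment_index]
        pose, _ = predict_pose(
            low_energy_pool(pool, settings.consolidation_window), lead.target, frag, match
        )
        out.append((name, mol, restraints, pose))
    return out


@pytest.fixture
def butane():
    return load_molecule("CCCC", name="butane")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
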