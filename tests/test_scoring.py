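"""Strain arithmetic, combined scores, and rank statistics."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from macroconf.chem import InputError
from macroconf.scoring import (
    estimate_strain,
    kendall_tau_with_ties,
    ligand_based_score,
    pairwise_rank_accuracy,
    pose_rmsd_summary,
    rank_report,
    score_analogs,
    structure_based_score,
)
from macroconf.search import ConformerPool, embed_conformer, minimize


@pytest.fixture
def pool_and_pose(butane):
    base = minimize(embed_conformer(butane, seed=1))
    lo = base.copy(energy=10.0)
    hi = base.copy(energy=15.0, provenance="pose")
    pool = ConformerPool(butane, [lo, hi])
    return pool, hi, lo


class TestStrain:
    def test_pose_at_global_minimum_zero(self, pool_and_pose):
        pool, _, lo = pool_and_pose
        est = estimate_strain(lo.copy(provenance="pose"), pool)
        assert est.strain == 0.0

    def test_arithmetic(self, pool_and_pose):
        pool, hi, _ = pool_and_pose
        est = estimate_strain(hi, pool)
        assert est.e_bound == 15.0 and est.e_globalmin == 10.0 and est.strain == 5.0

    def test_negative_strain_rejected(self, pool_and_pose):
        pool, _, lo = pool_and_pose
        bad_pose = lo.copy(energy=9.0)
        with pytest.raises(InputError):
            estimate_strain(bad_pose, pool)

    def test_cross_molecule_rejected(self, pool_and_pose):
        from macroconf.chem import load_molecule

        pool, hi, _ = pool_and_pose
        other = load_molecule("CCC")
        other_pose = minimize(embed_conformer(other, seed=1))
        with pytest.raises(InputError):
            estimate_strain(other_pose, pool)


class TestScores:
    @pytest.mark.parametrize("strain,expected", [(5.0, -19.0), (24.0, 0.0), (0.0, -24.0)])
    def test_ligand_score_offset(self, strain, expected):
        assert ligand_based_score(strain) == pytest.approx(expected)

    def test_structure_score(self):
        assert structure_based_score(-30.0, 5.0) == -25.0
        assert structure_based_score(-30.0, 0.0) == -30.0

    def test_equal_intermolecular_ranking_is_strain_ranking(self):
        strains = [1.0, 7.0, 3.0]
        scores = [structure_based_score(-20.0, s) for s in strains]
        assert np.argsort(scores).tolist() == np.argsort(strains).tolist()


class TestKendallTau:
    def test_identical_orderings(self):
        tau, _ = kendall_tau_with_ties([1, 2, 3, 4], [10, 20, 30, 40], 0.0)
        assert tau == pytest.approx(1.0)

    def test_thresholded_example(self):
        # pairs within 5 on pred are tied: C=3, D=0, tied=3
        tau, _ = kendall_tau_with_ties([1, 2, 3, 10], [1, 2, 3, 4], 5.0)
        assert tau == pytest.approx(3.0 / np.sqrt(3.0 * 6.0), abs=1e-12)

    def test_threshold_zero_matches_scipy_taub(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 12))
            pred = rng.integers(0, 6, size=n).astype(float)  # force some ties
            expt = rng.integers(0, 6, size=n).astype(float)
            ref = stats.kendalltau(pred, expt, variant="b").statistic
            if np.isnan(ref):
                continue
            tau, _ = kendall_tau_with_ties(pred, expt, 0.0)
            assert tau == pytest.approx(ref, abs=1e-12)

    def test_threshold_matches_bruteforce_counting(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 10))
            pred = rng.normal(size=n) * 5
            expt = rng.normal(size=n) * 5
            thr = float(rng.uniform(0, 4))
            tau, _ = kendall_tau_with_ties(pred, expt, thr)
            C = D = Tp = Te = 0
            for i in range(n - 1):
                for j in range(i + 1, n):
                    dp, de = pred[j] - pred[i], expt[j] - expt[i]
                    pt = dp == 0 or abs(dp) < thr
                    et = de == 0
                    Tp += pt
                    Te += et
                    if pt or et:
                        continue
                    if (dp > 0) == (de > 0):
                        C += 1
                    else:
                        D += 1
            n0 = n * (n - 1) // 2
            expected = (C - D) / np.sqrt((n0 - Tp) * (n0 - Te))
            assert tau == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry(self, rng):
        pred = rng.normal(size=8) * 4
        expt = rng.normal(size=8) * 4
        t1, _ = kendall_tau_with_ties(pred, expt, 2.0)
        t2, _ = kendall_tau_with_ties(-pred, expt, 2.0)
        assert t1 == pytest.approx(-t2, abs=1e-12)

    def test_raising_threshold_never_adds_discordant_pairs(self, rng):
        def discordant(pred, expt, thr):
            d = 0
            n = len(pred)
            for i in range(n - 1):
                for j in range(i + 1, n):
                    dp, de = pred[j] - pred[i], expt[j] - expt[i]
                    if dp == 0 or abs(dp) < thr or de == 0:
                        continue
                    if (dp > 0) != (de > 0):
                        d += 1
            return d

        pred = rng.normal(size=10) * 5
        expt = rng.normal(size=10) * 5
        counts = [discordant(pred, expt, t) for t in (0.0, 1.0, 2.0, 4.0, 8.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_all_tied_undefined(self):
        with pytest.raises(InputError):
            kendall_tau_with_ties([1.0, 1.0, 1.0], [1, 2, 3], 0.0)


class TestPairwiseAccuracy:
    def test_concordant_and_anticoncordant(self):
        assert pairwise_rank_accuracy([1, 2, 3], [1, 2, 3], 0.5) == 1.0
        assert pairwise_rank_accuracy([1, 2, 3], [3, 2, 1], 0.5) == 0.0

    def test_matches_bruteforce(self, rng):
        pred = rng.normal(size=6) * 5
        expt = rng.normal(size=6) * 5
        gap = 2.0
        good = total = 0
        for i in range(5):
            for j in range(i + 1, 6):
                dp, de = pred[j] - pred[i], expt[j] - expt[i]
                if abs(dp) < gap or dp == 0 or de == 0:
                    continue
                total += 1
                good += (dp > 0) == (de > 0)
        assert pairwise_rank_accuracy(pred, expt, gap) == pytest.approx(good / total)

    def test_no_qualifying_pairs_undefined(self):
        with pytest.raises(InputError):
            pairwise_rank_accuracy([1.0, 1.1], [1, 2], 5.0)


class TestPoseRmsdSummary:
    def test_identical_poses_full_fraction(self, butane):
        conf = minimize(embed_conformer(butane, seed=1))
        pools = [ConformerPool(butane, [conf.copy()]) for _ in range(3)]
        table = pose_rmsd_summary([conf.copy()] * 3, [conf.copy()] * 3, pools)
        assert table.loc[table["rmsd"] >= 0.25, "frac_predicted"].iloc[0] == 1.0

    def test_pessimistic_dominates_predicted(self, butane):
        c1 = minimize(embed_conformer(butane, seed=1))
        c2 = minimize(embed_conformer(butane, seed=9))
        c2.energy = c1.energy + 1.0
        pool = ConformerPool(butane, [c1.copy(), c2])
        table = pose_rmsd_summary([c1.copy()], [c1.copy()], [pool], window=10.0)
        per = table.attrs["per_analog"]
        assert (per["pessimistic"] >= per["predicted"]).all()

    def test_three_analog_table_matches_hand_enumeration(self, butane):
        c1 = minimize(embed_conformer(butane, seed=1))
        poses, refs, pools = [], [], []
        for seed in (1, 5, 9):
            p = minimize(embed_conformer(butane, seed=seed))
            poses.append(p)
            refs.append(c1.copy())
            pools.append(ConformerPool(butane, [p.copy()]))
        from macroconf.chem import rmsd

        expected = [rmsd(c1, p, superimpose=True, symmetry=True) for p in poses]
        table = pose_rmsd_summary(poses, refs, pools)
        grid = table["rmsd"].to_numpy()
        for r, frac in zip(grid, table["frac_predicted"]):
            assert frac == pytest.approx(np.mean([e <= r for e in expected]))


class TestScoreAnalogs:
    def test_join_and_derived_columns(self):
        activity = pd.DataFrame(
            {"id": ["a", "b"], "pIC50": [8.0, 6.0], "intermolecular": [-30.0, -28.0]}
        )
        df = score_analogs(activity, {"a": 2.0, "b": 10.0})
        assert df["ligand_score"].tolist() == [-22.0, -14.0]
        assert df["structure_score"].tolist() == [-28.0, -18.0]
        assert df["expt_kcal"].tolist() == pytest.approx([-10.912, -8.184])

    def test_missing_strain_rejected(self):
        activity = pd.DataFrame({"id": ["a", "b"], "pIC50": [8.0, 6.0]})
        with pytest.raises(InputError):
            score_analogs(activity, {"a": 2.0})

    def test_rank_report_fields(self, rng):
        pred = rng.normal(size=10) * 6
        expt = pred + rng.normal(size=10)
        rep = rank_report(pred, expt, tie_threshold=5.0, gap=5.0)
        assert -1 <= rep.tau_exact <= 1
        assert -1 <= rep.tau_tied <= 1
        assert 0 <= rep.pairwise_accuracy <= 1
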