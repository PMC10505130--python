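"""Bound-ligand strain estimation, analog scores, and rank-quality statistics.

Strain is the conformational energy of the bound pose minus the global
minimum conformational energy from an unrestrained search of the same
molecule with the same force field. Two scores are derived from it: a purely
ligand-based score (strain plus a constant offset of -24.0 kcal/mol that puts
it on a rough binding-enthalpy scale) and a structure-based score
(externally supplied intermolecular energy plus strain). Rank quality against
experiment is summarized with a tie-thresholded Kendall tau-b, Pearson r and
a pairwise ranking accuracy at a stated prediction gap.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chem import AtomMap, Conformer, InputError, rmsd
from .search import ConformerPool, low_energy_pool

__all__ = [
    "StrainEstimate",
    "AnalogScore",
    "RankReport",
    "estimate_strain",
    "ligand_based_score",
    "structure_based_score",
    "kendall_tau_with_ties",
    "pairwise_rank_accuracy",
    "pose_rmsd_summary",
    "rank_report",
    "score_analogs",
]

LIGAND_SCORE_OFFSET = -24.0  # kcal/mol, puts strain on a rough binding-enthalpy scale
PKD_PER_KCAL = -1.364  # display-only conversion kcal/mol -> pK_d units


@dataclass(frozen=True)
class StrainEstimate:
    e_bound: float
    e_globalmin: float
    provenance: str = ""

    @property
    def strain(self) -> float:
        return self.e_bound - self.e_globalmin


@dataclass
class AnalogScore:
    compound_id: str
    strain: float
    intermolecular: float | None = None
    pic50: float | None = None
    offset: float = LIGAND_SCORE_OFFSET

    @property
    def ligand_score(self) -> float:
        return self.strain + self.offset

    @property
    def structure_score(self) -> float | None:
        if self.intermolecular is None:
            return None
        return self.intermolecular + self.strain


@dataclass
class RankReport:
    tau_exact: float
    p_exact: float
    tau_tied: float
    p_tied: float
    pearson_r: float
    pairwise_accuracy: float
    tie_threshold: float
    gap: float
    table: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def estimate_strain(pose: Conformer, global_pool: ConformerPool) -> StrainEstimate:
    """Strain = pose conformational energy minus the global pool minimum.

    The pipeline seeds the unrestrained (global) search with the bound
    conformer, so a correctly assembled input can never give negative strain;
    a value below -0.01 kcal/mol means the global pool was not global.
    """
    if pose.molecule is not global_pool.molecule:
        raise InputError("pose and global pool belong to different molecules")
    if pose.energy is None:
        raise InputError("pose has no energy")
    est = StrainEstimate(
        e_bound=float(pose.energy),
        e_globalmin=float(global_pool.min_energy),
        provenance=f"pose:{pose.provenance};global:{global_pool.provenance}",
    )
    if est.strain < -0.01:
        raise InputError(
            f"negative strain {est.strain:.3f}: global pool does not contain "
            "a conformer at least as low as the pose (seed it with the pose)"
        )
    return est


def ligand_based_score(strain: float, offset: float = LIGAND_SCORE_OFFSET) -> float:
    """Strain plus a constant offset (-24.0 kcal/mol); more negative = better."""
    if not math.isfinite(strain):
        raise InputError("strain must be finite")
    return strain + offset


def structure_based_score(intermolecular: float, strain: float) -> float:
    """Intermolecular energy plus bound strain: the enthalpic estimate."""
    if not (math.isfinite(intermolecular) and math.isfinite(strain)):
        raise InputError("inputs must be finite")
    return intermolecular + strain


def _as_vectors(pred, expt):
    p = np.asarray(pred, dtype=float)
    e = np.asarray(expt, dtype=float)
    if p.shape != e.shape or p.ndim != 1:
        raise InputError("pred and expt must be equal-length 1D vectors")
    if p.size < 2:
        raise InputError("need at least two observations")
    return p, e


def kendall_tau_with_ties(
    pred, expt, tie_threshold: float = 0.0
) -> tuple[float, float]:
    """Kendall tau-b where prediction pairs within ``tie_threshold`` are ties.

    A pair is tied on the predictions when |dpred| < tie_threshold or exactly
    equal; experimental ties are exact-value ties. tau-b normalization:
    (C - D) / sqrt((n0 - n_tied_pred) (n0 - n_tied_expt)). The p-value uses
    the standard normal approximation for tau (approximate for small n and
    in the presence of threshold ties).
    """
    p, e = _as_vectors(pred, expt)
    if tie_threshold < 0:
        raise InputError("tie threshold must be >= 0")
    n = p.size
    conc = disc = tied_p = tied_e = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dp = p[j] - p[i]
            de = e[j] - e[i]
            p_tied = dp == 0.0 or abs(dp) < tie_threshold
            e_tied = de == 0.0
            if p_tied:
                tied_p += 1
            if e_tied:
                tied_e += 1
            if p_tied or e_tied:
                continue
            if (dp > 0) == (de > 0):
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - tied_p) * (n0 - tied_e))
    if denom == 0:
        raise InputError("all pairs tied: tau undefined")
    tau = (conc - disc) / denom
    z = 3.0 * tau * math.sqrt(n * (n - 1)) / math.sqrt(2.0 * (2 * n + 5))
    pval = 2.0 * stats.norm.sf(abs(z))
    return tau, pval


def pairwise_rank_accuracy(pred, expt, gap: float) -> float:
    """Among pairs with |dpred| >= gap (experimental exact ties excluded),
    the fraction ranked in the same order by prediction and experiment."""
    p, e = _as_vectors(pred, expt)
    if gap < 0:
        raise InputError("gap must be >= 0")
    good = total = 0
    n = p.size
    for i in range(n - 1):
        for j in range(i + 1, n):
            dp = p[j] - p[i]
            de = e[j] - e[i]
            if abs(dp) < gap or dp == 0.0 or de == 0.0:
                continue
            total += 1
            if (dp > 0) == (de > 0):
                good += 1
    if total == 0:
        raise InputError("no qualifying pairs at this gap")
    return good / total


def pose_rmsd_summary(
    poses: list[Conformer],
    references: list[Conformer],
    pools: list[ConformerPool],
    window: float = 10.0,
    maps: list[AtomMap] | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Predicted and pessimistic pose accuracy per analog, plus a cumulative table.

    For each analog the predicted RMSD is pose-vs-reference; the pessimistic
    RMSD is the most deviant member of the low-energy pool (within ``window``
    kcal/mol of the pool minimum). Returns a DataFrame with one row per grid
    radius and cumulative fractions of analogs at or below it; per-analog
    values are attached as ``df.attrs['per_analog']``.
    """
    if not (len(poses) == len(references) == len(pools)):
        raise InputError("poses, references and pools must be matched lists")
    if maps is None:
        maps = [None] * len(poses)
    rows = []
    for pose, ref, pool, amap in zip(poses, references, pools, maps):
        if len(pool) == 0:
            continue
        predicted = rmsd(ref, pose, amap, superimpose=True, symmetry=True)
        low = low_energy_pool(pool, window)
        pessimistic = max(
            rmsd(ref, c, amap, superimpose=True, symmetry=True) for c in low
        )
        rows.append({"predicted": predicted, "pessimistic": max(predicted, pessimistic)})
    if not rows:
        raise InputError("no analogs with non-empty pools")
    per_analog = pd.DataFrame(rows)
    if grid is None:
        grid = np.arange(0.0, 3.01, 0.25)
    table = pd.DataFrame(
        {
            "rmsd": grid,
            "frac_predicted": [
                float((per_analog["predicted"] <= r).mean()) for r in grid
            ],
            "frac_pessimistic": [
                float((per_analog["pessimistic"] <= r).mean()) for r in grid
            ],
        }
    )
    table.attrs["per_analog"] = per_analog
    return table


def rank_report(
    pred, expt, tie_threshold: float = 5.0, gap: float = 5.0, table: pd.DataFrame | None = None
) -> RankReport:
    """Full rank-quality summary of predicted scores against experiment.

    ``expt`` should be oriented so that concordance means agreement (e.g.
    experimental binding energies in kcal/mol against predicted scores, both
    negative-is-better).
    """
    p, e = _as_vectors(pred, expt)
    tau0, p0 = kendall_tau_with_ties(p, e, 0.0)
    taut, pt = kendall_tau_with_ties(p, e, tie_threshold)
    r = float(stats.pearsonr(p, e).statistic)
    acc = pairwise_rank_accuracy(p, e, gap)
    return RankReport(
        tau_exact=tau0,
        p_exact=p0,
        tau_tied=taut,
        p_tied=pt,
        pearson_r=r,
        pairwise_accuracy=acc,
        tie_threshold=tie_threshold,
        gap=gap,
        table=table if table is not None else pd.DataFrame(),
    )


def score_analogs(
    activity: pd.DataFrame,
    strains: dict[str, float],
    offset: float = LIGAND_SCORE_OFFSET,
) -> pd.DataFrame:
    """Join an activity table (columns: id, pIC50[, intermolecular]) with
    computed strains into a scored table.

    Adds ligand_score (strain + offset), structure_score where intermolecular
    is present, and expt_kcal = -1.364 * pIC50 (binding free energy scale,
    negative-is-better, so concordance with the scores means agreement).
    """
    if "id" not in activity.columns or "pIC50" not in activity.columns:
        raise InputError("activity table needs 'id' and 'pIC50' columns")
    df = activity.copy()
    df["strain"] = df["id"].map(strains)
    if df["strain"].isna().any():
        missing = df.loc[df["strain"].isna(), "id"].tolist()
        raise InputError(f"no strain for compounds: {missing}")
    df["ligand_score"] = df["strain"] + offset
    if "intermolecular" in df.columns:
        df["structure_score"] = df["intermolecular"] + df["strain"]
    df["expt_kcal"] = PKD_PER_KCAL * df["pIC50"]
    return df
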