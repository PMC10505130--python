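# Methods

## Problem setting

Macrocyclic peptides (here: 3–8-residue cyclic peptides, head-to-tail or
thioether-closed) bind their targets in conformations whose accessibility in
solution — pre-organization — is a major determinant of affinity. The toolkit
implements a restrained conformational-analysis workflow around three pieces
of machinery: NMR-style distance restraints over chemically equivalent spin
groups, square-well torsional restraints transferred from a lead conformer to
analogs by subgraph matching, and an iterative clustered-restart
conformational search. Analogs are scored by bound-ligand strain: the
conformational energy of the predicted bound pose minus the global-minimum
conformational energy of the free ligand.

## Spin-group distances

Chemically equivalent protons (methyl rotors, flipping aromatic pairs) share
one NMR signal, so a distance restraint addresses groups *a*, *b* rather than
atoms. Three treatments are implemented for the effective group–group
distance:

- `r6` — the r⁻⁶-averaged distance
  `r_eff = ((1/(n_a n_b)) Σ_ij r_ij⁻⁶)^(-1/6)`, the physically motivated
  NOE average;
- `center` — centroid-to-centroid distance plus an additive pseudo-atom
  correction `δ_ab = δ_a + δ_b` (defaults per group: methyl 1.0 Å, geminal
  methylene 0.9 Å, aromatic equivalent pair 2.0 Å, singleton 0 Å);
- `qmin` — the minimum pairwise proton–proton distance, a cheap lower
  approximation to `r_eff` whose derivative involves only the two atoms
  realizing the minimum. `qmin ≤ r_eff` holds for every geometry, and all
  three treatments coincide for singleton pairs with δ = 0.

All restraint penalties share one square-well quadratic form: zero inside the
allowed band, `k·v²` in the violation `v` outside, C¹-continuous at the
edges. Distance violations use the configured effective distance directly;
torsion violations are circular distances (degrees wrapped into (−180, 180],
converted to radians before squaring). Defaults: distance weight
50 kcal/mol/Å², torsion k = 20 kcal/mol/rad², torsion tolerance ±20°. The
defaults are deliberate compromises: wide enough that a restrained
minimization can relax real geometry, stiff enough to dominate single-bond
rotation barriers.

Backbone φ restraints can also be derived from amide ³J(HN–Hα) couplings via
a modified Karplus relation `J = A cos²θ + B cosθ + C`, θ = φ − 60°, with
coefficients (6.51, −1.76, 1.60) — a standard published parameterization,
exposed as configurable since other parameter sets are in circulation.
Couplings strictly above 8.0 Hz yield the extended-backbone interval
restraint φ ∈ [−155°, −95°]; the comparison is strict, so J = 8.0 Hz yields
no restraint.

## Force field and restrained minimization

Conformational energies come from MMFF94 as implemented in RDKit. Restrained
local minimization attaches flat-bottom distance and torsion constraint terms
to the RDKit force field. Group distance restraints are enforced during
minimization through the current minimum-distance proton pair — the qmin
treatment, chosen precisely because its gradient involves only that pair —
and the pair is re-selected between up to three minimization passes until it
is self-consistent. Reported penalties are always evaluated exactly under the
restraint's configured method (r6/center/qmin). Stored conformer energies
are force-field-only; penalties live in conformer metadata, so strain
arithmetic always compares like with like.

## Conformational search

One search round is a seeded multi-start procedure. Each start perturbs a
random subset of rotatable torsions (probability 0.6 per torsion, kick
magnitude itself randomized between 20% and 100% of 150° so a round mixes
coarse basin-hopping with fine exploration). Macrocycle ring torsions are
sampled by transiently snipping a single bond exclusive to the largest ring,
rotating in the resulting open chain, and letting the force field's bond term
re-close the ring during minimization. A quarter of the starts begin from
fresh ETKDG distance-geometry embeddings, which sample ring conformations
more broadly than torsion kicks. Candidates whose re-closure fails (bond
lengths outside 0.7–2.6 Å) or whose 3D geometry no longer realizes the
molecular graph's chiral tags — ring perturbation can push a stereocenter
through planarity, and the force field will not push it back — are discarded.
Under restraints, each start is minimized twice: once with the restraint
weights boosted ×10 (to pull the geometry into the allowed region) and once
at final weight ×1 (so reported energies are not restraint-dominated).

The deep protocol iterates rounds: after each round the accumulated pool is
consolidated into a non-redundant set (no two members within 0.5 Å
symmetry-corrected heavy-atom RMSD, lowest energy kept) inside a 10 kcal/mol
consolidation window, then clustered by greedy leader clustering in ascending
energy order. If any of the N (default 10) lowest-energy clusters is new —
its representative farther than the RMSD threshold from every previous
round's representatives — the next round restarts from the new clusters'
lowest-energy conformers; otherwise the search stops. A hard cap of 20
rounds guards pathological cases and is reported as a non-convergence flag.
Fixed seeds make every stage bit-reproducible: all stochastic choices flow
from one `numpy` generator, ETKDG seeds and per-round seeds are derived
deterministically, and SDF serialization uses fixed atom order and fixed
float formats.

RMSD comparisons are symmetry-corrected: the minimum over heavy-atom graph
automorphisms that permute the mapped atoms among themselves, so a phenyl
flip does not split clusters. Reported RMSDs therefore may be lower than
naive per-index values; this is a deliberate choice, since macrocycle side
chains contain symmetric rings.

## Preference transfer and pose prediction

A conformational preference is an ordered list of 3D subfragments extracted
from a lead conformer (most restrained first). Restrainable torsions are all
single bonds of the fragment with both atoms non-terminal, ring bonds
included — macrocycle backbone torsions are the point. For a new analog the
fragments are tried in order; the first with a subgraph embedding (element
and bond order, hydrogens and stereo tags excluded; stereo differences are
penalized by energy, not by match failure) wins, with the lowest
lexicographic analog-index embedding as the deterministic tie-break. Matched
torsions become square-well restraints whose targets are the dihedrals
measured on the fragment's reference geometry; torsions whose mapped bond
path no longer exists in the analog (e.g. a ring contraction) are skipped
with a warning.

Bound-pose prediction is fragment-anchored: every restrained conformer is
rigidly superposed (Kabsch, proper rotations only) onto the lead reference
over the matched fragment atoms, and the pose minimizing
`anchor RMSD + λ·(E − E_min)` is selected, λ = 0.05 Å/(kcal/mol). The
λ-term keeps a marginally better-anchored but strongly strained conformer
from displacing a relaxed one. Pose selection is invariant to rigid motion of
the input pool.

## Strain and scoring

`strain = E_bound − E_globalmin`, both energies MMFF94 from the same
machinery. The unrestrained (global) search is seeded with a relaxation of
the predicted pose plus an independent embedding: the former guarantees
strain ≥ 0 by construction, the latter prevents the global search from being
trapped in the pose basin. A strain below −0.01 kcal/mol is treated as an
internal-consistency error.

The ligand-based score is strain − 24.0 kcal/mol; the constant offset puts
the score on a rough binding-enthalpy scale and is configurable. The
structure-based score adds an externally supplied intermolecular energy to
the strain; the docking engine that would produce such energies is outside
this package's scope, so the column is an input. Rank quality is summarized
by Kendall τ-b in which prediction pairs closer than a stated threshold
(default 5 kcal/mol) count as ties, by Pearson r, and by pairwise ranking
accuracy among pairs whose predictions differ by at least a stated gap.
Thresholded "ties" are not transitive, so no exact tie-corrected variance
exists; p-values use the standard normal approximation for τ and are
documented as approximate, particularly below n = 10.

## Synthetic fixtures and what they do (and do not) show

The fixture generator builds cyclic peptides from one-letter sequences
(uppercase L-residues, lowercase D-residues, Z = azetidine-2-carboxylic acid,
head-to-tail amide or side-chain thioether closure), derives a target
conformer from a seeded deep search, and synthesizes NOE-emulating restraints
from that target: every inter-residue pair of equivalent-proton groups closer
than 4.5 Å contributes an upper bound of (distance + 0.5 Å padding, qmin
treatment), plus φ interval restraints of ±30° for residues with a defined φ.
The 0.5 Å padding mirrors typical NOE upper-bound slack. By construction the
target satisfies its own restraint set exactly, so restrained-recovery tests
have an unambiguous ground truth.

Two analog series serve different checks. The transfer series applies
side-chain edits (Phe→Ala, Phe→Leu, Ser→Ala, Ala→Val) that leave the lead's
backbone preference accessible; on these, ≥95% of transferred torsions are
expected to hold after restrained search. The strain series additionally
applies α-carbon inversions (L→D). An inverted residue robustly shifts the
analog's own preferred ring geometry away from the transferred preference,
so the forced pose carries 9–20 kcal/mol of strain — the desk-scale
counterpart of removing a conformational lock — while the L-edits carry
essentially zero. The deliberately large spread is what makes the
ground-truth strain ordering stable under search noise; the frustrated
analogs accept a few-tenths-kcal torsion violation in exchange for
kcal-scale relief, which is why they are excluded from the
torsion-fidelity set: the two properties are physically complementary, not
contradictory.

Ground truth is established by re-running the full pipeline at reference
search effort with independent seeds, never hand-edited; strains below the
minimizer's energy resolution (0.01 kcal/mol) are snapped to zero so that
tie ordering is well defined. Problem sizes (tetrapeptide strain series,
hexapeptide recovery fixture, search effort presets of 8×3, 16×6, 40×12 and
56×14 starts×rounds) were chosen so that reference searches reproduce their
global minima across seeds on the rigid fixtures; they are the package's
desk-scale study conditions, not estimates of what production use requires.

What passing these fixtures shows: the restraint mathematics, penalty
shapes, search protocol, transfer machinery and strain arithmetic behave as
specified, deterministically, on molecules small enough that the global
minimum is reliably attainable. What it does not show: performance on
13–15-residue macrocycles with 60+ rotatable bonds, solvent effects (MMFF94
is used with its default dielectric; real NOE-restrained refinement operates
in water), NOE peak-volume calibration, or absolute strain magnitudes
comparable across force fields — vacuum MMFF94 compresses side-chain
strain differences and exaggerates electrostatics relative to production
force fields.

## Numerical conventions

Dihedrals follow the IUPAC sign convention, degrees, wrapped into
(−180, 180]; angular differences are always taken modulo 360 into the same
interval. Atom indices are 0-based internally; 1-based file dialects
(CYANA-like upl/lol residue numbering) are converted at the I/O boundary.
Ties are broken by (energy, insertion order) everywhere a representative or
seed is selected; the qmin arg-min pair tie-breaks on the lowest atom-index
pair. SDF output stores energies in the `E_kcal` tag at 4 decimal places and
coordinates at V2000 precision (10⁻⁴ Å), which defines the granularity of
the determinism guarantees.
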