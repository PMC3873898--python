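# Methods

## Scope and data model

The package analyses ordered frames of backbone coordinates (N, CA, C, O
per residue, single chain) with an optional heme group, as exported to
multi-model PDB. Coordinates are held in Å internally; all reported
observables use nm/nm², the units in which these quantities are usually
quoted. Frame times come from a per-model `REMARK 250 TIME_PS` tag when
present, else from the model index times a configurable stride. Multi-chain
input is rejected: the target system (a monomeric globin) has one chain,
and silently analysing the first chain of an oligomer would be worse than
an error. Atomic masses come from a small built-in element table; unknown
elements fall back to 12 Da with a warning, which only perturbs
COM/R_g weighting.

## Secondary structure

Backbone hydrogen bonds are scored with the classic electrostatic model
E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol (distances in Å),
with a bond recorded when E < −0.5. Amide hydrogens are always re-placed
deterministically at 1.00 Å from N along the preceding carbonyl C←O
direction (first residue and prolines excluded), so assignment never
depends on whether the input file carried hydrogens. Codes follow the
hydrogen-bond repetition patterns: n-turns (n = 3, 4, 5) give G/H/I
minimal helices when two consecutive turns coincide; parallel and
antiparallel bridge patterns give B (isolated) or E (ladders of ≥ 2);
T marks turn residues, S bends with CA virtual angle κ > 70°; priority on
conflict is H > E > B > G > I > T > S.

Dialect choices, stated explicitly:

- at most the two lowest-energy acceptors per donor are kept;
- coincident atoms (< 0.5 Å) score the conventional −9.9 kcal/mol clash value;
- β-bulges are *not* merged into ladders — irrelevant for a helix-dominated
  protein and a significant complexity cost;
- candidate pairs are prefiltered by CA–CA ≤ 9.0 Å. The prefilter is
  verified loss-free against a brute-force all-pairs search in the test
  suite (the longest possible N–H···O=C geometry below the −0.5 kcal/mol
  threshold keeps the Cα atoms well inside 9 Å);
- ties between equal-priority patterns resolve toward the earlier-starting
  run, making assignment deterministic.

"Helical residues" counts codes {H, G, I} by default (a switch restricts
to {H}); helix segments are maximal helical runs, discarding runs shorter
than 4 residues — one full α-turn, and short enough that the truncation
penalty k ≈ 2.6–3 leaves them with essentially no CD signal.

## Ellipticity model

Forward model:
[θ]_222 = ([θ]_helix/N_r)·Σ_i max(r_i − k, 0) + [θ]_RC·(1 − f_H), with
f_H = Σ r_i/N_r. Parameters, units deg·cm²·dmol⁻¹ unless noted:

| parameter | default | meaning |
|---|---|---|
| N_r | 153 | residues in the protein |
| N_h | per call | number of helices assumed for the state |
| k | 2.57 residues | per-helix truncation penalty (typical range 2–5) |
| [θ]_helix | −36,800 | infinite-helix signal (−39,500 for a generic helix) |
| [θ]_RC | +1000 | random-coil signal, weighted by the coil fraction (1 − f_H) |

The inverse model solves the *unclamped* linear form
θ = (θ_helix/N_r)(R − k·N_h) + θ_RC(1 − R/N_r) for R, assuming all
segments exceed k — the appropriate reading when inverting a scalar
measurement, where per-segment lengths are unknown. Clamping applies in
the forward direction only. The random-coil term is applied proportional
to (1 − f_H); this is the reading under which the model reproduces the
published five-state helix-fraction table exactly at two decimals.
Forward∘inverse is an exact algebraic identity (tested to 1e-9) whenever
all segments exceed k and θ is in range.

Rounding is half-away-from-zero at 2 dp for fractions and to the nearest
integer for residue counts, matching how the published tables round. The
published residue row is reproduced within ±2 residues (121/96/87/63/29
against 122/97/88/63/27); the printed row is not consistent with any
single (θ_helix, rounding) choice at ±1, so the ±2 band is documented
rather than tuned away.

Per-frame trajectory traces floor the reported θ at +500 on the positive
side: the model loses meaning as N_h → 0 and the untruncated coil limit
(+1000 here) depends entirely on the θ_RC choice. Scalar calls are never
truncated.

## Trajectory metrics

Superposition is least-squares (Kabsch SVD with determinant sign
correction; reflections never returned), all-CA with no trimming of
flexible tails. R_g is mass-weighted over protein heavy atoms; heme and
hydrogens are opt-in flags since the literature values it is compared to
are protein-only crystal numbers. SASA is Shrake–Rupley with a
deterministic golden-spiral lattice (960 points by default; 240 in
whole-trajectory sweeps, which stays within 1 % of the 960-point value on
our fixtures), probe 1.4 Å, vdW radii N 1.55 / O 1.52 / C 1.70 / S 1.80 Å
and 1.80 Å otherwise. Contact maps default to Cα within 8.0 Å at
|i−j| ≥ 3, compared by Jaccard percent; the definition is conventional and
configurable, since no standard exists.

Heme dissociation uses the distance from the heme Fe to the mass-weighted
centre of mass of residue 93 (the proximal histidine): ≈ 0.64 nm in the
native state, with loss declared at twice that value, 1.28 nm. The
detector reports the first frame at or beyond the threshold.

## Intermediates

Frames are embedded in the (Cα-RMSD to native [nm], main-chain H-bond
count) plane and partitioned by k-means (k-means++ seeding, 10 restarts,
Lloyd iterations, squared-Euclidean assignment; deterministic given the
seed), validated by Euclidean silhouette widths (singletons score 0).
Features are used raw so cluster centres read directly in nm and bond
counts; a `standardize` flag is available. k defaults to 3 — native,
intermediate, unfolded — with a silhouette-over-k scan (k = 2..6) for
model selection. Cluster persistence in time is summarised as maximal
contiguous intervals dominated by one cluster (majority label within a
5-frame window). Plateau detection declares a point flat when the moving
least-squares slope over a window (default 1 ns) is at most
slope_tol × (global range / global duration); it operationalises what is
otherwise judged by eye from time-series plots.

## Synthetic data

The generator emulates the *observables* of a 153-residue hologlobin, not
its sequence or physics: poly-alanine backbones (His at 93) built by NeRF
chain extension with trans-peptide geometry (N–CA 1.458, CA–C 1.525,
C–N 1.329 Å; angles 111.2°/116.2°/121.7°; ω = 180°), helical (−57°, −47°),
strand (−119°, 113°), or seeded coil dihedrals. Carbonyl O and amide H are
placed geometrically. A coil-flanked geometric helix is assigned exactly
its own residue range by the H-bond patterns, so the eight default
segments (122 residues, disjoint with ≥ 3-residue linkers) land where
intended; the native build additionally renders the C-terminal residue of
helices ≥ 16 residues as coil ("end fraying"), putting the assigned
helical count near 117 — matching the observation that solvated native
globins assign ≈ 105–120 helical residues, slightly below crystal
helicity. The native state is compacted by a seeded Monte-Carlo collapse
(random pivot moves on linker residues, accepted when R_g shrinks without
Cα clashes < 3.2 Å) to R_g ≤ 1.8 nm, and a five-atom heme pseudo-group
(Fe + four placeholder nitrogens) is placed 0.64 nm from the His93 centre
of mass. The build verifies its own contract (eight assigned segments,
helical count in band) and retries with a fresh sub-seed otherwise.

Unfolding trajectories hold the intended helical count to
N(t) = residual + (122 − residual)·e^(−λt), removing residues from
segment ends (alternating ends) with the C- and F-analogue segments
weighted 2× — these helices unfold first in thermal denaturation — and
re-dihedralising removed residues to fixed seeded coil values, plus
Gaussian coordinate jitter (default σ = 0.25 Å). Defaults are the studied
unfolding conditions: λ = 0.2 ns⁻¹, 200 frames at 100 ps over 20 ns,
residual core of 20 residues, heme departure at t_loss = 3.7 ns. The heme
Fe follows a piecewise-linear distance schedule that sits at 0.64 nm and
crosses the 1.28 nm criterion exactly at t_loss (ramping on toward
2.5 nm), so detection accuracy is measured against an unambiguous ground
truth. A piecewise-stationary variant (`make_phase_trajectory`) emits
plateau phases for clustering tests, and `make_cluster_blobs` provides
labelled Gaussian fixtures in the (RMSD, H-bond) plane.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: side-chain packing and chemistry, solvent and
force-field energetics, realistic kinetics (barrier recrossings, partial
refolding, β-sheet formation from disordered states), heme–protein
contacts beyond the Fe–His distance, and experimental noise structure.
Recovery tests demonstrate that the *analysis* is correct and unbiased on
data whose generating process is known, not that any particular physical
system behaves this way.

## Problem sizes and budgets

The standard test fixture is 200 frames × 153 residues; assignment and
feature extraction over it take a few seconds each on one CPU, and the
full pipeline (generate → assign → metrics → ellipticity → cluster) runs
in under two minutes. The acceptance script evaluates closed-form model
algebra only and completes in well under a second; it accepts a seed for
interface uniformity even though nothing in it is stochastic.

## Known limitations

- The DSSP dialect omits β-bulge ladder merging and π-helix/chirality
  annotations; sheet-rich inputs will differ from full DSSP output.
- The inverse ellipticity model presumes every surviving helix is longer
  than k; states dominated by 2–3-residue helical fragments violate the
  linearisation (the forward model clamps them correctly).
- SASA uses a generic 1.80 Å radius outside C/N/O/S and ignores hydrogens;
  absolute values differ from all-atom calculators at the few-percent level.
- The compaction heuristic produces *a* compact fold, not the globin fold:
  contact maps of synthetic natives are not comparable to crystal contact
  maps beyond gross statistics.
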