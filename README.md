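# unfoldscope

Analysis toolkit for thermal-unfolding trajectories of holomyoglobin-like
globins. It covers the full post-simulation workflow for a 153-residue,
eight-helix heme protein: secondary-structure assignment from backbone
hydrogen bonds, conversion between helix composition and circular-dichroism
mean residue ellipticity at 222 nm, per-frame structural observables
(Cα RMSD, radius of gyration, SASA, contact maps, Fe–His93 distance),
heme-dissociation detection, and identification of unfolding intermediates
by clustering. A fully seeded synthetic-trajectory generator provides
ground-truth test data, so the entire pipeline is verifiable without any
simulation output on hand.

Intended users: structural bioinformaticians and simulators who export
multi-model PDB trajectories and want reproducible, scriptable unfolding
observables that can be compared directly against CD experiments.

## The core model

The mean residue ellipticity at 222 nm of an all-α protein is dominated by
its helices. With N_r residues, N_h helices of r_i residues each, an
infinite-helix signal [θ]_helix, a per-helix truncation penalty k
(residues), and a random-coil signal [θ]_RC:

    [θ]_222 = ([θ]_helix / N_r) · Σ_i max(r_i − k, 0) + [θ]_RC · (1 − f_H),
    f_H = Σ_i r_i / N_r

Because each helix pays its own truncation penalty k, the inferred helix
fraction for a given measured [θ]_222 depends on how many helices the state
actually retains: partially unfolded states that have lost whole helices
are *less* helical than a naive linear conversion suggests. The inverse
model solves the linear form of the equation for the total helical residue
count R at an assumed N_h.

Default parameters: N_r = 153, k = 2.57, [θ]_RC = +1000, and
[θ]_helix = −36,800 deg·cm²·dmol⁻¹ (myoglobin-optimised; −39,500 for a
generic helix). Secondary structure is assigned with the Kabsch–Sander
electrostatic hydrogen-bond model (H/G/I/E/B/T/S/C codes).

## Worked example

```python
from unfoldscope import EllipticityParams, invert_ellipticity, table2_preset

# A native holo state with [θ]222 = −24,000 and all eight helices:
res = invert_ellipticity(-24000, EllipticityParams(n_h=8))
print(f"f_H = {res.f_h_2dp:.2f}, helix residues = {res.helix_residues_rounded}")

# The five canonical myoglobin states, both infinite-helix calibrations:
print(table2_preset())
```

prints

```
f_H = 0.79, helix residues = 121
                            Holo, pH 7  Apo, pH 7  Apo, pH 6  ApoI, pH 4    I/U
f_H (theta_helix = -39500)        0.75       0.59       0.54        0.39   0.18
f_H (theta_helix = -36800)        0.79       0.63       0.57        0.41   0.19
helix residues                  121.00      96.00      87.00       63.00  29.00
```

i.e. the native holo state is ≈79 % helical (≈121 of 153 residues), while
an acid intermediate at −12,000 with only four surviving helices is 41 %
helical (63 residues) — 0.06 lower than the 0.47 obtained if one wrongly
assumes the native helix count.

A full synthetic pipeline from the shell:

```sh
unfoldscope simulate --preset unfold500K --seed 42 --lambda 0.2 \
    --t-loss-ns 3.7 --frames 200 --out synth.pdb --truth truth.tsv
unfoldscope assign --in synth.pdb --dt-ps 100 --out ss.tsv --raster raster.txt
unfoldscope metrics --in synth.pdb --dt-ps 100 --out metrics.tsv
unfoldscope ellipticity traj --in synth.pdb --dt-ps 100 --out theta.tsv
unfoldscope cluster --in synth.pdb --dt-ps 100 --k 3 --seed 42 \
    --out clusters.tsv --silhouette sil.tsv
```

`metrics` reports `heme lost at t = 3800 ps (threshold 1.28 nm)` for this
fixture (the generator schedules heme departure at 3.7 ns), `assign`
reports helical counts decaying from 117 to ≈15, and `theta.tsv` traces
[θ]222 rising from ≈ −22,000 toward the random-coil limit (truncated at
+500).

## Layout

- `structure_io` — multi-model PDB in/out, backbone validation, amide-H placement
- `secondary_structure` — Kabsch–Sander H-bonds, code assignment, helix segments, decay fits
- `ellipticity` — forward/inverse [θ]222 model, sensitivity tables, trajectory traces
- `trajectory_metrics` — RMSD/superposition, R_g, SASA, contacts, heme criterion
- `intermediates` — (RMSD, H-bond) clustering, silhouettes, plateau detection
- `synthetic_data` — seeded backbone builder, native globin mimic, unfolding/phase trajectories

See `docs/methods.md` for the scientific and numerical details.
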