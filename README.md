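# motoret

Cryo-electron-tomography analysis of flagellar stator–rotor structure, on
synthetic motor phantoms.

## The problem

The torque-generating stator units (MotA/MotB) of the bacterial flagellar
motor are dynamic: they assemble at a ring of discrete sites around the
rotor and their occupancy and the conformation of the rotor's cytoplasmic
C-ring respond to the proton gradient.  In the spirochete *Borrelia
burgdorferi* the motor offers an unusually clean readout: 16 collar-defined
stator sites at a 40 nm radius, a 46-fold C-ring whose wall tilts away from
the rotation axis by a strain-dependent angle (from 7.8° with no stators
down to 1.8° in fully powered wild type), and ring diameters (56/57–59/80
nm) measurable directly from subtomogram averages.

Quantifying those readouts from tomograms requires a chain of
missing-wedge-aware image analysis: subtomogram alignment and Fourier-space
averaging, rotational-symmetry determination, focused classification of the
stator sites into occupied/empty/ambiguous with an occupancy quotient
(occupied / total), and an ellipse fit to the symmetrized C-ring
cross-section whose major-axis angle against the rotation axis is the tilt.
`motoret` implements that chain as a tested, reusable library plus CLI, and
pairs it with a phantom simulator whose ground truth encodes the published
strain geometry — so every estimator is validated by parameter recovery
under a controlled noise and missing-wedge model.

Key quantities, in the field's notation:

* **wedge support** — a frequency **k** is sampled iff the inclination
  ψ = atan2(**k**·ẑ, **k**·(â×ẑ)) lies within the tilt range (±60° here);
  constrained cross-correlation and coverage-normalized Fourier averaging
  operate on these supports.
* **occupancy** — Θ = N_occupied / N_total over classified stator sites;
  mean stators per motor = 16·Θ.
* **C-ring tilt** — angle between the major axis of the intensity-weighted
  second-moment ellipse of the (16-fold symmetrized) C-ring wall
  cross-section and the rotation axis.

See `docs/methods.md` for the full model and estimator descriptions.

## Worked example

Run the full pipeline for the partially-powered `motB`-D24E mutant preset
(10 of 16 stator sites occupied, 3.2° tilt), four motors at SNR 0.5:

```python
from motoret.pipeline import run_strain

report = run_strain({"strain": "D24E", "sim": {"n_motors": 4, "snr": 0.5}},
                    seed=5, output_dir="d24e_out")
print(report.to_dict())
```

which prints (abridged):

```
{'strain': 'D24E', 'n_motors': 4,
 'detected_cring_order': 46, 'detected_collar_order': 16,
 'occupancy': {'n_occupied': 40, 'n_empty': 23, 'n_ambiguous': 1,
               'occupancy': 0.625, 'mean_stators_per_motor': 10.0},
 'tilt': {'tilt_deg': 2.97361, ...},
 'diameters_nm': {'cring_bottom': 56.0523, 'cring_top': 56.9417,
                  'stator_ring': 80.3129},
 'fsc_resolution': {'0.5': 0.139739, '0.143': 0.190515}}
```

Reading this: the C-ring's 46-fold and the collar/stator ring's 16-fold
symmetry are recovered from the noisy average; 40 of 64 site subvolumes
classify as occupied (Θ = 62.5%, i.e. 10 stators/motor, the ground-truth
configuration); the ellipse-fit tilt of 2.97° recovers the preset's 3.2°
within the estimator's ~1° accuracy; and the three ring diameters land on
the 56/57/80 nm geometry.  The half-set FSC crosses 0.5 at 0.14 cycles/nm
(~7 nm resolution for this 4-particle average).

The same stages are exposed as CLI subcommands operating on MRC2014 maps
and TSV particle tables:

```
motoret simulate --strain dmotB --n-motors 2 --seed 3 --out-prefix demo
motoret tilt demo_0000.mrc          # -> tilt: 8.10 deg (stator-free preset: 7.8 true)
motoret diameter demo_0000.mrc --z-slab -14 -11 --window 24 34   # -> 56.41 nm
motoret run D24E --seed 5 --out-dir d24e_out
motoret compare d24e_out/report.json wt_out/report.json
```

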