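# aclgait

Where a surgeon drills the tibial tunnel in single-bundle ACL reconstruction
decides how hard the graft works during every step the patient takes.
`aclgait` quantifies that: it models the reconstructed ACL as a passive
elastic strand between a femoral and a tibial insertion point, drives the
knee through a normalized gait cycle, and sweeps the tibial insertion site
(TIS) over a grid of surgically plausible placements — the centre of the
native footprint plus 2.5/5.0/7.5 mm displacements in the anterior,
posterior, medial and lateral directions (13 conditions) — reporting how
the force waveform and its stance-phase peaks change.

It is intended for biomechanics researchers and surgical-planning studies
that need a fast, fully reproducible desk-scale pipeline rather than a full
musculoskeletal simulation.

## Model

The graft runs on a straight line between its insertions; with length `L`,
resting length `L0` and strain `e = (L − L0)/L0`, the tension is the
standard toe-region ligament law

    f(e) = 0                 e ≤ 0          (slack)
    f(e) = 0.25 k e²/e_l     0 ≤ e ≤ 2e_l   (quadratic toe)
    f(e) = k (e − e_l)       e ≥ 2e_l       (linear)

with stiffness `k = 3100 N`, `e_l = 0.03`, `L0 = 2.8 cm` by default.  The
femur→tibia transform composes flexion/adduction/internal-rotation
rotations with a flexion-coupled anteroposterior translation; because the
element is passive, force follows from kinematics alone.  Knee angles come
either from the built-in seeded synthetic gait generator (101-point cycle,
calibrated to post-reconstruction landmarks: stance/swing flexion maxima
14°/64°, adduction peak 10° at 85% cycle, swing internal/external rotation
7°/12°) or from OpenSim-style `.mot`/`.sto` files.  Offset curves are
compared to the centre condition with Pearson correlations of the full
waveforms and paired t-tests on the two stance-phase peaks.  See
`docs/methods.md` for assumptions, calibration and limitations.

## Worked example

```python
from aclgait import RunConfig, generate_cohort, make_tis_grid, run_sweep, build_report

cfg = RunConfig()
cohort = generate_cohort(n_subjects=7, master_seed=0)
grid = make_tis_grid(cfg.ligament.tibial_insertion, cfg.convention(),
                     cfg.grid_magnitudes_mm)
sweep = run_sweep(cohort, grid, cfg.ligament, cfg.coupling(),
                  cfg.convention(), cfg.origin_offset_cm)
table = build_report(sweep)
print(table.peak_summary[["direction", "magnitude_mm",
                          "first_peak_mean_N", "first_peak_sig"]]
      .round(1).to_string(index=False))
```

prints

```
direction  magnitude_mm  first_peak_mean_N first_peak_sig
   center           0.0               85.4
 anterior           2.5              292.0             **
 anterior           5.0              508.3             **
 anterior           7.5              732.3             **
posterior           2.5                0.0             **
posterior           5.0                NaN            N/A
posterior           7.5                NaN            N/A
   medial           2.5              175.6             **
   medial           5.0              285.8             **
   medial           7.5              416.0             **
  lateral           2.5               32.2             **
  lateral           5.0               11.1             **
  lateral           7.5                4.9             **
```

Reading this: the centre placement loads the graft to ~85 N at initial
contact; every 2.5 mm of anterior displacement adds roughly 200 N, medial
displacement raises the force more gently, lateral displacement unloads the
graft, and from 5 mm posteriorly the graft is slack for the entire cycle
(`N/A` — no force generated), so it contributes nothing to knee restraint.
Stars mark paired-t significance vs. the centre (`** p < 0.01`).  The mean
waveform correlation with the centre condition decays with offset distance
(e.g. anterior: 0.926 → 0.813 → 0.733), i.e. larger tunnel misplacement
changes not just the magnitude but the shape of the loading pattern.

The same pipeline is scriptable from the shell:

```bash
aclgait all --seed 0 --out run_out   # kinematics + sweep CSV + tables + report.md
aclgait generate --seed 0 --out run_out
aclgait sweep run_out/kinematics --out run_out
aclgait report run_out/sweep_curves.csv --out run_out
```

All randomness flows from one master seed; identical seeds give
byte-identical output files.

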