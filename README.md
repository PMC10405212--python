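# vesiflow

Tools for studying charged glycolipid vesicles in silico: a minimal hybrid
particle-field (hPF) engine, coarse-grained-to-atomistic back-mapping, and
a vesicle analysis layer (morphology, head-group interactions, water
permeation), exercised end-to-end on synthetic vesicles with exact ground
truth.

## The problem

Lipid-A, the membrane anchor of bacterial lipopolysaccharide, aggregates in
water into micelles and vesicles.  Studying such a vesicle computationally
involves a chain of methods: hPF coarse-grained dynamics to self-assemble
it (pairwise nonbonded forces replaced by a density-field potential
`V_K = k_B T [Σ_K' χ_KK' φ_K' + (1/κ)(Σ φ - 1)]` with lattice-Ewald
electrostatics), rigid-superposition back-mapping to rebuild atomistic
coordinates from the CG beads (Kabsch fit of library conformers onto bead
centroids, accepted when the max site deviation < 0.2 nm), and trajectory
analysis on a *curved* membrane: leaflet-resolved area per lipid A_L,
head-to-head thickness D_HH, the deuterium order parameter
S_CD = ⟨(3cos²θ − 1)/2⟩ against the local surface normal, curvature order
parameter and sphericity, coordination numbers from g(r), geometric
hydrogen bonds (0.35 nm / 30°), and membrane-crossing statistics with
residence-time classes (1 / 270 ns) and Einstein-relation diffusion.

No trajectory of the original ~700k-atom system is publicly deposited, so
this package pairs every estimator with a synthetic-data generator whose
labels (leaflet, solvent region, crossing events, chain order) are exact by
construction — the analyses are validated against the generator, oracles
and closed-form results rather than against an unavailable trajectory.

## Worked example

Build a reduced vesicle (50/24 lipids, −2 e heads, +2 e counterions,
waters scaled down 100×), script fifteen membrane crossings into a 12 ns
trajectory, and run the detector:

```python
import numpy as np
from vesiflow import synthetic as sy, permeation as pe

spec = sy.VesicleSpec(outer_radius=5.0, inner_radius=3.0, n_outer=50,
                      n_inner=24, n_water_cavity=57, n_water_bulk=2046,
                      box=(18.0, 18.0, 18.0), seed=1)
system, labels = sy.build_vesicle(spec)
print(system.n_atoms, system.total_charge())   # 2695  0.0

bulk = np.nonzero(labels.water_region == "bulk")[0]
events = [sy.ScriptedCrossing(int(bulk[i]), 5 + 10*i, 11 + 10*i, "inward")
          for i in range(7)]
traj, truth, regions = sy.generate_trajectory(
    system, labels, sy.TrajectorySpec(n_frames=120, dt=0.1,
                                      scripted_crossings=events, seed=5))
detected = pe.detect_crossings(regions, traj.dt)
print(len(detected), detected[0].direction, detected[0].residence_ns)
# 7 inward 0.6000000000000001
```

All seven scripted events are recovered with exact frames and directions;
each spent 6 frames × 0.1 ns inside the membrane.  The same flow runs from
the shell:

```bash
vesiflow synth traj --out v --seed 3          # v.gro, v.xtc, v_events.tsv
vesiflow permeation --traj v.xtc --top v.gro --r-inner 3 --r-outer 5 --out perm/
vesiflow run --out full/ --seed 5             # the whole pipeline + manifest
```

The numbered scripts under `analysis/` run each stage as a narrative
driver and write tidy tables under `results/`: composition arithmetic
(644 lipids, 440/204 counterions, 210,299 waters at full scale), the
Coulomb-limit and NVE-conservation checks of the hPF engine (worst pair
energy error 0.39% against a direct Ewald sum; drift 0.46% of mean kinetic
energy over 10⁴ steps at dt = 10⁻³), the back-mapping round trip (max site
deviation ~10⁻¹⁵ nm, 100% vesicle acceptance at 0.2 nm), leaflet-resolved
morphology (outer/inner A_L 6.29/4.71 nm² on the 5/3 nm fixture, D_HH equal
to the 2 nm shell gap, S_CD recovering the −0.15 generator target), and
permeation (15/15 events, D 3.5 and 2.4 recovered to 3.49 ± 0.06 and
2.39 ± 0.03 × 10⁻⁵ cm²/s).

## Layout

    src/vesiflow/      library: synthetic, hpf, reference, backmap,
                       morphology, interactions, permeation, io, pipeline, cli
    analysis/          numbered narrative drivers (01..06)
    scripts/           acceptance.py
    tests/             pytest suite (unit, property and acceptance tests)
    docs/methods.md    model, estimator and design documentation
    results/           tables written by the analysis drivers
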