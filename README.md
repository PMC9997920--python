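# landsim

Predictive simulation of single-leg drop landings for studying ACL-injury
risk factors — a desk-scale, pure-Python pipeline for biomechanists and
students who want to run what-if landing studies without motion-capture
data or a commercial musculoskeletal stack.

Non-contact ACL ruptures cluster around the first ~50 ms of single-leg
landings. Because the ligament itself cannot be instrumented in vivo,
research works with proxy quantities sampled at the instant of peak
vertical ground-reaction force (vGRF): the knee joint reaction force
components (anterior AF, medial MF, compressive CF), the knee reaction
moments (abduction AbdM, internal rotation IRM), and the
quadriceps-to-hamstrings force ratio Q/H. `landsim` predicts landing
motions *de novo* and extracts exactly these quantities.

## What it does

* **Models** — two reduced rigid-body models of a 1.80 m / 75.16 kg
  subject: a planar 9-coordinate model with 16 grouped Hill-type
  muscle-tendon actuators, and a 3-D model defining 23 coordinates with
  12 left-leg actuators, the right limb locked clear of the ground, and
  five Hunt–Crossley contact spheres per foot.
* **Predict → track → predict** — a shooting stage (seeded CMA-ES over
  excitation knots) predicts a planar landing by minimizing a composite
  cost `p_s + p_j + p_GRF` (falling, joint-range and GRF-band penalties);
  a direct-collocation stage tracks that motion on the 3-D model; a final
  collocation stage re-predicts the landing under what-if scenarios with
  a squared-control effort goal `(1/d)∫Σ w_c|x_c|² dt`.
* **Scenario engine** — landing height (0.30–0.55 m), prescribed hip
  internal/external rotation, trunk flexion/extension and lateral
  bending, quadriceps/hamstrings strength permutations (F0 × 1.35 / ×
  0.65), and the effort-goal weight.
* **Risk factors** — every solved scenario is reduced to one row: peak
  vGRF in body weights and AF, MF, CF, AbdM, IRM, quadriceps force,
  hamstrings force and Q/H ratio at that instant.

See `docs/methods.md` for the model equations, solver details and known
limitations.

## Worked example

Track a synthetic 0.30 m landing reference on the 3-D model, then predict
the landing at three drop heights and tabulate the risk factors:

```python
import numpy as np
from landsim.pipeline import (ScenarioConfig, Stage2Settings, _pipeline_model,
                              run_case_study, stage2_track)
from landsim.synthetic import SyntheticLandingParams, generate_reference_landing

model = _pipeline_model()
ref = generate_reference_landing(model, SyntheticLandingParams(
    drop_height=0.30,
    touchdown_pose={"hip_flexion_l": np.deg2rad(20),
                    "knee_flexion_l": np.deg2rad(25),
                    "ankle_flexion_l": np.deg2rad(-10)},
    flexion_depth={"hip_flexion_l": np.deg2rad(35),
                   "knee_flexion_l": np.deg2rad(55),
                   "ankle_flexion_l": np.deg2rad(30)}))

baseline = stage2_track(ref)
print(baseline.solution.summary())

scenarios = [ScenarioConfig("landing_height", h, seed=1)
             for h in (0.30, 0.40, 0.55)]
table, results = run_case_study(scenarios, baseline.solution.trajectory)
print(table[["scenario", "vGRF", "AF(+)", "CF(-)", "Q/H_ratio"]].round(3))
```

On one CPU this takes a few minutes and prints (abridged):

```
status       : converged
defect norm  : 1.185e-08
tracking     : 0.39555
...
              scenario   vGRF  AF(+)  CF(-)  Q/H_ratio
0   landing_height=0.3  3.681  0.597 -2.835      7.864
1   landing_height=0.4  4.114  0.643 -3.189      7.148
2  landing_height=0.55  4.577  0.734 -3.312     10.189
```

Peak vGRF (in body weights) and the knee loads grow with the landing
height — the higher the drop, the larger the impact proxies associated
with ACL injury risk. Absolute magnitudes depend on the compliant-contact
parameters (see the methods note); the supported use is comparing
scenarios, not absolute values.

The same workflow is scriptable from a shell:

```sh
landsim build-model --variant reduced3d --out model.yaml
landsim fixtures make --name landing --out fixtures/
landsim report --stance --out stance.csv
```

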