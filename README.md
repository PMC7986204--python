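# gtvgen

Recover a lung tumor's **gross tumor volume (GTV)** from a routinely
delineated **iGTV** (the tumor's respiratory motion envelope) and a ten-phase
4D-CT series.

In SABR planning the tumor is often contoured only once, as the iGTV on a
maximum-intensity projection, so the GTV itself — needed for retrospective
prognostic modelling, dose analysis and radiomics — is never defined. With
the per-phase motion known, it can be reconstructed: treating the tumor as a
rigid body with envelope V<sub>env</sub> = V\*<sub>ref</sub> ∪ V\*<sub>SW</sub>
(reference tumor plus swept volume), shifting the envelope along the
*reverse* motion path keeps the reference tumor inside every copy,

&nbsp;&nbsp;&nbsp;&nbsp;V\*<sub>ref</sub> ⊆ ⋂<sub>k</sub> V<sub>env</sub>(t<sub>k</sub>),

with equality for convex tumors — so intersecting the shifted envelopes
removes the swept volume and yields the GTV. gtvgen implements the complete
flow for researchers working with routine 4D-CT archives:

* **imaging_io** — NIfTI volumes/masks, a JSON contour dialect,
  polygon↔mask conversion, 1 mm SI working-grid resampling;
* **registration** — VOI-restricted translation-only registration with the
  correlation-ratio cost, four VOI strategies (4/10 mm margins, chest-wall
  removal at >176 HU, 2 cm SI breathing prior), cyclic prematching and
  minimum-SD strategy selection;
* **gtv_generation** — reverse-path envelope intersection (GTV_gen) and
  forward-path reconstruction (iGTV_gen);
* **qa_metrics** — automated gates (registration fails if mean cost < 0.73
  or cost SD ≥ 0.13; contours with iGTV volume ratio
  vol(iGTV_gen)/vol(iGTV_obs) < 0.84 are routed to visual "check"), motion
  amplitude, and validation metrics (directed surface DTA, volume ratio,
  centre-of-mass distance);
* **phantom** — a synthetic lung 4D-CT generator with known tumor shape,
  motion, exact envelope ground truth and observer-variation perturbations,
  so the whole pipeline is testable without patient data;
* **cli** — a `gtvgen` command with `phantom`, `register`, `generate`, `qa`,
  `validate` and composite `run` subcommands.

## Worked example

Run the full pipeline on the default phantom — a 10 mm-radius tumor moving
10 mm peak-to-peak SI with a 2 mm hysteresis loop, rendered at the routine
512-style grid conventions (1.17 mm pixels, 3 mm slices) with 20 HU noise:

```python
from gtvgen.cli import run_pipeline

report = run_pipeline({"seed": 1, "phantom": {"seed": 1}}, "out")
print(report.method_id, round(report.cost_mean, 3), round(report.cost_sd, 4))
print(round(report.igtv_ratio, 3), report.category)
print(report.volumes_cc)
```

prints

```
4 0.982 0.0075
1.025 trust
{'igtv_obs': 7.687742, 'gtv_gen': 4.084798, 'igtv_gen': 7.879388}
```

Reading: VOI method 4 gave the most consistent correlation-ratio costs
(mean 0.982, SD 0.0075 — comfortably inside the 0.73/0.13 gate). The
7.7 cc observed iGTV was intersected along the nine estimated reverse
translations into a 4.08 cc GTV (the true tumor is 4.19 cc analytically);
re-sweeping that GTV along the forward path reconstructs the envelope with a
volume ratio of 1.025 — close to one, so the contour is consistent with the
motion and the run is categorised **trust**. Ratios slightly above 1 come
from working-grid interpolation and are benign; ratios well below 1 flag an
iGTV that the estimated motion cannot explain.

The same run from the shell:

```bash
echo '{"seed": 1, "phantom": {"seed": 1}}' > cfg.json
gtvgen run --config cfg.json --out out
```

which writes `qa_report.json`, the generated GTV as a NIfTI mask and JSON
contours, and the reconstructed envelope.

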