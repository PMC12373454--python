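# schemagaze

Simulation and analysis pipeline for a gaze-contingent memory experiment
on the 4-in-a-row board game (a tic-tac-toe extension on a 4×9 grid).
In the paradigm this package models, a participant previews a mid-game
board while their fixations are tracked; the next move is then chosen
*in real time* so that, independently, it is probable or improbable
under a gameplay model and predicted or unpredicted by the viewer's own
gaze.  That decorrelates two normally confounded quantities — stimulus
probability and prediction accuracy — and lets mixed-effects analyses
separate their contributions to memory, along with an eye-movement index
of schema use at retrieval.

The package is for cognitive scientists who want to (a) prototype and
power such gaze-contingent designs with a calibrated synthetic cohort
generator, and (b) run the complete measurement and analysis chain:
fixation smoothing, adaptive move sampling, schema-regression of
retrieval gaze, and the statistical models.

## What is computed

* **Gameplay model** — a linear myopic softmax policy
  P(m) ∝ exp(wᵀf(m)) over empty squares, with line-completion, blocking
  and center-proximity features; `move_logprob = log P(shown move)` is
  the per-trial probability measure.
* **Fixation smoothing** — soft assignment of a fixation (x_F, t_F) to
  square i with weight t_F·e^{−‖x_F−x_i‖²/25}/Σ_j e^{−‖x_F−x_j‖²/25}
  (pixels; 180-px squares); `pred_acc` is the empty-square fixation
  share on the shown move.
* **Adaptive sampling** — distribution inversion
  P(m) → (max P − P(m))/Σ(max P − P(i)), product combination, and the
  four probable×predicted conditions.
* **Schema-use index** — per-trial OLS of the normalized retrieval
  fixation map on the model's move-probability map and a correct-move
  indicator, giving `w_moveProb` and `w_correctMove`.
* **Analyses** — mixed-effects logistic/linear models (with lme4-style
  random-effect simplification ladder; the random-intercept logistic is
  an exact Gauss–Hermite ML engine validated against lme4), bootstrap
  mediation, a BIC Bayes factor, manipulation checks and guessing
  baselines.
* **Synthetic cohorts** — scenario files plant the target effect sizes
  as generative truth (95×80 or 37×80 trials) with calibrated
  fixation–probability coupling, so every analysis is validated by
  parameter recovery.  See `docs/methods.md` for the model details.

## Worked example

Simulate a small cohort, measure it, and fit the memory model:

```python
from schemagaze.cohort import generate_cohort, load_scenario
from schemagaze.stats import fit_memory_model

cfg = load_scenario("exp2_marginal")   # planted: b_prob 0.379, b_pred 0.334
cfg.n_subjects = 12                    # shrink the 95-subject design
ds = generate_cohort(cfg, seed=8)
fit = fit_memory_model(ds.trials)
print(fit.ladder_level)
for term in ("move_logprob_z", "pred_acc_z"):
    t = fit[term]
    print(f"{term}: {t['coef']:+.3f} (se {t['se']:.3f}, z {t['stat']:.2f})")
print(f"mean accuracy: {ds.trials.correct.mean():.3f}")
```

prints

```
intercept
move_logprob_z: +0.355 (se 0.076, z 4.68)
pred_acc_z: +0.272 (se 0.072, z 3.79)
mean accuracy: 0.557
```

i.e. the random-slopes level of the ladder did not converge (the fit
fell back to subject random intercepts, as recorded), and both planted
coefficients are recovered within sampling error of this small 960-trial
cohort: each SD of move probability or prediction accuracy independently
multiplies the odds of correct recall by about e^0.3 ≈ 1.4, on top of a
mean recall accuracy calibrated to 0.55.

The same pipeline is scriptable from the shell:

```bash
schemagaze simulate exp2_marginal --out cohort/ --seed 7
schemagaze measure cohort/
schemagaze analyze cohort/ --analyses memory,confidence,manipulation
schemagaze reproduce            # planted-vs-recovered pass/fail table
```

The numbered drivers under `analysis/` regenerate the packaged
artifacts: `01_train_policy.py` (default gameplay weights),
`02_calibrate_scenarios.py` (scenario calibration), `03–05` (cohort
simulation, memory models, retrieval-strategy analyses; summary tables
under `results/`).

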