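# dichotrack

Tools for **dynamic dichoptic contrast tracking** — a non-rivalrous,
continuous-report psychophysical paradigm for measuring interocular
interactions (e.g. in amblyopia). Observers view the same grating in
both eyes while the contrast of each eye's image is modulated
independently over time, and continuously report perceived contrast
with a joystick. The package generates the exact stimulus schedules of
that paradigm, simulates parameterized observers, fits a binocular
contrast-normalization model to joystick time-courses, and
forward-simulates classical dichoptic tasks (letter-chart balance
point, cyclopean phase balance, dichoptic masking) from fitted
parameters.

It is intended for visual psychophysicists and modellers who want to
analyze continuous contrast-report data, run parameter-recovery
studies for this class of paradigm, or compare normalization-model
parameters against other measures of binocular balance.

## The model

Each eye's input contrast is attenuated and then divisively normalized
by the other eye's signal; the percept is the sum of the two outputs.
With the amblyopic eye (AE) attenuated by `k_AE ∈ (0, 1]` and the
fellow eye (FE) fixed at weight 1:

    A_AE = k_AE · C_AE                A_FE = C_FE

    Ĉ_AE = A_AE / (μ_AE · C_FE + σ)   Ĉ_FE = C_FE / (μ_FE · A_AE + σ)

    Ĉ = Ĉ_AE + Ĉ_FE

`μ_AE` and `μ_FE` are interocular normalization (suppression) weights
and `σ > 0` is a saturation constant. Which physical eye is "amblyopic"
is decided by the fit, not by clinical label.

Fitting proceeds in three stages, each on a different trial phase:

1. **Calibration** (binocular phase): an affine map plus response
   delay, `Ĵ(t) = a + b·J(t + d)`, taking joystick position into
   contrast units (`d ∈ [0, 4] s`, `b > 0`; sessions using < 50% of the
   joystick range are excluded).
2. **Monocular attenuation** (monoptic phases): the reduced linear
   model `Ĉ = (k_R C_R + k_L C_L) / max(k_R, k_L)` yields `k_AE` and
   designates the AE.
3. **Interocular normalization** (dichoptic phases): grid search over
   `0 ≤ σ ≤ 1`, `0 ≤ μ ≤ 3` plus local refinement (unbounded above)
   for `(σ, μ_AE, μ_FE)`, after which `k_AE` is re-estimated on the
   full monoptic + dichoptic dataset. The last two steps alternate
   until the full-data MSE converges.

## Worked example

Simulate a noisy observer with the amblyopia group-mean parameters
(`k_AE = 0.42, μ_AE = 3.04, μ_FE = 0.20, σ = 1.02`), fit the
three-stage model, and forward-simulate the letter-chart balance point:

```python
import dichotrack as dt

trials = dt.make_trial_set(0)                      # the 28-trial session
truth  = dt.PRESETS["amblyopia"]
spec   = dt.ResponseSpec(noise_sd=0.05, delay=0.5, seed=1)
traces = dt.simulate_dataset(truth, spec, trials)  # joystick time-courses

fit = dt.fit_observer(traces, trials)
print(fit.calibration)       # a=-0.029 b=1.004 d=0.509  (truth: 0, ~1, 0.5)
print(fit.params)            # k_ae=0.393 mu_ae=3.02 mu_fe=0.22 sigma=1.07

bp  = dt.simulate_letter_balance(fit.params)
print(bp.bp)                 # 0.792 -> ~79% contrast needed in the AE
rel = dt.split_half_reliability(traces, trials)
print(rel.r)                 # 0.974 mean split-half correlation
```

The fitted delay (0.509 s) and slope recover the simulated response
lag and gain; `k_ae = 0.393` and `mu_ae = 3.02` recover the generating
attenuation and suppression to within the documented tolerances; the
balance point ~0.79 says this observer needs roughly four times more
contrast in the amblyopic than the fellow eye to perceive the two
equally.

The same pipeline is scriptable from the shell:

```bash
dichotrack simulate-observer --preset amblyopia --seed 1 --out traces.csv
dichotrack fit --in traces.csv --out report.json
dichotrack simulate-tasks --preset amblyopia --task letter
```

## Layout

- `src/dichotrack/stimulus.py` — trial/stimulus schedule generation
- `src/dichotrack/model.py` — the normalization observer model
- `src/dichotrack/observer.py` — synthetic joystick observers
- `src/dichotrack/calibration.py`, `monocular.py`, `binocular.py` —
  the three fitting stages (sklearn-style estimators)
- `src/dichotrack/tasks.py` — external-task forward simulations
- `src/dichotrack/evaluation.py` — split-half reliability, reduced
  (short-session) dataset comparison
- `src/dichotrack/io.py`, `pipeline.py`, `cli.py` — file formats,
  end-to-end driver, command line
- `docs/methods.md` — modelling and design notes
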