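# monitorlearn

Bayesian learning with performance monitoring: an agent that learns a
hidden target interval and feedback scale from scaled error feedback by
fusing its intended response with a noisy efference copy of what it
actually did, weighted by trial-wise confidence — plus the matching
trial-level analysis pipeline (behavioral error signals, a
confidence-calibration index, single-trial ERP features) and synthetic
data generators so the whole pipeline runs end to end with no external
data.

## What is in the package

| module | contents |
| --- | --- |
| `monitorlearn.task_model` | simulated time-estimation environment: feedback `f = (r - t)·s`, response noise, efference-copy noise levels |
| `monitorlearn.bayes_learner` | grid-approximate joint inference over `(t, s)`; precision-weighted fusion of intention and efference copy; outcome prediction; confidence report; confidence calibration `cc`; the `full`, `average_confidence` and `feedback_only` variants |
| `monitorlearn.experiments` | simulation harnesses: three-variant learning-curve comparison, calibration sweep, confidence-conditional prediction–feedback coupling, Shannon-surprise grid |
| `monitorlearn.behavior_metrics` | trial-table pipeline: outlier filtering, signed error / error magnitude / SPE / RPE / improvement, confidence-calibration index, predictor scaling, fixed-effects regression contract |
| `monitorlearn.erp_features` | epoch baseline correction, amplitude/gradient artifact rejection, FRN peak-to-peak at FCz, P3a/P3b ROI window means, subject-wise window derivation, HDF5 epoch I/O |
| `monitorlearn.synthetic_data` | synthetic participants (full-variant agents in ms units, target 1504 ms) and synthetic EEG epochs with injected, sign-controlled component effects |

## CLI

```bash
# model-level simulations
monitorlearn simulate compare  --n-agents 200 --n-trials 250 --out curves.csv
monitorlearn simulate cc-sweep --cc 0 --cc 0.75 --cc 1 --out sweep.csv
monitorlearn simulate surprise --out surprise.csv

# synthetic data
monitorlearn synth behavior --n-participants 40 --seed 1 --out trials.csv
monitorlearn synth bundle   --n-participants 40 --seed 1 --out-dir bundle/

# analysis pipeline
monitorlearn behavior run --in trials.csv --out signals.csv --exclusions log.json
monitorlearn synth erp    --trials signals.csv --out epochs.h5
monitorlearn erp features --in epochs.h5 --out features.csv
```

## Library quick start

```python
from monitorlearn import AgentConfig, TaskConfig, run_agent

traj = run_agent(AgentConfig(variant="full", cc=1.0, rng_seed=1),
                 TaskConfig(n_trials=250))
print(traj[-1].t_hat, traj[-1].s_hat)   # ≈ 19, ≈ 90
```
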