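# emgimu

Multi-modal movement-intent decoding from surface EMG and inertial
measurements (IM): a tested, reusable implementation of the full pipeline —
synthetic data generation, preprocessing, sliding-window feature extraction,
LDA classification with confidence rejection, repetition-wise cross-validated
evaluation, sequential forward sensor selection, a finite-state real-time
control simulator, and EMG-envelope reconstruction from inertial channels.

## Layout

| Module | Role |
| --- | --- |
| `emgimu.dataio` | Recording container (EMG @ 2 kHz + 9 IM channels/sensor @ 128 Hz, labels on the EMG timeline) and validated directory-of-CSV I/O |
| `emgimu.synthetic_data` | Class-structured sEMG + IM generator with planted ground truth (gains, IM offsets, coupling, label jitter) |
| `emgimu.preprocessing` | Hampel interference suppression, linear-interpolation synchronization, label-onset refinement |
| `emgimu.features` | 256 ms / 50 ms sliding windows; 7 time-domain EMG features (MAV, WL, AR1–4, LogVar) + 9 IM channel means per sensor; train-only standardization |
| `emgimu.classification` | Shared-covariance Gaussian (LDA) classifier, log-domain posteriors, posterior-threshold rejection (θ = 0.995 default) |
| `emgimu.evaluation` | Repetition-wise k-fold CV, rest-class balancing by temporal distance, accuracy/confusion metrics, bootstrap CIs |
| `emgimu.sensor_selection` | Grouped (16 features/sensor) greedy forward selection with per-fold majority voting and a 1-point marginal-gain stopping rule |
| `emgimu.control_sim` | Finite-state controller and pick-and-place trial simulator; completion-rate / completion-time metrics |
| `emgimu.envelope_recon` | Per-sensor OLS reconstruction of the EMG envelope (MAV series) from accelerometer/gyroscope/magnetometer window means, scored by cross-validated VAF |
| `emgimu.cli` | `emgimu` command-line entry point wiring all stages |

## CLI

```bash
# generate a synthetic recording (directory of CSVs + meta.json)
emgimu simulate --protocol realtime --out run/rec --seed 1

# filter + refine labels, extract features, evaluate
emgimu preprocess --in run/rec --out run/pre --refine
emgimu extract --in run/pre --out run/features.csv --modality both
emgimu evaluate --features run/features.csv --folds 5 --out run/result.json

# sensor selection and model training
emgimu select --features run/features.csv --folds 3 --out run/selection.json
emgimu train --features run/features.csv --model run/model.json

# envelope reconstruction VAF table
emgimu reconstruct --in run/rec --out run/vaf.csv

# or everything in one reproducible run
emgimu run --out run/full --classes 6 --reps 6 --seed 1
```

Each `run` directory carries a `manifest.json` with the seed, config hash
and stage timings; identical configs and seeds reproduce outputs
bit-for-bit.

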