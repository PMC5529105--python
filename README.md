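# pavcond

Analysis pipeline for Pavlovian-conditioning electrophysiology/behavior
sessions: putative dopamine-neuron classification, event-aligned firing-rate
and latency statistics, sign-test discrimination-onset estimation,
conditioned-licking quantification, inactivation contrasts, and d′-based
contrast-threshold deficit maps — plus a synthetic-session generator with
known ground truth for parameter-recovery testing.

## Modules

| module              | contents |
|---------------------|----------|
| `pavcond.session`   | session data model (trials, spike trains, waveforms, licks, psychometric records) and the plain-text bundle reader/writer/validator |
| `pavcond.synth`     | generators: interleaved LR/SR trial tables, inhomogeneous-Poisson spike trains (thinning, rectangular event bumps), lick point processes, biphasic waveform templates, psychometric trials, reversal-learning datasets, whole sessions with `truth.json` ground truth |
| `pavcond.spikes`    | spike width (trough→peak), DA/SNr classification, PSTHs, window firing rates, exact sign test / Wilcoxon / Welch / one-sample t comparisons, 2 SD response latency, persistence-qualified discrimination onset, waveform stability |
| `pavcond.behavior`  | lick-rate profiles (0.1 s bins), conditioned-response rates, CS-vs-baseline and LR-vs-SR tests, inactivation before/during contrasts, reversal curves with crossover-day detection |
| `pavcond.psycho`    | Michelson↔Weber conversion, saccade scoring windows, ML cumulative-Gaussian psychometric fits with d′ = 2 thresholds, deficit maps |
| `pavcond.recovery`  | the parameter-recovery experiment suite (latency, onset, classification, inactivation, Welch calibration, psychometric threshold, conservation identities) |
| `pavcond.cli`       | the `pipeline` command |

## CLI

```bash
# synthesize a session bundle (+ truth.json); deterministic per (config, seed)
pipeline synth --config config.yaml --out bundle/ [--seed 7]

# full analysis: classification → window rates → comparisons → latency →
# discrimination onset → lick profiles/tests → inactivation → deficit map
pipeline analyze --config config.yaml --bundle bundle/ --out run/

# parameter-recovery suite (verdict table; failures are verdicts, not errors)
pipeline recover --n-seeds 10 [--full] [--out dir]

# summarize an analysis run
pipeline report --run run/
```

The config is one JSON/YAML file (schema-validated); every analysis default
(FP/CS windows 0.1–0.3 s, RW window 0.15–0.35 s, 10 ms PSTH bins, 0.1 s lick
bins, α = 0.05, persistence {15, 50} ms, DA ∈ [1, 10] Hz & width > 0.45 ms,
SNr > 40 Hz) is visible in `pavcond.cli.AnalysisSettings`.

### Session bundle layout

```
bundle/
  trials.csv          trial_id,condition,field,epoch,fp_onset,cs_onset,cs_offset,
                      reward_time,reward_volume,ecc_deg,dir_deg,valid
  licks.csv           lick_time
  spikes/<id>.csv     spike_time
  waveforms/<id>.json {sample_interval_ms, epochs:[{label, samples}]}
  psychometrics.csv   ecc_deg,dir_deg,contrast,endpoint_x,endpoint_y,responded  (optional)
  metadata.json
  truth.json          generator ground truth (synthetic bundles only)
```

All times are seconds on one session clock; floats are serialized at 6
decimal places, so bundles round-trip losslessly and byte-identically.

## Tests

```bash
python -m pytest -q tests/            # full suite (~1 min)
```

`tests/test_acceptance.py` runs the acceptance criteria at their documented
sizes (100-seed recovery experiments, exhaustive sign-test enumeration up to
n = 12, 1000-simulation Welch calibration, exact conservation identities).

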