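# cueloop

Closed-loop, individualized, MVPA-based EEG neurofeedback for smoking cue
reactivity — as a tested library and CLI, with a synthetic-EEG virtual-subject
simulator so the entire offline-training + real-time-feedback loop runs with
no human and no data download.

The toolkit implements the two-phase paradigm end to end:

1. **Offline classifier construction** — a block-design cue-reactivity task
   (6 blocks in the order N,S,S,N,S,N; 55 trials per block, 5 attention-catch
   animal trials each) is recorded (or simulated), cleaned (0.5 Hz high-pass,
   recursive-least-squares blink removal, ±100 µV rejection), epoched on
   −200…1000 ms, and compared between conditions point-by-point in the
   time-amplitude domain and in five Morlet band-power domains (alpha 8–13,
   low beta 14–20, high beta 21–30, low gamma 31–48, high gamma 52–80 Hz).
   Significant points (label-permutation test, α = 0.05) are merged into
   spatio-temporal clusters corrected by the maximum cluster-mass permutation
   statistic; retained clusters feed a per-subject linear SVM with Platt
   probability calibration, evaluated by stratified 5-fold cross-validation
   (20% held out per fold, feature selection refit inside each training fold).
2. **Real-time neurofeedback** — 8 cycles of 40 updates, one update every 2 s
   (1 s of EEG acquisition + 1 s of classification). Each 1-s window passes
   through the causal online cleaning chain, is scored by the decoder into a
   probabilistic smoking-likeness score in [0,1], smoothed (first two points
   of the session fixed at 0.5, then a 3-point moving average), and mapped
   onto one of 11 picture craving levels. With a virtual subject as the
   source, the displayed picture feeds back into the next emitted window,
   closing the loop.

## Layout

| module                | contents |
|-----------------------|----------|
| `cueloop.synth`       | simulation spec, task schedule, synthetic recordings (planted P300-like ERP + alpha effect, 1/f noise, blinks), virtual subject |
| `cueloop.io`          | `RawRecording`/`EpochSet`, 16-bit EDF + events-TSV I/O, 60-channel modeling policy, epoching |
| `cueloop.preprocess`  | zero-phase/causal high-pass, streaming RLS blink filter, amplitude rejection |
| `cueloop.features`    | Morlet band power, point-wise permutation maps, cluster-mass correction, feature assembly |
| `cueloop.decoder`     | linear SVM + sigmoid calibration, JSON decoder artifact, leakage-safe cross-validation |
| `cueloop.closedloop`  | session engine, score smoothing, picture mapping, feedback traces |
| `cueloop.evalkit`     | ERP grand averages, split-half Pz SNR, score-vs-cycle regression, KS/t tests, topography tables |
| `cueloop.montage`     | 64-channel 10–20 layout, neighbour graphs |

## CLI

```bash
cueloop simulate --seed 1 --out run1/                 # EDF + events + YAML
cueloop train --recording run1/recording.edf --out decoder.json \
              --domains amplitude,alpha --n-perm 1000
cueloop crossvalidate --recording run1/recording.edf --k 5
cueloop run-nf --decoder decoder.json --seed 1 --out trace.csv
cueloop evaluate --recording run1/recording.edf --trace trace.csv --out report.json
```

`run-nf` drives a virtual subject whose latent craving state decreases when
the displayed score falls (reinforcing successful downregulation), so the
per-cycle mean displayed score declines over a session — the qualitative
closed-loop learning phenomenon — while a non-learning subject shows no
systematic trend.

## Notes

- Everything is deterministic given the seeds; simulations run on a virtual
  clock (no wall-time sleeps).
- EDF I/O is self-contained (no EDF library required); vendor continuous
  formats (e.g. NeuroScan CNT) are read through `mne` when it is installed.
- Band-power decoders are fully supported offline; the virtual subject emits
  only the craving-scaled condition-difference pattern, so closed-loop
  simulations are best driven by amplitude-domain decoders (see
  `cueloop.decoder.build_decoder`).
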