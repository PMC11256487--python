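version: 1
device: virtual
seed: 0
markers:
  standard: 1
  oddball: 2
tasks:
  - kind: free_recording
    duration_s: 30.0
  - kind: rest_eyes_open
    duration_s: 60.0
  - kind: rest_eyes_closed
    duration_s: 60.0
  - kind: oddball
    n_trials: 200
    p_oddball: 0.1
    isi_s: 1.0
    stim_duration_s: 0.2
    max_consecutive_oddballs: 2
  - kind: rest_eyes_open
    duration_s: 30.0
  - kind: oddball
    n_trials: 200
    p_oddball: 0.1
    isi_s: 1.0
    stim_duration_s: 0.2
    max_consecutive_oddballs: 2
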