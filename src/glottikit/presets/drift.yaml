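# Endoscope drift: 15 Hz sinusoidal camera motion, 8 px amplitude.
f0: 120.0
frame_rate: 4000.0
n_frames: 200
closed_fraction: 0.3
drift_freq: 15.0
drift_amp: 8.0
noise_sigma: 2.0
corner_artifacts: true
seed: 0
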