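# Split glottis: a bright tissue bridge divides the gap into two dark blobs.
f0: 120.0
frame_rate: 4000.0
n_frames: 200
closed_fraction: 0.3
split: true
split_pos: 0.5
noise_sigma: 2.0
corner_artifacts: true
seed: 0
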