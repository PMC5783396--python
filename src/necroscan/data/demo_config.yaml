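# Demo pipeline config: generates synthetic inputs, then runs every stage.
seed: 1
simulate:
  trajectory_mode: inactive
  n_frames: 300
number: {}
scan: {}
geometry: {}
trajectory: {}
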