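# Illustrative control-parameter protocol: two rise-and-fall arousal sweeps
# of the global coupling G over a 20-minute session.  The breakpoints are a
# demonstration waveform, not a calibrated experimental design; edit freely.
protocol:
  - [0.0, 1.5]
  - [150.0, 3.0]
  - [300.0, 1.5]
  - [450.0, 3.0]
  - [600.0, 1.5]
  - [750.0, 3.0]
  - [900.0, 1.5]
  - [1050.0, 3.0]
  - [1200.0, 1.5]
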