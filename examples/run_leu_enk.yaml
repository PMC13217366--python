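# End-to-end pipeline config: simulate the peptide preset on a reduced
# grid and retrieve its IR spectrum.  All randomness flows from `seed`.
seed: 1
scenario:
  preset: leu_enk
  wn_start: 1400.0
  wn_stop: 1800.0
  wn_step: 10.0
  cycles_per_wavenumber: 10
  source_rate: 2000.0
energy_profile: synthetic   # or a two-column CSV (wavenumber cm^-1, mJ)
retrieval:
  mz_window: auto           # untagged base peak +/- window_halfwidth
  reference_mode: tagged_off
  baseline_correct: true
mobilogram:
  n_events: 50000
  cycle_time: 10.0
  bin_width: 0.11
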