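# ciris

**Messenger-tagging cryogenic IR spectroscopy data processing, with a
forward instrument simulator.**

Gas-phase IR "action" spectroscopy adds a structure-specific dimension to
ion mobility–mass spectrometry (IM-MS): isobaric analytes that mobility can
only partially resolve — isomeric glycans are the canonical case — have
distinct vibrational fingerprints. In messenger tagging (cryogenic IR ion
spectroscopy), ions stored in a cold trap (~30–45 K) pick up weakly bound
N₂ tags (+28 Da per tag per charge); absorbing a single resonant IR photon
detaches a tag, so scanning the laser and watching the tagged/untagged
populations yields an IR spectrum of the cold ion.

`ciris` implements the data side of such an instrument, for spectroscopists
and MS method developers:

* **TOF processing** (`ciris.tof`) — `t = t0 + k·√(m/z)` flight-time
  calibration, rolling-quantile baseline correction, window integration,
  N₂ tag-series extraction and the mean-tag-count estimator;
* **ion mobility** (`ciris.mobility`) — mobilogram binning, peak detection
  (parabolic apex, half-height FWHM with shoulder handling), arrival-time
  slice windows and slice-purity diagnostics;
* **IR spectrum retrieval** (`ciris.irspec`) — paired laser-on/off
  averaging and, per wavenumber ν̃,

  F_dep = (I_ON − I_OFF) / I_OFF,  S = −ln(1 − F_dep),  σ_rel = S / (E(ν̃)·ν̃)

  i.e. depleted fraction, saturation linearization (ions that already lost
  their tag cannot report a second absorption), and photon-flux
  normalization (flux ∝ pulse energy over wavelength ∝ E·ν̃), with
  leave-one-pair-out jackknife errors;
* **forward simulator** (`ciris.simulate`) — trap cycle, Poisson N₂
  tagging, per-tag single-photon detagging, Gaussian arrival-time
  distributions, TOF transient synthesis with counting noise, plus presets
  for a protonated peptide standard and a sodiated trisaccharide isomer
  mixture — ground truth for testing every stage without an instrument;
* **IO + pipeline + CLI** (`ciris.io`, `ciris.pipeline`, `ciris.cli`) — a
  versioned binary container for raw paired transients ("CTIR"), CSV
  exports, a config-driven end-to-end pipeline with a reproducibility
  manifest, and `ciris simulate|calibrate|mobilogram|slice|retrieve|run`.

## Worked example

`examples/simulate_and_retrieve.py` simulates a paired on/off scan of the
peptide preset and runs the full retrieval chain:

```
instrument-like run: 4150 transients (83 grid points x 25 on/off pairs)
  strongest band at 1690 cm^-1 (ground truth: 1688 cm^-1)
  relative RMS vs true cross-section: 11.1% (shot noise + multi-tag saturation residual)
noiseless probe run: relative RMS 0.95%
```

The instrument-like run recovers the band positions; its residual comes
from electrospray shot noise and from the fact that the logarithmic
saturation correction is exact only for single-tag ions. In the noiseless
quasi-linear probe run the retrieved spectrum matches the simulator's true
cross-section to better than 1% after a single global scale factor — the
retrieval chain exactly inverts the forward model where it is designed to.

The other examples each print one capability: `tag_statistics.py` (Poisson
tagging yield, 63.2% of ions carry ≥1 tag at mean 1),
`mobility_slicing.py` (two isomer peaks at 4.76/5.35 ms; a 0.5 ms gate on
the early apex transmits it at 97% purity), and `calibration_fit.py`
(√(m/z) calibration recovery with standard errors).

A config-driven run of the same chain:

```sh
ciris run --config examples/run_leu_enk.yaml --out-dir out/
```

writes `spectrum.csv`, `mobilogram.csv` (when requested), `run.log` and a
`manifest.json` whose config hash + seed reproduce every artifact
bit-identically.

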