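"""Full round trip: simulate a paired on/off scan, retrieve the IR spectrum.

Runs the forward simulator for the leucine-enkephalin preset on a reduced
wavenumber grid and retrieves the relative absorption cross-section via
depletion -> linearization -> photon-flux normalization, twice:

1. an instrument-like stochastic run (electrospray fluctuation, counting
   noise, 50% peak tag depletion);
2. a noiseless probe run in the quasi-linear regime (~6% depletion), where
   the retrieval is expected to match the true band pattern to ~1%.

The gap between the two illustrates what limits quantitative band shapes
at high depletion: residual saturation of the multi-tag ensemble, which
the logarithmic correction removes exactly only for single-tag ions.
"""

import dataclasses

import numpy as np

import ciris


def retrieve(scenario, seed):
    dataset = ciris.simulate_scan(scenario, seed)
    base = scenario.species[0].mz
    spectrum = ciris.retrieve_spectrum(
        dataset,
        (base - 0.35, base + 0.35),
        scenario.scan.energy_profile,
        calibration=scenario.calibration,
        reference_mode="tagged_off",
        max_tags=8,
    )
    truth = scenario.species[0].true_sigma(spectrum.wn)
    rms = ciris.scale_matched_rms(spectrum.sigma_rel, truth)
    return dataset, spectrum, rms


scenario = ciris.make_preset("leu_enk")
scenario.scan = dataclasses.replace(scenario.scan, wn_step=10.0)
scenario.trap = dataclasses.replace(scenario.trap, cycles_per_wavenumber=25)
scenario.baseline = 0.0
ciris.set_peak_depletion(scenario, 0.50, mode="tagged")

dataset, spectrum, rms = retrieve(scenario, seed=4)
print(f"instrument-like run: {dataset.n_records} transients "
      f"({dataset.n_wn} grid points x {dataset.cycles_per_wn} on/off pairs)")
i_max = int(np.argmax(spectrum.sigma_rel))
print(f"  strongest band at {spectrum.wn[i_max]:.0f} cm^-1 "
      f"(ground truth: 1688 cm^-1)")
print(f"  relative RMS vs true cross-section: {100 * rms:.1f}% "
      "(shot noise + multi-tag saturation residual)")

probe = ciris.make_preset("leu_enk")
probe.scan = dataclasses.replace(probe.scan, wn_step=10.0)
probe.trap = dataclasses.replace(probe.trap, cycles_per_wavenumber=1)
probe.stochastic = False
probe.baseline = 0.0
ciris.set_peak_depletion(probe, 0.06, mode="tagged")

_, spectrum_p, rms_p = retrieve(probe, seed=4)
print(f"noiseless probe run: relative RMS {100 * rms_p:.2f}%")
print()
print(
    "sigma_rel is relative: its shape, not its scale, identifies the ion. "
    "In the quasi-linear regime the depletion/linearization/flux chain "
    "undoes everything the simulated instrument did to the band pattern."
)
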