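"""Isomer separation by arrival-time slicing.

Samples arrival events from the two-trisaccharide mixture preset (isobaric
sodiated melezitose + cellotriose), bins them into a mobilogram, detects the
two partially resolved peaks, and applies the 0.5 ms gate centered on the
early apex to isolate one isomer.
"""

import ciris

scenario = ciris.make_preset("trisaccharide_mixture")
times, labels = ciris.sample_mixture_events(scenario.species, 100_000, seed=2)

mob = ciris.bin_events(times, cycle_time=10.0, bin_width=0.11)
print(f"mobilogram: {mob.n_bins} bins of {mob.bin_width} ms over a {mob.cycle_time} ms cycle")
for peak in ciris.detect_peaks(mob, min_prominence=0.05):
    flag = " (shoulder-limited)" if peak.shoulder_limited else ""
    print(f"  peak: apex {peak.apex:.3f} ms, FWHM {peak.fwhm:.3f} ms{flag}")

window = ciris.SliceWindow(center=4.75, width=0.5)
report = ciris.slice_purity(times, labels, window)
print(f"\nslice window [{window.lo:.2f}, {window.hi:.2f}) ms "
      f"transmitted {report.n_transmitted} events:")
for name in sorted(report.purity):
    print(f"  {name}: purity {100 * report.purity[name]:.2f}%, "
          f"transmission {100 * report.transmission[name]:.1f}%")
print()
print(
    "The early-apex window passes the melezitose component at >95% purity: "
    "the gate isolates one isomer from an isobaric mixture before tagging."
)
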