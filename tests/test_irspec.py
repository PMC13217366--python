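"""Spectrum retrieval: pairing, depletion, linearization, normalization."""

import dataclasses
import math

import numpy as np
import pytest

import ciris
from ciris.irspec import (
    depletion_fraction,
    flux_normalize,
    linearize,
    pair_cycles,
    retrieve_spectrum,
    scale_matched_rms,
)
from ciris.simulate import GaussianBands, thin_tag_histogram
from conftest import reduce_scan


def _retrieval_window(scenario, halfwidth=0.35):
    base = scenario.species[0].mz
    return (base - halfwidth, base + halfwidth)


# ---------------------------------------------------------------------------
# the elementary equations

def test_depletion_fraction_definition():
    assert depletion_fraction(1.0, 1.0) == 0.0
    assert depletion_fraction(1.5, 1.0) == pytest.approx(0.5)
    assert depletion_fraction(0.5, 1.0) == pytest.approx(-0.5)
    with pytest.raises(ciris.CirisError):
        depletion_fraction(1.0, 0.0)


def test_depletion_fraction_forward_model_r_times_p(calibration, leu_enk):
    """With n0 untagged and n1 singly tagged ions and per-tag loss p, the
    untagged gain is F = (n1/n0) * p exactly (expectation algebra)."""
    s = leu_enk.species[0]
    n0, n1, p = 1000.0, 600.0, 0.4
    off = np.array([n0, n1])
    on = thin_tag_histogram(off, p)
    kw = dict(t_start=74.0, n_samples=9000)
    tr_off = ciris.synth_tof_trace([(s, off)], calibration, **kw)
    tr_on = ciris.synth_tof_trace([(s, on)], calibration, **kw)
    win = (s.mz - 0.35, s.mz + 0.35)
    I_off = ciris.integrate_window(ciris.trace_to_spectrum(tr_off, calibration), *win)
    I_on = ciris.integrate_window(ciris.trace_to_spectrum(tr_on, calibration), *win)
    assert depletion_fraction(I_on, I_off) == pytest.approx((n1 / n0) * p, rel=0.01)


def test_linearize_closed_forms():
    assert linearize(0.0) == 0.0
    # the 95% depletion operating maximum linearizes to -ln(0.05)
    assert linearize(0.95) == pytest.approx(-math.log(0.05), rel=1e-12)
    # first-order Taylor: S ~ F for small depletion
    for F in (0.001, 0.01, 0.02):
        assert linearize(F) == pytest.approx(F, rel=0.011)
    # negative noise passes through; capping replaces the domain error
    assert linearize(-0.05) == pytest.approx(math.log(1 / 1.05), rel=1e-9)
    assert linearize(2.0, cap=0.999) == pytest.approx(-math.log(0.001))
    with pytest.raises(ValueError):
        linearize(0.5, cap=1.5)


def test_flux_normalize_definition():
    assert flux_normalize(0.0, 1500.0, 2.0) == 0.0
    one = flux_normalize(0.3, 1500.0, 2.0)
    assert flux_normalize(0.3, 1500.0, 4.0) == pytest.approx(one / 2)
    with pytest.raises(ciris.CirisError):
        flux_normalize(0.3, 1500.0, 0.0)
    with pytest.raises(ciris.CirisError):
        flux_normalize(0.3, 0.0, 2.0)


# ---------------------------------------------------------------------------
# cycle pairing

def test_pair_cycles_counts_and_shuffle_invariance(leu_enk, fresh):
    sc = reduce_scan(fresh(leu_enk), wn_step=400.0, cycles=5, stochastic=True)
    ds = ciris.simulate_scan(sc, seed=31)
    win = _retrieval_window(sc)
    pairs = pair_cycles(ds, win, sc.calibration)
    assert all(on.size == 5 and off.size == 5 for on, off in pairs.values())
    # shuffle records: pairing is metadata-driven, so results are identical
    rng = np.random.default_rng(0)
    perm = rng.permutation(ds.n_records)
    shuffled = dataclasses.replace(
        ds,
        wn_index=ds.wn_index[perm],
        cycle_index=ds.cycle_index[perm],
        laser_on=ds.laser_on[perm],
        intensities=ds.intensities[perm],
    )
    pairs2 = pair_cycles(shuffled, win, sc.calibration)
    for wn in pairs:
        assert np.allclose(np.sort(pairs[wn][0]), np.sort(pairs2[wn][0]))


def test_pair_cycles_drops_unpaired_with_warning(leu_enk, fresh):
    sc = reduce_scan(fresh(leu_enk), wn_step=400.0, cycles=3, stochastic=True)
    ds = ciris.simulate_scan(sc, seed=32)
    keep = np.ones(ds.n_records, bool)
    keep[1] = False  # drop one laser-on record
    clipped = dataclasses.replace(
        ds,
        wn_index=ds.wn_index[keep],
        cycle_index=ds.cycle_index[keep],
        laser_on=ds.laser_on[keep],
        intensities=ds.intensities[keep],
    )
    win = _retrieval_window(sc)
    with pytest.warns(ciris.CirisWarning):
        pairs = pair_cycles(clipped, win, sc.calibration)
    assert pairs[float(ds.wn_grid[0])][0].size == 2


def test_pair_cycles_errors_on_grid_point_without_pairs(leu_enk, fresh):
    sc = reduce_scan(fresh(leu_enk), wn_step=400.0, cycles=1, stochastic=True)
    ds = ciris.simulate_scan(sc, seed=33)
    only_off = ds.laser_on == 0
    # keep the on-record everywhere except the first grid point
    drop = (ds.wn_index == 0) & ~only_off
    keep = ~drop
    broken = dataclasses.replace(
        ds,
        wn_index=ds.wn_index[keep],
        cycle_index=ds.cycle_index[keep],
        laser_on=ds.laser_on[keep],
        intensities=ds.intensities[keep],
    )
    with pytest.raises(ciris.CirisError, match="990"), pytest.warns(ciris.CirisWarning):
        pair_cycles(broken, _retrieval_window(sc), sc.calibration)


# ---------------------------------------------------------------------------
# retrieval round trips

def test_flat_sigma_with_varying_energy_retrieves_flat(leu_enk, fresh):
    """A flat true cross-section must come back flat even though the pulse
    energy varies strongly across the scan -- isolates flux normalization."""
    sc = reduce_scan(fresh(leu_enk), wn_step=20.0, cycles=1)
    sc.species[0] = dataclasses.replace(
        sc.species[0], true_sigma=GaussianBands((), floor=1.0)
    )
    ciris.set_peak_depletion(sc, 0.05, mode="tagged")
    ds = ciris.simulate_scan(sc, seed=34)
    spec = retrieve_spectrum(
        ds,
        _retrieval_window(sc),
        sc.scan.energy_profile,
        calibration=sc.calibration,
        reference_mode="tagged_off",
        max_tags=8,
    )
    flat = np.full(spec.wn.size, spec.sigma_rel.mean())
    assert np.sqrt(np.mean((spec.sigma_rel / flat - 1) ** 2)) < 0.02


def test_roundtrip_exact_for_single_tag_ions(leu_enk, fresh):
    """For ions carrying exactly one tag the linearized tagged-reference
    retrieval is exactly proportional to the true cross-section, even at the
    95% depletion operating point."""
    sc = reduce_scan(fresh(leu_enk), wn_step=20.0, cycles=1)
    sc.species[0] = dataclasses.replace(sc.species[0], tag_distribution="fixed")
    ciris.set_peak_depletion(sc, 0.95, mode="tagged")
    ds = ciris.simulate_scan(sc, seed=35)
    spec = retrieve_spectrum(
        ds,
        _retrieval_window(sc),
        sc.scan.energy_profile,
        calibration=sc.calibration,
        reference_mode="tagged_off",
        max_tags=3,
    )
    truth = sc.species[0].true_sigma(spec.wn)
    assert scale_matched_rms(spec.sigma_rel, truth) < 0.005


def test_retrieval_scale_invariance(leu_enk, fresh):
    """Multiplying every intensity by c > 0 leaves the spectrum unchanged."""
    sc = reduce_scan(fresh(leu_enk), wn_step=100.0, cycles=3, stochastic=True)
    ds = ciris.simulate_scan(sc, seed=36)
    kw = dict(calibration=sc.calibration)
    a = retrieve_spectrum(ds, _retrieval_window(sc), sc.scan.energy_profile, **kw)
    b = retrieve_spectrum(
        ds.scaled(3.7), _retrieval_window(sc), sc.scan.energy_profile, **kw
    )
    assert np.allclose(b.sigma_rel, a.sigma_rel, rtol=1e-4, atol=1e-9)


def test_untagged_reference_saturates_at_operating_fluence(leu_enk, fresh):
    """At the 95% tag-depletion operating point the untagged-gain reference
    exceeds its own laser-off signal (F > 1) on the strongest band, which the
    retrieval flags as saturated instead of hiding."""
    sc = reduce_scan(fresh(leu_enk), wn_step=20.0, cycles=1)
    ds = ciris.simulate_scan(sc, seed=37)
    spec = retrieve_spectrum(
        ds,
        _retrieval_window(sc),
        sc.scan.energy_profile,
        calibration=sc.calibration,
        reference_mode="untagged_off",
    )
    assert spec.saturated.any()
    # diagnostics records carry the raw F for every point
    sat_recs = [r for r in spec.records if r.saturated]
    assert all(r.F_dep >= 0.999 for r in sat_recs)


def test_unlinearized_option_returns_raw_fraction(leu_enk, fresh):
    sc = reduce_scan(fresh(leu_enk), wn_step=100.0, cycles=1)
    ciris.set_peak_depletion(sc, 0.5, mode="tagged")
    ds = ciris.simulate_scan(sc, seed=38)
    kw = dict(
        calibration=sc.calibration, reference_mode="tagged_off", max_tags=8
    )
    lin = retrieve_spectrum(ds, _retrieval_window(sc), sc.scan.energy_profile, **kw)
    raw = retrieve_spectrum(
        ds, _retrieval_window(sc), sc.scan.energy_profile, linearized=False, **kw
    )
    F = np.array([r.F_dep for r in raw.records])
    assert np.all(lin.sigma_rel[F > 0.05] > raw.sigma_rel[F > 0.05])


def test_jackknife_stderr_scales_as_inverse_sqrt_pairs(leu_enk, fresh):
    """Quadrupling the number of cycle pairs halves the jackknife standard
    error on homogeneous synthetic data (approximately)."""
    base = reduce_scan(
        fresh(leu_enk), wn_step=300.0, cycles=10, stochastic=True, fluence_scale=0.0
    )
    big = reduce_scan(
        fresh(leu_enk), wn_step=300.0, cycles=40, stochastic=True, fluence_scale=0.0
    )
    win = _retrieval_window(base)
    ratios = []
    for seed in (40, 41, 42):
        ds_small = ciris.simulate_scan(base, seed=seed)
        ds_big = ciris.simulate_scan(big, seed=seed + 100)
        s_small = retrieve_spectrum(
            ds_small, win, base.scan.energy_profile, calibration=base.calibration
        )
        s_big = retrieve_spectrum(
            ds_big, win, big.scan.energy_profile, calibration=big.calibration
        )
        ratios.extend(s_small.stderr / s_big.stderr)
    assert 1.4 < np.median(ratios) < 2.9


def test_normalization_max1(leu_enk, fresh):
    sc = reduce_scan(fresh(leu_enk), wn_step=50.0, cycles=1)
    ciris.set_peak_depletion(sc, 0.3, mode="tagged")
    ds = ciris.simulate_scan(sc, seed=43)
    spec = retrieve_spectrum(
        ds,
        _retrieval_window(sc),
        sc.scan.energy_profile,
        calibration=sc.calibration,
        reference_mode="tagged_off",
        max_tags=8,
        normalization="max1",
    )
    assert spec.sigma_rel.max() == pytest.approx(1.0)


def test_scale_matched_rms_basics():
    t = np.array([1.0, 2.0, 3.0])
    assert scale_matched_rms(10 * t, t) == pytest.approx(0.0, abs=1e-12)
    assert scale_matched_rms(t + 0.1, t) > 0
    with pytest.raises(ValueError):
        scale_matched_rms(np.zeros(3), t)
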