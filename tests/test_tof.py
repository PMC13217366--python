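"""TOF calibration, baseline handling, window integration and tag series."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ciris
from ciris.tof import (
    N2_MASS,
    MassSpectrum,
    TagSeries,
    TofCalibration,
    TofTrace,
    baseline_correct,
    extract_tag_series,
    fit_calibration,
    integrate_window,
    mean_tag_count,
    trace_to_spectrum,
)


# ---------------------------------------------------------------------------
# calibration

@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    mz=st.floats(1.0, 5000.0),
    t0=st.floats(0.0, 10.0),
    k=st.floats(0.1, 10.0),
)
def test_calibration_roundtrip_bijective(mz, t0, k):
    """tof_to_mz inverts mz_to_tof to within 1e-9 relative, for any m/z > 0."""
    cal = TofCalibration(t0=t0, k=k)
    back = float(cal.tof_to_mz(cal.mz_to_tof(mz)))
    assert back == pytest.approx(mz, rel=1e-9)


def test_calibration_monotone_in_mz():
    cal = TofCalibration(t0=0.5, k=3.2)
    mz = np.linspace(10, 2000, 500)
    assert np.all(np.diff(cal.mz_to_tof(mz)) > 0)


def test_calibration_requires_positive_slope():
    with pytest.raises(ValueError):
        TofCalibration(t0=0.0, k=-1.0)


def test_fit_exact_two_points():
    """Two points exactly on the model are interpolated with zero residual."""
    t0, k = 1.2, 0.7
    pairs = [(100.0, t0 + 10 * k), (400.0, t0 + 20 * k)]
    cal = fit_calibration(pairs)
    assert cal.t0 == pytest.approx(t0, abs=1e-9)
    assert cal.k == pytest.approx(k, abs=1e-9)
    assert cal.rmse == pytest.approx(0.0, abs=1e-9)


def test_fit_sqrt_scaling_quadruple_mz_doubles_time():
    """Flight time above t0 scales as sqrt(m/z): x4 in m/z gives x2 in t - t0."""
    cal = fit_calibration([(m, 0.8 + 2.5 * np.sqrt(m)) for m in (50, 200, 450, 800)])
    t1 = float(cal.mz_to_tof(150.0)) - cal.t0
    t2 = float(cal.mz_to_tof(600.0)) - cal.t0
    assert t2 == pytest.approx(2 * t1, rel=1e-12)


def test_fit_noisy_recovery_within_stderr():
    """With Gaussian timing noise the fit recovers the parameters and reports
    standard errors of the right scale (single-replicate sanity check; the
    full Monte-Carlo coverage study lives in the acceptance suite)."""
    rng = np.random.default_rng(42)
    t0, k, noise = 0.5, 3.2, 0.01
    mz = np.linspace(100, 1500, 50)
    t = t0 + k * np.sqrt(mz) + rng.normal(0, noise, mz.size)
    cal = fit_calibration(np.column_stack([mz, t]))
    se_t0, se_k = cal.param_stderr
    assert abs(cal.t0 - t0) < 3 * se_t0
    assert abs(cal.k - k) < 3 * se_k


def test_fit_rejects_degenerate_input():
    with pytest.raises(ValueError):
        fit_calibration([(100.0, 5.0)])
    with pytest.raises(ValueError):
        fit_calibration([(100.0, 5.0), (100.0, 6.0)])


# ---------------------------------------------------------------------------
# baseline correction

def _noise_trace(rng, n=4000, offset=5.0):
    return TofTrace(t_start=0.0, dt=0.002, counts=rng.poisson(offset, n).astype(float))


def test_baseline_constant_trace_goes_to_zero():
    trace = TofTrace(t_start=0.0, dt=0.01, counts=np.full(2000, 7.3))
    out = baseline_correct(trace, window=301, quantile=0.1)
    assert np.allclose(out.counts, 0.0, atol=1e-12)


def test_baseline_preserves_peak_area_and_removes_offset():
    """A Gaussian peak on a constant offset keeps its area to within 1%."""
    dt, sigma, area, offset = 0.002, 0.01, 5000.0, 40.0
    t = dt * np.arange(6000)
    center = t[3000]
    peak = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    trace = TofTrace(t_start=0.0, dt=dt, counts=peak + offset)
    out = baseline_correct(trace, window=501, quantile=0.1)
    got_area = out.counts[2800:3200].sum() * dt
    assert got_area == pytest.approx(area, rel=0.01)
    assert abs(np.mean(out.counts[:2000])) < 0.05 * offset


def test_baseline_pure_noise_median_near_zero():
    """With the median as the rolling quantile, pure noise centers on zero."""
    out = baseline_correct(_noise_trace(np.random.default_rng(1)), window=501, quantile=0.5)
    assert abs(np.median(out.counts)) <= 1.0  # discrete counts: within one count


def test_baseline_idempotent_within_noise():
    trace = _noise_trace(np.random.default_rng(2))
    once = baseline_correct(trace, window=501, quantile=0.5)
    twice = baseline_correct(once, window=501, quantile=0.5)
    assert np.mean(np.abs(twice.counts - once.counts)) < 0.5


def test_baseline_input_validation():
    trace = TofTrace(t_start=0.0, dt=0.01, counts=np.zeros(100))
    with pytest.raises(ValueError):
        baseline_correct(trace, window=101, quantile=0.1)  # longer than trace
    with pytest.raises(ValueError):
        baseline_correct(trace, window=50, quantile=0.1)  # even
    with pytest.raises(ValueError):
        baseline_correct(trace, window=51, quantile=0.7)  # quantile > 0.5


# ---------------------------------------------------------------------------
# time -> m/z conversion

def test_trace_to_spectrum_maps_grid_points_exactly(calibration):
    """A sample placed at t0 + k*sqrt(526.4) lands at m/z 526.4."""
    target = 526.4
    t_target = float(calibration.mz_to_tof(target))
    trace = TofTrace(t_start=t_target - 0.02, dt=0.002, counts=np.arange(21.0))
    spec = trace_to_spectrum(trace, calibration)
    assert spec.mz[10] == pytest.approx(target, rel=1e-12)
    assert np.all(np.diff(spec.mz) > 0)


def test_trace_to_spectrum_drops_pre_t0_samples(calibration):
    trace = TofTrace(t_start=calibration.t0 - 0.01, dt=0.002, counts=np.ones(100))
    spec = trace_to_spectrum(trace, calibration)
    assert spec.mz.size < 100
    early = TofTrace(t_start=calibration.t0 - 1.0, dt=0.002, counts=np.ones(10))
    with pytest.raises(ciris.CirisError):
        trace_to_spectrum(early, calibration)


# ---------------------------------------------------------------------------
# window integration

def test_integrate_window_additive_over_disjoint_windows():
    rng = np.random.default_rng(3)
    spec = MassSpectrum(mz=np.linspace(100, 200, 1001), intensity=rng.normal(5, 1, 1001))
    whole = integrate_window(spec, 120.0, 180.0)
    parts = integrate_window(spec, 120.0, 151.3) + integrate_window(spec, 151.3, 180.0)
    assert parts == pytest.approx(whole, rel=1e-12)


def test_integrate_window_gaussian_area():
    """A Gaussian peak fully inside the window integrates to its analytic area."""
    mz = np.linspace(500, 520, 4001)
    area, center, sigma = 1234.5, 510.0, 0.2
    spec = MassSpectrum(
        mz=mz,
        intensity=area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((mz - center) / sigma) ** 2),
    )
    assert integrate_window(spec, 508.0, 512.0) == pytest.approx(area, rel=0.01)


def test_integrate_window_outside_range_is_zero():
    spec = MassSpectrum(mz=np.linspace(100, 200, 101), intensity=np.ones(101))
    assert integrate_window(spec, 300.0, 310.0) == 0.0
    with pytest.raises(ValueError):
        integrate_window(spec, 150.0, 150.0)


# ---------------------------------------------------------------------------
# tag series

def _tagged_spectrum(populations, calibration, base_mz=556.28, noise_seed=None):
    species = ciris.IonSpeciesSpec(
        name="x",
        neutral_mass=base_mz - 1.00728,
        adduct_mass=1.00728,
        charge=1,
        arrival_mean=5.0,
        arrival_fwhm=0.4,
    )
    trace = ciris.synth_tof_trace(
        [(species, np.asarray(populations, dtype=float))],
        calibration,
        noise_seed=noise_seed,
    )
    return trace_to_spectrum(trace, calibration)


def test_tag_series_recovers_population_fractions(calibration):
    """Generator populations (40/40/20%) come back within 2% relative."""
    pops = np.array([40000.0, 40000.0, 20000.0])
    spec = _tagged_spectrum(pops, calibration)
    series = extract_tag_series(spec, 556.28, charge=1, max_tags=2)
    got = series.intensities / series.intensities.sum()
    want = pops / pops.sum()
    assert np.all(np.abs(got / want - 1) < 0.02)


def test_tag_series_spacing_is_28(calibration):
    spec = _tagged_spectrum([1000.0, 800.0, 300.0, 80.0], calibration)
    series = extract_tag_series(spec, 556.28, charge=1, max_tags=3)
    spacings = series.peak_spacings()
    assert spacings.size == 3
    assert np.allclose(spacings, N2_MASS, atol=0.05)
    assert np.all(np.rint(spacings) == 28)


def test_tag_series_untagged_only(calibration):
    spec = _tagged_spectrum([5000.0], calibration)
    series = extract_tag_series(spec, 556.28, charge=1, max_tags=3)
    assert series.intensities[0] > 0
    assert np.all(np.abs(series.intensities[1:]) < 1e-6 * series.intensities[0])


def test_tag_series_rejects_overlapping_windows():
    spec = MassSpectrum(mz=np.linspace(500, 700, 101), intensity=np.ones(101))
    with pytest.raises(ValueError):
        extract_tag_series(spec, 556.28, charge=1, window_halfwidth=15.0)
    with pytest.raises(ValueError):
        extract_tag_series(spec, 556.28, charge=2, window_halfwidth=8.0)


def test_mean_tag_count_basics():
    mk = lambda inten: TagSeries(
        base_mz=500.0,
        charge=1,
        intensities=np.asarray(inten, dtype=float),
        window_halfwidth=0.35,
        centroids=np.full(len(inten), np.nan),
    )
    assert mean_tag_count(mk([1.0, 0.0, 0.0])) == 0.0
    assert mean_tag_count(mk([0.0, 1.0])) == 1.0
    # negative intensities are clipped, not allowed to push the mean around
    assert mean_tag_count(mk([1.0, -5.0, 1.0])) == 1.0
    with pytest.raises(ciris.CirisError):
        mean_tag_count(mk([0.0, 0.0]))


def test_mean_tag_count_poisson_sample():
    """The estimator converges to the Poisson mean at large ion count."""
    counts = np.bincount(np.random.default_rng(4).poisson(2.0, 100_000))
    series = TagSeries(
        base_mz=500.0,
        charge=1,
        intensities=counts.astype(float),
        window_halfwidth=0.35,
        centroids=np.full(counts.size, np.nan),
    )
    assert mean_tag_count(series) == pytest.approx(2.0, rel=0.02)
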