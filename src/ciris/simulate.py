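"""Forward instrument simulator for messenger-tagging IR spectroscopy.

The simulator emulates the data-generating process of a cryogenic-trap
IM-MS-IR instrument well enough to exercise every downstream processing
stage against known ground truth:

* ions of one or more species arrive from the mobility cell with Gaussian
  arrival-time distributions and can be gated by a slice window;
* in the cryogenic trap each ion picks up a Poisson-distributed number of
  N2 tags (mean ``mean_tags``), shifting its m/z by 28.006/|z| per tag;
* on laser-on cycles a single resonant photon detaches a tag, so each tag
  is lost independently with probability
  ``p = 1 - exp(-fluence_scale * sigma(wn) * E(wn) * wn)``  -- the photon
  flux of a pulsed IR source is proportional to pulse energy over
  wavelength, i.e. to E times the wavenumber;
* the released packet is pushed into the TOF analyzer and digitized as a
  transient with Gaussian peaks at t = t0 + k*sqrt(m/z), Poisson counting
  noise and a constant baseline offset;
* paired off/on transients are produced at every step of a wavenumber scan,
  with per-cycle Poisson ion numbers emulating electrospray fluctuation.

Every random draw flows from one integer seed, so identical (scenario,
seed) inputs reproduce a dataset bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .dataset import RawDataset
from .mobility import SliceWindow
from .tof import FWHM_TO_SIGMA, N2_MASS, TofCalibration, TofTrace

__all__ = [
    "PROTON_MASS",
    "SODIUM_MASS",
    "DEFAULT_CALIBRATION",
    "GaussianBands",
    "LaserEnergyProfile",
    "IonSpeciesSpec",
    "TrapCycleConfig",
    "LaserScanConfig",
    "Scenario",
    "PRESETS",
    "make_preset",
    "sample_tag_counts",
    "detag_probability",
    "apply_laser",
    "sample_arrival_times",
    "sample_mixture_events",
    "expected_tag_histogram",
    "thin_tag_histogram",
    "synth_tof_trace",
    "simulate_scan",
    "peak_depletion",
    "set_peak_depletion",
]

#: Mass of a proton adduct, Da.
PROTON_MASS = 1.00728
#: Mass of a sodium cation adduct, Da.
SODIUM_MASS = 22.98922

#: Flight-time calibration used by all presets: t = 0.5 + 3.2*sqrt(m/z) us,
#: which places ions of m/z 500-700 in the 72-85 us range of the pusher era.
DEFAULT_CALIBRATION = TofCalibration(t0=0.5, k=3.2)


@dataclass(frozen=True)
class GaussianBands:
    """A synthetic relative absorption cross-section: a sum of Gaussian bands
    on a small constant floor.  Units are arbitrary (relative)."""

    bands: tuple[tuple[float, float, float], ...]  # (center cm^-1, height, fwhm cm^-1)
    floor: float = 0.0

    def __post_init__(self):
        for c, h, w in self.bands:
            if h < 0 or w <= 0:
                raise ValueError("band heights must be >= 0 and widths > 0")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")

    def __call__(self, wn) -> np.ndarray:
        wn = np.asarray(wn, dtype=float)
        out = np.full(wn.shape, float(self.floor))
        for c, h, w in self.bands:
            s = w / FWHM_TO_SIGMA
            out += h * np.exp(-0.5 * ((wn - c) / s) ** 2)
        return out


@dataclass(frozen=True)
class LaserEnergyProfile:
    """Measured pulse energy E (mJ) on a strictly increasing wavenumber grid.

    Queries are linearly interpolated inside the grid; extrapolation is
    refused because the profile of an OPO/OPA chain is not predictable
    outside its measured range.
    """

    wn: np.ndarray
    energy: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "wn", np.asarray(self.wn, dtype=float))
        object.__setattr__(self, "energy", np.asarray(self.energy, dtype=float))
        if self.wn.ndim != 1 or self.wn.size < 2 or self.wn.shape != self.energy.shape:
            raise ValueError("profile needs matching 1-D grids with >= 2 points")
        if np.any(np.diff(self.wn) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if np.any(self.energy <= 0):
            raise ValueError("pulse energies must be > 0 everywhere")

    def __call__(self, wn) -> np.ndarray:
        q = np.asarray(wn, dtype=float)
        if np.any(q < self.wn[0]) or np.any(q > self.wn[-1]):
            raise ValueError(
                f"wavenumber outside measured profile range [{self.wn[0]:g}, {self.wn[-1]:g}]"
            )
        return np.interp(q, self.wn, self.energy)

    @classmethod
    def synthetic(cls, wn_lo: float = 980.0, wn_hi: float = 1830.0, step: float = 10.0):
        """A smooth OPO-like profile rising from ~1.5 mJ near 1000 cm^-1
        toward ~3.2 mJ at the blue end of the fingerprint range."""
        wn = np.arange(wn_lo, wn_hi + 0.5 * step, step)
        energy = np.clip(1.5 + 2.0 * (wn - 1000.0) / 1000.0, 0.3, None)
        return cls(wn=wn, energy=energy)


@dataclass
class IonSpeciesSpec:
    """Ground-truth description of one analyte used by the simulator."""

    name: str
    neutral_mass: float
    adduct_mass: float
    charge: int
    arrival_mean: float
    arrival_fwhm: float
    rel_abundance: float = 1.0
    mean_tags: float = 1.0
    true_sigma: Callable[[np.ndarray], np.ndarray] = GaussianBands(())
    tag_distribution: str = "poisson"
    label_mz: float | None = None  # nominal value as printed on instrument readouts

    def __post_init__(self):
        if self.neutral_mass <= 0:
            raise ValueError("neutral_mass must be > 0")
        if self.charge == 0:
            raise ValueError("charge must be nonzero (sign encodes polarity)")
        if self.arrival_fwhm <= 0:
            raise ValueError("arrival_fwhm must be > 0")
        if self.rel_abundance < 0 or self.mean_tags < 0:
            raise ValueError("rel_abundance and mean_tags must be >= 0")
        if self.tag_distribution not in ("poisson", "fixed"):
            raise ValueError("tag_distribution must be 'poisson' or 'fixed'")
        if not np.isfinite(self.mz) or self.mz <= 0:
            raise ValueError("base m/z must be finite and > 0")

    @property
    def mz(self) -> float:
        z = abs(self.charge)
        return (self.neutral_mass + self.adduct_mass * z) / z

    @property
    def tag_spacing(self) -> float:
        return N2_MASS / abs(self.charge)


@dataclass
class TrapCycleConfig:
    """Timing of one trap cycle (all times in ms from the IMS start trigger).

    Ions accumulate and tag during ``accumulation_ms``; the tagging-gas
    pulse leads the ions by ``gas_pulse_lead_ms``; after release the pusher
    runs at ``pusher_freq_kHz`` inside ``pusher_window_ms`` and the laser
    fires at ``laser_fire_ms``.  One acquisition cycle holds two trap
    cycles, one with and one without irradiation.
    """

    accumulation_ms: tuple[float, float] = (0.0, 50.0)
    gas_pulse_lead_ms: float = 2.0
    laser_fire_ms: float = 50.092
    pusher_window_ms: tuple[float, float] = (50.045, 50.099)
    pusher_freq_kHz: float = 18.0
    acquisition_cycle_ms: float = 100.0
    cycles_per_wavenumber: int = 75
    on_off_alternation: bool = True
    temperature_K: float = 40.0  # carried as metadata only

    def __post_init__(self):
        a0, a1 = self.accumulation_ms
        p0, p1 = self.pusher_window_ms
        if not a0 < a1 <= p0 < p1:
            raise ValueError("accumulation must end before the pusher/release window")
        if not p0 <= self.laser_fire_ms <= p1:
            raise ValueError("laser must fire inside the post-release pusher window")
        if self.acquisition_cycle_ms <= 0 or self.cycles_per_wavenumber < 1:
            raise ValueError("invalid cycle configuration")


@dataclass
class LaserScanConfig:
    """Wavenumber scan grid plus the laser energy profile and the fluence
    calibration constant that converts sigma*E*wn into a detagging exponent."""

    wn_start: float = 990.0
    wn_stop: float = 1810.0
    wn_step: float = 2.0
    energy_profile: LaserEnergyProfile = field(
        default_factory=LaserEnergyProfile.synthetic
    )
    fluence_scale: float = 1e-4

    def __post_init__(self):
        if not self.wn_start < self.wn_stop:
            raise ValueError("wn_start must be < wn_stop")
        if self.wn_step <= 0:
            raise ValueError("wn_step must be > 0")
        if self.fluence_scale < 0:
            raise ValueError("fluence_scale must be >= 0")

    def grid(self) -> np.ndarray:
        n = int(math.floor((self.wn_stop - self.wn_start) / self.wn_step + 1e-9)) + 1
        return self.wn_start + self.wn_step * np.arange(n)


@dataclass
class Scenario:
    """Everything needed to simulate one acquisition.

    ``source_rate`` is the mean number of ions (all species) delivered per
    trap cycle; per-cycle numbers fluctuate as Poisson draws when
    ``stochastic`` is true, emulating electrospray instability.  With
    ``stochastic=False`` the simulator propagates expected values instead of
    samples and adds no counting noise, giving the noiseless limit used for
    round-trip verification.
    """

    species: list[IonSpeciesSpec]
    trap: TrapCycleConfig = field(default_factory=TrapCycleConfig)
    scan: LaserScanConfig = field(default_factory=LaserScanConfig)
    calibration: TofCalibration = DEFAULT_CALIBRATION
    source_rate: float = 3000.0
    peak_width: float = 0.01  # Gaussian sigma of one TOF peak, us
    dt: float = 0.002  # digitizer sampling interval, us
    baseline: float = 2.0  # constant detector offset, counts per sample
    gain: float = 1.0  # m/z-domain peak area per ion
    stochastic: bool = True
    counting_noise: bool = True
    slice_window: SliceWindow | None = None

    def __post_init__(self):
        if not self.species:
            raise ValueError("scenario needs at least one species")
        if self.source_rate < 0 or self.peak_width <= 0 or self.dt <= 0:
            raise ValueError("invalid scenario parameters")

    def shares(self) -> np.ndarray:
        a = np.array([s.rel_abundance for s in self.species], dtype=float)
        tot = a.sum()
        if tot <= 0:
            raise ValueError("total relative abundance must be > 0")
        return a / tot


# ---------------------------------------------------------------------------
# presets

def _leu_enk_species() -> IonSpeciesSpec:
    # Protonated leucine enkephalin (YGGFL) monomer; synthetic band pattern
    # loosely amide-like in the 990-1810 cm^-1 fingerprint range.
    return IonSpeciesSpec(
        name="leu_enk_H",
        neutral_mass=555.2693,
        adduct_mass=PROTON_MASS,
        charge=1,
        arrival_mean=6.10,
        arrival_fwhm=0.50,
        rel_abundance=1.0,
        mean_tags=1.0,
        true_sigma=GaussianBands(
            bands=(
                (1688.0, 1.00, 25.0),
                (1640.0, 0.45, 30.0),
                (1520.0, 0.55, 28.0),
                (1445.0, 0.25, 30.0),
                (1235.0, 0.30, 35.0),
                (1140.0, 0.20, 40.0),
            ),
            floor=0.01,
        ),
    )


_TRISACCHARIDE_MASS = 504.16903  # C18H32O16, monoisotopic


def _melezitose_species() -> IonSpeciesSpec:
    return IonSpeciesSpec(
        name="melezitose_Na",
        neutral_mass=_TRISACCHARIDE_MASS,
        adduct_mass=SODIUM_MASS,
        charge=1,
        arrival_mean=4.75,
        arrival_fwhm=0.40,
        rel_abundance=0.85,
        mean_tags=1.0,
        true_sigma=GaussianBands(
            bands=(
                (1030.0, 0.90, 30.0),
                (1080.0, 0.70, 28.0),
                (1150.0, 0.50, 30.0),
                (1340.0, 0.30, 40.0),
                (1440.0, 0.25, 35.0),
                (1640.0, 0.15, 40.0),
            ),
            floor=0.01,
        ),
        label_mz=526.4,
    )


def _cellotriose_species() -> IonSpeciesSpec:
    # mean_tags chosen so that an 0.85:1 melezitose:cellotriose mixture has
    # an average tag count of 2 while the sliced early component has 1:
    # (0.85*1.0 + 1.0*2.85) / 1.85 = 2.0
    return IonSpeciesSpec(
        name="cellotriose_Na",
        neutral_mass=_TRISACCHARIDE_MASS,
        adduct_mass=SODIUM_MASS,
        charge=1,
        arrival_mean=5.35,
        arrival_fwhm=0.40,
        rel_abundance=1.0,
        mean_tags=2.85,
        true_sigma=GaussianBands(
            bands=(
                (1045.0, 1.00, 32.0),
                (1110.0, 0.60, 30.0),
                (1165.0, 0.45, 28.0),
                (1370.0, 0.30, 40.0),
                (1420.0, 0.20, 35.0),
                (1660.0, 0.12, 40.0),
            ),
            floor=0.01,
        ),
        label_mz=526.4,
    )


PRESETS = ("leu_enk", "trisaccharide_mixture", "melezitose_sliced")


def make_preset(preset_name: str) -> Scenario:
    """Build a fully populated scenario for one of the named study systems.

    ``leu_enk``: one protonated peptide species with a mean of 1 N2 tag.
    ``trisaccharide_mixture``: two isobaric sodiated trisaccharides arriving
    at 4.75 and 5.35 ms (FWHM 0.4 ms) with mixture-average tag count 2.
    ``melezitose_sliced``: the early mixture component alone.

    The fluence calibration of every preset is set so that the strongest
    band reaches 95% tag depletion, the top of the instrument's stated
    90-95% operating range.
    """
    if preset_name == "leu_enk":
        species = [_leu_enk_species()]
    elif preset_name == "trisaccharide_mixture":
        species = [_melezitose_species(), _cellotriose_species()]
    elif preset_name == "melezitose_sliced":
        species = [_melezitose_species()]
    else:
        raise ValueError(
            f"unknown preset {preset_name!r}; valid presets: {', '.join(PRESETS)}"
        )
    scenario = Scenario(species=species)
    set_peak_depletion(scenario, 0.95, mode="tagged")
    return scenario


# ---------------------------------------------------------------------------
# elementary stochastic operations

def sample_tag_counts(mean_tags: float, n_ions: int, seed) -> np.ndarray:
    """``n_ions`` independent Poisson(mean_tags) tag-count draws."""
    if mean_tags < 0:
        raise ValueError("mean_tags must be >= 0")
    if n_ions < 0:
        raise ValueError("n_ions must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.poisson(mean_tags, int(n_ions))


def detag_probability(true_sigma_value, wn, energy, fluence_scale):
    """Per-tag loss probability ``1 - exp(-fluence_scale * sigma * E * wn)``.

    The exponent is the product of the relative cross-section and the photon
    flux, which for a pulsed source focused near the diffraction limit is
    proportional to pulse energy times wavenumber.  Vectorized; all inputs
    must be nonnegative and the result lies in [0, 1).
    """
    s = np.asarray(true_sigma_value, dtype=float)
    w = np.asarray(wn, dtype=float)
    e = np.asarray(energy, dtype=float)
    if np.any(s < 0) or np.any(w < 0) or np.any(e < 0) or fluence_scale < 0:
        raise ValueError("all inputs to detag_probability must be >= 0")
    p = -np.expm1(-fluence_scale * s * e * w)
    return p if p.ndim else float(p)


def apply_laser(tag_counts, p: float, seed) -> np.ndarray:
    """Remove each tag independently with probability ``p``.

    Surviving counts are Binomial(k, 1-p) draws, so counts never increase.
    Laser-off cycles use p = 0 and return the input unchanged.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"detagging probability must lie in [0, 1], got {p}")
    counts = np.asarray(tag_counts, dtype=int)
    if np.any(counts < 0):
        raise ValueError("tag counts must be >= 0")
    if p == 0.0:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.binomial(counts, 1.0 - p)


def sample_arrival_times(spec: IonSpeciesSpec, n: int, seed) -> np.ndarray:
    """Gaussian arrival-time draws (ms) with the species' mean and FWHM."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = spec.arrival_fwhm / FWHM_TO_SIGMA
    return rng.normal(spec.arrival_mean, sigma, int(n))


def sample_mixture_events(
    species: Sequence[IonSpeciesSpec], n: int, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` labelled arrival events from a mixture of species.

    Species are chosen proportionally to ``rel_abundance``; returns
    ``(times_ms, labels)`` with labels taken from the species names.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    a = np.array([s.rel_abundance for s in species], dtype=float)
    p = a / a.sum()
    idx = rng.choice(len(species), size=int(n), p=p)
    means = np.array([s.arrival_mean for s in species])
    sigmas = np.array([s.arrival_fwhm for s in species]) / FWHM_TO_SIGMA
    times = rng.normal(means[idx], sigmas[idx])
    labels = np.array([s.name for s in species])[idx]
    return times, labels


# ---------------------------------------------------------------------------
# tag-count bookkeeping (expected-value path)

def _kmax(spec: IonSpeciesSpec) -> int:
    if spec.tag_distribution == "fixed":
        return int(round(spec.mean_tags))
    if spec.mean_tags == 0:
        return 0
    return int(stats.poisson.ppf(1.0 - 1e-9, spec.mean_tags)) + 1


def expected_tag_histogram(spec: IonSpeciesSpec, kmax: int | None = None) -> np.ndarray:
    """Probability mass over tag counts 0..kmax for one species."""
    if kmax is None:
        kmax = _kmax(spec)
    k = np.arange(kmax + 1)
    if spec.tag_distribution == "fixed":
        pmf = np.zeros(kmax + 1)
        pmf[int(round(spec.mean_tags))] = 1.0
        return pmf
    pmf = stats.poisson.pmf(k, spec.mean_tags)
    pmf[-1] += max(0.0, 1.0 - pmf.sum())  # fold the truncated tail into kmax
    return pmf


def thin_tag_histogram(hist: np.ndarray, p: float) -> np.ndarray:
    """Expected tag-count histogram after independent per-tag loss with
    probability ``p`` (binomial thinning applied to each bin)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    hist = np.asarray(hist, dtype=float)
    out = np.zeros_like(hist)
    for k in range(hist.size):
        if hist[k] == 0:
            continue
        j = np.arange(k + 1)
        out[: k + 1] += hist[k] * stats.binom.pmf(j, k, 1.0 - p)
    return out


# ---------------------------------------------------------------------------
# TOF synthesis

def _deposit_peaks(
    counts: np.ndarray,
    populations: Sequence[tuple[IonSpeciesSpec, np.ndarray]],
    cal: TofCalibration,
    peak_width: float,
    t_start: float,
    dt: float,
    gain: float,
) -> None:
    """Add Gaussian TOF peaks for every (species, tag count) population.

    The per-ion response is normalized so that each ion contributes an
    m/z-domain peak area of ``gain``: the time-domain area is scaled by
    dt/d(m/z) = k / (2*sqrt(m/z)) at the peak center, which folds the
    flight-time Jacobian into the detector response and keeps window
    integrals proportional to ion numbers across the whole tag ladder.
    """
    n_samples = counts.size
    for spec, pops in populations:
        pops = np.asarray(pops, dtype=float)
        for k in np.flatnonzero(pops > 0):
            mz_k = spec.mz + k * spec.tag_spacing
            t_c = float(cal.mz_to_tof(mz_k))
            area_time = pops[k] * gain * cal.k / (2.0 * math.sqrt(mz_k))
            lo = max(0, int((t_c - 6 * peak_width - t_start) / dt))
            hi = min(n_samples, int((t_c + 6 * peak_width - t_start) / dt) + 1)
            if hi <= lo:
                continue
            t = t_start + dt * np.arange(lo, hi)
            counts[lo:hi] += (
                area_time
                / (peak_width * math.sqrt(2 * math.pi))
                * np.exp(-0.5 * ((t - t_c) / peak_width) ** 2)
            )


def synth_tof_trace(
    populations: Sequence[tuple[IonSpeciesSpec, np.ndarray]],
    calibration: TofCalibration,
    peak_width: float = 0.01,
    baseline: float = 0.0,
    noise_seed=None,
    *,
    t_start: float | None = None,
    dt: float = 0.002,
    n_samples: int | None = None,
    gain: float = 1.0,
    meta: dict | None = None,
) -> TofTrace:
    """Synthesize one digitized transient from per-tag-count ion numbers.

    ``populations`` is a sequence of ``(species, counts_by_tag_number)``
    pairs.  Each (species, n tags) population contributes a Gaussian peak of
    width ``peak_width`` (us, one sigma) at the flight time of its m/z.
    When ``noise_seed`` is given (an int or a numpy Generator), Poisson
    counting noise is applied on top of the constant baseline; an empty
    population set yields a pure baseline trace.
    """
    if peak_width <= 0:
        raise ValueError("peak_width must be > 0")
    populations = [(s, np.asarray(p, dtype=float)) for s, p in populations]
    for _, pops in populations:
        if np.any(pops < 0):
            raise ValueError("populations must be >= 0")
    centers = [
        float(calibration.mz_to_tof(s.mz + k * s.tag_spacing))
        for s, pops in populations
        for k in np.flatnonzero(pops > 0)
    ]
    if t_start is None:
        t_start = (min(centers) - 1.0) if centers else 45.0
    if n_samples is None:
        t_stop = (max(centers) + 1.0) if centers else t_start + 10.0
        n_samples = int(math.ceil((t_stop - t_start) / dt))
    counts = np.full(n_samples, float(baseline))
    _deposit_peaks(counts, populations, calibration, peak_width, t_start, dt, gain)
    if noise_seed is not None:
        rng = (
            noise_seed
            if isinstance(noise_seed, np.random.Generator)
            else np.random.default_rng(noise_seed)
        )
        counts = rng.poisson(counts).astype(float)
    return TofTrace(t_start=t_start, dt=dt, counts=counts, meta=meta or {})


# ---------------------------------------------------------------------------
# full scan simulation

def _slice_fraction(spec: IonSpeciesSpec, window: SliceWindow) -> float:
    sigma = spec.arrival_fwhm / FWHM_TO_SIGMA
    lo = (window.lo - spec.arrival_mean) / sigma
    hi = (window.hi - spec.arrival_mean) / sigma
    return float(stats.norm.cdf(hi) - stats.norm.cdf(lo))


def _scan_axis(scenario: Scenario) -> tuple[float, int]:
    cal = scenario.calibration
    mz_lo = min(s.mz for s in scenario.species) - 8.0
    mz_hi = max(s.mz + _kmax(s) * s.tag_spacing for s in scenario.species) + 8.0
    t_lo = float(cal.mz_to_tof(max(mz_lo, 1.0))) - 0.3
    t_hi = float(cal.mz_to_tof(mz_hi)) + 0.3
    return t_lo, int(math.ceil((t_hi - t_lo) / scenario.dt))


def simulate_scan(scenario: Scenario, seed) -> RawDataset:
    """Simulate a complete paired on/off wavenumber scan.

    Records are ordered by wavenumber, then cycle index, with the laser-off
    transient preceding the laser-on transient of each acquisition cycle.
    All transients share one time axis so the result maps directly onto the
    binary container format.
    """
    rng = np.random.default_rng(seed)
    cal = scenario.calibration
    grid = scenario.scan.grid()
    energies = scenario.scan.energy_profile(grid)
    cycles = scenario.trap.cycles_per_wavenumber
    shares = scenario.shares()
    kmaxes = [_kmax(s) for s in scenario.species]
    pmfs = [expected_tag_histogram(s, km) for s, km in zip(scenario.species, kmaxes)]
    slice_fracs = (
        [_slice_fraction(s, scenario.slice_window) for s in scenario.species]
        if scenario.slice_window is not None
        else [1.0] * len(scenario.species)
    )
    p_matrix = np.column_stack(
        [
            np.asarray(
                detag_probability(
                    s.true_sigma(grid), grid, energies, scenario.scan.fluence_scale
                )
            )
            for s in scenario.species
        ]
    )
    t_start, n_samples = _scan_axis(scenario)
    n_rec = grid.size * cycles * 2
    intensities = np.empty((n_rec, n_samples), dtype=np.float32)
    wn_index = np.empty(n_rec, dtype=np.uint32)
    cycle_index = np.empty(n_rec, dtype=np.uint32)
    laser_on = np.empty(n_rec, dtype=np.uint8)

    row = 0
    for wi, wn in enumerate(grid):
        p_detag = p_matrix[wi].tolist()
        if not scenario.stochastic:
            # expected-value path: every cycle at this wavenumber is identical
            pops_off = [
                (s, scenario.source_rate * share * frac * pmf)
                for s, share, frac, pmf in zip(
                    scenario.species, shares, slice_fracs, pmfs
                )
            ]
            pops_on = [
                (s, scenario.source_rate * share * frac * thin_tag_histogram(pmf, p))
                for s, share, frac, pmf, p in zip(
                    scenario.species, shares, slice_fracs, pmfs, p_detag
                )
            ]
            trace_pair = []
            for pops in (pops_off, pops_on):
                tr = synth_tof_trace(
                    pops,
                    cal,
                    peak_width=scenario.peak_width,
                    baseline=scenario.baseline,
                    t_start=t_start,
                    dt=scenario.dt,
                    n_samples=n_samples,
                    gain=scenario.gain,
                )
                trace_pair.append(tr.counts.astype(np.float32))
            for ci in range(cycles):
                for state, tr in enumerate(trace_pair):
                    intensities[row] = tr
                    wn_index[row] = wi
                    cycle_index[row] = ci
                    laser_on[row] = state
                    row += 1
            continue
        for ci in range(cycles):
            for state in (0, 1):
                pops = []
                for s, share, frac, km, p in zip(
                    scenario.species, shares, slice_fracs, kmaxes, p_detag
                ):
                    n = rng.poisson(scenario.source_rate * share)
                    if scenario.slice_window is not None and n > 0:
                        arrivals = rng.normal(
                            s.arrival_mean, s.arrival_fwhm / FWHM_TO_SIGMA, n
                        )
                        n = int(scenario.slice_window.contains(arrivals).sum())
                    if n == 0:
                        pops.append((s, np.zeros(km + 1)))
                        continue
                    if s.tag_distribution == "fixed":
                        tags = np.full(n, int(round(s.mean_tags)))
                    else:
                        tags = np.minimum(rng.poisson(s.mean_tags, n), km)
                    if state == 1 and p > 0:
                        tags = rng.binomial(tags, 1.0 - p)
                    pops.append((s, np.bincount(tags, minlength=km + 1).astype(float)))
                tr = synth_tof_trace(
                    pops,
                    cal,
                    peak_width=scenario.peak_width,
                    baseline=scenario.baseline,
                    noise_seed=rng if scenario.counting_noise else None,
                    t_start=t_start,
                    dt=scenario.dt,
                    n_samples=n_samples,
                    gain=scenario.gain,
                )
                intensities[row] = tr.counts.astype(np.float32)
                wn_index[row] = wi
                cycle_index[row] = ci
                laser_on[row] = state
                row += 1

    return RawDataset(
        t_start=t_start,
        dt=scenario.dt,
        n_samples=n_samples,
        wn_start=float(grid[0]),
        wn_step=scenario.scan.wn_step,
        n_wn=grid.size,
        cycles_per_wn=cycles,
        wn_index=wn_index,
        cycle_index=cycle_index,
        laser_on=laser_on,
        intensities=intensities,
    )


def simulate_tagging_spectrum(scenario: Scenario, n_ions: int, seed):
    """Simulate one laser-off tagging mass spectrum with ``n_ions`` total ions.

    Convenience wrapper around the per-cycle machinery for inspecting the
    tag ladder at high ion count: samples species (by relative abundance)
    and tag counts, synthesizes the transient with counting noise and the
    scenario baseline, subtracts a rolling-median baseline and returns the
    calibrated :class:`~ciris.tof.MassSpectrum`.
    """
    from .tof import baseline_correct, trace_to_spectrum

    if n_ions < 0:
        raise ValueError("n_ions must be >= 0")
    rng = np.random.default_rng(seed)
    numbers = rng.multinomial(int(n_ions), scenario.shares())
    pops = []
    for s, n, frac in zip(
        scenario.species,
        numbers,
        (
            [_slice_fraction(s, scenario.slice_window) for s in scenario.species]
            if scenario.slice_window is not None
            else [1.0] * len(scenario.species)
        ),
    ):
        km = _kmax(s)
        if scenario.slice_window is not None and n > 0:
            arrivals = rng.normal(s.arrival_mean, s.arrival_fwhm / FWHM_TO_SIGMA, n)
            n = int(scenario.slice_window.contains(arrivals).sum())
        if s.tag_distribution == "fixed":
            tags = np.full(n, int(round(s.mean_tags)))
        else:
            tags = np.minimum(rng.poisson(s.mean_tags, n), km)
        pops.append((s, np.bincount(tags, minlength=km + 1).astype(float)))
    t_start, n_samples = _scan_axis(scenario)
    trace = synth_tof_trace(
        pops,
        scenario.calibration,
        peak_width=scenario.peak_width,
        baseline=scenario.baseline,
        noise_seed=rng if scenario.counting_noise else None,
        t_start=t_start,
        dt=scenario.dt,
        n_samples=n_samples,
        gain=scenario.gain,
        meta={"laser_state": "off", "n_ions": int(n_ions)},
    )
    if scenario.baseline > 0:
        trace = baseline_correct(trace, window=501, quantile=0.5)
    return trace_to_spectrum(trace, scenario.calibration)


# ---------------------------------------------------------------------------
# fluence calibration

def peak_depletion(
    scenario: Scenario, fluence_scale: float | None = None, mode: str = "tagged"
) -> float:
    """Expected peak depleted fraction over the scan grid.

    ``mode="tagged"`` reports the maximum fractional loss of the summed
    tagged population (the quantity the instrument's 90-95% operating
    setting refers to); ``mode="untagged"`` reports the maximum fractional
    gain of the untagged population.
    """
    if mode not in ("tagged", "untagged"):
        raise ValueError("mode must be 'tagged' or 'untagged'")
    f = scenario.scan.fluence_scale if fluence_scale is None else fluence_scale
    grid = scenario.scan.grid()
    energies = scenario.scan.energy_profile(grid)
    shares = scenario.shares()
    off_t = off_u = 0.0
    on_t = np.zeros(grid.size)
    on_u = np.zeros(grid.size)
    for s, share in zip(scenario.species, shares):
        pmf = expected_tag_histogram(s)
        p = np.asarray(detag_probability(s.true_sigma(grid), grid, energies, f))
        k = np.arange(pmf.size)
        all_lost = p[:, None] ** k  # probability an ion with k tags loses every tag
        off_u += share * pmf[0]
        off_t += share * (1.0 - pmf[0])
        on_u += share * (all_lost @ pmf)
        on_t += share * ((1.0 - all_lost) @ pmf)
    if mode == "tagged":
        if off_t <= 0:
            return 0.0
        return float(np.max((off_t - on_t) / off_t))
    if off_u <= 0:
        return math.inf
    return float(np.max((on_u - off_u) / off_u))


def set_peak_depletion(
    scenario: Scenario, target: float, mode: str = "tagged"
) -> Scenario:
    """Set the scenario's fluence calibration so the strongest band reaches
    the target expected depletion (e.g. 0.90-0.95, the instrument's stated
    operating maximum).  Mutates and returns the scenario."""
    if not 0 < target < 1:
        raise ValueError("target depletion must lie in (0, 1)")

    def gap(log10_f: float) -> float:
        return peak_depletion(scenario, 10.0**log10_f, mode) - target

    log_f = optimize.brentq(gap, -12.0, 2.0, xtol=1e-10)
    scenario.scan = replace(scenario.scan, fluence_scale=10.0**log_f)
    return scenario
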