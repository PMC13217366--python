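"""Time-of-flight trace processing.

In a TOF analyzer operated at a fixed voltage gradient the flight time of an
ion scales with the square root of its mass-to-charge ratio,

    t(m/z) = t0 + k * sqrt(m/z),

so a two-parameter calibration maps between the time domain (digitized
transients) and the m/z domain (mass spectra).  This module provides that
calibration, baseline handling for raw transients, window integration of
calibrated spectra, and extraction of the N2 tag series -- the ladder of
peaks at base m/z + n * 28.006/|z| produced by ions carrying n weakly bound
nitrogen molecules.

Intensities are carried unchanged from the time to the m/z domain (no
Jacobian rescaling): the forward model calibrates its per-ion response so
that equal ion numbers produce equal m/z-domain peak areas, which keeps
window integrals comparable across the tag ladder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import CirisError

__all__ = [
    "N2_MASS",
    "FWHM_TO_SIGMA",
    "TofCalibration",
    "TofTrace",
    "MassSpectrum",
    "TagSeries",
    "fit_calibration",
    "baseline_correct",
    "trace_to_spectrum",
    "integrate_window",
    "extract_tag_series",
    "mean_tag_count",
]

logger = logging.getLogger(__name__)

#: Monoisotopic mass of molecular nitrogen (14N2), in Da.
N2_MASS = 28.006

#: Ratio between the FWHM and the standard deviation of a Gaussian.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class TofCalibration:
    """Square-root flight-time calibration ``t = t0 + k*sqrt(m/z)``.

    Parameters
    ----------
    t0 : float
        Time offset in microseconds.
    k : float
        Proportionality constant in us * (Da/charge)**-0.5; must be > 0 so
        that flight time is strictly increasing in m/z.
    residuals, param_stderr, rmse :
        Optional least-squares diagnostics attached by :func:`fit_calibration`.
    """

    t0: float
    k: float
    residuals: np.ndarray | None = field(default=None, repr=False, compare=False)
    param_stderr: tuple[float, float] | None = field(default=None, compare=False)
    rmse: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if not np.isfinite(self.t0) or not np.isfinite(self.k):
            raise ValueError("calibration parameters must be finite")
        if self.k <= 0:
            raise ValueError(f"calibration slope k must be > 0, got {self.k}")

    def mz_to_tof(self, mz):
        """Flight time (us) for one or more m/z values (Th)."""
        mz = np.asarray(mz, dtype=float)
        if np.any(mz < 0):
            raise ValueError("m/z must be nonnegative")
        return self.t0 + self.k * np.sqrt(mz)

    def tof_to_mz(self, t):
        """m/z (Th) for one or more flight times (us); inverse of mz_to_tof."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t0):
            raise ValueError("flight time precedes calibration offset t0")
        return ((t - self.t0) / self.k) ** 2


@dataclass
class TofTrace:
    """One digitized transient on a uniform time axis.

    ``meta`` carries acquisition-cycle context: ``laser_state`` ("on"/"off"),
    ``wavenumber`` (cm^-1) and ``cycle_index``.
    """

    t_start: float
    dt: float
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("sampling interval dt must be > 0")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a nonempty 1-D array")

    @property
    def n_samples(self) -> int:
        return self.counts.size

    def time(self) -> np.ndarray:
        """The uniform time axis, in microseconds."""
        return self.t_start + self.dt * np.arange(self.counts.size)


@dataclass
class MassSpectrum:
    """A calibrated mass spectrum on a strictly increasing m/z grid.

    Intensities may be negative after baseline subtraction; estimators that
    require nonnegativity (e.g. :func:`mean_tag_count`) clip internally.
    """

    mz: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size >= 2 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz grid must be strictly increasing")


@dataclass
class TagSeries:
    """Window-integrated intensities of the 0..N nitrogen-tag peaks.

    ``intensities[n]`` is the integral around ``base_mz + n*28.006/|charge|``;
    ``centroids[n]`` is the intensity-weighted m/z centroid inside that window
    (NaN where the window holds no positive signal).
    """

    base_mz: float
    charge: int
    intensities: np.ndarray
    window_halfwidth: float
    centroids: np.ndarray

    def expected_positions(self) -> np.ndarray:
        n = np.arange(self.intensities.size)
        return self.base_mz + n * N2_MASS / abs(self.charge)

    def detected(self, min_fraction: float = 0.05) -> np.ndarray:
        """Indices of tag peaks whose intensity exceeds ``min_fraction`` of the
        strongest peak and whose centroid is defined."""
        top = float(np.max(self.intensities)) if self.intensities.size else 0.0
        if top <= 0:
            return np.array([], dtype=int)
        ok = (self.intensities >= min_fraction * top) & np.isfinite(self.centroids)
        return np.flatnonzero(ok)

    def peak_spacings(self, min_fraction: float = 0.05) -> np.ndarray:
        """m/z differences between successive detected tag peaks."""
        idx = self.detected(min_fraction)
        return np.diff(self.centroids[idx])


def fit_calibration(pairs: Iterable[tuple[float, float]]) -> TofCalibration:
    """Least-squares fit of ``t = t0 + k*sqrt(m/z)`` to (m/z, flight time) pairs.

    Requires at least two pairs with distinct m/z.  The returned calibration
    carries residuals, the parameter standard errors (from the estimated
    residual variance, NaN for an exact two-point fit) and the fit RMSE.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (m/z, time) pairs")
    mz, t = arr[:, 0], arr[:, 1]
    if np.any(mz < 0):
        raise ValueError("m/z must be nonnegative")
    x = np.sqrt(mz)
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration input: all m/z identical")
    X = np.column_stack([np.ones_like(x), x])
    beta, _, _, _ = np.linalg.lstsq(X, t, rcond=None)
    t0, k = float(beta[0]), float(beta[1])
    resid = t - X @ beta
    n, p = len(t), 2
    if n > p:
        s2 = float(resid @ resid) / (n - p)
        cov = s2 * np.linalg.inv(X.T @ X)
        stderr = (float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])))
    else:
        stderr = (float("nan"), float("nan"))
    return TofCalibration(
        t0=t0,
        k=k,
        residuals=resid,
        param_stderr=stderr,
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


def baseline_correct(
    trace: TofTrace, window: int = 501, quantile: float = 0.1
) -> TofTrace:
    """Subtract a rolling-quantile baseline estimate from a transient.

    The quantile is evaluated on windows anchored every ``window // 8``
    samples and linearly interpolated in between, which gives the same
    slowly varying baseline as a dense rolling quantile at a fraction of
    the cost.  ``window`` must be odd, at least 3 and no longer than the
    trace; ``quantile`` must lie in (0, 0.5].
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd number of samples >= 3")
    n = trace.counts.size
    if window > n:
        raise ValueError(f"window ({window}) longer than trace ({n} samples)")
    if not 0 < quantile <= 0.5:
        raise ValueError("quantile must lie in (0, 0.5]")
    half = window // 2
    hop = max(1, window // 8)
    anchors = np.arange(half, n - half, hop)
    if anchors.size == 0 or anchors[-1] != n - 1 - half:
        anchors = np.append(anchors, n - 1 - half)
    levels = np.array(
        [np.quantile(trace.counts[a - half : a + half + 1], quantile) for a in anchors]
    )
    baseline = np.interp(np.arange(n), anchors, levels)
    return replace(trace, counts=trace.counts - baseline, meta=dict(trace.meta))


def trace_to_spectrum(trace: TofTrace, cal: TofCalibration) -> MassSpectrum:
    """Map a transient onto the m/z axis using a flight-time calibration.

    Samples at ``t <= t0`` have no m/z image and are dropped; intensities are
    carried over unchanged (see the module docstring on Jacobian handling).
    """
    t = trace.time()
    keep = t > cal.t0
    if not np.any(keep):
        raise CirisError("entire trace lies at or before the calibration offset t0")
    mz = ((t[keep] - cal.t0) / cal.k) ** 2
    return MassSpectrum(mz=mz, intensity=trace.counts[keep], meta=dict(trace.meta))


def integrate_window(spec: MassSpectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of intensity over the m/z window [lo, hi).

    Endpoints inside the grid are interpolated, so integrals are exactly
    additive over adjacent windows.  A window entirely outside the recorded
    range integrates to zero (logged as a warning rather than an error).
    """
    if not lo < hi:
        raise ValueError(f"require lo < hi, got [{lo}, {hi})")
    mz, inten = spec.mz, spec.intensity
    a, b = max(lo, float(mz[0])), min(hi, float(mz[-1]))
    if b <= a:
        logger.warning(
            "integration window [%g, %g) outside spectrum range [%g, %g]; returning 0",
            lo, hi, mz[0], mz[-1],
        )
        return 0.0
    inner = (mz > a) & (mz < b)
    xs = np.concatenate(([a], mz[inner], [b]))
    ys = np.concatenate(
        ([np.interp(a, mz, inten)], inten[inner], [np.interp(b, mz, inten)])
    )
    return float(np.trapezoid(ys, xs))


def extract_tag_series(
    spec: MassSpectrum,
    base_mz: float,
    charge: int,
    max_tags: int = 5,
    window_halfwidth: float = 0.35,
) -> TagSeries:
    """Integrate the N2 tag ladder of one base ion.

    Peak ``n`` is searched at ``base_mz + n*28.006/|charge|`` inside a window
    of the given half-width (Th).  The half-width must stay below half the
    tag spacing so adjacent windows cannot overlap.
    """
    if charge == 0:
        raise ValueError("charge must be nonzero")
    if max_tags < 0:
        raise ValueError("max_tags must be >= 0")
    spacing = N2_MASS / abs(charge)
    if not 0 < window_halfwidth < spacing / 2:
        raise ValueError(
            f"window_halfwidth must lie in (0, {spacing / 2:g}) Th so tag windows do not overlap"
        )
    intensities = np.empty(max_tags + 1)
    centroids = np.full(max_tags + 1, np.nan)
    for n in range(max_tags + 1):
        center = base_mz + n * spacing
        lo, hi = center - window_halfwidth, center + window_halfwidth
        intensities[n] = integrate_window(spec, lo, hi)
        sel = (spec.mz >= lo) & (spec.mz < hi)
        w = np.clip(spec.intensity[sel], 0.0, None)
        tot = w.sum()
        if tot > 0:
            centroids[n] = float(np.sum(spec.mz[sel] * w) / tot)
    return TagSeries(
        base_mz=base_mz,
        charge=charge,
        intensities=intensities,
        window_halfwidth=window_halfwidth,
        centroids=centroids,
    )


def mean_tag_count(series: TagSeries) -> float:
    """Intensity-weighted mean number of tags, ``sum(n*I_n) / sum(I_n)``.

    Negative intensities (possible after baseline subtraction) are clipped to
    zero so the estimate stays in range; an all-zero series is an error.
    """
    inten = np.clip(np.asarray(series.intensities, dtype=float), 0.0, None)
    total = inten.sum()
    if total <= 0:
        raise CirisError("tag series has no positive intensity")
    n = np.arange(inten.size)
    return float(np.sum(n * inten) / total)
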