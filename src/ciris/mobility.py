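"""Arrival-time (ion mobility) processing: mobilograms, peaks and slicing.

After traveling-wave mobility separation each ion reaches the end of the
mobility cell at an arrival time that reflects its collision cross-section.
Binning arrival events over one mobility cycle gives a mobilogram; isomers
with similar mobility appear as partially resolved peaks.  A slice window
emulates the exit-lens gate of the instrument, which blocks transmission
outside a user-chosen arrival-time interval so a single isomer can be
passed on to tagging and IR interrogation.

Conventions: arrival times are in milliseconds from trap release; all
intervals (bins and slice windows) are half-open, ``[lo, hi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import CirisError

__all__ = [
    "Mobilogram",
    "SliceWindow",
    "MobilityPeak",
    "SliceReport",
    "bin_events",
    "detect_peaks",
    "apply_slice",
    "gate_mobilogram",
    "slice_purity",
]


@dataclass
class Mobilogram:
    """Binned arrival-time distribution over one mobility cycle."""

    cycle_time: float
    bin_width: float
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.cycle_time <= 0:
            raise ValueError("cycle_time must be > 0")
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("mobilogram counts must be nonnegative")
        if self.counts.size * self.bin_width < self.cycle_time - 1e-9:
            raise ValueError("bins do not span the mobility cycle")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    def bin_starts(self) -> np.ndarray:
        return self.bin_width * np.arange(self.n_bins)

    def bin_centers(self) -> np.ndarray:
        return self.bin_starts() + 0.5 * self.bin_width


@dataclass(frozen=True)
class SliceWindow:
    """Half-open gating interval ``[center - width/2, center + width/2)``."""

    center: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("slice window width must be > 0")

    @property
    def lo(self) -> float:
        return self.center - self.width / 2

    @property
    def hi(self) -> float:
        return self.center + self.width / 2

    def contains(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.lo) & (t < self.hi)


@dataclass
class MobilityPeak:
    """One detected mobilogram peak.

    ``shoulder_limited`` marks a FWHM whose half-height crossing was not
    reached on at least one flank before the enclosing valley (typical for
    partially resolved peaks); the valley position is used instead.
    """

    apex: float
    fwhm: float
    height: float
    area: float
    shoulder_limited: bool = False


@dataclass
class SliceReport:
    """Per-species composition of the events transmitted by a slice window."""

    purity: dict
    transmission: dict
    n_transmitted: int


def bin_events(events, cycle_time: float, bin_width: float) -> Mobilogram:
    """Histogram arrival-time events into half-open bins ``[i*w, (i+1)*w)``.

    The number of bins is ``ceil(cycle_time / bin_width)`` and total counts
    are conserved.  Events outside ``[0, cycle_time)`` are an error (the
    message lists the offenders).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    t = np.asarray(events, dtype=float)
    bad = t[(t < 0) | (t >= cycle_time)]
    if bad.size:
        shown = ", ".join(f"{v:g}" for v in bad[:10])
        more = "" if bad.size <= 10 else f" (+{bad.size - 10} more)"
        raise CirisError(
            f"{bad.size} events outside the mobility cycle [0, {cycle_time:g}) ms: {shown}{more}"
        )
    n_bins = math.ceil(cycle_time / bin_width - 1e-12)
    idx = np.floor(t / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return Mobilogram(cycle_time=cycle_time, bin_width=bin_width, counts=counts)


def _half_crossing(counts, apex_idx, half, direction, stop):
    """Walk from the apex bin toward ``stop`` until counts fall below
    ``half``; return (offset_in_bins_from_apex, limited)."""
    i = apex_idx
    step = 1 if direction > 0 else -1
    while i != stop and counts[i + step] > half:
        i += step
    if i == stop and counts[i] > half:
        return abs(i - apex_idx), True
    # linear interpolation of the crossing between bins i and i+step
    y0, y1 = counts[i], counts[i + step]
    frac = (y0 - half) / (y0 - y1) if y0 != y1 else 0.5
    return abs(i - apex_idx) + frac, False


def detect_peaks(mob: Mobilogram, min_prominence: float = 0.05) -> list[MobilityPeak]:
    """Find local maxima with a prominence above ``min_prominence * max``.

    The apex is refined by a three-point parabolic fit; the FWHM is measured
    by linear interpolation at half the refined height on each flank,
    descending at most to the enclosing valleys (see
    :class:`MobilityPeak.shoulder_limited`).  Peaks are returned ordered by
    apex time; a mobilogram with no qualifying maximum yields an empty list.
    """
    if mob.n_bins < 3:
        raise ValueError("need at least 3 bins to detect peaks")
    y = mob.counts
    top = float(y.max())
    if top <= 0:
        return []
    idx, props = signal.find_peaks(y, prominence=min_prominence * top)
    if idx.size == 0:
        return []
    w = mob.bin_width
    peaks = []
    for j, p in enumerate(idx):
        # parabolic apex refinement on (p-1, p, p+1)
        if 0 < p < y.size - 1:
            denom = y[p - 1] - 2 * y[p] + y[p + 1]
            delta = 0.5 * (y[p - 1] - y[p + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            height = float(y[p] - 0.25 * (y[p - 1] - y[p + 1]) * delta)
        else:
            delta, height = 0.0, float(y[p])
        apex = (p + delta + 0.5) * w
        left_base = int(props["left_bases"][j])
        right_base = int(props["right_bases"][j])
        lw, llim = _half_crossing(y, p, height / 2, -1, left_base)
        rw, rlim = _half_crossing(y, p, height / 2, +1, right_base)
        area = float(y[left_base : right_base + 1].sum()) * w
        peaks.append(
            MobilityPeak(
                apex=float(apex),
                fwhm=float((lw + rw) * w),
                height=height,
                area=area,
                shoulder_limited=bool(llim or rlim),
            )
        )
    peaks.sort(key=lambda pk: pk.apex)
    return peaks


def apply_slice(events, window: SliceWindow) -> np.ndarray:
    """Return exactly the events inside the half-open window, order preserved."""
    t = np.asarray(events, dtype=float)
    return t[window.contains(t)]


def gate_mobilogram(mob: Mobilogram, window: SliceWindow) -> Mobilogram:
    """Multiply the bins of a measured mobilogram by a 0/1 gate.

    A bin passes when its center lies inside the window; this is the
    binned counterpart of :func:`apply_slice` for data where individual
    events are no longer available.
    """
    gate = window.contains(mob.bin_centers()).astype(float)
    out = replace(mob, counts=mob.counts * gate, meta=dict(mob.meta))
    out.meta["slice_window"] = (window.center, window.width)
    return out


def slice_purity(times, labels, window: SliceWindow) -> SliceReport:
    """Per-species composition of the transmitted events.

    ``purity`` maps each species label to its fraction among transmitted
    events (fractions sum to 1); ``transmission`` maps each label to the
    fraction of that species' events that survived the gate.  Zero
    transmitted events is an error.
    """
    t = np.asarray(times, dtype=float)
    lab = np.asarray(labels)
    if t.size == 0 or t.shape != lab.shape:
        raise ValueError("times and labels must be equal-length nonempty sequences")
    keep = window.contains(t)
    n_trans = int(keep.sum())
    if n_trans == 0:
        raise CirisError("slice window transmitted zero events")
    purity, transmission = {}, {}
    for species in np.unique(lab):
        mine = lab == species
        purity[species] = float((keep & mine).sum() / n_trans)
        transmission[species] = float((keep & mine).sum() / mine.sum())
    return SliceReport(purity=purity, transmission=transmission, n_transmitted=n_trans)
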