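"""Raw-data container and text import/export.

The raw container is a little-endian binary format ("CTIR", versioned)
purpose-built for paired laser-on/off transients: a fixed-size header with
the shared time axis and scan grid, followed by one fixed-size record per
transient.  Records can be streamed one at a time, so files larger than
memory remain readable.  Axes are stored as float64, intensities as
float32 (digitizer-class precision), which makes write-then-read
bit-exact for datasets produced by this package.

Text formats use ``.`` decimals, no thousands separators, and ``#``-prefixed
metadata header lines.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Iterator

import numpy as np

from .dataset import RawDataset
from .errors import (
    BadMagicError,
    CirisError,
    TruncatedFileError,
    UnsupportedVersionError,
)
from .irspec import IRSpectrum
from .mobility import Mobilogram
from .simulate import LaserEnergyProfile
from .tof import MassSpectrum, TofCalibration

__all__ = [
    "CONTAINER_MAGIC",
    "CONTAINER_VERSION",
    "write_container",
    "read_container",
    "iter_records",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_mass_spectrum_csv",
    "read_mass_spectrum_csv",
    "write_mobilogram_csv",
    "read_mobilogram_csv",
    "read_energy_profile_csv",
    "write_energy_profile_csv",
    "write_calibration_json",
    "read_calibration_json",
]

CONTAINER_MAGIC = b"CTIR"
CONTAINER_VERSION = 1

# magic 4s | version u16 | reserved u16 | t_start f64 | dt f64 | n_samples u32
# | wn_start f64 | wn_step f64 | n_wn u32 | cycles_per_wn u32
_HEADER = struct.Struct("<4sHHddIddII")
# cycle_index u32 | wn_index u32 | laser_state u8
_RECORD_HEAD = struct.Struct("<IIB")


def write_container(dataset: RawDataset, path) -> None:
    """Write a dataset to the binary container (lossless round trip)."""
    if dataset.n_records != dataset.n_wn * dataset.cycles_per_wn * 2:
        raise CirisError(
            "refusing to write an incomplete scan: record count "
            f"{dataset.n_records} != n_wn*cycles_per_wn*2"
        )
    with open(path, "wb") as fh:
        fh.write(
            _HEADER.pack(
                CONTAINER_MAGIC,
                CONTAINER_VERSION,
                0,
                dataset.t_start,
                dataset.dt,
                dataset.n_samples,
                dataset.wn_start,
                dataset.wn_step,
                dataset.n_wn,
                dataset.cycles_per_wn,
            )
        )
        for i in range(dataset.n_records):
            fh.write(
                _RECORD_HEAD.pack(
                    int(dataset.cycle_index[i]),
                    int(dataset.wn_index[i]),
                    int(dataset.laser_on[i]),
                )
            )
            fh.write(
                np.ascontiguousarray(dataset.intensities[i], dtype="<f4").tobytes()
            )


def _read_header(fh) -> tuple:
    raw = fh.read(_HEADER.size)
    if len(raw) < _HEADER.size:
        raise TruncatedFileError("incomplete container header", len(raw))
    magic, version, _, t_start, dt, n_samples, wn_start, wn_step, n_wn, cycles = (
        _HEADER.unpack(raw)
    )
    if magic != CONTAINER_MAGIC:
        raise BadMagicError(
            f"not a CTIR container (magic bytes {magic!r} != {CONTAINER_MAGIC!r})"
        )
    if version != CONTAINER_VERSION:
        raise UnsupportedVersionError(
            f"container version {version} not supported (reader supports {CONTAINER_VERSION})"
        )
    return t_start, dt, n_samples, wn_start, wn_step, n_wn, cycles


def iter_records(path) -> Iterator[tuple[int, int, int, np.ndarray]]:
    """Stream ``(cycle_index, wn_index, laser_state, intensities)`` records
    one at a time without loading the whole file."""
    with open(path, "rb") as fh:
        _, _, n_samples, *_ = _read_header(fh)
        rec_bytes = _RECORD_HEAD.size + 4 * n_samples
        offset = _HEADER.size
        while True:
            raw = fh.read(rec_bytes)
            if not raw:
                return
            if len(raw) < rec_bytes:
                raise TruncatedFileError("incomplete record", offset + len(raw))
            cycle, wn_i, state = _RECORD_HEAD.unpack_from(raw)
            data = np.frombuffer(raw, dtype="<f4", count=n_samples, offset=_RECORD_HEAD.size)
            yield cycle, wn_i, state, data.copy()
            offset += rec_bytes


def read_container(path) -> RawDataset:
    """Load a complete container into memory."""
    with open(path, "rb") as fh:
        t_start, dt, n_samples, wn_start, wn_step, n_wn, cycles = _read_header(fh)
    cycle_idx, wn_idx, states, blocks = [], [], [], []
    for cycle, wn_i, state, data in iter_records(path):
        cycle_idx.append(cycle)
        wn_idx.append(wn_i)
        states.append(state)
        blocks.append(data)
    return RawDataset(
        t_start=t_start,
        dt=dt,
        n_samples=n_samples,
        wn_start=wn_start,
        wn_step=wn_step,
        n_wn=n_wn,
        cycles_per_wn=cycles,
        wn_index=np.array(wn_idx, dtype=np.uint32),
        cycle_index=np.array(cycle_idx, dtype=np.uint32),
        laser_on=np.array(states, dtype=np.uint8),
        intensities=np.vstack(blocks) if blocks else np.empty((0, n_samples), "<f4"),
    )


# ---------------------------------------------------------------------------
# CSV / JSON text formats

def _write_csv(path, meta: dict, header: str, columns, fmt: str) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(header + "\n")
        for row in zip(*columns):
            fh.write(fmt % tuple(row) + "\n")


def _read_csv(path) -> tuple[dict, np.ndarray]:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            continue
        body.append(line)
    if body and not body[0][0].isdigit() and not body[0][0] in "+-.":
        body = body[1:]  # column-name header
    data = np.array(
        [[float(v) for v in line.split(",")] for line in body], dtype=float
    )
    return meta, data


def write_spectrum_csv(spectrum: IRSpectrum, path, extra_meta: dict | None = None):
    """Write a retrieved IR spectrum as CSV
    (wn_cm-1, sigma_rel, stderr, n_pairs, saturated_flag)."""
    meta = {
        "format": "ciris-irspectrum",
        "reference_mode": spectrum.reference_mode,
        "normalization": spectrum.normalization,
    }
    meta.update(extra_meta or {})
    _write_csv(
        path,
        meta,
        "wn_cm-1,sigma_rel,stderr,n_pairs,saturated_flag",
        (
            spectrum.wn,
            spectrum.sigma_rel,
            spectrum.stderr,
            spectrum.n_pairs,
            spectrum.saturated.astype(int),
        ),
        "%.6g,%.10g,%.10g,%d,%d",
    )


def read_spectrum_csv(path) -> IRSpectrum:
    meta, data = _read_csv(path)
    return IRSpectrum(
        wn=data[:, 0],
        sigma_rel=data[:, 1],
        stderr=data[:, 2],
        n_pairs=data[:, 3].astype(int),
        saturated=data[:, 4].astype(bool),
        normalization=meta.get("normalization", "none"),
        reference_mode=meta.get("reference_mode", "untagged_off"),
    )


def write_mass_spectrum_csv(spec: MassSpectrum, path):
    """Two-column (mz, intensity) CSV with # metadata header lines."""
    meta = {"format": "ciris-massspectrum"}
    meta.update({k: v for k, v in spec.meta.items()})
    _write_csv(path, meta, "mz,intensity", (spec.mz, spec.intensity), "%.8g,%.10g")


def read_mass_spectrum_csv(path) -> MassSpectrum:
    meta, data = _read_csv(path)
    meta.pop("format", None)
    return MassSpectrum(mz=data[:, 0], intensity=data[:, 1], meta=meta)


def write_mobilogram_csv(mob: Mobilogram, path):
    """Mobilogram CSV (bin_start_ms, counts)."""
    meta = {
        "format": "ciris-mobilogram",
        "cycle_time_ms": mob.cycle_time,
        "bin_width_ms": mob.bin_width,
    }
    meta.update({k: v for k, v in mob.meta.items()})
    _write_csv(path, meta, "bin_start_ms,counts", (mob.bin_starts(), mob.counts), "%.6g,%.10g")


def read_mobilogram_csv(path) -> Mobilogram:
    meta, data = _read_csv(path)
    return Mobilogram(
        cycle_time=float(meta["cycle_time_ms"]),
        bin_width=float(meta["bin_width_ms"]),
        counts=data[:, 1],
    )


def read_energy_profile_csv(path) -> LaserEnergyProfile:
    """Read a two-column (wavenumber cm^-1, energy mJ) pulse-energy table."""
    _, data = _read_csv(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise CirisError(f"energy profile {path} must have two columns (wn, energy)")
    return LaserEnergyProfile(wn=data[:, 0], energy=data[:, 1])


def write_energy_profile_csv(profile: LaserEnergyProfile, path):
    _write_csv(
        path,
        {"format": "ciris-energyprofile"},
        "wn_cm-1,energy_mJ",
        (profile.wn, profile.energy),
        "%.6g,%.8g",
    )


def write_calibration_json(cal: TofCalibration, path):
    payload = {"model": "t = t0 + k*sqrt(m/z)", "t0_us": cal.t0, "k_us_per_sqrt_Th": cal.k}
    if cal.param_stderr is not None:
        payload["stderr"] = {"t0": cal.param_stderr[0], "k": cal.param_stderr[1]}
    if cal.rmse is not None:
        payload["rmse_us"] = cal.rmse
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_calibration_json(path) -> TofCalibration:
    payload = json.loads(Path(path).read_text())
    return TofCalibration(t0=float(payload["t0_us"]), k=float(payload["k_us_per_sqrt_Th"]))
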