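"""Config-driven end-to-end runs: simulate (or load) -> slice -> retrieve.

A run is described by one YAML/JSON mapping (see :data:`CONFIG_SCHEMA` in
the docstrings below) and produces a spectrum CSV, an optional mobilogram
CSV, a log file and a machine-readable manifest recording the config hash,
seed and package versions -- enough to reproduce every artifact
bit-identically.  All randomness flows from the single top-level seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import scipy
import yaml

from . import __version__
from . import io as cio
from .errors import ConfigError
from .irspec import retrieve_spectrum
from .mobility import SliceWindow, bin_events, detect_peaks
from .simulate import (
    LaserEnergyProfile,
    PRESETS,
    make_preset,
    sample_mixture_events,
    simulate_scan,
)

__all__ = ["load_config", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_RETRIEVAL_DEFAULTS = {
    "mz_window": "auto",
    "reference_mode": "untagged_off",
    "cap": 0.999,
    "max_tags": 5,
    "normalization": "none",
    "baseline_correct": False,
    "window_halfwidth": 0.35,
}


def load_config(path) -> dict:
    """Load and validate a pipeline configuration file (YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    cfg = yaml.safe_load(path.read_text())
    validate_config(cfg, base_dir=path.parent)
    return cfg


def _require(cfg: dict, key: str, types, path: str):
    if key not in cfg:
        raise ConfigError(f"{path}{key}: required field missing")
    if not isinstance(cfg[key], types):
        raise ConfigError(
            f"{path}{key}: expected {getattr(types, '__name__', types)}, "
            f"got {type(cfg[key]).__name__}"
        )
    return cfg[key]


def validate_config(cfg, base_dir: Path | None = None) -> None:
    """Schema-check a config mapping; all violations are reported with the
    dotted field path, before any computation starts."""
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    _require(cfg, "seed", int, "")
    has_input = "input" in cfg and cfg["input"] is not None
    has_scenario = "scenario" in cfg and cfg["scenario"] is not None
    if not has_input and not has_scenario:
        raise ConfigError("scenario: required when no 'input' container is given")
    if has_scenario:
        sc = cfg["scenario"]
        if not isinstance(sc, dict):
            raise ConfigError("scenario: must be a mapping")
        preset = _require(sc, "preset", str, "scenario.")
        if preset not in PRESETS:
            raise ConfigError(
                f"scenario.preset: unknown preset {preset!r}; valid: {', '.join(PRESETS)}"
            )
        for key in ("wn_start", "wn_stop", "wn_step", "source_rate", "fluence_scale", "baseline"):
            if key in sc and not isinstance(sc[key], (int, float)):
                raise ConfigError(f"scenario.{key}: expected a number")
        if "cycles_per_wavenumber" in sc and (
            not isinstance(sc["cycles_per_wavenumber"], int)
            or sc["cycles_per_wavenumber"] < 1
        ):
            raise ConfigError("scenario.cycles_per_wavenumber: expected a positive integer")
        if "stochastic" in sc and not isinstance(sc["stochastic"], bool):
            raise ConfigError("scenario.stochastic: expected a boolean")
        if "slice" in sc and sc["slice"] is not None:
            sl = sc["slice"]
            if not isinstance(sl, dict):
                raise ConfigError("scenario.slice: must be a mapping")
            _require(sl, "center", (int, float), "scenario.slice.")
            width = _require(sl, "width", (int, float), "scenario.slice.")
            if width <= 0:
                raise ConfigError("scenario.slice.width: must be > 0")
    if has_input:
        p = Path(cfg["input"])
        if base_dir is not None and not p.is_absolute():
            p = base_dir / p
        if not p.exists():
            raise ConfigError(f"input: container file not found: {cfg['input']}")
    profile = cfg.get("energy_profile", "synthetic")
    if profile != "synthetic":
        p = Path(profile)
        if base_dir is not None and not p.is_absolute():
            p = base_dir / p
        if not p.exists():
            raise ConfigError(f"energy_profile: file not found: {profile}")
    retr = cfg.get("retrieval", {})
    if not isinstance(retr, dict):
        raise ConfigError("retrieval: must be a mapping")
    for key in retr:
        if key not in _RETRIEVAL_DEFAULTS:
            raise ConfigError(f"retrieval.{key}: unknown field")
    mzw = retr.get("mz_window", "auto")
    if mzw != "auto" and (
        not isinstance(mzw, (list, tuple)) or len(mzw) != 2 or mzw[0] >= mzw[1]
    ):
        raise ConfigError("retrieval.mz_window: expected 'auto' or [lo, hi] with lo < hi")
    if retr.get("reference_mode", "untagged_off") not in ("untagged_off", "tagged_off"):
        raise ConfigError("retrieval.reference_mode: must be untagged_off or tagged_off")
    mob = cfg.get("mobilogram", None)
    if mob is not None:
        if not isinstance(mob, dict):
            raise ConfigError("mobilogram: must be a mapping")
        if not has_scenario:
            raise ConfigError("mobilogram: requires a scenario (simulated events)")


def _build_scenario(sc_cfg: dict):
    scenario = make_preset(sc_cfg["preset"])
    scan_kw = {
        k: sc_cfg[k] for k in ("wn_start", "wn_stop", "wn_step", "fluence_scale") if k in sc_cfg
    }
    if scan_kw:
        scenario.scan = dataclasses.replace(scenario.scan, **scan_kw)
    if "cycles_per_wavenumber" in sc_cfg:
        scenario.trap = dataclasses.replace(
            scenario.trap, cycles_per_wavenumber=sc_cfg["cycles_per_wavenumber"]
        )
    for key in ("source_rate", "baseline", "stochastic"):
        if key in sc_cfg:
            setattr(scenario, key, sc_cfg[key])
    if sc_cfg.get("slice"):
        scenario.slice_window = SliceWindow(
            center=float(sc_cfg["slice"]["center"]), width=float(sc_cfg["slice"]["width"])
        )
    return scenario


def run_pipeline(config, output_dir=None) -> dict:
    """Execute a configured run and write its artifacts.

    ``config`` is a path to a YAML/JSON file or an already-loaded mapping.
    Returns a dict with the artifact paths and the in-memory results
    (``spectrum``, ``dataset``, optionally ``mobilogram``).
    """
    if isinstance(config, (str, Path)):
        base_dir = Path(config).parent
        cfg = load_config(config)
    else:
        cfg = config
        base_dir = Path.cwd()
        validate_config(cfg, base_dir=base_dir)

    out_dir = Path(output_dir or cfg.get("output_dir", "ciris_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ciris")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        seed = int(cfg["seed"])
        rng = np.random.default_rng(seed)
        sim_seed = int(rng.integers(2**31))
        mob_seed = int(rng.integers(2**31))

        profile_cfg = cfg.get("energy_profile", "synthetic")
        if profile_cfg == "synthetic":
            profile = LaserEnergyProfile.synthetic()
        else:
            p = Path(profile_cfg)
            profile = cio.read_energy_profile_csv(p if p.is_absolute() else base_dir / p)

        artifacts: dict = {"output_dir": str(out_dir)}
        scenario = None
        if cfg.get("scenario"):
            scenario = _build_scenario(cfg["scenario"])
            scenario.scan = dataclasses.replace(scenario.scan, energy_profile=profile)
        if cfg.get("input"):
            p = Path(cfg["input"])
            dataset = cio.read_container(p if p.is_absolute() else base_dir / p)
            logger.info("loaded container %s (%d records)", cfg["input"], dataset.n_records)
            calibration = scenario.calibration if scenario else None
            if calibration is None:
                from .simulate import DEFAULT_CALIBRATION

                calibration = DEFAULT_CALIBRATION
        else:
            logger.info(
                "simulating preset %s: %d grid points x %d cycle pairs (seed %d)",
                cfg["scenario"]["preset"],
                scenario.scan.grid().size,
                scenario.trap.cycles_per_wavenumber,
                sim_seed,
            )
            dataset = simulate_scan(scenario, sim_seed)
            calibration = scenario.calibration

        if cfg.get("mobilogram") is not None and scenario is not None:
            mcfg = cfg["mobilogram"]
            n_events = int(mcfg.get("n_events", 100_000))
            cycle_time = float(mcfg.get("cycle_time", 10.0))
            bin_width = float(mcfg.get("bin_width", 0.11))
            times, _ = sample_mixture_events(scenario.species, n_events, mob_seed)
            mob = bin_events(times, cycle_time, bin_width)
            mob_path = out_dir / "mobilogram.csv"
            cio.write_mobilogram_csv(mob, mob_path)
            artifacts["mobilogram_csv"] = str(mob_path)
            artifacts["mobilogram"] = mob
            for pk in detect_peaks(mob):
                logger.info(
                    "mobilogram peak: apex %.3f ms, FWHM %.3f ms%s",
                    pk.apex,
                    pk.fwhm,
                    " (shoulder-limited)" if pk.shoulder_limited else "",
                )

        retr = dict(_RETRIEVAL_DEFAULTS)
        retr.update(cfg.get("retrieval", {}))
        if retr["mz_window"] == "auto":
            if scenario is None:
                raise ConfigError(
                    "retrieval.mz_window: 'auto' needs a scenario to locate the base peak"
                )
            base = max(scenario.species, key=lambda s: s.rel_abundance)
            hw = float(retr["window_halfwidth"])
            mz_window = (base.mz - hw, base.mz + hw)
        else:
            mz_window = (float(retr["mz_window"][0]), float(retr["mz_window"][1]))
        baseline = retr["baseline_correct"]
        if baseline is True:
            baseline = {}
        baseline_arg = (
            (int(baseline.get("window", 501)), float(baseline.get("quantile", 0.5)))
            if isinstance(baseline, dict)
            else None
        )
        spectrum = retrieve_spectrum(
            dataset,
            mz_window,
            profile,
            calibration=calibration,
            reference_mode=retr["reference_mode"],
            cap=float(retr["cap"]),
            max_tags=int(retr["max_tags"]),
            baseline=baseline_arg,
            normalization=retr["normalization"],
        )
        n_sat = int(spectrum.saturated.sum())
        logger.info(
            "retrieved %d-point spectrum (%s), %d saturated points",
            spectrum.wn.size,
            spectrum.reference_mode,
            n_sat,
        )
        for rec in spectrum.records:
            logger.debug(
                "wn %.1f: %d pairs, F=%.4f%s",
                rec.wn,
                rec.n_pairs,
                rec.F_dep,
                " SATURATED" if rec.saturated else "",
            )
        spec_path = out_dir / "spectrum.csv"
        cio.write_spectrum_csv(
            spectrum, spec_path, extra_meta={"seed": seed, "mz_window": list(mz_window)}
        )
        artifacts["spectrum_csv"] = str(spec_path)
        artifacts["spectrum"] = spectrum
        artifacts["dataset"] = dataset

        canonical = json.dumps(cfg, sort_keys=True, default=str).encode()
        manifest = {
            "config_sha256": hashlib.sha256(canonical).hexdigest(),
            "seed": seed,
            "versions": {
                "ciris": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
            },
            "artifacts": sorted(
                k for k in artifacts if isinstance(artifacts[k], str) and k != "output_dir"
            ),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        artifacts["manifest_json"] = str(manifest_path)
        artifacts["log"] = str(log_path)
        return artifacts
    finally:
        root.removeHandler(handler)
        handler.close()
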