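"""End-to-end pipeline: synthesize/track -> fit -> calibrate -> classify.

A :class:`RunConfig` (YAML/JSON-friendly dict) drives a deterministic run
whose outputs — profiles CSV, L-W fits JSON, calibration JSON, tier-call
CSV and a log — all carry the hash of the configuration that produced
them.  Stages never mutate their inputs; a failure in a later stage
leaves earlier outputs on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import calibration as cal
from . import lw_model, synth
from .agglutination import KineticParams
from .flow_tracking import write_profiles_csv

logger = logging.getLogger("capflow")

SCHEMA_VERSION = "capflow-run-1"

REQUIRED_KEYS = ("frame_rate", "seed", "detection_frame", "alpha")


class ConfigError(ValueError):
    """The run configuration is missing keys or fails validation."""


def validate_config(config: Mapping[str, Any]) -> dict:
    missing = [k for k in REQUIRED_KEYS if k not in config]
    if missing:
        raise ConfigError(f"run config missing required keys: {missing}")
    if config.get("schema", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema {config.get('schema')!r}")
    for path_key in ("signals_csv",):
        if path_key in config and not Path(config[path_key]).exists():
            raise ConfigError(f"{path_key} does not exist: {config[path_key]}")
    return dict(config)


def config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _synth_config(config: Mapping[str, Any]) -> synth.SynthConfig:
    block = dict(config.get("synth", {}))
    kinetic = KineticParams(**block.pop("kinetic", {}))
    block.setdefault("seed", config["seed"])
    block.setdefault("fps", config["frame_rate"])
    return synth.SynthConfig(kinetic=kinetic, **block)


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Path]:
    """Run synth/load -> calibrate -> classify; return the output file map."""
    config = validate_config(config)
    chash = config_hash(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    t0 = time.time()
    frame = int(config["detection_frame"])

    # --- stage 1: data (synthetic assay, or user-supplied signal table)
    if "signals_csv" in config:
        df = pd.read_csv(config["signals_csv"], comment="#")
        dr = cal.DoseResponse.from_dataframe(df)
        truth = None
        logger.info("loaded %d signal rows from %s", len(df), config["signals_csv"])
    else:
        scfg = _synth_config(config)
        concs = config.get("concentrations", [0, 1, 5, 10, 20, 50, 100, 500, 1000])
        dr, truth = synth.gen_assay(
            scfg, concs, n_replicates=int(config.get("n_replicates", 8)), detection_frame=frame
        )
        profile, _ = synth.gen_profile(scfg)
        prof_path = out / f"profiles_{chash}.csv"
        write_profiles_csv([profile], prof_path, chip_id=f"synth_{chash}")
        _prepend_hash_comment(prof_path, chash)
        outputs["profiles"] = prof_path
        fits = [
            lw_model.fit_lw(profile, w).to_dict(profile.channel_id)
            for w in ((0, scfg.crossover_frame), (0, scfg.n_frames - 1))
        ]
        fits_path = out / f"lw_fits_{chash}.json"
        fits_path.write_text(json.dumps({"config_hash": chash, "fits": fits}, indent=2))
        outputs["lw_fits"] = fits_path
        logger.info("synthesized assay: %d concentrations", len(concs))

    # --- stage 2: calibration
    calib = cal.fit_sigmoid(dr)
    lod = cal.find_lod(dr, alpha=float(config["alpha"]))
    lin = cal.linear_range(dr)
    calib_path = out / f"calibration_{chash}.json"
    calib_path.write_text(
        json.dumps(
            {
                "config_hash": chash,
                "schema": SCHEMA_VERSION,
                "model": calib.model,
                "params": list(calib.params),
                "r2": calib.r2,
                "direction": calib.direction,
                "span": list(calib.span),
                "log_floor": calib.log_floor,
                "lod_pg_ml": lod,
                "linear_range": list(lin[:2]) if lin else None,
                "detection_frame": frame,
            },
            indent=2,
        )
    )
    outputs["calibration"] = calib_path
    logger.info("calibrated: model=%s lod=%s", calib.model, lod)

    # --- stage 3: tier classification of the replicate signals
    cuts = tuple(config.get("tier_cuts_pg_ml", (15.0, 60.0)))
    rows = []
    for conc, reps in zip(dr.concentrations, dr.replicates):
        for k, sig in enumerate(reps):
            tier = cal.classify_tier(float(sig), calib, cuts)
            rows.append(
                {
                    "concentration_pg_ml": conc,
                    "replicate": k,
                    "signal_cm": sig,
                    "tier": tier.label,
                    "est_concentration_pg_ml": tier.concentration,
                    "extrapolated": tier.extrapolated,
                }
            )
    tier_path = out / f"tiers_{chash}.csv"
    pd.DataFrame(rows).to_csv(tier_path, index=False)
    _prepend_hash_comment(tier_path, chash)
    outputs["tiers"] = tier_path

    log_path = out / f"run_{chash}.log.json"
    log_path.write_text(
        json.dumps(
            {
                "config_hash": chash,
                "schema": SCHEMA_VERSION,
                "elapsed_s": round(time.time() - t0, 3),
                "n_concentrations": int(len(dr.concentrations)),
                "outputs": {k: str(v) for k, v in outputs.items()},
            },
            indent=2,
        )
    )
    outputs["log"] = log_path
    return outputs


def _prepend_hash_comment(path: Path, chash: str) -> None:
    body = path.read_text()
    path.write_text(f"# config_hash={chash}\n{body}")
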