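"""End-to-end orchestration: simulate -> lifetimes -> chambers -> oxygen ->
consumption (-> morphometry / viability), driven by a single YAML config.

The same config drives both simulation and analysis so a whole run is
one-command reproducible: identical seed + config yields byte-identical
outputs, recorded in a manifest with SHA-256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chambers as chambers_mod
from . import consumption as consumption_mod
from . import io as io_mod
from . import morphology as morphology_mod
from . import oximetry as oximetry_mod
from . import synthetic_data as synth
from .errors import ConfigurationError

log = logging.getLogger("spheroxi")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration (see ``examples/demo.yaml``)."""

    scene: synth.SceneConfig
    acquisition: synth.AcquisitionConfig
    kinetics: synth.KineticsSpec
    calibration: oximetry_mod.CalibrationModel
    seed: int = 0
    groups: dict[int, str] = dataclasses.field(default_factory=dict)
    occupancy_overrides: dict[int, str] = dataclasses.field(default_factory=dict)
    rate_window: int = 5
    plateau_window: int = 7
    allow_global_tau0: bool = False
    simulate_viability: bool = False
    dead_fraction: float = 0.02
    n_cells: int = 200

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            scene_raw = dict(raw["scene"])
            scene_raw["image_shape"] = tuple(scene_raw["image_shape"])
            scene_raw["chamber_centers"] = [
                tuple(c) for c in scene_raw["chamber_centers"]
            ]
            scene = synth.SceneConfig(**scene_raw)
            acq = synth.AcquisitionConfig(**raw.get("acquisition", {}))
            kin = synth.KineticsSpec(**raw.get("kinetics", {}))
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"invalid config block: {exc}") from exc
        calib_raw = raw.get("calibration")
        calib = (
            oximetry_mod.calibrate_kq(
                calib_raw["tau_n"], calib_raw["tau_a"], calib_raw.get("o2_a", 20.9)
            )
            if calib_raw
            else synth.default_calibration()
        )
        analysis = raw.get("analysis", {})
        return cls(
            scene=scene,
            acquisition=acq,
            kinetics=kin,
            calibration=calib,
            seed=int(raw.get("seed", 0)),
            groups={int(k): v for k, v in raw.get("groups", {}).items()},
            occupancy_overrides={
                int(k): v for k, v in raw.get("occupancy_overrides", {}).items()
            },
            rate_window=int(analysis.get("rate_window", 5)),
            plateau_window=int(analysis.get("plateau_window", 7)),
            allow_global_tau0=bool(analysis.get("allow_global_tau0", False)),
            simulate_viability=bool(raw.get("simulate_viability", False)),
            dead_fraction=float(raw.get("dead_fraction", 0.02)),
            n_cells=int(raw.get("n_cells", 200)),
        )


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig.from_dict(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        dataclasses.asdict(config), sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir, seed: int | None = None) -> dict:
    """Execute the full pipeline and return the manifest dict.

    Stages: simulate device -> per-timepoint demodulation and phase-lifetime
    estimation -> chamber detection (FLIM DC image) with config-driven
    occupancy -> empty-chamber-referenced Stern-Volmer oxygen maps ->
    consumption metrics and optional group comparison -> brightfield
    morphometry (and viability when enabled).  Any stage failure aborts with
    a stage-tagged diagnostic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    artifacts: dict[str, Path] = {}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("simulate")
        dataset = synth.simulate_device(
            config.scene,
            config.acquisition,
            config.kinetics,
            config.calibration,
            seed=config.seed,
        )
        artifacts.update(io_mod.write_dataset(dataset, outdir))
        brightfield = synth.render_brightfield(config.scene, rng)
        bf_path = outdir / "brightfield.tif"
        import tifffile

        tifffile.imwrite(bf_path, brightfield.astype(np.float32))
        artifacts["brightfield"] = bf_path
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc

    try:
        stage("chambers")
        from .flim_core import demodulate, lifetime_from_phase

        dc_image = dataset.stack.intensities[0].mean(axis=0)
        cmap = chambers_mod.detect_chambers(
            dc_image,
            config.scene.chamber_diameter,
            config.scene.pixel_size,
        )
        # config-driven occupancy: match detected chambers to configured centers
        configured = np.asarray(config.scene.chamber_centers, dtype=float)
        for ch in cmap.chambers:
            dist = np.hypot(*(configured - np.asarray(ch.center)).T)
            ch.occupancy = config.scene.occupancy[int(np.argmin(dist))]
        for cid, occ in config.occupancy_overrides.items():
            cmap.chamber(cid).occupancy = occ
        cmap.label_image = cmap._render_labels()
        map_path = outdir / "chamber_map.json"
        map_path.write_text(json.dumps(cmap.to_dict(), indent=1, sort_keys=True))
        artifacts["chamber_map"] = map_path
    except Exception as exc:
        raise RuntimeError(f"[chambers] {exc}") from exc

    try:
        stage("oxygen")
        table = oximetry_mod.o2_timeseries(
            dataset.stack,
            cmap,
            config.calibration,
            allow_global_tau0=config.allow_global_tau0,
            system_modulation_depth=config.acquisition.system_modulation_depth,
        )
        o2_path = outdir / "chamber_o2.csv"
        table.to_csv(o2_path, index=False, float_format="%.6f")
        artifacts["chamber_o2"] = o2_path
        n_negative = int(table["n_negative"].sum())
        log.info("oxygen: %d chambers, %d negative-O2 pixels flagged", len(cmap), n_negative)
    except Exception as exc:
        raise RuntimeError(f"[oxygen] {exc}") from exc

    try:
        stage("consumption")
        series = consumption_mod.assemble_series(table, cmap, config.groups)
        if series:
            metrics = [
                consumption_mod.compute_metrics(
                    s, config.rate_window, config.plateau_window
                )
                for s in series
            ]
            metrics_path = outdir / "consumption_metrics.csv"
            consumption_mod.metrics_table(metrics).to_csv(
                metrics_path, index=False, float_format="%.6f"
            )
            artifacts["consumption_metrics"] = metrics_path
            by_group: dict[str, list] = {}
            for s in series:
                by_group.setdefault(s.group, []).append(s)
            names = sorted(by_group)
            if len(names) >= 2 and all(len(by_group[n]) >= 2 for n in names[:2]):
                cmp_table = consumption_mod.compare_groups(
                    by_group[names[0]], by_group[names[1]]
                )
                cmp_path = outdir / "group_comparison.csv"
                cmp_table.to_csv(cmp_path, index=False, float_format="%.6f")
                artifacts["group_comparison"] = cmp_path
    except Exception as exc:
        raise RuntimeError(f"[consumption] {exc}") from exc

    try:
        stage("morphometry")
        results = []
        for ch in cmap.chambers:
            r0, c0 = ch.center
            R = int(np.ceil(ch.radius))
            r0i, c0i = int(round(r0)), int(round(c0))
            roi = brightfield[
                max(0, r0i - R) : r0i + R + 1, max(0, c0i - R) : c0i + R + 1
            ]
            results.append(
                morphology_mod.measure_spheroid(
                    roi,
                    config.scene.pixel_size,
                    chamber_id=ch.chamber_id,
                    group=config.groups.get(ch.chamber_id, "untreated"),
                )
            )
        morph_path = outdir / "morphometry.csv"
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            morph_path, index=False, float_format="%.4f"
        )
        artifacts["morphometry"] = morph_path
    except Exception as exc:
        raise RuntimeError(f"[morphometry] {exc}") from exc

    if config.simulate_viability:
        try:
            stage("viability")
            green, red, truth = synth.render_viability_pair(
                config.scene, config.dead_fraction, config.n_cells, rng
            )
            result = morphology_mod.quantify_viability(green, red)
            via_path = outdir / "viability.csv"
            pd.DataFrame([dataclasses.asdict(result) | {"true_live": truth["n_live"], "true_dead": truth["n_dead"]}]).to_csv(
                via_path, index=False
            )
            artifacts["viability"] = via_path
        except Exception as exc:
            raise RuntimeError(f"[viability] {exc}") from exc

    manifest = {
        "schema_version": io_mod.SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "artifacts": {
            name: {"path": str(p.name), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
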