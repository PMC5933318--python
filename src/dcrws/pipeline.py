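"""Orchestration of the full analysis from a single config.

Stages: prepare (filter + gap-split) -> fit model 1 (48 h grid, all
tracks) -> classify/summarize -> optionally fit model 2 (6 h grid on a
configured subset) -> dive extraction against the fitted track.  Each
stage writes versioned outputs into the run directory and the manifest
records inputs, seeds, settings and convergence, so a rerun with the
same config and seed reproduces every CSV byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import argos_io, behavior, dive as dive_mod
from .simulate import SimScenario, simulate_dives, simulate_track
from .ssm import MCMCConfig, fit_dcrws
from .tdist import TDistParams

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline settings (see docs for the YAML schema)."""

    input_path: str | None = None          # raw Argos CSV; or simulate
    simulate: dict[str, Any] | None = None  # SimScenario overrides
    max_speed_kmh: float = argos_io.DEFAULT_MAX_SPEED_KMH
    gap_days: float = argos_io.DEFAULT_GAP_DAYS
    model1_step_hours: float = 48.0
    model2_step_hours: float = 6.0
    model2_tracks: list[str] | None = None  # None -> skip model 2
    depth_path: str | None = None
    dive_threshold_m: float = dive_mod.DIVE_THRESHOLD_M
    n_chains: int = 2
    n_iter: int = 15_000
    n_burnin: int = 5_000
    thin: int = 10
    seed: int = 0
    out_dir: str = "run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def mcmc(self) -> MCMCConfig:
        return MCMCConfig(n_chains=self.n_chains, n_iter=self.n_iter,
                          n_burnin=self.n_burnin, thin=self.thin,
                          seed=self.seed)


def _fit_stage(tracks, step_hours, cfg: RunConfig, out: Path, tag: str) -> dict:
    res = fit_dcrws(tracks, step_hours=step_hours, mcmc=cfg.mcmc(),
                    tdist=TDistParams())
    frames = [behavior.labelled_steps_frame(p) for p in res.tracks]
    pd.concat(frames, ignore_index=True).to_csv(
        out / f"posterior_tracks_{tag}.csv", index=False)
    rows = []
    for name, s in res.param_summary.items():
        rows.append({"parameter": name, **{k: round(v, 6)
                                           for k, v in s.items()}})
    pd.DataFrame(rows).to_csv(out / f"posterior_params_{tag}.csv", index=False)
    behavior.descriptors_table(res.tracks).to_csv(
        out / f"descriptors_{tag}.csv", index=False)
    diag = {"rhat": {k: round(v, 4) for k, v in res.rhat.items()},
            "converged": res.converged,
            "acceptance": {k: round(v, 4) for k, v in res.acceptance.items()},
            "retained_samples": res.retained_samples}
    (out / f"diagnostics_{tag}.json").write_text(json.dumps(diag, indent=2))
    return {"status": "ok", "converged": res.converged,
            "n_tracks": len(res.tracks), "result": res}


def run_all(cfg: RunConfig) -> dict:
    """Execute every configured stage; return (and write) the manifest.

    A stage failure is recorded in the manifest and later stages that
    depend on it are skipped; non-convergence is flagged, never fatal.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": cfg.seed,
        "settings": {k: v for k, v in dataclasses.asdict(cfg).items()
                     if k != "out_dir"},
        "stages": {},
    }
    stages = manifest["stages"]

    # ---- prepare ----------------------------------------------------------
    tracks = []
    truth = None
    try:
        if cfg.simulate is not None:
            scenario = SimScenario(**{**cfg.simulate, "seed": cfg.seed})
            truth, raw = simulate_track(scenario)
            raws = [raw]
        elif cfg.input_path:
            raws = argos_io.read_argos(cfg.input_path)
        else:
            raise ValueError("config needs input_path or simulate")
        tracks = argos_io.prepare_tracks(raws, cfg.max_speed_kmh, cfg.gap_days)
        argos_io.write_tracks_csv(tracks, out / "cleaned_tracks.csv")
        for tr in tracks:
            argos_io.write_track_geojson(tr, out / f"track_{tr.track_id}.geojson")
        stages["prepare"] = {"status": "ok", "n_tracks": len(tracks),
                             "n_fixes": sum(len(t) for t in tracks)}
    except Exception as exc:  # noqa: BLE001 - manifest records the failure
        stages["prepare"] = {"status": "failed", "error": str(exc)}
        manifest["ok"] = False
        _write_manifest(manifest, out)
        return manifest

    # ---- model 1 ----------------------------------------------------------
    fit1 = None
    try:
        r = _fit_stage(tracks, cfg.model1_step_hours, cfg, out, "model1")
        fit1 = r.pop("result")
        stages["fit_model1"] = r
    except Exception as exc:  # noqa: BLE001
        stages["fit_model1"] = {"status": "failed", "error": str(exc)}

    # ---- model 2 on the configured subset ---------------------------------
    if cfg.model2_tracks:
        subset = [t for t in tracks if t.track_id in cfg.model2_tracks]
        missing = set(cfg.model2_tracks) - {t.track_id for t in subset}
        if missing:
            stages["fit_model2"] = {"status": "failed",
                                    "error": f"unknown track(s) {sorted(missing)}"}
        else:
            try:
                r = _fit_stage(subset, cfg.model2_step_hours, cfg, out, "model2")
                r.pop("result")
                stages["fit_model2"] = r
            except Exception as exc:  # noqa: BLE001
                stages["fit_model2"] = {"status": "failed", "error": str(exc)}

    # ---- dives against the model-1 fitted track ---------------------------
    if cfg.depth_path or truth is not None:
        try:
            if cfg.depth_path:
                bouts = dive_mod.read_depth_csv(cfg.depth_path)
            else:
                bouts, _ = simulate_dives(scenario, truth)
                dive_mod.write_depth_csv(bouts, out / "depth_series.csv")
            dives = [d for b in bouts
                     for d in dive_mod.detect_dives(b, cfg.dive_threshold_m)]
            if fit1 is not None and fit1.tracks:
                post = fit1.tracks[0]
                times = [t.timestamp() for t in post.grid.times]

                def position_at(t, _times=times, _p=post):
                    import numpy as np
                    ts = t.timestamp()
                    return (float(np.interp(ts, _times, _p.mean_lon)),
                            float(np.interp(ts, _times, _p.mean_lat)))

                dives = dive_mod.tag_dives_diel(dives, position_at)
                dive_mod.bin_dive_stats(dives, post.grid).to_csv(
                    out / "dive_bins.csv", index=False)
            dive_mod.dives_to_frame(dives).to_csv(out / "dives.csv", index=False)
            dive_mod.whale_diel_summary(dives).to_csv(
                out / "dive_diel_summary.csv", index=False)
            stages["dives"] = {"status": "ok", "n_bouts": len(bouts),
                               "n_dives": len(dives)}
        except Exception as exc:  # noqa: BLE001
            stages["dives"] = {"status": "failed", "error": str(exc)}

    manifest["ok"] = all(s.get("status") == "ok" for s in stages.values())
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
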