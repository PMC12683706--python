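"""End-to-end pipeline: configuration, staged execution, run manifest.

Stages run in the study's order — isotope mixing, E-scape construction, trip
preparation, step-selection, HMM — each writing plain-text artifacts (CSV,
JSON, ASCII grids) into the output directory. A manifest records the config
hash, per-file checksums, timings and warnings; reruns with identical config
and seeds reproduce identical checksums for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .escape_map import EScapeBuilder, SOURCES, sample_hri
from .hmm import STATE_NAMES, CovariateHMM, foraging_segregation, transition_curves
from .mixing import TEF, IsotopeMixingModel, SourceSignature
from .raster import Raster, read_ascii_grid, write_ascii_grid
from .ssf import StepSelectionFunction, fit_kernel, make_controls, rss
from .trajectory import prepare_steps

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "default_config", "validate_config", "run_pipeline"]

ALL_STAGES = ("simulate", "mix", "escape", "trips", "ssf", "hmm")


def default_config(outdir: str = "escapes_run", seed: int = 0) -> dict:
    """A complete synthetic-mode configuration with the study defaults
    (500 m buffers, 1 km units, K=50 controls, 50 HMM restarts)."""
    return {
        "outdir": outdir,
        "synthetic": True,
        "stages": list(ALL_STAGES),
        "seeds": {
            "landscape": seed,
            "isotopes": seed + 1,
            "iei": seed + 2,
            "tracks": seed + 3,
            "controls": seed + 4,
            "mcmc": seed + 5,
            "hmm": seed + 6,
        },
        "landscape": {
            "width": 300,
            "height": 300,
            "cell_size": 10.0,
            "marsh_fraction": 0.3,
            "patch_scale": 8.0,
            "chl_gradient": [0.2, 1.0],
        },
        "truth": {"source_props": [0.68, 0.23, 0.09], "n_birds": 5, "steps_per_bird": 200},
        "mixing": {"chains": 3, "iters": 20000, "burn": 10000, "thin": 10, "n_samples": 100, "noise_sd": 0.5},
        "escape": {"radius": 500.0, "unit": 1000.0, "n_points": 1000, "edge_width": 10.0},
        "trajectory": {"colony_radius": 500.0, "dt": "15min", "max_gap": "60min"},
        "ssf": {"K": 50, "individual_deviations": False, "year_deviations": False, "ridge": "auto"},
        "hmm": {"n_restarts": 50, "maxiter_restart": 30, "maxiter": 500},
        "inputs": {},
    }


def validate_config(config: dict) -> dict:
    """Machine-readable config check; failures are reported, not raised."""
    errors: list[str] = []
    warnings: list[str] = []

    def need(path, cond, msg):
        if not cond:
            errors.append(f"{path}: {msg}")

    stages = config.get("stages", [])
    for s in stages:
        if s not in ALL_STAGES:
            errors.append(f"stages: unknown stage {s!r}")
    seeds = config.get("seeds", {})
    stochastic = {"simulate": ["landscape", "isotopes", "tracks"], "mix": ["mcmc"], "escape": ["iei"], "ssf": ["controls"], "hmm": ["hmm"]}
    for stage, keys in stochastic.items():
        if stage in stages:
            for k in keys:
                need(f"seeds.{k}", k in seeds and seeds[k] is not None, "missing explicit seed")
    esc = config.get("escape", {})
    need("escape.radius", esc.get("radius", 500.0) > 0, "radius must be > 0 (meters)")
    unit = esc.get("unit", 1000.0)
    cs = config.get("landscape", {}).get("cell_size", 10.0)
    need("escape.unit", unit >= cs, "landscape unit smaller than one cell")
    fsource = config.get("escape", {}).get("fsource") or config.get("truth", {}).get("source_props")
    if fsource is not None:
        total = float(np.sum(fsource))
        need("fsource", abs(total - 1) < 1e-6, f"source proportions sum to {total:.3g}, not 1")
        need("fsource", np.all(np.asarray(fsource) >= 0), "source proportions must be >= 0")
    ssf_cfg = config.get("ssf", {})
    need("ssf.K", int(ssf_cfg.get("K", 50)) >= 1, "K must be >= 1")
    if not config.get("synthetic", False):
        inputs = config.get("inputs", {})
        for key in ("habitat", "chl", "consumers", "sources", "gps", "colony_xy"):
            need(f"inputs.{key}", key in inputs, "required in real-data mode")
    return {"ok": not errors, "errors": errors, "warnings": warnings}


@dataclass
class RunManifest:
    """Provenance of a pipeline run."""

    config_hash: str
    version: str
    files: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    stages: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _register(manifest: RunManifest, outdir: Path, *paths: Path) -> None:
    for p in paths:
        manifest.files[str(p.relative_to(outdir))] = _sha256(p)


class PipelineConfig:
    """Thin loader/merger for the declarative config file."""

    @staticmethod
    def load(path) -> dict:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = default_config()
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
        return cfg


def run_pipeline(config: dict) -> RunManifest:
    """Execute the configured stages and write artifacts plus a manifest."""
    report = validate_config(config)
    if not report["ok"]:
        raise ValueError("invalid configuration: " + "; ".join(report["errors"]))
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    cfg_hash = hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash, version=__version__)
    stages = config.get("stages", list(ALL_STAGES))
    seeds = config["seeds"]
    state: dict = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
            manifest.stages[name] = "ok"
        except Exception as exc:
            manifest.stages[name] = f"failed: {exc}"
            (outdir / "manifest.json").write_text(manifest.to_json())
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.timings[name] = round(time.perf_counter() - t0, 3)

    # -- inputs ---------------------------------------------------------
    def stage_simulate():
        lc = simulate.LandscapeConfig(seed=seeds["landscape"], **config.get("landscape", {}))
        hab, chl = simulate.make_landscape(lc)
        state["hab"], state["chl"] = hab, chl
        truth_cfg = config.get("truth", {})
        colony = tuple(truth_cfg.get("colony_xy", (hab.extent[2] / 2, hab.extent[3] / 2)))
        truth = simulate.TruthParams(
            source_props=np.asarray(truth_cfg.get("source_props", [0.68, 0.23, 0.09])), colony_xy=colony
        )
        state["truth"] = truth
        state["sources"] = simulate.default_sources()
        mix_cfg = config.get("mixing", {})
        state["consumers"] = simulate.simulate_isotopes(
            truth.source_props,
            state["sources"],
            n=mix_cfg.get("n_samples", 100),
            noise_sd=mix_cfg.get("noise_sd", 0.5),
            seed=seeds["isotopes"],
        )
        write_ascii_grid(hab, outdir / "habitat.asc")
        write_ascii_grid(chl, outdir / "chl.asc")
        state["consumers"].to_csv(outdir / "consumers.csv", index=False)
        _register(manifest, outdir, outdir / "habitat.asc", outdir / "chl.asc", outdir / "consumers.csv")

    def stage_load():
        inputs = config["inputs"]
        state["hab"] = read_ascii_grid(inputs["habitat"], categorical=True)
        chls = inputs["chl"] if isinstance(inputs["chl"], list) else [inputs["chl"]]
        from .habitat import relative_chl

        state["chl"] = relative_chl([read_ascii_grid(p) for p in chls])
        state["consumers"] = pd.read_csv(inputs["consumers"])[["d13C", "d34S"]]
        state["sources"] = SourceSignature.from_frame(pd.read_csv(inputs["sources"]))
        state["gps"] = pd.read_csv(inputs["gps"])
        state["colony_xy"] = tuple(inputs["colony_xy"])

    def stage_mix():
        mix_cfg = {k: v for k, v in config.get("mixing", {}).items() if k in ("chains", "iters", "burn", "thin")}
        model = IsotopeMixingModel(
            sources=state["sources"], tef=TEF(), random_state=seeds["mcmc"], **mix_cfg
        )
        model.fit(state["consumers"].to_numpy(dtype=float))
        state["mixing"] = model
        if not model.converged_:
            manifest.warnings.append("mixing model R-hat > 1.1")
        model.posterior_.to_frame().to_csv(outdir / "mixing_posterior.csv", index=False)
        summary = model.summary_
        summary.to_csv(outdir / "mixing_summary.csv", index=False)
        (outdir / "mixing_report.json").write_text(
            json.dumps({"rhat": model.rhat_, "acceptance": model.acceptance_}, indent=2)
        )
        _register(
            manifest,
            outdir,
            outdir / "mixing_posterior.csv",
            outdir / "mixing_summary.csv",
            outdir / "mixing_report.json",
        )

    def stage_escape():
        esc = config.get("escape", {})
        if "mixing" in state:
            fsource = state["mixing"].summary_.set_index("source").loc[list(SOURCES), "median"].to_numpy()
            fsource = fsource / fsource.sum()
        else:
            fsource = np.asarray(esc.get("fsource") or config["truth"]["source_props"], dtype=float)
        builder = EScapeBuilder(
            fsource=fsource,
            n_points=esc.get("n_points", 1000),
            radius=esc.get("radius", 500.0),
            unit=esc.get("unit", 1000.0),
            edge_width=esc.get("edge_width", 10.0),
            random_state=seeds["iei"],
        )
        escape = builder.fit_transform((state["hab"], state["chl"]))
        state["escape"] = escape
        state["edge"] = builder.edge_
        escape.iei.summary.to_csv(outdir / "iei_summary.csv", index=False)
        escape.iei.points.to_csv(outdir / "iei_points.csv", index=False)
        write_ascii_grid(escape.hri, outdir / "hri.asc")
        write_ascii_grid(builder.edge_, outdir / "edge.asc")
        _register(
            manifest,
            outdir,
            outdir / "iei_summary.csv",
            outdir / "iei_points.csv",
            outdir / "hri.asc",
            outdir / "edge.asc",
        )

    def stage_trips():
        if config.get("synthetic", False):
            truth = state["truth"]
            traj, states = simulate.simulate_tracks(
                state["escape"],
                truth,
                n_birds=config["truth"].get("n_birds", 5),
                steps_per_bird=config["truth"].get("steps_per_bird", 200),
                seed=seeds["tracks"],
            )
            state["gps"] = traj
            state["true_states"] = states
            state["colony_xy"] = truth.colony_xy
            traj.to_csv(outdir / "gps.csv", index=False)
            states.to_csv(outdir / "true_states.csv", index=False)
            _register(manifest, outdir, outdir / "gps.csv", outdir / "true_states.csv")
        tcfg = config.get("trajectory", {})
        steps = prepare_steps(
            state["gps"],
            state["colony_xy"],
            colony_radius=tcfg.get("colony_radius", 500.0),
            dt=tcfg.get("dt", "15min"),
            max_gap=tcfg.get("max_gap", "60min"),
        )
        if steps.empty:
            raise ValueError("no complete trips found")
        state["steps"] = steps
        steps.to_csv(outdir / "steps.csv", index=False)
        _register(manifest, outdir, outdir / "steps.csv")

    def stage_ssf():
        scfg = config.get("ssf", {})
        kernel = fit_kernel(state["steps"])
        controls = make_controls(
            state["steps"], kernel, K=scfg.get("K", 50), escape=state["escape"], seed=seeds["controls"]
        )
        model = StepSelectionFunction(
            individual_deviations=scfg.get("individual_deviations", False),
            year_deviations=scfg.get("year_deviations", False),
            ridge=scfg.get("ridge", "auto"),
        )
        model.fit(controls)
        state["ssf"] = model
        controls.to_csv(outdir / "controls.csv", index=False)
        report = model.fit_.report()
        report["kernel"] = {"shape": kernel.shape, "scale": kernel.scale, "mu": kernel.mu, "kappa": kernel.kappa}
        report["rss_per_unit_log_hri"] = float(rss(model.fit_, 1.0)) if model.converged_ else None
        (outdir / "ssf_report.json").write_text(json.dumps(report, indent=2, default=float))
        _register(manifest, outdir, outdir / "controls.csv", outdir / "ssf_report.json")

    def stage_hmm():
        hcfg = config.get("hmm", {})
        steps = state["steps"]
        log_hri = np.nan_to_num(
            np.log(np.clip(sample_hri(state["escape"], steps[["x0", "y0"]].to_numpy(dtype=float)), 1e-12, None)),
            nan=0.0,
        )
        model = CovariateHMM(
            n_restarts=hcfg.get("n_restarts", 50),
            maxiter_restart=hcfg.get("maxiter_restart", 30),
            maxiter=hcfg.get("maxiter", 500),
            random_state=seeds["hmm"],
        )
        model.fit(steps, log_hri)
        state["hmm"] = model
        decoded = steps.copy()
        decoded["state"] = [STATE_NAMES[s] for s in model.predict(steps, log_hri)]
        decoded.to_csv(outdir / "steps_decoded.csv", index=False)
        fitp = model.params_
        report = {
            "loglik": model.loglik_,
            "converged": model.converged_,
            "states": [
                {
                    "name": STATE_NAMES[i],
                    "step_mean": fitp.means[i],
                    "step_sd": fitp.sds[i],
                    "turn_mu": fitp.mus[i],
                    "turn_kappa": fitp.kappas[i],
                }
                for i in range(3)
            ],
            "transition_slopes": model.fit_.slope_table().to_dict(orient="records"),
        }
        (outdir / "hmm_report.json").write_text(json.dumps(report, indent=2, default=float))
        curves = transition_curves(model.fit_, np.linspace(-1.5, 1.5, 25))
        curves.to_csv(outdir / "transition_curves.csv", index=False)
        model.restarts_.to_csv(outdir / "hmm_restarts.csv", index=False)
        _register(
            manifest,
            outdir,
            outdir / "steps_decoded.csv",
            outdir / "hmm_report.json",
            outdir / "transition_curves.csv",
            outdir / "hmm_restarts.csv",
        )

    if config.get("synthetic", False):
        if "simulate" in stages:
            run_stage("simulate", stage_simulate)
    else:
        run_stage("load", stage_load)
    for name, fn in (("mix", stage_mix), ("escape", stage_escape), ("trips", stage_trips), ("ssf", stage_ssf), ("hmm", stage_hmm)):
        if name in stages:
            run_stage(name, fn)

    (outdir / "manifest.json").write_text(manifest.to_json())
    manifest.files["manifest.json"] = "self"
    return manifest
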