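"""Reproducible build -> simulate -> analyze pipeline with a manifest.

A pipeline run is a pure function of its (YAML) configuration and
seed: every stage output is written under the output directory, hashed
(sha256) and recorded in ``manifest.json`` together with the effective
configuration, so a re-run can verify bitwise reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .engine import Schedule, run
from .forcefield import default_force_field, load_force_field
from .micelles import aggregation_series, find_micelles
from .mesophase import (PhaseAnalysisError, analyze_hexagonal,
                        analyze_lamellar, classify_phase)
from .synthetic import FixtureSpec
from .topology import (build_slens, composition_from_weight_percent,
                       default_aes_distribution, random_initial_configuration,
                       sample_ethoxylation)
from .xyzio import read_trajectory, write_trajectory


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    force_field_hash: str
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def record(self, stage: str, path: Path) -> None:
        self.outputs[str(path.name)] = {"stage": stage,
                                        "sha256": _sha256(path)}

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True,
                      default=str)


def run_pipeline(config, outdir=None) -> RunManifest:
    """Execute the stages named in a config document.

    ``config`` is a path to YAML or a mapping with keys among
    ``build`` / ``fixture``, ``simulate`` and ``analyze``; ``seed`` and
    ``outdir`` set determinism and output placement.  A stage failure
    is recorded in the manifest and downstream stages are skipped.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir if outdir is not None
                  else config.get("outdir", "mesodpd_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    ff = default_force_field() if "force_field" not in config \
        else load_force_field(config["force_field"])
    ff_hash = hashlib.sha256(
        json.dumps({"species": list(ff.species),
                    "a": ff.interactions.repulsion.tolist(),
                    "rc": ff.interactions.cutoff.tolist()},
                   sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(config=config, seed=seed, version=__version__,
                           force_field_hash=ff_hash)

    cfg0 = None
    try:
        if "fixture" in config:
            spec = FixtureSpec(seed=seed, **config["fixture"])
            built = spec.build(ff)
            cfg0 = built[0]
            frames0 = cfg0 if not isinstance(cfg0, list) else cfg0
            manifest.stages.append({"stage": "fixture", "status": "ok"})
        elif "build" in config:
            b = config["build"]
            n = b.get("n", 0)
            if n == "aes":
                dist = default_aes_distribution()
                tops = {k: build_slens(k, ff) for k in dist.support}
                counts = sample_ethoxylation(dist, 1000, seed)
                fracs = {k: c / 1000 for k, c in counts.items()}
                comp = composition_from_weight_percent(
                    b["box"], b["wt"], tops, ff, fractions=fracs)
            else:
                comp = composition_from_weight_percent(
                    b["box"], b["wt"], {n: build_slens(n, ff)}, ff)
            cfg0 = random_initial_configuration(comp, seed=seed)
            manifest.stages.append({"stage": "build", "status": "ok"})
        if cfg0 is not None and not isinstance(cfg0, list):
            path = outdir / "initial.extxyz"
            write_trajectory(cfg0, path)
            manifest.record("build", path)
    except Exception as exc:  # record and stop
        manifest.stages.append({"stage": "build", "status": "failed",
                                "error": str(exc)})
        manifest.write(outdir / "manifest.json")
        return manifest

    frames = [cfg0] if cfg0 is not None and not isinstance(cfg0, list) \
        else (cfg0 or [])
    if "simulate" in config and cfg0 is not None:
        s = config["simulate"]
        try:
            schedule = Schedule(steps=int(s["steps"]),
                                snapshot_stride=int(s.get("stride", 100)),
                                shear_rate=float(s.get("shear_rate", 0.0)),
                                seed=seed)
            frames = run(cfg0, ff, schedule)
            path = outdir / "trajectory.extxyz"
            write_trajectory(frames, path)
            manifest.record("simulate", path)
            manifest.stages.append({"stage": "simulate", "status": "ok",
                                    "steps": schedule.steps})
        except Exception as exc:
            manifest.stages.append({"stage": "simulate", "status": "failed",
                                    "error": str(exc)})
            manifest.write(outdir / "manifest.json")
            return manifest

    for analysis in config.get("analyze", []):
        result: dict = {"analysis": analysis}
        try:
            if analysis == "micelles":
                ms = find_micelles(frames[-1], tail_species=ff.tail_species())
                result.update({
                    "n_micelles": int(ms.n_micelles),
                    "n_agg": ms.aggregation_number(),
                    "sizes": ms.sizes.tolist(),
                    "radii": ms.radii.tolist()})
            elif analysis == "lamellar":
                lm = analyze_lamellar(frames[-1])
                result.update({"d": lm.d, "kappa": lm.kappa,
                               "theta": lm.theta,
                               "director": lm.director.tolist()})
            elif analysis == "hexagonal":
                hm = analyze_hexagonal(frames[-1],
                                       tail_species=ff.tail_species())
                result.update({"r_s": hm.r_s,
                               "a": hm.a.tolist(), "b": hm.b.tolist(),
                               "orientation": hm.orientation,
                               "commensurate": hm.commensurate})
            elif analysis == "phase":
                result.update({"label": classify_phase(
                    frames, tail_species=ff.tail_species())})
            else:
                raise ValueError(f"unknown analysis {analysis!r}")
            status = "ok"
        except (PhaseAnalysisError, ValueError) as exc:
            result["error"] = str(exc)
            status = "failed"
        path = outdir / f"analysis_{analysis}.json"
        with open(path, "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
        manifest.record(f"analyze:{analysis}", path)
        manifest.stages.append({"stage": f"analyze:{analysis}",
                                "status": status})

    manifest.write(outdir / "manifest.json")
    return manifest
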