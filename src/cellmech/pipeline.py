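"""End-to-end orchestration: generate synthetic inputs, quantify each
modality, and run the statistical comparison, from one YAML config and one
global seed.

The global seed fans out to per-stage seeds by fixed offsets so a single
number reproduces a full run bit-for-bit. Each stage writes only its own
artifacts; re-running one stage leaves the others' outputs untouched.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .afm import HertzParams, aggregate_force_map, read_force_curve, write_force_curve, ForceMap
from .errors import CellMechError
from .focal_adhesions import analyze_fa_image_set
from .images import read_image, write_image
from .migration import (
    chemotactic_index,
    compute_msd,
    compute_speed,
    ensemble_msd,
    fit_prw,
    read_trajectories,
    write_trajectories,
)
from .morphometry import measure_particles, records_to_frame
from .stats import GroupedSample, compare_groups, rout_outliers
from .synthetic import (
    bead_field,
    elliptical_cell_mask,
    generate_fa_image,
    generate_force_map,
    generate_prw_ensemble,
)

log = logging.getLogger("cellmech")

# Per-stage seed offsets: one global seed reproduces everything.
SEED_OFFSETS = {"beads": 11, "migration": 22, "afm": 33, "fa": 44, "stats": 55}

STAGES = ("generate", "morphometry", "migrate", "afm", "fa", "stats")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    pixel_size: float = 0.3
    n_beads: int = 100
    migration: dict = field(
        default_factory=lambda: {"n_tracks": 50, "D": 10.0, "tau": 5.0, "dt": 5.0, "n_steps": 72}
    )
    afm: dict = field(
        default_factory=lambda: {"n_curves": 25, "E": 1000.0, "noise_sd": 1e-11}
    )
    fa: dict = field(default_factory=lambda: {"n_fas": 12, "mean_area_um2": 8.0})
    morphometry_params: dict = field(default_factory=dict)
    hertz: dict = field(default_factory=lambda: {"nu": 0.45, "r": 30e-9})
    stats_params: dict = field(default_factory=lambda: {"alpha": 0.05, "rout_q": 1.0})
    inputs: dict = field(default_factory=dict)  # per-stage input path overrides

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.setdefault("outdir", "cellmech_out")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def stage_seed(self, name: str) -> int:
        return (self.seed + SEED_OFFSETS[name]) % (2**31 - 1)


def _stage_generate(cfg: RunConfig) -> dict:
    out = cfg.outdir
    image, truth = bead_field(
        cfg.n_beads, pixel_size=cfg.pixel_size, seed=cfg.stage_seed("beads")
    )
    write_image(out / "beads.tif", image)
    truth.to_csv(out / "beads_truth.csv", index=False)

    m = cfg.migration
    trajs = generate_prw_ensemble(
        m["n_tracks"], m["D"], m["tau"], m["dt"], m["n_steps"],
        seed=cfg.stage_seed("migration"),
    )
    write_trajectories(trajs, out / "trajectories.csv")

    a = cfg.afm
    fmap = generate_force_map(
        a["n_curves"], a["E"], cfg.hertz["nu"], cfg.hertz["r"],
        noise_sd=a.get("noise_sd", 0.0), seed=cfg.stage_seed("afm"),
    )
    curve_dir = out / "force_curves"
    curve_dir.mkdir(exist_ok=True)
    manifest = []
    for i, c in enumerate(fmap.curves):
        name = f"curve_{i:03d}.csv"
        write_force_curve(c, curve_dir / name)
        manifest.append({"cell_id": fmap.cell_id, "file": name})
    pd.DataFrame(manifest).to_csv(curve_dir / "manifest.csv", index=False)

    f = cfg.fa
    rng = np.random.default_rng(cfg.stage_seed("fa"))
    mask = elliptical_cell_mask((256, 256), cfg.pixel_size)
    areas = rng.gamma(4.0, f["mean_area_um2"] / 4.0, size=f["n_fas"])
    marker, actin, fa_truth = generate_fa_image(
        mask, f["n_fas"], fa_area_dist=areas, seed=cfg.stage_seed("fa")
    )
    write_image(out / "fa_marker.tif", marker)
    write_image(out / "fa_actin.tif", actin)
    fa_truth.to_csv(out / "fa_truth.csv", index=False)

    # three synthetic measurement groups for the stats stage demo
    rng_s = np.random.default_rng(cfg.stage_seed("stats"))
    rows = []
    for gname, mu in [("A", 10.0), ("B", 10.0), ("C", 12.0)]:
        for v in rng_s.lognormal(np.log(mu), 0.25, size=40):
            rows.append({"group": gname, "value": v})
    pd.DataFrame(rows).to_csv(out / "groups.csv", index=False)
    return {"n_beads": cfg.n_beads, "n_tracks": m["n_tracks"], "n_curves": a["n_curves"]}


def _stage_morphometry(cfg: RunConfig) -> dict:
    path = Path(cfg.inputs.get("morphometry", cfg.outdir / "beads.tif"))
    image = read_image(path, cfg.inputs.get("pixel_size"))
    records = measure_particles(image, **cfg.morphometry_params)
    df = records_to_frame(records)
    df.to_csv(cfg.outdir / "shape_records.csv", index=False)
    return {
        "n_particles": len(df),
        "mean_equiv_diameter_um": float(df["equiv_diameter_um"].mean()) if len(df) else None,
    }


def _stage_migrate(cfg: RunConfig) -> dict:
    path = Path(cfg.inputs.get("migrate", cfg.outdir / "trajectories.csv"))
    trajs = read_trajectories(path)
    rows = []
    for tr in trajs:
        rows.append(
            {
                "track_id": tr.track_id,
                "speed_um_min": compute_speed(tr),
                "chemotactic_index_x": chemotactic_index(tr),
            }
        )
    pd.DataFrame(rows).to_csv(cfg.outdir / "track_metrics.csv", index=False)
    msd = ensemble_msd(trajs)
    fit = fit_prw(msd)
    pd.DataFrame(
        {"lag_min": msd.lags, "msd_um2": msd.msd, "n_pairs": msd.n_pairs}
    ).to_csv(cfg.outdir / "msd.csv", index=False)
    pd.DataFrame(
        [{"D_um2_min": fit.D, "tau_min": fit.tau, "rss": fit.rss, "converged": fit.converged}]
    ).to_csv(cfg.outdir / "prw_fit.csv", index=False)
    return {"n_tracks": len(trajs), "D": fit.D, "tau": fit.tau}


def _stage_afm(cfg: RunConfig) -> dict:
    curve_dir = Path(cfg.inputs.get("afm", cfg.outdir / "force_curves"))
    manifest = pd.read_csv(curve_dir / "manifest.csv")
    params = HertzParams(nu=cfg.hertz["nu"], r=cfg.hertz["r"])
    rows = []
    for cell_id, g in manifest.groupby("cell_id"):
        curves = [read_force_curve(curve_dir / f) for f in g["file"]]
        result = aggregate_force_map(ForceMap(curves, str(cell_id)), params)
        rows.append(
            {
                "cell_id": cell_id,
                "E_Pa": result.E,
                "n_curves": result.n_curves,
                "n_converged": result.n_converged,
            }
        )
    pd.DataFrame(rows).to_csv(cfg.outdir / "afm_moduli.csv", index=False)
    return {"n_cells": len(rows)}


def _stage_fa(cfg: RunConfig) -> dict:
    marker = read_image(Path(cfg.inputs.get("fa_marker", cfg.outdir / "fa_marker.tif")))
    actin = read_image(Path(cfg.inputs.get("fa_actin", cfg.outdir / "fa_actin.tif")))
    stats = analyze_fa_image_set(marker, actin)
    stats.to_frame().to_csv(cfg.outdir / "fa_stats.csv", index=False)
    pd.DataFrame({"fa_area_um2": stats.fa_areas_um2}).to_csv(
        cfg.outdir / "fa_areas.csv", index=False
    )
    return {"fa_count": stats.fa_count, "density_per_um2": stats.density_per_um2}


def _stage_stats(cfg: RunConfig) -> dict:
    path = Path(cfg.inputs.get("stats", cfg.outdir / "groups.csv"))
    df = pd.read_csv(path)
    sp = cfg.stats_params
    # documented order of operations: flag outliers, exclude, then test
    kept = []
    for _, g in df.groupby("group", sort=False):
        vals = g["value"].values
        if len(vals) >= 10:
            flags = rout_outliers(vals, sp.get("rout_q", 1.0)).flags
            g = g.loc[~flags]
        kept.append(g)
    clean = pd.concat(kept, ignore_index=True)
    sample = GroupedSample.from_frame(clean)
    report = compare_groups(sample, alpha=sp.get("alpha", 0.05))
    report.pairwise.to_csv(cfg.outdir / "comparison_pairwise.csv", index=False)
    (cfg.outdir / "comparison_report.txt").write_text(report.summary() + "\n")
    return {
        "test_used": report.test_used,
        "p_value": report.p_value,
        "n_excluded": int(len(df) - len(clean)),
    }


_STAGE_FN = {
    "generate": _stage_generate,
    "morphometry": _stage_morphometry,
    "migrate": _stage_migrate,
    "afm": _stage_afm,
    "fa": _stage_fa,
    "stats": _stage_stats,
}

def _stage_input_paths(cfg: RunConfig, stage: str) -> list[Path]:
    if stage == "morphometry":
        return [Path(cfg.inputs.get("morphometry", cfg.outdir / "beads.tif"))]
    if stage == "migrate":
        return [Path(cfg.inputs.get("migrate", cfg.outdir / "trajectories.csv"))]
    if stage == "afm":
        return [Path(cfg.inputs.get("afm", cfg.outdir / "force_curves")) / "manifest.csv"]
    if stage == "fa":
        return [
            Path(cfg.inputs.get("fa_marker", cfg.outdir / "fa_marker.tif")),
            Path(cfg.inputs.get("fa_actin", cfg.outdir / "fa_actin.tif")),
        ]
    if stage == "stats":
        return [Path(cfg.inputs.get("stats", cfg.outdir / "groups.csv"))]
    return []


def _preflight(cfg: RunConfig) -> None:
    """Fail before any computation if a requested stage lacks its inputs."""
    if "generate" in cfg.stages:
        return  # generate produces the defaults for every later stage
    missing = [
        f"{stage}: {p}"
        for stage in cfg.stages
        for p in _stage_input_paths(cfg, stage)
        if not p.exists()
    ]
    if missing:
        raise CellMechError("missing inputs for requested stages: " + "; ".join(missing))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the selected stages in dependency order; return the run report.

    The report (also written to ``run_report.json``) records the seed, the
    per-stage parameters and outputs, and package versions — enough to
    reproduce the run exactly.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    _preflight(cfg)
    report: dict = {
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "versions": {"cellmech": __version__, "numpy": np.__version__},
        "results": {},
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        log.info("running stage %s", stage)
        report["results"][stage] = _STAGE_FN[stage](cfg)
    (cfg.outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
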