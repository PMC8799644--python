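"""Orchestration: run configuration, stage execution, reports, manifests.

A run executes the requested stages in dependency order on synthetic or
user-supplied inputs, writes one TSV per result table plus a JSON
manifest echoing the resolved configuration, package version, seeds and
per-stage status.  The manifest suffices to re-run bit-identically.
"""

from __future__ import annotations

import copy
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import hydration as hyd
from . import interactions as inter
from . import metadynamics as metad
from . import msm as msm_mod
from . import solvation, surfaces, synthetic

__all__ = ["RunConfig", "run_pipeline", "build_report", "quartile_summary"]

_FLOAT_FMT = "%.10g"

DEFAULTS = {
    "output_dir": "mdresidence_run",
    "seed": 1,
    "stages": ["synth", "interactions", "surfaces", "exposure", "msm",
               "hydration", "metadyn", "report"],
    "stride_ns": 1.0,
    "criteria": {
        "hbond_distance": 2.5, "hbond_donor_angle_min": 120.0,
        "hbond_acceptor_angle_min": 90.0, "pication_distance": 4.5,
        "waterbridge_distance": 2.8, "waterbridge_donor_angle_min": 110.0,
        "waterbridge_acceptor_angle_min": 90.0, "saltbridge_distance": 4.0,
        "min_frequency": 0.15,
    },
    "surfaces": {"probe": 1.4, "n_points": 960, "grid_spacing": 0.15,
                 "n_frames": 3},
    "exposure": {"cutoff": 3.0, "n_frames": 10},
    "msm": {"tica_lag_frames": 10, "msm_lag_frames": 15, "n_dims": 2,
            "n_states": 3, "kmeans_seed": 2022, "k_override": None,
            "n_frames": 20000},
    "hydration": {"radius": 1.0, "shell": 10.0, "overlap_threshold": 0.5,
                  "probe_offset": 1.4},
    "metadyn": {"threshold": 15.0,
                "per_state": {"S1": [59, 60], "S2": [54, 60], "S3": [53, 60]}},
    "synth": {"interaction_frames": 100, "interaction_on_fraction": 0.95,
              "water_frames": 100, "water_bulk_noise": 2},
}


class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    def __init__(self, overrides: dict | None = None):
        self.data = copy.deepcopy(DEFAULTS)
        if overrides:
            self._merge(self.data, overrides, path="")

    @staticmethod
    def _merge(base: dict, over: dict, path: str):
        for key, value in over.items():
            where = f"{path}.{key}" if path else key
            if key not in base:
                raise ValueError(f"unknown configuration key: {where}")
            if isinstance(base[key], dict) and isinstance(value, dict) and \
                    key != "per_state":
                RunConfig._merge(base[key], value, where)
            else:
                base[key] = value

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        return cls(overrides)

    def __getitem__(self, key):
        return self.data[key]


def plot_ic_surface(projected, path, kt: float = 0.616, bins: int = 80):
    """Pseudo free-energy map -kT ln(density) over the first two ICs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    proj = np.asarray(projected, dtype=float)
    if proj.ndim != 2 or proj.shape[1] < 2:
        raise ValueError("need at least two projected dimensions")
    h, xe, ye = np.histogram2d(proj[:, 0], proj[:, 1], bins=bins,
                               density=True)
    with np.errstate(divide="ignore"):
        f = -kt * np.log(h.T)
    f -= np.nanmin(f[np.isfinite(f)])
    fig, ax = plt.subplots(figsize=(5, 4))
    m = ax.pcolormesh(xe, ye, np.where(np.isfinite(f), f, np.nan),
                      shading="auto", cmap="viridis")
    fig.colorbar(m, ax=ax, label="free energy (kcal/mol)")
    ax.set_xlabel("IC 1")
    ax.set_ylabel("IC 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def quartile_summary(values) -> dict:
    """Median, type-7 quartiles, 1.5*IQR whiskers and outliers."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisk_lo = float(inside.min()) if inside.size else float(q1)
    whisk_hi = float(inside.max()) if inside.size else float(q3)
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": whisk_lo, "whisker_high": whisk_hi,
            "n_outliers": int(outliers.size),
            "outliers": [float(x) for x in outliers]}


def build_report(stage_outputs: dict) -> dict:
    """Summary tables from stage outputs.

    Box-plot statistics for per-frame surface areas, the frequency table
    filtered at > 15%, a dissociation count table, and the pi-weighted
    hydration score table, whichever inputs are present.
    """
    if not stage_outputs:
        raise ValueError("no stage outputs to report on")
    report: dict = {}
    if "surfaces" in stage_outputs:
        df = stage_outputs["surfaces"]
        rows = []
        for col in ("sasa", "sapsa", "buried", "buried_polar"):
            s = quartile_summary(df[col])
            s.pop("outliers")
            rows.append({"quantity": col, **s})
        report["surface_summary"] = pd.DataFrame(rows)
    if "interactions" in stage_outputs:
        table = stage_outputs["interactions"]
        if len(table) == 0:
            report["interaction_note"] = "no interactions above threshold"
        report["interaction_table"] = table
    if "metadyn" in stage_outputs:
        report["dissociation_table"] = stage_outputs["metadyn"].table
    if "hydration_weighted" in stage_outputs:
        report["weighted_score_table"] = stage_outputs["hydration_weighted"]
    return report


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig | dict | None = None,
                 output_dir=None) -> dict:
    """Execute the configured stages end-to-end on synthetic fixtures.

    Returns a dict of in-memory stage outputs; TSV tables and the run
    manifest land in the output directory.  Any stage error aborts with
    the stage name; partial outputs are retained on disk.
    """
    if config is None:
        config = RunConfig()
    elif isinstance(config, dict):
        config = RunConfig(config)
    outdir = Path(output_dir or config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = {"config": config.data, "version": __version__, "stages": {}}
    outputs: dict = {}
    stages = list(config["stages"])

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
            manifest["stages"][name] = {"status": "ok",
                                        "seconds": round(time.perf_counter() - t0, 3)}
        except Exception as exc:
            manifest["stages"][name] = {"status": f"error: {exc}"}
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=2, default=str))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    synth_cfg = config["synth"]

    def stage_synth():
        outputs["kinetics"] = synthetic.gen_metastable_trajectory(
            synthetic.KineticEmissionSpec(n_frames=config["msm"]["n_frames"],
                                          seed=seed))
        traj, mask = synthetic.gen_interaction_trajectory(
            "hbond", synth_cfg["interaction_frames"],
            synth_cfg["interaction_on_fraction"], seed=seed)
        outputs["interaction_traj"] = (traj, mask)
        nwf = synth_cfg["water_frames"]
        planted = [
            {"center": (0.0, 0.0, 0.0), "occupancy": int(0.9 * nwf),
             "delta_g": 3.0},
            {"center": (3.0, 0.0, 0.0), "occupancy": int(0.8 * nwf),
             "delta_g": 2.0},
            {"center": (0.0, 6.0, 0.0), "occupancy": int(0.7 * nwf),
             "delta_g": -1.0},
        ]
        outputs["water_ensemble"] = synthetic.gen_water_ensemble(
            planted, n_frames=synth_cfg["water_frames"],
            bulk_noise_per_frame=synth_cfg["water_bulk_noise"], seed=seed)
        per_state = {k: tuple(v) for k, v in config["metadyn"]["per_state"].items()}
        outputs["cv_traces"] = synthetic.gen_dissociation_traces(per_state,
                                                                 seed=seed)
        trace_dir = outdir / "cv_traces"
        trace_dir.mkdir(exist_ok=True)
        for tr in outputs["cv_traces"]:
            metad.write_cv_trace(tr, trace_dir / f"{tr.replica_id}.tsv")

    def stage_interactions():
        traj, _ = outputs["interaction_traj"]
        crit_kwargs = {k: v for k, v in config["criteria"].items()
                       if k != "min_frequency"}
        criteria = inter.InteractionCriteria(**crit_kwargs)
        events = inter.trajectory_events(traj, criteria, kinds=("hbond",))
        table = inter.tabulate_frequencies(events, traj.n_frames,
                                           config["criteria"]["min_frequency"])
        outputs["interactions"] = table
        _write_tsv(table, outdir / "interaction_frequencies.tsv")

    def stage_surfaces():
        scfg = config["surfaces"]
        traj, _ = outputs["interaction_traj"]
        sub = traj.topology.select_role("ligand")
        rows = []
        for i in range(min(scfg["n_frames"], traj.n_frames)):
            s = surfaces.compute_surface_decomposition(
                traj.frame(i), sub, probe=scfg["probe"],
                n_points=scfg["n_points"], grid_spacing=scfg["grid_spacing"],
                frame_index=i)
            rows.append({"frame": i, "sasa": s.sasa, "molsa": s.molsa,
                         "psa": s.psa, "sapsa": s.sapsa, "buried": s.buried,
                         "buried_polar": s.buried_polar})
        df = pd.DataFrame(rows)
        outputs["surfaces"] = df
        _write_tsv(df, outdir / "surface_areas.tsv")

    def stage_exposure():
        ecfg = config["exposure"]
        base = synthetic.gen_exposure_fixture([2.5, 2.9, 4.5])
        xyz = np.repeat(base.coords[None], ecfg["n_frames"], axis=0)
        from .core import Trajectory
        traj = Trajectory(base, xyz, stride_ns=config["stride_ns"])
        traces = solvation.exposure_trace(traj, [("A", 1)],
                                          cutoff=ecfg["cutoff"])
        frames = []
        for key, tr in traces.items():
            df = tr.to_frame()
            df.insert(0, "residue", f"{key[2]}{key[1]}")
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        outputs["exposure"] = df
        _write_tsv(df, outdir / "exposure_trace.tsv")

    def stage_msm():
        mcfg = config["msm"]
        kin = outputs["kinetics"]
        result = msm_mod.msm_pipeline(
            kin["features"], tica_lag=mcfg["tica_lag_frames"],
            msm_lag=mcfg["msm_lag_frames"], n_states=mcfg["n_states"],
            k_override=mcfg["k_override"], n_dims=mcfg["n_dims"],
            seed=mcfg["kmeans_seed"])
        outputs["msm"] = result
        part = result["partition"]
        order = np.argsort(-part.pi)
        df = pd.DataFrame({"state": [f"S{i + 1}" for i in range(len(order))],
                           "pi": part.pi[order]})
        _write_tsv(df, outdir / "metastable_states.tsv")
        plot_ic_surface(result["projected"], outdir / "ic_surface.png")

    def stage_hydration():
        hcfg = config["hydration"]
        ens = outputs["water_ensemble"]
        min_occ = max(5, int(0.3 * ens["n_frames"]))
        sites = hyd.cluster_hydration_sites(
            ens["positions_by_frame"], radius=hcfg["radius"],
            shell_center=np.zeros(3), shell=hcfg["shell"],
            min_occupancy=min_occ)
        # transfer planted energies to recovered sites by nearest center
        truth = ens["sites"]
        for s in sites:
            d = [np.linalg.norm(s.center - t["center"]) for t in truth]
            s.delta_g = truth[int(np.argmin(d))]["delta_g"]
        lig_pos = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        lig_rad = np.full(2, 1.7)
        result = hyd.ligand_displacement_score(
            sites, lig_pos, lig_rad, probe_offset=hcfg["probe_offset"],
            inclusion_shell=hcfg["shell"],
            displaced_threshold=hcfg["overlap_threshold"])
        outputs["hydration"] = (sites, result)
        hyd.write_site_table(sites, outdir / "hydration_sites.tsv")
        if "msm" in outputs:
            pi = outputs["msm"]["partition"].pi
            scores = [result.score * (1.0 + 0.05 * i) for i in range(len(pi))]
            ws = hyd.weighted_state_score(scores, pi)
            df = pd.DataFrame({"state": [f"S{i + 1}" for i in range(len(pi))],
                               "score": ws.state_scores, "pi": ws.weights})
            df.loc[len(df)] = ["weighted_average", ws.weighted_average, 1.0]
            outputs["hydration_weighted"] = df
            _write_tsv(df, outdir / "weighted_scores.tsv")

    def stage_metadyn():
        table = metad.build_dissociation_table(
            outputs["cv_traces"], threshold=config["metadyn"]["threshold"])
        outputs["metadyn"] = table
        table.to_tsv(outdir / "dissociation_table.tsv")

    def stage_report():
        report = build_report(outputs)
        outputs["report"] = report
        for name, obj in report.items():
            if isinstance(obj, pd.DataFrame):
                _write_tsv(obj, outdir / f"report_{name}.tsv")

    runners = {"synth": stage_synth, "interactions": stage_interactions,
               "surfaces": stage_surfaces, "exposure": stage_exposure,
               "msm": stage_msm, "hydration": stage_hydration,
               "metadyn": stage_metadyn, "report": stage_report}
    for name in stages:
        if name not in runners:
            raise ValueError(f"unknown stage {name!r}")
        run_stage(name, runners[name])
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return outputs
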