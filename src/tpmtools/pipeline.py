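"""End-to-end pipeline: simulate fixtures, fit kinetics, cluster PIEs,
score attack geometry.

Every run is driven by a flat key-value :class:`RunConfig` (loadable from
YAML) and a single integer seed.  Each stage writes a result envelope JSON
recording the package version, parameters, and content digests of its
inputs; numeric payloads are byte-identical across reruns with the same
config and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as tio
from .conformers import analyze_pie_matrix, dendrogram_newick, fragment_pie_profile
from .geometry import (
    AtomMap,
    extract_reactive_frames,
    optimal_phi_fraction,
    trajectory_geometry,
)
from .kinetics import KineticDataset, MMParams, fit_c1, fit_mm
from .synth import (
    GeomSpec,
    KineticDesign,
    PIEClusterSpec,
    TruncNormal,
    gen_dual_mm_rates,
    gen_mm_rates,
    gen_pie_matrix,
    gen_trajectory,
)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("tpmtools")

STAGES = ("simulate", "fit_kinetics", "cluster_pie", "geometry")


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration for a pipeline run.  Unset input paths default to
    the corresponding simulate-stage outputs inside ``out_dir``."""

    stages: tuple[str, ...] = STAGES
    out_dir: str = "tpmtools_out"
    seed: int = 0
    log_level: str = "INFO"
    # fit_kinetics
    kinetics_input: str | None = None
    kinetics_model: str = "mm"  # "mm" | "dual"
    gss_km: float = 209.0
    gss_vmax: float = 392.0
    h2s_km: float = 1978.0
    h2s_vmax: float = 5.37
    # cluster_pie
    cluster_input: str | None = None
    cluster_k: int | None = None
    cluster_cut: float | None = None
    alpha: float = 0.05
    # geometry
    geometry_input: str | None = None
    d_max: float = 4.0
    theta_min: float = 150.0
    theta_max: float = 180.0
    phi_min: float = 100.0
    phi_max: float = 180.0
    bin_width: float = 10.0
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}; valid stages are {list(STAGES)}")
        if self.kinetics_model not in ("mm", "dual"):
            raise ValueError(f"kinetics_model must be 'mm' or 'dual', got {self.kinetics_model!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


# demo ground truth: assay-scale kinetic parameters (uM, nmol/min/mg) and
# rate noise at 5% of Vmax
_DEMO_MM_TRUTH = MMParams(km=331.0, vmax=260.0)
_DEMO_DUAL_GSS = MMParams(km=209.0, vmax=392.0)
_DEMO_DUAL_H2S = MMParams(km=1978.0, vmax=5.37)
_DEMO_C1_UM = 50.0
_DEMO_N_FRAMES = 2000


def _demo_pie_spec(seed: int) -> PIEClusterSpec:
    """200 conformations in 9 planted clusters, 4 of them equally strong:
    distinct fragment profiles with a shared total near -400 kJ/mol, the
    rest clearly weaker."""
    n_frag = 15
    rng = np.random.default_rng(seed)
    profiles = []
    strong_total, weak_totals = -400.0, (-260.0, -220.0, -180.0, -140.0, -100.0)
    for c in range(4):
        base = rng.uniform(-30.0, 30.0, size=n_frag)
        base += (strong_total - base.sum()) / n_frag
        profiles.append(tuple(base))
    for total in weak_totals:
        base = rng.uniform(-30.0, 30.0, size=n_frag)
        base += (total - base.sum()) / n_frag
        profiles.append(tuple(base))
    sizes = (30, 25, 25, 20, 20, 20, 20, 20, 20)
    return PIEClusterSpec(
        n_fragments=n_frag,
        cluster_sizes=sizes,
        cluster_mean_profiles=tuple(profiles),
        within_sd=1.5,
        seed=seed,
    )


def _stage_simulate(cfg: RunConfig, out: Path) -> tio.ResultEnvelope:
    design = KineticDesign(noise_sd=0.05 * _DEMO_MM_TRUTH.vmax, seed=cfg.seed)
    kin = gen_mm_rates(_DEMO_MM_TRUTH, design, condition="Na2S2")
    tio.write_kinetic_csv(kin, out / "kinetic_mm.csv")

    dual_design = replace(design, seed=cfg.seed + 1, noise_sd=0.0)
    dual = gen_dual_mm_rates(_DEMO_DUAL_GSS, _DEMO_DUAL_H2S, _DEMO_C1_UM, dual_design,
                             condition="Na2S+GSH")
    tio.write_kinetic_csv(dual, out / "kinetic_dual.csv")

    pie, labels = gen_pie_matrix(_demo_pie_spec(cfg.seed + 2))
    tio.write_pie_tsv(pie, out / "pie.tsv")

    for name, phi_mean, seed in (
        ("traj_unhindered.xyz", 135.0, cfg.seed + 3),
        ("traj_hindered.xyz", 75.0, cfg.seed + 4),
    ):
        spec = GeomSpec(
            n_frames=_DEMO_N_FRAMES,
            d_dist=TruncNormal(3.5, 0.4),
            theta_dist=TruncNormal(160.0, 8.0),
            phi_dist=TruncNormal(phi_mean, 30.0),
            seed=seed,
        )
        tio.write_xyz(gen_trajectory(spec), out / name)

    truth = {
        "mm_truth": {"km": _DEMO_MM_TRUTH.km, "vmax": _DEMO_MM_TRUTH.vmax},
        "dual_truth": {
            "gss": {"km": _DEMO_DUAL_GSS.km, "vmax": _DEMO_DUAL_GSS.vmax},
            "h2s": {"km": _DEMO_DUAL_H2S.km, "vmax": _DEMO_DUAL_H2S.vmax},
            "c1": _DEMO_C1_UM,
        },
        "pie_true_labels": labels.tolist(),
        "phi_means": {"traj_unhindered.xyz": 135.0, "traj_hindered.xyz": 75.0},
        "seed": cfg.seed,
    }
    env = tio.ResultEnvelope(
        stage="simulate",
        version=__version__,
        input_digests={},
        parameters={"seed": cfg.seed, "noise_sd": design.noise_sd,
                    "design_uM": list(design.concentrations), "n_rep": design.n_rep},
        payload=truth,
    )
    tio.write_envelope(env, out / "simulate.envelope.json")
    return env


def _stage_fit_kinetics(cfg: RunConfig, out: Path) -> tio.ResultEnvelope:
    if cfg.kinetics_model == "mm":
        path = Path(cfg.kinetics_input or out / "kinetic_mm.csv")
        data = tio.read_kinetic_csv(path)
        fit = fit_mm(data)
        payload = {
            "model": "mm",
            "km_uM": fit.km,
            "vmax_nmol_min_mg": fit.vmax,
            "efficiency_L_min_g": fit.efficiency,
            "residual_ss": fit.residual_ss,
            "converged": fit.converged,
            "n_obs": fit.n_obs,
            "standard_errors": fit.standard_errors,
        }
    else:
        path = Path(cfg.kinetics_input or out / "kinetic_dual.csv")
        data = tio.read_kinetic_csv(path)
        gss = MMParams(cfg.gss_km, cfg.gss_vmax)
        h2s = MMParams(cfg.h2s_km, cfg.h2s_vmax)
        fit = fit_c1(data, gss, h2s)
        payload = {
            "model": "dual",
            "c1_uM": fit.model.c1,
            "gss": {"km": gss.km, "vmax": gss.vmax},
            "h2s": {"km": h2s.km, "vmax": h2s.vmax},
            "residual_ss": fit.residual_ss,
            "converged": fit.converged,
        }
    env = tio.ResultEnvelope(
        stage="fit_kinetics",
        version=__version__,
        input_digests={str(path): tio.sha256_digest(path)},
        parameters={"model": cfg.kinetics_model},
        payload=payload,
    )
    tio.write_envelope(env, out / "fit_kinetics.envelope.json")
    return env


def _read_pie_any(path: Path):
    with open(path) as fh:
        header = fh.readline()
    cols = header.rstrip("\n").split("\t")
    if cols[:3] == ["conformation_id", "fragment_label", "pie_kj_mol"]:
        return tio.read_pie_long(path)
    return tio.read_pie_tsv(path)


def _stage_cluster_pie(cfg: RunConfig, out: Path) -> tio.ResultEnvelope:
    path = Path(cfg.cluster_input or out / "pie.tsv")
    m = _read_pie_any(path)
    result, table = analyze_pie_matrix(
        m, n_clusters=cfg.cluster_k, cut_height=cfg.cluster_cut, alpha=cfg.alpha
    )
    (out / "dendrogram.nwk").write_text(
        dendrogram_newick(result, leaf_names=[str(i) for i in m.conformation_ids]) + "\n"
    )
    profile = fragment_pie_profile(m)
    payload = {
        "labels": result.labels.tolist(),
        "per_cluster_stats": result.per_cluster_stats,
        "letters": {str(k): v for k, v in (result.letters or {}).items()},
        "stable_ids": result.stable_ids,
        "tukey_table": table,
        "fragment_profile_kj_mol": profile,
        "linkage_info": result.linkage_info,
    }
    if cfg.plots:
        from .plots import cluster_box_plot

        cluster_box_plot(result, out / "cluster_totals.png")
    env = tio.ResultEnvelope(
        stage="cluster_pie",
        version=__version__,
        input_digests={str(path): tio.sha256_digest(path)},
        parameters={"k": cfg.cluster_k, "cut": cfg.cluster_cut, "alpha": cfg.alpha},
        payload=payload,
    )
    tio.write_envelope(env, out / "cluster_pie.envelope.json")
    return env


def _geometry_table(path: Path, atom_map: AtomMap):
    if path.suffix.lower() in (".tsv", ".csv"):
        import pandas as pd

        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        geo = pd.read_csv(path, sep=sep)
        required = {"d1_A", "theta_deg", "phi_deg"}
        if not required.issubset(geo.columns):
            raise ValueError(f"{path}: geometry table needs columns {sorted(required)}")
        return geo
    frames = tio.read_xyz(path)
    return trajectory_geometry(frames.coords, atom_map)


def _stage_geometry(cfg: RunConfig, out: Path) -> tio.ResultEnvelope:
    paths = (
        [Path(cfg.geometry_input)]
        if cfg.geometry_input
        else [out / "traj_unhindered.xyz", out / "traj_hindered.xyz"]
    )
    atom_map = AtomMap(s_sam=0, c_sam=1, nucleophile=2, substituent=3)
    payload, digests = {}, {}
    for path in paths:
        geo = _geometry_table(path, atom_map)
        subset = extract_reactive_frames(
            geo, d_max=cfg.d_max, theta_range=(cfg.theta_min, cfg.theta_max)
        )
        summary = optimal_phi_fraction(
            subset,
            n_frames_total=len(geo),
            phi_range=(cfg.phi_min, cfg.phi_max),
            bin_width=cfg.bin_width,
        )
        key = path.stem
        payload[key] = {
            "n_frames_total": summary.n_frames_total,
            "n_extracted": summary.n_extracted,
            "n_optimal": summary.n_optimal,
            "optimal_fraction_pct": summary.optimal_fraction,
            "phi_bin_edges_deg": summary.phi_bin_edges,
            "phi_counts": summary.phi_counts,
        }
        digests[str(path)] = tio.sha256_digest(path)
        hist_path = out / f"{key}.phi_histogram.csv"
        with open(hist_path, "w") as fh:
            fh.write("bin_lo_deg,bin_hi_deg,count\n")
            for lo, hi, c in zip(
                summary.phi_bin_edges[:-1], summary.phi_bin_edges[1:], summary.phi_counts
            ):
                fh.write(f"{lo:g},{hi:g},{c}\n")
        if cfg.plots:
            from .plots import phi_histogram_plot

            phi_histogram_plot(summary, out / f"{key}.phi_histogram.png")
    env = tio.ResultEnvelope(
        stage="geometry",
        version=__version__,
        input_digests=digests,
        parameters={
            "d_max_A": cfg.d_max,
            "theta_range_deg": [cfg.theta_min, cfg.theta_max],
            "phi_range_deg": [cfg.phi_min, cfg.phi_max],
            "bin_width_deg": cfg.bin_width,
        },
        payload=payload,
    )
    tio.write_envelope(env, out / "geometry.envelope.json")
    return env


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit_kinetics": _stage_fit_kinetics,
    "cluster_pie": _stage_cluster_pie,
    "geometry": _stage_geometry,
}


def run_pipeline(cfg: RunConfig) -> dict[str, tio.ResultEnvelope]:
    """Execute the requested stages in canonical order.

    The config is validated before any work; rerunning with the same config
    and seed reproduces identical numeric payloads.
    """
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("tpmtools %s | seed=%d | stages=%s | out=%s",
             __version__, cfg.seed, ",".join(cfg.stages), out)
    results: dict[str, tio.ResultEnvelope] = {}
    for stage in STAGES:
        if stage in cfg.stages:
            log.info("running stage %s", stage)
            results[stage] = _STAGE_FUNCS[stage](cfg, out)
    return results
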