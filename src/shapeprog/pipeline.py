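"""End-to-end scenarios: program a cap lattice, relax, quantify the shape.

``simulate_scenario`` builds the double-layer cap, assembles a spontaneous
strain field per stage (an analytic preset or a measured profile mapped onto
the lattice), relaxes quasi-statically through each stage, sections the
final state along the two symmetry planes (the plane through the two outDVB
origins, "across-DVB", and the orthogonal one, "along-DVB"), and reports
curvature-change profiles on 40 normalised positions together with residual
strain summaries.  ``extract_strains`` runs the measurement stack on a stage
pair of segmented networks; ``thickness_sweep`` repeats a scenario for
several h/R to probe bending stiffness.  Every run writes a manifest with
all parameters so outputs are reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import curves as cv
from .cap_lattice import CapLattice, build_cap_lattice, compute_cap_angle
from .deformation import decompose_inplane, deformation_field, residual_strain
from .observed_strain import map_profile_to_lattice, measure_stage, strain_profiles
from .relaxer import RelaxConfig, run_program
from .strain_frames import (RegionalFrame, assemble_strain_tensor,
                            assign_regions_and_frames, field_from_profile,
                            preset_patterns, read_profile_csv)
from .topo_coords import TopoChart, build_chart, find_DVB_origin, find_outDVB_origin

__all__ = ["ScenarioConfig", "ScenarioResult", "simulate_scenario",
           "extract_strains", "thickness_sweep", "SCENARIO_COLUMNS"]

# which profile columns feed (iso, aniso) for the single-behaviour scenarios
SCENARIO_COLUMNS = {
    "rearrangement": (None, "lambda_R"),
    "elongation": (None, "lambda_Q"),
    "area": ("lambda_A", None),
    "total": ("lambda_A", "lambda_total"),
}


@dataclass
class ScenarioConfig:
    """Geometry, strain source and relaxation settings for one scenario."""

    R: float = 77.66                  # outer radius of curvature (μm)
    h_over_R: float = 0.1             # double-layer thickness ratio
    refine_factor: int = 10           # icosphere subdivision
    theta_M: float | None = None      # cap half-angle (default: tissue value)
    w_DV: float = 0.0                 # boundary-band width (0: radial frame)
    replicates: int = 1               # cap placements averaged
    seed: int = 0                     # replicate-axis randomness
    preset: str | None = "uniform"    # analytic pattern name
    preset_params: dict = field(default_factory=dict)
    profile_csv: str | None = None    # tabulated (region, coordinate) profile
    scenario: str | None = None       # single-behaviour scenario on a profile
    T_F: int = 5
    step_factor: float = 0.01
    tolerance: float = 1e-9
    max_iterations: int = 5_000_000
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.h_over_R < 0.5:
            raise ValueError(f"h/R must be in (0, 0.5), got {self.h_over_R}")
        if self.scenario is not None and self.scenario not in SCENARIO_COLUMNS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {sorted(SCENARIO_COLUMNS)}")


@dataclass
class ScenarioResult:
    trajectory: list
    frame: RegionalFrame
    dkappa: dict                      # plane -> curvature-change DataFrame
    residual: pd.DataFrame
    reports: list
    manifest: dict


def _strain_field(lattice: CapLattice, frame: RegionalFrame, cfg: ScenarioConfig):
    if cfg.profile_csv is not None:
        profile = read_profile_csv(cfg.profile_csv)
        if cfg.scenario is not None:
            iso_col, aniso_col = SCENARIO_COLUMNS[cfg.scenario]
            rename = {"lambda_iso": "lambda_A", "lambda_aniso": "lambda_total"}
            prof = profile.rename(columns=rename)
            prof["lambda_R"] = prof.get("lambda_R", prof.get("lambda_total", 1.0))
            prof["lambda_Q"] = prof.get("lambda_Q", 1.0)
            return map_profile_to_lattice(prof, frame, iso_col, aniso_col)
        return field_from_profile(profile, frame)
    return preset_patterns(cfg.preset or "uniform", frame, **cfg.preset_params)


def simulate_scenario(cfg: ScenarioConfig) -> ScenarioResult:
    """Run one programmed-strain scenario end to end (see module docstring).

    With ``replicates > 1`` the cap is cut from different sphere regions
    (seeded axes) and the curvature-change profiles are averaged; lattices
    and residual fields are reported for the first replicate.
    """
    rng = np.random.default_rng(cfg.seed)
    relax_cfg = RelaxConfig(step_factor=cfg.step_factor, tolerance=cfg.tolerance,
                            T_F=cfg.T_F, max_iterations=cfg.max_iterations)
    theta_M = cfg.theta_M if cfg.theta_M is not None else compute_cap_angle(15.0, 59.77, cfg.R)
    dk_acc: dict[str, list[pd.DataFrame]] = {"across": [], "along": []}
    first: dict = {}
    for rep in range(cfg.replicates):
        axis = None if rep == 0 else rng.normal(size=3)
        lattice = build_cap_lattice(cfg.refine_factor, cfg.R, theta_M,
                                    cfg.h_over_R, axis=axis)
        frame = assign_regions_and_frames(lattice, cfg.w_DV)
        strain = _strain_field(lattice, frame, cfg)
        trajectory, reports = run_program(lattice, strain, relax_cfg)
        # across-DVB: the plane containing the origins O_D, O_V (xz);
        # along-DVB: the orthogonal vertical plane (yz)
        for plane_name, plane in (("across", "xz"), ("along", "yz")):
            sec0 = cv.section_lattice(trajectory[0], plane)
            sec1 = cv.section_lattice(trajectory[-1], plane)
            a0, a1 = cv.align_curves([sec0, sec1])
            dk = cv.curvature_change(a0.s, cv.curvature(a0), a1.s, cv.curvature(a1))
            dk_acc[plane_name].append(dk)
        if rep == 0:
            F = deformation_field(lattice)
            res, iso, aniso = residual_strain(F.F, strain)
            Fi, Fa = decompose_inplane(F.F, frame, warn_offdiag=False)
            first = {
                "trajectory": trajectory, "frame": frame, "reports": reports,
                "residual": pd.DataFrame({
                    "vertex": np.arange(lattice.n_vertices),
                    "layer": lattice.layer,
                    "region": frame.region,
                    "coord": frame.coord,
                    "F_iso": Fi, "F_aniso": Fa,
                    "lambda_res_iso": iso, "lambda_res_aniso": aniso,
                }),
            }
    dkappa = {name: _average_frames(frames) for name, frames in dk_acc.items()}
    manifest = {"config": {k: v for k, v in asdict(cfg).items()},
                "theta_M_deg": float(np.degrees(theta_M)),
                "iterations": [r.iterations for r in first["reports"]],
                "converged": [bool(r.converged) for r in first["reports"]],
                "final_energy": first["reports"][-1].final_energy if first["reports"] else 0.0}
    result = ScenarioResult(first["trajectory"], first["frame"], dkappa,
                            first["residual"], first["reports"], manifest)
    if cfg.outdir is not None:
        _write_outputs(result, cfg)
    return result


def _average_frames(frames: list[pd.DataFrame]) -> pd.DataFrame:
    if len(frames) == 1:
        return frames[0]
    out = frames[0].copy()
    for col in out.columns:
        if col != "position":
            out[col] = np.mean([f[col].to_numpy() for f in frames], axis=0)
    return out


def _write_outputs(result: ScenarioResult, cfg: ScenarioConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for T, lat in enumerate(result.trajectory):
        lat.save_vtk(out / f"lattice_T{T}.vtk")
    for name, dk in result.dkappa.items():
        dk.to_csv(out / f"dkappa_{name}.csv", index=False)
    result.residual.to_csv(out / "residual_strain.csv", index=False)
    energy_log = pd.DataFrame({
        "stage": np.arange(1, len(result.reports) + 1),
        "iterations": [r.iterations for r in result.reports],
        "converged": [r.converged for r in result.reports],
        "final_energy": [r.final_energy for r in result.reports],
    })
    energy_log.to_csv(out / "relaxation_log.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Measurement pipeline on segmented stage pairs
# ---------------------------------------------------------------------------

def _region_charts(net) -> dict[str, TopoChart]:
    """Charts for the regions present in a network's labels.

    Labels 'outDVB-D' / 'outDVB-V' / 'DVB' get the tissue origins; networks
    without a DVB label are charted as a single radial region whose origin is
    the cell maximally distant from the margin.
    """
    labels = set(str(r) for r in net.region)
    g = net.adjacency()
    charts: dict[str, TopoChart] = {}
    dvb_mask = np.array([str(r) == "DVB" for r in net.region])
    if not dvb_mask.any():
        from .topo_coords import _margin_cells, _multi_source_bfs

        mask = np.ones(net.n_cells, dtype=bool)
        margin = _margin_cells(net, mask)
        dist = _multi_source_bfs(g, [int(c) for c in margin])
        dmax = max(dist.values())
        far = sorted(c for c, d in dist.items() if d == dmax)
        target = net.centroids()[far].mean(axis=0)
        d = np.linalg.norm(net.centroids()[far] - target, axis=1)
        origin = int(np.asarray(far)[np.argmin(d)])
        charts["outDVB"] = build_chart(net, [origin], mask, graph=g)
        return charts
    missing = {"outDVB-D", "outDVB-V"} - labels
    if missing:
        raise ValueError(f"network lacks region label(s) {sorted(missing)}")
    origins = {}
    for name in ("outDVB-D", "outDVB-V"):
        mask = np.array([str(r) == name for r in net.region])
        origins[name] = find_outDVB_origin(net, mask, dvb_mask, graph=g)
        charts[name] = build_chart(net, [origins[name]], mask, graph=g)
    line = find_DVB_origin(net, dvb_mask, "larval",
                           center_D=origins["outDVB-D"],
                           center_V=origins["outDVB-V"], graph=g)
    charts["DVB"] = build_chart(net, line, dvb_mask, graph=g)
    return charts


def extract_strains(net_t, net_later, stages: tuple[str, str] = ("t", "t+dt")
                    ) -> tuple[pd.DataFrame, dict]:
    """Observed-strain profiles for a stage pair of cell networks.

    Runs origin finding, topological charting and per-ring measurement on
    both stages, matches bins by cumulative count, and returns the profile
    table (one block per region) plus a QC dict (dropped bins, off-diagonal
    elongation warnings).
    """
    qc: dict = {"warnings": []}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        charts_t = _region_charts(net_t)
        charts_l = _region_charts(net_later)
        blocks = []
        for name, chart_t in charts_t.items():
            if name not in charts_l:
                raise ValueError(f"later stage lacks region {name!r}")
            rings_t = measure_stage(net_t, chart_t)
            rings_l = measure_stage(net_later, charts_l[name])
            blocks.append(strain_profiles(rings_t, rings_l, region=name, stages=stages))
    qc["warnings"] = sorted({str(w.message) for w in caught})
    profile = pd.concat(blocks, ignore_index=True)
    qc["dropped_bins"] = int(profile["lambda_A"].isna().sum())
    return profile, qc


def thickness_sweep(cfg: ScenarioConfig, values=(0.05, 0.1, 0.15)) -> pd.DataFrame:
    """Repeat a scenario at several h/R; thicker shells bend less for the
    same anisotropic program."""
    values = list(values)
    if len(values) < 2:
        raise ValueError("a sweep needs at least two h/R values")
    rows = []
    for h in values:
        c = ScenarioConfig(**{**asdict(cfg), "h_over_R": h, "outdir": None})
        res = simulate_scenario(c)
        for plane, dk in res.dkappa.items():
            d = dk.copy()
            d["h_over_R"] = h
            d["plane"] = plane
            rows.append(d)
    return pd.concat(rows, ignore_index=True)
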