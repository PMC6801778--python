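"""End-to-end orchestration: config, reports, and cross-system comparison.

A run is described by a YAML config (validated through pydantic models),
executes the requested analysis stages in dependency order over one or more
systems (loaded from files or generated synthetically), and emits a
``report.json`` plus CSV tables/distributions. Outputs are deterministic
given identical config, inputs and seed; every file carries a provenance
header (config hash, package version, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from . import diffusion as dif
from . import membrane_props as mem
from . import protein_geometry as geo
from . import synthetic_data as synth
from . import traj_core as core

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SystemConfig", "Report", "run_analysis",
           "compare_systems", "load_config"]


# ---------------------------------------------------------------------------
# Config schema
# ---------------------------------------------------------------------------

class SelectionConfig(BaseModel):
    phosphorus: str = "element P and name P"
    chain_carbons: str = ("resname POPC PSM POPE POPS and name " +
                          " ".join(f"C{k}" for k in range(2, 16)))
    g_domain: str = "name CA and resid 15:185"
    switch_regions: str = "name CA and resid 50:60 or name CA and resid 75:92"
    anchor: str = "resname GGA and element C"


class SystemConfig(BaseModel):
    name: str
    # either file inputs ...
    topology: str | None = None
    trajectory: str | None = None
    time_step: float | None = None
    # ... or synthetic specs (dicts of BilayerSpec/TrackSpec/AnchorSpec fields)
    bilayer: dict | None = None
    tracks: dict | None = None
    protein: dict | None = None
    lipids_per_leaflet: int | None = None


class RunConfig(BaseModel):
    seed: int = 0
    outdir: str = "memanchor_out"
    analyses: list[str] = Field(default_factory=lambda: ["membrane", "diffusion", "geometry"])
    selections: SelectionConfig = Field(default_factory=SelectionConfig)
    lag: float = 1.0                  # ns, JDA lag
    jda_components: str | int = "auto"
    local_order_cutoff: float = 0.5   # nm
    grid_spacing: float = 0.2         # nm
    depth_bin_width: float = 0.05     # nm
    neighbor_cutoff: float = 1.0      # nm
    n_blocks: int = 5
    systems: list[SystemConfig] = Field(default_factory=list)


class ValueWithSd(BaseModel):
    value: float
    sd: float | None = None
    units: str = ""


class DiffusionRow(BaseModel):
    species: str
    d: ValueWithSd


class MembraneBlock(BaseModel):
    thickness: ValueWithSd
    area_per_lipid: ValueWithSd
    order: ValueWithSd


class GeometryBlock(BaseModel):
    depth: ValueWithSd
    depth_modality: int
    theta: ValueWithSd
    omega: ValueWithSd
    radius_of_gyration: ValueWithSd
    label_fractions: dict[str, float]


class SystemReport(BaseModel):
    name: str
    membrane: MembraneBlock | None = None
    diffusion: list[DiffusionRow] = Field(default_factory=list)
    geometry: GeometryBlock | None = None


class Provenance(BaseModel):
    config_hash: str
    package_version: str
    seed: int


class Report(BaseModel):
    systems: list[SystemReport]
    provenance: Provenance


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.model_validate(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _materialize(sys_cfg: SystemConfig, seed: int):
    """Return (membrane_traj, tracks, protein_traj, lipids_per_leaflet)."""
    bilayer = tracks = protein_traj = None
    lipids_per_leaflet = sys_cfg.lipids_per_leaflet
    if sys_cfg.topology is not None:
        traj = core.load_trajectory(sys_cfg.topology, sys_cfg.trajectory,
                                    time_step=sys_cfg.time_step)
        bilayer = protein_traj = traj
    if sys_cfg.bilayer is not None:
        spec = synth.BilayerSpec(**{"seed": seed, **sys_cfg.bilayer})
        bilayer = synth.make_bilayer(spec)
        lipids_per_leaflet = lipids_per_leaflet or spec.n_lipids_per_leaflet
    if sys_cfg.tracks is not None:
        tr = dict(sys_cfg.tracks)
        pops = [(p["species"], p["d"], p["fraction"]) for p in tr.pop("populations")] \
            if "populations" in tr else None
        spec = synth.TrackSpec(**{"seed": seed + 1,
                                  **({"populations": pops} if pops else {}), **tr})
        wrapped, _truth = synth.make_brownian_tracks(spec)
        atoms = core.select(wrapped.topology, "element P")
        tracks = dif.unwrap_tracks(wrapped, atoms)
    if sys_cfg.protein is not None:
        if bilayer is None:
            raise ValueError(f"system {sys_cfg.name}: protein spec needs a bilayer")
        spec = synth.AnchorSpec(**{"seed": seed + 2, **sys_cfg.protein})
        protein_traj = synth.make_anchored_protein(spec, bilayer)
    return bilayer, tracks, protein_traj, lipids_per_leaflet


def _membrane_stage(traj, cfg: RunConfig, lipids_per_leaflet):
    sel = cfg.selections
    phosphorus = core.select(traj.topology, sel.phosphorus)
    carbons = core.select(traj.topology, sel.chain_carbons)
    summary = mem.membrane_summary(traj, phosphorus, carbons,
                                   lipids_per_leaflet, n_blocks=cfg.n_blocks)
    return MembraneBlock(
        thickness=ValueWithSd(value=summary.thickness, sd=summary.thickness_sd, units="nm"),
        area_per_lipid=ValueWithSd(value=summary.area_per_lipid,
                                   sd=summary.area_per_lipid_sd, units="nm^2"),
        order=ValueWithSd(value=summary.order, sd=summary.order_sd, units=""),
    )


def _diffusion_stage(tracks, cfg: RunConfig):
    rows = []
    for species in sorted(set(tracks.labels)):
        sel = np.array([lbl == species for lbl in tracks.labels])
        sub = dif.TrackSet(tracks.positions[sel], tracks.dt,
                           [l for l in tracks.labels if l == species])
        fit = dif.jda_with_uncertainty(sub, cfg.lag, cfg.jda_components,
                                       n_segments=cfg.n_blocks, seed=cfg.seed)
        sd = fit.d_uncertainty[0] if fit.d_uncertainty else None
        rows.append(DiffusionRow(
            species=species,
            d=ValueWithSd(value=fit.d, sd=None if sd is None or np.isnan(sd) else sd,
                          units="1e-7 cm^2/s")))
    return rows


def _geometry_stage(traj, cfg: RunConfig):
    sel = cfg.selections
    top = traj.topology
    phosphorus = core.select(top, sel.phosphorus)
    anchor = core.select(top, sel.anchor)
    g_domain = core.select(top, sel.g_domain)
    switch = core.select(top, sel.switch_regions)
    depths = np.array([
        geo.anchor_insertion_depth(f, anchor, phosphorus, cfg.neighbor_cutoff)
        for f in traj.frames])
    dist = geo.depth_distribution(depths, cfg.depth_bin_width, seed=cfg.seed) \
        if len(depths) >= 100 else None
    orient = geo.orientation_series(traj, g_domain, switch, anchor)
    rgyr = np.array([geo.radius_of_gyration(f, top, g_domain) for f in traj.frames])
    label_fractions = {lbl: orient.labels.count(lbl) / len(orient.labels)
                       for lbl in ("endo", "exo", "intermediate")}
    return GeometryBlock(
        depth=ValueWithSd(value=float(depths.mean()), sd=float(depths.std(ddof=0)), units="nm"),
        depth_modality=dist.modality if dist else 1,
        theta=ValueWithSd(value=float(orient.theta.mean()),
                          sd=float(orient.theta.std(ddof=0)), units="deg"),
        omega=ValueWithSd(value=float(orient.omega.mean()),
                          sd=float(orient.omega.std(ddof=0)), units="deg"),
        radius_of_gyration=ValueWithSd(value=float(rgyr.mean()),
                                       sd=float(rgyr.std(ddof=0)), units="nm"),
        label_fractions=label_fractions,
    ), depths, orient


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------

def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, provenance: Provenance) -> None:
    with open(path, "w") as fh:
        fh.write(f"# memanchor {provenance.package_version} "
                 f"config={provenance.config_hash} seed={provenance.seed}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def run_analysis(config: RunConfig) -> Report:
    """Execute all requested stages for every system; write report + CSVs."""
    outdir = Path(config.outdir)
    provenance = Provenance(config_hash=_config_hash(config),
                            package_version=__version__, seed=config.seed)
    written: list[Path] = []

    def _write_tracked(df, path):
        _write_csv(df, path, provenance)
        written.append(path)

    try:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tables").mkdir(exist_ok=True)
        (outdir / "distributions").mkdir(exist_ok=True)
        sys_reports = []
        mem_rows, dif_rows = [], []
        for sys_cfg in config.systems:
            t0 = time.perf_counter()
            logger.info("system %s: materializing inputs", sys_cfg.name)
            try:
                bilayer, tracks, protein_traj, lpl = _materialize(sys_cfg, config.seed)
                rep = SystemReport(name=sys_cfg.name)
                if "membrane" in config.analyses and bilayer is not None and lpl:
                    rep.membrane = _membrane_stage(bilayer, config, lpl)
                    mem_rows.append({
                        "system": sys_cfg.name,
                        "thickness_nm": rep.membrane.thickness.value,
                        "thickness_sd": rep.membrane.thickness.sd,
                        "apl_nm2": rep.membrane.area_per_lipid.value,
                        "apl_sd": rep.membrane.area_per_lipid.sd,
                        "order": rep.membrane.order.value,
                        "order_sd": rep.membrane.order.sd,
                    })
                if "diffusion" in config.analyses and tracks is not None:
                    rep.diffusion = _diffusion_stage(tracks, config)
                    for row in rep.diffusion:
                        dif_rows.append({"system": sys_cfg.name, "species": row.species,
                                         "d_1e-7_cm2_s": row.d.value, "d_sd": row.d.sd})
                if "geometry" in config.analyses and protein_traj is not None \
                        and sys_cfg.protein is not None:
                    rep.geometry, depths, orient = _geometry_stage(protein_traj, config)
                    df = pd.DataFrame({"time_ns": protein_traj.times,
                                       "depth_nm": depths,
                                       "theta_deg": orient.theta,
                                       "omega_deg": orient.omega,
                                       "label": orient.labels})
                    _write_tracked(df, outdir / "distributions" / f"{sys_cfg.name}_geometry.csv")
                sys_reports.append(rep)
                logger.info("system %s done in %.2f s", sys_cfg.name,
                            time.perf_counter() - t0)
            except Exception as exc:
                raise RuntimeError(f"stage failure in system {sys_cfg.name!r}: {exc}") from exc
        if mem_rows:
            _write_tracked(pd.DataFrame(mem_rows), outdir / "tables" / "membrane.csv")
        if dif_rows:
            _write_tracked(pd.DataFrame(dif_rows), outdir / "tables" / "diffusion.csv")
        report = Report(systems=sys_reports, provenance=provenance)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report.model_dump(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    except Exception:
        # remove the files this run created so a failure leaves no partial outputs
        for path in written:
            path.unlink(missing_ok=True)
        raise


def compare_systems(reports: list[SystemReport]) -> pd.DataFrame:
    """Pairwise per-species diffusion ratios with propagated uncertainty.

    First-order propagation for r = a/b: sd_r = r * sqrt((sd_a/a)^2 +
    (sd_b/b)^2); ratios reported to 2 significant figures. Species missing
    from either system yield NA cells.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    rows = []
    for i, ra in enumerate(reports):
        for rb in reports[i + 1:]:
            species_a = {r.species: r.d for r in ra.diffusion}
            species_b = {r.species: r.d for r in rb.diffusion}
            for sp in sorted(set(species_a) | set(species_b)):
                if sp not in species_a or sp not in species_b or \
                        species_b[sp].value == 0:
                    rows.append({"system_a": ra.name, "system_b": rb.name,
                                 "species": sp, "ratio": np.nan, "ratio_sd": np.nan})
                    continue
                a, b = species_a[sp], species_b[sp]
                r = a.value / b.value
                if a.sd is not None and b.sd is not None:
                    sd = abs(r) * np.sqrt((a.sd / a.value) ** 2 + (b.sd / b.value) ** 2)
                else:
                    sd = np.nan
                rows.append({"system_a": ra.name, "system_b": rb.name, "species": sp,
                             "ratio": dif.round_sig(r, 2),
                             "ratio_sd": dif.round_sig(sd, 2) if np.isfinite(sd) else np.nan})
    return pd.DataFrame(rows)
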