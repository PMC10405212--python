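"""Umbrella pipeline: chain the stages over one synthetic vesicle.

Stage order: synth -> hpf -> backmap -> morpho -> interactions -> permeation.
Every stage writes tidy TSV outputs plus a provenance manifest (package
version, seed, parameters, output hashes).  Defaults carry the analysis
parameters of the study: back-mapping tolerance 0.2 nm, 25 ns statistics
windows, 0.35 nm / 30 deg hydrogen bonds, 10 ns crossing bars and 1 / 270 ns
residence-time thresholds.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from vesiflow import __version__, backmap as bm, hpf, interactions as ia, io as vio
from vesiflow import morphology as mo, permeation as pe, synthetic as sy

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All stage toggles and parameters of the pipeline.

    Analysis defaults equal the printed study parameters where one exists
    (0.2 nm, 25 ns, 0.35 nm / 30 deg, 10 ns, 1 ns, 270 ns).
    """

    # stage toggles
    run_synth: bool = True
    run_hpf: bool = True
    run_backmap: bool = True
    run_morpho: bool = True
    run_interactions: bool = True
    run_permeation: bool = True

    # vesicle composition (a reduced vesicle by default; the full study
    # composition is 440/204 lipids with matching counterions)
    n_outer: int = 50
    n_inner: int = 24
    outer_radius: float = 5.0
    inner_radius: float = 3.0
    lipid_charge: int = -2
    counterion_valence: int = 2
    n_water_cavity: int = 57
    n_water_bulk: int = 400
    box: tuple[float, float, float] = (18.0, 18.0, 18.0)

    # trajectory
    n_frames: int = 60
    dt_ns: float = 0.1
    n_scripted_inward: int = 3
    n_scripted_outward: int = 2
    n_scripted_reflected: int = 2
    chain_order_target: float | None = -0.15

    # hpf
    grid: int = 24
    kappa: float = 0.1
    bjerrum_nm: float = 0.7

    # backmap (tolerance 0.2 nm)
    backmap_tolerance_nm: float = 0.2
    library_size: int = 50

    # morphology (25 ns windows)
    window_ns: float = 25.0
    n_theta: int = 24
    n_phi: int = 48
    morpho_every: int = 5

    # interactions (0.35 nm cutoff, 30 deg)
    hbond_cutoff_nm: float = 0.35
    hbond_angle_deg: float = 30.0
    rdf_rmax_nm: float = 2.5
    rdf_bins: int = 80

    # permeation (10 ns bars, 1 / 270 ns thresholds)
    crossing_bin_ns: float = 10.0
    fast_ns: float = 1.0
    confined_ns: float = 270.0

    seed: int = 0


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML key/value file (unknown keys
    rejected)."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "box" in data:
        data["box"] = tuple(data["box"])
    return PipelineConfig(**data)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run the enabled stages in order, returning the provenance manifest.

    Downstream stages consume in-memory artifacts of upstream ones; a
    disabled prerequisite raises immediately, naming the missing stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    header = vio.provenance_header(seed=cfg.seed, config_hash=chash)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config": asdict(cfg), "config_hash": chash,
                      "stages": {}, "outputs": {}}

    def record(stage: str, started: float, files: list[Path]):
        manifest["stages"][stage] = {"seconds": round(time.time() - started, 3)}
        for f in files:
            manifest["outputs"][str(f.relative_to(outdir))] = _hash_file(f)

    system = labels = traj = events_true = regions_true = None

    # ---- synth -------------------------------------------------------
    if cfg.run_synth:
        t0 = time.time()
        spec = sy.VesicleSpec(
            outer_radius=cfg.outer_radius, inner_radius=cfg.inner_radius,
            n_outer=cfg.n_outer, n_inner=cfg.n_inner,
            lipid_charge=cfg.lipid_charge, counterion_valence=cfg.counterion_valence,
            n_water_cavity=cfg.n_water_cavity, n_water_bulk=cfg.n_water_bulk,
            box=cfg.box, seed=cfg.seed)
        system, labels = sy.build_vesicle(spec)
        events = _scripted_events(cfg, labels)
        tspec = sy.TrajectorySpec(n_frames=cfg.n_frames, dt=cfg.dt_ns,
                                  scripted_crossings=events,
                                  chain_order_target=cfg.chain_order_target,
                                  seed=cfg.seed + 1)
        traj, events_true, regions_true = sy.generate_trajectory(system, labels, tspec)
        gro = outdir / "vesicle.gro"
        vio.write_gro(system, gro, header_comment=header)
        ev = outdir / "events_ground_truth.tsv"
        vio.write_events_tsv(events_true, ev, header=header)
        meta = outdir / "vesicle_meta.json"
        vio.write_json_sidecar({"provenance": header, "spec": asdict(spec),
                                "trajectory": {"n_frames": cfg.n_frames, "dt_ns": cfg.dt_ns}},
                               meta)
        record("synth", t0, [gro, ev, meta])

    def need(stage: str, obj, name: str):
        if obj is None:
            raise RuntimeError(f"stage {stage!r} requires outputs of the disabled stage {name!r}")

    # ---- hpf ---------------------------------------------------------
    if cfg.run_hpf:
        need("hpf", system, "synth")
        t0 = time.time()
        chi_vals = np.zeros((6, 6))
        chi_vals[sy.P, sy.C] = chi_vals[sy.C, sy.P] = 8.0
        chi_vals[sy.C, sy.W] = chi_vals[sy.W, sy.C] = 12.0
        chi = hpf.ChiMatrix(chi_vals, kappa=cfg.kappa)
        fieldd = hpf.assign_density(system, (cfg.grid,) * 3)
        e_field = hpf.field_energy(fieldd, chi)
        coul = hpf.total_coulomb_energy(system, (cfg.grid,) * 3, l_B=cfg.bjerrum_nm)
        df = pd.DataFrame([{"field_energy_kBT": e_field, **{f"coulomb_{k}_kBT": v
                            for k, v in coul.items() if k != "alpha"},
                            "alpha_per_nm": coul["alpha"]}])
        f = outdir / "hpf_energy.tsv"
        with f.open("w") as fh:
            fh.write(f"# {header}\n")
            df.to_csv(fh, sep="\t", index=False)
        record("hpf", t0, [f])

    # ---- backmap -----------------------------------------------------
    if cfg.run_backmap:
        need("backmap", system, "synth")
        t0 = time.time()
        mapping = sy.default_lipid_mapping(n_tail_beads=labels.tail_indices.shape[1])
        spec_spacing = float(np.linalg.norm(
            system.positions[labels.tail_indices[0][0]] - system.positions[labels.head_index[0]]))
        library, _ = sy.make_library_fixture(cfg.library_size, mapping, seed=cfg.seed + 2,
                                             bead_spacing=spec_spacing)
        sites = [system.positions[labels.lipid_atoms(i)] for i in range(labels.n_lipids)]
        placed, report = bm.backmap_system(sites, library, tolerance=cfg.backmap_tolerance_nm)
        f = outdir / "backmap_report.tsv"
        with f.open("w") as fh:
            fh.write(f"# {header}\n")
            report.to_csv(fh, sep="\t", index=False)
        # write the rebuilt atomistic lipids
        aa = np.concatenate(placed) if placed else np.zeros((0, 3))
        aa_sys = _atoms_as_system(aa, system.box, labels)
        aagro = outdir / "backmapped.gro"
        vio.write_gro(aa_sys, aagro, header_comment=header)
        record("backmap", t0, [f, aagro])

    # ---- morpho ------------------------------------------------------
    morpho_df = None
    surfaces_last = None
    if cfg.run_morpho:
        need("morpho", traj, "synth")
        t0 = time.time()
        rows = []
        for f_idx in range(0, traj.n_frames, cfg.morpho_every):
            frame = traj.unwrapped[f_idx]
            heads = frame[labels.head_index]
            tail_ends = frame[labels.tail_indices[:, -1]]
            la = mo.assign_leaflets(heads, tail_ends, center=labels.center)
            for leaf, name in ((mo.OUTER, "outer"), (mo.INNER, "inner")):
                sel = la.leaflet == leaf
                if sel.sum() < 10:
                    continue
                surf = mo.fit_surface(heads[sel], center=labels.center,
                                      n_theta=cfg.n_theta, n_phi=cfg.n_phi)
                chains = np.concatenate(
                    [frame[labels.head_index[sel]][:, None, :],
                     frame[labels.tail_indices[sel]]], axis=1)
                normals = _surface_normals_at(surf, heads[sel], labels.center)
                scd = mo.order_parameter_scd(chains, normals)
                rows.append({
                    "frame": f_idx, "time_ns": f_idx * traj.dt, "leaflet": name,
                    "curvature_order": mo.curvature_order_parameter(surf),
                    "area_nm2": surf.area,
                    "area_per_lipid_nm2": mo.area_per_lipid(surf, int(sel.sum())),
                    "roundness": mo.roundness_index(surf),
                    "scd_mean": float(scd.mean()),
                })
                if name == "outer":
                    I = mo.moments_of_inertia(heads[sel])
                    rows[-1].update({"I1": I[0], "I2": I[1], "I3": I[2]})
            surf_out = mo.fit_surface(heads[la.leaflet == mo.OUTER], center=labels.center,
                                      n_theta=cfg.n_theta, n_phi=cfg.n_phi)
            surf_in = mo.fit_surface(heads[la.leaflet == mo.INNER], center=labels.center,
                                     n_theta=cfg.n_theta, n_phi=cfg.n_phi)
            dhh, _ = mo.bilayer_thickness(surf_out, surf_in)
            rows[-1]["dhh_nm"] = dhh
            surfaces_last = (surf_in, surf_out)
        morpho_df = pd.DataFrame(rows)
        f1 = outdir / "morphology.tsv"
        with f1.open("w") as fh:
            fh.write(f"# {header}\n")
            morpho_df.to_csv(fh, sep="\t", index=False)
        # 25 ns windowed summary of the curvature order parameter
        outer = morpho_df[morpho_df.leaflet == "outer"]
        win = mo.windowed_stats(outer["curvature_order"].to_numpy(),
                                outer["time_ns"].to_numpy(), cfg.window_ns)
        f2 = outdir / "morphology_windows.tsv"
        with f2.open("w") as fh:
            fh.write(f"# {header}\n")
            win.to_csv(fh, sep="\t", index=False)
        record("morpho", t0, [f1, f2])

    # ---- interactions ------------------------------------------------
    if cfg.run_interactions:
        need("interactions", traj, "synth")
        t0 = time.time()
        frame = traj.positions[0]
        heads = frame[labels.head_index]
        ions = frame[labels.ion_indices]
        waters = frame[labels.water_indices]
        rows = []
        for pair, (A, B) in {"PO4/ion": (heads, ions), "PO4/OW": (heads, waters),
                             "ion/OW": (ions, waters)}.items():
            prof = ia.rdf(A, B, system.box, r_max=cfg.rdf_rmax_nm, n_bins=cfg.rdf_bins, pair=pair)
            try:
                cn = ia.coordination_number(prof)
                cut = prof.first_minimum()
            except ValueError:
                cut = 0.7
                cn = ia.coordination_number(prof, cutoff=cut)
            rows.append({"pair": pair, "cn": cn, "cutoff_nm": cut})
        cn_df = pd.DataFrame(rows)
        # geometric hydrogen bonds: waters donate to the charged head groups
        h_pos, h_parent = sy.water_hydrogens(waters, seed=cfg.seed + 3)
        crit = ia.HBondCriterion(cutoff=cfg.hbond_cutoff_nm, angle=cfg.hbond_angle_deg)
        bonds = ia.hbond_count(waters, h_pos, heads, h_parent, crit, box=system.box)
        region = ia.classify_waters_radial(waters, labels.center,
                                           labels.r_inner, labels.r_outer)
        bonded = {b[1] for b in bonds}
        hb_rows = []
        for reg in ("cavity", "bulk"):
            sel = np.nonzero(region == reg)[0]
            frac = 100.0 * len(bonded & set(sel)) / max(len(sel), 1)
            hb_rows.append({"region": reg, "n_waters": len(sel),
                            "pct_with_hbond": frac})
        f1 = outdir / "coordination.tsv"
        f2 = outdir / "hbonds.tsv"
        with f1.open("w") as fh:
            fh.write(f"# {header}\n")
            cn_df.to_csv(fh, sep="\t", index=False)
        with f2.open("w") as fh:
            fh.write(f"# {header}\n")
            fh.write(f"# n_bonds={len(bonds)} per_phosphate={len(bonds)/max(len(heads),1):.3f}\n")
            pd.DataFrame(hb_rows).to_csv(fh, sep="\t", index=False)
        record("interactions", t0, [f1, f2])

    # ---- permeation --------------------------------------------------
    if cfg.run_permeation:
        need("permeation", traj, "synth")
        t0 = time.time()
        # detector route: radial region labels per frame (rigid boundaries)
        wpos = traj.unwrapped[:, labels.water_indices, :]
        det = np.empty((traj.n_frames, labels.n_waters), dtype=object)
        for f_idx in range(traj.n_frames):
            det[f_idx] = ia.classify_waters_radial(wpos[f_idx], labels.center,
                                                   labels.r_inner, labels.r_outer)
        events = pe.detect_crossings(det, traj.dt)
        ev_df = pe.events_to_frame(events)
        hist, edges = pe.crossing_histogram(events, bin_width=cfg.crossing_bin_ns, dt=traj.dt)
        _, _, classes = pe.residence_distribution(
            events, pe.ResidenceClasses(fast=cfg.fast_ns, confined=cfg.confined_ns))
        frac = pe.inside_outside_fraction(det)
        f1 = outdir / "crossing_events.tsv"
        vio.write_events_tsv(ev_df, f1, header=header)
        f2 = outdir / "crossing_histogram.tsv"
        with f2.open("w") as fh:
            fh.write(f"# {header}\n")
            pd.DataFrame({"t_lo_ns": edges[:-1], "t_hi_ns": edges[1:], "count": hist}).to_csv(
                fh, sep="\t", index=False)
        f3 = outdir / "inside_outside.tsv"
        with f3.open("w") as fh:
            fh.write(f"# {header}\n")
            frac.to_csv(fh, sep="\t", index=False)
        # region-wise diffusion from the generator's bulk waters
        bulk = labels.water_indices[labels.water_region == "bulk"]
        D, err = pe.msd_diffusion(traj.unwrapped[:, bulk, :], traj.dt)
        f4 = outdir / "diffusion.tsv"
        with f4.open("w") as fh:
            fh.write(f"# {header}\n")
            pd.DataFrame([{"region": "bulk", "D_1e-5_cm2_s": D, "stderr": err}]).to_csv(
                fh, sep="\t", index=False)
        record("permeation", t0, [f1, f2, f3, f4])

    vio.write_json_sidecar(manifest, outdir / "manifest.json")
    return manifest


def _scripted_events(cfg: PipelineConfig, labels) -> list:
    """Deterministic scripted crossings spread over the trajectory."""
    events = []
    n_bulk = int(np.sum(labels.water_region == "bulk"))
    bulk_ids = np.nonzero(labels.water_region == "bulk")[0]
    cav_ids = np.nonzero(labels.water_region == "cavity")[0]
    total = cfg.n_scripted_inward + cfg.n_scripted_outward + cfg.n_scripted_reflected
    if total == 0:
        return events
    span = max(cfg.n_frames - 10, 2)
    k = 0
    for i in range(cfg.n_scripted_inward):
        entry = 2 + (i * span) // max(total, 1)
        events.append(sy.ScriptedCrossing(int(bulk_ids[i % max(n_bulk, 1)]), entry,
                                          min(entry + 6, cfg.n_frames - 1), "inward"))
        k += 1
    for i in range(cfg.n_scripted_outward):
        entry = 2 + (k * span) // max(total, 1)
        events.append(sy.ScriptedCrossing(int(cav_ids[i % max(len(cav_ids), 1)]), entry,
                                          min(entry + 6, cfg.n_frames - 1), "outward"))
        k += 1
    for i in range(cfg.n_scripted_reflected):
        entry = 2 + (k * span) // max(total, 1)
        events.append(sy.ScriptedCrossing(int(bulk_ids[(cfg.n_scripted_inward + i) % max(n_bulk, 1)]),
                                          entry, min(entry + 4, cfg.n_frames - 1), "reflected"))
        k += 1
    return events


def _atoms_as_system(coords: np.ndarray, box, labels):
    from vesiflow.system import ParticleSystem

    n = len(coords)
    return ParticleSystem(positions=np.mod(coords, box), types=np.zeros(n, dtype=int),
                          charges=np.zeros(n), box=box, type_names=["C"],
                          names=["C"] * n)


def _surface_normals_at(surface, points: np.ndarray, center) -> np.ndarray:
    """Outward surface normal interpolated (nearest grid node) at each
    point's angular position."""
    d = points - center
    r = np.linalg.norm(d, axis=1)
    theta = np.arccos(np.clip(d[:, 2] / np.maximum(r, 1e-12), -1, 1))
    phi = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2 * np.pi)
    n_t, n_p = surface.radii.shape
    it = np.clip((theta / (np.pi / n_t) - 0.5).round().astype(int), 0, n_t - 1)
    ip = np.mod((phi / (2 * np.pi / n_p)).round().astype(int), n_p)
    return surface.normals[it, ip]
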