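"""End-to-end synthetic validation experiment.

Orchestrates: phantom construction, DWI simulation, tensor fitting, both
tracking schemes across a sweep of seed depths d_w, the histological DDM
chain (ground-truth centroids, gridding, deformation transfer with Jacobian
compensation, interface assignment), the tractographic interface densities,
and the regional/voxelwise comparison statistics, writing a reproducible
report bundle.  Everything derives deterministically from one integer seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dwi import make_scheme, simulate_dwi
from .histology import grid_counts
from .deformation import make_deformation
from .phantom import (
    BACKGROUND,
    GM,
    WM,
    CrossingSpec,
    PhantomConfig,
    make_ground_truth_fibers,
    make_phantom,
)
from .stats import (
    build_connectivity_table,
    classify_fp_fn,
    correlate,
    export_backbone,
    fit_proportional,
    regional_counts,
    streamline_sensitivity,
    topk_spearman,
    voxelwise_pearson,
)
from .tensors import fit_tensor
from .tracking import (
    SeedRegion,
    TrackingParams,
    build_seed_region,
    fact_track,
    probabilistic_track,
    select_streamlines,
    whole_brain_seeds,
)
from .tract_ddm import (
    probabilistic_interface_ddm,
    streamline_interface_ddm,
    terminal_ddm,
)
from .transfer import (
    bin_positions_volume,
    extract_interface,
    plane_density_to_interface,
    project_to_interface,
    transfer_ddm,
)
from . import io as tio

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ExperimentResult", "run_experiment", "make_report"]


@dataclass
class RunConfig:
    """Configuration of one full synthetic experiment.

    The phantom and acquisition defaults reproduce the study conditions
    (0.3 mm voxels, 31 directions at b = 1200, SNR ~ 25, d_w sweep 0 / 0.3 /
    0.6 mm).  The probabilistic sample count defaults to a desk-scale 32
    samples per seed voxel — the scheme contract is unchanged and counts
    simply scale with the sample number.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    schemes: tuple = ("ds", "prob")
    d_w_levels: tuple = (0.0, 0.3, 0.6)
    ds_params: TrackingParams = field(default_factory=TrackingParams)
    prob_params: TrackingParams = field(default_factory=lambda: TrackingParams(n_samples=32))
    orientation_sigma: float = 0.15  # radians
    micrograph_um_per_px: float = 7.5
    deformation_amplitude_px: float = 60.0
    s0: float = 1000.0
    output_dir: str = "tracerval_run"
    rng_seed: int = 0
    write_volumes: bool = True
    write_streamlines: bool = False
    cache: bool = False

    def __post_init__(self):
        if any(d < 0 for d in self.d_w_levels):
            raise ValueError("d_w levels must be nonnegative")
        bad = set(self.schemes) - {"ds", "prob", "prob2"}
        if bad:
            raise ValueError(f"unknown tracking schemes: {sorted(bad)}")

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        ph = d["phantom"]
        if ph.get("bundle_specs"):
            for b in ph["bundle_specs"]:
                if b.get("control_points") is not None:
                    b["control_points"] = np.asarray(b["control_points"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            if ph.get("crossing_spec") is not None and isinstance(ph["crossing_spec"], dict):
                ph["crossing_spec"] = CrossingSpec(**ph["crossing_spec"])
            if ph.get("bundle_specs"):
                from .phantom import BundleSpec

                ph["bundle_specs"] = [
                    b if isinstance(b, BundleSpec) else BundleSpec(**b) for b in ph["bundle_specs"]
                ]
            d["phantom"] = PhantomConfig(**ph)
        for key in ("ds_params", "prob_params"):
            if key in d and isinstance(d[key], dict):
                d[key] = TrackingParams(**d[key])
        d["schemes"] = tuple(d.get("schemes", ("ds", "prob")))
        d["d_w_levels"] = tuple(d.get("d_w_levels", (0.0, 0.3, 0.6)))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)

    def content_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # where a run lands does not change its content
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ExperimentResult:
    config: RunConfig
    tables: dict  # (scheme, d_w) -> ConnectivityTable DataFrame
    fits: dict  # (scheme, d_w) -> ProportionalFit
    correlations: pd.DataFrame  # tidy: scheme, d_w, metric, value, p, n
    voxelwise: pd.DataFrame  # scheme, d_w, roi, r_p, p, n
    fp_fn: dict  # (scheme, d_w) -> {"fn": [...], "fp": [...]}
    sensitivity: dict  # (scheme, d_w) -> fraction
    truth_counts: pd.Series  # ground-truth axon counts per ROI
    soma_counts: pd.Series
    fiber_counts: pd.Series
    mass_ledger: dict
    output_dir: Path
    report_path: Path = None


def _stage_seeds(root: int) -> dict:
    state = np.random.SeedSequence(root).generate_state(8) & 0x7FFFFFFF
    names = ["dwi", "truth", "deform", "prob0", "prob1", "prob2", "spare1", "spare2"]
    return {k: int(v) for k, v in zip(names, state)}


def _selection_band(tissue, interface, seed_region: SeedRegion):
    """Interface voxels under the injection, thickened by the seed extension.

    For d_w = 0 this is the plain interface-under-injection mask; for deeper
    seeds the same white-matter extension voxels are included, consistently
    with the rationale that the tracer (and hence the effective seed) reaches
    slightly below the cortex.
    """
    inj = tissue.injection_mask
    if_vox = interface.voxels
    under = if_vox[inj[tuple(if_vox.T)]]
    if seed_region.d_w > 0:
        wm = tissue.label_volume == WM
        ext = seed_region.voxels[wm[tuple(seed_region.voxels.T)]]
        if len(ext):
            under = np.vstack([under, ext])
    return under


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Run the full pipeline; returns the in-memory result and writes a report."""
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    hash_file = out / "run_hash.txt"
    chash = cfg.content_hash()
    if (
        cfg.cache
        and hash_file.exists()
        and hash_file.read_text().strip() == chash
        and (out / "summary.json").exists()
    ):
        log.info("cached run found for hash %s; skipping recompute", chash)
        return _load_cached_result(cfg, out)
    seeds = _stage_seeds(cfg.rng_seed)

    log.info("stage=phantom grid=%s seed=%d", cfg.phantom.grid_shape, cfg.rng_seed)
    tissue, tensors_true = make_phantom(cfg.phantom)
    labels = tissue.label_volume
    h = np.asarray(cfg.phantom.voxel_size)

    scheme = make_scheme()
    s0_map = np.where(labels != BACKGROUND, cfg.s0, 0.05 * cfg.s0)
    dwi = simulate_dwi(
        tensors_true, scheme, s0=s0_map,
        noise_sigma=cfg.phantom.noise_sigma * cfg.s0, rng_seed=seeds["dwi"],
    )
    tf = fit_tensor(dwi, mask=labels != BACKGROUND)
    log.info("stage=tensor_fit voxels=%d", int(tf.mask.sum()))

    interface = extract_interface(labels, h)
    roi_if_ids = tissue.roi_label_map[tuple(interface.voxels.T)]

    # ---- histological DDM chain -----------------------------------------
    fibers_px, somas_mm = make_ground_truth_fibers(
        tissue, seeds["truth"], micrograph_um_per_px=cfg.micrograph_um_per_px
    )
    px_per_mm = 1000.0 / cfg.micrograph_um_per_px
    image_size_px = float(cfg.phantom.extent_mm[0]) * px_per_mm
    all_cents = (
        np.vstack([v for v in fibers_px.values() if len(v)])
        if any(len(v) for v in fibers_px.values())
        else np.empty((0, 2))
    )
    ddm_micro = grid_counts(all_cents, image_size_px, (256, 256))
    npx = int(round(image_size_px))
    warp = make_deformation((npx, npx), cfg.deformation_amplitude_px, seeds["deform"])
    ddm_block = transfer_ddm(ddm_micro, warp)
    ddm_dti = transfer_ddm(ddm_block, warp.inverse())
    fiber_sddm = plane_density_to_interface(ddm_dti, interface, px_per_mm, provenance="bda_fiber")
    n_b = regional_counts(fiber_sddm, roi_if_ids)

    all_somas = (
        np.vstack([v for v in somas_mm.values() if len(v)])
        if any(len(v) for v in somas_mm.values())
        else np.empty((0, 3))
    )
    soma_vol = bin_positions_volume(all_somas, labels.shape, h)
    soma_sddm = project_to_interface(soma_vol, interface)
    soma_sddm.provenance = "bda_soma"
    n_s = regional_counts(soma_sddm, roi_if_ids)
    log.info(
        "stage=histology centroids=%d ddm_mass_in=%.1f ddm_mass_out=%.1f somas=%d",
        len(all_cents), ddm_micro.total(), ddm_dti.total(), len(all_somas),
    )

    truth = pd.Series(
        {r: tissue.bundle_truth[r]["axon_count"] for r in sorted(tissue.bundle_truth)},
        name="axon_count",
    )

    wm_mask = labels == WM
    gm_term = (labels == GM) & ~tissue.injection_mask

    # ---- tracking ---------------------------------------------------------
    records, vox_rows = [], []
    tables, fits, fp_fn, sensitivity = {}, {}, {}, {}
    surface_ddms = {"bda_fiber": fiber_sddm, "bda_soma": soma_sddm}

    ds_all = None
    if "ds" in cfg.schemes:
        ds_all = fact_track(tf, whole_brain_seeds(tf, cfg.ds_params), cfg.ds_params)
        log.info("stage=fact_track streamlines=%d", len(ds_all))

    secondary = None
    if "prob2" in cfg.schemes:
        secondary = np.zeros(labels.shape + (3,))
        if tissue.crossing_voxels is not None and tissue.crossing_voxels.any():
            # in crossing voxels, expose the occluded bundle's (vertical) direction
            secondary[tissue.crossing_voxels] = np.array([0.0, 0.0, 1.0])

    for scheme_name in cfg.schemes:
        for d_w in cfg.d_w_levels:
            seed_region = build_seed_region(
                tissue.injection_mask, interface, wm_mask, d_w, voxel_size=h
            )
            band = _selection_band(tissue, interface, seed_region)
            if scheme_name == "ds":
                sel = select_streamlines(ds_all, seed_region.voxels, band)
                sddm = streamline_interface_ddm(sel, interface)
                tddm = terminal_ddm(sel, tissue.roi_label_map, interface)
                n_d = regional_counts(sddm, roi_if_ids)
                n_t = regional_counts(tddm, roi_if_ids)
                table = build_connectivity_table(n_b=n_b, n_d=n_d, n_s=n_s, n_t=n_t)
                tp_rois = [int(r) for r in truth.index[truth > 0]]
                sensitivity[(scheme_name, d_w)] = streamline_sensitivity(
                    sel, tp_rois, tissue.roi_label_map
                )
                surface_ddms[f"ds_stream_dw{d_w:g}"] = sddm
                surface_ddms[f"ds_terminal_dw{d_w:g}"] = tddm
                if cfg.write_streamlines:
                    tio.save_trk(sel, out / f"ds_selected_dw{d_w:g}.trk")
                log.info("stage=ds_select d_w=%.1f selected=%d", d_w, len(sel))
            else:
                params = cfg.prob_params
                way = np.zeros(labels.shape, dtype=bool)
                way[tuple(band.T)] = True
                dens, info = probabilistic_track(
                    tf, seed_region, way, gm_term, params,
                    orientation_sigma=cfg.orientation_sigma,
                    rng_seed=seeds["prob2" if scheme_name == "prob2" else "prob0"] + int(d_w * 10),
                    secondary_directions=secondary if scheme_name == "prob2" else None,
                )
                sddm = probabilistic_interface_ddm(dens, interface)
                n_d = regional_counts(sddm, roi_if_ids)
                table = build_connectivity_table(n_b=n_b, n_d=n_d, n_s=n_s)
                surface_ddms[f"{scheme_name}_stream_dw{d_w:g}"] = sddm
                log.info(
                    "stage=prob_track scheme=%s d_w=%.1f retained=%d",
                    scheme_name, d_w, info["n_retained"],
                )

            tables[(scheme_name, d_w)] = table
            fit = fit_proportional(table["N_B"], table["N_D"])
            fits[(scheme_name, d_w)] = fit
            rs, ps = correlate(table["N_B"], table["N_D"], method="spearman")
            try:
                rtop, ptop, ktop = topk_spearman(table["N_B"], table["N_D"])
            except ValueError:
                rtop, ptop, ktop = float("nan"), float("nan"), 0
            fn, fp = classify_fp_fn(table)
            fp_fn[(scheme_name, d_w)] = {"fn": fn, "fp": fp}
            conn = truth[truth > 0]
            r_truth, p_truth = correlate(
                conn.to_numpy(), table.loc[conn.index, "N_D"].to_numpy(), method="pearson"
            )
            records += [
                dict(scheme=scheme_name, d_w=d_w, metric="r", value=fit.r, p=fit.p, n=len(table)),
                dict(scheme=scheme_name, d_w=d_w, metric="r_s", value=rs, p=ps, n=len(table)),
                dict(scheme=scheme_name, d_w=d_w, metric="r_s_top", value=rtop, p=ptop, n=ktop),
                dict(scheme=scheme_name, d_w=d_w, metric="slope_b", value=fit.b, p=float("nan"), n=len(table)),
                dict(scheme=scheme_name, d_w=d_w, metric="model_used", value=fit.model_used, p=float("nan"), n=len(table)),
                dict(scheme=scheme_name, d_w=d_w, metric="r_vs_truth", value=r_truth, p=p_truth, n=len(conn)),
                dict(scheme=scheme_name, d_w=d_w, metric="n_fn", value=len(fn), p=float("nan"), n=len(table)),
                dict(scheme=scheme_name, d_w=d_w, metric="n_fp", value=len(fp), p=float("nan"), n=len(table)),
            ]
            for roi in table.index:
                m = roi_if_ids == roi
                r_p, p_p, n_vox = voxelwise_pearson(fiber_sddm.density[m], sddm.density[m])
                vox_rows.append(dict(scheme=scheme_name, d_w=d_w, roi=roi, r_p=r_p, p=p_p, n=n_vox))

    # soma-based comparisons (histology-histology and soma vs DS terminals)
    if len(truth) >= 3:
        r_sf, p_sf = correlate(n_b.to_numpy(), n_s.to_numpy(), method="pearson")
        rs_sf, ps_sf = correlate(n_b.to_numpy(), n_s.to_numpy(), method="spearman")
        records += [
            dict(scheme="histology", d_w=float("nan"), metric="r_soma_fiber", value=r_sf, p=p_sf, n=len(n_b)),
            dict(scheme="histology", d_w=float("nan"), metric="r_s_soma_fiber", value=rs_sf, p=ps_sf, n=len(n_b)),
        ]
        for (sch, d_w), table in tables.items():
            if sch == "ds" and "N_T" in table:
                r_st, p_st = correlate(table["N_S"], table["N_T"], method="pearson")
                records.append(
                    dict(scheme=sch, d_w=d_w, metric="r_soma_terminal", value=r_st, p=p_st, n=len(table))
                )

    correlations = pd.DataFrame(records)
    voxelwise = pd.DataFrame(vox_rows)

    # ---- outputs ----------------------------------------------------------
    if cfg.write_volumes:
        tio.save_nifti(labels, h, out / "labels.nii")
        tio.save_nifti(tf.fa, h, out / "fa.nii")
        tio.save_nifti(tf.principal_direction, h, out / "principal_direction.nii")
        tio.save_tensor_nifti(tf.tensor, h, out / "tensors.nii")
        tio.save_dwi(dwi, out / "dwi")
    for name, sddm in surface_ddms.items():
        tio.save_surface_ddm_tsv(sddm, out / f"sddm_{name}.tsv")
    for (sch, d_w), table in tables.items():
        tio.save_tsv(table, out / f"connectivity_{sch}_dw{d_w:g}.tsv")
    if len(correlations):
        tio.save_tsv(correlations, out / "correlations.tsv", index=False)
    if len(voxelwise):
        tio.save_tsv(voxelwise, out / "voxelwise.tsv", index=False)

    roi_geometry = _roi_geometry(tissue)
    for (sch, d_w), table in tables.items():
        if d_w == max(cfg.d_w_levels, default=None):
            g = export_backbone(table, roi_geometry)
            import networkx as nx

            nx.write_graphml(g, out / f"backbone_{sch}.graphml")

    mass_ledger = {
        "centroids": float(len(all_cents)),
        "ddm_micro_total": ddm_micro.total(),
        "ddm_dti_total": ddm_dti.total(),
        "fiber_interface_total": fiber_sddm.total(),
        "fiber_unassigned": fiber_sddm.unassigned,
        "soma_total": soma_sddm.total(),
    }

    result = ExperimentResult(
        config=cfg, tables=tables, fits=fits, correlations=correlations,
        voxelwise=voxelwise, fp_fn=fp_fn, sensitivity=sensitivity,
        truth_counts=truth, soma_counts=n_s, fiber_counts=n_b,
        mass_ledger=mass_ledger, output_dir=out,
    )
    if len(cfg.schemes) == 0:
        result.report_path = _histology_only_report(result)
    else:
        result.report_path = make_report(result)
    _write_summary_json(result, out)
    hash_file.write_text(chash + "\n")
    cfg.to_yaml(out / "config.yaml")
    return result


def _write_summary_json(result: ExperimentResult, out: Path):
    summary = {
        "fp_fn": {f"{s}|{d:g}": v for (s, d), v in result.fp_fn.items()},
        "sensitivity": {f"{s}|{d:g}": v for (s, d), v in result.sensitivity.items()},
        "mass_ledger": result.mass_ledger,
        "truth_counts": {int(k): int(v) for k, v in result.truth_counts.items()},
        "fiber_counts": {int(k): float(v) for k, v in result.fiber_counts.items()},
        "soma_counts": {int(k): float(v) for k, v in result.soma_counts.items()},
        "tables": {f"{s}|{d:g}": f"connectivity_{s}_dw{d:g}.tsv" for (s, d) in result.tables},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True, allow_nan=True))


def _load_cached_result(cfg: RunConfig, out: Path) -> ExperimentResult:
    summary = json.loads((out / "summary.json").read_text())

    def _key(s):
        sch, d = s.split("|")
        return sch, float(d)

    tables = {
        _key(k): pd.read_csv(out / fname, sep="\t", index_col=0)
        for k, fname in summary["tables"].items()
    }
    corr_path = out / "correlations.tsv"
    vox_path = out / "voxelwise.tsv"
    return ExperimentResult(
        config=cfg,
        tables=tables,
        fits={k: fit_proportional(t["N_B"], t["N_D"]) for k, t in tables.items()},
        correlations=pd.read_csv(corr_path, sep="\t") if corr_path.exists() else pd.DataFrame(),
        voxelwise=pd.read_csv(vox_path, sep="\t") if vox_path.exists() else pd.DataFrame(),
        fp_fn={_key(k): v for k, v in summary["fp_fn"].items()},
        sensitivity={_key(k): v for k, v in summary["sensitivity"].items()},
        truth_counts=pd.Series({int(k): v for k, v in summary["truth_counts"].items()}),
        soma_counts=pd.Series({int(k): v for k, v in summary["soma_counts"].items()}),
        fiber_counts=pd.Series({int(k): v for k, v in summary["fiber_counts"].items()}),
        mass_ledger=summary["mass_ledger"],
        output_dir=out,
        report_path=out / "report.md",
    )


def _roi_geometry(tissue) -> dict:
    h = np.asarray(tissue.voxel_size)
    vol_per_vox = float(np.prod(h))
    geo = {}
    inj = np.argwhere(tissue.injection_mask)
    geo["injection"] = {
        "volume": len(inj) * vol_per_vox,
        "centre": tuple(((inj + 0.5) * h).mean(axis=0)) if len(inj) else (0, 0, 0),
    }
    for roi in sorted(tissue.bundle_truth):
        vox = np.argwhere(tissue.roi_label_map == roi)
        if len(vox):
            geo[roi] = {
                "volume": len(vox) * vol_per_vox,
                "centre": tuple(((vox + 0.5) * h).mean(axis=0)),
            }
    return geo


def _fmt(v: float) -> str:
    return "nan" if not np.isfinite(v) else f"{v:.3g}"


def _histology_only_report(result: ExperimentResult) -> Path:
    lines = [
        "# Synthetic tracer-vs-tractography validation report",
        "",
        "No tracking schemes were run: histology densities only.",
        "",
        f"- fiber counts per region: "
        f"{ {int(k): round(float(v), 1) for k, v in result.fiber_counts.items()} }",
        f"- soma counts per region: "
        f"{ {int(k): round(float(v), 1) for k, v in result.soma_counts.items()} }",
    ]
    path = result.output_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_report(result: ExperimentResult) -> Path:
    """Write a human-readable summary: regional correlations per scheme and
    seed depth (one table row per comparison, one column per d_w) and the
    per-region voxelwise correlation table."""
    out = result.output_dir
    corr = result.correlations
    lines = ["# Synthetic tracer-vs-tractography validation report", ""]
    lines.append(f"- phantom grid: {result.config.phantom.grid_shape}, "
                 f"voxel {result.config.phantom.voxel_size} mm")
    lines.append(f"- seed: {result.config.rng_seed}")
    lines.append(f"- ground-truth axon counts: "
                 f"{ {int(k): int(v) for k, v in result.truth_counts.items()} }")
    lines.append("")

    tracked = corr[corr["scheme"].isin(["ds", "prob", "prob2"])] if len(corr) else corr
    if len(tracked) == 0:
        raise ValueError("no comparisons computed: refusing to write an empty report")

    d_ws = sorted(tracked["d_w"].dropna().unique())
    lines.append("## Regional agreement (rows: scheme/metric, columns: d_w)")
    lines.append("")
    header = "| comparison | " + " | ".join(f"d_w = {d:g} mm" for d in d_ws) + " |"
    lines.append(header)
    lines.append("|" + "---|" * (len(d_ws) + 1))
    for sch in [s for s in ("ds", "prob", "prob2") if s in set(tracked["scheme"])]:
        for metric, label in [("r", "r"), ("r_s", "r_s"), ("r_s_top", "(r_s)_top")]:
            cells = []
            for d in d_ws:
                row = tracked[(tracked.scheme == sch) & (tracked.d_w == d) & (tracked.metric == metric)]
                if len(row):
                    v, p = float(row.value.iloc[0]), float(row.p.iloc[0])
                    cells.append(f"{_fmt(v)} (p<{_fmt(max(p, 1e-10))})")
                else:
                    cells.append("-")
            lines.append(f"| {sch}: N_B vs N_D, {label} | " + " | ".join(cells) + " |")
    lines.append("")

    lines.append("## False negatives / false positives")
    lines.append("")
    for (sch, d), d_fpfn in sorted(result.fp_fn.items()):
        lines.append(f"- {sch}, d_w = {d:g} mm: FN = {d_fpfn['fn']}, FP = {d_fpfn['fp']}")
    lines.append("")
    if result.sensitivity:
        lines.append("## Streamline sensitivity (fraction reaching true-positive regions)")
        lines.append("")
        for (sch, d), s in sorted(result.sensitivity.items()):
            lines.append(f"- {sch}, d_w = {d:g} mm: {_fmt(s)}")
        lines.append("")

    if len(result.voxelwise):
        lines.append("## Voxelwise agreement r_p (rows: scheme x d_w, columns: region)")
        lines.append("")
        pivot = result.voxelwise.pivot_table(index=["scheme", "d_w"], columns="roi", values="r_p")
        lines.append("| scheme | d_w | " + " | ".join(str(c) for c in pivot.columns) + " |")
        lines.append("|" + "---|" * (len(pivot.columns) + 2))
        for (sch, d), row in pivot.iterrows():
            lines.append(f"| {sch} | {d:g} | " + " | ".join(_fmt(v) for v in row) + " |")
        lines.append("")

    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
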