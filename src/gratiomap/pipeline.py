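"""End-to-end orchestration: simulate -> fit -> calibrate -> g -> stats.

The cohort runner works on in-memory subject bundles (dicts produced by
:func:`gratiomap.phantom.simulate_subject` or loaded from per-subject
manifests). Channels whose inputs are missing are skipped and reported;
every run is deterministic under a fixed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from . import phantom, voistats
from .config import PipelineConfig
from .epg import EPGParams
from .gratio import (CalibrationSpec, GRatioMaps, HydrationModel, NoddiFractions,
                     GRATIO_METHODS, calibrate_alpha, run_gratio_pipeline)
from .mtmaps import PdCalibration, calibrate_pd, compute_ihmtr, compute_mtv, fit_mtsat
from .relaxometry import T2Grid, fit_mwf_nnls, fit_mwf_spijn
from .volume import VolumeMap

__all__ = ["SubjectResult", "CohortResult", "run_subject_maps", "simulate_cohort",
           "run_cohort", "run_all", "load_subject_from_manifest",
           "MYELIN_METRICS", "G_METRICS"]

MYELIN_METRICS = ["MWF_NNLS", "MWF_SPIJN", "ihMTR", "MTsat", "MTV"]
G_METRICS = [f"g_{m}" for m in GRATIO_METHODS]

_METHOD_METRIC = {
    "mwf_nnls": "MWF_NNLS",
    "mwf_spijn": "MWF_SPIJN",
    "ihmtr": "ihMTR",
    "mtsat": "MTsat",
    "mtv": "MTV",
}


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    maps: dict[str, VolumeMap]
    vois: voistats.VOISet
    fractions: NoddiFractions | None
    gmaps: dict[str, GRatioMaps] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


@dataclass
class CohortResult:
    subjects: list[SubjectResult]
    calibration: CalibrationSpec
    stats: voistats.CohortStats | None
    config: PipelineConfig


def _grid_and_params(config: PipelineConfig) -> tuple[T2Grid, EPGParams]:
    grid = T2Grid.default(config.t2_min, config.t2_max, config.n_t2, config.window_max)
    params = EPGParams(refocusing_flip=config.refocusing_flip,
                       t1_assumed=config.t1_assumed,
                       echo_spacing=config.echo_spacing, n_echoes=config.n_echoes)
    return grid, params


def run_subject_maps(subject: dict, config: PipelineConfig) -> SubjectResult:
    """Compute every myelin-sensitive map available from a subject bundle.

    The bundle may omit inputs; the corresponding channels are recorded in
    ``skipped`` instead of failing.
    """
    vois: voistats.VOISet = subject["vois"]
    maps: dict[str, VolumeMap] = {}
    skipped: list[str] = []
    meta: dict = {}
    grid, params = _grid_and_params(config)

    series = subject.get("echo_series")
    if series is not None:
        if config.fit_mask == "wm":
            fit_mask = vois["WM"] | vois.masks.get("lesion", np.zeros_like(vois["WM"]))
            fit_mask = fit_mask | vois.masks.get("splenium", np.zeros_like(fit_mask))
            series = type(series)(data=series.data, echo_times=series.echo_times,
                                  mask=fit_mask & series.mask, affine=series.affine)
        mwf_nnls, meta_nnls = fit_mwf_nnls(series, grid, params, config.reg_factor,
                                           config.flip_correction)
        mwf_spijn, meta_spijn = fit_mwf_spijn(series, grid, params,
                                              config.sparsity_weight,
                                              config.max_components,
                                              config.flip_correction)
        maps["MWF_NNLS"] = mwf_nnls
        maps["MWF_SPIJN"] = mwf_spijn
        meta["nnls"] = meta_nnls
        meta["spijn"] = meta_spijn
    else:
        skipped += ["MWF_NNLS", "MWF_SPIJN"]

    quad = subject.get("mt_quadruple")
    if quad is not None:
        ihmtr, qc = compute_ihmtr(quad, config.ihmtr_dialect)
        maps["ihMTR"] = ihmtr
        meta["ihmtr_qc"] = qc
    else:
        skipped.append("ihMTR")

    mtsat_inputs = subject.get("mtsat_inputs")
    if mtsat_inputs is not None:
        mtsat, r1, a_app = fit_mtsat(mtsat_inputs)
        cal = PdCalibration(config.pd_mode)
        pd_map, pd_qc = calibrate_pd(a_app, cal, vois[cal.reference_mask_role])
        maps["MTsat"] = mtsat
        maps["R1"] = r1
        maps["A_app"] = a_app
        maps["PD"] = pd_map
        maps["MTV"] = compute_mtv(pd_map)
        meta["pd_qc"] = pd_qc
    else:
        skipped += ["MTsat", "PD", "MTV"]

    return SubjectResult(subject_id=subject.get("subject_id", f"sub-{subject.get('seed', 0)}"),
                         group="healthy" if subject["kind"] == "healthy" else "patient",
                         maps=maps, vois=vois, fractions=subject.get("noddi"),
                         skipped=skipped, meta=meta)


def simulate_cohort(config: PipelineConfig, seed: int | None = None) -> list[dict]:
    """Simulate all subjects of the configured cohort (deterministic)."""
    base_seed = config.seed if seed is None else seed
    spec = phantom.CohortSpec(
        n_healthy=config.n_healthy, n_patients=config.n_patients,
        grid_shape=config.grid_shape, voxel_size_mm=config.voxel_size_mm,
        lesion_count_per_patient=config.lesion_count_per_patient,
        lesion_radius_range=config.lesion_radius_range,
        lesion_demyelination=config.lesion_demyelination,
        noise_sigma=config.noise_sigma, nmvf_wm=config.nmvf_wm, seed=base_seed)
    subjects = []
    for i in range(spec.n_healthy):
        s = phantom.simulate_subject(spec, "healthy", base_seed + 10 * i,
                                     config.n_echoes, config.echo_spacing,
                                     config.refocusing_flip,
                                     config.mt_forward_slope, config.mtsat_slope)
        s["subject_id"] = f"hc-{i:02d}"
        subjects.append(s)
    for i in range(spec.n_patients):
        s = phantom.simulate_subject(spec, "patient", base_seed + 100000 + 10 * i,
                                     config.n_echoes, config.echo_spacing,
                                     config.refocusing_flip,
                                     config.mt_forward_slope, config.mtsat_slope)
        s["subject_id"] = f"ms-{i:02d}"
        subjects.append(s)
    return subjects


def _calibrate(results: list[SubjectResult], config: PipelineConfig) -> CalibrationSpec:
    cal = CalibrationSpec(g_target=config.g_target, calibration_voi=config.calibration_voi)
    healthy = [r for r in results if r.group == "healthy" and r.fractions is not None]
    for metric, attr in (("MTsat", "alpha_mtsat"), ("ihMTR", "alpha_ihmt")):
        ready = [r for r in healthy if metric in r.maps
                 and r.vois.masks.get(config.calibration_voi, np.zeros(1, bool)).any()]
        if not ready:
            continue
        alpha = calibrate_alpha([r.maps[metric] for r in ready],
                                [r.fractions for r in ready],
                                [r.vois[config.calibration_voi] for r in ready],
                                g_target=config.g_target)
        setattr(cal, attr, alpha)
    return cal


def run_cohort(config: PipelineConfig, seed: int | None = None,
               subjects: list[dict] | None = None) -> CohortResult:
    """Full pipeline: (simulate ->) fit maps -> calibrate -> g -> stats."""
    if subjects is None:
        subjects = simulate_cohort(config, seed)
    results = [run_subject_maps(s, config) for s in subjects]
    calibration = _calibrate(results, config)
    model = HydrationModel(config.kappa_my, config.kappa_nm)

    rows = []
    for res in results:
        if res.fractions is not None:
            for method in GRATIO_METHODS:
                metric = _METHOD_METRIC[method]
                if metric not in res.maps:
                    res.skipped.append(f"g_{method}")
                    continue
                if method in ("ihmtr", "mtsat"):
                    alpha = calibration.alpha_ihmt if method == "ihmtr" else calibration.alpha_mtsat
                    if alpha is None:
                        res.skipped.append(f"g_{method}")
                        continue
                res.gmaps[method] = run_gratio_pipeline(res.maps, method, res.fractions,
                                                        calibration, model)
        stat_maps = {k: v for k, v in res.maps.items() if k in MYELIN_METRICS + ["PD", "R1"]}
        for method, gm in res.gmaps.items():
            stat_maps[f"g_{method}"] = gm.g
            stat_maps[f"MVF_{method}"] = gm.mvf
            stat_maps[f"AVF_{method}"] = gm.avf
        tbl = voistats.extract_voi_means(stat_maps, res.vois, per_lesion=config.per_lesion)
        tbl.insert(0, "group", res.group)
        tbl.insert(0, "subject", res.subject_id)
        rows.append(tbl)

    subject_means = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["subject", "group", "voi", "metric", "mean", "n_voxels"])
    families = {"myelin": MYELIN_METRICS, "gratio": G_METRICS}
    stats = voistats.build_cohort_report(subject_means, metric_families=families)
    return CohortResult(subjects=results, calibration=calibration, stats=stats,
                        config=config)


# ---------------------------------------------------------------------------
# manifest loading (real-data pathway)
# ---------------------------------------------------------------------------

_MASK_ROLES = ("WM", "GM", "CSF", "CC", "CR", "IC", "splenium", "lesion",
               "perilesion", "lesion_shell")


def load_subject_from_manifest(subject_dir: str | Path) -> dict:
    """Assemble a subject bundle from a ``manifest.json`` directory.

    Missing roles simply leave the corresponding channel out of the bundle
    (the pipeline will skip it).
    """
    subject_dir = Path(subject_dir)
    manifest = gio.read_manifest(subject_dir)
    roles = manifest["roles"]
    params = manifest.get("parameters", {})

    def p(role: str) -> Path:
        return subject_dir / roles[role]

    bundle: dict = {"subject_id": manifest["subject"],
                    "kind": "healthy" if manifest["group"] == "healthy" else "patient",
                    "seed": params.get("seed", 0)}

    masks = {}
    for role in _MASK_ROLES:
        if role in roles:
            masks[role] = gio.read_mask(p(role))
    if not masks:
        raise ValueError("manifest provides no VOI masks")
    if "lesion" not in masks:
        masks["lesion"] = np.zeros(next(iter(masks.values())).shape, bool)
    bundle["vois"] = voistats.VOISet(masks=masks)

    if "echo_series" in roles and "brain_mask" in roles:
        bundle["echo_series"] = gio.read_echo_series(p("echo_series"), p("brain_mask"))
    if all(r in roles for r in ("s_plus", "s_minus", "s_dual_a", "s_dual_b", "m0")):
        from .mtmaps import MtQuadruple
        vols = {r: gio.read_volume(p(r), role="other").values
                for r in ("s_plus", "s_minus", "s_dual_a", "s_dual_b", "m0")}
        aff = gio.read_volume(p("m0"), role="other").affine
        bundle["mt_quadruple"] = MtQuadruple(affine=aff, **vols)
    if all(r in roles for r in ("s_t1w", "s_pdw", "s_mtw")):
        from .mtmaps import MtsatInputs
        vols = {r: gio.read_volume(p(r), role="other").values
                for r in ("s_t1w", "s_pdw", "s_mtw")}
        aff = gio.read_volume(p("s_t1w"), role="other").affine
        bundle["mtsat_inputs"] = MtsatInputs(
            flip_angles=tuple(params["flip_angles"]),
            repetition_times=tuple(params["repetition_times"]), affine=aff, **vols)
    if "v_ic" in roles and "v_iso" in roles:
        bundle["noddi"] = NoddiFractions(v_ic=gio.read_volume(p("v_ic"), "v_ic").values,
                                         v_iso=gio.read_volume(p("v_iso"), "v_iso").values)
    return bundle


def write_subject_bundle(subject: dict, out_dir: str | Path,
                         params: dict | None = None) -> Path:
    """Write one simulated subject (volumes, masks, truth, manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth: phantom.PhantomTruth = subject["truth"]
    aff = truth.affine
    roles: dict[str, str] = {}

    gio.write_echo_series(subject["echo_series"], out_dir / "echo_series.nii.gz")
    roles["echo_series"] = "echo_series.nii.gz"
    gio.write_mask(truth.brain_mask, aff, out_dir / "brain_mask.nii.gz")
    roles["brain_mask"] = "brain_mask.nii.gz"

    quad = subject["mt_quadruple"]
    for name in ("s_plus", "s_minus", "s_dual_a", "s_dual_b", "m0"):
        gio.write_volume(VolumeMap(getattr(quad, name), aff, role="other"),
                         out_dir / f"{name}.nii.gz")
        roles[name] = f"{name}.nii.gz"
    mtsat_in = subject["mtsat_inputs"]
    for name in ("s_t1w", "s_pdw", "s_mtw"):
        gio.write_volume(VolumeMap(getattr(mtsat_in, name), aff, role="other"),
                         out_dir / f"{name}.nii.gz")
        roles[name] = f"{name}.nii.gz"
    fr = subject["noddi"]
    gio.write_volume(VolumeMap(fr.v_ic, aff, role="v_ic"), out_dir / "v_ic.nii.gz")
    gio.write_volume(VolumeMap(fr.v_iso, aff, role="v_iso"), out_dir / "v_iso.nii.gz")
    roles["v_ic"] = "v_ic.nii.gz"
    roles["v_iso"] = "v_iso.nii.gz"

    vois: voistats.VOISet = subject["vois"]
    for role, mask in vois.masks.items():
        gio.write_mask(mask, aff, out_dir / f"mask_{role}.nii.gz")
        roles[role] = f"mask_{role}.nii.gz"

    for name in ("mvf_true", "avf_true", "mwf_true", "nmvf_true"):
        gio.write_volume(VolumeMap(getattr(truth, name), aff, role="truth"),
                         out_dir / f"{name}.nii.gz")
        roles[name] = f"{name}.nii.gz"

    params = dict(params or {})
    params.setdefault("flip_angles", list(mtsat_in.flip_angles))
    params.setdefault("repetition_times", list(mtsat_in.repetition_times))
    params.setdefault("seed", subject.get("seed", 0))
    group = "healthy" if subject["kind"] == "healthy" else "patient"
    subject_id = subject.get("subject_id", f"sub-{subject.get('seed', 0)}")
    return gio.write_manifest(out_dir, subject_id, group, roles, params)


# ---------------------------------------------------------------------------
# directory writer
# ---------------------------------------------------------------------------


def run_all(config: PipelineConfig, out_dir: str | Path, seed: int | None = None,
            manifest_dirs: list[str | Path] | None = None,
            write_volumes: bool = True) -> CohortResult:
    """Run the whole pipeline and write CSV tables (and optionally NIfTI
    volumes) plus provenance JSON under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = None
    if manifest_dirs is not None:
        subjects = [load_subject_from_manifest(d) for d in manifest_dirs]
    result = run_cohort(config, seed=seed, subjects=subjects)

    if result.stats is not None:
        result.stats.voi_means.to_csv(out_dir / "voi_means.csv", index=False)
        result.stats.ttests.to_csv(out_dir / "ttests.csv", index=False)
        result.stats.correlations.to_csv(out_dir / "correlations.csv", index=False)

    provenance = {
        "config": result.config.to_dict(),
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed if seed is None else seed,
        "alpha_mtsat": result.calibration.alpha_mtsat,
        "alpha_ihmt": result.calibration.alpha_ihmt,
        "g_target": result.calibration.g_target,
        "n_tests": result.stats.n_tests if result.stats is not None else 0,
        "skipped": {r.subject_id: r.skipped for r in result.subjects},
    }
    gio.write_json(provenance, out_dir / "provenance.json")

    if write_volumes:
        for res in result.subjects:
            sdir = out_dir / res.subject_id
            for name, vmap in res.maps.items():
                gio.write_volume(vmap, sdir / f"{name}.nii.gz")
            for method, gm in res.gmaps.items():
                gio.write_volume(gm.g, sdir / f"g_{method}.nii.gz")
                gio.write_volume(gm.mvf, sdir / f"MVF_{method}.nii.gz")
                gio.write_volume(gm.avf, sdir / f"AVF_{method}.nii.gz")
            for role, mask in res.vois.masks.items():
                gio.write_mask(mask, next(iter(res.maps.values())).affine
                               if res.maps else np.eye(4), sdir / f"mask_{role}.nii.gz")
    return result
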