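"""End-to-end study pipeline: scenes -> sectioning -> reconstruction ->
synapse metrics -> vesicle pools -> statistics -> report files.

One pipeline run simulates a morphometric study: ``n_boutons`` boutons per
layer preset, assigned round-robin to ``n_subjects`` subjects, measured
bouton by bouton through the TEM contour route (and optionally the FIB-SEM
voxel route), collected into a study table with one row per bouton, and
summarised by two-level subject aggregation and Kruskal–Wallis / U-test
group comparisons between layers.

Everything derives from a single integer seed; identical config + seed
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics, pools, reconstruct, scene_synth, sectioning, stats

REPORT_COLUMNS = [
    "subject_id",
    "layer",
    "bouton_id",
    "surface_area_um2",
    "volume_um3",
    "mesh_volume_um3",
    "completeness",
    "n_az",
    "az_shape",
    "preaz_area_um2",
    "psd_area_um2",
    "l_preaz_nm",
    "l_psd_nm",
    "cleft_lateral_nm",
    "cleft_central_nm",
    "cleft_excluded",
    "n_sv_total",
    "n_sv_tracks",
    "n_p10",
    "n_p20",
    "n_intermediate",
    "n_rp",
    "n_resting",
    "n_docked",
    "n_dense_core",
    "n_mitochondria",
    "mito_volume_fraction",
]

STAT_PARAMETERS = [
    "surface_area_um2",
    "volume_um3",
    "preaz_area_um2",
    "psd_area_um2",
    "cleft_lateral_nm",
    "cleft_central_nm",
    "n_sv_total",
    "n_p10",
    "n_p20",
    "n_rp",
    "n_resting",
]


def read_report(path) -> pd.DataFrame:
    """Read a study-table CSV with exact float round-trip parsing (the
    report write/read cycle is bit-for-bit reproducible)."""
    return pd.read_csv(path, float_precision="round_trip")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {detail}")


@dataclass(frozen=True)
class PipelineConfig:
    presets: tuple[str, ...] = ("L5_TLN",)
    n_boutons: int = 10          # per preset
    n_subjects: int = 5
    seed: int = 0
    modality: str = "tem"        # tem | fibsem | both
    thickness_nominal: float = 55.0
    thickness_jitter: float = 5.0
    loss_probability: float = 0.0
    misalignment_sd: float = 0.0
    perimeter_mode: str = "3d"
    outdir: str | None = None

    def __post_init__(self):
        if self.modality not in ("tem", "fibsem", "both"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.n_boutons < 1 or self.n_subjects < 1:
            raise ValueError("n_boutons and n_subjects must be >= 1")


@dataclass
class PipelineResult:
    table: pd.DataFrame
    stat_results: list[stats.StatResult]
    aggregates: dict
    modality_summary: dict | None
    provenance: dict
    log_lines: list[str] = field(default_factory=list)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def measure_bouton(
    scene: scene_synth.Scene,
    plan: sectioning.SectionPlan,
    section_seed: int,
    perimeter_mode: str = "3d",
    modality: str = "tem",
) -> tuple[dict, list[str]]:
    """Measure one bouton through the full contour route; returns the study
    row and log lines."""
    log: list[str] = []
    stack = sectioning.section_scene(scene, plan, seed=section_seed)
    aligned = reconstruct.align_stack(stack)
    model = reconstruct.reconstruct(aligned, labels=("bouton",))
    mesh = model.meshes["bouton"]

    sa_pre, l_pre, face_mask = metrics.extract_preaz(mesh, aligned)
    l_psd = metrics.density_contour_length(aligned, "psd_density")
    sa_psd = metrics.estimate_psd_area(sa_pre, l_psd, l_pre) if l_pre > 0 else 0.0
    shape = None
    if face_mask.any():
        sub = mesh.submesh([np.flatnonzero(face_mask)], append=True)
        try:
            shape = metrics.classify_az_shape(np.asarray(sub.vertices), np.asarray(sub.faces))
        except metrics.MetricsError:
            shape = None

    profiles = [
        metrics.CleftMeasurement(
            lateral_1=c.lateral_1,
            lateral_2=c.lateral_2,
            central=c.central,
            perpendicularity_ok=c.perpendicularity_ok,
        )
        for c in aligned.cleft_profiles
    ]
    kept, n_excl = metrics.measure_cleft(profiles)
    log.append(f"cleft profiles: {len(profiles)} measured, {n_excl} excluded (oblique cut)")
    cleft_lat = float(np.mean([p.lateral_mean for p in kept])) if kept else float("nan")
    cleft_cen = float(np.mean([p.central for p in kept])) if kept else float("nan")

    marks = [m for sec in aligned.sections for m in sec.marks]
    marks = pools.dedup_dense_core(marks)     # dense-core only; small clear SVs untouched
    recs = pools.build_records(marks, aligned, mode=perimeter_mode)
    pc = pools.classify_pools(recs)
    n_dense = sum(1 for m in marks if m.dense_core)
    log.append(
        f"marks: {len(marks)} ({n_dense} dense-core after de-dup), "
        f"{pc.n_excluded} excluded from pools"
    )

    mito_vol = reconstruct.cavalieri_volume(aligned, "mito") if any(
        "mito" in s.polygons for s in aligned.sections
    ) else 0.0
    n_mito = _count_tracks(aligned, "mito")

    row = {
        "surface_area_um2": model.surface_area_um2["bouton"],
        "volume_um3": model.volume_um3["bouton"],
        "mesh_volume_um3": model.mesh_volume_um3["bouton"],
        "completeness": model.completeness["bouton"],
        "n_az": len(scene.az_patches),
        "az_shape": shape or "",
        "preaz_area_um2": sa_pre,
        "psd_area_um2": sa_psd,
        "l_preaz_nm": l_pre,
        "l_psd_nm": l_psd,
        "cleft_lateral_nm": cleft_lat,
        "cleft_central_nm": cleft_cen,
        "cleft_excluded": n_excl,
        "n_sv_total": pc.n_total,
        "n_sv_tracks": len({m.track_id for m in marks if not m.dense_core and m.track_id >= 0}),
        "n_p10": pc.n_p10,
        "n_p20": pc.n_p20,
        "n_intermediate": pc.n_intermediate,
        "n_rp": pc.n_rp,
        "n_resting": pc.n_resting,
        "n_docked": pc.n_docked,
        "n_dense_core": n_dense,
        "n_mitochondria": n_mito,
        "mito_volume_fraction": (
            mito_vol / model.volume_um3["bouton"] if model.volume_um3["bouton"] > 0 else 0.0
        ),
    }

    if modality in ("fibsem", "both"):
        vol_aniso = sectioning.voxelize_scene(scene, (5.0, 5.0, 50.0), labels=("vesicle",))
        det_aniso = sectioning.detect_vesicles_voxel(vol_aniso)
        row["fibsem_detections_5x5x50"] = len(det_aniso)
        if modality == "both":
            vol_iso = sectioning.voxelize_scene(scene, (5.0, 5.0, 5.0), labels=("vesicle",))
            det_iso = sectioning.detect_vesicles_voxel(vol_iso)
            row["fibsem_detections_5x5x5"] = len(det_iso)
    return row, log


def _count_tracks(stack: sectioning.ContourStack, label: str, gate: float = 300.0) -> int:
    """Distinct objects of a label, counted by chaining per-section contour
    centroids across adjacent sections."""
    from shapely.geometry import Polygon

    open_tracks: list[tuple[int, np.ndarray]] = []
    n = 0
    for s in stack.sections:
        if s.lost:
            continue
        cents = [
            np.asarray(Polygon(p).centroid.coords[0])
            for p in s.polygons.get(label, [])
            if len(p) >= 3
        ]
        matched = []
        next_tracks = []
        for c in cents:
            best = None
            for i, (idx, pc) in enumerate(open_tracks):
                if i in matched:
                    continue
                if s.index - idx <= 2 and np.linalg.norm(c - pc) < gate:
                    best = i
                    break
            if best is None:
                n += 1
            else:
                matched.append(best)
            next_tracks.append((s.index, c))
        keep = [t for i, t in enumerate(open_tracks) if i not in matched and s.index - t[0] <= 2]
        open_tracks = keep + next_tracks
    return n


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full study; writes report files when config.outdir is set.

    Any stage failure aborts with a stage-named :class:`PipelineError` and
    partial outputs are removed.
    """
    log: list[str] = [f"pipeline seed={config.seed} presets={list(config.presets)}"]
    plan = sectioning.SectionPlan(
        thickness_nominal=config.thickness_nominal,
        thickness_jitter=config.thickness_jitter,
        loss_probability=config.loss_probability,
        misalignment_sd=config.misalignment_sd,
    )
    root = np.random.SeedSequence(config.seed)
    rows = []
    try:
        for preset in config.presets:
            for b in range(config.n_boutons):
                ss_scene, ss_plan = root.spawn(2)
                try:
                    params = scene_synth.preset_from_table1(preset, rng_seed=_child_seed(ss_scene))
                    scene = scene_synth.generate_scene(params)
                except Exception as e:  # noqa: BLE001
                    raise PipelineError("scene_synth", f"{preset} bouton {b}: {e}") from e
                try:
                    row, blog = measure_bouton(
                        scene,
                        plan,
                        section_seed=_child_seed(ss_plan),
                        perimeter_mode=config.perimeter_mode,
                        modality=config.modality,
                    )
                except Exception as e:  # noqa: BLE001
                    raise PipelineError("measurement", f"{preset} bouton {b}: {e}") from e
                row = {
                    "subject_id": f"subject{b % config.n_subjects}",
                    "layer": preset,
                    "bouton_id": f"{preset}_b{b}",
                    **row,
                }
                rows.append(row)
                log.extend(f"  [{preset} b{b}] {line}" for line in blog)

        table = pd.DataFrame(rows)
        ordered = [c for c in REPORT_COLUMNS if c in table.columns] + [
            c for c in table.columns if c not in REPORT_COLUMNS
        ]
        table = table[ordered]

        aggregates: dict = {}
        for preset in config.presets:
            sub = table[table["layer"] == preset]
            aggregates[preset] = {}
            for param in STAT_PARAMETERS:
                try:
                    agg = stats.aggregate_subjects(sub, param)
                except stats.StatsError:
                    continue
                aggregates[preset][param] = {
                    "grand_mean": agg.grand_mean,
                    "grand_sd": agg.grand_sd,
                    "n_subjects": agg.n_subjects,
                    "per_subject_mean": agg.per_subject_mean,
                }

        stat_results: list[stats.StatResult] = []
        if len(config.presets) >= 2:
            for param in STAT_PARAMETERS:
                groups = {
                    preset: table.loc[table["layer"] == preset, param].dropna().to_numpy()
                    for preset in config.presets
                }
                if all(len(v) >= 2 for v in groups.values()):
                    stat_results.append(stats.kruskal_posthoc(groups, parameter=param))

        modality_summary = None
        if config.modality == "both":
            aniso = table["fibsem_detections_5x5x50"].to_numpy()
            iso = table["fibsem_detections_5x5x5"].to_numpy()
            modality_summary = {
                "n_boutons": int(len(table)),
                "mean_detections_5x5x50": float(aniso.mean()),
                "mean_detections_5x5x5": float(iso.mean()),
                "frac_boutons_aniso_le_iso": float((aniso <= iso).mean()),
                "mean_undercount_ratio": float((aniso / np.maximum(iso, 1)).mean()),
            }

        provenance = {
            "config": dataclasses.asdict(config),
            "package": "synmorph",
            "report_columns": list(table.columns),
        }
        result = PipelineResult(
            table=table,
            stat_results=stat_results,
            aggregates=aggregates,
            modality_summary=modality_summary,
            provenance=provenance,
            log_lines=log,
        )
        if config.outdir:
            _write_outputs(result, config)
        return result
    except PipelineError:
        if config.outdir:
            _cleanup(config.outdir)
        raise


_OUTPUT_FILES = (
    "report.csv",
    "stats.json",
    "aggregates.json",
    "provenance.json",
    "modality_summary.json",
    "run.log",
)


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    os.makedirs(config.outdir, exist_ok=True)

    def path(name):
        return os.path.join(config.outdir, name)

    result.table.to_csv(path("report.csv"), index=False)
    with open(path("stats.json"), "w") as fh:
        json.dump(
            [stats.stat_result_to_dict(r) for r in result.stat_results],
            fh,
            sort_keys=True,
            indent=1,
        )
    with open(path("aggregates.json"), "w") as fh:
        json.dump(result.aggregates, fh, sort_keys=True, indent=1)
    with open(path("provenance.json"), "w") as fh:
        json.dump(result.provenance, fh, sort_keys=True, indent=1)
    if result.modality_summary is not None:
        with open(path("modality_summary.json"), "w") as fh:
            json.dump(result.modality_summary, fh, sort_keys=True, indent=1)
    with open(path("run.log"), "w") as fh:
        fh.write("\n".join(result.log_lines) + "\n")


def _cleanup(outdir: str) -> None:
    for name in _OUTPUT_FILES:
        p = os.path.join(outdir, name)
        if os.path.exists(p):
            os.remove(p)
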