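"""End-to-end orchestration: simulate → upsample → layer → unfold → thickness → stats.

The pipeline drives the whole analysis on synthetic data: it simulates a
cohort and per-subject phantom volumes, interpolates them through-plane,
grows gray-matter layers, flattens each volume by landmark MDS, measures
subregional thickness on the flat map, compares the measurements against
each subject's simulated ground truth, and runs the cohort statistics
(demographic table, interaction ANCOVA, stratified correlations).

Every run writes a manifest recording the seed, a hash of the configuration
and a checksum per output file, so a rerun with the same seed is verifiably
identical.  Imaging stages run on a configurable subset of subjects (the
default demo scale keeps grids coarse and subjects few); the statistics
stage runs on the full simulated cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, synthetic, thickness as thickness_mod, unfolding, volume_io
from .layering import grow_layers

log = logging.getLogger("hippoflat")

STAGES = ("simulate", "upsample", "layer", "unfold", "thickness", "stats")


class StageError(RuntimeError):
    def __init__(self, stage: str, completed: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.completed = completed


@dataclass
class PipelineConfig:
    """Pipeline settings; defaults are a fast demo scale."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    # imaging substrate (pre-interpolation)
    shape_kind: str = "folded_c_sheet"
    grid_dims: tuple[int, int, int] = (48, 48, 12)
    voxel_spacing_mm: tuple[float, float, float] = (0.6, 0.6, 1.8)
    interpolation_factor: int = 3
    n_subjects_imaging: int = 8
    # unfolding
    layer_connectivity: str = "face"
    geodesic_connectivity: str = "face+edge+corner"
    n_landmarks: int = 200
    pixel_size_mm: float = 0.6
    thickness_convention: str = "boundary_corrected"
    # statistics
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("grid_dims", "voxel_spacing_mm"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific settings (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# hippoflat seed={cfg.seed} config={cfg.config_hash()}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to out_dir)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": [],
        "outputs": {},
    }
    completed: dict[str, list[str]] = {}

    def finish(stage: str, files: list[Path]) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"][stage] = {f.name: _checksum(f) for f in files}
        completed[stage] = [str(f) for f in files]
        log.info("stage %s complete (%d outputs)", stage, len(files))

    state: dict = {}
    for stage in STAGES:
        try:
            files = _RUNNERS[stage](config, out, state)
        except Exception as e:  # noqa: BLE001 - rewrap with stage context
            raise StageError(stage, completed, e) from e
        finish(stage, files)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    cohort_spec = synthetic.CohortSpec(seed=cfg.seed)
    cohort = synthetic.generate_cohort_table(cohort_spec)
    cohort_path = out / "cohort.csv"
    _write_csv(cohort, cohort_path, cfg)

    phantom_spec = synthetic.PhantomSpec(
        shape_kind=cfg.shape_kind,
        grid_dims=cfg.grid_dims,
        voxel_spacing_mm=cfg.voxel_spacing_mm,
        n_subregion_bands=7,
        seed=cfg.seed,
    )
    imaged = cohort[cohort["mri_available"]].head(cfg.n_subjects_imaging)
    vols = synthetic.generate_subject_volumes(imaged, phantom_spec)
    files = [cohort_path]
    state["cohort"] = cohort
    state["volumes"] = vols
    for sid, (vol, _gt) in vols.items():
        p = out / f"phantom_{sid}.nii.gz"
        volume_io.write_label_volume(vol, p)
        files.append(p)
    return files


def _stage_upsample(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    state["upsampled"] = {
        sid: volume_io.upsample_through_plane(vol, cfg.interpolation_factor)
        for sid, (vol, _gt) in state["volumes"].items()
    }
    sid0, vol0 = next(iter(state["upsampled"].items()))
    p = out / f"upsampled_{sid0}.nii.gz"
    volume_io.write_label_volume(vol0, p)
    return [p]


def _stage_layer(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    layers = {}
    report = []
    for sid, vol in state["upsampled"].items():
        gm = volume_io.derive_gray_matter(vol)
        la = grow_layers(gm, vol.wm_mask(), cfg.layer_connectivity)
        layers[sid] = (gm, la)
        report.append({"subject_id": sid, "n_layers": la.n_layers,
                       "unreachable": la.unreachable_count,
                       "gm_voxels": int(gm.sum())})
    state["layers"] = layers
    p = out / "layering_report.csv"
    _write_csv(pd.DataFrame(report), p, cfg)
    return [p]


def _stage_unfold(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    flatmaps = {}
    report = []
    for sid, vol in state["upsampled"].items():
        gm, la = state["layers"][sid]
        fm = unfolding.unfold(
            gm, la, vol.spacing_mm,
            n_landmarks=cfg.n_landmarks,
            geodesic_connectivity=cfg.geodesic_connectivity,
            pixel_size_mm=cfg.pixel_size_mm,
            seed=cfg.seed,
        )
        flatmaps[sid] = fm
        report.append({"subject_id": sid, "stress1": fm.stress1,
                       "distance_correlation": fm.distance_correlation,
                       "n_pixels": len(fm.occupied_pixels())})
    state["flatmaps"] = flatmaps
    files = [out / "unfold_report.csv"]
    _write_csv(pd.DataFrame(report), files[0], cfg)
    # voxel<->pixel mapping of the first subject for inspection
    sid0 = next(iter(flatmaps))
    fm = flatmaps[sid0]
    ncols = fm.grid_shape[1]
    mapping = pd.DataFrame({
        "i": fm.voxel_indices[:, 0], "j": fm.voxel_indices[:, 1],
        "k": fm.voxel_indices[:, 2],
        "u": fm.node_pixel // ncols, "v": fm.node_pixel % ncols,
        "layer": fm.node_layer,
    })
    files.append(out / f"flatmap_mapping_{sid0}.csv")
    _write_csv(mapping, files[1], cfg)
    return files


def _stage_thickness(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    rows = []
    for sid, vol in state["upsampled"].items():
        gm, _la = state["layers"][sid]
        fm = state["flatmaps"][sid]
        dist = thickness_mod.distance_to_nongray(gm, vol.spacing_mm)
        per_pixel = thickness_mod.flatmap_thickness(fm, dist, cfg.thickness_convention)
        labels2d = unfolding.project_subregion_labels(vol.labels, fm)
        res = thickness_mod.subregion_mean_thickness(
            per_pixel, labels2d, cfg.thickness_convention)
        truth = state["cohort"].set_index("subject_id")
        for name, value in res.subregion_mean_mm.items():
            rows.append({
                "subject_id": sid, "subregion": name,
                "thickness_mm": value,
                "simulated_mm": float(truth.loc[sid, f"thick_{name}"]),
                "convention": cfg.thickness_convention,
            })
    measured = pd.DataFrame(rows)
    measured["error_mm"] = measured["thickness_mm"] - measured["simulated_mm"]
    state["measured"] = measured
    p = out / "measured_thickness.csv"
    _write_csv(measured, p, cfg)
    return [p]


def _stage_stats(cfg: PipelineConfig, out: Path, state: dict) -> list[Path]:
    cohort = state["cohort"]
    files = []
    t1 = cohort_stats.build_table1(cohort)
    files.append(out / "table1.csv")
    _write_csv(t1, files[-1], cfg)
    fit = cohort_stats.fit_education_risk_glm(cohort)
    files.append(out / "glm_terms.csv")
    _write_csv(fit.terms, files[-1], cfg)
    corr = cohort_stats.subgroup_correlations(cohort)
    files.append(out / "correlations.csv")
    _write_csv(corr, files[-1], cfg)
    return files


_RUNNERS = {
    "simulate": _stage_simulate,
    "upsample": _stage_upsample,
    "layer": _stage_layer,
    "unfold": _stage_unfold,
    "thickness": _stage_thickness,
    "stats": _stage_stats,
}
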