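"""Configuration, NIfTI I/O, heatmap rendering and end-to-end runs.

The pipeline runs either on a synthetic phantom cohort or on a manifest
of user-supplied co-registered NIfTI volumes, and emits, per threshold
and PET method: a tidy feature table (CSV), a Spearman correlation grid
(CSV for rho and p), a cross-method error report, optional heatmap PNGs,
and a run manifest (config hash, seed, version) that makes the run
reproducible bit for bit.

Registration is deliberately absent: volumes must already share one grid
(shape equal, spacings within 1e-3 mm), and incongruent inputs are
rejected with an explicit message rather than resampled.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .analysis import CorrelationGrid, correlation_grid, feature_error_report
from .features import cohort_feature_table
from .masking import DEFAULT_THRESHOLDS, ROIMask
from .phantom import (
    DEFAULT_BIAS_SPECS,
    REFERENCE_METHOD,
    PhantomSpec,
    SubjectData,
    generate_cohort,
)
from .quantitation import DoseRecord, VoxelGrid

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "write_subject",
    "read_subject",
    "write_cohort",
    "read_cohort",
    "render_heatmap",
]

logger = logging.getLogger(__name__)

SPACING_TOL_MM = 1e-3


class PipelineConfig(BaseModel):
    """Validated configuration for an end-to-end run."""

    mode: Literal["synthetic", "files"] = "synthetic"
    n_subjects: int = 27
    n_pz: int = 17
    coupling_rho: float = -0.5
    manifest: Optional[Path] = None
    thresholds: list[int] = Field(default=list(DEFAULT_THRESHOLDS))
    b_value: float = 800.0
    reference_method: str = REFERENCE_METHOD
    methods: list[str] = Field(default=["CT_reference", "MRI_like", "DL_like"])
    out_dir: Path = Path("petadc_out")
    seed: int = 0
    log_level: str = "INFO"
    render_heatmaps: bool = False

    @field_validator("thresholds")
    @classmethod
    def _thresholds_increasing(cls, v: list[int]) -> list[int]:
        if v != sorted(set(v)) or any(not 0 < p <= 100 for p in v):
            raise ValueError("thresholds must be strictly increasing integers in (0, 100]")
        return v

    @field_validator("b_value")
    @classmethod
    def _b_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("b_value must be positive")
        return v

    @classmethod
    def from_file(cls, path: Path | str) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.model_validate(data or {})

    def config_hash(self) -> str:
        """Hash of the scientific configuration only: where the outputs go,
        how loudly we log and whether PNGs are rendered do not change the
        numbers, so they are excluded."""
        payload = self.model_dump(mode="json")
        for key in ("out_dir", "log_level", "render_heatmaps"):
            payload.pop(key, None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    """RAS+ affine with the voxel spacing on the diagonal."""
    return np.diag([*spacing, 1.0])


def _save_nifti(values: np.ndarray, spacing, path: Path, dtype=np.float64) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=dtype), _affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {values.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return values, spacing


def write_subject(subject: SubjectData, out_dir: Path | str) -> dict:
    """Write one subject as NIfTI volumes plus a JSON sidecar.

    Volumes are float64 (lossless round trip); the ROI mask is uint8. The
    sidecar carries the dose record, ground-truth lesion means, zone, and
    the unit tag of every volume.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp = subject.true_adc.spacing_mm
    paths: dict[str, str] = {}
    volumes = {
        "dwi_b0": subject.dwi_b0,
        "dwi_b800": subject.dwi_b800,
        "true_adc": subject.true_adc,
        "true_suv": subject.true_suv,
    }
    for label, grid in subject.pet_by_method.items():
        volumes[f"pet_{label}"] = grid
    units = {}
    for name, grid in volumes.items():
        p = out / f"{subject.subject_id}_{name}.nii"
        _save_nifti(grid.values, sp, p)
        paths[name] = p.name
        units[name] = grid.units
    roi_path = out / f"{subject.subject_id}_roi.nii"
    _save_nifti(subject.roi.mask.astype(np.uint8), sp, roi_path, dtype=np.uint8)
    paths["roi"] = roi_path.name
    sidecar = {
        "subject_id": subject.subject_id,
        "zone": subject.roi.zone,
        "dose": {
            "injected_activity_MBq": subject.dose.injected_activity_MBq,
            "body_weight_kg": subject.dose.body_weight_kg,
            "injection_to_scan_s": subject.dose.injection_to_scan_s,
            "half_life_s": subject.dose.half_life_s,
            "branching_factor": subject.dose.branching_factor,
        },
        "truth": subject.truth,
        "units": units,
        "files": paths,
    }
    sidecar_path = out / f"{subject.subject_id}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return sidecar


def read_subject(subject_dir: Path | str, subject_id: str) -> SubjectData:
    """Load a subject written by :func:`write_subject`.

    The dose sidecar is required before any volume is read; all grids
    must be congruent (shape equal, spacing within 1e-3 mm) — there is no
    resampling, since registration is outside this pipeline's scope.
    """
    d = Path(subject_dir)
    sidecar_path = d / f"{subject_id}.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing dose sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    dose = DoseRecord(**sidecar["dose"])
    files = sidecar["files"]
    units = sidecar.get("units", {})

    grids: dict[str, VoxelGrid] = {}
    ref_shape = None
    ref_spacing = None
    for name, fname in files.items():
        if name == "roi":
            continue
        values, spacing = _load_nifti(d / fname)
        if ref_shape is None:
            ref_shape, ref_spacing = values.shape, spacing
        elif values.shape != ref_shape or any(
            abs(a - b) > SPACING_TOL_MM for a, b in zip(spacing, ref_spacing)
        ):
            raise ValueError(
                f"{fname}: grid {values.shape}@{spacing} incongruent with "
                f"{ref_shape}@{ref_spacing}; co-registration/resampling is out of scope"
            )
        grids[name] = VoxelGrid(values, spacing, units=units.get(name, "signal_au"))

    roi_values, roi_spacing = _load_nifti(d / files["roi"])
    if roi_values.shape != ref_shape:
        raise ValueError(
            f"ROI shape {roi_values.shape} incongruent with volumes {ref_shape}"
        )
    roi = ROIMask(roi_values > 0.5, zone=sidecar["zone"], provenance="manual")

    pet_by_method = {
        name[len("pet_"):]: grid for name, grid in grids.items() if name.startswith("pet_")
    }
    return SubjectData(
        subject_id=sidecar["subject_id"],
        true_adc=grids["true_adc"],
        true_suv=grids["true_suv"],
        dwi_b0=grids["dwi_b0"],
        dwi_b800=grids["dwi_b800"],
        pet_by_method=pet_by_method,
        roi=roi,
        dose=dose,
        truth=sidecar.get("truth", {}),
    )


def write_cohort(subjects: Sequence[SubjectData], out_dir: Path | str) -> Path:
    """Write every subject plus a cohort manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        write_subject(s, out)
        rows.append(
            {
                "subject_id": s.subject_id,
                "zone": s.roi.zone,
                "truth_adc_mean": s.truth.get("adc_mean", np.nan),
                "truth_suv_mean": s.truth.get("suv_mean", np.nan),
                "sidecar": f"{s.subject_id}.json",
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: Path | str) -> list[SubjectData]:
    """Load a cohort from its manifest, skipping unreadable subjects.

    Per-subject failures are logged and the run proceeds with the
    survivors; fewer than 3 readable subjects is an error.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    subjects = []
    failures: dict[str, str] = {}
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        try:
            subjects.append(read_subject(manifest_path.parent, sid))
        except (OSError, ValueError, KeyError, nib.filebasedimages.ImageFileError) as exc:
            failures[sid] = str(exc)
            logger.warning("excluding subject %s: %s", sid, exc)
    if len(subjects) < 3:
        raise ValueError(
            f"only {len(subjects)} readable subjects (need >= 3); failures: {failures}"
        )
    return subjects


def render_heatmap(grid: CorrelationGrid, path: Path | str) -> Path:
    """Render a 6x6 annotated Spearman heatmap (symmetric scale over [-1, 1]).

    Missing (NaN) cells are hatched, never interpolated.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    k = len(grid.feature_names)
    fig, ax = plt.subplots(figsize=(6.4, 5.4))
    masked = np.ma.masked_invalid(grid.rho)
    im = ax.imshow(masked, vmin=-1.0, vmax=1.0, cmap="RdBu_r")
    for i in range(k):
        for j in range(k):
            if np.isnan(grid.rho[i, j]):
                ax.add_patch(
                    plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False, hatch="///")
                )
            else:
                ax.text(
                    j, i, f"{grid.rho[i, j]:.2f}", ha="center", va="center", fontsize=8
                )
    ax.set_xticks(range(k), [f"SUV {f}" for f in grid.feature_names], rotation=45, ha="right")
    ax.set_yticks(range(k), [f"ADC {f}" for f in grid.feature_names])
    title = f"{grid.method_label}, "
    title += "manual ROI" if grid.threshold_pct == 0 else f"{grid.threshold_pct}% threshold"
    ax.set_title(f"Spearman rho ({title}, n={grid.n})")
    fig.colorbar(im, ax=ax, label="rho")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def _grid_to_csv(grid: CorrelationGrid, path: Path, provenance: dict) -> None:
    rho = grid.to_frame("rho").add_suffix("_rho")
    p = grid.to_frame("p").add_suffix("_p")
    out = pd.concat([rho, p], axis=1)
    for k, v in provenance.items():
        out[k] = v
    out.to_csv(path, index_label="adc_feature")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all artifacts under ``config.out_dir``.

    Returns a dict with the in-memory results (feature tables, grids,
    error report) and the paths written.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    provenance = {"seed": config.seed, "config_hash": chash}

    if config.mode == "synthetic":
        spec = PhantomSpec(coupling_rho=config.coupling_rho)
        subjects = generate_cohort(
            spec,
            n_subjects=config.n_subjects,
            n_pz=config.n_pz,
            seed=config.seed,
            methods=config.methods,
        )
    else:
        if config.manifest is None:
            raise ValueError("files mode requires a manifest path")
        subjects = read_cohort(config.manifest)

    pcts = [0, *config.thresholds]
    tables: dict[tuple[str, int], pd.DataFrame] = {}
    grids: dict[tuple[str, int], CorrelationGrid] = {}
    paths: dict[str, str] = {}
    (out / "features").mkdir(exist_ok=True)
    (out / "correlations").mkdir(exist_ok=True)
    for method in config.methods:
        for pct in pcts:
            table = cohort_feature_table(
                subjects,
                method,
                pct,
                b_value_s_mm2=config.b_value,
                reference_label=config.reference_method,
            )
            for k, v in provenance.items():
                table[k] = v
            fpath = out / "features" / f"features_{method}_t{pct:02d}.csv"
            table.to_csv(fpath, index=False)
            tables[(method, pct)] = table
            grid = correlation_grid(table, method, pct)
            gpath = out / "correlations" / f"corr_{method}_t{pct:02d}.csv"
            _grid_to_csv(grid, gpath, provenance)
            grids[(method, pct)] = grid
            if config.render_heatmaps:
                render_heatmap(grid, out / "heatmaps" / f"corr_{method}_t{pct:02d}.png")
    paths["features_dir"] = str(out / "features")
    paths["correlations_dir"] = str(out / "correlations")

    report = None
    others = [m for m in config.methods if m != config.reference_method]
    if others:
        report = feature_error_report(
            subjects,
            config.reference_method,
            others,
            threshold_pct=0,
            b_value_s_mm2=config.b_value,
        )
        rtable = report.table.copy()
        for k, v in provenance.items():
            rtable[k] = v
        rpath = out / "error_report.csv"
        rtable.to_csv(rpath)
        paths["error_report"] = str(rpath)

    manifest = {
        "config": config.model_dump(mode="json"),
        "config_hash": chash,
        "seed": config.seed,
        "petadc_version": __version__,
        "n_subjects_analyzed": len(subjects),
    }
    mpath = out / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["run_manifest"] = str(mpath)

    return {
        "subjects": subjects,
        "feature_tables": tables,
        "correlation_grids": grids,
        "error_report": report,
        "paths": paths,
    }
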