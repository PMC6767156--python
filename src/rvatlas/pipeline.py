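"""End-to-end discovery and validation runs.

The discovery arm chains excursion → pointwise covariate-adjusted map →
permutation/FDR significance → contiguous patch → patch PCA → SPM-O
location.  The validation arm consumes a *disjoint* cohort and runs the
marker-comparison battery.  Every run writes a manifest recording seeds,
configuration and package version, which suffices to reproduce every number
in every report.
"""

from __future__ import annotations

import json
import hashlib
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mesh import axial_coordinate, plane_vertices, surface_area
from .massuni import Patch, PointwiseMapResult, extract_patch, pointwise_map
from .marker import (
    MarkerDefinition,
    patch_pca,
    reconstruction_correlation,
    select_spm_o,
)
from .motion import local_frames, decompose_excursion, composition_percentages
from .synthetic import CohortDataset
from .validation import ValidationReport, validate_markers
from .io import write_json, write_vtk

__all__ = ["PipelineConfig", "DiscoveryResult", "run_discovery", "run_validation"]


@dataclass
class PipelineConfig:
    """Statistical and numerical settings for a pipeline run."""

    alpha: float = 0.05
    n_perm: int = 10_000
    n_boot: int = 10_000
    plane_tolerance_mm: float = 2.0
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("n_perm", "n_boot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DiscoveryResult:
    map: PointwiseMapResult
    patch: Patch
    components: list[dict]
    marker: MarkerDefinition | None
    pc1_variance_ratio: float | None
    composition: dict[str, float] | None
    manifest: dict = field(default_factory=dict)


def _manifest(config: PipelineConfig, stage: str, extra: dict | None = None) -> dict:
    cfg = asdict(config)
    m = {
        "stage": stage,
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        "elapsed_s": None,
    }
    if extra:
        m.update(extra)
    return m


def run_discovery(dataset: CohortDataset, config: PipelineConfig) -> DiscoveryResult:
    """Discovery arm on one cohort; writes artefacts if config.outdir is set."""
    t0 = time.perf_counter()
    mesh = dataset.mesh
    axial = axial_coordinate(mesh)
    pm = pointwise_map(
        dataset.excursion,
        dataset.covariates,
        dataset.rvef,
        n_perm=config.n_perm,
        n_boot=config.n_boot,
        alpha=config.alpha,
        seed=config.seed,
    )
    patch, components = extract_patch(pm.mask, mesh, axial)

    marker = None
    pc1_var = None
    composition = None
    if not patch.empty and patch.vertices.size >= 2:
        pca = patch_pca(dataset.excursion[:, patch.vertices])
        pc1_var = float(pca.explained_variance_ratio[0])
        corr = reconstruction_correlation(pca, dataset.excursion[:, patch.vertices], k=1)
        plane_set = plane_vertices(mesh, config.plane_tolerance_mm)
        try:
            marker = select_spm_o(corr, patch, plane_set, mesh)
        except ValueError:
            marker = None
        frames, _ = local_frames(mesh)
        comps = decompose_excursion(dataset.excursion_vectors, frames)
        composition = composition_percentages(comps, patch.vertices)

    manifest = _manifest(config, "discovery", {
        "n_subjects": dataset.n_subjects,
        "n_vertices": mesh.n_vertices,
        "total_surface_cm2": surface_area(mesh),
        "significant": not patch.empty,
    })
    manifest["elapsed_s"] = round(time.perf_counter() - t0, 3)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        pm.to_frame().to_csv(out / "pointwise_stats.csv", index=False)
        write_vtk(
            out / "pointwise_map.vtk",
            mesh.vertex_positions,
            mesh.faces,
            point_scalars={
                "slope": pm.slope,
                "q_fdr": pm.q_fdr,
                "significant": pm.mask.astype(float),
            },
        )
        write_json(out / "patch.json", {
            "patch": patch.summary(),
            "all_components": components,
            "vertices": [int(v) for v in patch.vertices],
        })
        if marker is not None:
            write_json(out / "marker.json", marker.to_dict())
        write_json(out / "manifest_discovery.json", manifest)

    return DiscoveryResult(
        map=pm,
        patch=patch,
        components=components,
        marker=marker,
        pc1_variance_ratio=pc1_var,
        composition=composition,
        manifest=manifest,
    )


def run_validation(
    dataset: CohortDataset, config: PipelineConfig, reference: str = "SPM-O"
) -> ValidationReport:
    """Validation arm: marker battery on a (disjoint) cohort."""
    missing = [m for m in ("SPM-O", "SFD-F", "TAPSE-F", "TAPSE", "SFD")
               if m not in dataset.markers.columns]
    if missing:
        raise KeyError(f"markers table is missing columns: {missing}")
    t0 = time.perf_counter()
    report = validate_markers(
        dataset.markers,
        dataset.covariates,
        dataset.rvef,
        dataset.edv,
        reference=reference,
        n_boot=config.n_boot,
        seed=config.seed,
    )
    manifest = _manifest(config, "validation", {"n_subjects": dataset.n_subjects})
    manifest["elapsed_s"] = round(time.perf_counter() - t0, 3)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(out / "validation_report.json", report.to_dict())
        pd.DataFrame(
            {
                m: {
                    "r": report.correlations[m]["r"],
                    "p_corr": report.correlations[m]["p"],
                    "steiger_p_vs_ref": report.steiger.get(m, {}).get("p", float("nan")),
                }
                for m in report.correlations
            }
        ).T.to_csv(out / "marker_correlations.csv", index_label="marker")
        pd.DataFrame(report.variance_fractions).T.to_csv(
            out / "variance_fractions.csv", index_label="marker"
        )
        pd.DataFrame(report.loo_errors_ml).T.to_csv(
            out / "loo_errors_ml.csv", index_label="marker"
        )
        write_json(out / "manifest_validation.json", manifest)
    return report
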