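"""Derivation of the optimised single-point marker (SPM-O).

Adjacent vertices move almost identically (multicollinearity), so the
discovered patch is summarised by principal component analysis of its
subjects × vertices excursion matrix.  Only the first component (PC1) is
retained — a deliberately conservative, single-variable summary directly
comparable to other single-point markers such as TAPSE.  The patch is then
reconstructed from PC1 alone, each vertex's reconstruction is correlated
with its original excursion, and the best-correlating vertex that coincides
with a conventional scanning plane becomes the marker location.  The marker
itself is the ED→ES displacement of that vertex in mm (and, in fractional
form, as a percentage of the base-to-apex axis length).

PCA operates on the column-centred but *unscaled* matrix: patch columns
share units (mm), so rescaling would only inflate low-variance vertices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .mesh import MeshGeometry, axial_coordinate
from .massuni import Patch
from .motion import MotionField, compute_excursion

__all__ = [
    "PCAResult",
    "MarkerDefinition",
    "patch_pca",
    "reconstruction_correlation",
    "select_spm_o",
    "measure_spm_o",
]


@dataclass
class PCAResult:
    """Orthogonal modes of patch motion variation.

    loadings — (vertices × components), orthonormal columns;
    explained_variance_ratio — non-increasing, sums to ≤ 1;
    scores — per-subject component scores; column_means — vertex means (mm).
    """

    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: np.ndarray
    column_means: np.ndarray
    n_retained: int = 1


@dataclass
class MarkerDefinition:
    """Location and provenance of the optimised single-point marker."""

    vertex: int
    reconstruction_correlation: float
    base_to_apex_fraction: float
    plane_name: str

    def to_dict(self) -> dict:
        return {
            "vertex": int(self.vertex),
            "reconstruction_correlation": float(self.reconstruction_correlation),
            "base_to_apex_fraction": float(self.base_to_apex_fraction),
            "plane": self.plane_name,
        }


def patch_pca(patch_matrix: np.ndarray) -> PCAResult:
    """Full PCA spectrum of the column-centred patch excursion matrix.

    PC1 is flagged as the retained component and oriented so that its score
    correlates positively with mean patch excursion.
    """
    X = np.asarray(patch_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("patch matrix must be (>=2 subjects, >=2 vertices)")
    Xc = X - X.mean(axis=0)
    if float(np.abs(Xc).max()) == 0.0:
        raise ValueError("patch matrix has zero variance")
    k = min(X.shape)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T
    mean_exc = X.mean(axis=1)
    r = np.corrcoef(scores[:, 0], mean_exc)[0, 1]
    if np.isfinite(r) and r < 0:
        scores[:, 0] *= -1.0
        loadings[:, 0] *= -1.0
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
        column_means=X.mean(axis=0),
    )


def reconstruction_correlation(
    pca: PCAResult, original: np.ndarray, k: int = 1
) -> np.ndarray:
    """Per-vertex Pearson correlation of the rank-k reconstruction with the
    original excursion column.

    Constant columns have undefined correlation; they are returned as NaN
    and excluded from marker selection downstream.
    """
    if k < 1 or k > pca.loadings.shape[1]:
        raise ValueError("k out of range")
    X = np.asarray(original, dtype=float)
    Xhat = pca.scores[:, :k] @ pca.loadings[:, :k].T + pca.column_means
    out = np.full(X.shape[1], np.nan)
    xs = X - X.mean(axis=0)
    hs = Xhat - Xhat.mean(axis=0)
    num = np.einsum("ij,ij->j", xs, hs)
    den = np.sqrt(np.einsum("ij,ij->j", xs, xs) * np.einsum("ij,ij->j", hs, hs))
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return out


def select_spm_o(
    correlations: np.ndarray,
    patch: Patch,
    plane_vertex_set: np.ndarray,
    mesh: MeshGeometry,
) -> MarkerDefinition:
    """Best plane-coinciding patch vertex by reconstruction correlation.

    ``correlations`` is indexed by position within the patch vertex list.
    Ties break to the smaller vertex index, making selection deterministic.
    """
    plane_set = set(np.asarray(plane_vertex_set).tolist())
    cand = [
        (i, v) for i, v in enumerate(patch.vertices.tolist())
        if v in plane_set and np.isfinite(correlations[i])
    ]
    if not cand:
        raise ValueError(
            "no patch vertex coincides with the scanning plane; "
            "increase the plane tolerance"
        )
    # max correlation, ties to the smaller vertex index
    best_i, best_v = max(cand, key=lambda iv: (correlations[iv[0]], -iv[1]))
    frac = axial_coordinate(mesh).fraction[best_v]
    return MarkerDefinition(
        vertex=int(best_v),
        reconstruction_correlation=float(correlations[best_i]),
        base_to_apex_fraction=float(frac),
        plane_name=mesh.plane_name,
    )


def measure_spm_o(
    motion: MotionField, marker: MarkerDefinition, mesh: MeshGeometry
) -> tuple[float, float]:
    """SPM-O for one subject: ED→ES displacement of the marker vertex.

    Returns ``(displacement_mm, fractional_pct)`` where the fractional form
    normalises by the subject's ED base-to-apex axis length.  Note the
    marker measures displacement, not deformation: a rigid translation of
    the whole ventricle registers in full.
    """
    if not (0 <= marker.vertex < motion.ed_positions.shape[0]):
        raise ValueError("marker vertex outside the motion field")
    exc = compute_excursion(motion)
    disp = float(exc.scalars[marker.vertex])
    base = motion.ed_positions[mesh.landmark_annulus].mean(axis=0)
    apex = motion.ed_positions[mesh.landmark_apex]
    axis_len = float(np.linalg.norm(apex - base))
    if axis_len <= 1e-12:
        raise ValueError("degenerate ED long axis")
    return disp, 100.0 * disp / axis_len
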