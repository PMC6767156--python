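"""Systolic excursion fields and their directional decomposition.

Regional function is quantified as *excursion*: the distance travelled in 3D
by each corresponded surface point from end-diastole (ED) to end-systole
(ES).  Each excursion vector is decomposed in a per-vertex orthonormal triad
aligned with the ventricular long axis: longitudinal (along the axis),
circumferential (tangent to the circle about the axis through the vertex)
and transverse (radial, toward/away from the axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import MeshGeometry

__all__ = [
    "MotionField",
    "ExcursionField",
    "compute_excursion",
    "local_frames",
    "decompose_excursion",
    "composition_percentages",
]

_COMPONENTS = ("longitudinal", "transverse", "circumferential")


@dataclass
class MotionField:
    """Per-subject ED and ES vertex positions (mm), corresponded to the mesh."""

    subject_id: str
    ed_positions: np.ndarray
    es_positions: np.ndarray

    def __post_init__(self) -> None:
        self.ed_positions = np.asarray(self.ed_positions, dtype=float)
        self.es_positions = np.asarray(self.es_positions, dtype=float)
        if self.ed_positions.shape != self.es_positions.shape:
            raise ValueError("ED and ES vertex counts differ")


@dataclass
class ExcursionField:
    """Per-vertex excursion: displacement vectors, scalar norms, components.

    ``components`` has columns (longitudinal, transverse, circumferential);
    the three components recompose the vector exactly in the local triad, so
    their squares sum to the squared scalar.
    """

    vectors: np.ndarray
    scalars: np.ndarray
    components: np.ndarray | None = None


def compute_excursion(motion: MotionField) -> ExcursionField:
    """ED→ES displacement vector and its Euclidean norm per vertex."""
    bad = ~np.isfinite(motion.ed_positions).all(axis=1) | ~np.isfinite(
        motion.es_positions
    ).all(axis=1)
    if bad.any():
        raise ValueError(
            f"non-finite coordinates at vertices {np.flatnonzero(bad)[:10].tolist()}"
        )
    vec = motion.es_positions - motion.ed_positions
    return ExcursionField(vectors=vec, scalars=np.linalg.norm(vec, axis=1))


def local_frames(mesh: MeshGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex orthonormal triad (longitudinal, transverse, circumferential).

    longitudinal — unit base→apex axis direction (identical at every vertex);
    circumferential — unit tangent to the circle about the long axis through
    the vertex; transverse — radial unit vector away from the axis, the cross
    product circumferential × longitudinal.

    Returns ``(frames, on_axis)`` where ``frames`` is (V, 3, 3) with rows
    (longitudinal, transverse, circumferential) and ``on_axis`` flags
    vertices lying on the axis, for which an arbitrary perpendicular is
    substituted.
    """
    base, u, length = mesh.long_axis()
    p = mesh.vertex_positions
    t = (p - base) @ u
    radial = p - (base + np.outer(t, u))
    rnorm = np.linalg.norm(radial, axis=1)
    on_axis = rnorm < 1e-9
    if on_axis.any():
        # arbitrary perpendicular to the axis for degenerate vertices
        ref = np.array([1.0, 0.0, 0.0])
        if abs(u @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        fallback = np.cross(u, ref)
        fallback /= np.linalg.norm(fallback)
        radial[on_axis] = fallback
        rnorm[on_axis] = 1.0
    radial = radial / rnorm[:, None]
    circ = np.cross(u[None, :], radial)
    circ /= np.linalg.norm(circ, axis=1)[:, None]
    longitudinal = np.broadcast_to(u, radial.shape)
    frames = np.stack([longitudinal, radial, circ], axis=1)
    return frames, on_axis


def decompose_excursion(vectors: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """Project excursion vectors onto the local triads.

    ``vectors`` is (V, 3) for one subject or (S, V, 3) for a cohort;
    the result has a trailing axis of length 3 ordered
    (longitudinal, transverse, circumferential).
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape[-2] != frames.shape[0]:
        raise ValueError("vertex count mismatch between vectors and frames")
    return np.einsum("...vj,vkj->...vk", vectors, frames)


def composition_percentages(
    components: np.ndarray, region: np.ndarray | None = None
) -> dict[str, float]:
    """Directional composition of motion in a region, as percentages.

    The contribution of each direction is the mean absolute component over
    the region's vertices (and subjects, if a cohort array is given),
    normalised so the three percentages sum to 100.  Mean absolute projection
    is used because the contributions are reported as positive shares.
    """
    comp = np.asarray(components, dtype=float)
    if region is not None:
        comp = comp[..., np.asarray(region, dtype=np.int64), :]
    mags = np.abs(comp).reshape(-1, 3).mean(axis=0)
    total = mags.sum()
    if total == 0:
        return {k: 0.0 for k in _COMPONENTS}
    pct = 100.0 * mags / total
    return dict(zip(_COMPONENTS, pct.tolist()))


def component_excursion_summary(
    components: np.ndarray, region: np.ndarray
) -> dict[str, dict[str, float]]:
    """Median (IQR [range]) of per-subject mean absolute component excursion.

    Summarised across subjects at the region (patch) level; ``components``
    must be a cohort array (S, V, 3).
    """
    comp = np.abs(components[:, np.asarray(region, dtype=np.int64), :]).mean(axis=1)
    out: dict[str, dict[str, float]] = {}
    for k, name in enumerate(_COMPONENTS):
        x = comp[:, k]
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        out[name] = {
            "median_mm": float(med),
            "iqr_low_mm": float(q1),
            "iqr_high_mm": float(q3),
            "min_mm": float(x.min()),
            "max_mm": float(x.max()),
        }
    return out
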