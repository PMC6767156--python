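"""Synthetic RV cohort generator.

No imaging cohort ships with this package, so every analysis stage is
exercised on synthetic data built to have the statistical structure the
pipeline assumes:

* a corresponded half-ellipsoid stand-in for the RV wall surface, with apex
  and tricuspid-annulus landmarks and a four-chamber plane;
* a cohort whose patch-vertex excursion is linearly coupled to a latent
  global-function variable (RVEF) with covariate confounding and spatially
  correlated residual noise (squared-exponential kernel);
* per-vertex motion directions mixing longitudinal / transverse /
  circumferential components, with the mix varying apex-to-base;
* a 2D-marker table (TAPSE, TAPSE-F, SFD, SFD-F, SPM-O) drawn jointly with
  RVEF from a Gaussian copula hitting target correlations;
* repeat-scan replicates with additive measurement noise.

One global seed governs all sub-generators through ``numpy``
``SeedSequence`` spawning, so a dataset is fully reproducible from
``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm, norm

from .mesh import MeshGeometry, axial_coordinate
from .motion import MotionField, local_frames

__all__ = [
    "GeneratorConfig",
    "CohortDataset",
    "RepeatScan",
    "generate_mesh",
    "generate_cohort",
    "generate_markers",
    "generate_repeat_scan",
    "planted_patch_vertices",
    "default_patch_center",
]

MARKER_NAMES = ("SPM-O", "SFD-F", "TAPSE-F", "TAPSE", "SFD")

#: Target Pearson correlation of each marker with RVEF.
DEFAULT_MARKER_RVEF_CORR = {
    "SPM-O": 0.44,
    "SFD-F": 0.43,
    "TAPSE-F": 0.40,
    "TAPSE": 0.24,
    "SFD": 0.22,
}

#: Plausible healthy-adult marker scales: (mean, SD).  TAPSE/SFD/SPM-O are
#: displacements in mm; the fractional forms are percentages.
MARKER_SCALES = {
    "SPM-O": (10.0, 2.5),
    "SFD-F": (30.0, 6.0),
    "TAPSE-F": (24.0, 4.0),
    "TAPSE": (22.0, 3.5),
    "SFD": (13.0, 3.0),
}

#: Pairwise correlations between markers (same-axis pairs high, the raw and
#: fractional form of a measure highly correlated).
DEFAULT_MARKER_MARKER_CORR = {
    ("SPM-O", "TAPSE"): 0.45,
    ("SPM-O", "TAPSE-F"): 0.50,
    ("SPM-O", "SFD"): 0.40,
    ("SPM-O", "SFD-F"): 0.50,
    ("TAPSE", "TAPSE-F"): 0.75,
    ("TAPSE", "SFD"): 0.40,
    ("TAPSE", "SFD-F"): 0.35,
    ("TAPSE-F", "SFD"): 0.35,
    ("TAPSE-F", "SFD-F"): 0.60,
    ("SFD", "SFD-F"): 0.75,
}

RACE_LEVELS = ("African", "Afro-Caribbean", "Asian", "Caucasian", "Chinese", "Other")
RACE_PROPORTIONS = (0.03, 0.05, 0.12, 0.75, 0.02, 0.03)


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    The defaults encode the emulated study conditions: 300 subjects per
    cohort, RVEF median 57 (IQR 52–62, range 40–73) %, covariates drawn from
    the healthy-volunteer baseline table, a contiguous basal-freewall signal
    patch with standardised RVEF effect 0.3, spatially correlated residual
    motion noise with a 10 mm correlation length, and marker–RVEF target
    correlations 0.44 / 0.43 / 0.40 / 0.24 / 0.22 for SPM-O, SFD-F, TAPSE-F,
    TAPSE and SFD.
    """

    n_subjects: int = 300
    n_vertices: int = 1000
    axis_length_mm: float = 70.0
    radius_mm: float = 25.0
    # signal patch: geodesic disc about a centre vertex; centre None means
    # "basal freewall on the four-chamber plane, 43% of the way from base to
    # apex" (the anatomy the discovery stage should find)
    patch_center: int | None = None
    patch_radius_mm: float = 20.0
    effect_size: float = 0.3  # standardised partial effect of excursion on RVEF
    # per-vertex excursion change (mm) per SD of covariate / per category:
    age_effect_mm: float = -0.4
    sex_effect_mm: float = 0.4
    bsa_effect_mm: float = 0.0
    race_effect_mm: float = 0.0
    noise_sd_mm: float = 1.5
    noise_corr_length_mm: float = 10.0
    baseline_base_mm: float = 10.0
    baseline_apex_mm: float = 4.0
    # directional mix (L1 weights) inside the patch: transverse 38%,
    # longitudinal 35%, circumferential 27%
    patch_mix: tuple[float, float, float] = (0.35, 0.38, 0.27)  # (long, trans, circ)
    rvef_mean: float = 57.0
    rvef_sd: float = 7.4
    rvef_bounds: tuple[float, float] = (40.0, 73.0)
    edv_mean_ml: float = 140.0
    edv_sd_ml: float = 25.0
    marker_rvef_corr: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_RVEF_CORR)
    )
    marker_marker_corr: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_MARKER_CORR)
    )
    repeat_noise_sd_mm: float = 0.6
    repeat_edv_noise_ml: float = 3.0
    repeat_rvef_noise: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd_mm", "repeat_noise_sd_mm", "repeat_edv_noise_ml",
                     "repeat_rvef_noise", "rvef_sd", "edv_sd_ml"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        # fail fast on a non-PSD copula target
        C = self.joint_correlation()
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-10:
            raise ValueError(
                f"marker/RVEF target correlation matrix is not positive "
                f"semi-definite (min eigenvalue {w.min():.3g})"
            )

    def joint_correlation(self) -> np.ndarray:
        """6x6 correlation matrix over (RVEF, SPM-O, SFD-F, TAPSE-F, TAPSE, SFD)."""
        names = ("RVEF",) + MARKER_NAMES
        k = len(names)
        C = np.eye(k)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i >= j:
                    continue
                if a == "RVEF":
                    r = self.marker_rvef_corr[b]
                else:
                    r = self.marker_marker_corr.get((a, b), self.marker_marker_corr.get((b, a)))
                    if r is None:
                        raise KeyError(f"no target correlation for marker pair ({a}, {b})")
                C[i, j] = C[j, i] = r
        return C


@dataclass
class CohortDataset:
    """Corresponded cohort: excursion matrix joined to covariates and markers."""

    mesh: MeshGeometry
    excursion: np.ndarray  # (S, V) scalar excursion, mm
    excursion_vectors: np.ndarray  # (S, V, 3) displacement vectors, mm
    covariates: pd.DataFrame  # age, sex, race, bsa
    rvef: np.ndarray  # %
    edv: np.ndarray  # ml
    markers: pd.DataFrame  # SPM-O, SFD-F, TAPSE-F, TAPSE, SFD
    patch_vertices: np.ndarray | None = None  # planted signal patch (oracle)
    config: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        S = self.excursion.shape[0]
        if not (len(self.covariates) == S == len(self.rvef) == len(self.edv) == len(self.markers)):
            raise ValueError("inconsistent subject counts across cohort tables")
        if self.excursion.shape[1] != self.mesh.n_vertices:
            raise ValueError("excursion vertex count does not match the mesh")
        if np.any((self.rvef <= 0) | (self.rvef >= 100)):
            raise ValueError("RVEF must lie in (0, 100)")
        if np.any(self.covariates["bsa"].to_numpy() <= 0):
            raise ValueError("BSA must be positive")

    @property
    def n_subjects(self) -> int:
        return self.excursion.shape[0]

    def motion(self, subject: int) -> MotionField:
        """Motion field for one subject (ED = atlas positions, ES = ED + displacement)."""
        ed = self.mesh.vertex_positions
        return MotionField(
            subject_id=f"S{subject:04d}",
            ed_positions=ed,
            es_positions=ed + self.excursion_vectors[subject],
        )


@dataclass
class RepeatScan:
    """Second-occasion measurements for the test–retest analysis."""

    excursion: np.ndarray
    edv: np.ndarray
    rvef: np.ndarray


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

def generate_mesh(
    n_vertices: int = 1000,
    axis_length_mm: float = 70.0,
    radius_mm: float = 25.0,
    seed: int = 0,
) -> MeshGeometry:
    """Triangulated open half-ellipsoid standing in for the RV wall.

    The rim (annulus ring) lies in the z = 0 plane with the given radius;
    the apex pole sits at z = -axis_length.  Vertices are laid out on
    latitude rings, so the realised vertex count is the nearest ring-grid
    size to ``n_vertices``.  Construction is deterministic; the seed is
    accepted for interface uniformity.
    """
    del seed  # construction is fully deterministic
    if n_vertices < 50:
        raise ValueError("n_vertices must be >= 50")
    if axis_length_mm <= 0 or radius_mm <= 0:
        raise ValueError("axis length and radius must be positive")
    a, c = float(radius_mm), float(axis_length_mm)

    n_theta = max(8, int(round(np.sqrt(2.0 * (n_vertices - 1)))))
    n_rings = max(3, (n_vertices - 1) // n_theta)
    phis = np.linspace(0.0, np.pi / 2.0, n_rings + 1)[:-1]  # rim .. near-pole
    thetas = 2.0 * np.pi * np.arange(n_theta) / n_theta

    verts = []
    for phi in phis:
        r = a * np.cos(phi)
        z = -c * np.sin(phi)
        verts.append(np.column_stack([r * np.cos(thetas), r * np.sin(thetas),
                                      np.full(n_theta, z)]))
    vertices = np.vstack(verts + [np.array([[0.0, 0.0, -c]])])
    apex_idx = vertices.shape[0] - 1

    faces = []
    for i in range(n_rings - 1):
        base0 = i * n_theta
        base1 = (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append((base0 + j, base0 + jn, base1 + j))
            faces.append((base0 + jn, base1 + jn, base1 + j))
    last = (n_rings - 1) * n_theta
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append((last + j, last + jn, apex_idx))

    return MeshGeometry(
        vertex_positions=vertices,
        faces=np.asarray(faces, dtype=np.int64),
        landmark_apex=apex_idx,
        landmark_annulus=np.arange(n_theta, dtype=np.int64),
        # four-chamber plane: contains the long axis (z) and the
        # freewall–septum bisector (+x) -> the xz-plane
        plane_point=np.zeros(3),
        plane_normal=np.array([0.0, 1.0, 0.0]),
        plane_name="four-chamber",
    )


def half_ellipsoid_area_cm2(axis_length_mm: float, radius_mm: float) -> float:
    """Analytic surface area of the half prolate spheroid (cm²)."""
    a, c = float(radius_mm), float(axis_length_mm)
    if c <= a:
        raise ValueError("expected a prolate spheroid (axis length > radius)")
    e = np.sqrt(1.0 - (a / c) ** 2)
    full = 2.0 * np.pi * a**2 * (1.0 + (c / (a * e)) * np.arcsin(e))
    return float(full / 2.0 / 100.0)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def default_patch_center(mesh: MeshGeometry, base_to_apex_fraction: float = 0.43) -> int:
    """Vertex nearest the freewall/four-chamber-plane intersection at the
    given base-to-apex fraction — the anatomical location the emulated
    signal patch is centred on."""
    ax = axial_coordinate(mesh)
    base, u, length = mesh.long_axis()
    axis_point = base + u * base_to_apex_fraction * length
    pos = mesh.vertex_positions
    # freewall side: +x half, close to the four-chamber (xz) plane
    d_plane = np.abs((pos - mesh.plane_point) @ mesh.plane_normal)
    score = (
        np.abs(ax.fraction - base_to_apex_fraction) * length
        + d_plane
        + np.where(pos[:, 0] > 0, 0.0, 1e6)
    )
    return int(np.argmin(score))


def planted_patch_vertices(
    mesh: MeshGeometry, center: int, radius_mm: float
) -> np.ndarray:
    """Geodesic disc of vertices within ``radius_mm`` of the centre vertex.

    Graph geodesics over mesh edges with Euclidean edge lengths.
    """
    from scipy.sparse.csgraph import dijkstra

    adj = mesh.adjacency.tocoo()
    pos = mesh.vertex_positions
    w = np.linalg.norm(pos[adj.row] - pos[adj.col], axis=1)
    import scipy.sparse as sp

    g = sp.csr_matrix((w, (adj.row, adj.col)), shape=adj.shape)
    dist = dijkstra(g, directed=False, indices=center)
    return np.flatnonzero(dist <= radius_mm)


def _sample_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = rng.uniform(19.0, 72.0, n)
    sex = (rng.random(n) < 0.55).astype(int)  # 1 = female
    race = rng.choice(len(RACE_LEVELS), size=n, p=RACE_PROPORTIONS)
    bsa = np.clip(rng.normal(1.80, 0.15, n), 1.2, 2.7)
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "race": pd.Categorical.from_codes(race, categories=list(RACE_LEVELS)),
            "bsa": bsa,
        }
    )


def _spatial_noise_factor(mesh: MeshGeometry, corr_length_mm: float) -> np.ndarray:
    """Cholesky factor of the squared-exponential vertex covariance."""
    pos = mesh.vertex_positions
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-0.5 * d2 / corr_length_mm**2)
    K[np.diag_indices_from(K)] += 1e-8
    return np.linalg.cholesky(K)


def generate_markers(
    config: GeneratorConfig, z_rvef: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Marker table drawn from the Gaussian copula, conditional on the
    latent standard-normal RVEF scores ``z_rvef``."""
    C = config.joint_correlation()
    n = z_rvef.shape[0]
    # condition the 5 marker coordinates on the RVEF coordinate
    c01 = C[0, 1:]
    S_cond = C[1:, 1:] - np.outer(c01, c01)
    L = np.linalg.cholesky(S_cond + 1e-12 * np.eye(5))
    z_m = np.outer(z_rvef, c01) + rng.standard_normal((n, 5)) @ L.T
    cols = {}
    for k, name in enumerate(MARKER_NAMES):
        mu, sd = MARKER_SCALES[name]
        cols[name] = mu + sd * z_m[:, k]
    return pd.DataFrame(cols)


def _truncnorm_from_z(z: np.ndarray, mean: float, sd: float,
                      lo: float, hi: float) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = norm.cdf(z)
    # keep strictly inside the open interval
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


class CohortGenerator:
    """Reusable generator bound to one mesh.

    Building the spatial-noise Cholesky factor is the expensive step, so the
    class computes it once and then draws independent cohorts cheaply —
    useful for Monte-Carlo replicate studies.
    """

    def __init__(self, config: GeneratorConfig, mesh: MeshGeometry | None = None):
        self.config = config
        self.mesh = mesh if mesh is not None else generate_mesh(
            config.n_vertices, config.axis_length_mm, config.radius_mm
        )
        self._L_noise = _spatial_noise_factor(self.mesh, config.noise_corr_length_mm)
        center = (
            config.patch_center
            if config.patch_center is not None
            else default_patch_center(self.mesh)
        )
        self.patch = planted_patch_vertices(self.mesh, center, config.patch_radius_mm)
        self._axial = axial_coordinate(self.mesh)
        self._frames, _ = local_frames(self.mesh)
        self._directions, self._weights = self._direction_field()

    def _direction_field(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit motion direction per vertex from the L1 component weights.

        Inside the patch the weights are the configured patch mix; elsewhere
        the longitudinal share ramps apex-to-base (motion is more
        longitudinal toward the base), with the remainder split between
        transverse and circumferential in the patch-mix ratio.
        """
        cfg = self.config
        V = self.mesh.n_vertices
        frac = self._axial.fraction  # 0 base .. 1 apex
        w = np.empty((V, 3))
        w_long = 0.25 + 0.20 * (1.0 - frac)  # 0.45 at base, 0.25 at apex
        rest = 1.0 - w_long
        t_share = cfg.patch_mix[1] / (cfg.patch_mix[1] + cfg.patch_mix[2])
        w[:, 0] = w_long
        w[:, 1] = rest * t_share
        w[:, 2] = rest * (1.0 - t_share)
        w[self.patch] = np.asarray(cfg.patch_mix)
        # direction = weighted triad sum; sign: longitudinal toward apex,
        # transverse inward (systolic contraction), circumferential +.
        d = (
            w[:, 0:1] * self._frames[:, 0, :]
            - w[:, 1:2] * self._frames[:, 1, :]
            + w[:, 2:3] * self._frames[:, 2, :]
        )
        d /= np.linalg.norm(d, axis=1)[:, None]
        return d, w

    def generate(self, seed: int | None = None) -> CohortDataset:
        cfg = self.config
        root = np.random.SeedSequence(cfg.seed if seed is None else seed)
        rng_cov, rng_rvef, rng_mark, rng_noise, rng_edv = (
            np.random.default_rng(s) for s in root.spawn(5)
        )
        S, V = cfg.n_subjects, self.mesh.n_vertices

        cov = _sample_covariates(S, rng_cov)
        z_rvef = rng_rvef.standard_normal(S)
        rvef = _truncnorm_from_z(z_rvef, cfg.rvef_mean, cfg.rvef_sd, *cfg.rvef_bounds)
        edv = np.clip(rng_edv.normal(cfg.edv_mean_ml, cfg.edv_sd_ml, S), 60.0, 260.0)
        markers = generate_markers(cfg, z_rvef, rng_mark)

        frac = self._axial.fraction
        baseline = cfg.baseline_apex_mm + (cfg.baseline_base_mm - cfg.baseline_apex_mm) * (
            1.0 - frac
        )
        # standardised partial effect rho -> slope in mm per SD of RVEF,
        # against residual noise SD sigma: gamma = sigma * rho / sqrt(1-rho^2)
        rho = cfg.effect_size
        gamma = cfg.noise_sd_mm * rho / np.sqrt(max(1.0 - rho**2, 1e-12)) if rho else 0.0
        coupling = np.zeros(V)
        coupling[self.patch] = gamma

        z_age = (cov["age"].to_numpy() - 45.5) / 15.3  # uniform(19,72) moments
        z_bsa = (cov["bsa"].to_numpy() - 1.80) / 0.15
        sexv = cov["sex"].to_numpy().astype(float)
        race_nonref = (cov["race"] != "Caucasian").to_numpy().astype(float)
        subject_shift = (
            cfg.age_effect_mm * z_age
            + cfg.sex_effect_mm * sexv
            + cfg.bsa_effect_mm * z_bsa
            + cfg.race_effect_mm * race_nonref
        )

        eta = rng_noise.standard_normal((S, V))
        noise = cfg.noise_sd_mm * (eta @ self._L_noise.T)
        scalars = baseline[None, :] + np.outer(z_rvef, coupling) + subject_shift[:, None] + noise
        scalars = np.maximum(scalars, 0.05)

        vectors = scalars[:, :, None] * self._directions[None, :, :]

        return CohortDataset(
            mesh=self.mesh,
            excursion=scalars,
            excursion_vectors=vectors,
            covariates=cov,
            rvef=rvef,
            edv=edv,
            markers=markers,
            patch_vertices=self.patch,
            config=cfg,
        )


def generate_cohort(
    config: GeneratorConfig, mesh: MeshGeometry | None = None, seed: int | None = None
) -> CohortDataset:
    """One-shot cohort generation (see :class:`CohortGenerator` for reuse)."""
    return CohortGenerator(config, mesh).generate(seed)


def generate_repeat_scan(
    dataset: CohortDataset, noise_sd_mm: float | None = None, seed: int = 0
) -> RepeatScan:
    """Second-occasion replicate: original measurements plus independent noise.

    Per-vertex excursion gains Gaussian noise of SD ``noise_sd_mm``; the
    derived volume measurements (EDV, RVEF) gain their own measurement noise
    from the generator config.
    """
    cfg = dataset.config if dataset.config is not None else GeneratorConfig()
    sd = cfg.repeat_noise_sd_mm if noise_sd_mm is None else noise_sd_mm
    if sd < 0:
        raise ValueError("noise SD must be >= 0")
    root = np.random.SeedSequence(seed)
    rng_e, rng_v, rng_f = (np.random.default_rng(s) for s in root.spawn(3))
    exc2 = dataset.excursion + sd * rng_e.standard_normal(dataset.excursion.shape)
    edv2 = dataset.edv + cfg.repeat_edv_noise_ml * rng_v.standard_normal(dataset.edv.shape)
    rvef2 = np.clip(
        dataset.rvef + cfg.repeat_rvef_noise * rng_f.standard_normal(dataset.rvef.shape),
        1.0,
        99.0,
    )
    return RepeatScan(excursion=exc2, edv=edv2, rvef=rvef2)
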