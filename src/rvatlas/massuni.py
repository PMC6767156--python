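"""Mass-univariate discovery of RVEF-associated surface regions.

One covariate-adjusted linear model is fitted per mesh vertex: standardised
RVEF regressed on the standardised excursion of that vertex plus age, sex,
race and body surface area.  Because only the excursion column differs
between vertices, everything is computed through the Frisch–Waugh–Lovell
decomposition — excursion columns and the outcome are residualised against
the shared covariate block once, after which per-vertex slopes and
t-statistics are plain vectorised inner products.  This is algebraically
identical to refitting the full model per vertex (the tests check this
against a normal-equations oracle).

Significance is assessed by Freedman–Lane permutation: residuals of the
reduced (covariates-only) model are permuted, pseudo-outcomes rebuilt, and
the excursion t-statistic recomputed under the same permutation sequence for
every vertex.  Per-vertex p-values are then Benjamini–Hochberg adjusted and
the significant vertices reduced to connected patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .mesh import (
    AxialCoordinate,
    MeshGeometry,
    connected_vertex_components,
    surface_area,
)

__all__ = [
    "PointwiseMapResult",
    "Patch",
    "build_design",
    "fit_pointwise",
    "permutation_pvalues",
    "fdr_adjust",
    "extract_patch",
    "pointwise_map",
    "jaccard",
]


@dataclass
class PointwiseMapResult:
    """Per-vertex association statistics for excursion vs RVEF."""

    slope: np.ndarray  # standardised excursion-term slope
    t_stat: np.ndarray
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    p_perm: np.ndarray
    q_fdr: np.ndarray
    mask: np.ndarray  # q < alpha
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        d = {
            "vertex": np.arange(self.slope.shape[0]),
            "slope": self.slope,
            "t": self.t_stat,
            "p_perm": self.p_perm,
            "q_fdr": self.q_fdr,
            "significant": self.mask.astype(int),
        }
        if self.ci_low is not None:
            d["ci_low"] = self.ci_low
            d["ci_high"] = self.ci_high
        return pd.DataFrame(d)


@dataclass
class Patch:
    """A contiguous significant region of the RV surface."""

    vertices: np.ndarray
    area_cm2: float
    fraction_of_surface: float
    apex_distance_range_cm: tuple[float, float]
    centroid_mm: np.ndarray

    @property
    def empty(self) -> bool:
        return self.vertices.size == 0

    def summary(self) -> dict:
        return {
            "n_vertices": int(self.vertices.size),
            "area_cm2": self.area_cm2,
            "fraction_of_surface": self.fraction_of_surface,
            "apex_distance_min_cm": self.apex_distance_range_cm[0],
            "apex_distance_max_cm": self.apex_distance_range_cm[1],
            "centroid_mm": [float(x) for x in self.centroid_mm],
        }


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def build_design(covariates: pd.DataFrame) -> np.ndarray:
    """Covariate block: intercept, z(age), sex, race dummies, z(BSA).

    Continuous covariates are z-scored; race is dummy-coded against the
    largest observed class.  Dummies for levels absent from the sample (or
    constant columns) are dropped with a warning, keeping the design full
    rank in small cohorts.
    """
    n = len(covariates)
    cols = [np.ones(n)]
    if "age" in covariates:
        cols.append(_zscore(covariates["age"].to_numpy()))
    if "sex" in covariates:
        cols.append(covariates["sex"].to_numpy().astype(float))
    if "race" in covariates:
        race = covariates["race"].astype("category")
        counts = race.value_counts()
        ref = counts.idxmax()
        for level in race.cat.categories:
            if level == ref:
                continue
            d = (race == level).to_numpy().astype(float)
            if d.sum() == 0:
                warnings.warn(
                    f"race level {level!r} absent from sample; dummy dropped",
                    stacklevel=2,
                )
                continue
            cols.append(d)
    if "bsa" in covariates:
        cols.append(_zscore(covariates["bsa"].to_numpy()))
    Z = np.column_stack(cols)
    # drop any residual constant / collinear columns beyond the intercept
    keep = [0]
    for j in range(1, Z.shape[1]):
        if np.ptp(Z[:, j]) == 0:
            warnings.warn(f"constant covariate column {j} dropped", stacklevel=2)
            continue
        keep.append(j)
    return Z[:, keep]


def _residualize(A: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residual of each column of A after OLS projection onto Z."""
    coef, *_ = np.linalg.lstsq(Z, A, rcond=None)
    return A - Z @ coef


def _fwl_stats(
    Xs: np.ndarray, y_s: np.ndarray, Z: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-vertex slope and t of the excursion term via FWL.

    Xs — (n, V) standardised excursion columns; y_s — standardised outcome;
    Z — covariate block including intercept.  Returns (slope, t, x_res,
    y_res); degrees of freedom are those of the full model n - p - 1.
    """
    n, V = Xs.shape
    Xr = _residualize(Xs, Z)
    yr = _residualize(y_s[:, None], Z)[:, 0]
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    sxy = Xr.T @ yr
    ok = sxx > 1e-12
    slope = np.zeros(V)
    slope[ok] = sxy[ok] / sxx[ok]
    dof = n - Z.shape[1] - 1
    syy = float(yr @ yr)
    rss = syy - np.where(ok, sxy**2 / np.where(ok, sxx, 1.0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 0.0) / max(dof, 1) / np.where(ok, sxx, np.inf))
        t = slope / se
    # 0/0 (constant column) -> 0; nonzero slope with exact fit -> +/- inf
    t = np.where(ok, np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf), 0.0)
    return slope, t, Xr, yr


def fit_pointwise(
    excursion: np.ndarray,
    covariates: pd.DataFrame,
    rvef: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    boot_chunk: int = 200,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None, np.ndarray]:
    """Standardised per-vertex slopes with subject-resampling bootstrap CIs.

    Returns ``(slope, ci_low, ci_high, t)``; the CIs are 2.5–97.5 percentile
    intervals over ``n_boot`` nonparametric subject resamples (``n_boot=0``
    skips the bootstrap).
    """
    excursion = np.asarray(excursion, dtype=float)
    n, V = excursion.shape
    Z = build_design(covariates)
    if n <= Z.shape[1] + 2:
        raise ValueError("too few subjects for the covariate-adjusted model")
    if not (np.isfinite(excursion).all() and np.isfinite(rvef).all()):
        raise ValueError("missing or non-finite values in inputs")
    Xs = (excursion - excursion.mean(axis=0)) / np.where(
        excursion.std(axis=0) > 0, excursion.std(axis=0), 1.0
    )
    y_s = _zscore(rvef)
    slope, t, _, _ = _fwl_stats(Xs, y_s, Z)
    if n_boot <= 0:
        return slope, None, None, t

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, V))
    for start in range(0, n_boot, boot_chunk):
        stop = min(start + boot_chunk, n_boot)
        for b in range(start, stop):
            idx = rng.integers(0, n, n)
            bs, *_ = _fwl_stats(Xs[idx], y_s[idx], Z[idx])
            boots[b] = bs
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5], axis=0)
    return slope, ci_low, ci_high, t


def permutation_pvalues(
    excursion: np.ndarray,
    covariates: pd.DataFrame,
    rvef: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    perm_chunk: int = 500,
) -> np.ndarray:
    """Freedman–Lane permutation p-values for the excursion term.

    The same permutation sequence is shared across vertices; p = (1 + #{
    |t_perm| >= |t_obs| }) / (1 + n_perm).  Vertices with constant excursion
    have an undefined statistic and receive p = 1.
    """
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives very coarse p-value resolution", stacklevel=2)
    excursion = np.asarray(excursion, dtype=float)
    n, V = excursion.shape
    Z = build_design(covariates)
    sd = excursion.std(axis=0)
    ok = sd > 1e-12
    Xs = (excursion - excursion.mean(axis=0)) / np.where(ok, sd, 1.0)
    y_s = _zscore(rvef)

    _, t_obs, Xr, _ = _fwl_stats(Xs, y_s, Z)
    # reduced model: y on covariates only
    fitted = y_s - _residualize(y_s[:, None], Z)[:, 0]
    resid = y_s - fitted

    dof = n - Z.shape[1] - 1
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    sxx_safe = np.where(sxx > 1e-12, sxx, np.inf)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(V, dtype=np.int64)
    for start in range(0, n_perm, perm_chunk):
        m = min(perm_chunk, n_perm - start)
        E = np.empty((n, m))
        for k in range(m):
            E[:, k] = resid[rng.permutation(n)]
        Ystar = fitted[:, None] + E
        Yr = _residualize(Ystar, Z)
        num = Xr.T @ Yr  # (V, m)
        syy = np.einsum("ij,ij->j", Yr, Yr)  # (m,)
        rss = syy[None, :] - num**2 / sxx_safe[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            tperm = (num / sxx_safe[:, None]) / np.sqrt(
                np.maximum(rss, 0.0) / max(dof, 1) / sxx_safe[:, None]
            )
        tperm = np.nan_to_num(tperm, nan=0.0, posinf=0.0, neginf=0.0)
        exceed += (np.abs(tperm) >= np.abs(t_obs)[:, None] - 1e-12).sum(axis=1)
    p = (1.0 + exceed) / (1.0 + n_perm)
    p[~ok] = 1.0
    return p


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def extract_patch(
    mask: np.ndarray,
    mesh: MeshGeometry,
    axial: AxialCoordinate,
) -> tuple[Patch, list[dict]]:
    """Largest contiguous component of the significance mask, as a Patch.

    Returns the patch plus a sidecar listing every connected component.  An
    empty mask yields an explicit empty patch (no exception).
    """
    comps = connected_vertex_components(mesh, mask)
    total = surface_area(mesh)
    sidecar = []
    best: Patch | None = None
    for comp in comps:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            area = surface_area(mesh, comp)
        d_cm = axial.distance_from_apex[comp] / 10.0
        patch = Patch(
            vertices=comp,
            area_cm2=area,
            fraction_of_surface=area / total if total > 0 else 0.0,
            apex_distance_range_cm=(float(d_cm.min()), float(d_cm.max())),
            centroid_mm=mesh.vertex_positions[comp].mean(axis=0),
        )
        sidecar.append(patch.summary())
        if best is None or patch.area_cm2 > best.area_cm2:
            best = patch
    if best is None:
        best = Patch(
            vertices=np.array([], dtype=np.int64),
            area_cm2=0.0,
            fraction_of_surface=0.0,
            apex_distance_range_cm=(float("nan"), float("nan")),
            centroid_mm=np.full(3, np.nan),
        )
    return best, sidecar


def pointwise_map(
    excursion: np.ndarray,
    covariates: pd.DataFrame,
    rvef: np.ndarray,
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PointwiseMapResult:
    """Full discovery map: slopes + bootstrap CIs + permutation p + BH q."""
    seq = np.random.SeedSequence(seed)
    s_boot, s_perm = (int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(2))
    slope, lo, hi, t = fit_pointwise(excursion, covariates, rvef, n_boot=n_boot, seed=s_boot)
    p = permutation_pvalues(excursion, covariates, rvef, n_perm=n_perm, seed=s_perm)
    q = fdr_adjust(p)
    return PointwiseMapResult(
        slope=slope, t_stat=t, ci_low=lo, ci_high=hi,
        p_perm=p, q_fdr=q, mask=q < alpha, alpha=alpha,
    )


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B| between two vertex-index sets."""
    sa, sb = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
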