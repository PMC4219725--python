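"""Group statistics: exact Mann-Whitney U, age-adjusted ANCOVA, Pearson
correlation, voxel-wise GLM t-maps and permutation cluster-level FWE.

The cohorts here are tiny (six per group), which drives every choice:

* the Mann-Whitney test is computed *exactly* by enumerating all
  C(n+m, n) group assignments of the observed values (mid-rank ties);
* the ANCOVA is ordinary least squares on [intercept, group, age] with the
  group-coefficient t on n - 3 degrees of freedom;
* the voxel-wise two-sample t-test with age as nuisance covariate is the
  same OLS applied per voxel — the single-voxel map equals the scalar
  ANCOVA by construction (shared code path);
* cluster-level familywise-error control uses the permutation distribution
  of the maximum supra-threshold cluster size under group-label exchange,
  which is distribution-free and valid at n = 6 + 6 (full enumeration when
  few enough distinct relabelings exist).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .masking import PSFModel, gaussian_blur
from .volumes import BinaryMask, Volume3D

__all__ = [
    "GroupTestResult",
    "TMap",
    "ClusterInfo",
    "ClusterSet",
    "mann_whitney",
    "bonferroni_alpha",
    "ancova_group_age",
    "pearson_r2",
    "smooth_cohort",
    "voxelwise_glm_t",
    "cluster_fwe",
]

EXACT_ENUMERATION_LIMIT = 16   # max combined n for exact Mann-Whitney


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of one group comparison or correlation."""

    method: str
    statistic: float
    p_two_sided: float
    df: Optional[float] = None
    effect_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {self.p_two_sided}")


# ---------------------------------------------------------------------------
# scalar tests

def _u_statistic(xs: np.ndarray, ys: np.ndarray) -> float:
    """Mann-Whitney U for xs vs ys by pair counting, half credit for ties."""
    diff = xs[:, None] - ys[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(xs: Sequence[float], ys: Sequence[float],
                 mode: str = "exact") -> GroupTestResult:
    """Two-sided Mann-Whitney U test.

    ``exact`` enumerates every C(n+m, n) assignment of the observed pooled
    values to the two groups (valid under ties, feasible for combined
    n <= 16); ``normal_approx`` uses the tie-corrected normal
    approximation without continuity correction.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n, m = len(xs), len(ys)
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(xs, ys)

    if mode == "exact":
        if n + m > EXACT_ENUMERATION_LIMIT:
            raise ValueError(
                f"exact enumeration limited to combined n <= "
                f"{EXACT_ENUMERATION_LIMIT}; use mode='normal_approx'")
        pooled = np.concatenate([xs, ys])
        total = math.comb(n + m, n)
        n_le = n_ge = 0
        for comb in itertools.combinations(range(n + m), n):
            sel = np.zeros(n + m, dtype=bool)
            sel[list(comb)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            if u <= u_obs + 1e-9:
                n_le += 1
            if u >= u_obs - 1e-9:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return GroupTestResult("mann_whitney_exact", u_obs, p,
                               effect_summary={"n_x": n, "n_y": m,
                                               "n_assignments": total})
    if mode == "normal_approx":
        pooled = np.concatenate([xs, ys])
        N = n + m
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float((counts ** 3 - counts).sum())
        mu = n * m / 2.0
        var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
        if var <= 0:
            return GroupTestResult("mann_whitney_normal", u_obs, 1.0,
                                   effect_summary={"n_x": n, "n_y": m})
        z = (u_obs - mu) / math.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        return GroupTestResult("mann_whitney_normal", u_obs, p,
                               effect_summary={"z": z, "n_x": n, "n_y": m})
    raise ValueError(f"unknown mode {mode!r}")


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if m < 1:
        raise ValueError("comparison count must be >= 1")
    return alpha / m


def _ols_group_t(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """t statistic for the group column (column 1) of design X, per column
    of Y.  Shared by the scalar ANCOVA and the voxel-wise GLM.

    Y : (n, V).  Returns (t (V,), df).  Voxels with zero residual variance
    get t = +/-inf if the coefficient is nonzero, else 0.
    """
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError(f"not enough observations: n={n}, p={p}")
    XtX_inv = np.linalg.inv(X.T @ X)
    P = XtX_inv @ X.T                       # (p, n)
    B = P @ Y                               # (p, V)
    resid = Y - X @ B
    s2 = (resid ** 2).sum(axis=0) / df
    se2 = s2 * XtX_inv[1, 1]
    scale = np.maximum((Y ** 2).sum(axis=0), 1.0)
    zero_var = se2 <= 1e-24 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var,
                     np.where(np.abs(B[1]) > 1e-12 * np.sqrt(scale), np.inf, 0.0)
                     * np.sign(B[1]),
                     B[1] / np.sqrt(np.where(zero_var, 1.0, se2)))
    return t, df


def _design(group: Sequence[str | int], age: Sequence[float]) -> np.ndarray:
    """[intercept, MS indicator, age] design matrix, with rank checks."""
    g = np.asarray([1 if str(x) in ("MS", "1") else 0 for x in group], float)
    a = np.asarray(age, dtype=float)
    if g.min() == g.max():
        raise ValueError("design is rank deficient: only one group present")
    if np.ptp(a) == 0:
        raise ValueError("design is rank deficient: age is constant")
    X = np.column_stack([np.ones_like(a), g, a])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("design is rank deficient: age is collinear with group")
    return X


def ancova_group_age(y: Sequence[float], group: Sequence[str | int],
                     age: Sequence[float]) -> GroupTestResult:
    """Age-adjusted group comparison: OLS of y on [intercept, group, age],
    two-sided t test of the group coefficient, df = n - 3.

    Group is coded MS = 1, HV = 0, so a positive statistic means MS > HV.
    A perfect fit (zero residual variance) is reported as p < 1e-12.
    """
    y = np.asarray(y, dtype=float)
    X = _design(group, age)
    if len(y) != len(X):
        raise ValueError("y, group and age must have equal length")
    t, df = _ols_group_t(X, y[:, None])
    t0 = float(t[0])
    if not np.isfinite(t0):
        p = 0.0
    else:
        p = float(min(1.0, 2.0 * sps.t.sf(abs(t0), df)))
    g = X[:, 1].astype(bool)
    return GroupTestResult(
        "ancova", t0, p, df=df,
        effect_summary={"mean_ms": float(y[g].mean()),
                        "mean_hv": float(y[~g].mean()),
                        "group_coefficient": float(np.linalg.lstsq(X, y, rcond=None)[0][1])})


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> GroupTestResult:
    """Pearson product-moment correlation with R^2 and the two-sided p from
    t = r * sqrt((n-2) / (1-r^2)) on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need matched samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) >= 1.0:
        p = 0.0
        t = math.inf * math.copysign(1.0, r)
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(min(1.0, 2.0 * sps.t.sf(abs(t), df)))
    return GroupTestResult("pearson", r, p, df=df,
                           effect_summary={"r": r, "r2": r * r, "t": t, "n": n})


# ---------------------------------------------------------------------------
# voxel-wise inference

@dataclass(frozen=True)
class TMap:
    """A voxel-wise group-contrast t map with the data needed to rebuild it
    under label permutations."""

    vol: Volume3D                     # t scores; 0 outside the analysis mask
    df: int
    design: str
    n_zero_variance: int = 0
    # data retained for permutation inference
    _Y: np.ndarray | None = None      # (n_subjects, n_masked_voxels)
    _age: np.ndarray | None = None
    _group: np.ndarray | None = None  # MS = 1 / HV = 0
    _mask: np.ndarray | None = None   # boolean analysis mask


@dataclass(frozen=True)
class ClusterInfo:
    cluster_id: int
    voxel_count: int
    peak_t: float
    peak_location_mm: tuple[float, float, float]
    p_fwe_cluster: float


@dataclass(frozen=True)
class ClusterSet:
    """Supra-threshold clusters with cluster-level FWE-corrected p values."""

    clusters: list[ClusterInfo]
    forming_t: float
    forming_p: float
    connectivity: int
    n_permutations: int
    exhaustive: bool
    labels: Volume3D | None = None    # integer cluster-id image

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"cluster_id": c.cluster_id, "voxel_count": c.voxel_count,
              "peak_t": c.peak_t,
              "peak_x_mm": c.peak_location_mm[0],
              "peak_y_mm": c.peak_location_mm[1],
              "peak_z_mm": c.peak_location_mm[2],
              "p_fwe_cluster": c.p_fwe_cluster}
             for c in self.clusters])


def smooth_cohort(vols: Sequence[Volume3D], fwhm_mm: float = 12.0) -> list[Volume3D]:
    """Blur every subject volume with an isotropic Gaussian kernel (default
    12-mm FWHM), the usual preconditioning step before voxel-wise tests."""
    if not vols:
        return []
    psf = PSFModel(fwhm_mm=fwhm_mm)
    for v in vols[1:]:
        vols[0].require_same_grid(v, "cohort volumes")
    return [gaussian_blur(v, psf) for v in vols]


def voxelwise_glm_t(vols: Sequence[Volume3D], group: Sequence[str | int],
                    age: Sequence[float], analysis_mask: BinaryMask) -> TMap:
    """Per-voxel OLS on [intercept, group, age]; t map for the group
    contrast (positive = MS > HV).  The HV > MS map is the exact negation.

    Voxels with zero residual variance get t = 0 and are counted in
    ``n_zero_variance``.
    """
    if len(vols) != len(age) or len(vols) != len(group):
        raise ValueError("one volume, group label and age per subject")
    X = _design(group, age)
    if min(int(X[:, 1].sum()), int(len(vols) - X[:, 1].sum())) < 2:
        raise ValueError("need at least 2 subjects per group")
    for v in vols:
        vols[0].require_same_grid(v, "subject volumes")
    vols[0].require_same_grid(analysis_mask, "volumes and analysis mask")
    m = analysis_mask.as_bool()
    Y = np.stack([v.data[m] for v in vols]).astype(np.float64)
    t, df = _ols_group_t(X, Y)
    n_zero = int(np.count_nonzero(~np.isfinite(t) | (t == 0)))
    t = np.where(np.isfinite(t), t, 0.0)
    tvol = np.zeros(vols[0].shape, dtype=np.float64)
    tvol[m] = t
    return TMap(Volume3D(tvol, vols[0].affine, "t-score"), df,
                design="intercept + group(MS=1) + age",
                n_zero_variance=n_zero,
                _Y=Y, _age=np.asarray(age, float),
                _group=X[:, 1].copy(), _mask=m)


_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _max_cluster_size(t_flat: np.ndarray, mask: np.ndarray, thresh: float,
                      struct: np.ndarray) -> int:
    vol = np.zeros(mask.shape, dtype=bool)
    vol[mask] = t_flat > thresh
    labelled, n = ndimage.label(vol, structure=struct)
    if n == 0:
        return 0
    return int(np.bincount(labelled.ravel())[1:].max())


def cluster_fwe(tmap: TMap, forming_p: float = 0.001, n_perm: int = 5000,
                seed: int = 0, connectivity: int = 18) -> ClusterSet:
    """Cluster-level familywise-error inference by group-label permutation.

    Clusters are connected components (6/18/26-neighbour, default 18) of
    voxels whose t exceeds the one-sided forming threshold
    ``t_{df}(forming_p)``.  The null distribution of the *maximum* cluster
    size is built by recomputing the map under random group relabelings —
    exhaustively over all C(n, n_MS) distinct assignments when there are at
    most ``n_perm`` of them, otherwise from ``n_perm`` Monte-Carlo draws
    with the (b+1)/(B+1) estimator.  A cluster's p_fwe is the proportion of
    null maxima at least as large as the cluster.
    """
    if tmap._Y is None:
        raise ValueError("TMap was built without permutation data")
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    struct = _CONNECTIVITY_STRUCTS[connectivity]
    Y, ages, g_obs, mask = tmap._Y, tmap._age, tmap._group, tmap._mask
    n = len(g_obs)
    k = int(g_obs.sum())
    n_distinct = math.comb(n, k)
    if n_distinct < 2:
        raise ValueError("fewer than 2 distinct group relabelings possible")
    t_thresh = float(sps.t.isf(forming_p, tmap.df))

    # observed clusters
    tvol = tmap.vol.data
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = tvol[mask] > t_thresh
    labelled, n_clust = ndimage.label(supra, structure=struct)

    def t_for_labels(g: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones(n), g, ages])
        t, _ = _ols_group_t(X, Y)
        return np.where(np.isfinite(t), t, 0.0)

    exhaustive = n_distinct <= n_perm
    null_max = []
    if exhaustive:
        for comb in itertools.combinations(range(n), k):
            g = np.zeros(n)
            g[list(comb)] = 1.0
            null_max.append(_max_cluster_size(t_for_labels(g), mask, t_thresh, struct))
        B = n_distinct
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            g = np.zeros(n)
            g[rng.choice(n, size=k, replace=False)] = 1.0
            null_max.append(_max_cluster_size(t_for_labels(g), mask, t_thresh, struct))
        B = n_perm
    null_max = np.asarray(null_max)

    clusters = []
    affine = tmap.vol.affine
    sizes = np.bincount(labelled.ravel())[1:] if n_clust else np.array([], int)
    order = np.argsort(-sizes)  # largest first
    for ci in order:
        cid = int(ci) + 1
        size = int(sizes[ci])
        sel = labelled == cid
        peak_flat = np.argmax(np.where(sel, tvol, -np.inf))
        pi, pj, pk = np.unravel_index(peak_flat, tvol.shape)
        peak_mm = tuple((affine[:3, :3] @ [pi, pj, pk] + affine[:3, 3]).tolist())
        if exhaustive:
            p = float((null_max >= size).sum() / B)
        else:
            p = float(((null_max >= size).sum() + 1) / (B + 1))
        clusters.append(ClusterInfo(cid, size, float(tvol[pi, pj, pk]),
                                    peak_mm, p))
    label_vol = Volume3D(labelled.astype(np.float32), affine, "cluster-id")
    return ClusterSet(clusters, t_thresh, forming_p, connectivity, B,
                      exhaustive, labels=label_vol)
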