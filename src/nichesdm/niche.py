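"""Realized-niche quantification and comparison in a 2-D PCA-environment space.

The workflow mirrors the COUE (Centroid, Overlap, Unfilling, Expansion)
framework for niche-shift analysis: climate variables are ordinated by a PCA
calibrated on the pooled available environments of the two ranges being
compared; occurrence and availability densities are kernel-smoothed on an
R x R grid of that space; the occupancy surface z is the occurrence density
corrected by environmental availability (z proportional to o/e), so that
comparisons are not confounded by the two regions offering different
climates.  Schoener's D measures overlap of the two occupancy surfaces and
the expansion/stability/unfilling indices decompose the change, restricted
to analogue climates (conditions available in both ranges).

Kernels are Gaussian with the per-axis normal-reference bandwidth and are
truncated at :data:`~nichesdm.synthetic.SUPPORT_SD` bandwidths, which makes
"occupancy absent" (z = 0) a deterministic statement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .occurrences import EnvTable
from .synthetic import SUPPORT_SD

__all__ = [
    "PCASpace",
    "NicheGrid",
    "NicheComparison",
    "calibrate_pca_env",
    "grid_niche",
    "grid_pair",
    "schoeners_d",
    "coue_indices",
    "equivalency_test",
    "similarity_test",
    "compare_niches",
]


class CalibrationError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class ComparisonError(ValueError):
    pass


def _as_matrix(env) -> np.ndarray:
    if isinstance(env, EnvTable):
        return env.values
    if hasattr(env, "to_numpy"):
        return env.to_numpy(dtype=float)
    return np.asarray(env, dtype=float)


# ---------------------------------------------------------------------------
# PCA calibration
# ---------------------------------------------------------------------------


@dataclass
class PCASpace:
    """Two-component PCA of standardized climate variables."""

    variables: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (k, 2), orthonormal columns
    explained_variance: np.ndarray  # all components, fractions summing to 1

    @property
    def explained_2d(self) -> float:
        """Fraction of variance carried by the two retained axes."""
        return float(self.explained_variance[:2].sum())

    def transform(self, env) -> np.ndarray:
        x = (_as_matrix(env) - self.center) / self.scale
        return x @ self.loadings


def calibrate_pca_env(background_env) -> PCASpace:
    """Calibrate the ordination on the pooled background environments.

    Variables are centered and scaled to unit variance; the first two
    principal components span the niche space.  A constant variable cannot
    be standardized and raises a :class:`CalibrationError` naming it.
    """
    if isinstance(background_env, EnvTable):
        variables = list(background_env.data.columns)
    elif hasattr(background_env, "columns"):
        variables = list(background_env.columns)
    else:
        variables = [f"v{i}" for i in range(np.asarray(background_env).shape[1])]
    x = _as_matrix(background_env)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise CalibrationError("need >= 3 background rows and >= 2 variables")
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    dead = [v for v, s in zip(variables, scale) if s == 0]
    if dead:
        raise CalibrationError(f"constant variable(s) cannot be ordinated: {dead}")
    xs = (x - center) / scale
    # SVD of the standardized matrix = PCA on the correlation matrix
    _, svals, vt = np.linalg.svd(xs, full_matrices=False)
    var = svals**2
    explained = var / var.sum()
    loadings = vt[:2].T
    # sign convention: heaviest-loading variable positive on each axis
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCASpace(
        variables=variables,
        center=center,
        scale=scale,
        loadings=loadings,
        explained_variance=explained,
    )


# ---------------------------------------------------------------------------
# Gridded niches
# ---------------------------------------------------------------------------


@dataclass
class NicheGrid:
    """Occurrence (o), availability (e) and occupancy (z) densities on an
    R x R grid of the 2-D niche space; each sums to 1 over its support."""

    R: int
    bounds: np.ndarray  # (2, 2): [[xmin, xmax], [ymin, ymax]]
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray
    bandwidth: tuple[float, float]
    n_occ: int

    @property
    def analogue_mask(self) -> np.ndarray:
        return self.e > 0

    def axis_centers(self, axis: int) -> np.ndarray:
        lo, hi = self.bounds[axis]
        edges = np.linspace(lo, hi, self.R + 1)
        return 0.5 * (edges[:-1] + edges[1:])


def _nrd_bandwidth(x: np.ndarray) -> float:
    """Normal-reference-distribution bandwidth (Gaussian kernel sd)."""
    n = len(x)
    sd = np.std(x, ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return 0.0
    return 1.06 * spread * n ** (-1 / 5)


def _kde_on_grid(points, cx, cy, hx, hy) -> np.ndarray:
    """Truncated-Gaussian product KDE evaluated at grid centres.

    Returns an (R, R) array (x index first) normalized to sum 1.
    """
    dx = (cx[None, :] - points[:, 0][:, None]) / hx
    dy = (cy[None, :] - points[:, 1][:, None]) / hy
    gx = np.exp(-0.5 * dx**2)
    gx[np.abs(dx) > SUPPORT_SD] = 0.0
    gy = np.exp(-0.5 * dy**2)
    gy[np.abs(dy) > SUPPORT_SD] = 0.0
    dens = gx.T @ gy
    total = dens.sum()
    if total > 0:
        dens /= total
    return dens


#: Default quantile of the positive availability density used to floor the
#: denominator of z = o/e.  The raw ratio is extremely noisy where few
#: background environments fall (a single occurrence over a near-empty
#: availability cell grabs a large share of the occupancy mass); flooring e
#: at its median over available cells stabilizes the surface while leaving
#: well-sampled environments fully corrected.
AVAILABILITY_FLOOR_QUANTILE = 0.5


def _occupancy_surface(o: np.ndarray, e: np.ndarray, floor_quantile: float) -> np.ndarray:
    """z proportional to o / max(e, floor) on e > 0, normalized to sum 1."""
    positive = e[e > 0]
    if positive.size == 0:
        raise InsufficientDataError("availability density is empty")
    floor = np.quantile(positive, floor_quantile) if floor_quantile > 0 else 0.0
    denom = np.maximum(e, floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(e > 0, o / np.where(denom > 0, denom, 1.0), 0.0)
    total = z.sum()
    if total > 0:
        z = z / total
    return z


def grid_niche(
    occ_scores,
    background_scores,
    R: int = 100,
    bandwidth_rule: str = "nrd",
    bounds: np.ndarray | None = None,
    availability_floor_quantile: float = AVAILABILITY_FLOOR_QUANTILE,
) -> NicheGrid:
    """Grid one range's niche in the shared 2-D space.

    ``bounds`` should span the pooled background of the whole comparison
    (see :func:`grid_pair`); by default the range's own background is used.
    The occupancy surface is z proportional to o/e on available cells
    (e > 0), with the denominator floored at the
    ``availability_floor_quantile`` quantile of positive e (pass 0 for the
    raw ratio), renormalized to sum 1.
    """
    occ = np.asarray(occ_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if occ.shape[0] < 5:
        raise InsufficientDataError(f"need >= 5 occurrences, got {occ.shape[0]}")
    if bg.shape[0] < 100:
        raise InsufficientDataError(f"need >= 100 background points, got {bg.shape[0]}")
    if bandwidth_rule != "nrd":
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    if bounds is None:
        bounds = np.column_stack([bg.min(axis=0), bg.max(axis=0)])
    bounds = np.asarray(bounds, dtype=float)
    cx = np.linspace(bounds[0, 0], bounds[0, 1], R + 1)
    cx = 0.5 * (cx[:-1] + cx[1:])
    cy = np.linspace(bounds[1, 0], bounds[1, 1], R + 1)
    cy = 0.5 * (cy[:-1] + cy[1:])

    cell = (
        (bounds[0, 1] - bounds[0, 0]) / R,
        (bounds[1, 1] - bounds[1, 0]) / R,
    )
    # One bandwidth (the occurrence reference bandwidth) for both densities:
    # smoothing o and e identically makes their edge rolloff cancel in the
    # ratio z = o/e, which otherwise explodes at the availability margin.
    h_occ = (max(_nrd_bandwidth(occ[:, 0]), cell[0]), max(_nrd_bandwidth(occ[:, 1]), cell[1]))

    o = _kde_on_grid(occ, cx, cy, *h_occ)
    e = _kde_on_grid(bg, cx, cy, *h_occ)
    z = _occupancy_surface(o, e, availability_floor_quantile)
    return NicheGrid(R=R, bounds=bounds, o=o, e=e, z=z, bandwidth=h_occ, n_occ=len(occ))


def grid_pair(
    occ1_scores,
    occ2_scores,
    bg1_scores,
    bg2_scores,
    R: int = 100,
    availability_floor_quantile: float = AVAILABILITY_FLOOR_QUANTILE,
) -> tuple[NicheGrid, NicheGrid]:
    """Grid two niches on one common frame (pooled-background bounds)."""
    bg1 = np.asarray(bg1_scores, dtype=float)
    bg2 = np.asarray(bg2_scores, dtype=float)
    pooled = np.vstack([bg1, bg2])
    bounds = np.column_stack([pooled.min(axis=0), pooled.max(axis=0)])
    g1 = grid_niche(
        occ1_scores, bg1, R=R, bounds=bounds,
        availability_floor_quantile=availability_floor_quantile,
    )
    g2 = grid_niche(
        occ2_scores, bg2, R=R, bounds=bounds,
        availability_floor_quantile=availability_floor_quantile,
    )
    return g1, g2


# ---------------------------------------------------------------------------
# Overlap and COUE indices
# ---------------------------------------------------------------------------


def schoeners_d(z1, z2) -> float:
    """Schoener's overlap D = 1 - 0.5 * sum |z1 - z2| in [0, 1].

    Accepts occupancy surfaces (arrays) or :class:`NicheGrid` objects on the
    same grid; surfaces are renormalized to sum 1 before comparison.
    """
    a = z1.z if isinstance(z1, NicheGrid) else np.asarray(z1, dtype=float)
    b = z2.z if isinstance(z2, NicheGrid) else np.asarray(z2, dtype=float)
    if a.shape != b.shape:
        raise ComparisonError(f"grid shapes differ: {a.shape} vs {b.shape}")
    if isinstance(z1, NicheGrid) and isinstance(z2, NicheGrid):
        if not np.allclose(z1.bounds, z2.bounds):
            raise ComparisonError("grids have different bounds")
    sa, sb = a.sum(), b.sum()
    if sa <= 0 or sb <= 0:
        raise ComparisonError("an occupancy surface has zero total mass")
    d = 1.0 - 0.5 * np.abs(a / sa - b / sb).sum()
    return float(min(max(d, 0.0), 1.0))


@dataclass
class NicheComparison:
    """Overlap and niche-dynamics indices for a native/invasive pair."""

    d: float
    expansion: float
    stability: float
    unfilling: float
    intersection_quantile: float = 0.0
    equivalency_p: float | None = None
    similarity_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "schoeners_d": self.d,
            "expansion": self.expansion,
            "stability": self.stability,
            "unfilling": self.unfilling,
            "intersection_quantile": self.intersection_quantile,
            "equivalency_p": self.equivalency_p,
            "similarity_p": self.similarity_p,
        }


def _availability_mask(grid: NicheGrid, quantile: float) -> np.ndarray:
    if quantile <= 0:
        return grid.e > 0
    positive = grid.e[grid.e > 0]
    return grid.e > np.quantile(positive, quantile)


def coue_indices(
    native: NicheGrid,
    invasive: NicheGrid,
    intersection_quantile: float = 0.0,
) -> NicheComparison:
    """Expansion / stability / unfilling over analogue climates.

    Analogue cells are those whose availability density exceeds the given
    quantile in *both* ranges (quantile 0: available in both).  Expansion is
    the share of invasive occupancy mass (within analogue cells) on cells
    where the native niche is absent (z = 0 after kernel truncation);
    unfilling is the mirror image for the native niche; stability is
    1 - expansion.  D is computed on the full occupancy surfaces.
    """
    if native.z.shape != invasive.z.shape or not np.allclose(
        native.bounds, invasive.bounds
    ):
        raise ComparisonError("niche grids are not on the same frame")
    analogue = _availability_mask(native, intersection_quantile) & _availability_mask(
        invasive, intersection_quantile
    )
    if not analogue.any():
        raise ComparisonError("no analogue environments shared by the two ranges")
    z_nat = np.where(analogue, native.z, 0.0)
    z_inv = np.where(analogue, invasive.z, 0.0)
    if z_inv.sum() <= 0 or z_nat.sum() <= 0:
        raise ComparisonError("a niche has no occupancy mass on analogue cells")
    expansion = float(z_inv[native.z == 0].sum() / z_inv.sum())
    unfilling = float(z_nat[invasive.z == 0].sum() / z_nat.sum())
    return NicheComparison(
        d=schoeners_d(native, invasive),
        expansion=expansion,
        stability=1.0 - expansion,
        unfilling=unfilling,
        intersection_quantile=intersection_quantile,
    )


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------


def _observed_and_grids(occ1, occ2, bg1, bg2, R):
    g1, g2 = grid_pair(occ1, occ2, bg1, bg2, R=R)
    return schoeners_d(g1, g2), g1, g2


def equivalency_test(
    occ1_scores,
    occ2_scores,
    bg1_scores,
    bg2_scores,
    n_perm: int = 99,
    seed: int = 0,
    R: int = 100,
    alternative: str = "lower",
) -> float:
    """Niche-equivalency permutation test on Schoener's D.

    The null pools both occurrence sets and reallocates range labels at
    random.  With ``alternative="lower"`` (default) small p means the
    observed niches are *less* equivalent than random relabelings:
    p = (1 + #{D_null <= D_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    occ1 = np.asarray(occ1_scores, dtype=float)
    occ2 = np.asarray(occ2_scores, dtype=float)
    if len(occ1) < 5 or len(occ2) < 5:
        raise InsufficientDataError("too few occurrences to permute")
    d_obs, g1, g2 = _observed_and_grids(occ1, occ2, bg1_scores, bg2_scores, R)
    pooled = np.vstack([occ1, occ2])
    n1 = len(occ1)
    rng = np.random.default_rng(seed)
    cx, cy = g1.axis_centers(0), g1.axis_centers(1)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(pooled))
        p1, p2 = pooled[perm[:n1]], pooled[perm[n1:]]
        null[i] = _null_d(p1, p2, g1, g2, cx, cy)
    return _p_value(d_obs, null, alternative)


def similarity_test(
    occ1_scores,
    occ2_scores,
    bg1_scores,
    bg2_scores,
    n_perm: int = 99,
    seed: int = 0,
    R: int = 100,
    alternative: str = "greater",
) -> float:
    """Niche-similarity permutation test on Schoener's D.

    The null randomly recentres the second observed niche within its own
    available environment (cells with e > 0) and recomputes D.  With
    ``alternative="greater"`` (default) small p means the niches are more
    similar than expected from their available climates:
    p = (1 + #{D_null >= D_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    occ1 = np.asarray(occ1_scores, dtype=float)
    occ2 = np.asarray(occ2_scores, dtype=float)
    if len(occ1) < 5 or len(occ2) < 5:
        raise InsufficientDataError("too few occurrences to shift")
    d_obs, g1, g2 = _observed_and_grids(occ1, occ2, bg1_scores, bg2_scores, R)
    cx, cy = g2.axis_centers(0), g2.axis_centers(1)
    avail_x, avail_y = np.nonzero(g2.e > 0)
    rng = np.random.default_rng(seed)
    centroid = occ2.mean(axis=0)
    null = np.empty(n_perm)
    for i in range(n_perm):
        j = rng.integers(len(avail_x))
        target = np.array([cx[avail_x[j]], cy[avail_y[j]]])
        shifted = occ2 + (target - centroid)
        null[i] = _null_d(occ1, shifted, g1, g2, g1.axis_centers(0), g1.axis_centers(1))
    return _p_value(d_obs, null, alternative)


def _null_d(p1, p2, g1, g2, cx, cy) -> float:
    """Recompute D for permuted/shifted occurrence sets on the fixed frame."""
    cell = (
        (g1.bounds[0, 1] - g1.bounds[0, 0]) / g1.R,
        (g1.bounds[1, 1] - g1.bounds[1, 0]) / g1.R,
    )
    h1 = (max(_nrd_bandwidth(p1[:, 0]), cell[0]), max(_nrd_bandwidth(p1[:, 1]), cell[1]))
    h2 = (max(_nrd_bandwidth(p2[:, 0]), cell[0]), max(_nrd_bandwidth(p2[:, 1]), cell[1]))
    o1 = _kde_on_grid(p1, cx, cy, *h1)
    o2 = _kde_on_grid(p2, cx, cy, *h2)
    z1 = _occupancy_surface(o1, g1.e, AVAILABILITY_FLOOR_QUANTILE)
    z2 = _occupancy_surface(o2, g2.e, AVAILABILITY_FLOOR_QUANTILE)
    if z1.sum() <= 0 or z2.sum() <= 0:
        return 0.0
    return schoeners_d(z1, z2)


def _p_value(d_obs: float, null: np.ndarray, alternative: str) -> float:
    if alternative == "lower":
        k = int((null <= d_obs).sum())
    elif alternative == "greater":
        k = int((null >= d_obs).sum())
    elif alternative == "both":
        k = 2 * min(int((null <= d_obs).sum()), int((null >= d_obs).sum()))
        k = min(k, len(null))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + k) / (len(null) + 1)


# ---------------------------------------------------------------------------
# One-call comparison
# ---------------------------------------------------------------------------


def compare_niches(
    occ_env_native,
    occ_env_invasive,
    bg_env_native,
    bg_env_invasive,
    R: int = 100,
    intersection_quantile: float = 0.0,
    n_perm: int = 0,
    seed: int = 0,
) -> tuple[PCASpace, NicheGrid, NicheGrid, NicheComparison]:
    """Full niche comparison from raw environment tables.

    Calibrates the PCA on the pooled backgrounds of the two ranges, grids
    both niches on the shared frame, computes D and the COUE indices, and —
    when ``n_perm`` > 0 — runs the equivalency and similarity permutation
    tests.
    """
    bg_nat = _as_matrix(bg_env_native)
    bg_inv = _as_matrix(bg_env_invasive)
    if isinstance(bg_env_native, EnvTable):
        import pandas as pd

        pooled = pd.concat([bg_env_native.data, bg_env_invasive.data], axis=0)
    else:
        pooled = np.vstack([bg_nat, bg_inv])
    pca = calibrate_pca_env(pooled)
    s_occ1 = pca.transform(occ_env_native)
    s_occ2 = pca.transform(occ_env_invasive)
    s_bg1 = pca.transform(bg_nat)
    s_bg2 = pca.transform(bg_inv)
    g_nat, g_inv = grid_pair(s_occ1, s_occ2, s_bg1, s_bg2, R=R)
    cmp_ = coue_indices(g_nat, g_inv, intersection_quantile=intersection_quantile)
    if n_perm > 0:
        cmp_.equivalency_p = equivalency_test(
            s_occ1, s_occ2, s_bg1, s_bg2, n_perm=n_perm, seed=seed, R=R
        )
        cmp_.similarity_p = similarity_test(
            s_occ1, s_occ2, s_bg1, s_bg2, n_perm=n_perm, seed=seed + 1, R=R
        )
    return pca, g_nat, g_inv, cmp_
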