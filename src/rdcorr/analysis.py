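"""Projections, orientation distributions and sub-volume statistics.

Solution ensembles are reduced to the reportable quantities: 2D/1D
projections of the pooled component cloud onto pairs of the log-scaled
coordinates (log10 R1, log10 R2, log10 Diso, log10 D_par/D_perp), an
orientation distribution function of the high-anisotropy components on a
geodesic spherical mesh, and per-bootstrap weights/means over axis-
aligned sub-volumes of the analysis space.

Component weights are normalized per solution before pooling, so every
bootstrap replicate contributes equal total mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .inversion import SolutionEnsemble
from .tensor_math import log10_ratio_from_delta

__all__ = [
    "AXIS_NAMES",
    "DEFAULT_AXIS_LIMITS",
    "ProjectionMap",
    "Marginal",
    "OrientationDistribution",
    "SubvolumeStats",
    "pooled_components",
    "project_2d",
    "project_1d",
    "odf",
    "subvolume_stats",
    "default_regions",
]

AXIS_NAMES = ("log10_r1", "log10_r2", "log10_diso", "log10_ratio")

#: Default binning limits per axis; the ratio axis absorbs the clamped
#: oblate/stick limits by clipping into range.
DEFAULT_AXIS_LIMITS: dict[str, tuple[float, float]] = {
    "log10_r1": (-1.0, 1.0),
    "log10_r2": (0.0, 3.0),
    "log10_diso": (-12.0, -8.0),
    "log10_ratio": (-4.0, 4.0),
}

#: Contour levels, fractions of the map maximum (7.5% .. 90%, linear).
CONTOUR_FRACTIONS = np.linspace(0.075, 0.90, 12)


@dataclass
class ProjectionMap:
    """2D histogram of pooled component weight on two log-scaled axes."""

    axes: tuple[str, str]
    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray           # raw (unsmoothed) weight per bin
    smoothing_sigma: float = 0.0  # display smoothing, in bins

    @property
    def smoothed(self) -> np.ndarray:
        if self.smoothing_sigma <= 0:
            return self.density
        return gaussian_filter(self.density, self.smoothing_sigma)

    @property
    def contour_levels(self) -> np.ndarray:
        return CONTOUR_FRACTIONS * self.smoothed.max()

    @property
    def total(self) -> float:
        return float(self.density.sum())


@dataclass
class Marginal:
    """1D histogram of pooled component weight on one log-scaled axis."""

    axis: str
    edges: np.ndarray
    density: np.ndarray
    smoothing_sigma: float = 0.0

    @property
    def smoothed(self) -> np.ndarray:
        if self.smoothing_sigma <= 0:
            return self.density
        return gaussian_filter1d(self.density, self.smoothing_sigma)

    @property
    def total(self) -> float:
        return float(self.density.sum())


@dataclass
class OrientationDistribution:
    """Weight density on a geodesic spherical mesh (antipodally symmetric)."""

    vertices: np.ndarray   # (n, 3) unit vectors
    density: np.ndarray    # weight per vertex
    colors: np.ndarray     # (n, 3) RGB = |x|, |y|, |z| of the vertex
    empty: bool = False

    @property
    def total(self) -> float:
        return float(self.density.sum())


@dataclass
class SubvolumeStats:
    """Per-bootstrap weight and means over one region of the analysis space.

    ``pvol`` holds the solution-normalized total weight inside the region
    for each bootstrap replicate; the mean arrays hold the weight-
    weighted means of each coordinate (NaN where the region is empty in
    that replicate).
    """

    region: dict[str, tuple[float, float]]
    pvol: np.ndarray
    means: dict[str, np.ndarray] = field(default_factory=dict)

    def summary(self) -> dict[str, dict[str, float]]:
        out = {
            "pvol": {
                "mean": float(np.mean(self.pvol)),
                "sd": float(np.std(self.pvol, ddof=1)) if len(self.pvol) > 1 else 0.0,
            }
        }
        for name, vals in self.means.items():
            ok = vals[np.isfinite(vals)]
            out[name] = {
                "mean": float(np.mean(ok)) if ok.size else float("nan"),
                "sd": float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0,
                "n_defined": int(ok.size),
            }
        return out


def pooled_components(ens: SolutionEnsemble):
    """Pool all components across solutions with per-solution weight
    normalization and equal per-replicate mass 1/n_solutions.

    Returns ``(coords, weights, solution_index)`` where coords is a dict
    of the four log-scaled coordinate arrays.
    """
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    rows, wts, sol_idx = [], [], []
    for i, sol in enumerate(ens.solutions):
        if not sol.components:
            continue
        total = sol.total_weight
        for c in sol.components:
            rows.append((c.R1, c.R2, c.Diso, c.Ddelta, c.theta, c.phi))
            wts.append(c.weight / total / len(ens))
            sol_idx.append(i)
    if not rows:
        raise ValueError("ensemble contains no components")
    arr = np.asarray(rows)
    coords = {
        "log10_r1": np.log10(arr[:, 0]),
        "log10_r2": np.log10(arr[:, 1]),
        "log10_diso": np.log10(arr[:, 2]),
        "log10_ratio": log10_ratio_from_delta(arr[:, 3]),
        "theta": arr[:, 4],
        "phi": arr[:, 5],
    }
    return coords, np.asarray(wts), np.asarray(sol_idx)


def _axis_values(coords: dict, axis: str, limits: dict) -> tuple[np.ndarray, np.ndarray]:
    if axis not in AXIS_NAMES:
        raise ValueError(f"unknown axis {axis!r}; expected one of {AXIS_NAMES}")
    lo, hi = limits[axis]
    # clip so out-of-range mass is conserved in the edge bins
    return np.clip(coords[axis], lo, hi), np.array([lo, hi])


def project_2d(
    ens: SolutionEnsemble,
    axes: tuple[str, str] = ("log10_diso", "log10_ratio"),
    grid: int = 64,
    smoothing_sigma: float = 0.0,
    limits: dict | None = None,
) -> ProjectionMap:
    """Project the pooled ensemble onto a pair of log-scaled coordinates."""
    if axes[0] == axes[1]:
        raise ValueError("axes must be distinct")
    if grid < 8:
        raise ValueError("grid resolution must be >= 8")
    limits = {**DEFAULT_AXIS_LIMITS, **(limits or {})}
    coords, weights, _ = pooled_components(ens)
    x, xr = _axis_values(coords, axes[0], limits)
    y, yr = _axis_values(coords, axes[1], limits)
    density, x_edges, y_edges = np.histogram2d(
        x, y, bins=grid, range=[xr, yr], weights=weights
    )
    return ProjectionMap(tuple(axes), x_edges, y_edges, density, smoothing_sigma)


def project_1d(
    ens: SolutionEnsemble,
    axis: str = "log10_diso",
    grid: int = 64,
    smoothing_sigma: float = 0.0,
    limits: dict | None = None,
) -> Marginal:
    """1D marginal; equals the axis-sum of any :func:`project_2d` sharing
    the axis and grid."""
    if grid < 8:
        raise ValueError("grid resolution must be >= 8")
    limits = {**DEFAULT_AXIS_LIMITS, **(limits or {})}
    coords, weights, _ = pooled_components(ens)
    x, xr = _axis_values(coords, axis, limits)
    density, edges = np.histogram(x, bins=grid, range=xr, weights=weights)
    return Marginal(axis, edges, density, smoothing_sigma)


# ---------------------------------------------------------------------------
# orientation distribution


def _icosphere(n_subdiv: int = 3) -> np.ndarray:
    """Vertices of a geodesically subdivided icosahedron (unit sphere).

    The icosahedron is antipodally symmetric, and subdivision preserves
    that symmetry, so every vertex has its antipode in the mesh.
    """
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    vlist = [tuple(v) for v in verts]
    index = {v: i for i, v in enumerate(vlist)}

    def midpoint(i, j):
        m = (np.array(vlist[i]) + np.array(vlist[j])) / 2.0
        m /= np.linalg.norm(m)
        key = tuple(np.round(m, 12))
        if key not in index:
            index[key] = len(vlist)
            vlist.append(key)
        return index[key]

    for _ in range(n_subdiv):
        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.asarray(vlist)


def odf(
    ens: SolutionEnsemble,
    ratio_threshold: float = 10.0,
    n_subdiv: int = 3,
) -> OrientationDistribution:
    """Orientation distribution of components with D_par/D_perp above
    ``ratio_threshold``, on a geodesic mesh with antipodal symmetrization.

    Each qualifying component deposits half of its pooled weight at the
    mesh vertex nearest its symmetry axis and half at the antipode.  An
    all-isotropic ensemble yields an empty (flagged) distribution.
    """
    if not ratio_threshold > 0:
        raise ValueError("ratio_threshold must be positive")
    verts = _icosphere(n_subdiv)
    colors = np.abs(verts)
    coords, weights, _ = pooled_components(ens)
    mask = coords["log10_ratio"] > np.log10(ratio_threshold)
    density = np.zeros(len(verts))
    if not np.any(mask):
        return OrientationDistribution(verts, density, colors, empty=True)
    st = np.sin(coords["theta"][mask])
    axes = np.column_stack(
        [
            np.cos(coords["phi"][mask]) * st,
            np.sin(coords["phi"][mask]) * st,
            np.cos(coords["theta"][mask]),
        ]
    )
    w = weights[mask]
    nearest = np.argmax(axes @ verts.T, axis=1)
    antipodal = np.argmax(-axes @ verts.T, axis=1)
    np.add.at(density, nearest, w / 2.0)
    np.add.at(density, antipodal, w / 2.0)
    return OrientationDistribution(verts, density, colors, empty=False)


# ---------------------------------------------------------------------------
# sub-volume statistics


def default_regions() -> dict[str, dict[str, tuple[float, float]]]:
    """Four analysis-space boxes containing the expected populations.

    Bounds are fixture choices spanning the default analysis limits:
    a prolate (liquid-crystal-like) box with D_par/D_perp > 10, fast and
    slow isotropic boxes split at log10 Diso = -10, and an oblate box
    capturing the shape-undersampling artefact.
    """
    r1 = DEFAULT_AXIS_LIMITS["log10_r1"]
    r2 = DEFAULT_AXIS_LIMITS["log10_r2"]
    return {
        "lc_prolate": {
            "log10_r1": r1, "log10_r2": r2,
            "log10_diso": (-10.0, -8.0), "log10_ratio": (1.0, 4.0),
        },
        "fast_isotropic": {
            "log10_r1": r1, "log10_r2": r2,
            "log10_diso": (-10.0, -8.0), "log10_ratio": (-1.0, 1.0),
        },
        "slow_isotropic": {
            "log10_r1": r1, "log10_r2": r2,
            "log10_diso": (-12.0, -10.0), "log10_ratio": (-1.0, 1.0),
        },
        "oblate_artefact": {
            "log10_r1": r1, "log10_r2": r2,
            "log10_diso": (-10.0, -8.0), "log10_ratio": (-4.0, -1.0),
        },
    }


def _regions_overlap(a: dict, b: dict) -> bool:
    for axis in AXIS_NAMES:
        alo, ahi = a[axis]
        blo, bhi = b[axis]
        if ahi <= blo or bhi <= alo:
            return False
    return True


def subvolume_stats(
    ens: SolutionEnsemble,
    regions: dict[str, dict[str, tuple[float, float]]],
) -> dict[str, SubvolumeStats]:
    """Per-bootstrap weight (Pvol) and weighted coordinate means per region.

    Regions are axis-aligned boxes over the four log-scaled, orientation-
    free coordinates; half-open on the upper edge so abutting boxes
    partition without double counting.  Overlapping regions are permitted
    but warned about.
    """
    names = list(regions)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if _regions_overlap(regions[a], regions[b]):
                warnings.warn(f"regions {a!r} and {b!r} overlap", stacklevel=2)

    coords, weights, sol_idx = pooled_components(ens)
    n_sol = len(ens)
    # undo the 1/n_sol pooling factor: per-solution normalized weights
    w_norm = weights * n_sol

    out: dict[str, SubvolumeStats] = {}
    for name in names:
        box = regions[name]
        mask = np.ones(len(w_norm), dtype=bool)
        for axis in AXIS_NAMES:
            lo, hi = box[axis]
            mask &= (coords[axis] >= lo) & (coords[axis] < hi)
        pvol = np.zeros(n_sol)
        means = {axis: np.full(n_sol, np.nan) for axis in AXIS_NAMES}
        for i in range(n_sol):
            sel = mask & (sol_idx == i)
            wi = w_norm[sel]
            pvol[i] = wi.sum()
            if pvol[i] > 0:
                for axis in AXIS_NAMES:
                    means[axis][i] = np.average(coords[axis][sel], weights=wi)
        out[name] = SubvolumeStats(region=box, pvol=pvol, means=means)
    return out
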