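"""Pseudo-random 6D acquisition scheme generation and serialization.

An acquisition point is one coordinate (tau_R, tau_e, b, b_delta, Theta,
Phi): repetition delay, echo time, b-value, b-tensor anisotropy, and the
orientation of the b-tensor symmetry axis.  The generator draws points
uniformly in the transformed space (linear tau_R, log tau_e, log b,
linear b_delta, linear cos Theta, linear Phi), shrinks the accessible
b_delta at low b-values, and then enforces four consecutive sampling
biases towards the linear-, spherical-, and planar-encoding lines and a
fixed stability-check point.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "B_MIN_DEFAULT",
    "DEFAULT_RANGES",
    "DEFAULT_BIASES",
    "AcquisitionPoint",
    "Scheme",
    "SchemeValidationError",
    "generate_scheme",
    "generate_grid_scheme",
    "write_scheme",
    "read_scheme",
]

#: Lowest b-value required for adequate gradient spoiling [m^-2 s].
B_MIN_DEFAULT = 6.06e8

#: Default coordinate limits, SI units.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "tau_R": (0.1, 5.0),          # s, sampled linearly
    "tau_e": (1e-3, 0.1),         # s, sampled log-uniformly
    "b": (B_MIN_DEFAULT, 1e11),   # m^-2 s, sampled log-uniformly
    "b_delta": (-0.5, 1.0),       # dimensionless, linear
    "cos_Theta": (-1.0, 1.0),     # linear (area-uniform orientations)
    "Phi": (0.0, 2.0 * math.pi),  # rad, linear
}

#: Fractions of the total point count assigned, in order, to the
#: linear-encoding line, the spherical line, the planar line, and the
#: fixed stability point.
DEFAULT_BIASES: tuple[float, float, float, float] = (0.30, 0.15, 0.10, 0.05)

BIAS_NAMES = ("linear", "spherical", "planar", "stability")

COLUMNS = ("tau_R", "tau_e", "b", "b_delta", "Theta", "Phi")


class SchemeValidationError(ValueError):
    """A scheme file or scheme array violates coordinate invariants."""


@dataclass(frozen=True)
class AcquisitionPoint:
    """A single 6D acquisition coordinate (SI units, angles in rad)."""

    tau_R: float
    tau_e: float
    b: float
    b_delta: float
    Theta: float
    Phi: float


@dataclass
class Scheme:
    """Ordered table of acquisition points plus generation provenance.

    ``bias_subsets`` maps bias names to the (disjoint) index arrays of
    points whose coordinates were overwritten by that bias.
    """

    tau_R: np.ndarray
    tau_e: np.ndarray
    b: np.ndarray
    b_delta: np.ndarray
    Theta: np.ndarray
    Phi: np.ndarray
    provenance: dict = field(default_factory=dict)
    bias_subsets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.tau_R)
        for name in COLUMNS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"column {name!r} has shape {arr.shape}, expected ({n},)")
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.tau_R)

    def point(self, i: int) -> AcquisitionPoint:
        return AcquisitionPoint(
            *(float(getattr(self, name)[i]) for name in COLUMNS)
        )

    def take(self, indices: np.ndarray) -> "Scheme":
        """Row subset/resampling (used by bootstrap)."""
        indices = np.asarray(indices)
        return Scheme(
            *(getattr(self, name)[indices] for name in COLUMNS),
            provenance={**self.provenance, "resampled": True},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({name: getattr(self, name) for name in COLUMNS})

    def validate(self, ranges: dict | None = None) -> None:
        """Raise :class:`SchemeValidationError` naming the first bad row."""
        ranges = ranges or DEFAULT_RANGES
        checks = [
            ("tau_R", self.tau_R, *ranges["tau_R"]),
            ("tau_e", self.tau_e, *ranges["tau_e"]),
            ("b", self.b, *ranges["b"]),
            ("b_delta", self.b_delta, -0.5, 1.0),
            ("Theta", self.Theta, 0.0, math.pi),
            ("Phi", self.Phi, 0.0, 2.0 * math.pi),
        ]
        for name, arr, lo, hi in checks:
            bad = np.flatnonzero((arr < lo) | (arr > hi))
            if bad.size:
                raise SchemeValidationError(
                    f"column {name!r} out of range [{lo}, {hi}] at row {bad[0]}"
                    f" (value {arr[bad[0]]})"
                )


def _bias_sizes(n: int, biases: tuple[float, ...]) -> list[int]:
    if sum(biases) > 1.0 + 1e-12:
        raise ValueError(f"bias fractions sum to {sum(biases)} > 1")
    sizes = [int(round(f * n)) for f in biases]
    if sum(sizes) > n:
        raise ValueError("bias subsets exceed the total point count")
    return sizes


def generate_scheme(
    n: int,
    ranges: dict | None = None,
    biases: tuple[float, float, float, float] = DEFAULT_BIASES,
    b_min: float = B_MIN_DEFAULT,
    seed: int | None = None,
    b_min_shape: float | None = None,
) -> Scheme:
    """Generate the pseudo-random 6D scheme.

    Step 1 draws ``n`` points uniformly in (tau_R, log tau_e, log b,
    b_delta, cos Theta, Phi) within ``ranges``.  Step 2 resamples
    ``b_delta <- b_delta * (b - b_min_shape) / b`` so the accessible
    b-tensor anisotropy shrinks to zero at the lowest b-value (gradient
    spoiling).  Step 3 overwrites four disjoint random subsets of sizes
    ``round(f_i * n)`` with, in order: the linear-encoding line
    ``b_delta = (b - b_min_shape)/b``, the spherical line ``b_delta = 0``,
    the planar line ``b_delta = -0.5 (b - b_min_shape)/b``, and the
    stability point ``(tau_R, tau_e, b) = (tau_R_max, tau_e_min, b_min)``
    (whose b_delta collapses to 0 through the step-2 rule).

    ``b_min_shape`` lets the anisotropy funnel be widened or narrowed at
    low b independently of the sampled b range (defaults to ``b_min``).

    Reproducible: the same ``seed`` yields a bitwise-identical scheme.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    if b_min_shape is None:
        b_min_shape = b_min
    sizes = _bias_sizes(n, biases)
    if n < sum(1 for f in biases if f > 0):
        raise ValueError("n smaller than the number of nonzero bias subsets")

    rng = np.random.default_rng(seed)
    tau_R = rng.uniform(*ranges["tau_R"], n)
    tau_e = 10.0 ** rng.uniform(*np.log10(ranges["tau_e"]), n)
    b = 10.0 ** rng.uniform(*np.log10(ranges["b"]), n)
    b_delta = rng.uniform(*ranges["b_delta"], n)
    Theta = np.arccos(rng.uniform(*ranges["cos_Theta"], n))
    Phi = rng.uniform(*ranges["Phi"], n)

    # Step 2: shrink anisotropy at low b.  The clip keeps b_delta valid
    # when the funnel is deliberately narrowed (b_min_shape > b_min).
    funnel = np.clip((b - b_min_shape) / b, 0.0, 1.0)
    b_delta = b_delta * funnel

    # Step 3: consecutive biases on disjoint subsets of the total.
    perm = rng.permutation(n)
    subsets: dict[str, np.ndarray] = {}
    start = 0
    for name, size in zip(BIAS_NAMES, sizes):
        idx = np.sort(perm[start : start + size])
        start += size
        subsets[name] = idx
    b_delta[subsets["linear"]] = funnel[subsets["linear"]]
    b_delta[subsets["spherical"]] = 0.0
    b_delta[subsets["planar"]] = -0.5 * funnel[subsets["planar"]]
    stab = subsets["stability"]
    tau_R[stab] = ranges["tau_R"][1]
    tau_e[stab] = ranges["tau_e"][0]
    b[stab] = b_min
    # re-apply the step-2 rule at the overwritten b-value
    b_delta[stab] = b_delta[stab] * np.clip((b[stab] - b_min_shape) / b[stab], 0.0, 1.0)

    provenance = {
        "generator": "pseudo-random",
        "seed": seed,
        "n": n,
        "biases": list(biases),
        "b_min": b_min,
        "b_min_shape": b_min_shape,
        "ranges": {k: list(v) for k, v in ranges.items()},
    }
    return Scheme(tau_R, tau_e, b, b_delta, Theta, Phi, provenance, subsets)


def generate_grid_scheme(
    n_per_dim: tuple[int, int, int, int, int, int],
    ranges: dict | None = None,
    cap: int = 100_000,
) -> Scheme:
    """Rectangular-grid scheme over the same coordinate transforms.

    Cartesian product of per-dimension grids: linear in tau_R, log10 in
    tau_e and b, linear in b_delta, cos Theta and Phi.  A dimension with
    a single level sits at the midpoint of its (transformed) range.
    """
    if len(n_per_dim) != 6:
        raise ValueError("n_per_dim must have six entries")
    if any(k < 1 for k in n_per_dim):
        raise ValueError("grid sizes must be >= 1")
    total = int(np.prod(n_per_dim))
    if total > cap:
        raise ValueError(f"grid of {total} points exceeds cap {cap}")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}

    def axis(lo: float, hi: float, k: int, log: bool = False, endpoint: bool = True):
        tlo, thi = (math.log10(lo), math.log10(hi)) if log else (lo, hi)
        vals = (
            np.array([(tlo + thi) / 2.0])
            if k == 1
            else np.linspace(tlo, thi, k, endpoint=endpoint)
        )
        # clip guards against 10**log10 round-off drifting past the limits
        return np.clip(10.0**vals, lo, hi) if log else vals

    axes = [
        axis(*ranges["tau_R"], n_per_dim[0]),
        axis(*ranges["tau_e"], n_per_dim[1], log=True),
        axis(*ranges["b"], n_per_dim[2], log=True),
        axis(*ranges["b_delta"], n_per_dim[3]),
        np.arccos(axis(*ranges["cos_Theta"], n_per_dim[4])),
        axis(*ranges["Phi"], n_per_dim[5], endpoint=False),
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    cols = [g.ravel() for g in grids]
    provenance = {
        "generator": "grid",
        "n_per_dim": list(n_per_dim),
        "ranges": {k: list(v) for k, v in ranges.items()},
    }
    return Scheme(*cols, provenance=provenance)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_scheme(scheme: Scheme, path: str | Path) -> None:
    """Write a CSV (17 significant digits; round-trip bit-stable) plus a
    JSON provenance sidecar at ``<path>.json``."""
    path = Path(path)
    scheme.to_frame().to_csv(path, index=False, float_format="%.17g")
    meta = {
        "provenance": scheme.provenance,
        "bias_subsets": {k: np.asarray(v).tolist() for k, v in scheme.bias_subsets.items()},
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_scheme(path: str | Path, validate: bool = True) -> Scheme:
    """Read a scheme CSV (and its JSON sidecar, if present)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemeValidationError(f"missing columns: {missing}")
    provenance: dict = {}
    subsets: dict[str, np.ndarray] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        provenance = meta.get("provenance", {})
        subsets = {k: np.asarray(v, dtype=int) for k, v in meta.get("bias_subsets", {}).items()}
    scheme = Scheme(
        *(df[c].to_numpy(dtype=float) for c in COLUMNS),
        provenance=provenance,
        bias_subsets=subsets,
    )
    if validate:
        ranges = provenance.get("ranges")
        scheme.validate({k: tuple(v) for k, v in ranges.items()} if ranges else None)
    return scheme
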