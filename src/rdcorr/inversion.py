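"""Model-free Monte-Carlo NNLS inversion of 6D relaxation-diffusion data.

The distribution over (R1, R2, Diso, Ddelta, theta, phi) is estimated as
a sparse set of discrete components.  Candidate components are drawn
uniformly in the transformed analysis space (log10 rates and
diffusivity, linear anisotropy, area-uniform orientations), weighted by
non-negative least squares against the measured signal, and iteratively
refined by proliferation (topping up with fresh random candidates) and
mutation (local Gaussian perturbation in the transformed coordinates).
Because every NNLS pass is solved on the union of the retained set and
the new candidates, the residual norm is non-increasing across rounds.

The only constraints are non-negativity of the weights and the analysis
range box — no smoothness or other regularization.  Solution variability
is quantified by bootstrap resampling of the acquisition points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .forward_model import Component, SignalDataset, kernel_matrix_from_params

__all__ = [
    "InversionConfig",
    "Solution",
    "SolutionEnsemble",
    "nnls_solve",
    "invert",
    "bootstrap_invert",
    "estimate_noise",
    "save_ensemble_json",
    "load_ensemble_json",
    "save_ensemble_hdf5",
    "load_ensemble_hdf5",
]

# parameter row layout used throughout this module
PARAM_NAMES = ("R1", "R2", "Diso", "Ddelta", "theta", "phi")


@dataclass(frozen=True)
class InversionConfig:
    """Analysis-space limits and Monte-Carlo search schedule."""

    log10_r1_range: tuple[float, float] = (-1.0, 1.0)
    log10_r2_range: tuple[float, float] = (0.0, 3.0)
    log10_diso_range: tuple[float, float] = (-12.0, -8.0)
    ddelta_range: tuple[float, float] = (-0.5, 1.0)
    n_candidates: int = 200
    n_prolif: int = 20
    n_mutate: int = 20
    n_offspring: int = 4           # mutated copies per retained component per round
    mutation_scale: float = 0.2    # log-units / radians / Ddelta units
    mutation_decay: float = 0.85   # geometric decay of the scale per round
    max_components: int = 50
    sparsify_rtol: float = 0.0     # >0: drop components while the residual
                                   # grows by at most this relative amount
    sparsify_atol: float = 0.0     # >0: ... or stays below this fraction of
                                   # the signal norm (collapses exact fits)
    shape_constraint: bool = False  # restrict candidates to isotropic-or-prolate

    def __post_init__(self) -> None:
        for name in ("log10_r1_range", "log10_r2_range", "log10_diso_range", "ddelta_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        if min(self.n_candidates, self.n_prolif, self.n_mutate, self.max_components) < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class Solution:
    """One discrete-component solution with its fit diagnostics."""

    components: list[Component]
    residual_norm: float
    noise_estimate: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum()) if self.components else 0.0


@dataclass
class SolutionEnsemble:
    """Bootstrap ensemble of solutions plus provenance."""

    solutions: list[Solution]
    provenance: dict = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.solutions)


def nnls_solve(design: np.ndarray, signal: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative least squares ``min ||K w - s||`` with w >= 0.

    All-zero columns are removed (with a warning) before solving and get
    zero weight in the returned full-length vector.
    """
    design = np.asarray(design, dtype=float)
    signal = np.asarray(signal, dtype=float)
    keep = np.flatnonzero(design.any(axis=0))
    if keep.size < design.shape[1]:
        warnings.warn(
            f"removed {design.shape[1] - keep.size} all-zero design columns",
            stacklevel=2,
        )
    weights = np.zeros(design.shape[1])
    if keep.size == 0:
        return weights, float(np.linalg.norm(signal))
    w, rnorm = _scipy_nnls(design[:, keep], signal)
    weights[keep] = w
    return weights, float(rnorm)


def _draw_candidates(m: int, cfg: InversionConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform draws in the transformed analysis space, rows of PARAM_NAMES."""
    if m <= 0:
        return np.empty((0, 6))
    r1 = 10.0 ** rng.uniform(*cfg.log10_r1_range, m)
    r2 = 10.0 ** rng.uniform(*cfg.log10_r2_range, m)
    diso = 10.0 ** rng.uniform(*cfg.log10_diso_range, m)
    lo, hi = cfg.ddelta_range
    if cfg.shape_constraint:
        lo = max(lo, 0.0)
    dd = rng.uniform(lo, hi, m)
    theta = np.arccos(rng.uniform(-1.0, 1.0, m))
    phi = rng.uniform(0.0, 2.0 * np.pi, m)
    return np.column_stack([r1, r2, diso, dd, theta, phi])


def _mutate(params: np.ndarray, scale: float, cfg: InversionConfig, rng: np.random.Generator) -> np.ndarray:
    """Gaussian perturbation in the transformed coordinates, clipped to range."""
    out = params.copy()
    n = len(out)
    for col, (lo, hi) in zip(
        range(3), (cfg.log10_r1_range, cfg.log10_r2_range, cfg.log10_diso_range)
    ):
        logv = np.log10(out[:, col]) + rng.normal(0.0, scale, n)
        out[:, col] = 10.0 ** np.clip(logv, lo, hi)
    lo, hi = cfg.ddelta_range
    if cfg.shape_constraint:
        lo = max(lo, 0.0)
    out[:, 3] = np.clip(out[:, 3] + rng.normal(0.0, scale, n), lo, hi)
    theta = out[:, 4] + rng.normal(0.0, scale, n)
    phi = out[:, 5] + rng.normal(0.0, scale, n)
    # reflect theta into [0, pi]; phi wraps
    theta = np.abs(theta)
    theta = np.where(theta > np.pi, 2.0 * np.pi - theta, theta)
    out[:, 4] = theta
    out[:, 5] = np.mod(phi, 2.0 * np.pi)
    return out


def estimate_noise(residuals: np.ndarray) -> float:
    """Robust residual scale: 1.4826 * median(|r - median(r)|)."""
    residuals = np.asarray(residuals, dtype=float)
    return float(1.4826 * np.median(np.abs(residuals - np.median(residuals))))


def _to_components(params: np.ndarray, weights: np.ndarray) -> list[Component]:
    return [
        Component(float(w), *map(float, row))
        for row, w in zip(params, weights)
    ]


def invert(
    ds: SignalDataset,
    cfg: InversionConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> Solution:
    """Single Monte-Carlo NNLS inversion of one dataset.

    Weights are expressed as signal fractions of ``ds.S0``.  Returns an
    empty solution (with a diagnostic flag) if no candidate ever attains
    positive weight.
    """
    cfg = cfg or InversionConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    s = ds.signal / ds.S0
    scheme = ds.scheme

    params = np.empty((0, 6))
    weights = np.empty(0)
    rnorm = float(np.linalg.norm(s))

    def _solve(cand: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        K = kernel_matrix_from_params(scheme, cand)
        w, rn = nnls_solve(K, s)
        keep = w > 0
        return cand[keep], w[keep], rn

    # proliferation: top the retained set back up with fresh random draws
    for _ in range(cfg.n_prolif):
        fresh = _draw_candidates(cfg.n_candidates - len(params), cfg, rng)
        params, weights, rnorm = _solve(np.vstack([params, fresh]))

    # mutation: local refinement with a geometrically shrinking scale
    for j in range(cfg.n_mutate):
        if len(params) == 0:
            break
        scale = cfg.mutation_scale * cfg.mutation_decay**j
        offspring = [
            _mutate(params, scale, cfg, rng) for _ in range(cfg.n_offspring)
        ]
        params, weights, rnorm = _solve(np.vstack([params, *offspring]))

    if len(params) == 0:
        return Solution(
            [], rnorm * ds.S0, estimate_noise(s * ds.S0), {"empty": True}
        )

    # prune to the largest weights (stable order breaks ties by draw order)
    if len(params) > cfg.max_components:
        order = np.argsort(-weights, kind="stable")[: cfg.max_components]
        params, weights, rnorm = _solve(params[np.sort(order)])

    # optional backward elimination: collapse redundant near-duplicates by
    # dropping the smallest weight while the fit barely degrades
    if cfg.sparsify_rtol > 0 or cfg.sparsify_atol > 0:
        s_norm = float(np.linalg.norm(s))
        while len(params) > 1:
            drop = int(np.argmin(weights))
            trial = np.delete(params, drop, axis=0)
            t_params, t_weights, t_rnorm = _solve(trial)
            if t_rnorm <= max(
                rnorm * (1.0 + cfg.sparsify_rtol), cfg.sparsify_atol * s_norm
            ):
                params, weights, rnorm = t_params, t_weights, t_rnorm
            else:
                break

    K = kernel_matrix_from_params(scheme, params)
    residuals = (s - K @ weights) * ds.S0
    return Solution(
        _to_components(params, weights),
        rnorm * ds.S0,
        estimate_noise(residuals),
        {"n_components": len(params)},
    )


def bootstrap_invert(
    ds: SignalDataset,
    cfg: InversionConfig | None = None,
    n_boot: int = 100,
    seed: int | None = None,
) -> SolutionEnsemble:
    """Ensemble of inversions on datasets resampled with replacement.

    Each replicate draws ``len(ds)`` acquisition points with replacement
    and runs :func:`invert` with an independent child seed; the ensemble
    is deterministic given ``seed``.  Replicates that raise are recorded
    in ``failures`` rather than silently dropped.
    """
    cfg = cfg or InversionConfig()
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_boot)
    solutions: list[Solution] = []
    failures: list[dict] = []
    n = len(ds)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, n)
        try:
            solutions.append(invert(ds.take(idx), cfg, rng))
        except Exception as exc:  # noqa: BLE001 - recorded, not dropped
            failures.append({"replicate": i, "error": repr(exc)})
    provenance = {
        "n_boot": n_boot,
        "seed": seed,
        "config": asdict(cfg),
        "n_points": n,
    }
    return SolutionEnsemble(solutions, provenance, failures)


# ---------------------------------------------------------------------------
# serialization


def _solution_record(sol: Solution) -> dict:
    return {
        "components": [
            {
                "weight": c.weight,
                "R1": c.R1,
                "R2": c.R2,
                "Diso": c.Diso,
                "Ddelta": c.Ddelta,
                "theta": c.theta,
                "phi": c.phi,
            }
            for c in sol.components
        ],
        "residual_norm": sol.residual_norm,
        "noise_estimate": sol.noise_estimate,
        "diagnostics": sol.diagnostics,
    }


def _solution_from_record(rec: dict) -> Solution:
    return Solution(
        [Component(**c) for c in rec["components"]],
        rec["residual_norm"],
        rec["noise_estimate"],
        rec.get("diagnostics", {}),
    )


def save_ensemble_json(ens: SolutionEnsemble, path: str | Path) -> None:
    rec = {
        "provenance": ens.provenance,
        "failures": ens.failures,
        "solutions": [_solution_record(s) for s in ens.solutions],
    }
    Path(path).write_text(json.dumps(rec))


def load_ensemble_json(path: str | Path) -> SolutionEnsemble:
    rec = json.loads(Path(path).read_text())
    return SolutionEnsemble(
        [_solution_from_record(r) for r in rec["solutions"]],
        rec.get("provenance", {}),
        rec.get("failures", []),
    )


def save_ensemble_hdf5(ens: SolutionEnsemble, path: str | Path) -> None:
    """Binary container for large ensembles (one group per solution)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["provenance"] = json.dumps(ens.provenance)
        f.attrs["failures"] = json.dumps(ens.failures)
        for i, sol in enumerate(ens.solutions):
            g = f.create_group(f"solution_{i:06d}")
            rows = np.array(
                [
                    [c.weight, c.R1, c.R2, c.Diso, c.Ddelta, c.theta, c.phi]
                    for c in sol.components
                ]
            ).reshape(-1, 7)
            g.create_dataset("components", data=rows)
            g.attrs["residual_norm"] = sol.residual_norm
            g.attrs["noise_estimate"] = sol.noise_estimate


def load_ensemble_hdf5(path: str | Path) -> SolutionEnsemble:
    import h5py

    with h5py.File(path, "r") as f:
        solutions = []
        for key in sorted(k for k in f.keys() if k.startswith("solution_")):
            g = f[key]
            rows = np.asarray(g["components"])
            comps = [Component(*map(float, row)) for row in rows]
            solutions.append(
                Solution(
                    comps,
                    float(g.attrs["residual_norm"]),
                    float(g.attrs["noise_estimate"]),
                )
            )
        return SolutionEnsemble(
            solutions,
            json.loads(f.attrs.get("provenance", "{}")),
            json.loads(f.attrs.get("failures", "[]")),
        )
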