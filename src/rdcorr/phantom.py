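"""Ground-truth generator for the three-compartment yeast + liquid-crystal voxel.

The synthetic voxel mimics an aligned lyotropic liquid crystal (highly
prolate diffusion along z) next to a yeast suspension whose intra- and
extracellular water are both isotropic but differ by two orders of
magnitude in diffusivity.  Parameter values (log10 scale):

    component       log10 R1  log10 R2  log10 Diso  D_par/D_perp
    liquid crystal      0        1.5        -9           100
    intracellular       0        2.0       -11             1
    extracellular       0        2.0        -9             1

These are the single source of truth used by the simulations, the
recovery tests and the acceptance report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .acquisition import Scheme
from .forward_model import Component, SignalDataset, add_noise, synthesize
from .tensor_math import delta_from_ratio

__all__ = [
    "PhantomSpec",
    "yeast_lc_phantom",
    "simulate_experiment",
    "YEAST_LC_TRUTH",
]

#: log10-scale ground truth of the three compartments.
YEAST_LC_TRUTH: dict[str, dict[str, float]] = {
    "liquid_crystal": {
        "log10_r1": 0.0,
        "log10_r2": 1.5,
        "log10_diso": -9.0,
        "log10_ratio": 2.0,
        "theta": 0.0,   # aligned with the main field (+z, lab frame)
        "phi": 0.0,
    },
    "intracellular": {
        "log10_r1": 0.0,
        "log10_r2": 2.0,
        "log10_diso": -11.0,
        "log10_ratio": 0.0,
        "theta": 0.0,
        "phi": 0.0,
    },
    "extracellular": {
        "log10_r1": 0.0,
        "log10_r2": 2.0,
        "log10_diso": -9.0,
        "log10_ratio": 0.0,
        "theta": 0.0,
        "phi": 0.0,
    },
}


@dataclass
class PhantomSpec:
    """Named discrete ground-truth components of a synthetic voxel."""

    name: str
    components: dict[str, Component] = field(default_factory=dict)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components.values()])

    def component_list(self) -> list[Component]:
        return list(self.components.values())

    def to_json(self, path: str | Path) -> None:
        rec = {
            "name": self.name,
            "components": {
                k: {
                    "weight": c.weight,
                    "R1": c.R1,
                    "R2": c.R2,
                    "Diso": c.Diso,
                    "Ddelta": c.Ddelta,
                    "theta": c.theta,
                    "phi": c.phi,
                }
                for k, c in self.components.items()
            },
        }
        Path(path).write_text(json.dumps(rec, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        rec = json.loads(Path(path).read_text())
        return cls(
            rec["name"],
            {k: Component(**v) for k, v in rec["components"].items()},
        )


def _component_from_truth(truth: dict[str, float], weight: float) -> Component:
    return Component(
        weight=weight,
        R1=10.0 ** truth["log10_r1"],
        R2=10.0 ** truth["log10_r2"],
        Diso=10.0 ** truth["log10_diso"],
        Ddelta=delta_from_ratio(10.0 ** truth["log10_ratio"]),
        theta=truth["theta"],
        phi=truth["phi"],
    )


def yeast_lc_phantom(
    weights: tuple[float, float, float] = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0),
    orientation_jitter: float | None = None,
    seed: int | None = None,
) -> PhantomSpec:
    """Build the three-compartment voxel from :data:`YEAST_LC_TRUTH`.

    ``weights`` orders (liquid_crystal, intracellular, extracellular) and
    must sum to 1.  The compartment signal fractions are not pinned down
    by the source experiments; equal thirds is the configurable default.
    ``orientation_jitter`` (rad) optionally tilts the liquid-crystal axis
    by a small Gaussian angle for robustness tests.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (3,):
        raise ValueError("weights must have three entries")
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")

    comps: dict[str, Component] = {}
    for (name, truth), w in zip(YEAST_LC_TRUTH.items(), weights):
        truth = dict(truth)
        if orientation_jitter and name == "liquid_crystal":
            rng = np.random.default_rng(seed)
            truth["theta"] = abs(rng.normal(0.0, orientation_jitter))
            truth["phi"] = rng.uniform(0.0, 2.0 * np.pi)
        comps[name] = _component_from_truth(truth, float(w))
    return PhantomSpec("yeast-lc", comps)


def simulate_experiment(
    spec: PhantomSpec,
    scheme: Scheme,
    snr: float | None = None,
    seed: int | None = None,
    S0: float = 1.0,
) -> SignalDataset:
    """Synthesize the phantom signal on ``scheme``, optionally with noise."""
    ds = synthesize(spec.component_list(), scheme, S0=S0)
    ds.meta["phantom"] = spec.name
    ds.meta["weights"] = spec.weights.tolist()
    if snr is not None and not np.isinf(snr):
        ds = add_noise(ds, snr, seed)
    return ds
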