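"""Relaxation-diffusion kernel evaluation and multi-component signal synthesis.

The signal of one microscopic environment at one acquisition point is

    K = [1 - exp(-tau_R * R1)] * exp(-tau_e * R2) * exp(-b:D)

i.e. the product of longitudinal recovery, transverse relaxation and
diffusion weighting.  A voxel is a weighted sum of such environments,
each an axisymmetric diffusion tensor with its own relaxation rates; the
synthesized signal is linear in the component weights.  Noise, when
requested, is plain additive Gaussian with standard deviation S0/SNR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import AcquisitionPoint, Scheme
from .tensor_math import AxisymmetricTensor, contract, p2

__all__ = [
    "Component",
    "SignalDataset",
    "kernel_value",
    "kernel_matrix",
    "synthesize",
    "add_noise",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class Component:
    """One discrete microscopic environment of the 6D analysis space."""

    weight: float      # signal fraction at full relaxation, >= 0
    R1: float          # longitudinal rate [1/s]
    R2: float          # transverse rate [1/s]
    Diso: float        # isotropic diffusivity [m^2/s]
    Ddelta: float      # normalized anisotropy, [-0.5, 1]
    theta: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.R1 <= 0 or self.R2 <= 0:
            raise ValueError("relaxation rates must be positive")
        if self.Diso < 0:
            raise ValueError("Diso must be >= 0")
        if not (-0.5 <= self.Ddelta <= 1.0):
            raise ValueError("Ddelta must lie in [-0.5, 1]")

    def tensor(self) -> AxisymmetricTensor:
        return AxisymmetricTensor(self.Diso, self.Ddelta, self.theta, self.phi)


@dataclass
class SignalDataset:
    """Signal amplitudes aligned with an acquisition scheme."""

    scheme: Scheme
    signal: np.ndarray
    S0: float = 1.0
    snr: float | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != (len(self.scheme),):
            raise ValueError(
                f"signal length {self.signal.shape} does not match scheme "
                f"length {len(self.scheme)}"
            )

    def __len__(self) -> int:
        return len(self.scheme)

    def take(self, indices: np.ndarray) -> "SignalDataset":
        """Row subset/resampling aligned across scheme and signal."""
        return SignalDataset(
            self.scheme.take(indices),
            self.signal[np.asarray(indices)],
            S0=self.S0,
            snr=self.snr,
            seed=self.seed,
            meta={**self.meta, "resampled": True},
        )


def kernel_value(point: AcquisitionPoint, component: Component) -> float:
    """Scalar kernel value in [0, 1] for one point/component pair."""
    b_tensor = AxisymmetricTensor(point.b / 3.0, point.b_delta, point.Theta, point.Phi)
    bD = contract(b_tensor, component.tensor())
    return (
        (1.0 - np.exp(-point.tau_R * component.R1))
        * np.exp(-point.tau_e * component.R2)
        * np.exp(-bD)
    )


def kernel_matrix(scheme: Scheme, components: list[Component]) -> np.ndarray:
    """Vectorized (n_points, n_components) kernel matrix."""
    pars = np.array(
        [[c.R1, c.R2, c.Diso, c.Ddelta, c.theta, c.phi] for c in components]
    )
    return kernel_matrix_from_params(scheme, pars)


def kernel_matrix_from_params(scheme: Scheme, pars: np.ndarray) -> np.ndarray:
    """Kernel matrix from raw parameter rows (R1, R2, Diso, Ddelta, theta, phi).

    Used directly by the inversion, which manipulates candidate
    components as arrays rather than objects.
    """
    pars = np.atleast_2d(pars)
    R1, R2, Diso, Ddelta, theta, phi = pars.T
    cos_beta = np.cos(scheme.Theta)[:, None] * np.cos(theta)[None, :] + np.cos(
        scheme.Phi[:, None] - phi[None, :]
    ) * np.sin(scheme.Theta)[:, None] * np.sin(theta)[None, :]
    bD = (
        scheme.b[:, None]
        * Diso[None, :]
        * (1.0 + 2.0 * scheme.b_delta[:, None] * Ddelta[None, :] * p2(cos_beta))
    )
    return (
        (1.0 - np.exp(-scheme.tau_R[:, None] * R1[None, :]))
        * np.exp(-scheme.tau_e[:, None] * R2[None, :])
        * np.exp(-bD)
    )


def synthesize(
    components: list[Component], scheme: Scheme, S0: float = 1.0
) -> SignalDataset:
    """Noise-free multi-component signal: S0 * sum_k w_k K(p_i, c_k)."""
    if not components:
        raise ValueError("at least one component is required")
    K = kernel_matrix(scheme, components)
    weights = np.array([c.weight for c in components])
    return SignalDataset(scheme, S0 * (K @ weights), S0=S0)


def add_noise(ds: SignalDataset, snr: float, seed: int | None = None) -> SignalDataset:
    """Add iid Gaussian noise of standard deviation S0/snr."""
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return replace(ds, snr=snr, seed=seed)
    rng = np.random.default_rng(seed)
    noisy = ds.signal + rng.normal(0.0, ds.S0 / snr, size=len(ds))
    return SignalDataset(ds.scheme, noisy, S0=ds.S0, snr=snr, seed=seed, meta=dict(ds.meta))


def write_dataset(ds: SignalDataset, path: str | Path, scheme_path: str | Path | None = None) -> None:
    """Write the signal as CSV (index, signal) plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"index": np.arange(len(ds)), "signal": ds.signal}).to_csv(
        path, index=False, float_format="%.17g"
    )
    meta = {
        "S0": ds.S0,
        "snr": None if ds.snr is None or np.isinf(ds.snr) else ds.snr,
        "seed": ds.seed,
        "scheme": str(scheme_path) if scheme_path else None,
        "meta": ds.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_dataset(path: str | Path, scheme: Scheme) -> SignalDataset:
    """Read a signal CSV written by :func:`write_dataset`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "signal" not in df.columns:
        raise ValueError(f"{path} has no 'signal' column")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SignalDataset(
        scheme,
        df["signal"].to_numpy(dtype=float),
        S0=meta.get("S0", 1.0),
        snr=meta.get("snr"),
        seed=meta.get("seed"),
        meta=meta.get("meta", {}),
    )
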