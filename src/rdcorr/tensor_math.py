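"""Axisymmetric second-order tensor algebra.

An axially symmetric, symmetric 3x3 tensor is fully described by four
numbers: its isotropic average ``iso`` (trace/3), its normalized
anisotropy ``delta``, and the polar/azimuthal angles ``(theta, phi)`` of
its symmetry axis in the laboratory frame.  The eigenvalues are

    lambda_par  = iso * (1 + 2 * delta)   (axial, along the symmetry axis)
    lambda_perp = iso * (1 - delta)       (radial, twofold degenerate)

so positive semidefiniteness restricts ``delta`` to [-0.5, 1]:
``delta < 0`` is oblate, ``delta = 0`` spherical, ``delta > 0`` prolate.

Both the diffusion tensor D and the diffusion-encoding b-tensor are
represented with the same type; for the b-tensor, ``iso = b / 3`` where
``b`` is the trace (the conventional b-value) and ``delta`` is the
b-tensor anisotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AxisymmetricTensor",
    "to_matrix",
    "eigenvalues_to_iso_delta",
    "contract",
    "p2",
    "bdelta_from_zeta",
    "zeta_from_bdelta",
    "ratio_from_delta",
    "delta_from_ratio",
    "log10_ratio_from_delta",
    "canonicalize_axis",
]

_DELTA_MIN = -0.5
_DELTA_MAX = 1.0


@dataclass(frozen=True)
class AxisymmetricTensor:
    """Size/shape/orientation parameterization of an axisymmetric tensor.

    Parameters
    ----------
    iso : float
        Isotropic average, trace/3.  Must be non-negative.
    delta : float
        Normalized anisotropy in [-0.5, 1].
    theta, phi : float
        Polar and azimuthal angles (radians) of the symmetry axis.
    """

    iso: float
    delta: float
    theta: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not self.iso >= 0.0:
            raise ValueError(f"iso must be non-negative, got {self.iso}")
        if not (_DELTA_MIN <= self.delta <= _DELTA_MAX):
            raise ValueError(
                f"delta must lie in [{_DELTA_MIN}, {_DELTA_MAX}], got {self.delta}"
            )

    @property
    def lambda_par(self) -> float:
        """Axial eigenvalue iso*(1 + 2*delta)."""
        return self.iso * (1.0 + 2.0 * self.delta)

    @property
    def lambda_perp(self) -> float:
        """Radial (doubly degenerate) eigenvalue iso*(1 - delta)."""
        return self.iso * (1.0 - self.delta)

    @property
    def axis(self) -> np.ndarray:
        """Unit vector of the symmetry axis in the laboratory frame."""
        st = math.sin(self.theta)
        return np.array(
            [
                math.cos(self.phi) * st,
                math.sin(self.phi) * st,
                math.cos(self.theta),
            ]
        )


def to_matrix(t: AxisymmetricTensor) -> np.ndarray:
    """Reconstruct the explicit symmetric 3x3 matrix of ``t``.

    The matrix is ``iso * (I + delta * (3 l l^T - I))`` where ``l`` is the
    symmetry axis; its eigenvalues are {lambda_par, lambda_perp,
    lambda_perp} and the eigenvector of lambda_par is ``l``.
    """
    l = t.axis
    return t.iso * (np.eye(3) + t.delta * (3.0 * np.outer(l, l) - np.eye(3)))


def eigenvalues_to_iso_delta(lambda_par: float, lambda_perp: float) -> tuple[float, float]:
    """Convert (axial, radial) eigenvalues to (iso, delta).

    Raises
    ------
    ValueError
        If an eigenvalue is negative, or both are zero (delta undefined).
    """
    if lambda_par < 0.0 or lambda_perp < 0.0:
        raise ValueError("eigenvalues must be non-negative")
    iso = (lambda_par + 2.0 * lambda_perp) / 3.0
    if iso == 0.0:
        raise ValueError("degenerate tensor: both eigenvalues are zero")
    delta = (lambda_par - lambda_perp) / (3.0 * iso)
    return iso, delta


def p2(x):
    """Second Legendre polynomial (3 x^2 - 1) / 2 (vectorized)."""
    x = np.asarray(x)
    out = (3.0 * x * x - 1.0) / 2.0
    return out if out.ndim else float(out)


def contract(b: AxisymmetricTensor, D: AxisymmetricTensor) -> float:
    """Generalized scalar product b:D = sum_ij b_ij D_ij.

    Closed form for two axisymmetric tensors:

        b : D = b * Diso * [1 + 2 bdelta Ddelta P2(cos beta)]

    with ``b = 3 * b.iso`` the b-tensor trace and ``beta`` the arc angle
    between the two symmetry axes.
    """
    cos_beta = math.cos(b.theta) * math.cos(D.theta) + math.cos(
        b.phi - D.phi
    ) * math.sin(b.theta) * math.sin(D.theta)
    b_trace = 3.0 * b.iso
    return b_trace * D.iso * (1.0 + 2.0 * b.delta * D.delta * p2(cos_beta))


def bdelta_from_zeta(zeta: float) -> float:
    """b-tensor anisotropy from the gradient-cone half angle: P2(cos zeta)."""
    return p2(math.cos(zeta))


def zeta_from_bdelta(b_delta: float) -> float:
    """Cone half angle in [0, pi/2] producing anisotropy ``b_delta``.

    Unique monotone-decreasing inverse of :func:`bdelta_from_zeta` on
    [0, pi/2]; errors for ``b_delta`` outside [-0.5, 1].
    """
    if not (_DELTA_MIN <= b_delta <= _DELTA_MAX):
        raise ValueError(f"b_delta must lie in [-0.5, 1], got {b_delta}")
    # P2(cos z) = bd  =>  cos^2 z = (2 bd + 1) / 3
    return math.acos(math.sqrt((2.0 * b_delta + 1.0) / 3.0))


def ratio_from_delta(d_delta: float) -> float:
    """Axial/radial eigenvalue ratio (1 + 2 d)/(1 - d) for d in [-0.5, 1).

    ``d_delta = 1`` (stick limit) gives an infinite ratio and raises.
    """
    if d_delta == _DELTA_MAX:
        raise ValueError("d_delta = 1 gives an infinite eigenvalue ratio")
    if not (_DELTA_MIN <= d_delta < _DELTA_MAX):
        raise ValueError(f"d_delta must lie in [-0.5, 1), got {d_delta}")
    return (1.0 + 2.0 * d_delta) / (1.0 - d_delta)


def delta_from_ratio(ratio: float, eps: float = 1e-9) -> float:
    """Normalized anisotropy from the eigenvalue ratio r: (r - 1)/(r + 2).

    Infinite ratios clamp to ``1 - eps`` so log-scale grids can include
    the prolate limit.
    """
    if ratio < 0.0:
        raise ValueError(f"ratio must be non-negative, got {ratio}")
    if math.isinf(ratio):
        return 1.0 - eps
    return min((ratio - 1.0) / (ratio + 2.0), 1.0 - eps)


def log10_ratio_from_delta(d_delta, eps: float = 1e-9):
    """log10 eigenvalue ratio with delta clamped to (-0.5, 1) (vectorized).

    The clamp keeps the oblate (ratio -> 0) and stick (ratio -> inf)
    limits finite for binning on logarithmic axes.
    """
    d = np.clip(np.asarray(d_delta, dtype=float), _DELTA_MIN + eps, _DELTA_MAX - eps)
    out = np.log10((1.0 + 2.0 * d) / (1.0 - d))
    return out if out.ndim else float(out)


def canonicalize_axis(theta: float, phi: float) -> tuple[float, float]:
    """Map a symmetry-axis orientation to theta in [0, pi/2].

    Axisymmetric tensors are invariant under axis inversion, so antipodal
    orientations are identified; this picks the upper-hemisphere member.
    """
    theta = theta % (2.0 * math.pi)
    if theta > math.pi:  # wrap into [0, pi]
        theta = 2.0 * math.pi - theta
        phi = phi + math.pi
    if theta > math.pi / 2.0:
        theta = math.pi - theta
        phi = phi + math.pi
    return theta, phi % (2.0 * math.pi)
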