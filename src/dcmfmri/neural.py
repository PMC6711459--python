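"""Bilinear neural dynamics.

Hidden neural activity z (one value per region) evolves as

    dz/dt = J(u) z + (C/16) u

where the effective-connectivity (Jacobian) matrix J combines an intrinsic
and an extrinsic part,

    J = -0.5 * exp(A_I + sum_k B_I^(k) u_k)   on the diagonal,
    J = A_E + sum_k B_E^(k) u_k               off the diagonal.

The exponential parametrisation keeps every self-connection strictly
negative (self-inhibiting) for all parameter values and inputs, which
precludes run-away excitation.  Element (m, n) of J is the connection from
region n to region m.  A self-connection rate -r (r > 0) corresponds to a
neural time constant tau = 1/r and a half-life tau * ln 2.
"""

from __future__ import annotations

import numpy as np

from .model import C_SCALE, SELF_RATE, ParameterSet

__all__ = ["neural_jacobian", "neural_flow", "time_constant", "half_life"]


def _jacobian_core(a: np.ndarray, b: np.ndarray, u: np.ndarray) -> np.ndarray:
    """J(u) with broadcasting over leading batch axes of ``a``/``b``.

    a: (..., R, R), b: (..., K, R, R), u: (K,) -> (..., R, R)
    """
    bu = np.einsum("...kij,k->...ij", b, u)
    total = a + bu
    R = total.shape[-1]
    eye = np.eye(R, dtype=bool)
    J = np.where(eye, 0.0, total)
    diag = SELF_RATE * np.exp(np.einsum("...ii->...i", total))
    J[..., np.arange(R), np.arange(R)] = diag
    return J


def neural_jacobian(params: ParameterSet, u) -> np.ndarray:
    """Effective connectivity J at input values ``u`` (length-K vector)."""
    u = np.asarray(u, dtype=float).ravel()
    K = params.b.shape[0]
    if u.size != K:
        raise ValueError(f"u has length {u.size}, expected {K} conditions")
    return _jacobian_core(params.a, params.b, u)


def neural_flow(z, u, params: ParameterSet) -> np.ndarray:
    """Rate of change of neural activity: J(u) z + (C/16) u."""
    z = np.asarray(z, dtype=float).ravel()
    if not np.isfinite(z).all():
        raise ValueError("non-finite neural state")
    u = np.asarray(u, dtype=float).ravel()
    J = neural_jacobian(params, u)
    if z.size != J.shape[0]:
        raise ValueError(f"z has length {z.size}, expected {J.shape[0]} regions")
    return J @ z + C_SCALE * (params.c @ u)


def time_constant(self_rate: float) -> float:
    """Neural time constant tau = 1/|rate| of a decaying self-connection (seconds)."""
    if not self_rate < 0:
        raise ValueError("self-connection rate must be negative (decaying)")
    return 1.0 / abs(self_rate)


def half_life(self_rate: float) -> float:
    """Time for activity to decay to half its level: tau * ln 2 (seconds)."""
    return time_constant(self_rate) * np.log(2.0)
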