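"""Balloon-Windkessel haemodynamics and the static BOLD observation equation.

Neural activity z drives, per region, a four-state cascade: a vasodilatory
signal s, normalised blood inflow f, normalised venous volume v and
normalised deoxyhaemoglobin content q.  With region-specific decay rate
kappa~ = 0.64 Hz * exp(decay) and transit time tau~ = 2.00 s * exp(transit):

    ds/dt = z - kappa~ s - gamma (f - 1)
    df/dt = s
    tau~ dv/dt = f - v^(1/alpha)
    tau~ dq/dt = f E(f, E0)/E0 - v^(1/alpha) q / v,   E(f, E0) = 1 - (1 - E0)^(1/f)

The rest point is (s, f, v, q) = (0, 1, 1, 1).  The BOLD signal is a static
function of (q, v):

    S = V0 (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v))
    k1 = 4.3 theta0 E0 TE,  k2 = exp(eps) r0 E0 TE,  k3 = 1 - exp(eps)

With the default V0 = 4 the output is in percent signal change, the scale
on which extracted, normalised region timeseries live and on which the
observation-noise prior (variance exp(-6) = 0.0025) is calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HaemoConstants", "HaemoState", "haemo_flow", "bold_signal",
           "KAPPA_BASE", "TRANSIT_BASE"]

#: baseline vasodilatory-signal decay rate (Hz); scaled by exp(decay)
KAPPA_BASE = 0.64
#: baseline haemodynamic transit time (s); scaled by exp(transit)
TRANSIT_BASE = 2.00


@dataclass(frozen=True)
class HaemoConstants:
    """Fixed haemodynamic and BOLD-equation constants.

    gamma
        Rate of decay of inflow feedback to the vasodilatory signal (Hz).
        The classic balloon-model value 0.41 Hz places the peak of the
        response to a brief stimulus at 5-6 s.
    alpha
        Grubb's exponent (vessel stiffness); outflow is v^(1/alpha).
    E0
        Resting oxygen extraction fraction.
    V0
        Resting venous blood volume scaling; 4 yields percent signal change.
    r0
        Slope of intravascular relaxation rate with oxygen extraction (Hz).
    theta0
        Frequency offset at the outer surface of magnetised vessels (Hz).
    """

    gamma: float = 0.41
    alpha: float = 0.32
    E0: float = 0.4
    V0: float = 4.0
    r0: float = 25.0
    theta0: float = 40.3

    def __post_init__(self):
        if not (self.gamma > 0 and self.V0 > 0 and self.r0 > 0 and self.theta0 > 0):
            raise ValueError("haemodynamic constants must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.E0 < 1:
            raise ValueError("E0 must lie in (0, 1)")


@dataclass
class HaemoState:
    """Per-region haemodynamic state (s, f, v, q); rest point is (0, 1, 1, 1)."""

    s: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        if not (self.s.shape == self.f.shape == self.v.shape == self.q.shape):
            raise ValueError("state components must share one shape")
        if (self.f <= 0).any() or (self.v <= 0).any() or (self.q <= 0).any():
            raise ValueError("f, v and q must be strictly positive")

    @classmethod
    def rest(cls, n_regions: int) -> "HaemoState":
        one = np.ones(n_regions)
        return cls(s=np.zeros(n_regions), f=one.copy(), v=one.copy(), q=one.copy())


def oxygen_extraction(f, E0: float):
    """Oxygen extraction fraction as a function of inflow: 1 - (1 - E0)^(1/f)."""
    return 1.0 - (1.0 - E0) ** (1.0 / f)


def haemo_flow(state: HaemoState, z, params, consts: HaemoConstants = HaemoConstants()):
    """Time derivatives (ds, df, dv, dq) of the haemodynamic cascade.

    ``z`` is the per-region neural activity; ``params`` supplies the free
    log-scaling parameters ``decay`` and ``transit``.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    s, f, v, q = state.s, state.f, state.v, state.q
    kappa = KAPPA_BASE * np.exp(params.decay)
    tau = TRANSIT_BASE * np.exp(params.transit)
    outflow = v ** (1.0 / consts.alpha)
    ds = z - kappa * s - consts.gamma * (f - 1.0)
    df = s
    dv = (f - outflow) / tau
    dq = (f * oxygen_extraction(f, consts.E0) / consts.E0 - outflow * q / v) / tau
    return ds, df, dv, dq


def bold_signal(state: HaemoState, eps_h: float,
                consts: HaemoConstants = HaemoConstants(), TE: float = 0.03):
    """Relative BOLD signal from venous volume and deoxyhaemoglobin."""
    k1, k2, k3 = bold_coefficients(eps_h, consts, TE)
    v, q = state.v, state.q
    return consts.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


def bold_coefficients(eps_h, consts: HaemoConstants, TE: float):
    """Coefficients (k1, k2, k3) of the BOLD signal equation."""
    ee = np.exp(eps_h)
    k1 = 4.3 * consts.theta0 * consts.E0 * TE
    k2 = ee * consts.r0 * consts.E0 * TE
    k3 = 1.0 - ee
    return k1, k2, k3
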