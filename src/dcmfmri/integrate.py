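"""Generation of predicted fMRI timeseries from parameters.

The coupled neural + haemodynamic system (5 states per region: z, s, ln f,
ln v, ln q) is advanced over the microtime grid of the input matrix with a
fixed-step classical Runge-Kutta (RK4) scheme and zero-order-hold inputs;
each microtime bin is subdivided so that no substep exceeds 62.5 ms.  The
inflow/volume/deoxyhaemoglobin states are integrated in log space, which
guarantees their positivity.  The BOLD signal of region r is sampled at
times j*TR + slice_times[r] (slice-timing model), and the confound term
X0 @ beta0 is added.  Integration is deterministic.

A batched code path integrates many parameter vectors simultaneously; the
inversion module uses it to obtain finite-difference sensitivities at the
cost of roughly one integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import InputMatrix
from .haemo import HaemoConstants, HaemoState, KAPPA_BASE, TRANSIT_BASE, bold_coefficients
from .model import C_SCALE, ModelSpec, ParameterSet, build_index
from .neural import _jacobian_core

__all__ = ["Dataset", "Prediction", "SystemState", "IntegrationError",
           "integrate_model", "step", "MAX_SUBSTEP"]

#: upper bound on the RK4 substep length (seconds)
MAX_SUBSTEP = 0.0625


class IntegrationError(RuntimeError):
    """Raised when the state trajectory becomes non-finite (numerical blow-up)."""


@dataclass
class Dataset:
    """Observed data together with the inputs needed to model them."""

    U: InputMatrix
    Y: np.ndarray          # (V, R) observed timeseries
    TR: float
    slice_times: np.ndarray
    X0: np.ndarray | None = None   # (V, C0) confounds; default one constant column

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[0] < 2:
            raise ValueError("Y must be a (V >= 2) x R array")
        if not np.isfinite(self.Y).all():
            raise ValueError("Y contains missing or non-finite values")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        self.slice_times = np.asarray(self.slice_times, dtype=float)
        if self.slice_times.shape != (self.Y.shape[1],):
            raise ValueError("one slice time per region is required")
        if ((self.slice_times < 0) | (self.slice_times > self.TR)).any():
            raise ValueError("slice_times must lie within [0, TR]")
        if self.X0 is None:
            self.X0 = np.ones((self.Y.shape[0], 1))
        self.X0 = np.atleast_2d(np.asarray(self.X0, dtype=float))
        if self.X0.shape[0] != self.Y.shape[0]:
            raise ValueError("X0 must have one row per volume")

    @property
    def n_volumes(self) -> int:
        return self.Y.shape[0]

    @property
    def n_regions(self) -> int:
        return self.Y.shape[1]


@dataclass
class Prediction:
    """Predicted timeseries, with optional stored microtime trajectories."""

    y_hat: np.ndarray
    states: dict | None = None

    def __post_init__(self):
        self.y_hat = np.asarray(self.y_hat, dtype=float)
        if not np.isfinite(self.y_hat).all():
            raise ValueError("prediction contains non-finite values")


@dataclass
class SystemState:
    """Combined neural + haemodynamic state of all regions."""

    z: np.ndarray
    haemo: HaemoState

    def __post_init__(self):
        self.z = np.atleast_1d(np.asarray(self.z, dtype=float))
        if self.z.shape != self.haemo.s.shape:
            raise ValueError("z and haemodynamic states must share one shape")

    @classmethod
    def rest(cls, n_regions: int) -> "SystemState":
        return cls(z=np.zeros(n_regions), haemo=HaemoState.rest(n_regions))


# ---------------------------------------------------------------------------
# core flow and RK4 stepping (batched: leading axes broadcast)
# ---------------------------------------------------------------------------

def _flow(z, s, lf, lv, lq, J, cu, kappa, tau, consts: HaemoConstants):
    f = np.exp(lf)
    dz = np.einsum("...ij,...j->...i", J, z) + cu
    ds = z - kappa * s - consts.gamma * (f - 1.0)
    dlf = s / f
    ev = np.exp((1.0 / consts.alpha - 1.0) * lv)   # v^(1/alpha) / v
    dlv = (f * np.exp(-lv) - ev) / tau
    E = 1.0 - (1.0 - consts.E0) ** (1.0 / f)
    dlq = (f * E / consts.E0 * np.exp(-lq) - ev) / tau
    return dz, ds, dlf, dlv, dlq


def _rk4_bin(state, J, cu, kappa, tau, consts, h, n_sub):
    z, s, lf, lv, lq = state
    for _ in range(n_sub):
        k1 = _flow(z, s, lf, lv, lq, J, cu, kappa, tau, consts)
        k2 = _flow(z + 0.5 * h * k1[0], s + 0.5 * h * k1[1], lf + 0.5 * h * k1[2],
                   lv + 0.5 * h * k1[3], lq + 0.5 * h * k1[4], J, cu, kappa, tau, consts)
        k3 = _flow(z + 0.5 * h * k2[0], s + 0.5 * h * k2[1], lf + 0.5 * h * k2[2],
                   lv + 0.5 * h * k2[3], lq + 0.5 * h * k2[4], J, cu, kappa, tau, consts)
        k4 = _flow(z + h * k3[0], s + h * k3[1], lf + h * k3[2],
                   lv + h * k3[3], lq + h * k3[4], J, cu, kappa, tau, consts)
        z = z + (h / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        s = s + (h / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        lf = lf + (h / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        lv = lv + (h / 6.0) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        lq = lq + (h / 6.0) * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
    return z, s, lf, lv, lq


def _n_substeps(dt: float, n_substeps: int | None) -> int:
    if n_substeps is not None:
        if n_substeps < 1:
            raise ValueError("n_substeps must be at least 1")
        return int(n_substeps)
    return max(1, int(np.ceil(dt / MAX_SUBSTEP - 1e-12)))


def _simulate(arrs: dict, U: InputMatrix, consts: HaemoConstants,
              n_substeps: int | None, store: tuple = ("lv", "lq")):
    """Advance the system over all microtime bins.

    ``arrs`` holds parameter arrays with an optional leading batch axis:
    a (..., R, R), b (..., K, R, R), c (..., R, K), transit (..., R),
    decay (..., R).  Returns a dict of boundary trajectories (T+1, ..., R)
    for the requested state names among z, s, lf, lv, lq.
    """
    a, b, c = arrs["a"], arrs["b"], arrs["c"]
    R = a.shape[-1]
    batch = a.shape[:-2]
    kappa = KAPPA_BASE * np.exp(arrs["decay"])
    tau = TRANSIT_BASE * np.exp(arrs["transit"])
    T = U.n_bins
    dt = U.dt
    n_sub = _n_substeps(dt, n_substeps)
    h = dt / n_sub

    z = np.zeros(batch + (R,))
    s = np.zeros_like(z)
    lf = np.zeros_like(z)
    lv = np.zeros_like(z)
    lq = np.zeros_like(z)
    names = ("z", "s", "lf", "lv", "lq")
    traj = {k: np.empty((T + 1,) + batch + (R,)) for k in store}
    state = (z, s, lf, lv, lq)
    for k in store:
        traj[k][0] = state[names.index(k)]
    # overflow during a blow-up is expected; the caller inspects finiteness
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        for t in range(T):
            u = U.values[t]
            J = _jacobian_core(a, b, u)
            cu = C_SCALE * np.einsum("...rk,k->...r", c, u)
            state = _rk4_bin(state, J, cu, kappa, tau, consts, h, n_sub)
            for k in store:
                traj[k][t + 1] = state[names.index(k)]
    return traj


def _bold_from_traj(traj, eps, consts: HaemoConstants, TE: float):
    """BOLD signal at every microtime boundary: (T+1, ..., R)."""
    k1, k2, k3 = bold_coefficients(eps, consts, TE)
    v = np.exp(traj["lv"])
    q = np.exp(traj["lq"])
    if np.ndim(eps) == 1:       # batched: eps (m,) against (T+1, m, R)
        k2 = np.asarray(k2)[None, :, None]
        k3 = np.asarray(k3)[None, :, None]
    return consts.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


def _sample_indices(spec: ModelSpec, n_volumes: int, dt: float, n_bins: int):
    times = np.arange(n_volumes)[:, None] * spec.TR + spec.slice_times[None, :]
    idx = np.rint(times / dt).astype(int)
    if idx.max() > n_bins:
        raise ValueError("sampling grid extends beyond the input matrix; "
                         "increase U's total duration")
    return idx


def _scatter(thetas: np.ndarray, spec: ModelSpec) -> dict:
    """Spread free-parameter vectors (m, n_p) into batched parameter arrays."""
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    m = thetas.shape[0]
    R, K, C0 = spec.n_regions, spec.n_conditions, spec.n_confounds
    arrs = {
        "a": np.zeros((m, R, R)),
        "b": np.zeros((m, K, R, R)),
        "c": np.zeros((m, R, K)),
        "transit": np.zeros((m, R)),
        "decay": np.zeros((m, R)),
        "epsilon": np.zeros(m),
        "beta0": np.zeros((m, C0, R)),
    }
    for pos, e in enumerate(build_index(spec)):
        if e.family == "epsilon":
            arrs["epsilon"] = thetas[:, pos]
        else:
            arrs[e.family][(slice(None),) + e.index] = thetas[:, pos]
    return arrs


def _integrate_batch(thetas: np.ndarray, spec: ModelSpec, U: InputMatrix,
                     n_volumes: int, X0: np.ndarray | None = None,
                     n_substeps: int | None = None,
                     consts: HaemoConstants = HaemoConstants()) -> np.ndarray:
    """Predicted timeseries (m, V, R) for a batch of free-parameter vectors."""
    arrs = _scatter(thetas, spec)
    traj = _simulate(arrs, U, consts, n_substeps)
    bold = _bold_from_traj(traj, arrs["epsilon"], consts, spec.TE)
    idx = _sample_indices(spec, n_volumes, U.dt, U.n_bins)
    m = bold.shape[1]
    R = spec.n_regions
    y = np.empty((m, n_volumes, R))
    for r in range(R):
        y[:, :, r] = bold[idx[:, r], :, r].T
    if spec.n_confounds:
        if X0 is None:
            X0 = np.ones((n_volumes, spec.n_confounds))
        y += np.einsum("vc,mcr->mvr", X0, arrs["beta0"])
    return y


def integrate_model(params: ParameterSet, spec: ModelSpec, U: InputMatrix,
                    n_volumes: int, X0: np.ndarray | None = None,
                    n_substeps: int | None = None,
                    consts: HaemoConstants = HaemoConstants(),
                    store_states: bool = False) -> Prediction:
    """Generate the predicted fMRI timeseries for one parameter set.

    States start at the exact rest point (z = 0, haemodynamics at rest);
    the system is advanced bin by bin with zero-order-hold inputs, region
    r's BOLD output is sampled at ``j*TR + slice_times[r]`` and the
    confound term ``X0 @ beta0`` is added.  Raises
    :class:`IntegrationError`, identifying the first bad bin, if the
    trajectory becomes non-finite.
    """
    if U.n_conditions != spec.n_conditions:
        raise ValueError("input matrix and spec disagree on the number of conditions")
    if n_volumes * spec.TR > U.duration + 1e-9:
        raise ValueError("U must cover the full scan duration (n_volumes * TR)")
    store = ("z", "s", "lf", "lv", "lq") if store_states else ("lv", "lq")
    arrs = _scatter(vec := _vector_of(params, spec), spec)
    traj = _simulate(arrs, U, consts, n_substeps, store=store)
    bad = ~np.isfinite(traj["lv"]).all(axis=(1, 2)) | ~np.isfinite(traj["lq"]).all(axis=(1, 2))
    if bad.any():
        first = int(np.argmax(bad))
        raise IntegrationError(
            f"non-finite state at microtime bin {max(first - 1, 0)} "
            f"(t = {(max(first - 1, 0)) * U.dt:.3f} s); the parameters are "
            "numerically unstable")
    bold = _bold_from_traj(traj, arrs["epsilon"], consts, spec.TE)
    idx = _sample_indices(spec, n_volumes, U.dt, U.n_bins)
    R = spec.n_regions
    y = np.empty((n_volumes, R))
    for r in range(R):
        y[:, r] = bold[idx[:, r], 0, r]
    if spec.n_confounds:
        if X0 is None:
            X0 = np.ones((n_volumes, spec.n_confounds))
        y += X0 @ params.beta0
    states = None
    if store_states:
        states = {
            "t": np.arange(U.n_bins + 1) * U.dt,
            "z": traj["z"][:, 0, :],
            "s": traj["s"][:, 0, :],
            "f": np.exp(traj["lf"][:, 0, :]),
            "v": np.exp(traj["lv"][:, 0, :]),
            "q": np.exp(traj["lq"][:, 0, :]),
            "bold": bold[:, 0, :],
        }
    return Prediction(y_hat=y, states=states)


def _vector_of(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    from .model import vectorise
    return vectorise(params, spec)[None, :]


def step(state: SystemState, u, params: ParameterSet, dt: float,
         consts: HaemoConstants = HaemoConstants()) -> SystemState:
    """One update of the combined state over ``dt`` (zero-order-hold input)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.asarray(u, dtype=float).ravel()
    J = _jacobian_core(params.a, params.b, u)
    cu = C_SCALE * (params.c @ u)
    kappa = KAPPA_BASE * np.exp(params.decay)
    tau = TRANSIT_BASE * np.exp(params.transit)
    n_sub = _n_substeps(dt, None)
    h = dt / n_sub
    hs = state.haemo
    out = _rk4_bin((state.z, hs.s, np.log(hs.f), np.log(hs.v), np.log(hs.q)),
                   J, cu, kappa, tau, consts, h, n_sub)
    if not all(np.isfinite(x).all() for x in out):
        raise IntegrationError("non-finite state after step; the parameters are "
                               "numerically unstable")
    z, s, lf, lv, lq = out
    return SystemState(z=z, haemo=HaemoState(s=s, f=np.exp(lf), v=np.exp(lv), q=np.exp(lq)))
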