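"""Model structure, parameter sets and Gaussian prior densities.

A model is specified by on/off masks over the bilinear connectivity
parameters (average connectivity ``A``, condition-specific modulation
``B``, driving inputs ``C``) together with acquisition metadata (TR, TE,
per-region slice-acquisition times).  The masks are translated into a
multivariate normal shrinkage prior: every switched-on parameter has
expectation zero and a family-specific variance; switched-off parameters
are excluded from the free-parameter vector altogether and the forward
model uses zero for them.

Prior variances (free parameters, zero prior mean throughout):

==========================  ==============  =========================
family                      prior variance  parametrisation
==========================  ==============  =========================
A (extrinsic, Hz)           1/64            used directly
A (self, log scaling)       1/64            -0.5 Hz * exp(A_ii)
B (extrinsic, Hz)           1               used directly
B (self, log scaling)       1               -0.5 Hz * exp(B_ii * u_k)
C (driving)                 1               effective rate = C/16 Hz
transit time (log scaling)  1/256           2.00 s * exp(.)
signal decay (log scaling)  1/256           0.64 Hz * exp(.)
epsilon (log scaling)       1/256           exp(.)
confound coefficients       1e8             effectively flat
==========================  ==============  =========================

Observation-noise log precisions have prior N(6, 1/128) per region,
implying a prior noise variance of exp(-6) = 0.0025 per observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "ParamEntry",
    "GaussianDensity",
    "build_index",
    "build_priors",
    "prior_credible_interval",
    "vectorise",
    "unvectorise",
    "PRIOR_VAR_A",
    "PRIOR_VAR_B",
    "PRIOR_VAR_C",
    "PRIOR_VAR_HAEMO",
    "PRIOR_VAR_CONFOUND",
    "LAMBDA_PRIOR_MEAN",
    "LAMBDA_PRIOR_VAR",
    "SELF_RATE",
    "C_SCALE",
]

PRIOR_VAR_A = 1.0 / 64.0
PRIOR_VAR_B = 1.0
PRIOR_VAR_C = 1.0
PRIOR_VAR_HAEMO = 1.0 / 256.0
PRIOR_VAR_CONFOUND = 1.0e8

LAMBDA_PRIOR_MEAN = 6.0
LAMBDA_PRIOR_VAR = 1.0 / 128.0

#: default self-connection strength (Hz); scaled by exponentiated log parameters
SELF_RATE = -0.5
#: internal scaling of the driving-input parameters: effective rate = C/16
C_SCALE = 1.0 / 16.0


def _as_binary(mask, shape, name):
    m = np.asarray(mask, dtype=float)
    if m.shape != shape:
        raise ValueError(f"{name} has shape {m.shape}, expected {shape}")
    if not np.isin(m, (0.0, 1.0)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return m.astype(np.int8)


@dataclass
class ModelSpec:
    """Structural definition of a DCM: which parameters exist, plus acquisition metadata.

    Parameters
    ----------
    region_names : list of str
        Labels of the R modelled regions.
    condition_names : list of str
        Labels of the K experimental conditions (columns of the input matrix).
    a_mask : (R, R) array of 0/1
        Off-diagonal entries switch extrinsic average connections on.  The
        diagonal (self-connections) is always on regardless of the mask.
    b_masks : (K, R, R) array of 0/1
        Per-condition modulation masks; diagonal entries are modulations of
        self-connections, off-diagonal entries modulate extrinsic connections.
    c_mask : (R, K) array of 0/1
        Driving-input mask.
    TR, TE : float
        Repetition and echo time, seconds.
    slice_times : (R,) array, optional
        Acquisition time of each region within the volume, seconds in
        ``[0, TR]``.  Defaults to the middle of the volume (TR/2).
    n_confounds : int
        Number of confound regressors (columns of X0); default a single
        constant column.
    """

    region_names: list
    condition_names: list
    a_mask: np.ndarray
    b_masks: np.ndarray
    c_mask: np.ndarray
    TR: float
    TE: float
    slice_times: np.ndarray | None = None
    n_confounds: int = 1

    def __post_init__(self):
        self.region_names = [str(r) for r in self.region_names]
        self.condition_names = [str(c) for c in self.condition_names]
        R, K = len(self.region_names), len(self.condition_names)
        if R < 1:
            raise ValueError("at least one region is required")
        self.a_mask = _as_binary(self.a_mask, (R, R), "a_mask")
        # self-connections are always estimated
        np.fill_diagonal(self.a_mask, 1)
        self.b_masks = _as_binary(self.b_masks, (K, R, R), "b_masks")
        self.c_mask = _as_binary(self.c_mask, (R, K), "c_mask")
        if not (self.TR > 0 and self.TE > 0):
            raise ValueError("TR and TE must be positive")
        if self.slice_times is None:
            self.slice_times = np.full(R, self.TR / 2.0)
        self.slice_times = np.asarray(self.slice_times, dtype=float)
        if self.slice_times.shape != (R,):
            raise ValueError(f"slice_times must have shape ({R},)")
        if ((self.slice_times < 0) | (self.slice_times > self.TR)).any():
            raise ValueError("slice_times must lie within [0, TR]")
        if self.n_confounds < 0:
            raise ValueError("n_confounds must be non-negative")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_names)


@dataclass
class ParameterSet:
    """One point in parameter space.

    The connectivity matrices follow the convention that the diagonal holds
    the intrinsic (self-connection) log-scaling parameters and the
    off-diagonal entries the extrinsic between-region rates in Hz; element
    ``(m, n)`` is the connection from region n to region m.  ``c`` is stored
    on the prior parametrisation (unit prior variance); the effective driving
    rate used by the neural flow is ``c / 16`` Hz.
    """

    a: np.ndarray        # (R, R)
    b: np.ndarray        # (K, R, R)
    c: np.ndarray        # (R, K)
    transit: np.ndarray  # (R,)   log scaling on 2.00 s transit time
    decay: np.ndarray    # (R,)   log scaling on 0.64 Hz vasodilatory decay
    epsilon: float       # log scaling on intra/extravascular ratio (global)
    beta0: np.ndarray    # (C0, R) confound coefficients

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.transit = np.asarray(self.transit, dtype=float)
        self.decay = np.asarray(self.decay, dtype=float)
        self.epsilon = float(self.epsilon)
        self.beta0 = np.atleast_2d(np.asarray(self.beta0, dtype=float))
        for name in ("a", "b", "c", "transit", "decay", "beta0"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"non-finite values in parameter block '{name}'")
        if not np.isfinite(self.epsilon):
            raise ValueError("non-finite epsilon")

    @classmethod
    def zeros(cls, spec: ModelSpec) -> "ParameterSet":
        R, K = spec.n_regions, spec.n_conditions
        return cls(
            a=np.zeros((R, R)),
            b=np.zeros((K, R, R)),
            c=np.zeros((R, K)),
            transit=np.zeros(R),
            decay=np.zeros(R),
            epsilon=0.0,
            beta0=np.zeros((spec.n_confounds, R)),
        )


@dataclass(frozen=True)
class ParamEntry:
    """One free parameter: its family, subscripts, display label and prior."""

    family: str       # 'a' | 'b' | 'c' | 'transit' | 'decay' | 'epsilon' | 'beta0'
    index: tuple
    label: str
    units: str
    prior_variance: float
    prior_mean: float = 0.0


def build_index(spec: ModelSpec) -> list[ParamEntry]:
    """Ordered list of free parameters for ``spec``.

    Ordering is stable and documented: A block (row-major over the R x R
    matrix), then one B block per condition (row-major), then C
    (column-major, i.e. condition by condition), then transit times per
    region, decay rates per region, the global epsilon, then confound
    coefficients (confound-major).  Switched-off entries do not appear.
    """
    R, K = spec.n_regions, spec.n_conditions
    names, conds = spec.region_names, spec.condition_names
    entries: list[ParamEntry] = []
    for m in range(R):
        for n in range(R):
            if m == n:
                entries.append(ParamEntry(
                    "a", (m, n), f"{names[m]} (self)", "None", PRIOR_VAR_A))
            elif spec.a_mask[m, n]:
                entries.append(ParamEntry(
                    "a", (m, n), f"{names[n]} → {names[m]}", "Hz", PRIOR_VAR_A))
    for k in range(K):
        for m in range(R):
            for n in range(R):
                if not spec.b_masks[k, m, n]:
                    continue
                if m == n:
                    label = f"{conds[k]} on {names[m]} (self)"
                    units = "None"
                else:
                    label = f"{conds[k]} on {names[n]} → {names[m]}"
                    units = "Hz"
                entries.append(ParamEntry("b", (k, m, n), label, units, PRIOR_VAR_B))
    for k in range(K):
        for m in range(R):
            if spec.c_mask[m, k]:
                entries.append(ParamEntry(
                    "c", (m, k), f"{conds[k]} → {names[m]} (driving)",
                    "Hz", PRIOR_VAR_C))
    for m in range(R):
        entries.append(ParamEntry(
            "transit", (m,), f"transit time on {names[m]}", "None", PRIOR_VAR_HAEMO))
    for m in range(R):
        entries.append(ParamEntry(
            "decay", (m,), f"signal decay on {names[m]}", "None", PRIOR_VAR_HAEMO))
    entries.append(ParamEntry(
        "epsilon", (), "intra/extravascular ratio", "None", PRIOR_VAR_HAEMO))
    for j in range(spec.n_confounds):
        for m in range(R):
            entries.append(ParamEntry(
                "beta0", (j, m), f"confound {j + 1} on {names[m]}", "a.u.",
                PRIOR_VAR_CONFOUND))
    return entries


@dataclass
class GaussianDensity:
    """Multivariate normal density over the vectorised free parameters."""

    mean: np.ndarray
    cov: np.ndarray
    index: list = field(default_factory=list)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        n = self.mean.size
        if self.cov.shape != (n, n):
            raise ValueError(f"covariance shape {self.cov.shape} does not match mean length {n}")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if self.index and len(self.index) != n:
            raise ValueError("index length does not match vector length")

    @property
    def n(self) -> int:
        return self.mean.size

    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def position(self, param_id) -> int:
        """Resolve a parameter identifier to a vector position.

        Accepts an integer position, a label string, or a
        ``(family, index-tuple)`` pair.
        """
        if isinstance(param_id, (int, np.integer)):
            pos = int(param_id)
            if not 0 <= pos < self.n:
                raise KeyError(f"parameter position {pos} out of range")
            return pos
        if not self.index:
            raise KeyError("density carries no parameter index")
        if isinstance(param_id, str):
            for i, e in enumerate(self.index):
                if e.label == param_id:
                    return i
            raise KeyError(f"unknown parameter label {param_id!r}")
        family, idx = param_id
        for i, e in enumerate(self.index):
            if e.family == family and e.index == tuple(idx):
                return i
        raise KeyError(f"unknown parameter {param_id!r}")

    def credible_interval(self, param_id, level: float = 0.90) -> tuple[float, float]:
        pos = self.position(param_id)
        z = stats.norm.ppf(0.5 + level / 2.0)
        sd = float(np.sqrt(self.cov[pos, pos]))
        mu = float(self.mean[pos])
        return (mu - z * sd, mu + z * sd)


def build_priors(spec: ModelSpec) -> GaussianDensity:
    """Translate a model specification into the multivariate normal prior.

    Every switched-on parameter receives expectation zero (confounds
    included) and the family variance from the table in the module
    docstring; the prior covariance is diagonal.  Switched-off parameters
    are excluded from the vector entirely — the forward model fixes them
    at zero.
    """
    index = build_index(spec)
    mean = np.array([e.prior_mean for e in index])
    var = np.array([e.prior_variance for e in index])
    return GaussianDensity(mean, np.diag(var), index)


def prior_credible_interval(density: GaussianDensity, param_id,
                            level: float = 0.90) -> tuple[float, float]:
    """Two-sided credible interval of one parameter under ``density``."""
    return density.credible_interval(param_id, level=level)


def vectorise(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Pack the switched-on entries of ``params`` into the free-parameter vector."""
    R, K = spec.n_regions, spec.n_conditions
    if params.a.shape != (R, R) or params.b.shape != (K, R, R) \
            or params.c.shape != (R, K) or params.transit.shape != (R,) \
            or params.decay.shape != (R,) or params.beta0.shape != (spec.n_confounds, R):
        raise ValueError("parameter shapes inconsistent with the model spec")
    out = []
    for e in build_index(spec):
        if e.family == "epsilon":
            out.append(params.epsilon)
        else:
            out.append(getattr(params, e.family)[e.index])
    return np.asarray(out, dtype=float)


def unvectorise(vector: np.ndarray, spec: ModelSpec) -> ParameterSet:
    """Inverse of :func:`vectorise`; switched-off entries are restored as zero."""
    vector = np.asarray(vector, dtype=float).ravel()
    index = build_index(spec)
    if vector.size != len(index):
        raise ValueError(f"vector length {vector.size} does not match the "
                         f"{len(index)} free parameters of the spec")
    params = ParameterSet.zeros(spec)
    for value, e in zip(vector, index):
        if e.family == "epsilon":
            params.epsilon = float(value)
        else:
            getattr(params, e.family)[e.index] = value
    return params
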