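"""Synthetic datasets with known ground truth.

The default configuration emulates a blocked factorial language design:
four frontal regions (left/right x ventral/dorsal), a driving condition
"Task" (brief events at every trial onset, entering all regions) and two
modulatory conditions "Pictures" and "Words" (alternating blocks that
scale the self-connection of every region).  Extrinsic connections link
dorsal and ventral regions within each hemisphere and homologous regions
across hemispheres — 24 free neural parameters in all.

Noise is additive IID Gaussian, scaled per region so that
sd(noise-free signal) / sd(noise) equals the requested SNR (the per-region
ratios are equal, so their average is the SNR).  The default ground-truth
driving strengths produce per-region signal standard deviations of about
0.05 percent signal change, the scale on which the observation-noise prior
(variance exp(-6) = 0.0025) is centred.  Everything is reproducible from
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import MICROTIME_BINS_PER_TR, ConditionTiming, build_input_matrix, mean_centre
from .haemo import HaemoConstants
from .integrate import Dataset, IntegrationError, integrate_model
from .model import ModelSpec, ParameterSet, build_priors, unvectorise

__all__ = ["SyntheticConfig", "generate_dataset", "default_spec",
           "default_timings", "default_true_params"]


def default_spec(TR: float = 3.6, TE: float = 0.03) -> ModelSpec:
    """Four-region, three-condition architecture of the default design."""
    regions = ["lvF", "ldF", "rvF", "rdF"]
    conditions = ["Task", "Pictures", "Words"]
    R, K = 4, 3
    a = np.zeros((R, R), dtype=int)
    # dorsal<->ventral within hemisphere, homologous across hemispheres
    for m, n in [(0, 1), (1, 0), (2, 3), (3, 2), (0, 2), (2, 0), (1, 3), (3, 1)]:
        a[m, n] = 1
    b = np.zeros((K, R, R), dtype=int)
    b[1] = np.eye(R, dtype=int)   # Pictures modulates every self-connection
    b[2] = np.eye(R, dtype=int)   # Words modulates every self-connection
    c = np.zeros((R, K), dtype=int)
    c[:, 0] = 1                   # Task drives all regions
    return ModelSpec(region_names=regions, condition_names=conditions,
                     a_mask=a, b_masks=b, c_mask=c, TR=TR, TE=TE)


def default_timings(n_volumes: int = 200, TR: float = 3.6) -> list:
    """Blocked factorial timing: alternating Pictures/Words blocks with rest.

    Each 72 s cycle holds one Pictures and one Words block of 21.6 s,
    separated by rest; Task events (duration 0) mark every trial onset,
    one per TR within each block.
    """
    total = n_volumes * TR
    cycle, block, gap = 72.0, 21.6, 14.4
    pic_on, word_on, task_on = [], [], []
    for i in range(int((total + 1e-9) // cycle)):
        p0 = i * cycle + gap
        w0 = p0 + block + gap
        pic_on.append(p0)
        word_on.append(w0)
        for j in range(int(round(block / TR))):
            task_on.append(p0 + j * TR)
            task_on.append(w0 + j * TR)
    task_on = sorted(task_on)
    return [
        ConditionTiming("Task", tuple(task_on), tuple(0.0 for _ in task_on)),
        ConditionTiming("Pictures", tuple(pic_on), tuple(block for _ in pic_on)),
        ConditionTiming("Words", tuple(word_on), tuple(block for _ in word_on)),
    ]


def default_true_params(spec: ModelSpec) -> ParameterSet:
    """Ground-truth parameters: moderate effects relative to the priors."""
    p = ParameterSet.zeros(spec)
    p.a[np.diag_indices(4)] = [-0.10, 0.05, -0.05, 0.10]
    for (m, n), v in {(1, 0): 0.30, (0, 1): -0.15, (3, 2): 0.25, (2, 3): -0.10,
                      (2, 0): 0.20, (0, 2): 0.30, (3, 1): 0.15, (1, 3): -0.20}.items():
        p.a[m, n] = v
    p.b[1][np.diag_indices(4)] = [-0.40, 0.80, 0.30, -0.20]   # Pictures
    p.b[2][np.diag_indices(4)] = [0.90, -0.30, 0.50, 0.20]    # Words
    p.c[:, 0] = [0.20, 0.25, 0.18, 0.22]
    p.transit[:] = [0.05, -0.05, 0.02, 0.0]
    p.decay[:] = [-0.03, 0.04, 0.0, 0.02]
    p.epsilon = 0.05
    return p


@dataclass
class SyntheticConfig:
    """Everything needed to generate one synthetic dataset."""

    spec: ModelSpec = field(default_factory=default_spec)
    true_params: ParameterSet | str | None = None   # None/'default' | 'prior' | set
    snr: float = 1.0
    n_volumes: int = 200
    seed: int = 0
    bins_per_tr: int = MICROTIME_BINS_PER_TR
    centre: bool = True
    consts: HaemoConstants = field(default_factory=HaemoConstants)
    max_resample: int = 8   # retries when prior-sampled parameters blow up

    def __post_init__(self):
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.n_volumes < 2:
            raise ValueError("at least two volumes are required")


def generate_dataset(cfg: SyntheticConfig) -> tuple[Dataset, ParameterSet]:
    """Simulate a dataset and return it with its ground-truth parameters.

    Builds the blocked factorial design, integrates the forward model,
    and adds IID Gaussian noise with per-region sd = sd(signal)/snr.
    ``snr=inf`` yields noise-free data.  With ``true_params='prior'``
    the ground truth is drawn from the prior, resampling (up to
    ``max_resample`` times) if the draw is numerically unstable.
    """
    spec = cfg.spec
    rng = np.random.default_rng(cfg.seed)
    dt = spec.TR / cfg.bins_per_tr
    total = cfg.n_volumes * spec.TR
    U = build_input_matrix(default_timings(cfg.n_volumes, spec.TR), total, dt)
    if cfg.centre:
        U = mean_centre(U)
    X0 = np.ones((cfg.n_volumes, spec.n_confounds))

    truth = cfg.true_params
    if truth is None or truth == "default":
        truth = default_true_params(spec)
    if isinstance(truth, str) and truth == "prior":
        prior = build_priors(spec)
        sd = prior.sd()
        # confounds stay at zero when sampling from the (flat) prior
        sd = np.where(np.array([e.family == "beta0" for e in prior.index]), 0.0, sd)
        pred = None
        for _ in range(cfg.max_resample):
            draw = prior.mean + sd * rng.standard_normal(prior.n)
            candidate = unvectorise(draw, spec)
            try:
                pred = integrate_model(candidate, spec, U, cfg.n_volumes, X0=X0,
                                       consts=cfg.consts)
            except IntegrationError:
                continue
            truth = candidate
            break
        if pred is None:
            raise IntegrationError("could not draw stable parameters from the prior")
    else:
        pred = integrate_model(truth, spec, U, cfg.n_volumes, X0=X0, consts=cfg.consts)

    signal = pred.y_hat
    sd_signal = signal.std(axis=0)
    if np.isinf(cfg.snr):
        Y = signal.copy()
    else:
        noise_sd = sd_signal / cfg.snr
        Y = signal + rng.standard_normal(signal.shape) * noise_sd[None, :]
    data = Dataset(U=U, Y=Y, TR=spec.TR, slice_times=spec.slice_times.copy(), X0=X0)
    return data, truth
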