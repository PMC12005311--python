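"""Discretized conditional densities of the confidence score.

For one nested binary task, the deferral rule needs the joint mass
p(z, h=a | y=b) of the AI confidence score z and the (binarised) reader
opinion h given the (binarised) truth y.  It is factored as

    p(z, h=a | y=b) = p(z | h=a, y=b) * p(h=a | y=b)

with the reader priors p(h|y) estimated by smoothed counting from historical
(tuning) data and the score densities p(z|h,y) by a discretized kernel
density estimate: z is binned into T uniform bins over [0, 1], per-bin counts
receive a pseudocount kappa, the histogram is convolved with a discrete
Gaussian kernel of bandwidth sigma (in bin-index units, truncated at
+/- ceil(4 sigma) and renormalised at the edges so no mass leaks outside
[0, 1]), and the result is normalised to sum to one.  kappa is added before
smoothing, which keeps the smoother linear and makes the kappa -> infinity
limit exactly uniform.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .ordinal import TASK_NAMES

__all__ = [
    "DensityConfig",
    "ConditionalDensityTable",
    "InsufficientDataError",
    "bin_of",
    "fit_priors",
    "fit_conditional_density",
    "fit_density_table",
    "joint_density",
]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Raised when a truth class required for estimation is empty."""


@dataclass(frozen=True)
class DensityConfig:
    """Hyperparameters of the discretized KDE.

    bins:            number of uniform z-bins T (>= 1)
    bandwidth:       Gaussian kernel SD sigma, in bin-index units (>= 0;
                     0 disables smoothing)
    pseudocount:     kappa added to every bin before smoothing (>= 0)
    prior_smoothing: add-lambda smoothing of the reader priors p(h|y)
                     (default 0.5, avoids exactly-zero advantage terms on
                     finite samples)
    """

    bins: int = 10
    bandwidth: float = 0.0
    pseudocount: float = 0.0
    prior_smoothing: float = 0.5

    def __post_init__(self):
        if self.bins < 1:
            raise ValueError("bins (T) must be >= 1")
        if self.bandwidth < 0:
            raise ValueError("bandwidth (sigma) must be >= 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount (kappa) must be >= 0")
        if self.prior_smoothing < 0:
            raise ValueError("prior_smoothing must be >= 0")


def bin_of(z, T: int):
    """Map scores in [0, 1] to 0-based indices of T uniform bins.

    Bins are half-open [l, u) except the last, which is closed so z = 1
    falls in bin T-1.  Scalar or array input.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0.0) or np.any(z_arr > 1.0):
        raise ValueError("confidence score must lie in [0, 1]")
    idx = np.minimum((z_arr * T).astype(int), T - 1)
    return int(idx) if np.isscalar(z) or idx.ndim == 0 else idx


def fit_priors(z, h, y, smoothing: float = 0.5) -> np.ndarray:
    """Estimate the reader priors p(h=a | y=b) by smoothed counting.

    Returns a (2, 2) array ``prior[a, b]``.  Requires at least one case in
    each truth class.
    """
    h = np.asarray(h, dtype=int)
    y = np.asarray(y, dtype=int)
    prior = np.empty((2, 2))
    for b in (0, 1):
        n_b = int(np.sum(y == b))
        if n_b == 0:
            raise InsufficientDataError(f"no tuning cases with truth y={b}")
        for a in (0, 1):
            n_ab = int(np.sum((h == a) & (y == b)))
            prior[a, b] = (n_ab + smoothing) / (n_b + 2.0 * smoothing)
    return prior


def _gaussian_kernel(sigma: float) -> np.ndarray:
    """Discrete Gaussian weights on bin-index offsets -R..R, R = ceil(4 sigma)."""
    if sigma == 0:
        return np.array([1.0])
    radius = int(math.ceil(4.0 * sigma))
    d = np.arange(-radius, radius + 1)
    w = np.exp(-0.5 * (d / sigma) ** 2)
    return w / w.sum()


def _smooth(counts: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve with the discrete Gaussian, renormalising the truncated
    kernel at each source bin so no mass leaks outside the support."""
    if sigma == 0:
        return counts.astype(float)
    T = counts.size
    kernel = _gaussian_kernel(sigma)
    radius = kernel.size // 2
    out = np.zeros(T)
    for i in range(T):
        lo, hi = max(0, i - radius), min(T - 1, i + radius)
        w = kernel[(lo - i) + radius: (hi - i) + radius + 1]
        out[lo: hi + 1] += counts[i] * (w / w.sum())
    return out


def fit_conditional_density(z, config: DensityConfig) -> np.ndarray:
    """Discretized KDE of p(z | h, y) for one (h, y) cell.

    Histogram + pseudocounts, Gaussian smoothing on bin indices, then
    normalisation.  An empty cell with kappa = 0 falls back to the uniform
    density with a logged warning (so a hyperparameter search never crashes
    on a sparse tuning set).
    """
    T = config.bins
    z = np.asarray(z, dtype=float)
    counts = np.bincount(bin_of(z, T), minlength=T).astype(float) if z.size else np.zeros(T)
    counts += config.pseudocount
    if counts.sum() == 0:
        logger.warning(
            "empty (h, y) cell with kappa=0: falling back to uniform density over %d bins", T
        )
        return np.full(T, 1.0 / T)
    smoothed = _smooth(counts, config.bandwidth)
    return smoothed / smoothed.sum()


@dataclass
class ConditionalDensityTable:
    """Fitted factored densities for one nested binary task.

    density[a][b] is the length-T probability vector of p(z | h=a, y=b);
    prior[a, b] is p(h=a | y=b); counts[a, b] the supporting case count.
    """

    task: int
    config: DensityConfig
    density: list = field(default_factory=list)   # density[a][b] -> np.ndarray(T)
    prior: np.ndarray | None = None               # (2, 2)
    counts: np.ndarray | None = None              # (2, 2) ints

    @property
    def fitted(self) -> bool:
        return self.prior is not None and len(self.density) == 2

    def to_json(self) -> str:
        return json.dumps(
            {
                "task": self.task,
                "task_name": TASK_NAMES[self.task],
                "config": {
                    "bins": self.config.bins,
                    "bandwidth": self.config.bandwidth,
                    "pseudocount": self.config.pseudocount,
                    "prior_smoothing": self.config.prior_smoothing,
                },
                "density": [[list(self.density[a][b]) for b in (0, 1)] for a in (0, 1)],
                "prior": self.prior.tolist(),
                "counts": self.counts.tolist(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ConditionalDensityTable":
        data = json.loads(text)
        cfg = DensityConfig(**data["config"])
        table = cls(task=data["task"], config=cfg)
        table.density = [
            [np.asarray(data["density"][a][b], float) for b in (0, 1)] for a in (0, 1)
        ]
        table.prior = np.asarray(data["prior"], float)
        table.counts = np.asarray(data["counts"], int)
        return table


def fit_density_table(z, h, y, task: int, config: DensityConfig) -> ConditionalDensityTable:
    """Fit priors and all four conditional densities for one task.

    ``z`` are confidence scores in [0, 1]; ``h`` and ``y`` are the reader
    opinion and truth already binarised for the task.
    """
    z = np.asarray(z, dtype=float)
    h = np.asarray(h, dtype=int)
    y = np.asarray(y, dtype=int)
    table = ConditionalDensityTable(task=task, config=config)
    table.prior = fit_priors(z, h, y, smoothing=config.prior_smoothing)
    table.density = [
        [fit_conditional_density(z[(h == a) & (y == b)], config) for b in (0, 1)]
        for a in (0, 1)
    ]
    table.counts = np.array(
        [[int(np.sum((h == a) & (y == b))) for b in (0, 1)] for a in (0, 1)]
    )
    return table


def joint_density(table: ConditionalDensityTable, z, h: int, y: int):
    """Joint mass p(z-bin, h | y) = p(z | h, y) * p(h | y).

    ``z`` may be scalar or array.
    """
    if not table.fitted:
        raise RuntimeError("density table is not fitted")
    idx = bin_of(z, table.config.bins)
    return table.density[h][y][idx] * table.prior[h, y]
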