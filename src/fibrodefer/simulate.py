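"""Synthetic cohort and covariate-shift simulators.

The deferral decision model consumes, per case, the triplet (confidence
score ``z``, reader opinion ``h``, truth stage ``y``).  No public cohort
carries all three, so this module generates cohorts with the joint structure
the decision model assumes:

* truth stage ``y`` drawn from a configurable prevalence vector;
* a latent severity ``u = y + Normal(0, tau^2)`` pushed through a logistic
  link at thresholds ``k - 0.5`` to yield the 4-component ordinal confidence
  vector ``z_k = logistic((u - (k - 0.5)) / s)`` -- a shared latent with
  increasing thresholds, so ``z`` is always component-wise non-increasing
  and its discrimination is controlled by one noise scale ``tau``;
* a reader opinion ``h`` drawn from a row-stochastic 5x5 confusion matrix;
* serum markers (AST, ALT, platelets, age) from stage-conditional normals
  truncated to positive values, and a liver-stiffness-like auxiliary score
  from a stage-conditional log-normal.

Reader confusion matrices are not published for the emulated study design;
the default here is illustrative (senior-reader-like: mostly correct with
adjacent-stage errors) and should be overridden when calibrating to a real
reader.  A separate generator produces source/target feature sets under an
affine covariate shift, as a fixture for test-time adaptation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import truncnorm

from .ordinal import N_STAGES, N_TASKS, parse_stage, stage_label

__all__ = [
    "CohortConfig",
    "ShiftConfig",
    "ConfigError",
    "generate_cohort",
    "generate_shifted_features",
    "coarsen_reader",
    "refine_three_level",
    "default_reader_confusion",
    "write_cohort",
    "read_cohort",
    "load_cohort_config",
    "load_shift_config",
]

COHORT_COLUMNS = [
    "case_id", "truth_stage", "z1", "z2", "z3", "z4",
    "reader_stage", "reader_3level", "ast", "alt", "plt", "age", "aux_score",
]


class ConfigError(ValueError):
    """Invalid simulator configuration."""


class SchemaError(ValueError):
    """A cohort file violates the expected schema."""


def default_reader_confusion() -> np.ndarray:
    """Illustrative senior-reader confusion matrix P(h = col | y = row).

    Mostly correct with adjacent-stage errors; early stages are harder to
    tell apart on imaging than cirrhosis.
    """
    m = np.array(
        [
            [0.78, 0.15, 0.05, 0.02, 0.00],
            [0.18, 0.60, 0.15, 0.05, 0.02],
            [0.05, 0.15, 0.60, 0.15, 0.05],
            [0.02, 0.05, 0.15, 0.63, 0.15],
            [0.00, 0.02, 0.05, 0.13, 0.80],
        ]
    )
    return m


# Stage-conditional marker distributions (mean, sd) per stage S0..S4.
# Units: AST and ALT in U/L, platelets in 10^9/L, age in years.  Chosen to
# mimic the direction and rough magnitude of serum changes with advancing
# fibrosis (transaminases rise, platelets fall with portal hypertension).
DEFAULT_MARKER_PARAMS = {
    "ast": ([28.0, 36.0, 48.0, 62.0, 78.0], [12.0, 16.0, 22.0, 28.0, 36.0]),
    "alt": ([30.0, 40.0, 48.0, 50.0, 46.0], [14.0, 18.0, 24.0, 26.0, 24.0]),
    "plt": ([235.0, 210.0, 180.0, 145.0, 105.0], [55.0, 55.0, 55.0, 50.0, 45.0]),
    "age": ([46.0, 49.0, 52.0, 54.0, 56.0], [12.0, 12.0, 11.0, 11.0, 10.0]),
}

# Median liver-stiffness surrogate (kPa-like) per stage, log-normal spread.
DEFAULT_AUX_MEDIANS = [4.8, 6.0, 8.0, 11.0, 18.0]
DEFAULT_AUX_LOG_SD = 0.30


@dataclass
class CohortConfig:
    """Parameters of the synthetic (z, h, y) cohort generator.

    ``prevalence`` defaults to a histology mix typical of a tertiary-care
    staging cohort (many S0 work-ups and many cirrhotics, few mid stages).
    ``latent_noise`` (tau) sets AI discrimination: tau -> 0 gives a perfect
    classifier, larger tau degrades it.  ``link_scale`` (s) sets confidence
    sharpness: s -> 0 gives hard 0/1 confidences.
    """

    n: int = 500
    prevalence: tuple = (0.37, 0.10, 0.12, 0.08, 0.33)
    latent_noise: float = 0.8
    link_scale: float = 0.3
    reader_confusion: np.ndarray = field(default_factory=default_reader_confusion)
    marker_params: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_PARAMS))
    aux_medians: tuple = tuple(DEFAULT_AUX_MEDIANS)
    aux_log_sd: float = DEFAULT_AUX_LOG_SD
    seed: int = 0

    def validate(self) -> "CohortConfig":
        p = np.asarray(self.prevalence, dtype=float)
        if p.shape != (N_STAGES,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ConfigError("prevalence must be 5 nonnegative probabilities summing to 1")
        c = np.asarray(self.reader_confusion, dtype=float)
        if c.shape != (N_STAGES, N_STAGES) or np.any(c < 0) or np.any(
            np.abs(c.sum(axis=1) - 1.0) > 1e-8
        ):
            raise ConfigError("reader_confusion must be a 5x5 row-stochastic matrix")
        if self.latent_noise < 0:
            raise ConfigError("latent_noise (tau) must be >= 0")
        if self.link_scale <= 0:
            raise ConfigError("link_scale (s) must be > 0")
        if self.n < 0:
            raise ConfigError("n must be >= 0")
        return self


def _substreams(seed: int, n_streams: int):
    """Independent child generators from one global seed.

    Each simulated component owns a fixed child index, so adding a new
    component (a new stream at the end) never perturbs earlier draws.
    """
    children = np.random.SeedSequence(seed).spawn(n_streams)
    return [np.random.default_rng(c) for c in children]


def _truncated_normal(rng, mean, sd, size):
    """Stage-conditional normal truncated to (0, inf)."""
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a synthetic staged cohort as a tidy DataFrame.

    Columns follow :data:`COHORT_COLUMNS`; stages are stored as integers 0-4
    in memory and rendered ``S0``..``S4`` on disk.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    n = config.n
    rng_truth, rng_latent, rng_reader, rng_marker, rng_aux = _substreams(config.seed, 5)

    y = rng_truth.choice(N_STAGES, size=n, p=np.asarray(config.prevalence, float))
    u = y + rng_latent.normal(0.0, config.latent_noise, size=n)
    thresholds = np.arange(1, N_STAGES) - 0.5
    z = expit((u[:, None] - thresholds[None, :]) / config.link_scale)

    conf = np.asarray(config.reader_confusion, dtype=float)
    # vectorised row-wise categorical draw via inverse CDF
    cum = np.cumsum(conf, axis=1)
    uh = rng_reader.random(n)
    h = (uh[:, None] > cum[y]).sum(axis=1)

    markers = {}
    for name in ("ast", "alt", "plt", "age"):
        means, sds = config.marker_params[name]
        means = np.asarray(means, float)[y]
        sds = np.asarray(sds, float)[y]
        markers[name] = _truncated_normal(rng_marker, means, sds, n)

    aux = np.exp(
        np.log(np.asarray(config.aux_medians, float))[y]
        + rng_aux.normal(0.0, config.aux_log_sd, size=n)
    )

    df = pd.DataFrame(
        {
            "case_id": np.arange(n),
            "truth_stage": y.astype(int),
            "z1": z[:, 0] if n else np.array([]),
            "z2": z[:, 1] if n else np.array([]),
            "z3": z[:, 2] if n else np.array([]),
            "z4": z[:, 3] if n else np.array([]),
            "reader_stage": h.astype(int),
            "reader_3level": coarsen_reader(h.astype(int)),
            "ast": markers["ast"],
            "alt": markers["alt"],
            "plt": markers["plt"],
            "age": markers["age"],
            "aux_score": aux,
        }
    )
    return df


def coarsen_reader(h):
    """Collapse a 5-stage read to the 3-level clinical report.

    Level 1 = basically normal (S0-1), level 2 = chronic liver disease
    (S2-3), level 3 = cirrhosis (S4).
    """
    h = np.asarray(h)
    out = np.where(h <= 1, 1, np.where(h <= 3, 2, 3))
    return out if out.ndim else int(out)


def refine_three_level(levels, p_upper: float = 0.5, rng=None):
    """Refine 3-level reads back to stages, emulating a second-look read.

    Level 1 -> S1, level 3 -> S4; level 2 (the ambiguous S2-3 band) is split
    S3 with probability ``p_upper`` (default 0.5), else S2.  The emulated
    workflow had humans re-stage the S2-3 band; here the split is a
    configurable Bernoulli draw.
    """
    levels = np.asarray(levels)
    if rng is None:
        rng = np.random.default_rng(0)
    upper = rng.random(levels.shape) < p_upper
    out = np.where(levels == 1, 1, np.where(levels == 3, 4, np.where(upper, 3, 2)))
    return out


# ---------------------------------------------------------------------------
# Covariate-shift fixture for test-time adaptation
# ---------------------------------------------------------------------------

def _default_stage_means(d: int = 4) -> np.ndarray:
    w = np.array([1.0, 0.6, -0.8, 0.3])[:d]
    return np.outer(np.arange(N_STAGES), w)


@dataclass
class ShiftConfig:
    """Source/target feature generator under an affine covariate shift.

    Source features follow stage-conditional Gaussians; target features are
    an independent draw pushed through ``x -> A x + b``.  The default shift
    (anisotropic rescale plus a large offset, several within-class SDs) is
    strong enough that a source-trained classifier degrades visibly on the
    target domain -- the situation test-time adaptation addresses.
    """

    feature_dim: int = 4
    stage_means: np.ndarray = field(default_factory=_default_stage_means)
    stage_covs: np.ndarray = field(
        default_factory=lambda: np.tile(np.eye(4), (N_STAGES, 1, 1))
    )
    shift_matrix: np.ndarray = field(default_factory=lambda: 1.5 * np.eye(4))
    shift_offset: np.ndarray = field(
        default_factory=lambda: np.array([2.5, -1.5, 2.0, 1.0])
    )
    prevalence: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    n_source: int = 2000
    n_target: int = 1000
    seed: int = 0

    def validate(self) -> "ShiftConfig":
        d = self.feature_dim
        if d < 1:
            raise ConfigError("feature_dim must be >= 1")
        covs = np.asarray(self.stage_covs, float)
        if covs.shape != (N_STAGES, d, d):
            raise ConfigError(f"stage_covs must have shape (5, {d}, {d})")
        for k in range(N_STAGES):
            if np.min(np.linalg.eigvalsh((covs[k] + covs[k].T) / 2)) < -1e-8:
                raise ConfigError(f"stage covariance {k} is not positive semidefinite")
        if np.asarray(self.stage_means, float).shape != (N_STAGES, d):
            raise ConfigError(f"stage_means must have shape (5, {d})")
        p = np.asarray(self.prevalence, float)
        if p.shape != (N_STAGES,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ConfigError("prevalence must be 5 nonnegative probabilities summing to 1")
        return self


def generate_shifted_features(config: ShiftConfig):
    """Draw (X_source, y_source, X_target, y_target) under the affine shift.

    Target labels are returned for evaluation only; adaptation itself never
    sees them.
    """
    config.validate()
    d = config.feature_dim
    means = np.asarray(config.stage_means, float)
    covs = np.asarray(config.stage_covs, float)
    rng_src, rng_tgt = _substreams(config.seed, 2)

    def draw(rng, n):
        y = rng.choice(N_STAGES, size=n, p=np.asarray(config.prevalence, float))
        X = np.empty((n, d))
        for k in range(N_STAGES):
            idx = np.nonzero(y == k)[0]
            if idx.size:
                X[idx] = rng.multivariate_normal(means[k], covs[k], size=idx.size)
        return X, y

    X_src, y_src = draw(rng_src, config.n_source)
    X_tgt, y_tgt = draw(rng_tgt, config.n_target)
    A = np.asarray(config.shift_matrix, float)
    b = np.asarray(config.shift_offset, float)
    X_tgt = X_tgt @ A.T + b
    return X_src, y_src, X_tgt, y_tgt


# ---------------------------------------------------------------------------
# Cohort file I/O (delimited text, stage tokens S0..S4)
# ---------------------------------------------------------------------------

def write_cohort(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a cohort CSV (UTF-8, '.' decimal, mandatory header).

    An optional ``meta`` dict (seed, config hash, ...) is embedded as a
    single leading ``#`` comment line; readers skip it.
    """
    out = df.copy()
    out["truth_stage"] = [stage_label(s) for s in out["truth_stage"]]
    out["reader_stage"] = [stage_label(s) for s in out["reader_stage"]]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if meta:
            fh.write("# meta: " + json.dumps(meta, sort_keys=True) + "\n")
        out.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`.

    Schema violations raise :class:`SchemaError` naming the offending column
    or row.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} is missing columns: {missing}")
    for col in ("truth_stage", "reader_stage"):
        try:
            df[col] = [parse_stage(tok) for tok in df[col]]
        except ValueError as exc:
            raise SchemaError(f"column {col!r} of {path}: {exc}") from exc
    z = df[["z1", "z2", "z3", "z4"]].to_numpy(float)
    bad = np.nonzero((z < 0) | (z > 1) | ~np.isfinite(z))[0]
    if bad.size:
        raise SchemaError(
            f"cohort file {path}: confidence out of [0,1] at data row {int(bad[0])}"
        )
    lv = df["reader_3level"].to_numpy()
    if not np.isin(lv, [1, 2, 3]).all():
        row = int(np.nonzero(~np.isin(lv, [1, 2, 3]))[0][0])
        raise SchemaError(f"cohort file {path}: reader_3level invalid at data row {row}")
    return df[COHORT_COLUMNS]


def _config_from_mapping(cls, data: dict):
    array_fields = {
        "reader_confusion", "stage_means", "stage_covs", "shift_matrix", "shift_offset",
    }
    kwargs = {}
    for key, value in data.items():
        kwargs[key] = np.asarray(value, float) if key in array_fields else value
    for tup in ("prevalence", "aux_medians"):
        if tup in kwargs:
            kwargs[tup] = tuple(kwargs[tup])
    return cls(**kwargs).validate()


def _load_mapping(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_cohort_config(path) -> CohortConfig:
    """Load a :class:`CohortConfig` from YAML or JSON."""
    return _config_from_mapping(CohortConfig, _load_mapping(path))


def load_shift_config(path) -> ShiftConfig:
    """Load a :class:`ShiftConfig` from YAML or JSON."""
    return _config_from_mapping(ShiftConfig, _load_mapping(path))
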