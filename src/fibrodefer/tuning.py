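"""Grid hyperparameter search for the deferral decision models.

Each sub-model (D2-4, D3-4, D4) is tuned independently on its binarised task
over an exhaustive grid of (theta, lambda, kappa, T, sigma).  For every grid
point the densities are re-fitted on the tuning set, the combined system is
simulated (AI call ``z > theta`` when adopted, reader call when deferred)
and scored with the weighted objective

    lambda * Sensitivity + (1 - lambda) * Specificity,

where the grid point's lambda doubles as the evaluation weight.  Named
operating points (OP1 sensitivity-leaning, OP2 specificity-leaning) are
produced by re-running the search with lambda pinned to a preset value.
Two sentinel policies -- never defer, always defer -- can be included as
degenerate candidates; ties are broken deterministically in favour of
cheaper policies (lowest deferral rate, then smaller T, sigma, kappa, then
theta closest to 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .deferral import CompositePolicy, DeferralModel
from .density import DensityConfig, fit_density_table
from .ordinal import TASK_NAMES

__all__ = [
    "GridSpec",
    "TaskOperatingPoint",
    "OperatingPoint",
    "sens_spec_binary",
    "policy_objective",
    "tune_task",
    "tune_policy",
    "tune_operating_points",
    "DEFAULT_OP_LAMBDAS",
]

logger = logging.getLogger(__name__)

#: Preset trade-off weights behind the two named operating points.
DEFAULT_OP_LAMBDAS = {"OP1": 0.67, "OP2": 0.33}


@dataclass
class GridSpec:
    """Candidate hyperparameter lists for the exhaustive search."""

    thetas: tuple = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
    lambdas: tuple = tuple(np.round(np.arange(0.1, 0.91, 0.1), 1))
    kappas: tuple = (0.0, 0.5, 1.0, 2.0)
    bins: tuple = (5, 10, 20)
    bandwidths: tuple = (0.0, 0.5, 1.0, 2.0)
    prior_smoothing: float = 0.5
    include_sentinels: bool = True

    def validate(self) -> "GridSpec":
        for name in ("thetas", "lambdas", "kappas", "bins", "bandwidths"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"grid list {name!r} must be non-empty")
        if any(not 0 <= t <= 1 for t in self.thetas) or any(
            not 0 <= l <= 1 for l in self.lambdas
        ):
            raise ValueError("theta and lambda candidates must lie in [0, 1]")
        if any(T < 1 for T in self.bins) or any(s < 0 for s in self.bandwidths) or any(
            k < 0 for k in self.kappas
        ):
            raise ValueError("invalid kappa/T/sigma candidates")
        return self


@dataclass
class TaskOperatingPoint:
    """Chosen hyperparameters and tuning-set performance for one sub-model."""

    task: int
    mode: str
    theta: float
    lam: float
    kappa: float
    bins: int
    bandwidth: float
    objective: float
    sensitivity: float
    specificity: float
    deferral_rate: float


@dataclass
class OperatingPoint:
    """A named full operating point: one TaskOperatingPoint per sub-model."""

    name: str
    tasks: dict = field(default_factory=dict)  # task index -> TaskOperatingPoint
    cutoff: float = 0.5
    objective: float = float("nan")
    deferral_rate: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cutoff": self.cutoff,
            "objective": self.objective,
            "deferral_rate": self.deferral_rate,
            "tasks": {str(t): asdict(op) for t, op in self.tasks.items()},
        }


def sens_spec_binary(calls, truth):
    """(sensitivity, specificity) of binary calls; an empty class scores 1
    by convention, with a logged warning."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0:
        logger.warning("no positive cases: sensitivity defined as 1 by convention")
        sens = 1.0
    else:
        sens = float(np.sum(calls & truth)) / n_pos
    if n_neg == 0:
        logger.warning("no negative cases: specificity defined as 1 by convention")
        spec = 1.0
    else:
        spec = float(np.sum(~calls & ~truth)) / n_neg
    return sens, spec


def policy_objective(model: DeferralModel, z, h, y, lam_eval: float):
    """Weighted objective of the combined system for one sub-model.

    ``z`` are confidence scores, ``h``/``y`` reader opinion and truth
    already binarised for the model's task.  Adopted cases contribute the
    AI call ``z > theta``; deferred cases contribute the reader call.
    """
    z = np.asarray(z, float)
    if z.size == 0:
        raise ValueError("no tuning cases supplied")
    from .deferral import decide_task

    defer = np.asarray(decide_task(model, z))
    calls = np.where(defer, np.asarray(h, bool), z > model.theta)
    sens, spec = sens_spec_binary(calls, y)
    return lam_eval * sens + (1.0 - lam_eval) * spec


def _evaluate_point(calls, h, y, defer, lam):
    final = np.where(defer, np.asarray(h, bool), calls)
    sens, spec = sens_spec_binary(final, y)
    return lam * sens + (1.0 - lam) * spec, sens, spec, float(np.mean(defer))


def _tiebreak_key(row):
    # maximize objective; then prefer low deferral, small T, sigma, kappa,
    # theta nearest 0.5
    return (
        -row["objective"],
        row["deferral_rate"],
        row["bins"],
        row["bandwidth"],
        row["kappa"],
        abs(row["theta"] - 0.5),
    )


def tune_task(z, h, y, task: int, grid: GridSpec):
    """Exhaustive grid search for one sub-model on its binarised task.

    Returns ``(TaskOperatingPoint, report)`` where report is a DataFrame of
    every evaluated grid point.
    """
    grid.validate()
    z = np.asarray(z, float)
    h = np.asarray(h, int)
    y = np.asarray(y, int)
    if z.size == 0:
        raise ValueError("tuning set is empty")
    rows = []
    for T in grid.bins:
        for sigma in grid.bandwidths:
            for kappa in grid.kappas:
                cfg = DensityConfig(
                    bins=T, bandwidth=sigma, pseudocount=kappa,
                    prior_smoothing=grid.prior_smoothing,
                )
                table = fit_density_table(z, h, y, task, cfg)
                idx = np.minimum((z * T).astype(int), T - 1)
                joint = np.array(
                    [[table.density[a][b][idx] * table.prior[a, b] for b in (0, 1)]
                     for a in (0, 1)]
                )  # (a, b, n)
                for lam in grid.lambdas:
                    adv_pos = (1 - lam) * joint[0, 0] - lam * joint[0, 1]
                    adv_neg = -((1 - lam) * joint[1, 0] - lam * joint[1, 1])
                    for theta in grid.thetas:
                        pos = z > theta
                        adv = np.where(pos, adv_pos, adv_neg)
                        obj, sens, spec, rate = _evaluate_point(pos, h, y, adv >= 0, lam)
                        rows.append(
                            dict(task=task, mode="normal", theta=float(theta),
                                 lam=float(lam), kappa=float(kappa), bins=int(T),
                                 bandwidth=float(sigma), objective=obj,
                                 sensitivity=sens, specificity=spec,
                                 deferral_rate=rate)
                        )
    if grid.include_sentinels:
        never = np.zeros(z.size, dtype=bool)
        always = np.ones(z.size, dtype=bool)
        for lam in grid.lambdas:
            for theta in grid.thetas:
                obj, sens, spec, rate = _evaluate_point(z > theta, h, y, never, lam)
                rows.append(
                    dict(task=task, mode="never_defer", theta=float(theta),
                         lam=float(lam), kappa=0.0, bins=0, bandwidth=0.0,
                         objective=obj, sensitivity=sens, specificity=spec,
                         deferral_rate=rate)
                )
            obj, sens, spec, rate = _evaluate_point(never, h, y, always, lam)
            rows.append(
                dict(task=task, mode="always_defer", theta=0.5, lam=float(lam),
                     kappa=0.0, bins=0, bandwidth=0.0, objective=obj,
                     sensitivity=sens, specificity=spec, deferral_rate=rate)
            )
    report = pd.DataFrame(rows)
    best = min(rows, key=_tiebreak_key)
    return TaskOperatingPoint(**best), report


def _build_model(z, h, y, top: TaskOperatingPoint, prior_smoothing: float) -> DeferralModel:
    if top.mode != "normal":
        return DeferralModel(task=top.task, theta=top.theta, lam=top.lam, mode=top.mode)
    cfg = DensityConfig(
        bins=top.bins, bandwidth=top.bandwidth, pseudocount=top.kappa,
        prior_smoothing=prior_smoothing,
    )
    table = fit_density_table(z, h, y, top.task, cfg)
    return DeferralModel(task=top.task, table=table, theta=top.theta, lam=top.lam)


def tune_policy(cohort: pd.DataFrame, grid: GridSpec, name: str = "OP",
                cutoff: float = 0.5):
    """Tune all three sub-models on a tuning cohort and assemble the policy.

    Returns ``(OperatingPoint, CompositePolicy, report)``; the report
    concatenates the per-task grid reports.
    """
    if len(cohort) == 0:
        raise ValueError("tuning cohort is empty")
    truth = cohort["truth_stage"].to_numpy(int)
    reader = cohort["reader_stage"].to_numpy(int)
    models, tops, reports = {}, {}, []
    for task in (2, 3, 4):
        z = cohort[f"z{task}"].to_numpy(float)
        h_bin = (reader >= task).astype(int)
        y_bin = (truth >= task).astype(int)
        top, report = tune_task(z, h_bin, y_bin, task, grid)
        tops[task] = top
        reports.append(report)
        models[task] = _build_model(z, h_bin, y_bin, top, grid.prior_smoothing)
    policy = CompositePolicy(d24=models[2], d34=models[3], d4=models[4], cutoff=cutoff)
    op = OperatingPoint(
        name=name,
        tasks=tops,
        cutoff=cutoff,
        objective=float(np.mean([t.objective for t in tops.values()])),
        deferral_rate=float(np.mean([t.deferral_rate for t in tops.values()])),
    )
    logger.info("%s: per-task objectives %s", name,
                {TASK_NAMES[t]: round(tops[t].objective, 4) for t in tops})
    return op, policy, pd.concat(reports, ignore_index=True)


def tune_operating_points(cohort: pd.DataFrame, grid: GridSpec | None = None,
                          presets: dict | None = None, cutoff: float = 0.5):
    """Produce the named operating points by pinning lambda to presets.

    Default presets: OP1 (lambda 0.67, sensitivity-leaning) and OP2
    (lambda 0.33, specificity-leaning).  Returns ``{name: (OperatingPoint,
    CompositePolicy, report)}``.
    """
    grid = (grid or GridSpec()).validate()
    presets = presets or DEFAULT_OP_LAMBDAS
    out = {}
    for name, lam in presets.items():
        sub = GridSpec(
            thetas=grid.thetas, lambdas=(lam,), kappas=grid.kappas,
            bins=grid.bins, bandwidths=grid.bandwidths,
            prior_smoothing=grid.prior_smoothing,
            include_sentinels=grid.include_sentinels,
        )
        out[name] = tune_policy(cohort, sub, name=name, cutoff=cutoff)
    return out
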