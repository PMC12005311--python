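"""Advantage-function deferral rule and the composite ordinal policy.

Per nested task the policy compares, for a case with confidence score z, the
expected contribution to the weighted objective

    lambda * Sensitivity + (1 - lambda) * Specificity

of adopting the AI call versus deferring to the reader.  The difference is
the advantage function

    Advantage(z) =  (1-lambda) p(z, h=0 | y=0) - lambda p(z, h=0 | y=1)   if z > theta
                 = -[(1-lambda) p(z, h=1 | y=0) - lambda p(z, h=1 | y=1)] if z <= theta

where theta is the threshold that turns the score into a positive/negative
AI call.  The case is deferred iff Advantage(z) >= 0 (boundary included).

The five-class system composes three such sub-models, D2-4, D3-4 and D4.
Routing depends on the decoded AI stage y_hat: S0/S1 consult D2-4 on z2
(there is no deferral gate for the S0-vs-S1-4 task); S2 consults D2-4 and
D3-4; S3 consults D3-4 and D4; S4 consults D4 only.  On two-model routes the
AI prediction is adopted only when both sub-models agree to adopt --
otherwise the case goes to the reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import ConditionalDensityTable, joint_density
from .ordinal import decode_matrix, decode_vector

__all__ = [
    "DeferralModel",
    "CompositePolicy",
    "ADOPT",
    "DEFER",
    "advantage",
    "decide_task",
    "decide_composite",
    "apply_policy",
]

ADOPT = "adopt_ai"
DEFER = "defer"


@dataclass
class DeferralModel:
    """One sub-task decision model: densities + (theta, lambda) + sentinel mode.

    ``mode`` is ``"normal"`` for the advantage rule, or a sentinel
    ``"never_defer"`` / ``"always_defer"`` that bypasses it (used as
    degenerate candidates in the hyperparameter search).
    """

    task: int
    table: ConditionalDensityTable | None = None
    theta: float = 0.5
    lam: float = 0.5
    mode: str = "normal"

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.mode not in ("normal", "never_defer", "always_defer"):
            raise ValueError(f"unknown sentinel mode {self.mode!r}")

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "theta": self.theta,
            "lambda": self.lam,
            "mode": self.mode,
            "table": None if self.table is None else json.loads(self.table.to_json()),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DeferralModel":
        table = data.get("table")
        return cls(
            task=data["task"],
            table=None if table is None else ConditionalDensityTable.from_json(json.dumps(table)),
            theta=data["theta"],
            lam=data["lambda"],
            mode=data.get("mode", "normal"),
        )


def advantage(model: DeferralModel, z):
    """Advantage of deferring a case with confidence score ``z``.

    Scalar or array ``z``.  Requires fitted densities in normal mode.
    """
    if model.table is None or not model.table.fitted:
        raise RuntimeError("deferral model has no fitted densities")
    lam = model.lam
    pos_branch = (1.0 - lam) * joint_density(model.table, z, 0, 0) - lam * joint_density(
        model.table, z, 0, 1
    )
    neg_branch = -(
        (1.0 - lam) * joint_density(model.table, z, 1, 0)
        - lam * joint_density(model.table, z, 1, 1)
    )
    out = np.where(np.asarray(z, float) > model.theta, pos_branch, neg_branch)
    return float(out) if np.isscalar(z) else out


def decide_task(model: DeferralModel, z):
    """Adopt-vs-defer decision for one sub-task: defer iff Advantage(z) >= 0.

    Sentinel modes override the rule.  Scalar z -> string decision; array z
    -> boolean array (True = defer).
    """
    if model.mode == "never_defer":
        defer = np.zeros(np.shape(z), dtype=bool)
    elif model.mode == "always_defer":
        defer = np.ones(np.shape(z), dtype=bool)
    else:
        defer = np.asarray(advantage(model, z)) >= 0.0
    if np.isscalar(z):
        return DEFER if bool(defer) else ADOPT
    return defer


def _routed_tasks(y_hat: int) -> list[int]:
    if y_hat <= 1:
        return [2]
    if y_hat == 2:
        return [2, 3]
    if y_hat == 3:
        return [3, 4]
    return [4]


@dataclass
class CompositePolicy:
    """The full ordinal deferral policy: sub-models D2-4, D3-4, D4."""

    d24: DeferralModel
    d34: DeferralModel
    d4: DeferralModel
    cutoff: float = 0.5

    def __post_init__(self):
        if (self.d24.task, self.d34.task, self.d4.task) != (2, 3, 4):
            raise ValueError("composite policy requires sub-models for tasks 2, 3 and 4")

    def model_for(self, task: int) -> DeferralModel:
        return {2: self.d24, 3: self.d34, 4: self.d4}[task]

    def to_json(self) -> str:
        return json.dumps(
            {
                "cutoff": self.cutoff,
                "models": {str(t): self.model_for(t).to_dict() for t in (2, 3, 4)},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CompositePolicy":
        data = json.loads(text)
        models = {int(k): DeferralModel.from_dict(v) for k, v in data["models"].items()}
        return cls(d24=models[2], d34=models[3], d4=models[4], cutoff=data.get("cutoff", 0.5))


def decide_composite(policy: CompositePolicy, v):
    """Route one ordinal vector through the composite policy.

    Returns ``(decision, record)`` where record lists, per consulted
    sub-model, the task, the score it saw, its advantage (None for
    sentinels) and its local decision.  Two-model routes adopt only on
    unanimous adoption.
    """
    y_hat = decode_vector(v, policy.cutoff)
    record = {"y_hat": y_hat, "consulted": []}
    adopt_all = True
    for task in _routed_tasks(y_hat):
        model = policy.model_for(task)
        z = float(np.asarray(v, float)[task - 1])
        adv = None if model.mode != "normal" else advantage(model, z)
        local = decide_task(model, z)
        record["consulted"].append(
            {"task": task, "z": z, "advantage": adv, "decision": local}
        )
        adopt_all &= local == ADOPT
    return (ADOPT if adopt_all else DEFER), record


class MissingReaderError(ValueError):
    """A deferred case has no reader stage to fall back on."""


def apply_policy(policy: CompositePolicy, cohort: pd.DataFrame) -> pd.DataFrame:
    """Apply the composite policy to a cohort; return the decision log.

    The log has one row per case: decoded AI stage ``y_hat``, the consulted
    sub-models with their advantages, the adopt/defer decision and the final
    stage (AI stage when adopted, reader stage when deferred).  The deferral
    rate is attached as ``log.attrs["deferral_rate"]``.
    """
    Z = cohort[["z1", "z2", "z3", "z4"]].to_numpy(float)
    n = len(cohort)
    y_hat = decode_matrix(Z, policy.cutoff) if n else np.array([], dtype=int)

    # vectorised per-task defer decisions, then per-case routing
    defer_by_task = {
        t: np.asarray(decide_task(policy.model_for(t), Z[:, t - 1])) for t in (2, 3, 4)
    }
    rows = []
    reader = cohort["reader_stage"].to_numpy() if "reader_stage" in cohort else None
    for i in range(n):
        tasks = _routed_tasks(int(y_hat[i]))
        defer = any(bool(defer_by_task[t][i]) for t in tasks)
        advs = []
        for t in tasks:
            m = policy.model_for(t)
            advs.append(
                float(advantage(m, float(Z[i, t - 1]))) if m.mode == "normal" else np.nan
            )
        if defer:
            if reader is None or not np.isfinite(float(reader[i])):
                raise MissingReaderError(
                    f"case {cohort['case_id'].iloc[i]} was deferred but has no reader stage"
                )
            final = int(reader[i])
        else:
            final = int(y_hat[i])
        rows.append(
            {
                "case_id": cohort["case_id"].iloc[i],
                "y_hat": int(y_hat[i]),
                "routed": "+".join(f"D{t}" for t in tasks),
                "advantages": ";".join(f"{a:.6g}" for a in advs),
                "decision": DEFER if defer else ADOPT,
                "final_stage": final,
            }
        )
    log = pd.DataFrame(
        rows,
        columns=["case_id", "y_hat", "routed", "advantages", "decision", "final_stage"],
    )
    log.attrs["deferral_rate"] = float((log["decision"] == DEFER).mean()) if n else 0.0
    return log
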