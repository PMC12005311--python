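"""Ordinal stage encoding shared by every other module.

Liver fibrosis is staged on the Scheuer scale S0 (no fibrosis) through S4
(cirrhosis).  The five-class staging problem is decomposed into four nested
binary tasks -- S0 vs S1-4, S0-1 vs S2-4, S0-2 vs S3-4 and S0-3 vs S4 -- and
a stage ``s`` is represented as a 4-bit ordinal vector whose bit ``k`` is 1
iff ``s >= k``.  A probabilistic classifier emits one confidence score per
task; the predicted stage is decoded as the highest task whose score strictly
exceeds a cut-off (0.5 by default).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "N_STAGES",
    "N_TASKS",
    "TASK_NAMES",
    "encode_stage",
    "decode_vector",
    "decode_matrix",
    "task_truth",
    "stage_label",
    "parse_stage",
    "validate_stage",
]

N_STAGES = 5
N_TASKS = N_STAGES - 1

#: Endpoint names of the four nested binary tasks, keyed by task index.
TASK_NAMES = {1: "S1-4", 2: "S2-4", 3: "S3-4", 4: "S4"}


class InvalidStageError(ValueError):
    """Raised for a stage outside {0, ..., 4}."""


def validate_stage(stage: int, n_stages: int = N_STAGES) -> int:
    """Return ``stage`` as an int after range-checking it."""
    s = int(stage)
    if s != stage or not 0 <= s < n_stages:
        raise InvalidStageError(
            f"stage must be an integer in [0, {n_stages - 1}], got {stage!r}"
        )
    return s


def encode_stage(stage: int, n_stages: int = N_STAGES) -> np.ndarray:
    """Encode a stage as its cumulative ("thermometer") ordinal vector.

    Component ``k`` (1-based) is 1 if ``stage >= k`` else 0, so S0 maps to
    (0,0,0,0), S2 to (1,1,0,0) and S4 to (1,1,1,1).  The output is
    component-wise non-increasing by construction.
    """
    s = validate_stage(stage, n_stages)
    return (np.arange(1, n_stages) <= s).astype(float)


def decode_vector(v, cutoff: float = 0.5) -> int:
    """Decode an ordinal probability vector to a stage.

    Returns the largest task index ``k`` with ``v[k-1] > cutoff`` (strictly
    exceeding), or stage 0 when no component exceeds the cut-off.  The rule is
    applied literally even to non-monotone vectors: components below the
    highest exceeding one are ignored.
    """
    v = np.asarray(v, dtype=float)
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    if np.any(v < 0.0) or np.any(v > 1.0):
        raise ValueError("ordinal vector components must lie in [0, 1]")
    above = np.nonzero(v > cutoff)[0]
    return int(above[-1]) + 1 if above.size else 0


def decode_matrix(V, cutoff: float = 0.5) -> np.ndarray:
    """Vectorised :func:`decode_vector` over the rows of an (n, 4) array."""
    V = np.asarray(V, dtype=float)
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    if np.any(V < 0.0) or np.any(V > 1.0):
        raise ValueError("ordinal vector components must lie in [0, 1]")
    exceed = V > cutoff
    # highest exceeding bit; 0 when none exceeds
    rev = exceed[:, ::-1]
    first = np.argmax(rev, axis=1)
    any_hit = exceed.any(axis=1)
    return np.where(any_hit, V.shape[1] - first, 0).astype(int)


def task_truth(stage: int, task: int) -> int:
    """Binarise a stage for one nested task: 1 iff ``stage >= task``."""
    s = validate_stage(stage)
    if task not in TASK_NAMES:
        raise ValueError(f"task index must be in {sorted(TASK_NAMES)}, got {task}")
    return int(s >= task)


def stage_label(stage: int) -> str:
    """Render a stage as the clinical token ``S0`` .. ``S4``."""
    return f"S{validate_stage(stage)}"


def parse_stage(token) -> int:
    """Parse ``S3`` / ``3`` / 3 back to the integer stage."""
    if isinstance(token, str):
        t = token.strip().upper()
        if t.startswith("S"):
            t = t[1:]
        try:
            return validate_stage(int(t))
        except (ValueError, TypeError):
            raise InvalidStageError(f"cannot parse stage token {token!r}") from None
    return validate_stage(token)
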