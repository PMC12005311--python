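"""Diagnostic-accuracy statistics for ordinal staging systems.

Covers the statistics conventionally reported for noninvasive fibrosis
tests: sensitivity/specificity with bootstrap confidence intervals,
empirical AUC with the DeLong paired comparison, the Obuchowski index (the
multinomial ROC summary for an ordinal gold standard: the probability that
a measure correctly orders two cases drawn from different truth categories,
ties counted one half) with jackknife CIs, difference and equivalence
testing, matched-operating-point contrasts ("higher specificity at
non-inferior sensitivity"), an audit of deferral decisions, and the serum
marker indices APRI and FIB-4.

Internal values are kept at full precision; half-up rounding to the printed
precision is applied only when rendering reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "MetricReport",
    "round_half_up",
    "render_rate",
    "sens_spec",
    "empirical_auc",
    "delong_compare",
    "obuchowski_index",
    "obuchowski_compare",
    "matched_op_comparison",
    "deferral_audit",
    "apri",
    "fib4",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    """One reported statistic with its CI and provenance."""

    name: str
    estimate: float
    ci: tuple | None = None
    ci_level: float = 0.95
    ci_method: str = ""
    n: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "estimate": self.estimate,
            "ci": None if self.ci is None else list(self.ci),
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
            "n": self.n,
            **self.extra,
        }


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (0.785 -> 0.79 at 2 decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def render_rate(numerator: int, denominator: int, decimals: int = 2) -> str:
    """Render a count-derived rate the way report tables print it."""
    val = round_half_up(numerator / denominator, decimals)
    return f"{val:.{decimals}f}"


# ---------------------------------------------------------------------------
# Sensitivity / specificity
# ---------------------------------------------------------------------------

def _sens_spec_point(calls, truth):
    tp = int(np.sum(calls & truth))
    fn = int(np.sum(~calls & truth))
    tn = int(np.sum(~calls & ~truth))
    fp = int(np.sum(calls & ~truth))
    sens = tp / (tp + fn) if tp + fn else 1.0
    spec = tn / (tn + fp) if tn + fp else 1.0
    return sens, spec, (tp, fp, tn, fn)


def sens_spec(calls, truth, ci_method: str = "bootstrap", B: int = 2000,
              seed: int = 0, level: float = 0.95):
    """Sensitivity and specificity with case-bootstrap percentile CIs.

    Returns ``(sens_report, spec_report)``.  A degenerate class (no
    positives / no negatives) yields an estimate of 1 by convention with a
    logged warning.  CIs are clipped to [0, 1].
    """
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    n = calls.size
    if n < 1:
        raise ValueError("need at least one case")
    sens, spec, (tp, fp, tn, fn) = _sens_spec_point(calls, truth)
    if tp + fn == 0:
        logger.warning("no positive cases: sensitivity set to 1 by convention")
    if tn + fp == 0:
        logger.warning("no negative cases: specificity set to 1 by convention")

    ci_s = ci_p = None
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(B, n))
        bs = np.empty(B)
        bp = np.empty(B)
        c, t = calls, truth
        for b in range(B):
            cb, tb = c[idx[b]], t[idx[b]]
            bs[b], bp[b], _ = _sens_spec_point(cb, tb)
        alpha = (1 - level) / 2
        ci_s = tuple(np.clip(np.quantile(bs, [alpha, 1 - alpha]), 0, 1))
        ci_p = tuple(np.clip(np.quantile(bp, [alpha, 1 - alpha]), 0, 1))
    elif ci_method is not None and ci_method != "none":
        raise ValueError(f"unknown ci_method {ci_method!r}")

    meth = f"bootstrap percentile (B={B})" if ci_method == "bootstrap" else "none"
    return (
        MetricReport("sensitivity", sens, ci_s, level, meth, n,
                     {"numerator": tp, "denominator": tp + fn}),
        MetricReport("specificity", spec, ci_p, level, meth, n,
                     {"numerator": tn, "denominator": tn + fp}),
    )


# ---------------------------------------------------------------------------
# AUC and the DeLong comparison
# ---------------------------------------------------------------------------

class InsufficientDataError(ValueError):
    """Both truth classes / at least two categories are required."""


def empirical_auc(scores, truth) -> float:
    """Empirical AUC (Mann-Whitney statistic, ties counted one half)."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, dtype=bool)
    m, n = int(truth.sum()), int((~truth).sum())
    if m == 0 or n == 0:
        raise InsufficientDataError("AUC needs both positive and negative cases")
    ranks = rankdata(scores)
    return float((ranks[truth].sum() - m * (m + 1) / 2) / (m * n))


def _delong_components(scores, truth):
    """Per-case structural components (V10 for positives, V01 for negatives)."""
    pos = scores[truth]
    neg = scores[~truth]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_compare(scores_a, scores_b, truth):
    """DeLong's paired comparison of two correlated empirical AUCs.

    Returns ``(z, p)`` with a two-sided normal p-value.  Identical score
    vectors give z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise InsufficientDataError("DeLong comparison needs both truth classes")
    auc_a, v10_a, v01_a = _delong_components(scores_a, truth)
    auc_b, v10_b, v01_b = _delong_components(scores_b, truth)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var)
    p = 1.0 if var <= 0 and diff == 0 else float(2 * norm.sf(abs(z)))
    return float(z), min(p, 1.0)


# ---------------------------------------------------------------------------
# Obuchowski index
# ---------------------------------------------------------------------------

def _obuchowski_point(scores, truth, weighting: str) -> float:
    cats = np.unique(truth)
    if cats.size < 2:
        raise InsufficientDataError("Obuchowski index needs >= 2 truth categories")
    num = den = 0.0
    for i_pos in range(cats.size):
        for j_pos in range(i_pos + 1, cats.size):
            lo, hi = cats[i_pos], cats[j_pos]
            mask = (truth == lo) | (truth == hi)
            auc = empirical_auc(scores[mask], truth[mask] == hi)
            w = (np.sum(truth == lo) * np.sum(truth == hi)
                 if weighting == "prevalence" else 1.0)
            num += w * auc
            den += w
    return num / den


def obuchowski_index(scores, truth, weighting: str = "prevalence",
                     ci: str | None = "jackknife", level: float = 0.95) -> MetricReport:
    """Obuchowski index of an ordinal measure against ordinal truth.

    A weighted mean of all pairwise category AUCs (ties one half); weights
    proportional to n_i * n_j (``weighting="prevalence"``) or equal
    (``"equal"``).  For binary truth it reduces exactly to the AUC.  CI by
    case-jackknife (normal approximation).
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth)
    if weighting not in ("prevalence", "equal"):
        raise ValueError(f"unknown weighting {weighting!r}")
    est = _obuchowski_point(scores, truth, weighting)
    n = scores.size
    bounds = None
    se = None
    if ci == "jackknife":
        loo = _jackknife_values(scores, truth, weighting)
        se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
        zq = norm.ppf(1 - (1 - level) / 2)
        bounds = (max(0.0, est - zq * se), min(1.0, est + zq * se))
    return MetricReport(
        "obuchowski_index", est, bounds, level,
        f"jackknife normal ({weighting}-weighted)" if ci else "none", n,
        {"weighting": weighting, "se": se},
    )


def _jackknife_values(scores, truth, weighting):
    n = scores.size
    out = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        out[i] = _obuchowski_point(scores[mask], truth[mask], weighting)
        mask[i] = True
    return out


def obuchowski_compare(scores_a, scores_b, truth, mode: str = "difference",
                       margin: float | None = None, weighting: str = "prevalence",
                       method: str = "jackknife", B: int = 2000, seed: int = 0) -> dict:
    """Compare two paired Obuchowski indices on the same cases.

    ``mode="difference"``: two-sided test of equal indices, either a paired
    z on the jackknife variance of the difference (default) or a label-swap
    permutation test.  ``mode="equivalence"``: two one-sided tests (TOST)
    against a user-supplied ``margin``; the reported p is the larger of the
    two one-sided p-values.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    truth = np.asarray(truth)
    ia = _obuchowski_point(scores_a, truth, weighting)
    ib = _obuchowski_point(scores_b, truth, weighting)
    diff = ia - ib
    n = truth.size

    loo_a = _jackknife_values(scores_a, truth, weighting)
    loo_b = _jackknife_values(scores_b, truth, weighting)
    d = loo_a - loo_b
    se = float(np.sqrt((n - 1) / n * np.sum((d - d.mean()) ** 2)))

    result = {"index_a": ia, "index_b": ib, "difference": diff,
              "se": se, "mode": mode, "method": method, "weighting": weighting}
    if mode == "difference":
        if method == "jackknife":
            z = diff / se if se > 0 else (0.0 if diff == 0 else np.sign(diff) * np.inf)
            p = 1.0 if se == 0 and diff == 0 else float(2 * norm.sf(abs(z)))
            result.update(statistic=float(z), p=min(p, 1.0))
        elif method == "permutation":
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(B):
                swap = rng.random(n) < 0.5
                sa = np.where(swap, scores_b, scores_a)
                sb = np.where(swap, scores_a, scores_b)
                if abs(_obuchowski_point(sa, truth, weighting)
                       - _obuchowski_point(sb, truth, weighting)) >= abs(diff) - 1e-15:
                    count += 1
            result.update(statistic=diff, p=(count + 1) / (B + 1))
        else:
            raise ValueError(f"unknown method {method!r}")
    elif mode == "equivalence":
        if margin is None or margin <= 0:
            raise ValueError("equivalence testing requires a positive margin")
        if se == 0:
            p_lo = 0.0 if diff > -margin else 1.0
            p_hi = 0.0 if diff < margin else 1.0
        else:
            p_lo = float(norm.sf((diff + margin) / se))
            p_hi = float(norm.sf((margin - diff) / se))
        result.update(margin=margin, p_lower=p_lo, p_upper=p_hi, p=max(p_lo, p_hi),
                      equivalent=max(p_lo, p_hi) < 0.05)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return result


# ---------------------------------------------------------------------------
# Matched operating points
# ---------------------------------------------------------------------------

def matched_op_comparison(ref_calls, cand_scores, truth, fix: str = "sensitivity") -> dict:
    """Best candidate operating point non-inferior to a reference.

    Fixes one metric (sensitivity or specificity): among all thresholds of
    the candidate score whose fixed metric is >= the reference's, return the
    one maximizing the free metric and the delta versus the reference.  When
    no threshold attains non-inferiority the result is flagged infeasible.
    """
    if fix not in ("sensitivity", "specificity"):
        raise ValueError("fix must be 'sensitivity' or 'specificity'")
    ref_calls = np.asarray(ref_calls, dtype=bool)
    cand_scores = np.asarray(cand_scores, float)
    truth = np.asarray(truth, dtype=bool)
    ref_sens, ref_spec, _ = _sens_spec_point(ref_calls, truth)

    thresholds = np.concatenate([[-np.inf], np.unique(cand_scores)])
    best = None
    for thr in thresholds:
        calls = cand_scores > thr
        sens, spec, _ = _sens_spec_point(calls, truth)
        fixed, free = (sens, spec) if fix == "sensitivity" else (spec, sens)
        ref_fixed = ref_sens if fix == "sensitivity" else ref_spec
        if fixed >= ref_fixed and (best is None or free > best["free"]):
            best = {"threshold": float(thr), "sensitivity": sens,
                    "specificity": spec, "free": free}
    out = {"fix": fix, "reference_sensitivity": ref_sens,
           "reference_specificity": ref_spec, "feasible": best is not None}
    if best is not None:
        ref_free = ref_spec if fix == "sensitivity" else ref_sens
        best.pop("free")
        out.update(best)
        free_name = "specificity" if fix == "sensitivity" else "sensitivity"
        out["delta"] = out[free_name] - ref_free
    return out


# ---------------------------------------------------------------------------
# Deferral audit
# ---------------------------------------------------------------------------

def deferral_audit(log: pd.DataFrame, truth) -> dict:
    """Audit a decision log against the truth stages.

    Counts deferred cases and those with a positive impact -- a deferred
    final (reader) stage equal to the truth, or ordinally strictly closer
    to it than the AI stage (equal distance does not count).  The adoption
    percentage 100*(n - n_deferred)/n is rounded half-up to one decimal.
    """
    truth = np.asarray(truth, int)
    if len(log) != truth.size:
        raise ValueError("decision log and truth stages have different lengths")
    n = len(log)
    deferred = log["decision"].to_numpy() == "defer"
    final = log["final_stage"].to_numpy(int)
    y_hat = log["y_hat"].to_numpy(int)
    positive = deferred & (
        (final == truth) | (np.abs(final - truth) < np.abs(y_hat - truth))
    )
    n_def = int(deferred.sum())
    return {
        "n": n,
        "n_deferred": n_def,
        "n_positive_impact": int(positive.sum()),
        "adoption_pct": round_half_up(100.0 * (n - n_def) / n, 1) if n else 100.0,
    }


# ---------------------------------------------------------------------------
# Serum marker indices
# ---------------------------------------------------------------------------

def apri(ast, plt):
    """Aspartate transaminase-to-platelet ratio index: AST(U/L) / PLT(10^9/L)."""
    ast = np.asarray(ast, float)
    plt = np.asarray(plt, float)
    if np.any(plt <= 0):
        raise ValueError("platelet count must be > 0")
    if np.any(ast < 0):
        raise ValueError("AST must be >= 0")
    out = ast / plt
    return float(out) if out.ndim == 0 else out


def fib4(age, ast, plt, alt):
    """FIB-4 index: Age(years) * AST(U/L) / (PLT(10^9/L) * sqrt(ALT(U/L)))."""
    age = np.asarray(age, float)
    ast = np.asarray(ast, float)
    plt = np.asarray(plt, float)
    alt = np.asarray(alt, float)
    if np.any(plt <= 0) or np.any(alt <= 0):
        raise ValueError("platelet count and ALT must be > 0")
    out = age * ast / (plt * np.sqrt(alt))
    return float(out) if out.ndim == 0 else out
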