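"""Cohort-level evaluation: summary tables, Wilcoxon comparison, ablation report.

Evaluates paired ground-truth/prediction cohorts into per-case metric rows with
mean ± sample-std summaries, and compares two segmentation variants case by
case with the two-sided Wilcoxon signed-rank test. The ablation report scores
the same cohort twice — raw predictions versus repaired predictions — which is
the standard way to isolate the contribution of the post-processing step.

Wilcoxon convention: zero differences are dropped; absolute differences are
ranked with mid-ranks for ties; the statistic is W = min(W+, W-). The p-value
is exact (distribution of W over all 2^n sign assignments of the observed
ranks) for n <= 12 after zero removal, and otherwise uses the normal
approximation with tie correction and a 0.5 continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import CohortTable, FillingParams, MaskVolume
from .metrics import evaluate_case
from .postprocess import postprocess_pipeline

__all__ = ["evaluate_cohort", "wilcoxon_signed_rank", "compare_models", "ablation_report", "AblationReport"]


def evaluate_cohort(
    pairs: list[tuple[MaskVolume, MaskVolume]],
    case_ids: list[str] | None = None,
) -> CohortTable:
    """Evaluate a list of (ground_truth, prediction) pairs into a CohortTable.

    Cases with undefined surface distances (an empty mask) keep NaN in their
    row and are excluded from the asd/hd summary; the exclusion count is kept
    on the table.
    """
    if not pairs:
        raise ValueError("cohort must contain at least one pair")
    if case_ids is None:
        case_ids = [f"case_{i:03d}" for i in range(len(pairs))]
    if len(case_ids) != len(pairs):
        raise ValueError("case_ids length must match pairs")
    rows = [evaluate_case(gt, pred, case_id=cid) for (gt, pred), cid in zip(pairs, case_ids)]
    return CohortTable(rows=rows)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = min(W+, W-)
    pvalue: float
    n: int  # pairs remaining after zero-difference removal
    method: str  # "exact" or "normal"
    all_zero: bool = False


def _exact_pvalue(ranks: np.ndarray, w_obs: float) -> float:
    """P(min(T, S-T) <= w_obs) over all 2^n equiprobable sign assignments.

    Uses a dynamic-programming convolution over doubled ranks (mid-ranks are
    half-integers, so doubling keeps sums integral).
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    t = np.arange(total + 1)
    favourable = counts[np.minimum(t, total - t) <= np.rint(2 * w_obs)].sum()
    return float(min(1.0, favourable / 2 ** len(ranks)))


def wilcoxon_signed_rank(
    scores_a: np.ndarray, scores_b: np.ndarray, exact_max_n: int = 12
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test of scores_a vs scores_b.

    Returns W = min(W+, W-) and the two-sided p-value (exact for up to
    ``exact_max_n`` nonzero differences, normal approximation with tie and
    continuity corrections beyond). All-zero differences give p = 1, flagged.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors must be 1D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired cases")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n=0, method="degenerate", all_zero=True)
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    n = len(d)
    if n <= exact_max_n:
        return WilcoxonResult(statistic=w, pvalue=_exact_pvalue(ranks, w), n=n, method="exact")
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups of |d|
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= ((tie_counts**3 - tie_counts) / 48.0).sum()
    if var <= 0:
        return WilcoxonResult(statistic=w, pvalue=1.0, n=n, method="normal")
    z = (w - mean + 0.5) / np.sqrt(var)  # continuity correction toward the mean
    p = float(min(1.0, 2.0 * stats.norm.cdf(z)))
    return WilcoxonResult(statistic=w, pvalue=p, n=n, method="normal")


def compare_models(scores_a, scores_b) -> tuple[float, float]:
    """(W statistic, two-sided p-value) of the paired Wilcoxon signed-rank test."""
    res = wilcoxon_signed_rank(scores_a, scores_b)
    return res.statistic, res.pvalue


@dataclass(frozen=True)
class AblationReport:
    """Raw-versus-repaired evaluation of one cohort."""

    raw: CohortTable
    repaired: CohortTable
    comparisons: dict  # metric -> WilcoxonResult, paired on commonly defined cases


def ablation_report(cohort, params: FillingParams = FillingParams(), n_keep: int = 2,
                    connectivity: int = 26) -> AblationReport:
    """Evaluate a phantom cohort before and after the repair pipeline.

    ``cohort`` is a list of PhantomCase (or any objects with gt/pred/case_id).
    Each metric is compared with the two-sided Wilcoxon signed-rank test over
    cases where both arms define the metric. Case order does not affect the
    summaries or p-values.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    gts = [c.gt for c in cohort]
    raws = [c.pred for c in cohort]
    ids = [c.case_id for c in cohort]
    fixed = [postprocess_pipeline(p, params, connectivity=connectivity, n_keep=n_keep) for p in raws]
    raw_table = evaluate_cohort(list(zip(gts, raws)), ids)
    fixed_table = evaluate_cohort(list(zip(gts, fixed)), ids)
    comparisons = {}
    for metric in ("dice", "iou", "osr", "usr", "asd", "hd"):
        va = raw_table.metric_values(metric, drop_nan=False)
        vb = fixed_table.metric_values(metric, drop_nan=False)
        ok = ~(np.isnan(va) | np.isnan(vb))
        if ok.sum() >= 2:
            comparisons[metric] = wilcoxon_signed_rank(va[ok], vb[ok])
    return AblationReport(raw=raw_table, repaired=fixed_table, comparisons=comparisons)
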