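"""Diagnostic-accuracy indices for a single 2x2 confusion table.

Point estimates and two-sided confidence intervals for sensitivity,
specificity, PPV, detection rate per 1000 screened, the positive and
negative likelihood ratios, and the trapezoidal single-test AUC
(sens + spec) / 2 — the area under the ROC polygon through (0,0),
(1 - spec, sens), (1,1), the standard convention for a binary test.

Proportion intervals default to Wilson (Clopper-Pearson optional).
Likelihood-ratio intervals use the log method of Simel:
se(ln LR+) = sqrt((1 - sens)/tp + spec/fp), and analogously for LR-.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .cohort import ConfusionTable

__all__ = [
    "Interval",
    "AccuracyResult",
    "proportion_ci",
    "accuracy_summary",
    "lr_ci",
    "round_half_up",
]

_Z = {0.95: 1.959963984540054}


def _zcrit(level: float) -> float:
    if level in _Z:
        return _Z[level]
    from scipy.stats import norm

    return float(norm.ppf(0.5 + level / 2.0))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed report conventions."""
    if not math.isfinite(x):
        return x
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class Interval:
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval lower bound exceeds upper bound")

    def __contains__(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wilson"
) -> Interval:
    """Two-sided CI for a binomial proportion k/n (Wilson or Clopper-Pearson)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    sm_method = {"wilson": "wilson", "clopper_pearson": "beta"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method=sm_method)
    lo = 0.0 if k == 0 else max(float(lo), 0.0)
    hi = 1.0 if k == n else min(float(hi), 1.0)
    return Interval(lo, hi, level)


@dataclass(frozen=True)
class AccuracyResult:
    """All indices for one strategy on one cohort, with intervals."""

    sensitivity: float
    specificity: float
    ppv: float
    detection_rate: float  # true-positive cases per 1000 tests
    lr_pos: float
    lr_neg: float
    auc: float
    sensitivity_ci: Interval
    specificity_ci: Interval
    ppv_ci: Interval
    detection_rate_ci: Interval
    lr_pos_ci: Interval
    lr_neg_ci: Interval
    auc_ci: Interval
    level: float = 0.95
    lr_pos_infinite: bool = False
    continuity_corrected: bool = False


def lr_ci(ct: ConfusionTable, level: float = 0.95) -> tuple[Interval, Interval]:
    """Log-method intervals for (LR+, LR-).

    Zero cells get a 0.5 continuity correction applied to all four cells
    (the returned intervals are then based on the corrected table).
    """
    tp, fp, fn, tn = ct.tp, ct.fp, ct.fn, ct.tn
    if min(tp, fp, fn, tn) == 0:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    z = _zcrit(level)
    lr_pos = sens / (1.0 - spec)
    lr_neg = (1.0 - sens) / spec
    se_pos = math.sqrt((1.0 - sens) / tp + spec / fp)
    se_neg = math.sqrt(sens / fn + (1.0 - spec) / tn)
    pos = Interval(
        math.exp(math.log(lr_pos) - z * se_pos),
        math.exp(math.log(lr_pos) + z * se_pos),
        level,
    )
    neg = Interval(
        math.exp(math.log(lr_neg) - z * se_neg),
        math.exp(math.log(lr_neg) + z * se_neg),
        level,
    )
    return pos, neg


def accuracy_summary(
    ct: ConfusionTable, level: float = 0.95, ci_method: str = "wilson"
) -> AccuracyResult:
    """Compute every accuracy index of the report from one 2x2 table."""
    if ct.cases == 0:
        raise ValueError("no cases: sensitivity undefined")
    if ct.non_cases == 0:
        raise ValueError("no non-cases: specificity undefined")
    if ct.positives == 0:
        raise ValueError("no positives: PPV undefined")

    sens = ct.tp / ct.cases
    spec = ct.tn / ct.non_cases
    ppv = ct.tp / ct.positives
    det = 1000.0 * ct.tp / ct.total
    auc = (sens + spec) / 2.0

    lr_pos_inf = (1.0 - spec) == 0.0
    lr_pos = math.inf if lr_pos_inf else sens / (1.0 - spec)
    lr_neg = (1.0 - sens) / spec

    sens_ci = proportion_ci(ct.tp, ct.cases, level, ci_method)
    spec_ci = proportion_ci(ct.tn, ct.non_cases, level, ci_method)
    ppv_ci = proportion_ci(ct.tp, ct.positives, level, ci_method)
    det_raw = proportion_ci(ct.tp, ct.total, level, ci_method)
    det_ci = Interval(det_raw.lower * 1000.0, det_raw.upper * 1000.0, level)
    # AUC CI by propagating the two independent proportion intervals.
    auc_ci = Interval(
        (sens_ci.lower + spec_ci.lower) / 2.0,
        (sens_ci.upper + spec_ci.upper) / 2.0,
        level,
    )
    corrected = min(ct.tp, ct.fp, ct.fn, ct.tn) == 0
    if lr_pos_inf:
        lr_pos_ci = Interval(0.0, math.inf, level)
        _, lr_neg_ci = lr_ci(ct, level)
    else:
        lr_pos_ci, lr_neg_ci = lr_ci(ct, level)

    return AccuracyResult(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        detection_rate=det,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        auc=auc,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        ppv_ci=ppv_ci,
        detection_rate_ci=det_ci,
        lr_pos_ci=lr_pos_ci,
        lr_neg_ci=lr_neg_ci,
        auc_ci=auc_ci,
        level=level,
        lr_pos_infinite=lr_pos_inf,
        continuity_corrected=corrected,
    )
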