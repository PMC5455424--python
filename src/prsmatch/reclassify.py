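"""Absolute 10-year risk and threshold reclassification in weighted samples.

A nested case-control sample over-represents cases, so absolute risks are
recovered by weighting cases and controls to reproduce the source cohort's
event rate (6% 10-year risk here).  Per-subject odds ratios are anchored to
a baseline odds ``o*`` solved so the weighted mean risk equals the target;
risks are then compared against a clinical decision threshold (8% 10-year
risk, the UK preventive-therapy offer level) before and after adding a new
score, and the movers are summarized by a reclassification table and the
up-vs-down odds ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "case_control_weights",
    "absolute_risk",
    "proportion_above_threshold",
    "ReclassTable",
    "reclassification_table",
    "reclassification_or",
]


def case_control_weights(
    n_case: int, n_ctrl: int, target_risk: float = 0.06
) -> tuple[float, float]:
    """Weights making cases a ``target_risk`` fraction of the weighted sample.

    Controls get weight 1; cases get
    ``w = (target / (1 - target)) * (n_ctrl / n_case)`` so that
    ``n_case * w / (n_case * w + n_ctrl) = target_risk`` exactly.
    """
    if n_case < 1 or n_ctrl < 1:
        raise ValueError("need at least one case and one control")
    if not 0.0 < target_risk < 1.0:
        raise ValueError("target risk must lie in (0, 1)")
    w_case = (target_risk / (1.0 - target_risk)) * (n_ctrl / n_case)
    return w_case, 1.0


def absolute_risk(
    or_values: Sequence[float],
    weights: Sequence[float],
    target_mean_risk: float,
    bracket: tuple[float, float] = (1e-8, 1e3),
) -> np.ndarray:
    """Convert relative odds ratios to absolute risks with a calibrated baseline.

    ``risk_i = o* OR_i / (1 + o* OR_i)`` where the baseline odds ``o*``
    solves ``weighted mean risk = target_mean_risk``.  The mean risk is
    strictly increasing in ``o*`` so the root is unique; it is found by
    Brent's method on the stated bracket.
    """
    o = np.asarray(or_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(o <= 0):
        raise ValueError("odds ratios must be positive")
    if np.any(w <= 0) or w.shape != o.shape:
        raise ValueError("weights must be positive and aligned with odds ratios")
    if not 0.0 < target_mean_risk < 1.0:
        raise ValueError("target mean risk must lie in (0, 1)")
    wsum = w.sum()

    def mean_risk(base: float) -> float:
        x = base * o
        return float(np.sum(w * x / (1.0 + x)) / wsum)

    lo, hi = bracket
    f_lo, f_hi = mean_risk(lo) - target_mean_risk, mean_risk(hi) - target_mean_risk
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"no baseline odds in bracket {bracket}: mean risk spans "
            f"[{f_lo + target_mean_risk:.4g}, {f_hi + target_mean_risk:.4g}] "
            f"vs target {target_mean_risk}"
        )
    o_star = optimize.brentq(
        lambda b: mean_risk(b) - target_mean_risk, lo, hi, xtol=1e-12, rtol=1e-12
    )
    x = o_star * o
    return x / (1.0 + x)


def proportion_above_threshold(
    risks: Sequence[float], weights: Sequence[float], threshold: float = 0.08
) -> float:
    """Weighted percentage of subjects with risk at or above the threshold.

    The boundary is inclusive (risk >= threshold counts as high), matching
    the convention of offering intervention at the stated risk level.
    """
    r = np.asarray(risks, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("risks must lie strictly in (0, 1)")
    return float(100.0 * np.sum(w * (r >= threshold)) / w.sum())


@dataclass
class ReclassTable:
    """Cross-tabulation of below/above threshold before vs after a new score."""

    threshold: float
    counts: pd.DataFrame = field(repr=False)  # raw counts
    weighted: pd.DataFrame = field(repr=False)  # weighted counts

    @property
    def up_cases(self) -> int:
        return int(self.counts.loc[("case", "below"), "above"])

    @property
    def up_controls(self) -> int:
        return int(self.counts.loc[("control", "below"), "above"])

    @property
    def down_cases(self) -> int:
        return int(self.counts.loc[("case", "above"), "below"])

    @property
    def down_controls(self) -> int:
        return int(self.counts.loc[("control", "above"), "below"])

    def to_csv(self, path) -> None:
        out = self.counts.copy()
        out.columns = [f"after_{c}" for c in out.columns]
        out.index.names = ["status", "before"]
        out.to_csv(path)


def reclassification_table(
    risk_before: Sequence[float],
    risk_after: Sequence[float],
    case_status: Sequence[bool],
    weights: Sequence[float],
    threshold: float = 0.08,
) -> ReclassTable:
    """Tabulate threshold crossings when a score is added to the classic model.

    "Up" means below-threshold before and at/above after; "down" the
    reverse.  Raw and weighted counts are kept for cases and controls
    separately.
    """
    rb = np.asarray(risk_before, dtype=float)
    ra = np.asarray(risk_after, dtype=float)
    y = np.asarray(case_status, dtype=bool)
    w = np.asarray(weights, dtype=float)
    if not (rb.shape == ra.shape == y.shape == w.shape):
        raise ValueError("all input vectors must align")
    hb = rb >= threshold
    ha = ra >= threshold

    def tab(weighted: bool) -> pd.DataFrame:
        rows = []
        for status, mask in (("case", y), ("control", ~y)):
            for before, bmask in (("below", ~hb), ("above", hb)):
                vals = {}
                for after, amask in (("below", ~ha), ("above", ha)):
                    sel = mask & bmask & amask
                    vals[after] = float(w[sel].sum()) if weighted else int(sel.sum())
                rows.append({"status": status, "before": before, **vals})
        return pd.DataFrame(rows).set_index(["status", "before"])

    return ReclassTable(threshold=threshold, counts=tab(False), weighted=tab(True))


class ReclassOr(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool


def reclassification_or(table: ReclassTable) -> ReclassOr:
    """Case-status odds ratio of upgraded vs downgraded subjects.

    ``OR = (cases_up / controls_up) / (cases_down / controls_down)`` with a
    Woolf log-scale CI (SE = sqrt of the sum of reciprocal cells) and a
    two-sided p from the log-OR z statistic.  Zero cells trigger the
    Haldane 0.5 continuity correction, flagged in the result.  Computed on
    raw counts (a matched-sample association); weighted counts are
    descriptive only.
    """
    a, b = table.up_cases, table.up_controls
    c, d = table.down_cases, table.down_controls
    if a + b + c + d == 0:
        raise ValueError("no reclassified subjects in any cell")
    corrected = min(a, b, c, d) == 0
    if corrected:
        warnings.warn(
            "zero cell in reclassification table: applying 0.5 continuity correction",
            stacklevel=2,
        )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a / b) - np.log(c / d)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = stats.norm.ppf(0.975)
    zstat = log_or / se
    return ReclassOr(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p_value=float(2.0 * stats.norm.sf(abs(zstat))),
        corrected=corrected,
    )
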