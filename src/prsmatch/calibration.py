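"""Calibration of a risk score in matched case-control and cohort data.

The primary summary is the calibration slope: the coefficient from a
conditional-logit regression of case status on the expected per-subject
log odds ratio.  A slope of 1 means relative risks behave exactly as
predicted; a slope below 1 means the score's spread is attenuated in the
data (e.g. a published polygenic score applied to a new, high-risk
population).  The slope doubles as a recalibration factor:
``recalibrated score = score ** slope``.

Decile diagnostics mirror the usual calibration plot: observed per-decile
odds ratios (from indicator covariates inside the conditional likelihood)
against the mean predicted score per control decile.  For full-cohort data
the module provides the observed/expected event ratio and the
Hosmer-Lemeshow chi-square by decile of expected risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matched import ConditionalLogit, ConditionalLogitResults

__all__ = [
    "CalibrationResult",
    "CohortCalibration",
    "calibration_slope",
    "decile_observed_vs_expected",
    "recalibrate_score",
    "cohort_oe_by_decile",
    "plot_calibration",
]


@dataclass
class CalibrationResult:
    """Calibration slope (observed fraction of expected log-OR) with Wald CI."""

    slope: float
    se: float
    ci_low: float
    ci_high: float
    results: ConditionalLogitResults = field(repr=False)
    decile_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def slope_percent(self) -> float:
        return 100.0 * self.slope


def calibration_slope(
    log_expected_or: Sequence[float],
    set_id: Sequence,
    is_case: Sequence[bool],
) -> CalibrationResult:
    """Regress case status on the expected log odds ratio within matched sets.

    ``slope = 1`` indicates perfectly calibrated relative risks; the Wald
    CI is reported on the coefficient scale.
    """
    model = ConditionalLogit(
        np.asarray(log_expected_or, dtype=float), is_case, set_id, names=["log_expected_or"]
    )
    res = model.fit()
    lo, hi = res.conf_int()[0]
    return CalibrationResult(
        slope=float(res.params[0]), se=float(res.bse[0]),
        ci_low=float(lo), ci_high=float(hi), results=res,
    )


def recalibrate_score(score, slope: float):
    """Shrink a multiplicative score by the calibration slope.

    ``exp(slope * log score)``; slope 1 is the identity and slope 0
    collapses every subject to the population average 1.
    """
    s = np.asarray(score, dtype=float)
    if np.any(s <= 0):
        raise ValueError("scores must be positive")
    out = np.exp(slope * np.log(s))
    return float(out) if np.isscalar(score) else out


def decile_observed_vs_expected(
    score: Sequence[float],
    set_id: Sequence,
    is_case: Sequence[bool],
    n_bins: int = 10,
) -> pd.DataFrame:
    """Observed vs predicted odds ratios by control-score decile.

    Cut points are deciles of the score among controls; every subject is
    binned.  Observed per-decile ORs come from a conditional-logit fit with
    decile indicator covariates; because the reference level is arbitrary
    within the conditional likelihood, the observed ORs are rescaled so
    their control-frequency-weighted mean is 1, making them directly
    comparable with the predicted ORs (the mean control score per decile,
    for a score normalized to population mean 1).

    Deciles without cases get an absent (NaN) observed OR rather than an
    exception.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(is_case, dtype=bool)
    sid = np.asarray(set_id)
    ctrl_scores = s[~y]
    if np.unique(ctrl_scores).size < n_bins:
        raise ValueError(f"need >= {n_bins} distinct control scores")
    cuts = np.percentile(ctrl_scores, np.linspace(0, 100, n_bins + 1)[1:-1])
    bins = np.searchsorted(cuts, s, side="right")

    # deciles with no cases make indicator coefficients diverge; drop them
    # from the design and report their OR as absent
    case_bins = set(np.unique(bins[y]).tolist())
    est_bins = sorted(b for b in range(n_bins) if b in case_bins)
    ref = est_bins[0]
    cols = [b for b in est_bins if b != ref]
    X = np.column_stack([(bins == b).astype(float) for b in cols]) if cols else None
    if X is None:
        raise ValueError("all cases fall in a single decile; no contrast to fit")
    res = ConditionalLogit(X, y, sid, names=[f"decile_{b}" for b in cols]).fit()

    log_or = np.full(n_bins, np.nan)
    se = np.full(n_bins, np.nan)
    log_or[ref] = 0.0
    se[ref] = 0.0
    for b, coef, s_e in zip(cols, res.params, res.bse):
        log_or[b] = coef
        se[b] = s_e

    ctrl_bin = bins[~y]
    w = np.array([(ctrl_bin == b).mean() for b in range(n_bins)])
    est = ~np.isnan(log_or)
    # rescale so the control-weighted mean observed OR is 1
    norm = np.log(np.sum(w[est] * np.exp(log_or[est])) / w[est].sum())
    log_or = log_or - norm

    pred = np.array(
        [ctrl_scores[ctrl_bin == b].mean() if (ctrl_bin == b).any() else np.nan
         for b in range(n_bins)]
    )
    z = stats.norm.ppf(0.975)
    lower = np.concatenate([[ctrl_scores.min()], cuts])
    upper = np.concatenate([cuts, [ctrl_scores.max()]])
    return pd.DataFrame(
        {
            "decile": np.arange(1, n_bins + 1),
            "cut_low": lower,
            "cut_high": upper,
            "n_cases": [int(np.sum(y & (bins == b))) for b in range(n_bins)],
            "n_controls": [int(np.sum(~y & (bins == b))) for b in range(n_bins)],
            "predicted_or": pred,
            "observed_or": np.exp(log_or),
            "observed_ci_low": np.exp(log_or - z * se),
            "observed_ci_high": np.exp(log_or + z * se),
        }
    )


@dataclass
class CohortCalibration:
    """Full-cohort observed vs expected events with Hosmer-Lemeshow test."""

    observed_events: float
    expected_events: float
    oe_ratio: float
    hl_chi2: float
    hl_df: int
    hl_p: float
    table: pd.DataFrame = field(repr=False)


def cohort_oe_by_decile(
    expected_risks: Sequence[float],
    outcomes: Sequence[int],
    n_bins: int = 10,
) -> CohortCalibration:
    """Observed/expected events by decile of predicted risk (cohort mode).

    Per decile ``O`` is the event count and ``E`` the sum of predicted
    risks; the Hosmer-Lemeshow statistic is
    ``sum (O - E)^2 / (E (1 - E / n_bin))`` on ``bins - 2`` degrees of
    freedom.  Bins with zero expected events are merged with a neighbor
    (df adjusted, with a warning).
    """
    r = np.asarray(expected_risks, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if r.shape != y.shape:
        raise ValueError("risks and outcomes must align")
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("expected risks must lie strictly in (0, 1)")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be 0/1")
    cuts = np.percentile(r, np.linspace(0, 100, n_bins + 1)[1:-1])
    bins = np.searchsorted(cuts, r, side="right")
    groups = [np.flatnonzero(bins == b) for b in range(n_bins)]
    groups = [g for g in groups if g.size > 0]

    # merge zero-expectation bins forward
    merged: list[np.ndarray] = []
    for g in groups:
        if merged and r[merged[-1]].sum() == 0:
            warnings.warn("bin with zero expected events merged with neighbor", stacklevel=2)
            merged[-1] = np.concatenate([merged[-1], g])
        else:
            merged.append(g)
    if len(merged) >= 2 and r[merged[-1]].sum() == 0:
        warnings.warn("bin with zero expected events merged with neighbor", stacklevel=2)
        merged[-2] = np.concatenate([merged[-2], merged[-1]])
        merged.pop()

    rows = []
    chi2 = 0.0
    for i, g in enumerate(merged):
        o = y[g].sum()
        e = r[g].sum()
        n = g.size
        denom = e * (1.0 - e / n)
        term = (o - e) ** 2 / denom if denom > 0 else 0.0
        chi2 += term
        rows.append({"bin": i + 1, "n": n, "observed": o, "expected": e})
    df_table = pd.DataFrame(rows)
    hl_df = max(len(merged) - 2, 1)
    return CohortCalibration(
        observed_events=float(y.sum()),
        expected_events=float(r.sum()),
        oe_ratio=float(y.sum() / r.sum()),
        hl_chi2=float(chi2),
        hl_df=hl_df,
        hl_p=float(stats.chi2.sf(chi2, hl_df)),
        table=df_table,
    )


def plot_calibration(decile_table: pd.DataFrame, slope: float, path=None):
    """Observed vs predicted log-OR per decile with the fitted slope line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = decile_table.dropna(subset=["observed_or", "predicted_or"])
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.log(t["predicted_or"])
    ax.errorbar(
        x, np.log(t["observed_or"]),
        yerr=[np.log(t["observed_or"]) - np.log(t["observed_ci_low"]),
              np.log(t["observed_ci_high"]) - np.log(t["observed_or"])],
        fmt="o", color="tab:blue", label="decile estimates",
    )
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, slope * grid, color="goldenrod", label=f"fitted slope {slope:.2f}")
    ax.plot(grid, grid, ":", color="gray", label="perfect calibration")
    ax.set_xlabel("predicted log OR")
    ax.set_ylabel("observed log OR")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
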