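"""Conditional logistic regression and discrimination measures for matched sets.

The unit of analysis is the matched set: one case and her matched controls
(1:1 or 1:2 here), matched on trial, treatment arm, age and follow-up time.
The conditional likelihood conditions on each set containing exactly one
case, eliminating all set-level nuisance effects:

    l(beta) = sum_sets [ x_case . beta - log sum_{j in set} exp(x_j . beta) ]

:class:`ConditionalLogit` maximizes this by Newton-Raphson with analytic
gradient and Hessian; :class:`ConditionalLogitResults` carries the
estimates, their covariance, likelihood-ratio statistics and the derived
reporting quantities (interquartile-range odds ratio, Wald CIs).  The
matched concordance index and a Spearman independence check complete the
module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Subject",
    "MatchedSet",
    "ConditionalLogit",
    "ConditionalLogitResults",
    "SeparationError",
    "IqOr",
    "matched_sets_from_dataframe",
    "matched_concordance",
    "interaction_test",
    "bivariable_fit",
    "spearman_independence",
]


class SeparationError(RuntimeError):
    """The conditional likelihood is monotone (complete separation)."""


@dataclass(frozen=True)
class Subject:
    sample_id: str
    set_id: str
    is_case: bool
    trial: str = ""
    arm: str = ""
    age_entry: float = float("nan")
    tc_or: float = float("nan")
    snp_score: float = float("nan")
    er_status: str | None = None


@dataclass(frozen=True)
class MatchedSet:
    """One case plus 1..m controls sharing the matching strata."""

    set_id: str
    case: Subject
    controls: tuple[Subject, ...]

    def __post_init__(self) -> None:
        if not self.case.is_case:
            raise ValueError(f"set {self.set_id}: designated case is not a case")
        if not self.controls:
            raise ValueError(f"set {self.set_id}: no controls")
        if any(c.is_case for c in self.controls):
            raise ValueError(f"set {self.set_id}: more than one case")
        for c in self.controls:
            if c.trial != self.case.trial or c.arm != self.case.arm:
                raise ValueError(
                    f"set {self.set_id}: members do not share trial/arm strata"
                )

    @property
    def size(self) -> int:
        return 1 + len(self.controls)


def matched_sets_from_dataframe(df: pd.DataFrame) -> list[MatchedSet]:
    """Build validated :class:`MatchedSet` objects from a subjects table.

    Expects columns ``sample_id, set_id, is_case`` and optionally
    ``trial, arm, age_entry, tc_or, snp_score, er_status``.
    """
    sets: list[MatchedSet] = []
    for set_id, grp in df.groupby("set_id", sort=True):
        subs = [
            Subject(
                sample_id=str(r.sample_id),
                set_id=str(set_id),
                is_case=bool(r.is_case),
                trial=str(getattr(r, "trial", "")),
                arm=str(getattr(r, "arm", "")),
                age_entry=float(getattr(r, "age_entry", np.nan)),
                tc_or=float(getattr(r, "tc_or", np.nan)),
                snp_score=float(getattr(r, "snp_score", np.nan)),
                er_status=(None if pd.isna(getattr(r, "er_status", None)) else str(r.er_status)),
            )
            for r in grp.itertuples()
        ]
        cases = [s for s in subs if s.is_case]
        if len(cases) != 1:
            raise ValueError(f"set {set_id}: expected exactly one case, found {len(cases)}")
        controls = tuple(s for s in subs if not s.is_case)
        sets.append(MatchedSet(set_id=str(set_id), case=cases[0], controls=controls))
    return sets


class ConditionalLogit:
    """Conditional logistic regression model for 1:m matched sets.

    Parameters
    ----------
    exog : (n, k) array-like
        Covariate values per subject.  Set-level variables (constant within
        every set) are inestimable under matching and raise an error; they
        enter only through interactions.
    case : (n,) boolean array-like
        Case indicator; exactly one case per set.
    set_id : (n,) array-like
        Matched-set labels.
    names : sequence of str, optional
        Covariate names for reporting.
    """

    def __init__(self, exog, case, set_id, names: Sequence[str] | None = None):
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] == 1 and np.asarray(case).size != 1:
            X = X.T
        y = np.asarray(case, dtype=bool)
        sid = np.asarray(set_id)
        if not (X.shape[0] == y.size == sid.size):
            raise ValueError("exog, case and set_id must have matching first dimension")
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates must be finite")

        # sort by set for segment reductions
        order = np.argsort(sid, kind="stable")
        self.exog = X[order]
        self.case = y[order]
        self._sid = sid[order]
        uniq, starts, sizes = np.unique(self._sid, return_index=True, return_counts=True)
        self._starts = starts
        self._sizes = sizes
        self.n_sets = uniq.size
        self.nobs = y.size
        self.k = X.shape[1]
        self.names = list(names) if names is not None else [f"x{i}" for i in range(self.k)]
        if len(self.names) != self.k:
            raise ValueError("names length mismatch")

        ncase = np.add.reduceat(self.case.astype(int), starts)
        if np.any(ncase != 1):
            bad = uniq[ncase != 1][0]
            raise ValueError(f"set {bad!r} does not contain exactly one case")
        if np.any(sizes < 2):
            bad = uniq[sizes < 2][0]
            raise ValueError(f"set {bad!r} has no controls")

        # within-set variation scale: SD of deviations from set means
        set_idx = np.repeat(np.arange(self.n_sets), sizes)
        means = np.add.reduceat(self.exog, starts, axis=0) / sizes[:, None]
        dev = self.exog - means[set_idx]
        self._scale = np.sqrt(np.mean(dev**2, axis=0))
        self._flat = bool(np.all(self._scale == 0))
        if self._flat:
            # completely flat conditional likelihood; beta = 0 is the
            # canonical root (handled in fit)
            self._scale = np.ones(self.k)
        elif np.any(self._scale == 0):
            j = int(np.argmax(self._scale == 0))
            raise ValueError(
                f"covariate {self.names[j]!r} has no within-set variation "
                "(set-level variables are absorbed by matching; include them "
                "only through interactions)"
            )
        self._set_idx = set_idx

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariates: Sequence[str],
        set_col: str = "set_id",
        case_col: str = "is_case",
    ) -> "ConditionalLogit":
        return cls(
            df[list(covariates)].to_numpy(dtype=float),
            df[case_col].to_numpy(dtype=bool),
            df[set_col].to_numpy(),
            names=list(covariates),
        )

    # -- likelihood machinery (all on the standardized scale internally) ----

    def _loglike_parts(self, Xs: np.ndarray, beta: np.ndarray):
        eta = Xs @ beta
        m = np.maximum.reduceat(eta, self._starts)
        ex = np.exp(eta - m[self._set_idx])
        denom = np.add.reduceat(ex, self._starts)
        lse = m + np.log(denom)
        llf = float(eta[self.case].sum() - lse.sum())
        w = ex / denom[self._set_idx]
        return llf, w

    def loglike(self, beta) -> float:
        """Conditional log-likelihood at ``beta`` (natural scale)."""
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        llf, _ = self._loglike_parts(self.exog, beta)
        return llf

    @property
    def llnull(self) -> float:
        return float(-np.sum(np.log(self._sizes)))

    def fit(
        self, maxiter: int = 100, gtol: float = 1e-8, xtol: float = 1e-10
    ) -> "ConditionalLogitResults":
        """Newton-Raphson with step-halving from ``beta = 0``.

        Convergence when the maximum absolute score falls below ``gtol`` or
        the step below ``xtol``.  Monotone likelihoods (complete
        separation) are detected as a diverging standardized coefficient
        norm (> 15) and reported as non-converged with the direction of
        divergence rather than silently truncated.
        """
        if self._flat:
            warnings.warn(
                "covariates identical within every set: likelihood is flat; "
                "beta = 0 taken as the canonical root",
                stacklevel=2,
            )
            return ConditionalLogitResults(
                model=self,
                params=np.zeros(self.k),
                cov=np.full((self.k, self.k), np.inf),
                llf=self.llnull,
                converged=True,
            )
        Xs = self.exog / self._scale
        beta = np.zeros(self.k)
        llf, w = self._loglike_parts(Xs, beta)
        converged = False
        separated = False
        for _ in range(maxiter):
            grad = Xs[self.case].sum(axis=0) - (w[:, None] * Xs).sum(axis=0)
            xbar = np.add.reduceat(w[:, None] * Xs, self._starts, axis=0)
            info = Xs.T @ (w[:, None] * Xs) - xbar.T @ xbar
            if np.max(np.abs(grad)) < gtol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, grad, rcond=None)[0]
            # step-halving on log-likelihood decrease
            lam = 1.0
            for _h in range(30):
                new_llf, new_w = self._loglike_parts(Xs, beta + lam * step)
                if new_llf >= llf - 1e-12:
                    break
                lam *= 0.5
            beta = beta + lam * step
            llf, w = new_llf, new_w
            if np.linalg.norm(beta) > 15.0:
                separated = True
                break
            if lam * np.max(np.abs(step)) < xtol:
                converged = True
                break

        grad = Xs[self.case].sum(axis=0) - (w[:, None] * Xs).sum(axis=0)
        xbar = np.add.reduceat(w[:, None] * Xs, self._starts, axis=0)
        info = Xs.T @ (w[:, None] * Xs) - xbar.T @ xbar
        # monotone likelihoods can meet the gradient tolerance at a huge but
        # finite beta; an exploding standardized SE gives them away
        if not separated and converged:
            try:
                diag = np.diag(np.linalg.inv(info))
            except np.linalg.LinAlgError:
                diag = np.array([np.inf])
            if np.any(diag > 1e4) and np.linalg.norm(beta) > 5.0:
                separated = True
        if separated:
            warnings.warn(
                "complete separation: conditional likelihood is monotone in "
                f"direction {np.sign(beta).astype(int).tolist()}; estimates diverge",
                stacklevel=2,
            )
            converged = False
        try:
            cov_s = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov_s = np.linalg.pinv(info)
        # back-transform to the natural covariate scale
        D = np.diag(1.0 / self._scale)
        params = D @ beta
        cov = D @ cov_s @ D
        return ConditionalLogitResults(
            model=self,
            params=params,
            cov=cov,
            llf=llf,
            converged=converged,
            separated=separated,
        )


class IqOr(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float
    iqr: float


class ConditionalLogitResults:
    """Fitted conditional-logit estimates, uncertainty and diagnostics."""

    def __init__(self, model, params, cov, llf, converged, separated=False):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.separated = bool(separated)
        self.n_sets = model.n_sets
        self.nobs = model.nobs
        self.names = model.names

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def cov_params(self) -> np.ndarray:
        return self.cov

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values."""
        return 2.0 * stats.norm.sf(np.abs(self.tvalues))

    @property
    def llnull(self) -> float:
        return self.model.llnull

    @property
    def llr(self) -> float:
        """Likelihood-ratio chi-square against the null (all betas 0)."""
        return 2.0 * (self.llf - self.llnull)

    @property
    def llr_df(self) -> int:
        return self.params.size

    @property
    def llr_pvalue(self) -> float:
        return float(stats.chi2.sf(self.llr, self.llr_df))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def iq_or(self, control_values: Sequence[float], index: int = 0) -> IqOr:
        """Interquartile-range odds ratio for one covariate.

        The covariate span is the interquartile range of ``control_values``
        (linear-interpolation quantiles among controls), the field's
        convention for summarizing a continuous score:
        ``IQ-OR = exp(beta * (Q3 - Q1))`` with a Wald CI.
        """
        v = np.asarray(control_values, dtype=float)
        if v.size < 4:
            raise ValueError("need at least 4 control values for quartiles")
        q1, q3 = np.percentile(v, [25, 75])
        delta = q3 - q1
        if delta == 0:
            warnings.warn("degenerate IQR (all control values equal)", stacklevel=2)
            return IqOr(1.0, 1.0, 1.0, 0.0)
        b, se = self.params[index], self.bse[index]
        z = stats.norm.ppf(0.975)
        return IqOr(
            estimate=float(np.exp(b * delta)),
            ci_low=float(np.exp(delta * (b - z * se))),
            ci_high=float(np.exp(delta * (b + z * se))),
            iqr=float(delta),
        )

    def summary(self) -> str:
        z = stats.norm.ppf(0.975)
        lines = [
            "Conditional logistic regression (matched sets)",
            f"  sets: {self.n_sets}   subjects: {self.nobs}   converged: {self.converged}",
            f"  log-likelihood: {self.llf:.4f}   null: {self.llnull:.4f}   "
            f"LR chi2({self.llr_df}) = {self.llr:.3f}  (P = {self.llr_pvalue:.3g})",
            f"  {'term':<16}{'coef':>10}{'se':>10}{'z':>8}{'P>|z|':>10}"
            f"{'[0.025':>10}{'0.975]':>10}",
        ]
        for j, name in enumerate(self.names):
            b, se = self.params[j], self.bse[j]
            lines.append(
                f"  {name:<16}{b:>10.4f}{se:>10.4f}{b / se:>8.2f}"
                f"{2 * stats.norm.sf(abs(b / se)):>10.3g}"
                f"{b - z * se:>10.4f}{b + z * se:>10.4f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ConditionalLogitResults params={np.round(self.params, 4).tolist()} "
            f"n_sets={self.n_sets}>"
        )


def matched_concordance(
    set_id: Sequence,
    is_case: Sequence[bool],
    score: Sequence[float],
    per_set_average: bool = False,
) -> float:
    """Matched concordance index: does the case outscore her matched controls?

    The default pools all case-control pairs over sets:
    ``mC = (# pairs with case > control + 0.5 # ties) / (# pairs)``.
    ``per_set_average=True`` averages the within-set concordance over sets
    instead (an alternative convention, labeled as such).
    """
    df = pd.DataFrame(
        {"set_id": np.asarray(set_id), "is_case": np.asarray(is_case, dtype=bool),
         "score": np.asarray(score, dtype=float)}
    )
    wins, ties, pairs = [], [], []
    for _, grp in df.groupby("set_id", sort=False):
        case_scores = grp.loc[grp.is_case, "score"].to_numpy()
        ctrl = grp.loc[~grp.is_case, "score"].to_numpy()
        if case_scores.size != 1 or ctrl.size == 0:
            raise ValueError("every set needs exactly one case and >=1 control")
        c = case_scores[0]
        wins.append(np.sum(ctrl < c))
        ties.append(np.sum(ctrl == c))
        pairs.append(ctrl.size)
    wins, ties, pairs = map(np.asarray, (wins, ties, pairs))
    if per_set_average:
        return float(np.mean((wins + 0.5 * ties) / pairs))
    return float((wins.sum() + 0.5 * ties.sum()) / pairs.sum())


class InteractionResult(NamedTuple):
    beta_main: float
    beta_interaction: float
    se_interaction: float
    p_het: float
    results: ConditionalLogitResults


def interaction_test(
    covariate: Sequence[float],
    group: Sequence,
    set_id: Sequence,
    is_case: Sequence[bool],
) -> InteractionResult:
    """Heterogeneity of a covariate effect across a set-level binary group.

    Fits ``[x, x * 1(group)]``; the group's main effect is absorbed by
    matching (it is constant within sets), so the interaction coefficient
    is the between-group difference in the covariate effect, with a
    two-sided Wald p-value.
    """
    x = np.asarray(covariate, dtype=float)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"group must have exactly 2 levels, found {levels.size}")
    ind = (g == levels[1]).astype(float)
    X = np.column_stack([x, x * ind])
    model = ConditionalLogit(
        X, is_case, set_id, names=["x", f"x:{levels[1]}"]
    )
    res = model.fit()
    return InteractionResult(
        beta_main=float(res.params[0]),
        beta_interaction=float(res.params[1]),
        se_interaction=float(res.bse[1]),
        p_het=float(res.pvalues[1]),
        results=res,
    )


class BivariableResult(NamedTuple):
    fit_two: ConditionalLogitResults
    fit_combined: ConditionalLogitResults
    chi2_two: float
    chi2_combined: float


def bivariable_fit(
    log_snp_score: Sequence[float],
    log_tc_or: Sequence[float],
    set_id: Sequence,
    is_case: Sequence[bool],
) -> BivariableResult:
    """Joint model of the SNP score and the classic-model risk.

    Returns the two-coefficient fit on ``[log S, log T]``, the
    one-coefficient fit on the multiplicatively combined score
    ``log(S * T)``, and the likelihood-ratio chi-square of each against the
    null.  Near-equality of the two chi-squares indicates the scores may be
    combined multiplicatively with unit weights.
    """
    s = np.asarray(log_snp_score, dtype=float)
    t = np.asarray(log_tc_or, dtype=float)
    fit2 = ConditionalLogit(
        np.column_stack([s, t]), is_case, set_id, names=["log_snp", "log_tc"]
    ).fit()
    fit1 = ConditionalLogit(s + t, is_case, set_id, names=["log_snp_tc"]).fit()
    return BivariableResult(
        fit_two=fit2, fit_combined=fit1, chi2_two=fit2.llr, chi2_combined=fit1.llr
    )


def spearman_independence(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with t-approximation p.

    Used to check that the SNP score carries information independent of the
    classic risk model among controls.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 10:
        raise ValueError("need paired vectors of length >= 10")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
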