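"""Synthetic matched prevention-trial data with the structure the analysis assumes.

The generator emulates a nested case-control study inside two tamoxifen
prevention trials: a larger trial contributing 1 case : 2 control matched
sets and a smaller pilot contributing 1:1 sets, with matching on trial,
treatment arm and age (+/- 2 years).  Disease risk is multiplicative on
the odds scale:

    odds_i = o* x S_i^lambda x T_i x (tamoxifen OR if treated)

where ``S`` is the true normalized polygenic score (genotypes drawn under
HWE, independent SNPs), ``lambda`` an attenuation factor on the published
effects (1 = published strengths hold; the calibration slope the analysis
estimates), ``T`` a lognormal classic-model odds ratio independent of
genotype, and ``o*`` a baseline solved so the population mean 10-year risk
hits the target (6%).  Everything is reproducible from a numpy Generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import ScorePanel, SnpDefinition, build_panel

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "MatchedStudy",
    "PowerResult",
    "simulate_panel",
    "simulate_cohort",
    "nested_case_control_sample",
    "power_estimate",
]

_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]  # non-ambiguous (strand-resolvable) ordered risk/other pairs


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults emulate the two-trial study conditions.

    ``n_sets_2ctrl``/``n_sets_1ctrl`` default to 277 and 82, the split of
    359 cases and 636 controls between a 1:2-matched and a 1:1-matched
    trial.  Effect sizes span published per-allele ORs (1.03-1.35); by
    default log-ORs follow a truncated exponential so the panel's analytic
    OR per SD lands near 1.6, the strength published panels of this size
    attain (a ``uniform`` option draws ORs flat on the range instead).
    """

    n_snps: int = 88
    or_range: tuple[float, float] = (1.03, 1.35)
    raf_range: tuple[float, float] = (0.05, 0.95)
    or_distribution: str = "exponential"  # or "uniform"
    or_log_scale: float = 0.045  # scale of the exponential log-OR tail
    attenuation: float = 1.0  # lambda_true in [0, 1]
    tc_log_sd: float = 0.28  # lognormal spread of the classic-model OR
    tamoxifen_or: float = 0.7
    target_10yr_risk: float = 0.06
    er_pos_fraction: float = 0.74
    er_specific_effect: bool = False  # genotype effect in ER+ disease only
    n_sets_2ctrl: int = 277
    n_sets_1ctrl: int = 82
    age_range: tuple[float, float] = (35.0, 70.0)
    age_tolerance: float = 2.0
    missing_rate: float = 0.0
    cohort_multiplier: float = 1.4  # oversampling so enough cases arise

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 < self.or_range[0] <= self.or_range[1]:
            raise ValueError(f"invalid or_range {self.or_range}")
        if not 0.0 < self.raf_range[0] <= self.raf_range[1] < 1.0:
            raise ValueError(f"invalid raf_range {self.raf_range}")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")
        if self.tc_log_sd < 0 or self.tamoxifen_or <= 0:
            raise ValueError("invalid tc_log_sd or tamoxifen_or")
        if not 0.0 < self.target_10yr_risk < 1.0:
            raise ValueError("target risk must lie in (0, 1)")
        if not 0.0 <= self.er_pos_fraction <= 1.0:
            raise ValueError("er_pos_fraction must lie in [0, 1]")
        if self.or_distribution not in ("exponential", "uniform"):
            raise ValueError("or_distribution must be 'exponential' or 'uniform'")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_panel(config: SimConfig, rng=None) -> ScorePanel:
    """Draw a synthetic SNP panel (labeled as such via rsids ``rsSIM...``).

    Risk-allele frequencies are uniform on the configured range.  Log
    per-allele ORs follow a truncated exponential on
    ``[log or_lo, log or_hi]`` by default, mimicking the many-small /
    few-large shape of published effect sizes; ``or_distribution='uniform'``
    draws the OR itself flat on the range.  Per-SNP standard errors (for
    shrinkage experiments) are drawn uniform on 0.02-0.08.
    """
    rng = _as_rng(rng)
    lo, hi = np.log(config.or_range[0]), np.log(config.or_range[1])
    if config.or_distribution == "uniform":
        log_r = np.log(rng.uniform(*config.or_range, size=config.n_snps))
    else:
        u = rng.uniform(size=config.n_snps)
        span = hi - lo
        if span == 0:
            log_r = np.full(config.n_snps, lo)
        else:
            # inverse CDF of Exponential(scale) truncated to [0, span]
            tail = 1.0 - np.exp(-span / config.or_log_scale)
            log_r = lo - config.or_log_scale * np.log1p(-u * tail)
    raf = rng.uniform(*config.raf_range, size=config.n_snps)
    ses = rng.uniform(0.02, 0.08, size=config.n_snps)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), config.n_snps)]
    defs = [
        SnpDefinition(
            rsid=f"rsSIM{i:04d}",
            risk_allele=pairs[i][0],
            other_allele=pairs[i][1],
            per_allele_or=float(np.exp(log_r[i])),
            raf=float(raf[i]),
            se_log_or=float(ses[i]),
            chrom=str(1 + i % 22),
            pos=1000 * (i + 1),
        )
        for i in range(config.n_snps)
    ]
    return build_panel(defs)


@dataclass
class SimulatedCohort:
    """A full simulated trial population before nested sampling."""

    trial: np.ndarray  # per-subject trial label
    arm: np.ndarray  # "tamoxifen" | "placebo"
    age_entry: np.ndarray
    tc_or: np.ndarray
    genotypes: np.ndarray  # (n, n_snps) float, nan = failed assay
    true_log_score: np.ndarray
    risk: np.ndarray
    is_case: np.ndarray
    er_status: np.ndarray  # "positive"/"negative" for cases, "" otherwise
    baseline_odds: float

    @property
    def n(self) -> int:
        return self.is_case.size


def _solve_baseline_odds(mult: np.ndarray, target: float) -> float:
    def mean_risk(base: float) -> float:
        x = base * mult
        return float(np.mean(x / (1.0 + x)))

    return optimize.brentq(
        lambda b: mean_risk(b) - target, 1e-10, 1e4, xtol=1e-12, rtol=1e-12
    )


def simulate_cohort(panel: ScorePanel, config: SimConfig, rng=None) -> SimulatedCohort:
    """Simulate the two-trial population the nested sampler draws from.

    Genotypes are Binomial(2, RAF) per SNP (HWE, independent SNPs); the
    classic-model OR ``T`` is lognormal with mean 1 and log-SD
    ``tc_log_sd``, independent of genotype; treatment halves the trial
    1:1.  With ``er_specific_effect`` the genotype effect operates only in
    the ER-positive disease process (two competing sub-risks calibrated to
    split the target risk 74/26); otherwise ER labels are assigned to
    cases independently of genotype.
    """
    rng = _as_rng(rng)
    sizes = []
    labels = []
    for label, n_sets, m in (("trialA", config.n_sets_2ctrl, 2), ("trialB", config.n_sets_1ctrl, 1)):
        if n_sets > 0:
            n = int(np.ceil(n_sets / config.target_10yr_risk * config.cohort_multiplier))
            sizes.append(n)
            labels.append(label)
    if not sizes:
        raise ValueError("at least one stratum must have sets")
    n_total = int(np.sum(sizes))
    trial = np.repeat(labels, sizes)

    arm = np.where(rng.uniform(size=n_total) < 0.5, "tamoxifen", "placebo")
    age = rng.uniform(*config.age_range, size=n_total)
    raf = np.array([s.raf for s in panel.snps])
    G = rng.binomial(2, raf[None, :], size=(n_total, len(panel))).astype(float)
    log_s = G @ panel._log_r - panel._log_mu.sum()
    sigma = config.tc_log_sd
    tc = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_total)) if sigma > 0 else np.ones(n_total)
    tam = np.where(arm == "tamoxifen", config.tamoxifen_or, 1.0)

    er = np.full(n_total, "", dtype=object)
    if config.er_specific_effect:
        base_mult = tc * tam
        pos_mult = base_mult * np.exp(config.attenuation * log_s)
        o_pos = _solve_baseline_odds(pos_mult, config.target_10yr_risk * config.er_pos_fraction)
        o_neg = _solve_baseline_odds(base_mult, config.target_10yr_risk * (1.0 - config.er_pos_fraction))
        r_pos = o_pos * pos_mult / (1.0 + o_pos * pos_mult)
        r_neg = o_neg * base_mult / (1.0 + o_neg * base_mult)
        case_pos = rng.uniform(size=n_total) < r_pos
        case_neg = rng.uniform(size=n_total) < r_neg
        is_case = case_pos | case_neg
        er[case_pos] = "positive"
        er[case_neg & ~case_pos] = "negative"
        risk = r_pos + r_neg - r_pos * r_neg
        o_star = o_pos
    else:
        mult = np.exp(config.attenuation * log_s) * tc * tam
        o_star = _solve_baseline_odds(mult, config.target_10yr_risk)
        risk = o_star * mult / (1.0 + o_star * mult)
        is_case = rng.uniform(size=n_total) < risk
        n_cases = int(is_case.sum())
        er_pos = rng.uniform(size=n_cases) < config.er_pos_fraction
        er[np.flatnonzero(is_case)] = np.where(er_pos, "positive", "negative")

    if config.missing_rate > 0:
        G[rng.uniform(size=G.shape) < config.missing_rate] = np.nan

    return SimulatedCohort(
        trial=trial, arm=arm, age_entry=age, tc_or=tc, genotypes=G,
        true_log_score=log_s, risk=risk, is_case=is_case, er_status=er,
        baseline_odds=float(o_star),
    )


@dataclass
class MatchedStudy:
    """A nested case-control sample: matched sets plus aligned genotypes."""

    sample_id: np.ndarray
    set_id: np.ndarray
    is_case: np.ndarray
    trial: np.ndarray
    arm: np.ndarray
    age_entry: np.ndarray
    tc_or: np.ndarray
    er_status: np.ndarray
    genotypes: np.ndarray  # aligned to panel order
    n_dropped_cases: int = 0

    @property
    def n(self) -> int:
        return self.is_case.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "set_id": self.set_id,
                "is_case": self.is_case,
                "trial": self.trial,
                "arm": self.arm,
                "age_entry": self.age_entry,
                "tc_or": self.tc_or,
                "er_status": self.er_status,
            }
        )


def nested_case_control_sample(
    cohort: SimulatedCohort, config: SimConfig, rng=None
) -> MatchedStudy:
    """Draw matched sets: 1:2 in the larger trial, 1:1 in the pilot.

    For each sampled case, controls are drawn without replacement from
    non-cases of the same trial and arm with entry age within the
    tolerance (+/- 2 years).  Cases whose stratum is exhausted are dropped
    with a warning and counted in ``n_dropped_cases``.
    """
    rng = _as_rng(rng)
    picked_rows: list[np.ndarray] = []
    set_ids: list[str] = []
    dropped = 0
    used = np.zeros(cohort.n, dtype=bool)

    for label, n_sets, m in (("trialA", config.n_sets_2ctrl, 2), ("trialB", config.n_sets_1ctrl, 1)):
        if n_sets == 0:
            continue
        in_trial = cohort.trial == label
        case_idx = np.flatnonzero(in_trial & cohort.is_case)
        if case_idx.size < n_sets:
            warnings.warn(
                f"{label}: only {case_idx.size} cases available for {n_sets} sets",
                stacklevel=2,
            )
        case_idx = rng.permutation(case_idx)[:n_sets]

        # per-arm control pools sorted by age for window lookups
        pools = {}
        for a in ("tamoxifen", "placebo"):
            ctrl = np.flatnonzero(in_trial & ~cohort.is_case & (cohort.arm == a))
            order = np.argsort(cohort.age_entry[ctrl], kind="stable")
            pools[a] = (ctrl[order], cohort.age_entry[ctrl[order]])

        for k, ci in enumerate(case_idx):
            pool, ages = pools[cohort.arm[ci]]
            lo = np.searchsorted(ages, cohort.age_entry[ci] - config.age_tolerance, "left")
            hi = np.searchsorted(ages, cohort.age_entry[ci] + config.age_tolerance, "right")
            cand = pool[lo:hi]
            cand = cand[~used[cand]]
            if cand.size < m:
                dropped += 1
                continue
            chosen = rng.choice(cand, size=m, replace=False)
            used[chosen] = True
            rows = np.concatenate([[ci], chosen])
            picked_rows.append(rows)
            set_ids.append(f"{label}_set{k:04d}")

    if dropped:
        warnings.warn(f"{dropped} case(s) dropped: matching stratum exhausted", stacklevel=2)
    if not picked_rows:
        return MatchedStudy(
            sample_id=np.array([], dtype=object), set_id=np.array([], dtype=object),
            is_case=np.array([], dtype=bool), trial=np.array([], dtype=object),
            arm=np.array([], dtype=object), age_entry=np.array([]),
            tc_or=np.array([]), er_status=np.array([], dtype=object),
            genotypes=np.empty((0, cohort.genotypes.shape[1])),
            n_dropped_cases=dropped,
        )

    idx = np.concatenate(picked_rows)
    sid = np.concatenate(
        [np.repeat(s, r.size) for s, r in zip(set_ids, picked_rows)]
    )
    return MatchedStudy(
        sample_id=np.array([f"subj{i:06d}" for i in idx], dtype=object),
        set_id=sid,
        is_case=cohort.is_case[idx],
        trial=cohort.trial[idx],
        arm=cohort.arm[idx],
        age_entry=cohort.age_entry[idx],
        tc_or=cohort.tc_or[idx],
        er_status=cohort.er_status[idx],
        genotypes=cohort.genotypes[idx],
        n_dropped_cases=dropped,
    )


class PowerResult(NamedTuple):
    power: float
    ci_low: float
    ci_high: float
    n_reject: int
    n_sims: int


def power_estimate(
    config: SimConfig,
    n_sims: int,
    alpha: float = 0.05,
    rng=None,
    panel: ScorePanel | None = None,
) -> PowerResult:
    """Simulation-based power of the design for the polygenic score effect.

    Each replicate runs the full pipeline — simulate a cohort, draw the
    nested case-control sample, score subjects from their genotypes, fit a
    conditional-logit model on the log score — and applies a two-sided
    Wald test at level ``alpha``.  The panel is drawn once (fixed across
    replicates) unless supplied.  Returns the rejection fraction with a
    95% Clopper-Pearson interval.
    """
    from .matched import ConditionalLogit
    from .panel import compute_scores

    if n_sims < 100:
        raise ValueError("use at least 100 simulations for a power estimate")
    rng = _as_rng(rng)
    if panel is None:
        panel = simulate_panel(config, rng)
    n_reject = 0
    for _ in range(n_sims):
        cohort = simulate_cohort(panel, config, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            study = nested_case_control_sample(cohort, config, rng)
        scores = compute_scores(study.genotypes, panel, sample_ids=study.sample_id)
        res = ConditionalLogit(
            scores["log_score"].to_numpy(), study.is_case, study.set_id,
            names=["log_score"],
        ).fit()
        if res.converged and res.pvalues[0] < alpha:
            n_reject += 1
    ci = stats.binomtest(n_reject, n_sims).proportion_ci(0.95)
    return PowerResult(
        power=n_reject / n_sims, ci_low=float(ci.low), ci_high=float(ci.high),
        n_reject=n_reject, n_sims=n_sims,
    )
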