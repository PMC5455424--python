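"""End-to-end orchestration: QC, scoring, inference, calibration, reclassification.

``run_pipeline`` executes the full analysis sequence on a panel, genotype
matrix and subjects table — whether read from files or freshly simulated —
and writes a versioned JSON results bundle, CSV tables, the calibration
figure and a text log with seed and exclusion accounting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    calibration_slope,
    decile_observed_vs_expected,
    plot_calibration,
    recalibrate_score,
)
from .matched import (
    ConditionalLogit,
    bivariable_fit,
    interaction_test,
    matched_concordance,
    spearman_independence,
)
from .panel import ScorePanel, build_panel, compute_scores
from .qc import GenotypeMatrix, run_qc
from .reclassify import (
    absolute_risk,
    case_control_weights,
    proportion_above_threshold,
    reclassification_or,
    reclassification_table,
)

__all__ = ["RunConfig", "run_pipeline"]

RESULTS_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Thresholds and toggles for a pipeline run."""

    output_dir: str | Path = "results"
    seed: int = 0
    max_fail_fraction: float = 0.02
    max_failed_snps: int = 10
    r2_threshold: float = 0.1
    target_risk: float = 0.06
    risk_threshold: float = 0.08
    subgroups: tuple[str, ...] = ("arm", "trial", "er")
    make_plot: bool = True

    def __post_init__(self) -> None:
        for name in ("max_fail_fraction", "target_risk", "risk_threshold", "r2_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.max_failed_snps < 0:
            raise ValueError("max_failed_snps must be nonnegative")


def _round_floats(obj, sig: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _fit_summary(res, control_vals=None):
    out = {
        "coef": res.params.tolist(),
        "se": res.bse.tolist(),
        "ci": res.conf_int().tolist(),
        "wald_p": res.pvalues.tolist(),
        "llr_chi2": res.llr,
        "llr_df": res.llr_df,
        "llr_p": res.llr_pvalue,
        "n_sets": res.n_sets,
        "converged": res.converged,
        "terms": res.names,
    }
    if control_vals is not None and res.converged:
        iq = res.iq_or(control_vals)
        out["iq_or"] = {"estimate": iq.estimate, "ci_low": iq.ci_low, "ci_high": iq.ci_high}
    return out


def _restrict_to_sets(df: pd.DataFrame, keep_sets) -> pd.DataFrame:
    return df[df["set_id"].isin(keep_sets)]


def run_pipeline(
    panel: ScorePanel,
    genotypes: GenotypeMatrix,
    subjects: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Run the complete analysis and write all artifacts to ``output_dir``.

    Stages: QC -> scoring -> univariable and bivariable conditional-logit
    fits with IQ-ORs and matched concordance -> subgroup interaction tests
    -> calibration slope and decile diagnostics -> recalibration ->
    weighted absolute-risk reclassification at the decision threshold.
    Returns the results bundle (also serialized as JSON).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"prsmatch {__version__} | seed {config.seed}"]
    results: dict = {"schema_version": RESULTS_SCHEMA_VERSION, "seed": config.seed}

    def stage(name):
        log.append(f"--- {name}")

    try:
        stage("qc")
        controls = subjects.loc[~subjects["is_case"], "sample_id"].tolist()
        qc_matrix, qc_report = run_qc(
            genotypes,
            control_ids=controls,
            max_fail_fraction=config.max_fail_fraction,
            max_failed_snps=config.max_failed_snps,
            r2_threshold=config.r2_threshold,
        )
        log.extend("  " + s for s in qc_report.summary_lines())
        (outdir / "qc_report.json").write_text(qc_report.to_json())
        kept = set(qc_report.kept_rsids)
        panel_defs = [d for d in panel.snps if d.rsid in kept]
        if len(panel_defs) < len(panel.snps):
            log.append(f"  panel reduced from {len(panel.snps)} to {len(panel_defs)} SNPs")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            panel_qc = build_panel(panel_defs)
        results["qc"] = {
            "n_snps_excluded": len(qc_report.excluded_snps),
            "n_samples_excluded": len(qc_report.excluded_samples),
            "n_snps_kept": len(qc_report.kept_rsids),
            "n_samples_kept": len(qc_report.kept_sample_ids),
            "aggregate_homozygotes": qc_report.aggregate_homozygotes,
            "n_r2_pairs": len(qc_report.r2_pairs),
        }

        stage("scoring")
        aligned = qc_matrix.subset(snps=panel_qc.rsids)
        scores = compute_scores(aligned.counts, panel_qc, sample_ids=aligned.sample_ids)
        scores.to_csv(outdir / "scores.tsv", sep="\t", index=False, float_format="%.10g")
        df = subjects.merge(scores, on="sample_id", how="inner")
        # drop sets broken by sample exclusions (must keep 1 case + >=1 control)
        ok = df.groupby("set_id")["is_case"].agg(["sum", "count"])
        good_sets = ok[(ok["sum"] == 1) & (ok["count"] >= 2)].index
        n_broken = ok.shape[0] - good_sets.size
        if n_broken:
            log.append(f"  {n_broken} matched set(s) dropped after exclusions")
        df = _restrict_to_sets(df, good_sets).reset_index(drop=True)
        df["log_tc"] = np.log(df["tc_or"].astype(float))
        ctrl = ~df["is_case"].to_numpy()
        log.append(f"  analysis sample: {int(df['is_case'].sum())} cases, {int(ctrl.sum())} controls")

        stage("univariable fits")
        fit_snp = ConditionalLogit.from_dataframe(df, ["log_score"]).fit()
        fit_tc = ConditionalLogit.from_dataframe(df, ["log_tc"]).fit()
        results["snp_score"] = _fit_summary(fit_snp, df.loc[ctrl, "log_score"])
        results["tc_model"] = _fit_summary(fit_tc, df.loc[ctrl, "log_tc"])
        results["snp_score"]["m_concordance"] = matched_concordance(
            df["set_id"], df["is_case"], df["log_score"]
        )
        results["tc_model"]["m_concordance"] = matched_concordance(
            df["set_id"], df["is_case"], df["log_tc"]
        )

        stage("bivariable / combined")
        bi = bivariable_fit(df["log_score"], df["log_tc"], df["set_id"], df["is_case"])
        comb = df["log_score"] + df["log_tc"]
        results["bivariable"] = {
            "two_param": _fit_summary(bi.fit_two),
            "combined": _fit_summary(bi.fit_combined, comb[ctrl]),
            "chi2_two": bi.chi2_two,
            "chi2_combined": bi.chi2_combined,
        }
        results["bivariable"]["combined"]["m_concordance"] = matched_concordance(
            df["set_id"], df["is_case"], comb
        )
        rho, p_rho = spearman_independence(df.loc[ctrl, "log_tc"], df.loc[ctrl, "log_score"])
        results["independence"] = {"spearman_rho": rho, "p": p_rho}

        stage("subgroups")
        results["subgroups"] = {}
        set_level = df.groupby("set_id").agg(
            arm=("arm", "first"), trial=("trial", "first")
        )
        case_er = (
            df[df["is_case"]]
            .assign(er=lambda d: d["er_status"].fillna(""))
            .set_index("set_id")["er"]
        )
        subgroup_defs = {
            "arm": df["arm"],
            "trial": df["trial"],
            "er": df["set_id"].map(case_er),
        }
        for name in config.subgroups:
            labels = subgroup_defs.get(name)
            if labels is None:
                continue
            lab = labels.replace("", np.nan).dropna()
            sub = df.loc[lab.index]
            if sub["set_id"].nunique() < 10 or lab.nunique() != 2:
                log.append(f"  subgroup {name}: skipped (insufficient structure)")
                continue
            try:
                it = interaction_test(
                    sub["log_score"], lab, sub["set_id"], sub["is_case"]
                )
            except ValueError as exc:
                log.append(f"  subgroup {name}: {exc}")
                continue
            per_level = {}
            for level in lab.unique():
                part = sub[lab == level]
                try:
                    fres = ConditionalLogit.from_dataframe(part, ["log_score"]).fit()
                    per_level[str(level)] = _fit_summary(
                        fres, part.loc[~part["is_case"], "log_score"]
                    )
                except ValueError as exc:
                    per_level[str(level)] = {"error": str(exc)}
            results["subgroups"][name] = {
                "p_heterogeneity": it.p_het,
                "beta_interaction": it.beta_interaction,
                "levels": per_level,
            }

        stage("calibration")
        cal = calibration_slope(df["log_score"], df["set_id"], df["is_case"])
        results["calibration"] = {
            "slope": cal.slope,
            "slope_percent": cal.slope_percent,
            "se": cal.se,
            "ci_low": cal.ci_low,
            "ci_high": cal.ci_high,
        }
        try:
            dec = decile_observed_vs_expected(df["score"], df["set_id"], df["is_case"])
            dec.to_csv(outdir / "calibration_deciles.csv", index=False)
            if config.make_plot:
                plot_calibration(dec, cal.slope, outdir / "calibration.png")
        except ValueError as exc:
            log.append(f"  decile diagnostics skipped: {exc}")

        stage("recalibration + reclassification")
        df["snp_recal"] = recalibrate_score(df["score"].to_numpy(), cal.slope)
        n_case = int(df["is_case"].sum())
        n_ctrl = int((~df["is_case"]).sum())
        w_case, w_ctrl = case_control_weights(n_case, n_ctrl, config.target_risk)
        w = np.where(df["is_case"], w_case, w_ctrl)
        # as-if-untreated risks: remove the treatment effect from the classic OR
        or_before = df["tc_or"].to_numpy(dtype=float)
        or_after = or_before * df["snp_recal"].to_numpy()
        risk_before = absolute_risk(or_before, w, config.target_risk)
        risk_after = absolute_risk(or_after, w, config.target_risk)
        tab = reclassification_table(
            risk_before, risk_after, df["is_case"].to_numpy(), w, config.risk_threshold
        )
        tab.to_csv(outdir / "reclassification.csv")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                ror = reclassification_or(tab)
                ror_dict = {
                    "odds_ratio": ror.odds_ratio, "ci_low": ror.ci_low,
                    "ci_high": ror.ci_high, "p": ror.p_value, "corrected": ror.corrected,
                }
            except ValueError as exc:
                ror_dict = {"error": str(exc)}
        results["reclassification"] = {
            "threshold": config.risk_threshold,
            "pct_above_before": proportion_above_threshold(risk_before, w, config.risk_threshold),
            "pct_above_after": proportion_above_threshold(risk_after, w, config.risk_threshold),
            "up_cases": tab.up_cases, "up_controls": tab.up_controls,
            "down_cases": tab.down_cases, "down_controls": tab.down_controls,
            "odds_ratio": ror_dict,
        }
    except Exception as exc:
        log.append(f"FAILED: {exc}")
        (outdir / "run.log").write_text("\n".join(log) + "\n")
        raise RuntimeError(f"pipeline stage {log[-2] if len(log) > 1 else '?'} failed: {exc}") from exc

    results = _round_floats(results)
    (outdir / "results.json").write_text(json.dumps(results, indent=2))
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return results
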