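"""Readers and writers for the package's tabular formats.

Panel CSV columns: ``rsid, chrom, pos, risk_allele, other_allele,
or_per_allele, raf`` with optional ``or_ci_low, or_ci_high`` (converted to
a log-OR standard error as ``(log hi - log lo) / (2 * 1.96)``).  Positions
are 1-based (VCF convention).

Genotype TSV: first column ``sample_id``, remaining columns rsids, cells
0/1/2 or ``NA``.  An optional VCF reader derives risk-allele counts from
GT after matching the risk allele to REF/ALT, flipping when the risk
allele is the REF; strand-ambiguous panel SNPs are rejected in VCF mode.

Subjects TSV: ``sample_id, set_id, status (case|control), trial, arm,
age_entry, tc_or`` (or ``tc_risk10``, converted to an odds ratio against
the population mean risk), ``er_status``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import SnpDefinition, PanelValidationError
from .qc import GenotypeMatrix

__all__ = [
    "read_panel",
    "write_panel",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "read_subjects",
    "write_subjects",
    "write_scores",
]

_Z95 = 1.959963984540054

_PANEL_REQUIRED = ["rsid", "risk_allele", "other_allele", "or_per_allele", "raf"]


def read_panel(path) -> list[SnpDefinition]:
    """Read and validate a panel CSV; errors name the offending line."""
    df = pd.read_csv(path, dtype={"rsid": str, "chrom": str})
    missing = [c for c in _PANEL_REQUIRED if c not in df.columns]
    if missing:
        raise PanelValidationError(f"panel file missing column(s): {', '.join(missing)}")
    has_ci = {"or_ci_low", "or_ci_high"}.issubset(df.columns)
    defs: list[SnpDefinition] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            se = None
            if has_ci and pd.notna(row["or_ci_low"]) and pd.notna(row["or_ci_high"]):
                lo, hi = float(row["or_ci_low"]), float(row["or_ci_high"])
                if not 0 < lo <= hi:
                    raise PanelValidationError(f"{row['rsid']}: invalid CI ({lo}, {hi})")
                se = (np.log(hi) - np.log(lo)) / (2.0 * _Z95)
            defs.append(
                SnpDefinition(
                    rsid=str(row["rsid"]),
                    risk_allele=str(row["risk_allele"]).upper(),
                    other_allele=str(row["other_allele"]).upper(),
                    per_allele_or=float(row["or_per_allele"]),
                    raf=float(row["raf"]),
                    se_log_or=se,
                    chrom=str(row["chrom"]) if "chrom" in df.columns and pd.notna(row.get("chrom")) else None,
                    pos=int(row["pos"]) if "pos" in df.columns and pd.notna(row.get("pos")) else None,
                )
            )
        except (PanelValidationError, ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise PanelValidationError(
            "invalid panel rows:\n  " + "\n  ".join(errors)
        )
    rsids = [d.rsid for d in defs]
    dups = {r for r in rsids if rsids.count(r) > 1}
    if dups:
        raise PanelValidationError(f"duplicate rsid(s): {', '.join(sorted(dups))}")
    return defs


def write_panel(defs, path) -> None:
    rows = []
    for d in defs:
        row = {
            "rsid": d.rsid, "chrom": d.chrom, "pos": d.pos,
            "risk_allele": d.risk_allele, "other_allele": d.other_allele,
            "or_per_allele": d.per_allele_or, "raf": d.raf,
        }
        if d.se_log_or is not None:
            b = np.log(d.per_allele_or)
            row["or_ci_low"] = float(np.exp(b - _Z95 * d.se_log_or))
            row["or_ci_high"] = float(np.exp(b + _Z95 * d.se_log_or))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_genotypes_tsv(path, panel=None) -> GenotypeMatrix:
    """Read a genotype TSV; with a panel, align columns to panel order.

    Unknown rsids are dropped with a warning; panel rsids absent from the
    file become all-missing columns with a warning.
    """
    import warnings

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("genotype file must have a 'sample_id' first column")
    sample_ids = df["sample_id"].tolist()
    geno = df.drop(columns=["sample_id"])
    counts = np.full(geno.shape, np.nan)
    for j, col in enumerate(geno.columns):
        vals = geno[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = numeric.notna() & ~numeric.isin([0, 1, 2])
        text_bad = vals.notna() & numeric.isna() & (vals.astype(str).str.upper() != "NA")
        if bad.any() or text_bad.any():
            i = int(np.flatnonzero(bad | text_bad)[0])
            raise ValueError(
                f"invalid genotype {vals.iloc[i]!r} at sample {sample_ids[i]}, SNP {col}"
            )
        counts[:, j] = numeric.to_numpy(dtype=float)
    matrix = GenotypeMatrix(sample_ids, list(geno.columns), counts)
    if panel is None:
        return matrix
    want = panel.rsids if hasattr(panel, "rsids") else [d.rsid for d in panel]
    have = set(matrix.rsids)
    extra = [r for r in matrix.rsids if r not in set(want)]
    if extra:
        warnings.warn(f"{len(extra)} unknown rsid column(s) dropped: {', '.join(extra[:5])}...", stacklevel=2)
    absent = [r for r in want if r not in have]
    if absent:
        warnings.warn(
            f"{len(absent)} panel SNP(s) absent from genotype file, set all-missing: "
            f"{', '.join(absent[:5])}", stacklevel=2,
        )
    aligned = np.full((len(sample_ids), len(want)), np.nan)
    col_of = {r: j for j, r in enumerate(matrix.rsids)}
    for j, r in enumerate(want):
        if r in col_of:
            aligned[:, j] = matrix.counts[:, col_of[r]]
    return GenotypeMatrix(sample_ids, list(want), aligned)


def write_genotypes_tsv(matrix: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(matrix.counts, columns=matrix.rsids)
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.insert(0, "sample_id", matrix.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_vcf(path, panel) -> GenotypeMatrix:
    """Risk-allele dosages from a VCF, matched to the panel by rsid.

    The risk allele must equal REF or ALT; when it is the REF the dosage
    is flipped (2 - alt count).  Strand-ambiguous panel SNPs are rejected
    in VCF mode since flips cannot be distinguished from strand swaps.
    SNPs not found, or whose alleles match neither way, become all-missing
    with a warning.  Missing genotype calls (./.) become NaN.
    """
    import warnings

    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF ingestion requires the optional cyvcf2 dependency") from exc

    defs = panel.snps if hasattr(panel, "snps") else list(panel)
    ambiguous = [d.rsid for d in defs if d.is_strand_ambiguous]
    if ambiguous:
        raise ValueError(
            f"strand-ambiguous SNP(s) not allowed in VCF mode: {', '.join(ambiguous)}"
        )
    by_rsid = {d.rsid: d for d in defs}
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    counts = np.full((len(samples), len(defs)), np.nan)
    order = {d.rsid: j for j, d in enumerate(defs)}
    seen = set()
    for rec in vcf:
        rid = rec.ID
        if rid not in by_rsid:
            continue
        d = by_rsid[rid]
        j = order[rid]
        seen.add(rid)
        alt = rec.ALT[0] if rec.ALT else None
        # gts012: gt_types is the alt-allele count 0/1/2, 3 = missing call
        alt_count = np.asarray(rec.gt_types, dtype=float)
        alt_count[alt_count == 3] = np.nan
        if d.risk_allele == alt:
            counts[:, j] = alt_count
        elif d.risk_allele == rec.REF and alt == d.other_allele:
            counts[:, j] = 2.0 - alt_count
        else:
            warnings.warn(
                f"{rid}: risk allele {d.risk_allele} matches neither REF nor ALT; set missing",
                stacklevel=2,
            )
            counts[:, j] = np.nan
    unseen = [d.rsid for d in defs if d.rsid not in seen]
    if unseen:
        warnings.warn(
            f"{len(unseen)} panel SNP(s) not in VCF, set all-missing: {', '.join(unseen[:5])}",
            stacklevel=2,
        )
    return GenotypeMatrix(samples, [d.rsid for d in defs], counts)


def read_subjects(path, population_risk: float = 0.06) -> pd.DataFrame:
    """Read the subjects table; derives ``is_case`` and fills ``tc_or``.

    Accepts either a ``tc_or`` column or a ``tc_risk10`` 10-year risk,
    converted to an odds ratio against the population odds of
    ``population_risk``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "set_id": str})
    required = {"sample_id", "set_id", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subjects file missing column(s): {', '.join(sorted(missing))}")
    status = df["status"].str.lower()
    if not status.isin(["case", "control"]).all():
        bad = df.loc[~status.isin(["case", "control"]), "status"].iloc[0]
        raise ValueError(f"status must be case|control, found {bad!r}")
    df["is_case"] = status == "case"
    if "tc_or" not in df.columns:
        if "tc_risk10" in df.columns:
            r = df["tc_risk10"].astype(float)
            if ((r <= 0) | (r >= 1)).any():
                raise ValueError("tc_risk10 must lie strictly in (0, 1)")
            pop_odds = population_risk / (1.0 - population_risk)
            df["tc_or"] = (r / (1.0 - r)) / pop_odds
        else:
            raise ValueError("subjects file needs a tc_or or tc_risk10 column")
    return df


def write_subjects(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "status" not in out.columns and "is_case" in out.columns:
        out["status"] = np.where(out["is_case"], "case", "control")
    cols = [c for c in ("sample_id", "set_id", "status", "trial", "arm",
                        "age_entry", "tc_or", "er_status") if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def write_scores(scores: pd.DataFrame, path) -> None:
    scores[["sample_id", "score", "log_score", "n_missing"]].to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
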